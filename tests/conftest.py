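import math

import numpy as np
import pytest

from puckmet.fes import FESGrid, GridAxis, HillsSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def puckering_axes():
    return (
        GridAxis("phi", 0.0, 2.0 * math.pi, 48, periodic=True),
        GridAxis("theta", 0.0, math.pi, 24, periodic=False),
    )


def random_hills(rng, n, axes, gamma=15.0):
    """Random well-tempered hills inside the given 2D domain."""
    centers = np.column_stack(
        [rng.uniform(ax.minimum, ax.maximum, n) for ax in axes]
    )
    sigmas = rng.uniform(0.05, 0.4, (n, 2))
    heights = rng.uniform(0.0, 1.0, n)
    return HillsSeries(
        time=np.arange(n, dtype=float),
        centers=centers,
        sigmas=sigmas,
        heights=heights,
        bias_factors=np.full(n, gamma),
        cv_names=(axes[0].name, axes[1].name),
        periodic={axes[0].name: (axes[0].minimum, axes[0].maximum)} if axes[0].periodic else {},
    )


def brute_force_bias(hills, axes):
    """Independent double-loop Gaussian summation over grid nodes and hills."""
    xs, ys = axes[0].nodes, axes[1].nodes
    V = np.zeros((len(xs), len(ys)))
    for i, x in enumerate(xs):
        for j, y in enumerate(ys):
            total = 0.0
            for k in range(len(hills)):
                dx = x - hills.centers[k, 0]
                if axes[0].periodic:
                    span = axes[0].span
                    dx -= span * round(dx / span)
                dy = y - hills.centers[k, 1]
                if axes[1].periodic:
                    span = axes[1].span
                    dy -= span * round(dy / span)
                total += hills.heights[k] * math.exp(
                    -(dx**2) / (2 * hills.sigmas[k, 0] ** 2)
                    - (dy**2) / (2 * hills.sigmas[k, 1] ** 2)
                )
            V[i, j] = total
    return V


def grid_from_function(axes, fn) -> FESGrid:
    X, Y = np.meshgrid(axes[0].nodes, axes[1].nodes, indexing="ij")
    U = fn(X, Y)
    return FESGrid(axes, U - U.min())
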