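"""Well-tempered metadynamics free-energy surfaces from deposited hills.

Reads/writes the PLUMED HILLS text dialect, reconstructs the 2D
free-energy surface as the rescaled negative of the accumulated Gaussian
bias, and aggregates region free energies for the reactive/nonreactive
partition statistic dG_r/nr.

Two height dialects are supported.  Metadynamics engines commonly store
the *tempered* (already damped) hill heights; the free energy is then
F(s) = -gamma/(gamma-1) * V(s).  If the heights were pre-scaled on
output, F(s) = -V(s) directly.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .ring import PartitionSpec

#: kT at 300 K in kcal/mol
KT_300K = 0.596

_PI_TOKENS = {"pi": math.pi, "-pi": -math.pi, "2pi": 2 * math.pi, "-2pi": -2 * math.pi}


def _parse_number(tok: str) -> float:
    key = tok.strip().lower()
    return _PI_TOKENS[key] if key in _PI_TOKENS else float(tok)


@dataclass
class HillsSeries:
    """Deposited Gaussian bias terms from a well-tempered run."""

    time: np.ndarray            # (n,)
    centers: np.ndarray         # (n, d)
    sigmas: np.ndarray          # (n, d)
    heights: np.ndarray         # (n,), kcal/mol
    bias_factors: np.ndarray    # (n,), dimensionless gamma
    cv_names: tuple[str, ...] = ("cv1", "cv2")
    periodic: dict = field(default_factory=dict)  # cv name -> (min, max)

    def __post_init__(self):
        self.time = np.atleast_1d(np.asarray(self.time, dtype=float))
        n = len(self.time)
        d = len(self.cv_names)
        self.centers = np.asarray(self.centers, dtype=float).reshape(n, -1) if n else \
            np.asarray(self.centers, dtype=float).reshape(0, d)
        self.sigmas = np.asarray(self.sigmas, dtype=float).reshape(n, -1) if n else \
            np.asarray(self.sigmas, dtype=float).reshape(0, d)
        self.heights = np.atleast_1d(np.asarray(self.heights, dtype=float))
        self.bias_factors = np.atleast_1d(np.asarray(self.bias_factors, dtype=float))
        n, d = self.centers.shape
        if self.sigmas.shape != (n, d) or len(self.heights) != n or len(self.bias_factors) != n:
            raise ValueError("inconsistent hills record shapes")
        if len(self.cv_names) != d:
            raise ValueError("cv_names must match CV dimensionality")
        if n and np.any(self.sigmas <= 0):
            raise ValueError("hill widths must be positive")
        if n and np.any(self.heights < 0):
            raise ValueError("hill heights must be non-negative")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def n_cvs(self) -> int:
        return self.centers.shape[1]


def read_hills(source) -> HillsSeries:
    """Parse a PLUMED-style HILLS text stream or path.

    The ``#! FIELDS`` header names the columns; ``#! SET min_<cv>`` /
    ``max_<cv>`` lines carry periodic-domain metadata (``pi`` tokens are
    understood).  Mandatory columns: time, one center and one ``sigma_``
    per CV, and ``height``; ``biasf`` defaults to infinity (non-tempered)
    when absent.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_hills(fh)
    fields: list[str] | None = None
    meta: dict[str, float] = {}
    rows: list[list[float]] = []
    for raw in source:
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#!"):
            parts = line[2:].split()
            if parts and parts[0] == "FIELDS":
                fields = parts[1:]
            elif parts and parts[0] == "SET" and len(parts) >= 3:
                try:
                    meta[parts[1]] = _parse_number(parts[2])
                except (TypeError, ValueError):
                    pass
            continue
        if line.startswith("#"):
            continue
        rows.append([float(t) for t in line.split()])
    if fields is None:
        raise ValueError("HILLS stream lacks a '#! FIELDS' header")
    sigma_cols = [f for f in fields if f.startswith("sigma_")]
    cv_names = tuple(f[len("sigma_"):] for f in sigma_cols)
    if "time" not in fields or not sigma_cols or "height" not in fields:
        raise ValueError("HILLS header must declare time, sigma_<cv> and height columns")
    for cv in cv_names:
        if cv not in fields:
            raise ValueError(f"HILLS header declares sigma_{cv} but no center column {cv}")
    idx = {f: i for i, f in enumerate(fields)}
    data = np.asarray(rows, dtype=float).reshape(len(rows), len(fields))
    time = data[:, idx["time"]] if len(rows) else np.empty(0)
    centers = data[:, [idx[c] for c in cv_names]] if len(rows) else np.empty((0, len(cv_names)))
    sigmas = data[:, [idx[c] for c in sigma_cols]] if len(rows) else np.empty((0, len(cv_names)))
    heights = data[:, idx["height"]] if len(rows) else np.empty(0)
    if "biasf" in idx and len(rows):
        biasf = data[:, idx["biasf"]]
    else:
        biasf = np.full(len(rows), math.inf)
    periodic = {}
    for cv in cv_names:
        if f"min_{cv}" in meta and f"max_{cv}" in meta:
            periodic[cv] = (meta[f"min_{cv}"], meta[f"max_{cv}"])
    if len(time) > 1 and np.any(np.diff(time) < 0):
        import warnings

        warnings.warn("HILLS times are not non-decreasing", stacklevel=2)
    return HillsSeries(time, centers, sigmas, heights, biasf, cv_names, periodic)


def write_hills(hills: HillsSeries, dest) -> None:
    """Write a HILLS series in the PLUMED text dialect (full precision)."""
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            write_hills(hills, fh)
            return
    names = list(hills.cv_names)
    cols = ["time", *names, *[f"sigma_{c}" for c in names], "height", "biasf"]
    dest.write("#! FIELDS " + " ".join(cols) + "\n")
    for cv, (lo, hi) in hills.periodic.items():
        dest.write(f"#! SET min_{cv} {lo!r}\n#! SET max_{cv} {hi!r}\n")
    for k in range(len(hills)):
        row = [hills.time[k], *hills.centers[k], *hills.sigmas[k], hills.heights[k], hills.bias_factors[k]]
        dest.write(" ".join(format(v, ".17g") for v in row) + "\n")


@dataclass(frozen=True)
class GridAxis:
    """One CV axis of a regular 2D grid."""

    name: str
    minimum: float
    maximum: float
    n_bins: int
    periodic: bool = False

    def __post_init__(self):
        if self.maximum <= self.minimum:
            raise ValueError("axis maximum must exceed minimum")
        if self.n_bins < 2:
            raise ValueError("axis needs at least two bins")

    @property
    def span(self) -> float:
        return self.maximum - self.minimum

    @property
    def nodes(self) -> np.ndarray:
        if self.periodic:
            # one period, endpoint excluded (it aliases the first node)
            return self.minimum + self.span * np.arange(self.n_bins) / self.n_bins
        return np.linspace(self.minimum, self.maximum, self.n_bins)

    @property
    def spacing(self) -> float:
        return self.span / self.n_bins if self.periodic else self.span / (self.n_bins - 1)


@dataclass
class FESGrid:
    """Free energy (kcal/mol) on a regular 2D grid, global minimum at zero."""

    axes: tuple[GridAxis, GridAxis]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        shape = (self.axes[0].n_bins, self.axes[1].n_bins)
        if self.values.shape != shape:
            raise ValueError(f"values shape {self.values.shape} does not match axes {shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("free energy values must be finite")

    @property
    def node_area(self) -> float:
        return self.axes[0].spacing * self.axes[1].spacing

    def meshgrid(self):
        return np.meshgrid(self.axes[0].nodes, self.axes[1].nodes, indexing="ij")

    def shifted(self) -> "FESGrid":
        return FESGrid(self.axes, self.values - self.values.min())


def write_fes(fes: FESGrid, dest) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            write_fes(fes, fh)
            return
    a0, a1 = fes.axes
    dest.write(f"#! FIELDS {a0.name} {a1.name} free_energy\n")
    for ax in (a0, a1):
        dest.write(
            f"#! SET min_{ax.name} {ax.minimum!r}\n#! SET max_{ax.name} {ax.maximum!r}\n"
            f"#! SET nbins_{ax.name} {ax.n_bins}\n#! SET periodic_{ax.name} {str(ax.periodic).lower()}\n"
        )
    x, y = fes.meshgrid()
    for i in range(a0.n_bins):
        for j in range(a1.n_bins):
            dest.write(f"{x[i, j]:.17g} {y[i, j]:.17g} {fes.values[i, j]:.17g}\n")


def read_fes(source) -> FESGrid:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_fes(fh)
    text = source.read() if hasattr(source, "read") else str(source)
    fields, meta, rows = None, {}, []
    for line in io.StringIO(text):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#!"):
            parts = line[2:].split()
            if parts[0] == "FIELDS":
                fields = parts[1:]
            elif parts[0] == "SET":
                meta[parts[1]] = parts[2]
            continue
        rows.append([float(t) for t in line.split()])
    if fields is None or len(fields) != 3:
        raise ValueError("FES file must declare two CV columns and free_energy")
    axes = []
    for name in fields[:2]:
        axes.append(
            GridAxis(
                name=name,
                minimum=_parse_number(meta[f"min_{name}"]),
                maximum=_parse_number(meta[f"max_{name}"]),
                n_bins=int(meta[f"nbins_{name}"]),
                periodic=meta.get(f"periodic_{name}", "false").lower() == "true",
            )
        )
    values = np.asarray([r[2] for r in rows]).reshape(axes[0].n_bins, axes[1].n_bins)
    return FESGrid((axes[0], axes[1]), values)


def _axis_delta(points: np.ndarray, centers: np.ndarray, axis: GridAxis) -> np.ndarray:
    """Pairwise CV differences, minimum-image on periodic axes."""
    d = points[:, None] - centers[None, :]
    if axis.periodic:
        d = d - axis.span * np.round(d / axis.span)
    return d


def accumulate_bias(hills: HillsSeries, axes: tuple[GridAxis, GridAxis]) -> np.ndarray:
    """Total deposited bias V(s) on the grid nodes (kcal/mol)."""
    if hills.n_cvs and hills.n_cvs != 2:
        raise ValueError("expected two collective variables")
    n0, n1 = axes[0].n_bins, axes[1].n_bins
    V = np.zeros((n0, n1))
    if len(hills) == 0:
        return V
    d0 = _axis_delta(axes[0].nodes, hills.centers[:, 0], axes[0])  # (n0, k)
    d1 = _axis_delta(axes[1].nodes, hills.centers[:, 1], axes[1])  # (n1, k)
    e0 = np.exp(-0.5 * (d0 / hills.sigmas[None, :, 0]) ** 2)
    e1 = np.exp(-0.5 * (d1 / hills.sigmas[None, :, 1]) ** 2)
    # V[i, j] = sum_k w_k e0[i, k] e1[j, k]
    V = (e0 * hills.heights[None, :]) @ e1.T
    return V


def reconstruct_fes(
    hills: HillsSeries,
    axes: tuple[GridAxis, GridAxis],
    dialect: str = "tempered",
) -> FESGrid:
    """Free-energy surface from deposited hills, min-shifted to zero.

    ``dialect='tempered'`` treats stored heights as the damped (deposited)
    heights and rescales by gamma/(gamma-1); ``'scaled'`` takes the bias
    at face value (F = -V).
    """
    if dialect not in ("tempered", "scaled"):
        raise ValueError("dialect must be 'tempered' or 'scaled'")
    V = accumulate_bias(hills, axes)
    if dialect == "tempered" and len(hills):
        gamma = float(hills.bias_factors[0])
        if not math.isinf(gamma):
            if gamma <= 1:
                raise ValueError("well-tempered bias factor must exceed 1")
            V = V * (gamma / (gamma - 1.0))
    F = -V
    return FESGrid(axes, F - F.min())


def reconstruct_fes_averaged(
    hills: HillsSeries,
    axes: tuple[GridAxis, GridAxis],
    dialect: str = "tempered",
    n_checkpoints: int = 8,
    tail_fraction: float = 0.5,
) -> FESGrid:
    """Time-averaged free-energy estimate over the tail of a tempered run.

    The instantaneous estimate F_k = -c(gamma) V_k fluctuates around the
    true surface once the bias is in the tempered regime; averaging the
    min-shifted estimates at ``n_checkpoints`` evenly spaced hill counts
    across the last ``tail_fraction`` of the deposition history damps
    those fluctuations.  Equivalent to ``reconstruct_fes`` when the
    series is empty or has a single checkpoint.
    """
    if not 0 < tail_fraction <= 1:
        raise ValueError("tail_fraction must be in (0, 1]")
    if n_checkpoints < 1:
        raise ValueError("need at least one checkpoint")
    n = len(hills)
    if n == 0 or n_checkpoints == 1:
        return reconstruct_fes(hills, axes, dialect)
    ks = np.unique(np.linspace(max(1, int(n * (1 - tail_fraction))), n, n_checkpoints, dtype=int))
    gamma = float(hills.bias_factors[0])
    if dialect == "tempered" and not math.isinf(gamma):
        if gamma <= 1:
            raise ValueError("well-tempered bias factor must exceed 1")
        c = gamma / (gamma - 1.0)
    else:
        c = 1.0
    acc = np.zeros((axes[0].n_bins, axes[1].n_bins))
    V = np.zeros_like(acc)
    prev = 0
    for k in ks:
        sub = HillsSeries(
            hills.time[prev:k], hills.centers[prev:k], hills.sigmas[prev:k],
            hills.heights[prev:k], hills.bias_factors[prev:k], hills.cv_names,
            hills.periodic,
        )
        V = V + accumulate_bias(sub, axes)
        F = -c * V
        acc += F - F.min()
        prev = k
    acc /= len(ks)
    return FESGrid(axes, acc - acc.min())


def region_free_energy(fes: FESGrid, mask: np.ndarray, kT: float = KT_300K) -> float:
    """Boltzmann-aggregated free energy of a grid region.

    -kT ln( sum_{nodes in mask} exp(-F/kT) dA ), with dA the uniform node
    area element of the grid.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != fes.values.shape:
        raise ValueError("mask shape must match the grid")
    if not mask.any():
        raise ValueError("region mask is empty")
    if kT <= 0:
        raise ValueError("kT must be positive")
    return float(-kT * (logsumexp(-fes.values[mask] / kT) + math.log(fes.node_area)))


def partition_masks(
    fes: FESGrid, spec: PartitionSpec | None = None, angles_in: str = "radians"
) -> tuple[np.ndarray, np.ndarray]:
    """(reactive, nonreactive) node masks of a puckering (phi, theta) grid."""
    spec = spec or PartitionSpec()
    phi, theta = fes.meshgrid()
    if angles_in == "radians":
        phi, theta = np.degrees(phi), np.degrees(theta)
    elif angles_in != "degrees":
        raise ValueError("angles_in must be 'radians' or 'degrees'")
    tb = spec.theta_boundary(phi)
    on_boundary = np.isclose(theta, tb, atol=1e-9)
    north = theta < tb
    if spec.inclusive_side == "reactive":
        reactive = north | on_boundary
    else:
        reactive = north & ~on_boundary
    return reactive, ~reactive


def delta_g_rnr(
    fes: FESGrid,
    spec: PartitionSpec | None = None,
    kT: float = KT_300K,
    mode: str = "boltzmann",
    angles_in: str = "radians",
) -> float:
    """Reactive-vs-nonreactive partition statistic dG_r/nr (kcal/mol).

    Negative values mean the reactive (northern, toward 4C1) puckering
    region is favored.  ``mode='boltzmann'`` aggregates each region at
    temperature kT; ``mode='minimum'`` compares the two region minima.
    """
    reactive, nonreactive = partition_masks(fes, spec, angles_in)
    if not reactive.any() or not nonreactive.any():
        raise ValueError("both partition regions must contain at least one grid node")
    if mode == "boltzmann":
        return region_free_energy(fes, reactive, kT) - region_free_energy(fes, nonreactive, kT)
    if mode == "minimum":
        return float(fes.values[reactive].min() - fes.values[nonreactive].min())
    raise ValueError("mode must be 'boltzmann' or 'minimum'")


def convergence_report(hills: HillsSeries, axes: tuple[GridAxis, GridAxis],
                       dialect: str = "tempered", stop_threshold: float = 14.0) -> dict:
    """Bookkeeping: hill count and whether the FES range passed the stop rule."""
    fes = reconstruct_fes(hills, axes, dialect)
    fes_range = float(fes.values.max())
    return {
        "n_hills": len(hills),
        "fes_range_kcal_mol": fes_range,
        "stop_threshold_kcal_mol": stop_threshold,
        "reached_stop_threshold": bool(fes_range >= stop_threshold),
    }
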