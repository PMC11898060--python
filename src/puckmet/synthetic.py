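"""Synthetic inputs with known ground truth for every pipeline stage.

* analytic 2D potentials on the puckering-like domain
  (periodic phi in [0, 2pi) x bounded theta in [0, pi]),
* an overdamped-Langevin well-tempered metadynamics sampler in CV space
  emitting PLUMED-style hills,
* six-ring geometries at prescribed Cremer-Pople coordinates,
* toy ligand-in-pocket complexes and catalytic-atom arrangements with
  closed-form observables.

The sampler is deliberately minimal dynamics in collective-variable
space: enough to exercise the bias-deposition and reconstruction
machinery with a known answer, not a model of any molecular system.
Defaults mirror a well-tempered puckering run: hill height 0.75
kcal/mol, widths 0.1 rad, bias factor 15, deposition every 75 steps,
stop once the implied free-energy range reaches 14 kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fes import GridAxis, HillsSeries
from .ring import PuckerCoords, RingGeometry, invert_cremer_pople
from .sasa import AtomSet, fibonacci_sphere

#: kT at 300 K, kcal/mol
KT_300K = 0.596

DOMAIN_X = (0.0, 2.0 * math.pi)   # periodic ("phi")
DOMAIN_Y = (0.0, math.pi)         # bounded, reflective ("theta")


@dataclass
class GaussianPotential2D:
    """Sum of 2D Gaussians (negative amplitude = well) on the CV domain.

    Analytic minima metadata (well centers) makes parameter-recovery
    tests self-contained.
    """

    centers: np.ndarray        # (k, 2)
    widths: np.ndarray         # (k, 2) per-term sigma
    amplitudes: np.ndarray     # (k,) kcal/mol, negative for wells
    periodic_x: bool = True

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)
        self.widths = np.asarray(self.widths, dtype=float).reshape(-1, 2)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float).ravel()
        if np.any(self.widths <= 0):
            raise ValueError("potential widths must be positive")

    def _delta(self, s: np.ndarray) -> np.ndarray:
        d = s[..., None, :] - self.centers  # (..., k, 2)
        if self.periodic_x:
            span = DOMAIN_X[1] - DOMAIN_X[0]
            d[..., 0] = d[..., 0] - span * np.round(d[..., 0] / span)
        return d

    def energy(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        d = self._delta(s)
        g = np.exp(-0.5 * ((d / self.widths) ** 2).sum(axis=-1))
        return g @ self.amplitudes

    def gradient(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        d = self._delta(s)
        g = np.exp(-0.5 * ((d / self.widths) ** 2).sum(axis=-1))
        w = self.amplitudes * g  # (..., k)
        return -(w[..., None] * d / self.widths**2).sum(axis=-2)

    @property
    def minima(self) -> np.ndarray:
        """Centers of the wells (negative-amplitude terms)."""
        return self.centers[self.amplitudes < 0]


@dataclass
class HarmonicPotential2D:
    """Isotropic harmonic well, for closed-form equipartition checks."""

    center: np.ndarray = field(default_factory=lambda: np.array([math.pi, math.pi / 2]))
    k: float = 5.0  # kcal/mol per rad^2
    periodic_x: bool = False

    def energy(self, s) -> np.ndarray:
        d = np.asarray(s, dtype=float) - self.center
        return 0.5 * self.k * (d**2).sum(axis=-1)

    def gradient(self, s) -> np.ndarray:
        return self.k * (np.asarray(s, dtype=float) - self.center)


#: well depth making the lowest pass sit 5.0 kcal/mol above the bottoms
#: for two equal Gaussian wells (sigma 0.55 rad) 1.997 rad apart:
#: barrier(D) = D (1 + e^{-d^2/(2 s^2)}) - 2 D e^{-d^2/(8 s^2)}
_DOUBLE_WELL_DEPTH = 5.0 / (
    1.0
    + math.exp(-(1.997**2) / (2 * 0.55**2))
    - 2.0 * math.exp(-(1.997**2) / (8 * 0.55**2))
)


def double_well_potential(asymmetry: float = 0.0) -> GaussianPotential2D:
    """The standard two-basin fixture on the puckering-like domain.

    Two Gaussian wells of width 0.55 rad: a northern one at an E5-like
    location (phi = 300 deg, theta = 54.7 deg) and a southern one at a
    1S3-like location (phi = 210 deg, theta = 125.3 deg), 1.997 rad
    apart.  With equal depths (8.087 kcal/mol) the lowest pass between
    them lies 5.0 kcal/mol above the well bottoms (closed form for two
    equal Gaussians; a detour through the flat far field would cost the
    full well depth and is never optimal).  ``asymmetry`` (kcal/mol) is
    added to the southern well depth: negative values favor the northern
    (reactive, E5-like) basin as in the wild-type enzyme, positive
    values favor the southern (nonreactive, 1S3-like) basin as in the
    dormant D74E variant.
    """
    c_north = np.array([math.radians(300.0), math.atan(math.sqrt(2.0))])
    c_south = np.array([math.radians(210.0), math.pi - math.atan(math.sqrt(2.0))])
    depth = _DOUBLE_WELL_DEPTH
    return GaussianPotential2D(
        centers=[c_north, c_south],
        widths=[[0.55, 0.55], [0.55, 0.55]],
        amplitudes=[-depth, -depth - asymmetry],
    )


@dataclass
class SamplerParams:
    """Well-tempered metadynamics sampler settings."""

    kT: float = KT_300K
    friction: float = 1.0
    dt: float = 0.002
    n_steps: int = 200_000
    pace: int = 75
    hill_height: float = 0.75     # kcal/mol, initial (undamped) height
    hill_widths: tuple[float, float] = (0.1, 0.1)  # rad
    bias_factor: float = 15.0
    seed: int = 0
    stop_threshold: float = 14.0  # kcal/mol, implied-FES-range stop rule
    start: tuple[float, float] | None = None

    def __post_init__(self):
        if self.kT <= 0:
            raise ValueError("kT must be positive")
        if self.bias_factor <= 1:
            raise ValueError("well-tempered bias factor must exceed 1")
        for name in ("friction", "dt", "pace", "hill_height", "stop_threshold"):
            if getattr(self, name) < 0 or (name != "hill_height" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")


class _GridField:
    """Potential + accumulated bias tabulated on an internal fine grid.

    The sampler reads forces by bilinear interpolation; each deposited
    hill is added to the value and gradient tables once (vectorized), so
    the per-step cost does not grow with the hill count.
    """

    def __init__(self, potential, widths, nx: int = 256, ny: int = 128):
        self.nx, self.ny = nx, ny
        self.span_x = DOMAIN_X[1] - DOMAIN_X[0]
        self.hx = self.span_x / nx                      # periodic x
        self.hy = (DOMAIN_Y[1] - DOMAIN_Y[0]) / (ny - 1)  # bounded y
        self.xs = DOMAIN_X[0] + self.hx * np.arange(nx)
        self.ys = np.linspace(*DOMAIN_Y, ny)
        X, Y = np.meshgrid(self.xs, self.ys, indexing="ij")
        pts = np.stack([X, Y], axis=-1)
        grad = potential.gradient(pts)
        self.V = np.zeros((nx, ny))                     # bias only
        self.gx = grad[..., 0].copy()                   # grad of U + bias
        self.gy = grad[..., 1].copy()
        self.widths = np.asarray(widths, dtype=float)
        self._X, self._Y = X, Y

    def add_hill(self, center, height) -> None:
        dx = self._X - center[0]
        dx -= self.span_x * np.round(dx / self.span_x)
        dy = self._Y - center[1]
        g = height * np.exp(-0.5 * ((dx / self.widths[0]) ** 2 + (dy / self.widths[1]) ** 2))
        self.V += g
        # dV/dx = -g dx / sigma_x^2
        self.gx += -g * dx / self.widths[0] ** 2
        self.gy += -g * dy / self.widths[1] ** 2

    def _locate(self, x: float, y: float):
        fx = (x - DOMAIN_X[0]) / self.hx
        i0 = int(fx) % self.nx
        tx = fx - int(fx)
        i1 = (i0 + 1) % self.nx
        fy = (y - DOMAIN_Y[0]) / self.hy
        j0 = int(fy)
        if j0 >= self.ny - 1:
            j0 = self.ny - 2
        ty = fy - j0
        return i0, i1, tx, j0, j0 + 1, ty

    def bias_value(self, x: float, y: float) -> float:
        i0, i1, tx, j0, j1, ty = self._locate(x, y)
        V = self.V
        return float(
            (1 - tx) * ((1 - ty) * V[i0, j0] + ty * V[i0, j1])
            + tx * ((1 - ty) * V[i1, j0] + ty * V[i1, j1])
        )

    def grad(self, x: float, y: float) -> tuple[float, float]:
        i0, i1, tx, j0, j1, ty = self._locate(x, y)
        gx, gy = self.gx, self.gy
        g0 = (
            (1 - tx) * ((1 - ty) * gx[i0, j0] + ty * gx[i0, j1])
            + tx * ((1 - ty) * gx[i1, j0] + ty * gx[i1, j1])
        )
        g1 = (
            (1 - tx) * ((1 - ty) * gy[i0, j0] + ty * gy[i0, j1])
            + tx * ((1 - ty) * gy[i1, j0] + ty * gy[i1, j1])
        )
        return float(g0), float(g1)


def sample_wt_metad(potential, params: SamplerParams) -> tuple[np.ndarray, HillsSeries]:
    """Overdamped Langevin sampling with well-tempered hill deposition.

    Update: s <- s - (dt/friction) grad(U + V_bias) + sqrt(2 kT dt/friction) xi,
    with periodic wrap on x and reflective walls on y.  Every ``pace``
    steps a Gaussian of height w0 exp(-V_bias(s) / ((gamma-1) kT)) is
    deposited at the current point.  Potential and bias forces are read
    from an internal fine interpolation grid so the step cost stays flat
    as hills accumulate.  The run terminates at the step cap or once the
    implied free-energy range gamma/(gamma-1) * (max - min of the
    accumulated bias over the domain) reaches ``stop_threshold``.
    Identical seeds give identical output.
    """
    rng = np.random.default_rng(params.seed)
    span_x = DOMAIN_X[1] - DOMAIN_X[0]
    gamma = params.bias_factor
    c_gamma = gamma / (gamma - 1.0)
    field_grid = _GridField(potential, params.hill_widths)
    max_hills = params.n_steps // max(params.pace, 1) + 1
    centers = np.empty((max_hills, 2))
    heights = np.empty(max_hills)
    n_hills = 0
    x, y = (params.start if params.start is not None else (math.pi, math.pi / 2.0))
    x, y = float(x), float(y)
    mob = params.dt / params.friction
    noise_scale = math.sqrt(2.0 * params.kT * mob)
    y_lo, y_hi = DOMAIN_Y
    x_lo = DOMAIN_X[0]
    record_every = max(params.pace, 1)
    traj = np.empty((params.n_steps // record_every + 1, 2))
    traj[0] = (x, y)
    n_rec = 1
    times = []
    fes_range = 0.0
    noise = noise_scale * rng.standard_normal((params.n_steps, 2))
    for step in range(1, params.n_steps + 1):
        gx, gy = field_grid.grad(x, y)
        x = x - mob * gx + noise[step - 1, 0]
        y = y - mob * gy + noise[step - 1, 1]
        x = x_lo + (x - x_lo) % span_x
        if y < y_lo:
            y = 2.0 * y_lo - y
        elif y > y_hi:
            y = 2.0 * y_hi - y
        y = min(max(y, y_lo), y_hi)
        if params.pace and step % params.pace == 0:
            if params.hill_height > 0:
                v_here = field_grid.bias_value(x, y)
                h = params.hill_height * math.exp(-v_here / ((gamma - 1.0) * params.kT))
                field_grid.add_hill((x, y), h)
                centers[n_hills] = (x, y)
                heights[n_hills] = h
                n_hills += 1
                times.append(step * params.dt)
                # implied FES range: the total bias grows without bound in a
                # well-tempered run, but its max-min over the domain plateaus
                # at (1 - 1/gamma) * (true FES range)
                if n_hills % 25 == 0:
                    fes_range = c_gamma * float(field_grid.V.max() - field_grid.V.min())
            traj[n_rec] = (x, y)
            n_rec += 1
            if params.hill_height > 0 and fes_range >= params.stop_threshold:
                break
    hills = HillsSeries(
        time=np.asarray(times),
        centers=centers[:n_hills].copy(),
        sigmas=np.tile(np.asarray(params.hill_widths, dtype=float), (n_hills, 1)),
        heights=heights[:n_hills].copy(),
        bias_factors=np.full(n_hills, gamma),
        cv_names=("phi", "theta"),
        periodic={"phi": DOMAIN_X},
    )
    return traj[:n_rec], hills


def default_axes(n_phi: int = 144, n_theta: int = 72) -> tuple[GridAxis, GridAxis]:
    """The default puckering reconstruction grid (phi periodic, theta bounded)."""
    return (
        GridAxis("phi", *DOMAIN_X, n_phi, periodic=True),
        GridAxis("theta", *DOMAIN_Y, n_theta, periodic=False),
    )


def make_ring(
    pucker: PuckerCoords,
    bond_length: float = 1.52,
    noise: float = 0.0,
    seed: int | None = None,
) -> RingGeometry:
    """Six-ring at a prescribed pucker, optionally with coordinate noise."""
    geom = invert_cremer_pople(pucker, bond_length=bond_length)
    if noise > 0:
        rng = np.random.default_rng(seed)
        geom = RingGeometry(geom.positions + rng.normal(scale=noise, size=(6, 3)),
                            labels=geom.labels)
    return geom


def make_toy_complex(
    ligand_radius: float = 1.7,
    shell_radius: float = 6.0,
    n_shell: int = 120,
    opening_half_angle: float = 0.0,
    shell_atom_radius: float = 1.7,
    seed: int | None = None,
    jitter: float = 0.0,
) -> AtomSet:
    """A single-atom ligand inside a (possibly open) spherical pocket shell.

    Shell atoms sit on a Fibonacci lattice of the sphere of
    ``shell_radius``; atoms within ``opening_half_angle`` (radians) of +z
    are removed, leaving a solvent-facing mouth.  ``opening_half_angle=0``
    gives a closed cage, ``n_shell=0`` an isolated ligand.
    """
    pts = fibonacci_sphere(n_shell) if n_shell else np.empty((0, 3))
    if opening_half_angle > 0 and n_shell:
        keep = np.arccos(np.clip(pts[:, 2], -1, 1)) > opening_half_angle
        pts = pts[keep]
    shell = shell_radius * pts
    if jitter > 0 and len(shell):
        rng = np.random.default_rng(seed)
        shell = shell + rng.normal(scale=jitter, size=shell.shape)
    positions = np.vstack([np.zeros((1, 3)), shell])
    radii = np.concatenate([[ligand_radius], np.full(len(shell), shell_atom_radius)])
    groups = np.array(["substrate"] + ["pocket"] * len(shell), dtype=object)
    return AtomSet(positions=positions, radii=radii, groups=groups)


def make_catalytic_frame(d1: float, d2: float, d3: float, d4: float,
                         pair_half_spacing: float = 1.1):
    """Catalytic-atom arrangement with prescribed d1..d4 (closed-form CVs).

    Atoms are laid out along +x: acid carboxylate midpoint at the origin,
    H_a at x=d1, O_g at x=d1+d2, C1' at x=d1+d2+d3, nucleophile midpoint
    at x=d1+d2+d3+d4.  By construction cv1 = d1-d2 and cv2 = d3-d4.
    """
    from .geometry import CatalyticFrame

    if min(d1, d2, d3, d4) <= 0:
        raise ValueError("distances d1..d4 must be positive")
    h = pair_half_spacing
    x_ha = d1
    x_og = d1 + d2
    x_c1 = d1 + d2 + d3
    x_nuc = d1 + d2 + d3 + d4
    coords = {
        "acid_pair": np.array([[0.0, h, 0.0], [0.0, -h, 0.0]]),
        "h_a": np.array([x_ha, 0.0, 0.0]),
        "o_g": np.array([x_og, 0.0, 0.0]),
        "c1p": np.array([x_c1, 0.0, 0.0]),
        "nuc_pair": np.array([[x_nuc, h, 0.0], [x_nuc, -h, 0.0]]),
        "o_n": np.array([x_nuc, h, 0.0]),
        "o_ring": np.array([x_c1, 1.43, 0.0]),
        "o_a": np.array([0.0, h, 0.0]),
    }
    return CatalyticFrame(coords=coords)
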