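"""Cremer-Pople puckering coordinates for six-membered rings.

The forward transform follows the standard construction: atom
displacements z_j perpendicular to the mean plane through the geometric
center, the (q2, phi2) pair from the weighted sine/cosine sums, the
alternating-sign amplitude q3, total amplitude Q = sqrt(q2^2 + q3^2),
polar angle theta = atan2(q2, q3) and azimuth phi = phi2.  With the ring
walked O5, C1 ... C5 the 4C1 chair of an alpha-D-pyranose maps to the
north pole (theta = 0).

Angles are degrees at every public interface; radians are used only
internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .conformers import CANONICAL_CONFORMERS, CONFORMER_ORDER

#: default ring-walk atom names, O5 first
RING_ATOM_ORDER: tuple[str, ...] = ("O5", "C1", "C2", "C3", "C4", "C5")

#: amplitude below which theta/phi are meaningless (coordinate noise floor)
DEGENERACY_TOL = 1e-4

#: acceptable range for consecutive ring-bond lengths, Angstrom
BOND_RANGE = (1.2, 1.8)

_N = 6
_J = np.arange(_N)


class RingGeometryError(ValueError):
    """Raised for rings that violate the six-ring geometry contract."""


@dataclass(frozen=True)
class PuckerCoords:
    """Cremer-Pople state (Q in Angstrom, theta/phi in degrees)."""

    Q: float
    theta: float
    phi: float
    degenerate: bool = False

    def __post_init__(self):
        if self.Q < 0:
            raise ValueError("puckering amplitude Q must be non-negative")
        if not self.degenerate:
            if not 0.0 <= self.theta <= 180.0:
                raise ValueError("theta must lie in [0, 180] degrees")
            object.__setattr__(self, "phi", self.phi % 360.0)


@dataclass
class RingGeometry:
    """Six ordered ring atoms (positions in Angstrom, fixed ring walk)."""

    positions: np.ndarray
    labels: tuple[str, ...] = RING_ATOM_ORDER

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (6, 3):
            raise RingGeometryError(
                f"a six-membered ring needs shape (6, 3), got {self.positions.shape}"
            )
        if len(self.labels) != 6:
            raise RingGeometryError("need exactly six atom labels")
        d = np.linalg.norm(self.positions - np.roll(self.positions, -1, axis=0), axis=1)
        if np.any(d < 1e-6):
            raise RingGeometryError("coincident consecutive ring atoms")

    def bond_lengths(self) -> np.ndarray:
        """Consecutive (ring-walk) bond lengths, wrapping 6 -> 1."""
        return np.linalg.norm(self.positions - np.roll(self.positions, -1, axis=0), axis=1)

    def validate_bonds(self, bond_range: tuple[float, float] = BOND_RANGE) -> None:
        d = self.bond_lengths()
        if np.any(d < bond_range[0]) or np.any(d > bond_range[1]):
            raise RingGeometryError(
                f"ring-walk bond lengths {np.round(d, 3)} outside {bond_range} Angstrom"
            )


@dataclass(frozen=True)
class ConformerLabel:
    """One of the 38 canonical ring conformers with its reference point."""

    label: str
    reference_theta: float
    reference_phi: float


@dataclass
class PartitionSpec:
    """Boundary polyline theta_b(phi) splitting the puckering sphere.

    Points strictly north of the boundary (theta < theta_b) belong to the
    reactive region (toward the 4C1 pole); points strictly south are
    nonreactive (toward 1C4).  ``inclusive_side`` says which region owns
    points exactly on the boundary.  The polyline is periodic in phi and
    interpolated linearly between knots.  The default is the equator.
    """

    phi_knots: np.ndarray = field(default_factory=lambda: np.array([0.0, 360.0]))
    theta_knots: np.ndarray = field(default_factory=lambda: np.array([90.0, 90.0]))
    inclusive_side: str = "nonreactive"

    def __post_init__(self):
        self.phi_knots = np.asarray(self.phi_knots, dtype=float)
        self.theta_knots = np.asarray(self.theta_knots, dtype=float)
        if self.phi_knots.ndim != 1 or self.phi_knots.shape != self.theta_knots.shape:
            raise ValueError("phi_knots and theta_knots must be 1-D and equal length")
        if self.phi_knots.size < 2:
            raise ValueError("boundary polyline needs at least two knots")
        if np.any(np.diff(self.phi_knots) <= 0):
            raise ValueError("phi_knots must be strictly increasing")
        span = self.phi_knots[-1] - self.phi_knots[0]
        if not math.isclose(span, 360.0, abs_tol=1e-9):
            raise ValueError("boundary polyline must close over one full period (360 deg)")
        if not math.isclose(self.theta_knots[0], self.theta_knots[-1], abs_tol=1e-9):
            raise ValueError("boundary polyline must close periodically in theta")
        if self.inclusive_side not in ("reactive", "nonreactive"):
            raise ValueError("inclusive_side must be 'reactive' or 'nonreactive'")

    def theta_boundary(self, phi_deg):
        """Boundary colatitude theta_b at azimuth phi (degrees, periodic)."""
        phi = np.mod(np.asarray(phi_deg, dtype=float) - self.phi_knots[0], 360.0) + self.phi_knots[0]
        return np.interp(phi, self.phi_knots, self.theta_knots)

    def swapped(self) -> "PartitionSpec":
        """Partition with reactive/nonreactive ownership of the boundary swapped."""
        other = "reactive" if self.inclusive_side == "nonreactive" else "nonreactive"
        return PartitionSpec(self.phi_knots.copy(), self.theta_knots.copy(), other)


def _ring_frame(positions: np.ndarray):
    """Center, unit normal and out-of-plane displacements of a six-ring."""
    center = positions.mean(axis=0)
    rel = positions - center
    ang = 2.0 * math.pi * _J / _N
    r_sin = (rel * np.sin(ang)[:, None]).sum(axis=0)
    r_cos = (rel * np.cos(ang)[:, None]).sum(axis=0)
    normal = np.cross(r_sin, r_cos)
    norm = np.linalg.norm(normal)
    if norm < 1e-12:
        raise RingGeometryError("degenerate ring: mean plane undefined")
    normal /= norm
    z = rel @ normal
    return center, normal, z


def cremer_pople(ring: RingGeometry) -> PuckerCoords:
    """Cremer-Pople (Q, theta, phi) of a six-membered ring.

    Returns a degenerate ``PuckerCoords`` (theta/phi meaningless, flagged)
    when the total amplitude falls below ``DEGENERACY_TOL`` (planar ring).
    """
    _, _, z = _ring_frame(ring.positions)
    ang2 = 4.0 * math.pi * _J / _N
    q2cos = math.sqrt(2.0 / _N) * float(z @ np.cos(ang2))
    q2sin = -math.sqrt(2.0 / _N) * float(z @ np.sin(ang2))
    q3 = float(z @ ((-1.0) ** _J)) / math.sqrt(_N)
    q2 = math.hypot(q2cos, q2sin)
    Q = math.hypot(q2, q3)
    if Q < DEGENERACY_TOL:
        return PuckerCoords(Q=Q, theta=0.0, phi=0.0, degenerate=True)
    theta = math.degrees(math.atan2(q2, q3))
    phi = math.degrees(math.atan2(q2sin, q2cos)) % 360.0
    return PuckerCoords(Q=Q, theta=theta, phi=phi)


def ideal_z_displacements(target: PuckerCoords) -> np.ndarray:
    """Out-of-plane displacements z_j realizing (Q, theta, phi) exactly."""
    th = math.radians(target.theta)
    ph = math.radians(target.phi)
    q2 = target.Q * math.sin(th)
    q3 = target.Q * math.cos(th)
    ang2 = 4.0 * math.pi * _J / _N
    return math.sqrt(2.0 / _N) * q2 * np.cos(ph + ang2) + q3 * ((-1.0) ** _J) / math.sqrt(_N)


def invert_cremer_pople(
    target: PuckerCoords,
    bond_length: float = 1.52,
    labels: tuple[str, ...] = RING_ATOM_ORDER,
) -> RingGeometry:
    """Build a six-ring whose forward Cremer-Pople map equals ``target``.

    The in-plane template is a regular hexagon of side ``bond_length``
    oriented so the mean-plane normal of the decorated ring is exactly +z;
    the prescribed displacements are then recovered without iteration.
    Raises ``RingGeometryError`` when the requested amplitude makes any
    ring-walk bond leave the plausible covalent range.
    """
    if target.Q < 0:
        raise RingGeometryError("Q must be non-negative")
    rho = bond_length  # circumradius of a regular hexagon equals its side
    ang = 2.0 * math.pi * _J / _N
    xy = np.column_stack([rho * np.sin(ang), rho * np.cos(ang)])
    z = ideal_z_displacements(target) if target.Q > 0 else np.zeros(_N)
    geom = RingGeometry(np.column_stack([xy, z]), labels=labels)
    try:
        geom.validate_bonds()
    except RingGeometryError as err:
        raise RingGeometryError(
            f"pucker amplitude Q={target.Q} infeasible for bond length {bond_length}: {err}"
        ) from err
    return geom


def _sphere_distance(theta1, phi1, theta2, phi2):
    """Great-circle distance (radians) between (theta, phi) points in degrees."""
    t1, p1, t2, p2 = (math.radians(a) for a in (theta1, phi1, theta2, phi2))
    c = math.sin(t1) * math.sin(t2) * math.cos(p1 - p2) + math.cos(t1) * math.cos(t2)
    return math.acos(min(1.0, max(-1.0, c)))


def classify_conformer(p: PuckerCoords) -> ConformerLabel:
    """Nearest canonical conformer by great-circle distance on the sphere.

    Ties are broken by the fixed table order, making the map deterministic.
    """
    if p.degenerate:
        raise ValueError("cannot classify a degenerate (planar) pucker")
    best, best_d = None, math.inf
    for label in CONFORMER_ORDER:
        t_ref, p_ref = CANONICAL_CONFORMERS[label]
        d = _sphere_distance(p.theta, p.phi, t_ref, p_ref)
        if d < best_d - 1e-12:
            best, best_d = label, d
    t_ref, p_ref = CANONICAL_CONFORMERS[best]
    return ConformerLabel(label=best, reference_theta=t_ref, reference_phi=p_ref)


def is_reactive(p: PuckerCoords, spec: PartitionSpec | None = None) -> bool:
    """Whether a pucker lies in the reactive (northern) region.

    Reactive means strictly north of the boundary polyline; points exactly
    on the boundary belong to ``spec.inclusive_side``.
    """
    if p.degenerate:
        raise ValueError("reactive/nonreactive is undefined for a planar ring")
    spec = spec or PartitionSpec()
    tb = float(spec.theta_boundary(p.phi))
    if math.isclose(p.theta, tb, abs_tol=1e-9):
        return spec.inclusive_side == "reactive"
    return p.theta < tb
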