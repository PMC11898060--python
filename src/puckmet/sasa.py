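"""Solvent-accessible surface area by deterministic sphere-point sampling.

Classic Shrake-Rupley: each atom's solvent-expanded sphere (radius
r + probe) is covered with a quasi-uniform Fibonacci point set; the
accessible area is the fraction of points not buried inside any other
atom's expanded sphere, times 4 pi (r + probe)^2.  The point set is a
fixed golden-angle spiral, so results are bit-stable across runs.

The substrate-positioning index SPI = SASA(substrate) / SASA(pocket),
with both group areas computed in the context of the full structure
(every atom occludes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

#: Bondi-style van der Waals radii, Angstrom
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "ZN": 1.39, "NA": 2.27,
}
DEFAULT_RADIUS = 1.70
#: heavy-atom radius inflation when hydrogens are implicit (united-atom)
UNITED_ATOM_INFLATION = 0.2

DEFAULT_PROBE = 1.4
DEFAULT_POINTS = 960


@dataclass
class AtomSet:
    """Positions, radii and group labels (substrate / pocket / other)."""

    positions: np.ndarray
    radii: np.ndarray
    groups: np.ndarray = None  # str array, optional

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float).ravel()
        n = len(self.positions)
        if len(self.radii) != n:
            raise ValueError("one radius per atom required")
        if np.any(self.radii <= 0):
            raise ValueError("radii must be positive")
        if self.groups is None:
            self.groups = np.array(["other"] * n)
        else:
            self.groups = np.asarray(self.groups, dtype=object)
            if len(self.groups) != n:
                raise ValueError("one group label per atom required")

    def __len__(self) -> int:
        return len(self.positions)

    def mask(self, group: str) -> np.ndarray:
        return self.groups == group


@dataclass
class SasaResult:
    """Per-atom accessible areas plus group sums and the SPI ratio."""

    per_atom: np.ndarray            # A^2
    sasa_sub: float                 # A^2
    sasa_pkt: float                 # A^2
    spi: float | None               # dimensionless; None when pocket area is 0
    probe: float = DEFAULT_PROBE
    n_points: int = DEFAULT_POINTS


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the golden-angle spiral (no RNG)."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = k * math.pi * (3.0 - math.sqrt(5.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley(
    atoms: AtomSet,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_POINTS,
) -> np.ndarray:
    """Per-atom solvent-accessible areas (A^2)."""
    if probe < 0:
        raise ValueError("probe radius must be non-negative")
    if n_points < 1:
        raise ValueError("need at least one sphere point")
    n = len(atoms)
    unit = fibonacci_sphere(n_points)
    expanded = atoms.radii + probe
    areas = np.zeros(n)
    if n == 0:
        return areas
    tree = cKDTree(atoms.positions)
    r_max = expanded.max()
    for i in range(n):
        ri = expanded[i]
        pts = atoms.positions[i] + ri * unit
        # candidate occluders: centers within ri + r_max of atom i
        cand = tree.query_ball_point(atoms.positions[i], ri + r_max)
        cand = [j for j in cand if j != i]
        accessible = np.ones(n_points, dtype=bool)
        if cand:
            cand = np.asarray(cand)
            d2 = ((pts[:, None, :] - atoms.positions[cand][None, :, :]) ** 2).sum(axis=2)
            accessible = ~np.any(d2 < (expanded[cand] ** 2)[None, :] - 1e-12, axis=1)
        areas[i] = accessible.mean() * 4.0 * math.pi * ri * ri
    return areas


def spi(
    atoms: AtomSet,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_POINTS,
    substrate_group: str = "substrate",
    pocket_group: str = "pocket",
) -> SasaResult:
    """Group SASAs and the substrate-positioning index for one structure.

    Per-atom areas are computed with every atom of the structure
    occluding; the substrate and pocket sums are then read off their
    group members.
    """
    sub = atoms.mask(substrate_group)
    pkt = atoms.mask(pocket_group)
    if not sub.any() or not pkt.any():
        raise ValueError("substrate and pocket groups must both be non-empty")
    per_atom = shrake_rupley(atoms, probe=probe, n_points=n_points)
    sasa_sub = float(per_atom[sub].sum())
    sasa_pkt = float(per_atom[pkt].sum())
    ratio = sasa_sub / sasa_pkt if sasa_pkt > 0 else None
    return SasaResult(per_atom=per_atom, sasa_sub=sasa_sub, sasa_pkt=sasa_pkt,
                      spi=ratio, probe=probe, n_points=n_points)


def spi_trajectory(frames: list[AtomSet], probe: float = DEFAULT_PROBE,
                   n_points: int = DEFAULT_POINTS) -> dict:
    """Per-frame SPI plus mean and spread over a list of structures."""
    results = [spi(f, probe=probe, n_points=n_points) for f in frames]
    values = np.array([r.spi for r in results if r.spi is not None])
    return {
        "per_frame": [
            {"sasa_sub": r.sasa_sub, "sasa_pkt": r.sasa_pkt, "spi": r.spi} for r in results
        ],
        "spi_mean": float(values.mean()) if len(values) else None,
        "spi_std": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
    }


def radii_for_elements(elements, table: dict | None = None,
                       united_atom: bool = False) -> np.ndarray:
    """Van der Waals radii for element symbols; unknown elements get carbon's."""
    table = table or VDW_RADII
    r = np.array([table.get(str(e).upper(), DEFAULT_RADIUS) for e in elements])
    if united_atom:
        r = r + UNITED_ATOM_INFLATION
    return r


def atomset_from_pdb(pdb_path, substrate_sel: str, pocket_sel: str,
                     united_atom: bool = False) -> AtomSet:
    """Build a grouped AtomSet from a PDB file via MDAnalysis selections.

    With ``united_atom`` hydrogens are dropped and heavy-atom radii
    inflated; otherwise hydrogens (when present) occlude explicitly.
    """
    import MDAnalysis as mda

    u = mda.Universe(str(pdb_path))
    all_atoms = u.select_atoms("not name H*") if united_atom else u.atoms
    elements = [_element_of(a) for a in all_atoms]
    groups = np.array(["other"] * len(all_atoms), dtype=object)
    sub = u.select_atoms(substrate_sel)
    pkt = u.select_atoms(pocket_sel)
    index_of = {a.ix: i for i, a in enumerate(all_atoms)}
    for a in sub:
        if a.ix in index_of:
            groups[index_of[a.ix]] = "substrate"
    for a in pkt:
        if a.ix in index_of and groups[index_of[a.ix]] == "other":
            groups[index_of[a.ix]] = "pocket"
    return AtomSet(
        positions=all_atoms.positions.astype(float),
        radii=radii_for_elements(elements, united_atom=united_atom),
        groups=groups,
    )


def _element_of(atom) -> str:
    try:
        el = atom.element
        if el:
            return el
    except Exception:
        pass
    name = atom.name.strip()
    return (name[:2].upper() if name[:2].upper() in VDW_RADII and not name[0].isdigit()
            else name.lstrip("0123456789")[0].upper())
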