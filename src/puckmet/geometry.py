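"""Reaction collective variables and catalytic geometry observables.

For a retaining glycosidase active site the two reaction coordinates are
distance differences:

* CV1 = d1 - d2 tracks the proton transfer from the acid/base
  carboxylate (D319 in human lysosomal alpha-mannosidase) to the
  glycosidic oxygen: d1 = |COM(acid carboxylate O pair) - H_a|,
  d2 = |H_a - O_g|.
* CV2 = d3 - d4 tracks glycosidic bond cleavage versus nucleophilic
  attack by D196: d3 = |O_g - C1'|, d4 = |C1' - COM(nucleophile
  carboxylate O pair)|.

The carboxylate COM is the plain midpoint of the two oxygens (equal
masses).  All distances in Angstrom, angles in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

#: roles a catalytic selection must resolve, with required atom counts
SELECTION_ROLES = {
    "acid_pair": 2,   # carboxylate oxygens of the acid/base (D319)
    "h_a": 1,         # transferred proton
    "o_g": 1,         # glycosidic oxygen
    "nuc_pair": 2,    # carboxylate oxygens of the nucleophile (D196)
    "o_n": 1,         # attacking nucleophile oxygen
    "c1p": 1,         # anomeric carbon C1'
    "o_ring": 1,      # ring oxygen O5 of the -1 sugar
    "o_a": 1,         # acid oxygen bonded to H_a
}

#: default MDAnalysis selections for the hLAMAN active site; PDB naming varies,
#: so these are a starting point, overridable per structure.
DEFAULT_SELECTIONS = {
    "acid_pair": "resid 319 and name OD1 OD2",
    "h_a": "resid 319 and name HD2",
    "o_g": "resname AMB MAN BMA and name O6",
    "nuc_pair": "resid 196 and name OD1 OD2",
    "o_n": "resid 196 and name OD1",
    "c1p": "resname AMB MAN BMA and name C1",
    "o_ring": "resname AMB MAN BMA and name O5",
    "o_a": "resid 319 and name OD2",
}


class SelectionError(ValueError):
    """A selection did not resolve to the declared atom count."""


@dataclass
class CatalyticSelection:
    """Named atom selections (MDAnalysis syntax) for the catalytic machinery."""

    selections: dict = field(default_factory=lambda: dict(DEFAULT_SELECTIONS))

    def __post_init__(self):
        missing = set(SELECTION_ROLES) - set(self.selections)
        if missing:
            raise SelectionError(f"missing selections for roles: {sorted(missing)}")

    @classmethod
    def from_yaml(cls, path) -> "CatalyticSelection":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        sel = dict(DEFAULT_SELECTIONS)
        sel.update(data.get("selections", data))
        return cls(sel)

    def resolve(self, universe, frame_index: int | None = None) -> "CatalyticFrame":
        """Resolve selections in an MDAnalysis Universe into coordinates."""
        coords = {}
        for role, count in SELECTION_ROLES.items():
            group = universe.select_atoms(self.selections[role])
            if len(group) != count:
                raise SelectionError(
                    f"role '{role}' ({self.selections[role]!r}) matched "
                    f"{len(group)} atoms, expected {count}"
                )
            pos = group.positions.astype(float)
            coords[role] = pos if count > 1 else pos[0]
        return CatalyticFrame(coords=coords, frame_index=frame_index)

    def dry_run(self, universe) -> dict:
        """Report what each selection matches, without failing."""
        report = {}
        for role in SELECTION_ROLES:
            group = universe.select_atoms(self.selections[role])
            report[role] = [f"{a.resname}{a.resid}:{a.name}" for a in group]
        return report


@dataclass
class CatalyticFrame:
    """Resolved catalytic-atom coordinates (Angstrom) at one time point."""

    coords: dict
    frame_index: int | None = None

    def __post_init__(self):
        for role, count in SELECTION_ROLES.items():
            if role not in self.coords:
                raise SelectionError(f"frame lacks coordinates for role '{role}'")
            arr = np.asarray(self.coords[role], dtype=float)
            expected = (count, 3) if count > 1 else (3,)
            if arr.shape != expected:
                raise SelectionError(f"role '{role}' has shape {arr.shape}, expected {expected}")
            if not np.all(np.isfinite(arr)):
                raise SelectionError(f"role '{role}' has non-finite coordinates")
            self.coords[role] = arr

    def __getitem__(self, role: str) -> np.ndarray:
        return self.coords[role]


def _midpoint(pair: np.ndarray) -> np.ndarray:
    return pair.mean(axis=0)


def _dist(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(a) - np.asarray(b)))


def cv1(frame: CatalyticFrame) -> float:
    """Proton-transfer coordinate d1 - d2 (Angstrom).

    Negative while the proton still sits on the acid; positive once it
    has moved to the glycosidic oxygen.
    """
    m = _midpoint(frame["acid_pair"])
    return _dist(m, frame["h_a"]) - _dist(frame["h_a"], frame["o_g"])


def cv2(frame: CatalyticFrame) -> float:
    """Bond cleavage / nucleophilic attack coordinate d3 - d4 (Angstrom)."""
    m = _midpoint(frame["nuc_pair"])
    return _dist(frame["o_g"], frame["c1p"]) - _dist(frame["c1p"], m)


def catalytic_distances(frame: CatalyticFrame) -> dict:
    """The four catalytic distances: C1'-O_g, O_n-C1', O_a-H_a, H_a-O_g."""
    return {
        "C1p-Og": _dist(frame["c1p"], frame["o_g"]),
        "On-C1p": _dist(frame["o_n"], frame["c1p"]),
        "Oa-Ha": _dist(frame["o_a"], frame["h_a"]),
        "Ha-Og": _dist(frame["h_a"], frame["o_g"]),
    }


def attack_angle(frame: CatalyticFrame) -> float:
    """Nucleophilic attack angle O_n - C1' - O_ring, degrees in [0, 180]."""
    v1 = frame["o_n"] - frame["c1p"]
    v2 = frame["o_ring"] - frame["c1p"]
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise ValueError("attack angle undefined: zero-length vector at C1'")
    c = float(np.dot(v1, v2) / (n1 * n2))
    return math.degrees(math.acos(min(1.0, max(-1.0, c))))


def analyze_structure(pdb_path, selection: CatalyticSelection | None = None) -> "pd.DataFrame":
    """CV1/CV2, catalytic distances and attack angle per model of a PDB file."""
    import MDAnalysis as mda
    import pandas as pd

    selection = selection or CatalyticSelection()
    u = mda.Universe(str(pdb_path))
    rows = []
    for ts in u.trajectory:
        frame = selection.resolve(u, frame_index=ts.frame)
        row = {"frame": ts.frame, "cv1": cv1(frame), "cv2": cv2(frame)}
        row.update(catalytic_distances(frame))
        row["attack_angle"] = attack_angle(frame)
        rows.append(row)
    return pd.DataFrame(rows)
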