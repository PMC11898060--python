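"""Minimal PDB writing for synthetic fixtures.

Reading goes through MDAnalysis everywhere in the package; writing of
the small generated fixtures uses plain ATOM/HETATM records so the files
stay human-readable text.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def write_pdb(dest, positions, names, resnames, resids, elements=None, chain="A") -> None:
    """Write one model of ATOM records (coordinates in Angstrom)."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    n = len(positions)
    elements = elements or [str(nm)[0] for nm in names]
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            write_pdb(fh, positions, names, resnames, resids, elements, chain)
            return
    for i in range(n):
        name = str(names[i])[:4]
        dest.write(
            f"ATOM  {i + 1:5d} {name:^4s} {str(resnames[i])[:3]:>3s} {chain}{int(resids[i]):4d}    "
            f"{positions[i, 0]:8.3f}{positions[i, 1]:8.3f}{positions[i, 2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {str(elements[i]):>2s}\n"
        )
    dest.write("END\n")
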