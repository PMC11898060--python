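"""Canonical six-membered-ring conformer references on the Cremer-Pople sphere.

The 38 canonical pyranose conformers (2 chairs, 6 boats, 6 skew-boats,
12 envelopes, 12 half-chairs) are placed at the (theta, phi) coordinates
obtained by feeding their idealized displacement patterns through the
Cremer-Pople transform with the ring walked O5, C1, C2, C3, C4, C5
(O5 at index 0).  Under that convention:

* a pure alternating pattern z_j = (-1)^j puts ``4C1`` at the north pole
  (theta = 0) and ``1C4`` at the south pole;
* a single displaced atom k gives an envelope at
  theta = atan(sqrt(2)) = 54.7356 deg (north, k even) with
  phi = -120 k mod 360 (atom above the plane) or the antipodal point
  (atom below);
* an adjacent up/down pair gives a half-chair at
  theta = atan(sqrt(6)/2) = 50.7685 deg (and its southern supplement);
* boats sit on the equator at even multiples of 30 deg of phi,
  skew-boats at odd multiples.

Labels use plain-text IUPAC style: leading locants are atoms above the
ring plane, trailing locants atoms below (``4C1``, ``E5``, ``1S3``,
``B2,5`` ...). ``O`` denotes the ring oxygen O5.
"""

from __future__ import annotations

import math

_THETA_E_N = math.degrees(math.atan(math.sqrt(2.0)))        # 54.7356...
_THETA_H_N = math.degrees(math.atan(math.sqrt(6.0) / 2.0))  # 50.7685...
_THETA_E_S = 180.0 - _THETA_E_N
_THETA_H_S = 180.0 - _THETA_H_N

#: label -> (reference theta [deg], reference phi [deg])
CANONICAL_CONFORMERS: dict[str, tuple[float, float]] = {
    # chairs (poles; phi arbitrary, stored as 0)
    "4C1": (0.0, 0.0),
    "1C4": (180.0, 0.0),
    # equator: boats at even 30-deg multiples, skew-boats at odd ones
    "3,OB": (90.0, 0.0),
    "3S1": (90.0, 30.0),
    "B1,4": (90.0, 60.0),
    "5S1": (90.0, 90.0),
    "2,5B": (90.0, 120.0),
    "2SO": (90.0, 150.0),
    "B3,O": (90.0, 180.0),
    "1S3": (90.0, 210.0),
    "1,4B": (90.0, 240.0),
    "1S5": (90.0, 270.0),
    "B2,5": (90.0, 300.0),
    "OS2": (90.0, 330.0),
    # northern tropic: envelopes and half-chairs alternate every 30 deg
    "OE": (_THETA_E_N, 0.0),
    "OH1": (_THETA_H_N, 30.0),
    "E1": (_THETA_E_N, 60.0),
    "2H1": (_THETA_H_N, 90.0),
    "2E": (_THETA_E_N, 120.0),
    "2H3": (_THETA_H_N, 150.0),
    "E3": (_THETA_E_N, 180.0),
    "4H3": (_THETA_H_N, 210.0),
    "4E": (_THETA_E_N, 240.0),
    "4H5": (_THETA_H_N, 270.0),
    "E5": (_THETA_E_N, 300.0),
    "OH5": (_THETA_H_N, 330.0),
    # southern tropic
    "3E": (_THETA_E_S, 0.0),
    "3H4": (_THETA_H_S, 30.0),
    "E4": (_THETA_E_S, 60.0),
    "5H4": (_THETA_H_S, 90.0),
    "5E": (_THETA_E_S, 120.0),
    "5HO": (_THETA_H_S, 150.0),
    "EO": (_THETA_E_S, 180.0),
    "1HO": (_THETA_H_S, 210.0),
    "1E": (_THETA_E_S, 240.0),
    "1H2": (_THETA_H_S, 270.0),
    "E2": (_THETA_E_S, 300.0),
    "3H2": (_THETA_H_S, 330.0),
}

#: deterministic tie-break order for classification
CONFORMER_ORDER: tuple[str, ...] = tuple(CANONICAL_CONFORMERS)
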