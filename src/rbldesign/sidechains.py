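"""Ideal-geometry sidechain construction for rotamer scanning.

Only the residue types the buttressing scans place are modeled:
Asn/Asp/Gln/His (bidentate hydrogen-bond donors/acceptors) and
Val/Leu/Ile/Met/Phe (hydrophobic contacts), plus Ala's CB.  Atoms are
built from internal coordinates (bond, angle, torsion) on an ideal
template; torsions are either fixed (ring/planarity) or driven by chi
angles.  Polar hydrogens are added on sidechain amide/imidazole
nitrogens so the geometric hydrogen-bond rule can be evaluated.
"""

from __future__ import annotations

import math
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .geometry_core import place_atom

#: bond count from CA for every sidechain atom we build (used for the
#: "≥3 bonds apart" exclusion in clash checking)
BRANCH_DEPTH = {
    "CB": 1,
    "CG": 2, "CG1": 2, "CG2": 2,
    "OD1": 3, "OD2": 3, "ND2": 3, "ND1": 3, "CD": 3, "CD1": 3, "CD2": 3,
    "SD": 3,
    "OE1": 4, "NE2": 4, "CE": 4, "CE1": 4, "CE2": 4,
    "CZ": 5,
}

#: number of chi angles per modeled residue type
N_CHI = {"A": 0, "V": 1, "N": 2, "D": 2, "L": 2, "I": 2, "F": 2,
         "H": 2, "M": 3, "Q": 3}

# atom: (ref_a, ref_b, ref_c, bond Å, angle deg, torsion)
# torsion is a float (fixed) or ("chi", k, offset_deg)
_TEMPLATES: Dict[str, List[tuple]] = {
    "N": [
        ("CG", "N", "CA", "CB", 1.516, 112.6, ("chi", 1, 0.0)),
        ("OD1", "CA", "CB", "CG", 1.231, 120.8, ("chi", 2, 0.0)),
        ("ND2", "CA", "CB", "CG", 1.328, 116.4, ("chi", 2, 180.0)),
        ("HD21", "CB", "CG", "ND2", 1.010, 120.0, 0.0),
        ("HD22", "CB", "CG", "ND2", 1.010, 120.0, 180.0),
    ],
    "D": [
        ("CG", "N", "CA", "CB", 1.516, 112.6, ("chi", 1, 0.0)),
        ("OD1", "CA", "CB", "CG", 1.249, 118.4, ("chi", 2, 0.0)),
        ("OD2", "CA", "CB", "CG", 1.249, 118.4, ("chi", 2, 180.0)),
    ],
    "Q": [
        ("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1, 0.0)),
        ("CD", "CA", "CB", "CG", 1.516, 112.6, ("chi", 2, 0.0)),
        ("OE1", "CB", "CG", "CD", 1.231, 120.8, ("chi", 3, 0.0)),
        ("NE2", "CB", "CG", "CD", 1.328, 116.4, ("chi", 3, 180.0)),
        ("HE21", "CG", "CD", "NE2", 1.010, 120.0, 0.0),
        ("HE22", "CG", "CD", "NE2", 1.010, 120.0, 180.0),
    ],
    "H": [
        ("CG", "N", "CA", "CB", 1.497, 113.8, ("chi", 1, 0.0)),
        ("ND1", "CA", "CB", "CG", 1.378, 122.7, ("chi", 2, 0.0)),
        ("CD2", "CA", "CB", "CG", 1.354, 131.2, ("chi", 2, 180.0)),
        ("CE1", "CB", "CG", "ND1", 1.321, 109.3, 180.0),
        ("NE2", "CG", "ND1", "CE1", 1.321, 111.7, 0.0),
        ("HD1", "CE1", "CG", "ND1", 1.010, 125.0, 180.0),
        ("HE2", "ND1", "CE1", "NE2", 1.010, 125.0, 180.0),
    ],
    "V": [
        ("CG1", "N", "CA", "CB", 1.521, 110.5, ("chi", 1, 0.0)),
        ("CG2", "N", "CA", "CB", 1.521, 110.5, ("chi", 1, 122.3)),
    ],
    "L": [
        ("CG", "N", "CA", "CB", 1.530, 116.3, ("chi", 1, 0.0)),
        ("CD1", "CA", "CB", "CG", 1.521, 110.7, ("chi", 2, 0.0)),
        ("CD2", "CA", "CB", "CG", 1.521, 110.7, ("chi", 2, 122.6)),
    ],
    "I": [
        ("CG1", "N", "CA", "CB", 1.530, 110.4, ("chi", 1, 0.0)),
        ("CG2", "N", "CA", "CB", 1.521, 110.5, ("chi", 1, -122.3)),
        ("CD1", "CA", "CB", "CG1", 1.513, 113.8, ("chi", 2, 0.0)),
    ],
    "M": [
        ("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1, 0.0)),
        ("SD", "CA", "CB", "CG", 1.803, 112.7, ("chi", 2, 0.0)),
        ("CE", "CB", "CG", "SD", 1.791, 100.9, ("chi", 3, 0.0)),
    ],
    "F": [
        ("CG", "N", "CA", "CB", 1.502, 113.8, ("chi", 1, 0.0)),
        ("CD1", "CA", "CB", "CG", 1.384, 120.7, ("chi", 2, 0.0)),
        ("CD2", "CA", "CB", "CG", 1.384, 120.7, ("chi", 2, 180.0)),
        ("CE1", "CB", "CG", "CD1", 1.382, 120.7, 180.0),
        ("CE2", "CB", "CG", "CD2", 1.382, 120.7, 180.0),
        ("CZ", "CG", "CD1", "CE1", 1.382, 120.0, 0.0),
    ],
    "A": [],
}

#: sidechain hydrogen-bond donors: nitrogen -> its hydrogens
SIDECHAIN_DONORS = {
    "N": {"ND2": ("HD21", "HD22")},
    "Q": {"NE2": ("HE21", "HE22")},
    "H": {"ND1": ("HD1",), "NE2": ("HE2",)},
}

#: sidechain hydrogen-bond acceptors (heavy atoms)
SIDECHAIN_ACCEPTORS = {
    "N": ("OD1",),
    "D": ("OD1", "OD2"),
    "Q": ("OE1",),
    "H": ("ND1", "NE2"),
}

#: atoms of the terminal functional group, per residue type (the group
#: whose bonds make a bidentate pair)
FUNCTIONAL_GROUP = {
    "N": ("OD1", "ND2"),
    "D": ("OD1", "OD2"),
    "Q": ("OE1", "NE2"),
    "H": ("ND1", "NE2"),
}


def build_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal CB from backbone N/CA/C (standard tetrahedral construction)."""
    b = ca - n
    c_v = c - ca
    a = np.cross(b, c_v)
    return ca + (-0.58273431 * a + 0.56802827 * b - 0.54067466 * c_v)


def build_sidechain(aa: str, n: np.ndarray, ca: np.ndarray, c: np.ndarray,
                    chis: Sequence[float]) -> Dict[str, np.ndarray]:
    """Build all sidechain atoms (incl. polar H) for ``aa`` at the given
    backbone position with the given chi angles (degrees)."""
    aa = aa.upper()
    if aa not in _TEMPLATES:
        raise ValueError(f"no sidechain template for residue type {aa!r}")
    if len(chis) < N_CHI[aa]:
        raise ValueError(f"{aa} needs {N_CHI[aa]} chi angles, got {len(chis)}")
    atoms: Dict[str, np.ndarray] = {"N": n, "CA": ca, "C": c,
                                    "CB": build_cb(n, ca, c)}
    for name, ra, rb, rc, bond, angle, tor in _TEMPLATES[aa]:
        if isinstance(tor, tuple):
            _, k, offset = tor
            torsion = chis[k - 1] + offset
        else:
            torsion = tor
        atoms[name] = place_atom(atoms[ra], atoms[rb], atoms[rc],
                                 bond, angle, torsion)
    for bb in ("N", "CA", "C"):
        del atoms[bb]
    return atoms
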