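"""Hydrogen-bond detection and secondary-structure assignment.

Backbone–backbone bonds use the Kabsch–Sander electrostatic model (the
DSSP energy): E = 27.888·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol,
with a bond reported when E < −0.5 kcal/mol.  Sidechain–backbone bonds
use a geometric rule (donor–acceptor < 3.5 Å, D–H⋯A angle > 120°),
since an orientation-dependent energy model is deliberately out of
scope.  The pseudo-hydrogen-bond criterion used during buttress rescue
is stricter on distance (< 3 Å) with the same angular cutoff (> 120°),
read as the D–H⋯A angle.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .geometry_core import bond_angle
from .sidechains import (FUNCTIONAL_GROUP, SIDECHAIN_ACCEPTORS,
                         SIDECHAIN_DONORS)
from .structure_model import BackboneModel

KS_COUPLING = 27.888  # kcal·Å/mol = 332 · 0.42 · 0.20
KS_CUTOFF = -0.5      # kcal/mol
SC_BB_DIST = 3.5      # Å
SC_BB_ANGLE = 120.0   # degrees
PSEUDO_DIST = 3.0     # Å  (donor–acceptor < 3 Å)
PSEUDO_ANGLE = 120.0  # degrees (hydrogen-bond angle > 120°)


@dataclasses.dataclass
class HBond:
    donor: Tuple[int, str]      # (0-based residue index, atom name)
    acceptor: Tuple[int, str]
    d_DA: float                 # donor–acceptor heavy-atom distance, Å
    angle_DHA: float            # degrees; NaN when no H is modeled
    energy: float               # kcal/mol (Kabsch–Sander) for bb_bb, else 0
    kind: str                   # "bb_bb" | "sc_bb"


@dataclasses.dataclass
class BidentateBond:
    residue: int                # sidechain residue (0-based)
    aa: str
    bonds: List[HBond]
    partner_unit: Optional[int]


def place_amide_hydrogens(model: BackboneModel) -> BackboneModel:
    """Add backbone amide H in the peptide plane, 1.01 Å from N, anti to
    the bisector of N→C(i−1) and N→CA.  Prolines, the first residue and
    residues following a chain break get no H.  Returns ``model``."""
    for i, res in enumerate(model.residues):
        res.atoms.pop("H", None)
        if i == 0 or res.aa == "P" or not model.is_bonded(i - 1, i):
            continue
        prev = model.residues[i - 1]
        if "C" not in prev or "N" not in res or "CA" not in res:
            continue
        n = res["N"]
        u = prev["C"] - n
        v = res["CA"] - n
        u /= np.linalg.norm(u)
        v /= np.linalg.norm(v)
        h_dir = -(u + v)
        h_dir /= np.linalg.norm(h_dir)
        res.atoms["H"] = n + 1.01 * h_dir
    return model


def kabsch_sander_energy(don_res, acc_res) -> float:
    """DSSP electrostatic energy of (N–H of don_res) → (C=O of acc_res)."""
    if "H" not in don_res.atoms:
        return 0.0
    N, H = don_res["N"], don_res["H"]
    C, O = acc_res["C"], acc_res["O"]
    r_on = np.linalg.norm(O - N)
    r_ch = np.linalg.norm(C - H)
    r_oh = np.linalg.norm(O - H)
    r_cn = np.linalg.norm(C - N)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return -9.9  # overlapping atoms: treat as strongly bonded/clashing
    return KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _bb_bb_hbonds(model: BackboneModel, cutoff: float) -> List[HBond]:
    donors = [(i, r) for i, r in enumerate(model.residues) if "H" in r.atoms]
    acceptors = [(j, r) for j, r in enumerate(model.residues)
                 if "O" in r.atoms and "C" in r.atoms]
    if not donors or not acceptors:
        return []
    dpos = np.array([r["N"] for _, r in donors])
    apos = np.array([r["O"] for _, r in acceptors])
    tree = cKDTree(apos)
    out: List[HBond] = []
    for (di, (i, dres)), neigh in zip(enumerate(donors),
                                      tree.query_ball_point(dpos, 5.5)):
        for aj in neigh:
            j, ares = acceptors[aj]
            if abs(i - j) < 2:
                continue  # self / chain neighbors
            e = kabsch_sander_energy(dres, ares)
            if e < cutoff:
                d_da = float(np.linalg.norm(ares["O"] - dres["N"]))
                ang = bond_angle(dres["N"], dres["H"], ares["O"])
                out.append(HBond((i, "N"), (j, "O"), d_da, ang, e, "bb_bb"))
    return out


def _iter_sc_donors(model: BackboneModel):
    for i, res in enumerate(model.residues):
        for natom, hs in SIDECHAIN_DONORS.get(res.aa, {}).items():
            if natom in res.atoms:
                yield i, natom, [h for h in hs if h in res.atoms]


def _iter_sc_acceptors(model: BackboneModel):
    for i, res in enumerate(model.residues):
        for a in SIDECHAIN_ACCEPTORS.get(res.aa, ()):
            if a in res.atoms:
                yield i, a


def _geom_bond(dres, datom, hs, ares, aatom) -> Optional[Tuple[float, float]]:
    d = float(np.linalg.norm(ares[aatom] - dres[datom]))
    if d >= SC_BB_DIST or d < 1.5:
        return None
    best = -1.0
    for h in hs:
        best = max(best, bond_angle(dres[datom], dres[h], ares[aatom]))
    if best <= SC_BB_ANGLE:
        return None
    return d, best


def _sc_bb_hbonds(model: BackboneModel) -> List[HBond]:
    out: List[HBond] = []
    # sidechain donor -> backbone carbonyl O
    for i, datom, hs in _iter_sc_donors(model):
        if not hs:
            continue
        dres = model.residues[i]
        for j, ares in enumerate(model.residues):
            if j == i or "O" not in ares.atoms:
                continue
            g = _geom_bond(dres, datom, hs, ares, "O")
            if g:
                out.append(HBond((i, datom), (j, "O"), g[0], g[1], 0.0, "sc_bb"))
    # backbone N–H donor -> sidechain acceptor
    for j, aatom in _iter_sc_acceptors(model):
        ares = model.residues[j]
        for i, dres in enumerate(model.residues):
            if i == j or "H" not in dres.atoms:
                continue
            g = _geom_bond(dres, "N", ["H"], ares, aatom)
            if g:
                out.append(HBond((i, "N"), (j, aatom), g[0], g[1], 0.0, "sc_bb"))
    return out


def detect_hbonds(model: BackboneModel, kind: str = "bb_bb",
                  cutoff: float = KS_CUTOFF) -> List[HBond]:
    """Detect hydrogen bonds of the requested class.

    ``kind``: "bb_bb" (Kabsch–Sander, energy < ``cutoff``), "sc_bb"
    (geometric rule) or "all".  Amide hydrogens must be placed.
    """
    out: List[HBond] = []
    if kind in ("bb_bb", "all"):
        out += _bb_bb_hbonds(model, cutoff)
    if kind in ("sc_bb", "all"):
        out += _sc_bb_hbonds(model)
    if kind not in ("bb_bb", "sc_bb", "all"):
        raise ValueError(f"unknown hbond class {kind!r}")
    return out


def detect_beta_turn(model: BackboneModel, i: int,
                     cutoff: float = KS_CUTOFF) -> bool:
    """True iff O(i) accepts a backbone hydrogen bond from N–H(i+3)."""
    if i < 0 or i + 3 >= len(model.residues):
        raise IndexError("turn window out of range")
    if not model.contiguous(i, i + 3):
        return False
    don = model.residues[i + 3]
    acc = model.residues[i]
    if "H" not in don.atoms or "O" not in acc.atoms:
        return False
    return kabsch_sander_energy(don, acc) < cutoff


def is_pseudo_hbond(donor: np.ndarray, hydrogen: np.ndarray,
                    acceptor: np.ndarray,
                    max_dist: float = PSEUDO_DIST,
                    min_angle: float = PSEUDO_ANGLE) -> bool:
    """Donor–acceptor distance < 3 Å and D–H⋯A angle > 120°."""
    if np.linalg.norm(acceptor - donor) >= max_dist:
        return False
    return bond_angle(donor, hydrogen, acceptor) > min_angle


def find_bidentate(model: BackboneModel, i: int,
                   sc_bonds: Optional[List[HBond]] = None,
                   neighbor_units: Optional[Sequence[int]] = None,
                   mode: str = "unit") -> List[BidentateBond]:
    """Bidentate bonds of residue i's sidechain functional group.

    In the default interloop mode, residue i's sidechain–backbone bonds
    are grouped by the repeat unit of the backbone partner and a
    :class:`BidentateBond` is emitted when at least two land on one
    *neighboring* unit (units k±1 of residue i's unit, or
    ``neighbor_units`` when given).  In ``mode="helix"`` (loop–helix
    buttressing) bonds are grouped by individual helix — (unit, region)
    of helical partners, the residue's own unit included.  Residues
    without a polar sidechain yield an empty list.
    """
    from .structure_model import HELIX_REGIONS

    res = model.residues[i]
    group = FUNCTIONAL_GROUP.get(res.aa)
    if group is None:
        return []
    if sc_bonds is None:
        sc_bonds = detect_hbonds(model, "sc_bb")
    by_key: Dict = {}
    for hb in sc_bonds:
        if hb.donor[0] == i and hb.donor[1] in group:
            partner = hb.acceptor[0]
        elif hb.acceptor[0] == i and hb.acceptor[1] in group:
            partner = hb.donor[0]
        else:
            continue
        # partner side must be backbone (N or O), on a different residue
        other_atom = hb.acceptor[1] if hb.donor[0] == i else hb.donor[1]
        if other_atom not in ("N", "O"):
            continue
        pres = model.residues[partner]
        if mode == "helix":
            if pres.region not in HELIX_REGIONS:
                continue
            key = (pres.repeat_unit, pres.region)
        else:
            key = pres.repeat_unit
        by_key.setdefault(key, []).append(hb)
    my_unit = res.repeat_unit
    if mode != "helix" and neighbor_units is None and my_unit is not None:
        neighbor_units = (my_unit - 1, my_unit + 1)
    out = []
    for key, bonds in by_key.items():
        if len(bonds) < 2:
            continue
        unit = key[0] if mode == "helix" else key
        if mode != "helix" and neighbor_units is not None \
                and unit not in neighbor_units:
            continue
        out.append(BidentateBond(residue=i, aa=res.aa, bonds=bonds,
                                 partner_unit=unit))
    return out


def assign_ss(model: BackboneModel,
              bonds: Optional[List[HBond]] = None) -> List[str]:
    """Per-residue secondary structure: H (α-helix), E (β-strand), L.

    Kabsch–Sander patterns: two consecutive i→i+4 turns mark residues
    i+1..i+4 helical; parallel/antiparallel bridge patterns mark both
    bridge partners as strand.  H wins over E.
    """
    n = len(model.residues)
    if bonds is None:
        bonds = detect_hbonds(model, "bb_bb")
    has = {(hb.acceptor[0], hb.donor[0]) for hb in bonds}  # (O res, N res)

    def hb(o: int, nn: int) -> bool:
        return (o, nn) in has

    ss = ["L"] * n
    turn4 = [hb(i, i + 4) for i in range(n)]
    for i in range(n):
        if turn4[i]:
            for k in range(i + 1, min(i + 5, n)):
                ss[k] = "H"
    for i in range(n):
        for j in range(i + 3, n):
            antiparallel = (hb(i, j) and hb(j, i)) or \
                (i - 1 >= 0 and j + 1 < n and hb(i - 1, j + 1) and hb(j - 1, i + 1))
            parallel = (i - 1 >= 0 and hb(i - 1, j) and hb(j, i + 1)) or \
                (j - 1 >= 0 and hb(j - 1, i) and hb(i, j + 1))
            if antiparallel or parallel:
                for k in (i, j):
                    if ss[k] == "L":
                        ss[k] = "E"
    return ss


def residue_hbond_energy(model: BackboneModel, i: int,
                         bonds: Optional[List[HBond]] = None) -> float:
    """Sum of Kabsch–Sander energies of backbone bonds involving residue i."""
    if bonds is None:
        bonds = detect_hbonds(model, "bb_bb")
    return sum(hb.energy for hb in bonds
               if hb.donor[0] == i or hb.acceptor[0] == i)
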