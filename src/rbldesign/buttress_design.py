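"""Sidechain buttressing: bidentate hydrogen-bond and hydrophobic
contact scanning on fixed loop backbones.

Each long-loop position is scanned with Asn/Asp/Gln/His rotamers (the
bidentate-capable set — Arg/Lys are excluded for their entropic cost)
and kept only when the sidechain functional group forms two hydrogen
bonds to the backbone of one neighboring repeat unit; otherwise the
position reverts to Ala.  Near-miss geometries (two pseudo-hydrogen
bonds: donor–acceptor < 3 Å, angle > 120°) are rescued by constrained
chi refinement that minimizes a harmonic restraint with target 2.0 Å
and s.d. 0.5 Å on each donor–acceptor pair.  Val/Leu/Ile/Met/Phe are
scanned analogously for loop–helix hydrophobic contacts.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

from .data_tables import rotamer_table
from .geometry_core import bond_angle, clash_check, power, RigidTransform
from .hbond_geometry import (HBond, BidentateBond, detect_hbonds,
                             find_bidentate, is_pseudo_hbond,
                             place_amide_hydrogens)
from .repeat_backbone import LayerAssignment, assign_layers
from .sidechains import (FUNCTIONAL_GROUP, SIDECHAIN_ACCEPTORS,
                         SIDECHAIN_DONORS, N_CHI, build_sidechain)
from .structure_model import BackboneModel

POLAR_SCAN_SET = ("N", "D", "Q", "H")
HYDROPHOBIC_SCAN_SET = ("V", "L", "I", "M", "F")
CONTACT_DIST = 4.5       # Å sidechain-heavy to helix-heavy
MIN_CONTACT_ATOMS = 4
HARMONIC_TARGET = 2.0    # Å donor–acceptor restraint target
HARMONIC_SD = 0.5        # Å restraint s.d.
BURIED_UNSAT_MAX = 3     # report-level threshold


@dataclasses.dataclass
class RotamerPlacement:
    position: int                       # 0-based residue index
    aa: str
    chis: List[float]
    bidentate: List[BidentateBond] = dataclasses.field(default_factory=list)
    contacts: int = 0
    accepted: bool = False
    mode: str = "unit"          # bidentate grouping: interloop or loop–helix


def _install(model: BackboneModel, pos: int, aa: str,
             chis: Sequence[float]) -> None:
    """Mutate residue ``pos`` in place: set aa and rebuild its sidechain."""
    res = model.residues[pos]
    res.aa = aa
    for name in [n for n in res.atoms if n not in ("N", "CA", "C", "O", "H")]:
        del res.atoms[name]
    if aa != "G":
        res.atoms.update(build_sidechain(aa, res["N"], res["CA"], res["C"], chis))


def sc_bonds_of(model: BackboneModel, i: int) -> List[HBond]:
    """Sidechain–backbone hydrogen bonds involving residue i's sidechain
    only (targeted version of the global sc_bb detection)."""
    res = model.residues[i]
    out: List[HBond] = []
    donors = SIDECHAIN_DONORS.get(res.aa, {})
    acceptors = SIDECHAIN_ACCEPTORS.get(res.aa, ())
    for j, other in enumerate(model.residues):
        if j == i:
            continue
        # residue i sidechain donor -> backbone O of j
        if "O" in other.atoms:
            for datom, hs in donors.items():
                if datom not in res.atoms:
                    continue
                d = float(np.linalg.norm(other["O"] - res[datom]))
                if d >= 3.5 or d < 1.5:
                    continue
                ang = max(bond_angle(res[datom], res[h], other["O"])
                          for h in hs if h in res.atoms)
                if ang > 120.0:
                    out.append(HBond((i, datom), (j, "O"), d, ang, 0.0, "sc_bb"))
        # backbone N–H of j -> residue i sidechain acceptor
        if "H" in other.atoms:
            for aatom in acceptors:
                if aatom not in res.atoms:
                    continue
                d = float(np.linalg.norm(res[aatom] - other["N"]))
                if d >= 3.5 or d < 1.5:
                    continue
                ang = bond_angle(other["N"], other["H"], res[aatom])
                if ang > 120.0:
                    out.append(HBond((j, "N"), (i, aatom), d, ang, 0.0, "sc_bb"))
    return out


def _pair_candidates(model: BackboneModel, pos: int, reach: float = 7.0,
                     mode: str = "unit", target_atoms=None):
    """Closest feasible (sidechain atom, partner backbone atom) bond
    pairs for residue pos's functional group, grouped by neighbor unit.

    Returns a list of (d1 + d2, [(sc_atom, role, partner_res), ...])
    with exactly two entries per item, both on the same neighbor unit;
    role is "don" (sidechain donates to backbone O) or "acc" (backbone
    N–H donates to the sidechain atom).  When ``target_atoms`` (a set
    of (residue, atom) keys) is given, only pairs touching at least one
    target are returned — used to aim placements at still-unsatisfied
    backbone polar atoms.
    """
    res = model.residues[pos]
    aa = res.aa
    group = FUNCTIONAL_GROUP.get(aa)
    if group is None:
        return []
    my_unit = res.repeat_unit
    donors = set(SIDECHAIN_DONORS.get(aa, {}))
    acceptors = set(SIDECHAIN_ACCEPTORS.get(aa, ()))
    from .structure_model import HELIX_REGIONS

    per_unit: Dict = {}
    for j, other in enumerate(model.residues):
        if j == pos or other.repeat_unit is None or my_unit is None:
            continue
        if mode == "helix":
            if other.region not in HELIX_REGIONS:
                continue
            key = (other.repeat_unit, other.region)
        else:
            if other.repeat_unit not in (my_unit - 1, my_unit + 1):
                continue
            key = other.repeat_unit
        slot = per_unit.setdefault(key, {})
        for sc in group:
            if sc not in res.atoms:
                continue
            if sc in donors and "O" in other.atoms:
                d = float(np.linalg.norm(other["O"] - res[sc]))
                if d < reach:
                    lst = slot.setdefault(sc, [])
                    lst.append((d, "don", j))
                    lst.sort()
                    del lst[2:]
            if sc in acceptors and "H" in other.atoms:
                d = float(np.linalg.norm(other["N"] - res[sc]))
                if d < reach:
                    lst = slot.setdefault(sc + "#a", [])
                    lst.append((d, "acc", j))
                    lst.sort()
                    del lst[2:]
    out = []
    for u, slot in per_unit.items():
        entries = []
        for key, cands in slot.items():
            sc = key.split("#")[0]
            for (d, role, j) in cands:
                entries.append((d, sc, role, j))
        entries.sort()
        # two bonds of one functional group: distinct (atom, partner)
        # combinations — one amide N–H2 may donate twice, one carbonyl
        # may accept twice, or two different group atoms participate
        best_pair = None
        for a in range(len(entries)):
            for b in range(a + 1, len(entries)):
                d1, sc1, r1, j1 = entries[a]
                d2, sc2, r2, j2 = entries[b]
                if (sc1, j1) == (sc2, j2):
                    continue
                if sc1 == sc2 and r1 == "don" and \
                        len(SIDECHAIN_DONORS[aa][sc1]) < 2:
                    continue  # single-H donor cannot donate twice
                if target_atoms is not None:
                    k1 = (j1, "O" if r1 == "don" else "N")
                    k2 = (j2, "O" if r2 == "don" else "N")
                    if k1 not in target_atoms and k2 not in target_atoms:
                        continue
                if best_pair is None or d1 + d2 < best_pair[0]:
                    best_pair = (d1 + d2, [(sc1, r1, j1), (sc2, r2, j2)])
        if best_pair:
            out.append(best_pair)
    out.sort(key=lambda t: t[0])
    return out


def _environment(model: BackboneModel, pos: int, radius: float = 10.0):
    """Fixed steric environment for chi refinement of residue pos:
    heavy atoms of every other residue plus pos's own backbone N/C/O
    (all ≥3 bonds from the chi-movable atoms), within ``radius`` of
    pos's CA.  Returns (coords array, radii array)."""
    from .geometry_core import VDW_RADII

    ca = model.residues[pos]["CA"]
    pts, radii = [], []
    for j, other in enumerate(model.residues):
        for name, xyz in other.heavy_atoms():
            if j == pos and name not in ("N", "C", "O"):
                continue
            if np.linalg.norm(xyz - ca) <= radius:
                pts.append(xyz)
                radii.append(VDW_RADII.get(name[0], 1.7))
    if not pts:
        return np.zeros((0, 3)), np.zeros(0)
    return np.array(pts), np.array(radii)


def _sc_clash_penalty(model: BackboneModel, pos: int, env,
                      margin: float = 0.1) -> float:
    """Soft steric penalty (quadratic in the overlap) of residue pos's
    sidechain against the precomputed environment, so refinement can
    slide a jammed rotamer out of collision."""
    from .geometry_core import VDW_RADII

    pts, radii = env
    if len(pts) == 0:
        return 0.0
    res = model.residues[pos]
    tot = 0.0
    for n1, p1 in res.heavy_atoms():
        if n1 in ("N", "CA", "C", "O", "CB"):
            continue  # CB does not move with chi
        lim = 0.6 * (VDW_RADII.get(n1[0], 1.7) + radii) + margin
        d = np.linalg.norm(pts - p1, axis=1)
        over = lim - d
        tot += float((over[over > 0] ** 2).sum())
    return tot


def _refine_chis(work: BackboneModel, pos: int, aa: str,
                 chis: Sequence[float], pair) -> Optional[List[float]]:
    """Nelder–Mead chi refinement pulling the two candidate bonds to
    hydrogen-bond geometry (2.9 Å heavy-atom, near-linear) under a soft
    steric penalty."""
    _, targets = pair
    env = _environment(work, pos)

    def objective(x):
        _install(work, pos, aa, list(x))
        res = work.residues[pos]
        tot = 50.0 * _sc_clash_penalty(work, pos, env)
        for sc, role, j in targets:
            other = work.residues[j]
            if role == "don":
                d = np.linalg.norm(other["O"] - res[sc])
                hs = SIDECHAIN_DONORS[aa][sc]
                ang = max(bond_angle(res[sc], res[h], other["O"])
                          for h in hs if h in res.atoms)
            else:
                d = np.linalg.norm(res[sc] - other["N"])
                ang = bond_angle(other["N"], other["H"], res[sc])
            tot += (d - 2.9) ** 2 + 0.002 * max(0.0, 155.0 - ang) ** 2
        return tot

    x0 = np.array(chis, dtype=float)
    best_x, best_f = x0, objective(x0)
    for start in (x0, x0 + 20.0, x0 - 20.0):
        fit = minimize(objective, start, method="Nelder-Mead",
                       options=dict(xatol=0.2, fatol=1e-4, maxiter=250))
        if np.isfinite(fit.fun) and fit.fun < best_f:
            best_x, best_f = fit.x, float(fit.fun)
    return [float(v) for v in best_x]


def _net_satisfaction(aa: str, bid, sc_bonds) -> int:
    """Placement quality: bond count rewarded, group atoms the bonds
    leave unsatisfied penalized (a placement should not import new
    buried polar atoms)."""
    group = FUNCTIONAL_GROUP[aa]
    engaged = set()
    for hb in sc_bonds:
        for side in (hb.donor, hb.acceptor):
            if side[1] in group:
                engaged.add(side[1])
    n_bonds = sum(len(b.bonds) for b in bid)
    return 2 * n_bonds + len(engaged) - len(group)


def scan_bidentate(model: BackboneModel, positions: Sequence[int],
                   rotamers: Optional[Dict[str, List[List[float]]]] = None,
                   aa_set: Sequence[str] = POLAR_SCAN_SET,
                   refine: bool = True,
                   mode: str = "unit",
                   target_atoms=None) -> List[RotamerPlacement]:
    """Scan each loop position for polar placements forming interloop
    bidentate hydrogen bonds; positions with no hit revert to Ala.

    The backbone is fixed throughout.  For every position ×
    Asn/Asp/Gln/His × rotamer the sidechain is built on ideal internal
    geometry and kept when its functional group makes ≥2 hydrogen
    bonds to the backbone of one neighboring unit; when no raw rotamer
    hits and ``refine`` is set, the most promising rotamer per residue
    type is chi-refined toward the nearest feasible donor/acceptor pair
    (the analogue of packing followed by constrained minimization).
    Returns one placement per position (best accepted rotamer, or an
    Ala reversion).  Arg/Lys are never attempted.
    """
    if rotamers is None:
        rotamers = rotamer_table()
    work = model.copy()
    place_amide_hydrogens(work)
    out: List[RotamerPlacement] = []
    for pos in positions:
        best: Optional[RotamerPlacement] = None
        best_score = -99
        promising = []  # (pair_dist, aa, chis, pair) for the refine stage
        for aa in aa_set:
            for chis in rotamers[aa]:
                _install(work, pos, aa, chis)
                clashed = clash_check(work, loop_range=(pos, pos))
                if not clashed:
                    sc = sc_bonds_of(work, pos)
                    bid = find_bidentate(work, pos, sc_bonds=sc, mode=mode)
                    if bid:
                        score = _net_satisfaction(aa, bid, sc)
                        if best is None or score > best_score:
                            best = RotamerPlacement(pos, aa, list(chis), bid,
                                                    accepted=True, mode=mode)
                            best_score = score
                        continue
                if refine and best is None:
                    pairs = _pair_candidates(work, pos, mode=mode,
                                             target_atoms=target_atoms)
                    if pairs:
                        promising.append((pairs[0][0], aa, list(chis),
                                          pairs[0]))
        if best is None and refine and promising:
            promising.sort(key=lambda t: t[0])
            for _, aa, chis, pair in promising[:6]:
                refined = _refine_chis(work, pos, aa, chis, pair)
                if refined is None:
                    continue
                _install(work, pos, aa, refined)
                if clash_check(work, loop_range=(pos, pos)):
                    continue
                sc = sc_bonds_of(work, pos)
                bid = find_bidentate(work, pos, sc_bonds=sc, mode=mode)
                if bid:
                    score = _net_satisfaction(aa, bid, sc)
                    if score > best_score:
                        best = RotamerPlacement(pos, aa, refined, bid,
                                                accepted=True, mode=mode)
                        best_score = score
                    break
        _install(work, pos, "A", [])
        out.append(best if best is not None
                   else RotamerPlacement(pos, "A", [], [], accepted=False))
    return out


# ---------------------------------------------------------------------------
# pseudo-bidentate rescue
# ---------------------------------------------------------------------------

def _pseudo_pairs(model: BackboneModel, pos: int
                  ) -> Dict[int, List[Tuple[Tuple[int, str], Tuple[int, str]]]]:
    """Donor/acceptor atom pairs of residue ``pos``'s functional group
    that satisfy the pseudo-hydrogen-bond criterion, grouped by the
    partner residue's repeat unit.  Pair = ((donor res, atom),
    (acceptor res, atom))."""
    res = model.residues[pos]
    group = FUNCTIONAL_GROUP.get(res.aa, ())
    by_unit: Dict[int, list] = {}
    donors = SIDECHAIN_DONORS.get(res.aa, {})
    acceptors = SIDECHAIN_ACCEPTORS.get(res.aa, ())
    for j, other in enumerate(model.residues):
        if j == pos or other.repeat_unit is None:
            continue
        unit = other.repeat_unit
        if res.repeat_unit is not None and unit not in (res.repeat_unit - 1,
                                                        res.repeat_unit + 1):
            continue
        if "O" in other.atoms:
            for datom, hs in donors.items():
                if datom not in group or datom not in res.atoms:
                    continue
                if any(is_pseudo_hbond(res[datom], res[h], other["O"])
                       for h in hs if h in res.atoms):
                    by_unit.setdefault(unit, []).append(
                        ((pos, datom), (j, "O")))
        if "H" in other.atoms:
            for aatom in acceptors:
                if aatom not in group or aatom not in res.atoms:
                    continue
                if is_pseudo_hbond(other["N"], other["H"], res[aatom]):
                    by_unit.setdefault(unit, []).append(
                        ((j, "N"), (pos, aatom)))
    return by_unit


def harmonic_objective(model: BackboneModel, pairs,
                       target: float = HARMONIC_TARGET,
                       sd: float = HARMONIC_SD) -> float:
    """Σ ((d(donor, acceptor) − target) / sd)² over restrained pairs."""
    tot = 0.0
    for (di, datom), (ai, aatom) in pairs:
        d = float(np.linalg.norm(model.residues[ai][aatom] -
                                 model.residues[di][datom]))
        tot += ((d - target) / sd) ** 2
    return tot


def rescue_pseudo_bidentate(model: BackboneModel, placement: RotamerPlacement,
                            target: float = HARMONIC_TARGET,
                            sd: float = HARMONIC_SD,
                            grid_span: float = 30.0,
                            grid_step: float = 2.0) -> RotamerPlacement:
    """Refine a placement with ≥2 pseudo-hydrogen bonds to one neighbor
    unit into a genuine bidentate pair.

    Chi angles move on a ±``grid_span`` grid in ``grid_step`` steps
    (coordinate-wise sweeps) followed by a local simplex polish,
    minimizing the harmonic donor–acceptor restraint subject to no
    clash; the refined chis are kept only if the objective did not
    increase and the bidentate check now passes.  Placements without a
    pseudo-bidentate pair are returned unchanged.
    """
    if placement.aa not in FUNCTIONAL_GROUP:
        return placement
    work = model.copy()
    place_amide_hydrogens(work)
    pos = placement.position
    _install(work, pos, placement.aa, placement.chis)
    groups = {u: prs for u, prs in _pseudo_pairs(work, pos).items()
              if len(prs) >= 2}
    if not groups:
        return placement
    unit, pairs = max(groups.items(), key=lambda kv: len(kv[1]))

    def objective(chis) -> float:
        _install(work, pos, placement.aa, list(chis))
        if clash_check(work, loop_range=(pos, pos)):
            return 1e6
        return harmonic_objective(work, pairs, target, sd)

    chis = np.array(placement.chis, dtype=float)
    f0 = objective(chis)
    best, fbest = chis.copy(), f0
    for _ in range(2):  # coordinate-wise grid sweeps
        for k in range(len(chis)):
            grid = best[k] + np.arange(-grid_span, grid_span + 1e-9, grid_step)
            for g in grid:
                trial = best.copy()
                trial[k] = g
                f = objective(trial)
                if f < fbest:
                    fbest, best = f, trial
    if len(best) > 0:
        res = minimize(objective, best, method="Nelder-Mead",
                       options=dict(xatol=0.05, fatol=1e-6, maxiter=400))
        if res.fun <= fbest:
            best, fbest = np.asarray(res.x), float(res.fun)
    if fbest > f0:  # never increase the restraint objective
        best, fbest = chis, f0
    _install(work, pos, placement.aa, list(best))
    bid = find_bidentate(work, pos, sc_bonds=sc_bonds_of(work, pos))
    return RotamerPlacement(pos, placement.aa, [float(v) for v in best],
                            bid, accepted=bool(bid))


# ---------------------------------------------------------------------------
# hydrophobic contacts
# ---------------------------------------------------------------------------

def scan_hydrophobic_contacts(model: BackboneModel, positions: Sequence[int],
                              rotamers: Optional[Dict[str, List[List[float]]]] = None,
                              min_atoms: int = MIN_CONTACT_ATOMS,
                              contact_dist: float = CONTACT_DIST
                              ) -> List[RotamerPlacement]:
    """Scan loop positions for Val/Leu/Ile/Met/Phe placements whose
    sidechain packs against a helix (≥ ``min_atoms`` sidechain heavy
    atoms within ``contact_dist`` Å of helix heavy atoms, no clash)."""
    if rotamers is None:
        rotamers = rotamer_table()
    helix_pts = []
    for r in model.residues:
        if r.region in ("helix1", "helix2", "cap"):
            helix_pts.extend(xyz for _, xyz in r.heavy_atoms())
    helix_pts = np.array(helix_pts) if helix_pts else np.zeros((0, 3))
    work = model.copy()
    place_amide_hydrogens(work)
    out: List[RotamerPlacement] = []
    for pos in positions:
        best: Optional[RotamerPlacement] = None
        for aa in HYDROPHOBIC_SCAN_SET:
            for chis in rotamers[aa]:
                _install(work, pos, aa, chis)
                if clash_check(work, loop_range=(pos, pos)):
                    continue
                sc = [xyz for name, xyz in work.residues[pos].heavy_atoms()
                      if name not in ("N", "CA", "C", "O")]
                if not sc or helix_pts.size == 0:
                    continue
                d = np.linalg.norm(helix_pts[None, :, :] -
                                   np.array(sc)[:, None, :], axis=2)
                n_contact = int((d.min(axis=1) <= contact_dist).sum())
                if n_contact >= min_atoms:
                    cand = RotamerPlacement(pos, aa, list(chis),
                                            contacts=n_contact, accepted=True)
                    if best is None or n_contact > best.contacts:
                        best = cand
        _install(work, pos, "A", [])
        out.append(best if best is not None
                   else RotamerPlacement(pos, "A", [], accepted=False))
    return out


# ---------------------------------------------------------------------------
# buried unsatisfied polar atoms
# ---------------------------------------------------------------------------

def buried_unsatisfied_atoms(model: BackboneModel,
                             layers: Optional[LayerAssignment] = None
                             ) -> List[Tuple[int, str]]:
    """Core-layer N/O atoms participating in no detected hydrogen bond
    (backbone Kabsch–Sander plus sidechain geometric)."""
    m = model.copy()
    place_amide_hydrogens(m)
    if layers is None:
        layers = assign_layers(m)
    bonds = detect_hbonds(m, "all")
    satisfied = set()
    for hb in bonds:
        satisfied.add(hb.donor)
        satisfied.add(hb.acceptor)
    out: List[Tuple[int, str]] = []
    for i, res in enumerate(m.residues):
        if layers.layers[i] != "core":
            continue
        for name in res.atoms:
            if name.startswith("H"):
                continue
            if name[0] not in ("N", "O"):
                continue
            if (i, name) not in satisfied:
                out.append((i, name))
    return out


def count_buried_unsatisfied(model: BackboneModel,
                             layers: Optional[LayerAssignment] = None) -> int:
    """Number of buried (core-layer) N/O atoms with no hydrogen bond."""
    return len(buried_unsatisfied_atoms(model, layers))


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------

def propagate_placements(model: BackboneModel,
                         placements: Sequence[RotamerPlacement],
                         t_unit: RigidTransform) -> Tuple[BackboneModel,
                                                          List[RotamerPlacement]]:
    """Copy accepted placements to the equivalent position of every
    repeat unit (same amino acid and chi angles on each unit's own
    backbone frame, which the exact repeat transform makes congruent).

    A placement that clashes in any unit is dropped from *all* units so
    per-unit sequence identity is preserved.  Returns the new model and
    the placements that survived.
    """
    out = model.copy()
    place_amide_hydrogens(out)
    units = out.units()
    kept: List[RotamerPlacement] = []
    for pl in placements:
        if not pl.accepted:
            continue
        hres = out.residues[pl.position]
        host_idx = [i for i, r in enumerate(out.residues)
                    if r.repeat_unit == hres.repeat_unit
                    and r.region == hres.region]
        offset = host_idx.index(pl.position)
        targets = []
        ok = True
        for u in units:
            idx = [i for i, r in enumerate(out.residues)
                   if r.repeat_unit == u and r.region == hres.region]
            if len(idx) <= offset:
                continue
            p = idx[offset]
            _install(out, p, pl.aa, pl.chis)
            targets.append(p)
            if clash_check(out, loop_range=(p, p)):
                ok = False
                break
        if not ok:
            for p in targets:
                _install(out, p, "A", [])
            continue
        kept.append(pl)
    return out, kept


def verify_placements(model: BackboneModel,
                      placements: Sequence[RotamerPlacement]
                      ) -> Dict[int, List[BidentateBond]]:
    """Re-verify bidentate bonds per installed position after
    propagation (symmetric-minimization stage replaced by per-unit
    geometric re-checking)."""
    m = model.copy()
    place_amide_hydrogens(m)
    out: Dict[int, List[BidentateBond]] = {}
    for pl in placements:
        hres = m.residues[pl.position]
        host_idx = [i for i, r in enumerate(m.residues)
                    if r.repeat_unit == hres.repeat_unit
                    and r.region == hres.region]
        offset = host_idx.index(pl.position)
        for u in m.units():
            idx = [i for i, r in enumerate(m.residues)
                   if r.repeat_unit == u and r.region == hres.region]
            if len(idx) <= offset:
                continue
            p = idx[offset]
            if m.residues[p].aa == pl.aa:
                out[p] = find_bidentate(m, p, sc_bonds=sc_bonds_of(m, p),
                                        mode=pl.mode)
    return out
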