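"""Long buttressed-loop assembly, kinematic closure and loop filters.

Loops are assembled from a helix-capping motif (4 residues), a β-turn
motif (4 residues, randomly positioned) and free residues drawn from a
Ramachandran density, all with ω fixed at 180° and ideal bond geometry.
Closure solves the six pivot torsions (φ/ψ of the first, middle and
last loop residues) so that the chain meets the downstream helix
anchor; a candidate is accepted when the seam deviates from ideal
peptide geometry by less than 0.08 Å in the C–N bond and 2° in the
flanking bond angles.

Accepted loops are propagated to every repeat unit with the unit
transform and screened by the buttressing filters: ≥2 intraloop and ≥1
interloop backbone hydrogen bonds, ≤5 consecutive helical residues,
≥5 loop residues within 8 Å of a helix, a 45–135° direction score and
a negative hydrophobic-contact motif score.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numba import njit
from scipy.optimize import least_squares

from . import geometry_core as geom
from .geometry_core import (ANGLE_C_N_CA, ANGLE_CA_C_N, BOND_C_N,
                            RigidTransform, clash_check, place_atom, power)
from .hbond_geometry import assign_ss, detect_hbonds, place_amide_hydrogens
from .motif_library import Motif, MotifLibrary
from .repeat_backbone import helix_ranges
from .sidechains import build_cb
from .structure_model import BackboneModel, Residue

CLOSURE_GAP_TOL = 0.08     # Å on the seam C–N bond
CLOSURE_ANGLE_TOL = 2.0    # degrees on the seam bond angles
DIRECTION_MIN = 45.0       # degrees
DIRECTION_MAX = 135.0
PROXIMITY_DIST = 8.0       # Å loop-residue-to-helix-CA
PROXIMITY_MIN = 5          # residues
MAX_CONSEC_HELIX = 5
MIN_INTRALOOP_HB = 2
MIN_INTERLOOP_HB = 1


# ---------------------------------------------------------------------------
# Ramachandran density (general case), 10° × 10° bins
# ---------------------------------------------------------------------------

def _rama_table() -> np.ndarray:
    """Binned general-residue φ/ψ density: a Gaussian mixture over the
    α, β, polyproline-II and left-handed-α basins plus a flat floor."""
    edges = np.arange(-180.0, 181.0, 10.0)
    centers = (edges[:-1] + edges[1:]) / 2
    phi, psi = np.meshgrid(centers, centers, indexing="ij")
    basins = [  # (weight, phi0, psi0, sigma)
        (0.34, -63.0, -43.0, 15.0),
        (0.33, -118.0, 130.0, 25.0),
        (0.21, -65.0, 145.0, 18.0),
        (0.07, 57.0, 40.0, 13.0),
    ]
    p = np.full(phi.shape, 0.05 / phi.size)
    for w, p0, s0, sig in basins:
        dphi = (phi - p0 + 180.0) % 360.0 - 180.0
        dpsi = (psi - s0 + 180.0) % 360.0 - 180.0
        g = np.exp(-(dphi ** 2 + dpsi ** 2) / (2 * sig ** 2))
        p += w * g / g.sum()
    return p / p.sum()


_RAMA_P = _rama_table()
_RAMA_CDF = np.cumsum(_RAMA_P.ravel())


def sample_rama(rng: np.random.Generator) -> Tuple[float, float]:
    """Inverse-CDF draw of (φ, ψ) in degrees from the binned density."""
    idx = int(np.searchsorted(_RAMA_CDF, rng.random()))
    i, j = divmod(idx, _RAMA_P.shape[1])
    phi = -180.0 + 10.0 * i + 10.0 * rng.random()
    psi = -180.0 + 10.0 * j + 10.0 * rng.random()
    return phi, psi


# ---------------------------------------------------------------------------
# loop assembly
# ---------------------------------------------------------------------------

def _clean(t: Tuple[float, float, float],
           fallback: Tuple[float, float]) -> Tuple[float, float, float]:
    phi = fallback[0] if math.isnan(t[0]) else t[0]
    psi = fallback[1] if math.isnan(t[1]) else t[1]
    return (phi, psi, 180.0)


def assemble_extended_loop(cap: Motif, turn: Motif, n_kic: int,
                           rng: np.random.Generator,
                           turn_position: Optional[int] = None
                           ) -> List[Tuple[float, float, float]]:
    """Stitch cap (4) + β-turn (4) + ``n_kic`` free residues into an
    extended-loop torsion list of 8 + n_kic triplets, ω = 180°.

    The cap occupies positions 0–3 (the loop grows from the helix
    C-terminus); the turn start is sampled uniformly among the legal
    slots in the free region unless ``turn_position`` (offset ≥ 4) is
    given.  Free φ/ψ come from the Ramachandran density.
    """
    if not (5 <= n_kic <= 10):
        raise ValueError("n_kic must be in [5, 10]")
    total = 8 + n_kic
    slots = list(range(4, total - 3))  # turn must fit after the cap
    if turn_position is None:
        turn_position = int(rng.choice(slots))
    if turn_position not in slots:
        raise ValueError(f"turn_position {turn_position} outside legal slots "
                         f"{slots[0]}..{slots[-1]}")
    tor: List[Optional[Tuple[float, float, float]]] = [None] * total
    for k in range(4):
        tor[k] = _clean(cap.torsions[k], (-57.0, -47.0))
    for k in range(4):
        tor[turn_position + k] = _clean(turn.torsions[k], sample_rama(rng))
    for k in range(total):
        if tor[k] is None:
            tor[k] = tuple(sample_rama(rng)) + (180.0,)
    return [t for t in tor]


# ---------------------------------------------------------------------------
# kinematic closure (pivot-torsion solver)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _nerf_nca(prev_n, prev_ca, prev_c, psi_prev, omega_prev, tor):
    """Numba NeRF: N/CA/C positions of len(tor) residues grown from the
    anchor frame, plus the implied next-residue N and CA.  ``tor`` is a
    (L, 3) array of (φ, ψ, ω) in degrees."""
    L = tor.shape[0]
    out = np.empty((L, 3, 3))

    def place(a, b, c, bond, angle_deg, dihedral_deg):
        angle = np.radians(angle_deg)
        dihedral = np.radians(dihedral_deg)
        bc = c - b
        bc = bc / np.linalg.norm(bc)
        ab = b - a
        n = np.cross(ab, bc)
        n = n / np.linalg.norm(n)
        m = np.cross(n, bc)
        d0 = -bond * np.cos(angle)
        d1 = bond * np.sin(angle) * np.cos(dihedral)
        d2 = bond * np.sin(angle) * np.sin(dihedral)
        return c + d0 * bc + d1 * m + d2 * n

    n0 = place(prev_n, prev_ca, prev_c, 1.329, 116.2, psi_prev)
    ca0 = place(prev_ca, prev_c, n0, 1.458, 121.7, omega_prev)
    c0 = place(prev_c, n0, ca0, 1.525, 111.2, tor[0, 0])
    out[0, 0] = n0
    out[0, 1] = ca0
    out[0, 2] = c0
    for i in range(L - 1):
        nn = place(out[i, 0], out[i, 1], out[i, 2], 1.329, 116.2, tor[i, 1])
        can = place(out[i, 1], out[i, 2], nn, 1.458, 121.7, tor[i, 2])
        cn = place(out[i, 2], nn, can, 1.525, 111.2, tor[i + 1, 0])
        out[i + 1, 0] = nn
        out[i + 1, 1] = can
        out[i + 1, 2] = cn
    n_next = place(out[L - 1, 0], out[L - 1, 1], out[L - 1, 2],
                   1.329, 116.2, tor[L - 1, 1])
    ca_next = place(out[L - 1, 1], out[L - 1, 2], n_next,
                    1.458, 121.7, tor[L - 1, 2])
    return out, n_next, ca_next


def _chain_positions(start: dict, torsions: Sequence[Tuple[float, float, float]]
                     ) -> List[dict]:
    """Backbone of len(torsions) residues grown out of the ``start``
    anchor frame, plus the implied next-residue N and CA."""
    res = geom.build_backbone(torsions, start=start)
    last = res[-1]
    psi_last = torsions[-1][1]
    n_next = place_atom(last["N"], last["CA"], last["C"],
                        BOND_C_N, ANGLE_CA_C_N, psi_last)
    ca_next = place_atom(last["CA"], last["C"], n_next,
                         geom.BOND_N_CA, ANGLE_C_N_CA, torsions[-1][2])
    return res, n_next, ca_next


@dataclasses.dataclass
class ClosureSolution:
    torsions: List[Tuple[float, float, float]]
    atoms: List[dict]
    gap: float            # |built N − anchor N|, Å
    angle_err: float      # max seam bond-angle error, degrees


def solve_closure(start: dict, target_n: np.ndarray, target_ca: np.ndarray,
                  torsions: Sequence[Tuple[float, float, float]],
                  pivots: Optional[Sequence[int]] = None,
                  rng: Optional[np.random.Generator] = None,
                  n_starts: int = 3,
                  max_nfev: int = 150,
                  max_solutions: int = 3) -> List[ClosureSolution]:
    """Solve the six pivot torsions so the chain's implied next-residue
    N and CA coincide with the downstream anchor.

    ``start`` holds the upstream anchor's N/CA/C plus its fixed ψ.
    Non-pivot torsions are never touched.  A damped least-squares
    search from the assembled torsions plus deterministic perturbed
    restarts stands in for the analytic tripeptide solver, behind the
    same acceptance contract.
    """
    L = len(torsions)
    if pivots is None:
        pivots = [0, L // 2, L - 1]
    torsions = [tuple(t) for t in torsions]
    if rng is None:
        rng = np.random.default_rng(0)

    def with_pivots(x):
        t = list(torsions)
        for k, p in enumerate(pivots):
            t[p] = (x[2 * k], x[2 * k + 1], t[p][2])
        return t

    prev_n = np.asarray(start["N"], dtype=float)
    prev_ca = np.asarray(start["CA"], dtype=float)
    prev_c = np.asarray(start["C"], dtype=float)
    psi_prev = float(start.get("psi", 180.0))
    omega_prev = float(start.get("omega", 180.0))
    tor_arr = np.array(torsions, dtype=float)

    def residual(x):
        t = tor_arr.copy()
        for k, p in enumerate(pivots):
            t[p, 0] = x[2 * k]
            t[p, 1] = x[2 * k + 1]
        _, n_next, ca_next = _nerf_nca(prev_n, prev_ca, prev_c,
                                       psi_prev, omega_prev, t)
        return np.concatenate([n_next - target_n, ca_next - target_ca])

    x0 = np.array([v for p in pivots for v in torsions[p][:2]])
    sols: List[ClosureSolution] = []
    for trial in range(n_starts):
        if trial == 0:
            xi = x0
        else:
            xi = x0 + rng.normal(0.0, 40.0, size=x0.shape)
        fit = least_squares(residual, xi, method="lm", max_nfev=max_nfev)
        if not np.isfinite(fit.cost):
            continue
        t = with_pivots(fit.x)
        atoms, n_next, ca_next = _chain_positions(start, t)
        gap = float(np.linalg.norm(n_next - target_n))
        last = atoms[-1]
        seam_bond = float(np.linalg.norm(target_n - last["C"]))
        a1 = geom.bond_angle(last["CA"], last["C"], target_n)
        a2 = geom.bond_angle(last["C"], target_n, target_ca)
        angle_err = max(abs(a1 - ANGLE_CA_C_N), abs(a2 - ANGLE_C_N_CA))
        if abs(seam_bond - BOND_C_N) < CLOSURE_GAP_TOL and gap < 0.3 \
                and angle_err < CLOSURE_ANGLE_TOL:
            # carbonyl O of the last residue: anti to the real anchor N
            atoms[-1]["O"] = place_atom(target_n, last["CA"], last["C"],
                                        geom.BOND_C_O, geom.ANGLE_CA_C_O, 180.0)
            sols.append(ClosureSolution(t, atoms, gap, angle_err))
            if len(sols) >= max_solutions:
                break
    return sols


def close_gap_with_torsions(model: BackboneModel, anchor_c: int, anchor_n: int,
                            torsions: Sequence[Tuple[float, float, float]],
                            region: str = "loop_long",
                            unit: Optional[int] = None,
                            rng: Optional[np.random.Generator] = None,
                            n_starts: int = 3,
                            return_all: bool = False):
    """Insert a closed loop between residues ``anchor_c`` and
    ``anchor_n`` (0-based; must flank a declared chain break).

    Returns the new model (or a list of models when ``return_all``), or
    None when no closure solution passes the seam tolerance.
    """
    if anchor_n != anchor_c + 1 or anchor_c not in model.breaks:
        raise ValueError("anchors must flank a declared chain break")
    up = model.residues[anchor_c]
    down = model.residues[anchor_n]
    # geometric feasibility: an L-residue chain spans at most ~3.6 Å each
    gap_dist = float(np.linalg.norm(down["N"] - up["C"]))
    if gap_dist > 3.7 * (len(torsions) + 1):
        return [] if return_all else None
    # recover the anchor's ψ from its carbonyl O (the next N is anti to O)
    psi_up = geom.dihedral(up["N"], up["CA"], up["C"], up["O"]) + 180.0
    start = {"N": up["N"], "CA": up["CA"], "C": up["C"],
             "psi": psi_up, "omega": 180.0}
    sols = solve_closure(start, down["N"], down["CA"], torsions, rng=rng,
                         n_starts=n_starts)
    out = []
    for sol in sols:
        new = model.copy()
        loop_res = []
        for k, atoms in enumerate(sol.atoms):
            loop_res.append(Residue(index=0, aa="A",
                                    atoms={n: np.asarray(p) for n, p in atoms.items()},
                                    repeat_unit=unit if unit is not None
                                    else up.repeat_unit,
                                    region=region))
        # re-place the upstream anchor's carbonyl O anti to the new N(1)
        n1 = loop_res[0]["N"]
        new.residues[anchor_c].atoms["O"] = place_atom(
            n1, up["CA"], up["C"], geom.BOND_C_O, geom.ANGLE_CA_C_O, 180.0)
        new.residues[anchor_c + 1:anchor_c + 1] = loop_res
        L = len(loop_res)
        new.breaks = {b if b < anchor_c else b + L
                      for b in new.breaks if b != anchor_c}
        new.renumber()
        out.append(new)
    if return_all:
        return out
    return out[0] if out else None


# ---------------------------------------------------------------------------
# candidates, propagation, filters
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FilterReport:
    intraloop_hbonds: Dict[int, int] = dataclasses.field(default_factory=dict)
    interloop_hbonds: Dict[Tuple[int, int], int] = dataclasses.field(default_factory=dict)
    consecutive_helix_max: int = 0
    direction_score: float = float("nan")
    motif_score: float = 0.0
    proximity_count: int = 0
    clash: bool = False
    closure_gap: float = float("nan")
    passes: Dict[str, bool] = dataclasses.field(default_factory=dict)
    # Rosetta-internal report fields, configuration-stubbed (never computed)
    packstat: Optional[float] = None
    hole_score: Optional[float] = None
    total_score_per_res: Optional[float] = None

    @property
    def all_pass(self) -> bool:
        return all(self.passes.values()) and not self.clash


@dataclasses.dataclass
class LoopCandidate:
    model: BackboneModel           # full model containing the closed loop(s)
    host_unit: int
    loop_start: int                # 0-based index of first loop residue
    loop_len: int
    torsions: List[Tuple[float, float, float]]
    closure_gap: float
    report: FilterReport = dataclasses.field(default_factory=FilterReport)

    def loop_indices(self) -> List[int]:
        return list(range(self.loop_start, self.loop_start + self.loop_len))


def loop_residue_indices(model: BackboneModel, unit: int,
                         region: str = "loop_long") -> List[int]:
    return [i for i, r in enumerate(model.residues)
            if r.repeat_unit == unit and r.region == region]


def propagate_loop(model: BackboneModel, candidate: LoopCandidate,
                   t_unit: RigidTransform) -> Tuple[Optional[BackboneModel], str]:
    """Copy the reference loop into every other unit gap via the repeat
    transform.  Returns (model, "") or (None, reason) when a propagated
    copy clashes."""
    base = candidate.model
    ref_unit = candidate.host_unit
    ref_idx = candidate.loop_indices()
    ref_res = [base.residues[i] for i in ref_idx]
    units = base.units()
    out = base.copy()
    # walk gaps top-down so indices stay valid while inserting
    for unit in sorted(units[:-1], reverse=True):
        if unit == ref_unit:
            continue
        t = power(t_unit, unit - ref_unit) if unit > ref_unit else \
            power(t_unit, ref_unit - unit).inverse()
        ranges = helix_ranges(out)
        h2 = [r for r in ranges if r[2] == unit and r[3] == "helix2"]
        anchor_c = h2[0][1]
        if anchor_c not in out.breaks:
            return None, f"unit {unit}: no open gap to receive the loop"
        new_res = []
        for r in ref_res:
            rr = r.copy()
            for name in rr.atoms:
                rr.atoms[name] = t.rotation @ rr.atoms[name] + t.translation
            rr.repeat_unit = unit
            new_res.append(rr)
        out.residues[anchor_c + 1:anchor_c + 1] = new_res
        L = len(new_res)
        out.breaks = {b if b < anchor_c else b + L
                      for b in out.breaks if b != anchor_c}
    out.renumber()
    # per-unit clash screen, reported with the offending unit
    for unit in units[:-1]:
        idx = loop_residue_indices(out, unit)
        if idx and clash_check(out, loop_range=(idx[0], idx[-1])):
            return None, f"propagated loop clashes in unit {unit}"
    return out, ""


def max_consecutive_helix(ss: Sequence[str], indices: Sequence[int]) -> int:
    best = run = 0
    for i in indices:
        if ss[i] == "H":
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


def direction_score(model: BackboneModel, unit: int,
                    frame: str = "unit") -> float:
    """Angle (degrees) between the loop protrusion vector **a** (from
    the center of mass of the two loop terminal residues to the farthest
    loop Cα) and **b** (from the same origin to the center of mass of
    the repeat unit — or of the whole protein with ``frame="protein"``)."""
    idx = loop_residue_indices(model, unit)
    if not idx:
        raise ValueError(f"unit {unit} has no long loop")
    first, last = model.residues[idx[0]], model.residues[idx[-1]]
    origin = np.mean([np.mean([xyz for _, xyz in r.heavy_atoms()], axis=0)
                      for r in (first, last)], axis=0)
    cas = np.array([model.residues[i]["CA"] for i in idx])
    d = np.linalg.norm(cas - origin, axis=1)
    a = cas[int(np.argmax(d))] - origin
    if frame == "unit":
        ref_idx = [i for i, r in enumerate(model.residues) if r.repeat_unit == unit]
    else:
        ref_idx = list(range(len(model.residues)))
    com = np.mean([model.residues[i]["CA"] for i in ref_idx], axis=0)
    b = com - origin
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-9 or nb < 1e-9:
        raise ValueError("degenerate loop geometry for direction score")
    return math.degrees(math.acos(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)))


def motif_pair_score(model: BackboneModel, table=None,
                     max_dist: float = 8.0) -> float:
    """Sum of CB–CB distance-bin log-odds over loop–helix residue pairs
    within ``max_dist`` Å (a packaged surrogate for native hydrophobic
    pair-motif matching; favorable packing bins are negative).  An
    empty pair set scores 0 (and is rejected by the <0 selection rule).
    """
    from .data_tables import motif_pair_table

    if table is None:
        table = motif_pair_table()
    loops, helices = [], []
    for i, r in enumerate(model.residues):
        cb = r.atoms.get("CB")
        if cb is None:
            cb = build_cb(r["N"], r["CA"], r["C"])
        if r.region == "loop_long":
            loops.append(cb)
        elif r.region in ("helix1", "helix2", "cap"):
            helices.append(cb)
    if not loops or not helices:
        return 0.0
    loops = np.array(loops)
    helices = np.array(helices)
    total = 0.0
    edges, values = table
    for cb in loops:
        d = np.linalg.norm(helices - cb, axis=1)
        for dist in d[d <= max_dist]:
            total += values[np.searchsorted(edges, dist) - 1]
    return float(total)


def filter_loops(model: BackboneModel,
                 min_intraloop: int = MIN_INTRALOOP_HB,
                 min_interloop: int = MIN_INTERLOOP_HB,
                 max_consec: int = MAX_CONSEC_HELIX,
                 direction_band: Tuple[float, float] = (DIRECTION_MIN, DIRECTION_MAX),
                 proximity_dist: float = PROXIMITY_DIST,
                 proximity_min: int = PROXIMITY_MIN,
                 direction_frame: str = "unit") -> FilterReport:
    """Evaluate every loop-level buttressing filter on a propagated model."""
    m = model.copy()
    place_amide_hydrogens(m)
    bonds = detect_hbonds(m, "bb_bb")
    ss = assign_ss(m, bonds)
    rep = FilterReport()
    units_with_loops = [u for u in m.units() if loop_residue_indices(m, u)]
    loop_sets = {u: set(loop_residue_indices(m, u)) for u in units_with_loops}

    for u, idx in loop_sets.items():
        rep.intraloop_hbonds[u] = sum(
            1 for hb in bonds if hb.donor[0] in idx and hb.acceptor[0] in idx)
    for u1, u2 in zip(units_with_loops, units_with_loops[1:]):
        rep.interloop_hbonds[(u1, u2)] = sum(
            1 for hb in bonds
            if (hb.donor[0] in loop_sets[u1] and hb.acceptor[0] in loop_sets[u2])
            or (hb.donor[0] in loop_sets[u2] and hb.acceptor[0] in loop_sets[u1]))
    all_loop_idx = sorted(set().union(*loop_sets.values())) if loop_sets else []
    rep.consecutive_helix_max = max(
        (max_consecutive_helix(ss, sorted(loop_sets[u])) for u in loop_sets),
        default=0)

    helix_cas = np.array([r["CA"] for r in m.residues
                          if r.region in ("helix1", "helix2", "cap")])
    prox_counts = []
    for u in units_with_loops:
        cnt = 0
        for i in sorted(loop_sets[u]):
            d = np.linalg.norm(helix_cas - m.residues[i]["CA"], axis=1)
            if d.min() <= proximity_dist:
                cnt += 1
        prox_counts.append(cnt)
    rep.proximity_count = min(prox_counts) if prox_counts else 0

    if units_with_loops:
        rep.direction_score = direction_score(m, units_with_loops[0],
                                              frame=direction_frame)
    rep.motif_score = motif_pair_score(m)
    rep.clash = bool(all_loop_idx) and clash_check(
        m, loop_range=(all_loop_idx[0], all_loop_idx[-1]))

    lo, hi = direction_band
    rep.passes = {
        "intraloop_hbonds": all(v >= min_intraloop
                                for v in rep.intraloop_hbonds.values()),
        "interloop_hbonds": all(v >= min_interloop
                                for v in rep.interloop_hbonds.values())
                            and bool(rep.interloop_hbonds),
        "consecutive_helix": rep.consecutive_helix_max <= max_consec,
        "direction_score": lo <= rep.direction_score <= hi
                           if not math.isnan(rep.direction_score) else False,
        "proximity": rep.proximity_count >= proximity_min,
        "motif_score": rep.motif_score < 0,
    }
    return rep


# ---------------------------------------------------------------------------
# sampling driver
# ---------------------------------------------------------------------------

def build_loop_candidates(model: BackboneModel, unit: int,
                          cap_lib: MotifLibrary, turn_lib: MotifLibrary,
                          rng: np.random.Generator,
                          n_attempts: int = 100,
                          kic_range: Tuple[int, int] = (5, 10)
                          ) -> List[LoopCandidate]:
    """Sample, close and clash-screen long-loop candidates bridging the
    gap after ``unit``'s H2 helix.

    The extended fragment is cap(4) + turn(4) + n_kic free residues;
    its first two residues overwrite the helix C-terminal two residues
    and its last two the next helix's N-terminal two (overlap
    convention), so the net inserted loop has n_kic + 4 = 9–14 residues.
    """
    out: List[LoopCandidate] = []
    ranges = helix_ranges(model)
    h2 = [r for r in ranges if r[2] == unit and r[3] == "helix2"]
    if not h2:
        return out
    anchor_c = h2[0][1]
    for _ in range(n_attempts):
        n_kic = int(rng.integers(kic_range[0], kic_range[1] + 1))
        cap = cap_lib.motifs[int(rng.integers(len(cap_lib.motifs)))]
        turn = turn_lib.motifs[int(rng.integers(len(turn_lib.motifs)))]
        frag = assemble_extended_loop(cap, turn, n_kic, rng)
        # overlap convention: trim two residues at each end of the fragment
        loop_tor = frag[2:-2]
        closed = close_gap_with_torsions(model, anchor_c, anchor_c + 1,
                                         loop_tor, region="loop_long",
                                         unit=unit, rng=rng)
        if closed is None:
            continue
        L = len(loop_tor)
        if clash_check(closed, loop_range=(anchor_c + 1, anchor_c + L)):
            continue
        seam = float(np.linalg.norm(
            closed.residues[anchor_c + L + 1]["N"] -
            closed.residues[anchor_c + L]["C"]))
        out.append(LoopCandidate(model=closed, host_unit=unit,
                                 loop_start=anchor_c + 1, loop_len=L,
                                 torsions=loop_tor,
                                 closure_gap=abs(seam - BOND_C_N)))
    return out
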