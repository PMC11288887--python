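"""Parametric repeat-protein backbone generation and scaffold filters.

A repeat unit is two ideal helices (H1, H2) related by a six-DOF
rigid-body transform; the unit is propagated by a second six-DOF
transform to build the tandem architecture.  Scaffolds are screened by
two geometric filters before long-loop construction: the gap to be
bridged by a buttressed long loop (H2 C-terminus of unit k to H1
N-terminus of unit k+1) must be at most 18 Å, and at least 28% of the
residues must sit in a buried core.
"""

from __future__ import annotations

import dataclasses
import math
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import geometry_core as geom
from .geometry_core import (HelixParams, RigidTransform, SixDOF, apply,
                            clash_check, compose, make_ideal_helix, power)
from .sidechains import build_cb
from .structure_model import HELIX_REGIONS, BackboneModel

TERMINI_CUTOFF = 18.0      # Å, max long-loop gap
CORE_MIN_FRACTION = 0.28   # min fraction of residues in the buried core
CORE_NEIGHBOR_CUTOFF = 18  # cone-neighbor count for "core"
BOUNDARY_NEIGHBOR_CUTOFF = 10
NEIGHBOR_DIST = 10.0       # Å, CB–CB
CONE_HALF_ANGLE = 100.0    # degrees off the CA→CB axis


@dataclasses.dataclass
class RepeatSpec:
    """Full parameterization of a disconnected repeat backbone."""

    h1: HelixParams
    h2: HelixParams
    intra_unit: SixDOF          # H1 → H2 placement
    inter_unit: SixDOF          # unit k → unit k+1
    n_repeats: int = 4

    def __post_init__(self):
        if self.n_repeats < 2:
            raise ValueError("need at least 2 repeats")
        for h in (self.h1, self.h2):
            if not (12 <= h.length <= 28):
                raise ValueError("helix lengths must be in [12, 28] for "
                                 "repeat sampling")


@dataclasses.dataclass
class LayerAssignment:
    layers: List[str]           # per residue: "core" | "boundary" | "surface"
    neighbor_counts: List[int]

    @property
    def core_fraction(self) -> float:
        if not self.layers:
            return 0.0
        return sum(1 for l in self.layers if l == "core") / len(self.layers)


def build_repeat_backbone(spec: RepeatSpec) -> BackboneModel:
    """Build the disconnected 2·n_repeats-helix backbone.

    Unit k (1-based) is exactly ``power(T_inter, k−1)`` applied to unit
    1; repeat-unit and region labels are set on every residue.  Chain
    breaks are declared between all sequence-adjacent helices (loops
    are installed later).
    """
    h1 = make_ideal_helix(spec.h1)
    h2 = apply(spec.intra_unit.to_transform(), make_ideal_helix(spec.h2))
    unit = BackboneModel(residues=[r.copy() for r in h1.residues] +
                         [r.copy() for r in h2.residues])
    for i, r in enumerate(unit.residues):
        r.region = "helix1" if i < spec.h1.length else "helix2"
    t_inter = spec.inter_unit.to_transform()
    residues = []
    breaks = set()
    for k in range(spec.n_repeats):
        u = apply(power(t_inter, k), unit)
        for i, r in enumerate(u.residues):
            r.repeat_unit = k
            residues.append(r)
        start = k * len(unit.residues)
        breaks.add(start + spec.h1.length - 1)          # H1|H2 gap
        if k > 0:
            breaks.add(start - 1)                        # unit gap
    model = BackboneModel(
        residues=residues,
        n_repeats=spec.n_repeats,
        repeat_len=len(unit.residues),
        provenance=f"repeat_backbone n={spec.n_repeats} "
                   f"h1={spec.h1.length} h2={spec.h2.length}",
        breaks=breaks,
    )
    model.renumber()
    return model


def unit_transform(spec: RepeatSpec) -> RigidTransform:
    return spec.inter_unit.to_transform()


def helix_ranges(model: BackboneModel) -> List[Tuple[int, int, int, str]]:
    """(start, end inclusive, unit, region) for every helix, in order."""
    out = []
    cur = None
    for i, r in enumerate(model.residues):
        key = (r.repeat_unit, r.region)
        if r.region in ("helix1", "helix2"):
            if cur and tuple(cur[2:]) == key:
                cur[1] = i
            else:
                if cur:
                    out.append(tuple(cur))
                cur = [i, i, r.repeat_unit, r.region]
        else:
            if cur:
                out.append(tuple(cur))
                cur = None
    if cur:
        out.append(tuple(cur))
    return [(a, b, u, reg) for a, b, u, reg in out]


def termini_distance(model: BackboneModel, unit: int) -> float:
    """Long-loop gap of unit k: C atom of H2's C-terminal residue to N
    atom of H1's N-terminal residue of unit k+1."""
    ranges = helix_ranges(model)
    h2 = [r for r in ranges if r[2] == unit and r[3] == "helix2"]
    h1n = [r for r in ranges if r[2] == unit + 1 and r[3] == "helix1"]
    if not h2 or not h1n:
        raise ValueError(f"no bridgeable pair for unit {unit}")
    c_atom = model.residues[h2[0][1]]["C"]
    n_atom = model.residues[h1n[0][0]]["N"]
    return float(np.linalg.norm(n_atom - c_atom))


def termini_distance_filter(model: BackboneModel,
                            cutoff: float = TERMINI_CUTOFF) -> List[bool]:
    """Per bridgeable unit pair: True iff the long-loop gap ≤ cutoff."""
    units = model.units()
    return [termini_distance(model, u) <= cutoff for u in units[:-1]]


def assign_layers(model: BackboneModel,
                  dist: float = NEIGHBOR_DIST,
                  cone_half_angle: float = CONE_HALF_ANGLE,
                  core_cut: int = CORE_NEIGHBOR_CUTOFF,
                  boundary_cut: int = BOUNDARY_NEIGHBOR_CUTOFF
                  ) -> LayerAssignment:
    """Cone-and-distance burial: residue j is a neighbor of i when its
    CB lies within ``dist`` Å of CB(i) and within ``cone_half_angle``
    degrees of the CA(i)→CB(i) axis (angle at CA).  The wide default
    cone (100° off-axis) mimics the soft angular falloff of
    sidechain-neighbor burial measures, which count neighbors well past
    the sidechain hemisphere boundary."""
    cas, cbs = [], []
    for r in model.residues:
        ca = r["CA"]
        cb = r.atoms.get("CB")
        if cb is None:
            cb = build_cb(r["N"], ca, r["C"])
        cas.append(ca)
        cbs.append(cb)
    cas = np.array(cas)
    cbs = np.array(cbs)
    v = cbs - cas
    v /= np.linalg.norm(v, axis=1)[:, None]
    cos_cut = math.cos(math.radians(cone_half_angle))
    counts = []
    for i in range(len(cas)):
        d = np.linalg.norm(cbs - cbs[i], axis=1)
        u = cbs - cas[i]
        du = np.linalg.norm(u, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = (u @ v[i]) / np.where(du > 0, du, 1.0)
        ok = (d <= dist) & (cosang >= cos_cut)
        ok[i] = False
        counts.append(int(ok.sum()))
    layers = ["core" if c >= core_cut else
              "boundary" if c >= boundary_cut else "surface" for c in counts]
    return LayerAssignment(layers=layers, neighbor_counts=counts)


def core_fraction_filter(model: BackboneModel,
                         min_frac: float = CORE_MIN_FRACTION,
                         layers: Optional[LayerAssignment] = None
                         ) -> Tuple[bool, float]:
    """(passes, fraction): at least ``min_frac`` of residues buried."""
    if layers is None:
        layers = assign_layers(model)
    frac = layers.core_fraction
    return frac >= min_frac, frac


def _capping_score(model: BackboneModel, anchor_c: int, L: int) -> int:
    """How many of the polar atoms around a closed short loop are
    hydrogen-bond satisfied: the two helix C-terminal carbonyls before
    the loop, the loop's own backbone N/O, and the next helix's first
    two amide N–H groups."""
    from .hbond_geometry import detect_hbonds, place_amide_hydrogens

    lo = max(0, anchor_c - 4)
    hi = min(len(model.residues), anchor_c + L + 5)
    sub = BackboneModel(residues=[model.residues[i].copy()
                                  for i in range(lo, hi)],
                        breaks={b - lo for b in model.breaks
                                if lo <= b < hi})
    place_amide_hydrogens(sub)
    bonds = detect_hbonds(sub, "bb_bb")
    sat = set()
    for hb in bonds:
        sat.add(hb.donor)
        sat.add(hb.acceptor)
    targets = []
    for i in range(anchor_c - 1, anchor_c + 1):        # helix C-term C=O
        targets.append((i - lo, "O"))
    for i in range(anchor_c + 1, anchor_c + L + 1):    # loop backbone
        targets.append((i - lo, "O"))
        targets.append((i - lo, "N"))
    for i in range(anchor_c + L + 1, anchor_c + L + 3):  # next helix N–H
        targets.append((i - lo, "N"))
    return sum(1 for t in targets if t in sat)


def connect_short_loops(model: BackboneModel, library=None,
                        lengths: Sequence[int] = (3, 4, 5, 6),
                        rng: Optional[np.random.Generator] = None,
                        attempts_per_length: int = 12,
                        inter_unit: Optional[RigidTransform] = None
                        ) -> BackboneModel:
    """Close the intra-unit H1→H2 gaps with short loops (3–6 residues).

    Torsions are drawn from the general Ramachandran density and closed
    with the same pivot-torsion engine used for long loops.  The loop
    is built once on the first repeat unit; when ``inter_unit`` (the
    repeat transform) is given, the chosen conformation is propagated
    to every unit so the backbone stays repeat-symmetric.  Among
    clash-free closures, the one satisfying the most flanking polar
    atoms (helix-capping hydrogen bonds) is kept.  Models whose gap
    cannot be closed at any length are returned with the gap open and
    the failure recorded in provenance.
    """
    from .loop_builder import close_gap_with_torsions, sample_rama

    if rng is None:
        rng = np.random.default_rng(0)
    out = model.copy()
    units = out.units()
    ref = units[0]
    ranges = helix_ranges(out)
    h1 = [r for r in ranges if r[2] == ref and r[3] == "helix1"]
    anchor_c = h1[0][1]
    best = None
    best_score = -1
    for L in lengths:
        for _ in range(attempts_per_length):
            tor = [tuple(sample_rama(rng)) + (180.0,) for _ in range(L)]
            new = close_gap_with_torsions(out, anchor_c, anchor_c + 1, tor,
                                          region="loop_short", unit=ref,
                                          rng=rng, n_starts=2)
            if new is None or clash_check(new,
                                          loop_range=(anchor_c + 1,
                                                      anchor_c + L)):
                continue
            score = _capping_score(new, anchor_c, L)
            if score > best_score:
                best, best_score, best_len = new, score, L
    if best is None:
        out.provenance += " unconnectable_units=all"
        out.renumber()
        return out
    out = best
    L = best_len
    if inter_unit is not None:
        loop_res = [out.residues[i] for i in
                    range(anchor_c + 1, anchor_c + 1 + L)]
        for unit in sorted(units[1:], reverse=True):
            ranges = helix_ranges(out)
            h1u = [r for r in ranges if r[2] == unit and r[3] == "helix1"]
            ac = h1u[0][1]
            t = power(inter_unit, unit - ref)
            new_res = []
            for r in loop_res:
                rr = r.copy()
                for name in rr.atoms:
                    rr.atoms[name] = t.rotation @ rr.atoms[name] + t.translation
                rr.repeat_unit = unit
                new_res.append(rr)
            out.residues[ac + 1:ac + 1] = new_res
            out.breaks = {b if b < ac else b + L
                          for b in out.breaks if b != ac}
    else:
        # close each remaining unit independently
        for unit in sorted(units[1:], reverse=True):
            ranges = helix_ranges(out)
            h1u = [r for r in ranges if r[2] == unit and r[3] == "helix1"]
            ac = h1u[0][1]
            closed = False
            for La in lengths:
                for _ in range(attempts_per_length):
                    tor = [tuple(sample_rama(rng)) + (180.0,)
                           for _ in range(La)]
                    new = close_gap_with_torsions(out, ac, ac + 1, tor,
                                                  region="loop_short",
                                                  unit=unit, rng=rng,
                                                  n_starts=2)
                    if new is not None and not clash_check(
                            new, loop_range=(ac + 1, ac + La)):
                        out = new
                        closed = True
                        break
                if closed:
                    break
            if not closed:
                out.provenance += f" unconnectable_units={unit}"
    out.renumber()
    return out
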