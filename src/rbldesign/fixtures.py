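"""Deterministic synthetic structures for testing and default libraries.

Every other module is testable without downloading coordinate files:
ideal helices, a β-hairpin with a genuine type-I′ turn and cross-strand
ladder hydrogen bonds, a gallery of canonical β-turn types, a
helix-with-capping-loop model, two-cluster fragment sets for
clustering tests, and a constructively planted bidentate arrangement.

The hairpin and capping-loop torsions were refined once (least-squares
on the target hydrogen-bond geometry with Cα repulsion) and are frozen
here so the fixtures are bit-reproducible; identical spec + seed give
bit-identical coordinates.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Union

import numpy as np
from scipy.optimize import least_squares

from . import geometry_core as geom
from .geometry_core import (HelixParams, RigidTransform, apply,
                            make_ideal_helix, rebuild_from_torsions)
from .motif_library import Motif, _canonical_frame, _window_coords
from .sidechains import build_sidechain
from .structure_model import BackboneModel

#: canonical β-turn types: central torsions (φ2, ψ2), (φ3, ψ3) and a
#: flanking ψ1 chosen so the CO(1)→NH(4) bond is well formed
TURN_TYPES = {
    "I":   {"central": ((-60.0, -30.0), (-90.0, 0.0)), "psi1": 135.0},
    "Ip":  {"central": ((60.0, 30.0), (90.0, 0.0)), "psi1": 30.0},
    "II":  {"central": ((-60.0, 120.0), (80.0, 0.0)), "psi1": -15.0},
    "IIp": {"central": ((60.0, -120.0), (-80.0, 0.0)), "psi1": -125.0},
}

#: 12-residue β-hairpin: 4-residue strands around a type-I′ two-residue
#: turn; gives the turn bond O(5)→N(8) (1-based) plus ladder bonds
HAIRPIN_TORSIONS = (
    (-130.00, 135.00, 180.0),
    (-120.79, 140.36, 180.0),
    (-103.92, 100.52, 180.0),
    (-176.47, 164.29, 180.0),
    (111.21, 113.65, 180.0),
    (60.00, 30.00, 180.0),
    (90.00, 0.00, 180.0),
    (154.53, 97.39, 180.0),
    (-142.26, 162.60, 180.0),
    (-72.68, 114.55, 180.0),
    (-114.05, 142.64, 180.0),
    (-130.00, 135.00, 180.0),
)

#: 4-residue capping loop appended to a 10-residue ideal helix; the
#: loop backbone donates into the helix's final turn (Schellman-like)
CAP_LOOP_TORSIONS = (
    (-29.07, -25.17, 180.0),
    (-145.07, 66.97, 180.0),
    (-90.00, 120.00, 180.0),
    (-120.00, 130.00, 180.0),
)

FIXTURE_KINDS = ("ideal_helix", "beta_hairpin", "turn_gallery",
                 "two_cluster_fragments", "helix_with_cap")


@dataclasses.dataclass
class FixtureSpec:
    kind: str
    length: int = 12
    n_fragments: int = 10
    seed: int = 0


def turn_fragment(turn_type: str, psi1: Optional[float] = None,
                  jitter: float = 0.0,
                  rng: Optional[np.random.Generator] = None) -> BackboneModel:
    """One canonical 4-residue β-turn fragment (optionally jittered)."""
    info = TURN_TYPES[turn_type]
    (p2, s2), (p3, s3) = info["central"]
    if psi1 is None:
        psi1 = info["psi1"]
    tor = [(-120.0, psi1, 180.0), (p2, s2, 180.0), (p3, s3, 180.0),
           (-120.0, 130.0, 180.0)]
    if jitter > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        tor = [(a + rng.uniform(-jitter, jitter),
                b + rng.uniform(-jitter, jitter), 180.0) for a, b, _ in tor]
    m = rebuild_from_torsions(tor)
    m.provenance = f"turn_{turn_type}"
    return m


def beta_hairpin() -> BackboneModel:
    m = rebuild_from_torsions(HAIRPIN_TORSIONS)
    m.provenance = "fixture_beta_hairpin"
    return m


def helix_with_cap(helix_len: int = 10) -> BackboneModel:
    tor = [(geom.IDEAL_HELIX_PHI, geom.IDEAL_HELIX_PSI, 180.0)] * helix_len \
        + list(CAP_LOOP_TORSIONS)
    m = rebuild_from_torsions(tor)
    m.provenance = f"fixture_helix_with_cap len={helix_len}"
    return m


def two_cluster_fragments(n: int = 10, seed: int = 0,
                          jitter: float = 4.0) -> List[Motif]:
    """Fragment set with two tight, well-separated clusters: jittered
    type-I turns and jittered helical 4-mers (inter-group backbone RMSD
    ≈ 2 Å, intra-group < 0.3 Å)."""
    rng = np.random.default_rng(seed)
    out: List[Motif] = []
    for k in range(n):
        if k % 2 == 0:
            m = turn_fragment("I", jitter=jitter, rng=rng)
        else:
            tor = [(-130.0 + rng.uniform(-jitter, jitter),
                    135.0 + rng.uniform(-jitter, jitter),
                    180.0) for _ in range(4)]
            m = rebuild_from_torsions(tor)
            m.provenance = "strand_4mer"
        coords = _canonical_frame(_window_coords(m, 0))
        out.append(Motif(kind="beta_turn",
                         torsions=[geom.torsions(m, i) for i in range(4)],
                         coords=coords, source=f"{m.provenance}:{k}"))
    return out


def make_fixture(spec: FixtureSpec) -> Union[BackboneModel,
                                             List[BackboneModel], List[Motif]]:
    """Build the synthetic structure(s) a :class:`FixtureSpec` names."""
    if spec.kind == "ideal_helix":
        return make_ideal_helix(HelixParams(length=spec.length))
    if spec.kind == "beta_hairpin":
        return beta_hairpin()
    if spec.kind == "turn_gallery":
        return [turn_fragment(t) for t in TURN_TYPES]
    if spec.kind == "two_cluster_fragments":
        return two_cluster_fragments(n=spec.n_fragments, seed=spec.seed)
    if spec.kind == "helix_with_cap":
        return helix_with_cap(helix_len=max(spec.length, 8))
    raise ValueError(f"unknown fixture kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# planted bidentate arrangement (inverse geometry)
# ---------------------------------------------------------------------------

def make_planted_bidentate(da_dist: float = 2.9, seed: int = 0
                           ) -> tuple:
    """Two helices on neighboring repeat units with an Asn on unit 0
    posed so its sidechain amide makes two hydrogen bonds (ND2→O and
    OD1←H–N) to unit 1's backbone, at donor–acceptor distance
    ``da_dist`` Å.

    The partner helix placement is solved by least squares over its six
    rigid-body degrees of freedom, so the fixture is constructed by
    inverse geometry rather than by the detector under test.  Returns
    (model, asn_index).
    """
    from .hbond_geometry import place_amide_hydrogens

    host = make_ideal_helix(HelixParams(length=12))
    asn_idx = 6
    res = host.residues[asn_idx]
    res.aa = "N"
    chis = [-65.0, -20.0]
    res.atoms.update(build_sidechain("N", res["N"], res["CA"], res["C"], chis))
    # the partner is an extended segment (a neighboring unit's loop):
    # its C=O and N–H of one residue point the same way, matching the
    # Asn amide span — the classic Asx-bridge arrangement
    partner0 = rebuild_from_torsions([(-130.0, 135.0, 180.0)] * 7)
    partner0 = apply(RigidTransform(np.eye(3), np.array([10.0, 0.0, 0.0])),
                     partner0)
    place_amide_hydrogens(partner0)
    q = 3  # partner residue supplying both the O acceptor and N–H donor

    host_pts = np.array([xyz for i, r0 in enumerate(host.residues)
                         for name, xyz in r0.heavy_atoms()
                         if not (i == asn_idx and
                                 name not in ("N", "CA", "C", "O"))])
    partner_pts0 = np.array([xyz for i, r0 in enumerate(partner0.residues)
                             for name, xyz in r0.heavy_atoms()
                             if not (i == q and name in ("O", "N"))])

    # solve the partner's rigid placement plus the Asn chi angles
    # against the two hydrogen-bond geometry criteria (hinge loss on
    # the angles), with soft repulsion against interpenetration
    def residual(x):
        t = geom.SixDOF(*x[:6]).to_transform()
        sc = build_sidechain("N", res["N"], res["CA"], res["C"],
                             [x[6], x[7]])
        nd2, od1 = sc["ND2"], sc["OD1"]
        p = apply(t, partner0)
        o_at = p.residues[q]["O"]
        n_at = p.residues[q]["N"]
        h_at = p.residues[q]["H"]
        moved = partner_pts0 @ t.rotation.T + t.translation
        d = np.linalg.norm(host_pts[:, None, :] - moved[None, :, :], axis=2)
        overlap = np.maximum(0.0, 3.0 - d).ravel()
        side_pts = np.array([sc[a] for a in ("CB", "CG", "OD1", "ND2")])
        ds = np.linalg.norm(side_pts[:, None, :] - moved[None, :, :], axis=2)
        overlap = np.concatenate([overlap,
                                  np.maximum(0.0, 2.6 - ds).ravel()])
        ang_don = max(geom.bond_angle(nd2, sc["HD21"], o_at),
                      geom.bond_angle(nd2, sc["HD22"], o_at))
        ang_acc = geom.bond_angle(n_at, h_at, od1)
        return np.concatenate([[
            np.linalg.norm(o_at - nd2) - da_dist,
            0.02 * min(0.0, ang_don - 150.0),
            np.linalg.norm(n_at - od1) - da_dist,
            0.02 * min(0.0, ang_acc - 150.0),
        ], 2.0 * overlap])

    from .geometry_core import clash_check

    def assemble(x):
        res.atoms.update(build_sidechain("N", res["N"], res["CA"], res["C"],
                                         [float(x[6]), float(x[7])]))
        t = geom.SixDOF(*x[:6]).to_transform()
        p = apply(t, partner0)
        out = BackboneModel(residues=[r.copy() for r in host.residues] +
                            [r.copy() for r in p.residues],
                            provenance="fixture_planted_bidentate")
        n_host = len(host.residues)
        for i, r in enumerate(out.residues):
            r.repeat_unit = 0 if i < n_host else 1
            r.region = "loop_long" if i == asn_idx else \
                ("helix1" if i < n_host else "loop_long")
        out.breaks.add(n_host - 1)
        out.renumber()
        return out

    rng = np.random.default_rng(seed)
    best = None
    for trial in range(30):
        x0 = np.concatenate([
            np.array([10.0, 0.0, 0.0, 0.0, 0.0, 0.0]) + rng.normal(0, 4.0, 6),
            np.array(chis) + rng.normal(0, 40.0, 2)])
        fit = least_squares(residual, x0, method="trf", max_nfev=400)
        bond_cost = float((fit.fun[:4] ** 2).sum())
        rep_cost = float((fit.fun[4:] ** 2).sum())
        if bond_cost < 5e-3 and rep_cost < 1e-6 and \
                not clash_check(assemble(fit.x)):
            best = fit
            break
        if best is None or fit.cost < best.cost:
            best = fit
    return assemble(best.x), asn_idx
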