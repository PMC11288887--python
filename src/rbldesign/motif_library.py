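"""β-turn and helix-capping motif libraries.

Four-residue backbone fragments are mined from coordinate sets, stored
in torsion + canonical-coordinate form, and clustered with the greedy
K-centers (farthest-point) algorithm under a backbone-RMSD metric
(N, CA, C, O of all four residues, after optimal superposition).  The
design protocol clusters at a maximum cluster distance of 0.63 Å.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import yaml

from . import geometry_core as geom
from .hbond_geometry import (assign_ss, detect_beta_turn, detect_hbonds,
                             place_amide_hydrogens)
from .structure_model import BackboneModel

SCHEMA_VERSION = 1
DEFAULT_CLUSTER_RADIUS = 0.63  # Å

_FRAME_ATOMS = ("N", "CA", "C", "O")


@dataclasses.dataclass
class Motif:
    """A four-residue backbone fragment (β-turn or helix-cap flavor)."""

    kind: str                               # "beta_turn" | "helix_cap"
    torsions: List[Tuple[float, float, float]]   # 4 × (φ, ψ, ω) degrees
    coords: np.ndarray                      # (16, 3): N/CA/C/O × 4, canonical frame
    source: str = ""
    cluster_id: Optional[int] = None

    def backbone_coords(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


@dataclasses.dataclass
class MotifLibrary:
    kind: str
    motifs: List[Motif]                     # cluster representatives
    cluster_radius: float = DEFAULT_CLUSTER_RADIUS
    counts: List[int] = dataclasses.field(default_factory=list)

    def __len__(self) -> int:
        return len(self.motifs)


def _canonical_frame(coords16: np.ndarray) -> np.ndarray:
    """Superpose residue 1's N/CA/C onto a fixed frame: CA at origin,
    N on −x, C in the xy-plane."""
    n, ca, c = coords16[0], coords16[1], coords16[2]
    x = n - ca
    x = -x / np.linalg.norm(x)          # N sits on −x
    z = np.cross(x, c - ca)
    z /= np.linalg.norm(z)
    y = np.cross(z, x)
    R = np.stack([x, y, z])             # rows = new basis
    return (coords16 - ca) @ R.T


def _window_coords(model: BackboneModel, i: int) -> np.ndarray:
    pts = []
    for k in range(i, i + 4):
        res = model.residues[k]
        for a in _FRAME_ATOMS:
            pts.append(res[a])
    return np.array(pts)


def _window_motif(model: BackboneModel, i: int, kind: str) -> Motif:
    tor = []
    for k in range(i, i + 4):
        phi, psi, omega = geom.torsions(model, k)
        res = model.residues[k]
        if np.isnan(psi):   # window end: recover ψ from the carbonyl O
            psi = geom.dihedral(res["N"], res["CA"], res["C"], res["O"]) + 180.0
        if np.isnan(omega):
            omega = 180.0
        tor.append((phi, psi, omega))
    coords = _canonical_frame(_window_coords(model, i))
    return Motif(kind=kind, torsions=tor, coords=coords,
                 source=f"{model.provenance}:{i}")


def _complete_window(model: BackboneModel, i: int) -> bool:
    if i < 0 or i + 3 >= len(model.residues):
        return False
    if not model.contiguous(i, i + 3):
        return False
    return all(model.residues[k].has_backbone() and not model.residues[k].incomplete
               for k in range(i, i + 4))


def mine_beta_turns(models: Sequence[BackboneModel]) -> List[Motif]:
    """All 4-residue windows with the defining CO(i)→NH(i+3) backbone
    hydrogen bond, canonicalized.  Windows across chain breaks are
    skipped."""
    out: List[Motif] = []
    for model in models:
        m = model.copy()
        place_amide_hydrogens(m)
        for i in range(len(m) - 3):
            if not _complete_window(m, i):
                continue
            if detect_beta_turn(m, i):
                out.append(_window_motif(m, i, "beta_turn"))
    return out


def mine_helix_caps(models: Sequence[BackboneModel]) -> List[Motif]:
    """4-residue windows straddling a helix C-terminus.

    The window starts at the last helical residue (position 1 of the
    motif) and must contain at least one backbone hydrogen bond from a
    window residue to the backbone of the helix's final turn (the four
    helical residues preceding the window)."""
    out: List[Motif] = []
    for model in models:
        m = model.copy()
        place_amide_hydrogens(m)
        bonds = detect_hbonds(m, "bb_bb")
        ss = assign_ss(m, bonds)
        partners = {}
        for hb in bonds:
            partners.setdefault(hb.donor[0], set()).add(hb.acceptor[0])
            partners.setdefault(hb.acceptor[0], set()).add(hb.donor[0])
        for i in range(len(m) - 3):
            if not _complete_window(m, i):
                continue
            if ss[i] != "H" or (i + 1 < len(m) and ss[i + 1] == "H"):
                continue  # i must be the last helical residue
            last_turn = set(range(max(0, i - 4), i + 1))
            hit = any(
                bool(partners.get(k, set()) & last_turn)
                for k in range(i, i + 4)
            )
            if hit:
                out.append(_window_motif(m, i, "helix_cap"))
    return out


# ---------------------------------------------------------------------------
# K-centers clustering
# ---------------------------------------------------------------------------

def fragment_rmsd(a: Motif, b: Motif) -> float:
    """Backbone RMSD (16 atoms) after optimal superposition."""
    _, r = geom.superpose_kabsch(a.backbone_coords(), b.backbone_coords())
    return r


def kcenters_cluster(fragments: Sequence[Motif], radius: float = DEFAULT_CLUSTER_RADIUS
                     ) -> MotifLibrary:
    """Greedy farthest-point K-centers clustering.

    The first fragment seeds cluster 1; the fragment farthest from all
    existing centers is promoted to a new center until every fragment
    lies within ``radius`` of some center; fragments are then assigned
    to their nearest center.  Deterministic for a fixed input order
    (ties break toward the lowest index).
    """
    if radius <= 0:
        raise ValueError("cluster radius must be positive")
    frags = list(fragments)
    if not frags:
        raise ValueError("cannot cluster an empty fragment set")
    n = len(frags)
    centers = [0]
    dist_to_center = np.array([fragment_rmsd(frags[0], f) for f in frags])
    nearest = np.zeros(n, dtype=int)
    while dist_to_center.max() > radius:
        far = int(np.argmax(dist_to_center))  # argmax returns lowest index on ties
        centers.append(far)
        d_new = np.array([fragment_rmsd(frags[far], f) for f in frags])
        closer = d_new < dist_to_center
        dist_to_center[closer] = d_new[closer]
        nearest[closer] = len(centers) - 1
    counts = [int((nearest == c).sum()) for c in range(len(centers))]
    reps = []
    for cid, idx in enumerate(centers):
        rep = dataclasses.replace(frags[idx], cluster_id=cid)
        reps.append(rep)
    kind = frags[0].kind
    return MotifLibrary(kind=kind, motifs=reps, cluster_radius=radius,
                        counts=counts)


def assign_to_centers(fragments: Sequence[Motif], library: MotifLibrary
                      ) -> List[int]:
    """Nearest-center assignment (index into ``library.motifs``)."""
    out = []
    for f in fragments:
        d = [fragment_rmsd(f, c) for c in library.motifs]
        out.append(int(np.argmin(d)))
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_library(library: MotifLibrary, path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "kind": library.kind,
        "cluster_radius": float(library.cluster_radius),
        "counts": [int(c) for c in library.counts],
        "motifs": [
            {
                "kind": m.kind,
                "cluster_id": m.cluster_id,
                "source": m.source,
                "torsions": [[round(float(t), 4) for t in tt] for tt in m.torsions],
                "coords": [[round(float(v), 4) for v in row] for row in m.coords],
            }
            for m in library.motifs
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_library(path) -> MotifLibrary:
    doc = yaml.safe_load(Path(path).read_text())
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"motif library schema version {doc.get('schema_version')} "
            f"not supported (expected {SCHEMA_VERSION})")
    motifs = [
        Motif(kind=d["kind"],
              torsions=[tuple(t) for t in d["torsions"]],
              coords=np.array(d["coords"], dtype=float),
              source=d.get("source", ""),
              cluster_id=d.get("cluster_id"))
        for d in doc["motifs"]
    ]
    lib = MotifLibrary(kind=doc["kind"], motifs=motifs,
                       cluster_radius=float(doc["cluster_radius"]),
                       counts=list(doc.get("counts", [])))
    if not lib.motifs:
        raise ValueError("motif library contains no motifs")
    return lib
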