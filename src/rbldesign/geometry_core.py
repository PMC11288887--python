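"""Rigid-body transforms, ideal backbone construction and superposition.

All internal angles are radians; public dataclass fields that a config
file would carry (:class:`SixDOF`, :class:`HelixParams`) are in degrees
and Å, the units a designer thinks in.

Bond lengths and angles follow the Engh–Huber idealization used for
crystallographic restraints; backbones built here therefore satisfy the
covalent-geometry invariants the rest of the package assumes.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .structure_model import BackboneModel, Residue

# Engh–Huber ideal backbone geometry (Å, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

#: Bondi van der Waals radii for the heavy elements we place
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

IDEAL_HELIX_PHI = -57.0
IDEAL_HELIX_PSI = -47.0


# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RigidTransform:
    """A proper rotation plus translation: x ↦ R·x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        R = self.rotation
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise ValueError("rotation must be proper (det +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)


def compose(t1: RigidTransform, t2: RigidTransform) -> RigidTransform:
    """Transform applying ``t2`` first, then ``t1``."""
    return RigidTransform(t1.rotation @ t2.rotation,
                          t1.rotation @ t2.translation + t1.translation)


def power(t: RigidTransform, k: int) -> RigidTransform:
    """k-fold self-composition (k ≥ 0)."""
    out = RigidTransform.identity()
    for _ in range(int(k)):
        out = compose(t, out)
    return out


def apply(t: RigidTransform, model: BackboneModel) -> BackboneModel:
    """Apply a rigid transform to every atom of a copy of ``model``."""
    out = model.copy()
    for res in out.residues:
        for name in res.atoms:
            res.atoms[name] = t.rotation @ res.atoms[name] + t.translation
    return out


@dataclasses.dataclass
class SixDOF:
    """Six rigid-body degrees of freedom: translation (Å) + intrinsic
    z–y–x Euler rotation (degrees)."""

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    rx: float = 0.0
    ry: float = 0.0
    rz: float = 0.0

    def to_transform(self) -> RigidTransform:
        R = Rotation.from_euler("ZYX", [self.rz, self.ry, self.rx],
                                degrees=True).as_matrix()
        return RigidTransform(R, np.array([self.tx, self.ty, self.tz]))

    @classmethod
    def from_transform(cls, t: RigidTransform) -> "SixDOF":
        rz, ry, rx = Rotation.from_matrix(t.rotation).as_euler("ZYX", degrees=True)
        tx, ty, tz = t.translation
        return cls(tx=tx, ty=ty, tz=tz, rx=rx, ry=ry, rz=rz)


@dataclasses.dataclass
class HelixParams:
    """Parameters of one ideal helix of the repeat unit."""

    length: int = 18          # residues; repeat sampling uses 12–28
    radius: float = 0.0       # Å displacement of the axis from z
    orientation: float = 0.0  # degrees, rotation about z after displacement


# ---------------------------------------------------------------------------
# internal-coordinate (NeRF) construction
# ---------------------------------------------------------------------------

def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Position atom d given predecessors a–b–c, |c–d|, ∠(b,c,d), ∠(a,b,c,d)."""
    angle = math.radians(angle_deg)
    dihedral = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(dihedral),
        bond * math.sin(angle) * math.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


def bond_angle(p0, p1, p2) -> float:
    """Angle at p1 in degrees."""
    u = p0 - p1
    v = p2 - p1
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(np.clip(c, -1.0, 1.0)))


def build_backbone(torsions: Sequence[Tuple[float, float, float]],
                   start: Optional[dict] = None) -> List[dict]:
    """Build backbone atoms (N, CA, C, O) from (φ, ψ, ω) triplets.

    ``torsions[i]`` gives residue i's φ and ψ and the ω of the peptide
    bond *following* it.  Residue 0's φ is ignored unless a ``start``
    frame (dict with N, CA, C of a virtual predecessor residue) is
    given, in which case the chain grows out of that anchor and residue
    0's φ is honored.

    Returns a list of atom dicts, one per residue.
    """
    n = len(torsions)
    res: List[dict] = [dict() for _ in range(n)]
    if start is None:
        # canonical seed frame
        res[0]["N"] = np.array([0.0, 0.0, 0.0])
        res[0]["CA"] = np.array([BOND_N_CA, 0.0, 0.0])
        ang = math.radians(ANGLE_N_CA_C)
        res[0]["C"] = res[0]["CA"] + BOND_CA_C * np.array(
            [-math.cos(ang), math.sin(ang), 0.0])
        first = 0
    else:
        prevN, prevCA, prevC = start["N"], start["CA"], start["C"]
        psi_prev = start.get("psi", 180.0)
        omega_prev = start.get("omega", 180.0)
        n0 = place_atom(prevN, prevCA, prevC, BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca0 = place_atom(prevCA, prevC, n0, BOND_N_CA, ANGLE_C_N_CA, omega_prev)
        c0 = place_atom(prevC, n0, ca0, BOND_CA_C, ANGLE_N_CA_C, torsions[0][0])
        res[0]["N"], res[0]["CA"], res[0]["C"] = n0, ca0, c0
        first = 0
    for i in range(n):
        phi_i, psi_i, omega_i = torsions[i]
        if i + 1 < n:
            phi_next = torsions[i + 1][0]
            Nn = place_atom(res[i]["N"], res[i]["CA"], res[i]["C"],
                            BOND_C_N, ANGLE_CA_C_N, psi_i)
            CAn = place_atom(res[i]["CA"], res[i]["C"], Nn,
                             BOND_N_CA, ANGLE_C_N_CA, omega_i)
            Cn = place_atom(res[i]["C"], Nn, CAn,
                            BOND_CA_C, ANGLE_N_CA_C, phi_next)
            res[i + 1]["N"], res[i + 1]["CA"], res[i + 1]["C"] = Nn, CAn, Cn
            # carbonyl O lies in the peptide plane, anti to the next N
            res[i]["O"] = place_atom(Nn, res[i]["CA"], res[i]["C"],
                                     BOND_C_O, ANGLE_CA_C_O, 180.0)
        else:
            # terminal O from ψ of the last residue
            res[i]["O"] = place_atom(res[i]["N"], res[i]["CA"], res[i]["C"],
                                     BOND_C_O, ANGLE_CA_C_O, psi_i - 180.0)
    return res


def atoms_to_model(atom_dicts: Sequence[dict], aa: str = "A",
                   provenance: str = "") -> BackboneModel:
    residues = [
        Residue(index=i + 1, aa=aa if len(aa) == 1 else aa[i],
                atoms={k: np.asarray(v, dtype=float) for k, v in d.items()})
        for i, d in enumerate(atom_dicts)
    ]
    return BackboneModel(residues=residues, provenance=provenance)


# ---------------------------------------------------------------------------
# torsion measurement / rebuild
# ---------------------------------------------------------------------------

def torsions(model: BackboneModel, i: int) -> Tuple[float, float, float]:
    """(φ, ψ, ω) of residue i (0-based), degrees; NaN where neighbors
    are missing, error across a declared chain break."""
    res = model.residues[i]
    phi = psi = omega = float("nan")
    if i > 0 and model.is_bonded(i - 1, i):
        prev = model.residues[i - 1]
        phi = dihedral(prev["C"], res["N"], res["CA"], res["C"])
    elif i > 0 and (i - 1) in model.breaks:
        pass
    if i + 1 < len(model.residues):
        if not model.is_bonded(i, i + 1):
            if i in model.breaks:
                return (phi, psi, omega)
        else:
            nxt = model.residues[i + 1]
            psi = dihedral(res["N"], res["CA"], res["C"], nxt["N"])
            omega = dihedral(res["CA"], res["C"], nxt["N"], nxt["CA"])
    return (phi, psi, omega)


def all_torsions(model: BackboneModel) -> List[Tuple[float, float, float]]:
    return [torsions(model, i) for i in range(len(model))]


def rebuild_from_torsions(torsion_list: Sequence[Tuple[float, float, float]],
                          start: Optional[dict] = None,
                          aa: str = "A") -> BackboneModel:
    """Rebuild an idealized backbone from (φ, ψ, ω) triplets.

    ω entries that are NaN (chain ends) are replaced by 180°, matching
    the fixed-ω convention used throughout loop construction.
    """
    cleaned = []
    for (phi, psi, omega) in torsion_list:
        cleaned.append((
            0.0 if math.isnan(phi) else phi,
            0.0 if math.isnan(psi) else psi,
            180.0 if math.isnan(omega) else omega,
        ))
    return atoms_to_model(build_backbone(cleaned, start=start), aa=aa,
                          provenance="rebuild_from_torsions")


# ---------------------------------------------------------------------------
# ideal helix
# ---------------------------------------------------------------------------

def helix_axis(ca: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Fit the helix axis: direction (unit, N→C) and a point on it.

    Uses the rotation-averaged local axis: for an ideal α-helix the
    bisector construction P(i) = CA(i-1) + CA(i+1) − 2·CA(i) points
    radially inward, so consecutive inward normals span the plane
    normal to the axis; the principal axis of the CA displacements
    gives the direction robustly for length ≥ 4.
    """
    ca = np.asarray(ca)
    d = ca - ca.mean(axis=0)
    # principal direction of the point cloud = helix axis for ≥1 turn
    _, _, vt = np.linalg.svd(d, full_matrices=False)
    axis = vt[0]
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    return axis, ca.mean(axis=0)


def _axis_center(ca: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Least-squares center of the helix circle in the plane ⟂ axis."""
    # build orthonormal frame (u, v, axis)
    u = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(u) < 1e-6:
        u = np.cross(axis, [0.0, 1.0, 0.0])
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    pts2 = np.stack([ca @ u, ca @ v], axis=1)
    # algebraic circle fit (Kåsa)
    A = np.column_stack([2 * pts2, np.ones(len(pts2))])
    b = (pts2 ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cu, cv = sol[0], sol[1]
    center3 = cu * u + cv * v
    return center3  # component of the axis line in the ⟂ plane


def make_ideal_helix(params: HelixParams, aa: str = "A") -> BackboneModel:
    """Build an ideal α-helix (φ −57°, ψ −47°, ω 180°).

    The helix is canonically framed: axis along +z (N-terminus at the
    bottom, z = 0), axis through the origin; then the whole helix is
    translated ``radius`` Å along +x and rotated ``orientation``
    degrees about z.
    """
    if params.length < 3:
        raise ValueError("helix needs at least 3 residues")
    tor = [(IDEAL_HELIX_PHI, IDEAL_HELIX_PSI, 180.0)] * params.length
    model = atoms_to_model(build_backbone(tor), aa=aa,
                           provenance=f"ideal_helix len={params.length}")
    ca = model.coords("CA")
    axis, _ = helix_axis(ca)
    center_perp = _axis_center(ca, axis)

    # rotation taking the fitted axis onto +z
    z = np.array([0.0, 0.0, 1.0])
    vcross = np.cross(axis, z)
    s = np.linalg.norm(vcross)
    c = np.dot(axis, z)
    if s < 1e-12:
        R = np.eye(3) if c > 0 else Rotation.from_euler("x", 180, degrees=True).as_matrix()
    else:
        vx = np.array([[0, -vcross[2], vcross[1]],
                       [vcross[2], 0, -vcross[0]],
                       [-vcross[1], vcross[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    T1 = RigidTransform(R, -R @ center_perp)
    model = apply(T1, model)
    zmin = model.coords("CA")[:, 2].min()
    model = apply(RigidTransform(np.eye(3), np.array([0.0, 0.0, -zmin])), model)
    place = compose(
        RigidTransform(Rotation.from_euler("z", params.orientation,
                                           degrees=True).as_matrix(), np.zeros(3)),
        RigidTransform(np.eye(3), np.array([params.radius, 0.0, 0.0])),
    )
    model = apply(place, model)
    model.provenance += f" r={params.radius} ori={params.orientation}"
    return model


# ---------------------------------------------------------------------------
# clash checking
# ---------------------------------------------------------------------------

def _atom_graph_positions(model: BackboneModel):
    """Flat atom list with (residue, name, coords, stem position, branch depth).

    Backbone atoms sit on the main chain at integer positions
    (N=3i, CA=3i+1, C=3i+2); O, H, CB and sidechain atoms hang off a
    stem atom at a branch depth, so the bond-count between two atoms is
    |stem1 − stem2| + depth1 + depth2 (exact for tree-shaped residues;
    ring closure in His/Phe shortens some intra-residue paths, which
    never affects inter-residue clash logic).
    """
    from .sidechains import BRANCH_DEPTH  # local import to avoid cycle

    names, coords, stems, depths, resids = [], [], [], [], []
    for i, res in enumerate(model.residues):
        for name, xyz in res.atoms.items():
            if name.startswith("H"):
                continue  # clash checking is heavy-atom only
            if name == "N":
                stem, depth = 3 * i, 0
            elif name == "CA":
                stem, depth = 3 * i + 1, 0
            elif name == "C":
                stem, depth = 3 * i + 2, 0
            elif name == "O":
                stem, depth = 3 * i + 2, 1
            elif name == "H":
                stem, depth = 3 * i, 1
            else:
                stem, depth = 3 * i + 1, BRANCH_DEPTH.get(name, 2)
            names.append(name)
            coords.append(xyz)
            stems.append(stem)
            depths.append(depth)
            resids.append(i)
    return (names, np.array(coords), np.array(stems), np.array(depths),
            np.array(resids))


def clash_check(model: BackboneModel, loop_range: Optional[Tuple[int, int]] = None,
                factor: float = 0.6) -> bool:
    """True iff any non-bonded heavy-atom pair (≥3 bonds apart) is closer
    than ``factor`` × the sum of Bondi van der Waals radii.

    ``loop_range`` (0-based, inclusive) restricts to pairs with at least
    one atom in that residue window.  Atoms across a declared chain
    break are never "bonded"; their graph separation is infinite.
    """
    names, coords, stems, depths, resids = _atom_graph_positions(model)
    if len(coords) == 0:
        return False
    radii = np.array([VDW_RADII.get(n[0], 1.7) if n != "H" else 1.0 for n in names])
    maxcut = factor * (radii.max() * 2)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(maxcut, output_type="ndarray")
    if len(pairs) == 0:
        return False
    i, j = pairs[:, 0], pairs[:, 1]
    if loop_range is not None:
        lo, hi = loop_range
        in_loop = ((resids[i] >= lo) & (resids[i] <= hi)) | \
                  ((resids[j] >= lo) & (resids[j] <= hi))
        i, j = i[in_loop], j[in_loop]
        if len(i) == 0:
            return False
    d = np.linalg.norm(coords[i] - coords[j], axis=1)
    close = d < factor * (radii[i] + radii[j])
    i, j, d = i[close], j[close], d[close]
    for a, b in zip(i, j):
        ra, rb = resids[a], resids[b]
        if ra == rb:
            if depths[a] >= 1 and depths[b] >= 1 and \
                    stems[a] == stems[b] == 3 * ra + 1:
                continue  # same sidechain branch: ideal template geometry
            sep = abs(stems[a] - stems[b]) + depths[a] + depths[b]
        elif abs(ra - rb) >= 1 and model.contiguous(min(ra, rb), max(ra, rb)):
            sep = abs(stems[a] - stems[b]) + depths[a] + depths[b]
        else:
            sep = 99
        if sep >= 3:
            return True
    return False


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def superpose_kabsch(mobile: np.ndarray, ref: np.ndarray
                     ) -> Tuple[RigidTransform, float]:
    """Optimal rigid superposition (Kabsch, SVD form).

    Returns the transform taking ``mobile`` onto ``ref`` and the
    minimal RMSD.  Collinear/degenerate point sets are flagged with a
    warning (the rotation is then not unique, the RMSD still is).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(ref, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    s = np.linalg.svd(P0, compute_uv=False)
    if s[1] < 1e-9 * max(1.0, s[0]):
        warnings.warn("degenerate (collinear) point set in superposition")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = P0 @ R.T - Q0
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return RigidTransform(R, t), rmsd


def rmsd_no_super(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a), np.asarray(b)
    return float(np.sqrt(((a - b) ** 2).sum() / len(a)))
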