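"""Coordinate data model and PDB input/output.

The package works on backbone-centric models: every residue carries at
least N, CA, C and O positions (in Å); amide hydrogens and sidechain
atoms are added by downstream modules.  Residues are stored 0-based
internally and serialized 1-based, following PDB convention.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: residues in these regions belong to helices of the repeat architecture
HELIX_REGIONS = frozenset({"helix1", "helix2", "cap"})

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


class PDBParseError(ValueError):
    """Raised when a coordinate file cannot be interpreted."""


@dataclasses.dataclass
class Residue:
    """One amino-acid position: a name and a map of atom coordinates."""

    index: int                      # 1-based sequential index
    aa: str = "A"                   # one-letter code
    atoms: Dict[str, np.ndarray] = dataclasses.field(default_factory=dict)
    repeat_unit: Optional[int] = None
    region: Optional[str] = None    # helix1 | loop_long | helix2 | loop_short | cap
    incomplete: bool = False

    def __getitem__(self, name: str) -> np.ndarray:
        return self.atoms[name]

    def __contains__(self, name: str) -> bool:
        return name in self.atoms

    def has_backbone(self) -> bool:
        return all(a in self.atoms for a in BACKBONE_ATOMS)

    def heavy_atoms(self) -> Iterable[tuple]:
        for name, xyz in self.atoms.items():
            if not name.startswith("H"):
                yield name, xyz

    def copy(self) -> "Residue":
        return Residue(
            index=self.index,
            aa=self.aa,
            atoms={k: v.copy() for k, v in self.atoms.items()},
            repeat_unit=self.repeat_unit,
            region=self.region,
            incomplete=self.incomplete,
        )


@dataclasses.dataclass
class BackboneModel:
    """An ordered chain of residues with optional repeat annotations.

    ``breaks`` holds the 0-based indices i for which there is *no*
    peptide bond between residue i and residue i+1 (declared chain
    breaks, e.g. between disconnected helices before loop closure).
    """

    residues: List[Residue] = dataclasses.field(default_factory=list)
    n_repeats: int = 0
    repeat_len: int = 0
    provenance: str = ""
    breaks: set = dataclasses.field(default_factory=set)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i: int) -> Residue:
        return self.residues[i]

    def __iter__(self):
        return iter(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def coords(self, atom: str = "CA") -> np.ndarray:
        """Stack one named atom per residue (residues missing it are skipped)."""
        return np.array([r.atoms[atom] for r in self.residues if atom in r.atoms])

    def heavy_coords(self) -> np.ndarray:
        pts = []
        for r in self.residues:
            for _, xyz in r.heavy_atoms():
                pts.append(xyz)
        return np.array(pts)

    def is_bonded(self, i: int, j: int) -> bool:
        """True if residues i and j (0-based) are peptide-bonded neighbors."""
        if abs(i - j) != 1:
            return False
        return min(i, j) not in self.breaks

    def contiguous(self, i: int, j: int) -> bool:
        """True if no chain break occurs in the residue window [i, j]."""
        return all(k not in self.breaks for k in range(i, j))

    def unit_indices(self, unit: int) -> List[int]:
        return [i for i, r in enumerate(self.residues) if r.repeat_unit == unit]

    def units(self) -> List[int]:
        seen = []
        for r in self.residues:
            if r.repeat_unit is not None and r.repeat_unit not in seen:
                seen.append(r.repeat_unit)
        return seen

    def copy(self) -> "BackboneModel":
        return BackboneModel(
            residues=[r.copy() for r in self.residues],
            n_repeats=self.n_repeats,
            repeat_len=self.repeat_len,
            provenance=self.provenance,
            breaks=set(self.breaks),
        )

    def renumber(self) -> None:
        for i, r in enumerate(self.residues):
            r.index = i + 1

    def validate_bonds(self, tol_lo: float = 1.2, tol_hi: float = 1.5) -> List[int]:
        """Return 0-based indices of undeclared breaks (C–N outside [lo, hi] Å)."""
        bad = []
        for i in range(len(self.residues) - 1):
            if i in self.breaks:
                continue
            a, b = self.residues[i], self.residues[i + 1]
            if "C" not in a or "N" not in b:
                continue
            d = float(np.linalg.norm(a["C"] - b["N"]))
            if not (tol_lo <= d <= tol_hi):
                bad.append(i)
        return bad


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def read_pdb(path, chain: Optional[str] = None) -> BackboneModel:
    """Read the first model of a PDB file into a :class:`BackboneModel`.

    Only ATOM records of standard amino acids are kept; altloc '' or 'A'
    wins; hydrogens are dropped (amide H is always rebuilt downstream).
    Residues missing any backbone atom are flagged ``incomplete`` and are
    excluded from geometric operations by callers.
    """
    import gemmi

    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # pragma: no cover - gemmi error text varies
        raise PDBParseError(f"cannot read {path}: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError(f"{path} contains no models")
    st.setup_entities()
    model = st[0]

    residues: List[Residue] = []
    prov_notes = []
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        for res in ch:
            if res.name not in _THREE_TO_ONE:
                continue
            atoms: Dict[str, np.ndarray] = {}
            for at in res:
                if at.altloc not in ("", "\x00", "A"):
                    logger.warning("dropping altloc %r of %s %s", at.altloc, res.name, res.seqid)
                    continue
                if at.element.is_hydrogen:
                    continue
                atoms[at.name] = np.array([at.pos.x, at.pos.y, at.pos.z], dtype=float)
            if not atoms:
                continue
            r = Residue(index=len(residues) + 1, aa=_THREE_TO_ONE[res.name], atoms=atoms)
            if not r.has_backbone():
                r.incomplete = True
            icode = res.seqid.icode.strip()
            if icode:
                prov_notes.append(f"{ch.name}{res.seqid.num}{icode}")
            residues.append(r)
        if chain is None and residues:
            break  # first chain only unless a chain id was requested

    if not residues:
        raise PDBParseError(f"no amino-acid ATOM records in {path}" +
                            (f" chain {chain}" if chain else ""))
    prov = f"read_pdb:{path.name}"
    if prov_notes:
        prov += " insertion_codes=" + ",".join(prov_notes)
    out = BackboneModel(residues=residues, provenance=prov)
    # undeclared discontinuities in experimental files become breaks
    for i in out.validate_bonds():
        out.breaks.add(i)
    return out


def write_pdb(model: BackboneModel, path) -> None:
    """Write fixed-width PDB v3.3 ATOM records (one chain, TER + END).

    Occupancy 1.00, B-factor 0.00, element column filled.  Residues are
    renumbered 1..N consecutively.
    """
    lines = []
    serial = 1
    last = None
    for i, res in enumerate(model.residues):
        res3 = _ONE_TO_THREE.get(res.aa.upper(), "ALA")
        names = [a for a in BACKBONE_ATOMS if a in res.atoms]
        names += [a for a in res.atoms if a not in BACKBONE_ATOMS]
        for name in names:
            if len(name) > 4:
                raise ValueError(f"atom name too long for PDB: {name!r}")
            xyz = res.atoms[name]
            element = name[0] if name[0] != "H" else "H"
            # column-13 alignment: 1-letter elements start in column 14
            aname = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {serial:5d} {aname}{'':1s}{res3:<3s} A{i + 1:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {element:>2s}"
            )
            serial += 1
        last = (serial, res3, i + 1)
    if last is not None:
        serial, res3, num = last
        lines.append(f"TER   {serial:5d}      {res3:<3s} A{num:4d}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
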