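"""Design-vs-experiment comparison: global and per-repeat-unit Cα RMSD.

The global number is the Kabsch-optimal Cα RMSD over all mapped
residues; per-unit numbers come from independent superpositions of
each repeat unit, which separates intra-unit accuracy from differences
in the inter-repeat transform (a designed solenoid can match each unit
at ~0.5 Å while the whole-model RMSD is several-fold larger purely
from curvature).
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .geometry_core import superpose_kabsch
from .structure_model import BackboneModel


@dataclasses.dataclass
class ComparisonReport:
    global_rmsd: float
    per_unit_rmsd: List[float]
    unit_mapping: List[Tuple[Tuple[int, int], Tuple[int, int]]]
    n_atoms_used: int


def _mapped_cas(design: BackboneModel, experimental: BackboneModel,
                mapping: Optional[Sequence[Tuple[int, int]]]
                ) -> Tuple[np.ndarray, np.ndarray, List[Tuple[int, int]]]:
    if mapping is None:
        n = min(len(design), len(experimental))
        mapping = [(i, i) for i in range(n)]
    pairs = [(i, j) for i, j in mapping
             if "CA" in design.residues[i] and "CA" in experimental.residues[j]]
    if len(pairs) < 3:
        raise ValueError("fewer than 3 mapped CA atoms")
    a = np.array([design.residues[i]["CA"] for i, _ in pairs])
    b = np.array([experimental.residues[j]["CA"] for _, j in pairs])
    return a, b, pairs


def compare(design: BackboneModel, experimental: BackboneModel,
            mapping: Optional[Sequence[Tuple[int, int]]] = None,
            units: Optional[Sequence[Tuple[int, int]]] = None
            ) -> ComparisonReport:
    """Superpose and report global + per-unit Cα RMSD.

    ``mapping`` pairs 0-based design/experimental residue indices
    (default: positional identity over the common length).  ``units``
    optionally lists (start, end) design-index ranges for per-unit
    superpositions; when absent, the design's repeat_unit labels are
    used.
    """
    a, b, pairs = _mapped_cas(design, experimental, mapping)
    _, global_rmsd = superpose_kabsch(a, b)

    if units is None:
        units = []
        for u in design.units():
            idx = design.unit_indices(u)
            if idx:
                units.append((idx[0], idx[-1]))
    per_unit = []
    unit_map = []
    lookup = dict(pairs)
    for (lo, hi) in units:
        sub = [(i, lookup[i]) for i in range(lo, hi + 1) if i in lookup]
        if len(sub) < 3:
            continue
        ua = np.array([design.residues[i]["CA"] for i, _ in sub])
        ub = np.array([experimental.residues[j]["CA"] for _, j in sub])
        _, r = superpose_kabsch(ua, ub)
        per_unit.append(r)
        unit_map.append(((lo, hi), (sub[0][1], sub[-1][1])))
    return ComparisonReport(global_rmsd=float(global_rmsd),
                            per_unit_rmsd=per_unit,
                            unit_mapping=unit_map,
                            n_atoms_used=len(pairs))


def compare_to_copies(design: BackboneModel,
                      copies: Sequence[BackboneModel]
                      ) -> Tuple[ComparisonReport, List[float]]:
    """Compare against every crystal copy; return the best report and
    the spread of global RMSDs (asymmetric units often hold several
    molecules)."""
    reports = [compare(design, c) for c in copies]
    rmsds = [r.global_rmsd for r in reports]
    best = reports[int(np.argmin(rmsds))]
    return best, rmsds
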