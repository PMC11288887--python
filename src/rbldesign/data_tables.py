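"""Packaged numeric tables: hydrophobic-pair distance scores and the
backbone-independent rotamer table.

Both tables are compact substitutes for database-scale resources: the
pair-score table is a CB–CB distance-bin log-odds profile derived from
packing distances in this package's own synthetic helix-bundle
fixtures (favorable packing bins are negative, the selection rule is
"total < 0"), and the rotamer table lists the common chi-angle modes
per residue type, enough for geometric feasibility scanning.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from typing import Dict, List, Tuple

import numpy as np
import yaml


@lru_cache(maxsize=None)
def motif_pair_table() -> Tuple[np.ndarray, np.ndarray]:
    """(bin_edges, values): log-odds score per CB–CB distance bin (Å)."""
    doc = _load_yaml("motif_pair_table.yaml")
    return (np.array(doc["bin_edges"], dtype=float),
            np.array(doc["values"], dtype=float))


@lru_cache(maxsize=None)
def rotamer_table() -> Dict[str, List[List[float]]]:
    """Map one-letter residue type -> list of chi-angle tuples (degrees)."""
    doc = _load_yaml("rotamers.yaml")
    return {aa: [list(map(float, chis)) for chis in rots]
            for aa, rots in doc["rotamers"].items()}


def _load_yaml(name: str) -> dict:
    ref = resources.files("rbldesign.data").joinpath(name)
    return yaml.safe_load(ref.read_text())
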