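"""Interactive-predictor construction: singles plus 2- and 3-way products.

A biomarker battery rarely responds one marker at a time; physiologically
coupled responses show up as co-variation that single markers miss.  The
feature set therefore contains every single biomarker plus the product of
every unordered pair and triple, each product entered as one predictor.
For nine biomarkers that is 9 + C(9,2) + C(9,3) = 9 + 36 + 84 = 129 columns.

By default each biomarker is z-scored across all units *before*
multiplication: raw activity levels span very different scales, and products
of raw values would be dominated by the largest-magnitude marker.  The raw
alternative is kept behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .dataset import BiomarkerDataset

__all__ = ["PredictorMatrix", "build_predictors", "predictor_label"]


def predictor_label(constituents: tuple[str, ...]) -> str:
    """Canonical display label, e.g. ``"AChEg x GPx x LPOdg"``."""
    return " x ".join(constituents)


@dataclass
class PredictorMatrix:
    """Units x predictors matrix with provenance labels.

    ``constituents[j]`` is the tuple of biomarkers multiplied into column j
    (length 1, 2 or 3); ``labels[j]`` is its display label.  ``center`` and
    ``scale`` record the per-biomarker standardisation applied before
    multiplication (empty dicts when standardisation was off).
    """

    values: np.ndarray
    labels: list[str]
    constituents: list[tuple[str, ...]]
    unit_ids: list
    center: dict[str, float] = field(default_factory=dict)
    scale: dict[str, float] = field(default_factory=dict)

    @property
    def n_predictors(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.labels,
                            index=pd.Index(self.unit_ids, name="unit_id"))

    def column(self, label_or_constituents) -> np.ndarray:
        if isinstance(label_or_constituents, tuple):
            label_or_constituents = predictor_label(label_or_constituents)
        j = self.labels.index(label_or_constituents)
        return self.values[:, j]

    def to_csv(self, path_or_buf=None):
        return self.to_frame().to_csv(path_or_buf)


def build_predictors(dataset: BiomarkerDataset,
                     standardize_first: bool = True,
                     max_order: int = 3) -> PredictorMatrix:
    """Build the interactive-predictor matrix from a unit-level dataset.

    Column order is canonical and stable: singles in battery order, then all
    unordered pairs, then all unordered triples, each in lexicographic
    constituent order.  With ``standardize_first`` each biomarker is z-scored
    (sample SD, ddof=1) across all units before any multiplication; a
    zero-variance biomarker is then an error naming the column.
    """
    names = dataset.biomarker_names
    if len(set(names)) != len(names):
        raise ValueError("duplicate biomarker names")
    X = dataset.values
    center: dict[str, float] = {}
    scale: dict[str, float] = {}
    if standardize_first:
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            raise ValueError(
                f"cannot standardize zero-variance biomarker {names[dead[0]]!r}")
        X = (X - mu) / sd
        center = dict(zip(names, mu.tolist()))
        scale = dict(zip(names, sd.tolist()))

    cols, labels, constituents = [], [], []
    for order in range(1, max_order + 1):
        for combo in combinations(range(len(names)), order):
            cols.append(np.prod(X[:, combo], axis=1))
            tup = tuple(names[i] for i in combo)
            constituents.append(tup)
            labels.append(predictor_label(tup))
    return PredictorMatrix(np.column_stack(cols), labels, constituents,
                           dataset.table["unit_id"].tolist(), center, scale)
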