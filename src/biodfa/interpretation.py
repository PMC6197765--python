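"""Interpretation layer: explained variance, predictor clustering, profiles
and temporal response trajectories.

After a canonical model is fitted, four views make it readable:

* cumulative percentage of explained variance per canonical function
  (lambda_i / sum lambda);
* hierarchical clustering of the retained predictors on their standardized
  coefficients over the significant functions, exported as a dendrogram
  (related predictors discriminate the groups in similar ways);
* per-predictor group profiles: one-way ANOVA + Duncan homogeneous-group
  letters across the pooled-control grouping, plus time-ordered mean +/- SE
  tables per concentration (the data behind a biomarker-profile figure);
* an integrated response index: the canonical-space distance of each
  (concentration, time) cell centroid from the pooled-control centroid.
  Because canonical scores are scaled to unit pooled within-group variance,
  Euclidean distance in canonical space is a Mahalanobis distance.  A
  trajectory whose distance keeps growing with exposure time is reported as
  "progressive"; one that falls back toward control after a peak is
  "recovery-consistent" (acclimation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .dataset import CONTROL_LABEL
from .dfa import CanonicalModel
from .features import PredictorMatrix
from .univariate import DegenerateDataError, duncan_groups, one_way_anova

__all__ = [
    "explained_variance", "cluster_predictors", "linkage_to_newick",
    "predictor_profiles", "response_trajectory", "PredictorDendrogram",
]


def explained_variance(eigenvalues) -> np.ndarray:
    """Cumulative percentage of between-group variance per canonical root.

    percentage_i = 100 * lambda_i / sum(lambda); the cumulative sequence is
    non-decreasing and ends at 100 (exactly, before any rounding).
    """
    lam = np.asarray(eigenvalues, float)
    if lam.size == 0 or lam.sum() <= 0:
        raise ValueError("explained variance undefined: no positive eigenvalue")
    return np.cumsum(100.0 * lam / lam.sum())


@dataclass
class PredictorDendrogram:
    """Agglomerative clustering of retained predictors on their standardized
    canonical coefficients."""

    labels: list[str]
    linkage: np.ndarray | None      # scipy linkage matrix; None for 1 leaf
    coordinates: np.ndarray         # predictors x functions used

    @property
    def merge_heights(self) -> np.ndarray:
        if self.linkage is None:
            return np.zeros(0)
        return self.linkage[:, 2]

    def leaf_order(self) -> list[str]:
        if self.linkage is None:
            return list(self.labels)
        order = sch.leaves_list(self.linkage)
        return [self.labels[i] for i in order]

    def to_newick(self) -> str:
        return linkage_to_newick(self.linkage, self.labels)


def cluster_predictors(model: CanonicalModel, n_functions: int | None = None,
                       method: str = "average") -> PredictorDendrogram:
    """Cluster the retained predictors by how they load on the significant
    canonical functions (Euclidean distance on standardized coefficients,
    UPGMA linkage by default).

    Canonical-axis signs were already fixed at fit time (largest-|weight|
    predictor positive per axis), so the distances are reproducible even
    though the sign of a canonical axis is mathematically arbitrary.
    """
    if model.empty or not model.predictor_labels:
        raise ValueError("cannot cluster predictors of an empty model")
    if n_functions is None:
        n_functions = max(model.n_significant_roots, 1)
    n_functions = min(n_functions, model.n_roots)
    coords = model.std_coefficients[:, :n_functions]
    labels = list(model.predictor_labels)
    if len(labels) == 1:
        return PredictorDendrogram(labels, None, coords)
    Z = sch.linkage(coords, method=method, metric="euclidean")
    return PredictorDendrogram(labels, Z, coords)


def linkage_to_newick(linkage: np.ndarray | None, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as Newick; branch lengths are the
    increments between successive merge heights."""
    if linkage is None:
        return f"{_esc(labels[0])}:0.0;"
    tree = sch.to_tree(linkage)

    def rec(node) -> tuple[str, float]:
        if node.is_leaf():
            return _esc(labels[node.id]), 0.0
        left, hl = rec(node.left)
        right, hr = rec(node.right)
        h = node.dist
        return (f"({left}:{h - hl:.6g},{right}:{h - hr:.6g})", h)

    body, _ = rec(tree)
    return body + ";"


def _esc(label: str) -> str:
    return label.replace(" ", "_").replace(",", "").replace("(", "").replace(")", "")


def predictor_profiles(pm: PredictorMatrix, grouping, predictors=None,
                       alpha: float = 0.05,
                       meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Group profiles of retained predictors.

    One row per (predictor, group): mean, SE, n, Duncan letter, plus the
    one-way ANOVA F and p of the predictor across grouping levels.  A
    (near-)constant predictor is reported as a single homogeneous group with
    F = 0.  If ``meta`` (treatment / time per unit) is given, rows carry the
    time ordering needed for a profile plot.
    """
    grouping = np.asarray(grouping, dtype=object)
    if predictors is None:
        predictors = list(pm.labels)
    rows = []
    for label in predictors:
        if label not in pm.labels:
            raise KeyError(f"unknown predictor {label!r}")
        x = pm.column(label)
        levels = list(pd.unique(grouping))
        if np.ptp(x) < 1e-12 * max(1.0, np.abs(x).max()):
            letters = {g: "a" for g in levels}
            F, p = 0.0, 1.0
        else:
            F, p, *_ = one_way_anova(x, grouping)
            try:
                letters = duncan_groups(x, grouping, alpha).as_dict()
            except DegenerateDataError:
                letters = {g: "a" for g in levels}
        for g in levels:
            xi = x[grouping == g]
            row = {"predictor": label, "group": g, "n": len(xi),
                   "mean": float(xi.mean()),
                   "se": float(xi.std(ddof=1) / np.sqrt(len(xi)))
                         if len(xi) > 1 else np.nan,
                   "duncan": letters[g], "anova_F": F, "anova_p": p}
            if meta is not None:
                sub = meta[grouping == g]
                row["treatment"] = sub["treatment"].iloc[0]
                row["time_days"] = int(sub["time_days"].iloc[0]) \
                    if sub["time_days"].nunique() == 1 else -1
            rows.append(row)
    return pd.DataFrame(rows)


def response_trajectory(model: CanonicalModel, X, grouping,
                        labels=None) -> pd.DataFrame:
    """Integrated response index per exposure cell.

    For every grouping level: the centroid on each significant canonical
    root and its Euclidean (= Mahalanobis, by score scaling) distance from
    the pooled-control centroid.  The control level has distance 0 by
    construction.  Per concentration the temporal trend is classified as
    "progressive" (distance at the last time exceeds the first) or
    "recovery-consistent" (distance falls back below its earlier peak).
    """
    if isinstance(X, PredictorMatrix):
        labels = X.labels
        X = X.values
    grouping = np.asarray(grouping, dtype=object)
    k = max(model.n_significant_roots, 1) if model.n_roots else 0
    scores = model.scores(X, labels=labels)[:, :k]
    ctrl = grouping == CONTROL_LABEL
    if not ctrl.any():
        raise ValueError("no pooled-control level in the grouping")
    ctrl_centroid = scores[ctrl].mean(axis=0) if k else np.zeros(0)
    rows = []
    for g in pd.unique(grouping):
        c = scores[grouping == g].mean(axis=0) if k else np.zeros(0)
        dist = float(np.linalg.norm(c - ctrl_centroid))
        row = {"group": g, "distance_from_control": dist}
        for r in range(k):
            row[f"root{r + 1}"] = float(c[r])
        if g != CONTROL_LABEL and "-" in str(g):
            treatment, day = str(g).rsplit("-", 1)
            row["treatment"], row["time_days"] = treatment, int(day)
        else:
            row["treatment"], row["time_days"] = str(g), -1
        rows.append(row)
    out = pd.DataFrame(rows)
    trends = {}
    for treatment, sub in out[out["group"] != CONTROL_LABEL].groupby("treatment"):
        sub = sub.sort_values("time_days")
        d = sub["distance_from_control"].to_numpy()
        if len(d) >= 2 and d[-1] < d.max() - 1e-12:
            trends[treatment] = "recovery-consistent"
        else:
            trends[treatment] = "progressive"
    out["trend"] = out["treatment"].map(trends).fillna("reference")
    return out
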