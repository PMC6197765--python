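"""Single-biomarker screening: Levene's test, balanced two-way ANOVA, Duncan.

This is the classical univariate pass over a biomarker battery before any
multivariate modelling: check variance homogeneity, test Treatment, Time and
their interaction in a full-factorial two-way ANOVA per biomarker, and use
one-way ANOVA plus Duncan's multiple range test to label homogeneous groups.

The two-way ANOVA is the textbook balanced decomposition (on a balanced
grid Type I/II/III sums of squares coincide).  Unbalanced layouts are
refused explicitly rather than silently reinterpreted.  Time-zero baseline
units are excluded from the factorial grid: they exist only for controls, so
a crossed Treatment x Time analysis is defined on the exposure times only
(a 3x3 grid with 3 replicates gives the (2, 18) / (4, 18) df pattern).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from .dataset import BiomarkerDataset

__all__ = [
    "AnovaResult", "HomogeneousGroups", "DegenerateDataError", "UnbalancedError",
    "levene_test", "two_way_anova", "balanced_two_way_F", "one_way_anova",
    "duncan_groups", "anova_screen_table",
]


class DegenerateDataError(ValueError):
    """Zero error variance (or similar) makes the requested test undefined."""


class UnbalancedError(ValueError):
    """The factorial grid is not balanced; the classical decomposition refuses."""


# ---------------------------------------------------------------------------
# Levene
# ---------------------------------------------------------------------------

def levene_test(values, groups) -> tuple[float, float]:
    """Levene's homogeneity-of-variance test with the group-mean center.

    W is the one-way ANOVA F computed on absolute deviations from the group
    means, referred to an F(k-1, N-k) distribution.  A dataset in which all
    absolute deviations are identical gives W = 0, p = 1.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in pd.unique(groups)]
    if len(samples) < 2:
        raise ValueError("Levene's test needs at least two groups")
    for s in samples:
        if len(s) < 2:
            raise ValueError("every group needs >= 2 observations")
    devs = np.concatenate([np.abs(s - s.mean()) for s in samples])
    if np.allclose(devs, devs.mean()):
        return 0.0, 1.0
    w, p = st.levene(*samples, center="mean")
    return float(w), float(p)


# ---------------------------------------------------------------------------
# balanced two-way ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """Per-effect F table for a balanced two-way factorial."""

    biomarker: str
    factor_a: str
    factor_b: str
    table: pd.DataFrame  # index: effect; columns: ss, df, ms, F, p
    df_error: int
    ss_error: float
    zero_error_variance: bool = False

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]

    @property
    def p_values(self) -> dict[str, float]:
        return {k: float(v) for k, v in self.table["p"].items()}


def balanced_two_way_F(y: np.ndarray) -> tuple[np.ndarray, np.ndarray, dict]:
    """Vectorised balanced two-way ANOVA.

    ``y`` has shape (..., a, b, n): leading axes are independent datasets,
    then factor-A level, factor-B level, replicate.  Returns ``(F, p, parts)``
    where F and p have shape (..., 3) ordered (A, B, AxB) and ``parts``
    carries the SS/df bookkeeping.
    """
    y = np.asarray(y, float)
    *lead, a, b, n = y.shape
    if min(a, b) < 2 or n < 2:
        raise ValueError("need >= 2 levels per factor and >= 2 replicates")
    grand = y.mean(axis=(-3, -2, -1), keepdims=True)
    cell = y.mean(axis=-1, keepdims=True)
    mean_a = y.mean(axis=(-2, -1), keepdims=True)
    mean_b = y.mean(axis=(-3, -1), keepdims=True)
    ss_a = (b * n) * ((mean_a - grand) ** 2).sum(axis=(-3, -2, -1))
    ss_b = (a * n) * ((mean_b - grand) ** 2).sum(axis=(-3, -2, -1))
    ss_ab = n * ((cell - mean_a - mean_b + grand) ** 2).sum(axis=(-3, -2, -1))
    ss_err = ((y - cell) ** 2).sum(axis=(-3, -2, -1))
    df = np.array([a - 1, b - 1, (a - 1) * (b - 1)])
    df_err = a * b * (n - 1)
    ss = np.stack([ss_a, ss_b, ss_ab], axis=-1)
    ms = ss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ms * df_err / ss_err[..., None]
    p = st.f.sf(F, df, df_err)
    # zero error SS: report F as +inf, p = 0 where the effect SS is positive
    zero = ss_err[..., None] == 0
    F = np.where(zero & (ss > 0), np.inf, F)
    p = np.where(zero & (ss > 0), 0.0, p)
    F = np.where(zero & (ss == 0), 0.0, F)
    p = np.where(zero & (ss == 0), 1.0, p)
    parts = {"ss": ss, "df": df, "ss_error": ss_err, "df_error": df_err,
             "ss_total": ss.sum(axis=-1) + ss_err}
    return F, p, parts


def two_way_anova(dataset: BiomarkerDataset, biomarker: str,
                  factor_a: str = "treatment", factor_b: str = "time_days",
                  drop_time_zero: bool = True) -> AnovaResult:
    """Full-factorial two-way ANOVA of one biomarker on a balanced grid.

    Raises :class:`UnbalancedError` if any cell is empty or cell counts
    differ, naming the cell.
    """
    if biomarker not in dataset.biomarker_names:
        raise ValueError(f"unknown biomarker {biomarker!r}")
    df = dataset.table
    if drop_time_zero and factor_b == "time_days":
        df = df[df["time_days"] != 0]
    a_levels = list(pd.unique(df[factor_a]))
    b_levels = list(pd.unique(df[factor_b]))
    counts = df.groupby([factor_a, factor_b]).size()
    for al in a_levels:
        for bl in b_levels:
            if (al, bl) not in counts.index:
                raise UnbalancedError(f"empty cell ({al}, {bl})")
    if counts.nunique() != 1:
        bad = counts.idxmin()
        raise UnbalancedError(
            f"unbalanced design: cell {bad} has {counts.min()} units, "
            f"others up to {counts.max()}")
    n = int(counts.iloc[0])
    if n < 2:
        raise UnbalancedError("need >= 2 replicates per cell")
    y = np.empty((len(a_levels), len(b_levels), n))
    for i, al in enumerate(a_levels):
        for j, bl in enumerate(b_levels):
            y[i, j] = df.loc[(df[factor_a] == al) & (df[factor_b] == bl),
                             biomarker].to_numpy()
    F, p, parts = balanced_two_way_F(y)
    effects = [factor_a.capitalize(), factor_b.capitalize().replace("_days", ""),
               f"{factor_a.capitalize()} x {factor_b.capitalize().replace('_days', '')}"]
    table = pd.DataFrame({
        "ss": parts["ss"], "df": parts["df"],
        "ms": parts["ss"] / parts["df"], "F": F, "p": p,
    }, index=pd.Index(effects, name="effect"))
    return AnovaResult(biomarker, factor_a, factor_b, table,
                       df_error=int(parts["df_error"]),
                       ss_error=float(parts["ss_error"]),
                       zero_error_variance=bool(parts["ss_error"] == 0))


def anova_screen_table(dataset: BiomarkerDataset, alpha: float = 0.05,
                       **kwargs) -> pd.DataFrame:
    """Screen every biomarker: one row per (biomarker, effect), columns
    df / F / p plus a significance flag — the layout of a published two-way
    ANOVA summary table."""
    rows = []
    for b in dataset.biomarker_names:
        res = two_way_anova(dataset, b, **kwargs)
        for effect, r in res.table.iterrows():
            rows.append({
                "biomarker": b, "effect": effect,
                "df": f"{int(r['df'])}, {res.df_error}",
                "F": r["F"], "p": r["p"], "significant": r["p"] < alpha,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# one-way ANOVA + Duncan's multiple range test
# ---------------------------------------------------------------------------

def one_way_anova(values, groups):
    """One-way ANOVA; returns (F, p, ms_error, df_error, means, counts)."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("one-way ANOVA needs >= 2 groups")
    samples = [values[groups == g] for g in levels]
    means = np.array([s.mean() for s in samples])
    counts = np.array([len(s) for s in samples])
    if (counts < 2).any():
        raise ValueError("every group needs >= 2 observations")
    grand = values.mean()
    ss_b = float((counts * (means - grand) ** 2).sum())
    ss_w = float(sum(((s - m) ** 2).sum() for s, m in zip(samples, means)))
    df_b, df_w = len(levels) - 1, len(values) - len(levels)
    ms_w = ss_w / df_w
    if ms_w == 0:
        if ss_b == 0:
            F, p = 0.0, 1.0
        else:
            F, p = np.inf, 0.0
    else:
        F = (ss_b / df_b) / ms_w
        p = float(st.f.sf(F, df_b, df_w))
    return F, p, ms_w, df_w, dict(zip(levels, means)), dict(zip(levels, counts))


@dataclass
class HomogeneousGroups:
    """Duncan multiple-range grouping: group labels ordered by mean, the
    letter set of each, and the protection level used."""

    levels: list            # group labels sorted by ascending mean
    means: np.ndarray       # sorted means
    letters: list[str]      # letter string per sorted group
    alpha: float

    def as_dict(self) -> dict:
        return dict(zip(self.levels, self.letters))


def _duncan_critical_range(alpha: float, span: int, df_err: int,
                           ms_err: float, n_harm: float) -> float:
    # Duncan's protection level for a span of r means: 1 - (1-alpha)^(r-1)
    q = st.studentized_range.ppf((1.0 - alpha) ** (span - 1), span, df_err)
    return float(q * np.sqrt(ms_err / n_harm))


def duncan_groups(values, groups, alpha: float = 0.05) -> HomogeneousGroups:
    """Duncan's multiple range test over a one-way layout.

    Means are sorted; the range of every window of r consecutive ordered
    means is compared against Duncan's least significant range (studentized
    range quantile at protection level 1-(1-alpha)^(r-1)).  Step-down rule:
    a window inside a window already declared homogeneous is not subdivided.
    Letters mark the maximal homogeneous windows; groups sharing a letter are
    not significantly different.  Unequal group sizes use the harmonic mean n.
    """
    F, p, ms_w, df_w, means_d, counts_d = one_way_anova(values, groups)
    if ms_w == 0:
        raise DegenerateDataError(
            "within-group variance is zero; Duncan ranges are undefined")
    order = sorted(means_d, key=means_d.get)
    m = np.array([means_d[g] for g in order])
    counts = np.array([counts_d[g] for g in order])
    k = len(order)
    n_harm = k / (1.0 / counts).sum()

    # homogeneous[i][j]: ordered means i..j (i<j) declared indistinguishable
    homogeneous = np.zeros((k, k), bool)
    for span in range(k, 1, -1):
        lsr = _duncan_critical_range(alpha, span, df_w, ms_w, n_harm)
        for i in range(0, k - span + 1):
            j = i + span - 1
            if homogeneous[i, j]:
                continue
            covered = any(homogeneous[a, b]
                          for a in range(0, i + 1)
                          for b in range(j, k)
                          if (a, b) != (i, j) and b - a > j - i)
            if covered or (m[j] - m[i]) < lsr:
                homogeneous[i, j] = True
    # maximal homogeneous intervals (singletons fill the gaps)
    intervals = []
    for i in range(k):
        for j in range(i + 1, k):
            if homogeneous[i, j]:
                intervals.append((i, j))
    maximal = [iv for iv in intervals
               if not any(o != iv and o[0] <= iv[0] and iv[1] <= o[1]
                          for o in intervals)]
    covered_pts = set()
    for i, j in maximal:
        covered_pts.update(range(i, j + 1))
    for i in range(k):
        if i not in covered_pts:
            maximal.append((i, i))
    maximal.sort()
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = ["" for _ in range(k)]
    for letter, (i, j) in zip(alphabet, maximal):
        for t in range(i, j + 1):
            letters[t] += letter
    return HomogeneousGroups(order, m, letters, alpha)
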