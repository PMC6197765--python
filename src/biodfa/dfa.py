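"""Canonical discriminant function analysis with forward stepwise entry.

Given a units x predictors matrix and a grouping factor with g levels, CDA
solves the generalized eigenproblem B a = lambda W a, where W and B are the
within- and between-group scatter matrices.  Each eigenvector defines one
canonical root (discriminant function); its eigenvalue lambda measures the
between/within separation along that axis, the canonical correlation is
R = sqrt(lambda/(1+lambda)), and Wilks' Lambda for the residual root set
{k, k+1, ...} is prod 1/(1+lambda_i), tested with Bartlett's chi-square
approximation

    chi2_k = -(N - 1 - (p + g)/2) * ln(Lambda_k),   df_k = (p-k)(g-k-1).

Predictors are entered forward, one at a time: at each step the candidate
with the smallest partial Wilks' Lambda (largest F-to-enter,
F = ((n-g-q)/(g-1)) * (1-L)/L on (g-1, n-g-q) df with q predictors already
in) is added if its p-to-enter clears the threshold and a sweep-pivot
tolerance guard passes.  There is no backward removal step.  Selection halts
before the within-scatter rank bound q >= N - g.

Classification uses linear classification functions (pooled within-group
covariance, group means, log priors); priors are the observed group
frequencies unless overridden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.stats as st

__all__ = [
    "CanonicalModel", "StepwiseTrace", "SingularWithinError",
    "scatter_matrices", "canonical_solve", "root_tests", "stepwise_dfa",
    "fit_canonical", "standardized_coefficients",
]


class SingularWithinError(np.linalg.LinAlgError):
    """Within-group scatter is numerically singular on the selected
    predictors; reduce the predictor cap or tighten the entry tolerance."""


# ---------------------------------------------------------------------------
# scatter matrices and the eigenproblem
# ---------------------------------------------------------------------------

def _group_index(y) -> tuple[list, list[np.ndarray]]:
    y = np.asarray(y)
    levels = list(pd.unique(y))
    return levels, [np.flatnonzero(y == g) for g in levels]


def scatter_matrices(X, y) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Within (W), between (B) and total (T = W + B) scatter matrices."""
    X = np.asarray(X, float)
    levels, idx = _group_index(y)
    for g, ii in zip(levels, idx):
        if len(ii) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 units")
    grand = X.mean(axis=0)
    W = np.zeros((X.shape[1],) * 2)
    B = np.zeros_like(W)
    for ii in idx:
        Xi = X[ii]
        mu = Xi.mean(axis=0)
        D = Xi - mu
        W += D.T @ D
        d = mu - grand
        B += len(ii) * np.outer(d, d)
    return W, B, W + B


def canonical_solve(W: np.ndarray, B: np.ndarray, n_units: int,
                    n_groups: int) -> tuple[np.ndarray, np.ndarray]:
    """Solve B a = lambda W a; return descending eigenvalues and raw
    coefficients scaled so each canonical score has pooled within-group
    variance 1.  At most min(p, g-1) roots are returned."""
    p = W.shape[0]
    m = min(p, n_groups - 1)
    try:
        evals, evecs = sla.eigh(B, W)
    except (np.linalg.LinAlgError, sla.LinAlgError) as exc:
        raise SingularWithinError(str(exc)) from exc
    order = np.argsort(evals)[::-1][:m]
    lam = np.clip(evals[order], 0.0, None)
    A = evecs[:, order]            # a' W a = 1
    A = A * np.sqrt(n_units - n_groups)   # score within-group variance = 1
    return lam, A


def root_tests(eigenvalues, N: int, p: int, g: int,
               alpha: float = 0.05) -> pd.DataFrame:
    """Bartlett's sequential chi-square tests of the residual canonical roots.

    Row k tests whether roots k..m-1 jointly carry significant separation;
    the "significant roots" count is the longest leading run with p < alpha.
    """
    lam = np.asarray(eigenvalues, float)
    if N <= p + g:
        warnings.warn("Bartlett approximation is unreliable for N <= p + g",
                      stacklevel=2)
    rows = []
    c = N - 1 - (p + g) / 2.0
    for k in range(len(lam)):
        wilks = float(np.prod(1.0 / (1.0 + lam[k:])))
        chi2 = -c * np.log(wilks) if wilks > 0 else np.inf
        df = (p - k) * (g - k - 1)
        pval = float(st.chi2.sf(chi2, df)) if df > 0 else 1.0
        rows.append({"root": k, "eigenvalue": float(lam[k]),
                     "canonical_R": float(np.sqrt(lam[k] / (1.0 + lam[k]))),
                     "wilks_lambda": wilks, "chi_square": float(chi2),
                     "df": df, "p": pval})
    out = pd.DataFrame(rows)
    sig = 0
    for pval in out["p"]:
        if pval < alpha:
            sig += 1
        else:
            break
    out.attrs["n_significant"] = sig
    return out


# ---------------------------------------------------------------------------
# forward stepwise selection
# ---------------------------------------------------------------------------

@dataclass
class StepwiseTrace:
    """Entry history: one row per step with the entered predictor, its
    partial Wilks' Lambda, F-to-enter, p-to-enter and the model Lambda."""

    table: pd.DataFrame
    stopped_because: str

    def __len__(self) -> int:
        return len(self.table)


def _forward_select(W, T, labels, n, g, p_enter, tolerance, cap):
    """Forward entry on precomputed full scatter matrices.

    Per step, for every candidate j the partial Wilks' Lambda ratio is the
    Schur-complement pivot ratio pW_j / pT_j, obtained with one Cholesky
    factorization of the selected blocks and vectorised solves.
    """
    P = W.shape[0]
    selected: list[int] = []
    rows = []
    log_lambda = 0.0
    diagW = np.diag(W).copy()
    stopped = "no candidate met the entry criterion"
    while len(selected) < cap:
        q = len(selected)
        cand = np.array([j for j in range(P) if j not in selected])
        if cand.size == 0:
            stopped = "all predictors entered"
            break
        if q == 0:
            pW = diagW[cand].copy()
            pT = np.diag(T)[cand].copy()
        else:
            S = np.ix_(selected, cand)
            SS = np.ix_(selected, selected)
            try:
                cW = sla.cho_factor(W[SS], lower=True)
                cT = sla.cho_factor(T[SS], lower=True)
            except (np.linalg.LinAlgError, sla.LinAlgError) as exc:
                raise SingularWithinError(
                    "within-scatter became singular during forward entry; "
                    "lower max_predictors or raise the tolerance") from exc
            aW = sla.cho_solve(cW, W[S])
            aT = sla.cho_solve(cT, T[S])
            pW = diagW[cand] - np.einsum("ij,ij->j", W[S], aW)
            pT = np.diag(T)[cand] - np.einsum("ij,ij->j", T[S], aT)
        with np.errstate(divide="ignore", invalid="ignore"):
            tol_j = pW / diagW[cand]
        ok = (pW > 0) & (pT > 0) & (tol_j > tolerance)
        if not ok.any():
            stopped = "tolerance guard excluded all remaining candidates"
            break
        lam_ratio = np.where(ok, pW / pT, np.inf)
        lam_ratio = np.minimum(lam_ratio, 1.0)
        df2 = n - g - q
        if df2 < 1:
            stopped = "within-scatter rank bound reached"
            break
        with np.errstate(divide="ignore"):
            F = (df2 / (g - 1.0)) * (1.0 - lam_ratio) / lam_ratio
        F = np.where(ok, F, -np.inf)
        best = int(np.argmax(F))        # ties: first in canonical column order
        pval = float(st.f.sf(F[best], g - 1, df2))
        if not (pval < p_enter):
            break
        j = int(cand[best])
        selected.append(j)
        log_lambda += float(np.log(lam_ratio[best]))
        rows.append({"step": q + 1, "predictor": labels[j],
                     "partial_lambda": float(lam_ratio[best]),
                     "F_to_enter": float(F[best]), "p_to_enter": pval,
                     "model_lambda": float(np.exp(log_lambda))})
    else:
        stopped = "predictor cap reached"
    trace = StepwiseTrace(pd.DataFrame(
        rows, columns=["step", "predictor", "partial_lambda", "F_to_enter",
                       "p_to_enter", "model_lambda"]), stopped)
    return selected, trace


# ---------------------------------------------------------------------------
# the fitted model
# ---------------------------------------------------------------------------

@dataclass
class CanonicalModel:
    """A fitted (possibly stepwise-selected) canonical discriminant model."""

    predictor_labels: list[str]          # entry order
    groups: list                          # group levels, first-appearance order
    priors: np.ndarray                    # observed frequencies (sum to 1)
    eigenvalues: np.ndarray               # descending
    raw_coefficients: np.ndarray          # selected predictors x roots
    std_coefficients: np.ndarray          # scaled by pooled within-group SD
    within_sd: np.ndarray                 # pooled within-group SD per predictor
    root_table: pd.DataFrame              # Bartlett tests per root
    n_significant_roots: int
    centroids: np.ndarray                 # groups x roots, canonical space
    class_coef: np.ndarray                # groups x predictors
    class_const: np.ndarray               # groups
    n_units: int
    alpha: float
    empty: bool = False
    trace: StepwiseTrace | None = None
    _label_pos: dict = field(default_factory=dict, repr=False)

    # ------------------------------------------------------------ properties
    @property
    def n_roots(self) -> int:
        return len(self.eigenvalues)

    @property
    def canonical_correlations(self) -> np.ndarray:
        lam = self.eigenvalues
        return np.sqrt(lam / (1.0 + lam))

    @property
    def wilks_lambda(self) -> float:
        return float(np.prod(1.0 / (1.0 + self.eigenvalues)))

    @property
    def explained_variance_pct(self) -> np.ndarray:
        lam = self.eigenvalues
        return 100.0 * lam / lam.sum() if lam.sum() > 0 else np.zeros_like(lam)

    # ---------------------------------------------------------------- scoring
    def _subset(self, X, labels=None) -> np.ndarray:
        X = np.asarray(X, float)
        if labels is None:
            if X.ndim == 1:
                X = X[None, :]
            if X.shape[1] == len(self.predictor_labels):
                return X
            raise ValueError("pass `labels` to map a wider matrix onto the "
                             "selected predictors")
        pos = [labels.index(l) for l in self.predictor_labels]
        if X.ndim == 1:
            X = X[None, :]
        return X[:, pos]

    def scores(self, X, labels=None) -> np.ndarray:
        """Canonical scores (units x roots)."""
        if self.empty:
            return np.zeros((np.atleast_2d(X).shape[0], 0))
        return self._subset(X, labels) @ self.raw_coefficients

    def predict(self, X, labels=None) -> tuple[np.ndarray, np.ndarray]:
        """Classify units: returns (predicted labels, posterior matrix).

        Ties on the classification score are broken by the higher prior,
        then by group order.
        """
        n = np.atleast_2d(np.asarray(X, float)).shape[0]
        if self.empty:
            post = np.tile(self.priors, (n, 1))
        else:
            Z = self._subset(X, labels)
            s = Z @ self.class_coef.T + self.class_const
            s -= s.max(axis=1, keepdims=True)
            post = np.exp(s)
            post /= post.sum(axis=1, keepdims=True)
        pred = []
        for row in post:
            best = row.max()
            tied = np.flatnonzero(row >= best - 1e-12)
            if len(tied) > 1:
                tied = tied[self.priors[tied] >= self.priors[tied].max() - 1e-12]
            pred.append(self.groups[int(tied[0])])
        return np.array(pred, dtype=object), post

    def classify(self, x, labels=None):
        """Single-unit classification: (group label, posterior dict)."""
        pred, post = self.predict(np.atleast_2d(x), labels)
        return pred[0], dict(zip(self.groups, post[0]))


def standardized_coefficients(raw_coef: np.ndarray,
                              within_sd: np.ndarray) -> np.ndarray:
    """Raw discriminant weights rescaled by each predictor's pooled
    within-group SD, making weights comparable across predictors."""
    return raw_coef * within_sd[:, None]


def _orient_signs(std_coef, raw_coef, centroids):
    """Fix the arbitrary sign of each canonical axis: the largest-|weight|
    predictor gets a positive standardized coefficient."""
    for r in range(std_coef.shape[1]):
        j = int(np.argmax(np.abs(std_coef[:, r])))
        if std_coef[j, r] < 0:
            std_coef[:, r] *= -1
            raw_coef[:, r] *= -1
            centroids[:, r] *= -1
    return std_coef, raw_coef, centroids


def fit_canonical(X, y, labels: list[str], selected: list[int],
                  trace: StepwiseTrace | None = None, alpha: float = 0.05,
                  priors=None) -> CanonicalModel:
    """Fit the canonical model on an explicit predictor subset."""
    X = np.asarray(X, float)
    levels, idx = _group_index(y)
    g = len(levels)
    n = X.shape[0]
    counts = np.array([len(ii) for ii in idx], float)
    pri = counts / n if priors is None else np.asarray(priors, float)
    pri = pri / pri.sum()

    if not selected:
        return CanonicalModel(
            predictor_labels=[], groups=levels, priors=pri,
            eigenvalues=np.zeros(0), raw_coefficients=np.zeros((0, 0)),
            std_coefficients=np.zeros((0, 0)), within_sd=np.zeros(0),
            root_table=pd.DataFrame(), n_significant_roots=0,
            centroids=np.zeros((g, 0)), class_coef=np.zeros((g, 0)),
            class_const=np.log(pri), n_units=n, alpha=alpha, empty=True,
            trace=trace)

    Xs = X[:, selected]
    W, B, T = scatter_matrices(Xs, y)
    lam, A = canonical_solve(W, B, n, g)
    within_sd = np.sqrt(np.diag(W) / (n - g))
    std = standardized_coefficients(A, within_sd)
    mus = np.vstack([Xs[ii].mean(axis=0) for ii in idx])
    centroids = mus @ A
    std, A, centroids = _orient_signs(std, A, centroids)

    p_sel = len(selected)
    table = root_tests(lam, n, p_sel, g, alpha)

    S = W / (n - g)
    try:
        Sinv_mu = np.linalg.solve(S, mus.T).T
    except np.linalg.LinAlgError as exc:
        raise SingularWithinError(str(exc)) from exc
    const = -0.5 * np.einsum("ij,ij->i", mus, Sinv_mu) + np.log(pri)

    return CanonicalModel(
        predictor_labels=[labels[j] for j in selected], groups=levels,
        priors=pri, eigenvalues=lam, raw_coefficients=A,
        std_coefficients=std, within_sd=within_sd, root_table=table,
        n_significant_roots=int(table.attrs["n_significant"]),
        centroids=centroids, class_coef=Sinv_mu, class_const=const,
        n_units=n, alpha=alpha, trace=trace)


def stepwise_dfa(X, y, labels: list[str] | None = None, p_enter: float = 0.05,
                 tolerance: float = 1e-7, max_predictors: int | None = None,
                 alpha: float = 0.05) -> CanonicalModel:
    """Forward-stepwise canonical DFA.

    ``X`` may be a :class:`~biodfa.features.PredictorMatrix` or a plain
    units x predictors array (then ``labels`` names the columns).  An empty
    model (no candidate qualifies at step 1) is returned flagged, not raised.
    """
    from .features import PredictorMatrix
    if isinstance(X, PredictorMatrix):
        labels = X.labels
        X = X.values
    X = np.asarray(X, float)
    if labels is None:
        labels = [f"x{j}" for j in range(X.shape[1])]
    if not 0.0 < p_enter <= 1.0:
        raise ValueError("p_enter must be in (0, 1]")
    levels, idx = _group_index(y)
    g = len(levels)
    if g < 2:
        raise ValueError("need >= 2 groups")
    n = X.shape[0]
    cap = max_predictors if max_predictors is not None else n - g - 1
    cap = min(cap, X.shape[1], n - g - 1)
    W, B, T = scatter_matrices(X, y)
    selected, trace = _forward_select(W, T, labels, n, g, p_enter,
                                      tolerance, cap)
    return fit_canonical(X, y, labels, selected, trace=trace, alpha=alpha)
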