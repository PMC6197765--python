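"""Repeated leave-group-out cross-validation of the stepwise model.

The validation routine mirrors a repeated-holdout design: in each round a
small holdout (default 3 units, 10% of the default 30-unit study) is drawn
at random, the *entire* stepwise selection and model fit are re-run on the
remaining units, and the held-out units are classified with that
recalculated model — so no information leaks from the full-data fit into the
validation classifications.  With the default 54 rounds x 3 held-out units
the report aggregates 162 validation classifications.

Holdouts are drawn without replacement within a round and independently
across rounds; a draw that would leave any group with fewer than 2 training
units is redrawn (and counted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dfa import stepwise_dfa
from .features import PredictorMatrix

__all__ = ["CrossValidationReport", "cross_validate", "percent_correct"]


def percent_correct(predictions, truth) -> float:
    """Percent of correct diagnostics: 100 x matches / total."""
    predictions = np.asarray(predictions, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if len(predictions) != len(truth):
        raise ValueError("predictions and truth differ in length")
    if len(truth) == 0:
        raise ValueError("cannot score an empty set of classifications")
    return 100.0 * float(np.mean(predictions == truth))


@dataclass
class CrossValidationReport:
    """Per-round holdout classifications plus aggregate percent-correct."""

    rounds: pd.DataFrame          # round, unit_id, true, predicted
    round_summaries: pd.DataFrame  # round, n_selected, train_pct_correct
    holdout_size: int
    n_rounds: int
    redraws: int

    @property
    def total_validation_classifications(self) -> int:
        return len(self.rounds)

    @property
    def validation_percent_correct(self) -> float:
        return percent_correct(self.rounds["predicted"], self.rounds["true"])

    @property
    def analysis_percent_correct(self) -> float:
        """Mean training-sample percent correct across rounds."""
        return float(self.round_summaries["train_pct_correct"].mean())

    def summary(self) -> dict:
        return {
            "rounds": self.n_rounds,
            "holdout_size": self.holdout_size,
            "validation_samples": self.total_validation_classifications,
            "analysis_pct_correct": self.analysis_percent_correct,
            "validation_pct_correct": self.validation_percent_correct,
            "redraws": self.redraws,
        }


def _draw_holdout(rng, y, holdout_size, max_attempts=10_000):
    n = len(y)
    y = np.asarray(y, dtype=object)
    for attempt in range(max_attempts):
        held = rng.choice(n, size=holdout_size, replace=False)
        remaining = np.delete(np.arange(n), held)
        counts = pd.Series(y[remaining]).value_counts()
        full = pd.Series(y).value_counts()
        if (counts.reindex(full.index, fill_value=0) >= 2).all():
            return np.sort(held), attempt
    raise ValueError("impossible stratification: could not draw a holdout "
                     "leaving >= 2 units in every group")


def cross_validate(X, y, holdout_size: int = 3, rounds: int = 54,
                   seed: int | None = None, unit_ids=None,
                   p_enter: float = 0.05, **fit_kwargs) -> CrossValidationReport:
    """Repeated-holdout cross-validation with full stepwise refits.

    Returns a report whose total number of validation classifications is
    exactly ``rounds * holdout_size``.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    labels = None
    if isinstance(X, PredictorMatrix):
        labels = X.labels
        if unit_ids is None:
            unit_ids = X.unit_ids
        X = X.values
    X = np.asarray(X, float)
    if labels is None:
        labels = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=object)
    if holdout_size >= len(y):
        raise ValueError("holdout_size must be smaller than the dataset")
    if unit_ids is None:
        unit_ids = list(range(len(y)))
    rng = np.random.default_rng(seed)

    rows, summaries = [], []
    redraws = 0
    for r in range(rounds):
        held, attempts = _draw_holdout(rng, y, holdout_size)
        redraws += attempts
        train = np.delete(np.arange(len(y)), held)
        model = stepwise_dfa(X[train], y[train], labels=labels,
                             p_enter=p_enter, **fit_kwargs)
        train_pred, _ = model.predict(X[train], labels=labels)
        val_pred, _ = model.predict(X[held], labels=labels)
        summaries.append({
            "round": r + 1,
            "n_selected": len(model.predictor_labels),
            "train_pct_correct": percent_correct(train_pred, y[train]),
        })
        for i, j in enumerate(held):
            rows.append({"round": r + 1, "unit_id": unit_ids[j],
                         "true": y[j], "predicted": val_pred[i]})
    return CrossValidationReport(
        rounds=pd.DataFrame(rows),
        round_summaries=pd.DataFrame(summaries),
        holdout_size=holdout_size, n_rounds=rounds, redraws=redraws)
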