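"""Synthetic factorial biomarker datasets with plantable interaction signals.

Emulates the structure of a semi-static exposure study: replicate aquaria per
treatment (control, low C1, high C2) and sampling time (7, 14, 21 days), plus
a time-zero baseline set drawn from the acclimation stock, i.e. control only.
Aquarium means are the statistical units, so with 3 replicates the default
grid yields 30 units (3 treatments x 3 exposure times x 3 replicates + 3
time-zero controls).

The generator's distinguishing feature is the *interaction-only* signal: a
group-mean shift of the product of k biomarkers that leaves every marginal
group mean (and, for k=3, every pairwise product mean) exactly unchanged in
expectation.  This is the data-generating scenario under which products of
biomarkers carry diagnostic information that single-marker screening cannot
see.

Construction: for each unit in the affected cell, draw a sign vector
(s_1..s_k) uniformly on {-1,+1}^k conditioned on the parity prod(s_i) = +1
(or -1 for a negative shift) and add s_i * d standard deviations to biomarker
i.  Each s_i is marginally symmetric and any sub-product of fewer than k
signs has mean zero, so marginal means and lower-order product means are
untouched, while E[prod(X_i)] moves by +/- d^k * prod(sigma_i).  Marginal
variances in the affected cell are inflated by d^2 sigma_i^2 -- the price of
planting a pure third (or second) moment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import prod

import numpy as np
import pandas as pd

from .dataset import BIOMARKERS, CONTROL_LABEL, GROUP_COLUMN, BiomarkerDataset

__all__ = [
    "StudyDesign", "EffectSpec", "InteractionEffect", "ConfigurationError",
    "generate_dataset", "pool_controls",
]


class ConfigurationError(ValueError):
    """Invalid study design or effect specification."""


#: Baseline means and within-group SDs on the measurement scale (activity in
#: nmol/min/mg protein; LPO in nmol TBARS/g ww).  Plausible magnitudes for
#: green crab tissues with ~15% coefficient of variation between aquaria.
DEFAULT_BASELINES: dict[str, tuple[float, float]] = {
    "AChEg": (60.0, 9.0),
    "AChEm": (25.0, 4.0),
    "LDH": (180.0, 27.0),
    "IDH": (12.0, 2.0),
    "GSTdg": (45.0, 7.0),
    "GSTgl": (30.0, 5.0),
    "GPx": (8.0, 1.5),
    "LPOdg": (55.0, 9.0),
    "LPOgl": (40.0, 7.0),
}


@dataclass(frozen=True)
class StudyDesign:
    """Factorial layout: which (treatment, time) cells exist and how many
    replicate-aquarium units each contains.

    Time zero exists only for the control treatment (baseline units sampled
    from the acclimation stock before exposure starts).
    """

    treatments: tuple[str, ...] = (CONTROL_LABEL, "C1", "C2")
    times_days: tuple[int, ...] = (0, 7, 14, 21)
    replicates_per_cell: int = 3
    biomarker_names: tuple[str, ...] = BIOMARKERS

    def __post_init__(self) -> None:
        if self.replicates_per_cell < 1:
            raise ConfigurationError("replicates_per_cell must be positive")
        if CONTROL_LABEL not in self.treatments:
            raise ConfigurationError(f"design must include a {CONTROL_LABEL!r} treatment")
        if len(set(self.biomarker_names)) != len(self.biomarker_names):
            raise ConfigurationError("duplicate biomarker names in design")

    def cells(self) -> list[tuple[str, int]]:
        """All populated (treatment, time) cells, in design order."""
        out = []
        for t in self.treatments:
            for d in self.times_days:
                if d == 0 and t != CONTROL_LABEL:
                    continue  # only controls exist before exposure begins
                out.append((t, d))
        return out

    @property
    def n_units(self) -> int:
        return self.replicates_per_cell * len(self.cells())

    @property
    def exposure_times(self) -> tuple[int, ...]:
        return tuple(d for d in self.times_days if d != 0)


@dataclass(frozen=True)
class InteractionEffect:
    """A planted interaction-only signal.

    ``product_shift`` is the shift of E[prod X_i] for the affected cell in
    units of prod(sigma_i); its sign selects the parity of the coupled sign
    vector.  The per-marker deviation magnitude is d = |product_shift|^(1/k)
    within-group SDs.
    """

    biomarkers: tuple[str, ...]
    treatment: str
    time_days: int
    product_shift: float

    @property
    def order(self) -> int:
        return len(self.biomarkers)

    @property
    def deviation(self) -> float:
        return abs(self.product_shift) ** (1.0 / self.order)

    @property
    def parity(self) -> int:
        return 1 if self.product_shift >= 0 else -1


@dataclass(frozen=True)
class EffectSpec:
    """Where the synthetic signal lives.

    main_effects maps biomarker -> {(treatment, time): shift in within-group
    SD units}; interaction_effects plant product-mean shifts (see
    :class:`InteractionEffect`).  Noise is multivariate normal on the
    measurement scale with per-biomarker SDs and an optional common
    between-biomarker correlation.
    """

    seed: int
    baselines: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES))
    main_effects: dict[str, dict[tuple[str, int], float]] = field(default_factory=dict)
    interaction_effects: tuple[InteractionEffect, ...] = ()
    noise_scale: float = 1.0
    common_correlation: float = 0.0

    # ------------------------------------------------------------------ checks
    def validate(self, design: StudyDesign) -> None:
        for b in self.main_effects:
            if b not in design.biomarker_names:
                raise ConfigurationError(f"main effect names unknown biomarker {b!r}")
        for eff in self.interaction_effects:
            if eff.order not in (2, 3):
                raise ConfigurationError(
                    "interaction effects must couple 2 or 3 biomarkers")
            for b in eff.biomarkers:
                if b not in design.biomarker_names:
                    raise ConfigurationError(
                        f"interaction effect names unknown biomarker {b!r}")
            if len(set(eff.biomarkers)) != eff.order:
                raise ConfigurationError("interaction biomarkers must be distinct")
            if (eff.treatment, eff.time_days) not in design.cells():
                raise ConfigurationError(
                    f"interaction cell ({eff.treatment}, {eff.time_days}) "
                    "is not in the design")
        p = len(design.biomarker_names)
        rho = self.common_correlation
        if not (-1.0 / (p - 1) if p > 1 else -1.0) <= rho <= 1.0:
            raise ConfigurationError(
                f"common correlation {rho} gives a non-PSD noise covariance")
        if self.noise_scale < 0:
            raise ConfigurationError("noise_scale must be >= 0")
        for b in design.biomarker_names:
            if b not in self.baselines:
                raise ConfigurationError(f"no baseline (mean, sd) for {b!r}")

    # ------------------------------------------------- closed-form expectations
    def expected_marginal_mean(self, biomarker: str, treatment: str,
                               time_days: int) -> float:
        """Population group mean of one biomarker: baseline + main-effect
        shift; interaction-only effects do not move it."""
        mean, sd = self.baselines[biomarker]
        shift = self.main_effects.get(biomarker, {}).get((treatment, time_days), 0.0)
        return mean + shift * sd

    def expected_product_mean(self, biomarkers: tuple[str, ...], treatment: str,
                              time_days: int) -> float:
        """Population mean of prod(X_i) for a cell (uncorrelated noise).

        Valid when common_correlation == 0 and the queried tuple either is,
        or is disjoint from, each planted interaction tuple.
        """
        if self.common_correlation != 0.0:
            raise NotImplementedError("closed form derived for rho = 0 only")
        mus = [self.expected_marginal_mean(b, treatment, time_days) for b in biomarkers]
        sds = [self.baselines[b][1] for b in biomarkers]
        value = prod(mus)
        for eff in self.interaction_effects:
            if (eff.treatment, eff.time_days) != (treatment, time_days):
                continue
            common = set(eff.biomarkers) & set(biomarkers)
            if not common:
                continue
            if common != set(eff.biomarkers) or common != set(biomarkers):
                raise NotImplementedError(
                    "closed form derived for tuples equal to or disjoint from "
                    "the planted tuple")
            value += eff.product_shift * prod(sds)
        return value

    # -------------------------------------------------------- stock scenarios
    @staticmethod
    def null(seed: int) -> "EffectSpec":
        """Pure noise: no treatment- or time-related structure at all."""
        return EffectSpec(seed=seed)

    @staticmethod
    def default(seed: int) -> "EffectSpec":
        """The package's reference exposure scenario.

        A progressive interaction-only response of the high concentration:
        the (AChEg, GPx, LPOdg) triple product drifts further from baseline
        the longer the exposure lasts (product shifts 8, 15.6, 27 sigma^3 at
        7, 14, 21 d, i.e. per-marker couplings of 2.0, 2.5, 3.0 SD), while
        every marginal group mean stays at baseline.  This is the regime the
        interactive-predictor method is designed to detect and that
        single-marker screening is blind to.
        """
        triple = ("AChEg", "GPx", "LPOdg")
        return EffectSpec(
            seed=seed,
            interaction_effects=(
                InteractionEffect(triple, "C2", 7, 2.0 ** 3),
                InteractionEffect(triple, "C2", 14, 2.5 ** 3),
                InteractionEffect(triple, "C2", 21, 3.0 ** 3),
            ),
        )

    @staticmethod
    def separable(seed: int) -> "EffectSpec":
        """Perfectly separable main-effect scenario: every exposure cell is
        displaced 16 within-SD along its own dedicated marker axis, so each
        group is >= 16 SD from every other and a classifier should reach
        100% correct diagnostics."""
        axes = ["AChEg", "AChEm", "LDH", "IDH", "GSTdg", "GSTgl"]
        cells = [("C1", 7), ("C1", 14), ("C1", 21),
                 ("C2", 7), ("C2", 14), ("C2", 21)]
        return EffectSpec(seed=seed,
                          main_effects={m: {c: 16.0}
                                        for m, c in zip(axes, cells)})


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _noise_cholesky(spec: EffectSpec, p: int) -> np.ndarray:
    rho = spec.common_correlation
    corr = np.full((p, p), rho) + (1.0 - rho) * np.eye(p)
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError("noise covariance is not positive "
                                 "semi-definite") from exc


def _parity_signs(rng: np.random.Generator, k: int, parity: int) -> np.ndarray:
    """Uniform draw from {-1,+1}^k conditioned on prod(s) == parity."""
    s = rng.choice([-1.0, 1.0], size=k)
    s[-1] = parity * np.prod(s[:-1])
    return s


def generate_dataset(design: StudyDesign, effects: EffectSpec) -> BiomarkerDataset:
    """Draw one synthetic unit-level dataset.

    Deterministic given ``effects.seed``; group means follow the effect
    specification in expectation and the row count follows the design grid.
    """
    effects.validate(design)
    rng = np.random.default_rng(effects.seed)
    names = design.biomarker_names
    p = len(names)
    L = _noise_cholesky(effects, p)
    means = np.array([effects.baselines[b][0] for b in names])
    sds = np.array([effects.baselines[b][1] for b in names])
    idx = {b: j for j, b in enumerate(names)}

    rows = []
    unit = 0
    for treatment, day in design.cells():
        cell_effects = [e for e in effects.interaction_effects
                        if (e.treatment, e.time_days) == (treatment, day)]
        main = np.array([
            effects.main_effects.get(b, {}).get((treatment, day), 0.0)
            for b in names])
        for _ in range(design.replicates_per_cell):
            z = L @ rng.standard_normal(p)
            dev = np.zeros(p)
            for eff in cell_effects:
                s = _parity_signs(rng, eff.order, eff.parity)
                for b, sign in zip(eff.biomarkers, s):
                    dev[idx[b]] += sign * eff.deviation
            x = means + sds * (main + dev + effects.noise_scale * z)
            unit += 1
            rows.append({"unit_id": f"U{unit:03d}", "treatment": treatment,
                         "time_days": day,
                         **{b: x[j] for j, b in enumerate(names)}})
    return BiomarkerDataset(pd.DataFrame(rows), names)


def pool_controls(dataset: BiomarkerDataset) -> BiomarkerDataset:
    """Attach the pooled-control grouping variable.

    All control units (every sampling time, including time zero) form one
    "control" level representing natural variation in unexposed animals;
    every exposed (concentration, time) cell is its own level, labelled e.g.
    "C2-21".  The default study grid yields 7 levels.
    """
    df = dataset.table
    is_control = df["treatment"] == CONTROL_LABEL
    if not is_control.any():
        raise ConfigurationError("cannot pool controls: no control rows present")
    out = df.copy()
    out[GROUP_COLUMN] = np.where(
        is_control, CONTROL_LABEL,
        df["treatment"].astype(str) + "-" + df["time_days"].astype(str))
    pooled = dataset.copy()
    pooled.table = out
    return pooled
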