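"""End-to-end pipeline: config, orchestration, reports, run manifest.

One call runs the whole analysis on a dataset (read from CSV or generated
synthetically): univariate screening -> predictor construction -> stepwise
canonical DFA -> root tests -> cross-validation -> interpretation, writing
every report plus a machine-readable manifest (config echo, seed, package
versions, per-file SHA-256 checksums).  Identical config + seed gives
byte-identical outputs, hence identical manifest checksums.

The two toxicants of a spill study are handled as two independent runs, one
dataset each, never a joint model.  A config switch can drop the lowest test
concentration and refit (the grouping then has 4 levels instead of 7).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataset import CONTROL_LABEL, BiomarkerDataset, read_dataset
from .dfa import stepwise_dfa
from .features import build_predictors
from .interpretation import (cluster_predictors, explained_variance,
                             predictor_profiles, response_trajectory)
from .synthetic import EffectSpec, StudyDesign, generate_dataset, pool_controls
from .univariate import anova_screen_table, levene_test
from .validation import cross_validate

log = logging.getLogger("biodfa")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a run needs; the seed is mandatory for any stochastic step."""

    seed: int
    input_csv: str | None = None        # if None, a synthetic dataset is drawn
    synthetic_scenario: str = "default"  # default | null | separable
    p_enter: float = 0.05
    alpha: float = 0.05
    holdout_size: int = 3
    cv_rounds: int = 54
    standardize_first: bool = True
    max_predictors: int | None = None
    drop_lowest_concentration: bool = False
    include_time_zero_in_pool: bool = True
    output_dir: str = "runs/run"

    def __post_init__(self) -> None:
        for name in ("p_enter", "alpha"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    # -- file round trip -------------------------------------------------------
    @staticmethod
    def from_file(path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return PipelineConfig(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SCENARIOS = {
    "default": EffectSpec.default,
    "null": EffectSpec.null,
    "separable": EffectSpec.separable,
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, float_format="%.10g") -> None:
    df.to_csv(path, index=False, float_format=float_format)


def _load_or_simulate(config: PipelineConfig) -> BiomarkerDataset:
    if config.input_csv:
        return read_dataset(config.input_csv)
    scenario = _SCENARIOS.get(config.synthetic_scenario)
    if scenario is None:
        raise ValueError(f"unknown synthetic scenario "
                         f"{config.synthetic_scenario!r}; "
                         f"choose from {sorted(_SCENARIOS)}")
    return generate_dataset(StudyDesign(), scenario(config.seed))


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and write all reports; returns the run directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "data"
        ds = _load_or_simulate(config)
        ds.to_csv(out / "dataset.csv")
        pooled = pool_controls(ds)
        df = pooled.table
        if not config.include_time_zero_in_pool:
            df = df[~((df["treatment"] == CONTROL_LABEL)
                      & (df["time_days"] == 0))].reset_index(drop=True)
            pooled = dataclasses.replace(pooled, table=df)
        if config.drop_lowest_concentration:
            exposed = sorted(t for t in df["treatment"].unique()
                             if t != CONTROL_LABEL)
            if len(exposed) > 1:
                df = df[df["treatment"] != exposed[0]].reset_index(drop=True)
                pooled = dataclasses.replace(pooled, table=df)
                log.info("dropped lowest concentration %s", exposed[0])
        y = pooled.groups.to_numpy(dtype=object)

        stage = "univariate"
        screen = anova_screen_table(ds, alpha=config.alpha)
        screen.insert(0, "alpha", config.alpha)
        _write(screen, out / "anova_tables.csv")
        lev_rows = []
        for b in ds.biomarker_names:
            w, p = levene_test(pooled.table[b].to_numpy(float), y)
            lev_rows.append({"biomarker": b, "levene_W": w, "p": p,
                             "homogeneous": p >= config.alpha})
        _write(pd.DataFrame(lev_rows), out / "levene.csv")

        stage = "features"
        pm = build_predictors(pooled, standardize_first=config.standardize_first)

        stage = "dfa"
        model = stepwise_dfa(pm, y, p_enter=config.p_enter,
                             max_predictors=config.max_predictors,
                             alpha=config.alpha)
        summary = model.root_table.copy()
        summary.insert(0, "p_enter", config.p_enter)
        summary["n_selected_predictors"] = len(model.predictor_labels)
        summary["n_significant_roots"] = model.n_significant_roots
        _write(summary, out / "model_summary.csv")
        model.trace.table.to_csv(out / "stepwise_trace.csv", index=False,
                                 float_format="%.10g")

        if model.empty:
            log.warning("stepwise selected no predictor at p_enter=%g; "
                        "interpretation skipped", config.p_enter)
            (out / "NOTICE.txt").write_text(
                "Empty model: no predictor cleared p-to-enter "
                f"{config.p_enter}; interpretation stages skipped.\n")
        else:
            coef = pd.DataFrame(model.std_coefficients,
                                index=model.predictor_labels,
                                columns=[f"function_{r + 1}"
                                         for r in range(model.n_roots)])
            cum = explained_variance(model.eigenvalues)
            coef.loc["(cumulative % explained variance)"] = cum
            coef.index.name = "predictor"
            coef.to_csv(out / "coefficients.csv", float_format="%.10g")

        stage = "cross-validation"
        cv = cross_validate(pm, y, holdout_size=config.holdout_size,
                            rounds=config.cv_rounds, seed=config.seed,
                            p_enter=config.p_enter,
                            max_predictors=config.max_predictors)
        _write(cv.rounds, out / "cv_report.csv")
        _write(pd.DataFrame([cv.summary()]), out / "cv_summary.csv")

        stage = "interpretation"
        if not model.empty:
            if len(model.predictor_labels) >= 2:
                dend = cluster_predictors(model)
                (out / "dendrogram.nwk").write_text(dend.to_newick() + "\n")
            profiles = predictor_profiles(
                pm, y, predictors=model.predictor_labels, alpha=config.alpha,
                meta=pooled.table[["treatment", "time_days"]])
            _write(profiles, out / "profiles.csv")
            traj = response_trajectory(model, pm, y)
            _write(traj, out / "trajectory.csv")
    except Exception as exc:
        log.error("pipeline failed at stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    stage = "manifest"
    files = sorted(p for p in out.iterdir()
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "package": "biodfa",
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "checksums": {p.name: _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return out
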