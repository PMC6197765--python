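#!/usr/bin/env python
"""Interpret the fitted models: predictor clustering, Duncan profiles and
temporal response trajectories.

Per toxicant: hierarchical clustering (UPGMA on standardized coefficients
over the significant functions) written as Newick; per-predictor group
profiles (one-way ANOVA + Duncan letters, time-ordered mean +/- SE) for the
retained predictors; and the integrated response index — the canonical-space
distance of each (concentration, time) cell from the pooled-control
centroid — classified per concentration as progressive vs
recovery-consistent.
"""

from pathlib import Path

from biodfa.dataset import read_dataset
from biodfa.dfa import stepwise_dfa
from biodfa.features import build_predictors
from biodfa.interpretation import (cluster_predictors, predictor_profiles,
                                   response_trajectory)
from biodfa.synthetic import pool_controls

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    for name in ("toxA", "toxB"):
        ds = read_dataset(RESULTS / "data" / f"{name}.csv")
        pooled = pool_controls(ds)
        pm = build_predictors(pooled)
        y = pooled.groups.to_numpy(object)
        model = stepwise_dfa(pm, y, p_enter=0.05)
        if model.empty:
            print(f"{name}: empty model, nothing to interpret")
            continue

        if len(model.predictor_labels) >= 2:
            nwk = cluster_predictors(model).to_newick()
            (RESULTS / f"dendrogram_{name}.nwk").write_text(nwk + "\n")

        profiles = predictor_profiles(
            pm, y, predictors=model.predictor_labels,
            meta=pooled.table[["treatment", "time_days"]])
        profiles.to_csv(RESULTS / f"profiles_{name}.csv", index=False,
                        float_format="%.6g")

        traj = response_trajectory(model, pm, y)
        traj.to_csv(RESULTS / f"trajectory_{name}.csv", index=False,
                    float_format="%.6g")

        top = model.predictor_labels[0]
        letters = dict(zip(profiles[profiles["predictor"] == top]["group"],
                           profiles[profiles["predictor"] == top]["duncan"]))
        print(f"{name}: top predictor {top!r}; Duncan letters {letters}")
        for t, sub in traj[traj["group"] != "control"].groupby("treatment"):
            sub = sub.sort_values("time_days")
            d = ", ".join(f"{r['time_days']}d={r['distance_from_control']:.2f}"
                          for _, r in sub.iterrows())
            print(f"  {t}: {sub['trend'].iloc[0]} ({d})")


if __name__ == "__main__":
    main()
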