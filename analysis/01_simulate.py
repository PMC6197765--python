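#!/usr/bin/env python
"""Generate the two synthetic exposure-study datasets analysed downstream.

Two toxicants are modelled as two independent 30-unit factorial datasets
(3 replicate aquaria x {control, C1, C2} x {7, 14, 21} d, plus 3 time-zero
control units), with signals carried only by biomarker products:

* toxicant A — the reference scenario: a progressive interaction-only
  response of the (AChEg, GPx, LPOdg) triple at the high concentration
  (product shifts 8 / 15.6 / 27 sigma^3 at 7 / 14 / 21 d);
* toxicant B — a weaker scenario: a single late interaction-only response
  of (AChEg, IDH, LPOgl) at C2/21 d only, so the model should be weaker
  and its cross-validation poorer (the second toxicant of a spill study is
  rarely as clear-cut as the first).

Writes results/data/toxA.csv and toxB.csv.
"""

import argparse
from pathlib import Path

from biodfa.synthetic import (EffectSpec, InteractionEffect, StudyDesign,
                              generate_dataset)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def spec_toxB(seed: int) -> EffectSpec:
    return EffectSpec(seed=seed, interaction_effects=(
        InteractionEffect(("AChEg", "IDH", "LPOgl"), "C2", 21, 15.6),))


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=20180927)
    args = ap.parse_args()

    out = RESULTS / "data"
    out.mkdir(parents=True, exist_ok=True)
    design = StudyDesign()
    for name, spec in [("toxA", EffectSpec.default(args.seed)),
                       ("toxB", spec_toxB(args.seed + 1))]:
        ds = generate_dataset(design, spec)
        ds.to_csv(out / f"{name}.csv")
        print(f"{name}: {len(ds)} units -> {out / (name + '.csv')}")


if __name__ == "__main__":
    main()
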