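"""Predictors of one-year visual acuity: univariable screen (p <= 0.10)
followed by bidirectional stepwise regression with a VIF guard.

Reads results/data/cohort, writes results/regression_va_w52.json.
"""

import argparse
import json
from pathlib import Path

from hefq.cohort import analysis_frame, stepwise_fit, univariable_screen
from hefq.io import read_cohort
from hefq.synth import apply_inclusion_filters

CANDIDATES = [
    "cst_w52", "or_he_baseline", "pseudophakic", "age", "hba1c",
    "dm_duration", "cst_baseline", "he_total_baseline",
    "mean_arterial_bp", "bmi",
]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort, _ = apply_inclusion_filters(read_cohort(args.data / "cohort"))
    frame = analysis_frame(cohort)
    screen = univariable_screen(frame, "va_w52", CANDIDATES, threshold=0.10)
    passed = list(screen.loc[screen.passed, "candidate"])
    print(f"univariable screen: {len(passed)}/{len(CANDIDATES)} candidates "
          f"at p<=0.10: {passed}")

    model = stepwise_fit(frame, "va_w52", passed, screen_log=screen)
    args.out.mkdir(parents=True, exist_ok=True)
    (args.out / "regression_va_w52.json").write_text(
        json.dumps(model.to_dict(), indent=2)
    )
    print(f"stepwise model for week-52 VA (n={model.n}, "
          f"adjusted R^2={model.adjusted_r2:.3f}):")
    for p in model.predictors:
        print(f"  {p.name}: beta={p.beta_standardized:+.3f} "
              f"(p={p.p:.2g}, partial R^2={p.partial_r2:.3f}, VIF={p.vif:.2f})")


if __name__ == "__main__":
    main()
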