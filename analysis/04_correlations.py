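"""Pearson correlation screen: which baseline clinical variables track
baseline hard-exudate burden?

Reads results/data/cohort, writes results/correlations.csv.
"""

import argparse
from pathlib import Path

from hefq.cohort import analysis_frame, pearson_screen
from hefq.io import read_cohort
from hefq.synth import apply_inclusion_filters


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort, _ = apply_inclusion_filters(read_cohort(args.data / "cohort"))
    frame = analysis_frame(cohort)
    table = pearson_screen(
        frame,
        ["age", "hba1c", "dm_duration", "mean_arterial_bp", "bmi", "cst_baseline"],
        ["he_total_baseline", "or_he_baseline", "he_csf_baseline"],
    )
    args.out.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "correlations.csv", index=False)
    sig = table[table.p < 0.05].sort_values("p")
    print(f"{len(sig)}/{len(table)} correlations significant at p<0.05; strongest:")
    for row in sig.head(5).itertuples():
        print(f"  {row.x} vs {row.y}: r={row.r:+.3f} (p={row.p:.2g}, n={row.n})")


if __name__ == "__main__":
    main()
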