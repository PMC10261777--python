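#!/usr/bin/env python
"""Compute per-treatment quality metrics.

Reads results/treatments.csv and results/curves.csv, derives the
rehydration ratio, geometric mean diameter, total colour difference
against the fresh reference, and average rehydration rate, and writes
results/quality_metrics.csv.
"""

from pathlib import Path

from rehydkin.pipeline import quality_table, read_curve_table, read_treatment_table
from rehydkin.synthetic_data import FRESH_COLOR

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    treatments = read_treatment_table(OUT / "treatments.csv")
    curves = read_curve_table(OUT / "curves.csv")
    quality = quality_table(treatments, curves, FRESH_COLOR)
    quality.to_csv(OUT / "quality_metrics.csv", index=False, float_format="%.12g")
    print(quality.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    by_pre = quality.groupby("pretreatment")["delta_e"].mean().sort_values()
    print("\nmean colour change by pretreatment (low = better retention):")
    print(by_pre.to_string(float_format=lambda v: f"{v:.2f}"))
    print(f"\nrehydration ratio span: {quality['rehydration_ratio'].min():.2f}"
          f"-{quality['rehydration_ratio'].max():.2f}")
    print(f"average rehydration rate span: "
          f"{quality['avg_rehydration_rate'].min():.4f}"
          f"-{quality['avg_rehydration_rate'].max():.4f} g/(g·min)")


if __name__ == "__main__":
    main()
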