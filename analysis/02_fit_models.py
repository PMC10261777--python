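#!/usr/bin/env python
"""Fit the Peleg, Weibull and logarithmic models to every soaking curve.

Reads results/curves.csv (run 01_simulate.py first), fits all three models
per condition, writes the per-condition fit table and the per-model
averages, and prints the model ranking by mean R².
"""

from pathlib import Path

from rehydkin.pipeline import fit_curves, read_curve_table, summarize_fits

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    curves = read_curve_table(OUT / "curves.csv")
    fits, n_excluded = fit_curves(curves)
    summary = summarize_fits(fits, n_excluded)
    fits.to_csv(OUT / "fits.csv", index=False, float_format="%.12g")
    summary.to_csv(OUT / "model_summary.csv", index=False, float_format="%.12g")
    print(f"fitted {len(fits)} (condition, model) pairs; {n_excluded} excluded")
    print("\nper-model averages over the 16 conditions:")
    print(summary.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    best = summary.sort_values("mean_R2", ascending=False).iloc[0]
    print(f"\nbest average fit: {best['model']} "
          f"(R2={best['mean_R2']:.4f}, RMSE={best['mean_RMSE']:.4f} g/g)")
    peleg = fits[fits.model == "peleg"]
    print(f"Peleg equilibrium moisture span: "
          f"{peleg['Xeq_derived'].min():.3f}-{peleg['Xeq_derived'].max():.3f} g/g")


if __name__ == "__main__":
    main()
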