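"""End-to-end orchestration: data in → model fits → quality metrics → clustering.

`run_pipeline` takes a RunConfig naming either delimited-text input tables
(curves + treatment properties) or the synthetic generator, fits the three
rehydration models to every curve, computes the quality metrics, clusters
the treatments, and writes all stage outputs as comma-delimited UTF-8
tables (plus Newick dendrograms and a provenance JSON) under the output
directory.  Runs are deterministic for a given config and seed: repeating
a run reproduces the numeric output files byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .compound_correlation import (
    cluster_treatments,
    cut_tree,
    export_dendrogram,
    standardize_features,
)
from .fitting import (
    MODEL_NAMES,
    DegenerateCurveError,
    ModelFit,
    RehydrationCurve,
    fit_all_models,
)
from .quality_metrics import (
    ColorLab,
    KernelDimensions,
    MassPair,
    geometric_mean_diameter,
    rehydration_rate,
    rehydration_ratio,
    total_color_difference,
)
from .synthetic_data import FRESH_COLOR, SyntheticSpec, generate_curves, generate_treatment_table

__all__ = [
    "RunConfig",
    "RunReport",
    "run_pipeline",
    "read_curve_table",
    "write_curve_table",
    "read_treatment_table",
    "write_report",
    "DEFAULT_FEATURE_SETS",
]

logger = logging.getLogger("rehydkin")

_CURVE_COLUMNS = ["pretreatment", "temperature_c", "time_min", "moisture_g_per_g"]
_TREATMENT_COLUMNS = [
    "pretreatment", "temperature_c", "mass_fresh_g", "mass_dried_g",
    "mass_rehydrated_g", "L_mm", "W_mm", "T_mm", "Lstar", "astar", "bstar",
    "total_sugar_g_per_100g", "ascorbic_acid_mg_per_100g", "sensory_score",
]

#: Property columns entering each clustering run (quality-metric table columns).
DEFAULT_FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "physical": ("mass_dried_g", "mass_rehydrated_g", "rehydration_ratio",
                 "Dg_mm", "delta_e"),
    "overall": ("mass_dried_g", "mass_rehydrated_g", "rehydration_ratio",
                "Dg_mm", "delta_e", "total_sugar_g_per_100g",
                "ascorbic_acid_mg_per_100g", "sensory_score"),
}

_FLOAT_FMT = "%.12g"


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one data source: leave both paths None to use the synthetic
    generator, or give both a curve table and a treatment table.
    """

    curves_path: Optional[str] = None
    treatments_path: Optional[str] = None
    models: tuple = MODEL_NAMES
    residual_on: str = "moisture"
    linkage: str = "ward"
    distance: str = "euclidean"
    cut_fraction: float = 0.5
    feature_sets: dict = field(default_factory=lambda: dict(DEFAULT_FEATURE_SETS))
    reference_color: tuple = (FRESH_COLOR.L_star, FRESH_COLOR.a_star, FRESH_COLOR.b_star)
    out_dir: str = "results"
    seed: int = 0
    noise_sd: float = 0.05
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.curves_path is None) != (self.treatments_path is None):
            raise ValueError(
                "provide both curves_path and treatments_path, or neither (synthetic run)"
            )

    @property
    def synthetic(self) -> bool:
        return self.curves_path is None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["models"] = list(self.models)
        d["reference_color"] = list(self.reference_color)
        d["feature_sets"] = {k: list(v) for k, v in self.feature_sets.items()}
        return d


@dataclass
class RunReport:
    """All stage outputs of one pipeline run."""

    fits: pd.DataFrame              # one row per (condition, model)
    model_summary: pd.DataFrame     # per-model averaged R2 / chi2 / RMSE
    quality: pd.DataFrame           # per-treatment quality metrics
    curves: pd.DataFrame            # the long-format curve table used
    treatments: pd.DataFrame        # the treatment-property table used
    dendrograms: dict               # feature-set name -> Newick string
    cluster_assignments: pd.DataFrame
    n_excluded: int                 # fits excluded from the averages
    provenance: dict


# ---------------------------------------------------------------------------
# delimited-text I/O (comma default, tab accepted on read; UTF-8, header row)

def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
    except OSError as exc:
        raise OSError(f"cannot read input table {path}: {exc}") from exc
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, encoding="utf-8")


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_curve_table(path: str | Path) -> list[RehydrationCurve]:
    """Read a long-format curve table into RehydrationCurve objects.

    Columns: pretreatment, temperature_c, time_min, moisture_g_per_g.
    One curve per (pretreatment, temperature_c); rows need not be sorted.
    """
    df = _read_delimited(path)
    _require_columns(df, _CURVE_COLUMNS, path)
    if df.empty:
        warnings.warn(f"{path}: header-only curve table, no curves read")
        return []
    for idx, row in df.iterrows():
        if row["time_min"] < 0:
            raise ValueError(f"{path}, row {idx + 2}: negative time {row['time_min']}")
        if row["moisture_g_per_g"] < 0:
            raise ValueError(
                f"{path}, row {idx + 2}: negative moisture {row['moisture_g_per_g']}"
            )
    curves = []
    for (pre, temp), grp in df.groupby(["pretreatment", "temperature_c"], sort=True):
        grp = grp.sort_values("time_min")
        t = grp["time_min"].to_numpy(float)
        x = grp["moisture_g_per_g"].to_numpy(float)
        xw0 = float(x[0]) if t[0] == 0 else float(x[0])
        curves.append(RehydrationCurve(str(pre), float(temp), t, x, xw0))
    return curves


def curves_to_frame(curves: Sequence[RehydrationCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for t, x in zip(c.times, c.moistures):
            rows.append({"pretreatment": c.pretreatment, "temperature_c": c.temperature_c,
                         "time_min": float(t), "moisture_g_per_g": float(x)})
    return pd.DataFrame(rows, columns=_CURVE_COLUMNS)


def write_curve_table(curves: Sequence[RehydrationCurve], path: str | Path) -> None:
    curves_to_frame(curves).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_treatment_table(path: str | Path) -> pd.DataFrame:
    """Read the treatment-property table (one row per condition)."""
    df = _read_delimited(path)
    _require_columns(df, _TREATMENT_COLUMNS, path)
    if df.empty:
        warnings.warn(f"{path}: header-only treatment table")
    return df


# ---------------------------------------------------------------------------
# pipeline stages

def _fit_row(fit: ModelFit, curve: RehydrationCurve) -> dict:
    row = {
        "pretreatment": curve.pretreatment,
        "temperature_c": curve.temperature_c,
        "model": fit.model,
        "k1": np.nan, "k2": np.nan, "alpha": np.nan, "beta": np.nan, "k": np.nan,
        "Xeq_derived": fit.Xeq_derived if fit.Xeq_derived is not None else np.nan,
        "R2": np.nan, "chi2": np.nan, "RMSE": np.nan,
        "N": np.nan, "Z": np.nan,
        "converged": fit.converged,
    }
    p = fit.params
    if fit.model == "peleg" and p is not None:
        row["k1"], row["k2"] = p.k1, p.k2
    elif fit.model == "weibull" and p is not None:
        row["alpha"], row["beta"] = p.alpha, p.beta
    elif fit.model == "proposed" and p is not None:
        row["k"] = p.k
    if fit.stats is not None:
        row.update(R2=fit.stats.R2, chi2=fit.stats.chi2, RMSE=fit.stats.RMSE,
                   N=fit.stats.N, Z=fit.stats.Z)
    return row


def fit_curves(curves: Sequence[RehydrationCurve], models: Sequence[str] = MODEL_NAMES,
               residual_on: str = "moisture") -> tuple[pd.DataFrame, int]:
    """Fit every model to every curve; returns (fits table, #excluded).

    A curve whose fit degenerates or fails to converge is logged and
    excluded from the statistics columns (its row is kept with
    converged=False where a parameter estimate exists, or dropped when the
    fit raised).
    """
    rows, excluded = [], 0
    for curve in curves:
        for model in models:
            try:
                (fit,) = fit_all_models(curve, [model], residual_on=residual_on)
            except (DegenerateCurveError, ValueError) as exc:
                logger.warning("fit failed for %s/%s: %s", curve.label, model, exc)
                excluded += 1
                continue
            if not fit.converged:
                logger.warning("fit did not converge for %s/%s", curve.label, model)
                excluded += 1
            rows.append(_fit_row(fit, curve))
    fits = pd.DataFrame(rows)
    return fits, excluded


def summarize_fits(fits: pd.DataFrame, n_excluded: int) -> pd.DataFrame:
    """Per-model arithmetic means of R², chi² and RMSE over converged fits."""
    ok = fits[fits["converged"]]
    summary = (
        ok.groupby("model", sort=True)[["R2", "chi2", "RMSE"]]
        .mean()
        .reset_index()
        .rename(columns={"R2": "mean_R2", "chi2": "mean_chi2", "RMSE": "mean_RMSE"})
    )
    summary["n_fits"] = ok.groupby("model", sort=True).size().to_numpy()
    summary["n_excluded_total"] = n_excluded
    return summary


def quality_table(treatments: pd.DataFrame, curves: Sequence[RehydrationCurve],
                  reference_color: ColorLab) -> pd.DataFrame:
    """Per-treatment quality metrics derived from the property table and curves."""
    rate_by_cond = {
        (c.pretreatment, c.temperature_c): rehydration_rate(c).average for c in curves
    }
    rows = []
    for _, rec in treatments.iterrows():
        dims = KernelDimensions(rec["L_mm"], rec["W_mm"], rec["T_mm"])
        color = ColorLab(rec["Lstar"], rec["astar"], rec["bstar"])
        pair = MassPair(rec["mass_dried_g"], rec["mass_rehydrated_g"])
        cond = (rec["pretreatment"], float(rec["temperature_c"]))
        rows.append({
            "pretreatment": rec["pretreatment"],
            "temperature_c": float(rec["temperature_c"]),
            "mass_dried_g": rec["mass_dried_g"],
            "mass_rehydrated_g": rec["mass_rehydrated_g"],
            "rehydration_ratio": rehydration_ratio(pair),
            "Dg_mm": geometric_mean_diameter(dims),
            "delta_e": total_color_difference(reference_color, color),
            "avg_rehydration_rate": rate_by_cond.get(cond, np.nan),
            "total_sugar_g_per_100g": rec["total_sugar_g_per_100g"],
            "ascorbic_acid_mg_per_100g": rec["ascorbic_acid_mg_per_100g"],
            "sensory_score": rec["sensory_score"],
        })
    return pd.DataFrame(rows)


def cluster_quality(quality: pd.DataFrame, feature_sets: dict, linkage: str,
                    distance: str, cut_fraction: float):
    """Cluster treatments once per feature set; returns (newicks, assignments)."""
    newicks: dict[str, str] = {}
    assign_rows = []
    labels = [f"{p}_{t:g}C" for p, t in zip(quality["pretreatment"],
                                            quality["temperature_c"])]
    for name, cols in feature_sets.items():
        feats = quality[list(cols)].copy()
        feats.index = labels
        tree = cluster_treatments(standardize_features(feats), distance=distance,
                                  linkage=linkage)
        newicks[name] = export_dendrogram(tree)
        for label, cid in sorted(cut_tree(tree, cut_fraction).items()):
            assign_rows.append({"feature_set": name, "treatment": label, "cluster": cid})
    return newicks, pd.DataFrame(assign_rows, columns=["feature_set", "treatment", "cluster"])


def write_report(report: RunReport, out_dir: str | Path) -> None:
    """Write every stage output under out_dir with a fixed numeric format."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.curves.to_csv(out / "curves.csv", index=False, float_format=_FLOAT_FMT)
    report.treatments.to_csv(out / "treatments.csv", index=False, float_format=_FLOAT_FMT)
    report.fits.to_csv(out / "fits.csv", index=False, float_format=_FLOAT_FMT)
    report.model_summary.to_csv(out / "model_summary.csv", index=False,
                                float_format=_FLOAT_FMT)
    report.quality.to_csv(out / "quality_metrics.csv", index=False, float_format=_FLOAT_FMT)
    report.cluster_assignments.to_csv(out / "cluster_assignments.csv", index=False)
    for name, nwk in report.dendrograms.items():
        (out / f"dendrogram_{name}.nwk").write_text(nwk + "\n", encoding="utf-8")
    (out / "provenance.json").write_text(
        json.dumps(report.provenance, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def run_pipeline(config: RunConfig, write: bool = True) -> RunReport:
    """Run the full analysis described by `config`; optionally write outputs."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    if config.synthetic:
        spec = SyntheticSpec(seed=config.seed, noise_sd=config.noise_sd)
        curves = generate_curves(spec)
        treatments = generate_treatment_table(spec)
        logger.info("generated %d synthetic curves (seed=%d)", len(curves), config.seed)
    else:
        curves = read_curve_table(config.curves_path)
        treatments = read_treatment_table(config.treatments_path)
        logger.info("read %d curves from %s", len(curves), config.curves_path)

    fits, n_excluded = fit_curves(curves, config.models, config.residual_on)
    summary = summarize_fits(fits, n_excluded)
    ref = ColorLab(*config.reference_color)
    quality = quality_table(treatments, curves, ref)
    newicks, assignments = cluster_quality(quality, config.feature_sets, config.linkage,
                                           config.distance, config.cut_fraction)

    cfg = config.to_dict()
    provenance = {
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "version": __version__,
        "n_curves": len(curves),
        "n_fit_rows": int(len(fits)),
        "n_excluded": n_excluded,
    }
    report = RunReport(
        fits=fits, model_summary=summary, quality=quality,
        curves=curves_to_frame(curves), treatments=treatments,
        dendrograms=newicks, cluster_assignments=assignments,
        n_excluded=n_excluded, provenance=provenance,
    )
    if write:
        write_report(report, config.out_dir)
        logger.info("wrote report to %s", config.out_dir)
    return report
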