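"""End-to-end calibration workflow.

Ties the stages together the way a full faecal-nitrogen study runs:
simulate or load spectra -> average replicate scans -> calibrate the
eight-treatment grid (per species and pooled) -> external validation ->
hold-out species prediction -> AICc model comparison -> Bland-Altman
agreement between monospecies and multispecies predictions. Every number
an emitted table contains is reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bland_altman import AgreementResult, agreement_plot, bland_altman
from .model_compare import ModelTable, compare_models
from .mpls import CalibrationResult, calibrate, predict
from .preprocess import default_spec_grid
from .spectra_io import average_replicates, read_spectra_csv
from .synthetic_data import default_config, generate
from .valstats import ValidationReport, evaluate, round_half_away


@dataclass
class RunConfig:
    """Settings of one pipeline run; the seed drives all randomness."""

    input_csv: str | None = None      # None -> simulate with default config
    output_dir: str = "nirscal_out"
    seed: int = 0
    n_groups: int = 5
    max_factors: int | None = None
    t_crit: float = 2.5
    max_passes: int = 2
    n_aicc: int | None = None         # default: number of validation pairs
    write_figures: bool = True


@dataclass
class SpeciesResult:
    """Best calibration of one species (or the pooled multispecies set)."""

    name: str
    best: CalibrationResult
    calibration_report: ValidationReport
    cross_val_report: ValidationReport | None
    external_report: ValidationReport | None
    all_results: list[CalibrationResult] = field(default_factory=list)


@dataclass
class PipelineResult:
    config: RunConfig
    monospecies: dict[str, SpeciesResult]
    multispecies: SpeciesResult
    per_species_external: dict[str, ValidationReport]
    holdout_reports: dict[str, ValidationReport]
    holdout_predictions: pd.DataFrame
    model_table: ModelTable
    agreement: AgreementResult
    validation_pairs: pd.DataFrame


def _species_result(name, cal_set, val_set, specs, cfg) -> SpeciesResult:
    results = calibrate(cal_set, specs, max_factors=cfg.max_factors,
                        n_groups=cfg.n_groups, seed=cfg.seed,
                        t_crit=cfg.t_crit, max_passes=cfg.max_passes)
    best = results[0]
    cleaned = cal_set.subset(best.model.training_ids)
    cal_report = evaluate(best.model, cleaned, role="calibration")
    cv = best.cv_report
    y = cleaned.fn_vector()
    yhat_cv = np.array([cv.heldout_predictions[sid] for sid in cleaned.sample_ids])
    from .valstats import report_from_pairs

    cv_report = report_from_pairs(yhat_cv, y, role="cross_validation")
    ext_report = (evaluate(best.model, val_set, role="external_validation")
                  if val_set is not None and len(val_set) >= 3 else None)
    return SpeciesResult(name=name, best=best, calibration_report=cal_report,
                         cross_val_report=cv_report, external_report=ext_report,
                         all_results=results)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the whole study workflow and return all reports."""
    if config.input_csv is not None:
        raw = read_spectra_csv(config.input_csv)
    else:
        raw = generate(default_config(seed=config.seed))
    data = average_replicates(raw)

    cal = data.by_set("calibration")
    val = data.by_set("validation")
    pred = data.by_set("prediction")
    if len(cal) == 0:
        raise ValueError("no calibration samples in the input set")

    specs = default_spec_grid()
    species_names = sorted(set(cal.species))

    monospecies: dict[str, SpeciesResult] = {}
    for name in species_names:
        monospecies[name] = _species_result(
            name, cal.by_species(name), val.by_species(name), specs, config
        )
    multispecies = _species_result("multispecies", cal, val, specs, config)

    # per-species external validation with the pooled equation
    per_species_external: dict[str, ValidationReport] = {}
    for name in species_names:
        vs = val.by_species(name)
        if len(vs) >= 3:
            per_species_external[name] = evaluate(
                multispecies.best.model, vs, role="external_validation"
            )

    # hold-out species predicted by the pooled equation
    holdout_reports: dict[str, ValidationReport] = {}
    holdout_rows = []
    for name in sorted(set(pred.species)):
        ps = pred.by_species(name)
        yhat = predict(multispecies.best.model, ps)
        for sid, value in zip(ps.sample_ids, yhat):
            holdout_rows.append({"sample_id": sid, "species": name,
                                 "fn_predicted": value,
                                 "fn_ref": ps.fn_ref.get(sid, np.nan)})
        if len(ps) >= 3 and not np.any(np.isnan(ps.fn_vector())):
            holdout_reports[name] = evaluate(multispecies.best.model, ps,
                                             role="prediction")
    holdout_predictions = pd.DataFrame(
        holdout_rows, columns=["sample_id", "species", "fn_predicted", "fn_ref"]
    )

    # paired mono/multi predictions on the shared validation samples
    pair_rows = []
    for name in species_names:
        vs = val.by_species(name)
        if len(vs) == 0 or name not in monospecies:
            continue
        mono_hat = predict(monospecies[name].best.model, vs)
        multi_hat = predict(multispecies.best.model, vs)
        for sid, m1, m2 in zip(vs.sample_ids, mono_hat, multi_hat):
            pair_rows.append({"sample_id": sid, "species": name,
                              "fn_lab": vs.fn_ref[sid],
                              "fn_mono": m1, "fn_multi": m2})
    pairs = pd.DataFrame(
        pair_rows, columns=["sample_id", "species", "fn_lab", "fn_mono", "fn_multi"]
    )

    n_aicc = config.n_aicc if config.n_aicc is not None else len(pairs)
    model_table = compare_models(pairs["fn_lab"], pairs["fn_multi"],
                                 pairs["species"], n_aicc=n_aicc)
    agreement = bland_altman(pairs["fn_mono"].to_numpy(),
                             pairs["fn_multi"].to_numpy(),
                             sample_ids=list(pairs["sample_id"]))

    return PipelineResult(
        config=config,
        monospecies=monospecies,
        multispecies=multispecies,
        per_species_external=per_species_external,
        holdout_reports=holdout_reports,
        holdout_predictions=holdout_predictions,
        model_table=model_table,
        agreement=agreement,
        validation_pairs=pairs,
    )


# -- report rendering ------------------------------------------------------


def _report_row(name: str, sr: SpeciesResult) -> dict:
    best = sr.best
    d, g, s1, s2 = best.spec.math
    row = {
        "equation": name,
        "math_treatment": f"{d},{g},{s1},{s2}",
        "scatter": best.spec.scatter,
        "n": sr.calibration_report.n,
        "n_factors": best.model.n_factors,
        "R2": sr.calibration_report.r2,
        "SEC": sr.calibration_report.se,
        "r2_cv": sr.cross_val_report.r2 if sr.cross_val_report else np.nan,
        "SECV": best.cv_report.secv,
    }
    ext = sr.external_report
    if ext is not None:
        row.update({"r2_val": ext.r2, "SEP": ext.se, "Bias": ext.bias,
                    "Slope": ext.slope,
                    "RPD": round_half_away(ext.rpd),
                    "RER": round_half_away(ext.rer)})
    return row


def calibration_table(result: PipelineResult) -> pd.DataFrame:
    """Per-equation calibration/validation summary (monospecies rows then
    the pooled multispecies row)."""
    rows = [_report_row(name, sr) for name, sr in result.monospecies.items()]
    rows.append(_report_row("multispecies", result.multispecies))
    return pd.DataFrame(rows)


def per_species_validation_table(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for name, rep in result.per_species_external.items():
        rows.append({"species": name, "n": rep.n, "r2": rep.r2, "SEP": rep.se,
                     "Bias": rep.bias, "Slope": rep.slope,
                     "RPD": round_half_away(rep.rpd),
                     "RER": round_half_away(rep.rer)})
    return pd.DataFrame(rows)


def holdout_prediction_table(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for name, rep in result.holdout_reports.items():
        preds = result.holdout_predictions.query("species == @name")["fn_predicted"]
        rows.append({"species": name, "n": rep.n,
                     "pred_range": f"{preds.min():.2f}-{preds.max():.2f}",
                     "pred_mean": preds.mean(), "pred_sd": preds.std(ddof=1),
                     "r2": rep.r2, "SEP": rep.se, "Bias": rep.bias,
                     "Slope": rep.slope, "RPD": round_half_away(rep.rpd),
                     "RER": round_half_away(rep.rer)})
    return pd.DataFrame(rows)


def agreement_table(result: PipelineResult) -> pd.DataFrame:
    a = result.agreement
    return pd.DataFrame([{
        "n": a.n, "mean_difference": a.d, "sd_differences": a.sd_diff,
        "loa_lower": a.loa_lower, "loa_upper": a.loa_upper,
        "ci_d_low": a.ci_d[0], "ci_d_high": a.ci_d[1],
        "n_outside": len(a.outside_ids),
    }])


def write_reports(result: PipelineResult, output_dir,
                  write_figures: bool | None = None) -> list[Path]:
    """Write all tables (CSV), figures and the run log; returns the paths.

    ``write_figures`` overrides the run config's setting when given.
    """
    if write_figures is None:
        write_figures = result.config.write_figures
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    tables = {
        "calibration_statistics.csv": calibration_table(result),
        "per_species_validation.csv": per_species_validation_table(result),
        "holdout_prediction.csv": holdout_prediction_table(result),
        "model_comparison.csv": result.model_table.rows,
        "bland_altman.csv": agreement_table(result),
        "validation_pairs.csv": result.validation_pairs,
        "holdout_predictions.csv": result.holdout_predictions,
    }
    for fname, df in tables.items():
        path = out / fname
        df.to_csv(path, index=False)
        written.append(path)

    if write_figures:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        ax = agreement_plot(result.agreement,
                            result.validation_pairs["fn_mono"].to_numpy(),
                            result.validation_pairs["fn_multi"].to_numpy(),
                            species=result.validation_pairs["species"].to_numpy())
        fig_path = out / "bland_altman.png"
        ax.figure.savefig(fig_path, dpi=120)
        plt.close(ax.figure)
        written.append(fig_path)

        fig, ax = plt.subplots(figsize=(7, 5))
        for name, grp in result.validation_pairs.groupby("species"):
            ax.scatter(grp["fn_multi"], grp["fn_lab"], s=25, label=name, alpha=0.8)
            b = np.polyfit(grp["fn_multi"], grp["fn_lab"], 1)
            xs = np.linspace(grp["fn_multi"].min(), grp["fn_multi"].max(), 10)
            ax.plot(xs, np.polyval(b, xs), linewidth=1)
        ax.set_xlabel("NIRS-predicted FN (% DM)")
        ax.set_ylabel("Laboratory FN (% DM)")
        ax.legend(fontsize=8)
        fig_path = out / "species_regressions.png"
        fig.savefig(fig_path, dpi=120)
        plt.close(fig)
        written.append(fig_path)

    log = {
        "package_version": __version__,
        "config": dataclasses.asdict(result.config),
        "seed": result.config.seed,
        "n_calibration": int(result.multispecies.calibration_report.n),
        "n_validation": int(len(result.validation_pairs)),
        "best_multispecies_treatment": result.multispecies.best.spec.label(),
    }
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2))
    written.append(log_path)
    return written
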