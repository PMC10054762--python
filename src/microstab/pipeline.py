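"""End-to-end orchestration: simulate/load -> calibrate -> validate -> stability.

A run is described by a :class:`RunConfig` (constructed in code or from
a YAML/JSON file). Each stage writes its outputs before the next stage
starts; the merged run report is written both machine-readable
(report.json) and as a human-readable text summary whose every number
also appears in the JSON. Identical config + seed gives a byte-identical
JSON report.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import calibration as cal
from . import io, simulate, stability, validation
from .datatypes import AcceptanceThresholds, ClearanceBands, StudyDesign
from .errors import ConfigError, MicrostabError

__all__ = ["RunConfig", "StabilityOptions", "load_config", "run_pipeline"]

logger = logging.getLogger(__name__)


class StabilityOptions(BaseModel):
    mode: str = "manual"
    window: tuple[float, float] = (0.0, 30.0)
    min_points: int = 4
    r2_floor: float = 0.98
    slope_decimals: Optional[int] = None
    thalf_decimals: Optional[int] = None


class MatrixSimBlock(BaseModel):
    true_me_analyte: float = 100.0
    true_me_is: float = 100.0
    cv: float = 0.02
    n: int = 6


class RunConfig(BaseModel):
    """Everything one pipeline run needs.

    Stages run only when they have an input: either a file path or a
    simulation block. ``seed`` is required whenever any simulation block
    is present.
    """

    design: StudyDesign = Field(default_factory=StudyDesign)
    thresholds: AcceptanceThresholds = Field(default_factory=AcceptanceThresholds)
    bands: ClearanceBands = Field(default_factory=ClearanceBands)
    stability: StabilityOptions = Field(default_factory=StabilityOptions)

    # simulation blocks (None = do not simulate that stage)
    sim_calibration: Optional[simulate.CalibrationSimParams] = None
    sim_qc_batches: int = 3
    sim_qc_replicates: int = 6
    sim_matrix: Optional[MatrixSimBlock] = None
    sim_depletion: Optional[simulate.DepletionSimParams] = None
    n_calibration_curves: int = 3

    # file inputs (take precedence over simulation)
    standards_csv: Optional[str] = None
    qc_csv: Optional[str] = None
    matrix_set1_csv: Optional[str] = None
    matrix_set2_csv: Optional[str] = None
    timecourse_csv: Optional[str] = None
    blank_analyte_area: Optional[float] = None

    seed: Optional[int] = None
    out_dir: str = "microstab_run"


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load a RunConfig from YAML (or JSON, a YAML subset)."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    try:
        return RunConfig(**(payload or {}))
    except Exception as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def _require_seed(cfg: RunConfig) -> int:
    if cfg.seed is None:
        raise ConfigError("seed is required when any simulation block is present")
    return cfg.seed


def _json_ready(obj):
    if isinstance(obj, dict):
        return {k: _json_ready(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_ready(v) for v in obj]
    if hasattr(obj, "__dataclass_fields__"):
        return _json_ready(
            {k: getattr(obj, k) for k in obj.__dataclass_fields__}
        )
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and write the merged report.

    Returns the machine-readable report as a dict. On stage failure the
    partial outputs are retained next to a FAILED marker naming the
    stage, and the error is re-raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": []}
    stage = "setup"
    try:
        # ---- calibration -------------------------------------------------
        fit = None
        if config.standards_csv or config.sim_calibration:
            stage = "calibration"
            if config.standards_csv:
                standards = io.measurements_to_frame(
                    io.read_measurement_table(config.standards_csv)
                )
                curves = [standards]
            else:
                seed = _require_seed(config)
                params = config.sim_calibration
                curves = []
                for i in range(config.n_calibration_curves):
                    p = params.model_copy(update={"seed": seed + i})
                    curves.append(simulate.simulate_calibration(p, config.design))
                standards = curves[0]
            fits = [cal.fit_calibration(c) for c in curves]
            fit = fits[0]
            logger.info(
                "calibration: %d rows, slope=%.6g intercept=%.6g r2=%.6g",
                len(standards), fit.slope, fit.intercept, fit.r2,
            )
            # per-level back-calculation summary (Table-1 style)
            ratios = standards["analyte_area"] / standards["is_area"]
            back = fit.back_calculate(ratios.to_numpy())
            levels = []
            for nominal, grp in standards.assign(back=back).groupby("nominal_conc"):
                if len(grp) >= 2:
                    levels.append(cal.summarize_level(grp["back"], nominal))
            level_df = pd.DataFrame([_json_ready(s) for s in levels])
            level_df.to_csv(out / "calibration_levels.csv", index=False)
            cal_block = {
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r2": fit.r2,
                "n_points": fit.n_points,
                "levels": [_json_ready(s) for s in levels],
            }
            if len(fits) >= 2:
                lod, loq = cal.lod_loq(fits)
                cal_block["lod_ng_ml"] = lod
                cal_block["loq_ng_ml"] = loq
            report["calibration"] = cal_block
            report["stages"].append("calibration")

        # ---- validation --------------------------------------------------
        qc_stats: list[validation.QcStatistics] = []
        if config.qc_csv or (config.sim_calibration and fit is not None):
            stage = "validation"
            if config.qc_csv:
                qc = io.measurements_to_frame(io.read_measurement_table(config.qc_csv))
            else:
                qc = simulate.simulate_qc(
                    config.sim_calibration,
                    config.design,
                    n_replicates=config.sim_qc_replicates,
                    n_batches=config.sim_qc_batches,
                    seed=_require_seed(config) + 1000,
                )
            level_by_conc = {v: k for k, v in config.design.qc_levels.items()}
            qc = qc.assign(
                back=fit.back_calculate((qc["analyte_area"] / qc["is_area"]).to_numpy())
            )
            for nominal, grp in qc.groupby("nominal_conc"):
                name = level_by_conc.get(nominal, f"{nominal:g}")
                first = grp[grp["batch_id"] == grp["batch_id"].min()]
                qc_stats.append(
                    validation.qc_statistics(first["back"], nominal, "intra_batch", name)
                )
                if grp["batch_id"].nunique() > 1:
                    qc_stats.append(
                        validation.qc_statistics(grp["back"], nominal, "inter_batch", name)
                    )
            pd.DataFrame([_json_ready(s) for s in qc_stats]).to_csv(
                out / "qc_statistics.csv", index=False
            )
            logger.info("validation: %d QC rows, %d level stats", len(qc), len(qc_stats))
            report["qc_statistics"] = [_json_ready(s) for s in qc_stats]
            report["stages"].append("validation")

        matrix_result = None
        if (config.matrix_set1_csv and config.matrix_set2_csv) or config.sim_matrix:
            stage = "matrix_effect"
            if config.matrix_set1_csv:
                s1 = io.measurements_to_frame(io.read_measurement_table(config.matrix_set1_csv))
                s2 = io.measurements_to_frame(io.read_measurement_table(config.matrix_set2_csv))
            else:
                m = config.sim_matrix
                s1, s2 = simulate.simulate_matrix_effect_sets(
                    m.true_me_analyte, m.true_me_is, m.cv, m.n,
                    seed=_require_seed(config) + 2000,
                )
            me_analyte = validation.matrix_effect(s1["analyte_area"], s2["analyte_area"])
            me_is = validation.matrix_effect(s1["is_area"], s2["is_area"])
            matrix_result = validation.MatrixEffectResult(
                me_analyte_pct=me_analyte,
                me_is_pct=me_is,
                is_normalized_me=validation.is_normalized_me(me_analyte, me_is),
            )
            report["matrix_effect"] = _json_ready(matrix_result)
            report["stages"].append("matrix_effect")

        carry = None
        if config.blank_analyte_area is not None and fit is not None:
            stage = "carryover"
            lloq = min(config.design.qc_levels.values())
            # compare like with like: LLOQ response expressed as an area
            lloq_area = (fit.slope * lloq + fit.intercept) * simulate.IS_AREA
            carry = validation.carryover_check(
                config.blank_analyte_area, lloq_area, config.thresholds
            )
            report["carryover"] = _json_ready(carry)
            report["stages"].append("carryover")

        if qc_stats:
            stage = "acceptance"
            acceptance = validation.evaluate_acceptance(
                qc_stats,
                config.thresholds,
                calibration_r2=fit.r2 if fit else None,
                matrix_result=matrix_result,
                carryover=carry,
            )
            report["acceptance"] = {
                "overall_pass": acceptance.overall_pass,
                "criteria": [_json_ready(c) for c in acceptance.criteria],
            }
            report["stages"].append("acceptance")

        # ---- stability ---------------------------------------------------
        if config.timecourse_csv or config.sim_depletion:
            stage = "stability"
            if config.timecourse_csv:
                tc = io.read_timecourse_table(config.timecourse_csv)
            else:
                p = config.sim_depletion.model_copy(
                    update={"seed": _require_seed(config) + 3000}
                )
                tc = simulate.simulate_depletion(p)
            opts = config.stability
            model = stability.DepletionKinetics(
                mode=opts.mode,
                window=tuple(opts.window),
                min_points=opts.min_points,
                r2_floor=opts.r2_floor,
                slope_decimals=opts.slope_decimals,
                thalf_decimals=opts.thalf_decimals,
                design=config.design,
                bands=config.bands,
            ).fit(tc)
            model.timecourse_.to_frame().to_csv(out / "stability_timecourse.csv", index=False)
            res = model.result_
            pd.DataFrame([_json_ready(res)]).to_csv(out / "stability_result.csv", index=False)
            logger.info(
                "stability: %d timepoints, k=%.4g /min, t1/2=%.4g min, CLint=%.4g mL/min/kg (%s)",
                model.timecourse_.times_min.size, res.k_dep, res.t_half_min,
                res.clint_ml_min_kg, res.clearance_class,
            )
            report["stability"] = _json_ready(res)
            report["stages"].append("stability")

        report_json = _json_ready(report)
        with open(out / "report.json", "w") as fh:
            json.dump(report_json, fh, indent=2, sort_keys=True)
            fh.write("\n")
        (out / "summary.txt").write_text(render_summary(report_json))
        return report_json
    except MicrostabError:
        (out / "FAILED").write_text(f"stage: {stage}\n")
        logger.error("pipeline failed at stage %s", stage)
        raise


def render_summary(report: dict) -> str:
    """Human-readable run summary; every number here is also in the JSON."""
    lines = ["microstab run summary", "====================="]
    if "calibration" in report:
        c = report["calibration"]
        lines.append(
            f"calibration: ratio = {c['slope']:.6g} * conc + {c['intercept']:.6g}"
            f" (r2 = {c['r2']:.6g}, n = {c['n_points']})"
        )
        if "lod_ng_ml" in c:
            lines.append(
                f"  LOD = {c['lod_ng_ml']:.6g} ng/mL, LOQ = {c['loq_ng_ml']:.6g} ng/mL"
            )
    for s in report.get("qc_statistics", []):
        lines.append(
            f"QC {s['level_name']} ({s['scope']}, n={s['n']}): mean {s['mean']:.6g} ng/mL,"
            f" RSD {s['precision_rsd_pct']:.6g}%, accuracy {s['accuracy_pct']:.6g}%,"
            f" recovery {s['recovery_pct']:.6g}%"
        )
    if "matrix_effect" in report:
        m = report["matrix_effect"]
        lines.append(
            f"matrix effect: analyte {m['me_analyte_pct']:.6g}%, IS {m['me_is_pct']:.6g}%,"
            f" IS-normalized {m['is_normalized_me']:.6g}"
        )
    if "carryover" in report:
        c = report["carryover"]
        verdict = "pass" if c["passed"] else "FAIL"
        lines.append(
            f"carryover: {c['fraction_of_lloq']:.6g} of LLOQ (limit {c['limit']:.6g}) -> {verdict}"
        )
    if "acceptance" in report:
        a = report["acceptance"]
        lines.append(f"validation acceptance: {'PASS' if a['overall_pass'] else 'FAIL'}")
        for crit in a["criteria"]:
            if not crit["passed"]:
                lines.append(
                    f"  FAILED {crit['name']}: {crit['value']:.6g} vs {crit['limit']}"
                )
    if "stability" in report:
        s = report["stability"]
        lines.append(
            f"stability: ln(%remaining) = {s['slope']:.6g} * t + {s['intercept_ln']:.6g}"
            f" (r2 = {s['r2']:.6g}), window {s['window'][0]:g}-{s['window'][1]:g} min"
        )
        lines.append(
            f"  k = {s['k_dep']:.6g} /min, in vitro t1/2 = {s['t_half_min']:.6g} min,"
            f" CLint = {s['clint_ml_min_kg']:.6g} mL/min/kg"
            f" ({s['clint_ul_min_mg']:.6g} uL/min/mg), class = {s['clearance_class']}"
        )
    return "\n".join(lines) + "\n"
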