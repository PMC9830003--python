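"""End-to-end pipeline: synthesize → dehydration → OCT → MicroCT → statistics.

One call renders a full synthetic cohort, analyses every modality with the
measurement modules (never with the generator's ground truth), joins the
per-lesion measurements, runs the cohort statistics and writes a report
directory.  Everything is deterministic given the seed: the report files are
byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import activity_stats, microct, oct, synth
from .dehydration import analyze_stack
from .io import PipelineConfig, write_records

__all__ = ["analyze_cohort", "run_pipeline"]

log = logging.getLogger("cario")


def _measure_lesion(truth: synth.LesionTruth, config: synth.CohortConfig) -> dict:
    """Render and measure one lesion across all four modalities."""
    swir_stack, rois = synth.render_swir_stack(truth, config)
    thermal_stack, _ = synth.render_thermal_stack(truth, config)
    res_i = analyze_stack(swir_stack, rois)
    res_q = analyze_stack(thermal_stack, rois)

    oct_img = synth.render_oct_bscan(
        truth,
        axial_pitch_um_optical=config.oct_axial_pitch_um_optical,
        noise_sd=config.noise_sd_oct,
        rng=synth.lesion_rng(config.seed, truth.lesion_id, "oct"),
    )
    bscan = oct.BScan(image=oct_img, axial_pitch_um_optical=config.oct_axial_pitch_um_optical)
    morph = oct.measure_bscan(bscan, synth.oct_lesion_cols(oct_img.shape[1]))

    ct_img = synth.render_microct_slice(
        truth,
        pitch_um=config.microct_pitch_um,
        noise_sd=config.noise_sd_microct,
        rng=synth.lesion_rng(config.seed, truth.lesion_id, "microct"),
    )
    ct = microct.CtSlice(image=ct_img, pitch_um=config.microct_pitch_um)
    cols = synth.microct_lesion_cols(ct_img.shape[1])
    mid = (cols.start + cols.stop) // 2
    ct_morph = microct.line_profile_depth(
        ct, line=((0.0, float(mid)), (float(ct_img.shape[0] - 1), float(mid)))
    )

    return {
        "lesion_id": truth.lesion_id,
        "surface_type": truth.surface_type,
        "dI_diff": res_i.diff,
        "dI_ratio": res_i.ratio,
        "dQ_diff": res_q.diff,
        "dQ_ratio": res_q.ratio,
        "ld_oct_um": morph.lesion_depth_um,
        "delta_R": morph.delta_R,
        "tsl_um": morph.tsl_thickness_um,
        "tsl_detected": morph.tsl_detected,
        "ld_ct_um": ct_morph.lesion_depth_um,
        "sl_um": ct_morph.sl_thickness_um,
        "truth_tsl_um": truth.tsl_thickness_um,
        "truth_depth_um": truth.lesion_depth_um,
        "truth_mineral_loss": truth.mineral_loss_frac,
        "truth_permeability": truth.permeability,
    }


def analyze_cohort(config: synth.CohortConfig) -> pd.DataFrame:
    """Generate a cohort and measure every lesion; returns the joined table."""
    cohort = synth.sample_cohort(config)
    rows = [_measure_lesion(truth, config) for truth in cohort]
    return pd.DataFrame(rows)


def _report_to_jsonable(report: dict) -> dict:
    def convert(obj):
        if isinstance(obj, activity_stats.CorrelationReport):
            d = dataclasses.asdict(obj)
            d["pair"] = list(d["pair"])
            return d
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, (np.floating, float)):
            f = float(obj)
            return None if np.isnan(f) else f
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, np.bool_):
            return bool(obj)
        return obj

    return convert(report)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full workflow and write the report directory.

    Writes ``truth.csv`` (ground truth), ``records.csv`` (measured per-lesion
    table), ``correlations.csv`` and ``summary.json`` (statistics, seed and
    config echo).  Returns the report directory path.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
    log.info("pipeline start: seed=%d n=%d", config.seed, cohort_cfg.n_lesions)

    truth_frame = pd.DataFrame([dataclasses.asdict(t) for t in synth.sample_cohort(cohort_cfg)])
    truth_frame.to_csv(out / "truth.csv", index=False, float_format="%.10g")

    records = analyze_cohort(cohort_cfg)
    write_records(records, out / "records.csv")

    report = activity_stats.run_statistics(
        records,
        cut_um=config.tsl_cut_um,
        include_undetected=config.include_undetected_tsl,
        equal_var=config.equal_var_ttest,
    )
    corr_rows = [dataclasses.asdict(c) for c in report["correlations"]]
    for stratum, reports in report["surface_strata"].items():
        corr_rows.extend(dataclasses.asdict(c) for c in reports)
    for band in report["band_analysis"]["bands"].values():
        corr_rows.extend(dataclasses.asdict(c) for c in band.values())
    corr_frame = pd.DataFrame(corr_rows)
    corr_frame["pair"] = corr_frame["pair"].map(lambda p: f"{p[0]}~{p[1]}")
    corr_frame.to_csv(out / "correlations.csv", index=False, float_format="%.10g")

    summary = {
        "seed": config.seed,
        "n_lesions": report["n_lesions"],
        "n_tsl_detected": report["n_tsl_detected"],
        "tsl_cut_um": config.tsl_cut_um,
        "activity_class_counts": {
            c: int(n) for c, n in sorted(pd.Series(report["activity_class"]).value_counts().items())
        },
        "band_analysis": _report_to_jsonable(report["band_analysis"]),
        "correlations": _report_to_jsonable(report["correlations"]),
        "config": {
            "cohort": dataclasses.asdict(cohort_cfg),
            "tsl_cut_um": config.tsl_cut_um,
            "include_undetected_tsl": config.include_undetected_tsl,
            "equal_var_ttest": config.equal_var_ttest,
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=1))
    log.info("pipeline done: report in %s", out)
    return out
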