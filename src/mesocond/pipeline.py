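"""Study-level drought analysis: RSWC staging, summaries, group contrasts.

Drought stress is staged by relative soil water content: well-watered
(RSWC > 50%), moderate (50-35%) and severe (< 35%), with boundary values
falling to the drier stage.  Within each stage x genotype cell the gas
exchange and gm variables are summarized and contrasted between wild type
and mutant by a Welch two-sample t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import fluorescence, laisk as laisk_mod, variable_j
from .fvcb import fit_fvcb, aci_to_acc
from .io import GasExchangeRecord, PotWeights, compute_rswc, records_to_frame
from .simulate import laisk_curves_from_records

log = logging.getLogger("mesocond.pipeline")


@dataclass(frozen=True)
class DroughtStage:
    label: str
    rswc_low: float
    rswc_high: float


#: half-open bins, upper-exclusive; boundary RSWC falls to the drier stage
STAGES = (
    DroughtStage("severe", 0.0, 35.0),
    DroughtStage("moderate", 35.0, 50.0),
    DroughtStage("well_watered", 50.0, float("inf")),
)

#: variables summarized per stage and genotype
SUMMARY_VARIABLES = ("An", "gsw", "gm", "wue_i", "drawdown_surface", "drawdown_mesophyll")


def assign_stage(rswc: float) -> str:
    """Stage label for a positive RSWC percentage."""
    if rswc <= 0:
        raise ValueError("RSWC must be positive")
    for stage in STAGES:
        if stage.rswc_low < rswc <= stage.rswc_high:
            return stage.label
    raise AssertionError("unreachable: stages partition (0, inf)")


def welch_contrast(a: np.ndarray, b: np.ndarray) -> float:
    """Welch two-sample t-test p-value; identical degenerate groups give p = 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        return float("nan")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def summarize(df: pd.DataFrame, variables=SUMMARY_VARIABLES,
              reference_genotype: str | None = None) -> pd.DataFrame:
    """Per stage x genotype x variable summary with WT-vs-mutant contrasts.

    ``df`` must carry ``genotype``, ``stage`` and the variable columns.  Each
    record is one observation (no per-plant averaging).  The contrast column
    holds the Welch p-value against the reference genotype (default: first
    genotype in sorted order) within the same stage; cells with n < 2 skip
    the contrast with a note.
    """
    if df.empty:
        raise ValueError("nothing to summarize")
    genotypes = sorted(df["genotype"].unique())
    ref = reference_genotype or genotypes[0]
    rows = []
    for stage in [s.label for s in STAGES]:
        stage_df = df[df["stage"] == stage]
        for geno in genotypes:
            cell = stage_df[stage_df["genotype"] == geno]
            for var in variables:
                vals = cell[var].dropna().to_numpy() if not cell.empty else np.array([])
                row = {
                    "genotype": geno, "stage": stage, "variable": var, "n": vals.size,
                    "mean": vals.mean() if vals.size else np.nan,
                    "sd": vals.std(ddof=1) if vals.size > 1 else np.nan,
                    "median": np.median(vals) if vals.size else np.nan,
                    "q25": np.percentile(vals, 25) if vals.size else np.nan,
                    "q75": np.percentile(vals, 75) if vals.size else np.nan,
                    "contrast_p": np.nan,
                    "note": "",
                }
                if geno != ref:
                    ref_vals = stage_df[stage_df["genotype"] == ref][var].dropna().to_numpy()
                    if vals.size >= 2 and ref_vals.size >= 2:
                        row["contrast_p"] = welch_contrast(ref_vals, vals)
                    else:
                        row["note"] = "contrast skipped: n < 2"
                rows.append(row)
    return pd.DataFrame(rows)


def estimate_study_gm(
    survey: list[GasExchangeRecord],
    calibration: list[GasExchangeRecord],
    laisk_records: list[GasExchangeRecord],
    gamma_star_mode: str = "iterative",
    laisk_rd_for_calibration: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Per-record gm estimates for a whole study.

    For each genotype: calibrate the fluorescence J from its 1% O2 curve
    (using the Laisk Rd inside PhiCO2), run the Laisk intersection, resolve
    Gamma*, then estimate gm for every survey record of that genotype.
    Returns the estimates joined to the survey frame, plus per-genotype
    calibration/Laisk provenance.
    """
    frame = records_to_frame(survey)
    by_geno: dict[str, dict] = {}
    est_rows = []
    for geno in sorted({r.genotype for r in survey}):
        geno_cal_recs = [r for r in calibration if r.genotype == geno]
        geno_laisk = [r for r in laisk_records if r.genotype == geno]
        geno_survey = [r for r in survey if r.genotype == geno]
        curves = laisk_curves_from_records(geno_laisk)
        lk = laisk_mod.estimate_laisk(curves)
        rd_for_cal = lk.Rd if laisk_rd_for_calibration else 0.0
        cal = fluorescence.calibrate(geno_cal_recs, rd_for_cal)
        estimates, resolved = variable_j.estimate_gm_chain(
            geno_survey, cal, lk, gamma_star_mode=gamma_star_mode)
        by_geno[geno] = {"calibration": cal, "laisk": resolved}
        for rec, est in zip(geno_survey, estimates):
            est_rows.append({
                "genotype": geno, "plant_id": rec.plant_id, "day": rec.day,
                "curve_id": rec.curve_id, "An": rec.An, "gsw": rec.gsw,
                "Ci_corr": est.Ci_corr, "Cc": est.Cc, "gm": est.gm,
                "J_used": est.J_used, "gsc": est.gsc, "wue_i": est.wue_i,
                "drawdown_surface": est.drawdown_surface,
                "drawdown_mesophyll": est.drawdown_mesophyll,
                "reliable": est.reliable, "sensitivity": est.sensitivity,
            })
    del frame
    return pd.DataFrame(est_rows), by_geno


def run_pipeline(bundle: dict, gamma_star_mode: str = "iterative") -> dict:
    """Run the full study analysis over an in-memory bundle.

    ``bundle`` is the structure produced by :func:`mesocond.simulate.simulate_study`
    (or assembled from CSVs read with :mod:`mesocond.io`).  Returns stage
    summaries, the per-record gm table, per-genotype calibration and Laisk
    results, FvCB fits of the day-0 calibration-grade curves, and the
    anatomical comparison when anatomy rows are present.
    """
    estimates, provenance = estimate_study_gm(
        bundle["survey"], bundle["calibration"], bundle["laisk"],
        gamma_star_mode=gamma_star_mode)

    pots = pd.DataFrame(bundle["pot_weights"])
    pots["rswc"] = [
        compute_rswc(PotWeights(PW=r.PW, DW=r.DW, t0W=r.t0W))
        for r in pots.itertuples()
    ]
    joined = estimates.merge(pots[["plant_id", "day", "rswc"]], on=["plant_id", "day"])
    joined["stage"] = joined["rswc"].map(assign_stage)
    usable = joined[joined["reliable"]]
    if len(usable) < len(joined):
        log.warning("%d unreliable gm estimates excluded from summaries",
                    len(joined) - len(usable))
    summaries = summarize(usable)

    anat_result = None
    if bundle.get("anatomy"):
        from .anatomy import AnatomyMeasurements, compose_gm, compare_genotypes

        results = {}
        for row in bundle["anatomy"]:
            fields = {k: v for k, v in row.items()
                      if k in AnatomyMeasurements.__dataclass_fields__ and v is not None}
            results[row["genotype"]] = compose_gm(AnatomyMeasurements(**fields))
        anat_result = {"per_genotype": results}
        genos = list(results)
        if len(genos) == 2:
            anat_result["comparison"] = compare_genotypes(results[genos[0]], results[genos[1]])

    return {
        "estimates": joined,
        "summaries": summaries,
        "provenance": provenance,
        "anatomy": anat_result,
    }
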