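"""DAS28-ESR and SDAI disease-activity scoring, EULAR/SDAI response
classification and cohort response summaries for rheumatoid arthritis.

DAS28-ESR (standard published coefficients):

    DAS28 = 0.56*sqrt(TJC28) + 0.28*sqrt(SJC28) + 0.70*ln(ESR) + 0.014*GH

with TJC28/SJC28 the 28-joint tender/swollen counts, ESR in mm/h and GH
the patient global assessment on a 0-100 mm scale. Categories: < 2.6
remission, 2.6-3.2 low, > 3.2-5.1 moderate, > 5.1 high.

SDAI = TJC28 + SJC28 + PGA + EGA + CRP with the patient/physician globals
in cm (0-10) and CRP in mg/dL; remission at SDAI <= 3.3. SDAI response is
the percent reduction from baseline: > 85% major (MaR), > 70% moderate
(MoR), > 50% minor (MiR).

EULAR response from DAS28 improvement (delta = baseline - attained) and
the attained level: good (GR) if delta > 1.2 and attained <= 3.2; moderate
(MR) if delta > 1.2 at higher attained levels or 0.6 < delta <= 1.2 with
attained <= 5.1; otherwise no response (NR). A patient in remission at
both timepoints whose grid result would be NR is labelled stable
remission (SR).

The packaged `table1.csv` fixture transcribes the study cohort's printed
DAS28/SDAI values and demographics; `cohort_summary` recomputes the
cohort-level response numbers from it.
"""

from __future__ import annotations

import math
from importlib import resources

import numpy as np
import pandas as pd

DAS28_REMISSION = 2.6
DAS28_LOW_MAX = 3.2
DAS28_MODERATE_MAX = 5.1
SDAI_REMISSION_MAX = 3.3

#: RF/ACPA positivity cutoffs (U/L). The RF assay floors at 14, so RF
#: positivity is strict (> 14); ACPA at >= 17. Both inferred from assay
#: conventions, configurable at call sites.
RF_THRESHOLD = 14.0
ACPA_THRESHOLD = 17.0


def das28_esr(tjc28: float, sjc28: float, esr: float, gh: float) -> float:
    """DAS28 from the ESR variant of the composite score.

    tjc28/sjc28: tender/swollen 28-joint counts (0-28); esr: erythrocyte
    sedimentation rate in mm/h (> 0); gh: patient global health on a
    0-100 mm visual analogue scale.
    """
    if not 0 <= tjc28 <= 28 or not 0 <= sjc28 <= 28:
        raise ValueError("joint counts must be within 0..28")
    if esr <= 0:
        raise ValueError("ESR must be positive for DAS28-ESR")
    if not 0 <= gh <= 100:
        raise ValueError("GH must be on a 0-100 mm scale")
    return (
        0.56 * math.sqrt(tjc28)
        + 0.28 * math.sqrt(sjc28)
        + 0.70 * math.log(esr)
        + 0.014 * gh
    )


def sdai(tjc28: float, sjc28: float, pga: float, ega: float, crp: float) -> float:
    """Simplified disease activity index: plain sum of joint counts,
    patient and physician globals (cm, 0-10) and CRP (mg/dL)."""
    if not 0 <= tjc28 <= 28 or not 0 <= sjc28 <= 28:
        raise ValueError("joint counts must be within 0..28")
    if not 0 <= pga <= 10 or not 0 <= ega <= 10:
        raise ValueError("globals must be on a 0-10 cm scale")
    if crp < 0:
        raise ValueError("CRP must be >= 0")
    return float(tjc28 + sjc28 + pga + ega + crp)


def das28_category(score: float) -> str:
    """remission < 2.6; low 2.6-3.2; moderate > 3.2-5.1; high > 5.1."""
    if score < 0:
        raise ValueError("DAS28 must be >= 0")
    if score < DAS28_REMISSION:
        return "remission"
    if score <= DAS28_LOW_MAX:
        return "low"
    if score <= DAS28_MODERATE_MAX:
        return "moderate"
    return "high"


def sdai_category(score: float) -> str:
    """remission <= 3.3; low <= 11; moderate <= 26; high above."""
    if score < 0:
        raise ValueError("SDAI must be >= 0")
    if score <= SDAI_REMISSION_MAX:
        return "remission"
    if score <= 11:
        return "low"
    if score <= 26:
        return "moderate"
    return "high"


def sdai_response(sdai_t0: float, sdai_t3: float) -> dict:
    """SDAI percent change and response class.

    percent_change = 100 * (t3 - t0) / t0; a reduction > 85% is a major
    response (MaR), > 70% moderate (MoR), > 50% minor (MiR), otherwise
    'none'. Remission if the attained SDAI is <= 3.3.
    """
    if sdai_t0 <= 0:
        raise ValueError("SDAI response undefined for baseline SDAI <= 0")
    pct = 100.0 * (sdai_t3 - sdai_t0) / sdai_t0
    reduction = -pct
    if reduction > 85:
        response = "MaR"
    elif reduction > 70:
        response = "MoR"
    elif reduction > 50:
        response = "MiR"
    else:
        response = "none"
    return {
        "percent_change": pct,
        "response": response,
        "remission": sdai_t3 <= SDAI_REMISSION_MAX,
    }


def eular_response(das28_t0: float, das28_t3: float) -> str:
    """EULAR response from DAS28 improvement and attained level.

    Standard grid; the stable-remission label (SR) applies only when both
    scores are below the remission cut and the grid itself would say NR.
    """
    delta = das28_t0 - das28_t3
    if delta > 1.2:
        grid = "GR" if das28_t3 <= DAS28_LOW_MAX else "MR"
    elif delta > 0.6 and das28_t3 <= DAS28_MODERATE_MAX:
        grid = "MR"
    else:
        grid = "NR"
    if (
        grid == "NR"
        and das28_t0 < DAS28_REMISSION
        and das28_t3 < DAS28_REMISSION
    ):
        return "SR"
    return grid


def seropositivity(
    rf: float,
    acpa: float,
    rf_threshold: float = RF_THRESHOLD,
    acpa_threshold: float = ACPA_THRESHOLD,
) -> dict:
    """RF/ACPA positivity flags; seropositive if either is positive.

    RF positivity is strict (> threshold: the assay reports 14 as a floor
    value), ACPA positivity inclusive (>= threshold).
    """
    rf_pos = rf > rf_threshold
    acpa_pos = acpa >= acpa_threshold
    return {
        "rf_positive": bool(rf_pos),
        "acpa_positive": bool(acpa_pos),
        "seropositive": bool(rf_pos or acpa_pos),
    }


def load_table1() -> pd.DataFrame:
    """Packaged transcription of the study cohort's clinical table
    (DAS28/SDAI scores at T0..T3, demographics, serology, therapy).

    Columns ending in `_printed` carry the labels as printed in the
    source table; all response/category labels are otherwise recomputed.
    """
    with resources.files("microfast.data").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh)


def score_panel(scores: pd.DataFrame) -> pd.DataFrame:
    """Derived per-patient panel from a DAS28/SDAI score table.

    Expects columns patient, das28_t0..das28_t3, sdai_t0..sdai_t3 and
    adds deltas, categories, EULAR and SDAI responses and remission flags.
    """
    out = scores.copy()
    out["delta_das28"] = out["das28_t3"] - out["das28_t0"]
    out["sdai_pct_change"] = 100.0 * (out["sdai_t3"] - out["sdai_t0"]) / out["sdai_t0"]
    for tp in ("t0", "t1", "t2", "t3"):
        out[f"das28_category_{tp}"] = out[f"das28_{tp}"].map(das28_category)
    out["sdai_category_t3"] = out["sdai_t3"].map(sdai_category)
    for tp in ("t1", "t2", "t3"):
        out[f"eular_response_{tp}"] = [
            eular_response(r.das28_t0, getattr(r, f"das28_{tp}"))
            for r in out.itertuples()
        ]
    out["eular_response"] = out["eular_response_t3"]
    # best response attained at any post-baseline timepoint (GR > MR > SR > NR)
    order = {"GR": 3, "MR": 2, "SR": 1, "NR": 0}
    out["eular_best"] = (
        out[["eular_response_t1", "eular_response_t2", "eular_response_t3"]]
        .apply(lambda row: max(row, key=order.get), axis=1)
    )
    out["sdai_response"] = [
        sdai_response(r.sdai_t0, r.sdai_t3)["response"] for r in out.itertuples()
    ]
    out["das28_remission_t3"] = out["das28_t3"] < DAS28_REMISSION
    out["sdai_remission_t3"] = out["sdai_t3"] <= SDAI_REMISSION_MAX
    return out


def cohort_summary(scores: pd.DataFrame) -> dict:
    """Cohort-level response summary from a DAS28/SDAI score table.

    Returns the median per-patient DAS28 change and SDAI percent change
    (T3 vs T0), the number of improved patients, remission counts per
    timepoint, response-category tallies and demographic/serology
    summaries where the columns are present. Medians of even-sized
    cohorts average the two central values.
    """
    if len(scores) == 0:
        raise ValueError("empty score table")
    panel = score_panel(scores)
    n = len(panel)
    summary = {
        "n_patients": n,
        "median_delta_das28": float(panel["delta_das28"].median()),
        "median_sdai_pct_change": float(panel["sdai_pct_change"].median()),
        "n_improved": int((panel["delta_das28"] < 0).sum()),
        "largest_das28_decrease": float(panel["delta_das28"].min()),
        "das28_remission": {
            tp.upper(): int((panel[f"das28_{tp}"] < DAS28_REMISSION).sum())
            for tp in ("t0", "t1", "t2", "t3")
        },
        "sdai_remission_t3": int(panel["sdai_remission_t3"].sum()),
        "eular_counts": panel["eular_response"].value_counts().to_dict(),
        "eular_best_counts": panel["eular_best"].value_counts().to_dict(),
        "sdai_response_counts": panel["sdai_response"].value_counts().to_dict(),
        "n_nonresponders": int((panel["eular_response"] == "NR").sum()),
    }
    if "age" in panel.columns:
        summary["age"] = {
            "mean": float(panel["age"].mean()),
            "min": float(panel["age"].min()),
            "max": float(panel["age"].max()),
        }
    if "bmi" in panel.columns:
        summary["bmi"] = {
            "mean": float(panel["bmi"].mean()),
            "min": float(panel["bmi"].min()),
            "max": float(panel["bmi"].max()),
        }
    if {"rf_u_l", "acpa_u_l"} <= set(panel.columns):
        sero = [
            seropositivity(r.rf_u_l, r.acpa_u_l) for r in panel.itertuples()
        ]
        summary["serology"] = {
            "rf_positive": sum(s["rf_positive"] for s in sero),
            "acpa_positive": sum(s["acpa_positive"] for s in sero),
            "seropositive": sum(s["seropositive"] for s in sero),
        }
    return summary
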