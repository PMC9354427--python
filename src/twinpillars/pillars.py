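"""Coding of raw twin-survey responses into health pillars and outcomes.

Five dichotomous lifestyle "pillars" are derived from self-report items:

* **sleep** -- at least 8 h of sleep per night (7 h under the sensitivity
  standard),
* **fruit/vegetables** -- roughly five or more daily servings combined,
  coded from two ordinal serving-category items,
* **sedentary time** -- at most 2 h per day of sitting screen time,
* **MVPA** -- at least 150 min/week of moderate-to-vigorous physical
  activity, reconstructed from days/week of vigorous (20-min bouts) and
  moderate (30-min bouts) activity,
* **non-smoking** -- not a current smoker.

Each indicator is tri-state: ``1.0`` (met), ``0.0`` (not met), ``NaN``
(missing).  The pillar count 0-5 is the sum of the indicators and is
missing whenever any single indicator is missing -- a count from partial
data would only be a lower bound, not a sum.

Outcomes: BMI (kg/m^2) from US-customary height/weight, analysed on the
natural-log scale; the two-item PHQ-2 depression screener summed to 0-6,
analysed on the square-root scale.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FV_LEVELS",
    "SEDENTARY_LEVELS",
    "PILLAR_COLUMNS",
    "PILLAR_ORDER",
    "compute_bmi",
    "code_sleep",
    "code_fruit_veg",
    "compute_mvpa_minutes",
    "code_mvpa",
    "code_sedentary",
    "code_smoking",
    "count_pillars",
    "code_dataset",
    "read_registry",
]

#: ordinal serving categories for the fruit and vegetable items
FV_LEVELS = ["0", "1-2", "3-4", "5+"]
#: ordinal daily sedentary-time categories
SEDENTARY_LEVELS = ["0h", "1-2h", "3-4h", "5+h"]

#: canonical pillar order, used for tie-breaking throughout the package
PILLAR_ORDER = ("sleep", "fv", "sedentary", "mvpa", "nonsmoking")
PILLAR_COLUMNS = tuple(f"{p}_met" for p in PILLAR_ORDER)

MVPA_TARGET_MINUTES = 150
VIGOROUS_BOUT_MIN = 20
MODERATE_BOUT_MIN = 30

SLEEP_STANDARDS = {"8h": 8.0, "7h": 7.0}


def _rank(values, levels) -> np.ndarray:
    """Map ordinal category labels to integer ranks; unknown/missing -> NaN."""
    mapping = {lab: i for i, lab in enumerate(levels)}
    s = pd.Series(values)
    out = s.map(mapping).astype(float)
    bad = s.notna() & out.isna()
    if bad.any():
        logger.warning("%d unrecognized ordinal labels set to missing", int(bad.sum()))
    return out.to_numpy()


def compute_bmi(height_in, weight_lb):
    """BMI in kg/m^2 from height in inches and weight in pounds (703 w / h^2).

    Non-positive or missing inputs yield NaN (logged), never an exception.
    """
    h = np.asarray(pd.to_numeric(pd.Series(height_in), errors="coerce"), float)
    w = np.asarray(pd.to_numeric(pd.Series(weight_lb), errors="coerce"), float)
    with np.errstate(invalid="ignore", divide="ignore"):
        valid = (h > 0) & (w > 0)
        bmi = np.where(valid, 703.0 * w / np.square(h), np.nan)
    n_bad = int(np.sum(~valid & ~(np.isnan(h) | np.isnan(w))))
    if n_bad:
        logger.warning("%d non-positive height/weight values set to missing", n_bad)
    return bmi if bmi.ndim else float(bmi)


def code_sleep(sleep_hours, standard: str = "8h"):
    """Sleep pillar: met iff average nightly sleep >= the standard (8 h or 7 h)."""
    if standard not in SLEEP_STANDARDS:
        raise ValueError(f"sleep standard must be one of {sorted(SLEEP_STANDARDS)}")
    cut = SLEEP_STANDARDS[standard]
    h = np.asarray(pd.to_numeric(pd.Series(sleep_hours), errors="coerce"), float)
    neg = h < 0
    if np.any(neg):
        logger.warning("%d negative sleep durations set to missing", int(neg.sum()))
        h = np.where(neg, np.nan, h)
    out = np.where(np.isnan(h), np.nan, (h >= cut).astype(float))
    return out


def code_fruit_veg(fruit_cat, veg_cat, symmetric: bool = False):
    """Fruit/vegetable pillar from the two ordinal serving items.

    The default ("literal") rule codes *met* when

    * fruit >= "3-4" servings and vegetables >= "1-2", or
    * vegetables = "5+" and fruit >= "1-2".

    ``symmetric=True`` additionally grants *met* for vegetables = "3-4"
    with fruit >= "1-2", mirroring the fruit clause on the vegetable side.
    """
    f = _rank(fruit_cat, FV_LEVELS)
    v = _rank(veg_cat, FV_LEVELS)
    met = ((f >= 2) & (v >= 1)) | ((v == 3) & (f >= 1))
    if symmetric:
        met = met | ((v == 2) & (f >= 1))
    out = np.where(np.isnan(f) | np.isnan(v), np.nan, met.astype(float))
    return out


def compute_mvpa_minutes(vigorous_days, moderate_days):
    """Weekly MVPA minutes: 20 min x vigorous days + 30 min x moderate days."""
    vd = np.asarray(pd.to_numeric(pd.Series(vigorous_days), errors="coerce"), float)
    md = np.asarray(pd.to_numeric(pd.Series(moderate_days), errors="coerce"), float)
    bad = (vd < 0) | (vd > 7) | (md < 0) | (md > 7)
    if np.any(bad):
        logger.warning("%d activity-day values outside 0-7 set to missing", int(bad.sum()))
    vd = np.where(bad, np.nan, vd)
    md = np.where(bad, np.nan, md)
    return VIGOROUS_BOUT_MIN * vd + MODERATE_BOUT_MIN * md


def code_mvpa(vigorous_days, moderate_days):
    """MVPA pillar: met iff reconstructed weekly minutes >= 150."""
    minutes = compute_mvpa_minutes(vigorous_days, moderate_days)
    return np.where(np.isnan(minutes), np.nan, (minutes >= MVPA_TARGET_MINUTES).astype(float))


def code_sedentary(sedentary_cat):
    """Sedentary pillar: met for the "0h" or "1-2h" daily categories."""
    r = _rank(sedentary_cat, SEDENTARY_LEVELS)
    return np.where(np.isnan(r), np.nan, (r <= 1).astype(float))


def code_smoking(current_smoker):
    """Non-smoking pillar: met iff not currently smoking."""
    s = pd.Series(current_smoker)
    num = s.map({True: 1.0, False: 0.0, "True": 1.0, "False": 0.0, 1: 1.0, 0: 0.0})
    num = pd.to_numeric(num, errors="coerce")
    return np.where(num.isna(), np.nan, (num == 0).astype(float))


def count_pillars(indicators) -> np.ndarray:
    """Pillar count 0-5; missing whenever any of the five indicators is missing."""
    arr = np.column_stack([np.asarray(c, float) for c in indicators])
    if arr.shape[1] != 5:
        raise ValueError("expected five pillar indicators")
    total = arr.sum(axis=1)
    total[np.isnan(arr).any(axis=1)] = np.nan
    return total


def code_dataset(
    df: pd.DataFrame, sleep_standard: str = "8h", symmetric_fv: bool = False
) -> pd.DataFrame:
    """Append pillar indicators, pillar count, and transformed outcomes.

    Expects the raw registry schema (one row per twin); returns a copy with
    ``bmi, log_bmi, phq_total, sqrt_phq``, the five ``*_met`` indicators,
    and ``n_pillars`` columns.  Re-coding a coded frame is idempotent.
    """
    out = df.copy()
    out["bmi"] = compute_bmi(df["height"], df["weight"])
    with np.errstate(invalid="ignore"):
        out["log_bmi"] = np.log(out["bmi"].to_numpy(float))
    p1 = pd.to_numeric(df["phq_item1"], errors="coerce")
    p2 = pd.to_numeric(df["phq_item2"], errors="coerce")
    ok = p1.between(0, 3) & p2.between(0, 3)
    total = np.where(ok, p1 + p2, np.nan)
    out["phq_total"] = total
    out["sqrt_phq"] = np.sqrt(total)

    out["sleep_met"] = code_sleep(df["sleep_duration"], sleep_standard)
    out["fv_met"] = code_fruit_veg(df["fruit_cat"], df["veg_cat"], symmetric_fv)
    out["sedentary_met"] = code_sedentary(df["sedentary_cat"])
    out["mvpa_met"] = code_mvpa(df["vigorous_days"], df["moderate_days"])
    out["nonsmoking_met"] = code_smoking(df["current_smoker"])
    out["n_pillars"] = count_pillars([out[c] for c in PILLAR_COLUMNS])
    return out


def read_registry(path) -> pd.DataFrame:
    """Read a raw registry CSV, keeping ordinal categories as strings."""
    df = pd.read_csv(
        path,
        dtype={
            "family_id": str,
            "zygosity": str,
            "sex": str,
            "fruit_cat": str,
            "veg_cat": str,
            "sedentary_cat": str,
            "race": str,
        },
    )
    return df
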