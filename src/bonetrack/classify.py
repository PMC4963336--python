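"""Per-lesion response classification from two-time-point uptake.

A lesion is called progressive when its uptake rises by strictly more than
the threshold (default 30 %), regressive when it falls by strictly more than
the threshold, and stable otherwise — the RECIST/PERCIST-style rule applied
to SUV_peak (absolute mode) or to the lesion-to-reference uptake ratio
(ratio mode). A change of exactly +/-30 % is stable (strict inequalities).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

CATEGORIES = ("progressive", "stable", "regressive")

logger = logging.getLogger(__name__)


def fractional_change(v1: float, v2: float) -> float:
    """(v2 - v1) / v1 for positive baseline v1."""
    if v1 <= 0:
        raise ValueError("baseline uptake must be positive")
    return (v2 - v1) / v1


def classify_change(delta: float, threshold: float = 0.30) -> str:
    """Map a fractional change to progressive / stable / regressive."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if delta > threshold:
        return "progressive"
    if delta < -threshold:
        return "regressive"
    return "stable"


@dataclass(frozen=True)
class LesionChange:
    """One lesion's uptake pair, fractional change and category."""

    lesion_id: str
    value_tp1: float
    value_tp2: float
    delta: float
    mode: str
    category: str


def _lesion_values(metrics: pd.DataFrame, mode: str) -> pd.Series:
    """Per-lesion analysis value for one time point's metrics table.

    Absolute mode: SUV_peak. Ratio mode: SUV_peak / reference SUV_mean. With
    a ``subject`` column, each lesion is normalised by its own subject's
    reference row; otherwise the table's single reference row applies to all
    lesions. Lesions whose subject has no usable reference get NaN.
    """
    lesions = metrics[metrics["label"] == "lesion"].set_index("voi_id")
    values = lesions["suv_peak"].astype(float)
    if mode != "ratio":
        return values
    refs = metrics[metrics["label"] == "reference"]
    if "subject" in metrics.columns:
        ref_by_subject = {
            r.subject: float(r.suv_mean) for r in refs.itertuples() if r.suv_mean > 0
        }
        denom = lesions["subject"].map(ref_by_subject)
        return values / denom.astype(float)
    if len(refs) == 0 or float(refs["suv_mean"].iloc[0]) <= 0:
        return pd.Series(np.nan, index=values.index)
    return values / float(refs["suv_mean"].iloc[0])


def classify_lesions(
    metrics_tp1: pd.DataFrame,
    metrics_tp2: pd.DataFrame,
    mode: str = "absolute",
    threshold: float = 0.30,
) -> pd.DataFrame:
    """Classify every lesion present at both time points.

    Inputs are metrics tables as produced by ``quant.extract_metrics`` (one
    row per VOI, with ``voi_id``, ``label``, ``suv_peak``, ``suv_mean``).
    Lesion ids must match across time points. In ratio mode, lesions without
    a usable reference region are excluded with a logged notice; the output
    then contains only the ratio-evaluable lesions.

    Returns a table with columns lesion_id, mode, value_tp1, value_tp2,
    delta, category.
    """
    if mode not in ("absolute", "ratio"):
        raise ValueError(f"mode must be 'absolute' or 'ratio', got {mode!r}")
    v1 = _lesion_values(metrics_tp1, mode)
    v2 = _lesion_values(metrics_tp2, mode)
    if set(v1.index) != set(v2.index):
        missing = set(v1.index) ^ set(v2.index)
        raise ValueError(f"lesion ids differ between time points: {sorted(missing)}")
    v2 = v2.reindex(v1.index)
    usable = v1.notna() & v2.notna()
    n_skipped = int((~usable).sum())
    if n_skipped:
        logger.info(
            "ratio mode: %d lesion(s) without a usable reference region excluded",
            n_skipped,
        )
    rows = []
    for lesion_id in v1.index[usable]:
        a, b = float(v1[lesion_id]), float(v2[lesion_id])
        delta = fractional_change(a, b)
        rows.append(
            {
                "lesion_id": lesion_id,
                "mode": mode,
                "value_tp1": a,
                "value_tp2": b,
                "delta": delta,
                "category": classify_change(delta, threshold),
            }
        )
    out = pd.DataFrame(rows, columns=["lesion_id", "mode", "value_tp1", "value_tp2", "delta", "category"])
    out.attrs["n_skipped_no_reference"] = n_skipped
    return out
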