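"""File I/O, study bundles, and reconstruction of published agreement tables.

The fixtures below transcribe the per-reader classification tallies of a
19-patient longitudinal bone-SPECT/CT cohort: 52 osseous metastases
classified progressive/stable/regressive by each of two readers, visually on
planar scintigraphy and on SPECT/CT, and quantitatively from SUV_peak
changes; 46 of the lesions additionally via lesion-to-reference uptake
ratios. Only marginal counts per method plus the number of lesions rated
discrepantly between each visual reading and the quantitative reading were
published — which is exactly enough to recompute the aggregated inter-method
Cohen's kappas, since unweighted kappa depends only on marginals and the
agreement count.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .agreement import (
    CATEGORIES,
    KappaResult,
    MarginalSummary,
    RatingVector,
    kappa_from_marginals,
)
from .geometry import EllipsoidVOI
from .quant import AcquisitionMeta
from .volumes import VoxelVolume, read_nifti

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# published-cohort fixtures (category order: progressive, stable, regressive)
# --------------------------------------------------------------------------

#: Absolute-SUV_peak comparison, 52 lesions per reader. Per reader:
#: marginals of the quantitative classification, of each visual method, and
#: the count of lesions where that visual method disagreed with quantitative.
ABSOLUTE_CLASSIFICATION_COUNTS = {
    "n_per_reader": 52,
    "reader1": {
        "quantitative": (13, 13, 26),
        "visual_planar": {"marginals": (15, 21, 16), "n_discrepant_vs_quant": 18},
        "visual_spect": {"marginals": (11, 16, 25), "n_discrepant_vs_quant": 11},
    },
    "reader2": {
        "quantitative": (12, 15, 25),
        "visual_planar": {"marginals": (20, 12, 20), "n_discrepant_vs_quant": 22},
        "visual_spect": {"marginals": (18, 12, 22), "n_discrepant_vs_quant": 14},
    },
}

#: Uptake-ratio comparison, 46 lesions per reader (reference region
#: available in 17 of 19 patients).
RATIO_CLASSIFICATION_COUNTS = {
    "n_per_reader": 46,
    "reader1": {
        "quantitative": (12, 20, 14),
        "visual_planar": {"marginals": (14, 18, 14), "n_discrepant_vs_quant": 14},
        "visual_spect": {"marginals": (10, 15, 21), "n_discrepant_vs_quant": 16},
    },
    "reader2": {
        "quantitative": (10, 22, 14),
        "visual_planar": {"marginals": (19, 9, 18), "n_discrepant_vs_quant": 23},
        "visual_spect": {"marginals": (18, 8, 20), "n_discrepant_vs_quant": 19},
    },
}


def validate_fixtures() -> None:
    """Check that every transcribed marginal row sums to its lesion count."""
    for fix in (ABSOLUTE_CLASSIFICATION_COUNTS, RATIO_CLASSIFICATION_COUNTS):
        n = fix["n_per_reader"]
        for reader in ("reader1", "reader2"):
            block = fix[reader]
            if sum(block["quantitative"]) != n:
                raise ValueError(f"{reader} quantitative marginals do not sum to {n}")
            for method in ("visual_planar", "visual_spect"):
                if sum(block[method]["marginals"]) != n:
                    raise ValueError(f"{reader} {method} marginals do not sum to {n}")


def aggregated_marginals(fixtures: dict, visual_method: str) -> MarginalSummary:
    """Pool both readers' counts for one visual-vs-quantitative comparison.

    Marginals and discrepancy counts add across readers (each reader
    contributes n_per_reader independent lesion ratings to the pooled set).
    """
    n = 2 * fixtures["n_per_reader"]
    visual = tuple(
        fixtures["reader1"][visual_method]["marginals"][i]
        + fixtures["reader2"][visual_method]["marginals"][i]
        for i in range(3)
    )
    quant = tuple(
        fixtures["reader1"]["quantitative"][i] + fixtures["reader2"]["quantitative"][i]
        for i in range(3)
    )
    n_discrepant = (
        fixtures["reader1"][visual_method]["n_discrepant_vs_quant"]
        + fixtures["reader2"][visual_method]["n_discrepant_vs_quant"]
    )
    return MarginalSummary(
        marginals_a=visual, marginals_b=quant, n_agree=n - n_discrepant, n=n
    )


def reproduce_agreement_table() -> pd.DataFrame:
    """Recompute the four reconstructible aggregated inter-method kappas.

    Returns one row per comparison (visual planar / visual SPECT/CT, each
    against the quantitative SUV_peak classification and against the
    uptake-ratio classification) with n, p0, pe, kappa (rounded half-up to
    2 dp at report time only) and the Landis-Koch label of the unrounded
    kappa.
    """
    validate_fixtures()
    comparisons = [
        ("visual planar vs quantitative SPECT/CT", ABSOLUTE_CLASSIFICATION_COUNTS, "visual_planar"),
        ("visual SPECT/CT vs quantitative SPECT/CT", ABSOLUTE_CLASSIFICATION_COUNTS, "visual_spect"),
        ("visual planar vs uptake ratio SPECT/CT", RATIO_CLASSIFICATION_COUNTS, "visual_planar"),
        ("visual SPECT/CT vs uptake ratio SPECT/CT", RATIO_CLASSIFICATION_COUNTS, "visual_spect"),
    ]
    rows = []
    for name, fixtures, method in comparisons:
        res = kappa_from_marginals(aggregated_marginals(fixtures, method))
        rows.append(
            {
                "comparison": name,
                "n": res.n,
                "p0": res.p0,
                "pe": res.pe,
                "kappa": round_half_up(res.kappa, 2),
                "kappa_unrounded": res.kappa,
                "label": res.label,
            }
        )
    return pd.DataFrame(rows)


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (0.425 -> 0.43), used only at report time."""
    from decimal import Decimal, ROUND_HALF_UP

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# --------------------------------------------------------------------------
# study bundles and CSV round trips
# --------------------------------------------------------------------------

VOI_COLUMNS = ["voi_id", "label", "region", "cx_mm", "cy_mm", "cz_mm", "ax_mm", "ay_mm", "az_mm"]


@dataclass
class StudyBundle:
    """One subject's paired studies, ready for quantification."""

    volume_tp1: VoxelVolume
    volume_tp2: VoxelVolume
    meta_tp1: AcquisitionMeta
    meta_tp2: AcquisitionMeta
    vois: list[EllipsoidVOI]
    ground_truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.volume_tp1.grid != self.volume_tp2.grid:
            raise ValueError(
                "the two time points must share one grid (overlapping field of view); "
                f"got {self.volume_tp1.grid} vs {self.volume_tp2.grid}"
            )


def write_vois(vois: list[EllipsoidVOI], path: str | Path) -> None:
    rows = [
        {
            "voi_id": v.voi_id, "label": v.label, "region": v.region,
            "cx_mm": v.center[0], "cy_mm": v.center[1], "cz_mm": v.center[2],
            "ax_mm": v.semi_axes[0], "ay_mm": v.semi_axes[1], "az_mm": v.semi_axes[2],
        }
        for v in vois
    ]
    pd.DataFrame(rows, columns=VOI_COLUMNS).to_csv(path, index=False)


def read_vois(path: str | Path) -> list[EllipsoidVOI]:
    df = pd.read_csv(path)
    missing = set(VOI_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing VOI columns {sorted(missing)}")
    return [
        EllipsoidVOI(
            str(r.voi_id),
            (r.cx_mm, r.cy_mm, r.cz_mm),
            (r.ax_mm, r.ay_mm, r.az_mm),
            str(r.label),
            "" if pd.isna(r.region) else str(r.region),
        )
        for r in df.itertuples()
    ]


def load_study(
    volume_tp1: str | Path,
    meta_tp1: str | Path,
    volume_tp2: str | Path,
    meta_tp2: str | Path,
    vois: str | Path,
    ground_truth: str | Path | None = None,
) -> StudyBundle:
    """Assemble and validate a two-time-point study from files on disk."""
    bundle = StudyBundle(
        volume_tp1=read_nifti(volume_tp1),
        volume_tp2=read_nifti(volume_tp2),
        meta_tp1=AcquisitionMeta.from_json(meta_tp1),
        meta_tp2=AcquisitionMeta.from_json(meta_tp2),
        vois=read_vois(vois),
        ground_truth=pd.read_csv(ground_truth) if ground_truth else None,
    )
    logger.info(
        "loaded study: grid %s, %d VOIs", bundle.volume_tp1.grid.shape, len(bundle.vois)
    )
    return bundle


def write_metrics(metrics: pd.DataFrame, path: str | Path) -> None:
    metrics.to_csv(path, index=False)


def read_metrics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"voi_id", "label", "suv_peak", "suv_mean"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metrics columns {sorted(missing)}")
    return df


def write_ratings(ratings: pd.DataFrame, path: str | Path) -> None:
    ratings.to_csv(path, index=False)


def read_ratings(path: str | Path, source: str = "") -> RatingVector:
    df = pd.read_csv(path)
    missing = {"lesion_id", "category"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing ratings columns {sorted(missing)}")
    return RatingVector(
        ids=tuple(str(i) for i in df["lesion_id"]),
        categories=tuple(str(c) for c in df["category"]),
        source=source or str(path),
    )


def write_kappa_report(results: dict[str, KappaResult], path: str | Path) -> None:
    payload = {
        name: {
            "kappa": r.kappa,
            "p0": r.p0,
            "pe": r.pe,
            "n": r.n,
            "label": r.label,
            "kappa_2dp": round_half_up(r.kappa, 2),
        }
        for name, r in results.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
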