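"""Count-to-SUV quantification and VOI uptake metrics.

The measurement chain mirrors clinical quantitative bone SPECT/CT:

1. reconstructed counts -> activity concentration at acquisition time via a
   single linear calibration factor (counts per second per kBq in a voxel)
   and the dwell time;
2. decay correction of the concentration back to injection time
   (all quantities are referenced to injection time);
3. normalisation by net injected activity (prepared minus residual syringe
   activity, both decayed to injection time) per unit body weight, assuming
   1 g/mL tissue density, which yields the dimensionless SUV;
4. extraction of SUV_max, SUV_mean and SUV_peak (mean over a 1 cm^3 sphere
   centred on the hottest VOI voxel, the PERCIST-style convention) from
   ellipsoidal VOIs, and of the lesion-to-reference uptake ratio.

All timestamps are minutes on a common clock. Tc-99m half-life defaults to
360.4 min (6.0067 h).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import EllipsoidVOI, GridGeometry, voi_mask
from .volumes import VoxelVolume, concentration_volume, suv_volume

TC99M_HALF_LIFE_MIN = 360.4

#: radius in mm of a sphere of volume 1 mL
PEAK_SPHERE_RADIUS_1ML_MM = (3.0 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class AcquisitionMeta:
    """Everything needed to turn counts into SUV for one study.

    Activities are MBq; times are minutes on a shared clock; the calibration
    factor ``calibration_cps_per_kbq`` is the detected count rate per kBq of
    activity in a voxel of the reconstructed volume.
    """

    prepared_activity_mbq: float
    t_prepared_min: float
    residual_activity_mbq: float
    t_residual_min: float
    t_injection_min: float
    t_acquisition_start_min: float
    body_weight_kg: float
    calibration_cps_per_kbq: float = 1.0
    dwell_time_s: float = 15.0
    half_life_min: float = TC99M_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        if not (self.prepared_activity_mbq >= self.residual_activity_mbq >= 0):
            raise ValueError("need prepared_activity >= residual_activity >= 0")
        if self.body_weight_kg <= 0:
            raise ValueError("body weight must be > 0 kg")
        if self.calibration_cps_per_kbq <= 0:
            raise ValueError("calibration factor must be > 0")
        if self.dwell_time_s <= 0:
            raise ValueError("dwell time must be > 0 s")
        if self.half_life_min <= 0:
            raise ValueError("half-life must be > 0 min")
        if not (self.t_prepared_min <= self.t_injection_min <= self.t_acquisition_start_min):
            raise ValueError("timestamps must satisfy t_prepared <= t_injection <= t_acquisition")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "AcquisitionMeta":
        try:
            payload = json.loads(Path(path).read_text())
            return cls(**payload)
        except (json.JSONDecodeError, TypeError, ValueError) as exc:
            raise ValueError(f"malformed acquisition metadata in {path}: {exc}") from exc


@dataclass(frozen=True)
class UptakeMetrics:
    """SUV summary statistics of one VOI at one time point."""

    suv_max: float
    suv_mean: float
    suv_peak: float
    activity_concentration_peak_kbq_ml: float
    n_voxels: int
    n_voxels_peak: int


def decay_factor(delta_t_min: float, half_life_min: float = TC99M_HALF_LIFE_MIN) -> float:
    """Decay-correction factor 2^(dt / T_half).

    Multiplying an activity measured ``delta_t_min`` after the reference time
    by this factor corrects it back to the reference time. Negative ``dt``
    decays forward instead.
    """
    if half_life_min <= 0:
        raise ValueError("half-life must be > 0")
    return float(2.0 ** (delta_t_min / half_life_min))


def net_injected_activity(meta: AcquisitionMeta) -> float:
    """Net injected activity in MBq, referenced to injection time.

    Prepared activity is decayed from its measurement time to injection;
    the residual syringe activity (measured after injection) is decayed back
    to injection time before subtraction.
    """
    hl = meta.half_life_min
    prepared_at_inj = meta.prepared_activity_mbq * decay_factor(
        -(meta.t_injection_min - meta.t_prepared_min), hl
    )
    residual_at_inj = meta.residual_activity_mbq * decay_factor(
        meta.t_residual_min - meta.t_injection_min, hl
    )
    a_net = prepared_at_inj - residual_at_inj
    if a_net <= 0:
        raise ValueError(
            f"non-positive net injected activity ({a_net:.3g} MBq): "
            "residual exceeds decayed prepared activity"
        )
    return float(a_net)


def counts_to_concentration(counts: VoxelVolume, meta: AcquisitionMeta) -> VoxelVolume:
    """Convert a count volume to activity concentration at injection time.

    C_acq = counts / (v_vox[mL] * S * T); C_inj = C_acq * 2^(dt/T_half) with
    dt = t_acquisition - t_injection.
    """
    if counts.unit != "counts":
        raise ValueError(f"expected a counts volume, got unit {counts.unit!r}")
    v_vox = counts.grid.voxel_volume_ml
    c_acq = counts.data / (v_vox * meta.calibration_cps_per_kbq * meta.dwell_time_s)
    dt = meta.t_acquisition_start_min - meta.t_injection_min
    c_inj = c_acq * decay_factor(dt, meta.half_life_min)
    return concentration_volume(c_inj, counts.grid)


def concentration_to_suv(
    conc: VoxelVolume, a_net_mbq: float, weight_kg: float
) -> VoxelVolume:
    """SUV = C[kBq/mL] * W[g] / A_net[kBq], with 1 g/mL tissue density."""
    if conc.unit != "kBq/mL":
        raise ValueError(f"expected a concentration volume, got unit {conc.unit!r}")
    if a_net_mbq <= 0:
        raise ValueError("net injected activity must be > 0")
    if weight_kg <= 0:
        raise ValueError("body weight must be > 0")
    suv = conc.data * (weight_kg * 1000.0) / (a_net_mbq * 1000.0)
    return suv_volume(suv, conc.grid)


def quantify_counts(counts: VoxelVolume, meta: AcquisitionMeta) -> VoxelVolume:
    """Full counts -> SUV chain for one study."""
    conc = counts_to_concentration(counts, meta)
    return concentration_to_suv(conc, net_injected_activity(meta), meta.body_weight_kg)


def suv_mean(suv: VoxelVolume, mask: np.ndarray) -> float:
    """Arithmetic mean SUV over masked voxels."""
    if not np.any(mask):
        raise ValueError("empty mask")
    return float(suv.data[mask].mean())


def suv_max(suv: VoxelVolume, mask: np.ndarray) -> float:
    """Maximum SUV over masked voxels."""
    if not np.any(mask):
        raise ValueError("empty mask")
    return float(suv.data[mask].max())


def _sphere_offsets(grid: GridGeometry, radius_mm: float) -> np.ndarray:
    """Relative voxel-index offsets whose centres lie within radius_mm.

    Because the grid is regular, a sphere centred on any voxel centre covers
    the same set of index offsets (before clipping at the grid border).
    """
    reach = [int(np.floor(radius_mm / s)) for s in grid.spacing]
    axes = [np.arange(-r, r + 1) for r in reach]
    di, dj, dk = np.meshgrid(*axes, indexing="ij")
    d2 = (
        (di * grid.spacing[0]) ** 2
        + (dj * grid.spacing[1]) ** 2
        + (dk * grid.spacing[2]) ** 2
    )
    keep = d2 <= radius_mm**2
    return np.stack([di[keep], dj[keep], dk[keep]], axis=1)


def _sphere_average(
    data: np.ndarray, idx: tuple[int, int, int], offsets: np.ndarray
) -> tuple[float, int]:
    """Mean over the sphere's voxels around ``idx``, clipped to the grid."""
    pts = offsets + np.asarray(idx)
    in_grid = np.all((pts >= 0) & (pts < np.asarray(data.shape)), axis=1)
    pts = pts[in_grid]
    vals = data[pts[:, 0], pts[:, 1], pts[:, 2]]
    return float(vals.mean()), int(len(vals))


def peak_sphere_center(
    suv: VoxelVolume, mask: np.ndarray, peak_volume_ml: float = 1.0
) -> tuple[int, int, int]:
    """Index of the hottest masked voxel.

    Exact ties at the maximum (which arise in noiseless synthetic data) are
    broken in favour of the tied voxel whose peak sphere has the greatest
    average — so a homogeneous lesion much larger than the sphere yields its
    interior — and any remaining tie goes to the lowest C-order linear index.
    """
    if not np.any(mask):
        raise ValueError("empty mask")
    masked = np.where(mask, suv.data, -np.inf)
    vmax = masked.max()
    tied = np.argwhere(masked == vmax)
    if len(tied) == 1:
        return tuple(int(i) for i in tied[0])
    radius = (3.0 * peak_volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    offsets = _sphere_offsets(suv.grid, radius)
    best_idx, best_avg = None, -np.inf
    for cand in tied:  # argwhere yields ascending C-order, so first win = lowest index
        avg, _ = _sphere_average(suv.data, tuple(cand), offsets)
        if avg > best_avg:
            best_idx, best_avg = tuple(int(i) for i in cand), avg
    return best_idx


def suv_peak(
    suv: VoxelVolume, mask: np.ndarray, peak_volume_ml: float = 1.0
) -> float:
    """SUV_peak: mean SUV in a fixed-volume sphere about the VOI maximum.

    The sphere (default 1 cm^3, radius ~6.204 mm) is centred on the centre of
    the hottest voxel inside the mask; it may extend beyond the VOI but is
    clipped to the grid; membership is by voxel centre.
    """
    if peak_volume_ml <= 0:
        raise ValueError("peak volume must be > 0 mL")
    idx = peak_sphere_center(suv, mask, peak_volume_ml)
    radius = (3.0 * peak_volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    avg, _ = _sphere_average(suv.data, idx, _sphere_offsets(suv.grid, radius))
    return avg


def uptake_ratio(lesion_suv_peak: float, reference_suv_mean: float) -> float:
    """Lesion SUV_peak over reference-region SUV_mean.

    The ratio corrects for global fluctuations in bone metabolism between
    time points. A missing or non-positive reference is an error (in the
    clinical setting such lesions are simply excluded from ratio analysis).
    """
    if reference_suv_mean <= 0:
        raise ValueError("reference SUV_mean must be > 0 (no usable reference region)")
    return float(lesion_suv_peak / reference_suv_mean)


def voi_metrics(
    suv: VoxelVolume, voi: EllipsoidVOI, peak_volume_ml: float = 1.0
) -> UptakeMetrics:
    """All uptake metrics for one VOI.

    The injection-time peak activity concentration is not derivable from the
    SUV volume alone and is reported as NaN here; :func:`extract_metrics`
    fills it in from the acquisition metadata.
    """
    mask = voi_mask(voi, suv.grid)
    idx = peak_sphere_center(suv, mask, peak_volume_ml)
    radius = (3.0 * peak_volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    pk, n_peak = _sphere_average(suv.data, idx, _sphere_offsets(suv.grid, radius))
    return UptakeMetrics(
        suv_max=suv_max(suv, mask),
        suv_mean=suv_mean(suv, mask),
        suv_peak=pk,
        activity_concentration_peak_kbq_ml=float("nan"),
        n_voxels=int(mask.sum()),
        n_voxels_peak=n_peak,
    )


def extract_metrics(
    suv: VoxelVolume,
    vois: list[EllipsoidVOI],
    meta: AcquisitionMeta | None = None,
    peak_volume_ml: float = 1.0,
) -> pd.DataFrame:
    """Uptake metrics for a list of VOIs, one row per VOI.

    If ``meta`` is given, the injection-time peak activity concentration
    (kBq/mL) is also reported by inverting the SUV normalisation.
    """
    rows = []
    for voi in vois:
        m = voi_metrics(suv, voi, peak_volume_ml)
        conc_peak = float("nan")
        if meta is not None:
            a_net = net_injected_activity(meta)
            conc_peak = m.suv_peak * (a_net * 1000.0) / (meta.body_weight_kg * 1000.0)
        rows.append(
            {
                "voi_id": voi.voi_id,
                "label": voi.label,
                "region": voi.region,
                "suv_max": m.suv_max,
                "suv_mean": m.suv_mean,
                "suv_peak": m.suv_peak,
                "conc_peak_kbq_ml": conc_peak,
                "n_voxels": m.n_voxels,
                "n_voxels_peak": m.n_voxels_peak,
            }
        )
    return pd.DataFrame(rows)
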