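"""Synthetic two-time-point bone-SPECT/CT studies.

Emulates the structure of a longitudinal skeletal SPECT/CT cohort: per
subject, a baseline (TP1) and follow-up (TP2) study ~10 months apart, up to
six ellipsoidal osseous metastases, one healthy-vertebra reference region,
and soft-tissue background. The forward model works in the already
reconstructed, calibrated image domain (attenuation, scatter and resolution
recovery are assumed corrected, as they are after a quantitative OSEM
reconstruction): each voxel's target SUV is painted, converted to an
injection-time activity concentration, decayed forward to acquisition start,
and turned into Poisson counts through the calibration factor and dwell time.

Defaults follow the cohort the package models: lesion SUV_peak ~20.4 at TP1
falling to ~16.4 at TP2, reference SUV_mean 5.6 / 4.9, injected activity
573 / 542 MBq, acquisition 231 / 234 min post injection, 73 kg body weight.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import EllipsoidVOI, GridGeometry, voi_mask
from .quant import AcquisitionMeta, decay_factor, net_injected_activity
from .volumes import VoxelVolume, concentration_volume, count_volume, suv_volume

MAX_LESIONS_PER_SUBJECT = 6

CATEGORIES = ("progressive", "stable", "regressive")


@dataclass(frozen=True)
class LesionSpec:
    """One synthetic osseous metastasis.

    ``fractional_change`` is d such that SUV at TP2 = SUV at TP1 * (1 + d);
    d > 0.30 makes the lesion truly progressive under the standard threshold.
    """

    lesion_id: str
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    suv_tp1: float
    fractional_change: float
    region: str = ""

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError(f"lesion {self.lesion_id!r}: semi-axes must be > 0")
        if self.suv_tp1 <= 0:
            raise ValueError(f"lesion {self.lesion_id!r}: suv_tp1 must be > 0")
        if self.fractional_change <= -1:
            raise ValueError(f"lesion {self.lesion_id!r}: fractional_change must be > -1")

    @property
    def suv_tp2(self) -> float:
        return self.suv_tp1 * (1.0 + self.fractional_change)

    def true_category(self, threshold: float = 0.30) -> str:
        if self.fractional_change > threshold:
            return "progressive"
        if self.fractional_change < -threshold:
            return "regressive"
        return "stable"

    def to_voi(self) -> EllipsoidVOI:
        return EllipsoidVOI(self.lesion_id, self.center, self.semi_axes, "lesion", self.region)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic subject across both time points."""

    grid: GridGeometry
    lesions: tuple[LesionSpec, ...]
    reference_voi: EllipsoidVOI
    background_suv: float = 0.5
    reference_suv_tp1: float = 5.6
    reference_suv_tp2: float = 4.9
    subject_weight_kg: float = 73.0
    injected_activity_mbq: tuple[float, float] = (573.0, 542.0)
    time_to_acquisition_min: tuple[float, float] = (231.0, 234.0)
    calibration_cps_per_kbq: float = 1.0
    dwell_time_s: float = 15.0
    half_life_min: float = 360.4

    def __post_init__(self) -> None:
        object.__setattr__(self, "lesions", tuple(self.lesions))
        if len(self.lesions) > MAX_LESIONS_PER_SUBJECT:
            raise ValueError(
                f"{len(self.lesions)} lesions requested but a maximum of six "
                "metastases per subject is supported"
            )
        if min(self.background_suv, self.reference_suv_tp1, self.reference_suv_tp2) < 0:
            raise ValueError("all SUVs must be >= 0")
        if self.subject_weight_kg <= 0:
            raise ValueError("subject weight must be > 0 kg")
        if self.reference_voi.label != "reference":
            raise ValueError("reference_voi must carry the 'reference' label")
        if not self.reference_voi.inside_grid(self.grid):
            raise ValueError("reference VOI extends outside the grid")
        for lesion in self.lesions:
            if not lesion.to_voi().inside_grid(self.grid):
                raise ValueError(f"lesion {lesion.lesion_id!r} extends outside the grid")
        ids = [l.lesion_id for l in self.lesions]
        if len(set(ids)) != len(ids):
            raise ValueError("lesion ids must be unique")

    def reference_suv(self, time_point: int) -> float:
        return self.reference_suv_tp1 if time_point == 1 else self.reference_suv_tp2

    def meta(self, time_point: int) -> AcquisitionMeta:
        """Acquisition metadata for one time point.

        Activity is taken as measured at injection time with zero residual,
        so net injected activity equals the spec value exactly.
        """
        tp = _check_tp(time_point)
        return AcquisitionMeta(
            prepared_activity_mbq=self.injected_activity_mbq[tp - 1],
            t_prepared_min=0.0,
            residual_activity_mbq=0.0,
            t_residual_min=0.0,
            t_injection_min=0.0,
            t_acquisition_start_min=self.time_to_acquisition_min[tp - 1],
            body_weight_kg=self.subject_weight_kg,
            calibration_cps_per_kbq=self.calibration_cps_per_kbq,
            dwell_time_s=self.dwell_time_s,
            half_life_min=self.half_life_min,
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "grid": {"shape": self.grid.shape, "spacing": self.grid.spacing, "origin": self.grid.origin},
            "lesions": [asdict(l) for l in self.lesions],
            "reference_voi": asdict(self.reference_voi),
            "background_suv": self.background_suv,
            "reference_suv_tp1": self.reference_suv_tp1,
            "reference_suv_tp2": self.reference_suv_tp2,
            "subject_weight_kg": self.subject_weight_kg,
            "injected_activity_mbq": self.injected_activity_mbq,
            "time_to_acquisition_min": self.time_to_acquisition_min,
            "calibration_cps_per_kbq": self.calibration_cps_per_kbq,
            "dwell_time_s": self.dwell_time_s,
            "half_life_min": self.half_life_min,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        try:
            p = json.loads(Path(path).read_text())
            grid = GridGeometry(tuple(p["grid"]["shape"]), tuple(p["grid"]["spacing"]), tuple(p["grid"]["origin"]))
            lesions = tuple(
                LesionSpec(
                    lesion_id=l["lesion_id"], center=tuple(l["center"]),
                    semi_axes=tuple(l["semi_axes"]), suv_tp1=l["suv_tp1"],
                    fractional_change=l["fractional_change"], region=l.get("region", ""),
                )
                for l in p["lesions"]
            )
            r = p["reference_voi"]
            ref = EllipsoidVOI(r["voi_id"], tuple(r["center"]), tuple(r["semi_axes"]), r["label"], r.get("region", ""))
            return cls(
                grid=grid, lesions=lesions, reference_voi=ref,
                background_suv=p["background_suv"],
                reference_suv_tp1=p["reference_suv_tp1"],
                reference_suv_tp2=p["reference_suv_tp2"],
                subject_weight_kg=p["subject_weight_kg"],
                injected_activity_mbq=tuple(p["injected_activity_mbq"]),
                time_to_acquisition_min=tuple(p["time_to_acquisition_min"]),
                calibration_cps_per_kbq=p["calibration_cps_per_kbq"],
                dwell_time_s=p["dwell_time_s"],
                half_life_min=p["half_life_min"],
            )
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise ValueError(f"malformed phantom spec in {path}: {exc}") from exc


def default_phantom(
    n_lesions: int = 3,
    fractional_changes: tuple[float, ...] | None = None,
    lesion_suv_tp1: float = 20.4,
    grid: GridGeometry | None = None,
) -> PhantomSpec:
    """A ready-to-use subject on a 64^3, 2.4 mm grid.

    Lesions are 12 mm-radius spheres spread along x; the reference vertebra
    is a 15x15x20 mm ellipsoid. By default every lesion shows the cohort-mean
    decline 20.4 -> 16.4 (fractional change ~ -0.196, i.e. stable).
    """
    if grid is None:
        grid = GridGeometry((64, 64, 64), (2.4, 2.4, 2.4))
    if fractional_changes is None:
        fractional_changes = tuple([16.4 / 20.4 - 1.0] * n_lesions)
    if len(fractional_changes) != n_lesions:
        raise ValueError("need one fractional change per lesion")
    lo, hi = grid.bounds()
    span = hi - lo
    center_y = lo[1] + 0.30 * span[1]
    center_z = lo[2] + 0.50 * span[2]
    lesions = []
    for i in range(n_lesions):
        cx = lo[0] + (i + 1) / (n_lesions + 1) * span[0]
        lesions.append(
            LesionSpec(
                lesion_id=f"L{i + 1:02d}",
                center=(float(cx), float(center_y), float(center_z)),
                semi_axes=(12.0, 12.0, 12.0),
                suv_tp1=lesion_suv_tp1,
                fractional_change=float(fractional_changes[i]),
                region="thoracic spine",
            )
        )
    reference = EllipsoidVOI(
        "REF",
        (float(lo[0] + 0.5 * span[0]), float(lo[1] + 0.72 * span[1]), float(center_z)),
        (15.0, 15.0, 20.0),
        "reference",
        "lumbar spine",
    )
    return PhantomSpec(grid=grid, lesions=tuple(lesions), reference_voi=reference)


def _check_tp(time_point: int) -> int:
    if time_point not in (1, 2):
        raise ValueError(f"time_point must be 1 or 2, got {time_point}")
    return time_point


def build_suv_map(spec: PhantomSpec, time_point: int) -> VoxelVolume:
    """Ground-truth SUV map: background, overpainted by reference, then lesions.

    Precedence is lesion > reference > background (a metastasis replaces
    marrow uptake). Overlapping lesions are an error naming the collisions.
    """
    tp = _check_tp(time_point)
    data = np.full(spec.grid.shape, float(spec.background_suv))
    data[voi_mask(spec.reference_voi, spec.grid)] = spec.reference_suv(tp)
    claimed = np.zeros(spec.grid.shape, dtype=bool)
    collisions = []
    for lesion in spec.lesions:
        mask = voi_mask(lesion.to_voi(), spec.grid)
        if np.any(claimed & mask):
            collisions.append(lesion.lesion_id)
        claimed |= mask
        data[mask] = lesion.suv_tp1 if tp == 1 else lesion.suv_tp2
    if collisions:
        raise ValueError(f"overlapping lesions: {collisions}")
    return suv_volume(data, spec.grid)


def build_activity_volume(spec: PhantomSpec, time_point: int) -> VoxelVolume:
    """Injection-time activity concentration (kBq/mL) implied by the SUV map.

    Inverts the SUV definition: C = SUV * A_net[kBq] / W[g] at 1 g/mL.
    """
    tp = _check_tp(time_point)
    suv_map = build_suv_map(spec, tp)
    meta = spec.meta(tp)
    a_net_kbq = net_injected_activity(meta) * 1000.0
    weight_g = meta.body_weight_kg * 1000.0
    return concentration_volume(suv_map.data * a_net_kbq / weight_g, spec.grid)


def expected_counts(activity: VoxelVolume, meta: AcquisitionMeta) -> VoxelVolume:
    """Noise-free mean counts per voxel for a given injection-time concentration.

    lambda = C_inj decayed forward to acquisition start, times voxel volume
    [mL], calibration factor [counts/s/kBq] and dwell time [s].
    """
    if activity.unit != "kBq/mL":
        raise ValueError(f"expected a concentration volume, got unit {activity.unit!r}")
    if np.any(activity.data < 0):
        raise ValueError("negative concentrations")
    dt = meta.t_acquisition_start_min - meta.t_injection_min
    c_acq = activity.data * decay_factor(-dt, meta.half_life_min)
    lam = c_acq * activity.grid.voxel_volume_ml * meta.calibration_cps_per_kbq * meta.dwell_time_s
    return count_volume(lam, activity.grid)


def simulate_counts(activity: VoxelVolume, meta: AcquisitionMeta, seed: int) -> VoxelVolume:
    """Poisson count realisation of :func:`expected_counts`; seed-reproducible."""
    lam = expected_counts(activity, meta)
    rng = np.random.default_rng(seed)
    return count_volume(rng.poisson(lam.data).astype(float), activity.grid)


@dataclass(frozen=True)
class Study:
    """One simulated acquisition: counts, metadata, and the VOI set."""

    time_point: int
    counts: VoxelVolume
    meta: AcquisitionMeta
    vois: tuple[EllipsoidVOI, ...]
    truth_suv: VoxelVolume


def ground_truth_table(spec: PhantomSpec, threshold: float = 0.30) -> pd.DataFrame:
    """Per-lesion ground truth: SUVs, true fractional change, true category."""
    rows = [
        {
            "lesion_id": l.lesion_id,
            "region": l.region,
            "true_suv_tp1": l.suv_tp1,
            "true_suv_tp2": l.suv_tp2,
            "true_change": l.fractional_change,
            "true_category": l.true_category(threshold),
        }
        for l in spec.lesions
    ]
    return pd.DataFrame(rows)


def make_longitudinal_pair(spec: PhantomSpec, seeds: tuple[int, int]) -> tuple[Study, Study]:
    """Simulate both time points of one subject with independent count noise."""
    vois = tuple([l.to_voi() for l in spec.lesions] + [spec.reference_voi])
    studies = []
    for tp, seed in zip((1, 2), seeds):
        activity = build_activity_volume(spec, tp)
        meta = spec.meta(tp)
        counts = simulate_counts(activity, meta, seed)
        studies.append(Study(tp, counts, meta, vois, build_suv_map(spec, tp)))
    return studies[0], studies[1]


@dataclass(frozen=True)
class ReaderModel:
    """Stochastic stand-in for a human reader.

    ``confusion`` is row-stochastic: rows index the true change category,
    columns the emitted rating, both in the order (progressive, stable,
    regressive). An identity matrix is an infallible reader.
    """

    confusion: tuple[tuple[float, float, float], ...]
    seed: int

    def __post_init__(self) -> None:
        m = np.asarray(self.confusion, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("confusion matrix must be 3x3")
        if np.any(m < 0) or np.any(m > 1):
            raise ValueError("confusion entries must lie in [0, 1]")
        if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("confusion rows must each sum to 1 within 1e-12")
        object.__setattr__(self, "confusion", tuple(tuple(float(v) for v in row) for row in m))

    @classmethod
    def identity(cls, seed: int = 0) -> "ReaderModel":
        return cls(((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0)), seed)


def simulate_reader(true_categories: list[str], model: ReaderModel) -> list[str]:
    """Emit one rating per true category from the reader's confusion rows."""
    for c in true_categories:
        if c not in CATEGORIES:
            raise ValueError(f"unknown category {c!r}; expected one of {CATEGORIES}")
    rng = np.random.default_rng(model.seed)
    m = np.asarray(model.confusion)
    out = []
    for c in true_categories:
        row = m[CATEGORIES.index(c)]
        out.append(CATEGORIES[rng.choice(3, p=row)])
    return out
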