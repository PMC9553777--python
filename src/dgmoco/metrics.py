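"""SUV conversion, VOI statistics, image-quality ratios and wall thickness.

The four image-quality ratios are computed from myocardium and blood-pool
VOI statistics:

    CR  = SUVmean(myo) / SUVmean(blood)
    SNR = SUVmean(myo) / SUVsd(blood)
    CV  = SUVsd(myo)  / SUVmean(myo)            (reported in %)
    CNR = (SUVmean(myo) - SUVmean(blood)) / SUVsd(blood)

Myocardial wall thickness (MWT) is the full width at half maximum of an
intensity profile across the left-ventricular wall; the baseline is the
larger of the two profile end values, since blood-pool and background
uptake are nonzero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from dgmoco.errors import MetricsError, ParameterError

__all__ = [
    "SubjectMeta",
    "VOIStats",
    "QualityReport",
    "compute_suv",
    "voi_statistics",
    "image_quality_metrics",
    "myocardial_wall_thickness",
    "evaluate_methods",
    "close_mask",
]

F18_HALF_LIFE_MIN = 109.77


@dataclass(frozen=True)
class SubjectMeta:
    """Injected dose, timing and weight needed for SUV normalization."""

    dose_MBq: float = 305.0
    weight_kg: float = 81.0
    delay_min: float = 0.0
    half_life_min: float = F18_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        if self.dose_MBq <= 0 or self.weight_kg <= 0 or self.half_life_min <= 0:
            raise ParameterError("dose, weight and half-life must be positive")
        if self.delay_min < 0:
            raise ParameterError("delay must be >= 0")

    @property
    def decay_corrected_dose_MBq(self) -> float:
        """Dose decayed from injection to scan start."""
        return self.dose_MBq * 2.0 ** (-self.delay_min / self.half_life_min)


@dataclass(frozen=True)
class VOIStats:
    """Mean/SD SUV and volume of one region."""

    suv_mean: float
    suv_sd: float
    volume_cm3: float
    label: str

    def __post_init__(self) -> None:
        if self.suv_sd < 0 or self.volume_cm3 <= 0:
            raise ParameterError("SD must be >= 0 and volume > 0")


def compute_suv(activity_kbq_ml: np.ndarray, meta: SubjectMeta) -> np.ndarray:
    """SUV (g/mL) = C [kBq/mL] * weight [kg] / decay-corrected dose [MBq]."""
    return np.asarray(activity_kbq_ml, dtype=float) * (
        meta.weight_kg / meta.decay_corrected_dose_MBq)


def voi_statistics(suv_image: np.ndarray, mask: np.ndarray, spacing_mm,
                   label: str = "myocardium") -> VOIStats:
    """Sample mean/SD over the mask; volume from voxel count x voxel volume."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != suv_image.shape:
        raise ParameterError("mask and image grids must match")
    n = int(mask.sum())
    if n == 0:
        raise MetricsError("empty VOI mask")
    vals = suv_image[mask]
    spacing = np.broadcast_to(np.asarray(spacing_mm, dtype=float),
                              (suv_image.ndim,))
    vox_cm3 = float(np.prod(spacing)) / 1000.0
    sd = float(vals.std(ddof=1)) if n > 1 else 0.0
    return VOIStats(suv_mean=float(vals.mean()), suv_sd=sd,
                    volume_cm3=n * vox_cm3, label=label)


def image_quality_metrics(myo: VOIStats, blood: VOIStats) -> dict:
    """CR, SNR, CV (%) and CNR from the two VOI statistics.

    Zero denominators yield NaN (flagged, not raised).
    """
    def safe_div(a: float, b: float) -> float:
        return a / b if b > 0 else math.nan

    return {
        "CR": safe_div(myo.suv_mean, blood.suv_mean),
        "SNR": safe_div(myo.suv_mean, blood.suv_sd),
        "CV": 100.0 * safe_div(myo.suv_sd, myo.suv_mean),
        "CNR": safe_div(myo.suv_mean - blood.suv_mean, blood.suv_sd),
    }


def _profile(image: np.ndarray, p0_mm, p1_mm, spacing_mm, step_mm: float):
    p0 = np.asarray(p0_mm, dtype=float)
    p1 = np.asarray(p1_mm, dtype=float)
    spacing = np.broadcast_to(np.asarray(spacing_mm, dtype=float), (image.ndim,))
    length = float(np.linalg.norm(p1 - p0))
    if length <= 0:
        raise ParameterError("profile endpoints coincide")
    n = int(np.floor(length / step_mm)) + 1
    t = np.linspace(0.0, 1.0, n)
    pts_mm = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    coords = (pts_mm / spacing).T
    vals = ndimage.map_coordinates(image.astype(float), coords, order=1,
                                   mode="nearest")
    dist = t * length
    return dist, vals


def myocardial_wall_thickness(image: np.ndarray, p0_mm, p1_mm, spacing_mm,
                              step_mm: float = 0.5) -> float:
    """FWHM (mm) of the uptake profile sampled between two points.

    Endpoints are voxel-index-space positions in mm (index * spacing).  The
    half-maximum level is ``baseline + 0.5 * (peak - baseline)`` with the
    baseline at the larger profile end value; the width is measured between
    the linearly interpolated crossings bracketing the peak.
    """
    if step_mm <= 0:
        raise ParameterError("step_mm must be positive")
    dist, prof = _profile(image, p0_mm, p1_mm, spacing_mm, step_mm)
    k = int(np.argmax(prof))
    peak = prof[k]
    baseline = max(prof[0], prof[-1])
    if not (peak > prof[0] and peak > prof[-1]):
        raise MetricsError("profile peak must lie strictly above both ends")
    half = baseline + 0.5 * (peak - baseline)

    def cross(side: str) -> float:
        idx = range(k, 0, -1) if side == "left" else range(k, len(prof) - 1)
        for i in idx:
            j = i - 1 if side == "left" else i + 1
            if prof[j] < half <= prof[i] or (prof[i] >= half > prof[j]):
                frac = (prof[i] - half) / (prof[i] - prof[j])
                return float(dist[i] + frac * (dist[j] - dist[i]))
        raise MetricsError(f"profile does not cross half maximum on the {side}")

    return abs(cross("right") - cross("left"))


@dataclass(frozen=True)
class QualityReport:
    """Per-method VOI statistics, quality ratios and wall thickness."""

    rows: dict = field(default_factory=dict)

    COLUMNS = ("SUV_myo", "SUV_sd_myo", "SUV_blood", "SUV_sd_blood",
               "CR", "SNR", "CV", "CNR", "MWT")

    def to_json(self, path=None) -> str:
        text = json.dumps(self.rows, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "QualityReport":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            return cls(rows=json.loads(source))
        with open(source) as fh:
            return cls(rows=json.load(fh))

    def to_table(self) -> str:
        """Plain-text table: CR, SNR, CV (%), CNR, MWT (mm) per method."""
        cols = ("CR", "SNR", "CV", "CNR", "MWT")
        header = f"{'Method':<10}" + "".join(f"{c:>10}" for c in
                                             ("CR", "SNR", "CV (%)", "CNR", "MWT (mm)"))
        lines = [header]
        for method, row in self.rows.items():
            lines.append(f"{method:<10}" + "".join(
                f"{row[c]:>10.2f}" for c in cols))
        return "\n".join(lines)


def evaluate_methods(images: dict, myo_mask: np.ndarray,
                     blood_mask: np.ndarray, spacing_mm,
                     profile_endpoints_mm: tuple,
                     meta: SubjectMeta | None = None,
                     images_are_suv: bool = True) -> QualityReport:
    """Full quality report for a set of method images on one grid.

    ``images`` maps method name (e.g. NG/DG/MoCo/MoCo-4D) to a volume; if
    ``images_are_suv`` is false, volumes are kBq/mL and converted with
    ``meta`` first.
    """
    shapes = {im.shape for im in images.values()}
    if len(shapes) != 1:
        raise ParameterError("all method images must share one grid")
    p0, p1 = profile_endpoints_mm
    rows = {}
    for name, img in images.items():
        suv = img if images_are_suv else compute_suv(img, meta or SubjectMeta())
        myo = voi_statistics(suv, myo_mask, spacing_mm, "myocardium")
        blood = voi_statistics(suv, blood_mask, spacing_mm, "blood_pool")
        row = {
            "SUV_myo": myo.suv_mean, "SUV_sd_myo": myo.suv_sd,
            "SUV_blood": blood.suv_mean, "SUV_sd_blood": blood.suv_sd,
        }
        row.update(image_quality_metrics(myo, blood))
        row["MWT"] = myocardial_wall_thickness(suv, p0, p1, spacing_mm)
        rows[name] = row
    return QualityReport(rows=rows)


def close_mask(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    """Morphological closing for imperfect real-data VOI masks."""
    return ndimage.binary_closing(np.asarray(mask, dtype=bool),
                                  iterations=iterations)
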