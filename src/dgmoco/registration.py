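"""Non-rigid registration and end-diastolic respiratory motion correction.

The registration is a coarse-to-fine demons / level-set optical-flow
scheme.  At each iteration the per-voxel update is

    d = step * (F - M∘u) * grad(M∘u) / (|grad|^2 + kappa * (F - M∘u)^2 + eps)

computed in voxel units at the current pyramid level, Gaussian-smoothed
(sigma in voxels) and added to the accumulated field.  The accumulated
field is additionally diffusion-regularized (Gaussian, sigma_field voxels)
after every iteration, which keeps flat-plateau voxels from drifting.  The
field is stored in mm so it transfers unchanged between pyramid levels;
composition is additive.  The procedure is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from dgmoco.errors import ParameterError, RegistrationError

__all__ = [
    "RegistrationSchedule",
    "register_nonrigid",
    "warp_image",
    "motion_correct_diastole",
    "MotionCorrectedImage",
]


@dataclass(frozen=True)
class RegistrationSchedule:
    """Multi-resolution schedule (defaults: 3 levels, 10/10/30 iterations,
    update smoothing sigma 0.2 voxels, 1 mm moving-image pre-smoothing)."""

    downsample_factors: tuple[int, ...] = (4, 2, 1)
    iterations: tuple[int, ...] = (10, 10, 30)
    sigma_update_vox: float = 0.2
    sigma_field_vox: float = 1.0
    presmooth_mm: float = 1.0
    step: float = 1.0
    max_step_vox: float = 1.0
    kappa: float = 1.0
    epsilon_rel: float = 1e-6
    force: str = "demons"  # "demons" keeps the kappa term, "levelset" drops it

    def __post_init__(self) -> None:
        if len(self.downsample_factors) != len(self.iterations):
            raise ParameterError("one iteration count per pyramid level required")
        if (self.sigma_update_vox < 0 or self.sigma_field_vox < 0
                or self.presmooth_mm < 0):
            raise ParameterError("smoothing parameters must be >= 0")
        if self.max_step_vox <= 0:
            raise ParameterError("max_step_vox must be positive")
        if self.force not in ("demons", "levelset"):
            raise ParameterError(f"unknown force model {self.force!r}")

    @property
    def levels(self) -> int:
        return len(self.downsample_factors)


def _as_spacing(spacing_mm, ndim: int) -> np.ndarray:
    return np.broadcast_to(np.asarray(spacing_mm, dtype=float), (ndim,)).copy()


def warp_image(image: np.ndarray, field_mm: np.ndarray, spacing_mm,
               order: int = 1) -> np.ndarray:
    """Pull-back warp: ``out(x) = image(x + u(x))``, trilinear, 0 outside."""
    if field_mm.shape != image.shape + (image.ndim,):
        raise ParameterError("field shape must be image shape + (ndim,)")
    spacing = _as_spacing(spacing_mm, image.ndim)
    coords = np.meshgrid(*[np.arange(n, dtype=float) for n in image.shape],
                         indexing="ij", sparse=False)
    sample = [coords[d] + field_mm[..., d] / spacing[d]
              for d in range(image.ndim)]
    return ndimage.map_coordinates(image.astype(float), sample, order=order,
                                   mode="constant", cval=0.0)


def _downsample(image: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return image.astype(float)
    sm = ndimage.gaussian_filter(image.astype(float), sigma=factor / 2.0,
                                 mode="nearest")
    return ndimage.zoom(sm, 1.0 / factor, order=1, mode="nearest",
                        grid_mode=True)


def _resample_field(field: np.ndarray, target_shape: tuple[int, ...]) -> np.ndarray:
    src = field.shape[:-1]
    if src == tuple(target_shape):
        return field
    zoom = [t / s for t, s in zip(target_shape, src)] + [1.0]
    return ndimage.zoom(field, zoom, order=1, mode="nearest", grid_mode=True)


def register_nonrigid(moving: np.ndarray, fixed: np.ndarray,
                      schedule: RegistrationSchedule | None = None,
                      spacing_mm=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Estimate the field u (mm) such that ``moving(x + u(x)) ~= fixed(x)``.

    Returns the displacement field with shape ``fixed.shape + (ndim,)``.
    Raises :class:`RegistrationError` on grid mismatch or if the field
    diverges beyond a third of the field of view.
    """
    sched = schedule or RegistrationSchedule()
    if moving.shape != fixed.shape:
        raise RegistrationError("moving and fixed images are on different grids")
    if not (np.all(np.isfinite(moving)) and np.all(np.isfinite(fixed))):
        raise RegistrationError("images must be finite")
    ndim = fixed.ndim
    spacing = _as_spacing(spacing_mm, ndim)

    scale = float(np.max(np.abs(fixed)))
    if scale == 0:
        return np.zeros(fixed.shape + (ndim,))
    eps = (sched.epsilon_rel * scale) ** 2

    if sched.presmooth_mm > 0:
        # both images get the same kernel so identical inputs give zero
        # force (and the force compares images at matched resolution)
        sig = sched.presmooth_mm / spacing
        moving = ndimage.gaussian_filter(moving.astype(float), sigma=sig,
                                         mode="nearest")
        fixed = ndimage.gaussian_filter(fixed.astype(float), sigma=sig,
                                        mode="nearest")

    fov_mm = np.asarray(fixed.shape) * spacing
    max_disp_mm = float(fov_mm.max()) / 3.0

    field = None  # mm, shape + (ndim,)
    for factor, n_iter in zip(sched.downsample_factors, sched.iterations):
        mov_l = _downsample(moving, factor)
        fix_l = _downsample(fixed, factor)
        sp_l = spacing * factor
        if field is None:
            field = np.zeros(mov_l.shape + (ndim,))
        else:
            field = _resample_field(field, mov_l.shape)

        for _ in range(n_iter):
            mw = warp_image(mov_l, field, sp_l)
            diff = fix_l - mw
            grads = np.gradient(mw)  # intensity per voxel
            g2 = sum(g * g for g in grads)
            denom = g2 + eps
            if sched.force == "demons":
                denom = denom + sched.kappa * diff * diff
            upd = np.empty_like(field)
            for d in range(ndim):
                upd[..., d] = sched.step * diff * grads[d] / denom
            # cap the per-iteration step (needed for the levelset force,
            # whose denominator can vanish on flat plateaus)
            mag = np.sqrt(np.sum(upd * upd, axis=-1))
            over = mag > sched.max_step_vox
            if np.any(over):
                upd[over] *= (sched.max_step_vox / mag[over])[..., None]
            if sched.sigma_update_vox > 0:
                for d in range(ndim):
                    upd[..., d] = ndimage.gaussian_filter(
                        upd[..., d], sigma=sched.sigma_update_vox, mode="nearest")
            field = field + upd * sp_l  # voxel update -> mm
            if sched.sigma_field_vox > 0:
                for d in range(ndim):
                    field[..., d] = ndimage.gaussian_filter(
                        field[..., d], sigma=sched.sigma_field_vox, mode="nearest")
            if np.max(np.abs(field)) > max_disp_mm:
                raise RegistrationError(
                    "registration diverged: |u| exceeded a third of the FOV "
                    f"({np.max(np.abs(field)):.1f} mm)")

    return _resample_field(field, fixed.shape)


@dataclass(frozen=True)
class MotionCorrectedImage:
    """Combined motion-corrected image with its data-preservation fraction."""

    image: np.ndarray
    total_dwell_fraction: float
    fields_mm: dict
    used_bins: tuple[int, ...]


def motion_correct_diastole(bin_images: dict, dwell_fractions: dict,
                            spacing_mm,
                            schedule: RegistrationSchedule | None = None,
                            reference_bin: int = 25,
                            bins: tuple[int, ...] = (21, 22, 23, 24, 25),
                            weighting: str = "dwell") -> MotionCorrectedImage:
    """Register diastolic respiratory gates to the reference and combine.

    Bins other than the reference are registered to it, warped, and all
    usable bins averaged (dwell-fraction weights by default, uniform with
    ``weighting="uniform"``).  Empty/missing bins are skipped.
    """
    if weighting not in ("dwell", "uniform"):
        raise ParameterError(f"unknown weighting {weighting!r}")
    usable = [b for b in bins if b in bin_images
              and dwell_fractions.get(b, 0.0) > 0]
    if reference_bin not in usable:
        raise RegistrationError(f"reference bin {reference_bin} empty or missing")
    if len(usable) < 2:
        raise RegistrationError("fewer than 2 usable diastolic bins")

    ref = bin_images[reference_bin]
    acc = np.zeros_like(ref, dtype=float)
    wsum = 0.0
    fields = {}
    for b in usable:
        w = dwell_fractions[b] if weighting == "dwell" else 1.0
        if b == reference_bin:
            warped = ref.astype(float)
            fields[b] = np.zeros(ref.shape + (ref.ndim,))
        else:
            field = register_nonrigid(bin_images[b], ref, schedule, spacing_mm)
            warped = warp_image(bin_images[b], field, spacing_mm)
            fields[b] = field
        acc += w * warped
        wsum += w
    total = sum(dwell_fractions.get(b, 0.0) for b in usable)
    return MotionCorrectedImage(image=acc / wsum, total_dwell_fraction=total,
                                fields_mm=fields, used_bins=tuple(usable))
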