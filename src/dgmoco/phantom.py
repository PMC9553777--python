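"""Synthetic gating signals and a 4D cardiac-torso phantom with known motion.

The phantom is a deliberately simple geometric torso: an elliptic-cylinder
body (soft tissue), two lung ellipsoids, and a spherical-shell left
ventricle whose wall contracts over the cardiac cycle and which translates
superior-inferior (SI, the z axis) with respiration.  All motion is
analytic, so every frame carries an exact ground-truth displacement field
that registration tests can be validated against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from dgmoco.errors import ParameterError

__all__ = [
    "RespiratoryTrace",
    "TriggerList",
    "PhantomSpec",
    "PhantomFrame",
    "DualGateStudy",
    "generate_respiratory_trace",
    "generate_cardiac_triggers",
    "render_phantom_frame",
    "simulate_gated_study",
]


# --------------------------------------------------------------------------
# Signal containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RespiratoryTrace:
    """Uniformly sampled respiratory amplitude signal (larger = more inspired).

    ``cycle_bounds``/``invalid_cycles`` carry the generator's ground truth
    (sample indices delimiting breathing cycles, and which cycles were
    deliberately corrupted); they are ``None`` for traces read from file.
    """

    time: np.ndarray
    amplitude: np.ndarray
    cycle_bounds: np.ndarray | None = None
    invalid_cycles: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        a = np.asarray(self.amplitude, dtype=float)
        if t.ndim != 1 or a.shape != t.shape:
            raise ParameterError("time and amplitude must be 1-D arrays of equal length")
        if t.size < 2 or not np.all(np.diff(t) > 0):
            raise ParameterError("time must be strictly increasing with >= 2 samples")
        if not np.all(np.isfinite(a)):
            raise ParameterError("amplitude must be finite")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "amplitude", a)

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    @property
    def sampling_rate(self) -> float:
        return float(1.0 / np.median(np.diff(self.time)))

    def to_csv(self, path) -> None:
        header = "time_s,amplitude"
        np.savetxt(path, np.column_stack([self.time, self.amplitude]),
                   delimiter=",", header=header, comments="", fmt="%.9g")

    @classmethod
    def from_csv(cls, path) -> "RespiratoryTrace":
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(time=data[:, 0], amplitude=data[:, 1])


@dataclass(frozen=True)
class TriggerList:
    """Sorted ECG R-peak times in seconds."""

    r_peak_times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.r_peak_times, dtype=float)
        if t.ndim != 1:
            raise ParameterError("r_peak_times must be 1-D")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ParameterError("r_peak_times must be strictly increasing")
        object.__setattr__(self, "r_peak_times", t)

    @property
    def rr_intervals(self) -> np.ndarray:
        """Successive R-R intervals in seconds."""
        return np.diff(self.r_peak_times)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.r_peak_times[:, None], delimiter=",",
                   header="r_peak_s", comments="", fmt="%.9g")

    @classmethod
    def from_csv(cls, path) -> "TriggerList":
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=1)
        return cls(r_peak_times=np.atleast_1d(np.squeeze(data)))


# --------------------------------------------------------------------------
# Phantom specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Geometric and kinetic parameters of the synthetic subject.

    Activities are in SUV-equivalent g/mL, attenuation in cm^-1, lengths in
    mm.  The left-ventricle shell sits at the volume centre; the body is an
    elliptic cylinder spanning the full z extent so that a pure SI
    translation leaves the background unchanged.
    """

    shape: tuple[int, int, int] = (128, 128, 48)
    spacing_mm: tuple[float, float, float] = (2.73, 2.73, 2.73)
    r_endo_mm: float = 25.0
    r_epi_mm: float = 35.0
    act_myocardium: float = 2.15
    act_blood: float = 0.86
    act_background: float = 0.4
    act_lung: float = 0.1
    mu_soft: float = 0.096
    mu_lung: float = 0.03
    si_amplitude_mm: float = 12.0
    contraction_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.r_epi_mm > self.r_endo_mm > 0):
            raise ParameterError("need epicardial radius > endocardial radius > 0")
        for name in ("act_myocardium", "act_blood", "act_background", "act_lung"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not (0.0 <= self.contraction_fraction < 1.0):
            raise ParameterError("contraction_fraction must be in [0, 1)")
        if any(s <= 0 for s in self.spacing_mm) or any(n <= 0 for n in self.shape):
            raise ParameterError("shape and spacing must be positive")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))

    @property
    def fov_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing_mm))

    @property
    def wall_thickness_mm(self) -> float:
        """Diastolic wall thickness (epicardial minus endocardial radius)."""
        return self.r_epi_mm - self.r_endo_mm

    def to_yaml(self, path) -> None:
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for k in ("shape", "spacing_mm"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def with_(self, **kwargs) -> "PhantomSpec":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PhantomFrame:
    """One motion state: activity, mu-map, masks and ground-truth motion.

    ``displacement_mm`` has shape ``shape + (3,)`` and maps the reference
    state (end-expiration, end-diastole) to this frame: warping this frame
    by pull-back with this field recovers the reference image.
    """

    activity: np.ndarray
    mu: np.ndarray
    myo_mask: np.ndarray
    blood_mask: np.ndarray
    displacement_mm: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.mu < 0):
            raise ParameterError("mu must be non-negative")
        if np.any(self.activity < 0):
            raise ParameterError("activity must be non-negative")
        if np.any(self.myo_mask & self.blood_mask):
            raise ParameterError("myocardium and blood-pool masks must be disjoint")


# --------------------------------------------------------------------------
# Signal generators
# --------------------------------------------------------------------------

def generate_respiratory_trace(
    duration: float,
    period: float = 5.0,
    period_jitter: float = 0.0,
    amplitude: float = 10.0,
    amplitude_jitter: float = 0.0,
    baseline_drift: float = 0.0,
    invalid_cycle_rate: float = 0.0,
    waveform: str = "sinusoid",
    seed: int | None = None,
    sampling_rate: float = 25.0,
) -> RespiratoryTrace:
    """Quasi-periodic RPM-like breathing trace built cycle by cycle.

    Each cycle starts and ends at end-expiration (amplitude 0 before
    drift).  With ``invalid_cycle_rate`` > 0 a Bernoulli draw per cycle
    corrupts it by amplitude collapse (x0.1) or a period outlier (x2.5),
    giving the downstream valid-cycle logic realistic rejects; the
    corrupted flags are carried on the returned trace as ground truth.

    Parameters
    ----------
    duration : float
        Requested length in seconds (>= 2 periods).  The trace is extended
        to the end of the last started cycle so it terminates at a minimum.
    waveform : {"sinusoid", "cos4"}
        ``sinusoid`` gives ``A (1 - cos) / 2`` (arcsine dwell);
        ``cos4`` gives ``A sin^4`` which dwells longer at end-expiration.
    """
    if duration <= 0 or period <= 0:
        raise ParameterError("duration and period must be positive")
    if duration < 2 * period:
        raise ParameterError("duration must cover at least two breathing cycles")
    if period_jitter < 0 or amplitude_jitter < 0:
        raise ParameterError("jitters must be >= 0")
    if not 0.0 <= invalid_cycle_rate <= 1.0:
        raise ParameterError("invalid_cycle_rate must be in [0, 1]")
    if waveform not in ("sinusoid", "cos4"):
        raise ParameterError(f"unknown waveform {waveform!r}")
    if sampling_rate < 20.0:
        raise ParameterError("sampling_rate must be >= 20 Hz")

    rng = np.random.default_rng(seed)
    starts = [0.0]
    periods, amps, corrupted = [], [], []
    t = 0.0
    while t < duration:
        bad = bool(rng.random() < invalid_cycle_rate)
        p = period * max(1.0 + period_jitter * rng.standard_normal(), 0.3)
        a = amplitude * max(1.0 + amplitude_jitter * rng.standard_normal(), 0.05)
        if bad:
            if rng.random() < 0.5:
                a *= 0.1           # amplitude collapse
            else:
                p *= 2.5           # period outlier
        periods.append(p)
        amps.append(a)
        corrupted.append(bad)
        t += p
        starts.append(t)
    starts_arr = np.asarray(starts)
    periods_arr = np.asarray(periods)
    amps_arr = np.asarray(amps)

    time = np.arange(0.0, starts_arr[-1], 1.0 / sampling_rate)
    idx = np.clip(np.searchsorted(starts_arr, time, side="right") - 1, 0,
                  len(periods) - 1)
    phase = (time - starts_arr[idx]) / periods_arr[idx]
    if waveform == "sinusoid":
        shape_fn = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    else:  # cos4
        shape_fn = np.sin(np.pi * phase) ** 4
    amp = amps_arr[idx] * shape_fn + baseline_drift * time

    bounds = np.searchsorted(time, starts_arr)
    bounds[-1] = time.size  # last cycle ends at the final sample
    return RespiratoryTrace(
        time=time,
        amplitude=amp,
        cycle_bounds=bounds,
        invalid_cycles=np.asarray(corrupted, dtype=bool),
    )


def generate_cardiac_triggers(
    duration: float,
    mean_hr: float = 61.95,
    sd_hr: float = 11.71,
    seed: int | None = None,
    min_rr_s: float = 0.3,
) -> TriggerList:
    """ECG R-peak times with R-R intervals from a truncated normal.

    The R-R distribution is normal with mean ``60/mean_hr`` s and SD
    ``60 * sd_hr / mean_hr**2`` s (delta method from the bpm statistics),
    truncated below at ``min_rr_s``.  First R-peak at t = 0.
    """
    if mean_hr <= 0:
        raise ParameterError("mean_hr must be positive")
    if sd_hr < 0:
        raise ParameterError("sd_hr must be >= 0")
    if duration <= 0:
        raise ParameterError("duration must be positive")

    rr_mean = 60.0 / mean_hr
    rr_sd = 60.0 * sd_hr / mean_hr**2
    if duration < rr_mean:
        warnings.warn("duration shorter than one beat; trigger list may be empty",
                      stacklevel=2)

    rng = np.random.default_rng(seed)
    times = [0.0]
    t = 0.0
    while True:
        if rr_sd == 0:
            rr = rr_mean
        else:
            rr = rr_mean + rr_sd * rng.standard_normal()
            while rr <= min_rr_s:  # truncation by rejection
                rr = rr_mean + rr_sd * rng.standard_normal()
        t += rr
        if t > duration:
            break
        times.append(t)
    if duration < rr_mean and times == [0.0]:
        times = []
    return TriggerList(r_peak_times=np.asarray(times, dtype=float))


# --------------------------------------------------------------------------
# Frame rendering
# --------------------------------------------------------------------------

def _grid_mm(spec: PhantomSpec):
    """Voxel-centre coordinates in mm, centred on the volume."""
    axes = [(np.arange(n) - (n - 1) / 2.0) * s
            for n, s in zip(spec.shape, spec.spacing_mm)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _body_mask(spec: PhantomSpec, x, y):
    fx, fy, _ = spec.fov_mm
    ax, ay = 0.45 * fx, 0.42 * fy
    return (x / ax) ** 2 + (y / ay) ** 2 <= 1.0


def _lung_masks(spec: PhantomSpec, x, y, z, dz: float):
    fx, fy, fz = spec.fov_mm
    cx = 0.27 * fx
    sx, sy, sz = 0.14 * fx, 0.33 * fy, 0.33 * fz
    masks = []
    for sign in (-1.0, 1.0):
        masks.append(((x - sign * cx) / sx) ** 2 + (y / sy) ** 2
                     + ((z - dz) / sz) ** 2 <= 1.0)
    return masks


def _radial_scales(spec: PhantomSpec, cardiac_phase: float) -> tuple[float, float]:
    """Endo/epi radius scale factors; phase 0 = end-diastole (maximal radii).

    The endocardium contracts by the full contraction fraction, the
    epicardium by half of it, so the wall thickens toward systole.
    """
    bump = 0.5 * (1.0 - np.cos(2.0 * np.pi * cardiac_phase))
    k_endo = 1.0 - spec.contraction_fraction * bump
    k_epi = 1.0 - 0.5 * spec.contraction_fraction * bump
    return float(k_endo), float(k_epi)


def render_phantom_frame(
    spec: PhantomSpec,
    resp_level: float,
    cardiac_phase: float,
    with_field: bool = True,
) -> PhantomFrame:
    """Render one motion state of the phantom.

    ``resp_level`` in [0, 1] scales the SI translation (0 = end-expiration,
    the reference); ``cardiac_phase`` in [0, 1) modulates the LV radii
    (0 = end-diastole, the reference; 0.5 = end-systole).
    """
    if not 0.0 <= resp_level <= 1.0:
        raise ParameterError("resp_level must be in [0, 1]")
    if not 0.0 <= cardiac_phase < 1.0:
        raise ParameterError("cardiac_phase must be in [0, 1)")

    x, y, z = _grid_mm(spec)
    dz = resp_level * spec.si_amplitude_mm
    k_endo, k_epi = _radial_scales(spec, cardiac_phase)
    r_endo = k_endo * spec.r_endo_mm
    r_epi = k_epi * spec.r_epi_mm

    body = _body_mask(spec, x, y) & np.ones_like(z, dtype=bool)
    lungs = _lung_masks(spec, x, y, z, dz)

    r = np.sqrt(x**2 + y**2 + (z - dz) ** 2)
    blood = r < r_endo
    myo = (r >= r_endo) & (r < r_epi)
    heart = r < r_epi

    activity = np.where(body, spec.act_background, 0.0)
    for lm in lungs:
        activity = np.where(lm & body, spec.act_lung, activity)
    activity = np.where(blood, spec.act_blood, activity)
    activity = np.where(myo, spec.act_myocardium, activity)

    mu = np.where(body, spec.mu_soft, 0.0)
    for lm in lungs:
        mu = np.where(lm & body, spec.mu_lung, mu)
    mu = np.where(heart, spec.mu_soft, mu)

    displacement = None
    if with_field:
        # Radial map from reference radii to this frame's radii, identity
        # beyond 1.6 x epicardial radius; SI translation inside the body.
        r_ref = np.sqrt(x**2 + y**2 + z**2)
        r_outer = 1.6 * spec.r_epi_mm
        knots_ref = np.array([0.0, spec.r_endo_mm, spec.r_epi_mm, r_outer])
        knots_new = np.array([0.0, r_endo, r_epi, r_outer])
        r_mapped = np.where(r_ref >= r_outer, r_ref,
                            np.interp(r_ref, knots_ref, knots_new))
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(r_ref > 0, r_mapped / np.maximum(r_ref, 1e-12), 1.0)
        displacement = np.zeros(spec.shape + (3,), dtype=float)
        displacement[..., 0] = (scale - 1.0) * x
        displacement[..., 1] = (scale - 1.0) * y
        displacement[..., 2] = (scale - 1.0) * z + np.where(body, dz, 0.0)

    return PhantomFrame(
        activity=activity,
        mu=mu,
        myo_mask=myo,
        blood_mask=blood,
        displacement_mm=displacement,
    )


# --------------------------------------------------------------------------
# Gated-study simulation
# --------------------------------------------------------------------------

@dataclass
class DualGateStudy:
    """25 dual-gated bin images with dwell bookkeeping and mu-maps.

    ``bin_means`` are the noise-free dwell-weighted mean frames;
    ``bin_images`` the Poisson-noisy realizations; keys are dual-bin
    numbers 1..25 (missing key = empty bin, listed in ``log``).
    ``mu_phases`` maps respiratory bin 1..5 to its dwell-weighted mu-map.
    """

    spec: PhantomSpec
    bin_means: dict
    bin_images: dict
    dwell_fractions: dict
    mu_phases: dict
    resp_fractions: dict
    ng_mean: np.ndarray
    ng_image: np.ndarray
    myo_mask: np.ndarray
    blood_mask: np.ndarray
    fraction_report: "object"
    thresholds: "object"
    counts_budget: float
    log: list = field(default_factory=list)

    @property
    def spacing_mm(self) -> tuple[float, float, float]:
        return self.spec.spacing_mm


def simulate_gated_study(
    spec: PhantomSpec,
    trace: RespiratoryTrace,
    triggers: TriggerList,
    gating_config=None,
    counts_budget: float = 5e6,
    seed: int | None = None,
    n_resp_levels: int = 8,
    n_phase_levels: int = 8,
    nominal_rr_s: float = 1.0,
) -> DualGateStudy:
    """Simulate the dual-gated acquisition of the moving phantom.

    Runs the gating module on the two signals, maps every time sample to a
    quantized (respiratory level, cardiac phase) motion state, accumulates
    dwell-weighted mean frames per dual bin, and draws one Poisson
    realization per bin with expected total counts proportional to
    ``dwell fraction x counts_budget``.  The non-gated ground truth is the
    dwell-weighted average over *all* samples at the full budget.
    """
    from dgmoco import gating as _gating

    cfg = gating_config or _gating.GatingConfig()
    cycles = _gating.detect_cycles(trace, cfg.validity_rule)
    thresholds = _gating.compute_thresholds(cycles)
    resp = _gating.assign_respiratory_bins(trace, cycles, thresholds, cfg.n_resp_bins)
    cardiac = _gating.assign_cardiac_bins(trace.time, triggers, cfg.division_ms)
    assignment = _gating.combine_dual(resp, cardiac)
    report = _gating.data_fractions(
        assignment, invalid_cycle_loss=_gating.invalid_cycle_loss(trace, cycles))

    # Motion state per sample: respiratory level from the amplitude position
    # between the gating thresholds, cardiac phase from time since R-peak on
    # a nominal cycle (contraction completes by nominal_rr_s and holds).
    a = np.clip(trace.amplitude, thresholds.a_min, thresholds.a_max)
    span = thresholds.a_max - thresholds.a_min
    resp_level = (a - thresholds.a_min) / span if span > 0 else np.zeros_like(a)
    tau = _gating.time_since_r_peak(trace.time, triggers)
    phase = np.clip(np.where(np.isfinite(tau), tau, 0.0) / nominal_rr_s, 0.0, 1.0)
    phase = np.where(phase >= 1.0, 0.0, phase)  # relaxed == end-diastole

    ri = np.clip(np.round(resp_level * (n_resp_levels - 1)).astype(int),
                 0, n_resp_levels - 1)
    pi = np.clip(np.round(phase * n_phase_levels).astype(int) % n_phase_levels,
                 0, n_phase_levels - 1)
    keys = ri * n_phase_levels + pi
    n_samples = trace.time.size

    dual = assignment.dual
    shape = spec.shape
    bin_sums = {}
    bin_counts = {b: 0 for b in range(1, 26)}
    mu_sums = {r: np.zeros(shape) for r in range(1, 6)}
    mu_counts = {r: 0 for r in range(1, 6)}
    ng_sum = np.zeros(shape)

    for key in np.unique(keys):
        sel = keys == key
        kri, kpi = divmod(int(key), n_phase_levels)
        frame = render_phantom_frame(
            spec,
            resp_level=kri / max(n_resp_levels - 1, 1),
            cardiac_phase=kpi / n_phase_levels,
            with_field=False,
        )
        ng_sum += sel.sum() * frame.activity
        for b in np.unique(dual[sel]):
            if b < 1:
                continue
            n = int(np.sum(sel & (dual == b)))
            if b not in bin_sums:
                bin_sums[b] = np.zeros(shape)
            bin_sums[b] += n * frame.activity
            bin_counts[b] += n
        for r in np.unique(resp.labels[sel]):
            if r < 1:
                continue
            n = int(np.sum(sel & (resp.labels == r)))
            mu_sums[r] += n * frame.mu
            mu_counts[r] += n

    ng_mean = ng_sum / n_samples
    bin_means = {b: bin_sums[b] / bin_counts[b] for b in bin_sums}
    mu_phases = {r: mu_sums[r] / mu_counts[r] for r in range(1, 6) if mu_counts[r] > 0}
    resp_fractions = {r: mu_counts[r] / n_samples for r in range(1, 6)}
    dwell = {b: bin_counts[b] / n_samples for b in range(1, 26)}

    log = [f"bin {b} empty (dwell fraction 0)" for b in range(1, 26)
           if bin_counts[b] == 0]

    # Poisson noise: expected counts per voxel scale with dwell x budget.
    rng = np.random.default_rng(seed)
    act_total = float(ng_mean.sum())
    if act_total <= 0:
        raise ParameterError("phantom has no activity")
    bin_images = {}
    for b, mean_img in sorted(bin_means.items()):
        scale = dwell[b] * counts_budget / act_total
        lam = mean_img * scale
        bin_images[b] = rng.poisson(lam).astype(float) / scale
    ng_scale = counts_budget / act_total
    ng_image = rng.poisson(ng_mean * ng_scale).astype(float) / ng_scale

    ref = render_phantom_frame(spec, 0.0, 0.0, with_field=False)
    return DualGateStudy(
        spec=spec,
        bin_means=bin_means,
        bin_images=bin_images,
        dwell_fractions=dwell,
        mu_phases=mu_phases,
        resp_fractions=resp_fractions,
        ng_mean=ng_mean,
        ng_image=ng_image,
        myo_mask=ref.myo_mask,
        blood_mask=ref.blood_mask,
        fraction_report=report,
        thresholds=thresholds,
        counts_budget=counts_budget,
        log=log,
    )
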