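"""Amplitude respiratory gating, fixed-time cardiac gating, dual bins.

Conventions
-----------
* Respiratory bins 1..5: bin 1 = most-inspired (top amplitude interval),
  bin 5 = end-expiration (bottom interval).  Amplitudes below the minimum
  threshold are clipped into bin 5; amplitudes above the maximum threshold
  are rejected, as are samples in invalid cycles.
* Cardiac bins 1..5 from fixed times since the R-peak with division points
  50, 120, 420, 550 and 1500 ms; intervals are half-open, closed below.
  Samples at >= 1500 ms, before the first or at/after the last trigger are
  rejected.
* Dual bin b = (c - 1) * 5 + r, so bin 25 = end-diastolic/end-expiratory
  and bins 21..25 form the diastolic set across respiration.
* ``REJECTED`` (-1) marks samples excluded from every bin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from dgmoco.errors import GatingError, ParameterError
from dgmoco.phantom import RespiratoryTrace, TriggerList

__all__ = [
    "REJECTED",
    "ValidityRule",
    "GatingConfig",
    "CycleSet",
    "GatingThresholds",
    "RespiratoryAssignment",
    "CardiacAssignment",
    "BinAssignment",
    "DataFractionReport",
    "detect_cycles",
    "compute_thresholds",
    "assign_respiratory_bins",
    "assign_cardiac_bins",
    "combine_dual",
    "data_fractions",
    "invalid_cycle_loss",
    "time_since_r_peak",
    "gate_study",
]

REJECTED: int = -1

DEFAULT_DIVISION_MS: tuple[float, ...] = (50.0, 120.0, 420.0, 550.0, 1500.0)


@dataclass(frozen=True)
class ValidityRule:
    """Cycle-validity rule standing in for the RPM's proprietary criterion.

    A cycle is valid when its period lies within ``period_range`` times the
    median period and its peak-to-trough range is at least
    ``min_range_fraction`` times the median range.
    """

    period_range: tuple[float, float] = (0.5, 2.0)
    min_range_fraction: float = 0.3


@dataclass(frozen=True)
class GatingConfig:
    n_resp_bins: int = 5
    division_ms: tuple[float, ...] = DEFAULT_DIVISION_MS
    validity_rule: ValidityRule = field(default_factory=ValidityRule)


@dataclass(frozen=True)
class CycleSet:
    """Respiratory cycles delimited at successive end-expiratory minima."""

    start_idx: np.ndarray          # sample index of cycle start (inclusive)
    end_idx: np.ndarray            # sample index of cycle end (exclusive)
    start_time: np.ndarray
    end_time: np.ndarray
    max_amplitude: np.ndarray
    min_amplitude: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.end_idx[:-1] > self.start_idx[1:]):
            raise GatingError("cycles must be non-overlapping and ordered")

    @property
    def n_cycles(self) -> int:
        return int(self.start_idx.size)

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid))


@dataclass(frozen=True)
class GatingThresholds:
    """Amplitude gating thresholds with equidistant bin edges."""

    a_max: float
    a_min: float
    n_bins: int = 5

    def __post_init__(self) -> None:
        if not self.a_max > self.a_min:
            raise GatingError("a_max must exceed a_min")

    @property
    def edges(self) -> np.ndarray:
        """``n_bins + 1`` strictly increasing edges from a_min to a_max."""
        return np.linspace(self.a_min, self.a_max, self.n_bins + 1)


@dataclass(frozen=True)
class RespiratoryAssignment:
    time: np.ndarray
    labels: np.ndarray  # 1..n_bins or REJECTED


@dataclass(frozen=True)
class CardiacAssignment:
    time: np.ndarray
    labels: np.ndarray  # 1..5 or REJECTED


@dataclass(frozen=True)
class BinAssignment:
    """Per-sample respiratory, cardiac and dual labels on one time base."""

    time: np.ndarray
    resp: np.ndarray
    cardiac: np.ndarray
    dual: np.ndarray

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.time, self.resp, self.cardiac, self.dual])
        np.savetxt(path, arr, delimiter=",", comments="",
                   header="time_s,resp_bin,cardiac_bin,dual_bin",
                   fmt=["%.9g", "%d", "%d", "%d"])

    @classmethod
    def from_csv(cls, path) -> "BinAssignment":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(time=arr[:, 0], resp=arr[:, 1].astype(int),
                   cardiac=arr[:, 2].astype(int), dual=arr[:, 3].astype(int))


@dataclass(frozen=True)
class DataFractionReport:
    """Dwell-fraction bookkeeping relative to the full acquisition (= 1)."""

    bin_fractions: dict
    rejected_fraction: float
    invalid_cycle_loss: float
    dg_fraction: float
    moco_fraction: float

    def to_json(self, path=None) -> str:
        d = {
            "bin_fractions": {str(k): v for k, v in self.bin_fractions.items()},
            "rejected_fraction": self.rejected_fraction,
            "invalid_cycle_loss": self.invalid_cycle_loss,
            "dg_fraction": self.dg_fraction,
            "moco_fraction": self.moco_fraction,
        }
        text = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "DataFractionReport":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            bin_fractions={int(k): v for k, v in d["bin_fractions"].items()},
            rejected_fraction=d["rejected_fraction"],
            invalid_cycle_loss=d["invalid_cycle_loss"],
            dg_fraction=d["dg_fraction"],
            moco_fraction=d["moco_fraction"],
        )


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------

def detect_cycles(trace: RespiratoryTrace,
                  validity_rule: ValidityRule | None = None) -> CycleSet:
    """Delimit breathing cycles at successive end-expiratory minima.

    Interior minima are detected with a small prominence floor (2% of the
    signal range) so that amplitude-collapsed cycles are still delimited;
    the first and last samples close the outermost cycles.
    """
    rule = validity_rule or ValidityRule()
    a = trace.amplitude
    ptp = float(np.ptp(a))
    if ptp <= 0:
        raise GatingError("flat trace: no respiratory cycles detectable")
    minima, _ = find_peaks(-a, prominence=0.02 * ptp)
    bounds = np.concatenate([[0], minima, [a.size]])
    if bounds.size < 3:
        raise GatingError("fewer than 2 detectable respiratory cycles")

    start_idx = bounds[:-1].astype(int)
    end_idx = bounds[1:].astype(int)
    t = trace.time
    start_time = t[start_idx]
    end_time = t[np.minimum(end_idx, t.size - 1)]
    max_amp = np.array([a[s:e].max() for s, e in zip(start_idx, end_idx)])
    min_amp = np.array([a[s:e].min() for s, e in zip(start_idx, end_idx)])

    period = end_time - start_time
    med_period = float(np.median(period))
    rng = max_amp - min_amp
    med_range = float(np.median(rng))
    valid = (
        (period >= rule.period_range[0] * med_period)
        & (period <= rule.period_range[1] * med_period)
        & (rng >= rule.min_range_fraction * med_range)
    )
    return CycleSet(start_idx=start_idx, end_idx=end_idx,
                    start_time=start_time, end_time=end_time,
                    max_amplitude=max_amp, min_amplitude=min_amp, valid=valid)


def compute_thresholds(cycles: CycleSet, n_bins: int = 5) -> GatingThresholds:
    """Maximum threshold = mean + sample SD of the valid-cycle maxima;
    minimum threshold = mean of the valid-cycle minima."""
    if cycles.n_valid < 2:
        raise GatingError("need >= 2 valid cycles to compute thresholds")
    maxima = cycles.max_amplitude[cycles.valid]
    minima = cycles.min_amplitude[cycles.valid]
    a_max = float(maxima.mean() + maxima.std(ddof=1))
    a_min = float(minima.mean())
    if a_max <= a_min:
        raise GatingError("degenerate trace: maximum threshold <= minimum threshold")
    return GatingThresholds(a_max=a_max, a_min=a_min, n_bins=n_bins)


def assign_respiratory_bins(
    trace: RespiratoryTrace,
    cycles: CycleSet,
    thresholds: GatingThresholds,
    n_bins: int = 5,
) -> RespiratoryAssignment:
    """Label every sample with its amplitude bin (1 = top, n_bins = bottom).

    Samples in invalid cycles or outside every cycle are REJECTED, as are
    amplitudes above the maximum threshold; amplitudes below the minimum
    threshold are clipped into the bottom (end-expiratory) bin.
    """
    if n_bins != thresholds.n_bins:
        thresholds = GatingThresholds(thresholds.a_max, thresholds.a_min, n_bins)
    a = trace.amplitude
    labels = np.full(a.shape, REJECTED, dtype=int)

    in_valid = np.zeros(a.shape, dtype=bool)
    for s, e, ok in zip(cycles.start_idx, cycles.end_idx, cycles.valid):
        if ok:
            in_valid[s:e] = True

    h = (thresholds.a_max - thresholds.a_min) / n_bins
    clipped = np.maximum(a, thresholds.a_min)
    idx_from_bottom = np.minimum(
        np.floor((clipped - thresholds.a_min) / h).astype(int), n_bins - 1)
    bins = n_bins - idx_from_bottom
    ok = in_valid & (a <= thresholds.a_max)
    labels[ok] = bins[ok]
    return RespiratoryAssignment(time=trace.time, labels=labels)


def time_since_r_peak(times: np.ndarray, triggers: TriggerList) -> np.ndarray:
    """Seconds since the previous R-peak; NaN outside [first, last) trigger."""
    peaks = triggers.r_peak_times
    if peaks.size == 0:
        raise GatingError("empty trigger list")
    idx = np.searchsorted(peaks, times, side="right") - 1
    tau = np.where(idx >= 0, times - peaks[np.clip(idx, 0, peaks.size - 1)], np.nan)
    tau = np.where(times >= peaks[-1], np.nan, tau)
    return tau


def assign_cardiac_bins(
    times: np.ndarray,
    triggers: TriggerList,
    division_ms: tuple[float, ...] = DEFAULT_DIVISION_MS,
) -> CardiacAssignment:
    """Fixed-time cardiac bins from milliseconds since the previous R-peak.

    Half-open intervals closed below: c = 1 for [0, d1), ..., c = 5 for
    [d4, d5); tau >= d5 is rejected, as are times before the first or
    at/after the last trigger.
    """
    division = np.asarray(division_ms, dtype=float)
    if division.ndim != 1 or division.size < 2 or np.any(np.diff(division) <= 0):
        raise ParameterError("division_ms must be strictly increasing")
    times = np.asarray(times, dtype=float)
    tau = time_since_r_peak(times, triggers)
    tau_ms = tau * 1000.0

    labels = np.full(times.shape, REJECTED, dtype=int)
    with np.errstate(invalid="ignore"):
        inside = np.isfinite(tau_ms) & (tau_ms >= 0) & (tau_ms < division[-1])
    c = np.searchsorted(division[:-1], tau_ms[inside], side="right") + 1
    labels[inside] = c
    return CardiacAssignment(time=times, labels=labels)


def combine_dual(resp: RespiratoryAssignment,
                 cardiac: CardiacAssignment,
                 n_resp_bins: int = 5) -> BinAssignment:
    """Joint bins b = (c - 1) * n_resp_bins + r; REJECTED if either is."""
    if resp.time.shape != cardiac.time.shape or not np.allclose(
            resp.time, cardiac.time):
        raise GatingError("respiratory and cardiac labels are on different time bases")
    both = (resp.labels != REJECTED) & (cardiac.labels != REJECTED)
    dual = np.full(resp.labels.shape, REJECTED, dtype=int)
    dual[both] = (cardiac.labels[both] - 1) * n_resp_bins + resp.labels[both]
    return BinAssignment(time=resp.time, resp=resp.labels,
                         cardiac=cardiac.labels, dual=dual)


def invalid_cycle_loss(trace: RespiratoryTrace, cycles: CycleSet) -> float:
    """Fraction of samples lost to invalid cycles."""
    n = trace.time.size
    lost = sum(int(e - s) for s, e, ok in
               zip(cycles.start_idx, cycles.end_idx, cycles.valid) if not ok)
    return lost / n


def data_fractions(assignment: BinAssignment,
                   invalid_cycle_loss: float = 0.0,
                   n_bins: int = 25,
                   n_resp_bins: int = 5) -> DataFractionReport:
    """Dwell fractions per dual bin plus DG (bin 25) and MoCo (21..25) sums."""
    n = assignment.dual.size
    if n == 0:
        raise GatingError("empty assignment")
    fractions = {b: float(np.count_nonzero(assignment.dual == b)) / n
                 for b in range(1, n_bins + 1)}
    rejected = float(np.count_nonzero(assignment.dual == REJECTED)) / n
    dg = fractions[n_bins]
    moco = sum(fractions[b] for b in range(n_bins - n_resp_bins + 1, n_bins + 1))
    return DataFractionReport(bin_fractions=fractions,
                              rejected_fraction=rejected,
                              invalid_cycle_loss=float(invalid_cycle_loss),
                              dg_fraction=dg, moco_fraction=moco)


def gate_study(trace: RespiratoryTrace, triggers: TriggerList,
               config: GatingConfig | None = None
               ) -> tuple[BinAssignment, DataFractionReport, GatingThresholds]:
    """Run the full gating chain on one signal pair."""
    cfg = config or GatingConfig()
    cycles = detect_cycles(trace, cfg.validity_rule)
    thresholds = compute_thresholds(cycles, cfg.n_resp_bins)
    resp = assign_respiratory_bins(trace, cycles, thresholds, cfg.n_resp_bins)
    cardiac = assign_cardiac_bins(trace.time, triggers, cfg.division_ms)
    assignment = combine_dual(resp, cardiac, cfg.n_resp_bins)
    report = data_fractions(assignment,
                            invalid_cycle_loss=invalid_cycle_loss(trace, cycles),
                            n_resp_bins=cfg.n_resp_bins)
    return assignment, report, thresholds
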