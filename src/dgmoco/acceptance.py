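"""Self-contained numeric targets recomputed from scratch by the gating chain.

Each function generates its synthetic inputs, runs the package's own
operations, and measures the quantity; nothing is looked up or hard-coded
beyond the printed design parameters of the gating scheme (5 + 5 bins,
fixed-time cardiac division, amplitude threshold rule).
"""

from __future__ import annotations

import numpy as np

from dgmoco import gating
from dgmoco.phantom import generate_cardiac_triggers, generate_respiratory_trace

__all__ = ["dual_gate_bin_count", "end_expiratory_occupancy",
           "moco_extra_data_pp", "compute_all_targets"]

# sampling incommensurate with the 5 s period so the sampled occupancy
# converges to the continuous-time closed form instead of quantizing
_SAMPLING_HZ = 24.7
_PERIOD_S = 5.0

# diastolic gate holds (RR - 550 ms) / RR of each beat; 35% -> RR = 550/0.65
_DIASTOLIC_DESIGN_FRACTION = 0.35
_DIASTOLIC_ONSET_MS = 550.0


def _sinusoid(duration: float, seed) -> "object":
    return generate_respiratory_trace(duration=duration, period=_PERIOD_S,
                                      seed=seed, sampling_rate=_SAMPLING_HZ)


def dual_gate_bin_count(seed: int = 0, duration: float = 60.0) -> dict:
    """t1: number of distinct non-rejected joint bins on a synthetic pair."""
    trace = _sinusoid(duration, seed)
    triggers = generate_cardiac_triggers(duration=duration, mean_hr=61.95,
                                         sd_hr=0.0, seed=seed)
    assignment, _, _ = gating.gate_study(trace, triggers)
    distinct = np.unique(assignment.dual[assignment.dual != gating.REJECTED])
    return {"value": int(distinct.size), "n": int(assignment.dual.size)}


def end_expiratory_occupancy(seed: int = 0, duration: float = 100.0) -> dict:
    """t2: % of samples in the lowest amplitude bin, rounded to 1%."""
    trace = _sinusoid(duration, seed)
    cycles = gating.detect_cycles(trace)
    thresholds = gating.compute_thresholds(cycles)
    labels = gating.assign_respiratory_bins(trace, cycles, thresholds).labels
    percent = 100.0 * np.mean(labels == 5)
    return {"value": float(np.round(percent)), "n": int(labels.size)}


def moco_extra_data_pp(seed: int = 0, duration: float = 300.0) -> dict:
    """t3: extra data preserved by bins 21-25 over bin 25 alone (pp)."""
    trace = _sinusoid(duration, seed)
    rr_s = _DIASTOLIC_ONSET_MS / 1000.0 / (1.0 - _DIASTOLIC_DESIGN_FRACTION)
    triggers = generate_cardiac_triggers(duration=duration,
                                         mean_hr=60.0 / rr_s, sd_hr=0.0,
                                         seed=seed)
    _, report, _ = gating.gate_study(trace, triggers)
    extra_pp = 100.0 * (report.moco_fraction - report.dg_fraction)
    return {"value": float(np.round(extra_pp)), "n": int(trace.time.size)}


def compute_all_targets(seed: int = 0) -> dict:
    return {
        "t1": dual_gate_bin_count(seed),
        "t2": end_expiratory_occupancy(seed),
        "t3": moco_extra_data_pp(seed),
    }
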