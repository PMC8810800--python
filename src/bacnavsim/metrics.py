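"""Action-potential feature extraction from simulated voltage traces.

Features reported across all experiments: resting membrane potential
(RMP), AP amplitude (APA), AP duration at p% repolarization (APD_p,
measured from the maximum-upstroke instant, linear interpolation between
samples), and maximum upstroke velocity (dV/dt max).

APD is anchored at the max-dV/dt instant rather than stimulus onset so
that latency between stimulus and regenerative upstroke does not inflate
the duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, NoCaptureError

__all__ = ["ApFeatures", "extract_features", "has_dome"]


@dataclass
class ApFeatures:
    """AP features; durations in ms, potentials in mV, upstroke in V/s."""

    rmp: float
    apa: float
    apd: dict            # repolarization percent -> APD (ms)
    dvdt_max: float      # V/s
    peak_vm: float
    peak_time: float     # ms
    upstroke_time: float  # ms

    @property
    def apd80(self) -> float:
        return self.apd[80]


def _crossing_time(t, v, level, start_idx):
    """First downward crossing of ``level`` at/after ``start_idx``,
    linearly interpolated; nan if none."""
    below = v[start_idx:] <= level
    if not below.any():
        return float("nan")
    k = start_idx + int(np.argmax(below))
    if k == 0 or v[k] == v[k - 1]:
        return float(t[k])
    frac = (level - v[k - 1]) / (v[k] - v[k - 1])
    return float(t[k - 1] + frac * (t[k] - t[k - 1]))


def extract_features(
    t,
    vm,
    stim_time: float = 0.0,
    percents=(20, 50, 80, 90),
    rmp_window_ms: float = 10.0,
) -> ApFeatures:
    """Extract AP features from a single-beat voltage trace.

    RMP is the mean Vm over ``rmp_window_ms`` before ``stim_time`` (or the
    first sample if the trace starts at the stimulus).  APD_p is the time
    from the maximum-dV/dt instant to the repolarization crossing of
    ``RMP + (1 - p/100) * APA``.
    """
    t = np.asarray(t, dtype=float)
    vm = np.asarray(vm, dtype=float)
    if t.ndim != 1 or t.size != vm.size or t.size < 4:
        raise InvalidInputError("need matching 1D t/vm with >= 4 samples")

    pre = (t < stim_time) & (t >= stim_time - rmp_window_ms)
    rmp = float(vm[pre].mean()) if pre.any() else float(vm[0])

    peak_idx = int(np.argmax(vm))
    peak_vm = float(vm[peak_idx])
    apa = peak_vm - rmp
    if apa < 10.0:
        raise NoCaptureError(
            f"no AP in trace (peak {peak_vm:.1f} mV, RMP {rmp:.1f} mV)")

    dvdt = np.gradient(vm, t)
    up_idx = int(np.argmax(dvdt[: peak_idx + 1]))
    dvdt_max = float(dvdt[up_idx])

    apd = {}
    for p in percents:
        level = rmp + (1.0 - p / 100.0) * apa
        tc = _crossing_time(t, vm, level, peak_idx)
        apd[p] = tc - float(t[up_idx]) if np.isfinite(tc) else float("nan")

    return ApFeatures(
        rmp=rmp,
        apa=apa,
        apd=apd,
        dvdt_max=dvdt_max,  # mV/ms == V/s
        peak_vm=peak_vm,
        peak_time=float(t[peak_idx]),
        upstroke_time=float(t[up_idx]),
    )


def has_dome(t, vm, notch_search_ms: float = 50.0, min_notch_depth: float = 5.0,
             dome_level: float = 0.0, plateau_ms: float = 20.0) -> bool:
    """Phase-2 dome detection for epicardial-style APs.

    The AP has a dome iff either (a) after the phase-1 minimum (the
    lowest Vm within ``notch_search_ms`` after the spike) Vm re-ascends
    above ``dome_level`` with the notch at least ``min_notch_depth`` mV
    below that secondary maximum (classic spike-notch-dome morphology),
    or (b) Vm sustains a plateau above ``dome_level`` for at least
    ``plateau_ms`` beyond the spike window (notchless plateau, e.g. when
    an added inward current fills the notch).  Dome loss -- the potential
    collapsing toward rest right after the spike -- fails both clauses.
    """
    t = np.asarray(t, dtype=float)
    vm = np.asarray(vm, dtype=float)
    # the phase-0 spike: maximum within 15 ms of the fastest upstroke
    # (the absolute maximum may be the dome itself)
    dvdt = np.gradient(vm, t)
    up_idx = int(np.argmax(dvdt))
    spike_win = np.flatnonzero((t >= t[up_idx]) & (t <= t[up_idx] + 15.0))
    peak_idx = spike_win[int(np.argmax(vm[spike_win]))]
    # (b) sustained plateau above the dome level past the spike window
    beyond = (t > t[peak_idx] + 15.0)
    above = beyond & (vm > dome_level)
    if above.any():
        dur = np.ptp(t[above])
        if dur >= plateau_ms:
            return True
    # (a) notch followed by secondary rise
    win = (t > t[peak_idx]) & (t <= t[peak_idx] + notch_search_ms)
    if not win.any():
        return False
    widx = np.flatnonzero(win)
    notch_idx = widx[int(np.argmin(vm[widx]))]
    dome_max = float(vm[notch_idx:].max())
    return dome_max > dome_level and (dome_max - vm[notch_idx]) >= min_notch_depth
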