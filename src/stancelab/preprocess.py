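"""Signal conditioning: zero-lag filtering, stance detection, time normalization.

Stance events are the 30 N crossings of the vertical ground reaction force;
each stance is then linearly resampled onto 101 nodes (0-100% of stance).
Kinematic channels are low-pass filtered at 10 Hz and GRF at 80 Hz by the
pipeline before any extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import DataError, ParameterError

N_NODES = 101
EVENT_THRESHOLD_N = 30.0


@dataclass(frozen=True)
class StanceWindow:
    """One ground-contact interval, indexed into the GRF series."""

    heel_strike_index: int
    toe_off_index: int
    rate: float

    def __post_init__(self):
        if self.heel_strike_index >= self.toe_off_index:
            raise DataError("heel strike must precede toe off")
        if self.rate <= 0:
            raise ParameterError("rate must be positive")

    @property
    def duration_s(self) -> float:
        return (self.toe_off_index - self.heel_strike_index) / self.rate

    @property
    def start_s(self) -> float:
        return self.heel_strike_index / self.rate

    @property
    def end_s(self) -> float:
        return self.toe_off_index / self.rate


@dataclass
class NormalizedTrajectory:
    """A named variable resampled to 101 stance nodes.

    ``values`` has shape (n_planes, 101); scalar variables use the single
    plane label ``"scalar"``. Node 0 is heel strike, node 100 toe off.
    """

    name: str
    planes: tuple
    values: np.ndarray

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, float))
        if self.values.shape != (len(self.planes), N_NODES):
            raise DataError(
                f"{self.name}: values must be (n_planes, {N_NODES}), "
                f"got {self.values.shape}")

    def plane(self, name: str) -> np.ndarray:
        return self.values[self.planes.index(name)]


def butterworth_zero_lag(series, rate, cutoff_hz, effective_order: int = 4):
    """Dual-pass (zero phase lag) low-pass Butterworth filter.

    The conventional "fourth-order, zero-lag" filter of gait analysis: a
    2nd-order Butterworth run forward then backward, giving an effective 4th
    order and a gain of exactly 0.5 at the cutoff. ``effective_order=8``
    selects the alternative reading (4th-order dual-pass). Edges are padded
    by odd reflection, pad length 3x the effective order.
    """
    x = np.asarray(series, float)
    if effective_order not in (4, 8):
        raise ParameterError("effective_order must be 4 or 8")
    if not 0.0 < cutoff_hz < rate / 2.0:
        raise ParameterError(f"cutoff_hz={cutoff_hz} must lie in (0, rate/2)")
    padlen = 3 * effective_order
    if x.shape[-1] <= padlen:
        raise DataError(f"series too short for filtering (need > {padlen} samples)")
    b, a = butter(effective_order // 2, cutoff_hz / (rate / 2.0))
    return filtfilt(b, a, x, axis=-1, padtype="odd", padlen=padlen)


def detect_stance(grf_v, rate, threshold_n: float = EVENT_THRESHOLD_N,
                  min_stance_s: float = 0.0, min_flight_s: float = 0.0):
    """Find stance windows as threshold-crossing pairs of the vertical GRF.

    Heel strike is the first sample at or above ``threshold_n`` after a
    below-threshold run, toe off the last such sample before the next
    below-threshold run. Optional hysteresis rejects chatter: below-threshold
    gaps shorter than ``min_flight_s`` are bridged, then contacts shorter
    than ``min_stance_s`` are dropped. Runs touching the series boundaries
    (incomplete stances) are discarded. Returns a (possibly empty) list of
    :class:`StanceWindow`.
    """
    x = np.asarray(grf_v, float)
    if rate <= 0:
        raise ParameterError("rate must be positive")
    if np.isnan(x).any():
        raise DataError("NaN in vertical GRF")
    above = x >= threshold_n
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1))
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(x) - 1)
    runs = [[s, e] for s, e in zip(starts, ends)]

    merged = []
    for s, e in runs:
        if merged and (s - merged[-1][1] - 1) / rate < min_flight_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    min_samples = max(int(np.ceil(min_stance_s * rate)), 2)
    return [StanceWindow(s, e, rate) for s, e in merged
            if s > 0 and e < len(x) - 1 and (e - s + 1) >= min_samples]


def resample_to_window(series, rate, t_start, t_end, n_nodes: int = N_NODES):
    """Linearly interpolate a series onto n_nodes spanning [t_start, t_end] s."""
    x = np.asarray(series, float)
    if t_end <= t_start:
        raise DataError("window end must follow window start")
    t = np.arange(x.shape[-1]) / rate
    if t_start < t[0] - 1e-12 or t_end > t[-1] + 1e-12:
        raise DataError("stance window extends beyond the recorded series")
    nodes = np.linspace(t_start, t_end, n_nodes)
    if x.ndim == 1:
        return np.interp(nodes, t, x)
    return np.stack([np.interp(nodes, t, row) for row in x])


def normalize_to_stance(series, window: StanceWindow, rate,
                        n_nodes: int = N_NODES):
    """Resample a series (sampled at ``rate``) onto the stance-percent grid.

    ``window`` may come from a GRF series at a different rate; its times are
    what matter. The window must span at least 2 samples of ``series``.
    """
    if (window.end_s - window.start_s) * rate < 1.0:
        raise DataError("stance window shorter than 2 samples at this rate")
    return resample_to_window(series, rate, window.start_s, window.end_s, n_nodes)
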