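"""Discrete biomechanical risk factors extracted per trial.

Six scalars per stance: MLA range of motion (max - min, deg), rearfoot
frontal-plane peaks (Sha-Cal inversion = most negative, eversion = most
positive, deg), vertical impact peak (first local maximum of the vertical GRF
at initial contact, body weights), vertical average loading rate (secant
slope between 20% and 80% of the contact-to-impact-peak interval, BW/s), and
peak braking force (most negative anterior-posterior GRF, BW).

Forces are normalized to body weight with g = 9.80665 m/s^2. A missing
impact transient (forefoot-strike-like waveform) propagates as NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DataError, ParameterError, ResolutionError
from .preprocess import StanceWindow

GRAVITY = 9.80665

OUTCOME_NAMES = ("mla_rom", "shacal_inv_peak", "shacal_eve_peak",
                 "vertical_impact_peak", "valr", "peak_braking_force")

#: impact transient search region as a fraction of stance
IMPACT_SEARCH_FRAC = 0.30


@dataclass
class DiscreteOutcomes:
    mla_rom: float
    shacal_inv_peak: float
    shacal_eve_peak: float
    vertical_impact_peak: float  # NaN when no impact transient
    valr: float                  # NaN when no impact transient
    peak_braking_force: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in OUTCOME_NAMES}


def _finite_or_raise(traj, what):
    x = np.asarray(traj, float)
    if not np.isfinite(x).all():
        raise DataError(f"non-finite values in {what}")
    return x


def mla_rom(mla_trajectory) -> float:
    """Range of motion of the MLA angle over stance: max - min, degrees."""
    x = _finite_or_raise(mla_trajectory, "MLA trajectory")
    return float(x.max() - x.min())


def rearfoot_peaks(shacal_frontal_trajectory):
    """(inversion peak, eversion peak) of the Sha-Cal frontal angle, degrees.

    Inversion is the minimum (most negative by convention), eversion the
    maximum; hence eversion peak >= inversion peak always.
    """
    x = _finite_or_raise(shacal_frontal_trajectory, "Sha-Cal frontal trajectory")
    return float(x.min()), float(x.max())


def _local_max_indices(x):
    """Indices i with x[i-1] < x[i] >= x[i+1] (interior strict rises)."""
    x = np.asarray(x, float)
    return np.flatnonzero((x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:])) + 1


def _impact_index(grf_v, window: StanceWindow, search_frac: float):
    """Sample index of the impact transient, or None if absent.

    Returns the first local maximum of the stance segment that lies within
    the early-stance search region. Raises DataError when the stance segment
    has no interior local maximum at all (monotone trace).
    """
    hs, to = window.heel_strike_index, window.toe_off_index
    seg = _finite_or_raise(np.asarray(grf_v, float)[hs:to + 1], "vertical GRF")
    peaks = _local_max_indices(seg)
    if peaks.size == 0:
        raise DataError("no local maximum anywhere in stance")
    limit = search_frac * (to - hs)
    first = peaks[0]
    if first > limit:
        return None
    return hs + int(first)


def impact_peak(grf_v_raw_time, window: StanceWindow, body_weight_n,
                search_frac: float = IMPACT_SEARCH_FRAC) -> float:
    """Vertical impact peak in body weights; NaN when no transient exists."""
    if body_weight_n <= 0:
        raise ParameterError("body_weight_n must be positive")
    idx = _impact_index(grf_v_raw_time, window, search_frac)
    if idx is None:
        return float("nan")
    return float(np.asarray(grf_v_raw_time, float)[idx] / body_weight_n)


def valr(grf_v_raw_time, window: StanceWindow, body_weight_n,
         method: str = "secant", search_frac: float = IMPACT_SEARCH_FRAC,
         min_interval_samples: int = 5) -> float:
    """Vertical average loading rate in BW/s.

    With t0 the heel-strike time and tp the impact-peak time, the default
    reading is the secant slope of the line through the force values at
    t0 + 0.2*(tp-t0) and t0 + 0.8*(tp-t0). ``method="regression"`` fits a
    least-squares line to all samples in that interval instead. NaN when the
    impact transient is absent.
    """
    if method not in ("secant", "regression"):
        raise ParameterError("method must be 'secant' or 'regression'")
    if body_weight_n <= 0:
        raise ParameterError("body_weight_n must be positive")
    idx = _impact_index(grf_v_raw_time, window, search_frac)
    if idx is None:
        return float("nan")
    if idx - window.heel_strike_index < min_interval_samples:
        raise ResolutionError(
            "contact-to-impact-peak interval shorter than "
            f"{min_interval_samples} samples")
    x = np.asarray(grf_v_raw_time, float)
    rate = window.rate
    t = np.arange(x.size) / rate
    t0, tp = window.heel_strike_index / rate, idx / rate
    delta = tp - t0
    t20, t80 = t0 + 0.2 * delta, t0 + 0.8 * delta
    if method == "secant":
        f20, f80 = np.interp([t20, t80], t, x)
        slope = (f80 - f20) / (0.6 * delta)
    else:
        inside = (t >= t20) & (t <= t80)
        ts = np.r_[t20, t[inside], t80]
        fs = np.r_[np.interp(t20, t, x), x[inside], np.interp(t80, t, x)]
        slope = np.polyfit(ts, fs, 1)[0]
    return float(slope / body_weight_n)


def peak_braking(grf_ap_raw_time, window: StanceWindow, body_weight_n,
                 posterior_negative: bool = True) -> float:
    """Maximum posterior (braking) force in BW, returned negative.

    ``posterior_negative=False`` declares the opposite sign convention in the
    input; the result is always reported posterior-negative.
    """
    if body_weight_n <= 0:
        raise ParameterError("body_weight_n must be positive")
    x = _finite_or_raise(grf_ap_raw_time, "anterior-posterior GRF")
    seg = x[window.heel_strike_index:window.toe_off_index + 1]
    if not posterior_negative:
        seg = -seg
    if seg.min() >= 0:
        warnings.warn("anterior-posterior trace has no posterior (negative) "
                      "phase; returning in-stance minimum", stacklevel=2)
    return float(seg.min() / body_weight_n)


def extract_outcomes(mla_trajectory, shacal_frontal_trajectory, grf_v, grf_ap,
                     window: StanceWindow, body_mass_kg: float,
                     valr_method: str = "secant") -> DiscreteOutcomes:
    """All six discrete outcomes for one processed trial."""
    bw = body_mass_kg * GRAVITY
    inv, eve = rearfoot_peaks(shacal_frontal_trajectory)
    return DiscreteOutcomes(
        mla_rom=mla_rom(mla_trajectory),
        shacal_inv_peak=inv,
        shacal_eve_peak=eve,
        vertical_impact_peak=impact_peak(grf_v, window, bw),
        valr=valr(grf_v, window, bw, method=valr_method),
        peak_braking_force=peak_braking(grf_ap, window, bw),
    )
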