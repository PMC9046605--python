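"""Synthetic running cohorts with known (planted) group-by-time effects.

The generator emulates the measurement set-up of a two-arm pre/post trial of
recreational runners: per subject and session one stance of treadmill running,
with vertical + anterior-posterior ground reaction force sampled at 1000 Hz,
five foot-segment poses and a reduced marker set sampled at 200 Hz, and
subject metadata (group, body mass ~ N(70.5, 13.1) kg truncated at +-3 sd).

Every trial carries its planted ground truth: the six discrete outcomes the
downstream pipeline extracts are built into the waveforms analytically, so
that with zero noise the full pipeline recovers them exactly:

* the vertical GRF rises linearly (slope = VALR x BW) from exactly 30 N at a
  grid-aligned contact sample to a grid-aligned impact-transient maximum of
  exactly impact_peak x BW, then dips and rises to the active peak, and
  descends through exactly 30 N at the grid-aligned toe-off sample;
* the braking minimum of the AP force sits on a grid sample;
* the MLA and Sha-Cal frontal angle programs place their extrema on nodes of
  both the 200 Hz grid and the 101-node stance grid.

Joint angle programs are composed into segment rotation matrices in the exact
inverse order of the JCS decomposition, so decomposition round-trips to the
programs at numerical precision. Smoothness (low-order Fourier wiggles and
raised-cosine bumps) keeps the trajectories compatible with the smooth-field
assumptions of the 1D random-field statistics downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, GenerationError
from .footkin import jcs_compose
from .outcomes import GRAVITY, OUTCOME_NAMES
from .preprocess import EVENT_THRESHOLD_N

GROUPS = ("IG", "CG")
TIMES = ("baseline", "week8")
SEGMENTS = ("shank", "calcaneus", "midfoot", "metatarsus", "hallux")

#: flank of sub-threshold signal on each side of stance, seconds
FLANK_S = 0.05
#: lead-in over which the vertical GRF climbs from 0 toward 30 N
LEAD_IN_S = 0.02


@dataclass(frozen=True)
class EffectCell:
    """Configured means (and sds) for one outcome across the four cells."""

    ig_pre: float
    ig_post: float
    cg_pre: float
    cg_post: float
    sd: tuple  # scalar broadcast to 4 cells, or (ig_pre, ig_post, cg_pre, cg_post)

    def means(self) -> dict:
        return {("IG", "baseline"): self.ig_pre, ("IG", "week8"): self.ig_post,
                ("CG", "baseline"): self.cg_pre, ("CG", "week8"): self.cg_post}

    def sds(self) -> dict:
        sd = self.sd if isinstance(self.sd, (tuple, list)) else (self.sd,) * 4
        if len(sd) != 4:
            raise ConfigError("effect_table sd must be a scalar or a 4-tuple")
        return dict(zip(self.means().keys(), (float(s) for s in sd)))


def default_effect_table() -> dict:
    """Cell means and sds of the six discrete outcomes (study conditions)."""
    return {
        "mla_rom": EffectCell(6.16, 0.17, 3.59, 2.88, (8.14, 6.86, 7.89, 5.36)),
        "shacal_inv_peak": EffectCell(-0.56, -5.74, -3.30, -3.51, (7.42, 6.31, 8.71, 5.70)),
        "shacal_eve_peak": EffectCell(6.72, 5.90, 6.89, 6.39, (3.29, 2.95, 2.35, 1.88)),
        "vertical_impact_peak": EffectCell(1.13, 1.14, 1.21, 1.09, (0.39, 0.55, 0.44, 0.58)),
        "valr": EffectCell(75.19, 77.17, 73.48, 72.84, (46.43, 57.52, 43.17, 65.73)),
        "peak_braking_force": EffectCell(-0.24, -0.24, -0.24, -0.24, (0.05, 0.07, 0.05, 0.05)),
    }


@dataclass
class TrajectoryEffect:
    """Smooth group/time-dependent offset added to one kinematic channel."""

    channel: str
    plane: str  # "sagittal"/"frontal"/"transverse" or "scalar"
    amplitudes: dict  # (group, time) -> degrees
    center_frac: float = 0.5
    halfwidth_frac: float = 0.25


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    ``n_per_group`` is an int or an (IG, CG) pair; the default reproduces the
    41/46 split of the emulated trial. ``between_subject_sd`` optionally maps
    outcome -> sd of the subject random intercept (same units as the
    outcome); by default half of each outcome's smallest cell variance goes
    into the intercept, so the configured cell sds are reproduced exactly.
    """

    n_per_group: object = (41, 46)
    seed: int = 0
    effect_table: dict = field(default_factory=default_effect_table)
    between_subject_sd: dict | None = None
    noise_sd_marker: float = 0.5            # mm
    trajectory_noise_sd_deg: float = 1.5    # smooth per-trial angle variability
    swing_noise_sd_n: float = 0.0           # sub-threshold GRF noise in swing
    stance_duration_s: float = 0.25
    kin_rate: float = 200.0
    grf_rate: float = 1000.0
    body_mass_mean_kg: float = 70.5
    body_mass_sd_kg: float = 13.1
    active_peak_bw: float = 2.4
    trajectory_effects: list = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    @property
    def n_ig(self) -> int:
        return self.n_per_group[0] if isinstance(self.n_per_group, (tuple, list)) \
            else int(self.n_per_group)

    @property
    def n_cg(self) -> int:
        return self.n_per_group[1] if isinstance(self.n_per_group, (tuple, list)) \
            else int(self.n_per_group)

    def validate(self) -> None:
        if self.n_ig < 2 or self.n_cg < 2:
            raise ConfigError("n_per_group: need at least 2 subjects per arm")
        for fld in ("kin_rate", "grf_rate", "stance_duration_s",
                    "body_mass_mean_kg", "active_peak_bw"):
            if getattr(self, fld) <= 0:
                raise ConfigError(f"{fld}: must be positive")
        for fld in ("noise_sd_marker", "trajectory_noise_sd_deg",
                    "swing_noise_sd_n", "body_mass_sd_kg"):
            if getattr(self, fld) < 0:
                raise ConfigError(f"{fld}: must be non-negative")
        for name, cell in self.effect_table.items():
            if name not in OUTCOME_NAMES:
                raise ConfigError(f"effect_table: unknown outcome '{name}'")
            if any(s < 0 for s in cell.sds().values()):
                raise ConfigError(f"effect_table[{name}]: sd must be non-negative")
        if self.between_subject_sd is not None:
            for name, sb in self.between_subject_sd.items():
                if name not in self.effect_table:
                    raise ConfigError(f"between_subject_sd: unknown outcome '{name}'")
                if sb < 0 or sb > min(self.effect_table[name].sds().values()):
                    raise ConfigError(
                        f"between_subject_sd[{name}]: must lie in [0, min cell sd]")
        # grid alignment: contact, toe-off and mid-stance must fall on samples
        for rate, nm in ((self.kin_rate, "kin_rate"), (self.grf_rate, "grf_rate")):
            for dur, dnm in ((self.stance_duration_s, "stance_duration_s"),
                             (FLANK_S, "flank"), (self.stance_duration_s / 2, "half-stance")):
                if abs(dur * rate - round(dur * rate)) > 1e-9:
                    raise ConfigError(
                        f"stance_duration_s/{nm}: {dnm} must span a whole "
                        f"number of samples at {nm}={rate}")

    def subject_sd(self, outcome: str) -> float:
        if self.between_subject_sd and outcome in self.between_subject_sd:
            return float(self.between_subject_sd[outcome])
        return min(self.effect_table[outcome].sds().values()) / np.sqrt(2.0)


@dataclass
class TrialRecording:
    """Raw synchronized recording for one subject-session."""

    subject_id: str
    group: str
    time: str
    body_mass: float
    grf_rate: float
    kin_rate: float
    grf_v: np.ndarray
    grf_ap: np.ndarray
    segment_poses: dict   # segment -> (rotations (n,3,3), origins (n,3) mm)
    markers: dict         # name -> (n,3) mm
    true_events: tuple = None   # (contact_index, toe_off_index) in grf samples
    planted: dict = None        # outcome -> ground-truth value


@dataclass
class Cohort:
    trials: list
    planted: pd.DataFrame   # long: subject_id, group, time, body_mass, outcome, value
    config: CohortConfig


# ---------------------------------------------------------------------------
# Ground reaction force synthesis


def _hermite(t, t0, t1, f0, f1, m0, m1):
    """Cubic Hermite segment evaluated at t."""
    h = t1 - t0
    s = (t - t0) / h
    h00 = (1 + 2 * s) * (1 - s) ** 2
    h10 = s * (1 - s) ** 2
    h01 = s * s * (3 - 2 * s)
    h11 = s * s * (s - 1)
    return h00 * f0 + h10 * h * m0 + h01 * f1 + h11 * h * m1


@dataclass
class GRFWaveform:
    grf_v: np.ndarray
    grf_ap: np.ndarray
    rate: float
    contact_index: int
    toe_off_index: int
    impact_peak_index: int


def synth_grf(stance_duration_s, body_mass, impact_peak_bw, active_peak_bw,
              valr_bw_s, braking_peak_bw, rate,
              propulsive_peak_bw: float = 0.22) -> GRFWaveform:
    """Analytic stance-phase GRF with exactly plantable loading metrics.

    The returned series span ``FLANK_S`` of sub-threshold signal on either
    side of stance. Contact (vertical force exactly 30 N, rising), the
    impact-transient maximum (exactly ``impact_peak_bw x BW``), toe-off
    (exactly 30 N, falling) and the braking minimum all fall on grid samples,
    and the 20-80% contact-to-impact-peak interval lies on the linear rise
    whose slope is exactly ``valr_bw_s x BW``.
    """
    bw = body_mass * GRAVITY
    f_imp = impact_peak_bw * bw
    f_act = active_peak_bw * bw
    slope = valr_bw_s * bw
    T = round(stance_duration_s * rate) / rate
    if braking_peak_bw > 0:
        raise GenerationError("braking_peak_bw must be <= 0 (posterior negative)")
    if impact_peak_bw <= 0 or slope <= 0:
        raise GenerationError("impact peak and VALR must be positive")
    if f_imp <= EVENT_THRESHOLD_N:
        raise GenerationError("impact peak must exceed the 30 N event threshold")
    if f_act <= f_imp:
        raise GenerationError("impact peak must lie below the active peak")

    delta_exact = (f_imp - EVENT_THRESHOLD_N) / slope
    delta_k = int(np.ceil(delta_exact * rate - 1e-9))
    delta = delta_k / rate
    if delta_k < 6:
        raise GenerationError("impact rise shorter than 6 samples; lower VALR "
                              "or raise the impact peak")
    if delta > 0.25 * T:
        raise GenerationError("impact rise longer than 25% of stance; raise "
                              "VALR or shorten the impact peak")

    n_flank = round(FLANK_S * rate)
    n = int(2 * n_flank + round(T * rate)) + 1
    k = np.arange(n) - n_flank       # sample offset from contact
    t = k / rate                     # time relative to contact

    t_v = delta + max(0.06 * T, 0.02)
    f_v = 0.85 * f_imp
    t_a = max(0.45 * T, t_v + 0.05 * T)
    m_end = 2.0 * (EVENT_THRESHOLD_N - f_act) / (T - t_a)

    v = np.zeros(n)
    m = (t >= -LEAD_IN_S) & (t < 0)
    v[m] = EVENT_THRESHOLD_N * ((t[m] + LEAD_IN_S) / LEAD_IN_S) ** 2 * 0.95
    # linear rise at exactly the planted loading rate; the peak sample itself
    # carries the exact planted impact maximum (the last linear sample never
    # exceeds it because the grid time delta is the ceiling of the exact rise)
    m = (k >= 0) & (k < delta_k)
    v[m] = EVENT_THRESHOLD_N + slope * t[m]
    v[k == delta_k] = f_imp
    m = (t > delta) & (t <= t_v)
    v[m] = _hermite(t[m], delta, t_v, f_imp, f_v, 0.0, 0.0)
    m = (t > t_v) & (t <= t_a)
    v[m] = _hermite(t[m], t_v, t_a, f_v, f_act, 0.0, 0.0)
    m = (t > t_a) & (t <= T)
    v[m] = _hermite(t[m], t_a, T, f_act, EVENT_THRESHOLD_N, 0.0, m_end)
    m = t > T
    v[m] = np.clip(EVENT_THRESHOLD_N + m_end * (t[m] - T), 0.0, None)

    # anterior-posterior: braking lobe then propulsive lobe
    ap = np.zeros(n)
    t_b = round(0.24 * T * rate) / rate
    t_z = 2 * t_b
    m = (t >= 0) & (t <= t_z)
    ap[m] = braking_peak_bw * bw * np.sin(np.pi * t[m] / t_z) ** 2
    m = (t > t_z) & (t <= T)
    ap[m] = propulsive_peak_bw * bw * np.sin(np.pi * (t[m] - t_z) / (T - t_z)) ** 2

    return GRFWaveform(v, ap, rate, n_flank, n_flank + round(T * rate),
                       n_flank + delta_k)


# ---------------------------------------------------------------------------
# Angle programs and pose/marker synthesis


def _bump(frac, center, halfwidth):
    """C1 raised-cosine bump: exactly 1 at center, 0 outside +-halfwidth."""
    x = np.asarray(frac, float)
    out = np.zeros_like(x)
    m = np.abs(x - center) < halfwidth
    out[m] = np.cos(np.pi * (x[m] - center) / (2 * halfwidth)) ** 2
    return out


def _wiggle(frac, coefs):
    """Smooth low-order Fourier perturbation; coefs shape (k, 2)."""
    out = np.zeros_like(np.asarray(frac, float))
    for k, (a, b) in enumerate(coefs, start=1):
        out += (a * np.cos(2 * np.pi * k * frac) + b * np.sin(2 * np.pi * k * frac)) / k
    return out


#: fraction of stance at which the eversion / inversion peaks are planted;
#: both are multiples of 0.02 so they fall on kin samples and stance nodes
EVE_PEAK_FRAC, INV_PEAK_FRAC = 0.30, 0.80
MLA_BASE_DEG = 125.0


def shacal_frontal_program(inv_peak, eve_peak):
    """Frontal Sha-Cal curve whose min/max are exactly the planted peaks."""
    mid = 0.5 * (inv_peak + eve_peak)
    a, b = eve_peak - mid, mid - inv_peak

    def f(frac):
        return (mid + a * _bump(frac, EVE_PEAK_FRAC, 0.26)
                - b * _bump(frac, INV_PEAK_FRAC, 0.20))
    return f


def mla_program(rom, base=MLA_BASE_DEG):
    """MLA angle curve: min ``base`` at contact/toe-off, max ``base+rom`` at 50%."""
    def f(frac):
        return base + rom * (0.5 - 0.5 * np.cos(2 * np.pi * np.asarray(frac, float)))
    return f


def default_joint_programs(rng, noise_sd, shacal_frontal=None):
    """Template JCS programs (deg as functions of stance fraction) per joint.

    Templates are loosely shaped on normative barefoot running curves; each
    plane gets an independent smooth Fourier wiggle with sd ``noise_sd``.
    The Sha-Cal frontal program is supplied by the caller (planted).
    """
    def wig():
        c = rng.normal(0.0, noise_sd, size=(3, 2)) if noise_sd > 0 else np.zeros((3, 2))
        return lambda frac, c=c: _wiggle(frac, c)

    def combine(base, w):
        return lambda frac: base(frac) + w(frac)

    progs = {
        "Sha-Cal": {
            "sagittal": combine(lambda f: -5.0 + 12.0 * np.sin(np.pi * f), wig()),
            "frontal": shacal_frontal or combine(lambda f: 2.0 * np.sin(2 * np.pi * f), wig()),
            "transverse": combine(lambda f: 3.0 - 5.0 * _bump(f, 0.5, 0.45), wig()),
        },
        "Cal-Mid": {
            "sagittal": combine(lambda f: 2.0 + 6.0 * _bump(f, 0.45, 0.4), wig()),
            "frontal": combine(lambda f: -1.0 + 4.0 * _bump(f, 0.35, 0.3), wig()),
            "transverse": combine(lambda f: -2.0 + 3.0 * np.sin(np.pi * f), wig()),
        },
        "Mid-Met": {
            "sagittal": combine(lambda f: -3.0 - 8.0 * _bump(f, 0.85, 0.2)
                                + 4.0 * _bump(f, 0.4, 0.3), wig()),
            "frontal": combine(lambda f: 1.5 * np.sin(np.pi * f), wig()),
            "transverse": combine(lambda f: -1.0 + 2.0 * _bump(f, 0.6, 0.35), wig()),
        },
        "Met-Hal": {
            "sagittal": combine(lambda f: 5.0 + 28.0 * _bump(f, 0.85, 0.2), wig()),
            "frontal": combine(lambda f: 1.0 * np.sin(np.pi * f), wig()),
            "transverse": combine(lambda f: -2.0 + 4.0 * _bump(f, 0.7, 0.3), wig()),
        },
    }
    return progs


def default_planar_programs(rng, noise_sd, mla=None):
    """Template planar-angle programs (deg of stance fraction)."""
    def wig():
        c = rng.normal(0.0, noise_sd, size=(3, 2)) if noise_sd > 0 else np.zeros((3, 2))
        return lambda frac, c=c: _wiggle(frac, c)

    def combine(base, w):
        return lambda frac: base(frac) + w(frac)

    return {
        "F2G": combine(lambda f: 20.0 - 8.0 * np.sin(np.pi * f)
                       + 14.0 * _bump(f, 0.92, 0.16), wig()),
        "S2G": combine(lambda f: 15.0 - 6.0 * np.sin(np.pi * f)
                       + 12.0 * _bump(f, 0.92, 0.16), wig()),
        "V2G": combine(lambda f: 8.0 - 4.0 * np.sin(np.pi * f)
                       + 8.0 * _bump(f, 0.92, 0.16), wig()),
        "S2F": combine(lambda f: 7.0 + 2.0 * np.sin(np.pi * f), wig()),
        "S2V": combine(lambda f: 16.0 + 3.0 * np.sin(np.pi * f), wig()),
        "MLA": mla or combine(lambda f: MLA_BASE_DEG
                              + 4.0 * (0.5 - 0.5 * np.cos(2 * np.pi * f)), wig()),
    }


#: static base points of the marker construction, mm, lab frame (x anterior,
#: y vertical, z medio-lateral)
_MARKER_BASES = {
    "heel": np.array([-60.0, 25.0, 0.0]),
    "met1_base": np.array([15.0, 28.0, -25.0]),
    "met2_base": np.array([10.0, 25.0, 0.0]),
    "met5_base": np.array([5.0, 20.0, 25.0]),
}
_MET_LENGTHS = {"met1": 70.0, "met2": 75.0, "met5": 72.0}

_SEGMENT_ORIGINS = {
    "shank": np.array([0.0, 400.0, 0.0]),
    "calcaneus": np.array([-60.0, 30.0, 0.0]),
    "midfoot": np.array([0.0, 25.0, 0.0]),
    "metatarsus": np.array([60.0, 20.0, 0.0]),
    "hallux": np.array([120.0, 15.0, 0.0]),
}


def _met_markers(base, length, inclination_deg, azimuth_deg):
    inc = np.radians(np.asarray(inclination_deg, float))
    azi = np.radians(np.asarray(azimuth_deg, float))
    d = np.stack([np.cos(inc) * np.cos(azi), -np.sin(inc),
                  np.cos(inc) * np.sin(azi)], axis=-1)
    return base + length * d


def _arch_apex(heel, met1_head, mla_deg):
    """Apex marker making the heel-apex-head angle exactly ``mla_deg``."""
    a = np.asarray(heel, float)
    c = np.asarray(met1_head, float)
    mid = 0.5 * (a + c)
    d = c - a
    w = 0.5 * np.linalg.norm(d, axis=-1)
    dn = d / np.linalg.norm(d, axis=-1, keepdims=True)
    up = np.array([0.0, 1.0, 0.0]) - dn * dn[..., 1:2]
    up = up / np.linalg.norm(up, axis=-1, keepdims=True)
    h = w / np.tan(np.radians(np.asarray(mla_deg, float)) / 2.0)
    return mid + up * h[..., None]


def synth_segment_poses(angle_programs, rate, duration, planar_programs=None,
                        contact_time_s: float = 0.0, total_duration_s=None,
                        marker_noise_sd_mm: float = 0.0, rng=None,
                        lab_offset=(0.0, 0.0, 0.0)):
    """Build segment poses and markers whose decomposition equals the programs.

    ``angle_programs``: {joint: {plane: f(stance_frac)}} for the chain joints
    Sha-Cal, Cal-Mid, Mid-Met, Met-Hal (Cal-Met emerges by composition).
    ``planar_programs``: {name: f(stance_frac)} for F2G/S2G/V2G/S2F/S2V/MLA.
    The programs are evaluated on stance fractions clipped to [0, 1], so the
    series can extend beyond stance (``total_duration_s``).
    """
    total = duration if total_duration_s is None else total_duration_s
    n = int(round(total * rate)) + 1
    t = np.arange(n) / rate
    frac = np.clip((t - contact_time_s) / duration, 0.0, 1.0)

    chain = ("Sha-Cal", "Cal-Mid", "Mid-Met", "Met-Hal")
    rel = {}
    for joint in chain:
        progs = angle_programs[joint]
        sag = np.asarray(progs["sagittal"](frac), float)
        fro = np.asarray(progs["frontal"](frac), float)
        tra = np.asarray(progs["transverse"](frac), float)
        for nm, ang in (("sagittal", sag), ("frontal", fro), ("transverse", tra)):
            if np.any(np.abs(ang) >= 89.0):
                raise GenerationError(
                    f"{joint} {nm} program reaches {np.abs(ang).max():.1f} deg "
                    "(gimbal proximity)")
        rel[joint] = jcs_compose(sag, fro, tra)

    eye = np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
    R = {"shank": eye}
    R["calcaneus"] = R["shank"] @ rel["Sha-Cal"]
    R["midfoot"] = R["calcaneus"] @ rel["Cal-Mid"]
    R["metatarsus"] = R["midfoot"] @ rel["Mid-Met"]
    R["hallux"] = R["metatarsus"] @ rel["Met-Hal"]

    off = np.asarray(lab_offset, float)
    poses = {seg: (R[seg], np.broadcast_to(_SEGMENT_ORIGINS[seg] + off, (n, 3)).copy())
             for seg in SEGMENTS}

    markers = {}
    if planar_programs is not None:
        p = {name: np.asarray(fn(frac), float) for name, fn in planar_programs.items()}
        markers["heel"] = np.broadcast_to(_MARKER_BASES["heel"] + off, (n, 3)).copy()
        for met, incl, azi in (("met1", p["F2G"], -p["S2F"]),
                               ("met2", p["S2G"], np.zeros(n)),
                               ("met5", p["V2G"], -p["S2V"])):
            base = np.broadcast_to(_MARKER_BASES[f"{met}_base"] + off, (n, 3)).copy()
            markers[f"{met}_base"] = base
            markers[f"{met}_head"] = _met_markers(base, _MET_LENGTHS[met], incl, azi)
        markers["arch_apex"] = _arch_apex(markers["heel"], markers["met1_head"], p["MLA"])
        markers["hallux"] = poses["hallux"][1] + np.einsum(
            "nij,j->ni", poses["hallux"][0], np.array([20.0, 0.0, 0.0]))
        if marker_noise_sd_mm > 0:
            if rng is None:
                rng = np.random.default_rng()
            for name in markers:
                markers[name] = markers[name] + rng.normal(
                    0.0, marker_noise_sd_mm, markers[name].shape)
    return poses, markers


# ---------------------------------------------------------------------------
# Cohort assembly


def _truncated_normal(rng, mean, sd, n, nsd=3.0):
    x = rng.normal(mean, sd, size=n)
    while True:
        bad = np.abs(x - mean) > nsd * sd
        if not bad.any():
            return x
        x[bad] = rng.normal(mean, sd, size=bad.sum())


def simulate_outcome_table(config: CohortConfig, rng=None) -> pd.DataFrame:
    """Planted outcome values only (no waveforms), unconstrained Gaussian.

    Per subject a random intercept N(0, sigma_b) shared across times, plus a
    cell-specific residual so that the marginal sd of each cell equals the
    configured value. This is the path used for statistical-recovery
    simulations; physical-feasibility clamping is applied only when waveforms
    are synthesized.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = []
    for group, n_g in (("IG", config.n_ig), ("CG", config.n_cg)):
        mass = _truncated_normal(rng, config.body_mass_mean_kg,
                                 config.body_mass_sd_kg, n_g)
        for i in range(n_g):
            sid = f"{group}{i + 1:03d}"
            intercepts = {name: rng.normal(0.0, config.subject_sd(name))
                          for name in config.effect_table}
            for time in TIMES:
                for name, cell in config.effect_table.items():
                    sd_cell = cell.sds()[(group, time)]
                    sig_b = config.subject_sd(name)
                    resid_sd = np.sqrt(max(sd_cell ** 2 - sig_b ** 2, 0.0))
                    val = (cell.means()[(group, time)] + intercepts[name]
                           + rng.normal(0.0, resid_sd))
                    rows.append((sid, group, time, mass[i], name, val))
    return pd.DataFrame(rows, columns=["subject_id", "group", "time",
                                       "body_mass_kg", "outcome", "value"])


def _clamp_planted(vals: dict, body_mass: float, config: CohortConfig) -> dict:
    """Project a planted draw onto the physically synthesizable region."""
    bw = body_mass * GRAVITY
    out = dict(vals)
    out["mla_rom"] = max(out["mla_rom"], 0.0)
    if out["shacal_eve_peak"] < out["shacal_inv_peak"]:
        mid = 0.5 * (out["shacal_eve_peak"] + out["shacal_inv_peak"])
        out["shacal_eve_peak"] = out["shacal_inv_peak"] = mid
    out["vertical_impact_peak"] = float(np.clip(
        out["vertical_impact_peak"], 1.5 * EVENT_THRESHOLD_N / bw,
        config.active_peak_bw - 0.15))
    f_imp = out["vertical_impact_peak"] * bw
    # keep the impact rise between 7 GRF samples and 24% of stance (margin
    # against the grid snap on either side)
    lo = (f_imp - EVENT_THRESHOLD_N) / (0.24 * config.stance_duration_s * bw)
    hi = (f_imp - EVENT_THRESHOLD_N) * config.grf_rate / (7.0 * bw)
    out["valr"] = float(np.clip(out["valr"], lo, hi))
    out["peak_braking_force"] = min(out["peak_braking_force"], -0.02)
    return out


def generate_cohort(config: CohortConfig) -> Cohort:
    """Synthesize the full cohort of trial recordings with ground truth."""
    rng = np.random.default_rng(config.seed)
    table = simulate_outcome_table(config, rng)
    wide = table.pivot_table(index=["subject_id", "group", "time", "body_mass_kg"],
                             columns="outcome", values="value").reset_index()
    T = config.stance_duration_s
    total = T + 2 * FLANK_S
    trials = []
    planted_rows = []
    # stable ordering for determinism
    wide = wide.sort_values(["group", "subject_id", "time"],
                            ascending=[False, True, True]).reset_index(drop=True)
    for row in wide.itertuples(index=False):
        vals = {name: getattr(row, name) for name in config.effect_table}
        vals = _clamp_planted(vals, row.body_mass_kg, config)
        noise_rng = rng  # single stream keeps the cohort deterministic

        grf = synth_grf(T, row.body_mass_kg, vals["vertical_impact_peak"],
                        config.active_peak_bw, vals["valr"],
                        vals["peak_braking_force"], config.grf_rate)
        if config.swing_noise_sd_n > 0:
            swing = np.ones(grf.grf_v.size, bool)
            swing[grf.contact_index:grf.toe_off_index + 1] = False
            noise = noise_rng.normal(0.0, config.swing_noise_sd_n, swing.sum())
            grf.grf_v[swing] = np.clip(
                grf.grf_v[swing] + np.clip(noise, -25.0, 25.0),
                0.0, EVENT_THRESHOLD_N - 1.0)

        frontal = shacal_frontal_program(vals["shacal_inv_peak"],
                                         vals["shacal_eve_peak"])
        mla = mla_program(vals["mla_rom"])
        joints = default_joint_programs(noise_rng, config.trajectory_noise_sd_deg,
                                        shacal_frontal=frontal)
        planar = default_planar_programs(noise_rng, config.trajectory_noise_sd_deg,
                                         mla=mla)
        for eff in config.trajectory_effects:
            amp = eff.amplitudes.get((row.group, row.time), 0.0)
            if amp == 0.0:
                continue
            add = (lambda f, a=amp, e=eff: a * _bump(f, e.center_frac, e.halfwidth_frac))
            if eff.channel in joints:
                old = joints[eff.channel][eff.plane]
                joints[eff.channel][eff.plane] = \
                    (lambda f, o=old, g=add: o(f) + g(f))
            else:
                old = planar[eff.channel]
                planar[eff.channel] = (lambda f, o=old, g=add: o(f) + g(f))

        poses, markers = synth_segment_poses(
            joints, config.kin_rate, T, planar_programs=planar,
            contact_time_s=FLANK_S, total_duration_s=total,
            marker_noise_sd_mm=config.noise_sd_marker, rng=noise_rng,
            lab_offset=(noise_rng.uniform(-5, 5), 0.0, noise_rng.uniform(-5, 5)))

        trials.append(TrialRecording(
            subject_id=row.subject_id, group=row.group, time=row.time,
            body_mass=row.body_mass_kg, grf_rate=config.grf_rate,
            kin_rate=config.kin_rate, grf_v=grf.grf_v, grf_ap=grf.grf_ap,
            segment_poses=poses, markers=markers,
            true_events=(grf.contact_index, grf.toe_off_index), planted=vals))
        for name, val in vals.items():
            planted_rows.append((row.subject_id, row.group, row.time,
                                 row.body_mass_kg, name, val))

    planted = pd.DataFrame(planted_rows, columns=[
        "subject_id", "group", "time", "body_mass_kg", "outcome", "value"])
    return Cohort(trials, planted, config)


def null_config(**overrides) -> CohortConfig:
    """A cohort configuration with no group-by-time effects planted.

    All four cells of every outcome share the all-participants baseline mean;
    sds are kept at the study values.
    """
    base = default_effect_table()
    flat = {}
    for name, cell in base.items():
        m = cell.ig_pre  # any common value; use the IG baseline mean
        flat[name] = EffectCell(m, m, m, m, cell.sd)
    cfg = CohortConfig(effect_table=flat, **overrides)
    return cfg


# ---------------------------------------------------------------------------
# Plain-text serialization


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write metadata CSV, per-trial long CSVs, and a planted-truth JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    meta = pd.DataFrame(
        [(t.subject_id, t.group, t.time, t.body_mass) for t in cohort.trials],
        columns=["subject_id", "group", "time", "body_mass_kg"])
    meta.to_csv(out / "metadata.csv", index=False)
    cohort.planted.to_csv(out / "planted.csv", index=False,
                          float_format="%.17g")
    for t in cohort.trials:
        rows = []
        tg = np.arange(t.grf_v.size) / t.grf_rate
        for name, arr in (("grf_v", t.grf_v), ("grf_ap", t.grf_ap)):
            rows.append(pd.DataFrame({"time_s": tg, "channel": name, "value": arr}))
        nk = next(iter(t.segment_poses.values()))[0].shape[0]
        tk = np.arange(nk) / t.kin_rate
        for seg, (R, o) in t.segment_poses.items():
            for i in range(3):
                for j in range(3):
                    rows.append(pd.DataFrame({"time_s": tk,
                                              "channel": f"pose_{seg}_r{i}{j}",
                                              "value": R[:, i, j]}))
            for ax, nm in enumerate("xyz"):
                rows.append(pd.DataFrame({"time_s": tk,
                                          "channel": f"origin_{seg}_{nm}",
                                          "value": o[:, ax]}))
        for mname, arr in t.markers.items():
            for ax, nm in enumerate("xyz"):
                rows.append(pd.DataFrame({"time_s": tk,
                                          "channel": f"marker_{mname}_{nm}",
                                          "value": arr[:, ax]}))
        df = pd.concat(rows, ignore_index=True)
        df.to_csv(out / f"trial_{t.subject_id}_{t.time}.csv", index=False,
                  float_format="%.17g")


def read_cohort(indir) -> Cohort:
    """Reconstruct a cohort from :func:`write_cohort` output."""
    indir = Path(indir)
    meta = pd.read_csv(indir / "metadata.csv")
    planted = (pd.read_csv(indir / "planted.csv")
               if (indir / "planted.csv").exists() else pd.DataFrame())
    trials = []
    for row in meta.itertuples(index=False):
        df = pd.read_csv(indir / f"trial_{row.subject_id}_{row.time}.csv")
        piv = {ch: g.sort_values("time_s") for ch, g in df.groupby("channel")}
        tg = piv["grf_v"]["time_s"].to_numpy()
        grf_rate = round(1.0 / np.diff(tg).mean())
        some_pose = next(ch for ch in piv if ch.startswith("pose_"))
        tk = piv[some_pose]["time_s"].to_numpy()
        kin_rate = round(1.0 / np.diff(tk).mean())
        nk = tk.size
        poses = {}
        for seg in SEGMENTS:
            R = np.empty((nk, 3, 3))
            for i in range(3):
                for j in range(3):
                    R[:, i, j] = piv[f"pose_{seg}_r{i}{j}"]["value"].to_numpy()
            o = np.stack([piv[f"origin_{seg}_{nm}"]["value"].to_numpy()
                          for nm in "xyz"], axis=1)
            poses[seg] = (R, o)
        marker_names = sorted({ch[len("marker_"):-2] for ch in piv
                               if ch.startswith("marker_")})
        markers = {m: np.stack([piv[f"marker_{m}_{nm}"]["value"].to_numpy()
                                for nm in "xyz"], axis=1) for m in marker_names}
        trials.append(TrialRecording(
            subject_id=row.subject_id, group=row.group, time=row.time,
            body_mass=row.body_mass_kg, grf_rate=float(grf_rate),
            kin_rate=float(kin_rate),
            grf_v=piv["grf_v"]["value"].to_numpy(),
            grf_ap=piv["grf_ap"]["value"].to_numpy(),
            segment_poses=poses, markers=markers))
    cfg = CohortConfig(n_per_group=(max(2, (meta.group == "IG").sum() // 2),
                                    max(2, (meta.group == "CG").sum() // 2)))
    return Cohort(trials, planted, cfg)
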