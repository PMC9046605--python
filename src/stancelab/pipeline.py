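"""End-to-end orchestration: simulate -> preprocess -> kinematics -> outcomes
-> statistics, with plain-text artifacts and a provenance manifest.

Stages communicate through in-memory objects; every stage can also be run
from / written to CSV + JSON so the intermediate artifacts are independently
inspectable. Defaults reproduce the reference measurement settings: 10 Hz /
80 Hz zero-lag Butterworth cutoffs for kinematics / GRF, a 30 N event
threshold with 10 ms stance / 50 ms flight hysteresis, 101 stance nodes and
a 5% significance level.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError, DataError, StancelabError
from .footkin import JOINTS, PLANES, joint_angle_channels, planar_channels
from .mixedfx import summarize_outcomes
from .outcomes import OUTCOME_NAMES, extract_outcomes
from .preprocess import (EVENT_THRESHOLD_N, N_NODES, butterworth_zero_lag,
                         detect_stance, normalize_to_stance)
from .spmfield import sidak_alpha, spm_test, suprathreshold_clusters
from .synthgait import Cohort, CohortConfig, TIMES, generate_cohort

log = logging.getLogger("stancelab")

SCALAR_CHANNELS = ("F2G", "S2G", "V2G", "S2F", "S2V", "MLA")


@dataclass
class RunConfig:
    """Pipeline settings; the defaults are the reference analysis settings."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    filter_kin_hz: float | None = 10.0
    filter_grf_hz: float | None = 80.0
    event_threshold_n: float = EVENT_THRESHOLD_N
    detect_on_filtered: bool = True
    min_stance_s: float = 0.01
    min_flight_s: float = 0.05
    alpha: float = 0.05
    valr_method: str = "secant"       # or "regression"
    spm_method: str = "rft"           # or "permutation"
    n_perm: int = 1000
    make_plots: bool = False

    def validate(self):
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha: must lie in (0, 1)")
        if self.valr_method not in ("secant", "regression"):
            raise ConfigError("valr_method: must be 'secant' or 'regression'")
        if self.spm_method not in ("rft", "permutation"):
            raise ConfigError("spm_method: must be 'rft' or 'permutation'")
        for fld in ("min_stance_s", "min_flight_s", "n_perm"):
            if getattr(self, fld) < 0:
                raise ConfigError(f"{fld}: must be non-negative")
        return self


def config_from_yaml(path) -> RunConfig:
    import yaml

    from .synthgait import EffectCell
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    ccfg = raw.pop("cohort", {})
    table = ccfg.pop("effect_table", None)
    if table is not None:
        ccfg["effect_table"] = {
            name: EffectCell(*row[:4], tuple(row[4]) if isinstance(row[4], list)
                             else row[4])
            for name, row in table.items()}
    if "n_per_group" in ccfg and isinstance(ccfg["n_per_group"], list):
        ccfg["n_per_group"] = tuple(ccfg["n_per_group"])
    try:
        cohort = CohortConfig(**ccfg)
        cfg = RunConfig(cohort=cohort, **raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from None
    return cfg.validate()


# ---------------------------------------------------------------------------
# Trial processing


@dataclass
class ProcessedTrial:
    subject_id: str
    group: str
    time: str
    body_mass: float
    trajectories: dict    # channel -> (planes, values (n_planes, 101))
    outcomes: dict        # outcome name -> value (NaN allowed)
    warnings: list


def process_trial(trial, cfg: RunConfig) -> ProcessedTrial:
    """Filter, detect stance, normalize all channels, extract outcomes."""
    notes = []
    grf_v = trial.grf_v
    grf_ap = trial.grf_ap
    if cfg.filter_grf_hz:
        grf_v = butterworth_zero_lag(grf_v, trial.grf_rate, cfg.filter_grf_hz)
        grf_ap = butterworth_zero_lag(grf_ap, trial.grf_rate, cfg.filter_grf_hz)

    detect_series = grf_v if cfg.detect_on_filtered else trial.grf_v
    windows = detect_stance(detect_series, trial.grf_rate,
                            cfg.event_threshold_n, cfg.min_stance_s,
                            cfg.min_flight_s)
    if not windows:
        raise DataError(f"{trial.subject_id}/{trial.time}: no stance detected")
    window = max(windows, key=lambda w: w.duration_s)

    joints = joint_angle_channels(trial.segment_poses)
    planar = planar_channels(trial.markers) if trial.markers else {}

    def condition(series):
        if cfg.filter_kin_hz:
            series = butterworth_zero_lag(series, trial.kin_rate, cfg.filter_kin_hz)
        return normalize_to_stance(series, window, trial.kin_rate)

    traj = {}
    for joint, ang in joints.items():
        if np.any(ang.gimbal):
            notes.append(f"{joint}: gimbal proximity flagged")
        traj[joint] = (PLANES, np.stack([condition(ang.plane(p)) for p in PLANES]))
    for name, series in planar.items():
        traj[name] = (("scalar",), condition(series)[None, :])

    out = {k: np.nan for k in OUTCOME_NAMES}
    if planar:
        disc = extract_outcomes(
            traj["MLA"][1][0], traj["Sha-Cal"][1][PLANES.index("frontal")],
            grf_v, grf_ap, window, trial.body_mass, cfg.valr_method)
        out = disc.as_dict()
        if np.isnan(out["vertical_impact_peak"]):
            notes.append("impact transient absent; impact peak and VALR missing")
    return ProcessedTrial(trial.subject_id, trial.group, trial.time,
                          trial.body_mass, traj, out, notes)


def process_cohort(cohort: Cohort, cfg: RunConfig):
    """Process every trial; failures are logged and skipped with counts."""
    processed, failed = [], 0
    for trial in cohort.trials:
        try:
            processed.append(process_trial(trial, cfg))
        except StancelabError as exc:
            failed += 1
            log.warning("trial %s/%s skipped: %s", trial.subject_id, trial.time, exc)
    if failed:
        log.warning("%d/%d trials skipped", failed, len(cohort.trials))
    if not processed:
        raise DataError("no trial could be processed")
    return processed


def outcomes_table(processed) -> pd.DataFrame:
    rows = []
    for p in processed:
        for name, val in p.outcomes.items():
            rows.append((p.subject_id, p.group, p.time, p.body_mass, name, val))
    return pd.DataFrame(rows, columns=["subject_id", "group", "time",
                                       "body_mass_kg", "outcome", "value"])


def trajectory_matrices(processed, channel: str) -> dict:
    """Stack one channel into {(group, time): matrix} with aligned rows.

    Scalar channels give (n, 101); joint channels (n, 101, 3). Row order is
    sorted subject id within each cell, so paired comparisons line up.
    """
    cells = {}
    for p in sorted(processed, key=lambda q: q.subject_id):
        planes, values = p.trajectories[channel]
        arr = values[0] if planes == ("scalar",) else values.T  # (101, 3)
        cells.setdefault((p.group, p.time), []).append(arr)
    return {k: np.stack(v) for k, v in cells.items()}


# ---------------------------------------------------------------------------
# SPM stage


def spm_analysis(processed, cfg: RunConfig) -> dict:
    """Whole-stance comparisons per channel, mirroring the black-bar figures.

    Scalar channels: two-way (group x time) field ANOVA followed by post-hoc
    between-group t fields at each time. Vector (joint) channels: independent
    Hotelling's T^2 between groups at each time, plus paired T^2 within each
    group across time, with component-wise post-hoc t fields at the
    Sidak-adjusted level (k = 3 components).
    """
    from .spmfield import f_fields_twoway, rft_threshold, estimate_fwhm

    results = {}
    for channel in SCALAR_CHANNELS:
        cells = trajectory_matrices(processed, channel)
        entry = {"kind": "scalar"}
        anova = f_fields_twoway(cells)
        resid = np.vstack([m - m.mean(axis=0) for m in cells.values()])
        fwhm = estimate_fwhm(resid)
        entry["anova"] = {}
        for effect, (F, dof) in anova.items():
            crit = rft_threshold("F", dof, N_NODES, fwhm, cfg.alpha, False)
            cl = suprathreshold_clusters(F, crit, fwhm, "F", dof)
            entry["anova"][effect] = _spm_dict(F, dof, fwhm, crit, cl, cfg.alpha)
        entry["posthoc"] = {}
        for time in TIMES:
            res = spm_test(cells[("IG", time)], cells[("CG", time)], "t",
                           alpha=cfg.alpha)
            entry["posthoc"][f"IG_vs_CG_{time}"] = _spm_dict(
                res.field, res.dof, res.fwhm, res.critical_threshold,
                res.clusters, res.alpha)
        results[channel] = entry

    k_components = 3
    a_sidak = sidak_alpha(cfg.alpha, k_components)
    for joint in JOINTS:
        cells = trajectory_matrices(processed, joint)
        entry = {"kind": "vector", "sidak_alpha": a_sidak}
        for time in TIMES:
            res = spm_test(cells[("IG", time)], cells[("CG", time)], "T2",
                           alpha=cfg.alpha)
            entry[f"T2_IG_vs_CG_{time}"] = _spm_dict(
                res.field, res.dof, res.fwhm, res.critical_threshold,
                res.clusters, res.alpha)
        for group in ("IG", "CG"):
            try:
                res = spm_test(cells[(group, "week8")], cells[(group, "baseline")],
                               "T2", paired=True, alpha=cfg.alpha)
                entry[f"T2_{group}_week8_vs_baseline"] = _spm_dict(
                    res.field, res.dof, res.fwhm, res.critical_threshold,
                    res.clusters, res.alpha)
            except StancelabError as exc:
                log.warning("%s paired T2 skipped: %s", joint, exc)
        entry["posthoc"] = {}
        for time in TIMES:
            for ci, plane in enumerate(PLANES):
                res = spm_test(cells[("IG", time)][:, :, ci],
                               cells[("CG", time)][:, :, ci], "t",
                               alpha=a_sidak)
                entry["posthoc"][f"{plane}_IG_vs_CG_{time}"] = _spm_dict(
                    res.field, res.dof, res.fwhm, res.critical_threshold,
                    res.clusters, res.alpha)
        results[joint] = entry
    return results


def _spm_dict(field_vals, dof, fwhm, crit, clusters, alpha) -> dict:
    return {
        "field": np.asarray(field_vals).round(6).tolist(),
        "dof": list(dof),
        "fwhm": round(float(fwhm), 4),
        "critical_threshold": round(float(crit), 4),
        "alpha": alpha,
        "clusters": [{"start_pct": c.start_node, "end_pct": c.end_node,
                      "p": None if np.isnan(c.p) else round(c.p, 5)}
                     for c in clusters],
    }


# ---------------------------------------------------------------------------
# Report bundle


def run_pipeline(cfg: RunConfig, outdir=None) -> dict:
    """Simulate (or accept) a cohort, process it, and run both analyses.

    Returns the report bundle: outcomes table, the discrete-results table
    (cell means/sds, interaction p, Cohen's d per outcome), per-channel SPM
    JSON-ready dicts, and a provenance manifest. Writes plain-text artifacts
    to ``outdir`` when given.
    """
    cfg.validate()
    cohort = generate_cohort(cfg.cohort)
    return analyze_cohort(cohort, cfg, outdir)


def analyze_cohort(cohort: Cohort, cfg: RunConfig, outdir=None) -> dict:
    processed = process_cohort(cohort, cfg)
    table = outcomes_table(processed)
    model_table = summarize_outcomes(table)
    spm = spm_analysis(processed, cfg)
    bundle = {
        "outcomes": table,
        "model_table": model_table,
        "spm": spm,
        "manifest": _manifest(cfg),
        "processed": processed,
    }
    if outdir is not None:
        write_report(bundle, outdir, cfg)
    return bundle


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    table = d["cohort"].get("effect_table", {})
    d["cohort"]["effect_table"] = {
        k: list(v) if isinstance(v, tuple) else v for k, v in table.items()}
    return json.loads(json.dumps(d, default=lambda o: list(o) if
                                 isinstance(o, (tuple, np.ndarray)) else str(o)))


def _manifest(cfg: RunConfig) -> dict:
    import scipy
    cfg_json = json.dumps(_config_dict(cfg), sort_keys=True)
    return {
        "config": _config_dict(cfg),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": cfg.cohort.seed,
        "versions": {"stancelab": __version__, "numpy": np.__version__,
                     "scipy": scipy.__version__, "pandas": pd.__version__},
    }


def write_report(bundle: dict, outdir, cfg: RunConfig) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["outcomes"].to_csv(out / "outcomes.csv", index=False,
                              float_format="%.10g")
    bundle["model_table"].to_csv(out / "discrete_results.csv", index=False,
                                 float_format="%.10g")
    with open(out / "spm_results.json", "w") as fh:
        json.dump(bundle["spm"], fh, indent=1, sort_keys=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle["manifest"], fh, indent=1, sort_keys=True)
    if cfg.make_plots:
        plot_trajectories(bundle, out / "figures")


def plot_trajectories(bundle: dict, figdir) -> None:
    """Mean +- SD trajectory plots with black significance bars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = Path(figdir)
    figdir.mkdir(parents=True, exist_ok=True)
    processed = bundle["processed"]
    x = np.arange(N_NODES)
    for channel, entry in bundle["spm"].items():
        cells = trajectory_matrices(processed, channel)
        n_planes = 1 if entry["kind"] == "scalar" else 3
        fig, axes = plt.subplots(n_planes, 2, figsize=(9, 2.8 * n_planes),
                                 squeeze=False, sharex=True)
        for col, time in enumerate(TIMES):
            for pi in range(n_planes):
                ax = axes[pi][col]
                for group, color in (("CG", "tab:green"), ("IG", "tab:blue")):
                    m = cells[(group, time)]
                    y = m if m.ndim == 2 else m[:, :, pi]
                    mu, sd = y.mean(axis=0), y.std(axis=0, ddof=1)
                    ax.plot(x, mu, color=color, label=group)
                    ax.fill_between(x, mu - sd, mu + sd, color=color, alpha=0.2)
                key = (f"IG_vs_CG_{time}" if entry["kind"] == "scalar"
                       else f"{PLANES[pi]}_IG_vs_CG_{time}")
                ph = entry["posthoc"].get(key)
                if ph:
                    y0 = ax.get_ylim()[0]
                    for cl in ph["clusters"]:
                        ax.plot([cl["start_pct"], cl["end_pct"]], [y0, y0],
                                color="black", lw=4, solid_capstyle="butt")
                if pi == 0:
                    ax.set_title(f"{channel} — {time}")
                if pi == n_planes - 1:
                    ax.set_xlabel("stance (%)")
        axes[0][0].legend(frameon=False, fontsize=8)
        fig.tight_layout()
        fig.savefig(figdir / f"{channel.replace('-', '_')}.png", dpi=110)
        plt.close(fig)
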