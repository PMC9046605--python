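# stancelab

Analysis pipeline for stance-phase running biomechanics in pre/post two-arm
trials: from raw ground-reaction-force (GRF) and multi-segment foot
kinematic recordings to discrete injury-risk parameters, mixed-model
group×time inference, and one-dimensional statistical parametric mapping
(1D-SPM) over the whole stance phase. It is written for movement-science
researchers who want the full chain — event detection, zero-lag filtering,
Joint Coordinate System (JCS) angles, arch/metatarsal planar angles,
loading-rate metrics, random-field-theory (RFT) thresholds — as tested,
reusable code, together with a synthetic-cohort generator that plants known
effects so every stage can be verified against ground truth.

## What it computes

**Per trial** (stance delimited by 30 N crossings of vertical GRF, signals
zero-lag Butterworth filtered at 10 Hz / 80 Hz, all channels resampled to
101 stance nodes):

* five JCS joint-rotation series (Sha-Cal, Cal-Mid, Mid-Met, Cal-Met,
  Met-Hal; sagittal about proximal z, frontal about the floating axis,
  transverse about distal y),
* planar angles: metatarsal inclinations F2G/S2G/V2G, transverse
  divergences S2F/S2V, and the medial longitudinal arch (MLA) angle,
* six discrete risk factors: MLA range of motion (max − min, deg), Sha-Cal
  inversion/eversion peaks (deg), vertical impact peak (BW), vertical
  average loading rate (VALR: secant slope between 20% and 80% of the
  contact-to-first-peak interval, BW·s⁻¹), and peak braking force (BW).

**Per cohort**:

* a linear mixed model per outcome, y = β₀ + β_g·IG + β_t·post +
  β_gt·IG·post + u_subject + ε, REML; the group×time interaction β_gt (the
  difference-in-differences) is the primary comparison, with
  Bonferroni-adjusted estimated marginal means and Cohen's d
  (d = |m₁−m₂| / s_pooled; <0.2 negligible, 0.2–0.5 small, 0.5–0.8 medium,
  ≥0.8 large),
* 1D-SPM: node-wise t, F and Hotelling's T² fields with RFT critical
  thresholds u\* solving P(max > u\*) ≈ P₀(u\*) + (100/FWHM)·ρ₁(u\*) = α,
  suprathreshold clusters reported as stance-percent intervals (the
  "black-bar" figures), Šidák-corrected component post-hocs, and a
  max-statistic permutation oracle.

## Worked example

```python
from stancelab.synthgait import CohortConfig, generate_cohort
from stancelab.pipeline import RunConfig, analyze_cohort

cfg = CohortConfig(seed=1)              # 41 + 46 subjects, default effect table
bundle = analyze_cohort(generate_cohort(cfg), RunConfig(cohort=cfg))
print(bundle["model_table"][["outcome", "ig_pre_mean", "ig_post_mean",
                             "cg_pre_mean", "cg_post_mean",
                             "interaction_p", "cohens_d"]].round(3))
```

```
             outcome  ig_pre_mean  ig_post_mean  cg_pre_mean  cg_post_mean  interaction_p  cohens_d
             mla_rom        5.944         2.529        5.196         3.746          0.118     0.341
     shacal_inv_peak       -0.968        -5.598       -1.260        -1.629          0.009     0.769
     shacal_eve_peak        6.098         5.132        7.108         6.169          0.969     0.419
vertical_impact_peak        0.942         0.991        1.186         1.137          0.413     0.285
                valr       63.908        63.553       59.793        58.439          0.914     0.168
  peak_braking_force       -0.230        -0.246       -0.238        -0.243          0.412     0.040
```

The default effect table plants a training effect on rearfoot kinematics
and none on the kinetic outcomes; in this seed the inversion-peak
interaction is detected (p = 0.009, the intervention arm lands ~4.6° more
inverted after training) while impact peak, VALR and braking force stay
null — the configured pattern. The SPM stage localizes the same effect in
time: the Sha-Cal frontal post-hoc t field exceeds its threshold
(t\* = 3.04) over 0–18% and 43–100% of stance:

```python
bundle["spm"]["Sha-Cal"]["posthoc"]["frontal_IG_vs_CG_week8"]["clusters"]
# [{'start_pct': 0, 'end_pct': 18, 'p': 0.00798},
#  {'start_pct': 43, 'end_pct': 100, 'p': 9e-05}]
```

A command-line interface mirrors the stages (`stancelab simulate / process
/ analyze / report / all`), exchanging plain CSV/JSON artifacts, with
optional mean±SD trajectory figures with black significance bars.

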