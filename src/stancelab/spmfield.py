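"""One-dimensional statistical parametric mapping over 101 stance nodes.

Node-wise t, F and Hotelling's T^2 statistic fields are thresholded with
random-field-theory (RFT) critical values that control the family-wise error
of the whole smooth field. The probability that the field maximum exceeds u
is approximated by the expected Euler characteristic of the excursion set,

    P(max > u)  ~=  P0(u) + R * rho1(u),

where P0 is the pointwise tail probability, R = (Q-1)/FWHM is the resel
count of a field of Q nodes with smoothness FWHM, and rho1 is the 1D EC
density of the field type (Worsley-family results):

    t:  rho1(u) = sqrt(4 ln2)/(2 pi) (1 + u^2/nu)^(-(nu-1)/2)
    F:  rho1(u) = sqrt(4 ln2) sqrt(2)/sqrt(2 pi)
                  * Gamma((nu+k-1)/2)/(Gamma(nu/2) Gamma(k/2))
                  * (k u/nu)^((k-1)/2) (1 + k u/nu)^(-(nu+k-2)/2)

T^2 fields with p components are thresholded through their monotone F
transform F = (nu-p+1)/(nu p) T^2 ~ F(p, nu-p+1). t tests are two-sided by
default (the threshold applies to |t|). Smoothness is estimated from the
gradient of variance-normalized residual fields. A permutation oracle
(max-statistic label permutation / sign flipping) provides a nonparametric
alternative and validates the RFT thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb, gamma as _gamma_fn

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import brentq
from scipy.special import gammaln

from .errors import DataError, ParameterError, SampleSizeError

SQRT4LN2 = np.sqrt(4.0 * np.log(2.0))


@dataclass
class Cluster:
    start_node: int
    end_node: int
    p: float


@dataclass
class SPMResult:
    statistic_name: str       # "t", "F", "T2"
    field: np.ndarray
    dof: tuple
    fwhm: float
    critical_threshold: float
    clusters: list
    alpha: float
    two_sided: bool


# ---------------------------------------------------------------------------
# Statistic fields


def _check_matrix(m, min_rows=3):
    m = np.asarray(m, float)
    if m.ndim < 2:
        raise DataError("trajectory matrix must be (subjects, nodes[, components])")
    if m.shape[0] < min_rows:
        raise SampleSizeError(f"need at least {min_rows} rows, got {m.shape[0]}")
    if not np.isfinite(m).all():
        raise DataError("non-finite values in trajectory matrix")
    return m


def t_field(matrix_a, matrix_b=None, paired: bool = False):
    """Node-wise t statistic field and its degrees of freedom.

    Two-sample (pooled variance) by default; ``paired=True`` computes the
    paired t on row-matched matrices. A single matrix gives the one-sample t.
    """
    a = _check_matrix(matrix_a)
    if matrix_b is None:
        d = a
    elif paired:
        b = _check_matrix(matrix_b)
        if a.shape != b.shape:
            raise DataError("paired matrices must have identical shapes")
        d = a - b
    else:
        b = _check_matrix(matrix_b)
        n1, n2 = a.shape[0], b.shape[0]
        v1 = a.var(axis=0, ddof=1)
        v2 = b.var(axis=0, ddof=1)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        return (a.mean(axis=0) - b.mean(axis=0)) / se, (n1 + n2 - 2,)
    n = d.shape[0]
    se = d.std(axis=0, ddof=1) / np.sqrt(n)
    return d.mean(axis=0) / se, (n - 1,)


def f_field(matrices):
    """Node-wise one-way ANOVA F field over >= 2 groups of trajectories."""
    groups = [_check_matrix(m, min_rows=2) for m in matrices]
    if len(groups) < 2:
        raise DataError("need at least two groups")
    k = len(groups)
    N = sum(g.shape[0] for g in groups)
    grand = np.vstack(groups).mean(axis=0)
    ss_between = sum(g.shape[0] * (g.mean(axis=0) - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean(axis=0)) ** 2).sum(axis=0) for g in groups)
    dof = (k - 1, N - k)
    return (ss_between / dof[0]) / (ss_within / dof[1]), dof


def f_fields_twoway(cells: dict):
    """Two-way (group x time) ANOVA F fields from the four cell matrices.

    ``cells`` maps (group_level, time_level) -> (n_i, Q) matrix; rows are
    treated as independent. Returns {"group": (field, dof), "time": ...,
    "interaction": ...} via node-wise OLS model comparisons (type-III sums of
    squares with effect coding, valid for unbalanced cells).
    """
    keys = sorted(cells.keys())
    a_levels = sorted({k[0] for k in keys})
    b_levels = sorted({k[1] for k in keys})
    if len(a_levels) != 2 or len(b_levels) != 2:
        raise DataError("two-way field ANOVA expects a 2x2 design")
    Y, A, B = [], [], []
    for (ga, tb) in keys:
        m = _check_matrix(cells[(ga, tb)], min_rows=2)
        Y.append(m)
        A.extend([1.0 if ga == a_levels[1] else -1.0] * m.shape[0])
        B.extend([1.0 if tb == b_levels[1] else -1.0] * m.shape[0])
    Y = np.vstack(Y)
    A = np.asarray(A)
    B = np.asarray(B)
    ones = np.ones_like(A)
    full = np.column_stack([ones, A, B, A * B])

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        r = Y - X @ beta
        return (r ** 2).sum(axis=0)

    rss_full = rss(full)
    dfe = Y.shape[0] - 4
    out = {}
    for name, drop in (("group", 1), ("time", 2), ("interaction", 3)):
        Xr = np.delete(full, drop, axis=1)
        F = (rss(Xr) - rss_full) / (rss_full / dfe)
        out[name] = (F, (1, dfe))
    return out


def hotelling_t2_field(matrix_a, matrix_b=None, paired: bool = False,
                       ridge: float = 1e-10):
    """Node-wise Hotelling's T^2 field for vector trajectories.

    Matrices have shape (subjects, nodes, components), components in {1,2,3}.
    Independent two-sample form: T^2 = n1 n2/(n1+n2) d' W^-1 d with W the
    pooled within-group covariance at the node; paired form: T^2 = n dbar'
    S^-1 dbar on the row differences. Singular node covariances are
    ridge-stabilized with a warning.
    """
    a = _check_matrix(matrix_a)
    if a.ndim == 2:
        a = a[..., None]
    p = a.shape[2]
    if p not in (1, 2, 3):
        raise DataError("component count must be 1, 2 or 3")

    if matrix_b is not None and not paired:
        b = _check_matrix(matrix_b)
        if b.ndim == 2:
            b = b[..., None]
        n1, n2 = a.shape[0], b.shape[0]
        da = a - a.mean(axis=0)
        db = b - b.mean(axis=0)
        W = (np.einsum("nqi,nqj->qij", da, da)
             + np.einsum("nqi,nqj->qij", db, db)) / (n1 + n2 - 2)
        diff = a.mean(axis=0) - b.mean(axis=0)      # (Q, p)
        scale = n1 * n2 / (n1 + n2)
        nu = n1 + n2 - 2
    else:
        if matrix_b is not None:
            b = _check_matrix(matrix_b)
            if b.ndim == 2:
                b = b[..., None]
            if a.shape != b.shape:
                raise DataError("paired matrices must have identical shapes")
            d = a - b
        else:
            d = a
        n = d.shape[0]
        dd = d - d.mean(axis=0)
        W = np.einsum("nqi,nqj->qij", dd, dd) / (n - 1)
        diff = d.mean(axis=0)
        scale = float(n)
        nu = n - 1

    det = np.linalg.det(W)
    tr = np.trace(W, axis1=1, axis2=2)
    bad = det < ridge * np.maximum(tr, 1.0) ** p
    if bad.any():
        warnings.warn(f"singular node covariance at {bad.sum()} node(s); "
                      "ridge-stabilized", stacklevel=2)
        W = W + (ridge * np.maximum(tr, 1.0) / p)[:, None, None] * np.eye(p)
    sol = np.linalg.solve(W, diff[..., None])[..., 0]
    t2 = scale * np.einsum("qi,qi->q", diff, sol)
    return t2, (p, nu)


# ---------------------------------------------------------------------------
# Smoothness and RFT thresholds


def estimate_fwhm(residual_matrix, eps: float = 1e-12) -> float:
    """Field smoothness (FWHM, in nodes) from variance-normalized residuals.

    FWHM = sqrt(4 ln2) / RMS gradient of the unit-variance residual field;
    implemented per node and averaged in resels-per-node, the standard 1D
    estimator. Zero-variance nodes are excluded with a warning.
    """
    R = np.asarray(residual_matrix, float)
    if R.ndim != 2 or R.shape[0] < 2 or R.shape[1] < 3:
        raise DataError("need >= 2 residual rows and >= 3 nodes")
    ssq = (R ** 2).sum(axis=0)
    good = ssq > eps
    if not good.all():
        warnings.warn(f"{(~good).sum()} zero-variance node(s) excluded from "
                      "smoothness estimation", stacklevel=2)
    if good.sum() < 3:
        raise DataError("too few non-degenerate nodes for smoothness estimation")
    g = np.gradient(R, axis=1)
    v = (g ** 2).sum(axis=0)[good] / ssq[good]
    resels_per_node = np.sqrt(v / (4.0 * np.log(2.0)))
    return float(1.0 / resels_per_node.mean())


def _ec1_t(u, nu):
    return SQRT4LN2 / (2.0 * np.pi) * (1.0 + u ** 2 / nu) ** (-(nu - 1) / 2.0)


def _ec1_f(u, k, nu):
    lnc = gammaln((nu + k - 1) / 2.0) - gammaln(nu / 2.0) - gammaln(k / 2.0)
    return (SQRT4LN2 * np.sqrt(2.0) / np.sqrt(2.0 * np.pi) * np.exp(lnc)
            * (k * u / nu) ** ((k - 1) / 2.0)
            * (1.0 + k * u / nu) ** (-(nu + k - 2) / 2.0))


def _max_exceedance_prob(u, statistic_name, dof, resels, two_sided):
    if statistic_name == "t":
        (nu,) = dof
        p = stats.t.sf(u, nu) + resels * _ec1_t(u, nu)
        return 2.0 * p if two_sided else p
    if statistic_name == "F":
        k, nu = dof
        return stats.f.sf(u, k, nu) + resels * _ec1_f(u, k, nu)
    raise ParameterError(f"unknown statistic '{statistic_name}'")


def rft_threshold(statistic_name, dof, n_nodes, fwhm, alpha: float = 0.05,
                  two_sided: bool = True) -> float:
    """RFT critical value u* with P(max field > u*) = alpha.

    ``dof``: (nu,) for t, (k, nu) for F, (p, nu) for T^2 (nu the error df;
    the T^2 threshold is solved on the F transform and mapped back). For t
    fields the threshold applies to |t| when ``two_sided`` (the default).
    Solved by bracketed root finding to 1e-6.
    """
    if not 0.0 < alpha <= 0.5:
        raise ParameterError("alpha must lie in (0, 0.5]")
    if fwhm <= 0:
        raise ParameterError("fwhm must be positive")
    if statistic_name == "T2":
        p, nu = dof
        if nu - p + 1 <= 0:
            raise ParameterError("error dof too small for the component count")
        fstar = rft_threshold("F", (p, nu - p + 1), n_nodes, fwhm, alpha,
                              two_sided=False)
        return float(fstar * nu * p / (nu - p + 1))
    resels = (n_nodes - 1) / fwhm

    def f(u):
        return _max_exceedance_prob(u, statistic_name, dof, resels, two_sided) - alpha

    lo, hi = 1e-6, 10.0
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e6:
            raise ParameterError("threshold search failed to bracket")
    u = float(brentq(f, lo, hi, xtol=1e-6))
    # the field is only observed at the nodes, so the Bonferroni quantile
    # over nodes is a valid cap (binding only for very rough fields, where
    # the continuous EC approximation over-counts)
    a_bonf = alpha / n_nodes
    if statistic_name == "t":
        u_bonf = stats.t.ppf(1.0 - (a_bonf / 2.0 if two_sided else a_bonf), dof[0])
    else:
        u_bonf = stats.f.ppf(1.0 - a_bonf, *dof)
    return min(u, float(u_bonf))


def suprathreshold_clusters(field, critical, fwhm=None, statistic_name=None,
                            dof=None, two_sided: bool = False):
    """Maximal runs of consecutive nodes exceeding the critical value.

    Returns a list of :class:`Cluster` with start/end node indices (a
    101-node field maps directly onto stance percent). When the field type,
    dof and smoothness are supplied, each cluster gets an RFT cluster-extent
    p-value (secondary inference); otherwise ``p`` is NaN.
    """
    x = np.asarray(field, float)
    if not np.isfinite(x).all():
        raise DataError("non-finite field values")
    exceed = (np.abs(x) if two_sided else x) > critical
    if not exceed.any():
        return []
    d = np.diff(exceed.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1))
    if exceed[0]:
        starts.insert(0, 0)
    if exceed[-1]:
        ends.append(x.size - 1)
    clusters = []
    for s, e in zip(starts, ends):
        p = np.nan
        if fwhm is not None and statistic_name is not None and dof is not None:
            p = _cluster_p(e - s + 1, critical, x.size, fwhm, statistic_name,
                           dof, two_sided)
        clusters.append(Cluster(int(s), int(e), float(p)))
    return clusters


def _cluster_p(extent_nodes, u, n_nodes, fwhm, statistic_name, dof, two_sided):
    """RFT cluster-extent p: P(>= 1 cluster of this size at threshold u)."""
    resels = (n_nodes - 1) / fwhm
    if statistic_name == "T2":
        p_comp, nu = dof
        u = u * (nu - p_comp + 1) / (nu * p_comp)
        statistic_name, dof = "F", (p_comp, nu - p_comp + 1)
    mult = 2.0 if (statistic_name == "t" and two_sided) else 1.0
    if statistic_name == "t":
        rho1 = _ec1_t(u, dof[0])
        p0 = stats.t.sf(u, dof[0])
    else:
        rho1 = _ec1_f(u, *dof)
        p0 = stats.f.sf(u, *dof)
    Em = mult * resels * rho1
    if Em <= 0:
        return 1.0
    En = p0 * resels / (resels * rho1)   # expected cluster extent, resels
    k = extent_nodes / fwhm
    beta = (_gamma_fn(1.5) / En) ** 2
    p_ext = np.exp(-beta * k * k)
    return float(1.0 - np.exp(-Em * p_ext))


def sidak_alpha(alpha: float, k: int) -> float:
    """Per-comparison level 1 - (1-alpha)^(1/k) for k post-hoc tests."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    return 1.0 - (1.0 - alpha) ** (1.0 / k)


# ---------------------------------------------------------------------------
# Permutation oracle


def _max_stat(stat, a, b):
    if stat == "t":
        f, _ = t_field(a, b)
        return np.abs(f).max()
    if stat == "t_paired":
        f, _ = t_field(a, b, paired=True)
        return np.abs(f).max()
    if stat == "T2":
        f, _ = hotelling_t2_field(a, b)
        return f.max()
    if stat == "T2_paired":
        f, _ = hotelling_t2_field(a, b, paired=True)
        return f.max()
    raise ParameterError(f"unknown statistic '{stat}'")


def permutation_threshold(matrices, statistic_name: str, n_perm: int = 1000,
                          seed: int = 0, alpha: float = 0.05) -> float:
    """Nonparametric critical value from the max-statistic null distribution.

    Independent designs permute group labels; paired designs flip the signs
    of row differences. ``matrices`` is (a, b). Deterministic under ``seed``.
    Raises when fewer than 1/alpha distinct relabellings exist.
    """
    if n_perm < 100:
        raise ParameterError("n_perm must be >= 100")
    a, b = (np.asarray(m, float) for m in matrices)
    rng = np.random.default_rng(seed)
    paired = statistic_name.endswith("_paired")
    base = statistic_name.replace("_paired", "")
    if paired:
        if a.shape != b.shape:
            raise DataError("paired matrices must match in shape")
        n = a.shape[0]
        if 2 ** min(n, 60) < 1.0 / alpha:
            raise ParameterError("too few distinct sign flips for this alpha")
        d = a - b
        maxs = np.empty(n_perm)
        for i in range(n_perm):
            signs = rng.choice([-1.0, 1.0], size=n)
            flipped = d * signs.reshape((-1,) + (1,) * (d.ndim - 1))
            maxs[i] = _max_stat(f"{base}_paired", flipped + b, b)
    else:
        n1 = a.shape[0]
        pool = np.concatenate([a, b], axis=0)
        n = pool.shape[0]
        if comb(n, n1) < 1.0 / alpha:
            raise ParameterError("too few distinct label permutations for this alpha")
        maxs = np.empty(n_perm)
        for i in range(n_perm):
            idx = rng.permutation(n)
            maxs[i] = _max_stat(base, pool[idx[:n1]], pool[idx[n1:]])
    return float(np.quantile(maxs, 1.0 - alpha))


# ---------------------------------------------------------------------------
# Smooth Gaussian null fields (simulation utility)


def smooth_gaussian_fields(rng, n_fields: int, n_nodes: int, fwhm: float):
    """Unit-variance smooth Gaussian fields with the given FWHM (nodes).

    White noise convolved with a Gaussian kernel whose FWHM equals the target
    field smoothness (the standard construction); padding removes edge
    attenuation and the output is rescaled to unit pointwise variance.
    """
    sigma = fwhm / np.sqrt(8.0 * np.log(2.0))
    pad = int(np.ceil(4.0 * sigma)) + 1
    w = rng.standard_normal((n_fields, n_nodes + 2 * pad))
    s = gaussian_filter1d(w, sigma, axis=-1, mode="constant")[:, pad:pad + n_nodes]
    delta = np.zeros(2 * pad + 1)
    delta[pad] = 1.0
    kernel = gaussian_filter1d(delta, sigma, mode="constant")
    return s / np.sqrt((kernel ** 2).sum())


# ---------------------------------------------------------------------------
# High-level test wrapper


def spm_test(matrix_a, matrix_b=None, statistic_name: str = "t",
             paired: bool = False, alpha: float = 0.05,
             two_sided: bool = True) -> SPMResult:
    """Field statistic + smoothness + RFT threshold + clusters in one call."""
    if statistic_name == "t":
        field, dof = t_field(matrix_a, matrix_b, paired=paired)
    elif statistic_name == "T2":
        field, dof = hotelling_t2_field(matrix_a, matrix_b, paired=paired)
        two_sided = False
    elif statistic_name == "F":
        field, dof = f_field(matrix_a)
        two_sided = False
    else:
        raise ParameterError(f"unknown statistic '{statistic_name}'")
    residuals = _residuals(matrix_a, matrix_b, paired, statistic_name)
    fwhm = estimate_fwhm(residuals)
    n_nodes = np.asarray(field).shape[-1]
    crit = rft_threshold(statistic_name, dof, n_nodes, fwhm, alpha, two_sided)
    clusters = suprathreshold_clusters(field, crit, fwhm, statistic_name, dof,
                                       two_sided=two_sided)
    return SPMResult(statistic_name, np.asarray(field), dof, fwhm, crit,
                     clusters, alpha, two_sided)


def _residuals(matrix_a, matrix_b, paired, statistic_name):
    """Mean-centered residual rows; vector components stacked as extra rows."""
    def center(m):
        m = np.asarray(m, float)
        return m - m.mean(axis=0)

    if statistic_name == "F":
        parts = [center(m) for m in matrix_a]
    elif paired and matrix_b is not None:
        parts = [center(np.asarray(matrix_a, float) - np.asarray(matrix_b, float))]
    elif matrix_b is None:
        parts = [center(matrix_a)]
    else:
        parts = [center(matrix_a), center(matrix_b)]
    rows = []
    for p in parts:
        if p.ndim == 3:
            rows.extend(p[:, :, c] for c in range(p.shape[2]))
        else:
            rows.append(p)
    return np.vstack(rows)
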