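"""Covariate statistics along tract trajectories.

The group model at every tract voxel is

    TSA = b0 + b1 * Age + b2 * Sex + b3 * Age x Sex + e

with sex coded 1 = male / 2 = female, uncentred, and the interaction the
literal product. Coefficient t-statistics are summarised per flood-fill
distance stratum by weighting each voxel's t with the tract probability,
``t'(j) = t(j) * P_tract(j)**lambda``, and taking the (unweighted) t of the
voxel with extremal t' — the maximum for the positive tail and the minimum
for the negative tail, so both signs of effect can surface.

The resulting per-distance t-series is treated as a stationary 1D random
field. Residual smoothness is estimated as an FWHM in stratum units, the
critical height t* solves the expected-Euler-characteristic survival
approximation at the chosen level, supra-threshold runs shorter than the
minimum extent are discarded, surviving runs get an expected-extent
(exponential) cluster p-value, and cluster p-values across all tracts are
corrected with the two-stage non-negative (BKY) FDR step-up. Significant
t-values are finally summed per tract, separately by sign, as a compact
effect-extent summary.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import optimize
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import CohortTable, ScalarVolume, VoxelGrid, _check_same_grid
from .tract import DistanceMap

__all__ = [
    "ContrastMaps",
    "DistanceProfile",
    "Cluster",
    "ClusterResult",
    "CONTRASTS",
    "voxelwise_glm",
    "weighted_distance_summary",
    "stratum_residual_field",
    "estimate_residual_fwhm",
    "rft_critical_t",
    "cluster_inference",
    "fdr_across_tracts",
    "signed_sums",
    "analyse_tract",
    "combine_tracts",
]

CONTRASTS = ("age", "sex", "age_sex")
DEFAULT_LAMBDA = 1.0
DEFAULT_ALPHA_LEVEL = 0.05
DEFAULT_MIN_EXTENT = 3
DEFAULT_FDR_Q = 0.05


class DesignError(ValueError):
    """The covariate design matrix is rank deficient."""


@dataclasses.dataclass
class ContrastMaps:
    """Voxel-wise GLM output: t-maps per contrast, residuals for smoothness."""

    grid: VoxelGrid
    mask: np.ndarray  # voxels fitted in every participant
    t: dict  # contrast -> (X, Y, Z) t map (nan outside mask)
    nu: int  # residual degrees of freedom, n - 4
    residuals: np.ndarray  # (n_participants, n_mask_voxels)
    mask_index: np.ndarray  # (n_mask_voxels, 3) voxel indices, C-order


@dataclasses.dataclass
class DistanceProfile:
    """Per-distance summarised t-series for one tract and contrast."""

    tract_id: str
    contrast: str
    distances: np.ndarray  # (Q,) stratum labels, increasing
    t_pos: np.ndarray  # (Q,) positive-tail summary
    t_neg: np.ndarray  # (Q,) negative-tail summary

    @property
    def field_length(self) -> int:
        return len(self.distances)


@dataclasses.dataclass
class Cluster:
    start: int  # first stratum label in the run
    end: int  # last stratum label (inclusive)
    extent: int
    peak_t: float
    p_value: float
    adjusted_p: float = float("nan")
    survives: bool = False


@dataclasses.dataclass
class ClusterResult:
    tract_id: str
    contrast: str
    sign: str  # "positive" | "negative"
    clusters: list

    @property
    def p_values(self) -> list:
        return [c.p_value for c in self.clusters]


# ---------------------------------------------------------------------------
# voxel-wise GLM


def _design_matrix(cohort: CohortTable) -> np.ndarray:
    age = cohort.ages
    sex = cohort.sexes
    return np.column_stack([np.ones(len(cohort)), age, sex, age * sex])


def voxelwise_glm(tsa_stack, cohort: CohortTable) -> ContrastMaps:
    """OLS of TSA on (1, Age, Sex, Age x Sex) at every voxel fitted in all
    participants (listwise exclusion keeps each voxel's design balanced).

    ``tsa_stack`` is a sequence of TSAVolume, one per cohort row, in cohort
    order. Voxels with zero TSA variance across participants get t = 0 at
    every contrast (degenerate but defined).
    """
    if len(tsa_stack) != len(cohort):
        raise ValueError("tsa_stack length must match cohort size")
    if len(cohort) < 6:
        raise ValueError("need at least 6 participants")
    grid = tsa_stack[0].grid
    for t_ in tsa_stack:
        _check_same_grid(grid, t_.grid)
    X = _design_matrix(cohort)
    if np.linalg.matrix_rank(X) < 4:
        names = ["intercept", "age", "sex", "age_sex"]
        for j in range(1, 4):  # first column dependent on its predecessors
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                raise DesignError(
                    f"design matrix is rank deficient: column {names[j]!r} is collinear"
                )
        raise DesignError("design matrix is rank deficient")
    mask = np.logical_and.reduce([t_.fitted for t_ in tsa_stack])
    mask_index = np.argwhere(mask)
    n = len(cohort)
    nu = n - X.shape[1]
    Y = np.stack([t_.beta[mask] for t_ in tsa_stack])  # (n, V)
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y  # (4, V)
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / nu
    # zero-variance voxels (all participants identical) are degenerate: t = 0
    degenerate = sigma2 <= 1e-24 + 1e-15 * np.mean(Y ** 2, axis=0)
    xtx_inv_diag = np.diag(np.linalg.inv(X.T @ X))
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2[None, :] * xtx_inv_diag[:, None])
        ok = (se > 0) & ~degenerate[None, :]
        tvals = np.where(ok, beta / np.where(ok, se, 1.0), 0.0)
    t_maps = {}
    for j, name in enumerate(CONTRASTS, start=1):
        m = np.full(grid.dims, np.nan)
        m[mask] = tvals[j]
        t_maps[name] = m
    return ContrastMaps(grid, mask, t_maps, nu, resid, mask_index)


# ---------------------------------------------------------------------------
# distance-wise summarisation


def weighted_distance_summary(
    contrast_maps: ContrastMaps,
    contrast: str,
    p_tract: ScalarVolume,
    distance_map: DistanceMap,
    lambda_decay: float = DEFAULT_LAMBDA,
    tract_id: str = "",
) -> DistanceProfile:
    """Summarise a contrast's t-map at each distance stratum.

    Within a stratum, ``t'(j) = t(j) * P_tract(j)**lambda``; the reported
    positive-tail value is the unweighted t of the voxel with maximal t',
    and the negative-tail value that of the voxel with minimal t'. Strata
    with no analysable voxel are skipped with a warning.
    """
    if lambda_decay < 0:
        raise ValueError("lambda must be non-negative")
    if contrast not in contrast_maps.t:
        raise KeyError(f"unknown contrast {contrast!r}")
    _check_same_grid(contrast_maps.grid, p_tract.grid, distance_map.grid)
    t_map = contrast_maps.t[contrast]
    labels = distance_map.labels
    distances, t_pos, t_neg = [], [], []
    for d in range(1, distance_map.max_distance + 1):
        sel = (labels == d) & contrast_maps.mask & np.isfinite(t_map)
        if not sel.any():
            warnings.warn(f"distance stratum {d} has no analysable voxels; skipped")
            continue
        t_s = t_map[sel]
        w = p_tract.data[sel] ** lambda_decay
        t_prime = t_s * w
        distances.append(d)
        t_pos.append(t_s[np.argmax(t_prime)])
        t_neg.append(t_s[np.argmin(t_prime)])
    return DistanceProfile(
        tract_id, contrast, np.asarray(distances), np.asarray(t_pos), np.asarray(t_neg)
    )


def stratum_residual_field(
    contrast_maps: ContrastMaps,
    p_tract: ScalarVolume,
    distance_map: DistanceMap,
) -> np.ndarray:
    """(n_participants, Q) residual field along the tract, taking each
    stratum's core voxel (maximal P_tract among analysable voxels)."""
    labels = distance_map.labels
    lin = {tuple(ix): k for k, ix in enumerate(map(tuple, contrast_maps.mask_index))}
    cols = []
    for d in range(1, distance_map.max_distance + 1):
        sel = (labels == d) & contrast_maps.mask
        if not sel.any():
            continue
        idx = np.argwhere(sel)
        best = idx[np.argmax(p_tract.data[sel])]
        cols.append(lin[tuple(best)])
    if not cols:
        return np.zeros((contrast_maps.residuals.shape[0], 0))
    return contrast_maps.residuals[:, cols]


# ---------------------------------------------------------------------------
# 1D random field theory

_4LOG2 = 4.0 * np.log(2.0)


def estimate_residual_fwhm(residuals: np.ndarray) -> float:
    """Smoothness (FWHM, stratum units) of a (n, Q) residual field.

    Standard random-field estimator: the per-node gradient variance of the
    unit-normalised residual field gives resels per node
    ``sqrt(v / (4 log 2))``; FWHM is the reciprocal of their mean. A field
    with (numerically) zero gradient variance returns ``inf`` — the smooth
    limit.
    """
    R = np.asarray(residuals, float)
    if R.ndim != 2 or R.shape[1] < 2:
        raise ValueError("need a (n, Q>=2) residual field")
    ssq = (R ** 2).sum(axis=0)
    grad = np.gradient(R, axis=1)
    v = (grad ** 2).sum(axis=0)
    good = ssq > 0
    if not good.any():
        return float("inf")
    v = v[good] / ssq[good]
    resels_per_node = np.sqrt(v / _4LOG2)
    mean_rpn = resels_per_node.mean()
    if mean_rpn <= 1e-12:
        return float("inf")
    return float(1.0 / mean_rpn)


def _ec_density_1d(u: float, nu: float | None) -> float:
    """EC density (per resel) of a 1D t-field (or Gaussian field, nu=None)."""
    if nu is None:
        return float(np.sqrt(_4LOG2) / (2 * np.pi) * np.exp(-(u ** 2) / 2))
    return float(
        np.sqrt(_4LOG2) / (2 * np.pi) * (1 + u ** 2 / nu) ** (-(nu - 1) / 2.0)
    )


def _height_p(u: float, nu: float | None) -> float:
    return float(sps.norm.sf(u)) if nu is None else float(sps.t.sf(u, nu))


def _expected_ec(u: float, resels: float, nu: float | None) -> float:
    """Expected Euler characteristic (approx. P(max > u)) of the 1D field."""
    return _height_p(u, nu) + resels * _ec_density_1d(u, nu)


def rft_critical_t(
    fwhm: float,
    field_length: int,
    nu: float | None,
    alpha: float = DEFAULT_ALPHA_LEVEL,
) -> float:
    """Critical height t*: P(field maximum > t*) = alpha under the
    expected-EC approximation for a stationary 1D field of ``field_length``
    strata and the given smoothness. ``nu=None`` selects the Gaussian-field
    formula (matching software that treats large-sample t's as Gaussian);
    otherwise the t-field expression with ``nu`` degrees of freedom is used.
    In the smooth limit (resels -> 0) t* falls back to the one-sided
    point-wise quantile."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    resels = max(field_length - 1, 0) / fwhm if np.isfinite(fwhm) else 0.0
    f = lambda u: _expected_ec(u, resels, nu) - alpha
    lo, hi = 1e-3, 50.0
    if f(lo) < 0:  # alpha above the EC at ~0: essentially pointwise
        return float(sps.norm.isf(alpha)) if nu is None else float(sps.t.isf(alpha, nu))
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def _runs(above: np.ndarray):
    """Maximal runs of True: list of (start_index, end_index) inclusive."""
    runs = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def _cluster_p(extent: int, t_star: float, fwhm: float, field_length: int,
               nu: float | None) -> float:
    """Cluster-wise p for a supra-threshold run of ``extent`` strata.

    Expected-extent exponential model: with E[N] supra-threshold strata and
    E[C] expected clusters from the EC density, the extent of one cluster is
    approximately exponential with mean E[N]/E[C]; the reported p is the
    probability that a field of this smoothness contains at least one
    cluster at least this large, 1 - exp(-E[C] * P(S >= extent)).
    """
    resels = max(field_length - 1, 0) / fwhm if np.isfinite(fwhm) else 0.0
    e_clusters = max(resels * _ec_density_1d(t_star, nu), 1e-300)
    e_supra = field_length * _height_p(t_star, nu)
    mean_extent = max(e_supra / e_clusters, 1e-12)
    p_extent = np.exp(-extent / mean_extent)
    return float(1.0 - np.exp(-e_clusters * p_extent))


def cluster_inference(
    profile: DistanceProfile,
    t_star: float,
    min_extent: int = DEFAULT_MIN_EXTENT,
    fwhm: float = 1.0,
    nu: float | None = None,
) -> list:
    """Find supra-threshold clusters in both tails of a distance profile.

    Positive-tail clusters are maximal runs with ``t_d > t_star`` in the
    positive summary, negative-tail clusters runs with ``t_d < -t_star`` in
    the negative summary; runs shorter than ``min_extent`` strata are
    discarded. Returns ``[ClusterResult(positive), ClusterResult(negative)]``.
    """
    if profile.field_length == 0:
        return [
            ClusterResult(profile.tract_id, profile.contrast, "positive", []),
            ClusterResult(profile.tract_id, profile.contrast, "negative", []),
        ]
    out = []
    for sign, series in (("positive", profile.t_pos), ("negative", profile.t_neg)):
        above = series > t_star if sign == "positive" else series < -t_star
        clusters = []
        for i, j in _runs(above):
            extent = j - i + 1
            if extent < min_extent:
                continue
            seg = series[i : j + 1]
            peak = float(seg.max() if sign == "positive" else seg.min())
            p = _cluster_p(extent, t_star, fwhm, profile.field_length, nu)
            clusters.append(
                Cluster(
                    start=int(profile.distances[i]),
                    end=int(profile.distances[j]),
                    extent=extent,
                    peak_t=peak,
                    p_value=p,
                )
            )
        out.append(ClusterResult(profile.tract_id, profile.contrast, sign, clusters))
    return out


# ---------------------------------------------------------------------------
# FDR and summaries


def fdr_across_tracts(p_values, q: float = DEFAULT_FDR_Q):
    """Two-stage non-negative (BKY) FDR step-up over all cluster p-values.

    Returns ``(adjusted_p, survives)`` arrays; an empty input returns two
    empty arrays.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, adj, _, _ = multipletests(p, alpha=q, method="fdr_tsbky")
    adj = np.clip(np.maximum(adj, p), 0.0, 1.0)  # adjusted p never below raw p
    return adj, reject


def apply_fdr(cluster_results, q: float = DEFAULT_FDR_Q) -> None:
    """Attach adjusted p-values and survives flags across all tracts in place."""
    flat = [c for res in cluster_results for c in res.clusters]
    adj, rej = fdr_across_tracts([c.p_value for c in flat], q)
    for c, a, r in zip(flat, adj, rej):
        c.adjusted_p = float(a)
        c.survives = bool(r)


def signed_sums(results, profiles) -> dict:
    """Per-tract/contrast sums of significant t-values, by sign.

    ``results`` are ClusterResult lists after FDR; ``profiles`` the matching
    DistanceProfile per (tract, contrast). Returns
    ``{(tract_id, contrast): (positive_sum, negative_sum)}``.
    """
    prof_by_key = {(p.tract_id, p.contrast): p for p in profiles}
    sums: dict = {}
    for res in results:
        key = (res.tract_id, res.contrast)
        pos, neg = sums.get(key, (0.0, 0.0))
        prof = prof_by_key[key]
        series = prof.t_pos if res.sign == "positive" else prof.t_neg
        for c in res.clusters:
            if not c.survives:
                continue
            sel = (prof.distances >= c.start) & (prof.distances <= c.end)
            if res.sign == "positive":
                pos += float(series[sel].sum())
            else:
                neg += float(series[sel].sum())
        sums[key] = (pos, neg)
    return sums


# ---------------------------------------------------------------------------
# orchestration helpers


def analyse_tract(
    tsa_stack,
    cohort: CohortTable,
    p_tract: ScalarVolume,
    distance_map: DistanceMap,
    tract_id: str = "tract",
    lambda_decay: float = DEFAULT_LAMBDA,
):
    """GLM + summarisation + residual field for a single tract.

    Returns ``(contrast_maps, profiles, residual_field)`` where ``profiles``
    is a list of DistanceProfile (one per contrast).
    """
    cm = voxelwise_glm(tsa_stack, cohort)
    profiles = [
        weighted_distance_summary(cm, c, p_tract, distance_map, lambda_decay, tract_id)
        for c in CONTRASTS
    ]
    resid = stratum_residual_field(cm, p_tract, distance_map)
    return cm, profiles, resid


def combine_tracts(
    per_tract,
    nu: int,
    alpha_level: float = DEFAULT_ALPHA_LEVEL,
    min_extent: int = DEFAULT_MIN_EXTENT,
    fdr_q: float = DEFAULT_FDR_Q,
    field_model: str = "t",
):
    """Cluster inference + FDR across a collection of analysed tracts.

    ``per_tract`` maps tract_id -> (profiles, residual_field). Residual
    smoothness is estimated per tract and averaged (tracts with < 2 strata
    or infinite smoothness are excluded from the average); the shared mean
    FWHM drives one critical height per tract. Returns
    ``(cluster_results, sums, mean_fwhm, t_star)``.
    """
    nu_field = None if field_model == "gaussian" else nu
    fwhms = []
    for profiles, resid in per_tract.values():
        if resid.shape[1] >= 2:
            f = estimate_residual_fwhm(resid)
            if np.isfinite(f):
                fwhms.append(f)
    mean_fwhm = float(np.mean(fwhms)) if fwhms else float("inf")
    results = []
    t_star = float("nan")
    for tract_id, (profiles, _) in per_tract.items():
        q_len = profiles[0].field_length if profiles else 0
        t_star = rft_critical_t(mean_fwhm, q_len, nu_field, alpha_level)
        for prof in profiles:
            results.extend(
                cluster_inference(prof, t_star, min_extent, mean_fwhm, nu_field)
            )
    apply_fdr(results, fdr_q)
    all_profiles = [p for profiles, _ in per_tract.values() for p in profiles]
    sums = signed_sums(results, all_profiles)
    return results, sums, mean_fwhm, t_star
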