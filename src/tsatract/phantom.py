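"""Synthetic tractography phantoms with known ground truth.

Generates everything the downstream stages consume, without real data:

* directed visitation-probability volumes concentrated in a Gaussian tube
  around a smooth 3D curve joining two spherical ROIs, optionally with
  competing alternative routes at lower amplitude;
* a per-voxel mean streamline-orientation field tangent to the curve;
* single-shell DWI signals from the single-stick forward model
  ``s/s0 = beta * exp(-b * delta * (r . v)^2) + c`` with a known anisotropy
  fraction ``beta``, optionally carrying injected linear age / sex /
  interaction effects inside a designated region;
* reproducible cohorts with a controlled female fraction.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import (
    CohortTable,
    GradientTable,
    ROIMask,
    ScalarVolume,
    VectorVolume,
    VoxelGrid,
)

__all__ = [
    "PhantomSpec",
    "SignalSpec",
    "straight_curve",
    "arc_curve",
    "make_probability_pair",
    "make_probability_pairs",
    "make_cohort",
    "make_dwi_signal",
    "ParticipantSignal",
]

ORIENTATION_SUPPORT_THRESHOLD = 1e-3  # probability below which no tangent is recorded


class GeometryError(ValueError):
    """Phantom geometry incompatible with the voxel grid."""


class GenerationError(ValueError):
    """A requested effect produces physically impossible signal fractions."""


def straight_curve(start, end, n: int = 200) -> np.ndarray:
    """Straight polyline from ``start`` to ``end`` in mm, ``n`` samples."""
    t = np.linspace(0.0, 1.0, n)[:, None]
    return np.asarray(start, float) * (1 - t) + np.asarray(end, float) * t


def arc_curve(centre, radius: float, angle_start: float, angle_end: float,
              plane: str = "xy", offset: float = 0.0, n: int = 200) -> np.ndarray:
    """Circular arc of given radius in a coordinate plane, in mm.

    ``offset`` displaces the arc along the axis normal to the plane.
    """
    theta = np.linspace(angle_start, angle_end, n)
    u = radius * np.cos(theta)
    v = radius * np.sin(theta)
    centre = np.asarray(centre, float)
    axes = {"xy": (0, 1, 2), "xz": (0, 2, 1), "yz": (1, 2, 0)}[plane]
    out = np.tile(centre, (n, 1))
    out[:, axes[0]] += u
    out[:, axes[1]] += v
    out[:, axes[2]] += offset
    return out


@dataclasses.dataclass
class PhantomSpec:
    """Geometry of a synthetic tract phantom.

    Parameters
    ----------
    grid : VoxelGrid
        Target voxel lattice (2 mm isotropic by default elsewhere).
    curve : (N, 3) array
        Ground-truth core trajectory in world mm.
    tube_sigma : float
        Radial Gaussian decay (mm) of visitation probability around the curve.
    alt_curves : sequence of (curve, amplitude)
        Competing routes; each contributes with relative amplitude in (0, 1).
    roi_radius : float
        Radius (mm) of the two spherical terminal ROIs.
    jitter_sd : float
        SD of the voxel-wise multiplicative log-normal jitter applied
        independently per seeding direction (and per participant), mimicking
        seed-direction asymmetry of streamline counts.
    seed : int
        Base seed for all randomness.
    """

    grid: VoxelGrid
    curve: np.ndarray
    tube_sigma: float = 4.0
    alt_curves: Sequence[tuple[np.ndarray, float]] = ()
    roi_radius: float = 4.0
    jitter_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.curve = np.asarray(self.curve, dtype=float)
        if self.curve.ndim != 2 or self.curve.shape[1] != 3 or len(self.curve) < 2:
            raise ValueError("curve must be an (N>=2, 3) array of mm points")
        if self.tube_sigma <= 0:
            raise ValueError("tube_sigma must be positive")
        for _, amp in self.alt_curves:
            if not 0 < amp < 1:
                raise ValueError("alternative-curve amplitudes must be in (0, 1)")
        self._check_inside()

    def _check_inside(self) -> None:
        lo = self.grid.voxel_to_world([0, 0, 0])
        hi = self.grid.voxel_to_world([d - 1 for d in self.grid.dims])
        lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)
        curves = [self.curve] + [np.asarray(c, float) for c, _ in self.alt_curves]
        for c in curves:
            if (c < lo - 1e-9).any() or (c > hi + 1e-9).any():
                raise GeometryError("curve leaves the voxel grid")
        for endpoint in (self.curve[0], self.curve[-1]):
            if ((endpoint - lo) < self.roi_radius - 1e-9).any() or (
                (hi - endpoint) < self.roi_radius - 1e-9
            ).any():
                raise GeometryError(
                    "curve endpoints must keep a roi_radius margin inside the grid"
                )


def _resample_curve(curve: np.ndarray, spacing: float = 0.25) -> np.ndarray:
    """Resample a polyline at roughly uniform arc-length spacing (mm)."""
    seg = np.diff(curve, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    total = s[-1]
    n = max(int(np.ceil(total / spacing)) + 1, 2)
    si = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for k in range(3):
        out[:, k] = np.interp(si, s, curve[:, k])
    return out


def _curve_field(grid: VoxelGrid, curve: np.ndarray, sigma: float):
    """Base probability exp(-r^2 / 2 sigma^2) to the nearest curve point, and
    the unit tangent of the curve at that point, for every voxel."""
    dense = _resample_curve(curve)
    tang = np.gradient(dense, axis=0)
    norms = np.linalg.norm(tang, axis=1)
    norms[norms == 0] = 1.0
    tang = tang / norms[:, None]
    centres = grid.voxel_centres()
    dist, idx = cKDTree(dense).query(centres, k=1)
    prob = np.exp(-(dist ** 2) / (2.0 * sigma ** 2)).reshape(grid.dims)
    tangents = tang[idx].reshape(grid.dims + (3,))
    return prob, tangents


def _base_fields(spec: PhantomSpec):
    prob, tangents = _curve_field(spec.grid, spec.curve, spec.tube_sigma)
    for alt, amp in spec.alt_curves:
        p_alt, t_alt = _curve_field(spec.grid, np.asarray(alt, float), spec.tube_sigma)
        p_alt = amp * p_alt
        take = p_alt > prob
        prob = np.where(take, p_alt, prob)
        tangents[take] = t_alt[take]
    support = prob > ORIENTATION_SUPPORT_THRESHOLD
    tangents = np.where(support[..., None], tangents, 0.0)
    return prob, tangents, support


def _roi_ball(grid: VoxelGrid, centre_mm, radius: float, label: str) -> ROIMask:
    d = np.linalg.norm(grid.voxel_centres() - np.asarray(centre_mm, float), axis=1)
    return ROIMask(grid, (d <= radius).reshape(grid.dims), label=label)


def make_probability_pair(spec: PhantomSpec, rng: np.random.Generator | None = None):
    """Generate one participant's directed visitation probabilities.

    Returns ``(p_ab, p_ba, orientation, roi_a, roi_b)`` where the directed
    scalar volumes are the Gaussian-tube base field under independent
    voxel-wise multiplicative log-normal jitter per direction (clipped to
    [0, 1]), the orientation volume holds unit curve tangents wherever the
    base probability exceeds 1e-3, and the ROIs are balls of ``roi_radius``
    at the curve endpoints.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    prob, tangents, _ = _base_fields(spec)

    def jittered() -> ScalarVolume:
        if spec.jitter_sd > 0:
            j = np.exp(spec.jitter_sd * rng.standard_normal(spec.grid.dims))
        else:
            j = 1.0
        return ScalarVolume(spec.grid, np.clip(prob * j, 0.0, 1.0))

    p_ab = jittered()
    p_ba = jittered()
    orient = VectorVolume(spec.grid, tangents)
    roi_a = _roi_ball(spec.grid, spec.curve[0], spec.roi_radius, "roi_a")
    roi_b = _roi_ball(spec.grid, spec.curve[-1], spec.roi_radius, "roi_b")
    return p_ab, p_ba, orient, roi_a, roi_b


def make_probability_pairs(spec: PhantomSpec, n_participants: int):
    """Per-participant directed pairs sharing the phantom's population field.

    Each participant draws fresh direction-specific jitter from the same seed
    stream, so participants are distinguishable but concentrated on the same
    tube. Returns ``(pairs, orientation, roi_a, roi_b)``.
    """
    rng = np.random.default_rng(spec.seed)
    pairs = []
    orient = roi_a = roi_b = None
    for _ in range(n_participants):
        p_ab, p_ba, orient, roi_a, roi_b = make_probability_pair(spec, rng=rng)
        pairs.append((p_ab, p_ba))
    return pairs, orient, roi_a, roi_b


def make_cohort(
    n: int,
    age_range: tuple[float, float] = (18.0, 80.0),
    female_fraction: float = 86 / 130,
    seed: int = 0,
) -> CohortTable:
    """Synthetic cohort: uniform ages over ``age_range``; the number of
    female (sex=2) rows is ``round(n * female_fraction)``; row order shuffled.
    Deterministic given ``seed``."""
    if n < 2:
        raise ValueError("cohort needs at least 2 participants")
    rng = np.random.default_rng(seed)
    ages = rng.uniform(age_range[0], age_range[1], size=n)
    n_female = int(round(n * female_fraction))
    sexes = np.array([2] * n_female + [1] * (n - n_female))
    rng.shuffle(sexes)
    table = pd.DataFrame(
        {
            "participant_id": [f"sub-{i + 1:03d}" for i in range(n)],
            "age": np.round(ages, 2),
            "sex": sexes,
        }
    )
    return CohortTable(table)


@dataclasses.dataclass
class SignalSpec:
    """Forward model for synthetic single-shell DWI signals.

    The noiseless normalised signal at gradient ``r_i`` in voxel ``j`` is
    ``beta_pj * exp(-b * delta * (r_i . v_j)^2) + c_j`` where ``beta_pj`` is
    the participant's anisotropy fraction: ``beta_true(j)`` plus the injected
    ``age_slope * age + sex_effect * sex + interaction_effect * age * sex``
    inside ``effect_mask`` (sex coded 1/2, uncentred). ``s0`` is a fixed
    non-diffusion-weighted constant; noise is additive on the normalised
    signal (Gaussian by default, Rician optionally) and the stored signal is
    clipped at zero.
    """

    gradients: GradientTable
    cohort: CohortTable
    diffusivity: float = 1e-3  # mm^2/s, typical white matter
    beta_true: float | np.ndarray = 0.5
    intercept_true: float | np.ndarray = 0.2
    noise_sd: float = 0.0
    age_slope: float = 0.0
    sex_effect: float = 0.0
    interaction_effect: float = 0.0
    effect_mask: np.ndarray | None = None
    s0: float = 1000.0
    noise_model: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")
        if np.any(np.asarray(self.beta_true) + np.asarray(self.intercept_true) > 1 + 1e-12):
            raise ValueError("beta_true + intercept_true must be <= 1 before effects")


@dataclasses.dataclass
class ParticipantSignal:
    participant_id: str
    signal: np.ndarray  # (X, Y, Z, M)
    b0: ScalarVolume


def _participant_betas(spec: SignalSpec) -> np.ndarray:
    """Injected per-participant additive effect on the anisotropy fraction."""
    ages = spec.cohort.ages
    sexes = spec.cohort.sexes
    return (
        spec.age_slope * ages
        + spec.sex_effect * sexes
        + spec.interaction_effect * ages * sexes
    )


def make_dwi_signal(
    spec: SignalSpec,
    orientation: VectorVolume,
    mask: np.ndarray | None = None,
) -> Iterator[ParticipantSignal]:
    """Yield one participant's 4D DWI signal at a time (memory-bounded).

    The stick model is evaluated at voxels with a defined orientation
    (restricted further by ``mask`` when given); elsewhere the signal is the
    flat baseline ``s0 * c``. Noise is drawn only at modelled voxels.
    Raises :class:`GenerationError` if an injected effect pushes any
    participant's anisotropy fraction outside [0, 1] in the effect region.
    """
    grid = orientation.grid
    support = orientation.support
    if mask is not None:
        support = support & np.asarray(mask, dtype=bool)
    beta = np.broadcast_to(np.asarray(spec.beta_true, float), grid.dims)
    intercept = np.broadcast_to(np.asarray(spec.intercept_true, float), grid.dims)
    if np.ndim(spec.beta_true) > 0:
        anisotropic = beta > 0 if mask is None else (beta > 0) & np.asarray(mask, bool)
        if np.any(anisotropic & ~orientation.support):
            raise ValueError("orientation must be nonzero wherever beta_true > 0")
    vox = np.argwhere(support)
    v = orientation.data[support]  # (V, 3)
    b_vox = beta[support]
    c_vox = intercept[support]

    effect = _participant_betas(spec)  # (P,)
    if spec.effect_mask is not None:
        in_effect = np.asarray(spec.effect_mask, bool)[support]
    else:
        in_effect = np.ones(len(vox), dtype=bool) if np.any(effect) else np.zeros(len(vox), bool)
    if in_effect.any() and len(effect):
        b_eff = b_vox[in_effect][None, :] + effect[:, None]
        bad = (b_eff < -1e-12) | (b_eff > 1 + 1e-12)
        if bad.any():
            offenders = vox[in_effect][np.unique(np.nonzero(bad)[1])]
            raise GenerationError(
                f"injected effects push beta outside [0, 1] at voxels {offenders[:10].tolist()}"
            )

    gtab = spec.gradients
    # (V, M) stick regressor exp(-b * delta * (r_i . v_j)^2)
    proj = v @ gtab.bvecs.T
    g = np.exp(-gtab.b_value * spec.diffusivity * proj ** 2)

    rng = np.random.default_rng(spec.seed)
    b0 = ScalarVolume(grid, np.full(grid.dims, spec.s0))
    for p, pid in enumerate(spec.cohort.participant_ids):
        b_p = b_vox.copy()
        if in_effect.any():
            b_p[in_effect] += effect[p]
        y = b_p[:, None] * g + c_vox[:, None]
        if spec.noise_sd > 0:
            if spec.noise_model == "gaussian":
                y = y + spec.noise_sd * rng.standard_normal(y.shape)
            else:  # rician: magnitude of complex Gaussian perturbation
                y = np.sqrt(
                    (y + spec.noise_sd * rng.standard_normal(y.shape)) ** 2
                    + (spec.noise_sd * rng.standard_normal(y.shape)) ** 2
                )
        dense = np.empty(grid.dims + (gtab.n_gradients,))
        dense[...] = (spec.s0 * intercept)[..., None]
        dense[support] = np.clip(spec.s0 * y, 0.0, None)
        yield ParticipantSignal(pid, dense, b0)
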