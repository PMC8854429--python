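"""Tract-specific anisotropy (TSA) estimation.

For each participant and voxel j on the tract support, the fraction of the
normalised diffusion-weighted signal oriented along the tract's mean
streamline direction v_j is estimated by ordinary least squares on the
single-stick model

    s_j / s0_j = beta_j * exp(-b * delta * (R v_j)^2) + c_j

where R holds the M gradient orientations and delta is the diffusivity. The
slope beta_j is the TSA value; it is a plain regression coefficient, so
negative estimates are retained and flow into the statistics stage. The
regressor depends on v_j only through the squared projection, so flipping
the sign of any orientation leaves beta unchanged (antipodal symmetry).

The diffusivity delta may be supplied as a per-voxel map (for real data, a
tensor-fit mean-diffusivity map is the documented choice) or as a scalar;
the default 1e-3 mm^2/s is typical deep white matter.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .io import GradientTable, ScalarVolume, VectorVolume, VoxelGrid, _check_same_grid
from .tract import fwhm_to_sigma

__all__ = [
    "TSAVolume",
    "tsa_regressor",
    "fit_tsa_voxel",
    "fit_tsa_participant",
    "smooth_tsa",
    "DEFAULT_DIFFUSIVITY",
    "DEFAULT_TSA_SMOOTH_FWHM",
]

DEFAULT_DIFFUSIVITY = 1e-3  # mm^2/s
DEFAULT_TSA_SMOOTH_FWHM = 1.5  # mm


@dataclasses.dataclass
class TSAVolume:
    """Per-participant TSA map: slope beta and intercept c per voxel, defined
    only where ``fitted`` is set."""

    grid: VoxelGrid
    beta: np.ndarray
    intercept: np.ndarray
    fitted: np.ndarray
    participant_id: str = ""

    def __post_init__(self) -> None:
        for name in ("beta", "intercept"):
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != self.grid.dims:
                raise ValueError(f"{name} shape does not match grid dims")
            setattr(self, name, arr)
        self.fitted = np.asarray(self.fitted, bool)
        if self.fitted.shape != self.grid.dims:
            raise ValueError("fitted shape does not match grid dims")


def tsa_regressor(
    v_bar: np.ndarray, gradients: GradientTable, diffusivity: float = DEFAULT_DIFFUSIVITY
) -> np.ndarray:
    """Stick regressor exp(-b * delta * (r_i . v)^2), one value per gradient."""
    v = np.asarray(v_bar, float)
    if np.linalg.norm(v) == 0:
        raise ValueError("orientation vector is zero: regressor undefined")
    if diffusivity <= 0:
        raise ValueError("diffusivity must be positive")
    proj = gradients.bvecs @ v
    return np.exp(-gradients.b_value * diffusivity * proj ** 2)


def fit_tsa_voxel(signal: np.ndarray, s0: float, regressor: np.ndarray):
    """OLS of the normalised signal on (regressor, 1) -> (beta, intercept).

    Returns ``(nan, nan)`` — the unfitted marker — for non-positive s0 or a
    regressor that is constant across gradients (collinear with the
    intercept).
    """
    signal = np.asarray(signal, float)
    g = np.asarray(regressor, float)
    if s0 <= 0 or signal.shape != g.shape or g.size < 2:
        return float("nan"), float("nan")
    if np.ptp(g) < 1e-12:
        return float("nan"), float("nan")
    y = signal / s0
    m = g.size
    sg = g.sum()
    sgg = float(g @ g)
    sy = y.sum()
    sgy = float(g @ y)
    denom = m * sgg - sg * sg
    beta = (m * sgy - sg * sy) / denom
    intercept = (sy - beta * sg) / m
    return float(beta), float(intercept)


def fit_tsa_participant(
    dwi: np.ndarray,
    b0: ScalarVolume,
    orientation: VectorVolume,
    support: np.ndarray,
    gradients: GradientTable,
    diffusivity: float | ScalarVolume = DEFAULT_DIFFUSIVITY,
    participant_id: str = "",
) -> TSAVolume:
    """Fit the stick regression at every support voxel of one participant.

    ``dwi`` is the (X, Y, Z, M) diffusion-weighted stack (b0 volumes already
    separated out), ``b0`` the non-diffusion-weighted reference. Voxels
    failing a precondition (zero orientation, non-positive b0, constant
    regressor) are flagged unfitted rather than raising.
    """
    grid = orientation.grid
    if isinstance(diffusivity, ScalarVolume):
        _check_same_grid(grid, diffusivity.grid, b0.grid)
        delta = diffusivity.data
    else:
        _check_same_grid(grid, b0.grid)
        delta = np.full(grid.dims, float(diffusivity))
    if dwi.shape != grid.dims + (gradients.n_gradients,):
        raise ValueError(
            f"dwi shape {dwi.shape} does not match grid {grid.dims} + (M={gradients.n_gradients},)"
        )
    support = np.asarray(support, bool)
    ok = support & orientation.support & (b0.data > 0) & (delta > 0)
    beta = np.full(grid.dims, np.nan)
    intercept = np.full(grid.dims, np.nan)
    fitted = np.zeros(grid.dims, bool)
    if ok.any():
        v = orientation.data[ok]  # (V, 3)
        proj = v @ gradients.bvecs.T  # (V, M)
        g = np.exp(-gradients.b_value * delta[ok][:, None] * proj ** 2)
        y = dwi[ok] / b0.data[ok][:, None]
        m = gradients.n_gradients
        sg = g.sum(axis=1)
        sgg = np.einsum("ij,ij->i", g, g)
        sy = y.sum(axis=1)
        sgy = np.einsum("ij,ij->i", g, y)
        denom = m * sgg - sg ** 2
        good = denom > 1e-10 * m  # constant regressor -> collinear, unfitted
        b = np.where(good, (m * sgy - sg * sy) / np.where(good, denom, 1.0), np.nan)
        c = np.where(good, (sy - b * sg) / m, np.nan)
        idx = np.argwhere(ok)
        beta[tuple(idx.T)] = b
        intercept[tuple(idx.T)] = c
        fit_ok = np.zeros(grid.dims, bool)
        fit_ok[tuple(idx[good].T)] = True
        fitted = fit_ok
    return TSAVolume(grid, beta, intercept, fitted, participant_id)


def smooth_tsa(tsa: TSAVolume, fwhm: float = DEFAULT_TSA_SMOOTH_FWHM) -> TSAVolume:
    """Masked Gaussian smoothing of the beta map within the fitted mask.

    Unfitted voxels contribute to neither the numerator nor the kernel
    normalisation, so constants are preserved and no mass leaks across the
    tract boundary. ``fwhm = 0`` is the identity.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm == 0 or not tsa.fitted.any():
        return tsa
    sigma_vox = fwhm_to_sigma(fwhm) / tsa.grid.voxel_size
    mask = tsa.fitted.astype(float)
    values = np.where(tsa.fitted, tsa.beta, 0.0)
    num = ndimage.gaussian_filter(values, sigma=sigma_vox)
    den = ndimage.gaussian_filter(mask, sigma=sigma_vox)
    beta = np.full(tsa.grid.dims, np.nan)
    inside = tsa.fitted & (den > 0)
    beta[inside] = num[inside] / den[inside]
    return TSAVolume(tsa.grid, beta, tsa.intercept, tsa.fitted, tsa.participant_id)
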