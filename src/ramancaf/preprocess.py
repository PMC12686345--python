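"""Spectral preprocessing: baseline removal, smoothing, internal-standard normalization.

The processing order is fixed as baseline -> Savitzky-Golay smoothing ->
normalization to the 1,040 cm^-1 paraformaldehyde (PFA) band, applied
independently to every spectrum (no training statistics are involved, so the
step cannot leak information across a train/test split).

Baseline removal is the iterative modified-polynomial ("modpoly") scheme:
fit a polynomial, clip the working spectrum toward the fit, refit, and stop
when the fitted values change by less than a relative tolerance.  Peaks are
progressively excluded from the fit because clipping pulls the working
spectrum down to the fluorescence envelope.  By default the clipping level
is ``fit + SD(residual)`` (the noise-aware "improved modpoly" variant): with
plain ``min(y, fit)`` clipping the baseline converges to the lower noise
envelope instead of the noise mean, and the resulting additive offset badly
distorts internal-standard normalization at realistic noise levels.  Plain
clipping remains available via ``baseline_noise_aware=False``.  Negative
post-baseline intensities are retained: clipping them would bias band
statistics.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from scipy.signal import savgol_filter

from .spectral import Spectrum, SpectralDataset, WavenumberGrid

__all__ = [
    "PreprocessConfig",
    "BaselineModel",
    "fit_baseline",
    "correct_baseline",
    "smooth",
    "normalize_pfa",
    "preprocess_dataset",
    "NormalizationError",
    "PreprocessError",
]


class NormalizationError(ValueError):
    """Internal-standard band mean is non-positive or outside the grid."""


class PreprocessError(RuntimeError):
    """Aggregated per-spectrum preprocessing failure."""


@dataclasses.dataclass(frozen=True)
class PreprocessConfig:
    baseline_order: int = 5
    baseline_max_iter: int = 100
    baseline_tol: float = 1e-4
    baseline_noise_aware: bool = True
    sg_window: int = 11
    sg_polyorder: int = 3
    norm_center: float = 1040.0
    norm_half_width: float = 2.0

    def __post_init__(self) -> None:
        if self.baseline_order < 0:
            raise ValueError("baseline_order must be >= 0")
        if self.sg_window % 2 == 0:
            raise ValueError("sg_window must be odd")
        if self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must exceed sg_polyorder")
        if self.norm_half_width < 0:
            raise ValueError("norm_half_width must be >= 0")


@dataclasses.dataclass
class BaselineModel:
    """Fitted polynomial baseline (coefficients on the scaled domain [-1, 1])."""

    order: int
    coefficients: np.ndarray
    fitted_values: np.ndarray


def _design_matrix(grid: WavenumberGrid, order: int) -> np.ndarray:
    # scaled domain keeps the Vandermonde well conditioned at order 5
    w = grid.values
    t = 2.0 * (w - w[0]) / (w[-1] - w[0]) - 1.0
    return np.vander(t, order + 1, increasing=True)


def _fit_baseline_matrix(
    matrix: np.ndarray, grid: WavenumberGrid, config: PreprocessConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized modpoly over the rows of ``matrix``.

    Returns ``(coefficients, fitted)`` with shapes (n, order+1) and (n, p).
    Each row iterates until its own relative change drops below tolerance;
    converged rows are frozen while the rest continue.
    """
    if matrix.shape[1] <= config.baseline_order + 1:
        raise ValueError(
            f"grid length {matrix.shape[1]} too short for baseline order "
            f"{config.baseline_order}"
        )
    A = _design_matrix(grid, config.baseline_order)
    # Least squares through the thin QR: the fit is the projection
    # y Q Q^T onto the polynomial column space; coefficients R^-1 Q^T y.
    Q, R = np.linalg.qr(A)
    n = matrix.shape[0]
    out_coeffs = np.empty((n, config.baseline_order + 1))
    out_fitted = np.empty_like(matrix)
    # active working set, compacted as rows converge to bound copying
    idx = np.arange(n)
    work = matrix.copy()
    fitted = (work @ Q) @ Q.T
    for _ in range(config.baseline_max_iter):
        if config.baseline_noise_aware:
            # clip at fit + residual SD so the baseline tracks the noise mean
            dev = (work - fitted).std(axis=1, ddof=0)
            np.minimum(work, fitted + dev[:, None], out=work)
        else:
            np.minimum(work, fitted, out=work)
        new_fit = (work @ Q) @ Q.T
        denom = np.linalg.norm(fitted, axis=1)
        denom[denom == 0.0] = 1.0
        change = np.linalg.norm(new_fit - fitted, axis=1) / denom
        fitted = new_fit
        done = change < config.baseline_tol
        if done.any():
            rows = idx[done]
            out_fitted[rows] = fitted[done]
            out_coeffs[rows] = np.linalg.solve(R, Q.T @ work[done].T).T
            keep = ~done
            idx, work, fitted = idx[keep], work[keep], fitted[keep]
            if idx.size == 0:
                break
    if idx.size:  # rows that hit max_iter
        out_fitted[idx] = fitted
        out_coeffs[idx] = np.linalg.solve(R, Q.T @ work.T).T
    return out_coeffs, out_fitted


def fit_baseline(spectrum: Spectrum, config: PreprocessConfig = PreprocessConfig()) -> BaselineModel:
    """Iterative modified-polynomial baseline of one spectrum."""
    coeffs, fitted = _fit_baseline_matrix(
        spectrum.intensities[None, :], spectrum.grid, config
    )
    return BaselineModel(
        order=config.baseline_order, coefficients=coeffs[0], fitted_values=fitted[0]
    )


def correct_baseline(
    spectrum: Spectrum, config: PreprocessConfig = PreprocessConfig()
) -> Spectrum:
    """Subtract the fitted baseline; small negatives are kept."""
    model = fit_baseline(spectrum, config)
    return dataclasses.replace(
        spectrum, intensities=spectrum.intensities - model.fitted_values
    )


def smooth(spectrum: Spectrum, config: PreprocessConfig = PreprocessConfig()) -> Spectrum:
    """Savitzky-Golay smoothing (endpoints by polynomial extrapolation)."""
    if config.sg_window > len(spectrum.grid):
        raise ValueError("sg_window exceeds grid length")
    smoothed = savgol_filter(
        spectrum.intensities, config.sg_window, config.sg_polyorder, mode="interp"
    )
    return dataclasses.replace(spectrum, intensities=smoothed)


def _band_mean(
    matrix: np.ndarray, grid: WavenumberGrid, center: float, half_width: float
) -> np.ndarray:
    mask = grid.band_mask(center - half_width, center + half_width)
    if not mask.any():
        raise NormalizationError(
            f"normalization band {center} +/- {half_width} cm^-1 outside grid"
        )
    return matrix[:, mask].mean(axis=1)


def normalize_pfa(
    spectrum: Spectrum, config: PreprocessConfig = PreprocessConfig()
) -> Spectrum:
    """Divide by the mean intensity of the PFA internal-standard band."""
    scale = _band_mean(
        spectrum.intensities[None, :], spectrum.grid, config.norm_center, config.norm_half_width
    )[0]
    if scale <= 0:
        raise NormalizationError(
            f"band mean at {config.norm_center} cm^-1 is {scale:.4g}; cannot normalize"
        )
    return dataclasses.replace(spectrum, intensities=spectrum.intensities / scale)


def preprocess_dataset(
    dataset: SpectralDataset, config: Optional[PreprocessConfig] = None
) -> SpectralDataset:
    """Baseline-correct, smooth and PFA-normalize every spectrum of a dataset.

    Labels, cell ids and row order are preserved.  Any per-spectrum failure is
    aggregated into one :class:`PreprocessError` naming the offending rows.
    """
    if config is None:
        config = PreprocessConfig()
    if dataset.n_spectra == 0:
        return dataset.subset(np.array([], dtype=int))

    _, fitted = _fit_baseline_matrix(dataset.matrix, dataset.grid, config)
    corrected = dataset.matrix - fitted
    if config.sg_window > dataset.n_wavenumbers:
        raise ValueError("sg_window exceeds grid length")
    smoothed = savgol_filter(
        corrected, config.sg_window, config.sg_polyorder, axis=1, mode="interp"
    )
    scales = _band_mean(smoothed, dataset.grid, config.norm_center, config.norm_half_width)
    bad = np.flatnonzero(scales <= 0)
    if bad.size:
        names = [str(dataset.cell_ids[i]) for i in bad[:10]]
        raise PreprocessError(
            f"normalization band non-positive for {bad.size} spectra "
            f"(rows {bad[:10].tolist()}, cells {names})"
        )
    normalized = smoothed / scales[:, None]
    return SpectralDataset(
        grid=dataset.grid,
        matrix=normalized,
        labels=dataset.labels.copy(),
        cell_ids=dataset.cell_ids.copy(),
        class_order=dataset.class_order,
        pixels=None if dataset.pixels is None else dataset.pixels.copy(),
    )
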