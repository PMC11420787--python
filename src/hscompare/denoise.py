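"""Additive-noise estimation by per-band regression, and its subtraction.

Hyperspectral bands are strongly inter-correlated: the clean signal at any
one band is well predicted by a linear combination of the remaining bands,
while additive sensor noise is not.  The noise at band ``b`` is therefore
estimated as the residual of a least-squares regression of band ``b``'s
pixel vector on all other bands, and denoising subtracts that residual
cube from the input.  Noise is assumed additive; pixels are flattened
spatially (no spatial model).

Bands are mean-centered before regression, which is equivalent to
including an intercept.  The per-band solves share one matrix inverse: with
``P = (C + lambda I)^-1`` for the centered band covariance ``C``, the
residual of band ``b`` regressed on the others is ``(X @ P[:, b]) / P[b, b]``
(partitioned-inverse identity), so the whole estimate costs one ``B x B``
inverse plus one matmul instead of ``B`` separate solves.  A small ridge
term (default ``1e-6 * trace(C) / B``) keeps near-collinear cubes
well-conditioned; with ``ridge_lambda=0`` the residuals are exactly
orthogonal to the regressor bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cube import HyperCube
from .errors import UnderdeterminedError

__all__ = ["NoiseEstimate", "estimate_noise", "denoise"]


@dataclass
class NoiseEstimate:
    """Per-pixel, per-band noise residuals and their band variances."""

    noise_cube: np.ndarray
    per_band_variance: np.ndarray

    @property
    def per_band_sd(self) -> np.ndarray:
        return np.sqrt(self.per_band_variance)


def _default_ridge(cov: np.ndarray) -> float:
    return 1e-6 * float(np.trace(cov)) / cov.shape[0]


def estimate_noise(cube: HyperCube, ridge_lambda: float | None = None) -> NoiseEstimate:
    """Estimate additive noise per band via regression on the other bands.

    Parameters
    ----------
    cube
        Input cube with at least 3 bands and more pixels than bands.
    ridge_lambda
        Ridge regularization added to the band covariance; ``None`` selects
        ``1e-6 * trace(C) / bands``.  Pass 0 for plain least squares.

    Returns
    -------
    NoiseEstimate with ``noise_cube`` shaped like the input and
    ``per_band_variance`` holding the sample variance (ddof=1) of each
    band's residuals.
    """
    b = cube.bands
    if b < 3:
        raise ValueError(f"noise estimation needs >= 3 bands, got {b}")
    x = cube.data.reshape(-1, b).astype(float)
    n = x.shape[0]
    if n < b + 1:
        if ridge_lambda is None or ridge_lambda <= 0:
            raise UnderdeterminedError(
                f"{n} pixels < {b} + 1 bands: regression underdetermined; "
                "pass ridge_lambda > 0 to regularize"
            )
    xc = x - x.mean(axis=0, keepdims=True)
    cov = xc.T @ xc
    lam = _default_ridge(cov) if ridge_lambda is None else float(ridge_lambda)
    p = np.linalg.inv(cov + lam * np.eye(b))
    # residual of band b on all others: (Xc @ P[:, b]) / P[b, b]
    noise = (xc @ p) / np.diag(p)[None, :]
    # residual variance with degrees-of-freedom correction (intercept +
    # b-1 regressors consume b parameters per band)
    if n > b:
        var = (noise ** 2).sum(axis=0) / (n - b)
    elif n > 1:
        var = noise.var(axis=0, ddof=1)
    else:
        var = np.zeros(b)
    return NoiseEstimate(
        noise_cube=noise.reshape(cube.shape),
        per_band_variance=var,
    )


def denoise(cube: HyperCube, ridge_lambda: float | None = None) -> HyperCube:
    """Subtract the estimated additive noise from the cube.

    ``output = cube - noise_cube`` elementwise, applied to each image
    independently; wavelengths and shape are unchanged and the provenance
    records the step.
    """
    est = estimate_noise(cube, ridge_lambda=ridge_lambda)
    return cube.with_data(cube.data - est.noise_cube, step="denoise")
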