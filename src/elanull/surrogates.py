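"""Stationary, linear null models (surrogate-data generators).

Four nulls, each preserving a chosen statistic of an input series:

* :func:`static_null` — i.i.d. multivariate Gaussian with the input's mean
  and covariance (lag-0 structure only);
* :func:`arr_null` — autoregressive randomization: a VAR(1) fitted to the
  input (:func:`arr_fit`) and iterated from a randomly chosen real row
  (lag-0 and lag-1 structure);
* :func:`pr_null` — phase randomization: random phases, shared across
  channels, added to every positive DFT frequency (all auto- and
  cross-spectra, hence all circular lagged covariances, preserved exactly);
* :func:`binary_static_null` — dichotomized Gaussian producing ±1 sequences
  with specified means and correlations (the binary analogue of the static
  null, fitted to binarized data via :func:`binary_null_targets`).
"""
from __future__ import annotations

import warnings
from typing import Optional, Tuple

import numpy as np
from scipy.stats import multivariate_normal, norm

from .datatypes import (BinaryNullTargets, RoiTimeSeries, SurrogateSpec,
                        VarModel)
from .errors import ConvergenceError, FeasibilityError, ValidityError

__all__ = [
    "static_null",
    "arr_fit",
    "arr_null",
    "pr_null",
    "binary_null_targets",
    "binary_static_null",
    "make_surrogate",
]


def _out_length(spec: SurrogateSpec, t_in: int) -> int:
    return int(round(spec.length_factor * t_in))


def _sample_cov(data: np.ndarray) -> np.ndarray:
    t, n = data.shape
    cov = np.cov(data, rowvar=False)
    if t < n + 1:
        warnings.warn(
            f"T={t} < N+1={n + 1}: sample covariance rank-deficient; "
            "clipping eigenvalues", RuntimeWarning, stacklevel=2)
        w, v = np.linalg.eigh(0.5 * (cov + cov.T))
        cov = (v * np.clip(w, 0.0, None)) @ v.T
    return 0.5 * (cov + cov.T)


def static_null(x: RoiTimeSeries, spec: SurrogateSpec) -> RoiTimeSeries:
    """I.i.d. Gaussian surrogate matching the input mean and covariance."""
    data = x.data
    mean = data.mean(axis=0)
    cov = _sample_cov(data)
    rng = np.random.default_rng(spec.seed)
    out = rng.multivariate_normal(mean, cov, size=_out_length(spec, len(data)),
                                  method="eigh")
    return RoiTimeSeries(out, list(x.channel_names), dt=x.dt)


def arr_fit(x: RoiTimeSeries, ridge: float = 1e-8) -> VarModel:
    """Least-squares VAR(1) fit: A1 = C1 C0^-1 on mean-centred data.

    The innovation covariance is the symmetrized Lyapunov residual
    C0 - A1 C0 A1' with negative eigenvalues clipped to zero.  When C0 is
    ill-conditioned its inverse is ridge-regularized (scaled by
    ``ridge * trace(C0)/N``) with a warning.
    """
    data = x.data
    t, n = data.shape
    if t < n + 2:
        raise ValidityError(f"need T >= N+2 to fit a VAR(1), got T={t}, N={n}")
    mu = data.mean(axis=0)
    xc = data - mu
    c0 = xc.T @ xc / (t - 1)
    c1 = xc[1:].T @ xc[:-1] / (t - 1)
    cond = np.linalg.cond(c0)
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn("lag-0 covariance ill-conditioned; applying ridge",
                      RuntimeWarning, stacklevel=2)
        c0 = c0 + (ridge * np.trace(c0) / n) * np.eye(n)
    a1 = c1 @ np.linalg.inv(c0)
    resid = c0 - a1 @ c0 @ a1.T
    resid = 0.5 * (resid + resid.T)
    w, v = np.linalg.eigh(resid)
    sigma = (v * np.clip(w, 0.0, None)) @ v.T
    return VarModel(a1, 0.5 * (sigma + sigma.T), mu)


def arr_null(x: RoiTimeSeries, spec: SurrogateSpec,
             model: Optional[VarModel] = None) -> RoiTimeSeries:
    """Autoregressive-randomization surrogate.

    The fitted VAR(1) is iterated with Gaussian innovations, seeded from a
    randomly selected row of the input (no burn-in).
    """
    if model is None:
        model = arr_fit(x)
    data = x.data
    t_out = _out_length(spec, len(data))
    rng = np.random.default_rng(spec.seed)
    start = data[rng.integers(len(data))]
    n = model.n_channels
    out = np.empty((t_out, n))
    out[0] = start
    noise = rng.multivariate_normal(np.zeros(n), model.Sigma,
                                    size=t_out - 1, method="eigh")
    mu, a1 = model.mu, model.A1
    for t in range(1, t_out):
        out[t] = mu + a1 @ (out[t - 1] - mu) + noise[t - 1]
    return RoiTimeSeries(out, list(x.channel_names), dt=x.dt)


def pr_null(x: RoiTimeSeries, spec: SurrogateSpec,
            phases: Optional[np.ndarray] = None) -> RoiTimeSeries:
    """Phase-randomization surrogate.

    Each positive DFT frequency is rotated by a phase drawn uniformly in
    [0, 2pi); the same phase is applied to every channel at a given
    frequency, so cross-spectra (and thus all circular lagged auto- and
    cross-covariances) are preserved exactly.  DC and, for even T, the
    Nyquist coefficient are left untouched to keep the output real.
    Output length equals input length (``length_factor`` must be 1).

    ``phases`` overrides the random draw (mainly for testing): an array of
    one phase per strictly-positive non-Nyquist rfft frequency.
    """
    if spec.length_factor != 1.0:
        raise ValidityError("phase randomization requires length_factor = 1")
    data = x.data
    t = data.shape[0]
    spec_f = np.fft.rfft(data, axis=0)
    n_freq = spec_f.shape[0]
    # indices 1 .. n_freq-1; for even T the last one is Nyquist (untouched)
    hi = n_freq - 1 if t % 2 == 0 else n_freq
    n_random = hi - 1
    if phases is None:
        rng = np.random.default_rng(spec.seed)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=n_random)
    else:
        phases = np.asarray(phases, dtype=float)
        if phases.shape != (n_random,):
            raise ValidityError(
                f"phases must have shape ({n_random},), got {phases.shape}")
    rot = np.ones(n_freq, dtype=complex)
    rot[1:hi] = np.exp(1j * phases)
    out = np.fft.irfft(spec_f * rot[:, None], n=t, axis=0)
    return RoiTimeSeries(out, list(x.channel_names), dt=x.dt)


def binary_null_targets(b: np.ndarray) -> BinaryNullTargets:
    """Target moments (per-channel P(+1) and ±1 correlation matrix) of a
    binarized ±1 matrix."""
    b = np.asarray(b)
    if b.ndim != 2 or not np.all(np.abs(b) == 1):
        raise ValidityError("b must be a T x N ±1 matrix")
    p = (b > 0).mean(axis=0)
    if np.any(p == 0.0) or np.any(p == 1.0):
        bad = int(np.flatnonzero((p == 0) | (p == 1))[0])
        raise ValidityError(f"channel {bad} is constant in the binary data")
    r = np.corrcoef(b.astype(float), rowvar=False)
    r = 0.5 * (r + r.T)
    np.fill_diagonal(r, 1.0)
    return BinaryNullTargets(p, r)


def _upper_orthant(zi: float, zj: float, rho: float) -> float:
    """P(X > zi, Y > zj) for standard bivariate normal with correlation rho.

    By central symmetry this equals the CDF at (-zi, -zj).
    """
    return float(multivariate_normal.cdf(
        [-zi, -zj], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]))


def _latent_correlation(pi: float, pj: float, rij: float,
                        zi: float, zj: float,
                        tol: float = 1e-10, max_iter: int = 200) -> float:
    """Root-find (bisection) the latent Gaussian correlation reproducing the
    target joint probability P(sigma_i=+1, sigma_j=+1)."""
    target = pi * pj + rij * np.sqrt(pi * (1 - pi) * pj * (1 - pj))
    lo_frechet = max(0.0, pi + pj - 1.0)
    hi_frechet = min(pi, pj)
    if target < lo_frechet - 1e-12 or target > hi_frechet + 1e-12:
        raise FeasibilityError(
            f"target correlation {rij:.4f} infeasible for marginals "
            f"({pi:.4f}, {pj:.4f})")
    # comonotone / antitone limits map to latent rho = ±1 exactly
    if target >= hi_frechet - 1e-12:
        return 1.0
    if target <= lo_frechet + 1e-12:
        return -1.0
    lo, hi = -1.0 + 1e-9, 1.0 - 1e-9
    f_lo = _upper_orthant(zi, zj, lo) - target
    f_hi = _upper_orthant(zi, zj, hi) - target
    if f_lo > 0 or f_hi < 0:          # target outside numeric range: clamp
        return hi if f_hi < 0 else lo
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = _upper_orthant(zi, zj, mid) - target
        if abs(f_mid) < tol or hi - lo < 1e-13:
            return mid
        if f_mid < 0:
            lo = mid
        else:
            hi = mid
    raise ConvergenceError(
        f"latent-correlation bisection did not converge for pair with "
        f"target {rij:.4f}")


def _nearest_psd_correlation(m: np.ndarray) -> np.ndarray:
    """Eigenvalue-clipped, unit-diagonal-rescaled PSD repair."""
    w, v = np.linalg.eigh(0.5 * (m + m.T))
    if w.min() >= 0:
        return m
    repaired = (v * np.clip(w, 1e-12, None)) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return 0.5 * (repaired + repaired.T)


def latent_gaussian_parameters(
        targets: BinaryNullTargets) -> Tuple[np.ndarray, np.ndarray]:
    """Thresholds and latent correlation matrix of the dichotomized
    Gaussian calibrated to the targets."""
    n = targets.n_channels
    z = norm.ppf(1.0 - targets.p)
    latent = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            rho = _latent_correlation(targets.p[i], targets.p[j],
                                      targets.R[i, j], z[i], z[j])
            latent[i, j] = latent[j, i] = rho
    return z, _nearest_psd_correlation(latent)


def binary_static_null(targets: BinaryNullTargets, n_samples: int,
                       seed: int) -> np.ndarray:
    """Dichotomized-Gaussian ±1 sampler with specified means/correlations.

    A latent standard multivariate normal is calibrated per pair so that
    thresholding at z_i = Phi^-1(1 - p_i) reproduces the target joint
    probabilities; rows are then sampled i.i.d. and thresholded.
    """
    if n_samples < 1:
        raise ValidityError("n_samples must be >= 1")
    z, latent = latent_gaussian_parameters(targets)
    rng = np.random.default_rng(seed)
    w, v = np.linalg.eigh(latent)
    rootm = v * np.sqrt(np.clip(w, 0.0, None))
    g = rng.standard_normal((n_samples, targets.n_channels)) @ rootm.T
    return np.where(g > z, 1, -1).astype(np.int8)


def make_surrogate(x: RoiTimeSeries, spec: SurrogateSpec):
    """Dispatch on ``spec.kind``.  Continuous kinds return a
    :class:`RoiTimeSeries`; ``binary_static`` binarizes the input first and
    returns a ±1 matrix."""
    if spec.kind == "static":
        return static_null(x, spec)
    if spec.kind == "arr":
        return arr_null(x, spec)
    if spec.kind == "pr":
        return pr_null(x, spec)
    from .ela import binarize
    targets = binary_null_targets(binarize(x))
    return binary_static_null(targets,
                              _out_length(spec, x.n_samples), spec.seed)
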