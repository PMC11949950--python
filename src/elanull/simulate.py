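"""Synthetic-data generators: the pipeline's input side.

Three generators cover the inputs the analysis needs without any external
download:

* :func:`simulate_var` — stationary Gaussian VAR(1) "pseudo-real" data with
  realistic covariance and lag-1 autocorrelation, the linear regime that
  resting-state ROI time courses are well approximated by;
* :func:`simulate_switching` — a hidden-Markov mixture of Gaussians, a
  genuinely nonlinear two-regime process used as the contrast case for the
  topological analysis;
* :func:`simulate_ising` — exact i.i.d. samples from an enumerated pairwise
  maximum-entropy (Ising) distribution, for parameter-recovery tests.

All generators are bit-reproducible under a fixed integer seed.
"""
from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

from .datatypes import PmemModel, RoiTimeSeries, SwitchingModel, VarModel
from .errors import CapacityError, ValidityError

__all__ = [
    "stationary_covariance",
    "simulate_var",
    "simulate_switching",
    "simulate_ising",
    "concatenate_sessions",
    "hcp_like_var_model",
    "hcp_like_series",
    "two_regime_model",
]

#: Enumeration limit for exact 2**N work.
MAX_ENUM_CHANNELS = 20

#: Default sampling interval (seconds); matches the HCP repetition time.
DEFAULT_DT = 0.72


def _default_names(n: int) -> List[str]:
    return [f"roi{i}" for i in range(n)]


def _spawn_seeds(seed: int, n: int) -> List[int]:
    """Deterministically derive `n` independent 31-bit child seeds."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2 ** 31)) for s in state]


def stationary_covariance(model: VarModel) -> np.ndarray:
    """Lag-0 covariance C0 of the stationary VAR(1), from the discrete
    Lyapunov identity C0 = A1 C0 A1' + Sigma."""
    c0 = solve_discrete_lyapunov(model.A1, model.Sigma)
    return 0.5 * (c0 + c0.T)


def simulate_var(model: VarModel, n_samples: int, seed: int,
                 channel_names: Optional[Sequence[str]] = None,
                 dt: float = DEFAULT_DT) -> RoiTimeSeries:
    """Draw a length-T path of the stationary VAR(1).

    The initial state is drawn from the exact stationary distribution
    (Lyapunov solution), so there is no burn-in transient.
    """
    if n_samples < 2:
        raise ValidityError("n_samples must be >= 2")
    n = model.n_channels
    rng = np.random.default_rng(seed)
    c0 = stationary_covariance(model)
    x = np.empty((n_samples, n))
    x[0] = rng.multivariate_normal(model.mu, c0, method="eigh")
    noise = rng.multivariate_normal(np.zeros(n), model.Sigma,
                                    size=n_samples - 1, method="eigh")
    mu = model.mu
    a1 = model.A1
    for t in range(1, n_samples):
        x[t] = mu + a1 @ (x[t - 1] - mu) + noise[t - 1]
    names = list(channel_names) if channel_names is not None else _default_names(n)
    return RoiTimeSeries(x, names, dt=dt)


def simulate_switching(model: SwitchingModel, n_samples: int, seed: int,
                       channel_names: Optional[Sequence[str]] = None,
                       dt: float = DEFAULT_DT,
                       ) -> Tuple[RoiTimeSeries, np.ndarray]:
    """Draw a regime-switching series; returns (series, hidden labels).

    The hidden regime is a K-state Markov chain started from its stationary
    distribution; observations are i.i.d. Gaussians of the active regime.
    """
    if n_samples < 2:
        raise ValidityError("n_samples must be >= 2")
    k, n = model.n_regimes, model.n_channels
    rng = np.random.default_rng(seed)
    trans = model.transition_probabilities()
    # stationary distribution of the chain
    w, v = np.linalg.eig(trans.T)
    idx = np.argmin(np.abs(w - 1.0))
    pi = np.real(v[:, idx])
    pi = np.abs(pi) / np.abs(pi).sum()
    labels = np.empty(n_samples, dtype=np.int64)
    labels[0] = rng.choice(k, p=pi)
    u = rng.random(n_samples - 1)
    cum = np.cumsum(trans, axis=1)
    cum[:, -1] = 1.0
    for t in range(1, n_samples):
        labels[t] = np.searchsorted(cum[labels[t - 1]], u[t - 1], side="right")
    x = np.empty((n_samples, n))
    for regime in range(k):
        mask = labels == regime
        cnt = int(mask.sum())
        if cnt:
            x[mask] = rng.multivariate_normal(
                model.means[regime], model.covariances[regime],
                size=cnt, method="eigh")
    names = list(channel_names) if channel_names is not None else _default_names(n)
    return RoiTimeSeries(x, names, dt=dt), labels


def simulate_ising(model: PmemModel, n_samples: int, seed: int) -> np.ndarray:
    """Exact i.i.d. ±1 samples from the enumerated Boltzmann distribution.

    Rows are drawn by inverse-CDF over all 2**N states, so the empirical
    state histogram converges to exp(-E)/Z without any Monte-Carlo chain.
    """
    from .ela import boltzmann_probabilities, states_matrix

    n = model.n_channels
    if n > MAX_ENUM_CHANNELS:
        raise CapacityError(
            f"N={n} exceeds the 2**N enumeration limit ({MAX_ENUM_CHANNELS})")
    if n_samples < 1:
        raise ValidityError("n_samples must be >= 1")
    probs = boltzmann_probabilities(model)
    rng = np.random.default_rng(seed)
    cdf = np.cumsum(probs)
    cdf[-1] = 1.0
    idx = np.searchsorted(cdf, rng.random(n_samples), side="right")
    return states_matrix(n).astype(np.int8)[idx]


def concatenate_sessions(series: Sequence[RoiTimeSeries]) -> RoiTimeSeries:
    """Stack sessions/participants along time (rows), in list order.

    All inputs must share channel names; this mirrors concatenating several
    scans to meet the data demand of pairwise maximum-entropy fitting.
    """
    if not series:
        raise ValidityError("need at least one series")
    first = series[0]
    for s in series[1:]:
        if s.channel_names != first.channel_names:
            raise ValidityError("channel names differ between sessions")
    data = np.vstack([s.data for s in series])
    return RoiTimeSeries(data, list(first.channel_names), dt=first.dt)


def hcp_like_var_model(n_channels: int = 7, seed: int = 0) -> VarModel:
    """A seeded random stable VAR(1) emulating resting-state ROI statistics.

    Diagonal lag-1 coefficients are drawn uniformly in [0.5, 0.8] (channel
    autocorrelations in the range typical of fast-TR fMRI), off-diagonal
    coefficients are small random couplings, and the innovation covariance
    carries a random correlated structure.  The model is rescaled so the
    stationary covariance has unit variances, which makes downstream
    covariance tolerances scale-free.
    """
    rng = np.random.default_rng(seed)
    n = n_channels
    a1 = np.diag(rng.uniform(0.5, 0.8, size=n))
    a1 += rng.normal(0.0, 0.1 / np.sqrt(n), size=(n, n)) * (1 - np.eye(n))
    radius = np.abs(np.linalg.eigvals(a1)).max()
    if radius >= 0.95:
        a1 *= 0.95 / radius
    w = rng.normal(size=(n, n))
    sigma = w @ w.T / n + 0.2 * np.eye(n)
    model = VarModel(a1, sigma, np.zeros(n))
    # rescale to unit stationary variances
    d = np.sqrt(np.diag(stationary_covariance(model)))
    dinv = np.diag(1.0 / d)
    a1 = dinv @ a1 @ np.diag(d)
    sigma = dinv @ sigma @ dinv
    return VarModel(a1, 0.5 * (sigma + sigma.T), np.zeros(n))


def hcp_like_series(seed: int, n_channels: int = 7, n_samples: int = 8000,
                    dt: float = DEFAULT_DT) -> Tuple[RoiTimeSeries, VarModel]:
    """Convenience preset: a fresh HCP-like VAR model and one draw from it."""
    model_seed, sim_seed = _spawn_seeds(seed, 2)
    model = hcp_like_var_model(n_channels, seed=model_seed)
    series = simulate_var(model, n_samples, seed=sim_seed, dt=dt)
    return series, model


def two_regime_model(n_channels: int = 7, separation: float = 4.0,
                     stay_prob: float = 0.95, seed: int = 0) -> SwitchingModel:
    """A two-regime switching preset with well-separated means.

    The regime means sit ``separation`` apart (in units of the within-regime
    standard deviation) along a random direction; each regime has its own
    random correlated covariance with unit variances.
    """
    rng = np.random.default_rng(seed)
    n = n_channels
    direction = rng.normal(size=n)
    direction /= np.linalg.norm(direction)
    means = np.vstack([-0.5 * separation * direction,
                       +0.5 * separation * direction])
    covs = np.empty((2, n, n))
    for kreg in range(2):
        w = rng.normal(size=(n, n))
        c = w @ w.T / n + 0.3 * np.eye(n)
        d = np.sqrt(np.diag(c))
        covs[kreg] = c / np.outer(d, d)
    return SwitchingModel(means, covs, np.array([stay_prob, stay_prob]))
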