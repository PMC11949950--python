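"""Core container types shared across the pipeline.

All containers are plain dataclasses over numpy arrays, validated at
construction.  Binary activity patterns are always coded as ±1 integers;
a pattern over N channels maps to a state index ``s = sum_i b_i 2**i`` with
``b_i = (sigma_i + 1)/2`` and channel 0 the least-significant bit.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import StationarityError, ValidityError

__all__ = [
    "RoiTimeSeries",
    "VarModel",
    "SwitchingModel",
    "PmemModel",
    "EnergyLandscape",
    "BasinLabelSeries",
    "TransitionMatrix",
    "SurrogateSpec",
    "BinaryNullTargets",
    "MapperConfig",
    "MapperNode",
    "MapperGraph",
]


def _as_float_matrix(a, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2:
        raise ValidityError(f"{name} must be a 2-D matrix, got ndim={a.ndim}")
    if not np.all(np.isfinite(a)):
        raise ValidityError(f"{name} contains non-finite values")
    return a


def check_symmetric_psd(m: np.ndarray, name: str, tol: float = 1e-8) -> None:
    if m.shape[0] != m.shape[1]:
        raise ValidityError(f"{name} must be square, got {m.shape}")
    if not np.allclose(m, m.T, atol=tol):
        raise ValidityError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(0.5 * (m + m.T))
    if w.min() < -tol * max(1.0, abs(w.max())):
        raise ValidityError(f"{name} must be positive semidefinite "
                            f"(min eigenvalue {w.min():.3g})")


@dataclass
class RoiTimeSeries:
    """A T x N multichannel time series (e.g. ROI-averaged BOLD signals).

    Parameters
    ----------
    data : (T, N) float array
        One row per time point, one column per channel.
    channel_names : sequence of N unique strings
    dt : float
        Sampling interval in seconds (metadata only; 0.72 mirrors the HCP
        repetition time).
    """

    data: np.ndarray
    channel_names: Sequence[str]
    dt: float = 0.72

    def __post_init__(self) -> None:
        self.data = _as_float_matrix(self.data, "data")
        t, n = self.data.shape
        if t < 2 or n < 2:
            raise ValidityError(f"need T >= 2 and N >= 2, got T={t}, N={n}")
        self.channel_names = [str(c) for c in self.channel_names]
        if len(self.channel_names) != n:
            raise ValidityError(
                f"{len(self.channel_names)} channel names for {n} channels")
        if len(set(self.channel_names)) != n:
            raise ValidityError("channel names must be unique")
        if not (self.dt > 0):
            raise ValidityError("dt must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class VarModel:
    """First-order vector autoregression x(t) = mu + A1 (x(t-1) - mu) + eta.

    ``eta ~ N(0, Sigma)``.  Stationarity (spectral radius of A1 below 1)
    is enforced at construction.
    """

    A1: np.ndarray
    Sigma: np.ndarray
    mu: np.ndarray

    def __post_init__(self) -> None:
        self.A1 = _as_float_matrix(self.A1, "A1")
        self.Sigma = _as_float_matrix(self.Sigma, "Sigma")
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        n = self.A1.shape[0]
        if self.A1.shape != (n, n):
            raise ValidityError("A1 must be square")
        if self.Sigma.shape != (n, n) or self.mu.shape != (n,):
            raise ValidityError("A1, Sigma, mu dimensions disagree")
        rho = np.abs(np.linalg.eigvals(self.A1)).max()
        if rho >= 1.0:
            raise StationarityError(
                f"A1 spectral radius {rho:.4f} >= 1: VAR(1) is not stationary")
        check_symmetric_psd(self.Sigma, "Sigma")

    @property
    def n_channels(self) -> int:
        return self.A1.shape[0]


@dataclass
class SwitchingModel:
    """Hidden-Markov mixture of Gaussians: a K-regime switching generator.

    The hidden regime follows a Markov chain that stays with probability
    ``stay_prob[k]`` and otherwise jumps to one of the other regimes with
    equal probability; observations are i.i.d. draws from the active
    regime's Gaussian.
    """

    means: np.ndarray          # (K, N)
    covariances: np.ndarray    # (K, N, N)
    stay_prob: np.ndarray      # (K,)

    def __post_init__(self) -> None:
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        k, n = self.means.shape
        if k < 2:
            raise ValidityError("need at least K = 2 regimes")
        if self.covariances.shape != (k, n, n):
            raise ValidityError("covariances must have shape (K, N, N)")
        sp = np.asarray(self.stay_prob, dtype=float)
        if sp.ndim == 0:
            sp = np.full(k, float(sp))
        if sp.shape != (k,):
            raise ValidityError("stay_prob must be scalar or length K")
        if np.any(sp <= 0.0) or np.any(sp >= 1.0):
            raise ValidityError("stay_prob entries must lie strictly in (0, 1)")
        self.stay_prob = sp
        for i in range(k):
            check_symmetric_psd(self.covariances[i], f"covariances[{i}]")

    @property
    def n_regimes(self) -> int:
        return self.means.shape[0]

    @property
    def n_channels(self) -> int:
        return self.means.shape[1]

    def transition_probabilities(self) -> np.ndarray:
        """K x K regime-switching matrix implied by the stay probabilities."""
        k = self.n_regimes
        p = np.empty((k, k))
        for i in range(k):
            p[i] = (1.0 - self.stay_prob[i]) / (k - 1)
            p[i, i] = self.stay_prob[i]
        return p


@dataclass
class PmemModel:
    """Pairwise maximum-entropy (Ising) model with fields h and couplings J.

    Energy of a ±1 pattern sigma:
    ``E(sigma) = -sum_i h_i sigma_i - 1/2 sum_{i != j} J_ij sigma_i sigma_j``.
    J is symmetric with zero diagonal.
    """

    h: np.ndarray
    J: np.ndarray

    def __post_init__(self) -> None:
        self.h = np.atleast_1d(np.asarray(self.h, dtype=float))
        self.J = _as_float_matrix(self.J, "J")
        n = self.h.shape[0]
        if self.J.shape != (n, n):
            raise ValidityError("h and J dimensions disagree")
        if not np.allclose(self.J, self.J.T, atol=1e-12):
            raise ValidityError("J must be symmetric")
        if not np.allclose(np.diag(self.J), 0.0, atol=1e-12):
            raise ValidityError("J must have zero diagonal")

    @property
    def n_channels(self) -> int:
        return self.h.shape[0]


@dataclass
class EnergyLandscape:
    """Exhaustive energy landscape of a fitted pairwise maximum-entropy model.

    Attributes
    ----------
    energies : (2**N,) float array
        Energy of every state, indexed by the LSB-first state code.
    minima : sorted int array
        States strictly lower in energy than all N single-flip neighbours.
    basin_of : (2**N,) int array
        Steepest-descent attractor (a member of ``minima``) of every state.
    barriers : (B, B) float array or None
        Ultrametric saddle energies between minima (ordered as ``minima``);
        the diagonal holds the minima's own energies.
    tree : nested tuple or int or None
        Disconnectivity tree: a minimum state index at the leaves,
        ``(energy, left, right)`` at internal merge nodes.
    """

    n_channels: int
    energies: np.ndarray
    minima: np.ndarray
    basin_of: np.ndarray
    barriers: Optional[np.ndarray] = None
    tree: object = None

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        self.minima = np.asarray(self.minima, dtype=np.int64)
        self.basin_of = np.asarray(self.basin_of, dtype=np.int64)
        size = 2 ** self.n_channels
        if self.energies.shape != (size,) or self.basin_of.shape != (size,):
            raise ValidityError("energies/basin_of must have length 2**N")
        if not np.all(np.isin(self.basin_of, self.minima)):
            raise ValidityError("every basin_of target must be a minimum")
        if not np.all(self.basin_of[self.minima] == self.minima):
            raise ValidityError("each minimum must be its own attractor")

    @property
    def n_minima(self) -> int:
        return len(self.minima)


@dataclass
class BasinLabelSeries:
    """Per-volume basin labels (minimum state indices) of a binary series."""

    labels: np.ndarray
    landscape: EnergyLandscape

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if not np.all(np.isin(self.labels, self.landscape.minima)):
            raise ValidityError("labels must all be minima of the landscape")


@dataclass
class TransitionMatrix:
    """Row-stochastic basin-switching probabilities over successive volumes.

    Rows of basins never visited as a transition source carry zero counts,
    are all-zero in P, and are flagged in ``visited`` so comparisons can
    exclude them pairwise.
    """

    basins: np.ndarray
    P: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.basins = np.asarray(self.basins, dtype=np.int64)
        self.P = np.asarray(self.P, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        b = len(self.basins)
        if self.P.shape != (b, b) or self.counts.shape != (b, b):
            raise ValidityError("P and counts must be B x B")
        if np.any(self.counts < 0):
            raise ValidityError("counts must be nonnegative")
        if np.any(self.P < -1e-12) or np.any(self.P > 1 + 1e-12):
            raise ValidityError("P entries must lie in [0, 1]")
        row = self.counts.sum(axis=1)
        ok = row > 0
        if ok.any():
            sums = self.P[ok].sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-12):
                raise ValidityError("visited rows of P must sum to 1")

    @property
    def visited(self) -> np.ndarray:
        return self.counts.sum(axis=1) > 0


_SURROGATE_KINDS = ("static", "arr", "pr", "binary_static")


@dataclass
class SurrogateSpec:
    """Which null model to draw, how long, and from which seed."""

    kind: str
    length_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _SURROGATE_KINDS:
            raise ValidityError(
                f"kind must be one of {_SURROGATE_KINDS}, got {self.kind!r}")
        if not (self.length_factor >= 1.0):
            raise ValidityError("length_factor must be >= 1")


@dataclass
class BinaryNullTargets:
    """Target moments for the dichotomized-Gaussian binary null.

    ``p[i]`` is P(sigma_i = +1); ``R`` is the Pearson correlation matrix of
    the ±1 variables.
    """

    p: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.atleast_1d(np.asarray(self.p, dtype=float))
        self.R = _as_float_matrix(self.R, "R")
        n = self.p.shape[0]
        if self.R.shape != (n, n):
            raise ValidityError("p and R dimensions disagree")
        if np.any(self.p <= 0.0) or np.any(self.p >= 1.0):
            raise ValidityError("p entries must lie strictly in (0, 1)")
        if not np.allclose(self.R, self.R.T, atol=1e-10):
            raise ValidityError("R must be symmetric")
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-10):
            raise ValidityError("R must have unit diagonal")
        if np.any(np.abs(self.R) > 1 + 1e-12):
            raise ValidityError("R entries must lie in [-1, 1]")

    @property
    def n_channels(self) -> int:
        return self.p.shape[0]


@dataclass
class MapperConfig:
    """Knobs of the Mapper shape-graph construction.

    resolution is the number of bins per embedding axis (14 matches the
    published analysis); overlap_fraction is the proportion of a bin's
    width shared with each neighbouring bin.
    """

    k_neighbors: int = 12
    resolution: int = 14
    overlap_fraction: float = 0.5
    cluster_histogram_bins: int = 10

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValidityError("k_neighbors must be >= 1")
        if self.resolution < 2:
            raise ValidityError("resolution must be >= 2")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValidityError("overlap_fraction must lie in [0, 1)")
        if self.cluster_histogram_bins < 2:
            raise ValidityError("cluster_histogram_bins must be >= 2")


@dataclass
class MapperNode:
    node_id: int
    bin_id: tuple
    members: np.ndarray

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=np.int64)


@dataclass
class MapperGraph:
    """Mapper shape graph: bin-cluster nodes, shared-volume edges."""

    nodes: list = field(default_factory=list)
    edges: list = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def degrees(self) -> np.ndarray:
        deg = np.zeros(len(self.nodes), dtype=np.int64)
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def to_networkx(self):
        import networkx as nx
        g = nx.Graph()
        for node in self.nodes:
            g.add_node(node.node_id, bin_id=node.bin_id,
                       members=node.members.tolist())
        g.add_edges_from(self.edges)
        return g
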