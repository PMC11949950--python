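"""Energy landscape analysis core.

Binarization, exact pairwise maximum-entropy model (PMEM/Ising) fitting by
gradient ascent on the enumerated log-likelihood, the full 2**N energy
landscape, local minima, steepest-descent basins of attraction, and the
disconnectivity tree of saddle energies between minima.

State coding: a ±1 pattern sigma maps to index ``s = sum_i b_i 2**i`` with
``b_i = (sigma_i + 1) / 2``; channel 0 is the least-significant bit.

Determinism: binarization thresholds are computed with correctly-rounded
(`math.fsum`) column sums and all PMEM sufficient statistics are exact
integer sums, so fitting and landscape construction are exactly invariant
to any permutation of the input rows — the landscape carries no temporal
information whatsoever.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np

from .datatypes import EnergyLandscape, PmemModel, RoiTimeSeries
from .errors import (CapacityError, ConvergenceError, DegenerateStatisticError,
                     ValidityError)

__all__ = [
    "states_matrix",
    "encode_states",
    "decode_state",
    "binarize",
    "empirical_moments",
    "energy",
    "energies_all",
    "boltzmann_probabilities",
    "fit_pmem",
    "FitInfo",
    "build_landscape",
    "landscape_correlation",
    "same_basin_structure",
]

MAX_ENUM_CHANNELS = 20


def states_matrix(n_channels: int) -> np.ndarray:
    """(2**N, N) matrix of all ±1 patterns; row s decodes state index s."""
    if n_channels > MAX_ENUM_CHANNELS:
        raise CapacityError(f"N={n_channels} exceeds enumeration limit")
    idx = np.arange(2 ** n_channels)
    bits = (idx[:, None] >> np.arange(n_channels)) & 1
    return (2 * bits - 1).astype(float)


def encode_states(b: np.ndarray) -> np.ndarray:
    """Map rows of a ±1 matrix to state indices (channel 0 = LSB)."""
    b = np.asarray(b)
    n = b.shape[-1]
    bits = (b > 0).astype(np.int64)
    return bits @ (1 << np.arange(n, dtype=np.int64))


def decode_state(state: int, n_channels: int) -> np.ndarray:
    """Inverse of :func:`encode_states` for a single index."""
    bits = (int(state) >> np.arange(n_channels)) & 1
    return (2 * bits - 1).astype(np.int8)


def _column_means_exact(data: np.ndarray) -> np.ndarray:
    """Per-column means via fsum: correctly rounded, order-independent."""
    t = data.shape[0]
    return np.array([math.fsum(data[:, j]) / t for j in range(data.shape[1])])


def binarize(x: Union[RoiTimeSeries, np.ndarray]) -> np.ndarray:
    """Threshold each channel at its temporal mean: above -> +1, else -1.

    Values exactly at the threshold map to -1.  The result is invariant to
    any per-channel positive-gain affine rescaling of the input.
    """
    data = x.data if isinstance(x, RoiTimeSeries) else np.asarray(x, dtype=float)
    if data.ndim != 2:
        raise ValidityError("input must be 2-D (time x channels)")
    if np.any(np.ptp(data, axis=0) == 0):
        bad = int(np.flatnonzero(np.ptp(data, axis=0) == 0)[0])
        raise ValidityError(f"channel {bad} is constant; threshold undefined")
    means = _column_means_exact(data)
    return np.where(data > means, 1, -1).astype(np.int8)


def empirical_moments(b: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """First and second sample moments <sigma_i>, <sigma_i sigma_j> of a ±1
    matrix.  Sums of ±1 are exact integers, hence order-independent."""
    b = np.asarray(b, dtype=np.float64)
    t = b.shape[0]
    m1 = b.sum(axis=0) / t
    m2 = (b.T @ b) / t
    return m1, m2


def energies_all(model: PmemModel) -> np.ndarray:
    """Energies of all 2**N states under the Ising form."""
    s = states_matrix(model.n_channels)
    return -(s @ model.h) - 0.5 * ((s @ model.J) * s).sum(axis=1)


def energy(model: PmemModel, state: int) -> float:
    """Energy of one state index."""
    n = model.n_channels
    if not (0 <= int(state) < 2 ** n):
        raise ValidityError(f"state index {state} out of range for N={n}")
    sigma = decode_state(state, n).astype(float)
    return float(-(model.h @ sigma) - 0.5 * sigma @ model.J @ sigma)


def boltzmann_probabilities(model: PmemModel) -> np.ndarray:
    """Normalized state probabilities exp(-E)/Z over all 2**N states."""
    e = energies_all(model)
    w = np.exp(-(e - e.min()))
    return w / w.sum()


@dataclass
class FitInfo:
    """Diagnostics of a PMEM fit: achieved max moment discrepancy,
    iterations used, and the final per-sample log-likelihood."""

    discrepancy: float
    n_iter: int
    log_likelihood: float


def _moment_name(i: int, j: Optional[int] = None) -> str:
    return f"<s{i}>" if j is None else f"<s{i}s{j}>"


def fit_pmem(b: Optional[np.ndarray] = None, *,
             moments: Optional[Tuple[np.ndarray, np.ndarray]] = None,
             tol: float = 1e-6, max_iter: int = 1_000_000,
             learning_rate: float = 0.2) -> Tuple[PmemModel, FitInfo]:
    """Fit the pairwise maximum-entropy model by exact gradient ascent.

    Parameters
    ----------
    b : (T, N) ±1 matrix, optional
        Binarized data.  Alternatively pass precomputed ``moments``.
    moments : (m1, m2) pair, optional
        First- and second-moment targets (m2 with unit diagonal).
    tol : float
        Convergence threshold on the maximum absolute discrepancy between
        model and data moments.
    max_iter : int
        Maximum number of moment-update sweeps.
    learning_rate : float
        Initial step size; halved whenever a step decreases the
        log-likelihood (the step is then retried from the accepted point).

    Returns
    -------
    (PmemModel, FitInfo)

    Raises
    ------
    ConvergenceError
        If the tolerance is not reached, e.g. for boundary moments
        (perfectly aligned or perfectly correlated channels make the
        maximum-likelihood couplings diverge).  The message names the
        worst-matched moment.
    """
    if (b is None) == (moments is None):
        raise ValidityError("pass exactly one of b or moments")
    if b is not None:
        b = np.asarray(b)
        if b.ndim != 2 or b.shape[0] < 1:
            raise ValidityError("b must be a T x N matrix with T >= 1")
        if not np.all(np.abs(b) == 1):
            raise ValidityError("b must contain only ±1")
        m1, m2 = empirical_moments(b)
    else:
        m1, m2 = moments
        m1 = np.asarray(m1, dtype=float)
        m2 = np.asarray(m2, dtype=float)
    n = m1.shape[0]
    if n > MAX_ENUM_CHANNELS:
        raise CapacityError(f"N={n} exceeds enumeration limit")
    m2_off = m2 - np.diag(np.diag(m2))

    s = states_matrix(n)
    h = np.zeros(n)
    j = np.zeros((n, n))
    eps = float(learning_rate)

    def evaluate(h_, j_):
        e = -(s @ h_) - 0.5 * ((s @ j_) * s).sum(axis=1)
        emin = e.min()
        w = np.exp(-(e - emin))
        z = w.sum()
        p = w / z
        logz = np.log(z) - emin
        ll = h_ @ m1 + 0.5 * float((j_ * m2_off).sum()) - logz
        mm1 = p @ s
        mm2 = (s * p[:, None]).T @ s
        return ll, mm1, mm2

    ll, mm1, mm2 = evaluate(h, j)
    g1 = m1 - mm1
    g2 = m2_off - (mm2 - np.diag(np.diag(mm2)))
    disc = max(np.abs(g1).max(), np.abs(g2).max())
    it = 0
    while disc >= tol and it < max_iter and eps > 1e-14:
        h_new = h + eps * g1
        j_new = j + eps * g2
        ll_new, mm1, mm2 = evaluate(h_new, j_new)
        it += 1
        if ll_new < ll - 1e-13:
            eps *= 0.5          # overshoot: retry smaller from accepted point
            continue
        h, j, ll = h_new, j_new, ll_new
        g1 = m1 - mm1
        g2 = m2_off - (mm2 - np.diag(np.diag(mm2)))
        disc = max(np.abs(g1).max(), np.abs(g2).max())
    if disc >= tol:
        flat = np.abs(g2)
        if np.abs(g1).max() >= flat.max():
            i = int(np.argmax(np.abs(g1)))
            worst = _moment_name(i)
        else:
            i, jj = np.unravel_index(int(np.argmax(flat)), flat.shape)
            worst = _moment_name(int(i), int(jj))
        raise ConvergenceError(
            f"PMEM fit did not reach tol={tol:g} in {it} iterations "
            f"(worst moment {worst}, discrepancy {disc:.3g}); boundary "
            "moments such as perfectly correlated channels are unfittable")
    model = PmemModel(h, 0.5 * (j + j.T))
    return model, FitInfo(discrepancy=float(disc), n_iter=it,
                          log_likelihood=float(ll))


class _UnionFind:
    def __init__(self, size: int):
        self.parent = np.arange(size)

    def find(self, a: int) -> int:
        p = self.parent
        root = a
        while p[root] != root:
            root = p[root]
        while p[a] != root:
            p[a], a = root, p[a]
        return root

    def union(self, a: int, b: int) -> int:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra
        return ra


def build_landscape(model: PmemModel) -> EnergyLandscape:
    """Enumerate the landscape: energies, minima, basins, disconnectivity.

    * minima: states strictly below all N single-flip neighbours;
    * basins: steepest descent — repeatedly move to the lowest-energy
      strictly-lower neighbour, ties broken by smallest state index;
    * disconnectivity: states are activated in ascending energy order and
      merged over single-flip edges (union-find); when two components that
      each contain a minimum first join, the activating state's energy is
      the saddle (barrier) between every cross pair of their minima.  The
      resulting barrier matrix is the minimax path energy, an ultrametric.
    """
    n = model.n_channels
    if n > MAX_ENUM_CHANNELS:
        raise CapacityError(f"N={n} exceeds enumeration limit")
    size = 2 ** n
    e = energies_all(model)
    idx = np.arange(size)
    nbr = idx[:, None] ^ (1 << np.arange(n))        # (2**N, N) flip table
    e_nbr = e[nbr]
    is_min = (e[:, None] < e_nbr).all(axis=1)
    minima = np.flatnonzero(is_min)
    if minima.size == 0:
        raise ValidityError(
            "no strict local minimum (all-tied energies); landscape degenerate")

    lower = e_nbr < e[:, None]
    masked = np.where(lower, e_nbr, np.inf)
    best = masked.min(axis=1)
    has_lower = np.isfinite(best)
    if np.any(~has_lower & ~is_min):
        raise ValidityError(
            "exact energy tie blocks steepest descent; landscape degenerate")
    cand = np.where(lower & (e_nbr == best[:, None]), nbr, size)
    nxt = cand.min(axis=1)
    nxt[~has_lower] = idx[~has_lower]
    basin = nxt.copy()
    while True:
        hop = basin[basin]
        if np.array_equal(hop, basin):
            break
        basin = hop

    # disconnectivity by ascending activation + union-find
    order = np.lexsort((idx, e))
    uf = _UnionFind(size)
    active = np.zeros(size, dtype=bool)
    mins_of: dict = {}          # root -> list of minima in component
    tree_of: dict = {}          # root -> nested tree
    n_min = minima.size
    pos = {int(m): k for k, m in enumerate(minima)}
    barriers = np.full((n_min, n_min), np.nan)
    barriers[np.arange(n_min), np.arange(n_min)] = e[minima]
    for sstate in order:
        sstate = int(sstate)
        active[sstate] = True
        root = sstate
        if is_min[sstate]:
            mins_of[root] = [sstate]
            tree_of[root] = sstate
        else:
            mins_of[root] = []
            tree_of[root] = None
        for t in nbr[sstate]:
            t = int(t)
            if not active[t]:
                continue
            ra, rb = uf.find(sstate), uf.find(t)
            if ra == rb:
                continue
            ma, mb = mins_of.pop(ra), mins_of.pop(rb)
            ta, tb = tree_of.pop(ra), tree_of.pop(rb)
            if ma and mb:
                for a in ma:
                    for bmin in mb:
                        ka, kb = pos[a], pos[bmin]
                        barriers[ka, kb] = barriers[kb, ka] = e[sstate]
                new_tree = (float(e[sstate]), ta, tb)
            else:
                new_tree = ta if ta is not None else tb
            new_root = uf.union(ra, rb)
            mins_of[new_root] = ma + mb
            tree_of[new_root] = new_tree
    final_root = uf.find(int(order[0]))
    tree = tree_of.get(final_root)
    return EnergyLandscape(n_channels=n, energies=e, minima=minima,
                           basin_of=basin, barriers=barriers, tree=tree)


def landscape_correlation(e1: EnergyLandscape, e2: EnergyLandscape) -> float:
    """Pearson correlation of the two 2**N energy vectors."""
    if e1.n_channels != e2.n_channels:
        raise ValidityError("landscapes have different channel counts")
    a, b = e1.energies, e2.energies
    if a.std() == 0 or b.std() == 0:
        raise DegenerateStatisticError("zero-variance energies")
    return float(np.corrcoef(a, b)[0, 1])


def same_basin_structure(e1: EnergyLandscape, e2: EnergyLandscape,
                         mode: str = "strict") -> bool:
    """Whether two landscapes share their attractor structure.

    ``mode='strict'`` requires identical minima sets and state-by-state
    identical basin maps; ``mode='minima'`` requires only identical minima
    sets.
    """
    if e1.n_channels != e2.n_channels:
        raise ValidityError("landscapes have different channel counts")
    if mode not in ("strict", "minima"):
        raise ValidityError("mode must be 'strict' or 'minima'")
    if not np.array_equal(e1.minima, e2.minima):
        return False
    if mode == "minima":
        return True
    return bool(np.array_equal(e1.basin_of, e2.basin_of))
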