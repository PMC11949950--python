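"""Basin-label time courses and transition-probability matrices.

Each binary volume is assigned to the basin of attraction containing it;
consecutive labels yield a row-stochastic transition matrix.  Surrogate
dynamics can be projected through the REAL data's basins
(:func:`project_surrogate_dynamics`), which never requires the surrogate's
own landscape to share minima with the real one.
"""
from __future__ import annotations

import numpy as np

from .datatypes import BasinLabelSeries, EnergyLandscape, TransitionMatrix
from .ela import encode_states
from .errors import (DegenerateStatisticError, OffdiagIneligibleError,
                     ValidityError)

__all__ = [
    "label_series",
    "transition_matrix",
    "project_surrogate_dynamics",
    "tm_correlation",
]

#: "More than three basins" eligibility rule for off-diagonal comparisons.
DEFAULT_MIN_BASINS_OFFDIAG = 4


def label_series(b: np.ndarray, landscape: EnergyLandscape) -> BasinLabelSeries:
    """Map every row of a ±1 matrix to its steepest-descent attractor."""
    b = np.asarray(b)
    if b.ndim != 2 or b.shape[1] != landscape.n_channels:
        raise ValidityError(
            f"binary data has {b.shape[-1]} channels, landscape expects "
            f"{landscape.n_channels}")
    labels = landscape.basin_of[encode_states(b)]
    return BasinLabelSeries(labels, landscape)


def transition_matrix(s: BasinLabelSeries) -> TransitionMatrix:
    """Counts and row-normalized probabilities over consecutive label pairs.

    Basins never visited as a source keep an all-zero row; such rows are
    flagged via ``TransitionMatrix.visited`` and excluded pairwise from
    downstream correlations.
    """
    labels = s.labels
    if len(labels) < 2:
        raise ValidityError("need at least two labels (T >= 2)")
    basins = s.landscape.minima
    index = {int(m): k for k, m in enumerate(basins)}
    nb = len(basins)
    counts = np.zeros((nb, nb), dtype=np.int64)
    src = np.fromiter((index[int(v)] for v in labels[:-1]), dtype=np.int64)
    dst = np.fromiter((index[int(v)] for v in labels[1:]), dtype=np.int64)
    np.add.at(counts, (src, dst), 1)
    row = counts.sum(axis=1)
    p = np.zeros((nb, nb))
    nonzero = row > 0
    p[nonzero] = counts[nonzero] / row[nonzero, None]
    return TransitionMatrix(basins=basins, P=p, counts=counts)


def project_surrogate_dynamics(b_surr: np.ndarray,
                               real_landscape: EnergyLandscape
                               ) -> TransitionMatrix:
    """Transition matrix of surrogate data labelled with the REAL basins."""
    return transition_matrix(label_series(b_surr, real_landscape))


def tm_correlation(t1: TransitionMatrix, t2: TransitionMatrix,
                   mode: str = "all",
                   min_basins: int = DEFAULT_MIN_BASINS_OFFDIAG) -> float:
    """Elementwise Pearson correlation between two transition matrices.

    ``mode='all'`` uses every element of rows visited in both matrices;
    ``mode='offdiag'`` drops the diagonal and requires at least
    ``min_basins`` basins (default 4, i.e. "more than three"), raising
    :class:`OffdiagIneligibleError` otherwise.
    """
    if mode not in ("all", "offdiag"):
        raise ValidityError("mode must be 'all' or 'offdiag'")
    if not np.array_equal(t1.basins, t2.basins):
        raise ValidityError("transition matrices index different basin lists")
    nb = len(t1.basins)
    if mode == "offdiag" and nb < min_basins:
        raise OffdiagIneligibleError(
            f"off-diagonal comparison needs >= {min_basins} basins, got {nb}")
    rows = t1.visited & t2.visited
    select = np.broadcast_to(rows[:, None], (nb, nb)).copy()
    if mode == "offdiag":
        np.fill_diagonal(select, False)
    a = t1.P[select]
    b = t2.P[select]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        raise DegenerateStatisticError(
            "transition-matrix correlation undefined (zero variance or "
            "fewer than two comparable elements)")
    return float(np.corrcoef(a, b)[0, 1])
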