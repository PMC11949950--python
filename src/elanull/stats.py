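"""Population-level comparison statistics over (real, surrogate) pairs.

A tidy :func:`comparison_table` (sample id, null kind, metric, value,
eligible flag) is summarized per cell as mean ± sd, and compared with
paired / two-sample t-tests.  Cross-sample energy-landscape similarity
supports the within- vs between-group contrast used to establish that
fitted landscapes are sample- and network-specific.
"""
from __future__ import annotations

import warnings
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import EnergyLandscape
from .ela import landscape_correlation
from .errors import DegenerateStatisticError, ValidityError

__all__ = [
    "comparison_table",
    "summarize",
    "paired_test",
    "two_sample_test",
    "cross_sample_el_similarity",
]

TABLE_COLUMNS = ("sample", "kind", "metric", "value", "eligible")


def comparison_table(rows: Iterable[tuple]) -> pd.DataFrame:
    """Build the tidy table from (sample, kind, metric, value[, eligible])
    tuples; a missing eligible flag defaults to True."""
    records = []
    for row in rows:
        row = tuple(row)
        if len(row) == 4:
            row = row + (True,)
        if len(row) != 5:
            raise ValidityError("rows must have 4 or 5 fields")
        records.append(row)
    df = pd.DataFrame.from_records(records, columns=TABLE_COLUMNS)
    vals = df.loc[df["eligible"], "value"].astype(float)
    if ((vals < -1 - 1e-9) | (vals > 1 + 1e-9)).any():
        raise ValidityError("eligible metric values must lie in [-1, 1]")
    return df


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per (kind, metric): mean, (n-1)-denominator sd, and n over eligible
    rows.  Empty cells are omitted with a warning."""
    eligible = table[table["eligible"]].copy()
    dropped = (set(map(tuple, table[["kind", "metric"]].values))
               - set(map(tuple, eligible[["kind", "metric"]].values)))
    for cell in sorted(dropped):
        warnings.warn(f"cell {cell} has no eligible values; omitted",
                      RuntimeWarning, stacklevel=2)
    grouped = eligible.groupby(["kind", "metric"])["value"]
    out = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
    out["sd"] = out["sd"].fillna(0.0) if len(out) else out["sd"]
    return out


def paired_test(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided paired t-test on matched vectors; returns (t, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValidityError("need two matched 1-D vectors of length >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return 0.0, 1.0
        raise DegenerateStatisticError(
            "paired differences have zero variance but nonzero mean")
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p)


def two_sample_test(a: Sequence[float], b: Sequence[float],
                    welch: bool = False) -> Tuple[float, float]:
    """Two-sided two-sample t-test (pooled variance by default; Welch by
    flag); returns (t, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or len(a) < 2 or len(b) < 2:
        raise ValidityError("need two 1-D vectors of length >= 2 each")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise DegenerateStatisticError(
            "zero pooled variance with unequal means")
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def cross_sample_el_similarity(
        landscapes: Sequence[EnergyLandscape],
        pairing: str = "within",
        other: Optional[Sequence[EnergyLandscape]] = None) -> np.ndarray:
    """Energy-landscape correlations across samples.

    ``pairing='within'`` correlates all unordered pairs of ``landscapes``
    (k(k-1)/2 values); ``pairing='between'`` correlates every landscape in
    ``landscapes`` with every landscape in ``other``.  All landscapes must
    share the channel count; for between-network use the caller supplies
    equal-size channel subsets with a fixed (arbitrary) correspondence.
    """
    if pairing not in ("within", "between"):
        raise ValidityError("pairing must be 'within' or 'between'")
    n_ch = {ls.n_channels for ls in landscapes}
    if other is not None:
        n_ch |= {ls.n_channels for ls in other}
    if len(n_ch) != 1:
        raise ValidityError("all landscapes must share the channel count")
    values: List[float] = []
    if pairing == "within":
        for i in range(len(landscapes)):
            for j in range(i + 1, len(landscapes)):
                values.append(landscape_correlation(landscapes[i],
                                                    landscapes[j]))
    else:
        if other is None:
            raise ValidityError("pairing='between' requires a second list")
        for la in landscapes:
            for lb in other:
                values.append(landscape_correlation(la, lb))
    return np.asarray(values)
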