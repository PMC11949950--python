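"""Delimited-text readers and writers, Newick trees, and run manifests.

All artifacts are plain text: TSV/CSV matrices and tidy tables, a small
structured text format for fitted models, Newick for disconnectivity
trees, and YAML manifests.  Floats are serialized with Python's shortest
round-trip repr, so write -> read is bit-exact.
"""
from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .datatypes import (EnergyLandscape, PmemModel, RoiTimeSeries,
                        TransitionMatrix)
from .ela import decode_state
from .errors import ParseError

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_binary_matrix",
    "write_binary_matrix",
    "write_labels",
    "write_model",
    "read_model",
    "write_landscape",
    "read_landscape",
    "landscape_to_newick",
    "write_transition_matrix",
    "write_manifest",
    "read_manifest",
]

PathLike = Union[str, Path]


def _delimiter_for(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in ("tsv", "csv"):
            raise ParseError(f"unknown format {fmt!r}")
        return "," if fmt == "csv" else "\t"
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_timeseries(path: PathLike, fmt: Optional[str] = None,
                    dt: float = 0.72) -> RoiTimeSeries:
    """Read a header + numeric-body delimited matrix.

    Parse errors (ragged rows, non-numeric cells, duplicate headers) name
    the offending line number.
    """
    path = Path(path)
    delim = _delimiter_for(path, fmt)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        header = [c.strip() for c in header]
        if len(set(header)) != len(header):
            dup = sorted({c for c in header if header.count(c) > 1})
            raise ParseError(f"{path}, line 1: duplicate header(s) {dup}")
        n = len(header)
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != n:
                raise ParseError(
                    f"{path}, line {lineno}: expected {n} fields, "
                    f"got {len(row)}")
            try:
                rows.append([float(c) for c in row])
            except ValueError:
                bad = next(c for c in row if not _is_float(c))
                raise ParseError(
                    f"{path}, line {lineno}: non-numeric cell {bad!r}"
                ) from None
    return RoiTimeSeries(np.asarray(rows, dtype=float), header, dt=dt)


def _is_float(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


def write_timeseries(series: RoiTimeSeries, path: PathLike,
                     fmt: Optional[str] = None) -> None:
    path = Path(path)
    delim = _delimiter_for(path, fmt)
    df = pd.DataFrame(series.data, columns=series.channel_names)
    df.to_csv(path, sep=delim, index=False)


def write_binary_matrix(b: np.ndarray, path: PathLike,
                        channel_names: Optional[list] = None) -> None:
    b = np.asarray(b)
    names = channel_names or [f"roi{i}" for i in range(b.shape[1])]
    pd.DataFrame(b.astype(int), columns=names).to_csv(
        Path(path), sep="\t", index=False)


def read_binary_matrix(path: PathLike) -> np.ndarray:
    series = read_timeseries(path)
    b = series.data
    if not np.all(np.abs(b) == 1):
        raise ParseError(f"{path}: matrix is not ±1-valued")
    return b.astype(np.int8)


def write_labels(labels: np.ndarray, path: PathLike) -> None:
    """Single-column TSV of integer labels (regimes or basins)."""
    pd.DataFrame({"label": np.asarray(labels, dtype=int)}).to_csv(
        Path(path), sep="\t", index=False)


def write_model(model: PmemModel, path: PathLike) -> None:
    """Structured text: an `h` line then N `J` rows, tab-separated."""
    with open(path, "w") as fh:
        fh.write("h\t" + "\t".join(repr(float(v)) for v in model.h) + "\n")
        for row in model.J:
            fh.write("J\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_model(path: PathLike) -> PmemModel:
    h = None
    j_rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if not parts or parts[0] == "":
                continue
            tag, values = parts[0], parts[1:]
            try:
                values = [float(v) for v in values]
            except ValueError:
                raise ParseError(
                    f"{path}, line {lineno}: non-numeric value") from None
            if tag == "h":
                h = np.asarray(values)
            elif tag == "J":
                j_rows.append(values)
            else:
                raise ParseError(f"{path}, line {lineno}: unknown tag {tag!r}")
    if h is None or not j_rows:
        raise ParseError(f"{path}: missing h or J block")
    return PmemModel(h, np.asarray(j_rows))


def _pattern_string(state: int, n: int) -> str:
    return "".join("+" if v > 0 else "-" for v in decode_state(state, n))


def write_landscape(ls: EnergyLandscape, path: PathLike) -> None:
    """2**N-row TSV: state index, ±1 pattern, energy, basin label."""
    n = ls.n_channels
    size = 2 ** n
    df = pd.DataFrame({
        "state": np.arange(size),
        "pattern": [_pattern_string(s, n) for s in range(size)],
        "energy": ls.energies,
        "basin": ls.basin_of,
    })
    df.to_csv(Path(path), sep="\t", index=False)


def read_landscape(path: PathLike) -> EnergyLandscape:
    """Rebuild a landscape from its TSV (barriers/tree not serialized)."""
    df = pd.read_csv(Path(path), sep="\t", float_precision="round_trip")
    energies = df["energy"].to_numpy(dtype=float)
    basin_of = df["basin"].to_numpy(dtype=np.int64)
    n = int(np.log2(len(df)))
    if 2 ** n != len(df):
        raise ParseError(f"{path}: row count {len(df)} is not a power of two")
    minima = np.unique(basin_of)
    return EnergyLandscape(n_channels=n, energies=energies, minima=minima,
                           basin_of=basin_of)


def landscape_to_newick(ls: EnergyLandscape) -> str:
    """Disconnectivity tree as Newick, leaves named `m<state>_<pattern>`.

    Branch lengths are energy drops: for a leaf, parent-saddle energy minus
    the minimum's energy; for an internal merge node, parent-saddle energy
    minus this node's saddle energy.
    """
    n = ls.n_channels

    def height(node) -> float:
        if isinstance(node, tuple):
            return node[0]
        return float(ls.energies[int(node)])

    def render(node, parent_height: Optional[float]) -> str:
        if isinstance(node, tuple):
            e, left, right = node
            body = f"({render(left, e)},{render(right, e)})"
        else:
            state = int(node)
            body = f"m{state}_{_pattern_string(state, n)}"
        if parent_height is None:
            return body
        return f"{body}:{parent_height - height(node):.10g}"

    if ls.tree is None:
        raise ParseError("landscape carries no disconnectivity tree")
    return render(ls.tree, None) + ";"


def write_transition_matrix(tm: TransitionMatrix, path: PathLike) -> None:
    """TSV with basin headers; probability block then count block."""
    names = [f"b{int(b)}" for b in tm.basins]
    prob = pd.DataFrame(tm.P, index=names, columns=names)
    cnt = pd.DataFrame(tm.counts, index=names, columns=names)
    with open(path, "w") as fh:
        fh.write("# probabilities\n")
        prob.to_csv(fh, sep="\t")
        fh.write("# counts\n")
        cnt.to_csv(fh, sep="\t")


def write_manifest(manifest: dict, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def read_manifest(path: PathLike) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
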