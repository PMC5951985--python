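"""Delimited-text interchange for time series, adjacencies and CSD stacks.

Conventions
-----------
Time series: tab-separated, one row per node, first column the node label,
remaining columns the samples; a sidecar ``<path>.meta`` holds ``key = value``
metadata (``dt`` is mandatory on read).  Adjacency: tab-separated square
matrix with a label header row and label first column; ``matrix[i, j]`` is
the influence of node j on node i (row = target, column = source).  CSD
stacks: a single sectioned text file with per-frequency complex matrices.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import CrossSpectralDensity, TimeSeriesSet

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_adjacency",
    "write_adjacency",
    "read_csd",
    "write_csd",
]


class ParseError(ValueError):
    pass


def _meta_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta")


def write_timeseries(
    ts: TimeSeriesSet, path: str | Path, *, metadata: dict | None = None,
    float_fmt: str = "%.10g",
) -> None:
    path = Path(path)
    df = pd.DataFrame(ts.data, index=pd.Index(ts.node_labels, name="node"))
    df.to_csv(path, sep="\t", float_format=float_fmt)
    meta = {"dt": ts.dt, **(metadata or {})}
    with open(_meta_path(path), "w") as fh:
        for k, v in meta.items():
            fh.write(f"{k} = {v}\n")


def read_metadata(path: str | Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    mp = _meta_path(Path(path))
    if mp.exists():
        for line in mp.read_text().splitlines():
            if "=" in line:
                k, v = line.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta


def read_timeseries(path: str | Path, dt: float | None = None) -> TimeSeriesSet:
    """Read a node x sample table; dt comes from the sidecar unless given."""
    path = Path(path)
    meta = read_metadata(path)
    if dt is None:
        if "dt" not in meta:
            raise ParseError(
                f"no sampling interval: pass dt or provide {_meta_path(path).name}"
            )
        dt = float(meta["dt"])
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    data = df.to_numpy()
    if data.dtype == object:
        raise ParseError(f"{path}: non-numeric cells present")
    if np.isnan(data).any():
        r, c = np.argwhere(np.isnan(data))[0]
        raise ParseError(
            f"{path}: missing/NaN value at node {df.index[r]!r}, sample {c} "
            f"(line {r + 2})"
        )
    labels = [str(x) for x in df.index]
    if len(set(labels)) != len(labels):
        raise ParseError(f"{path}: duplicate node labels")
    return TimeSeriesSet(data=data, dt=dt, node_labels=labels)


def write_adjacency(
    net: np.ndarray, path: str | Path, labels: list[str] | None = None,
    float_fmt: str = "%.10g",
) -> None:
    net = np.asarray(net)
    if net.ndim != 2 or net.shape[0] != net.shape[1]:
        raise ValueError("adjacency must be square")
    if labels is None:
        labels = [f"n{i}" for i in range(net.shape[0])]
    df = pd.DataFrame(net, index=labels, columns=labels)
    df.to_csv(Path(path), sep="\t", float_format=float_fmt)


def read_adjacency(path: str | Path) -> tuple[np.ndarray, list[str], bool]:
    """Read a square labeled matrix; returns (matrix, labels, is_symmetric)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path}: empty matrix")
    if df.shape[0] != df.shape[1]:
        raise ParseError(
            f"{path}: matrix is {df.shape[0]}x{df.shape[1]}, not square"
        )
    if [str(i) for i in df.index] != [str(c) for c in df.columns]:
        raise ParseError(f"{path}: row and column labels differ")
    mat = df.to_numpy(dtype=float)
    sym = bool(np.allclose(mat, mat.T))
    return mat, [str(i) for i in df.index], sym


def write_csd(csd: CrossSpectralDensity, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            f"# csdnet cross-spectral density\n"
            f"# nfft = {csd.nfft}\n# n_segments = {csd.n_segments}\n"
            f"# window = {csd.window}\n# overlap = {csd.overlap}\n"
            f"# dt = {csd.dt}\n# n_nodes = {csd.n_nodes}\n"
        )
        for f, mat in zip(csd.frequencies, csd.matrices):
            fh.write(f"# frequency = {float(f)!r}\n")
            for row in mat:
                fh.write("\t".join(repr(complex(z)) for z in row) + "\n")


def read_csd(path: str | Path) -> CrossSpectralDensity:
    path = Path(path)
    header: dict[str, str] = {}
    freqs: list[float] = []
    mats: list[list[list[complex]]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                k, v = k.strip(), v.strip()
                if k == "frequency":
                    freqs.append(float(v))
                    mats.append([])
                else:
                    header[k] = v
            continue
        if not mats:
            raise ParseError(f"{path}:{lineno}: data before any frequency header")
        try:
            mats[-1].append([complex(tok) for tok in line.split("\t")])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if not mats:
        raise ParseError(f"{path}: no frequency slices found")
    return CrossSpectralDensity(
        matrices=np.asarray(mats, dtype=complex),
        frequencies=np.asarray(freqs),
        nfft=int(header.get("nfft", 0)),
        n_segments=int(header.get("n_segments", 0)),
        window=header.get("window", "hann"),
        overlap=float(header.get("overlap", 0.5)),
        dt=float(header.get("dt", 1.0)),
    )
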