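"""Core data containers and delimited-text I/O.

All pipeline stages exchange three objects: a regional timeseries
(time x regions), a weighted structural connectome (square symmetric
adjacency) and a regional scalar map.  Files are plain tab-separated
text with a header row of region labels so that everything stays
readable and diffable; joins between objects are keyed on labels,
never on position.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RegionalTimeseries",
    "Connectome",
    "RegionalMap",
    "read_timeseries",
    "write_timeseries",
    "read_connectome",
    "write_connectome",
    "read_map",
    "write_map",
]

_FLOAT_FMT = "%.17g"


def _default_labels(n: int) -> list[str]:
    return [f"R{i:03d}" for i in range(n)]


@dataclass
class RegionalTimeseries:
    """Multichannel timeseries, rows are timepoints, columns regions."""

    values: np.ndarray
    labels: list[str] = field(default_factory=list)
    tr: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("timeseries must be 2-D (time x regions)")
        if not self.labels:
            self.labels = _default_labels(self.values.shape[1])
        if len(self.labels) != self.values.shape[1]:
            raise ValueError("label count does not match number of regions")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("region labels must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("timeseries contains non-finite values")
        if self.tr <= 0:
            raise ValueError("sampling interval tr must be positive")

    @property
    def n_time(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def zscored(self) -> "RegionalTimeseries":
        """Per-region z-scoring; constant regions are left centred at zero."""
        v = self.values - self.values.mean(axis=0)
        sd = self.values.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        return replace(self, values=v / sd)


@dataclass
class Connectome:
    """Weighted undirected structural network (nonnegative, hollow)."""

    weights: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("connectome weights must be a square matrix")
        if not self.labels:
            self.labels = _default_labels(w.shape[0])
        if len(self.labels) != w.shape[0]:
            raise ValueError("label count does not match matrix size")
        if not np.all(np.isfinite(w)):
            raise ValueError("connectome contains non-finite weights")
        if np.any(w < 0):
            raise ValueError("connectome weights must be nonnegative")
        if np.max(np.abs(w - w.T)) > 1e-8:
            raise ValueError("connectome must be symmetric (tolerance 1e-8)")
        if np.any(np.abs(np.diag(w)) > 0):
            raise ValueError("connectome diagonal must be zero")
        # exact symmetry downstream
        self.weights = (w + w.T) / 2.0
        np.fill_diagonal(self.weights, 0.0)

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def density(self) -> float:
        n = self.n
        return float(np.count_nonzero(np.triu(self.weights, 1)) / (n * (n - 1) / 2))

    def strengths(self) -> np.ndarray:
        return self.weights.sum(axis=0)

    def degrees(self) -> np.ndarray:
        return (self.weights > 0).sum(axis=0)


@dataclass
class RegionalMap:
    """Per-region scalar values (e.g. gene expression or a synthetic gradient)."""

    values: np.ndarray
    labels: list[str] = field(default_factory=list)
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not self.labels:
            self.labels = _default_labels(self.values.size)
        if len(self.labels) != self.values.size:
            raise ValueError("label count does not match number of values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("map contains non-finite values")
        if self.normalized and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("normalized map must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.values.size

    def reordered(self, labels: list[str]) -> "RegionalMap":
        """Return the map aligned to a new label order (label-keyed join)."""
        idx = {lab: i for i, lab in enumerate(self.labels)}
        missing = [lab for lab in labels if lab not in idx]
        if missing:
            raise ValueError(f"labels missing from map: {missing[:5]}")
        order = [idx[lab] for lab in labels]
        return RegionalMap(self.values[order], list(labels), self.normalized)


# ---------------------------------------------------------------------------
# readers / writers


def write_timeseries(ts: RegionalTimeseries, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# tr\t{ts.tr!r}\n")
        df = pd.DataFrame(ts.values, columns=ts.labels)
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_timeseries(path: str | Path) -> RegionalTimeseries:
    path = Path(path)
    tr = 1.0
    with open(path) as fh:
        text = fh.read()
    lines = text.splitlines(keepends=True)
    body_start = 0
    for line in lines:
        if line.startswith("#"):
            body_start += 1
            parts = line[1:].split()
            if len(parts) == 2 and parts[0] == "tr":
                tr = float(parts[1])
        else:
            break
    try:
        df = pd.read_csv(_io.StringIO("".join(lines[body_start:])), sep=r"[\t,]",
                         engine="python")
        values = df.to_numpy(dtype=float)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"{path}: cannot parse timeseries: {exc}") from exc
    return RegionalTimeseries(values, list(df.columns), tr=tr)


def write_connectome(conn: Connectome, path: str | Path) -> None:
    df = pd.DataFrame(conn.weights, index=conn.labels, columns=conn.labels)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_connectome(path: str | Path) -> Connectome:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=r"[\t,]", engine="python", index_col=0)
        values = df.to_numpy(dtype=float)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"{path}: cannot parse connectome: {exc}") from exc
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels disagree")
    return Connectome(values, [str(c) for c in df.columns])


def write_map(m: RegionalMap, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# normalized\t{int(m.normalized)}\n")
        df = pd.DataFrame({"label": m.labels, "value": m.values})
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_map(path: str | Path) -> RegionalMap:
    path = Path(path)
    normalized = False
    with open(path) as fh:
        lines = fh.read().splitlines(keepends=True)
    body_start = 0
    for line in lines:
        if line.startswith("#"):
            body_start += 1
            parts = line[1:].split()
            if len(parts) == 2 and parts[0] == "normalized":
                normalized = bool(int(parts[1]))
        else:
            break
    try:
        df = pd.read_csv(_io.StringIO("".join(lines[body_start:])), sep=r"[\t,]",
                         engine="python")
        values = df["value"].to_numpy(dtype=float)
    except (KeyError, ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"{path}: cannot parse regional map: {exc}") from exc
    return RegionalMap(values, [str(x) for x in df["label"]], normalized)


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
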