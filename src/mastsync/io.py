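"""Ensemble CSV formats, config files and provenance sidecars.

The on-disk interchange format for an ensemble of annual production
series is a rectangular CSV: header row of tree IDs, first column the
year label, one numeric cell per tree-year.  Missing data are not
supported -- surveys with gaps must be handled upstream -- and a load
error names the offending cell.  A JSON sidecar records provenance
(seed, parameters, package version).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "EnsembleSeries",
    "read_ensemble",
    "write_ensemble",
    "write_metadata",
    "load_config",
]


@dataclass
class EnsembleSeries:
    """An (N, T) matrix of per-tree annual production with labels."""

    values: NDArray[np.float64]
    tree_ids: list[str]
    years: list[int]

    @property
    def n_trees(self) -> int:
        return self.values.shape[0]

    @property
    def n_years(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_matrix(
        cls,
        values: ArrayLike,
        tree_ids: Sequence[str] | None = None,
        years: Sequence[int] | None = None,
    ) -> "EnsembleSeries":
        v = np.atleast_2d(np.asarray(values, dtype=float))
        ids = list(tree_ids) if tree_ids is not None else [f"tree{i:03d}" for i in range(v.shape[0])]
        yrs = list(years) if years is not None else list(range(v.shape[1]))
        if len(ids) != v.shape[0] or len(yrs) != v.shape[1]:
            raise ValueError("label lengths do not match matrix shape")
        return cls(values=v, tree_ids=ids, years=[int(y) for y in yrs])


def write_ensemble(path: str | Path, series: EnsembleSeries) -> None:
    """Write the year x tree CSV layout (rows = years)."""
    df = pd.DataFrame(
        series.values.T, index=pd.Index(series.years, name="year"),
        columns=series.tree_ids,
    )
    df.to_csv(path)


def read_ensemble(path: str | Path) -> EnsembleSeries:
    """Load an ensemble CSV, validating shape and cell contents."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")[1:]
    seen: set[str] = set()
    dupes = [h for h in header if h in seen or seen.add(h)]
    if dupes:
        raise ValueError(f"duplicate tree IDs in {path}: {dupes}")
    # round_trip parser: the CSV is the interchange format, so reading
    # back must reproduce the written floats bit for bit
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        year, tree = next(
            (idx, col) for col in df.columns for idx in df.index if bad.at[idx, col]
        )
        raise ValueError(
            f"missing or non-numeric cell in {path}: year {year}, tree {tree!r}"
        )
    return EnsembleSeries(
        values=numeric.to_numpy(dtype=float).T,
        tree_ids=[str(c) for c in df.columns],
        years=[int(y) for y in df.index],
    )


def write_metadata(path: str | Path, meta: Mapping[str, Any]) -> None:
    """JSON provenance sidecar next to a data file."""
    from . import __version__

    record = {"mastsync_version": __version__, **meta}
    Path(path).write_text(json.dumps(record, indent=2, default=_json_default))


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def load_config(path: str | Path) -> dict[str, Any]:
    """Key-value config file (YAML; JSON is a YAML subset) to a dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg
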