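"""CSV ingestion and emission for the zoning pipeline.

All tabular interchange uses UTF-8 CSV with a header row and a leading
``site_id`` column (community, environment, sites, truth tables).  Reading is
strict: duplicated site identifiers, non-numeric abundance or measurement
cells, and missing headers raise ``ValueError`` naming the offending file.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd

#: canonical physicochemical gradient order used throughout the package
GRADIENTS = ["DO", "pH", "WT", "TC", "DOC", "TN", "DTN", "TP", "DTP", "TSi", "DSi"]

# Writers rely on pandas' shortest-roundtrip float repr: lossless on re-read
# and deterministic, so identical in-memory tables serialize to identical
# bytes (the pipeline manifest checksums rely on this).


def _read_indexed(path: str | os.PathLike, kind: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except OSError as exc:
        raise FileNotFoundError(f"cannot read {kind} table {path!r}: {exc}") from exc
    if df.columns.empty or df.columns[0] != "site_id":
        raise ValueError(f"{kind} table {path!r}: first column must be 'site_id'")
    df = df.set_index("site_id")
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"{kind} table {path!r}: duplicated site_id values {dupes}")
    return df


def read_community(path: str | os.PathLike) -> pd.DataFrame:
    """Read a site x taxon abundance table (rows = sites, columns = taxa)."""
    df = _read_indexed(path, "community")
    df = df.apply(pd.to_numeric, errors="raise")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"community table {path!r}: negative abundances present")
    return df


def read_environment(path: str | os.PathLike) -> pd.DataFrame:
    """Read a site x gradient measurement table."""
    df = _read_indexed(path, "environment")
    return df.apply(pd.to_numeric, errors="raise")


def read_sites(path: str | os.PathLike) -> pd.DataFrame:
    """Read site metadata (lon, lat, channel in {mainstream, tributary})."""
    df = _read_indexed(path, "sites")
    if "channel" in df.columns:
        bad = set(df["channel"].unique()) - {"mainstream", "tributary"}
        if bad:
            raise ValueError(f"sites table {path!r}: unknown channel values {sorted(bad)}")
    return df


def read_truth(path: str | os.PathLike) -> pd.Series:
    """Read planted per-site zone labels (synthetic fixtures only)."""
    df = _read_indexed(path, "truth")
    if "zone" not in df.columns:
        raise ValueError(f"truth table {path!r}: missing 'zone' column")
    return df["zone"].astype(int)


def write_table(df: pd.DataFrame, path: str | os.PathLike, index_label: str = "site_id") -> None:
    """Write a table with a named index column and deterministic float repr."""
    df.to_csv(path, index_label=index_label)


def check_matched_sites(frames: Iterable[pd.DataFrame | pd.Series]) -> None:
    """Raise if the site index sets of the given tables differ."""
    frames = list(frames)
    ref = set(frames[0].index)
    for other in frames[1:]:
        diff = ref.symmetric_difference(other.index)
        if diff:
            raise ValueError(f"site sets differ; symmetric difference: {sorted(diff)}")
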