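"""Feature x sample count tables (assembly, validation, TSV round trip).

The canonical in-memory container is a pandas DataFrame of non-negative
integers with feature ids as the index (name ``feature_id``) and sample ids
as columns.  On disk: tab-separated, header row of sample ids, first column
``feature_id``, integer cells.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._io import PathLike
from .reference import ReferenceSet


def validate_count_table(table: pd.DataFrame) -> None:
    if table.index.has_duplicates:
        raise ValueError("duplicate feature ids in count table")
    if table.columns.has_duplicates:
        raise ValueError("duplicate sample ids in count table")
    if not all(np.issubdtype(dt, np.integer) for dt in table.dtypes):
        raise ValueError("count table cells must be integers")
    if (table.to_numpy() < 0).any():
        raise ValueError("count table contains negative entries")


def merge_counts(
    columns: Iterable[tuple[str, Mapping[str, int]]],
    features: ReferenceSet | Sequence[str],
) -> pd.DataFrame:
    """Assemble per-sample count columns into one table.

    Rows cover the full feature universe (absent features filled with 0);
    column order follows input order.  Duplicate sample ids are an error.
    """
    feature_ids = features.ids if isinstance(features, ReferenceSet) else list(features)
    data: dict[str, list[int]] = {}
    for sample_id, col in columns:
        if sample_id in data:
            raise ValueError(f"duplicate sample id {sample_id!r}")
        data[sample_id] = [int(col.get(fid, 0)) for fid in feature_ids]
    table = pd.DataFrame(data, index=pd.Index(feature_ids, name="feature_id"))
    table = table.astype(np.int64)
    validate_count_table(table)
    return table


def write_count_table(table: pd.DataFrame, path: PathLike) -> None:
    validate_count_table(table)
    table.to_csv(path, sep="\t", index_label="feature_id")


def read_count_table(path: PathLike) -> pd.DataFrame:
    """Read a count TSV back; non-integer cells, ragged rows and a missing
    header are hard errors."""
    table = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if table.index.name != "feature_id":
        raise ValueError(
            f"{path}: missing or malformed header (first column must be "
            f"'feature_id', got {table.index.name!r})"
        )
    if table.isna().to_numpy().any():
        raise ValueError(f"{path}: ragged rows or missing cells")
    try:
        table = table.astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-integer count cell ({exc})")
    validate_count_table(table)
    return table
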