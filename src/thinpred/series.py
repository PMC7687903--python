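"""Time-series containers and CSV round-tripping.

Two containers cover everything the package manipulates:

``CountSeries``
    A ground-truth or observed event-count signal: non-negative integers at
    regular intervals. Regular spacing is implicit — only index arithmetic is
    used, never timestamps.

``RealSeries``
    An external (auxiliary) real-valued signal of the same cadence, e.g. a
    search-trend proxy correlated with the count process.

CSV layout is two columns with a header: ``t,count`` for counts and
``t,value`` for real signals, comma-delimited UTF-8.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CountSeries",
    "RealSeries",
    "read_count_series",
    "write_count_series",
    "read_real_series",
    "write_real_series",
]


def _freeze(arr: np.ndarray) -> np.ndarray:
    arr.flags.writeable = False
    return arr


@dataclass(frozen=True)
class CountSeries:
    """Event counts per interval.

    Parameters
    ----------
    values
        Sequence of non-negative integers. Float input is rejected, not
        rounded — silent coercion would mask upstream errors.
    start_index
        Integer time origin (bookkeeping only).
    label
        Free-text name carried through pipelines.
    """

    values: np.ndarray
    start_index: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("a count series must be one-dimensional and non-empty")
        if not np.issubdtype(arr.dtype, np.integer):
            if np.issubdtype(arr.dtype, np.bool_):
                arr = arr.astype(np.int64)
            else:
                raise TypeError(
                    f"count values must be integers, got dtype {arr.dtype}; "
                    "refusing to round floats"
                )
        if np.any(arr < 0):
            raise ValueError("count values must be non-negative")
        object.__setattr__(self, "values", _freeze(arr.astype(np.int64)))

    def __len__(self) -> int:
        return self.values.size

    def with_values(self, values: np.ndarray, label: str | None = None) -> "CountSeries":
        """New series sharing this one's origin, with replaced values."""
        return CountSeries(values, self.start_index, self.label if label is None else label)


@dataclass(frozen=True)
class RealSeries:
    """A real-valued external signal aligned with a count series."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("a real series must be one-dimensional and non-empty")
        if not np.all(np.isfinite(arr)):
            raise ValueError("real series must not contain NaN or infinite values")
        object.__setattr__(self, "values", _freeze(arr))

    def __len__(self) -> int:
        return self.values.size


def read_count_series(path: str | Path, label: str | None = None) -> CountSeries:
    """Read a ``t,count`` CSV into a :class:`CountSeries`."""
    df = pd.read_csv(path)
    if not {"t", "count"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 't' and 'count', got {list(df.columns)}")
    counts = df["count"].to_numpy()
    if not np.issubdtype(counts.dtype, np.integer):
        # pandas may parse an all-integer column as float if blanks are present
        if np.any(~np.isfinite(counts.astype(float))) or np.any(counts != np.floor(counts)):
            raise ValueError(f"{path}: 'count' column must be integer-valued")
        counts = counts.astype(np.int64)
    start = int(df["t"].iloc[0]) if len(df) else 0
    return CountSeries(counts, start_index=start, label=label or str(path))


def write_count_series(x: CountSeries, path: str | Path) -> None:
    t = np.arange(x.start_index, x.start_index + len(x))
    pd.DataFrame({"t": t, "count": x.values}).to_csv(path, index=False)


def read_real_series(path: str | Path, label: str | None = None) -> RealSeries:
    """Read a ``t,value`` CSV into a :class:`RealSeries`."""
    df = pd.read_csv(path)
    if not {"t", "value"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 't' and 'value', got {list(df.columns)}")
    return RealSeries(df["value"].to_numpy(dtype=np.float64), label=label or str(path))


def write_real_series(s: RealSeries, path: str | Path) -> None:
    pd.DataFrame({"t": np.arange(len(s)), "value": s.values}).to_csv(path, index=False)
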