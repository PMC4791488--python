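"""Reading statistic files and writing result tables.

Two statistics-CSV dialects are accepted: a ``statistic`` column holding
test statistics directly, or ``ofv_full`` / ``ofv_reduced`` columns holding
objective-function values in the -2 log-likelihood convention of common
estimation software, in which case ``statistic = ofv_reduced - ofv_full``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_statistics", "write_curve", "read_curve"]


def read_statistics(path) -> np.ndarray:
    """Raw test statistics from a delimited text file (CSV with header)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError("no usable statistics: file is empty")
    cols = {c.strip().lower(): c for c in frame.columns}
    if "statistic" in cols:
        vals = frame[cols["statistic"]].to_numpy(dtype=float)
    elif "ofv_full" in cols and "ofv_reduced" in cols:
        vals = (
            frame[cols["ofv_reduced"]].to_numpy(dtype=float)
            - frame[cols["ofv_full"]].to_numpy(dtype=float)
        )
    else:
        raise ValueError(
            "unknown columns: expected 'statistic' or 'ofv_full'/'ofv_reduced', "
            f"found {list(frame.columns)}"
        )
    if vals.size == 0:
        raise ValueError("no usable statistics: file holds no rows")
    return vals


def write_curve(curve, path) -> None:
    """Power curve as CSV with columns n, lambda, power, ci_low, ci_high."""
    curve.to_frame().to_csv(path, index=False)


def read_curve(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    expected = {"n", "lambda", "power", "ci_low", "ci_high"}
    if not expected.issubset(frame.columns):
        raise ValueError(f"not a power-curve CSV: columns {list(frame.columns)}")
    return frame
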