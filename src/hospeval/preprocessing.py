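"""Tendency treatment: map raw indicators onto a [0, 1] bigger-is-better scale.

Benefit columns use (x - min)/(max - min), cost columns (max - x)/(max - min).
Interval columns score 1 inside the best band [low, high] and decay linearly
towards 0 at the observed extremes; the band comes from the indicator's
reference interval when present and otherwise from mean +/- sample sd of the
observed column.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .indicator_system import IndicatorHierarchy

__all__ = [
    "read_matrix_csv",
    "write_matrix_csv",
    "check_matrix",
    "interval_bounds_from_stats",
    "normalize_column",
    "normalize_matrix",
]

log = logging.getLogger(__name__)


def read_matrix_csv(path: str | Path) -> pd.DataFrame:
    """Read a hospitals x indicators matrix (first column = hospital id)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "hospital_id"
    return df


def write_matrix_csv(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = "hospital_id"
    out.to_csv(path)


def check_matrix(m: pd.DataFrame, h: IndicatorHierarchy) -> None:
    """Validate a raw matrix against the hierarchy leaf set."""
    if m.index.has_duplicates:
        raise ValueError("duplicate hospital ids in matrix")
    missing = set(h.leaf_ids) - set(m.columns)
    extra = set(m.columns) - set(h.leaf_ids)
    if missing or extra:
        raise ValueError(
            f"matrix columns do not match hierarchy leaves "
            f"(missing={sorted(missing)}, unexpected={sorted(extra)})"
        )
    values = m.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("matrix contains non-finite values")


def interval_bounds_from_stats(values) -> tuple[float, float]:
    """Best band (mean - sd, mean + sd) with sample sd (ddof=1).

    Used for interval indicators whose best value is not provided.  An
    all-equal vector yields a degenerate zero-width band (logged).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values to estimate interval bounds")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        log.warning("interval bounds degenerate: all values equal %g", mean)
    return mean - sd, mean + sd


def normalize_column(
    x,
    attribute: str,
    reference: float | tuple[float, float] | None = None,
) -> np.ndarray:
    """Tendency-normalize one indicator column to [0, 1]."""
    x = np.asarray(x, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))

    if attribute == "interval":
        if isinstance(reference, tuple):
            low, high = reference
        else:
            low, high = interval_bounds_from_stats(x)
        out = np.ones_like(x)
        below = x < low
        above = x > high
        if np.any(below):
            span = low - lo
            out[below] = 1.0 - (low - x[below]) / span if span > 0 else 0.0
        if np.any(above):
            span = hi - high
            out[above] = 1.0 - (x[above] - high) / span if span > 0 else 0.0
        return np.clip(out, 0.0, 1.0)

    if hi == lo:
        # constant column: no discriminating information, score everyone 1
        log.warning("degenerate constant column normalized to 1")
        return np.ones_like(x)
    if attribute == "benefit":
        return (x - lo) / (hi - lo)
    if attribute == "cost":
        return (hi - x) / (hi - lo)
    raise ValueError(f"unknown attribute {attribute!r}")


def normalize_matrix(m: pd.DataFrame, h: IndicatorHierarchy) -> pd.DataFrame:
    """Tendency-normalize a raw matrix; columns follow hierarchy leaf order."""
    check_matrix(m, h)
    if len(m) < 2:
        raise ValueError("need at least two hospitals to normalize")
    out = {}
    for leaf in h.leaves:
        out[leaf.id] = normalize_column(
            m[leaf.id].to_numpy(), leaf.attribute, leaf.reference
        )
    return pd.DataFrame(out, index=m.index)
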