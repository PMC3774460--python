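"""Weighted TOPSIS: relative approach degree C_i and ranking.

Operates on the tendency-normalized matrix, so every column is already
benefit-oriented and the ideal / anti-ideal points are the column-wise
max / min of the weighted matrix.  C_i = D- / (D+ + D-); higher is better.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .indicator_system import WeightSet

__all__ = ["TopsisResult", "weighted_topsis", "rank_table"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TopsisResult:
    hospital_ids: tuple[str, ...]
    c: np.ndarray = field(repr=False)  # relative approach degree, [0, 1]
    d_plus: np.ndarray = field(repr=False)  # distance to ideal point
    d_minus: np.ndarray = field(repr=False)  # distance to anti-ideal point
    rank: np.ndarray = field(repr=False)  # 1 = best; stable in input order

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "c": self.c,
                "d_plus": self.d_plus,
                "d_minus": self.d_minus,
                "rank": self.rank,
            },
            index=pd.Index(self.hospital_ids, name="hospital_id"),
        )


def weighted_topsis(
    nm: pd.DataFrame,
    w: WeightSet | np.ndarray,
    *,
    vector_normalize: bool = False,
) -> TopsisResult:
    """Score hospitals by distance to the ideal and anti-ideal points.

    ``vector_normalize`` applies the classical root-sum-square column
    scaling before weighting; it is off by default because tendency
    treatment already maps every column to [0, 1].
    """
    if isinstance(w, WeightSet):
        missing = set(w.leaf_ids) - set(nm.columns)
        if missing:
            raise ValueError(f"matrix lacks weighted columns: {sorted(missing)}")
        x = nm[list(w.leaf_ids)].to_numpy(dtype=float)
        weights = w.weights
    else:
        x = nm.to_numpy(dtype=float)
        weights = np.asarray(w, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("TOPSIS needs at least two hospitals")
    if x.shape[1] != len(weights):
        raise ValueError("weight vector does not match matrix columns")

    if vector_normalize:
        norms = np.sqrt((x**2).sum(axis=0))
        x = x / np.where(norms == 0, 1.0, norms)

    v = x * weights
    ideal = v.max(axis=0)
    anti = v.min(axis=0)
    d_plus = np.sqrt(((v - ideal) ** 2).sum(axis=1))
    d_minus = np.sqrt(((v - anti) ** 2).sum(axis=1))

    denom = d_plus + d_minus
    degenerate = denom == 0
    if np.any(degenerate):
        log.warning(
            "TOPSIS: %d hospital(s) coincide with both ideal points; C_i := 0.5",
            int(degenerate.sum()),
        )
    c = np.where(degenerate, 0.5, d_minus / np.where(degenerate, 1.0, denom))

    # stable rank: descending C, ties keep input order
    order = np.argsort(-c, kind="stable")
    rank = np.empty(len(c), dtype=int)
    rank[order] = np.arange(1, len(c) + 1)

    return TopsisResult(
        hospital_ids=tuple(map(str, nm.index)),
        c=c,
        d_plus=d_plus,
        d_minus=d_minus,
        rank=rank,
    )


def rank_table(r: TopsisResult, path: str | Path | None = None) -> pd.DataFrame:
    """Report rows sorted by rank, C_i printed to 4 decimals."""
    df = pd.DataFrame(
        {
            "hospital_id": r.hospital_ids,
            "c": np.round(r.c, 4),
            "rank": r.rank,
        }
    ).sort_values("rank", kind="stable").reset_index(drop=True)
    if len(np.unique(r.c)) < len(r.c):
        log.info("TOPSIS rank table contains tied C_i values (input-order ties)")
    if path is not None:
        df.to_csv(path, index=False)
    return df
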