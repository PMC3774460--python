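"""Indicator weighting: AHP for the upper levels, entropy for the leaves.

AHP priority vectors are extracted from positive reciprocal pairwise
comparison matrices by power iteration on the principal eigenvector
(geometric-mean weights are available as an alternative), with Saaty's
consistency ratio.  Leaf weights within each level-2 sibling group come
from the entropy weight method applied to the tendency-normalized matrix.
Comprehensive weights are the per-leaf products across the three levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .indicator_system import IndicatorHierarchy, WeightSet

__all__ = [
    "PairwiseMatrix",
    "AhpResult",
    "EntropyState",
    "ahp_weights",
    "geometric_mean_weights",
    "entropy_weights",
    "assemble_weights",
    "entropy_pipeline_weights",
    "CR_THRESHOLD",
    "RANDOM_INDEX",
]

log = logging.getLogger(__name__)

#: Saaty random consistency index by matrix order
RANDOM_INDEX = {
    1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32, 8: 1.41,
    9: 1.45, 10: 1.49, 11: 1.51, 12: 1.48, 13: 1.56, 14: 1.57, 15: 1.59,
}

CR_THRESHOLD = 0.1


@dataclass(frozen=True)
class PairwiseMatrix:
    """Positive reciprocal judgment matrix (Saaty 1-9 scale)."""

    values: np.ndarray = field(repr=False)
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        a = np.asarray(self.values, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("pairwise matrix must be square")
        if np.any(a <= 0):
            raise ValueError("pairwise matrix entries must be positive")
        if not np.allclose(np.diag(a), 1.0, atol=1e-9):
            raise ValueError("pairwise matrix diagonal must be 1")
        if not np.allclose(a * a.T, 1.0, atol=1e-9):
            raise ValueError("pairwise matrix must be reciprocal (a_uv = 1/a_vu)")
        object.__setattr__(self, "values", a)
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"item{i+1}" for i in range(a.shape[0]))
            )
        elif len(self.labels) != a.shape[0]:
            raise ValueError("labels must match matrix order")

    @property
    def order(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_csv(cls, path) -> "PairwiseMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(values=df.to_numpy(dtype=float), labels=tuple(map(str, df.columns)))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)


@dataclass(frozen=True)
class AhpResult:
    weights: np.ndarray
    lambda_max: float
    consistency_index: float
    consistency_ratio: float
    consistent: bool
    labels: tuple[str, ...] = ()


def ahp_weights(
    p: PairwiseMatrix | np.ndarray,
    *,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> AhpResult:
    """Priority vector and consistency ratio of a reciprocal judgment matrix.

    The vector is the normalized principal eigenvector obtained by power
    iteration.  CR > 0.1 sets ``consistent=False`` (a warning flag, not an
    error); CR is defined as 0 for order <= 2.
    """
    if not isinstance(p, PairwiseMatrix):
        p = PairwiseMatrix(values=np.asarray(p, dtype=float))
    a = p.values
    k = p.order
    if not 2 <= k <= 15:
        raise ValueError(f"pairwise matrix order {k} outside supported range 2-15")

    w = np.full(k, 1.0 / k)
    for _ in range(max_iter):
        w_new = a @ w
        w_new /= w_new.sum()
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            break
        w = w_new
    lambda_max = float(np.mean((a @ w) / w))

    if k <= 2:
        ci = 0.0
        cr = 0.0
    else:
        ci = (lambda_max - k) / (k - 1)
        cr = ci / RANDOM_INDEX[k]
    consistent = cr <= CR_THRESHOLD
    if not consistent:
        log.warning("AHP consistency ratio %.4f exceeds %.2f", cr, CR_THRESHOLD)
    return AhpResult(
        weights=w,
        lambda_max=lambda_max,
        consistency_index=float(ci),
        consistency_ratio=float(cr),
        consistent=consistent,
        labels=p.labels,
    )


def geometric_mean_weights(p: PairwiseMatrix | np.ndarray) -> np.ndarray:
    """Alternative AHP weights: normalized row geometric means."""
    if not isinstance(p, PairwiseMatrix):
        p = PairwiseMatrix(values=np.asarray(p, dtype=float))
    g = np.exp(np.mean(np.log(p.values), axis=1))
    return g / g.sum()


@dataclass(frozen=True)
class EntropyState:
    """Intermediate and final quantities of the entropy weight method."""

    shares: np.ndarray  # p_ij, columns sum to 1 (degenerate columns excepted)
    entropy: np.ndarray  # h_j in [0, 1]
    weights: np.ndarray  # w_j, sums to 1
    degenerate_columns: tuple[int, ...] = ()
    uniform_fallback: bool = False


def entropy_weights(nm: pd.DataFrame | np.ndarray) -> EntropyState:
    """Entropy weights for one group of non-negative normalized columns.

    p_ij = x_ij / sum_i x_ij; h_j = -(1/ln n) sum_i p_ij ln p_ij with
    0 * ln 0 := 0; w_j = (1 - h_j) / sum_j (1 - h_j).  A zero-sum column
    carries no information and gets h_j = 1; if every column is
    uninformative the weights fall back to uniform (both cases logged).
    """
    x = np.asarray(nm, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, k = x.shape
    if n < 2:
        raise ValueError("entropy weighting needs at least two subjects")
    if np.any(x < 0):
        raise ValueError("entropy weighting requires non-negative values")

    col_sums = x.sum(axis=0)
    degenerate = np.flatnonzero(col_sums == 0)
    safe_sums = np.where(col_sums == 0, 1.0, col_sums)
    p = x / safe_sums

    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    h = -plogp.sum(axis=0) / np.log(n)
    h[degenerate] = 1.0
    h = np.clip(h, 0.0, 1.0)
    if degenerate.size:
        log.warning("entropy: zero-sum columns %s treated as h=1", degenerate.tolist())

    d = 1.0 - h
    total = d.sum()
    if total <= 0:
        log.warning("entropy: all columns uninformative; uniform-weight fallback")
        return EntropyState(
            shares=p,
            entropy=h,
            weights=np.full(k, 1.0 / k),
            degenerate_columns=tuple(degenerate.tolist()),
            uniform_fallback=True,
        )
    return EntropyState(
        shares=p,
        entropy=h,
        weights=d / total,
        degenerate_columns=tuple(degenerate.tolist()),
    )


def assemble_weights(
    h: IndicatorHierarchy,
    ahp_l1: np.ndarray,
    ahp_l2: dict[str, np.ndarray],
    entropy_l3: dict[tuple[str, str], EntropyState | np.ndarray],
) -> WeightSet:
    """Comprehensive weights: leaf = l1 x l2 x l3 products.

    ``ahp_l1`` follows level-1 node order, ``ahp_l2[l1_name]`` the level-2
    order within that branch, and ``entropy_l3[(l1, l2)]`` the leaf order
    within that level-2 group.
    """
    ahp_l1 = np.asarray(ahp_l1, dtype=float)
    if len(ahp_l1) != len(h.level1):
        raise ValueError(
            f"level-1 weight vector has {len(ahp_l1)} entries, "
            f"hierarchy has {len(h.level1)} level-1 nodes"
        )
    ids: list[str] = []
    weights: list[float] = []
    for i1, l1 in enumerate(h.level1):
        try:
            w2 = np.asarray(ahp_l2[l1.name], dtype=float)
        except KeyError:
            raise ValueError(f"missing level-2 weights for branch {l1.name!r}") from None
        if len(w2) != len(l1.children):
            raise ValueError(f"level-2 weight length mismatch in branch {l1.name!r}")
        for i2, l2 in enumerate(l1.children):
            try:
                state = entropy_l3[(l1.name, l2.name)]
            except KeyError:
                raise ValueError(
                    f"missing leaf weights for branch {l1.name!r}/{l2.name!r}"
                ) from None
            w3 = state.weights if isinstance(state, EntropyState) else np.asarray(state, float)
            if len(w3) != len(l2.leaves):
                raise ValueError(
                    f"leaf weight length mismatch in branch {l1.name!r}/{l2.name!r}"
                )
            for leaf, w in zip(l2.leaves, w3):
                ids.append(leaf.id)
                weights.append(float(ahp_l1[i1]) * float(w2[i2]) * float(w))
    return WeightSet(leaf_ids=tuple(ids), weights=np.asarray(weights))


def entropy_pipeline_weights(
    h: IndicatorHierarchy,
    nm: pd.DataFrame,
    *,
    ahp_l1: np.ndarray | None = None,
    ahp_l2: dict[str, np.ndarray] | None = None,
) -> WeightSet:
    """Comprehensive weights with entropy-derived leaf weights.

    Level-1/2 weights default to the hierarchy's stored (printed) values;
    pass AHP results to override.  Leaf weights are computed per level-2
    sibling group from the normalized matrix.
    """
    l1 = (
        np.asarray(ahp_l1, dtype=float)
        if ahp_l1 is not None
        else np.array([n.weight for n in h.level1])
    )
    l2 = ahp_l2 or {
        n.name: np.array([c.weight for c in n.children]) for n in h.level1
    }
    l3: dict[tuple[str, str], EntropyState] = {}
    for node1 in h.level1:
        for node2 in node1.children:
            cols = [leaf.id for leaf in node2.leaves]
            l3[(node1.name, node2.name)] = entropy_weights(nm[cols])
    return assemble_weights(h, l1, l2, l3)
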