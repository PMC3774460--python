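"""Synthetic hospital data with the statistical structure the pipeline assumes.

Each hospital draws a latent quality score q ~ N(0, 1).  Benefit leaves
increase in q, cost leaves decrease in q, and interval leaves sit closer to
their best band for higher q; indicator-specific location/scale are seeded
from the hierarchy reference values so simulated numbers stay on plausible
scales.  An optional nonlinearity adds a quadratic term in q to a subset of
leaves, creating the regime where a nonlinear surrogate should beat a
linear baseline.

Also provides near-consistent random pairwise judgment matrices for
exercising the AHP stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .indicator_system import IndicatorHierarchy, IndicatorSpec
from .weighting import PairwiseMatrix

__all__ = [
    "SimConfig",
    "simulate_hospitals",
    "simulate_pairwise",
    "nonlinear_benchmark_config",
]


@dataclass(frozen=True)
class SimConfig:
    n_hospitals: int = 14
    seed: int = 0
    signal: float = 1.0  # per-indicator signal strength beta (scale units)
    noise_sd: float = 0.1  # sd of the additive noise (scale units)
    interval_steepness: float = 1.0  # how sharply interval deviations shrink in q
    nonlinear: bool = False
    nonlinear_strength: float = 0.6
    nonlinear_every: int = 3  # every k-th benefit/cost leaf gets the q^2 term

    def __post_init__(self) -> None:
        if self.n_hospitals < 3:
            raise ValueError("need at least three hospitals")
        if self.noise_sd < 0 or self.signal <= 0:
            raise ValueError("signal must be positive, noise_sd non-negative")
        if self.interval_steepness <= 0:
            raise ValueError("interval_steepness must be positive")


def nonlinear_benchmark_config(seed: int = 0) -> SimConfig:
    """The frozen surrogate-comparison regime.

    Threshold-like interval responses (steepness 6) make the score a
    markedly nonlinear function of the indicators, which a logistic-hidden
    network represents natively but a linear baseline cannot; the larger
    sample keeps leave-one-out estimates of the network stable.
    """
    return SimConfig(
        n_hospitals=30, seed=seed, noise_sd=0.02, interval_steepness=6.0
    )


def _leaf_location_scale(leaf: IndicatorSpec) -> tuple[float, float]:
    """Plausible centre and spread for a leaf, from its reference value."""
    ref = leaf.reference
    if isinstance(ref, tuple):
        low, high = ref
        centre = 0.5 * (low + high)
        spread = max(0.5 * (high - low), 0.15 * abs(centre), 0.5)
        return centre, spread
    if ref is not None:
        return float(ref), max(0.15 * abs(ref), 0.5)
    return 0.0, 1.0  # unit scale when no reference exists


def simulate_hospitals(
    cfg: SimConfig, h: IndicatorHierarchy
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate a hospitals x leaves raw matrix; returns (matrix, latent q)."""
    rng = np.random.default_rng(cfg.seed)
    q = rng.standard_normal(cfg.n_hospitals)
    ids = [f"H{i+1}" for i in range(cfg.n_hospitals)]

    cols: dict[str, np.ndarray] = {}
    directional_index = 0  # counts benefit/cost leaves for the nonlinearity
    for leaf in h.leaves:
        centre, scale = _leaf_location_scale(leaf)
        eps = rng.normal(0.0, cfg.noise_sd * scale, size=cfg.n_hospitals)
        if leaf.attribute == "interval":
            # deviation from the best band shrinks as quality grows;
            # high steepness makes the shrinkage threshold-like
            sign = rng.choice([-1.0, 1.0], size=cfg.n_hospitals)
            deviation = scale * sign / (1.0 + np.exp(cfg.interval_steepness * q))
            values = centre + deviation + eps
        else:
            direction = 1.0 if leaf.attribute == "benefit" else -1.0
            values = centre + direction * cfg.signal * scale * q + eps
            if cfg.nonlinear and directional_index % cfg.nonlinear_every == 0:
                values = values + direction * cfg.nonlinear_strength * scale * q**2
            directional_index += 1
        cols[leaf.id] = values

    matrix = pd.DataFrame(cols, index=pd.Index(ids, name="hospital_id"))
    return matrix, q


def simulate_pairwise(
    w, perturbation_sd: float = 0.0, *, seed: int = 0, labels=()
) -> PairwiseMatrix:
    """Reciprocal judgment matrix around target weights w.

    a_uv = (w_u / w_v) * exp(eta_uv) with eta_uv ~ N(0, sd^2) for u < v and
    a_vu = 1 / a_uv, so reciprocity holds exactly; sd = 0 gives a perfectly
    consistent matrix.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("target weights must be positive")
    k = len(w)
    rng = np.random.default_rng(seed)
    a = np.ones((k, k))
    for u in range(k):
        for v in range(u + 1, k):
            eta = rng.normal(0.0, perturbation_sd) if perturbation_sd > 0 else 0.0
            a[u, v] = (w[u] / w[v]) * np.exp(eta)
            a[v, u] = 1.0 / a[u, v]
    return PairwiseMatrix(values=a, labels=tuple(labels) or ())
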