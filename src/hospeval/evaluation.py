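"""Model assessment: leave-one-out cross-validation, hidden-size selection,
a PLSR baseline (NIPALS), and the prediction error table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import neural_net as nn
from .neural_net import MetricsReport, TrainConfig

__all__ = [
    "CVReport",
    "ErrorTable",
    "PLSRModel",
    "loocv",
    "loocv_predictor",
    "select_hidden_size",
    "plsr_fit",
    "plsr_predict",
    "plsr_loocv",
    "select_plsr_components",
    "error_table",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVReport:
    """Leave-one-out results: one held-out prediction per sample.

    ``pooled`` metrics are computed on the concatenated held-out pairs
    (primary); ``fold_mean_absolute_error`` is the average of the per-fold
    absolute errors — with a single test sample per fold, per-fold R^2 is
    undefined, so only pooled R^2 is reported.
    """

    ids: tuple[str, ...]
    observed: np.ndarray = field(repr=False)
    predicted: np.ndarray = field(repr=False)
    pooled: MetricsReport = None
    hidden: int | None = None
    seed: int | None = None
    failed_folds: tuple[int, ...] = ()

    @property
    def complete(self) -> bool:
        return not self.failed_folds

    @property
    def fold_mean_absolute_error(self) -> float:
        return float(np.mean(np.abs(self.observed - self.predicted)))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"hospital_id": self.ids, "observed": self.observed,
             "predicted": self.predicted}
        )


def loocv_predictor(x, y, predictor, *, ids=None) -> CVReport:
    """Generic leave-one-out driver.

    ``predictor(x_train, y_train, x_test, fold_index)`` returns the
    prediction for the single held-out row.  A fold that raises is marked
    failed (prediction NaN) and flagged on the report.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 3:
        raise ValueError("LOOCV needs at least three samples")
    if ids is None:
        ids = [str(i) for i in range(n)]
    preds = np.full(n, np.nan)
    failed: list[int] = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            preds[i] = float(predictor(x[mask], y[mask], x[i : i + 1], i))
        except Exception as exc:  # noqa: BLE001 - fold failure is reported, not fatal
            log.warning("LOOCV fold %d failed: %s", i, exc)
            failed.append(i)
    ok = ~np.isnan(preds)
    pooled = nn.metrics(y[ok], preds[ok]) if ok.sum() >= 2 else None
    if failed:
        log.warning("LOOCV incomplete: %d/%d folds failed", len(failed), n)
    return CVReport(
        ids=tuple(map(str, ids)),
        observed=y,
        predicted=preds,
        pooled=pooled,
        failed_folds=tuple(failed),
    )


def loocv(x, y, hidden: int, cfg: TrainConfig | None = None, *, ids=None) -> CVReport:
    """Leave-one-out assessment of the neural network.

    Deterministic given ``cfg.seed``: fold i trains with seed ``seed + i``.
    """
    cfg = cfg or TrainConfig()

    def predictor(x_tr, y_tr, x_te, fold):
        fold_cfg = replace(cfg, seed=cfg.seed + fold)
        model = nn.fit_model(x_tr, y_tr, hidden, fold_cfg)
        return nn.predict(model, x_te)[0]

    report = loocv_predictor(x, y, predictor, ids=ids)
    return replace(report, hidden=hidden, seed=cfg.seed)


def select_hidden_size(
    x, y, candidates, cfg: TrainConfig | None = None, *, ids=None
) -> tuple[int, pd.DataFrame]:
    """LOOCV sweep over hidden sizes; returns (best size, per-size table).

    Best = highest pooled R^2; ties broken by lower RMSE, then smaller size.
    The table mirrors the published per-size summary (columns: neurons,
    r2, rmse, mape).
    """
    candidates = sorted(set(int(c) for c in candidates))
    if not candidates:
        raise ValueError("no hidden-size candidates supplied")
    rows = []
    for h in candidates:
        rep = loocv(x, y, h, cfg, ids=ids)
        m = rep.pooled
        rows.append(
            {
                "neurons": h,
                "r2": m.r2 if m else np.nan,
                "rmse": m.rmse if m else np.nan,
                "mape": m.mape if m else np.nan,
                "complete": rep.complete,
            }
        )
    table = pd.DataFrame(rows)
    ranked = table.sort_values(
        by=["r2", "rmse", "neurons"], ascending=[False, True, True], kind="stable"
    )
    best = int(ranked.iloc[0]["neurons"])
    return best, table


# ---------------------------------------------------------------------------
# PLSR baseline (PLS1, NIPALS with deflation)


@dataclass(frozen=True)
class PLSRModel:
    n_components: int
    x_mean: np.ndarray = field(repr=False)
    y_mean: float = 0.0
    x_weights: np.ndarray = field(repr=False, default=None)  # W (p, a)
    x_loadings: np.ndarray = field(repr=False, default=None)  # P (p, a)
    y_loadings: np.ndarray = field(repr=False, default=None)  # q (a,)
    coef: np.ndarray = field(repr=False, default=None)  # (p,)


def plsr_fit(x, y, n_components: int) -> PLSRModel:
    """PLS1 regression via NIPALS with deflation; deterministic.

    ``n_components = 0`` gives the mean predictor.  Components are capped
    implicitly by the data: extraction stops early if a residual direction
    vanishes.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = x.shape
    if len(y) != n:
        raise ValueError("X rows and y length differ")
    if np.std(y) == 0:
        raise ValueError("target has zero variance")
    if n_components < 0 or n_components > min(n - 1, p):
        raise ValueError(
            f"n_components must be in [0, min(n-1, p)] = [0, {min(n - 1, p)}]"
        )

    x_mean = x.mean(axis=0)
    y_mean = float(y.mean())
    if n_components == 0:
        return PLSRModel(
            n_components=0, x_mean=x_mean, y_mean=y_mean, coef=np.zeros(p)
        )

    e = x - x_mean
    f = y - y_mean
    ws, ps, qs = [], [], []
    for _ in range(n_components):
        w = e.T @ f
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            log.warning("PLSR: residual X-y covariance vanished; stopping early")
            break
        w /= norm
        t = e @ w
        tt = float(t @ t)
        if tt < 1e-14:
            break
        pvec = e.T @ t / tt
        q = float(f @ t / tt)
        e = e - np.outer(t, pvec)
        f = f - q * t
        ws.append(w)
        ps.append(pvec)
        qs.append(q)

    w_mat = np.column_stack(ws)
    p_mat = np.column_stack(ps)
    q_vec = np.asarray(qs)
    # regression coefficients on centred data: B = W (P'W)^-1 q
    coef = w_mat @ np.linalg.solve(p_mat.T @ w_mat, q_vec)
    return PLSRModel(
        n_components=len(qs),
        x_mean=x_mean,
        y_mean=y_mean,
        x_weights=w_mat,
        x_loadings=p_mat,
        y_loadings=q_vec,
        coef=coef,
    )


def plsr_predict(model: PLSRModel, x) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return model.y_mean + (x - model.x_mean) @ model.coef


def plsr_loocv(x, y, n_components: int, *, ids=None) -> CVReport:
    """Leave-one-out assessment of the PLSR baseline."""

    def predictor(x_tr, y_tr, x_te, fold):
        comp = min(n_components, len(y_tr) - 1, x_tr.shape[1])
        return plsr_predict(plsr_fit(x_tr, y_tr, comp), x_te)[0]

    return loocv_predictor(x, y, predictor, ids=ids)


def select_plsr_components(x, y, *, max_components: int | None = None) -> int:
    """Component count maximizing LOOCV pooled R^2 over 1..min(N-1, 10)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[0]
    upper = min(n - 1, x.shape[1], max_components or 10)
    best_a, best_r2 = 1, -np.inf
    for a in range(1, upper + 1):
        r2 = plsr_loocv(x, y, a).pooled.r2
        if r2 > best_r2 + 1e-12:
            best_a, best_r2 = a, r2
    return best_a


# ---------------------------------------------------------------------------
# error analysis table


@dataclass(frozen=True)
class ErrorTable:
    """Per-hospital observed/predicted comparison with an R^2 footer.

    ``table`` keeps full precision; use :meth:`formatted` for the report
    rounding (absolute error 4 dp, relative error 2 dp).
    """

    table: pd.DataFrame
    r2: float

    def formatted(self) -> pd.DataFrame:
        out = self.table.copy()
        out["observed"] = out["observed"].round(4)
        out["predicted"] = out["predicted"].round(4)
        out["absolute_error"] = out["absolute_error"].round(4)
        out["relative_error_pct"] = out["relative_error_pct"].round(2)
        return out

    def to_csv(self, path: str | Path) -> None:
        self.formatted().to_csv(path, index=False)


def error_table(observed, predicted, ids=None) -> ErrorTable:
    """Absolute (observed - predicted) and relative (100|err|/observed) errors.

    Rows with observed value 0 get a NaN relative error and a warning.
    """
    observed = np.asarray(observed, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted lengths differ")
    if ids is None:
        ids = [f"H{i+1}" for i in range(len(observed))]

    abs_err = observed - predicted
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_err = np.where(
            observed != 0, 100.0 * np.abs(abs_err) / np.abs(observed), np.nan
        )
    if np.any(observed == 0):
        log.warning(
            "error table: %d row(s) with observed 0 have undefined relative error",
            int((observed == 0).sum()),
        )
    table = pd.DataFrame(
        {
            "hospital_id": list(map(str, ids)),
            "observed": observed,
            "predicted": predicted,
            "absolute_error": abs_err,
            "relative_error_pct": rel_err,
        }
    )
    r2 = nn.metrics(observed, predicted).r2 if len(observed) >= 2 else float("nan")
    return ErrorTable(table=table, r2=r2)
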