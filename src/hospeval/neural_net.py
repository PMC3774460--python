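"""Single-hidden-layer feedforward regression network trained from scratch.

Architecture: n inputs -> h logistic hidden units -> 1 linear output.
Features and target are min-max scaled to [0, 1] before training; the
fitted model stores the scaler parameters so predictions come back on the
original target scale.  The default trainer is Levenberg-Marquardt on the
residual Jacobian; plain gradient descent is available as an alternative
backend.  Training stops at the first of: MSE <= goal, epoch budget
exhausted, or gradient norm below the floor.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "ScalerParams",
    "TrainConfig",
    "NetworkModel",
    "MetricsReport",
    "hidden_size_candidates",
    "minmax_scale",
    "apply_scale",
    "inverse_scale",
    "init_network",
    "forward",
    "train",
    "fit_model",
    "predict",
    "metrics",
    "save_model",
    "load_model",
]

log = logging.getLogger(__name__)

MU_MAX = 1e10


def hidden_size_candidates(n: int, m: int) -> list[int]:
    """Candidate hidden-layer sizes ceil(sqrt(n + m) + a) for a = 1..10."""
    if n < 1 or m < 1:
        raise ValueError("layer sizes must be >= 1")
    return [math.ceil(math.sqrt(n + m) + a) for a in range(1, 11)]


# ---------------------------------------------------------------------------
# min-max scaling


@dataclass(frozen=True)
class ScalerParams:
    min_: np.ndarray = field(repr=False)
    max_: np.ndarray = field(repr=False)

    @property
    def span(self) -> np.ndarray:
        return self.max_ - self.min_


def minmax_scale(x: np.ndarray) -> tuple[np.ndarray, ScalerParams]:
    """Scale each feature to [0, 1]; constant features map to 0.5 (logged)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    params = ScalerParams(min_=x.min(axis=0), max_=x.max(axis=0))
    return apply_scale(params, x), params


def apply_scale(params: ScalerParams, x: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    span = params.span
    constant = span == 0
    if np.any(constant):
        log.warning("min-max scaling: %d constant feature(s) mapped to 0.5",
                    int(constant.sum()))
    safe = np.where(constant, 1.0, span)
    out = (x - params.min_) / safe
    out[:, constant] = 0.5
    return out


def inverse_scale(params: ScalerParams, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x * params.span + params.min_


# ---------------------------------------------------------------------------
# model


@dataclass(frozen=True)
class TrainConfig:
    """Training settings (defaults mirror the study's reported values)."""

    damping: float = 0.05  # initial LM damping mu / GD learning rate
    max_epochs: int = 3000
    mse_goal: float = 1e-5
    min_gradient: float = 1e-5
    algorithm: str = "lm"  # "lm" | "gd"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.damping <= 0 or self.mse_goal <= 0 or self.min_gradient <= 0:
            raise ValueError("damping, mse_goal and min_gradient must be positive")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")
        if self.algorithm not in ("lm", "gd"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")


@dataclass(frozen=True)
class NetworkModel:
    """Weights, biases and scalers of a fitted (or initial) network."""

    n_in: int
    n_hidden: int
    w_hidden: np.ndarray = field(repr=False)  # (h, n)
    b_hidden: np.ndarray = field(repr=False)  # (h,)
    w_out: np.ndarray = field(repr=False)  # (h,)
    b_out: float = 0.0
    n_out: int = 1
    x_scaler: ScalerParams | None = None
    y_scaler: ScalerParams | None = None
    trace: tuple[tuple[int, float], ...] = ()

    @property
    def n_params(self) -> int:
        return self.n_hidden * (self.n_in + 2) + 1


def init_network(n_in: int, n_hidden: int, *, seed: int = 0) -> NetworkModel:
    """Random initial network, weights ~ Uniform(-0.5, 0.5) from the seed."""
    rng = np.random.default_rng(seed)
    return NetworkModel(
        n_in=n_in,
        n_hidden=n_hidden,
        w_hidden=rng.uniform(-0.5, 0.5, size=(n_hidden, n_in)),
        b_hidden=rng.uniform(-0.5, 0.5, size=n_hidden),
        w_out=rng.uniform(-0.5, 0.5, size=n_hidden),
        b_out=float(rng.uniform(-0.5, 0.5)),
    )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _pack(model: NetworkModel) -> np.ndarray:
    return np.concatenate(
        [model.w_hidden.ravel(), model.b_hidden, model.w_out, [model.b_out]]
    )


def _unpack(model: NetworkModel, theta: np.ndarray) -> NetworkModel:
    h, n = model.n_hidden, model.n_in
    i = h * n
    return replace(
        model,
        w_hidden=theta[:i].reshape(h, n),
        b_hidden=theta[i : i + h],
        w_out=theta[i + h : i + 2 * h],
        b_out=float(theta[-1]),
    )


def forward(model: NetworkModel, x: np.ndarray) -> np.ndarray:
    """Forward pass on scaled inputs; returns scaled outputs (N,)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.n_in:
        raise ValueError(
            f"expected {model.n_in} input features, got {x.shape[1]}"
        )
    hidden = _sigmoid(x @ model.w_hidden.T + model.b_hidden)
    return hidden @ model.w_out + model.b_out


def _residuals_and_jacobian(
    model: NetworkModel, x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Residuals e = yhat - y and Jacobian de/dtheta, shape (N, P)."""
    hidden = _sigmoid(x @ model.w_hidden.T + model.b_hidden)  # (N, h)
    yhat = hidden @ model.w_out + model.b_out
    e = yhat - y
    dhidden = hidden * (1.0 - hidden) * model.w_out  # (N, h)
    j_w = dhidden[:, :, None] * x[:, None, :]  # (N, h, n)
    jac = np.concatenate(
        [
            j_w.reshape(x.shape[0], -1),
            dhidden,
            hidden,
            np.ones((x.shape[0], 1)),
        ],
        axis=1,
    )
    return e, jac


def _stop_reason(mse: float, grad_norm: float, cfg: TrainConfig) -> str | None:
    if mse <= cfg.mse_goal:
        return "mse_goal"
    if grad_norm <= cfg.min_gradient:
        return "min_gradient"
    return None


def train(
    model: NetworkModel, x: np.ndarray, y: np.ndarray, cfg: TrainConfig
) -> NetworkModel:
    """Train on pre-scaled data; deterministic given the initial model.

    LM step: solve (J'J + mu I) d = J'e; accept when MSE drops (mu /= 10),
    otherwise retry with mu *= 10 up to mu = 1e10.  The recorded trace holds
    (epoch, MSE) at epoch 0 and after every accepted step.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if x.shape[0] != y.shape[0]:
        raise ValueError("X rows and y length differ")
    if x.shape[1] != model.n_in:
        raise ValueError("feature count does not match the model")

    theta = _pack(model)
    e, jac = _residuals_and_jacobian(model, x, y)
    mse = float(np.mean(e**2))
    if not np.isfinite(mse):
        raise FloatingPointError("non-finite loss at initialization")
    trace = [(0, mse)]
    n = len(y)
    mu = cfg.damping

    for epoch in range(1, cfg.max_epochs + 1):
        grad = 2.0 / n * (jac.T @ e)
        reason = _stop_reason(mse, float(np.max(np.abs(grad))), cfg)
        if reason:
            log.debug("training stopped (%s) at epoch %d, mse=%.3e", reason, epoch, mse)
            break

        if cfg.algorithm == "gd":
            theta = theta - cfg.damping * grad
            candidate = _unpack(model, theta)
            e, jac = _residuals_and_jacobian(candidate, x, y)
            mse = float(np.mean(e**2))
            if not np.isfinite(mse):
                raise FloatingPointError("non-finite loss during training")
            trace.append((epoch, mse))
            continue

        # Levenberg-Marquardt
        jtj = jac.T @ jac
        jte = jac.T @ e
        accepted = False
        while mu <= MU_MAX:
            try:
                delta = np.linalg.solve(jtj + mu * np.eye(len(theta)), jte)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            cand_theta = theta - delta
            candidate = _unpack(model, cand_theta)
            e_new, jac_new = _residuals_and_jacobian(candidate, x, y)
            mse_new = float(np.mean(e_new**2))
            if np.isfinite(mse_new) and mse_new < mse:
                theta, e, jac, mse = cand_theta, e_new, jac_new, mse_new
                mu = max(mu / 10.0, 1e-20)
                accepted = True
                break
            mu *= 10.0
        if not accepted:
            log.debug("LM: no acceptable step at epoch %d (mu capped)", epoch)
            break
        trace.append((epoch, mse))

    return replace(_unpack(model, theta), trace=tuple(trace))


def fit_model(
    x_raw: np.ndarray,
    y_raw: np.ndarray,
    n_hidden: int,
    cfg: TrainConfig | None = None,
) -> NetworkModel:
    """Scale features and target to [0, 1], then train a fresh network."""
    cfg = cfg or TrainConfig()
    x_raw = np.atleast_2d(np.asarray(x_raw, dtype=float))
    y_raw = np.asarray(y_raw, dtype=float).ravel()
    xs, x_scaler = minmax_scale(x_raw)
    ys2d, y_scaler = minmax_scale(y_raw[:, None])
    model = init_network(x_raw.shape[1], n_hidden, seed=cfg.seed)
    model = replace(model, x_scaler=x_scaler, y_scaler=y_scaler)
    trained = train(model, xs, ys2d.ravel(), cfg)
    return replace(trained, x_scaler=x_scaler, y_scaler=y_scaler)


def predict(model: NetworkModel, x_raw: np.ndarray) -> np.ndarray:
    """Predict on raw-scale inputs, returning the original target scale."""
    x_raw = np.atleast_2d(np.asarray(x_raw, dtype=float))
    xs = apply_scale(model.x_scaler, x_raw) if model.x_scaler else x_raw
    yhat = forward(model, xs)
    if model.y_scaler is not None:
        yhat = inverse_scale(model.y_scaler, yhat[:, None]).ravel()
    return yhat


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class MetricsReport:
    mse: float
    rmse: float
    r2: float
    mape: float  # percent; terms with y_i = 0 excluded
    observed: np.ndarray = field(repr=False, default=None)
    predicted: np.ndarray = field(repr=False, default=None)
    n_mape_excluded: int = 0


def metrics(y, yhat, *, r2_definition: str = "ss") -> MetricsReport:
    """MSE, RMSE, R^2 and MAPE for paired observed/predicted vectors.

    ``r2_definition``: "ss" gives 1 - SS_res/SS_tot; "corr" gives the
    squared Pearson correlation.  MAPE terms with y_i = 0 are excluded with
    a warning.
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("observed and predicted must be equal-length, n >= 2")

    err = y - yhat
    mse = float(np.mean(err**2))
    ss_res = float(np.sum(err**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if r2_definition == "ss":
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    elif r2_definition == "corr":
        sy, syh = np.std(y), np.std(yhat)
        r2 = float(np.corrcoef(y, yhat)[0, 1] ** 2) if sy > 0 and syh > 0 else 0.0
    else:
        raise ValueError(f"unknown r2_definition {r2_definition!r}")

    nonzero = y != 0
    n_excluded = int((~nonzero).sum())
    if n_excluded:
        log.warning("MAPE: excluding %d term(s) with observed value 0", n_excluded)
    if nonzero.any():
        mape = float(100.0 * np.mean(np.abs(err[nonzero] / y[nonzero])))
    else:
        mape = float("nan")

    return MetricsReport(
        mse=mse,
        rmse=math.sqrt(mse),
        r2=float(r2),
        mape=mape,
        observed=y,
        predicted=yhat,
        n_mape_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# serialization


def save_model(model: NetworkModel, path: str | Path) -> None:
    doc = {
        "n_in": model.n_in,
        "n_hidden": model.n_hidden,
        "n_out": model.n_out,
        "w_hidden": model.w_hidden.tolist(),
        "b_hidden": model.b_hidden.tolist(),
        "w_out": model.w_out.tolist(),
        "b_out": model.b_out,
        "x_scaler": None
        if model.x_scaler is None
        else {"min": model.x_scaler.min_.tolist(), "max": model.x_scaler.max_.tolist()},
        "y_scaler": None
        if model.y_scaler is None
        else {"min": model.y_scaler.min_.tolist(), "max": model.y_scaler.max_.tolist()},
        "trace": [[int(ep), float(m)] for ep, m in model.trace],
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_model(path: str | Path) -> NetworkModel:
    doc = json.loads(Path(path).read_text())

    def scaler(d):
        if d is None:
            return None
        return ScalerParams(min_=np.asarray(d["min"]), max_=np.asarray(d["max"]))

    return NetworkModel(
        n_in=int(doc["n_in"]),
        n_hidden=int(doc["n_hidden"]),
        n_out=int(doc.get("n_out", 1)),
        w_hidden=np.asarray(doc["w_hidden"], dtype=float),
        b_hidden=np.asarray(doc["b_hidden"], dtype=float),
        w_out=np.asarray(doc["w_out"], dtype=float),
        b_out=float(doc["b_out"]),
        x_scaler=scaler(doc.get("x_scaler")),
        y_scaler=scaler(doc.get("y_scaler")),
        trace=tuple((int(ep), float(m)) for ep, m in doc.get("trace", [])),
    )
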