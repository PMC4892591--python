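"""Winter-temperature → growth response surface via a small neural network.

A feed-forward network (2 standardized inputs — previous November–December
mean temperature and current January temperature — one sigmoidal hidden
layer, linear output) is trained by backpropagation on squared error with
early stopping, taking the best of several seeded restarts. The trained
model is evaluated on a temperature grid to obtain a response surface, and
a two-segment continuous piecewise-linear fit of the surface's January-axis
profile estimates the temperature below which growth stops responding
linearly (the sensitivity threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.neural_network import MLPRegressor
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "GrowthANN",
    "ResponseSurface",
    "ThresholdEstimate",
    "response_surface",
    "detect_sensitivity_threshold",
    "estimate_threshold",
]


class GrowthANN(RegressorMixin, BaseEstimator):
    """Feed-forward backpropagation regressor for climate–growth mapping.

    Architecture: n_inputs -> ``hidden`` logistic units -> linear output.
    Inputs and target are standardized internally (invertible); training
    minimizes squared error with early stopping on a validation split and
    keeps the best of ``n_restarts`` seeded restarts by validation score.

    Attributes
    ----------
    model_ : the winning fitted MLP
    x_mean_, x_sd_, y_mean_, y_sd_ : standardization parameters
    x_min_, x_max_ : training envelope per input, for extrapolation flags
    best_loss_curve_ : cumulative-best training loss (non-increasing record)
    validation_score_ : validation R^2 of the winning restart
    """

    def __init__(self, hidden: int = 4, epochs: int = 5000,
                 learning_rate: float = 0.01, n_restarts: int = 5,
                 validation_fraction: float = 0.2, patience: int = 100,
                 tol: float = 1e-7, random_state=None):
        self.hidden = hidden
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.n_restarts = n_restarts
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-D (years x predictors)")
        if len(X) < 30:
            raise ValueError(f"need >= 30 training years, got {len(X)}")
        self.x_mean_ = X.mean(axis=0)
        self.x_sd_ = np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))
        self.y_mean_ = float(y.mean())
        self.y_sd_ = float(y.std()) or 1.0
        self.x_min_, self.x_max_ = X.min(axis=0), X.max(axis=0)
        xz = (X - self.x_mean_) / self.x_sd_
        yz = (y - self.y_mean_) / self.y_sd_
        rng = np.random.default_rng(self.random_state)
        seeds = rng.integers(0, 2**31 - 1, size=self.n_restarts)
        best = None
        for s in seeds:
            mlp = MLPRegressor(
                hidden_layer_sizes=(self.hidden,), activation="logistic",
                solver="adam", learning_rate_init=self.learning_rate,
                max_iter=self.epochs, early_stopping=True,
                validation_fraction=self.validation_fraction,
                n_iter_no_change=self.patience, tol=self.tol,
                random_state=int(s),
            )
            mlp.fit(xz, yz)
            if not np.isfinite(mlp.loss_):
                raise ValueError("non-finite training loss")
            score = mlp.best_validation_score_
            if best is None or score > best[0]:
                best = (score, mlp)
        self.validation_score_ = float(best[0])
        self.model_ = best[1]
        self.best_loss_curve_ = np.minimum.accumulate(np.asarray(self.model_.loss_curve_))
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        xz = (X - self.x_mean_) / self.x_sd_
        return self.model_.predict(xz) * self.y_sd_ + self.y_mean_


@dataclass
class ResponseSurface:
    """Predicted growth index over a (Jan temperature × Nov–Dec temperature) grid."""

    jan_grid: np.ndarray
    novdec_grid: np.ndarray
    values: np.ndarray               # shape (len(novdec_grid), len(jan_grid))
    extrapolated: bool


def response_surface(model: GrowthANN,
                     jan_range: tuple[float, float] = (-11.0, -6.5),
                     novdec_range: tuple[float, float] = (-6.8, -4.0),
                     step: float = 0.1,
                     max_extrapolation: float = 3.0) -> ResponseSurface:
    """Evaluate the trained model on a regular temperature grid.

    Predictor column order is (novdec, jan), matching training. Grids
    reaching beyond ``max_extrapolation`` °C outside the training envelope
    set the ``extrapolated`` flag.
    """
    check_is_fitted(model, "model_")
    jan = np.arange(jan_range[0], jan_range[1] + step / 2, step)
    novdec = np.arange(novdec_range[0], novdec_range[1] + step / 2, step)
    if len(jan) == 0 or len(novdec) == 0:
        raise ValueError("empty evaluation grid")
    jj, nn = np.meshgrid(jan, novdec)
    X = np.column_stack([nn.ravel(), jj.ravel()])
    lo = model.x_min_ - max_extrapolation
    hi = model.x_max_ + max_extrapolation
    extrapolated = bool(np.any(X < lo) or np.any(X > hi))
    values = model.predict(X).reshape(nn.shape)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite prediction on the grid")
    return ResponseSurface(jan, novdec, values, extrapolated)


@dataclass
class ThresholdEstimate:
    breakpoint: float | None         # °C; None when unidentifiable
    slope_below: float
    slope_above: float
    slope_ratio: float               # below / above
    identifiable: bool
    sse_one_segment: float
    sse_two_segment: float


def detect_sensitivity_threshold(surface: ResponseSurface,
                                 min_improvement: float = 0.01) -> ThresholdEstimate:
    """Two-segment continuous piecewise-linear fit of the surface's
    January-axis mean profile; the knot of the best least-squares fit is the
    sensitivity threshold. Flagged unidentifiable when the broken line
    improves on a single line by less than ``min_improvement`` (relative SSE).
    """
    x = surface.jan_grid
    if len(x) < 10:
        raise ValueError("need >= 10 grid points along the scanned axis")
    profile = surface.values.mean(axis=0)
    if len(np.unique(np.round(profile, 12))) < 3:
        raise ValueError("profile has fewer than 3 distinct values")
    # single-line baseline
    A1 = np.column_stack([np.ones_like(x), x])
    coef1, res1, *_ = np.linalg.lstsq(A1, profile, rcond=None)
    sse1 = float(np.sum((A1 @ coef1 - profile) ** 2))
    best = None
    for knot in x[2:-2]:
        A = np.column_stack([np.ones_like(x), x, np.maximum(x - knot, 0.0)])
        coef, *_ = np.linalg.lstsq(A, profile, rcond=None)
        sse = float(np.sum((A @ coef - profile) ** 2))
        if best is None or sse < best[0]:
            best = (sse, float(knot), coef)
    sse2, knot, coef = best
    slope_below = float(coef[1])
    slope_above = float(coef[1] + coef[2])
    ratio = slope_below / slope_above if slope_above != 0 else float("inf")
    identifiable = sse1 > 1e-12 and (sse1 - sse2) / sse1 > min_improvement
    return ThresholdEstimate(
        breakpoint=knot if identifiable else None,
        slope_below=slope_below, slope_above=slope_above, slope_ratio=ratio,
        identifiable=identifiable, sse_one_segment=sse1, sse_two_segment=sse2,
    )


def estimate_threshold(X, y, grid_quantiles: tuple[float, float] = (0.05, 0.95),
                       step: float = 0.1, random_state=None,
                       **ann_params) -> tuple[ThresholdEstimate, GrowthANN]:
    """Train a :class:`GrowthANN` on (novdec, jan) predictors and estimate the
    January-temperature sensitivity threshold from its response surface.

    The surface is evaluated between the ``grid_quantiles`` of each training
    predictor — thresholds are only sought where the data give support, since
    the network output saturates in the unsampled tails.
    """
    import numpy as _np
    X = _np.asarray(X, dtype=float)
    y = _np.asarray(y, dtype=float)
    model = GrowthANN(random_state=random_state, **ann_params).fit(X, y)
    qlo, qhi = grid_quantiles
    nd_lo, nd_hi = _np.quantile(X[:, 0], [qlo, qhi])
    jan_lo, jan_hi = _np.quantile(X[:, 1], [qlo, qhi])
    surf = response_surface(model, (jan_lo, jan_hi), (nd_lo, nd_hi), step)
    return detect_sensitivity_threshold(surf), model


def train_growth_ann(predictors, target, hidden: int = 4, epochs: int = 5000,
                     learning_rate: float = 0.01, seed=None,
                     validation_fraction: float = 0.2) -> GrowthANN:
    """Thin functional wrapper over :class:`GrowthANN`."""
    return GrowthANN(hidden=hidden, epochs=epochs, learning_rate=learning_rate,
                     validation_fraction=validation_fraction,
                     random_state=seed).fit(predictors, target)


def export_growth_ann(model: GrowthANN, path) -> None:
    """Persist weights and standardization parameters as structured text."""
    import json
    check_is_fitted(model, "model_")
    payload = {
        "architecture": {"inputs": int(model.model_.coefs_[0].shape[0]),
                         "hidden": model.hidden, "activation": "logistic",
                         "output": "linear"},
        "weights": [w.tolist() for w in model.model_.coefs_],
        "biases": [b.tolist() for b in model.model_.intercepts_],
        "x_mean": model.x_mean_.tolist(), "x_sd": model.x_sd_.tolist(),
        "y_mean": model.y_mean_, "y_sd": model.y_sd_,
        "x_min": model.x_min_.tolist(), "x_max": model.x_max_.tolist(),
        "validation_r2": model.validation_score_,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
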