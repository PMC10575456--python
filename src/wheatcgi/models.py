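"""Inversion regressors: PLS, random forest, ELM and PSO-ELM.

The extreme learning machine (ELM) is a single-hidden-layer feedforward
network whose input weights and hidden biases are random and fixed; only the
output weights are trained, by solving a linear least-squares problem through
the Moore–Penrose pseudoinverse.  Its particle-swarm-optimized variant
(PSO-ELM) searches the input weights and biases with a swarm that minimizes
training RMSE, removing the accuracy penalty of a single unlucky random
draw.  PLS and random-forest regression delegate to scikit-learn with the
study's fixed hyperparameters (100 trees / minimum leaf 5 for the forest).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class ELMModel:
    """A fitted extreme learning machine for regression.

    Features are min–max scaled to [−1, 1] with the training ranges before
    entering the hidden layer ``H = sigmoid(X W + b)``; predictions are
    ``H @ beta``.
    """

    input_weights: np.ndarray   # (n_features, n_hidden)
    biases: np.ndarray          # (n_hidden,)
    output_weights: np.ndarray  # (n_hidden,)
    feature_min: np.ndarray
    feature_max: np.ndarray
    activation: str = "sigmoid"
    seed: int | None = None

    @property
    def n_hidden(self) -> int:
        return self.input_weights.shape[1]

    def _scale(self, x: np.ndarray) -> np.ndarray:
        span = self.feature_max - self.feature_min
        safe = np.where(span == 0, 1.0, span)
        scaled = 2.0 * (x - self.feature_min) / safe - 1.0
        return np.where(span == 0, 0.0, scaled)

    def hidden(self, x: np.ndarray) -> np.ndarray:
        return _sigmoid(self._scale(x) @ self.input_weights + self.biases)

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        squeeze = x.ndim == 1
        if squeeze:
            x = x[None, :]
        if x.shape[1] != self.input_weights.shape[0]:
            raise ValueError(
                f"expected {self.input_weights.shape[0]} features, got {x.shape[1]}"
            )
        out = self.hidden(x) @ self.output_weights
        return out[0] if squeeze else out

    def to_json(self) -> str:
        doc = {
            "kind": "elm",
            "activation": self.activation,
            "seed": self.seed,
            "input_weights": self.input_weights.tolist(),
            "biases": self.biases.tolist(),
            "output_weights": self.output_weights.tolist(),
            "feature_min": self.feature_min.tolist(),
            "feature_max": self.feature_max.tolist(),
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ELMModel":
        doc = json.loads(text)
        return cls(
            input_weights=np.asarray(doc["input_weights"], dtype=float),
            biases=np.asarray(doc["biases"], dtype=float),
            output_weights=np.asarray(doc["output_weights"], dtype=float),
            feature_min=np.asarray(doc["feature_min"], dtype=float),
            feature_max=np.asarray(doc["feature_max"], dtype=float),
            activation=doc.get("activation", "sigmoid"),
            seed=doc.get("seed"),
        )


def _validate_xy(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if x.ndim != 2:
        raise ValueError("X must be 2-D")
    if x.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    return x, y


def _feature_range(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    fmin, fmax = x.min(axis=0), x.max(axis=0)
    if np.any(fmax == fmin):
        warnings.warn("constant feature(s) scaled to 0", stacklevel=3)
    return fmin, fmax


def _solve_output_weights(h: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.pinv(h) @ y


#: Relative Tikhonov strength of the swarm-optimized output-weight solve.
RIDGE_REL = 1e-4


def _solve_output_weights_ridge(h: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Ridge-stabilized least squares, lambda = RIDGE_REL * sigma_max^2.

    A swarm minimizing training RMSE otherwise steers the hidden layer into
    near-singular configurations whose huge output weights explode on
    validation data; a small relative ridge caps that variance while leaving
    well-conditioned solves essentially untouched.
    """
    u, s, vt = np.linalg.svd(h, full_matrices=False)
    lam = RIDGE_REL * s[0] ** 2
    return vt.T @ ((s / (s ** 2 + lam)) * (u.T @ y))


def fit_elm(
    x: np.ndarray, y: np.ndarray, n_hidden: int = 5, seed: int = 0
) -> ELMModel:
    """Train an ELM with random hidden parameters.

    Input weights and biases are drawn uniformly on [−1, 1] from ``seed``;
    output weights solve ``H beta = y`` in the least-squares sense via the
    pseudoinverse.  The default of 5 hidden sigmoid neurons follows the
    winter-wheat tuning of the source study.
    """
    x, y = _validate_xy(x, y)
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    rng = np.random.default_rng(seed)
    w = rng.uniform(-1.0, 1.0, size=(x.shape[1], n_hidden))
    b = rng.uniform(-1.0, 1.0, size=n_hidden)
    fmin, fmax = _feature_range(x)
    model = ELMModel(
        input_weights=w,
        biases=b,
        output_weights=np.zeros(n_hidden),
        feature_min=fmin,
        feature_max=fmax,
        seed=seed,
    )
    model.output_weights = _solve_output_weights(model.hidden(x), y)
    return model


def predict_elm(model: ELMModel, x: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`ELMModel.predict`."""
    return model.predict(x)


@dataclass
class PSOConfig:
    """Particle-swarm settings (study defaults: 100 iterations, 40 particles,
    accelerations c1 = 2.8 and c2 = 1.3, velocities clamped to [−1, 1]).

    The inertia weight decays linearly from ``inertia[0]`` to ``inertia[1]``
    over the iterations, a standard schedule; positions are clamped to the
    same box as the ELM weight initialization.
    """

    max_iter: int = 100
    n_particles: int = 40
    c1: float = 2.8
    c2: float = 1.3
    inertia: tuple[float, float] = (0.9, 0.4)
    velocity_bounds: tuple[float, float] = (-1.0, 1.0)
    position_bounds: tuple[float, float] = (-1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("accelerations must be positive")
        if self.velocity_bounds[0] >= self.velocity_bounds[1]:
            raise ValueError("velocity bounds must be ordered")
        if self.position_bounds[0] >= self.position_bounds[1]:
            raise ValueError("position bounds must be ordered")


@dataclass
class FitResult:
    """Bookkeeping of a swarm-optimized fit: per-iteration best training
    RMSE (nonincreasing) and the seed used."""

    model: ELMModel
    fitness_trace: np.ndarray
    seed: int


def pso_optimize(
    fitness: Callable[[np.ndarray], float],
    dim: int,
    config: PSOConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Minimize ``fitness`` over a box with a particle swarm.

    Velocity and position updates per particle i and dimension d::

        v <- w v + c1 r1 (p_best - x) + c2 r2 (g_best - x)
        x <- x + v

    with fresh uniform r1, r2 per particle and dimension each iteration,
    clamping both v and x to their bounds.  Returns the global best position
    and the nonincreasing trace of best fitness per iteration.
    """
    cfg = config or PSOConfig()
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    xlo, xhi = cfg.position_bounds
    vlo, vhi = cfg.velocity_bounds
    x = rng.uniform(xlo, xhi, size=(cfg.n_particles, dim))
    v = rng.uniform(vlo, vhi, size=(cfg.n_particles, dim))

    def evaluate(positions: np.ndarray) -> np.ndarray:
        vals = np.empty(positions.shape[0])
        for i, pos in enumerate(positions):
            fi = float(fitness(pos))
            if not np.isfinite(fi):
                raise ValueError(f"non-finite fitness for particle {i}")
            vals[i] = fi
        return vals

    p_best = x.copy()
    p_fit = evaluate(x)
    g_idx = int(np.argmin(p_fit))
    g_best, g_fit = p_best[g_idx].copy(), float(p_fit[g_idx])
    trace = np.empty(cfg.max_iter)

    w0, w1 = cfg.inertia
    for it in range(cfg.max_iter):
        w = w0 + (w1 - w0) * (it / max(cfg.max_iter - 1, 1))
        r1 = rng.uniform(size=(cfg.n_particles, dim))
        r2 = rng.uniform(size=(cfg.n_particles, dim))
        v = w * v + cfg.c1 * r1 * (p_best - x) + cfg.c2 * r2 * (g_best - x)
        v = np.clip(v, vlo, vhi)
        x = np.clip(x + v, xlo, xhi)
        fit = evaluate(x)
        improved = fit < p_fit
        p_best[improved] = x[improved]
        p_fit[improved] = fit[improved]
        best = int(np.argmin(p_fit))
        if p_fit[best] < g_fit:
            g_fit = float(p_fit[best])
            g_best = p_best[best].copy()
        trace[it] = g_fit
    return g_best, trace


def fit_pso_elm(
    x: np.ndarray,
    y: np.ndarray,
    n_hidden: int = 5,
    pso: PSOConfig | None = None,
) -> FitResult:
    """Train an ELM whose hidden parameters are chosen by a particle swarm.

    Each particle encodes the flattened input weights followed by the biases
    (dimension ``n_features * n_hidden + n_hidden``).  A particle's fitness
    is the training RMSE after solving the output weights for its hidden
    layer by pseudoinverse — the same objective the plain ELM leaves to
    chance.
    """
    x, y = _validate_xy(x, y)
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    cfg = pso or PSOConfig()
    n_features = x.shape[1]
    fmin, fmax = _feature_range(x)
    proto = ELMModel(
        input_weights=np.zeros((n_features, n_hidden)),
        biases=np.zeros(n_hidden),
        output_weights=np.zeros(n_hidden),
        feature_min=fmin,
        feature_max=fmax,
        seed=cfg.seed,
    )
    xs = proto._scale(x)

    def unpack(pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        w = pos[: n_features * n_hidden].reshape(n_features, n_hidden)
        b = pos[n_features * n_hidden:]
        return w, b

    def fitness(pos: np.ndarray) -> float:
        w, b = unpack(pos)
        h = _sigmoid(xs @ w + b)
        beta = _solve_output_weights_ridge(h, y)
        resid = h @ beta - y
        return float(np.sqrt(np.mean(resid ** 2)))

    best, trace = pso_optimize(fitness, n_features * n_hidden + n_hidden, cfg)
    w, b = unpack(best)
    proto.input_weights = w
    proto.biases = b
    proto.output_weights = _solve_output_weights_ridge(_sigmoid(xs @ w + b), y)
    return FitResult(model=proto, fitness_trace=trace, seed=cfg.seed)


class SKRegressor:
    """Thin wrapper giving scikit-learn regressors a flat 1-D predict."""

    def __init__(self, estimator):
        self.estimator = estimator

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(np.asarray(x, dtype=float))).ravel()

    def config_json(self) -> str:
        params = {
            k: v for k, v in self.estimator.get_params().items()
            if isinstance(v, (int, float, str, bool, type(None)))
        }
        return json.dumps(
            {"kind": type(self.estimator).__name__, "params": params}, indent=1
        )


def fit_pls(x: np.ndarray, y: np.ndarray, n_components: int = 3) -> SKRegressor:
    """Partial least squares regression with ``n_components`` latent components.

    The component count is capped at the feasible maximum (min of feature
    count and n_samples − 1) with a warning rather than an error.
    """
    x, y = _validate_xy(x, y)
    cap = min(x.shape[1], x.shape[0] - 1)
    if n_components > cap:
        warnings.warn(
            f"n_components reduced from {n_components} to {cap}", stacklevel=2
        )
        n_components = cap
    est = PLSRegression(n_components=n_components)
    est.fit(x, y)
    return SKRegressor(est)


def fit_rf(
    x: np.ndarray,
    y: np.ndarray,
    n_trees: int = 100,
    min_leaf: int = 5,
    seed: int = 0,
) -> SKRegressor:
    """Random-forest regression (study configuration: 100 trees, min leaf 5)."""
    x, y = _validate_xy(x, y)
    est = RandomForestRegressor(
        n_estimators=n_trees, min_samples_leaf=min_leaf, random_state=seed
    )
    est.fit(x, y)
    return SKRegressor(est)
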