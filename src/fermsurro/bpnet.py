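"""Feed-forward 5-h-1 surrogate network with back-propagation training.

The network has one sigmoid hidden layer and, by default, a sigmoid
(saturating) output unit. Inputs are min-max scaled to [0, 1] and targets
to [0.1, 0.9], keeping every unit in its responsive range while leaving
headroom above the best observed response. The saturating output bounds
extrapolation: a surrogate used for condition search cannot then predict
wildly outside the range spanned by its training responses. A linear
output (``output_activation="linear"``) is available for unbounded
regression. Training is batch gradient descent with momentum and an
adaptive learning rate on the mean squared error, stopping at a goal MSE
or a maximum epoch count.

`hidden_neuron_scan` implements the structure-selection protocol: for each
candidate hidden size, repeatedly split the runs into training and test
subsets, train, and record the 2-norm of training and prediction residuals
(on the scaled output space); the recommended size minimises the mean
prediction error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "Scaler",
    "MLPParams",
    "NetworkConfig",
    "TrainConfig",
    "TrainingDiverged",
    "init_params",
    "forward",
    "train_bp",
    "hidden_neuron_scan",
    "BPNetRegressor",
]


class TrainingDiverged(RuntimeError):
    def __init__(self, epoch: int, last_mse: float):
        self.epoch = epoch
        self.last_mse = last_mse
        super().__init__(
            f"training diverged at epoch {epoch}; last finite MSE {last_mse:.3e}"
        )


@dataclass
class Scaler:
    """Min-max scaler for inputs (to [0, 1]) and target (to [0.1, 0.9])."""

    x_min: np.ndarray
    x_max: np.ndarray
    y_min: float
    y_max: float
    x_interval: tuple[float, float] = (0.0, 1.0)
    y_interval: tuple[float, float] = (0.1, 0.9)

    @classmethod
    def fit(
        cls,
        X,
        y,
        x_interval=(0.0, 1.0),
        y_interval=(0.1, 0.9),
    ) -> "Scaler":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        x_min, x_max = X.min(axis=0), X.max(axis=0)
        if np.any(x_max <= x_min):
            bad = np.nonzero(x_max <= x_min)[0]
            raise ValueError(f"constant input column(s): {bad.tolist()}")
        y_min, y_max = float(y.min()), float(y.max())
        if y_max <= y_min:
            raise ValueError("constant target; nothing to scale")
        return cls(x_min, x_max, y_min, y_max, tuple(x_interval), tuple(y_interval))

    def transform_x(self, X) -> np.ndarray:
        lo, hi = self.x_interval
        X = np.asarray(X, dtype=float)
        return lo + (X - self.x_min) / (self.x_max - self.x_min) * (hi - lo)

    def inverse_x(self, Xs) -> np.ndarray:
        lo, hi = self.x_interval
        return self.x_min + (np.asarray(Xs) - lo) / (hi - lo) * (self.x_max - self.x_min)

    def transform_y(self, y) -> np.ndarray:
        lo, hi = self.y_interval
        return lo + (np.asarray(y, dtype=float) - self.y_min) / (
            self.y_max - self.y_min
        ) * (hi - lo)

    def inverse_y(self, ys) -> np.ndarray:
        lo, hi = self.y_interval
        return self.y_min + (np.asarray(ys) - lo) / (hi - lo) * (self.y_max - self.y_min)

    def to_dict(self) -> dict:
        return {
            "x_min": self.x_min.tolist(),
            "x_max": self.x_max.tolist(),
            "y_min": self.y_min,
            "y_max": self.y_max,
            "x_interval": list(self.x_interval),
            "y_interval": list(self.y_interval),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scaler":
        return cls(
            np.asarray(d["x_min"], dtype=float),
            np.asarray(d["x_max"], dtype=float),
            float(d["y_min"]),
            float(d["y_max"]),
            tuple(d["x_interval"]),
            tuple(d["y_interval"]),
        )


@dataclass(frozen=True)
class NetworkConfig:
    n_input: int = 5
    n_hidden: int = 9
    n_output: int = 1

    def __post_init__(self):
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")

    @property
    def n_genes(self) -> int:
        """Length of the flattened (W1, b1, W2, b2) parameter vector."""
        return (
            self.n_hidden * self.n_input
            + self.n_hidden
            + self.n_output * self.n_hidden
            + self.n_output
        )


@dataclass(frozen=True)
class TrainConfig:
    """Back-propagation settings.

    With ``adaptive=True`` (default) the learning rate follows the classic
    variable-learning-rate scheme: grow by ``lr_inc`` while the error
    falls, and on an error jump above ``max_perf_inc`` retract the step,
    shrink the rate by ``lr_dec`` and reset the momentum. ``adaptive=False``
    gives plain fixed-rate gradient descent with momentum.
    """

    max_epoch: int = 2000
    goal: float = 1e-6
    learning_rate: float = 0.05
    momentum: float = 0.9
    adaptive: bool = True
    lr_inc: float = 1.05
    lr_dec: float = 0.7
    max_perf_inc: float = 1.04
    seed: int = 0

    def __post_init__(self):
        if self.max_epoch < 1:
            raise ValueError("max_epoch must be >= 1")
        if self.goal <= 0:
            raise ValueError("goal must be > 0")


def _sigmoid(z):
    # overflow in exp is benign: exp(-z) -> inf gives sigmoid -> 0 exactly
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-z))


_ACTIVATIONS = {
    "sigmoid": (_sigmoid, lambda a: a * (1.0 - a)),
    "linear": (lambda z: z, lambda a: np.ones_like(a)),
}


@dataclass
class MLPParams:
    """Weights and thresholds of the 1-hidden-layer perceptron."""

    W1: np.ndarray  # hidden x input
    b1: np.ndarray  # hidden
    W2: np.ndarray  # output x hidden
    b2: np.ndarray  # output
    hidden_activation: str = "sigmoid"
    output_activation: str = "sigmoid"

    @property
    def config(self) -> NetworkConfig:
        return NetworkConfig(self.W1.shape[1], self.W1.shape[0], self.W2.shape[0])

    def flatten(self) -> np.ndarray:
        return np.concatenate(
            [self.W1.ravel(), self.b1.ravel(), self.W2.ravel(), self.b2.ravel()]
        )

    @classmethod
    def unflatten(
        cls,
        genes: np.ndarray,
        config: NetworkConfig,
        hidden_activation: str = "sigmoid",
        output_activation: str = "sigmoid",
    ) -> "MLPParams":
        genes = np.asarray(genes, dtype=float).ravel()
        if genes.size != config.n_genes:
            raise ValueError(
                f"expected {config.n_genes} genes for {config}, got {genes.size}"
            )
        h, i, o = config.n_hidden, config.n_input, config.n_output
        k = 0
        W1 = genes[k : k + h * i].reshape(h, i); k += h * i
        b1 = genes[k : k + h]; k += h
        W2 = genes[k : k + o * h].reshape(o, h); k += o * h
        b2 = genes[k : k + o]
        return cls(W1, b1.copy(), W2, b2.copy(), hidden_activation, output_activation)

    def to_dict(self) -> dict:
        return {
            "n_input": self.config.n_input,
            "n_hidden": self.config.n_hidden,
            "n_output": self.config.n_output,
            "hidden_activation": self.hidden_activation,
            "output_activation": self.output_activation,
            "genes": self.flatten().tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPParams":
        cfg = NetworkConfig(d["n_input"], d["n_hidden"], d["n_output"])
        return cls.unflatten(
            np.asarray(d["genes"], dtype=float),
            cfg,
            d.get("hidden_activation", "sigmoid"),
            d.get("output_activation", "sigmoid"),
        )


def init_params(
    config: NetworkConfig,
    seed: int,
    bound: float = 1.0,
    output_activation: str = "sigmoid",
) -> MLPParams:
    """Uniform [-bound, bound] initialisation, reproducible from the seed."""
    rng = np.random.default_rng(seed)
    return MLPParams.unflatten(
        rng.uniform(-bound, bound, size=config.n_genes),
        config,
        output_activation=output_activation,
    )


def forward(params: MLPParams, X) -> np.ndarray:
    """Network output for one input vector or a matrix of rows (scaled space)."""
    act_h, _ = _ACTIVATIONS[params.hidden_activation]
    act_o, _ = _ACTIVATIONS[params.output_activation]
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    X2 = np.atleast_2d(X)
    if X2.shape[1] != params.W1.shape[1]:
        raise ValueError(
            f"input has {X2.shape[1]} features, network expects {params.W1.shape[1]}"
        )
    a = act_h(X2 @ params.W1.T + params.b1)
    out = act_o(a @ params.W2.T + params.b2)
    y = out[:, 0] if params.W2.shape[0] == 1 else out
    return float(y[0]) if single and np.ndim(y) == 1 and y.size == 1 else y


def train_bp(
    params: MLPParams,
    X,
    y,
    cfg: TrainConfig | None = None,
) -> tuple[MLPParams, np.ndarray]:
    """Batch gradient descent with momentum on the MSE (scaled space).

    Returns trained parameters and the per-epoch MSE trace (the entry at
    index 0 is the pre-training MSE). Raises :class:`TrainingDiverged` if
    the loss becomes non-finite.
    """
    cfg = cfg or TrainConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if len(X) != len(y):
        raise ValueError("X and y row counts differ")
    act_h, dact_h = _ACTIVATIONS[params.hidden_activation]
    act_o, dact_o = _ACTIVATIONS[params.output_activation]
    W1, b1 = params.W1.copy(), params.b1.copy()
    W2, b2 = params.W2.copy(), params.b2.copy()
    vW1 = np.zeros_like(W1); vb1 = np.zeros_like(b1)
    vW2 = np.zeros_like(W2); vb2 = np.zeros_like(b2)
    n = len(y)
    trace = []
    lr, mu = cfg.learning_rate, cfg.momentum
    prev = None  # snapshot for step retraction under adaptive lr
    prev_mse = np.inf
    for epoch in range(cfg.max_epoch + 1):
        a = act_h(X @ W1.T + b1)            # n x h
        out = act_o(a @ W2.T + b2)[:, 0]    # n
        err = out - y
        with np.errstate(over="ignore"):
            mse = float(np.mean(err**2))
        if not np.isfinite(mse):
            raise TrainingDiverged(epoch, trace[-1] if trace else np.nan)
        if cfg.adaptive and prev is not None and mse > prev_mse * cfg.max_perf_inc:
            # error jumped: retract the step, damp the rate, kill momentum
            W1, b1, W2, b2 = (m.copy() for m in prev)
            lr *= cfg.lr_dec
            vW1[:] = 0; vb1[:] = 0; vW2[:] = 0; vb2[:] = 0
            a = act_h(X @ W1.T + b1)
            out = act_o(a @ W2.T + b2)[:, 0]
            err = out - y
            mse = prev_mse
        elif cfg.adaptive and prev is not None and mse < prev_mse:
            lr *= cfg.lr_inc
        trace.append(mse)
        if mse <= cfg.goal or epoch == cfg.max_epoch:
            break
        # backward pass
        delta_o = (2.0 / n) * err * dact_o(out)             # n
        gW2 = delta_o[None, :] @ a                          # 1 x h
        gb2 = np.array([delta_o.sum()])
        delta_h = np.outer(delta_o, W2[0]) * dact_h(a)      # n x h
        gW1 = delta_h.T @ X
        gb1 = delta_h.sum(axis=0)
        prev = (W1.copy(), b1.copy(), W2.copy(), b2.copy())
        prev_mse = mse
        vW2 = mu * vW2 - lr * gW2; W2 = W2 + vW2
        vb2 = mu * vb2 - lr * gb2; b2 = b2 + vb2
        vW1 = mu * vW1 - lr * gW1; W1 = W1 + vW1
        vb1 = mu * vb1 - lr * gb1; b1 = b1 + vb1
    trained = MLPParams(
        W1, b1, W2, b2, params.hidden_activation, params.output_activation
    )
    return trained, np.asarray(trace)


def hidden_neuron_scan(
    X,
    y,
    h_range=range(3, 13),
    n_train: int = 13,
    n_test: int = 2,
    replicates: int = 10,
    seed: int = 0,
    train_config: TrainConfig | None = None,
) -> tuple[pd.DataFrame, int]:
    """Scan hidden-layer sizes by repeated train/test splitting.

    For each hidden size ``h`` and each replicate: draw ``n_train`` runs
    without replacement as the training set (remainder is the test set),
    scale on the training portion, train from a fresh random
    initialisation, and record the 2-norms of the training- and test-set
    residual vectors in scaled output space. Errors are averaged over
    replicates; the recommended size is the ``argmin`` of the mean
    prediction (test) error.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n_test <= 0:
        raise ValueError("n_test must be >= 1 (prediction error undefined otherwise)")
    if n_train + n_test != n:
        raise ValueError(f"n_train + n_test must equal the sample count {n}")
    h_range = list(h_range)
    if not h_range:
        raise ValueError("h_range is empty")
    base = TrainConfig() if train_config is None else train_config
    rng = np.random.default_rng(seed)
    rows = []
    for h in h_range:
        tr_errs, te_errs = [], []
        for rep in range(replicates):
            perm = rng.permutation(n)
            tr, te = perm[:n_train], perm[n_train:]
            scaler = Scaler.fit(X[tr], y[tr])
            Xs_tr, ys_tr = scaler.transform_x(X[tr]), scaler.transform_y(y[tr])
            Xs_te, ys_te = scaler.transform_x(X[te]), scaler.transform_y(y[te])
            p0 = init_params(
                NetworkConfig(X.shape[1], h, 1),
                seed=int(rng.integers(2**31 - 1)),
            )
            trained, _ = train_bp(p0, Xs_tr, ys_tr, base)
            tr_errs.append(float(np.linalg.norm(forward(trained, Xs_tr) - ys_tr)))
            te_errs.append(float(np.linalg.norm(forward(trained, Xs_te) - ys_te)))
        rows.append(
            {
                "n_hidden": h,
                "training_error": float(np.mean(tr_errs)),
                "prediction_error": float(np.mean(te_errs)),
            }
        )
    table = pd.DataFrame(rows)
    best = int(table.loc[table["prediction_error"].idxmin(), "n_hidden"])
    return table, best


class BPNetRegressor(BaseEstimator, RegressorMixin):
    """GA-initialised back-propagation network (scikit-learn estimator).

    ``fit`` scales the data, optionally runs a real-coded genetic algorithm
    over the flattened weights (fitness = sum of absolute training errors),
    then refines by back-propagation. ``init="random"`` skips the GA;
    ``refine_bp=False`` keeps the GA's best weights untrained.

    Attributes (after fit): ``params_``, ``scaler_``, ``loss_trace_``,
    ``ga_run_`` (None without GA), ``n_features_in_``.
    """

    def __init__(
        self,
        n_hidden: int = 9,
        max_epoch: int = 2000,
        goal: float = 1e-6,
        learning_rate: float = 0.05,
        momentum: float = 0.9,
        init: str = "ga",
        refine_bp: bool = True,
        output_activation: str = "sigmoid",
        weight_bound: float = 3.0,
        ga_maxgen: int = 50,
        ga_sizepop: int = 20,
        ga_pcross: float = 0.8,
        ga_pmutation: float = 0.05,
        random_state: int = 0,
    ):
        self.n_hidden = n_hidden
        self.max_epoch = max_epoch
        self.goal = goal
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.init = init
        self.refine_bp = refine_bp
        self.output_activation = output_activation
        self.weight_bound = weight_bound
        self.ga_maxgen = ga_maxgen
        self.ga_sizepop = ga_sizepop
        self.ga_pcross = ga_pcross
        self.ga_pmutation = ga_pmutation
        self.random_state = random_state

    def fit(self, X, y):
        from . import ga  # local import to avoid a cycle

        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        self.n_features_in_ = X.shape[1]
        cfg = NetworkConfig(X.shape[1], self.n_hidden, 1)
        scaler = Scaler.fit(X, y)
        Xs, ys = scaler.transform_x(X), scaler.transform_y(y)
        self.ga_run_ = None
        if self.init == "ga":
            fitness = ga.fitness_weights(
                cfg, Xs, ys, output_activation=self.output_activation
            )
            gacfg = ga.GAConfig(
                maxgen=self.ga_maxgen,
                sizepop=self.ga_sizepop,
                pcross=self.ga_pcross,
                pmutation=self.ga_pmutation,
                bounds=np.tile(
                    [-self.weight_bound, self.weight_bound], (cfg.n_genes, 1)
                ),
                mode="minimize",
                seed=self.random_state,
            )
            run = ga.run_ga(fitness, gacfg)
            params = MLPParams.unflatten(
                run.best_individual, cfg, output_activation=self.output_activation
            )
            self.ga_run_ = run
        elif self.init == "random":
            params = init_params(
                cfg, seed=self.random_state, output_activation=self.output_activation
            )
        else:
            raise ValueError("init must be 'ga' or 'random'")
        if self.refine_bp:
            params, trace = train_bp(
                params,
                Xs,
                ys,
                TrainConfig(
                    max_epoch=self.max_epoch,
                    goal=self.goal,
                    learning_rate=self.learning_rate,
                    momentum=self.momentum,
                    seed=self.random_state,
                ),
            )
        else:
            err = forward(params, Xs) - ys
            trace = np.array([float(np.mean(err**2))])
        self.params_ = params
        self.scaler_ = scaler
        self.loss_trace_ = trace
        return self

    def predict(self, X):
        check_is_fitted(self, "params_")
        Xs = self.scaler_.transform_x(np.atleast_2d(np.asarray(X, dtype=float)))
        return self.scaler_.inverse_y(forward(self.params_, Xs))

    def maximize(self, bounds, maxgen=100, sizepop=80, pcross=0.4, pmutation=0.05,
                 seed: int | None = None):
        """GA search for the input maximising the network's prediction.

        Returns ``(argmax (physical units), max predicted value)``.
        """
        from . import ga

        check_is_fitted(self, "params_")
        fitness = ga.fitness_conditions(self.params_, self.scaler_)
        cfg = ga.GAConfig(
            maxgen=maxgen,
            sizepop=sizepop,
            pcross=pcross,
            pmutation=pmutation,
            bounds=np.asarray(bounds, dtype=float),
            mode="maximize",
            seed=self.random_state if seed is None else seed,
        )
        run = ga.run_ga(fitness, cfg)
        return run.best_individual, run.best_fitness
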