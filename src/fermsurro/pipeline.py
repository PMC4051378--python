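"""End-to-end protocol: design -> regression baseline -> ANN scan -> GA-ANN
-> condition search -> verification arithmetic, plus the bioassay formula
and a synthetic response-surface generator.

Unit conventions: the algicidal ratio (Y1) lives on fraction scale
internally (0.8957, displayed as 89.57 %) and the dry mycelial weight (Y2)
in g per 100 mL broth. `verification_metrics` works on whatever scale its
three inputs share.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bpnet import BPNetRegressor, TrainConfig, hidden_neuron_scan
from .design import DesignTable, FactorSpec, generate_uniform_table, map_levels
from .regress import PolyModel, QuadraticSurface, unconstrained_factors

log = logging.getLogger("fermsurro")

__all__ = [
    "Dataset",
    "SynthSpec",
    "algicidal_ratio",
    "verification_metrics",
    "generate_synthetic",
    "run_protocol",
    "ProtocolResult",
    "comparison_table",
]


@dataclass
class Dataset:
    """Runs x factors with the two fermentation responses.

    ``y1`` is the algicidal ratio on fraction scale; ``y2`` the dry
    mycelial weight in g/100 mL. Observed y1 may be negative (growth
    promotion) but never exceeds 1; y2 is nonnegative.
    """

    X: np.ndarray
    y1: np.ndarray | None = None
    y2: np.ndarray | None = None
    run_labels: list[str] = field(default_factory=list)
    factor_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = len(self.X)
        for attr in ("y1", "y2"):
            v = getattr(self, attr)
            if v is not None:
                v = np.asarray(v, dtype=float).ravel()
                if len(v) != n:
                    raise ValueError(f"{attr} length {len(v)} != {n} runs")
                setattr(self, attr, v)
        if self.y1 is not None and np.any(self.y1 > 1.0 + 1e-9):
            raise ValueError(
                "observed algicidal ratios must not exceed 1 on fraction scale "
                "(got values that look like percents; divide by 100)"
            )
        if self.y2 is not None and np.any(self.y2 < 0):
            raise ValueError("dry mycelial weight must be nonnegative")
        if not self.run_labels:
            self.run_labels = [f"N{i + 1}" for i in range(n)]
        if not self.factor_names:
            self.factor_names = [f"X{j + 1}" for j in range(self.X.shape[1])]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Dataset":
        """Build from a frame in the packaged dataset's layout
        (columns X1..Xs plus Y1 in percent and/or Y2 raw)."""
        xcols = [c for c in df.columns if c.upper().startswith("X")]
        return cls(
            X=df[xcols].to_numpy(float),
            y1=df["Y1"].to_numpy(float) / 100.0 if "Y1" in df else None,
            y2=df["Y2"].to_numpy(float) if "Y2" in df else None,
            run_labels=[str(i) for i in df.index],
            factor_names=xcols,
        )

    def response(self, name: str) -> np.ndarray:
        y = {"Y1": self.y1, "Y2": self.y2}[name.upper()]
        if y is None:
            raise ValueError(f"dataset has no {name} response")
        return y


def algicidal_ratio(F0, Ft):
    """Bioassay statistic ``(F0 - Ft) / F0`` on fraction scale.

    ``F0`` is the chlorophyll fluorescence (RFU) of the untreated control
    culture and ``Ft`` that of the treated culture; multiply by 100 for
    display. Vectorised; negative values mean the treatment promoted algal
    growth.
    """
    F0 = np.asarray(F0, dtype=float)
    Ft = np.asarray(Ft, dtype=float)
    if np.any(F0 <= 0):
        raise ValueError("control fluorescence F0 must be positive")
    if np.any(Ft < 0):
        raise ValueError("treated fluorescence Ft must be nonnegative")
    out = (F0 - Ft) / F0
    return float(out) if out.ndim == 0 else out


def verification_metrics(predicted: float, experimental: float, control: float):
    """Improvement over control and model prediction error, both in percent.

    ``improvement = (experimental - control) / control * 100``;
    ``prediction_error = |predicted - experimental| / experimental * 100``.
    All three inputs must share a scale and be positive.
    """
    if control <= 0:
        raise ValueError("control must be positive")
    if experimental <= 0:
        raise ValueError("experimental must be positive")
    improvement = (experimental - control) / control * 100.0
    prediction_error = abs(predicted - experimental) / experimental * 100.0
    return improvement, prediction_error


@dataclass
class SynthSpec:
    """Ground truth for the synthetic response-surface generator.

    ``model`` is the true quadratic surface; ``saturating`` optionally
    squashes it through ``L * tanh(y / L)`` to mimic an assay that cannot
    exceed a ceiling (the algicidal ratio saturating near 100 %);
    ``noise_sd`` is the sd of additive Gaussian measurement noise.
    """

    model: PolyModel
    noise_sd: float = 0.0
    saturating: bool = False
    saturation_level: float = 1.0
    n_runs: int = 15
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_synthetic(
    spec: SynthSpec,
    factors: list[FactorSpec],
    design: DesignTable | np.ndarray | None = None,
) -> tuple[Dataset, np.ndarray]:
    """Sample a uniform design and evaluate the true surface on it.

    Returns the measured dataset (response stored as ``y2``) and the exact
    noise-free ground-truth vector. Measurements are floored at zero — a
    dry-weight assay cannot read negative — so where the true surface dips
    below zero the dataset and the ground truth differ by construction.

    ``design`` overrides the internally generated lattice with an explicit
    :class:`DesignTable` (mapped) or a plain run x factor matrix; useful
    because good-lattice-point designs can exactly alias quadratic
    monomials, which no refit can then disentangle.
    """
    if spec.model.n_factors != len(factors):
        raise ValueError("model factor count does not match factor specs")
    if design is None:
        table = generate_uniform_table(spec.n_runs, len(factors), seed=spec.seed)
        X = map_levels(table, factors).mapped
    elif isinstance(design, DesignTable):
        X = design.mapped if design.mapped is not None else map_levels(
            design, factors
        ).mapped
    else:
        X = np.atleast_2d(np.asarray(design, dtype=float))
    truth = spec.model.predict(X)
    if spec.saturating:
        L = spec.saturation_level
        truth = L * np.tanh(truth / L)
    rng = np.random.default_rng(spec.seed)
    noisy = truth + rng.normal(0.0, spec.noise_sd, size=len(truth))
    ds = Dataset(X=X, y2=np.maximum(noisy, 0.0), factor_names=[f.name for f in factors])
    return ds, truth


@dataclass
class ProtocolResult:
    """Per-response outcome of the full optimization protocol."""

    response: str
    regression_model: PolyModel
    regression_stats: object
    regression_optimum: tuple[np.ndarray, float]
    regression_unconstrained: list[int]
    scan_table: pd.DataFrame | None
    n_hidden: int
    network: BPNetRegressor
    ga_ann_optimum: tuple[np.ndarray, float]


def run_protocol(
    dataset: Dataset,
    factors: list[FactorSpec],
    responses: tuple[str, ...] = ("Y1", "Y2"),
    regression_terms="stepwise",
    scan_hidden=range(3, 13),
    scan_replicates: int = 10,
    default_hidden: dict | None = None,
    run_scan: bool = True,
    train_config: TrainConfig | None = None,
    ga_weights: dict | None = None,
    ga_conditions: dict | None = None,
    seed: int = 0,
) -> dict[str, ProtocolResult]:
    """Execute the full protocol for each requested response.

    Stages per response: (1) quadratic regression baseline (stepwise by
    default, or a fixed published term set via ``regression_terms``) and its
    box-constrained maximum; (2) hidden-neuron scan (skippable with
    ``run_scan=False``, falling back to ``default_hidden``); (3) GA-seeded
    back-propagation training on all runs; (4) GA search over the factor box
    for the surrogate's maximum. Stage failures are logged and surfaced;
    completed responses are preserved.
    """
    if len(dataset.X) < 8:
        raise ValueError("protocol needs at least 8 runs")
    bounds = [(f.minimum, f.maximum) for f in factors]
    default_hidden = default_hidden or {"Y1": 12, "Y2": 9}
    ga_weights = ga_weights or {}
    ga_conditions = ga_conditions or {}
    tc = train_config or TrainConfig()
    results: dict[str, ProtocolResult] = {}
    for resp in responses:
        y = dataset.response(resp)
        scale = "fraction" if resp.upper() == "Y1" else "raw"
        log.info("[%s] regression baseline (terms=%s)", resp, regression_terms)
        terms = (
            regression_terms[resp]
            if isinstance(regression_terms, dict)
            else regression_terms
        )
        reg = QuadraticSurface(terms=terms, response_scale=scale)
        reg.fit(dataset.X, y)
        reg_opt = reg.maximize(bounds)
        free = unconstrained_factors(reg.model_)
        if free:
            log.warning(
                "[%s] factors %s appear in no selected term; the regression "
                "optimum is unconstrained in them",
                resp,
                [dataset.factor_names[i] for i in free],
            )
        if run_scan:
            log.info("[%s] hidden-neuron scan over %s", resp, list(scan_hidden))
            scan_table, n_hidden = hidden_neuron_scan(
                dataset.X,
                y,
                h_range=scan_hidden,
                n_train=len(y) - 2,
                n_test=2,
                replicates=scan_replicates,
                seed=seed,
                train_config=tc,
            )
        else:
            scan_table, n_hidden = None, default_hidden[resp.upper()]
        log.info("[%s] GA-BP training (h=%d)", resp, n_hidden)
        net = BPNetRegressor(
            n_hidden=n_hidden,
            max_epoch=tc.max_epoch,
            goal=tc.goal,
            learning_rate=tc.learning_rate,
            momentum=tc.momentum,
            random_state=seed,
            **ga_weights,
        )
        net.fit(dataset.X, y)
        log.info("[%s] GA condition search", resp)
        ga_opt = net.maximize(bounds, seed=seed + 1, **ga_conditions)
        results[resp] = ProtocolResult(
            response=resp,
            regression_model=reg.model_,
            regression_stats=reg.stats_,
            regression_optimum=reg_opt,
            regression_unconstrained=free,
            scan_table=scan_table,
            n_hidden=n_hidden,
            network=net,
            ga_ann_optimum=ga_opt,
        )
    return results


def comparison_table(results: dict[str, ProtocolResult]) -> pd.DataFrame:
    """Side-by-side predicted optima, shaped like a verification table's
    prediction rows (display scale: Y1 in percent)."""
    rows = []
    for resp, r in results.items():
        disp = 100.0 if r.regression_model.response_scale == "fraction" else 1.0
        rows.append(
            {
                "response": resp,
                "regression_prediction": r.regression_optimum[1] * disp,
                "ga_ann_prediction": r.ga_ann_optimum[1] * disp,
            }
        )
    return pd.DataFrame(rows).set_index("response")
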