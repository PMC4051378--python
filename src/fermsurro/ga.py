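"""Real-coded genetic algorithm for weight and condition optimization.

One GA serves two roles: minimising a network's training error over its
flattened weights and thresholds, and maximising a trained surrogate's
prediction over the fermentation-condition box. Operators are the standard
real-coded trio — roulette selection on linear rank weights, whole-arithmetic
crossover, per-gene uniform-reset mutation — with single-individual elitism,
which makes the best-fitness trace non-worsening by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bpnet import MLPParams, NetworkConfig, Scaler, forward

__all__ = ["GAConfig", "GARun", "run_ga", "fitness_weights", "fitness_conditions"]


@dataclass
class GAConfig:
    maxgen: int = 100
    sizepop: int = 80
    pcross: float = 0.4
    pmutation: float = 0.05
    bounds: np.ndarray = None  # (n_genes, 2)
    mode: str = "minimize"
    seed: int = 0
    elitism: int = 1
    mutation: str = "nonuniform"  # or "uniform" (reset within bounds)
    mutation_shape: float = 1.0  # non-uniform decay exponent b

    def __post_init__(self):
        if self.mutation not in ("nonuniform", "uniform"):
            raise ValueError("mutation must be 'nonuniform' or 'uniform'")
        if self.sizepop < 2:
            raise ValueError("sizepop must be >= 2")
        if self.maxgen < 1:
            raise ValueError("maxgen must be >= 1")
        if self.mode not in ("minimize", "maximize"):
            raise ValueError("mode must be 'minimize' or 'maximize'")
        if not (0 <= self.pcross <= 1 and 0 <= self.pmutation <= 1):
            raise ValueError("pcross and pmutation must lie in [0, 1]")
        self.bounds = np.asarray(self.bounds, dtype=float)
        if self.bounds.ndim != 2 or self.bounds.shape[1] != 2:
            raise ValueError("bounds must have shape (n_genes, 2)")
        if not np.all(np.isfinite(self.bounds)):
            raise ValueError("bounds must be finite")
        if np.any(self.bounds[:, 1] <= self.bounds[:, 0]):
            raise ValueError("each bound must satisfy low < high")


@dataclass
class GARun:
    best_individual: np.ndarray
    best_fitness: float
    trace: pd.DataFrame  # columns: generation, best, mean

    @property
    def fitness_trace(self) -> np.ndarray:
        return self.trace["best"].to_numpy()


def _evaluate(fitness, pop: np.ndarray) -> np.ndarray:
    vals = np.empty(len(pop))
    for i, ind in enumerate(pop):
        v = float(fitness(ind))
        if not np.isfinite(v):
            raise ValueError(
                f"fitness returned a non-finite value ({v}) for individual "
                f"{i}: {np.array2string(ind, precision=4)}"
            )
        vals[i] = v
    return vals


def run_ga(fitness, config: GAConfig) -> GARun:
    """Generational real-coded GA.

    ``fitness`` maps an in-bounds gene vector to a finite real. Selection is
    roulette on linear rank weights (best rank gets weight ``sizepop``,
    worst gets 1), which handles minimisation, maximisation and negative
    fitness uniformly. The best individual of each generation survives
    unchanged (elitism of ``config.elitism``), so the per-generation best is
    monotone. Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.bounds[:, 0], config.bounds[:, 1]
    n_genes = len(lo)
    sign = 1.0 if config.mode == "minimize" else -1.0

    pop = rng.uniform(lo, hi, size=(config.sizepop, n_genes))
    vals = _evaluate(fitness, pop)
    records = []
    for gen in range(1, config.maxgen + 1):
        order = np.argsort(sign * vals)  # best first
        elite = pop[order[: config.elitism]].copy()
        elite_vals = vals[order[: config.elitism]].copy()

        # linear rank weights: best gets sizepop, worst gets 1
        weights = np.empty(config.sizepop)
        weights[order] = np.arange(config.sizepop, 0, -1)
        probs = weights / weights.sum()
        parents = pop[rng.choice(config.sizepop, size=config.sizepop, p=probs)]

        # whole-arithmetic crossover on consecutive pairs
        children = parents.copy()
        for i in range(0, config.sizepop - 1, 2):
            if rng.random() < config.pcross:
                alpha = rng.random()
                a, b = parents[i], parents[i + 1]
                children[i] = alpha * a + (1 - alpha) * b
                children[i + 1] = alpha * b + (1 - alpha) * a

        # per-gene mutation: non-uniform (generation-decaying step toward a
        # random bound, Michalewicz-style — coarse early, refining late) or
        # plain uniform reset within bounds
        mask = rng.random(children.shape) < config.pmutation
        if config.mutation == "uniform":
            resets = rng.uniform(lo, hi, size=children.shape)
            children[mask] = resets[mask]
        else:
            frac = (1.0 - gen / config.maxgen) ** config.mutation_shape
            r = rng.random(children.shape)
            up = rng.random(children.shape) < 0.5
            step = np.where(
                up, (hi - children), (children - lo)
            ) * (1.0 - r ** frac)
            children[mask] = (
                children + np.where(up, step, -step)
            )[mask]
        np.clip(children, lo, hi, out=children)

        child_vals = _evaluate(fitness, children)
        # elitism: best of the previous generation replaces the worst child
        worst = np.argsort(sign * child_vals)[::-1][: config.elitism]
        children[worst] = elite
        child_vals[worst] = elite_vals
        pop, vals = children, child_vals
        best_idx = np.argmin(sign * vals)
        records.append(
            {"generation": gen, "best": vals[best_idx], "mean": float(vals.mean())}
        )

    best_idx = int(np.argmin(sign * vals))
    return GARun(
        best_individual=pop[best_idx].copy(),
        best_fitness=float(vals[best_idx]),
        trace=pd.DataFrame(records),
    )


def fitness_weights(
    net_config: NetworkConfig, Xs, ys, output_activation: str = "sigmoid"
):
    """Fitness over flattened network parameters: sum of absolute training errors.

    ``Xs``/``ys`` are already in scaled space. Minimise.
    """
    Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
    ys = np.asarray(ys, dtype=float).ravel()

    def fitness(genes: np.ndarray) -> float:
        genes = np.asarray(genes, dtype=float).ravel()
        if genes.size != net_config.n_genes:
            raise ValueError(
                f"gene vector has {genes.size} entries, network needs "
                f"{net_config.n_genes}"
            )
        params = MLPParams.unflatten(
            genes, net_config, output_activation=output_activation
        )
        return float(np.abs(forward(params, Xs) - ys).sum())

    return fitness


def fitness_conditions(params: MLPParams, scaler: Scaler):
    """Fitness over physical condition vectors: the surrogate's prediction.

    Genes are fermentation conditions in physical units; the network input
    is min-max scaled and the output inverse-scaled, so the fitness is the
    predicted response on its physical scale. Maximise.
    """

    def fitness(x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float).ravel()
        xs = scaler.transform_x(x[None, :])
        return float(scaler.inverse_y(forward(params, xs))[0])

    return fitness
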