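"""Uniform experimental designs :math:`U_n(n^s)` by the good-lattice-point method.

A uniform design spreads *n* runs of *s* factors over the factor space so that
every factor visits each of its *n* equally spaced levels exactly once (each
design column is a permutation of ``1..n``) and the point set minimises a
discrepancy measure — here the centered :math:`L_2`-discrepancy.

The good-lattice-point (GLP) construction takes a generator vector
:math:`h = (h_1, \\dots, h_s)` of integers coprime with *n* and sets

.. math:: x_{ij} = (i \\cdot h_j \\bmod n) + 1, \\qquad i = 0, \\dots, n-1.

Each candidate generator set yields a valid lattice; the one with the smallest
centered :math:`L_2`-discrepancy is returned, ties broken by the
lexicographically smallest generator vector so generation is deterministic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FactorSpec",
    "DesignTable",
    "centered_l2_discrepancy",
    "generate_uniform_table",
    "map_levels",
    "levels_from_values",
    "validate_design",
]

# Exhaustive enumeration of generator sets is capped at this many candidates;
# beyond it a seeded random subsample is searched instead.
_MAX_CANDIDATES = 20_000


@dataclass(frozen=True)
class FactorSpec:
    """One fermentation factor with bounded, equally spaced levels.

    Parameters
    ----------
    name : str
        Column identifier, e.g. ``"X1"``.
    minimum, maximum : float
        Physical bounds of the factor (inclusive), in ``units``.
    n_levels : int
        Number of equally spaced levels; level 1 maps to ``minimum`` and
        level ``n_levels`` to ``maximum``.
    units : str
        Physical units, e.g. ``"g/L"`` or ``"h"``.
    label : str
        Human-readable name (``"starch"``); defaults to ``name``.
    """

    name: str
    minimum: float
    maximum: float
    n_levels: int
    units: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        if not self.maximum > self.minimum:
            raise ValueError(
                f"factor {self.name!r}: maximum ({self.maximum}) must exceed "
                f"minimum ({self.minimum})"
            )
        if self.n_levels < 2:
            raise ValueError(f"factor {self.name!r}: n_levels must be >= 2")
        if not self.label:
            object.__setattr__(self, "label", self.name)

    @property
    def step(self) -> float:
        """Physical increment between adjacent levels."""
        return (self.maximum - self.minimum) / (self.n_levels - 1)

    def level_to_value(self, level) -> np.ndarray | float:
        """Map integer level(s) in ``1..n_levels`` to physical value(s)."""
        return self.minimum + (np.asarray(level) - 1) * self.step

    def value_to_level(self, value) -> np.ndarray | float:
        """Inverse of :meth:`level_to_value` (rounded to the nearest level)."""
        return np.rint((np.asarray(value) - self.minimum) / self.step).astype(int) + 1


@dataclass
class DesignTable:
    """An ``n_runs x n_factors`` uniform design.

    ``levels`` holds integer levels ``1..n_runs`` (each column a permutation);
    ``mapped`` holds the same runs in physical units once factor specs have
    been applied via :func:`map_levels`.
    """

    levels: np.ndarray
    discrepancy: float = math.nan
    mapped: np.ndarray | None = None
    generator: tuple[int, ...] | None = None
    factor_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=int)
        if self.levels.ndim != 2:
            raise ValueError("levels must be a 2-D integer matrix")
        if not self.factor_names:
            self.factor_names = [f"X{j + 1}" for j in range(self.n_factors)]

    @property
    def n_runs(self) -> int:
        return self.levels.shape[0]

    @property
    def n_factors(self) -> int:
        return self.levels.shape[1]


def _coprime_generators(n: int) -> list[int]:
    return [h for h in range(1, n) if math.gcd(h, n) == 1]


def centered_l2_discrepancy(points: np.ndarray) -> float:
    """Centered :math:`L_2`-discrepancy of points in the unit cube.

    Uses the closed form of Hickernell's centered discrepancy for an
    ``n x s`` point set :math:`\\{u_i\\}` in :math:`[0,1]^s`:

    .. math::

        CD_2^2 = \\left(\\tfrac{13}{12}\\right)^s
          - \\frac{2}{n} \\sum_i \\prod_j
            \\left(1 + \\tfrac12|u_{ij}-\\tfrac12| - \\tfrac12|u_{ij}-\\tfrac12|^2\\right)
          + \\frac{1}{n^2} \\sum_{i,k} \\prod_j
            \\left(1 + \\tfrac12|u_{ij}-\\tfrac12| + \\tfrac12|u_{kj}-\\tfrac12|
                   - \\tfrac12|u_{ij}-u_{kj}|\\right)

    Returns the square root, :math:`CD_2`.
    """
    u = np.asarray(points, dtype=float)
    if u.ndim != 2:
        raise ValueError("points must be a 2-D array")
    n, s = u.shape
    d = np.abs(u - 0.5)
    term1 = (13.0 / 12.0) ** s
    term2 = (2.0 / n) * np.prod(1.0 + 0.5 * d - 0.5 * d**2, axis=1).sum()
    # pairwise product over factors
    cross = 1.0 + 0.5 * (d[:, None, :] + d[None, :, :]) - 0.5 * np.abs(
        u[:, None, :] - u[None, :, :]
    )
    term3 = np.prod(cross, axis=2).sum() / n**2
    return math.sqrt(max(term1 - term2 + term3, 0.0))


def _levels_to_unit(levels: np.ndarray, n: int) -> np.ndarray:
    # midpoint convention: level k -> (k - 1/2)/n
    return (levels - 0.5) / n


def generate_uniform_table(n_runs: int, n_factors: int, seed: int = 0) -> DesignTable:
    """Generate a :math:`U_n(n^s)` uniform design by good-lattice-point search.

    All generator vectors (combinations of integers coprime with ``n_runs``)
    are enumerated — or, past a size cap, a seeded subsample — and the design
    with the lowest centered :math:`L_2`-discrepancy is returned.

    Parameters
    ----------
    n_runs : int
        Number of runs *n* (>= 3); each factor takes *n* levels.
    n_factors : int
        Number of factors *s*; must satisfy ``s < n`` and leave at least one
        unused coprime generator.
    seed : int
        Only consulted when the candidate set is subsampled; full enumeration
        is deterministic regardless.

    Returns
    -------
    DesignTable
        With ``levels``, ``discrepancy`` and ``generator`` populated.
    """
    if n_runs < 3:
        raise ValueError("n_runs must be >= 3")
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")
    if n_factors >= n_runs:
        raise ValueError("n_factors must be < n_runs")
    gens = _coprime_generators(n_runs)
    if n_factors >= len(gens):
        raise ValueError(
            f"n_factors={n_factors} requires at least {n_factors + 1} integers "
            f"coprime with {n_runs}, found {len(gens)}"
        )

    n_comb = math.comb(len(gens), n_factors)
    combos: "itertools.chain | itertools.combinations | list"
    if n_comb <= _MAX_CANDIDATES:
        combos = itertools.combinations(gens, n_factors)
    else:
        rng = np.random.default_rng(seed)
        seen = set()
        while len(seen) < _MAX_CANDIDATES:
            pick = tuple(sorted(rng.choice(len(gens), size=n_factors, replace=False)))
            seen.add(tuple(gens[i] for i in pick))
        combos = sorted(seen)

    i = np.arange(n_runs)[:, None]
    best: tuple[float, tuple[int, ...], np.ndarray] | None = None
    for h in combos:
        levels = (i * np.asarray(h)[None, :]) % n_runs + 1
        disc = centered_l2_discrepancy(_levels_to_unit(levels, n_runs))
        # strict < keeps the lexicographically smallest generator on ties
        # (combinations are enumerated in lexicographic order)
        if best is None or disc < best[0] - 1e-12:
            best = (disc, tuple(h), levels)
    assert best is not None
    disc, h, levels = best
    return DesignTable(levels=levels, discrepancy=disc, generator=h)


def map_levels(table: DesignTable, factors: list[FactorSpec]) -> DesignTable:
    """Fill the ``mapped`` matrix of a design from factor specifications.

    Every factor must carry exactly ``n_runs`` levels (the defining property
    of a :math:`U_n(n^s)` table).
    """
    if len(factors) != table.n_factors:
        raise ValueError(
            f"got {len(factors)} factor specs for a {table.n_factors}-factor table"
        )
    for f in factors:
        if f.n_levels != table.n_runs:
            raise ValueError(
                f"factor {f.name!r} has {f.n_levels} levels, table has "
                f"{table.n_runs} runs"
            )
    mapped = np.column_stack(
        [f.level_to_value(table.levels[:, j]) for j, f in enumerate(factors)]
    )
    return replace(
        table,
        mapped=mapped,
        factor_names=[f.name for f in factors],
        levels=table.levels.copy(),
    )


def levels_from_values(values: np.ndarray, factors: list[FactorSpec]) -> np.ndarray:
    """Invert the linear level mapping, rounding to the nearest integer level."""
    values = np.asarray(values, dtype=float)
    return np.column_stack(
        [f.value_to_level(values[:, j]) for j, f in enumerate(factors)]
    )


def validate_design(table: DesignTable) -> dict:
    """Check the permutation property column by column.

    Returns a report ``{"passed": bool, "columns": [{...}, ...]}``; never
    raises — intended for inspecting externally supplied designs.
    """
    expected = np.arange(1, table.n_runs + 1)
    columns = []
    for j in range(table.n_factors):
        col = table.levels[:, j]
        ok = bool(np.array_equal(np.sort(col), expected))
        columns.append(
            {"factor": table.factor_names[j], "is_permutation": ok}
        )
    return {"passed": all(c["is_permutation"] for c in columns), "columns": columns}
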