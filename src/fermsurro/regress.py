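"""Quadratic response-surface regression with stepwise term selection.

The response surface over *s* factors is modelled as

.. math::

    y = b_0 + \\sum_i b_i X_i + \\sum_i b_{ii} X_i^2 + \\sum_{i<j} b_{ij} X_i X_j

with terms either fixed in advance or chosen by forward selection with
backward elimination on partial *F*-tests. Fit diagnostics follow the
response-surface tradition: multiple correlation coefficient *R*, overall
*F* and its *p*-value, and the Durbin–Watson statistic of the residuals in
run order.

Terms are represented as sorted index tuples: ``(0,)`` is ``X1``, ``(0, 0)``
is ``X1*X1`` and ``(0, 2)`` is ``X1*X3``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

Term = tuple[int, ...]

__all__ = [
    "Term",
    "PolyModel",
    "FitStats",
    "SingularTermsError",
    "build_quadratic_terms",
    "term_name",
    "parse_term",
    "ols_fit",
    "stepwise_fit",
    "evaluate_polynomial",
    "maximize_polynomial",
    "durbin_watson",
    "QuadraticSurface",
]


class SingularTermsError(np.linalg.LinAlgError):
    """Raised when the term matrix is rank deficient; names the collinear terms."""


def build_quadratic_terms(n_factors: int) -> list[Term]:
    """Full candidate set: linear, pure-quadratic and pairwise interactions.

    For *s* factors this is ``s + s + s(s-1)/2`` monomials, in the order
    linear, squares, interactions (``i < j``, lexicographic).
    """
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")
    linear = [(i,) for i in range(n_factors)]
    squares = [(i, i) for i in range(n_factors)]
    inter = [(i, j) for i, j in itertools.combinations(range(n_factors), 2)]
    return linear + squares + inter


def term_name(term: Term) -> str:
    """``(0, 2) -> "X1*X3"`` — 1-based display names."""
    return "*".join(f"X{i + 1}" for i in term)


def parse_term(name: str) -> Term:
    """Inverse of :func:`term_name`; accepts ``"X1"`` or ``"X1*X3"``."""
    idx = tuple(sorted(int(p.strip().lstrip("Xx")) - 1 for p in name.split("*")))
    if any(i < 0 for i in idx) or len(idx) not in (1, 2):
        raise ValueError(f"cannot parse term {name!r}")
    return idx


def _monomials(X: np.ndarray, terms: list[Term]) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    cols = [np.prod(X[:, list(t)], axis=1) for t in terms]
    return np.column_stack(cols) if cols else np.empty((len(X), 0))


@dataclass
class PolyModel:
    """A fitted (or published) quadratic polynomial.

    ``coefficients`` maps term tuples to reals; ``response_scale`` records
    whether the response lives on a raw physical scale or an internal
    fraction scale (e.g. an algicidal ratio stored as 0.8957 for 89.57 %).
    """

    intercept: float
    coefficients: dict[Term, float]
    response_name: str = "y"
    response_scale: str = "raw"
    n_factors: int | None = None

    def __post_init__(self) -> None:
        if self.n_factors is None:
            self.n_factors = 1 + max(
                (i for t in self.coefficients for i in t), default=0
            )

    @property
    def terms(self) -> list[Term]:
        return list(self.coefficients)

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.intercept + _monomials(X, self.terms) @ np.array(
            list(self.coefficients.values())
        )

    def __call__(self, x) -> float:
        return float(self.predict(np.atleast_2d(x))[0])

    def to_dict(self) -> dict:
        return {
            "response_name": self.response_name,
            "response_scale": self.response_scale,
            "n_factors": self.n_factors,
            "intercept": self.intercept,
            "coefficients": {term_name(t): c for t, c in self.coefficients.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PolyModel":
        return cls(
            intercept=float(d["intercept"]),
            coefficients={parse_term(k): float(v) for k, v in d["coefficients"].items()},
            response_name=d.get("response_name", "y"),
            response_scale=d.get("response_scale", "raw"),
            n_factors=d.get("n_factors"),
        )


@dataclass
class FitStats:
    """Diagnostics of an OLS fit.

    ``R`` is the multiple correlation coefficient, ``sqrt(1 - SSE/SST)``;
    ``F_value``/``p_value`` test the overall regression with ``(k, n-k-1)``
    degrees of freedom; ``durbin_watson`` is computed from the residuals in
    run order. ``R`` is ``nan`` (flagged) for a zero-variance response.
    """

    R: float
    F_value: float
    p_value: float
    durbin_watson: float
    residuals: np.ndarray
    df_resid: int
    sse: float
    sst: float
    zero_variance_response: bool = False


@dataclass
class StepEvent:
    action: str  # "add" | "remove"
    term: Term
    partial_F: float
    p_value: float


def durbin_watson(residuals) -> float:
    """Durbin–Watson statistic ``sum(diff(e)^2) / sum(e^2)`` in run order.

    Values near 2 indicate no first-order autocorrelation; near 0 positive,
    near 4 negative autocorrelation.
    """
    e = np.asarray(residuals, dtype=float)
    if e.size < 2:
        raise ValueError("need at least 2 residuals")
    denom = float(e @ e)
    if denom == 0.0:
        raise ValueError("Durbin-Watson undefined for all-zero residuals")
    return float(np.sum(np.diff(e) ** 2) / denom)


def _fit_stats(y: np.ndarray, resid: np.ndarray, k: int) -> FitStats:
    n = len(y)
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    df_resid = n - k - 1
    zero_var = sst == 0.0
    if zero_var:
        R = np.nan
    else:
        R = float(np.sqrt(max(1.0 - sse / sst, 0.0)))
    if k >= 1 and df_resid >= 1 and not zero_var and sse > 0:
        F = ((sst - sse) / k) / (sse / df_resid)
        p = float(stats.f.sf(F, k, df_resid))
    else:
        F, p = np.nan, np.nan
    try:
        dw = durbin_watson(resid)
    except ValueError:
        dw = np.nan
    return FitStats(
        R=R,
        F_value=float(F),
        p_value=p,
        durbin_watson=dw,
        residuals=resid,
        df_resid=df_resid,
        sse=sse,
        sst=sst,
        zero_variance_response=zero_var,
    )


def ols_fit(
    X,
    y,
    terms: list[Term],
    response_name: str = "y",
    response_scale: str = "raw",
) -> tuple[PolyModel, FitStats]:
    """Least-squares fit of a fixed monomial set (QR via ``lstsq``).

    Requires at least one residual degree of freedom; a near-saturated fit
    (``df_resid == 1``) is permitted with a warning, since reproducing a
    15-run / 13-term published model needs exactly that. Rank deficiency
    raises :class:`SingularTermsError` naming the collinear terms.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, k = len(y), len(terms)
    if n <= k + 1:
        raise ValueError(
            f"{n} runs cannot support {k} terms + intercept "
            "(need at least one residual degree of freedom)"
        )
    M = np.column_stack([np.ones(n), _monomials(X, terms)])
    # equilibrate columns before the QR solve: monomials such as X5^2 span
    # wildly different magnitudes and would otherwise dominate the
    # conditioning of the least-squares system
    scale = np.linalg.norm(M, axis=0)
    scale[scale == 0] = 1.0
    beta, _, rank, _ = np.linalg.lstsq(M / scale, y, rcond=None)
    beta = beta / scale
    if rank < M.shape[1]:
        # identify offenders via pivoted QR: columns whose R diagonal collapses
        from scipy.linalg import qr as _qr

        _, r, piv = _qr(M, mode="economic", pivoting=True)
        tol = np.abs(r[0, 0]) * max(M.shape) * np.finfo(float).eps
        bad = [piv[i] for i in range(M.shape[1]) if abs(r[i, i]) < tol]
        names = [("intercept" if j == 0 else term_name(terms[j - 1])) for j in bad]
        raise SingularTermsError(
            f"term matrix is rank deficient (rank {rank} < {M.shape[1]}); "
            f"collinear columns: {', '.join(names)}"
        )
    if n - k - 1 == 1:
        warnings.warn(
            f"near-saturated fit: {k} terms on {n} runs leaves a single "
            "residual degree of freedom; diagnostics are fragile",
            UserWarning,
            stacklevel=2,
        )
    resid = y - M @ beta
    model = PolyModel(
        intercept=float(beta[0]),
        coefficients={t: float(b) for t, b in zip(terms, beta[1:])},
        response_name=response_name,
        response_scale=response_scale,
        n_factors=X.shape[1],
    )
    return model, _fit_stats(y, resid, k)


def _sse(M: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(M, y, rcond=None)
    r = y - M @ beta
    return float(r @ r)


def stepwise_fit(
    X,
    y,
    candidates: list[Term] | None = None,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
    response_name: str = "y",
    response_scale: str = "raw",
) -> tuple[PolyModel, FitStats, list[StepEvent]]:
    """Forward selection with backward elimination on partial *F*-tests.

    At each forward step the not-yet-included candidate with the smallest
    partial-*F* *p*-value enters if ``p < alpha_enter``; after each entry,
    included terms whose removal *p*-value exceeds ``alpha_remove`` are
    dropped (worst first). Entry stops when no candidate qualifies or when
    another term would exhaust the residual degrees of freedom.

    Returns the selected model, its diagnostics and the ordered trace of
    enter/remove events. If nothing enters, an intercept-only model is
    returned with a warning.
    """
    if alpha_enter > alpha_remove:
        raise ValueError("alpha_enter must be <= alpha_remove")
    if candidates is None:
        candidates = build_quadratic_terms(np.asarray(X).shape[1])
    if not candidates:
        raise ValueError("need at least one candidate term")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    ones = np.ones((n, 1))
    selected: list[Term] = []
    trace: list[StepEvent] = []
    sst = float(np.sum((y - y.mean()) ** 2))
    # SSE below this is an exact fit to working precision: entry stops and
    # redundant terms (removal leaves the fit exact) are dropped
    tol = max(1e-12 * max(sst, 1.0), 1e-30)

    def model_matrix(terms: list[Term]) -> np.ndarray:
        return np.hstack([ones, _monomials(X, terms)]) if terms else ones

    def partial_f(sse_red: float, sse_full: float, df: int) -> tuple[float, float]:
        if sse_full <= tol:
            return (np.inf, 0.0) if sse_red > tol else (0.0, 1.0)
        F = (sse_red - sse_full) / (sse_full / df)
        return F, float(stats.f.sf(F, 1, df))

    max_steps = 4 * len(candidates) + 10
    while max_steps > 0:
        max_steps -= 1
        changed = False
        # ---- forward step
        p_cur = len(selected)
        sse_cur = _sse(model_matrix(selected), y)
        if n - (p_cur + 1) - 1 >= 1 and sse_cur > tol:  # room + imperfect fit
            best: tuple[float, float, Term] | None = None
            for t in candidates:
                if t in selected:
                    continue
                Mt = model_matrix(selected + [t])
                if np.linalg.matrix_rank(Mt) < Mt.shape[1]:
                    continue
                sse_t = _sse(Mt, y)
                F, p = partial_f(sse_cur, sse_t, n - (p_cur + 1) - 1)
                if best is None or p < best[0] or (p == best[0] and F > best[1]):
                    best = (p, F, t)
            if best is not None and best[0] < alpha_enter:
                selected.append(best[2])
                trace.append(StepEvent("add", best[2], best[1], best[0]))
                changed = True
        # ---- backward step
        while len(selected) > 1:
            sse_full = _sse(model_matrix(selected), y)
            df = n - len(selected) - 1
            worst: tuple[float, float, Term] | None = None
            for t in selected:
                reduced = [u for u in selected if u != t]
                sse_red = _sse(model_matrix(reduced), y)
                F, p = partial_f(sse_red, sse_full, df)
                if worst is None or p > worst[0]:
                    worst = (p, F, t)
            if worst is not None and worst[0] > alpha_remove:
                selected.remove(worst[2])
                trace.append(StepEvent("remove", worst[2], worst[1], worst[0]))
                changed = True
            else:
                break
        if not changed:
            break

    if not selected:
        warnings.warn(
            "no candidate term passed the entry threshold; returning an "
            "intercept-only model",
            UserWarning,
            stacklevel=2,
        )
        resid = y - y.mean()
        model = PolyModel(
            intercept=float(y.mean()),
            coefficients={},
            response_name=response_name,
            response_scale=response_scale,
            n_factors=X.shape[1],
        )
        return model, _fit_stats(y, resid, 0), trace

    model, fit = ols_fit(
        X, y, selected, response_name=response_name, response_scale=response_scale
    )
    return model, fit, trace


def evaluate_polynomial(model: PolyModel, x) -> float:
    """Value of the polynomial at one factor-value vector."""
    x = np.asarray(x, dtype=float).ravel()
    if model.n_factors is not None and len(x) != model.n_factors:
        raise ValueError(f"expected {model.n_factors} factor values, got {len(x)}")
    return model(x)


def maximize_polynomial(
    model: PolyModel,
    bounds,
    n_grid: int = 21,
    n_polish: int = 5,
) -> tuple[np.ndarray, float]:
    """Global maximum of the polynomial over a box.

    Dense-grid seeding (``n_grid`` points per axis, evaluated in chunks)
    followed by bounded local polish (L-BFGS-B) from the ``n_polish`` best
    grid points. Deterministic. The argmax may lie on the boundary — for a
    response surface whose ridge leaves the design box this is the honest
    answer, not a failure.
    """
    bounds = [(float(lo), float(hi)) for lo, hi in bounds]
    if any(not np.isfinite([lo, hi]).all() for lo, hi in bounds):
        raise ValueError("bounds must be finite")
    axes = [np.linspace(lo, hi, n_grid) for lo, hi in bounds]
    s = len(axes)

    # scan the full grid, chunked over the first axis to bound memory
    best_pts: list[tuple[float, np.ndarray]] = []
    tail = axes[1:] if s > 1 else []
    for x0 in axes[0]:
        if tail:
            mesh = np.meshgrid(*tail, indexing="ij")
            pts = np.column_stack(
                [np.full(mesh[0].size, x0)] + [m.ravel() for m in mesh]
            )
        else:
            pts = np.array([[x0]])
        vals = model.predict(pts)
        order = np.argsort(vals)[::-1][:n_polish]
        best_pts.extend((float(vals[i]), pts[i]) for i in order)
        best_pts = sorted(best_pts, key=lambda t: -t[0])[:n_polish]

    best_val, best_x = best_pts[0]
    for v0, x0 in best_pts:
        res = optimize.minimize(
            lambda z: -model(z), x0, method="L-BFGS-B", bounds=bounds
        )
        if -res.fun > best_val:
            best_val = float(-res.fun)
            best_x = np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds])
    return np.asarray(best_x, dtype=float), float(best_val)


def unconstrained_factors(model: PolyModel) -> list[int]:
    """Indices of factors that appear in no term (optimum is indifferent)."""
    used = {i for t in model.coefficients for i in t}
    return [i for i in range(model.n_factors or 0) if i not in used]


class QuadraticSurface(BaseEstimator, RegressorMixin):
    """Quadratic response-surface regressor (scikit-learn estimator).

    Parameters
    ----------
    terms : "full", "stepwise" or list of term tuples
        ``"full"`` fits every linear/quadratic/interaction monomial,
        ``"stepwise"`` selects terms by partial-*F* stepwise regression,
        and an explicit list refits exactly those monomials (the route used
        to reproduce published equations).
    alpha_enter, alpha_remove : float
        Stepwise entry/removal significance thresholds (``enter <= remove``).
    response_scale : str
        ``"raw"`` or ``"fraction"``; carried into the fitted model for
        display conversion only.

    Attributes
    ----------
    model_ : PolyModel
    stats_ : FitStats
    trace_ : list of StepEvent (empty unless stepwise)
    intercept_ : float
    coef_ : ndarray of selected-term coefficients
    terms_ : list of term tuples actually in the model
    """

    def __init__(
        self,
        terms="stepwise",
        alpha_enter: float = 0.05,
        alpha_remove: float = 0.10,
        response_scale: str = "raw",
    ):
        self.terms = terms
        self.alpha_enter = alpha_enter
        self.alpha_remove = alpha_remove
        self.response_scale = response_scale

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one row per response value")
        self.n_features_in_ = X.shape[1]
        if isinstance(self.terms, str) and self.terms == "stepwise":
            model, fit, trace = stepwise_fit(
                X,
                y,
                alpha_enter=self.alpha_enter,
                alpha_remove=self.alpha_remove,
                response_scale=self.response_scale,
            )
        else:
            terms = (
                build_quadratic_terms(X.shape[1])
                if isinstance(self.terms, str) and self.terms == "full"
                else [tuple(t) for t in self.terms]
            )
            model, fit = ols_fit(X, y, terms, response_scale=self.response_scale)
            trace = []
        self.model_ = model
        self.stats_ = fit
        self.trace_ = trace
        self.terms_ = model.terms
        self.intercept_ = model.intercept
        self.coef_ = np.array(list(model.coefficients.values()))
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(X)

    def maximize(self, bounds, **kw):
        check_is_fitted(self, "model_")
        return maximize_polynomial(self.model_, bounds, **kw)
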