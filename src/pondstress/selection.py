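"""Best-subset AIC selection over contracted variables, and stepwise
confirmation over the uncontracted pool.

Every non-empty subset of the explanatory columns is fitted both as a fixed
Poisson regression and (optionally) as a random-intercept mixed model;
models with more free parameters than one-third of the pond count are
excluded.  The admissible fit with the lowest AIC is the best model; the
"delta set" collects every admissible fit within ``c_delta`` AIC of it
(default 2.0).

Ties in AIC are broken deterministically: fewer free parameters first, then
lexicographic variable order, then fixed before mixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .glm import FitResult, fit_fixed, fit_mixed

__all__ = [
    "ModelSpec",
    "SelectionResult",
    "BestSubsetAIC",
    "enumerate_admissible",
    "select_best",
    "stepwise_uncontracted",
    "parameter_cap",
]


@dataclass(frozen=True)
class ModelSpec:
    """A candidate model: a subset of columns plus the mixed flag."""

    variables: tuple[str, ...]
    mixed: bool

    @property
    def k(self) -> int:
        return len(self.variables)

    @property
    def n_free(self) -> int:
        # intercept always; sigma counted for mixed fits
        return self.k + 1 + (1 if self.mixed else 0)


@dataclass
class SelectionResult:
    best_spec: ModelSpec
    best_fit: FitResult
    delta_set: list[tuple[ModelSpec, FitResult]]
    c_delta: float
    trace: list[tuple[ModelSpec, float, float]] = field(default_factory=list)
    n_failed: int = 0

    @property
    def best_aic(self) -> float:
        return self.best_fit.aic

    def trace_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variables": "+".join(s.variables),
                "mixed": s.mixed,
                "n_free": s.n_free,
                "loglik": ll,
                "aic": a,
                "delta_aic": a - self.best_aic,
            }
            for s, a, ll in self.trace
        ]
        return pd.DataFrame(rows)


def parameter_cap(n_ponds: int) -> int:
    """Maximum free parameters: one-third of the sample size (floored)."""
    return n_ponds // 3


def enumerate_admissible(columns: list[str], n_ponds: int,
                         include_mixed: bool = True,
                         cap: int | None = None) -> list[ModelSpec]:
    """All non-empty subsets x {fixed, mixed} within the free-parameter cap."""
    if cap is None:
        cap = parameter_cap(n_ponds)
    if cap < 2:
        raise ValueError(f"parameter cap {cap} admits no model (need >= 6 ponds)")
    specs: list[ModelSpec] = []
    max_k_fixed = cap - 1
    max_k_mixed = cap - 2
    for k in range(1, min(max_k_fixed, len(columns)) + 1):
        for sub in combinations(columns, k):
            specs.append(ModelSpec(sub, mixed=False))
            if include_mixed and k <= max_k_mixed:
                specs.append(ModelSpec(sub, mixed=True))
    return specs


def _tie_key(spec: ModelSpec, aic: float, order: dict[str, int]):
    return (aic, spec.n_free, tuple(order[v] for v in spec.variables), spec.mixed)


def _fit_spec(spec: ModelSpec, X: pd.DataFrame, y: np.ndarray, n_quad: int,
              compute_cov: bool = False) -> FitResult:
    sub = X[list(spec.variables)]
    if spec.mixed:
        return fit_mixed(sub, y, n_quad=n_quad, compute_cov=compute_cov)
    return fit_fixed(sub, y)


def select_best(X: pd.DataFrame, y, specs: list[ModelSpec],
                c_delta: float = 2.0, n_quad: int = 21) -> SelectionResult:
    """Fit every spec; return the AIC-best model and the delta-AIC set.

    Fits that fail to converge (or are rank-deficient) are excluded from the
    candidate set rather than aborting the selection.
    """
    y = np.asarray(y)
    order = {c: i for i, c in enumerate(X.columns)}
    fits: list[tuple[ModelSpec, FitResult]] = []
    trace: list[tuple[ModelSpec, float, float]] = []
    n_failed = 0
    for spec in specs:
        fit = _fit_spec(spec, X, y, n_quad)
        if not fit.valid:
            n_failed += 1
            continue
        fits.append((spec, fit))
        trace.append((spec, fit.aic, fit.loglik))
    if not fits:
        raise ValueError("no valid fit among the admissible models")
    best_spec, best_fit = min(fits, key=lambda sf: _tie_key(sf[0], sf[1].aic, order))
    if best_fit.cov is None:
        best_fit = _fit_spec(best_spec, X, y, n_quad, compute_cov=True)
    delta = [(s, f) for s, f in fits if f.aic - best_fit.aic <= c_delta]
    delta.sort(key=lambda sf: _tie_key(sf[0], sf[1].aic, order))
    return SelectionResult(best_spec=best_spec, best_fit=best_fit,
                           delta_set=delta, c_delta=c_delta, trace=trace,
                           n_failed=n_failed)


class BestSubsetAIC(BaseEstimator):
    """Exhaustive best-subset AIC selection (meta-estimator).

    Parameters
    ----------
    c_delta : float, default 2.0
        Half-width of the delta-AIC set.
    include_mixed : bool, default True
        Also fit the random-intercept variant of every subset.
    cap : int or None
        Free-parameter cap; default ``floor(M / 3)``.
    n_quad : int, default 21
        Gauss-Hermite nodes for mixed fits.

    Attributes
    ----------
    result_ : SelectionResult
    best_spec_, best_fit_, delta_set_ : convenience views of ``result_``.
    """

    def __init__(self, c_delta: float = 2.0, include_mixed: bool = True,
                 cap: int | None = None, n_quad: int = 21):
        self.c_delta = c_delta
        self.include_mixed = include_mixed
        self.cap = cap
        self.n_quad = n_quad

    def fit(self, X, y):
        X = _frame(X)
        specs = enumerate_admissible(list(X.columns), X.shape[0],
                                     include_mixed=self.include_mixed,
                                     cap=self.cap)
        self.result_ = select_best(X, y, specs, c_delta=self.c_delta,
                                   n_quad=self.n_quad)
        self.best_spec_ = self.result_.best_spec
        self.best_fit_ = self.result_.best_fit
        self.delta_set_ = self.result_.delta_set
        return self


def _expand_initial(best_spec: ModelSpec, member_map: dict[str, list[str]],
                    X_unc: pd.DataFrame, y, cap: int, mixed: bool,
                    n_quad: int) -> list[str]:
    """Map the contracted best model onto uncontracted variables.

    Single variables enter as themselves; a grouped variable is replaced by
    all its members, added greedily by marginal AIC improvement if the full
    expansion would exceed the parameter cap.
    """
    singles: list[str] = []
    grouped_members: list[str] = []
    for v in best_spec.variables:
        members = member_map.get(v, [v])
        if len(members) == 1:
            if members[0] not in singles:
                singles.append(members[0])
        else:
            for m in members:
                if m not in grouped_members:
                    grouped_members.append(m)
    budget = cap - 1 - (1 if mixed else 0)
    grouped_members = [m for m in grouped_members if m not in singles]
    if len(singles) + len(grouped_members) <= budget:
        return singles + grouped_members
    current = list(singles[:budget])
    while len(current) < budget and grouped_members:
        best_aic, best_m = np.inf, None
        for m in grouped_members:
            fit = fit_mixed(X_unc[current + [m]], y, n_quad=n_quad) if mixed \
                else fit_fixed(X_unc[current + [m]], y)
            if fit.valid and fit.aic < best_aic:
                best_aic, best_m = fit.aic, m
        if best_m is None:
            break
        current.append(best_m)
        grouped_members.remove(best_m)
    return current


def stepwise_uncontracted(X_unc: pd.DataFrame, y, best_spec: ModelSpec,
                          member_map: dict[str, list[str]],
                          cap: int | None = None,
                          include_mixed: bool = True,
                          n_quad: int = 21) -> tuple[ModelSpec, FitResult]:
    """Bidirectional stepwise AIC over uncontracted variables.

    The initial model is the contracted best model mapped onto uncontracted
    members; each step tries adding or dropping one variable (both fixed and
    mixed variants, within the cap) and accepts the move with the lowest
    AIC, stopping at a local minimum.
    """
    X_unc = _frame(X_unc)
    y = np.asarray(y)
    if cap is None:
        cap = parameter_cap(X_unc.shape[0])
    order = {c: i for i, c in enumerate(X_unc.columns)}

    def evaluate(vars_: tuple[str, ...]) -> tuple[ModelSpec, FitResult] | None:
        cands = []
        for mixed in ([False, True] if include_mixed else [False]):
            spec = ModelSpec(vars_, mixed)
            if spec.n_free > cap:
                continue
            fit = _fit_spec(spec, X_unc, y, n_quad)
            if fit.valid:
                cands.append((spec, fit))
        if not cands:
            return None
        return min(cands, key=lambda sf: _tie_key(sf[0], sf[1].aic, order))

    init_vars = _expand_initial(best_spec, member_map, X_unc, y, cap,
                                best_spec.mixed, n_quad)
    current = evaluate(tuple(sorted(init_vars, key=order.get)))
    if current is None:
        raise ValueError("initial uncontracted model could not be fitted")
    while True:
        cur_vars = set(current[0].variables)
        moves: list[tuple[ModelSpec, FitResult]] = []
        for v in X_unc.columns:
            if v in cur_vars:
                new = tuple(x for x in current[0].variables if x != v)
                if not new:
                    continue  # any model keeps at least one variable
            else:
                new = tuple(sorted(cur_vars | {v}, key=order.get))
            cand = evaluate(new)
            if cand is not None:
                moves.append(cand)
        if not moves:
            break
        best_move = min(moves, key=lambda sf: _tie_key(sf[0], sf[1].aic, order))
        if best_move[1].aic < current[1].aic - 1e-10:
            current = best_move
        else:
            break
    spec, fit = current
    if fit.cov is None:
        fit = _fit_spec(spec, X_unc, y, n_quad, compute_cov=True)
    return spec, fit


def write_trace(result: SelectionResult, path) -> None:
    """Selection trace log (TSV): subset, mixed flag, loglik, AIC, delta."""
    result.trace_frame().to_csv(path, sep="\t", index=False)


def _frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
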