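"""Selection-aware inference: the three-condition "statistically
contributive" screen, the permutation-of-regressor-residuals (PRR) test,
the selection-embedding permutation test, and the interaction scan.

A variable is *statistically contributive* when

  (i)  it appears in every model of the delta-AIC set (AIC within 2.0 of
       the best model) with a consistently signed coefficient;
  (ii) its PRR p-value in the best model is below 0.05;
  (iii) it is retained, with the same sign, in the uncontracted best model
       found by stepwise AIC started from the contracted best model.

Contributive variables then receive a one-sided p-value from a permutation
test that re-runs the entire best-subset selection on each resampled
dataset: the focal column is permuted across ponds, selection is repeated,
and the test statistic is the focal coefficient in the re-selected best
model (0 when excluded).  A *significant stressor* is a contributive
variable with permutation p < 0.05 and a negative coefficient.

All permutation p-values use the add-one convention
p = (1 + #{statistic <= observed}) / (1 + B), so p is in [1/(B+1), 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .contraction import rescale_unit
from .glm import _newton_poisson
from .selection import (
    ModelSpec,
    SelectionResult,
    _fit_spec,
    _tie_key,
    enumerate_admissible,
    parameter_cap,
    select_best,
    stepwise_uncontracted,
)

__all__ = [
    "VariableVerdict",
    "ContributiveReport",
    "condition_i",
    "prr_test",
    "selection_permutation_test",
    "screen_variables",
    "interaction_scan",
    "interaction_candidates",
]


@dataclass
class VariableVerdict:
    """Per-variable screening outcome."""

    variable: str
    coefficient: float
    cond_i: bool
    prr_p: float | None
    cond_ii: bool | None
    cond_iii: bool | None
    contributive: bool
    perm_p: float | None = None
    significant: bool | None = None


@dataclass
class ContributiveReport:
    category: str
    selection: SelectionResult
    verdicts: list[VariableVerdict] = field(default_factory=list)

    @property
    def contributive(self) -> list[str]:
        return [v.variable for v in self.verdicts if v.contributive]

    @property
    def significant_stressors(self) -> list[str]:
        return [v.variable for v in self.verdicts if v.significant]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(v) for v in self.verdicts])


def condition_i(selection: SelectionResult, variable: str) -> bool:
    """In every delta-AIC model, with a consistently signed coefficient."""
    if not selection.delta_set:
        raise ValueError("empty delta-AIC set")
    signs = []
    for spec, fit in selection.delta_set:
        if variable not in spec.variables:
            return False
        signs.append(np.sign(fit.coef[spec.variables.index(variable)]))
    return len(set(signs)) == 1 and signs[0] != 0


def prr_test(X: pd.DataFrame, y, spec: ModelSpec, focal: str, B: int = 1000,
             rng: np.random.Generator | None = None,
             n_quad: int = 21) -> float:
    """Permutation-of-regressor-residuals p-value for one coefficient.

    The focal column is regressed linearly on the other columns of the
    model (plus intercept); its residuals are permuted and added back to
    the fitted part, the Poisson model is refitted with the reconstructed
    column, and the one-sided (negative-effect) p-value counts permuted
    coefficients at or below the observed one.
    """
    if B < 19:
        raise ValueError("B < 19 gives too coarse a p-value resolution")
    if focal not in spec.variables:
        raise ValueError(f"{focal!r} is not in the model")
    rng = np.random.default_rng(rng)
    y = np.asarray(y)
    cols = list(spec.variables)
    x = X[focal].to_numpy(dtype=float)
    others = [c for c in cols if c != focal]
    A = np.column_stack([np.ones(len(x))] + [X[c].to_numpy(dtype=float) for c in others])
    coef_ols, *_ = np.linalg.lstsq(A, x, rcond=None)
    fitted_part = A @ coef_ols
    resid = x - fitted_part
    if np.ptp(resid) < 1e-12:
        # degenerate: permutation cannot change the reconstructed column,
        # so every permuted statistic equals the observed one
        return 1.0

    def refit(col: np.ndarray) -> float:
        Xp = X[cols].copy()
        Xp[focal] = col
        fit = _fit_spec(spec, Xp, y, n_quad)
        if not fit.valid:
            return np.nan
        return fit.coef[cols.index(focal)]

    obs = refit(x)
    if np.isnan(obs):
        raise ValueError("best model does not refit on the observed data")
    count = 0
    for _ in range(B):
        perm = rng.permutation(len(resid))
        b = refit(fitted_part + resid[perm])
        if not np.isnan(b) and b <= obs + 1e-12:
            count += 1
    return (1 + count) / (1 + B)


def _best_focal_coef_fixed(Xarr: np.ndarray, y: np.ndarray,
                           subsets: list[tuple[int, ...]], focal_idx: int) -> float:
    """Fast fixed-effects-only best-subset selection on raw arrays.

    Returns the focal column's coefficient in the AIC-best model (0.0 when
    the focal column is not selected).  Enumeration order matches
    ``enumerate_admissible`` so exact AIC ties resolve identically.
    """
    n = Xarr.shape[0]
    ones = np.ones((n, 1))
    best_aic = np.inf
    best_coef = 0.0
    for sub in subsets:
        Z = np.concatenate([ones, Xarr[:, sub]], axis=1)
        theta, ll, _, ok = _newton_poisson(Z, y)
        if not ok:
            continue
        a = -2.0 * ll + 2.0 * Z.shape[1]
        if a < best_aic - 1e-12:
            best_aic = a
            best_coef = theta[1 + sub.index(focal_idx)] if focal_idx in sub else 0.0
    return best_coef


def selection_permutation_test(X: pd.DataFrame, y, focal: str, B: int = 1000,
                               seed=None, c_delta: float = 2.0,
                               include_mixed: bool = True,
                               cap: int | None = None,
                               n_quad: int = 21) -> float:
    """Selection-embedding permutation test (one-sided, negative effects).

    For each of B resamples the focal contracted column is permuted across
    ponds and the full best-subset selection is re-run; the statistic is
    the focal coefficient in the re-selected best model, 0 if the focal
    variable is excluded.  p = (1 + #{stat <= observed}) / (1 + B).

    A resample in which no admissible model fits contributes statistic 0.
    """
    rng = np.random.default_rng(seed)
    X = X.copy()
    y = np.asarray(y)
    cols = list(X.columns)
    if focal not in cols:
        raise ValueError(f"unknown focal variable {focal!r}")
    if cap is None:
        cap = parameter_cap(X.shape[0])

    if not include_mixed:
        # fast array path: identical selection, no per-fit object overhead
        focal_idx = cols.index(focal)
        idx_subsets = [
            tuple(cols.index(v) for v in s.variables)
            for s in enumerate_admissible(cols, X.shape[0], include_mixed=False, cap=cap)
        ]
        Xarr = X.to_numpy(dtype=float)
        obs = _best_focal_coef_fixed(Xarr, y, idx_subsets, focal_idx)
        count = 0
        for _ in range(B):
            Xp = Xarr.copy()
            Xp[:, focal_idx] = Xarr[rng.permutation(len(y)), focal_idx]
            stat = _best_focal_coef_fixed(Xp, y, idx_subsets, focal_idx)
            if stat <= obs + 1e-12:
                count += 1
        return (1 + count) / (1 + B)

    specs = enumerate_admissible(cols, X.shape[0], include_mixed=True, cap=cap)

    def statistic(Xd: pd.DataFrame) -> float:
        try:
            sel = select_best(Xd, y, specs, c_delta=c_delta, n_quad=n_quad)
        except ValueError:
            return 0.0
        if focal in sel.best_spec.variables:
            return float(sel.best_fit.coef[sel.best_spec.variables.index(focal)])
        return 0.0

    obs = statistic(X)
    count = 0
    base = X[focal].to_numpy(dtype=float)
    for _ in range(B):
        Xp = X.copy()
        Xp[focal] = base[rng.permutation(len(y))]
        if statistic(Xp) <= obs + 1e-12:
            count += 1
    return (1 + count) / (1 + B)


def screen_variables(X: pd.DataFrame, y, selection: SelectionResult,
                     X_uncontracted: pd.DataFrame | None = None,
                     member_map: dict[str, list[str]] | None = None,
                     prr_B: int = 1000, perm_B: int = 1000,
                     alpha: float = 0.05, seed=None,
                     include_mixed: bool = True, n_quad: int = 21,
                     category: str = "") -> ContributiveReport:
    """Apply conditions (i)-(iii) to every best-model variable, then the
    selection-embedding permutation test to the contributive ones."""
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    report = ContributiveReport(category=category, selection=selection)
    best_spec, best_fit = selection.best_spec, selection.best_fit

    step_result = None
    if X_uncontracted is not None:
        step_result = stepwise_uncontracted(
            X_uncontracted, y, best_spec, member_map or {},
            include_mixed=include_mixed, n_quad=n_quad)

    for vi, var in enumerate(best_spec.variables):
        beta = float(best_fit.coef[vi])
        c1 = condition_i(selection, var)
        prr_p = cond2 = cond3 = None
        contributive = False
        if c1:
            child = np.random.default_rng(ss.spawn(1)[0])
            prr_p = prr_test(X, y, best_spec, var, B=prr_B, rng=child,
                             n_quad=n_quad)
            cond2 = bool(prr_p < alpha) or alpha >= 1.0  # alpha=1 degenerate
            if cond2:
                if step_result is None:
                    cond3 = True  # no uncontracted pool supplied
                else:
                    sspec, sfit = step_result
                    members = (member_map or {}).get(var, [var])
                    kept = [m for m in members if m in sspec.variables]
                    cond3 = bool(kept) and all(
                        np.sign(sfit.coef[sspec.variables.index(m)]) == np.sign(beta)
                        for m in kept
                    )
                contributive = bool(cond3)
        report.verdicts.append(VariableVerdict(
            variable=var, coefficient=beta, cond_i=c1, prr_p=prr_p,
            cond_ii=cond2, cond_iii=cond3, contributive=contributive))

    for v in report.verdicts:
        if v.contributive:
            child = ss.spawn(1)[0]
            v.perm_p = selection_permutation_test(
                X, y, v.variable, B=perm_B, seed=child,
                include_mixed=include_mixed, n_quad=n_quad)
            v.significant = bool(v.perm_p < alpha and v.coefficient < 0)
        else:
            v.significant = False
    return report


def interaction_candidates(X: pd.DataFrame, mains: list[str]) -> pd.DataFrame:
    """Design of contributive mains plus all their pairwise products.

    Products are taken on the unit-scaled columns and rescaled back to
    [0, 1]; hierarchy is not enforced downstream (an interaction may be
    selected without its mains).
    """
    out = X[mains].copy()
    for a, b in combinations(mains, 2):
        out[f"{a}:{b}"] = X[a] * X[b]
    return rescale_unit(out)


def interaction_scan(X: pd.DataFrame, y, mains: list[str],
                     c_delta: float = 2.0, include_mixed: bool = True,
                     cap: int | None = None, n_quad: int = 21,
                     prr_B: int = 1000, perm_B: int = 1000,
                     alpha: float = 0.05, seed=None,
                     mains_best_aic: float | None = None,
                     category: str = "") -> ContributiveReport | None:
    """Best-subset selection over contributive mains and their pairwise
    interaction products, with the contributive screen applied to the
    interaction terms.

    Returns None when fewer than two mains are supplied, or when the
    with-interaction best model has a higher AIC than the mains-only best
    model (``mains_best_aic``).
    """
    if len(mains) < 2:
        return None
    Xi = interaction_candidates(X, mains)
    y = np.asarray(y)
    if cap is None:
        cap = parameter_cap(Xi.shape[0])
    specs = enumerate_admissible(list(Xi.columns), Xi.shape[0],
                                 include_mixed=include_mixed, cap=cap)
    sel = select_best(Xi, y, specs, c_delta=c_delta, n_quad=n_quad)
    if mains_best_aic is not None and sel.best_fit.aic > mains_best_aic + 1e-9:
        return None
    return screen_variables(Xi, y, sel, prr_B=prr_B, perm_B=perm_B,
                            alpha=alpha, seed=seed, include_mixed=include_mixed,
                            n_quad=n_quad, category=category)
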