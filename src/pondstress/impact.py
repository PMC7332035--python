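"""Multiplicative impact estimation from a fitted Poisson model.

With the log link, a stressor j with coefficient beta_j on a unit-scaled
intensity column divides the expected richness by exp(-beta_j x_j).  The
*mean impact* evaluates this at the stressor's mean intensity x-bar_j among
ponds, the *maximum impact* at intensity 1 (the worst pond).  Percent loss
is 100 (1 - 1/impact).  The baseline R is the expected richness of a
hypothetical pond free of all contributive stressors, with the remaining
covariates held at their means.  Impacts of multiple stressors are exactly
multiplicative (additive on the log scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .glm import FitResult

__all__ = [
    "ImpactEstimate",
    "impact",
    "percent_loss",
    "impact_ci",
    "stressor_free_richness",
    "combined_impact",
    "impact_report",
]


@dataclass
class ImpactEstimate:
    stressor: str
    beta: float
    x_mean: float
    mean_impact: float
    max_impact: float
    mean_loss_pct: float
    max_loss_pct: float
    mean_ci: tuple[float, float]
    max_ci: tuple[float, float]

    def to_dict(self) -> dict:
        d = vars(self).copy()
        d["mean_ci"] = list(self.mean_ci)
        d["max_ci"] = list(self.max_ci)
        return d


def impact(beta_j: float, x_mean_j: float) -> tuple[float, float]:
    """(mean impact, max impact) = (exp(-beta x-bar), exp(-beta))."""
    return float(np.exp(-beta_j * x_mean_j)), float(np.exp(-beta_j))


def percent_loss(impact_value: float, rounded: bool = False) -> float:
    """Percent loss 100 (1 - 1/impact); optionally rounded to integer
    percent for reporting."""
    if impact_value <= 0:
        raise ValueError("impact must be positive")
    loss = 100.0 * (1.0 - 1.0 / impact_value)
    return float(round(loss)) if rounded else float(loss)


def impact_ci(fit: FitResult, j: int, x_scale: float,
              level: float = 0.95) -> tuple[float, float]:
    """Wald CI for exp(-(beta_j) * x_scale); x_scale is x-bar_j or 1."""
    if fit.cov is None:
        raise ValueError("fit has no coefficient covariance")
    se = np.sqrt(fit.cov[j + 1, j + 1])  # +1 skips the intercept row
    if not np.isfinite(se):
        raise ValueError("singular covariance")
    z = norm.ppf(0.5 + level / 2.0)
    beta = fit.coef[j]
    lo = np.exp(-(beta + z * se) * x_scale)
    hi = np.exp(-(beta - z * se) * x_scale)
    return (float(min(lo, hi)), float(max(lo, hi)))


def stressor_free_richness(fit: FitResult, contributive: list[str],
                           design: pd.DataFrame) -> float:
    """Baseline R = exp(alpha + sum over non-contributive covariates of
    beta_k x-bar_k): contributive stressors at intensity 0, the rest at
    their mean."""
    eta = fit.intercept
    for k, name in enumerate(fit.names):
        if name not in contributive:
            eta += fit.coef[k] * float(design[name].mean())
    return float(np.exp(eta))


def combined_impact(fit: FitResult, stressors: list[str],
                    design: pd.DataFrame, pond=None) -> float:
    """Product over stressors of exp(-beta_j x_{j,i}) at pond i; with
    ``pond=None`` each stressor enters at its mean intensity."""
    log_imp = 0.0
    for s in stressors:
        if s not in fit.names:
            raise ValueError(f"{s!r} is not a term of the fitted model")
        beta = fit.coef[fit.names.index(s)]
        x = float(design[s].mean()) if pond is None else float(design.loc[pond, s])
        log_imp += -beta * x
    return float(np.exp(log_imp))


def impact_report(fit: FitResult, stressors: list[str],
                  design: pd.DataFrame, level: float = 0.95) -> list[ImpactEstimate]:
    """Mean/max impacts with Wald CIs for each stressor of the best model."""
    out = []
    for s in stressors:
        j = fit.names.index(s)
        xbar = float(design[s].mean())
        mean_i, max_i = impact(fit.coef[j], xbar)
        out.append(ImpactEstimate(
            stressor=s, beta=float(fit.coef[j]), x_mean=xbar,
            mean_impact=mean_i, max_impact=max_i,
            mean_loss_pct=percent_loss(mean_i), max_loss_pct=percent_loss(max_i),
            mean_ci=impact_ci(fit, j, xbar, level),
            max_ci=impact_ci(fit, j, 1.0, level),
        ))
    return out


def figure_data(fit: FitResult, stressors: list[str], design: pd.DataFrame,
                y=None) -> pd.DataFrame:
    """Per-pond table behind the impact bar/curve/scatter plots.

    Columns: each stressor's intensity, the combined impact factor, the
    expected richness R / combined, and (when ``y`` is given) the
    scatter value R exp(beta_j x_{j,i}) + residual bookkeeping.
    """
    R = stressor_free_richness(fit, stressors, design)
    rows = []
    for pond in design.index:
        ci = combined_impact(fit, stressors, design, pond=pond)
        row = {"pond": pond, "combined_impact": ci, "expected_richness": R / ci}
        for s in stressors:
            row[f"x[{s}]"] = float(design.loc[pond, s])
        if y is not None:
            row["observed"] = float(np.asarray(y)[list(design.index).index(pond)])
        rows.append(row)
    return pd.DataFrame(rows)
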