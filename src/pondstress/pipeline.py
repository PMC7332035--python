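"""End-to-end orchestration: contract -> select -> screen -> test -> impacts.

``StressorAnalysis`` runs the whole chain for one response category;
``run`` loops it over every category of a dataset and writes the report
bundle (grouping summary, selection traces, p-value matrix, impact and
figure-data tables).

Permutation counts default to a screening resolution (B = 199); the
full-resolution analysis uses B = 1000 (``full_B=True`` or the config).
All randomness flows from one master seed through deterministic
per-(category, variable) streams, so re-runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .contraction import VariableContractor, rescale_unit, write_grouping_report
from .impact import figure_data, impact_report, stressor_free_richness
from .inference import ContributiveReport, interaction_scan, screen_variables
from .selection import BestSubsetAIC, write_trace

__all__ = ["RunConfig", "StressorAnalysis", "run"]


@dataclass
class RunConfig:
    """Reproducible configuration of a full analysis run."""

    correlation_threshold: float = 0.52
    min_explained: float = 0.65
    c_delta_aic: float = 2.0
    alpha: float = 0.05
    prr_B: int = 199
    perm_B: int = 199
    include_mixed: bool = True
    n_quad: int = 21
    seed: int = 0
    categories: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not 0 < self.correlation_threshold < 1:
            raise ValueError("correlation_threshold must be in (0, 1)")
        if not 0 < self.min_explained <= 1:
            raise ValueError("min_explained must be in (0, 1]")
        if self.c_delta_aic < 0:
            raise ValueError("c_delta_aic must be non-negative")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class StressorAnalysis(BaseEstimator):
    """Full stressor screen for one animal category.

    Parameters mirror :class:`RunConfig`.  ``fit(X, y)`` takes the
    uncontracted pond x environmental-variable table and the category's
    richness counts.

    Attributes
    ----------
    contractor_ : VariableContractor
    design_ : DataFrame               unit-scaled contracted design
    selection_ : SelectionResult      best-subset outcome
    report_ : ContributiveReport      main-effect screen and permutation tests
    interaction_report_ : ContributiveReport or None
    impacts_ : list of ImpactEstimate for the significant stressors
    baseline_richness_ : float        stressor-free expected richness R
    """

    def __init__(self, correlation_threshold: float = 0.52,
                 min_explained: float = 0.65, c_delta_aic: float = 2.0,
                 alpha: float = 0.05, prr_B: int = 199, perm_B: int = 199,
                 include_mixed: bool = True, n_quad: int = 21, seed=None,
                 scan_interactions: bool = True):
        self.correlation_threshold = correlation_threshold
        self.min_explained = min_explained
        self.c_delta_aic = c_delta_aic
        self.alpha = alpha
        self.prr_B = prr_B
        self.perm_B = perm_B
        self.include_mixed = include_mixed
        self.n_quad = n_quad
        self.seed = seed
        self.scan_interactions = scan_interactions

    def fit(self, X: pd.DataFrame, y, category: str = ""):
        y = np.asarray(y)
        self.contractor_ = VariableContractor(self.correlation_threshold,
                                              self.min_explained)
        self.design_ = self.contractor_.fit_transform(X)
        member_map = {c: p["members"]
                      for c, p in self.contractor_.provenance_.items()}

        selector = BestSubsetAIC(c_delta=self.c_delta_aic,
                                 include_mixed=self.include_mixed,
                                 n_quad=self.n_quad)
        selector.fit(self.design_, y)
        self.selection_ = selector.result_

        ss = self.seed if isinstance(self.seed, np.random.SeedSequence) \
            else np.random.SeedSequence(self.seed)
        seeds = ss.spawn(2)
        X_unc = rescale_unit(X)
        self.report_ = screen_variables(
            self.design_, y, self.selection_, X_uncontracted=X_unc,
            member_map=member_map, prr_B=self.prr_B, perm_B=self.perm_B,
            alpha=self.alpha, seed=seeds[0], include_mixed=self.include_mixed,
            n_quad=self.n_quad, category=category)

        self.interaction_report_ = None
        if self.scan_interactions and len(self.report_.contributive) >= 2:
            self.interaction_report_ = interaction_scan(
                self.design_, y, self.report_.contributive,
                c_delta=self.c_delta_aic, include_mixed=self.include_mixed,
                n_quad=self.n_quad, prr_B=self.prr_B, perm_B=self.perm_B,
                alpha=self.alpha, seed=seeds[1],
                mains_best_aic=self.selection_.best_fit.aic,
                category=category)

        rep = self._reporting_view()
        fit = rep.selection.best_fit
        design = (self.design_ if rep is self.report_
                  else _with_interactions(self.design_, rep))
        self.impacts_ = impact_report(fit, rep.significant_stressors, design) \
            if rep.significant_stressors else []
        self.baseline_richness_ = stressor_free_richness(
            fit, rep.contributive, design)
        return self

    def _reporting_view(self) -> ContributiveReport:
        """The with-interaction report when it exists (its best AIC is no
        higher than the mains-only best model's), else the main report."""
        return self.interaction_report_ or self.report_

    def summary(self) -> pd.DataFrame:
        frames = [self.report_.frame().assign(scan="mains")]
        if self.interaction_report_ is not None:
            frames.append(self.interaction_report_.frame().assign(scan="interactions"))
        return pd.concat(frames, ignore_index=True)


def _with_interactions(design: pd.DataFrame, rep: ContributiveReport) -> pd.DataFrame:
    from .inference import interaction_candidates
    mains = sorted({v for t in rep.selection.best_spec.variables
                    for v in t.split(":")})
    extra = interaction_candidates(design, mains)
    out = design.copy()
    for c in extra.columns:
        if c not in out:
            out[c] = extra[c]
    return out


def run(env: pd.DataFrame, responses: dict[str, np.ndarray],
        config: RunConfig | None = None, outdir=None) -> dict[str, StressorAnalysis]:
    """Run the full analysis for every category; optionally write reports.

    The report bundle under ``outdir``: ``config.json`` (with digest and
    seed), ``grouping.{tsv,json}``, and per-category selection traces,
    verdict tables, impact tables and figure data.
    """
    config = config or RunConfig()
    cats = config.categories or list(responses)
    results: dict[str, StressorAnalysis] = {}
    ss = np.random.SeedSequence(config.seed)
    cat_seeds = dict(zip(sorted(responses), ss.spawn(len(responses))))
    for cat in cats:
        model = StressorAnalysis(
            correlation_threshold=config.correlation_threshold,
            min_explained=config.min_explained,
            c_delta_aic=config.c_delta_aic, alpha=config.alpha,
            prr_B=config.prr_B, perm_B=config.perm_B,
            include_mixed=config.include_mixed, n_quad=config.n_quad,
            seed=cat_seeds[cat])
        model.fit(env, responses[cat], category=cat)
        results[cat] = model

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = asdict(config)
        meta["config_digest"] = config.digest()
        with open(outdir / "config.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
        first = results[cats[0]]
        write_grouping_report(first.contractor_, outdir / "grouping.tsv",
                              outdir / "grouping.json")
        pmat = []
        for cat, model in results.items():
            write_trace(model.selection_, outdir / f"trace_{cat}.tsv")
            model.summary().to_csv(outdir / f"verdicts_{cat}.tsv",
                                   sep="\t", index=False)
            rep = model._reporting_view()
            for v in rep.verdicts:
                pmat.append({"category": cat, "variable": v.variable,
                             "coefficient": v.coefficient,
                             "prr_p": v.prr_p, "perm_p": v.perm_p,
                             "contributive": v.contributive,
                             "significant": v.significant})
            if model.impacts_:
                pd.DataFrame([e.to_dict() for e in model.impacts_]).to_csv(
                    outdir / f"impacts_{cat}.tsv", sep="\t", index=False)
                design = (model.design_ if rep is model.report_
                          else _with_interactions(model.design_, rep))
                figure_data(rep.selection.best_fit, rep.significant_stressors,
                            design, responses[cat]).to_csv(
                    outdir / f"figure_data_{cat}.tsv", sep="\t", index=False)
        pd.DataFrame(pmat).to_csv(outdir / "pvalue_matrix.tsv", sep="\t",
                                  index=False)
    return results
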