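"""Contraction of correlated environmental variables.

Variables are z-standardised, then grouped by connecting any two variables
whose absolute Pearson correlation exceeds a threshold (default 0.52) and
taking connected components.  Singleton components pass through as "single
variables"; each multi-member component is replaced by the minimal number of
leading principal-component scores explaining more than ``min_explained``
(default 65%) of its variance ("grouped variables").  All resulting columns
are finally rescaled to the range [0, 1], which is the scale the impact
formulas assume (maximum observed intensity = 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

__all__ = [
    "ContractionGroups",
    "GroupedVariable",
    "VariableContractor",
    "standardize",
    "build_groups",
    "represent_group",
    "rescale_unit",
    "contract",
    "grouping_summary",
]


@dataclass
class GroupedVariable:
    """A multi-member contraction group represented by PCA axes."""

    members: list[str]
    loadings: np.ndarray          # (n_axes, n_members), unit-norm rows
    explained: np.ndarray         # explained-variance fraction per retained axis
    axis_names: list[str] = field(default_factory=list)


@dataclass
class ContractionGroups:
    """Partition of variable names into correlation-linked groups."""

    groups: list[list[str]]
    threshold: float

    @property
    def singles(self) -> list[str]:
        return [g[0] for g in self.groups if len(g) == 1]

    @property
    def grouped(self) -> list[list[str]]:
        return [g for g in self.groups if len(g) > 1]


def standardize(X: pd.DataFrame) -> pd.DataFrame:
    """Scale columns to mean 0, sample SD 1 (ddof=1)."""
    X = _as_frame(X)
    sd = X.std(ddof=1)
    bad = sd[(sd == 0) | sd.isna()].index.tolist()
    if bad:
        raise ValueError(f"constant column(s) cannot be standardized: {bad}")
    return (X - X.mean()) / sd


def build_groups(X: pd.DataFrame, threshold: float = 0.52) -> ContractionGroups:
    """Connected components of the graph with edges |Pearson r| > threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    X = _as_frame(X)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 ponds to compute correlations")
    names = list(X.columns)
    r = np.corrcoef(X.to_numpy(dtype=float), rowvar=False)
    adj = (np.abs(r) > threshold).astype(np.int8)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups = [[] for _ in range(n_comp)]
    for name, lab in zip(names, labels):
        groups[lab].append(name)
    # deterministic order: by first member's column position
    pos = {n: i for i, n in enumerate(names)}
    groups.sort(key=lambda g: min(pos[n] for n in g))
    return ContractionGroups(groups=groups, threshold=threshold)


def represent_group(Xg: pd.DataFrame, min_explained: float = 0.65,
                    prefix: str | None = None) -> tuple[pd.DataFrame, GroupedVariable]:
    """PCA scores of a standardized group submatrix.

    Retains the minimal number of leading axes whose cumulative
    explained-variance fraction strictly exceeds ``min_explained``.  Axis
    signs are fixed so the largest-magnitude loading on each axis is
    positive.
    """
    Xg = _as_frame(Xg)
    if Xg.shape[1] < 2:
        raise ValueError("represent_group applies to groups of size >= 2")
    pca = PCA()
    scores = pca.fit_transform(Xg.to_numpy(dtype=float))
    frac = pca.explained_variance_ratio_
    n_axes = int(np.searchsorted(np.cumsum(frac), min_explained, side="right")) + 1
    n_axes = min(n_axes, len(frac))
    load = pca.components_[:n_axes].copy()
    sc = scores[:, :n_axes].copy()
    for a in range(n_axes):
        j = np.argmax(np.abs(load[a]))
        if load[a, j] < 0:
            load[a] *= -1.0
            sc[:, a] *= -1.0
    prefix = prefix or "+".join(Xg.columns[:2])
    axis_names = [f"{prefix}.PC{a + 1}" for a in range(n_axes)]
    gv = GroupedVariable(members=list(Xg.columns), loadings=load,
                         explained=frac[:n_axes].copy(), axis_names=axis_names)
    return pd.DataFrame(sc, index=Xg.index, columns=axis_names), gv


def rescale_unit(X: pd.DataFrame) -> pd.DataFrame:
    """Rescale each column to range exactly [0, 1]."""
    X = _as_frame(X)
    lo, hi = X.min(), X.max()
    bad = lo[(hi - lo) == 0].index.tolist()
    if bad:
        raise ValueError(f"constant column(s) cannot be rescaled: {bad}")
    return (X - lo) / (hi - lo)


class VariableContractor(TransformerMixin, BaseEstimator):
    """Contract correlated explanatory variables to singles + PCA axes.

    Parameters
    ----------
    threshold : float, default 0.52
        Absolute-correlation cutoff for linking two variables.
    min_explained : float, default 0.65
        Minimum cumulative explained-variance fraction (strict) for the
        retained PCA axes of each multi-member group.

    Attributes
    ----------
    groups_ : ContractionGroups
    grouped_variables_ : list of GroupedVariable
    columns_ : list of str
        Names of the contracted columns (singles keep their names; PCA axes
        are named ``<group>.PC<k>``).
    provenance_ : dict mapping contracted column -> {"kind", "members"}
    """

    def __init__(self, threshold: float = 0.52, min_explained: float = 0.65):
        self.threshold = threshold
        self.min_explained = min_explained

    def fit(self, X, y=None):
        self.fit_transform(X, y)
        return self

    def fit_transform(self, X, y=None):
        X = _as_frame(X)
        Z = standardize(X)
        self.groups_ = build_groups(Z, self.threshold)
        blocks: list[pd.DataFrame] = []
        self.grouped_variables_ = []
        self.provenance_ = {}
        for gi, g in enumerate(self.groups_.groups):
            if len(g) == 1:
                blocks.append(Z[[g[0]]])
                self.provenance_[g[0]] = {"kind": "single", "members": g}
            else:
                scores, gv = represent_group(Z[g], self.min_explained,
                                             prefix=f"G{gi + 1}")
                self.grouped_variables_.append(gv)
                blocks.append(scores)
                for ax in gv.axis_names:
                    self.provenance_[ax] = {"kind": "grouped", "members": g}
        design = rescale_unit(pd.concat(blocks, axis=1))
        self.columns_ = list(design.columns)
        self.design_ = design
        return design

    def transform(self, X):
        # the contraction is defined on the full pond set; transform returns
        # the fitted design (stateless projection of new ponds is not part of
        # the procedure)
        if not hasattr(self, "design_"):
            raise ValueError("VariableContractor is not fitted")
        return self.design_


def contract(X: pd.DataFrame, threshold: float = 0.52,
             min_explained: float = 0.65) -> tuple[pd.DataFrame, VariableContractor]:
    """One-shot contraction; returns (unit-scaled design, fitted contractor)."""
    vc = VariableContractor(threshold=threshold, min_explained=min_explained)
    design = vc.fit_transform(X)
    return design, vc


def grouping_summary(vc: VariableContractor) -> pd.DataFrame:
    """Table-style summary of the contraction (one row per contracted column)."""
    rows = []
    for col in vc.columns_:
        prov = vc.provenance_[col]
        rows.append({
            "contracted_variable": col,
            "kind": prov["kind"],
            "n_members": len(prov["members"]),
            "members": ";".join(prov["members"]),
        })
    return pd.DataFrame(rows)


def write_grouping_report(vc: VariableContractor, tsv_path, json_path=None) -> None:
    df = grouping_summary(vc)
    df.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = {
            "threshold": vc.threshold,
            "min_explained": vc.min_explained,
            "n_groups": len(vc.groups_.groups),
            "n_contracted": len(vc.columns_),
            "groups": vc.groups_.groups,
            "grouped_variables": [
                {
                    "members": gv.members,
                    "axes": gv.axis_names,
                    "explained": gv.explained.tolist(),
                }
                for gv in vc.grouped_variables_
            ],
        }
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
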