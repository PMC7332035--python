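"""Reading and preparing pond environment and taxon-incidence tables.

Environmental measurements arrive as a long table with one row per
(pond, variable, sampling occasion).  Aggregation follows the survey's
rules: pesticide concentrations below their detection limit are replaced
by the detection limit before taking the per-pond maximum (compounds never
detected in any pond are dropped); water-quality series are averaged;
static variables are taken as-is.  Derived stressor-oriented transforms
are then added: F-/E-plant noncoverage = 100 - coverage, shallowness =
(maximum depth among ponds) - depth, and the natural log of the dipnet
sampling number as a sampling-effort covariate.

Taxon incidence is a long table with one row per (pond, taxon) presence,
tagged with an animal category and an exclusion flag (invasive aliens and
pest insects are never counted in any response).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import BASE_CATEGORIES, COMPOSITE_CATEGORIES

__all__ = [
    "aggregate_pesticide",
    "aggregate_pesticides",
    "aggregate_water_quality",
    "derive_transforms",
    "build_richness",
    "read_environment_long",
    "read_incidence",
    "read_environment_xlsx",
    "CATEGORIES",
]

CATEGORIES: dict[str, list[str]] = {c: [c] for c in BASE_CATEGORIES}
CATEGORIES.update(COMPOSITE_CATEGORIES)


def aggregate_pesticide(series, detection_limit: float) -> float:
    """Per-pond pesticide summary: substitute sub-detection-limit values
    with the detection limit, then take the maximum over the series."""
    arr = np.asarray(list(series), dtype=float)
    if arr.size == 0:
        raise ValueError("empty measurement series")
    if detection_limit <= 0:
        raise ValueError("detection limit must be positive")
    return float(np.max(np.maximum(arr, detection_limit)))


def aggregate_water_quality(series) -> float:
    """Per-pond water-quality summary: arithmetic mean of the series."""
    arr = np.asarray(list(series), dtype=float)
    if arr.size == 0:
        raise ValueError("empty measurement series")
    return float(np.mean(arr))


def aggregate_pesticides(long_df: pd.DataFrame,
                         detection_limits: dict[str, float]) -> pd.DataFrame:
    """Aggregate a long (pond_id, variable, value) pesticide table.

    Compounds with no raw measurement above their detection limit in any
    pond are dropped from the design.
    """
    out = {}
    for compound, dl in detection_limits.items():
        sub = long_df[long_df["variable"] == compound]
        if sub.empty:
            continue
        if not (sub["value"] > dl).any():
            continue  # never detected anywhere
        out[compound] = sub.groupby("pond_id")["value"].apply(
            lambda s: aggregate_pesticide(s, dl))
    return pd.DataFrame(out)


def derive_transforms(wide: pd.DataFrame) -> pd.DataFrame:
    """Add the stressor-oriented transforms, replacing their sources.

    ``fplant_coverage``/``eplant_coverage`` become noncoverages,
    ``depth`` becomes the shallowness index, and ``dipnet_samples``
    becomes its natural logarithm.  Other columns pass through unchanged.
    """
    wide = wide.copy()
    for src, dst in (("fplant_coverage", "Fplant_noncoverage"),
                     ("eplant_coverage", "Eplant_noncoverage")):
        if src in wide:
            cov = wide.pop(src)
            if ((cov < 0) | (cov > 100)).any():
                raise ValueError(f"{src} outside [0, 100]")
            wide[dst] = 100.0 - cov
    if "depth" in wide:
        depth = wide.pop("depth")
        if (depth <= 0).any():
            raise ValueError("pond depth must be positive")
        wide["Shallowness"] = depth.max() - depth
    if "dipnet_samples" in wide:
        n = wide.pop("dipnet_samples")
        if (n < 1).any():
            raise ValueError("dipnet sample count must be >= 1")
        wide["log_dipnet"] = np.log(n.astype(float))
    return wide


def build_richness(incidence: pd.DataFrame, category: str) -> pd.Series:
    """Distinct-taxon counts per pond for one animal category.

    Excluded taxa (invasive aliens, pest insects) are never counted;
    nested identifications are distinct taxa by construction of the input
    (one row per lowest identified taxon).  Ponds with no taxa in the
    category get a count of 0.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}; expected one of "
                         f"{sorted(CATEGORIES)}")
    base = CATEGORIES[category]
    keep = incidence[~incidence["excluded"].astype(bool)
                     & incidence["category"].isin(base)]
    counts = keep.groupby("pond_id")["taxon"].nunique()
    all_ponds = pd.Index(sorted(incidence["pond_id"].unique()), name="pond_id")
    return counts.reindex(all_ponds, fill_value=0).rename(category)


def read_environment_long(path) -> pd.DataFrame:
    """Read a long environment CSV/TSV: pond_id, variable, occasion, value."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    required = {"pond_id", "variable", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"environment table missing columns: {sorted(missing)}")
    if df["value"].isna().any():
        raise ValueError("missing values are not allowed")
    return df


def read_incidence(path) -> pd.DataFrame:
    """Read a taxon incidence CSV/TSV: pond_id, taxon, category, excluded."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    required = {"pond_id", "taxon", "category"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"incidence table missing columns: {sorted(missing)}")
    if "excluded" not in df.columns:
        df["excluded"] = False
    return df


def read_environment_xlsx(path, sheet: int | str = 0,
                          index_col: int = 0) -> pd.DataFrame:
    """Read a wide ponds-x-variables workbook (shape of a survey's
    supplementary environment tables)."""
    df = pd.read_excel(path, sheet_name=sheet, index_col=index_col)
    if df.isna().any().any():
        raise ValueError("missing values are not allowed")
    return df


def aggregate_environment(long_df: pd.DataFrame,
                          detection_limits: dict[str, float] | None = None,
                          water_quality: list[str] | None = None) -> pd.DataFrame:
    """Full aggregation of a long table to one row per pond.

    ``detection_limits`` names the pesticide columns; ``water_quality``
    names the repeatedly measured properties to average; every other
    variable must have exactly one measurement per pond.
    """
    detection_limits = detection_limits or {}
    water_quality = water_quality or []
    blocks = []
    if detection_limits:
        blocks.append(aggregate_pesticides(long_df, detection_limits))
    if water_quality:
        wq = long_df[long_df["variable"].isin(water_quality)]
        blocks.append(wq.pivot_table(index="pond_id", columns="variable",
                                     values="value", aggfunc="mean"))
    rest = long_df[~long_df["variable"].isin(set(detection_limits) | set(water_quality))]
    if not rest.empty:
        counts = rest.groupby(["pond_id", "variable"]).size()
        if (counts > 1).any():
            dup = counts[counts > 1].index[0][1]
            raise ValueError(f"static variable {dup!r} has repeated measurements")
        blocks.append(rest.pivot(index="pond_id", columns="variable", values="value"))
    wide = pd.concat(blocks, axis=1)
    if wide.isna().any().any():
        raise ValueError("missing values after aggregation (incomplete table)")
    wide.columns.name = None
    return wide
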