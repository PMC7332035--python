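import numpy as np
import pandas as pd
import pytest

from pondstress.ingest import (
    CATEGORIES,
    aggregate_environment,
    aggregate_pesticide,
    aggregate_pesticides,
    aggregate_water_quality,
    build_richness,
    derive_transforms,
    read_environment_long,
    read_environment_xlsx,
    read_incidence,
)
from pondstress.simulate import BASE_CATEGORIES, fixture_incidence_table


@pytest.mark.parametrize("series,dl,expected", [
    ([0.002, 0.004, 0.009], 0.01, 0.01),      # all below DL -> DL
    ([0.005, 0.03, 0.08], 0.01, 0.08),        # max of substituted values
    ([0.008, 0.002], 0.01, 0.01),
    ([0.5], 0.1, 0.5),                         # single value unchanged
])
def test_pesticide_aggregation_substitutes_then_maxes(series, dl, expected):
    assert aggregate_pesticide(series, dl) == pytest.approx(expected)


def test_pesticide_aggregation_rejects_bad_input():
    with pytest.raises(ValueError):
        aggregate_pesticide([], 0.01)
    with pytest.raises(ValueError):
        aggregate_pesticide([0.1], 0.0)


def test_never_detected_compound_is_dropped():
    rows = []
    for pond in range(3):
        for occ in range(4):
            rows.append({"pond_id": pond, "variable": "cmpA", "value": 0.001})
            rows.append({"pond_id": pond, "variable": "cmpB",
                         "value": 0.05 if occ == 2 else 0.001})
    long_df = pd.DataFrame(rows)
    wide = aggregate_pesticides(long_df, {"cmpA": 0.01, "cmpB": 0.01})
    assert list(wide.columns) == ["cmpB"]       # cmpA never above its DL
    assert wide["cmpB"].tolist() == [0.05, 0.05, 0.05]


@pytest.mark.parametrize("series,expected", [
    ([14.0], 14.0),
    ([1, 2, 3, 4, 5, 6, 7], 4.0),
])
def test_water_quality_mean(series, expected):
    assert aggregate_water_quality(series) == pytest.approx(expected)


def test_aggregation_idempotent_on_single_values():
    assert aggregate_water_quality([3.7]) == 3.7
    assert aggregate_pesticide([0.3], 0.01) == 0.3


def _survey_layout_wide():
    rng = np.random.default_rng(0)
    n = 8
    data = {f"pest{i:02d}": rng.uniform(0.01, 1, n) for i in range(30)}
    for wq in ["WT", "pH", "TN", "TP", "SS", "Chla"]:
        data[wq] = rng.uniform(1, 20, n)
    data.update({
        "Ignition_loss": rng.uniform(1, 20, n),
        "Area": rng.uniform(2000, 22000, n),
        "Concrete_bank": rng.uniform(0, 1, n),
        "Pond_drainage": rng.integers(0, 3, n).astype(float),
        "Bluegill": rng.integers(0, 2, n).astype(float),
        "Largemouth_bass": rng.integers(0, 2, n).astype(float),
        "Red_swamp_crayfish": rng.integers(0, 2, n).astype(float),
        "Bullfrog": rng.integers(0, 2, n).astype(float),
        "depth": rng.uniform(0.3, 4.83, n),
        "fplant_coverage": rng.uniform(0, 93, n),
        "eplant_coverage": rng.uniform(0, 90, n),
        "dipnet_samples": rng.integers(3, 14, n).astype(float),
    })
    return pd.DataFrame(data)


def test_derived_transforms_and_full_layout():
    wide = _survey_layout_wide()
    wide.loc[0, "fplant_coverage"] = 93.0
    wide.loc[0, "depth"] = wide["depth"].max() + 1  # make pond 0 the deepest
    wide.loc[0, "dipnet_samples"] = 1.0
    out = derive_transforms(wide)
    assert out.shape[1] == 48                     # survey variable layout
    assert out.loc[0, "Fplant_noncoverage"] == pytest.approx(7.0)
    assert out.loc[0, "Shallowness"] == pytest.approx(0.0)
    assert out.loc[0, "log_dipnet"] == pytest.approx(0.0)
    assert "depth" not in out and "fplant_coverage" not in out


def test_transform_input_errors():
    wide = _survey_layout_wide()
    wide.loc[0, "fplant_coverage"] = 120.0
    with pytest.raises(ValueError):
        derive_transforms(wide)
    wide = _survey_layout_wide()
    wide.loc[0, "depth"] = -1.0
    with pytest.raises(ValueError):
        derive_transforms(wide)


def test_category_partition_and_composites(fixture_data):
    inc = fixture_incidence_table(fixture_data)
    counts = {c: build_richness(inc, c) for c in CATEGORIES}
    base_sum = sum(counts[c] for c in BASE_CATEGORIES)
    pd.testing.assert_series_equal(base_sum, counts["all_sampled"],
                                   check_names=False)
    large = sum(counts[c] for c in
                ["reptile", "fish", "mollusk", "crustacean", "large_insect"])
    pd.testing.assert_series_equal(large, counts["large_animals"],
                                   check_names=False)
    invert = counts["all_sampled"] - counts["vertebrates"]
    pd.testing.assert_series_equal(invert, counts["invertebrates"],
                                   check_names=False)


def test_excluded_taxa_never_counted(fixture_data):
    inc = fixture_incidence_table(fixture_data)
    with_excl = build_richness(inc, "fish")
    without = build_richness(inc[~inc["excluded"]], "fish")
    pd.testing.assert_series_equal(with_excl, without)
    assert inc["excluded"].any()  # the fixture does contain excluded rows


def test_empty_pond_counts_zero():
    inc = pd.DataFrame({
        "pond_id": [1, 1, 2],
        "taxon": ["a", "b", "a"],
        "category": ["fish", "fish", "fish"],
        "excluded": [False, False, False],
    })
    inc = pd.concat([inc, pd.DataFrame({
        "pond_id": [3], "taxon": ["z"], "category": ["annelid"],
        "excluded": [False]})], ignore_index=True)
    counts = build_richness(inc, "fish")
    assert counts.loc[3] == 0
    assert counts.loc[1] == 2


def test_unknown_category_rejected():
    inc = pd.DataFrame({"pond_id": [1], "taxon": ["a"],
                        "category": ["fish"], "excluded": [False]})
    with pytest.raises(ValueError, match="unknown category"):
        build_richness(inc, "amphibian")


def test_aggregate_environment_full_long_table():
    rows = []
    for pond in [10, 11]:
        for occ in range(7):
            rows.append({"pond_id": pond, "variable": "pestX",
                         "occasion": occ, "value": 0.001 + 0.01 * occ})
            rows.append({"pond_id": pond, "variable": "WT",
                         "occasion": occ, "value": 10.0 + occ})
        rows.append({"pond_id": pond, "variable": "depth",
                     "occasion": 0, "value": 2.0 + pond / 10})
    wide = aggregate_environment(pd.DataFrame(rows),
                                 detection_limits={"pestX": 0.01},
                                 water_quality=["WT"])
    assert wide.loc[10, "pestX"] == pytest.approx(0.061)
    assert wide.loc[10, "WT"] == pytest.approx(13.0)
    assert wide.loc[11, "depth"] == pytest.approx(3.1)


def test_static_variable_with_repeats_rejected():
    rows = [{"pond_id": 1, "variable": "depth", "occasion": i, "value": 2.0}
            for i in range(2)]
    with pytest.raises(ValueError, match="repeated"):
        aggregate_environment(pd.DataFrame(rows))


def test_readers_round_trip(tmp_path, fixture_data):
    env = fixture_data.environment
    # long CSV
    long_rows = env.reset_index().melt(id_vars="pond_id", var_name="variable")
    long_path = tmp_path / "env_long.csv"
    long_rows.to_csv(long_path, index=False)
    back = read_environment_long(long_path)
    assert set(back.columns) >= {"pond_id", "variable", "value"}
    # incidence TSV
    inc = fixture_incidence_table(fixture_data)
    inc_path = tmp_path / "incidence.tsv"
    inc.to_csv(inc_path, sep="\t", index=False)
    back_inc = read_incidence(inc_path)
    assert len(back_inc) == len(inc)
    # wide XLSX shaped like the supplementary environment table
    xlsx = tmp_path / "env.xlsx"
    env.to_excel(xlsx)
    back_x = read_environment_xlsx(xlsx)
    assert np.allclose(back_x.to_numpy(), env.to_numpy())


def test_missing_values_rejected(tmp_path):
    df = pd.DataFrame({"pond_id": [1], "variable": ["WT"], "value": [np.nan]})
    p = tmp_path / "bad.csv"
    df.to_csv(p, index=False)
    with pytest.raises(ValueError, match="missing"):
        read_environment_long(p)
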