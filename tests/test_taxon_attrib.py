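import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mpmeta.aggregate import (
    FeatureTable,
    aggregate_deepest_taxon_function,
    aggregate_functions,
)
from mpmeta.peptide_io import filter_microbial, renormalize
from mpmeta.taxon_attrib import (
    attribution_matrix,
    genus_specificity,
    paired_t,
    phylum_contrast,
)


def tf_table(dataset_id, rows, subjects):
    """rows: {(taxon, function): [values]}"""
    df = pd.DataFrame(rows).T.set_axis(subjects, axis=1).astype(float)
    df.index = pd.MultiIndex.from_tuples(df.index, names=["taxon", "function"])
    return FeatureTable(dataset_id, "genus-KO", df)


# --- paired t ---------------------------------------------------------------

def test_paired_t_matches_scipy_reference():
    rng = np.random.default_rng(0)
    a = rng.normal(5, 2, 20)
    b = rng.normal(4, 2, 20)
    t, p = paired_t(a - b)
    ref = stats.ttest_rel(a, b)
    assert t == pytest.approx(ref.statistic, abs=1e-10)
    assert p == pytest.approx(ref.pvalue, abs=1e-10)


def test_paired_t_zero_variance_rules():
    assert paired_t(np.zeros(5)) == (0.0, 1.0)
    t, p = paired_t(np.full(5, 0.7))
    assert p == 0.0 and t > 0 and not math.isfinite(t)


# --- phylum contrast --------------------------------------------------------

def _contrast_tables(seed=0, n=10):
    rng = np.random.default_rng(seed)
    subj = [f"s{i}" for i in range(n)]
    rows = {
        ("Bacillota", "K00001"): rng.uniform(1, 5, n),
        ("Bacteroidota", "K00001"): rng.uniform(1, 5, n),
        ("Bacillota", "K00002"): rng.uniform(2, 4, n),
        ("Bacteroidota", "K00002"): rng.uniform(0.5, 1, n),
    }
    return [FeatureTable("d1", "phylum-KO",
                         pd.DataFrame(rows).T.set_axis(subj, axis=1)
                         .set_axis(pd.MultiIndex.from_tuples(rows), axis=0))]


def test_identical_phyla_give_null_result():
    subj = ["s1", "s2", "s3"]
    vals = [2.0, 3.0, 4.0]
    t = tf_table("d1", {("Bacillota", "K1"): vals, ("Bacteroidota", "K1"): vals}, subj)
    res = phylum_contrast([t], pseudocount=0.0)
    row = res.iloc[0]
    assert row.mean_log_ratio == 0.0 and row.t == 0.0 and row.p == 1.0


def test_constant_doubling_gives_log2_ratio_and_degenerate_p():
    subj = ["s1", "s2", "s3"]
    t = tf_table("d1", {("Bacillota", "K1"): [2, 4, 8],
                        ("Bacteroidota", "K1"): [1, 2, 4]}, subj)
    res = phylum_contrast([t], pseudocount=0.0)
    row = res.iloc[0]
    assert row.mean_log_ratio == pytest.approx(math.log(2))
    assert row.degenerate and row.p == 0.0


def test_contrast_matches_textbook_oracle():
    tabs = _contrast_tables(seed=1, n=20)
    res = phylum_contrast(tabs, pseudocount=0.0)
    df = tabs[0].data
    for _, row in res.iterrows():
        a = np.log(df.loc[("Bacillota", row.function)].to_numpy())
        b = np.log(df.loc[("Bacteroidota", row.function)].to_numpy())
        ref = stats.ttest_rel(a, b)
        assert row.t == pytest.approx(ref.statistic, abs=1e-10)
        assert row.p == pytest.approx(ref.pvalue, abs=1e-10)


def test_contrast_antisymmetry():
    tabs = _contrast_tables(seed=2)
    ab = phylum_contrast(tabs, "Bacillota", "Bacteroidota").set_index("function")
    ba = phylum_contrast(tabs, "Bacteroidota", "Bacillota").set_index("function")
    for f in ab.index:
        assert ab.loc[f, "mean_log_ratio"] == pytest.approx(-ba.loc[f, "mean_log_ratio"])
        assert ab.loc[f, "p"] == pytest.approx(ba.loc[f, "p"], abs=1e-12)


def test_contrast_log_base_switch():
    subj = ["s1", "s2", "s3", "s4"]
    t = tf_table("d1", {("Bacillota", "K1"): [2, 4, 8, 3],
                        ("Bacteroidota", "K1"): [1, 2, 4, 1.5]}, subj)
    nat = phylum_contrast([t], pseudocount=0.0).iloc[0]
    b2 = phylum_contrast([t], pseudocount=0.0, log_base=2).iloc[0]
    assert b2.mean_log_ratio == pytest.approx(1.0)
    assert nat.mean_log_ratio == pytest.approx(math.log(2))


# --- genus specificity ------------------------------------------------------

def spec_table(missing, shares, subjects=("s1", "s2"), function="K1", ds="d1"):
    """One function with given missing fraction and genus shares (of total)."""
    total = 10.0
    rows = {("unassigned", function): [missing * total / len(subjects)] * len(subjects)}
    for g, sh in shares.items():
        rows[(g, function)] = [(1 - missing) * sh * total / len(subjects)] * len(subjects)
    return tf_table(ds, rows, list(subjects))


@pytest.mark.parametrize(
    "missing,shares,expected",
    [
        (0.2, {"A": 0.95, "B": 0.05}, "genus-specific"),
        (0.6, {"A": 0.95, "B": 0.05}, "not-evaluable"),
        (0.5, {"A": 0.95, "B": 0.05}, "not-evaluable"),  # boundary: >= 50%
        (0.1, {"A": 0.6, "B": 0.4}, "shared"),
        (0.1, {"A": 0.9, "B": 0.1}, "genus-specific"),   # boundary: >= 90%
        (0.1, {"A": 0.8, "B": 0.2}, "intermediate"),
        (0.1, {"A": 0.75, "B": 0.25}, "intermediate"),   # boundary: not < 75%
        (0.1, {"A": 0.7499, "B": 0.2501}, "shared"),
    ],
)
def test_specificity_classification_rules(missing, shares, expected):
    res = genus_specificity([spec_table(missing, shares)])
    assert res.iloc[0]["class"] == expected
    if expected != "not-evaluable":
        assert res.iloc[0]["top_genus"] == "A"
        assert res.iloc[0]["top_share"] == pytest.approx(max(shares.values()))


def test_specificity_averages_unweighted_across_datasets():
    t1 = spec_table(0.2, {"A": 1.0}, ds="d1")
    t2 = spec_table(0.4, {"A": 0.8, "B": 0.2}, ds="d2")
    res = genus_specificity([t1, t2])
    assert res.iloc[0]["missing_frac"] == pytest.approx(0.3)
    assert res.iloc[0]["top_share"] == pytest.approx(0.9)
    assert res.iloc[0]["class"] == "genus-specific"


def test_specificity_invariant_to_dataset_rescaling():
    t1 = spec_table(0.3, {"A": 0.92, "B": 0.08}, ds="d1")
    scaled = FeatureTable("d1", "genus-KO", t1.data * 37.5)
    r1 = genus_specificity([t1])
    r2 = genus_specificity([scaled])
    assert r1.iloc[0]["class"] == r2.iloc[0]["class"]
    assert r1.iloc[0]["top_share"] == pytest.approx(r2.iloc[0]["top_share"])


def test_specificity_shares_sum_to_one():
    t = spec_table(0.2, {"A": 0.5, "B": 0.3, "C": 0.2})
    res = genus_specificity([t])
    assert res.iloc[0]["top_share"] == pytest.approx(0.5)


# --- attribution matrix -----------------------------------------------------

def deep_table(ds, rows, subjects):
    df = pd.DataFrame(rows).T.set_axis(subjects, axis=1).astype(float)
    df.index = pd.MultiIndex.from_tuples(df.index, names=["taxon", "function"])
    return FeatureTable(ds, "deepest-KO", df)


def test_attribution_detection_boundary_strict():
    # K00001 detected in exactly 6 of 7 datasets -> excluded (> 6 required);
    # K00002 in all 7 -> kept
    tabs = []
    for d in range(7):
        rows = {("genus:G1", "K00002"): [1.0, 1.0]}
        if d < 6:
            rows[("genus:G1", "K00001")] = [1.0, 1.0]
        tabs.append(deep_table(f"d{d}", rows, ["s1", "s2"]))
    mat = attribution_matrix(tabs, ["K00001", "K00002"], min_datasets=6)
    assert list(mat.columns) == ["K00002"]


def test_attribution_single_genus_carries_total():
    tabs = [
        deep_table(f"d{d}", {("genus:G1", "K00001"): [2.0, 4.0]}, ["s1", "s2"])
        for d in range(8)
    ]
    mat = attribution_matrix(tabs, ["K00001"], min_datasets=6)
    assert mat.loc["genus:G1", "K00001"] == pytest.approx(3.0)
    assert mat.loc["total", "K00001"] == pytest.approx(3.0)


def test_attribution_totals_match_plain_ko_means_on_synthetic(small_cohort):
    datasets, _ = small_cohort
    normed = [renormalize(filter_microbial(d)) for d in datasets]
    deep = [aggregate_deepest_taxon_function(d, "KO") for d in normed]
    plain = [aggregate_functions(d, "KO") for d in normed]
    kos = sorted(plain[0].data.index[:20])
    mat = attribution_matrix(deep, kos, plain_ko_tables=plain,
                             min_datasets=1, min_mean_pct=0.0)
    plain_means = pd.concat(
        [t.data.reindex(mat.columns, fill_value=0.0).mean(axis=1) for t in plain],
        axis=1,
    ).mean(axis=1)
    assert np.allclose(mat.loc["total"].to_numpy(), plain_means.to_numpy(), atol=1e-9)


def test_attribution_empty_ko_list_rejected():
    with pytest.raises(ValueError):
        attribution_matrix([], [])
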