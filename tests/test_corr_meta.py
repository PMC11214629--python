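import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mpmeta.aggregate import FeatureTable
from mpmeta.corr_meta import (
    bh_adjust,
    correlate_with_covariate,
    fisher_z,
    meta_correlate,
    order_by_clustering,
    reml_combine,
    reml_criterion,
    rho_matrix,
    select_pathways,
    select_top_ko,
    spearman,
)


def ft(dataset_id, data, subjects):
    return FeatureTable(dataset_id, "KO", pd.DataFrame(data).T.set_axis(subjects, axis=1).astype(float))


# --- spearman ---------------------------------------------------------------

def test_spearman_monotone_cases():
    x = np.arange(10.0)
    assert spearman(x, np.exp(x))[0] == pytest.approx(1.0)
    assert spearman(x, -x ** 3)[0] == pytest.approx(-1.0)


def test_spearman_matches_rank_then_pearson():
    x = np.array([1, 2, 3, 4, 5.0])
    y = np.array([3, 1, 2, 5, 4.0])
    rho, n = spearman(x, y)
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    oracle = np.corrcoef(rx, ry)[0, 1]
    assert n == 5 and rho == pytest.approx(oracle, abs=1e-12)


def test_spearman_degenerate_and_short_inputs():
    assert math.isnan(spearman([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])[0])
    with pytest.raises(ValueError):
        spearman([1, 2, 3], [1, 2, 3])


# --- fisher z ---------------------------------------------------------------

def test_fisher_z_values():
    z, v = fisher_z(0.0, 10)
    assert z == 0.0 and v == pytest.approx(1 / 7)
    z, v = fisher_z(0.5, 20)
    assert z == pytest.approx(0.5 * math.log(3), abs=1e-12)
    assert v == pytest.approx(1 / 17)
    assert fisher_z(0.5, 20, "fieller")[1] == pytest.approx(1.06 / 17)


def test_fisher_z_round_trip_and_clamp():
    for rho in (-0.9, -0.3, 0.0, 0.42, 0.97):
        z, _ = fisher_z(rho, 30)
        assert math.tanh(z) == pytest.approx(rho, abs=1e-12)
    with pytest.warns(UserWarning):
        z, _ = fisher_z(1.0, 30)
    assert math.isfinite(z)


# --- REML -------------------------------------------------------------------

def test_reml_zero_heterogeneity_identical_inputs():
    res = reml_combine([0.3, 0.3], [0.1, 0.1])
    assert res.mu == pytest.approx(0.3, abs=1e-10)
    assert res.tau2 == 0.0


def test_reml_with_equal_variances_mu_between_inputs():
    res = reml_combine([0.1, 0.5], [0.1, 0.1])
    # equal variances: mu is the arithmetic mean regardless of tau2
    assert res.mu == pytest.approx(0.3, abs=1e-10)
    assert res.tau2 >= 0.0 and res.se > 0 and 0 <= res.p <= 1


def test_reml_requires_two_studies_and_positive_variances():
    with pytest.raises(ValueError, match="2 datasets"):
        reml_combine([0.3], [0.1])
    with pytest.raises(ValueError):
        reml_combine([0.1, 0.2], [0.1, 0.0])


def grid_reml(zs, vs, hi=2.0):
    """Two-stage exhaustive grid maximization of the REML criterion."""
    zs, vs = np.asarray(zs), np.asarray(vs)
    coarse = np.arange(0.0, hi + 1e-12, 1e-4)
    c = [reml_criterion(t, zs, vs) for t in coarse]
    t0 = coarse[int(np.argmin(c))]
    fine = np.arange(max(0.0, t0 - 2e-4), t0 + 2e-4, 1e-6)
    cf = [reml_criterion(t, zs, vs) for t in fine]
    tau2 = float(fine[int(np.argmin(cf))])
    w = 1.0 / (vs + tau2)
    return tau2, float(np.dot(w, zs) / w.sum())


def test_reml_matches_grid_oracle_on_spec_example():
    zs, vs = [0.1, 0.5, 0.9], [0.04, 0.05, 0.06]
    tau2_g, mu_g = grid_reml(zs, vs)
    res = reml_combine(zs, vs)
    assert res.tau2 == pytest.approx(tau2_g, abs=1e-5)
    assert res.mu == pytest.approx(mu_g, abs=1e-6)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_reml_matches_metafor():
    """Independent cross-check against the reference REML implementation."""
    zs = [0.12, 0.55, 0.30, -0.10, 0.48]
    vs = [0.05, 0.08, 0.04, 0.10, 0.06]
    script = (
        "suppressMessages(library(metafor));"
        f"r <- rma(yi=c({','.join(map(str, zs))}), vi=c({','.join(map(str, vs))}),"
        "method='REML', control=list(tol=1e-10));"
        "cat(sprintf('%.10f %.10f %.10f', r$b[1], r$tau2, r$se))"
    )
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
    )
    assert out.returncode == 0, out.stderr
    mu_r, tau2_r, se_r = map(float, out.stdout.split())
    res = reml_combine(zs, vs)
    assert res.mu == pytest.approx(mu_r, abs=1e-6)
    assert res.tau2 == pytest.approx(tau2_r, abs=1e-5)
    assert res.se == pytest.approx(se_r, abs=1e-5)


def test_back_transformed_rho_within_input_range_when_homogeneous():
    rng = np.random.default_rng(5)
    for _ in range(20):
        rhos = rng.uniform(-0.6, 0.6, size=4)
        zvs = [fisher_z(r, 20) for r in rhos]
        res = reml_combine([z for z, _ in zvs], [v for _, v in zvs])
        if res.tau2 == 0.0:
            assert min(rhos) - 1e-12 <= math.tanh(res.mu) <= max(rhos) + 1e-12


# --- BH ---------------------------------------------------------------------

def bh_definitional(p):
    """Literal step-up definition, O(m^2)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for pos, idx in enumerate(order, start=1):
        q[idx] = min(
            min(p[order[j - 1]] * m / j for j in range(pos, m + 1)), 1.0
        )
    return q


def test_bh_examples():
    assert bh_adjust([0.03]) == pytest.approx([0.03])
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests
    rng = np.random.default_rng(1)
    p = rng.random(200)
    q = bh_adjust(p)
    _, q_sm, _, _ = multipletests(p, method="fdr_bh")
    assert np.allclose(q, q_sm, atol=1e-12)


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
@settings(max_examples=100, deadline=None)
def test_bh_properties(p):
    q = bh_adjust(p)
    assert np.all(q >= np.asarray(p) - 1e-15)  # q >= p
    assert np.all((q >= 0) & (q <= 1))
    # monotone in p-rank: sorting p sorts q
    order = np.argsort(p, kind="mergesort")
    assert np.all(np.diff(q[order]) >= -1e-15)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.1, 1.5])


# --- meta_correlate / selection --------------------------------------------

def _three_dataset_tables(rho_sign=1.0, seed=0):
    rng = np.random.default_rng(seed)
    tabs = []
    for d in range(3):
        n = 12
        x = rng.random(n) * 10
        y = rho_sign * x + rng.normal(0, 1.0, n)
        z = rng.random(n) * 5
        tabs.append(ft(f"d{d}", {"A": x, "B": y, "C": z},
                       [f"d{d}s{i}" for i in range(n)]))
    return tabs


def test_meta_correlate_identical_rows_give_clamped_rho_one():
    tabs = []
    rng = np.random.default_rng(2)
    for d in range(3):
        x = rng.random(8)
        tabs.append(ft(f"d{d}", {"A": x, "B": x.copy(), "C": rng.random(8)},
                       [f"d{d}s{i}" for i in range(8)]))
    res = meta_correlate(tabs)
    ab = res[(res.featureA == "A") & (res.featureB == "B")].iloc[0]
    assert ab.rho_combined == pytest.approx(1.0, abs=1e-4)
    assert ab.q == res.q.min()


def test_meta_correlate_skips_constant_features_and_small_k():
    tabs = _three_dataset_tables()
    # make C constant in two datasets -> only 1 defined rho -> not pooled
    for t in tabs[:2]:
        t.data.loc["C"] = 1.0
    res = meta_correlate(tabs)
    ac = res[(res.featureA == "A") & (res.featureB == "C")].iloc[0]
    assert ac.k == 1 and not ac.pooled and math.isnan(ac.q)
    ab = res[(res.featureA == "A") & (res.featureB == "B")].iloc[0]
    assert ab.pooled and ab.k == 3


def test_select_top_ko_rules():
    s = pd.DataFrame({
        "mean_pct": [9.0, 8.0, 7.0, 6.0],
        "mean_det_freq": [1.0, 0.75, 0.74, 1.0],
        "core_datasets": [True, True, True, False],
    }, index=["ribo", "boundary", "lowdet", "notalld"])
    got = select_top_ko(s, n=4, ribosomal_kos={"ribo"})
    # detection boundary 0.75 included (>=); 9/10-dataset feature excluded
    assert got == ["boundary"]
    with_ribo = select_top_ko(s, n=4, ribosomal_kos={"ribo"},
                              exclude_ribosomal=False)
    assert with_ribo == ["ribo", "boundary"]


def test_select_pathways_strict_threshold():
    s = pd.DataFrame({
        "mean_pct": [1.0, 1.01, 5.0],
        "core_subjects": [True, True, False],
    }, index=["at", "above", "notcore"])
    assert select_pathways(s) == ["above"]
    # lowering the threshold never removes pathways
    assert set(select_pathways(s, 0.5)) >= set(select_pathways(s))


def test_covariate_self_copy_is_top_hit():
    tabs = _three_dataset_tables()
    meta_rows = []
    for t in tabs:
        for s in t.data.columns:
            meta_rows.append({"subject": s, "dataset": t.dataset_id,
                              "age": float(t.data.loc["A", s])})
    metadata = pd.DataFrame(meta_rows)
    res = correlate_with_covariate(tabs, metadata, "age")
    best = res.sort_values("q").iloc[0]
    assert best.feature == "A" and best.rho_combined == pytest.approx(1.0, abs=1e-4)


def test_covariate_constant_or_missing():
    tabs = _three_dataset_tables()
    meta_rows = [
        {"subject": s, "dataset": t.dataset_id, "age": 50.0}
        for t in tabs for s in t.data.columns
    ]
    res = correlate_with_covariate(tabs, pd.DataFrame(meta_rows), "age")
    assert (~res.pooled).all()  # constant covariate: every dataset skipped
    with pytest.raises(ValueError):
        correlate_with_covariate(tabs, pd.DataFrame(meta_rows), "bmi")


# --- clustering order -------------------------------------------------------

def naive_average_linkage(d):
    """O(n^3) agglomeration; returns the merge sequence as frozensets."""
    clusters = {i: [i] for i in range(len(d))}
    merges = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                dist = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or dist < best[0] - 1e-15:
                    best = (dist, a, b)
        dist, a, b = best
        merges.append((frozenset(clusters[a]), frozenset(clusters[b]), dist))
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return merges


def test_correlated_pair_adjacent_in_ordering():
    rho = pd.DataFrame(
        [[1.0, 0.95, -0.8], [0.95, 1.0, -0.7], [-0.8, -0.7, 1.0]],
        index=list("abc"), columns=list("abc"),
    )
    order = order_by_clustering(rho)
    ia, ib = order.index("a"), order.index("b")
    assert abs(ia - ib) == 1


def test_identity_matrix_keeps_input_order():
    rho = pd.DataFrame(np.eye(4), index=list("wxyz"), columns=list("wxyz"))
    assert order_by_clustering(rho) == list("wxyz")


def test_linkage_merge_heights_match_naive_oracle():
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform
    rng = np.random.default_rng(3)
    r = rng.uniform(-1, 1, size=(5, 5))
    r = (r + r.T) / 2
    np.fill_diagonal(r, 1.0)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    merges = naive_average_linkage(d)
    Z = linkage(squareform(d, checks=False), method="average")
    assert np.allclose(sorted(m[2] for m in merges), sorted(Z[:, 2]), atol=1e-12)
    # and the module's ordering is a permutation consistent with that tree
    rho = pd.DataFrame(r, index=list("abcde"), columns=list("abcde"))
    order = order_by_clustering(rho)
    assert sorted(order) == list("abcde")


def test_rho_matrix_is_symmetric_with_unit_diagonal():
    tabs = _three_dataset_tables()
    res = meta_correlate(tabs)
    m = rho_matrix(res, ["A", "B", "C"])
    assert np.allclose(m.to_numpy(), m.to_numpy().T)
    assert np.allclose(np.diag(m.to_numpy()), 1.0)
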