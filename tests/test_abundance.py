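import numpy as np
import pandas as pd
import pytest

from herdqg import abundance as ab


def _table(counts, depth=None):
    counts = np.asarray(counts)
    return ab.OtuTable(
        counts,
        [f"s{i}" for i in range(counts.shape[0])],
        [f"o{j}" for j in range(counts.shape[1])],
        depth=depth,
    )


# ---------------------------------------------------------------------------
# filtering


def test_filter_threshold_is_inclusive():
    t = _table(np.array([[600, 599, 2500], [600, 600, 2500]]))
    out = ab.filter_sparse_otus(t, min_total=1200)
    assert out.otu_ids == ["o0", "o2"]  # totals 1200, 1199, 5000


def test_filter_zero_threshold_is_identity_and_oracle():
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 50, size=(12, 30))
    t = _table(counts)
    assert ab.filter_sparse_otus(t, 0).otu_ids == t.otu_ids
    for thr in (10, 100, 400):
        got = set(ab.filter_sparse_otus(t, thr).otu_ids)
        want = {f"o{j}" for j in range(30) if counts[:, j].sum() >= thr}
        assert got == want
    with pytest.raises(ab.AbundanceError, match="threshold"):
        ab.filter_sparse_otus(t, 10**9)


# ---------------------------------------------------------------------------
# rarefaction


def test_rarefy_row_sums_and_support():
    rng = np.random.default_rng(1)
    counts = rng.integers(0, 400, size=(10, 25))
    t = _table(counts)
    depth = int(counts.sum(axis=1).min())
    out = ab.rarefy(t, depth, seed=4)
    assert (out.counts.sum(axis=1) == depth).all()
    assert np.all(out.counts <= counts)  # no OTU appears that was absent


def test_rarefy_exact_depth_is_identity():
    counts = np.array([[4, 3, 3]])
    out = ab.rarefy(_table(counts), 10, seed=0)
    assert np.array_equal(out.counts, counts)


def test_rarefy_drops_shallow_samples_with_warning():
    t = _table([[50, 50], [2, 3]])
    with pytest.warns(UserWarning, match="below depth"):
        out = ab.rarefy(t, 60, seed=0)
    assert out.sample_ids == ["s0"]


def test_rarefy_hypergeometric_mean():
    """An OTU holding half the reads keeps depth/2 on average."""
    total, depth = 2000, 500
    counts = np.tile([total // 2, total // 4, total // 4], (400, 1))
    t = ab.OtuTable(counts, [f"s{i}" for i in range(400)], ["a", "b", "c"])
    out = ab.rarefy(t, depth, seed=7)
    draws = out.counts[:, 0]
    mean = depth / 2
    # hypergeometric variance with finite-population correction
    var = depth * 0.5 * 0.5 * (total - depth) / (total - 1)
    se = np.sqrt(var / 400)
    assert abs(draws.mean() - mean) < 3 * se


# ---------------------------------------------------------------------------
# aggregation and transforms


@pytest.fixture()
def toy_tax():
    return ab.TaxonomyMap(
        {
            "o0": {"phylum": "Firmicutes", "genus": "Clostridium"},
            "o1": {"phylum": "Firmicutes", "genus": "Clostridium"},
            "o2": {"phylum": "Bacteroidetes", "genus": "Prevotella"},
        }
    )


def test_aggregate_sums_within_rank_and_conserves_totals(toy_tax):
    t = _table([[1, 2, 3], [4, 5, 6]])
    m = ab.aggregate_taxa(t, toy_tax, "genus")
    frame = m.to_frame()
    assert frame["Clostridium"].tolist() == [3, 9]
    assert frame["Prevotella"].tolist() == [3, 6]
    assert np.array_equal(m.values.sum(axis=1), t.counts.sum(axis=1))


def test_aggregate_unmapped_goes_to_unclassified(toy_tax):
    t = _table([[1, 2, 3, 4], [0, 0, 0, 1]])  # o3 unmapped
    m = ab.aggregate_taxa(t, toy_tax, "phylum")
    assert set(m.taxa) == {"Firmicutes", "Bacteroidetes", "unclassified"}
    with pytest.raises(ab.AbundanceError, match="valid"):
        ab.aggregate_taxa(t, toy_tax, "kingdom")


def test_relative_abundance_values_and_idempotence():
    m = ab.relative_abundance(_table([[10, 30, 60]]))
    assert m.values[0] == pytest.approx([0.1, 0.3, 0.6])
    again = ab.relative_abundance(m)
    assert np.allclose(again.values, m.values)
    with pytest.raises(ab.AbundanceError, match="zero-sum"):
        ab.relative_abundance(_table([[0, 0]]))


def test_log_center_rows_have_zero_mean():
    rng = np.random.default_rng(3)
    counts = rng.integers(0, 100, size=(6, 12))
    counts[:, 0] = 0  # force zeros handled by pseudocount
    counts[:, 1] += 1
    m = ab.log_center_transform(ab.relative_abundance(_table(counts + 1)))
    assert np.allclose(m.values.mean(axis=1), 0.0, atol=1e-9)


def test_log_center_closed_form_two_taxa():
    m = ab.AbundanceMatrix(
        np.array([[0.1, 0.9]]), ["s"], ["a", "b"], transform="relative"
    )
    out = ab.log_center_transform(m)
    c = 0.5 * (np.log(0.1) + np.log(0.9))
    assert out.values[0] == pytest.approx([np.log(0.1) - c, np.log(0.9) - c])


# ---------------------------------------------------------------------------
# coverage


@pytest.mark.parametrize(
    "counts, expected",
    [([5, 3, 2], 1.0), ([1, 1], 0.0), ([4, 1], 0.8)],
)
def test_goods_coverage_closed_forms(counts, expected):
    cov = ab.goods_coverage(_table([counts]))
    assert cov.iloc[0] == pytest.approx(expected)


def test_goods_coverage_empty_sample_missing():
    cov = ab.goods_coverage(_table([[0, 0], [3, 1]]))
    assert np.isnan(cov.iloc[0])
    assert cov.iloc[1] == pytest.approx(0.75)


# ---------------------------------------------------------------------------
# Kruskal-Wallis screen


def test_kruskal_wallis_matches_rank_formula_oracle():
    """Groups (1,2,3) vs (4,5,6): H = 12/(n(n+1)) * sum n_i (Rbar_i - Rbar)^2
    = 27/7 with no ties."""
    m = ab.AbundanceMatrix(
        np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]]),
        [f"s{i}" for i in range(6)], ["t"],
    )
    out = ab.kruskal_wallis_screen(m, np.array(list("aaabbb")))
    assert out.loc["t", "H"] == pytest.approx(27 / 7, abs=1e-9)


def test_kruskal_wallis_constant_taxon_and_bonferroni():
    rng = np.random.default_rng(5)
    vals = rng.normal(0, 1, size=(20, 100))
    vals[:, 0] = 7.0  # constant
    vals[:10, 1] += 50.0  # huge shift
    m = ab.AbundanceMatrix(vals, [f"s{i}" for i in range(20)],
                           [f"t{j}" for j in range(100)])
    groups = np.array(["x"] * 10 + ["y"] * 10)
    out = ab.kruskal_wallis_screen(m, groups)
    assert out.loc["t0", "H"] == 0.0
    assert out.loc["t0", "p_adj"] == 1.0
    assert out.loc["t1", "p_adj"] == pytest.approx(
        min(1.0, out.loc["t1", "p_raw"] * 100)
    )


def test_kruskal_wallis_two_group_matches_scipy_rank_sum():
    """Cross-check against an independent exhaustive rank statistic on all
    two-group splits of 6 values."""
    from itertools import combinations

    from scipy import stats

    vals = np.array([3.1, 0.2, 5.5, 2.2, 4.4, 1.0])
    for idx in combinations(range(6), 3):
        groups = np.array(["b"] * 6)
        groups[list(idx)] = "a"
        m = ab.AbundanceMatrix(vals[:, None], [f"s{i}" for i in range(6)], ["t"])
        ours = ab.kruskal_wallis_screen(m, groups).loc["t", "H"]
        ref = stats.kruskal(vals[groups == "a"], vals[groups == "b"])[0]
        assert ours == pytest.approx(ref, abs=1e-12)


# ---------------------------------------------------------------------------
# PCA


def test_pca_collinear_data_single_component():
    x = np.arange(10.0)
    m = ab.AbundanceMatrix(
        np.column_stack([x, 2 * x]), [f"s{i}" for i in range(10)], ["a", "b"]
    )
    res = ab.pca_composition(m)
    assert res.proportion[0] == pytest.approx(100.0)


def test_pca_contributions_sum_to_100():
    rng = np.random.default_rng(8)
    m = ab.AbundanceMatrix(
        rng.normal(size=(15, 6)), [f"s{i}" for i in range(15)],
        [f"t{j}" for j in range(6)],
    )
    res = ab.pca_composition(m)
    assert res.contributions.sum(axis=0).to_numpy() == pytest.approx(
        [100.0, 100.0], abs=1e-6
    )
    assert np.all(np.diff(res.proportion) <= 1e-9)  # non-increasing


def test_pca_eigenvalues_match_characteristic_polynomial():
    """3x2 toy matrix: eigenvalues of the 2x2 covariance from the quadratic
    formula."""
    X = np.array([[0.0, 0.0], [1.0, 2.0], [3.0, 1.0]])
    m = ab.AbundanceMatrix(X, ["s0", "s1", "s2"], ["a", "b"])
    C = np.cov(X.T)
    tr, det = C[0, 0] + C[1, 1], C[0, 0] * C[1, 1] - C[0, 1] ** 2
    lam = np.array(
        [(tr + np.sqrt(tr**2 - 4 * det)) / 2, (tr - np.sqrt(tr**2 - 4 * det)) / 2]
    )
    res = ab.pca_composition(m)
    got = res.proportion / 100 * lam.sum()
    assert got == pytest.approx(lam, abs=1e-10)


def test_pca_reconstruction():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(12, 5))
    m = ab.AbundanceMatrix(X, [f"s{i}" for i in range(12)],
                           [f"t{j}" for j in range(5)])
    res = ab.pca_composition(m)
    rec = res.reconstruct(X.mean(axis=0))
    assert np.linalg.norm(rec - X) < 1e-8


# ---------------------------------------------------------------------------
# I/O round trip


def test_otu_tsv_round_trip(tmp_path, toy_tax):
    t = _table([[1, 2, 3], [4, 5, 6]])
    path = tmp_path / "otu.tsv"
    ab.write_otu_table(t, path, toy_tax)
    back, tax = ab.read_otu_table(path)
    assert np.array_equal(back.counts, t.counts)
    assert back.sample_ids == t.sample_ids
    assert back.otu_ids == t.otu_ids
    assert tax is not None
    assert tax.rank_label("o0", "genus") == "Clostridium"
    assert tax.rank_label("o0", "species") == "unclassified"
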