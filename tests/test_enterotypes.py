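from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from herdqg import enterotypes as et
from herdqg.abundance import AbundanceMatrix


def _mat(values, rank="genus"):
    v = np.asarray(values, dtype=float)
    return AbundanceMatrix(
        v, [f"s{i}" for i in range(v.shape[0])],
        [f"g{j}" for j in range(v.shape[1])], rank=rank, transform="relative",
    )


# ---------------------------------------------------------------------------
# Jensen-Shannon distance


def test_jsd_identical_profiles_zero():
    d = et.jsd_distance_matrix(_mat([[0.3, 0.7], [0.3, 0.7]]))
    assert d.d[0, 1] == pytest.approx(0.0, abs=1e-6)


def test_jsd_disjoint_profiles_maximal():
    d = et.jsd_distance_matrix(_mat([[1.0, 0.0], [0.0, 1.0]]))
    assert d.d[0, 1] == pytest.approx(np.sqrt(np.log(2)), abs=1e-4)


def test_jsd_hand_value():
    """JSD((.5,.5),(1,0)) = 0.2157 via M=(0.75,0.25); distance 0.4645."""
    d = et.jsd_distance_matrix(_mat([[0.5, 0.5], [1.0, 0.0]]))
    assert d.d[0, 1] ** 2 == pytest.approx(0.2157, abs=1e-4)
    assert d.d[0, 1] == pytest.approx(0.4645, abs=1e-4)


def test_jsd_matches_scipy_pairwise():
    from scipy.spatial.distance import jensenshannon

    rng = np.random.default_rng(0)
    P = rng.dirichlet(np.ones(8), size=6)
    d = et.jsd_distance_matrix(_mat(P)).d
    for i in range(6):
        for j in range(6):
            assert d[i, j] == pytest.approx(
                jensenshannon(P[i], P[j]), abs=1e-6
            )


def test_sqrt_jsd_triangle_inequality():
    rng = np.random.default_rng(42)
    P = rng.dirichlet(np.full(10, 0.5), size=60)
    D = et.jsd_distance_matrix(_mat(P)).d
    trips = rng.integers(0, 60, size=(1000, 3))
    for i, j, k in trips:
        assert D[i, k] <= D[i, j] + D[j, k] + 1e-12


def test_jsd_rejects_negative():
    with pytest.raises(et.EnterotypeError):
        et.jsd_distance_matrix(np.array([[-0.1, 1.1], [0.5, 0.5]]))


# ---------------------------------------------------------------------------
# PAM


def _exhaustive_kmedoids(D, k):
    n = D.shape[0]
    best, best_obj = None, np.inf
    for med in combinations(range(n), k):
        obj = D[:, med].min(axis=1).sum()
        if obj < best_obj - 1e-12:
            best, best_obj = med, obj
    return best, best_obj


@pytest.mark.parametrize("n, k, seed", [(6, 2, 0), (8, 2, 1), (8, 3, 2), (7, 3, 3)])
def test_pam_matches_exhaustive_kmedoids(n, k, seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 2))
    D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
    labels, medoids = et.pam_cluster(D, k)
    _, best_obj = _exhaustive_kmedoids(D, k)
    assert et.pam_objective(D, medoids) == pytest.approx(best_obj, abs=1e-10)


@pytest.mark.parametrize("seed", range(6))
def test_pam_heuristic_close_to_exact_and_never_better(seed):
    """BUILD+SWAP is a descent method: it can only match or exceed the
    exhaustive optimum, and on mildly structured data it stays close."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(12, 2))
    D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
    _, med_h = et.pam_cluster(D, 3, exact=False)
    _, best_obj = _exhaustive_kmedoids(D, 3)
    obj_h = et.pam_objective(D, med_h)
    assert obj_h >= best_obj - 1e-10
    assert obj_h <= 1.2 * best_obj


@pytest.mark.parametrize("exact", [True, False])
def test_pam_recovers_planted_split(exact):
    rng = np.random.default_rng(7)
    X = np.vstack([rng.normal(0, 0.1, (30, 2)), rng.normal(10, 0.1, (30, 2))])
    D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
    labels, _ = et.pam_cluster(D, 2, exact=exact)
    assert len(set(labels[:30])) == 1 and len(set(labels[30:])) == 1
    assert labels[0] != labels[30]


def test_pam_k_equals_n_minus_one():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(6, 2))
    D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
    labels, medoids = et.pam_cluster(D, 5)
    off = D[np.triu_indices(6, 1)]
    assert et.pam_objective(D, medoids) == pytest.approx(off.min())


def test_pam_rejects_bad_k():
    D = np.zeros((3, 3))
    with pytest.raises(et.EnterotypeError):
        et.pam_cluster(D, 3)


# ---------------------------------------------------------------------------
# cluster indices


def test_ch_infinite_for_point_masses():
    # two exact point clouds: within-cluster dispersion zero
    D = np.array(
        [[0, 0, 5, 5], [0, 0, 5, 5], [5, 5, 0, 0], [5, 5, 0, 0]], dtype=float
    )
    ch = et.calinski_harabasz(D, np.array([0, 0, 1, 1]))
    assert np.isinf(ch)


def test_pcoa_embedding_reproduces_euclidean_distances():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(10, 4))
    D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
    Y = et.pcoa_embedding(D)
    D2 = np.sqrt(((Y[:, None] - Y[None]) ** 2).sum(-1))
    assert np.linalg.norm(D - D2) < 1e-6


def test_ch_agrees_with_sklearn_on_euclidean_data():
    from sklearn.metrics import calinski_harabasz_score

    rng = np.random.default_rng(5)
    X = np.vstack([rng.normal(0, 1, (15, 3)), rng.normal(4, 1, (15, 3))])
    D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
    labels = np.repeat([0, 1], 15)
    ours = et.calinski_harabasz(D, labels)
    ref = calinski_harabasz_score(X, labels)
    assert ours == pytest.approx(ref, rel=1e-6)


def test_silhouette_hand_case_and_equidistant():
    # 4 points, two tight pairs far apart
    D = np.array(
        [
            [0.0, 1.0, 10.0, 11.0],
            [1.0, 0.0, 9.0, 10.0],
            [10.0, 9.0, 0.0, 1.0],
            [11.0, 10.0, 1.0, 0.0],
        ]
    )
    labels = np.array([0, 0, 1, 1])
    mean_s, s = et.silhouette_width(D, labels)
    # hand: s(0) = (10.5-1)/10.5, s(1)=(9.5-1)/9.5, symmetric for 2,3
    expect = np.array([9.5 / 10.5, 8.5 / 9.5, 8.5 / 9.5, 9.5 / 10.5])
    assert s == pytest.approx(expect)
    # all equidistant: a == b so s == 0
    De = np.ones((4, 4)) - np.eye(4)
    _, se = et.silhouette_width(De, labels)
    assert se == pytest.approx(np.zeros(4), abs=1e-12)


# ---------------------------------------------------------------------------
# selection on planted mixtures


def _planted(rng, templates, n_per, conc=150.0):
    rows, labels = [], []
    for t_i, tmpl in enumerate(templates):
        for _ in range(n_per):
            rows.append(rng.dirichlet(conc * np.asarray(tmpl)))
            labels.append(t_i)
    return _mat(np.array(rows)), np.array(labels)


def test_select_enterotypes_recovers_planted_k():
    rng = np.random.default_rng(0)
    t1 = [0.55, 0.15, 0.1, 0.1, 0.05, 0.05]
    t2 = [0.05, 0.15, 0.1, 0.1, 0.05, 0.55]
    t3 = [0.1, 0.1, 0.55, 0.05, 0.15, 0.05]
    m2, lab2 = _planted(rng, [t1, t2], 40)
    fit2 = et.select_enterotypes(m2, (2, 6))
    assert fit2.k == 2
    from sklearn.metrics import adjusted_rand_score

    assert adjusted_rand_score(lab2, fit2.assignments.to_numpy()) > 0.95
    m3, lab3 = _planted(rng, [t1, t2, t3], 30)
    fit3 = et.select_enterotypes(m3, (2, 6))
    assert fit3.k == 3
    assert adjusted_rand_score(lab3, fit3.assignments.to_numpy()) > 0.95


def test_select_enterotypes_flags_structureless_data():
    rng = np.random.default_rng(1)
    m, _ = _planted(rng, [[1 / 6] * 6], 60, conc=30.0)
    with pytest.warns(UserWarning, match="unstable"):
        fit = et.select_enterotypes(m, (2, 6))
    assert fit.stability_warning


# ---------------------------------------------------------------------------
# LDA effect size


def _lda_frame(rng, n=40, shift_ppm=0.0):
    """Two classes differing only in genera 0 and 2 (mass moved between
    them, so row sums stay constant); class B reuses class A's exact values
    for genera 3+ to make them identical across classes."""
    base = rng.dirichlet(np.full(8, 20.0), size=n)
    a = base.copy()
    delta = np.minimum(shift_ppm / 1e6, 0.9 * a[:, 2])
    a[:, 0] += delta
    a[:, 2] -= delta
    rows = np.vstack([a, base])
    labels = np.repeat(["A", "B"], n)
    return _mat(rows), labels


def test_lda_null_genus_excluded_strong_genus_passes():
    rng = np.random.default_rng(2)
    m, labels = _lda_frame(rng, shift_ppm=3e5)
    res = et.lda_effect_size(m, labels, seed=0)
    tab = res.table
    assert tab.iloc[0]["significant"]
    assert tab.iloc[0]["lda_score"] > 2
    assert tab.iloc[0]["enriched_class"] == "A"
    # identical-distribution genera rarely pass KW at alpha; none should
    # clear the LDA threshold
    assert not tab.iloc[3:]["significant"].any()


def test_lda_label_swap_negates_scores():
    rng = np.random.default_rng(3)
    m, labels = _lda_frame(rng, shift_ppm=2e5)
    r1 = et.lda_effect_size(m, labels, n_boot=0)
    swapped = np.where(labels == "A", "B", "A")
    r2 = et.lda_effect_size(m, swapped, n_boot=0)
    assert np.allclose(r1.table["lda_score"], -r2.table["lda_score"])
    assert (
        r1.table["lda_score"].abs().rank().tolist()
        == r2.table["lda_score"].abs().rank().tolist()
    )


def test_lda_scores_monotone_in_planted_effect():
    from scipy.stats import spearmanr

    rng = np.random.default_rng(4)
    shifts = [2e4, 5e4, 1e5, 2e5, 4e5]
    scores = []
    for s in shifts:
        m, labels = _lda_frame(rng, shift_ppm=s)
        r = et.lda_effect_size(m, labels, seed=1)
        scores.append(abs(r.table.iloc[0]["lda_score"]))
    rho, _ = spearmanr(shifts, scores)
    assert rho > 0.9


def test_lda_requires_two_populated_classes():
    rng = np.random.default_rng(5)
    m, labels = _lda_frame(rng)
    with pytest.raises(et.EnterotypeError):
        et.lda_effect_size(m, np.array(["A"] * len(labels)))


# ---------------------------------------------------------------------------
# transitions and family association


def test_transitions_hand_tally():
    a = pd.Series([1, 1, 1, 2, 2, 2, 2, 1, 2, 1],
                  index=[f"p{i}" for i in range(10)])
    b = pd.Series([1, 2, 1, 2, 2, 1, 2, 1, 2, 2],
                  index=[f"p{i}" for i in range(10)])
    out = et.enterotype_transitions({"t1": a, "t2": b})
    tab = out[("t1", "t2")]
    counts = tab["count"]
    assert counts.loc[1, 1] == 3 and counts.loc[1, 2] == 2
    assert counts.loc[2, 1] == 1 and counts.loc[2, 2] == 4
    pct = tab["percent"]
    assert pct.sum(axis=1).tolist() == pytest.approx([100.0, 100.0])


def test_transitions_identity_when_labels_stable():
    a = pd.Series([1, 2, 1, 2], index=list("wxyz"))
    out = et.enterotype_transitions({"t1": a, "t2": a})
    pct = out[("t1", "t2")]["percent"]
    assert pct.loc[1, 1] == 100.0 and pct.loc[2, 2] == 100.0
    assert pct.loc[1, 2] == 0.0


def test_family_association_chi_square_oracle():
    fam = pd.Series(np.repeat(["f1", "f2"], 40))
    ent = pd.Series([1] * 30 + [2] * 10 + [1] * 10 + [2] * 30)
    chi2, dof, p, tab = et.enterotype_family_association(ent, fam)
    # direct sum((O-E)^2/E): all expected 20, all |O-E| = 10 -> 4*100/20
    assert chi2 == pytest.approx(20.0)
    assert dof == 1
    assert p < 1e-4


def test_family_association_null_table():
    fam = pd.Series(np.repeat(["f1", "f2"], 20))
    ent = pd.Series([1, 2] * 20)
    chi2, dof, p, _ = et.enterotype_family_association(ent, fam)
    assert chi2 == pytest.approx(0.0)
    assert p == pytest.approx(1.0)
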