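"""Enterotype discovery and characterization.

Samples are clustered on the square root of the Jensen-Shannon divergence
between genus-level relative-abundance profiles (a metric), using
partitioning around medoids (PAM): exact enumeration on tiny instances and
the deterministic BUILD+SWAP heuristic otherwise.  The
number of clusters is chosen by maximizing the Calinski-Harabasz index in a
principal-coordinates embedding of the distance matrix; mean silhouette width
is reported alongside.  Genera driving the separation between the two
enterotypes are ranked by a LEfSe-style LDA effect size, and longitudinal
stability is summarized by per-animal transition tables plus a sire-family
association chi-square.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import silhouette_samples

from .abundance import AbundanceMatrix, relative_abundance


class EnterotypeError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    d: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape[0] != d.shape[1]:
            raise EnterotypeError("distance matrix not square")
        self.d = d


# ---------------------------------------------------------------------------
# Jensen-Shannon distance


def jsd_distance_matrix(
    m: AbundanceMatrix | np.ndarray,
    pseudocount: float = 1e-10,
    sample_ids: list[str] | None = None,
) -> DistanceMatrix:
    """Pairwise sqrt-JSD between rows of a relative-abundance matrix.

    Zeros are replaced by ``pseudocount`` and rows renormalized; natural log
    throughout, so distances are bounded by sqrt(ln 2).
    """
    if isinstance(m, AbundanceMatrix):
        if m.transform != "relative":
            m = relative_abundance(m)
        P = m.values
        ids = list(m.sample_ids)
    else:
        P = np.asarray(m, dtype=float)
        ids = sample_ids or [str(i) for i in range(P.shape[0])]
    if np.any(P < 0):
        raise EnterotypeError("negative abundances")
    P = np.where(P <= 0, pseudocount, P)
    P = P / P.sum(axis=1, keepdims=True)
    # JSD(P,Q) = H((P+Q)/2) - (H(P)+H(Q))/2 with H in nats
    logP = np.log(P)
    h = -(P * logP).sum(axis=1)  # per-row entropy
    n = P.shape[0]
    D = np.zeros((n, n))
    # blockwise to bound memory on large n
    block = max(1, int(2e7 // max(1, P.shape[1] * n)))
    for start in range(0, n, block):
        stop = min(n, start + block)
        M = 0.5 * (P[start:stop, None, :] + P[None, :, :])
        hM = -(M * np.log(M)).sum(axis=2)
        jsd = hM - 0.5 * (h[start:stop, None] + h[None, :])
        D[start:stop] = jsd
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(np.sqrt(np.maximum(D, 0.0)), ids)


# ---------------------------------------------------------------------------
# PAM (k-medoids, deterministic BUILD + SWAP)


def pam_cluster(
    dist: DistanceMatrix | np.ndarray,
    k: int,
    max_iter: int = 200,
    exact: bool | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Partitioning around medoids; returns (labels in 0..k-1, medoid indices).

    Tiny instances (at most ~3000 candidate medoid sets) are solved exactly
    by enumeration; larger ones use the deterministic BUILD+SWAP heuristic —
    BUILD greedily adds the medoid that most reduces the total distance of
    every point to its nearest medoid, SWAP exchanges a medoid with a
    non-medoid while any exchange lowers the objective.  Ties break on the
    lowest sample index, so the procedure is fully deterministic either way.
    """
    D = dist.d if isinstance(dist, DistanceMatrix) else np.asarray(dist)
    n = D.shape[0]
    if not 1 <= k < n:
        raise EnterotypeError(f"need 1 <= k < n, got k={k}, n={n}")
    if exact is None:
        exact = _n_choose_k(n, k) <= 3000
    if exact:
        from itertools import combinations

        best, best_obj = None, np.inf
        for med in combinations(range(n), k):
            obj = D[:, med].min(axis=1).sum()
            if obj < best_obj - 1e-12:
                best, best_obj = med, obj
        medoids = np.array(best)
        labels = np.argmin(D[:, medoids], axis=1)
        return labels, medoids
    # BUILD
    medoids = [int(np.argmin(D.sum(axis=1)))]
    dn = D[:, medoids[0]].copy()  # distance to nearest medoid
    while len(medoids) < k:
        gains = np.minimum(dn[None, :], D).sum(axis=1)
        gains[medoids] = np.inf
        medoids.append(int(np.argmin(gains)))
        dn = np.minimum(dn, D[:, medoids[-1]])
    medoids = sorted(medoids)
    # SWAP
    for _ in range(max_iter):
        Dm = D[:, medoids]  # n x k
        order = np.argsort(Dm, axis=1)
        dn = Dm[np.arange(n), order[:, 0]]
        ds = Dm[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)
        best = (0.0, None)
        current = dn.sum()
        med_mask = np.zeros(n, dtype=bool)
        med_mask[medoids] = True
        for mi, m in enumerate(medoids):
            in_m = order[:, 0] == mi
            # objective if medoid m is replaced by candidate h, all h at once
            base = np.where(in_m, ds, dn)
            sums = np.minimum(base[:, None], D).sum(axis=0)
            sums[med_mask] = np.inf
            h = int(np.argmin(sums))
            delta = sums[h] - current
            if delta < best[0] - 1e-12:
                best = (delta, (mi, h))
        if best[1] is None:
            break
        mi, h = best[1]
        medoids[mi] = h
        medoids = sorted(medoids)
    Dm = D[:, medoids]
    labels = np.argmin(Dm, axis=1)
    return labels, np.array(medoids)


def pam_objective(D: np.ndarray, medoids: np.ndarray) -> float:
    return float(D[:, medoids].min(axis=1).sum())


def _n_choose_k(n: int, k: int) -> int:
    from math import comb

    return comb(n, k)


# ---------------------------------------------------------------------------
# cluster-number indices


def pcoa_embedding(dist: DistanceMatrix | np.ndarray, tol: float = 1e-9):
    """Classical principal coordinates; negative-eigenvalue axes dropped."""
    D = dist.d if isinstance(dist, DistanceMatrix) else np.asarray(dist)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = 0.5 * (B + B.T)
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > tol * max(1.0, vals.max())
    return vecs[:, keep] * np.sqrt(vals[keep])


def calinski_harabasz(
    dist: DistanceMatrix | np.ndarray,
    labels: np.ndarray,
    coords: np.ndarray | None = None,
) -> float:
    """CH = [B/(k-1)] / [W/(n-k)] in a PCoA embedding of the distances.

    Zero within-cluster dispersion returns +inf.
    """
    labels = np.asarray(labels)
    ks = np.unique(labels)
    if len(ks) < 2:
        raise EnterotypeError("CH undefined for a single cluster")
    X = coords if coords is not None else pcoa_embedding(dist)
    n = X.shape[0]
    overall = X.mean(axis=0)
    W = 0.0
    B = 0.0
    for c in ks:
        Xi = X[labels == c]
        ci = Xi.mean(axis=0)
        W += ((Xi - ci) ** 2).sum()
        B += len(Xi) * ((ci - overall) ** 2).sum()
    k = len(ks)
    if W <= 1e-12:
        return np.inf
    return float((B / (k - 1)) / (W / (n - k)))


def silhouette_width(
    dist: DistanceMatrix | np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean and per-sample silhouette on the precomputed distances."""
    D = dist.d if isinstance(dist, DistanceMatrix) else np.asarray(dist)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise EnterotypeError("silhouette requires k >= 2")
    s = silhouette_samples(D, labels, metric="precomputed")
    return float(s.mean()), s


# ---------------------------------------------------------------------------
# enterotype selection


@dataclass
class EnterotypeFit:
    assignments: pd.Series  # sample_id -> 1..k
    medoids: list[str]
    k: int
    ch_by_k: dict[int, float]
    silhouette_by_k: dict[int, float]
    labels_by_k: dict[int, np.ndarray] = field(repr=False, default_factory=dict)
    stability_warning: bool = False


def select_enterotypes(
    m: AbundanceMatrix,
    k_range: range | tuple[int, int] = (2, 10),
    pseudocount: float = 1e-10,
) -> EnterotypeFit:
    """JSD -> PAM over a range of k; the k maximizing CH is chosen.

    Sexes are analyzed combined.  A flat CH curve (max within 5% of the
    median over k) raises a stability warning flag instead of a confident
    cluster number.
    """
    if isinstance(k_range, tuple):
        ks = list(range(k_range[0], k_range[1] + 1))
    else:
        ks = list(k_range)
    if not ks:
        raise EnterotypeError("empty k range")
    dist = jsd_distance_matrix(m, pseudocount=pseudocount)
    n = dist.d.shape[0]
    ks = [k for k in ks if 1 < k < n]
    if not ks:
        raise EnterotypeError(f"no feasible k for n={n}")
    coords = pcoa_embedding(dist)
    ch, sil, labs = {}, {}, {}
    for k in ks:
        labels, med = pam_cluster(dist, k)
        ch[k] = calinski_harabasz(dist, labels, coords=coords)
        sil[k] = silhouette_width(dist, labels)[0]
        labs[k] = labels
    finite = {k: v for k, v in ch.items() if np.isfinite(v)}
    ref = finite if finite else ch
    chosen = max(ref, key=lambda k: ref[k])
    vals = np.array([v for v in ch.values() if np.isfinite(v)])
    flat = vals.size > 1 and (vals.max() - np.median(vals)) < 0.25 * abs(
        np.median(vals)
    )
    if flat:
        warnings.warn("CH curve is flat across k; cluster number is unstable")
    labels = labs[chosen]
    _, med = pam_cluster(dist, chosen)
    return EnterotypeFit(
        assignments=pd.Series(
            labels + 1, index=dist.sample_ids, name="enterotype"
        ),
        medoids=[dist.sample_ids[i] for i in med],
        k=chosen,
        ch_by_k=ch,
        silhouette_by_k=sil,
        labels_by_k=labs,
        stability_warning=bool(flat),
    )


# ---------------------------------------------------------------------------
# LDA effect size (LEfSe-style, two classes)


@dataclass
class LdaResult:
    table: pd.DataFrame  # genus, enriched_class, lda_score, kw_p, significant

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def lda_effect_size(
    m: AbundanceMatrix,
    labels: np.ndarray | pd.Series,
    alpha: float = 0.05,
    threshold: float = 2.0,
    n_boot: int = 30,
    seed: int | None = 0,
    ridge: float = 1e-6,
) -> LdaResult:
    """Two-class LDA effect size after a Kruskal-Wallis significance filter.

    Abundances are rescaled per sample to sum to one million.  For each genus
    passing KW at ``alpha``, the effect size is log10 of the absolute average
    of (i) the raw class-mean difference and (ii) the class-mean difference of
    the genus's component along the unit-norm Fisher discriminant axis
    (ridge-regularized pooled covariance), averaged over ``n_boot`` bootstrap
    resamples (``n_boot=0`` gives a single deterministic fit).  The sign marks
    the enriched class; |score| must exceed ``threshold`` (strictly) for the
    significant set.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise EnterotypeError(f"need exactly two classes, got {classes}")
    for c in classes:
        if (labels == c).sum() < 2:
            raise EnterotypeError(f"class {c!r} has < 2 samples")
    X = np.asarray(m.values, dtype=float)
    X = X / X.sum(axis=1, keepdims=True) * 1e6

    kw_p = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.all(col == col[0]):
            kw_p[j] = 1.0
        else:
            kw_p[j] = stats.kruskal(col[labels == classes[0]],
                                    col[labels == classes[1]])[1]
    retained = kw_p < alpha

    rng = np.random.default_rng(seed)
    reps = max(1, n_boot)
    scores_acc = np.zeros(X.shape[1])
    for _ in range(reps):
        if n_boot == 0:
            idx = np.arange(len(labels))
        else:
            idx = np.concatenate(
                [
                    rng.choice(np.flatnonzero(labels == c),
                               (labels == c).sum(), replace=True)
                    for c in classes
                ]
            )
        Xb, lb = X[idx], labels[idx]
        mu = [Xb[lb == c].mean(axis=0) for c in classes]
        raw_diff = mu[0] - mu[1]
        # Fisher axis with ridge-regularized pooled covariance
        Sw = sum(np.cov(Xb[lb == c].T, bias=False) * ((lb == c).sum() - 1)
                 for c in classes) / (len(lb) - 2)
        Sw = np.atleast_2d(Sw)
        lam = ridge * np.trace(Sw) / Sw.shape[0] + 1e-12
        w = np.linalg.solve(Sw + lam * np.eye(Sw.shape[0]), raw_diff)
        nw = np.linalg.norm(w)
        if nw > 0:
            w = w / nw
        # per-feature component along the axis, class-mean difference
        proj_diff = w * raw_diff  # feature contribution difference
        eff = 0.5 * (np.abs(raw_diff) + np.abs(proj_diff))
        scores_acc += eff
        if n_boot == 0:
            break
    eff = scores_acc / (1 if n_boot == 0 else reps)
    with np.errstate(divide="ignore"):
        mag = np.where(eff > 0, np.log10(1.0 + eff), 0.0)
    mu_all = [X[labels == c].mean(axis=0) for c in classes]
    sign = np.where(mu_all[0] >= mu_all[1], 1.0, -1.0)
    enriched = np.where(sign > 0, classes[0], classes[1])
    score = sign * mag
    table = pd.DataFrame(
        {
            "enriched_class": enriched,
            "lda_score": score,
            "kw_p": kw_p,
            "retained": retained,
            "significant": retained & (np.abs(score) > threshold),
        },
        index=pd.Index(m.taxa, name=m.rank),
    )
    return LdaResult(table)


# ---------------------------------------------------------------------------
# longitudinal structure


def enterotype_transitions(
    assignments: dict[str, pd.Series],
    animal_of_sample: pd.Series | None = None,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Source -> destination contingency tables between consecutive fits.

    ``assignments`` maps time-point name -> per-sample enterotype labels; the
    index is matched on animal id (via ``animal_of_sample`` if sample ids are
    not animal ids).  Row percentages sum to 100.
    """
    times = list(assignments)
    out = {}
    for a, b in zip(times[:-1], times[1:]):
        sa, sb = assignments[a], assignments[b]
        if animal_of_sample is not None:
            sa = sa.rename(index=animal_of_sample)
            sb = sb.rename(index=animal_of_sample)
        shared = sa.index.intersection(sb.index)
        if len(shared) == 0:
            warnings.warn(f"no shared animals between {a} and {b}")
            out[(a, b)] = pd.DataFrame()
            continue
        tab = pd.crosstab(sa.loc[shared], sb.loc[shared])
        tab.index.name = a
        tab.columns.name = b
        pct = tab.div(tab.sum(axis=1), axis=0) * 100.0
        out[(a, b)] = pd.concat({"count": tab, "percent": pct}, axis=1)
    return out


def enterotype_family_association(
    assignments: pd.Series, family: pd.Series
) -> tuple[float, int, float, pd.DataFrame]:
    """Pearson chi-square of the family x enterotype contingency table."""
    df = pd.DataFrame({"enterotype": assignments, "family": family}).dropna()
    tab = pd.crosstab(df["family"], df["enterotype"])
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise EnterotypeError("need >= 2 families and >= 2 enterotypes")
    chi2, p, dof, expected = stats.chi2_contingency(tab, correction=False)
    if (expected < 1).any():
        warnings.warn("expected cell count < 1; chi-square approximation weak")
    return float(chi2), int(dof), float(p), tab
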