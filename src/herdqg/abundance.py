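"""OTU-table processing: filtering, rarefaction, aggregation, transforms,
coverage, differential-abundance screening, and compositional PCA.

Counts live in an :class:`OtuTable` (integer samples x OTUs); derived real
matrices (relative abundance, log-centered) are :class:`AbundanceMatrix`
objects tagged with their transform so downstream steps can assert the input
they expect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

RANKS = ("phylum", "class", "order", "family", "genus", "species")
UNCLASSIFIED = "unclassified"


class AbundanceError(ValueError):
    pass


@dataclass
class OtuTable:
    """Integer count matrix, samples x OTUs, with optional rarefaction depth."""

    counts: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]
    depth: int | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise AbundanceError("negative counts")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise AbundanceError("duplicate sample ids")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise AbundanceError("duplicate OTU ids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)


@dataclass
class TaxonomyMap:
    """otu_id -> 7-rank lineage; missing ranks propagate as unclassified."""

    lineages: dict[str, dict[str, str]]

    def rank_label(self, otu_id: str, rank: str) -> str:
        if rank not in RANKS:
            raise AbundanceError(f"unknown rank {rank!r}; valid: {RANKS}")
        lin = self.lineages.get(otu_id)
        if lin is None:
            return UNCLASSIFIED
        return lin.get(rank, UNCLASSIFIED) or UNCLASSIFIED


@dataclass
class AbundanceMatrix:
    """Real samples x taxa matrix at a named rank with a transform tag."""

    values: np.ndarray
    sample_ids: list[str]
    taxa: list[str]
    rank: str = "otu"
    transform: str = "counts"  # counts | relative | log-centered | per-million

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxa)


# ---------------------------------------------------------------------------
# I/O: classic QIIME-style TSV


def read_otu_table(path: str | Path) -> tuple[OtuTable, TaxonomyMap | None]:
    """Read a classic tab-separated OTU table (first column OTU id, one column
    per sample, optional trailing semicolon-delimited taxonomy column)."""
    df = pd.read_csv(path, sep="\t", comment=None, dtype=str)
    first = df.columns[0]
    if first.startswith("#"):
        df = df.rename(columns={first: "otu_id"})
    else:
        df = df.rename(columns={first: "otu_id"})
    tax = None
    cols = list(df.columns[1:])
    if cols and cols[-1].lower() in ("taxonomy", "consensus lineage", "lineage"):
        taxcol = cols.pop()
        tax = TaxonomyMap(
            {
                str(o): _parse_lineage(t)
                for o, t in zip(df["otu_id"], df[taxcol])
            }
        )
        df = df.drop(columns=[taxcol])
    counts = df[cols].astype(float).to_numpy().T  # samples x OTUs
    if not np.allclose(counts, np.round(counts)):
        warnings.warn("non-integer counts rounded")
    table = OtuTable(
        np.round(counts).astype(np.int64), cols, [str(o) for o in df["otu_id"]]
    )
    return table, tax


def write_otu_table(
    table: OtuTable, path: str | Path, tax: TaxonomyMap | None = None
) -> None:
    df = pd.DataFrame(
        table.counts.T, index=pd.Index(table.otu_ids, name="#OTU ID"),
        columns=table.sample_ids,
    )
    if tax is not None:
        df["taxonomy"] = [
            "; ".join(
                tax.rank_label(o, r) for r in RANKS
            )
            for o in table.otu_ids
        ]
    df.to_csv(path, sep="\t")


def _parse_lineage(s: str | float) -> dict[str, str]:
    if not isinstance(s, str) or not s.strip():
        return {}
    parts = [p.strip() for p in s.split(";")]
    out = {}
    for rank, part in zip(RANKS, parts):
        label = part.split("__")[-1] if "__" in part else part
        out[rank] = label if label else UNCLASSIFIED
    return out


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read otu_id <tab> semicolon-delimited lineage."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    id_col, lin_col = df.columns[0], df.columns[1]
    return TaxonomyMap(
        {str(o): _parse_lineage(t) for o, t in zip(df[id_col], df[lin_col])}
    )


# ---------------------------------------------------------------------------
# operations


def filter_sparse_otus(table: OtuTable, min_total: int = 1200) -> OtuTable:
    """Drop OTUs with grand total below ``min_total`` (boundary retained)."""
    totals = table.counts.sum(axis=0)
    keep = totals >= min_total
    if not keep.any():
        raise AbundanceError(
            f"no OTU reaches total {min_total}; lower the threshold"
        )
    return OtuTable(
        table.counts[:, keep],
        table.sample_ids,
        [o for o, k in zip(table.otu_ids, keep) if k],
        table.depth,
    )


def rarefy(table: OtuTable, depth: int = 10000, seed: int | None = 0) -> OtuTable:
    """Subsample each sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped with a warning;
    drawing is multivariate hypergeometric per sample.
    """
    if depth <= 0:
        raise AbundanceError("depth must be positive")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep = totals >= depth
    if not keep.all():
        dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
        warnings.warn(
            f"{len(dropped)} sample(s) below depth {depth} dropped: "
            + ", ".join(dropped[:5])
        )
    rows = []
    for i in np.flatnonzero(keep):
        row = table.counts[i]
        if totals[i] == depth:
            rows.append(row.copy())
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth))
    return OtuTable(
        np.array(rows, dtype=np.int64),
        [s for s, k in zip(table.sample_ids, keep) if k],
        list(table.otu_ids),
        depth=depth,
    )


def aggregate_taxa(
    table: OtuTable, tax: TaxonomyMap, rank: str
) -> AbundanceMatrix:
    """Sum counts within rank labels; per-sample totals are preserved."""
    labels = [tax.rank_label(o, rank) for o in table.otu_ids]
    frame = pd.DataFrame(table.counts, columns=labels)
    agg = frame.T.groupby(level=0).sum().T
    return AbundanceMatrix(
        agg.to_numpy().astype(float),
        list(table.sample_ids),
        list(agg.columns),
        rank=rank,
        transform="counts",
    )


def relative_abundance(m: AbundanceMatrix | OtuTable) -> AbundanceMatrix:
    if isinstance(m, OtuTable):
        m = AbundanceMatrix(
            m.counts.astype(float), list(m.sample_ids), list(m.otu_ids), "otu"
        )
    totals = m.values.sum(axis=1)
    bad = np.flatnonzero(totals <= 0)
    if bad.size:
        raise AbundanceError(f"zero-sum sample(s): {[m.sample_ids[i] for i in bad]}")
    return replace(
        m, values=m.values / totals[:, None], transform="relative"
    )


def log_center_transform(
    m: AbundanceMatrix, pseudocount: float | None = None
) -> AbundanceMatrix:
    """Natural-log transform with zero replacement, then row centering.

    Zeros are replaced by ``pseudocount`` (default: half the smallest nonzero
    value in the matrix); each row of logs is centered to mean zero, the usual
    compositional normalization before PCA or rank tests.
    """
    if m.transform != "relative":
        m = relative_abundance(m)
    vals = m.values.copy()
    nz = vals[vals > 0]
    if nz.size == 0:
        raise AbundanceError("all-zero matrix")
    eps = pseudocount if pseudocount is not None else 0.5 * nz.min()
    vals[vals <= 0] = eps
    logs = np.log(vals)
    logs -= logs.mean(axis=1, keepdims=True)
    return replace(m, values=logs, transform="log-centered")


def goods_coverage(table: OtuTable) -> pd.Series:
    """Good's coverage per sample: 1 - singletons / total reads."""
    singles = (table.counts == 1).sum(axis=1)
    totals = table.sample_totals().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = 1.0 - singles / totals
    cov = np.where(totals > 0, cov, np.nan)
    return pd.Series(cov, index=table.sample_ids, name="goods_coverage")


def kruskal_wallis_screen(
    m: AbundanceMatrix,
    groups: np.ndarray | pd.Series,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Per-taxon Kruskal-Wallis H with Bonferroni-adjusted p values.

    The Bonferroni factor is the number of taxa tested in this screen.  A
    taxon constant across all samples gets H = 0, p = 1.
    """
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise AbundanceError("need at least two groups")
    rows = []
    ntaxa = len(m.taxa)
    for j, taxon in enumerate(m.taxa):
        col = m.values[:, j]
        samples = [col[groups == lv] for lv in levels]
        if any(len(s) < 2 for s in samples):
            raise AbundanceError("need >= 2 observations per group")
        if np.all(col == col[0]):
            H, p = 0.0, 1.0
        else:
            H, p = stats.kruskal(*samples)
        rows.append((taxon, H, p))
    out = pd.DataFrame(rows, columns=["taxon", "H", "p_raw"]).set_index("taxon")
    if correction == "bonferroni":
        out["p_adj"] = np.minimum(1.0, out["p_raw"] * ntaxa)
    else:
        out["p_adj"] = out["p_raw"]
    out["significant"] = out["p_adj"] < alpha
    return out


@dataclass
class PcaResult:
    scores: np.ndarray
    proportion: np.ndarray  # percent of variance per component
    contributions: pd.DataFrame  # taxa x [PC1, PC2], percent
    components: np.ndarray = field(repr=False, default=None)

    def reconstruct(self, center: np.ndarray) -> np.ndarray:
        return self.scores @ self.components + center


def pca_composition(m: AbundanceMatrix) -> PcaResult:
    """PCA of the column-centered covariance of (log-centered) abundances.

    Reports percent of total variance per component and each taxon's percent
    contribution (squared-loading share) to PC1 and PC2.
    """
    X = np.asarray(m.values, dtype=float)
    if X.shape[0] < 2:
        raise AbundanceError("need at least two samples for PCA")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (X.shape[0] - 1)
    total = var.sum()
    prop = 100.0 * var / total if total > 0 else np.zeros_like(var)
    scores = U * s
    ncomp = min(2, Vt.shape[0])
    contrib = {}
    for c in range(ncomp):
        load2 = Vt[c] ** 2
        contrib[f"PC{c+1}"] = 100.0 * load2 / load2.sum()
    return PcaResult(
        scores=scores,
        proportion=prop,
        contributions=pd.DataFrame(contrib, index=m.taxa),
        components=Vt,
    )
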