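"""End-to-end orchestration: simulate -> abundance -> diversity ->
enterotypes -> quantgen, with a manifest of checksums, timings, and warnings.

All inter-stage artifacts are plain-text TSV/CSV/JSON, so a run with a fixed
config and seed is byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict, replace as dc_replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance as ab
from . import diversity as dv
from . import enterotypes as et
from .models import (
    heritability,
    likelihood_ratio_test,
    model_spec,
    reml_univariate,
)
from .pedigree import read_pedigree
from .relmatrix import numerator_relationship_matrix
from .simulate import TIME_POINTS, SimulationConfig, simulate_herd


@dataclass
class RunConfig:
    out_dir: str = "herdqg_run"
    seed: int = 0
    simulate: dict | None = field(default_factory=dict)  # None => use inputs
    otu_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    pedigree_path: str | None = None
    traits_path: str | None = None
    stages: tuple[str, ...] = ("abundance", "diversity", "enterotypes", "quantgen")
    min_total: int = 1200
    depth: int = 10000
    rank: str = "genus"
    k_range: tuple[int, int] = (2, 6)
    lda_threshold: float = 2.0
    quantgen_models: tuple[int, ...] = (3, 4, 5)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    timings: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    completed: list[str] = field(default_factory=list)
    failed: str | None = None

    def to_json(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _register(manifest: RunManifest, *paths: Path) -> None:
    for p in paths:
        manifest.outputs[p.name] = _sha(p)


def run_pipeline(config: RunConfig) -> RunManifest:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash())

    if config.simulate is None:
        for p in (config.otu_path, config.metadata_path):
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"required input missing: {p}")

    stage_list = ["simulate"] if config.simulate is not None else []
    stage_list += [s for s in config.stages]
    state: dict = {}
    for stage in stage_list:
        t0 = time.time()
        with warnings.catch_warnings(record=True) as wrec:
            warnings.simplefilter("always")
            try:
                _STAGES[stage](config, out, state, manifest)
            except Exception as exc:  # noqa: BLE001
                manifest.failed = f"{stage}: {exc}"
                manifest.warnings.append(f"stage {stage} failed: {exc}")
                break
        manifest.warnings.extend(f"{stage}: {w.message}" for w in wrec)
        manifest.timings[stage] = round(time.time() - t0, 3)
        manifest.completed.append(stage)
    manifest.to_json(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: RunConfig, out: Path, state: dict, man: RunManifest):
    simcfg = SimulationConfig(**{**(config.simulate or {}), "seed": config.seed})
    herd = simulate_herd(simcfg)
    herd.pedigree.write_csv(out / "pedigree.csv")
    herd.frame.to_csv(out / "metadata.tsv", sep="\t", index=False)
    herd.traits.to_csv(out / "traits.tsv", sep="\t", index=False)
    ab.write_otu_table(herd.otu, out / "otu_table.tsv", herd.taxonomy)
    herd.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    state.update(
        otu=herd.otu, tax=herd.taxonomy, meta=herd.frame, traits=herd.traits,
        pedigree=herd.pedigree,
    )
    _register(man, out / "pedigree.csv", out / "metadata.tsv",
              out / "traits.tsv", out / "otu_table.tsv", out / "truth.tsv")


def _load_inputs(config: RunConfig, state: dict) -> None:
    if "otu" not in state and config.otu_path:
        table, tax = ab.read_otu_table(config.otu_path)
        state["otu"] = table
        if tax is not None:
            state["tax"] = tax
    if "tax" not in state and config.taxonomy_path:
        state["tax"] = ab.read_taxonomy(config.taxonomy_path)
    if "meta" not in state and config.metadata_path:
        state["meta"] = pd.read_csv(config.metadata_path, sep="\t")
    if "pedigree" not in state and config.pedigree_path:
        state["pedigree"] = read_pedigree(config.pedigree_path)
    if "traits" not in state and config.traits_path:
        state["traits"] = pd.read_csv(config.traits_path, sep="\t")


def _stage_abundance(config: RunConfig, out: Path, state: dict, man: RunManifest):
    _load_inputs(config, state)
    table = state["otu"]
    table = ab.filter_sparse_otus(table, config.min_total)
    if table.depth is None or (table.sample_totals() != table.depth).any():
        table = ab.rarefy(table, config.depth, seed=config.seed)
    state["rarefied"] = table
    genus = ab.aggregate_taxa(table, state["tax"], config.rank)
    rel = ab.relative_abundance(genus)
    state["genus_rel"] = rel
    rel.to_frame().to_csv(out / f"{config.rank}_relative.tsv", sep="\t")
    cov = ab.goods_coverage(table)
    cov.to_frame().to_csv(out / "goods_coverage.tsv", sep="\t")
    pca = ab.pca_composition(ab.log_center_transform(rel))
    pd.DataFrame(
        {"proportion_pct": pca.proportion[:10]},
        index=[f"PC{i+1}" for i in range(len(pca.proportion[:10]))],
    ).to_csv(out / "pca_variance.tsv", sep="\t")
    _register(man, out / f"{config.rank}_relative.tsv",
              out / "goods_coverage.tsv", out / "pca_variance.tsv")


def _stage_diversity(config: RunConfig, out: Path, state: dict, man: RunManifest):
    _load_inputs(config, state)
    table = state.get("rarefied", state["otu"])
    div = dv.diversity_table(table)
    meta = state["meta"].set_index("sample_id")
    div = div.join(meta[["animal", "time_point", "sex", "family", "cg"]])
    adj = []
    for tp, sub in div.groupby("time_point"):
        s = sub["shannon"]
        r = sub["richness"].astype(float)
        if tp != "weaning":  # weaning precedes contemporary grouping
            s = dv.pre_adjust_for_group(s, sub["cg"])
            r = dv.pre_adjust_for_group(r, sub["cg"])
        sub = sub.assign(shannon_adj=s, richness_adj=r)
        adj.append(sub)
    div = pd.concat(adj)
    state["diversity"] = div
    div.to_csv(out / "diversity.tsv", sep="\t")
    _register(man, out / "diversity.tsv")


def _stage_enterotypes(config: RunConfig, out: Path, state: dict, man: RunManifest):
    _load_inputs(config, state)
    rel = state["genus_rel"]
    meta = state["meta"].set_index("sample_id")
    tp_of = meta["time_point"]
    assignments: dict[str, pd.Series] = {}
    index_rows, lda_frames = [], []
    for tp in TIME_POINTS:
        ids = [s for s in rel.sample_ids if tp_of.get(s) == tp]
        if len(ids) < max(config.k_range) + 1:
            continue
        sel = [rel.sample_ids.index(s) for s in ids]
        sub = dc_replace(rel, values=rel.values[sel], sample_ids=ids)
        fit = et.select_enterotypes(sub, config.k_range)
        assignments[tp] = fit.assignments
        for k in sorted(fit.ch_by_k):
            index_rows.append((tp, k, fit.ch_by_k[k], fit.silhouette_by_k[k]))
        if fit.k == 2:
            lda = et.lda_effect_size(
                sub, fit.assignments.to_numpy(),
                threshold=config.lda_threshold, seed=config.seed,
            )
            frame = lda.table.assign(time_point=tp)
            lda_frames.append(frame)
    state["assignments"] = assignments
    pd.DataFrame(
        index_rows, columns=["time_point", "k", "calinski_harabasz", "silhouette"]
    ).to_csv(out / "cluster_indices.tsv", sep="\t", index=False)
    pd.concat(
        [s.rename("enterotype").to_frame().assign(time_point=tp)
         for tp, s in assignments.items()]
    ).to_csv(out / "enterotype_assignments.tsv", sep="\t")
    if lda_frames:
        pd.concat(lda_frames).to_csv(out / "lda_scores.tsv", sep="\t")
    # transitions + family association
    animal_of = meta["animal"]
    trans = et.enterotype_transitions(assignments, animal_of)
    with open(out / "transitions.tsv", "w") as fh:
        for (a, b), tab in trans.items():
            fh.write(f"# {a} -> {b}\n")
            if not tab.empty:
                tab.to_csv(fh, sep="\t")
    fam_rows = []
    for tp, s in assignments.items():
        fam = meta.loc[s.index, "family"]
        chi2, dof, p, _tab = et.enterotype_family_association(s, fam)
        fam_rows.append((tp, chi2, dof, p))
    pd.DataFrame(
        fam_rows, columns=["time_point", "chi2", "df", "p"]
    ).to_csv(out / "family_association.tsv", sep="\t", index=False)
    _register(man, out / "cluster_indices.tsv",
              out / "enterotype_assignments.tsv", out / "transitions.tsv",
              out / "family_association.tsv")
    if lda_frames:
        _register(man, out / "lda_scores.tsv")


def _stage_quantgen(config: RunConfig, out: Path, state: dict, man: RunManifest):
    _load_inputs(config, state)
    ped = state["pedigree"]
    A = numerator_relationship_matrix(ped)
    div = state["diversity"]
    meta = state["meta"].drop_duplicates("animal").set_index("animal")
    rows, fits = [], {}
    for tp in TIME_POINTS:
        sub = div[div["time_point"] == tp].set_index("animal")
        data = meta.join(sub[["shannon_adj"]], how="inner").reset_index()
        data = data.rename(columns={"shannon_adj": "shannon"})
        for m in config.quantgen_models:
            if m == 5 and tp == "weaning":
                continue  # pens exist only after weaning
            spec = model_spec(m, "shannon")
            res = reml_univariate(data, spec, A)
            h2, se = heritability(res)
            fits[(tp, m)] = res
            rows.append(
                dict(time_point=tp, model=m, h2=h2, h2_se=se,
                     loglik=res.loglik, converged=res.converged,
                     **{f"var_{k}": v for k, v in res.varcomp.items()})
            )
    vc = pd.DataFrame(rows)
    vc.to_csv(out / "variance_components.tsv", sep="\t", index=False)
    lrt_rows = []
    for tp in TIME_POINTS:
        for red, full in ((3, 4), (4, 5)):
            if (tp, red) in fits and (tp, full) in fits:
                lrt = likelihood_ratio_test(fits[(tp, red)], fits[(tp, full)])
                lrt_rows.append(
                    dict(time_point=tp, reduced=f"model{red}",
                         full=f"model{full}", statistic=lrt.statistic,
                         p_mixture=lrt.p_mixture, p_chi2=lrt.p_chi2)
                )
    pd.DataFrame(lrt_rows).to_csv(out / "lrt.tsv", sep="\t", index=False)
    state["varcomp"] = vc
    _register(man, out / "variance_components.tsv", out / "lrt.tsv")


_STAGES = {
    "simulate": _stage_simulate,
    "abundance": _stage_abundance,
    "diversity": _stage_diversity,
    "enterotypes": _stage_enterotypes,
    "quantgen": _stage_quantgen,
}


# ---------------------------------------------------------------------------
# report


def format_triangular(
    h2: dict[str, tuple[float, float]],
    rp: dict[tuple[str, str], tuple[float, float]],
    rg: dict[tuple[str, str], tuple[float, float]],
    order: list[str],
) -> pd.DataFrame:
    """Triangular parameter table: diagonal h2, above phenotypic r, below
    genetic r, each formatted ``est ± SE``."""

    def fmt(pair):
        if pair is None or not np.isfinite(pair[0]):
            return "-"
        return f"{pair[0]:.2f} ± {pair[1]:.2f}"

    tab = pd.DataFrame("-", index=order, columns=order)
    for t in order:
        if t in h2:
            tab.loc[t, t] = fmt(h2[t])
    for (a, b), v in rp.items():
        if a in order and b in order:
            i, j = order.index(a), order.index(b)
            tab.iloc[min(i, j), max(i, j)] = fmt(v)
    for (a, b), v in rg.items():
        if a in order and b in order:
            i, j = order.index(a), order.index(b)
            tab.iloc[max(i, j), min(i, j)] = fmt(v)
    return tab


def write_report(manifest: RunManifest, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    lines = ["# herdqg run report", ""]
    lines.append(f"config hash: `{manifest.config_hash}`")
    lines.append("")
    lines.append("| stage | seconds |")
    lines.append("|---|---|")
    for k, v in manifest.timings.items():
        lines.append(f"| {k} | {v} |")
    vc_path = out / "variance_components.tsv"
    if vc_path.exists():
        vc = pd.read_csv(vc_path, sep="\t")
        lines.append("")
        lines.append("## Heritability of the Shannon index")
        lines.append("")
        lines.append("| time point | model | h2 |")
        lines.append("|---|---|---|")
        for _, r in vc.iterrows():
            lines.append(
                f"| {r['time_point']} | model{int(r['model'])} "
                f"| {r['h2']:.2f} ± {r['h2_se']:.2f} |"
            )
    if manifest.warnings:
        lines += ["", "## Warnings", ""] + [f"- {w}" for w in manifest.warnings]
    path = out / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path
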