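"""Synthetic-herd generator with known ground truth.

Emulates a commercial half-sib breeding study: purebred sires mated to
crossbred dams, progeny penned by sire family and sex in replicated
contemporary groups, fecal microbiota sampled at weaning, week 15, and
off-test, and production traits (back fat, average daily gain) recorded on
test.  Everything downstream of sequencing is generated: a pedigree, the
experimental design, traits drawn under the animal model with user-chosen
variance components and genetic correlations, and OTU count tables with a
planted two-enterotype Dirichlet-multinomial mixture per time point.

All randomness flows from one root seed through named substreams (pedigree /
design / traits / otu) so each stage can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .abundance import OtuTable, TaxonomyMap
from .pedigree import Pedigree, PedigreeRecord
from .relmatrix import numerator_relationship_matrix

TIME_POINTS = ("weaning", "week15", "offtest")

_SUBSTREAMS = {"pedigree": 1, "design": 2, "traits": 3, "otu": 4}


class ConfigError(ValueError):
    pass


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _SUBSTREAMS[stage]])


# ---------------------------------------------------------------------------
# default trait architecture

DEFAULT_TRAITS = (
    "Sha_w", "Sha_15", "Sha_off", "BF_18", "BF_22", "ADGw_14", "ADG14_22",
)

#: total phenotypic variance and fractional components per trait; weaning
#: diversity is nearly non-heritable, post-weaning diversity moderately so,
#: production traits in the usual 0.3 range, pen applies only after weaning
DEFAULT_VARIANCE_FRACTIONS = {
    "Sha_w": dict(total=0.36, animal=0.04, litter=0.20, pen=0.00),
    "Sha_15": dict(total=0.09, animal=0.17, litter=0.10, pen=0.05),
    "Sha_off": dict(total=0.10, animal=0.19, litter=0.10, pen=0.05),
    "BF_18": dict(total=0.25, animal=0.30, litter=0.05, pen=0.05),
    "BF_22": dict(total=0.30, animal=0.28, litter=0.05, pen=0.05),
    "ADGw_14": dict(total=0.010, animal=0.30, litter=0.06, pen=0.06),
    "ADG14_22": dict(total=0.012, animal=0.17, litter=0.05, pen=0.06),
}

DEFAULT_TRAIT_MEANS = {
    "Sha_w": 3.8, "Sha_15": 4.5, "Sha_off": 4.6,
    "BF_18": 1.2, "BF_22": 1.6, "ADGw_14": 0.75, "ADG14_22": 0.95,
}

#: two-factor loading construction guarantees a positive semi-definite
#: genetic correlation matrix: a production axis and a post-weaning
#: diversity axis, with weaning diversity weakly anti-correlated to both
_GENETIC_LOADINGS = {
    "Sha_w": (0.25, -0.40),
    "Sha_15": (-0.70, 0.50),
    "Sha_off": (-0.50, 0.60),
    "BF_18": (0.75, 0.20),
    "BF_22": (0.72, 0.15),
    "ADGw_14": (0.65, -0.15),
    "ADG14_22": (0.60, 0.00),
}


def default_genetic_corr(traits=DEFAULT_TRAITS) -> np.ndarray:
    L = np.array([_GENETIC_LOADINGS[t] for t in traits])
    R = L @ L.T
    np.fill_diagonal(R, 1.0)
    return R


# ---------------------------------------------------------------------------
# default enterotype templates

#: genus -> (phylum, class_, order, family_) used for synthetic lineages
GENUS_LINEAGES = {
    "Clostridium": ("Firmicutes", "Clostridia", "Clostridiales", "Clostridiaceae"),
    "Escherichia": ("Proteobacteria", "Gammaproteobacteria", "Enterobacteriales", "Enterobacteriaceae"),
    "Bacteroides": ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Bacteroidaceae"),
    "Prevotella": ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae"),
    "Ruminococcus": ("Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae"),
    "Fusobacterium": ("Fusobacteria", "Fusobacteriia", "Fusobacteriales", "Fusobacteriaceae"),
    "Campylobacter": ("Proteobacteria", "Epsilonproteobacteria", "Campylobacterales", "Campylobacteraceae"),
    "Eubacterium": ("Firmicutes", "Clostridia", "Clostridiales", "Eubacteriaceae"),
    "Lactobacillus": ("Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae"),
    "Streptococcus": ("Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae"),
    "Turicibacter": ("Firmicutes", "Erysipelotrichia", "Erysipelotrichales", "Turicibacteraceae"),
    "Enterococcus": ("Firmicutes", "Bacilli", "Lactobacillales", "Enterococcaceae"),
    "Blautia": ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae"),
    "Roseburia": ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae"),
    "Faecalibacterium": ("Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae"),
    "Treponema": ("Spirochaetes", "Spirochaetia", "Spirochaetales", "Spirochaetaceae"),
    "Megasphaera": ("Firmicutes", "Negativicutes", "Selenomonadales", "Veillonellaceae"),
    "Oscillibacter": ("Firmicutes", "Clostridia", "Clostridiales", "Oscillospiraceae"),
    "unclassified": ("unclassified",) * 4,
}

GENERA = tuple(GENUS_LINEAGES)


def _template(weights: dict[str, float]) -> np.ndarray:
    """Genus mean vector over GENERA; unlisted genera share the remainder."""
    v = np.full(len(GENERA), np.nan)
    for g, w in weights.items():
        v[GENERA.index(g)] = w
    rest = 1.0 - np.nansum(v)
    free = np.isnan(v)
    v[free] = rest / free.sum()
    return v


def default_enterotype_templates() -> dict[str, tuple[np.ndarray, np.ndarray, float]]:
    """Per time point: (template_1, template_2, Dirichlet concentration).

    Weaning contrasts an Escherichia/Enterococcus-led community with a more
    even Prevotella-led one; later ages contrast Clostridium/Turicibacter
    against Lactobacillus/Streptococcus/Prevotella, mirroring the usual
    post-weaning succession in pigs.
    """
    weaning_a = _template({
        "Escherichia": 0.30, "Enterococcus": 0.10, "Bacteroides": 0.12,
        "Clostridium": 0.10, "Fusobacterium": 0.08, "Campylobacter": 0.05,
        "Prevotella": 0.02,
    })
    weaning_b = _template({
        "Prevotella": 0.18, "Bacteroides": 0.10, "Clostridium": 0.10,
        "Ruminococcus": 0.08, "Escherichia": 0.02, "Lactobacillus": 0.06,
    })
    later_c = _template({
        "Clostridium": 0.25, "Turicibacter": 0.12, "Streptococcus": 0.06,
        "Prevotella": 0.08, "Lactobacillus": 0.04, "Escherichia": 0.003,
    })
    later_d = _template({
        "Lactobacillus": 0.18, "Streptococcus": 0.14, "Prevotella": 0.14,
        "Clostridium": 0.12, "Turicibacter": 0.03, "Escherichia": 0.002,
    })
    return {
        "weaning": (weaning_a, weaning_b, 60.0),
        "week15": (later_c, later_d, 60.0),
        "offtest": (later_c * 0.98 + later_d * 0.02,
                    later_d * 0.98 + later_c * 0.02, 60.0),
    }


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimulationConfig:
    """Design constants and generative parameters of the synthetic herd.

    Defaults reproduce the study design this generator emulates: 28 paternal
    half-sib families, 26 litters per sire (~728 litters), 1-2 sampled
    progeny per litter, single-sex single-family pens of up to 20, 6
    contemporary groups, 3 birth sites, 2 dam lines, 3 time points, and OTU
    tables rarefied to 10,000 reads per sample.
    """

    n_sires: int = 28
    dams_per_sire: int = 26
    progeny_per_dam: int = 2
    pen_size: int = 20
    n_pens: int | None = None  # derived when None
    n_contemporary_groups: int = 6
    n_birth_sites: int = 3
    n_dam_lines: int = 2
    traits: tuple[str, ...] = DEFAULT_TRAITS
    variance_components: dict = field(default_factory=dict)
    genetic_corr: np.ndarray | None = None
    trait_means: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_MEANS))
    fixed_effect_sizes: dict = field(
        default_factory=lambda: {
            "sex": {"M": 0.0, "F": 0.08},
            "bs": {"bs1": 0.0, "bs2": 0.12, "bs3": -0.10},
            "dl": {"dl1": 0.0, "dl2": 0.03},
        }
    )
    enterotype_templates: dict = field(default_factory=default_enterotype_templates)
    enterotype_family_logit_sd: float = 0.8
    diversity_coupling: float = 1.0
    otus_per_genus: int = 5
    depth: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sires", "dams_per_sire", "progeny_per_dam", "pen_size",
                     "n_contemporary_groups", "n_birth_sites", "n_dam_lines"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.depth <= 0:
            raise ConfigError("depth must be positive")
        if not self.variance_components:
            self.variance_components = {}
            for t in self.traits:
                f = DEFAULT_VARIANCE_FRACTIONS[t]
                tot = f["total"]
                vc = {
                    "animal": f["animal"] * tot,
                    "litter": f["litter"] * tot,
                    "pen": f["pen"] * tot,
                }
                vc["residual"] = tot - sum(vc.values())
                self.variance_components[t] = vc
        for t, vc in self.variance_components.items():
            for k, v in vc.items():
                if v < 0:
                    raise ConfigError(f"negative variance {k} for trait {t}")
        if self.genetic_corr is None:
            self.genetic_corr = default_genetic_corr(self.traits)
        R = np.asarray(self.genetic_corr, dtype=float)
        if R.shape != (len(self.traits), len(self.traits)):
            raise ConfigError("genetic_corr shape does not match traits")
        if not np.allclose(R, R.T):
            raise ConfigError("genetic_corr not symmetric")
        if not np.allclose(np.diag(R), 1.0):
            raise ConfigError("genetic_corr diagonal must be 1")
        ev = np.linalg.eigvalsh(R)
        if ev.min() < -1e-8:
            i, j = _most_offending_pair(R)
            raise ConfigError(
                f"genetic_corr not positive semi-definite (pair "
                f"{self.traits[i]!r}/{self.traits[j]!r})"
            )
        self.genetic_corr = R
        templates = self.enterotype_templates
        lens = {len(t1) for (t1, t2, _c) in templates.values()}
        lens |= {len(t2) for (t1, t2, _c) in templates.values()}
        if len(lens) != 1:
            raise ConfigError("template length mismatch across time points")
        for tp, (t1, t2, conc) in templates.items():
            for tv in (t1, t2):
                if not np.isclose(np.sum(tv), 1.0):
                    raise ConfigError(f"template for {tp} does not sum to 1")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _most_offending_pair(R: np.ndarray) -> tuple[int, int]:
    ev, V = np.linalg.eigh(R)
    v = np.abs(V[:, 0])
    i, j = np.argsort(v)[-2:]
    return int(min(i, j)), int(max(i, j))


# ---------------------------------------------------------------------------
# pedigree


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Base generation of unrelated sires and dams plus their progeny.

    Deterministic given the config; progeny count is exactly
    n_sires * dams_per_sire * progeny_per_dam.
    """
    records = []
    sires = [f"S{i+1:03d}" for i in range(config.n_sires)]
    for s in sires:
        records.append(PedigreeRecord(s, None, None))
    dams = []
    for si, s in enumerate(sires):
        for di in range(config.dams_per_sire):
            d = f"D{si+1:03d}_{di+1:03d}"
            dams.append((d, s))
            records.append(PedigreeRecord(d, None, None))
    k = 0
    for d, s in dams:
        for _ in range(config.progeny_per_dam):
            k += 1
            records.append(PedigreeRecord(f"P{k:05d}", s, d))
    return Pedigree(records)


# ---------------------------------------------------------------------------
# design


def simulate_design(ped: Pedigree, config: SimulationConfig) -> pd.DataFrame:
    """Assign sex, litter, pen, contemporary group, birth site, and dam line.

    Litters are nested in dams (one litter per dam); sexes alternate within
    litter to balance the design; pens are single-sex, single-family groups
    of at most ``pen_size`` animals, assigned to contemporary groups in
    rotation.  Three time-point rows are instantiated per animal with
    realistic ages in days.
    """
    rng = _rng(config.seed, "design")
    progeny = [r for r in ped if r.sire is not None]
    rows = []
    litter_meta: dict[str, dict] = {}
    per_litter_count: dict[str, int] = {}
    for r in progeny:
        dam = r.dam
        if dam not in litter_meta:
            li = len(litter_meta)
            litter_meta[dam] = {
                "litter": f"L{li+1:04d}",
                "bs": f"bs{(li % config.n_birth_sites) + 1}",
                "dl": f"dl{(li % config.n_dam_lines) + 1}",
            }
            per_litter_count[dam] = 0
        c = per_litter_count[dam]
        per_litter_count[dam] += 1
        sex = "M" if c % 2 == 0 else "F"
        meta = litter_meta[dam]
        rows.append(
            dict(animal=r.animal, sire=r.sire, family=r.sire, sex=sex,
                 litter=meta["litter"], bs=meta["bs"], dl=meta["dl"])
        )
    df = pd.DataFrame(rows)
    # pens: single family x sex, chunked; cg rotates per pen within family
    pen_ids = []
    pen_of: dict[str, str] = {}
    cg_of: dict[str, str] = {}
    counter = 0
    for (fam, sex), grp in df.groupby(["family", "sex"], sort=True):
        members = grp["animal"].tolist()
        for ci, start in enumerate(range(0, len(members), config.pen_size)):
            counter += 1
            pen = f"pen{counter:04d}"
            cg = f"cg{(ci % config.n_contemporary_groups) + 1}"
            for a in members[start:start + config.pen_size]:
                pen_of[a] = pen
                cg_of[a] = cg
    df["pen"] = df["animal"].map(pen_of)
    df["cg"] = df["animal"].map(cg_of)

    ages = {"weaning": (18.6, 1.09), "week15": (118.2, 1.18),
            "offtest": (196.4, 7.86)}
    frames = []
    for tp in TIME_POINTS:
        mu, sd = ages[tp]
        sub = df.copy()
        sub["time_point"] = tp
        sub["days"] = np.round(rng.normal(mu, sd, len(sub)), 1)
        sub["sample_id"] = sub["animal"] + "_" + tp
        frames.append(sub)
    out = pd.concat(frames, ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# traits


def simulate_traits(
    ped: Pedigree, frame: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Draw traits under the animal model with the configured architecture.

    Breeding values are sampled by the gene-flow recursion
    ``u_i = (u_sire + u_dam)/2 + mendelian``, which realizes the
    lower-triangular factorization of A exactly (Mendelian sampling variance
    ``[1 - (a_ss + a_dd)/4] G0`` with unknown-parent terms of 1); litter, pen,
    and residual effects are iid with their nominal variances.  Fixed effects
    from ``fixed_effect_sizes`` are added for sex, birth site, and dam line.
    Returns one row per animal with measured traits and true values
    (``tbv_*`` columns, plus true litter/pen effects summed into the traits).
    """
    rng = _rng(config.seed, "traits")
    traits = list(config.traits)
    t = len(traits)
    R = config.genetic_corr
    sda = np.array(
        [np.sqrt(config.variance_components[tr]["animal"]) for tr in traits]
    )
    G0 = R * np.outer(sda, sda)
    # PSD guaranteed by config validation; factor for correlated sampling
    w, V = np.linalg.eigh(G0)
    Lg = V @ np.diag(np.sqrt(np.maximum(w, 0.0)))

    A = numerator_relationship_matrix(ped)
    diag = np.diag(A.A)
    parents = ped.parent_indices()
    n = len(ped)
    u = np.zeros((n, t))
    z = rng.standard_normal((n, t))
    for i, (s, d) in enumerate(parents):
        mean = np.zeros(t)
        msv = 1.0
        if s >= 0:
            mean += 0.5 * u[s]
            msv -= 0.25 * diag[s]
        if d >= 0:
            mean += 0.5 * u[d]
            msv -= 0.25 * diag[d]
        u[i] = mean + np.sqrt(max(msv, 0.0)) * (Lg @ z[i])

    animals = frame.drop_duplicates("animal").set_index("animal")
    ids = animals.index.tolist()
    idx = np.array([ped.index_of(a) for a in ids])
    litters = animals["litter"].astype(str)
    pens = animals["pen"].astype(str)
    lit_levels = {l: k for k, l in enumerate(pd.unique(litters))}
    pen_levels = {p: k for k, p in enumerate(pd.unique(pens))}

    out = pd.DataFrame(index=pd.Index(ids, name="animal"))
    out["sex"] = animals["sex"]
    for col in ("family", "litter", "pen", "bs", "dl", "cg"):
        out[col] = animals[col]
    fes = config.fixed_effect_sizes
    fixed = np.zeros(len(ids))
    for eff, levels in fes.items():
        if eff in animals:
            fixed += animals[eff].map(levels).fillna(0.0).to_numpy()
    for j, tr in enumerate(traits):
        vc = config.variance_components[tr]
        le = rng.normal(0, np.sqrt(vc["litter"]), len(lit_levels))
        pe = rng.normal(0, np.sqrt(vc["pen"]), len(pen_levels))
        e = rng.normal(0, np.sqrt(vc["residual"]), len(ids))
        tbv = u[idx, j]
        y = (
            config.trait_means.get(tr, 0.0)
            + fixed
            + tbv
            + le[[lit_levels[l] for l in litters]]
            + pe[[pen_levels[p] for p in pens]]
            + e
        )
        out[tr] = y
        out[f"tbv_{tr}"] = tbv
    # ages at production-trait measurement (days)
    wean_age = rng.normal(18.6, 1.09, len(ids))
    out["days_BF_18"] = np.round(wean_age + 18 * 7, 1)
    out["days_BF_22"] = np.round(wean_age + 22 * 7, 1)
    return out.reset_index()


# ---------------------------------------------------------------------------
# OTU tables


def _genus_names(g: int) -> list[str]:
    names = []
    for i in range(g):
        base = GENERA[i % len(GENERA)]
        names.append(base if i < len(GENERA) else f"{base}_{i // len(GENERA)}")
    return names


def _expand_templates(config: SimulationConfig, rng: np.random.Generator,
                      n_genera: int):
    """Split each genus mean into per-OTU means (shared across templates)."""
    k = config.otus_per_genus
    g = n_genera
    genera = _genus_names(g)
    splits = rng.dirichlet(np.full(k, 5.0), size=g)  # genus x otus-in-genus
    otu_ids = [f"OTU_{i+1:04d}" for i in range(g * k)]
    lineages = {}
    for gi, genus in enumerate(genera):
        ph, cl, od, fa = GENUS_LINEAGES[GENERA[gi % len(GENERA)]]
        for oi in range(k):
            lineages[otu_ids[gi * k + oi]] = dict(
                phylum=ph, class_=cl, order=od, family=fa, genus=genus,
                species=f"{genus.lower()} sp. {oi+1}" if genus != "unclassified"
                else "unclassified",
            )
    # fix key name: TaxonomyMap uses "class"
    lineages = {
        o: {("class" if k_ == "class_" else k_): v for k_, v in lin.items()}
        for o, lin in lineages.items()
    }
    return splits, otu_ids, TaxonomyMap(lineages)


def simulate_otu_table(
    frame: pd.DataFrame, config: SimulationConfig, traits: pd.DataFrame | None = None
) -> tuple[OtuTable, TaxonomyMap, pd.DataFrame]:
    """Dirichlet-multinomial OTU counts with a planted enterotype mixture.

    Each sample draws a latent enterotype whose propensity carries a
    per-family logit shift (so family and enterotype are associated, as in
    real herds); counts come from a Dirichlet-multinomial around the
    enterotype's genus template at the configured depth.  When ``traits`` is
    given, each animal's latent diversity trait shifts its community toward
    (or away from) evenness, giving the measured Shannon index a heritable
    component.  Returns (table, taxonomy, truth frame with latent labels).
    """
    rng = _rng(config.seed, "otu")
    n_genera = len(next(iter(config.enterotype_templates.values()))[0])
    splits, otu_ids, tax = _expand_templates(config, rng, n_genera)
    k = config.otus_per_genus
    trait_of_tp = {"weaning": "Sha_w", "week15": "Sha_15", "offtest": "Sha_off"}

    fams = sorted(frame["family"].unique())
    rows, meta = [], []
    for tp in TIME_POINTS:
        if tp not in config.enterotype_templates:
            continue
        t1, t2, conc = config.enterotype_templates[tp]
        fam_shift = dict(
            zip(fams, rng.normal(0, config.enterotype_family_logit_sd, len(fams)))
        )
        sub = frame[frame["time_point"] == tp]
        z = None
        tbv_col = f"tbv_{trait_of_tp[tp]}"
        if traits is not None and tbv_col in traits:
            lat = traits.set_index("animal")[tbv_col]
            if lat.std() > 0:
                z = ((lat - lat.mean()) / lat.std()).to_dict()
        for _, r in sub.iterrows():
            logit = fam_shift[r["family"]]
            p2 = 1.0 / (1.0 + np.exp(-logit))
            label = 2 if rng.random() < p2 else 1
            tmpl = t1 if label == 1 else t2
            if z is not None:
                wz = float(np.clip(
                    0.25 + 0.12 * config.diversity_coupling * z.get(r["animal"], 0.0),
                    0.02, 0.85,
                ))
                tmpl = (1 - wz) * tmpl + wz * np.full(len(tmpl), 1.0 / len(tmpl))
            otu_mean = (tmpl[:, None] * splits).ravel()
            alpha = np.maximum(conc * otu_mean, 1e-6)
            p = rng.dirichlet(alpha)
            counts = rng.multinomial(config.depth, p)
            rows.append(counts)
            meta.append(dict(sample_id=r["sample_id"], animal=r["animal"],
                             time_point=tp, enterotype_true=label))
    table = OtuTable(
        np.array(rows, dtype=np.int64),
        [m["sample_id"] for m in meta],
        otu_ids,
        depth=config.depth,
    )
    truth = pd.DataFrame(meta)
    return table, tax, truth


# ---------------------------------------------------------------------------
# one-call convenience


@dataclass
class SyntheticHerd:
    config: SimulationConfig
    pedigree: Pedigree
    frame: pd.DataFrame
    traits: pd.DataFrame
    otu: OtuTable
    taxonomy: TaxonomyMap
    truth: pd.DataFrame


def simulate_herd(config: SimulationConfig | None = None, **overrides) -> SyntheticHerd:
    config = config or SimulationConfig(**overrides)
    ped = simulate_pedigree(config)
    frame = simulate_design(ped, config)
    traits = simulate_traits(ped, frame, config)
    otu, tax, truth = simulate_otu_table(frame, config, traits)
    return SyntheticHerd(config, ped, frame, traits, otu, tax, truth)
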