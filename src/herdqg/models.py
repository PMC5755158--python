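"""Animal-model variance components, heritability, and correlations.

Maps trait data frames plus a pedigree relationship matrix onto the REML
machinery.  The model vocabulary follows standard animal-breeding usage:

* fixed effects — intercept, sex, birth site (``bs``), dam line (``dl``),
  sire family, age (time point), age x family, enterotype, and the continuous
  covariate ``days`` (age at measurement);
* random effects — ``animal`` (additive genetic, covariance A * sigma2_a),
  ``litter`` and ``pen`` (permanent/common environment, identity covariance),
  and the residual.

Heritability is computed as sigma2_animal over the sum of all fitted variance
components, with delta-method standard errors from the inverse
average-information matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .relmatrix import RelMatrix
from .reml import RandomTerm, RemlError, RemlResult, ai_reml


@dataclass(frozen=True)
class ModelSpec:
    """Declarative mixed-model specification.

    ``fixed`` lists factor or covariate column names ("days" is continuous,
    everything else categorical); the intercept is implicit.  ``random`` lists
    random-effect column names; the name ``animal`` gets the pedigree
    relationship structure, every other random factor an identity structure.
    The residual is always present.
    """

    response: str
    fixed: tuple[str, ...] = ()
    random: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ("days",)

    def requires_pedigree(self) -> bool:
        return "animal" in self.random


#: The fixed/random layouts used for the longitudinal diversity analysis.
#: Model 1 screens fixed effects across ages; model 2 adds a litter term at a
#: single age; models 3-5 are the animal models of increasing environmental
#: detail (3: animal; 4: +litter; 5: +pen, post-weaning ages only).
STANDARD_MODELS: dict[str, ModelSpec] = {
    "model1": ModelSpec("shannon", fixed=("sex", "age", "family", "age:family", "bs", "dl")),
    "model2": ModelSpec("shannon", fixed=("sex", "family", "bs"), random=("litter",)),
    "model3": ModelSpec("shannon", fixed=("sex", "bs"), random=("animal",)),
    "model4": ModelSpec("shannon", fixed=("sex", "bs"), random=("animal", "litter")),
    "model5": ModelSpec("shannon", fixed=("sex", "bs"), random=("animal", "litter", "pen")),
}


def model_spec(which: int | str, response: str = "shannon") -> ModelSpec:
    key = f"model{which}" if not str(which).startswith("model") else str(which)
    base = STANDARD_MODELS[key]
    return ModelSpec(response, base.fixed, base.random, base.covariates)


# ---------------------------------------------------------------------------
# design-matrix construction


def _interaction(data: pd.DataFrame, term: str) -> pd.Series:
    parts = term.split(":")
    s = data[parts[0]].astype(str)
    for p in parts[1:]:
        s = s + "|" + data[p].astype(str)
    return s


def build_fixed_design(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(data))]
    names = ["mu"]
    for term in spec.fixed:
        if term in spec.covariates:
            v = data[term].astype(float).to_numpy()
            cols.append(v - v.mean())
            names.append(term)
            continue
        f = _interaction(data, term) if ":" in term else data[term].astype(str)
        dummies = pd.get_dummies(f, drop_first=True, dtype=float)
        for lvl in dummies.columns:
            cols.append(dummies[lvl].to_numpy())
            names.append(f"{term}[{lvl}]")
    return np.column_stack(cols), names


def _incidence(labels: pd.Series) -> tuple[np.ndarray, list[str]]:
    d = pd.get_dummies(labels.astype(str), dtype=float)
    return d.to_numpy(), list(d.columns)


def build_random_terms(
    data: pd.DataFrame, spec: ModelSpec, A: RelMatrix | None
) -> list[RandomTerm]:
    terms: list[RandomTerm] = []
    for name in spec.random:
        if name == "animal":
            if A is None:
                raise RemlError("animal term requires a relationship matrix")
            ids = data["animal"].astype(str).tolist()
            K = A.submatrix(ids)
            terms.append(RandomTerm("animal", K=K, nlevels=len(set(ids))))
        else:
            Z, _ = _incidence(data[name])
            terms.append(RandomTerm(name, U=Z))
    terms.append(RandomTerm("residual"))
    return terms


# ---------------------------------------------------------------------------
# univariate


@dataclass
class VarCompResult:
    """Variance components with genetic-parameter accessors."""

    reml: RemlResult
    spec: ModelSpec
    fixed_names: list[str]
    wald: pd.DataFrame | None = None

    @property
    def varcomp(self) -> dict[str, float]:
        return self.reml.varcomp

    @property
    def loglik(self) -> float:
        return self.reml.loglik

    @property
    def converged(self) -> bool:
        return self.reml.converged

    def fixed_effects(self) -> pd.Series:
        return pd.Series(self.reml.beta, index=self.fixed_names)


def reml_univariate(
    data: pd.DataFrame,
    spec: ModelSpec,
    A: RelMatrix | None = None,
    **kwargs,
) -> VarCompResult:
    """Fit one trait by AI-REML under ``spec``; complete cases only."""
    needed = (
        [spec.response]
        + [c for t in spec.fixed for c in t.split(":")]
        + list(spec.random)
    )
    df = data.dropna(subset=[c for c in dict.fromkeys(needed) if c in data])
    y = df[spec.response].astype(float).to_numpy()
    X, fixed_names = build_fixed_design(df, spec)
    terms = build_random_terms(df, spec, A)
    res, engine = ai_reml(y, X, terms, **kwargs)
    res.fixed_names = fixed_names
    wald = _wald_table(y, X, fixed_names, spec, engine, res)
    return VarCompResult(res, spec, fixed_names, wald)


def _wald_table(y, X, fixed_names, spec, engine, res) -> pd.DataFrame:
    """Incremental (sequential) Wald F tests at the converged V."""
    term_of = {}
    for j, nm in enumerate(fixed_names):
        term_of.setdefault(nm.split("[")[0], []).append(j)
    order = ["mu"] + [t for t in spec.fixed if t in term_of and t != "mu"]
    ViX = engine.vi_dot(res.theta, X)
    Viy = engine.vi_dot(res.theta, y[:, None])[:, 0]
    yViy = float(y @ Viy)

    def rss(cols):
        Xm = X[:, cols]
        XtViX = Xm.T @ ViX[:, cols]
        b = np.linalg.lstsq(XtViX, Xm.T @ Viy, rcond=None)[0]
        return yViy - float((Xm.T @ Viy) @ b)

    rows = []
    cols: list[int] = []
    prev = yViy
    full_cols = list(range(X.shape[1]))
    rss_full = rss(full_cols)
    dfe = len(y) - len(full_cols)
    scale = rss_full / dfe if dfe > 0 else np.nan
    for t in order:
        cols += term_of[t]
        cur = rss(cols)
        df_t = len(term_of[t])
        F = ((prev - cur) / df_t) / scale if scale > 0 else np.nan
        p = stats.f.sf(F, df_t, dfe) if np.isfinite(F) else np.nan
        rows.append((t, df_t, F, p))
        prev = cur
    return pd.DataFrame(rows, columns=["term", "df", "F", "p"]).set_index("term")


def heritability(
    res: VarCompResult, component: str = "animal"
) -> tuple[float, float]:
    """h2 = sigma2_component / total, SE by the delta method."""
    theta = res.reml.theta
    names = res.reml.names
    total = float(theta.sum())
    if total <= 0:
        raise RemlError("zero total variance")
    k = names.index(component)
    h2 = theta[k] / total
    grad = np.full(len(theta), -theta[k] / total**2)
    grad[k] += 1.0 / total
    var = float(grad @ res.reml.theta_cov @ grad)
    return float(h2), float(np.sqrt(max(var, 0.0)))


# ---------------------------------------------------------------------------
# bivariate


@dataclass
class BivariateResult:
    reml: RemlResult
    traits: tuple[str, str]
    term_names: list[str]
    bent: bool = False

    def covariance_matrix(self, term: str) -> np.ndarray:
        v = self.reml.varcomp
        return np.array(
            [
                [v[f"{term}:11"], v[f"{term}:12"]],
                [v[f"{term}:12"], v[f"{term}:22"]],
            ]
        )

    @property
    def loglik(self) -> float:
        return self.reml.loglik

    @property
    def converged(self) -> bool:
        return self.reml.converged


def _pair_structure(units: np.ndarray, base: str, data: pd.DataFrame,
                    A: RelMatrix | None) -> np.ndarray:
    """n_units x n_units base covariance among record units (animals)."""
    if base == "animal":
        return A.submatrix(list(units))
    lab = (
        data.drop_duplicates("animal").set_index("animal")[base].astype(str)
    )
    vals = lab.loc[list(units)].to_numpy()
    return (vals[:, None] == vals[None, :]).astype(float)


def reml_bivariate(
    data: pd.DataFrame,
    trait1: str,
    trait2: str,
    fixed: tuple[str, ...] = ("sex", "bs"),
    random: tuple[str, ...] = ("animal",),
    A: RelMatrix | None = None,
    covariates: tuple[str, ...] = ("days",),
    **kwargs,
) -> BivariateResult:
    """Two-trait AI-REML with 2x2 covariance matrices per random structure.

    Records missing one trait are retained (they inform the marginal
    components).  Each animal contributes at most one record per trait.
    The residual covariance between traits is estimated through the shared
    animal; trait-specific residual variances are always estimated.
    """
    df = data.copy()
    df["animal"] = df["animal"].astype(str)
    stacked = []
    for t_i, trait in enumerate((trait1, trait2)):
        sub = df.dropna(subset=[trait]).copy()
        sub["_y"] = sub[trait].astype(float)
        sub["_trait"] = t_i
        stacked.append(sub)
    longdf = pd.concat(stacked, ignore_index=True)
    y = longdf["_y"].to_numpy()
    n = len(longdf)
    tmask = [longdf["_trait"].to_numpy() == i for i in (0, 1)]

    # trait-specific fixed effects: block design
    Xs, names = [], []
    for t_i, trait in enumerate((trait1, trait2)):
        spec = ModelSpec(trait, fixed, (), covariates)
        sub = longdf[tmask[t_i]]
        Xt, nm = build_fixed_design(sub, spec)
        blk = np.zeros((n, Xt.shape[1]))
        blk[tmask[t_i], :] = Xt
        Xs.append(blk)
        names += [f"{trait}:{x}" for x in nm]
    X = np.hstack(Xs)

    units = longdf["animal"].to_numpy()
    uniq = pd.unique(units)
    uidx = pd.Series(np.arange(len(uniq)), index=uniq)[units].to_numpy()

    terms: list[RandomTerm] = []
    term_names = list(random) + ["residual"]
    vys = [np.var(y[mk]) for mk in tmask]
    start = []
    for base in term_names:
        Kb = (
            np.eye(len(uniq))
            if base == "residual"
            else _pair_structure(uniq, base, df, A)
        )
        Kfull = Kb[np.ix_(uidx, uidx)]
        M11 = np.where(tmask[0][:, None] & tmask[0][None, :], Kfull, 0.0)
        M22 = np.where(tmask[1][:, None] & tmask[1][None, :], Kfull, 0.0)
        cross = tmask[0][:, None] & tmask[1][None, :]
        M12 = np.where(cross | cross.T, Kfull, 0.0)
        nlev = len(uniq)
        frac = 0.5 / max(1, len(term_names) - 1)
        for tag, M, isvar, s0 in (
            ("11", M11, True, (frac if base != "residual" else 0.5) * vys[0]),
            ("12", M12, False, 0.0),
            ("22", M22, True, (frac if base != "residual" else 0.5) * vys[1]),
        ):
            terms.append(
                RandomTerm(f"{base}:{tag}", K=M, nlevels=nlev, is_variance=isvar)
            )
            start.append(s0)
    res, _ = ai_reml(y, X, terms, start=np.array(start), **kwargs)
    res.fixed_names = names

    out = BivariateResult(res, (trait1, trait2), term_names)
    # bend any term whose 2x2 leaves the PSD cone
    for base in term_names:
        G = out.covariance_matrix(base)
        lim = np.sqrt(max(G[0, 0], 0.0) * max(G[1, 1], 0.0))
        if abs(G[0, 1]) > lim:
            k = res.names.index(f"{base}:12")
            res.theta[k] = np.sign(G[0, 1]) * 0.999 * lim
            out.bent = True
            warnings.warn(f"covariance for term {base!r} bent to PSD boundary")
    return out


def correlations(res: BivariateResult) -> pd.DataFrame:
    """Genetic and phenotypic correlations with delta-method SEs."""
    names = res.reml.names
    theta = res.reml.theta
    C = res.reml.theta_cov
    rows = []

    def corr_of(weights11, weights12, weights22):
        v1 = float(weights11 @ theta)
        v2 = float(weights22 @ theta)
        c = float(weights12 @ theta)
        if v1 <= 0 or v2 <= 0:
            return np.nan, np.nan
        r = c / np.sqrt(v1 * v2)
        grad = (
            weights12 / np.sqrt(v1 * v2)
            - 0.5 * c * weights11 / (v1**1.5 * v2**0.5)
            - 0.5 * c * weights22 / (v2**1.5 * v1**0.5)
        )
        var = float(grad @ C @ grad)
        return r, float(np.sqrt(max(var, 0.0)))

    def indicator(suffix, bases):
        w = np.zeros(len(names))
        for b in bases:
            w[names.index(f"{b}:{suffix}")] = 1.0
        return w

    bases = res.term_names
    if "animal" in bases:
        rg, rg_se = corr_of(
            indicator("11", ["animal"]),
            indicator("12", ["animal"]),
            indicator("22", ["animal"]),
        )
        rows.append(("genetic", rg, rg_se))
    rp, rp_se = corr_of(
        indicator("11", bases), indicator("12", bases), indicator("22", bases)
    )
    rows.append(("phenotypic", rp, rp_se))
    return pd.DataFrame(rows, columns=["kind", "r", "se"]).set_index("kind")


# ---------------------------------------------------------------------------
# model comparison


@dataclass
class LrtResult:
    statistic: float
    p_mixture: float
    p_chi2: float
    df: int = 1


def likelihood_ratio_test(
    reduced: VarCompResult | RemlResult, full: VarCompResult | RemlResult
) -> LrtResult:
    """LRT for one extra variance component, boundary-corrected.

    The statistic 2*(LL_full - LL_reduced) is clipped at zero.  Because the
    null value (variance = 0) lies on the boundary, the reference
    distribution is the 50:50 mixture chi2_0 : chi2_1; the naive chi2_1
    p-value is reported alongside.  A statistic of exactly 0 gets the mixture
    point-mass p of 0.5.
    """
    ll_r = reduced.loglik
    ll_f = full.loglik
    nr = set((reduced.reml if isinstance(reduced, VarCompResult) else reduced).names)
    nf = set((full.reml if isinstance(full, VarCompResult) else full).names)
    if not nr < nf:
        raise RemlError(
            f"models not nested: reduced terms {sorted(nr)} vs full {sorted(nf)}"
        )
    stat = max(0.0, 2.0 * (ll_f - ll_r))
    p_chi2 = float(stats.chi2.sf(stat, df=1))
    p_mix = 0.5 if stat == 0.0 else float(0.5 * stats.chi2.sf(stat, df=1))
    return LrtResult(stat, p_mix, p_chi2)


# ---------------------------------------------------------------------------
# fixed-effect-only models


@dataclass
class FixedFitResult:
    coefficients: pd.Series
    anova: pd.DataFrame
    contrasts: dict[str, float]
    sigma2: float
    n: int


def fit_fixed_model(
    data: pd.DataFrame, spec: ModelSpec
) -> FixedFitResult:
    """Ordinary least squares with sequential (type-I) F tests.

    Used for the fixed-effect screens: the repeated-measures significance
    model and the enterotype-impact model, whose enterotype contrast is
    reported in trait units.
    """
    from statsmodels.stats.anova import anova_lm
    import statsmodels.formula.api as smf

    # build formula; interactions as C(a):C(b)
    parts = []
    for t in spec.fixed:
        if t in spec.covariates:
            parts.append(t)
        elif ":" in t:
            a, b = t.split(":")
            parts.append(f"C({a}):C({b})")
        else:
            parts.append(f"C({t})")
    formula = f"{spec.response} ~ " + " + ".join(parts) if parts else f"{spec.response} ~ 1"
    df = data.dropna(subset=[spec.response]).copy()
    fit = smf.ols(formula, data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            anova = anova_lm(fit, typ=1)
        except Exception:
            anova = pd.DataFrame()
    contrasts = {}
    for name, val in fit.params.items():
        if "C(enterotype)" in name:
            contrasts[name] = float(val)
    return FixedFitResult(
        coefficients=fit.params,
        anova=anova,
        contrasts=contrasts,
        sigma2=float(fit.mse_resid),
        n=int(fit.nobs),
    )


# ---------------------------------------------------------------------------
# longitudinal family profile


@dataclass
class FamilyProfile:
    effects: pd.DataFrame  # ages x families, centered within age
    correlations: pd.DataFrame
    varcomp: dict[str, float]


def family_effect_profile(
    data: pd.DataFrame,
    response: str = "shannon",
    fixed: tuple[str, ...] = ("sex", "bs"),
    age_col: str = "age",
    family_col: str = "family",
) -> FamilyProfile:
    """Age-specific sire-family effects and their cross-age correlations.

    Fits ``y = mu + fixed + (age x family) + e`` with the age-by-family
    interaction as a random (shrunken) effect, predicts its BLUPs, centers
    them within age, and correlates the per-family profiles between ages
    (pairwise-complete).
    """
    df = data.dropna(subset=[response]).copy()
    spec = ModelSpec(response, fixed, ())
    y = df[response].astype(float).to_numpy()
    X, fixed_names = build_fixed_design(df, spec)
    labels = df[age_col].astype(str) + "|" + df[family_col].astype(str)
    Z, level_names = _incidence(labels)
    terms = [RandomTerm("age_family", U=Z), RandomTerm("residual")]
    res, _ = ai_reml(y, X, terms)
    u = res.ranef["age_family"]
    eff = pd.Series(u, index=level_names)
    idx = pd.MultiIndex.from_tuples(
        [tuple(s.split("|", 1)) for s in level_names], names=[age_col, family_col]
    )
    eff.index = idx
    table = eff.unstack(family_col)
    table = table.sub(table.mean(axis=1), axis=0)
    corr = table.T.corr()
    return FamilyProfile(table, corr, res.varcomp)
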