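"""Quantitative genetics of drought response: ANOVA, model selection,
variance components, repeatability and evolvability.

Repeated drought events act as repeated measurements on the same trees, so
the intraclass correlation r = sigma2_A / (sigma2_A + sigma2_W) from a
tree-random-intercept model is the repeatability of the drought trait — the
upper limit of its narrow-sense heritability (the additive variance can
never exceed the among-individual variance).  From r the potential additive
genetic variance is V_A = r * V_P and the mean-standardized evolvability is
CV_A = 100 * sqrt(V_A) / mean.

Responses are log-transformed and z-scored before variance-component
estimation (ratio traits are right-skewed); note that r itself is invariant
to the affine part of that transform.  Model comparisons across fixed
effects (drought event, provenance, their interaction) use maximum
likelihood, while all reported variance components use REML.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .mixed import NestedFit, RandomInterceptFit, fit_nested, fit_random_intercept
from .response import ResponseTable

__all__ = [
    "TransformedResponse",
    "VarianceComponents",
    "RepeatabilityResult",
    "EvolvabilityResult",
    "ModelComparison",
    "standardize_log",
    "reml_variance_components",
    "repeatability",
    "species_repeatability",
    "provenance_repeatability",
    "repeatability_table",
    "evolvability",
    "evolvability_table",
    "two_way_anova",
    "posthoc_pairwise",
    "compact_letter_display",
    "repeated_measures_selection",
]

Z_CRIT = 1.959963984540054  # two-sided 5% normal quantile


@dataclass(frozen=True)
class TransformedResponse:
    """Log-transformed, z-scored responses with an invertible transform record."""

    values: np.ndarray
    center: float   # mean of log values
    scale: float    # sample SD (n-1) of log values
    log_base: str = "e"

    def inverse(self) -> np.ndarray:
        return np.exp(self.values * self.scale + self.center)


@dataclass(frozen=True)
class VarianceComponents:
    sigma2_A: float               # among trees
    sigma2_W: float               # within trees (residual)
    sigma2_P: float | None = None  # among provenances (nested model only)
    method: str = "REML"
    cov: np.ndarray | None = None  # (A, W) or (A, P, W) order, matching the fit
    boundary: bool = False
    n_obs: int = 0
    n_trees: int = 0


@dataclass(frozen=True)
class RepeatabilityResult:
    r: float
    se_r: float
    scope: str = "provenance"   # or "species"
    trait: str = ""
    n_trees: int = 0
    n_events: int = 0
    boundary: bool = False
    significant: bool | None = None
    reason: str | None = None


@dataclass(frozen=True)
class EvolvabilityResult:
    V_A: float
    V_P: float
    trait_mean: float
    CV_A: float  # percent


@dataclass
class ModelComparison:
    """Stepwise nested-model sequence with AIC / logLik / likelihood ratios."""

    trait: str
    table: pd.DataFrame
    fits: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Transform
# ---------------------------------------------------------------------------

def standardize_log(values) -> TransformedResponse:
    """Natural log, then center to mean 0 and scale to sample SD 1."""
    x = np.asarray(values, dtype=float)
    bad = np.where(~(x > 0))[0]
    if bad.size:
        raise ValueError(f"nonpositive responses at positions {bad[:10].tolist()}; "
                         "exclude degenerate records upstream")
    logs = np.log(x)
    center = float(logs.mean())
    scale = float(logs.std(ddof=1)) if logs.size > 1 else 0.0
    if scale <= 0:
        raise ValueError("degenerate trait: zero variance after log transform")
    return TransformedResponse((logs - center) / scale, center, scale)


# ---------------------------------------------------------------------------
# Variance components and repeatability
# ---------------------------------------------------------------------------

def reml_variance_components(values, tree_ids, provenance_ids=None) -> VarianceComponents:
    """REML variance components for tree (optionally provenance + tree) intercepts."""
    if provenance_ids is None:
        fit = fit_random_intercept(values, tree_ids, method="REML")
        return VarianceComponents(fit.sigma2_group, fit.sigma2_resid, None, "REML",
                                  fit.cov_components, fit.boundary, fit.n_obs, fit.n_groups)
    nfit = fit_nested(values, provenance_ids, tree_ids, method="REML")
    return VarianceComponents(nfit.sigma2_tree, nfit.sigma2_resid, nfit.sigma2_prov, "REML",
                              nfit.cov_components, nfit.boundary, nfit.n_obs, nfit.n_trees)


def _delta_se_r(a: float, w: float, cov_aw: np.ndarray | None) -> float:
    """Delta-method SE of r = a/(a+w) from the (a, w) covariance block."""
    if cov_aw is None:
        return math.nan
    tot = a + w
    grad = np.array([w, -a]) / tot**2
    var = float(grad @ cov_aw @ grad)
    return math.sqrt(var) if var >= 0 else math.nan


def repeatability(components: VarianceComponents, scope: str = "provenance",
                  trait: str = "", n_events: int = 0) -> RepeatabilityResult:
    """r = sigma2_A / (sigma2_A + sigma2_W), with a delta-method SE.

    Boundary estimates (sigma2_A truncated at 0) report r = 0 with SE 0;
    significance is |r| / se > 1.96 where the SE is defined.
    """
    a, w = components.sigma2_A, components.sigma2_W
    if a + w <= 0:
        raise ValueError("total variance is zero; repeatability undefined")
    r = a / (a + w)
    if a == 0:
        return RepeatabilityResult(0.0, 0.0, scope, trait,
                                   components.n_trees, n_events, True, False)
    if w == 0:
        return RepeatabilityResult(1.0, 0.0, scope, trait,
                                   components.n_trees, n_events, True, True)
    if components.boundary:
        return RepeatabilityResult(float(r), 0.0, scope, trait,
                                   components.n_trees, n_events, True, False)
    cov = components.cov
    if cov is not None and cov.shape == (3, 3):
        # nested order (tree, prov, resid): marginalize to (tree, resid)
        cov = cov[np.ix_([0, 2], [0, 2])]
    se = _delta_se_r(a, w, cov)
    sig = bool(se > 0 and r / se > Z_CRIT) if np.isfinite(se) else None
    return RepeatabilityResult(float(r), float(se), scope, trait,
                               components.n_trees, n_events, False, sig)


def _trait_records(table: ResponseTable, trait: str) -> pd.DataFrame:
    d = table.defined(trait)
    return d[d[trait] > 0]


def species_repeatability(table: ResponseTable, trait: str) -> RepeatabilityResult:
    """Species-level r from a provenance + tree random-intercept model.

    Provenance variance is estimated separately and excluded from the
    repeatability denominator, which keeps r the among-tree fraction of the
    within-provenance phenotypic variance.
    """
    d = _trait_records(table, trait)
    if d["provenance_id"].nunique() < 2:
        raise ValueError("single provenance supplied; use provenance_repeatability instead")
    tr = standardize_log(d[trait].to_numpy())
    comps = reml_variance_components(tr.values, d["tree_id"].to_numpy(),
                                     d["provenance_id"].to_numpy())
    return repeatability(comps, scope="species", trait=trait,
                         n_events=int(d["event_year"].nunique()))


def provenance_repeatability(table: ResponseTable, trait: str,
                             provenance_id: str) -> RepeatabilityResult:
    """Per-provenance r from a tree-only random-intercept model."""
    d = _trait_records(table, trait)
    d = d[d["provenance_id"] == provenance_id]
    n_trees = d["tree_id"].nunique()
    repeated = (d.groupby("tree_id").size() >= 2).sum()
    if n_trees < 2 or repeated < 1:
        return RepeatabilityResult(math.nan, math.nan, "provenance", trait, n_trees,
                                   int(d["event_year"].nunique()) if len(d) else 0,
                                   False, None, reason="too few trees or repeated records")
    tr = standardize_log(d[trait].to_numpy())
    comps = reml_variance_components(tr.values, d["tree_id"].to_numpy())
    return repeatability(comps, scope="provenance", trait=trait,
                         n_events=int(d["event_year"].nunique()))


def repeatability_table(table: ResponseTable, trait: str) -> pd.DataFrame:
    """Per-provenance repeatability rows (r, SE, significance, counts)."""
    provs = sorted(_trait_records(table, trait)["provenance_id"].unique())
    rows = []
    for pid in provs:
        res = provenance_repeatability(table, trait, pid)
        rows.append((pid, res.r, res.se_r, res.significant, res.boundary,
                     res.n_trees, res.n_events, res.reason or ""))
    return pd.DataFrame(rows, columns=["provenance_id", "r", "se_r", "significant",
                                       "boundary", "n_trees", "n_events", "reason"])


def repeatability_summary(table: ResponseTable, trait: str) -> dict:
    """Species summary: r_sp +/- SE and the share of significant provenances."""
    sp = species_repeatability(table, trait)
    per = repeatability_table(table, trait)
    sig = per[per["significant"].fillna(False).astype(bool)]
    n_prov = len(per)
    return {
        "trait": trait,
        "r_sp": sp.r,
        "se_sp": sp.se_r,
        "n_sig": int(len(sig)),
        "n_prov": n_prov,
        "share_sig": len(sig) / n_prov if n_prov else math.nan,
        "r_sig_min": float(sig["r"].min()) if len(sig) else math.nan,
        "r_sig_max": float(sig["r"].max()) if len(sig) else math.nan,
        "r_sig_mean": float(sig["r"].mean()) if len(sig) else math.nan,
    }


# ---------------------------------------------------------------------------
# Evolvability
# ---------------------------------------------------------------------------

def evolvability(r: float, V_P: float, trait_mean: float) -> EvolvabilityResult:
    """V_A = r * V_P and CV_A = 100 * sqrt(V_A) / mean (percent)."""
    if trait_mean <= 0:
        raise ValueError("trait mean must be positive for a coefficient of variation")
    if V_P < 0:
        raise ValueError("phenotypic variance must be nonnegative")
    if not np.isfinite(r):
        raise ValueError("repeatability is undefined")
    v_a = r * V_P
    return EvolvabilityResult(float(v_a), float(V_P), float(trait_mean),
                              float(100.0 * math.sqrt(v_a) / trait_mean))


def evolvability_table(table: ResponseTable, trait: str) -> pd.DataFrame:
    """Per-provenance CV_A from provenance repeatability and raw-scale V_P.

    V_P is the sample variance of the raw (untransformed) trait over the
    provenance's tree-event records, and the mean is the provenance trait
    mean on the same scale.
    """
    d = _trait_records(table, trait)
    rows = []
    for pid in sorted(d["provenance_id"].unique()):
        sub = d[d["provenance_id"] == pid][trait]
        rep = provenance_repeatability(table, trait, pid)
        if not np.isfinite(rep.r) or len(sub) < 2:
            rows.append((pid, math.nan, math.nan, float(sub.mean()), math.nan))
            continue
        ev = evolvability(rep.r, float(sub.var(ddof=1)), float(sub.mean()))
        rows.append((pid, rep.r, ev.V_A, ev.trait_mean, ev.CV_A))
    return pd.DataFrame(rows, columns=["provenance_id", "r", "V_A", "trait_mean", "CV_A"])


# ---------------------------------------------------------------------------
# Species-level ANOVA and post-hoc letters
# ---------------------------------------------------------------------------

def two_way_anova(df: pd.DataFrame, trait: str, species_col: str = "species",
                  event_col: str = "event_year") -> pd.DataFrame:
    """Fixed-effects two-way ANOVA with interaction on individual-tree records.

    Returns one row per term (species, drought year, interaction, residual)
    with degrees of freedom, sums of squares, F and p.
    """
    d = df[[species_col, event_col, trait]].dropna().rename(
        columns={species_col: "species", event_col: "event", trait: "value"})
    counts = d.groupby(["species", "event"]).size().unstack(fill_value=0)
    empty = [(s, int(e)) for s in counts.index for e in counts.columns if counts.loc[s, e] == 0]
    if empty:
        raise ValueError(f"empty species x drought-year cell(s): {empty}")
    model = smf.ols("value ~ C(species) * C(event)", data=d).fit()
    an = sm.stats.anova_lm(model, typ=2)
    an = an.rename(index={"C(species)": "species", "C(event)": "drought_year",
                          "C(species):C(event)": "interaction", "Residual": "residual"})
    an["df"] = an["df"].astype(int)
    return an[["df", "sum_sq", "F", "PR(>F)"]].rename(columns={"PR(>F)": "p"})


def compact_letter_display(groups: list[str], sig_pairs: set[frozenset]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``groups`` are ordered (typically by descending mean); groups sharing a
    letter are not significantly different under ``sig_pairs``.
    """
    sets: list[set] = [set(groups)]
    for a, b in sorted((tuple(sorted(p)) for p in sig_pairs)):
        new_sets = []
        for s in sets:
            if a in s and b in s:
                new_sets.extend([s - {a}, s - {b}])
            else:
                new_sets.append(s)
        # absorb: drop sets contained in another
        sets = [s for s in new_sets
                if s and not any(s < t or (s == t and new_sets.index(t) < new_sets.index(s))
                                 for t in new_sets if t is not s)]
        # deduplicate while preserving order
        seen, uniq = [], []
        for s in sets:
            if s not in seen:
                seen.append(s)
                uniq.append(s)
        sets = uniq
    letters = "abcdefghijklmnopqrstuvwxyz"
    # order letter sets by the first (best) group they contain
    rank = {g: i for i, g in enumerate(groups)}
    sets.sort(key=lambda s: min(rank[g] for g in s))
    out = {g: "" for g in groups}
    for i, s in enumerate(sets):
        for g in s:
            out[g] += letters[i % len(letters)]
    return {g: "".join(sorted(out[g])) for g in groups}


def posthoc_pairwise(df: pd.DataFrame, trait: str, group_col: str,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons summarised as a compact letter display."""
    d = df[[group_col, trait]].dropna()
    means = d.groupby(group_col)[trait].mean().sort_values(ascending=False)
    groups = [str(g) for g in means.index]
    if len(groups) < 2:
        return pd.DataFrame({"group": groups, "mean": means.to_numpy(), "letters": ["a"] * len(groups)})
    tk = pairwise_tukeyhsd(d[trait].to_numpy(), d[group_col].astype(str).to_numpy(), alpha=alpha)
    res = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    sig = {frozenset((str(r["group1"]), str(r["group2"]))) for _, r in res.iterrows() if r["reject"]}
    cld = compact_letter_display(groups, sig)
    return pd.DataFrame({"group": groups,
                         "mean": [float(means[g]) for g in groups],
                         "letters": [cld[g] for g in groups]})


# ---------------------------------------------------------------------------
# Repeated-measures model selection
# ---------------------------------------------------------------------------

def _design(d: pd.DataFrame, terms: str) -> np.ndarray:
    ev = pd.get_dummies(d["event_year"].astype(str), prefix="ev", drop_first=True, dtype=float)
    pv = pd.get_dummies(d["provenance_id"].astype(str), prefix="pr", drop_first=True, dtype=float)
    cols = [pd.Series(np.ones(len(d)), index=d.index, name="intercept")]
    if "drought" in terms:
        cols.append(ev)
    if "provenance" in terms:
        cols.append(pv)
    if "interaction" in terms:
        inter = pd.DataFrame(
            {f"{e}:{p}": ev[e] * pv[p] for e in ev.columns for p in pv.columns}, index=d.index)
        cols.append(inter)
    return pd.concat(cols, axis=1).to_numpy(dtype=float)


def repeated_measures_selection(table: ResponseTable, trait: str,
                                transform: bool = True) -> ModelComparison:
    """Stepwise fixed-effect sequence with a tree random intercept (ML fits).

    Models: intercept -> + drought event -> + provenance -> + interaction.
    Each step reports parameter count (fixed effects + 2 variance
    components), AIC, log-likelihood, and the likelihood ratio against the
    previous model with a chi-square p-value on the parameter difference.
    """
    d = _trait_records(table, trait).copy()
    if d["event_year"].nunique() < 2:
        raise ValueError("need at least 2 drought events")
    if d["provenance_id"].nunique() < 2:
        raise ValueError("need at least 2 provenances for the provenance steps")
    y = standardize_log(d[trait].to_numpy()).values if transform else d[trait].to_numpy()
    tree = d["tree_id"].to_numpy()
    steps = [
        ("intercept", ""),
        ("drought", "drought"),
        ("provenance", "drought provenance"),
        ("drought_x_provenance", "drought provenance interaction"),
    ]
    rows, fits, prev = [], [], None
    for name, terms in steps:
        X = _design(d, terms)
        try:
            fit = fit_random_intercept(y, tree, X=X, method="ML")
        except Exception as exc:  # noqa: BLE001 - partial output contract
            rows.append((name, X.shape[1] + 2, math.nan, math.nan, math.nan, math.nan,
                         f"failed: {exc}"))
            fits.append(None)
            prev = None
            continue
        if prev is not None:
            lr = 2.0 * (fit.loglik - prev.loglik)
            ddf = fit.n_params - prev.n_params
            p = float(chi2.sf(max(lr, 0.0), ddf))
        else:
            lr, p = math.nan, math.nan
        rows.append((name, fit.n_params, fit.aic, fit.loglik, lr, p, ""))
        fits.append(fit)
        prev = fit
    tab = pd.DataFrame(rows, columns=["model", "n_params", "AIC", "logLik",
                                      "L_ratio", "p_value", "note"])
    return ModelComparison(trait, tab, fits)
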