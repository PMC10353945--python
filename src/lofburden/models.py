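"""Multivariable rare-variant / polygenic-score association models.

Carriers are split by the estimated gene-level autism OR at a threshold of
10 (``<= 10`` low stratum, ``> 10`` high, infinity counting as high) and the
resulting indicators enter logistic (diagnosis), linear (continuous traits),
ordinal-logistic (income/qualification bands) and 2x2 (questionnaire
participation) models, alongside the polygenic score, sex (female = 1), age
and four genotype principal components, with the interactions the study
formulas name.  Continuous predictors and continuous outcomes are z-scored
so linear effects read as standardized betas; binary carrier indicators stay
unstandardized so their effects read per carrier.  P values are adjusted by
Benjamini-Hochberg FDR separately per covariate within the stated outcome
groups; the Townsend deprivation index is reversed before modelling so that
more deprivation carries a negative sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.stats.multitest import multipletests

from .filters import CarrierMatrix

__all__ = [
    "RegressionSpec",
    "PRESET_TERMS",
    "split_lof_by_or",
    "prepare_model_frame",
    "fit_model",
    "fit_diagnosis_model",
    "fit_trait_linear",
    "fit_ordinal",
    "reverse_townsend",
    "fdr_adjust",
    "participation_or",
]


#: Term sets of the study's printed model formulas; ``LoF`` is substituted
#: with the chosen carrier-indicator column at fit time.
PRESET_TERMS: dict[str, tuple[str, ...]] = {
    "diagnosis": ("LoF", "pgs", "sex", "LoF:pgs", "pc1", "pc2", "pc3", "pc4"),
    "family_trait": ("LoF", "pgs", "sex", "LoF:pgs", "pc1", "pc2", "pc3", "pc4"),
    "population_trait": ("LoF", "pgs", "sex", "LoF:pgs", "age",
                         "pc1", "pc2", "pc3", "pc4"),
    "socioeconomic_ordinal": ("LoF", "pgs", "sex", "LoF:pgs", "age",
                              "pc1", "pc2", "pc3", "pc4"),
    "brain_global": ("LoF", "pgs", "sex", "age", "LoF:pgs", "LoF:sex",
                     "LoF:age", "sex:age", "age2", "site"),
    "brain_regional": ("LoF", "pgs", "sex", "age", "LoF:pgs", "LoF:sex",
                       "LoF:age", "sex:age", "age2", "site", "total"),
    "brain_covariate": ("LoF", "pgs", "sex", "age", "LoF:pgs", "LoF:sex",
                        "LoF:age", "sex:age", "age2", "site", "covariate",
                        "LoF:covariate", "pgs:covariate"),
}


@dataclass(frozen=True)
class RegressionSpec:
    """One model: outcome column, family and term list.

    ``terms`` may contain column names, ``age2`` (squared age), and ``a:b``
    interactions whose main effects must also be present.  ``lof_column``
    replaces the ``LoF`` placeholder used by the presets.
    """

    outcome: str
    family: str  # binary_logistic | linear | ordinal_logistic
    terms: tuple[str, ...]
    lof_column: str = "lof_high"
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.family not in ("binary_logistic", "linear", "ordinal_logistic"):
            raise ValueError(f"unknown family {self.family!r}")
        resolved = self.resolved_terms()
        mains = {t for t in resolved if ":" not in t}
        for t in resolved:
            if ":" in t:
                a, b = t.split(":")
                if a not in mains or b not in mains:
                    raise ValueError(f"interaction {t} lacks a main effect")

    def resolved_terms(self) -> tuple[str, ...]:
        return tuple(t.replace("LoF", self.lof_column) for t in self.terms)

    @classmethod
    def from_preset(cls, outcome: str, family: str, preset: str,
                    lof_column: str = "lof_high", **kw) -> "RegressionSpec":
        return cls(outcome, family, PRESET_TERMS[preset], lof_column, **kw)


# ---------------------------------------------------------------------------
# Indicators and model frame
# ---------------------------------------------------------------------------


def split_lof_by_or(carriers: CarrierMatrix, gene_or: pd.Series,
                    threshold: float = 10.0) -> pd.DataFrame:
    """Carrier indicators split by gene-level autism OR.

    ``lof_low`` marks carriers in genes with OR <= ``threshold``;
    ``lof_high`` carriers in genes with OR > ``threshold`` (+inf counts as
    high).  An individual carrying in genes on both sides is 1 in both
    columns.  Genes with an undefined OR are excluded.
    """
    ors = gene_or.reindex(carriers.genes)
    long = carriers.to_long().merge(ors.rename("autism_or"),
                                    left_on="gene_id", right_index=True)
    long = long.dropna(subset=["autism_or"])
    high_ids = set(long.loc[long["autism_or"] > threshold, "individual_id"])
    low_ids = set(long.loc[long["autism_or"] <= threshold, "individual_id"])
    out = pd.DataFrame(index=carriers.individuals)
    out["lof_low"] = out.index.isin(low_ids).astype(np.int8)
    out["lof_high"] = out.index.isin(high_ids).astype(np.int8)
    return out


def prepare_model_frame(cohort: pd.DataFrame,
                        indicators: pd.DataFrame | None = None,
                        phenotypes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Merge cohort, carrier indicators and phenotypes; code sex female = 1."""
    df = cohort.set_index("individual_id").copy()
    df["sex"] = (df["sex"] == "F").astype(np.int8)
    df["diagnosed"] = df["diagnosed"].astype(np.int8)
    for extra in (indicators, phenotypes):
        if extra is not None:
            df = df.join(extra, how="left")
    return df


def _is_binary(col: pd.Series) -> bool:
    vals = col.dropna().unique()
    return len(vals) <= 2 and set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}


def _build_design(data: pd.DataFrame, spec: RegressionSpec) -> pd.DataFrame:
    """Design matrix: mains (continuous z-scored), then interactions."""
    cols: dict[str, np.ndarray] = {}
    terms = spec.resolved_terms()
    for t in terms:
        if ":" in t:
            continue
        if t == "age2":
            base = data["age"].astype(float) ** 2
        else:
            if t not in data.columns:
                raise KeyError(f"term {t!r} has no matching column")
            base = data[t].astype(float)
        if spec.standardize and not _is_binary(base):
            sd = base.std(ddof=0)
            if sd == 0:
                raise ValueError(f"term {t!r} is constant")
            base = (base - base.mean()) / sd
        cols[t] = base.to_numpy()
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            cols[t] = cols[a] * cols[b]
    X = pd.DataFrame(cols, index=data.index)
    return sm.add_constant(X, has_constant="add")


def _tidy(spec: RegressionSpec, params, conf, pvals, n: int,
          exponentiate: bool, flags: Mapping | None = None) -> pd.DataFrame:
    rows = []
    for term in params.index:
        if term == "const":
            continue
        est, lo, hi = params[term], conf.loc[term, 0], conf.loc[term, 1]
        row = dict(outcome=spec.outcome, family=spec.family, term=term,
                   estimate=est, ci_low=lo, ci_high=hi,
                   p_value=pvals[term], n=n)
        if exponentiate:
            row.update(odds_ratio=np.exp(est), or_ci_low=np.exp(lo),
                       or_ci_high=np.exp(hi))
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs.update(flags or {})
    return out


# ---------------------------------------------------------------------------
# Fits
# ---------------------------------------------------------------------------


def fit_diagnosis_model(data: pd.DataFrame, spec: RegressionSpec,
                        ridge_on_separation: bool = False) -> pd.DataFrame:
    """Binary logistic fit of diagnosis; LoF effects exponentiate to ORs.

    Quasi-separation (diverging coefficients or non-convergence) is flagged
    in ``result.attrs['separation']``; with ``ridge_on_separation`` the
    model is refit with a small L2 penalty instead.
    """
    sub = data.dropna(subset=[spec.outcome, *{t for t in spec.resolved_terms() if ":" not in t and t != "age2"}])
    y = sub[spec.outcome].astype(float)
    X = _build_design(sub, spec)
    model = sm.Logit(y, X)
    separation = False
    penalized = False
    try:
        res = model.fit(disp=False, maxiter=200)
        if not res.mle_retvals.get("converged", True) or np.abs(res.params).max() > 15:
            separation = True
    except Exception:
        separation = True
        res = None
    if separation and (ridge_on_separation or res is None):
        # small L2 penalty keeps the fit finite under quasi-separation
        res = model.fit_regularized(alpha=1.0, L1_wt=0.0, disp=False, maxiter=500)
        penalized = True
    conf = res.conf_int()
    return _tidy(spec, res.params, conf, res.pvalues, int(len(sub)),
                 exponentiate=True,
                 flags={"separation": separation, "penalized": penalized})


def fit_trait_linear(data: pd.DataFrame, spec: RegressionSpec) -> pd.DataFrame:
    """OLS fit of a continuous trait; coefficients are standardized betas."""
    sub = data.dropna(subset=[spec.outcome, *{t for t in spec.resolved_terms() if ":" not in t and t != "age2"}])
    y = sub[spec.outcome].astype(float)
    if spec.standardize:
        y = (y - y.mean()) / y.std(ddof=0)
    X = _build_design(sub, spec)
    res = sm.OLS(y, X).fit()
    return _tidy(spec, res.params, res.conf_int(), res.pvalues, int(len(sub)),
                 exponentiate=False)


def fit_ordinal(data: pd.DataFrame, spec: RegressionSpec,
                empty_levels: str = "error") -> pd.DataFrame:
    """Proportional-odds (ordinal logistic) fit of a banded outcome.

    Outcome levels are ordered by their numeric value.  Empty intermediate
    levels raise by default or are collapsed away with
    ``empty_levels='collapse'``.  Per-term estimates are latent-scale betas
    with exponentiated ORs.
    """
    sub = data.dropna(subset=[spec.outcome, *{t for t in spec.resolved_terms() if ":" not in t and t != "age2"}])
    y_raw = sub[spec.outcome]
    levels = sorted(y_raw.unique())
    if empty_levels == "error":
        full = list(range(int(min(levels)), int(max(levels)) + 1))
        if all(float(l).is_integer() for l in levels) and [int(l) for l in levels] != full:
            raise ValueError(f"empty outcome levels in {spec.outcome}; "
                             "use empty_levels='collapse'")
    y = pd.Categorical(y_raw, categories=levels, ordered=True)
    X = _build_design(sub, spec).drop(columns="const")  # thresholds absorb it
    model = OrderedModel(y, X, distr="logit")
    res = model.fit(method="bfgs", disp=False, maxiter=200)
    params = res.params[X.columns]
    conf = res.conf_int().loc[X.columns]
    pvals = res.pvalues[X.columns]
    return _tidy(spec, params, conf, pvals, int(len(sub)), exponentiate=True)


def fit_model(data: pd.DataFrame, spec: RegressionSpec, **kw) -> pd.DataFrame:
    """Dispatch on the spec's outcome family."""
    if spec.family == "binary_logistic":
        return fit_diagnosis_model(data, spec, **kw)
    if spec.family == "linear":
        return fit_trait_linear(data, spec)
    return fit_ordinal(data, spec, **kw)


# ---------------------------------------------------------------------------
# Conventions and corrections
# ---------------------------------------------------------------------------


def reverse_townsend(values):
    """Negate the Townsend index so more deprivation reads as negative."""
    return -pd.Series(values) if not isinstance(values, (pd.Series, np.ndarray)) else -values


def fdr_adjust(results: pd.DataFrame,
               group_cols: Sequence[str] = ("term", "outcome_group"),
               p_col: str = "p_value") -> pd.DataFrame:
    """Benjamini-Hochberg adjustment within each covariate/outcome group.

    The study corrects separately for each covariate, independently within
    (1) diagnosis + core autism traits, (2) developmental milestones and
    (3) socioeconomic/fluid-intelligence outcomes; callers encode that
    grouping in ``group_cols``.
    """
    out = results.copy()
    out["p_fdr"] = np.nan
    present = [c for c in group_cols if c in out.columns]
    groups = out.groupby(present, dropna=False).groups if present else {None: out.index}
    for _, idx in groups.items():
        p = out.loc[idx, p_col].to_numpy(dtype=float)
        ok = ~np.isnan(p)
        if ok.any():
            adj = multipletests(p[ok], method="fdr_bh")[1]
            values = np.full(len(p), np.nan)
            values[ok] = adj
            out.loc[idx, "p_fdr"] = values
    return out


def participation_or(carrier, responded, haldane: bool = True) -> dict:
    """Questionnaire-participation OR for carriers, with Woolf logit CI.

    Returns the 2x2 cells, OR = (carrier-respondent x noncarrier-non-
    respondent) / (carrier-nonrespondent x noncarrier-respondent), the
    Woolf CI exp(log OR +/- 1.96*sqrt(sum 1/cell)) and the Fisher two-sided
    p.  With a zero cell the point OR is reported from the raw cells (0 or
    inf) while the CI uses Haldane-corrected (+0.5) cells when ``haldane``.
    """
    carrier = np.asarray(carrier, dtype=bool)
    responded = np.asarray(responded, dtype=bool)
    a = int((carrier & responded).sum())       # carrier, responded
    b = int((carrier & ~responded).sum())
    c = int((~carrier & responded).sum())
    d = int((~carrier & ~responded).sum())
    from .burden import fisher_exact_2x2
    _, p = fisher_exact_2x2([[a, b], [c, d]])
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    cells = np.array([a, b, c, d], dtype=float)
    if (cells == 0).any():
        if not haldane:
            return dict(a=a, b=b, c=c, d=d, odds_ratio=odds,
                        ci_low=np.nan, ci_high=np.nan, p_value=p)
        cells = cells + 0.5
    log_or = np.log((cells[0] * cells[3]) / (cells[1] * cells[2]))
    half = 1.96 * np.sqrt((1.0 / cells).sum())
    return dict(a=a, b=b, c=c, d=d, odds_ratio=odds,
                ci_low=float(np.exp(log_or - half)),
                ci_high=float(np.exp(log_or + half)), p_value=p)
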