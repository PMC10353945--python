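"""Cohort-level burden statistics.

Carrier proportions with normal-approximation 95% CIs, two-sided Fisher
exact contrasts (probability-mass rule), Bonferroni correction within
(variant type, gene set) groups, female-vs-male carrier enrichment,
Mann-Whitney U comparisons of OR distributions (exact by enumeration for
small samples), OR-expression correlations across brain regions and
developmental periods, and coexpression-module OR summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .odds import cap_infinite_or

__all__ = [
    "ProportionCI",
    "carrier_proportion_ci",
    "round_half_away",
    "fisher_exact_2x2",
    "bonferroni",
    "sex_ratio_test",
    "mann_whitney_u",
    "or_expression_correlation",
    "module_or_summary",
]


@dataclass(frozen=True)
class ProportionCI:
    """A carrier proportion with its normal-approximation 95% CI."""

    k: int
    n: int
    p: float
    se: float
    ci_low: float
    ci_high: float


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (the convention used for reported percentages)."""
    factor = 10.0 ** decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def carrier_proportion_ci(k: int, n: int) -> ProportionCI:
    """Proportion k/n with SE sqrt(p(1-p)/n) and 95% CI p +/- 1.96*SE.

    The CI is clamped to [0, 1]; the degenerate k = 0 (or k = n) case has
    zero SE and a point CI.
    """
    if n <= 0:
        raise ValueError("group size must be positive")
    if not 0 <= k <= n:
        raise ValueError("carrier count must be within [0, n]")
    p = k / n
    se = float(np.sqrt(p * (1.0 - p) / n))
    return ProportionCI(k, n, p, se,
                        max(0.0, p - 1.96 * se), min(1.0, p + 1.96 * se))


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test: (sample odds ratio, p).

    The two-sided p follows the probability-mass rule (sum of hypergeometric
    tables whose point probability is <= the observed table's).  A zero
    margin yields p = 1 with an undefined (NaN) OR.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 integer table")
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        return float("nan"), 1.0
    a, b = t[0]
    c, d = t[1]
    odds = float("inf") if b * c == 0 else (a * d) / (b * c)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return odds, float(p)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment min(1, p*m); m defaults to the number of tests."""
    p = np.asarray(p_values, dtype=float)
    m = len(p) if m is None else m
    return np.minimum(1.0, p * m)


def sex_ratio_test(female_carriers: int, female_total: int,
                   male_carriers: int, male_total: int) -> tuple[float, float]:
    """Female-over-male carrier enrichment OR and two-sided Fisher p."""
    fn = female_total - female_carriers
    mn = male_total - male_carriers
    table = [[female_carriers, fn], [male_carriers, mn]]
    _, p = fisher_exact_2x2(table)
    if male_carriers * fn == 0:
        odds = float("inf") if female_carriers * mn > 0 else float("nan")
    else:
        odds = (female_carriers * mn) / (male_carriers * fn)
    return odds, p


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a: pairs with a > b count 1, ties count 0.5."""
    return float((a[:, None] > b[None, :]).sum() + 0.5 * (a[:, None] == b[None, :]).sum())


def mann_whitney_u(a, b, exact_max_n: int = 8) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact p by complete enumeration of label assignments (ties handled by
    half-counting) when the smaller sample has at most ``exact_max_n``
    observations; normal approximation with tie correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    u_obs = _u_statistic(a, b)
    n, m = len(a), len(b)
    mu = n * m / 2.0
    if min(n, m) <= exact_max_n:
        pooled = np.concatenate([a, b])
        # pairwise win matrix of the pooled values, reused by every arrangement
        win = (pooled[:, None] > pooled[None, :]) + 0.5 * (pooled[:, None] == pooled[None, :])
        total = 0
        hits = 0
        dev_obs = abs(u_obs - mu) - 1e-9
        all_idx = frozenset(range(n + m))
        for a_idx in combinations(range(n + m), n):
            b_idx = tuple(all_idx - set(a_idx))
            u = win[np.ix_(a_idx, b_idx)].sum()
            total += 1
            if abs(u - mu) >= dev_obs:
                hits += 1
        return u_obs, hits / total
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


# ---------------------------------------------------------------------------
# Expression correlations and module summaries
# ---------------------------------------------------------------------------


def or_expression_correlation(gene_or: pd.Series, expression: pd.DataFrame,
                              method: str = "kendall",
                              min_expression: float = 1.0) -> pd.DataFrame:
    """Correlate gene-level autism OR with expression per (region, period).

    ``gene_or`` is indexed by gene (infinite values are capped to the
    highest finite OR; undefined ORs -- genes without diagnosed carriers --
    are dropped).  ``expression`` is a long table with columns
    ``gene_id, region, period, expression``; values <= ``min_expression``
    are excluded.  ``method`` is ``"kendall"`` (tau-b) or
    ``"pearson_log10"`` (Pearson on log10 OR vs log10 expression).  Cells
    whose OR or expression vector is constant are flagged undefined.
    """
    if method not in ("kendall", "pearson_log10"):
        raise ValueError(f"unknown correlation method {method!r}")
    ors = gene_or.dropna()
    capped = pd.Series(cap_infinite_or(ors.to_numpy()), index=ors.index)
    expr = expression[expression["expression"] > min_expression]
    rows = []
    for (region, period), grp in expr.groupby(["region", "period"], sort=True):
        merged = grp.set_index("gene_id")["expression"].to_frame().join(
            capped.rename("autism_or"), how="inner").dropna()
        n = len(merged)
        if n < 3 or merged["autism_or"].nunique() == 1 or merged["expression"].nunique() == 1:
            rows.append((region, period, n, np.nan, np.nan, True))
            continue
        if method == "kendall":
            r = stats.kendalltau(merged["autism_or"], merged["expression"])
        else:
            r = stats.pearsonr(np.log10(merged["autism_or"]),
                               np.log10(merged["expression"]))
        rows.append((region, period, n, float(r.statistic), float(r.pvalue), False))
    return pd.DataFrame(rows, columns=["region", "period", "n_genes",
                                       "statistic", "p_value", "undefined"])


def module_or_summary(gene_or: pd.Series, assignments: pd.DataFrame,
                      module_cell_types: Mapping[str, str] | None = None
                      ) -> tuple[pd.DataFrame, dict]:
    """Coexpression-module OR summary and neuron-vs-mixed contrast.

    ``assignments`` has columns ``gene_id, module`` (one module per row).
    Returns per-module mean capped OR in descending order, and -- when
    ``module_cell_types`` labels each module with its cell type(s) -- a
    Mann-Whitney contrast between genes found exclusively in
    neuron/interneuron modules and the rest.  With fewer than two modules
    the contrast is flagged unavailable.
    """
    ors = gene_or.dropna()
    capped = pd.Series(cap_infinite_or(ors.to_numpy()), index=ors.index)
    merged = assignments.merge(capped.rename("autism_or"),
                               left_on="gene_id", right_index=True)
    summary = (merged.groupby("module")["autism_or"]
               .agg(mean_or="mean", n_genes="size")
               .sort_values("mean_or", ascending=False)
               .reset_index())
    contrast: dict = {"available": False, "u": np.nan, "p": np.nan}
    if module_cell_types is not None and summary["module"].nunique() >= 2:
        neuronal = {m for m, t in module_cell_types.items()
                    if t and set(t.replace(";", ",").split(",")) <= {"neuron", "interneuron"}}
        per_gene = merged.groupby("gene_id").agg(
            autism_or=("autism_or", "first"),
            neuron_only=("module", lambda mods: set(mods) <= neuronal))
        a = per_gene.loc[per_gene["neuron_only"], "autism_or"].to_numpy()
        b = per_gene.loc[~per_gene["neuron_only"], "autism_or"].to_numpy()
        if a.size and b.size:
            u, p = mann_whitney_u(a, b)
            contrast = {"available": True, "u": u, "p": p,
                        "n_neuron_only": int(a.size), "n_mixed": int(b.size)}
    return summary, contrast
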