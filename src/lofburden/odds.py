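"""Gene-level autism odds ratio with sub-sampling and bootstrap empirical P.

The case group (diagnosed) is tiny relative to the undiagnosed pool, and the
definition of a singleton variant depends on group size, so the estimator
equalizes the groups: it runs 100 iterations that (1) draw as many
undiagnosed individuals as there are diagnosed individuals, without
replacement, and (2) re-select singleton variants within each group
separately, then uses the *average* undiagnosed carrier count (a real
number, never rounded) in

    autism_OR = (carriers_diag * noncarriers_undiag)
              / (carriers_undiag * noncarriers_diag)

with both denominators at the matched (diagnosed) group size.  The OR is
+inf when no undiagnosed carrier is ever drawn while diagnosed carriers
exist, and undefined (NaN) when there are no diagnosed carriers.

Significance comes from a relabeling bootstrap: each of N replicates draws a
pseudo-diagnosed set of the diagnosed size from the pooled cohort, labels
the remainder undiagnosed and reruns the same estimator; with M the number
of replicates whose OR is >= the observed OR (inf >= inf counts), the
empirical P value is (M + 1) / (N + 1), with 95% CI
P +/- 1.96 * sqrt(P(1-P)/(N+1)) and significance declared when the CI's
upper bound is < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .filters import CarrierMatrix

__all__ = [
    "SubsamplingConfig",
    "autism_or",
    "subsample_undiagnosed",
    "singleton_mask",
    "estimate_gene_or",
    "bootstrap_null",
    "empirical_p_ci",
    "significance_flag",
    "cap_infinite_or",
    "gene_or_table",
]


@dataclass(frozen=True)
class SubsamplingConfig:
    """Sub-sampling parameters of the OR estimator.

    ``singleton_mode='per_group_singletons'`` re-applies the allele-count-1
    rule within the diagnosed group and within each undiagnosed sub-sample;
    ``'prefiltered_only'`` relies on the upstream rarity filters alone.
    ``n_iterations_boot`` optionally reduces the inner iteration count inside
    each bootstrap replicate (1 = fast single-pass bootstrap); ``None`` keeps
    the full count.
    """

    n_iterations: int = 100
    singleton_mode: str = "per_group_singletons"
    seed: int = 0
    n_iterations_boot: int | None = None

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.singleton_mode not in ("per_group_singletons", "prefiltered_only"):
            raise ValueError(f"unknown singleton_mode {self.singleton_mode!r}")
        if self.n_iterations_boot is not None and self.n_iterations_boot < 1:
            raise ValueError("n_iterations_boot must be >= 1")


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def autism_or(n_carriers_diagnosed: float, n_noncarriers_diagnosed: float,
              n_carriers_undiagnosed: float, n_noncarriers_undiagnosed: float) -> float:
    """Cross-product odds ratio; +inf or NaN at the boundary cases."""
    cd, nd = n_carriers_diagnosed, n_noncarriers_diagnosed
    cu, nu = n_carriers_undiagnosed, n_noncarriers_undiagnosed
    if min(cd, nd, cu, nu) < 0:
        raise ValueError("counts must be non-negative")
    if cd == 0:
        return float("nan")
    den = cu * nd
    if den == 0:
        return float("inf")
    return (cd * nu) / den


def _or_vector(cd: np.ndarray, cu: np.ndarray, group_size: float) -> np.ndarray:
    """Vectorized autism OR with matched group sizes on both margins."""
    cd = np.asarray(cd, dtype=float)
    cu = np.asarray(cu, dtype=float)
    num = cd * (group_size - cu)
    den = cu * (group_size - cd)
    out = np.full(cd.shape, np.nan)
    undef = cd == 0
    inf = (~undef) & (den == 0)
    ok = (~undef) & (~inf)
    out[inf] = np.inf
    out[ok] = num[ok] / den[ok]
    return out


def subsample_undiagnosed(pool: np.ndarray, n_diagnosed: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Uniform draw without replacement of ``n_diagnosed`` pool members."""
    pool = np.asarray(pool)
    if len(pool) < n_diagnosed:
        raise ValueError(
            f"undiagnosed pool ({len(pool)}) smaller than diagnosed group ({n_diagnosed})")
    if len(pool) == n_diagnosed:
        return pool
    return rng.choice(pool, size=n_diagnosed, replace=False)


def singleton_mask(variant_codes: np.ndarray, in_group: np.ndarray) -> np.ndarray:
    """Entry-level mask of variants with allele count 1 within the group.

    ``variant_codes`` are integer variant codes per carrier entry and
    ``in_group`` a boolean mask over entries; the returned mask keeps the
    in-group entries whose variant occurs exactly once within the group.
    """
    variant_codes = np.asarray(variant_codes)
    in_group = np.asarray(in_group, dtype=bool)
    if len(variant_codes) == 0:
        return in_group.copy()
    counts = np.bincount(variant_codes[in_group], minlength=variant_codes.max() + 1)
    return in_group & (counts[variant_codes] == 1)


def _group_carrier_counts(gene_codes: np.ndarray, indiv_codes: np.ndarray,
                          var_codes: np.ndarray, entry_mask: np.ndarray,
                          n_genes: int, singletons: bool) -> np.ndarray:
    """Per-gene count of distinct carrier individuals among masked entries."""
    mask = singleton_mask(var_codes, entry_mask) if singletons else entry_mask
    if not mask.any():
        return np.zeros(n_genes, dtype=np.int64)
    g = gene_codes[mask].astype(np.int64)
    i = indiv_codes[mask].astype(np.int64)
    pairs = np.unique(g * (i.max() + 1) + i)
    return np.bincount(pairs // (i.max() + 1), minlength=n_genes)


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------


def _aligned_diag_mask(carriers: CarrierMatrix, cohort: pd.DataFrame) -> np.ndarray:
    diag = (cohort.set_index("individual_id")["diagnosed"]
            .reindex(carriers.individuals))
    if diag.isna().any():
        raise ValueError("carrier matrix contains individuals absent from the cohort")
    return diag.to_numpy(dtype=bool)


def estimate_gene_or(carriers: CarrierMatrix, cohort: pd.DataFrame,
                     config: SubsamplingConfig = SubsamplingConfig(),
                     rng: np.random.Generator | None = None,
                     diag_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Sub-sampled autism OR for every gene of the carrier matrix.

    The diagnosed carrier count is computed once on the full diagnosed
    group; the undiagnosed count is the mean over ``n_iterations``
    sub-samples of the undiagnosed pool, each of the diagnosed size.  When
    the pool already equals the diagnosed size every sub-sample is the whole
    pool, and the estimator coincides with the direct full-sample OR.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if diag_mask is None:
        diag_mask = _aligned_diag_mask(carriers, cohort)
    gene_codes, indiv_codes, var_codes = carriers.arrays()
    n_genes = carriers.n_genes
    n_diag = int(diag_mask.sum())
    pool = np.flatnonzero(~diag_mask)
    if len(pool) < n_diag:
        raise ValueError(
            f"undiagnosed pool ({len(pool)}) smaller than diagnosed group ({n_diag})")
    singletons = config.singleton_mode == "per_group_singletons"

    entry_diag = diag_mask[indiv_codes] if len(indiv_codes) else np.zeros(0, dtype=bool)
    cd = _group_carrier_counts(gene_codes, indiv_codes, var_codes, entry_diag,
                               n_genes, singletons)

    if len(pool) == n_diag:
        cu_mean = _group_carrier_counts(gene_codes, indiv_codes, var_codes,
                                        ~entry_diag, n_genes, singletons).astype(float)
    else:
        acc = np.zeros(n_genes, dtype=float)
        member = np.zeros(carriers.n_individuals, dtype=bool)
        for _ in range(config.n_iterations):
            subset = subsample_undiagnosed(pool, n_diag, rng)
            member[:] = False
            member[subset] = True
            entry_mask = member[indiv_codes] if len(indiv_codes) else np.zeros(0, dtype=bool)
            acc += _group_carrier_counts(gene_codes, indiv_codes, var_codes,
                                         entry_mask, n_genes, singletons)
        cu_mean = acc / config.n_iterations

    ors = _or_vector(cd, cu_mean, n_diag)
    return pd.DataFrame({
        "gene_id": carriers.genes,
        "n_carriers_diagnosed": cd,
        "n_noncarriers_diagnosed": n_diag - cd,
        "n_carriers_undiagnosed": cu_mean,
        "n_noncarriers_undiagnosed": n_diag - cu_mean,
        "group_size": n_diag,
        "autism_or": ors,
    }).set_index("gene_id")


def bootstrap_null(carriers: CarrierMatrix, cohort: pd.DataFrame,
                   n_bootstraps: int = 10_000,
                   config: SubsamplingConfig = SubsamplingConfig(),
                   seed: int = 1,
                   observed: pd.DataFrame | None = None) -> pd.DataFrame:
    """Relabeling bootstrap and empirical P value per gene.

    Each replicate draws, without replacement from the pooled cohort, a
    pseudo-diagnosed set of the diagnosed size, relabels the remainder
    undiagnosed and reruns the sub-sampled estimator.  A vectorized exact
    shortcut is taken when every variant has a single carrier (the per-group
    singleton rule is then vacuous) and the relabelled remainder equals the
    diagnosed size (the inner sub-sample is then the identity); otherwise
    the full estimator runs per replicate.
    """
    if n_bootstraps < 1:
        raise ValueError("n_bootstraps must be >= 1")
    diag_mask = _aligned_diag_mask(carriers, cohort)
    n = carriers.n_individuals
    n_diag = int(diag_mask.sum())
    n_rest = n - n_diag
    if n_rest < n_diag:
        raise ValueError("pooled cohort too small to relabel a pseudo-diagnosed group")
    if observed is None:
        observed = estimate_gene_or(carriers, cohort, config, diag_mask=diag_mask)
    obs_or = observed["autism_or"].to_numpy()

    rng = np.random.default_rng(seed)
    fast = carriers.max_carriers_per_variant() <= 1 and n_rest == n_diag
    if fast:
        C = carriers.bool_matrix()
        totals = C.sum(axis=0)
        boot = np.empty((n_bootstraps, carriers.n_genes))
        for b in range(n_bootstraps):
            idx = rng.permutation(n)[:n_diag]
            cd = C[idx].sum(axis=0)
            boot[b] = _or_vector(cd, totals - cd, n_diag)
    else:
        inner = config.n_iterations_boot or config.n_iterations
        inner_cfg = SubsamplingConfig(inner, config.singleton_mode, config.seed)
        boot = np.empty((n_bootstraps, carriers.n_genes))
        pseudo = np.zeros(n, dtype=bool)
        for b in range(n_bootstraps):
            pseudo[:] = False
            pseudo[rng.permutation(n)[:n_diag]] = True
            est = estimate_gene_or(carriers, cohort, inner_cfg, rng=rng, diag_mask=pseudo)
            boot[b] = est["autism_or"].to_numpy()

    with np.errstate(invalid="ignore"):
        M = (boot >= obs_or[None, :]).sum(axis=0)
    p = (M + 1) / (n_bootstraps + 1)
    p = np.where(np.isnan(obs_or), np.nan, p)
    lo, hi = empirical_p_ci(p, n_bootstraps)
    out = observed.copy()
    out["M"] = M
    out["n_bootstraps"] = n_bootstraps
    out["empirical_p"] = p
    out["p_ci_low"] = lo
    out["p_ci_high"] = hi
    out["significant"] = significance_flag(out["p_ci_high"]) & ~np.isnan(p)
    return out


def empirical_p_ci(p, n_bootstraps: int):
    """95% CI around the empirical P: p +/- 1.96*sqrt(p(1-p)/(N+1)), clamped."""
    p = np.asarray(p, dtype=float)
    half = 1.96 * np.sqrt(p * (1.0 - p) / (n_bootstraps + 1))
    lo = np.clip(p - half, 0.0, 1.0)
    hi = np.clip(p + half, 0.0, 1.0)
    if p.ndim == 0:
        return float(lo), float(hi)
    return lo, hi


def significance_flag(ci_high):
    """Significant iff the empirical-P CI upper bound is strictly below 0.05."""
    return np.asarray(ci_high) < 0.05 if np.ndim(ci_high) else bool(ci_high < 0.05)


def cap_infinite_or(values) -> np.ndarray:
    """Replace +inf ORs by the highest finite OR of the gene set.

    NaN (undefined) entries are preserved.  Raises when no finite reference
    OR exists.
    """
    arr = np.asarray(values, dtype=float).copy()
    is_inf = np.isposinf(arr)
    if not is_inf.any():
        return arr
    finite = arr[np.isfinite(arr)]
    if finite.size == 0:
        raise ValueError("no_finite_reference")
    arr[is_inf] = finite.max()
    return arr


def gene_or_table(carriers: CarrierMatrix, cohort: pd.DataFrame,
                  config: SubsamplingConfig = SubsamplingConfig(),
                  n_bootstraps: int = 10_000, seed: int = 1) -> pd.DataFrame:
    """Full per-gene results: counts, OR, capped OR, empirical P, CI, flag.

    Capping is performed over the genes with at least one diagnosed carrier
    (the set the study summarizes); genes without diagnosed carriers keep an
    undefined OR and empirical P.
    """
    out = bootstrap_null(carriers, cohort, n_bootstraps, config, seed)
    capped = out["autism_or"].to_numpy().copy()
    observed = ~np.isnan(capped)
    if np.isposinf(capped[observed]).any():
        capped[observed] = cap_infinite_or(capped[observed])
    out["capped_or"] = capped
    return out
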