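"""Seeded synthetic cohorts, variants, genotype metrics and phenotypes.

The generators reproduce the statistical structure the downstream analysis
assumes -- a small diagnosed group embedded in family studies, a much larger
undiagnosed population sample, per-gene carrier-frequency contrasts, genotype
QC metrics with controllable failure rates, and phenotypes produced by the
same linear/latent-variable models the regression stage fits -- so that every
stage can be exercised, and its parameter recovery checked, without any
controlled-access download.

All randomness flows through one ``numpy.random.Generator`` per call, seeded
from the spec, so identical (spec, seed) pairs give byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "GeneSpec",
    "EffectSpec",
    "TraitSpec",
    "QCSimSpec",
    "VariantSimConfig",
    "build_cohort",
    "default_gene_panel",
    "simulate_variants",
    "simulate_genotype_metrics",
    "simulate_phenotypes",
    "carrier_indicators",
    "default_traits",
]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Composition of a synthetic case/control cohort.

    ``family_fraction`` of diagnosed individuals are probands of trio/quad
    families whose parents (always undiagnosed) and, for a fraction of
    families, one undiagnosed sibling are drawn from the undiagnosed budget.
    ``sex_ratio_diagnosed`` is the male:female odds among diagnosed
    individuals (4:1 by default, the ratio observed in autism cohorts).
    ``pgs_shift_diagnosed`` shifts the standardized polygenic score of the
    diagnosed group upward by that many SD.
    """

    n_diagnosed: int
    n_undiagnosed: int
    family_fraction: float = 0.6
    sibling_fraction: float = 0.4
    sex_ratio_diagnosed: float = 4.0
    pgs_shift_diagnosed: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_diagnosed <= 0 or self.n_undiagnosed <= 0:
            raise ValueError("cohort counts must be positive")
        for name in ("family_fraction", "sibling_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.sex_ratio_diagnosed <= 0:
            raise ValueError("sex_ratio_diagnosed must be positive")


@dataclass(frozen=True)
class GeneSpec:
    """Per-gene generative parameters.

    ``carrier_freq_diagnosed`` / ``carrier_freq_undiagnosed`` are the
    probabilities that an individual of each group carries a qualifying LoF
    variant in the gene; their contrast fixes the gene's true autism OR.
    ``exon_boundaries`` are ordered, non-overlapping 1-based closed CDS
    intervals tiling [1, cds_length]; ``exon_pext`` is the per-exon brain
    pext value in [0, 1].
    """

    gene_id: str
    gene_set: str = "other"  # autism_associated | constrained | other
    carrier_freq_diagnosed: float = 0.0
    carrier_freq_undiagnosed: float = 0.0
    cds_length: int = 3000
    exon_boundaries: tuple[tuple[int, int], ...] = ()
    exon_pext: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        for name in ("carrier_freq_diagnosed", "carrier_freq_undiagnosed"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.cds_length <= 0:
            raise ValueError("cds_length must be positive")
        bounds = self.exon_boundaries or ((1, self.cds_length),)
        pext = self.exon_pext or tuple(1.0 for _ in bounds)
        if len(bounds) != len(pext):
            raise ValueError("one pext value per exon required")
        pos = 1
        for start, end in bounds:
            if start != pos or end < start:
                raise ValueError("exon intervals must tile [1, cds_length] in order")
            pos = end + 1
        if pos != self.cds_length + 1:
            raise ValueError("exon intervals must cover the full CDS")
        if any(not 0.0 <= p <= 1.0 for p in pext):
            raise ValueError("pext values must be in [0, 1]")
        object.__setattr__(self, "exon_boundaries", tuple(bounds))
        object.__setattr__(self, "exon_pext", tuple(pext))


@dataclass(frozen=True)
class EffectSpec:
    """Generative effect sizes for one trait.

    The latent predictor is ``beta_lof_high * LoF_high + beta_lof_low *
    LoF_low + beta_pgs * PGS + beta_sex * sex(female=1) + noise``.  Ordinal
    traits threshold the latent variable at ``band_thresholds`` (strictly
    increasing); questionnaire-response traits are Bernoulli with carrier
    odds multiplied by ``participation_or_carrier``.
    """

    beta_lof_high: float = 0.0
    beta_lof_low: float = 0.0
    beta_pgs: float = 0.0
    beta_sex: float = 0.0
    noise_sd: float = 1.0
    band_thresholds: tuple[float, ...] | None = None
    participation_or_carrier: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.band_thresholds is not None:
            t = tuple(self.band_thresholds)
            if any(nxt <= prev for prev, nxt in zip(t, t[1:])):
                raise ValueError("band_thresholds must be strictly increasing")
            object.__setattr__(self, "band_thresholds", t)
        if self.participation_or_carrier <= 0:
            raise ValueError("participation_or_carrier must be positive")


@dataclass(frozen=True)
class TraitSpec:
    """One phenotype column: its kind, generative effects and scale."""

    kind: str  # continuous | ordinal | response
    effects: EffectSpec = field(default_factory=EffectSpec)
    mean: float = 0.0
    scale: float = 1.0
    clip_low: float | None = None
    baseline_response_rate: float = 0.85
    noise_dist: str = "normal"  # normal | logistic (latent noise for ordinal)

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "ordinal", "response"):
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if self.kind == "ordinal" and self.effects.band_thresholds is None:
            raise ValueError("ordinal traits need band_thresholds")
        if not 0.0 < self.baseline_response_rate < 1.0:
            raise ValueError("baseline_response_rate must be in (0, 1)")


@dataclass(frozen=True)
class QCSimSpec:
    """Fractions of genotype calls violating each QC threshold."""

    fail_call_rate: float = 0.0
    fail_genotype_quality: float = 0.0
    fail_depth: float = 0.0
    fail_allelic_fraction_low: float = 0.0
    fail_allelic_fraction_high: float = 0.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class VariantSimConfig:
    """Nuisance structure of the simulated variant table.

    Signal carriers always receive one LoF record; the annotation noise knobs
    below control what fraction of records fail each downstream filter, so
    classification recovers a predictable subset of the generative truth.
    """

    syn_carrier_freq: float = 0.002   # synonymous negative-control carriers
    p_splice: float = 0.05            # LoF records encoded as splice-site
    p_unmappable_splice: float = 0.1  # splice records beyond the +/-3 bp window
    p_low_confidence: float = 0.04
    p_loftee_flagged: float = 0.03
    p_nonzero_ref_af: float = 0.12    # present in the reference population
    multi_variant: bool = False       # allow >1 record per carrier per gene


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


def build_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Build a cohort table of ``n_diagnosed + n_undiagnosed`` individuals.

    Columns: ``individual_id, diagnosed, role, sex, age, cohort, family_id,
    pgs, pc1..pc4``.  Parents are always undiagnosed; undiagnosed individuals
    not used as relatives get role ``population``.
    """
    rng = np.random.default_rng(spec.seed)
    n_d, n_u = spec.n_diagnosed, spec.n_undiagnosed

    n_family = int(round(spec.family_fraction * n_d))
    n_sib = int(round(spec.sibling_fraction * n_family))
    n_relatives = 2 * n_family + n_sib
    if n_relatives > n_u:
        raise ValueError(
            f"family structure needs {n_relatives} undiagnosed relatives but "
            f"only {n_u} undiagnosed individuals are available"
        )

    rows: dict[str, list] = {k: [] for k in ("role", "diagnosed", "sex", "age", "cohort", "family_id")}

    p_male = spec.sex_ratio_diagnosed / (1.0 + spec.sex_ratio_diagnosed)
    diag_sex = np.where(rng.random(n_d) < p_male, "M", "F")
    diag_age = rng.uniform(4.0, 18.0, n_d)
    for i in range(n_d):
        fam = f"F{i:06d}" if i < n_family else ""
        rows["role"].append("proband" if fam else "case")
        rows["diagnosed"].append(True)
        rows["sex"].append(diag_sex[i])
        rows["age"].append(diag_age[i])
        rows["cohort"].append("family_study" if fam else "case_control_study")
        rows["family_id"].append(fam)

    sib_families = rng.choice(n_family, size=n_sib, replace=False) if n_sib else np.array([], dtype=int)
    sib_set = set(int(f) for f in sib_families)
    for i in range(n_family):
        fam = f"F{i:06d}"
        for role, sex in (("mother", "F"), ("father", "M")):
            rows["role"].append(role)
            rows["diagnosed"].append(False)
            rows["sex"].append(sex)
            rows["age"].append(float(rng.uniform(28.0, 55.0)))
            rows["cohort"].append("family_study")
            rows["family_id"].append(fam)
        if i in sib_set:
            rows["role"].append("sibling")
            rows["diagnosed"].append(False)
            rows["sex"].append("M" if rng.random() < 0.5 else "F")
            rows["age"].append(float(rng.uniform(4.0, 18.0)))
            rows["cohort"].append("family_study")
            rows["family_id"].append(fam)

    n_pop = n_u - n_relatives
    pop_sex = np.where(rng.random(n_pop) < 0.5, "M", "F")
    pop_age = rng.uniform(40.0, 70.0, n_pop)
    rows["role"].extend(["population"] * n_pop)
    rows["diagnosed"].extend([False] * n_pop)
    rows["sex"].extend(pop_sex.tolist())
    rows["age"].extend(pop_age.tolist())
    rows["cohort"].extend(["population_study"] * n_pop)
    rows["family_id"].extend([""] * n_pop)

    n = n_d + n_u
    df = pd.DataFrame(rows)
    df.insert(0, "individual_id", [f"I{i:07d}" for i in range(n)])
    diag = df["diagnosed"].to_numpy()
    pgs = rng.standard_normal(n)
    pgs[diag] += spec.pgs_shift_diagnosed
    df["pgs"] = pgs
    for j in range(1, 5):
        df[f"pc{j}"] = rng.standard_normal(n)
    return df


# ---------------------------------------------------------------------------
# Gene panel
# ---------------------------------------------------------------------------


def _make_gene(rng: np.random.Generator, gene_id: str, gene_set: str,
               freq_d: float, freq_u: float) -> GeneSpec:
    n_exons = int(rng.integers(4, 15))
    sizes = rng.multinomial(n_exons * 50, np.full(n_exons, 1.0 / n_exons)) + 60
    cds_length = int(sizes.sum())
    bounds, pos = [], 1
    for s in sizes:
        bounds.append((pos, pos + int(s) - 1))
        pos += int(s)
    # most exons constitutively expressed in brain, a minority poorly retained
    pext = tuple(
        float(rng.uniform(0.6, 1.0)) if rng.random() > 0.15 else float(rng.uniform(0.0, 0.1))
        for _ in range(n_exons)
    )
    return GeneSpec(gene_id, gene_set, freq_d, freq_u, cds_length, tuple(bounds), pext)


def default_gene_panel(n_autism: int = 40, n_constrained: int = 60,
                       n_other: int = 20, seed: int = 0) -> list[GeneSpec]:
    """A gene panel with the carrier-frequency structure of the study.

    Autism-associated genes carry strong diagnosed/undiagnosed contrasts
    (true ORs roughly 5 to infinity, a few with zero undiagnosed carriers),
    constrained genes modest contrasts, and ``other`` genes none (null).
    """
    rng = np.random.default_rng(seed)
    genes: list[GeneSpec] = []
    for i in range(n_autism):
        freq_d = float(rng.uniform(0.001, 0.008))
        freq_u = 0.0 if rng.random() < 0.12 else freq_d / float(rng.uniform(5.0, 60.0))
        genes.append(_make_gene(rng, f"AUT{i:03d}", "autism_associated", freq_d, freq_u))
    for i in range(n_constrained):
        freq_d = float(rng.uniform(0.0005, 0.004))
        freq_u = freq_d / float(rng.uniform(1.5, 6.0))
        genes.append(_make_gene(rng, f"CON{i:03d}", "constrained", freq_d, freq_u))
    for i in range(n_other):
        f = float(rng.uniform(0.001, 0.005))
        genes.append(_make_gene(rng, f"OTH{i:03d}", "other", f, f))
    return genes


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------


def _exon_of_position(spec: GeneSpec, position: np.ndarray) -> np.ndarray:
    ends = np.array([e for _, e in spec.exon_boundaries])
    return np.searchsorted(ends, position, side="left")


def simulate_variants(
    cohort: pd.DataFrame,
    genes: Sequence[GeneSpec],
    seed: int = 0,
    config: VariantSimConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an annotated variant table and the generative carrier truth.

    Each true carrier receives one variant record (gene, consequence, CDS
    position uniform over the CDS, Loftee-style confidence, reference-
    population frequency with a point mass at zero, within-sample allele
    count, exon assignment, splice encoding).  ``carrier_truth`` records the
    pre-filter ground truth used by recovery tests.
    """
    if not genes:
        raise ValueError("gene specs must be non-empty")
    cfg = config or VariantSimConfig()
    rng = np.random.default_rng(seed)
    diag = cohort["diagnosed"].to_numpy()
    ids = cohort["individual_id"].to_numpy()
    n = len(cohort)

    v_rows: list[dict] = []
    t_rows: list[dict] = []
    counter = 0

    def _add_variant(gene: GeneSpec, indiv: str, consequence: str) -> None:
        nonlocal counter
        pos = int(rng.integers(1, gene.cds_length + 1))
        exon = int(_exon_of_position(gene, np.array([pos]))[0])
        is_splice = consequence == "LoF" and rng.random() < cfg.p_splice
        splice_offset = 0
        if is_splice:
            start, end = gene.exon_boundaries[exon]
            mappable = rng.random() >= cfg.p_unmappable_splice
            off = int(rng.integers(1, 4)) if mappable else int(rng.integers(4, 9))
            splice_offset = -off if rng.random() < 0.5 else off
            pos = start if splice_offset < 0 else end
        if consequence == "LoF":
            r = rng.random()
            flag = ("low_confidence" if r < cfg.p_low_confidence else "high_confidence")
            aux = "PHYLOCSF_WEAK" if (flag == "high_confidence" and rng.random() < cfg.p_loftee_flagged) else ""
        else:
            flag, aux = "high_confidence", ""
        ref_af = float(rng.uniform(1e-6, 5e-4)) if rng.random() < cfg.p_nonzero_ref_af else 0.0
        v_rows.append(dict(
            variant_id=f"V{counter:07d}",
            gene_id=gene.gene_id,
            individual_id=indiv,
            consequence=consequence,
            loftee_flag=flag,
            loftee_aux_flags=aux,
            ref_pop_af=ref_af,
            allele_count=1,
            sample_af=1.0 / (2 * n),
            cds_position=pos,
            exon_index=exon,
            is_splice_site=is_splice,
            splice_offset=splice_offset,
        ))
        counter += 1

    for gene in genes:
        p = np.where(diag, gene.carrier_freq_diagnosed, gene.carrier_freq_undiagnosed)
        carriers = np.flatnonzero(rng.random(n) < p)
        for idx in carriers:
            _add_variant(gene, ids[idx], "LoF")
            t_rows.append(dict(individual_id=ids[idx], gene_id=gene.gene_id, variant_class="lof"))
            if cfg.multi_variant and rng.random() < 0.1:
                _add_variant(gene, ids[idx], "LoF")
        if cfg.syn_carrier_freq > 0:
            syn_carriers = np.flatnonzero(rng.random(n) < cfg.syn_carrier_freq)
            for idx in syn_carriers:
                _add_variant(gene, ids[idx], "synonymous")
                t_rows.append(dict(individual_id=ids[idx], gene_id=gene.gene_id, variant_class="syn"))

    cols = ["variant_id", "gene_id", "individual_id", "consequence", "loftee_flag",
            "loftee_aux_flags", "ref_pop_af", "allele_count", "sample_af",
            "cds_position", "exon_index", "is_splice_site", "splice_offset"]
    variants = pd.DataFrame(v_rows, columns=cols)
    truth = pd.DataFrame(t_rows, columns=["individual_id", "gene_id", "variant_class"])
    known = {g.gene_id for g in genes}
    unknown = set(variants["gene_id"]) - known
    if unknown:
        raise ValueError(f"variants reference unknown genes: {sorted(unknown)}")
    return variants, truth


# ---------------------------------------------------------------------------
# Genotype metrics
# ---------------------------------------------------------------------------


def simulate_genotype_metrics(
    variants: pd.DataFrame, qc_spec: QCSimSpec | None = None, seed: int = 0
) -> pd.DataFrame:
    """Per-call depth, genotype quality, allelic fraction and call rate.

    Calls are generated comfortably inside the QC thresholds; each
    ``fail_*`` fraction independently pushes that fraction of calls past the
    corresponding threshold.
    """
    if variants.empty:
        raise ValueError("variant table must be non-empty")
    qc = qc_spec or QCSimSpec()
    rng = np.random.default_rng(seed)
    m = len(variants)

    depth = rng.integers(30, 120, m).astype(float)
    gq = rng.integers(45, 100, m).astype(float)
    af = np.clip(rng.normal(0.5, 0.05, m), 0.30, 0.70)
    call_rate = rng.uniform(0.95, 1.0, m)

    # independently push a fraction of calls past each threshold
    mask = rng.random(m) < qc.fail_depth
    depth[mask] = rng.integers(1, 21, int(mask.sum()))
    mask = rng.random(m) < qc.fail_genotype_quality
    gq[mask] = rng.integers(0, 30, int(mask.sum()))
    mask = rng.random(m) < qc.fail_allelic_fraction_low
    af[mask] = rng.uniform(0.01, 0.249, int(mask.sum()))
    mask = rng.random(m) < qc.fail_allelic_fraction_high
    af[mask] = rng.uniform(0.751, 0.99, int(mask.sum()))
    mask = rng.random(m) < qc.fail_call_rate
    call_rate[mask] = rng.uniform(0.5, 0.9, int(mask.sum()))

    return pd.DataFrame(dict(
        variant_id=variants["variant_id"].to_numpy(),
        individual_id=variants["individual_id"].to_numpy(),
        depth=depth,
        genotype_quality=gq,
        allelic_fraction=af,
        call_rate=call_rate,
        autosomal=True,
    ))


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def carrier_indicators(
    carrier_truth: pd.DataFrame,
    genes: Sequence[GeneSpec],
    cohort: pd.DataFrame,
    high_sets: frozenset[str] = frozenset({"autism_associated"}),
) -> pd.DataFrame:
    """Per-individual ``lof_high`` / ``lof_low`` carrier indicators.

    Genes in ``high_sets`` count toward the high-effect stratum; all other
    genes with any LoF carrier count toward the low stratum.  This is the
    generative analogue of splitting carriers by estimated gene OR.
    """
    gene_set = {g.gene_id: g.gene_set for g in genes}
    lof = carrier_truth[carrier_truth["variant_class"] == "lof"]
    high_ids = set(lof.loc[lof["gene_id"].map(gene_set).isin(high_sets), "individual_id"])
    low_ids = set(lof.loc[~lof["gene_id"].map(gene_set).isin(high_sets), "individual_id"])
    out = pd.DataFrame(index=pd.Index(cohort["individual_id"], name="individual_id"))
    out["lof_high"] = out.index.isin(high_ids).astype(np.int8)
    out["lof_low"] = out.index.isin(low_ids).astype(np.int8)
    return out


def default_traits() -> dict[str, TraitSpec]:
    """The study's phenotype battery with its generative effect sizes.

    Effect sizes printed by the study are used directly (fluid intelligence
    -0.19/-0.37 for low/high-OR carriers; reversed-Townsend -0.2/-0.15, hence
    +0.2/+0.15 on the raw deprivation scale; income ORs 0.62/0.51 and
    qualification ORs 0.82/0.49 as latent log-odds); the remaining traits use
    modest negative carrier effects or pure noise.
    """
    logit5 = tuple(float(np.log(q / (1 - q))) for q in (0.25, 0.50, 0.75, 0.92))
    logit10 = tuple(float(np.log(q / (1 - q))) for q in
                    (0.02, 0.05, 0.10, 0.20, 0.32, 0.47, 0.75, 0.85, 0.93))
    traits = {
        "fluid_intelligence": TraitSpec("continuous", EffectSpec(
            beta_lof_high=-0.37, beta_lof_low=-0.19, beta_pgs=0.05)),
        "townsend_index": TraitSpec("continuous", EffectSpec(
            beta_lof_high=0.15, beta_lof_low=0.20)),
        "scq_t_score": TraitSpec("continuous", EffectSpec(
            beta_lof_high=0.10, beta_lof_low=0.05), mean=65.0, scale=10.0),
        "income_band": TraitSpec("ordinal", EffectSpec(
            beta_lof_high=float(np.log(0.51)), beta_lof_low=float(np.log(0.62)),
            band_thresholds=logit5), noise_dist="logistic"),
        "qualification_band": TraitSpec("ordinal", EffectSpec(
            beta_lof_high=float(np.log(0.49)), beta_lof_low=float(np.log(0.82)),
            band_thresholds=logit5), noise_dist="logistic"),
        "iq_bin": TraitSpec("ordinal", EffectSpec(
            beta_lof_high=-0.6, beta_lof_low=-0.3,
            band_thresholds=logit10), noise_dist="logistic"),
        "milestone_walking_months": TraitSpec("continuous", EffectSpec(
            beta_lof_high=0.25, beta_lof_low=0.10), mean=13.0, scale=3.0, clip_low=0.0),
        "milestone_words_months": TraitSpec("continuous", EffectSpec(
            beta_lof_high=0.30, beta_lof_low=0.12), mean=18.0, scale=6.0, clip_low=0.0),
    }
    for k in range(1, 7):
        traits[f"factor_f{k}"] = TraitSpec("continuous", EffectSpec())
    for name, rate in (("response_income", 0.86), ("response_qualification", 0.83),
                       ("response_fluid_intelligence", 0.60), ("response_imaging", 0.11)):
        traits[name] = TraitSpec(
            "response", EffectSpec(participation_or_carrier=0.8),
            baseline_response_rate=rate)
    return traits


def simulate_phenotypes(
    cohort: pd.DataFrame,
    indicators: pd.DataFrame,
    traits: Mapping[str, TraitSpec] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate the phenotype table from the latent-variable trait models.

    Continuous traits are linear predictor + Gaussian noise (then shifted /
    scaled / clipped per trait); ordinal traits threshold the latent variable
    into 1-based bands; response indicators are Bernoulli with the carrier
    odds multiplier.  The Townsend index is oriented so larger = more
    deprived.
    """
    traits = dict(traits) if traits is not None else default_traits()
    rng = np.random.default_rng(seed)
    ind = indicators.reindex(cohort["individual_id"]).fillna(0)
    lof_high = ind["lof_high"].to_numpy(dtype=float)
    lof_low = ind["lof_low"].to_numpy(dtype=float)
    any_lof = np.maximum(lof_high, lof_low)
    pgs = cohort["pgs"].to_numpy(dtype=float)
    sex = (cohort["sex"] == "F").to_numpy(dtype=float)
    n = len(cohort)

    out = pd.DataFrame(index=pd.Index(cohort["individual_id"], name="individual_id"))
    for name, trait in traits.items():
        e = trait.effects
        lin = (e.beta_lof_high * lof_high + e.beta_lof_low * lof_low
               + e.beta_pgs * pgs + e.beta_sex * sex)
        if trait.kind == "response":
            p0 = trait.baseline_response_rate
            logit = np.log(p0 / (1 - p0)) + np.log(e.participation_or_carrier) * any_lof
            out[name] = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(np.int8)
            continue
        if trait.kind == "ordinal" and trait.noise_dist == "logistic":
            noise = rng.logistic(0.0, 1.0, n) * e.noise_sd
        else:
            noise = rng.standard_normal(n) * e.noise_sd
        latent = lin + noise
        if trait.kind == "ordinal":
            out[name] = (np.searchsorted(np.asarray(e.band_thresholds), latent) + 1).astype(np.int16)
        else:
            values = trait.mean + trait.scale * latent
            if trait.clip_low is not None:
                values = np.maximum(values, trait.clip_low)
            out[name] = values
    return out
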