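"""Stringent-LoF (S-LoF) and stringent-synonymous (S-SYN) classification.

A variant reaches the S-LoF class only if it survives, in order: genotype
QC (call rate > 0.9, GQ >= 30, depth > 20, allelic fraction >= 0.25 and
<= 0.75 on autosomes), a rarity filter (absent from the reference population
and at <= 1% within the sample, or a plain 1% MAF mode), a recurrent-gene
blocklist, Loftee high-confidence status with no auxiliary flags, an
in-phase MNV rescue check, a brain exon-expression filter (max pext across
13 brain tissues > 0.10) and a protein-truncation filter (> 10% of the
encoded protein lost).  Synonymous variants pass through the same QC,
frequency, pext and position filters to form the S-SYN negative-control
class.  Thresholds keep the printed strictness: strict ``>`` for call rate,
depth, pext and truncation; inclusive for GQ and allelic fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import GeneSpec

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_RECURRENT_GENES",
    "N_BRAIN_TISSUES",
    "FilterConfig",
    "GeneModel",
    "VariantClass",
    "qc_genotype",
    "frequency_filter",
    "recurrent_gene_filter",
    "loftee_filter",
    "map_splice_to_exon",
    "brain_pext",
    "truncated_fraction",
    "mnv_phase_filter",
    "classify_variant",
    "classify_table",
    "carrier_matrix",
    "CarrierMatrix",
]

#: Genes recurrently mutated across unrelated families, excluded a priori.
DEFAULT_RECURRENT_GENES = frozenset(
    {"MUC4", "MUC12", "HLA-A", "HLA-B", "HYDIN", "TTN", "PAX5", "OR2T10", "MYH4"}
)

N_BRAIN_TISSUES = 13


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and modes of the classification cascade."""

    pext_min: float = 0.10          # strict >, exon retained in >10% of brain transcripts
    truncation_min: float = 0.10    # strict >, >10% of the protein truncated
    frequency_mode: str = "strict"  # strict: absent from reference pop; maf: MAF <= 1%
    sample_af_max: float = 0.01
    blocklist: frozenset[str] = DEFAULT_RECURRENT_GENES
    splice_window: int = 3          # bp, inclusive
    mnv_window: int = 2             # bp, "close vicinity" = same codon by default

    def __post_init__(self) -> None:
        if self.frequency_mode not in ("strict", "maf"):
            raise ValueError("frequency_mode must be 'strict' or 'maf'")


class GeneModel:
    """CDS exon structure and per-exon brain pext values of one gene.

    ``exon_boundaries`` are 1-based closed CDS intervals that must tile
    ``[1, cds_length]`` in order; ``exon_pext`` is an (n_exons, 13) array of
    per-tissue pext values (NaN allowed for missing tissues).
    """

    def __init__(self, gene_id: str, cds_length: int,
                 exon_boundaries: Sequence[tuple[int, int]],
                 exon_pext: np.ndarray):
        self.gene_id = gene_id
        self.cds_length = int(cds_length)
        self.exon_starts = np.array([s for s, _ in exon_boundaries], dtype=int)
        self.exon_ends = np.array([e for _, e in exon_boundaries], dtype=int)
        pext = np.asarray(exon_pext, dtype=float)
        if pext.ndim == 1:
            pext = pext[:, None]
        self.exon_pext = pext
        pos = 1
        for s, e in zip(self.exon_starts, self.exon_ends):
            if s != pos or e < s:
                raise ValueError(f"{gene_id}: exons must tile [1, cds_length] in order")
            pos = e + 1
        if pos != self.cds_length + 1:
            raise ValueError(f"{gene_id}: exons do not cover the CDS")
        if len(pext) != len(self.exon_starts):
            raise ValueError(f"{gene_id}: one pext row per exon required")

    @classmethod
    def from_gene_spec(cls, spec: GeneSpec) -> "GeneModel":
        bounds = spec.exon_boundaries or ((1, spec.cds_length),)
        pext = spec.exon_pext or tuple(1.0 for _ in bounds)
        # replicate the per-exon brain summary across the 13 tissue slots
        mat = np.tile(np.asarray(pext, dtype=float)[:, None], (1, N_BRAIN_TISSUES))
        return cls(spec.gene_id, spec.cds_length, bounds, mat)

    def exon_of(self, cds_position: int) -> int:
        if not 1 <= cds_position <= self.cds_length:
            raise ValueError(f"{self.gene_id}: CDS position {cds_position} out of range")
        return int(np.searchsorted(self.exon_ends, cds_position, side="left"))


@dataclass(frozen=True)
class VariantClass:
    """Classification outcome: S_LOF, S_SYN or OTHER with failure reasons."""

    label: str
    failed: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.label in ("S_LOF", "S_SYN") and self.failed:
            raise ValueError("a stringent class cannot carry failure reasons")


# ---------------------------------------------------------------------------
# Individual filters
# ---------------------------------------------------------------------------


def _missing(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value))


def qc_genotype(call: Mapping) -> tuple[bool, str | None]:
    """Genotype-level QC: (pass, reason-if-failed).

    call rate > 0.9, GQ >= 30, depth > 20, allelic fraction >= 0.25, and
    <= 0.75 for autosomal variants only.
    """
    metrics = ("call_rate", "genotype_quality", "depth", "allelic_fraction")
    for m in metrics:
        if m not in call or _missing(call[m]):
            return False, "missing_metric"
    if not call["call_rate"] > 0.9:
        return False, "call_rate"
    if not call["genotype_quality"] >= 30:
        return False, "genotype_quality"
    if not call["depth"] > 20:
        return False, "depth"
    if not call["allelic_fraction"] >= 0.25:
        return False, "allelic_fraction_low"
    if call.get("autosomal", True) and not call["allelic_fraction"] <= 0.75:
        return False, "allelic_fraction_high"
    return True, None


def frequency_filter(ref_pop_af: float, sample_af: float,
                     mode: str = "strict", sample_af_max: float = 0.01) -> bool:
    """Rarity filter.

    ``strict``: absent from the reference population (AF exactly 0) and at
    most 1% within the sample.  ``maf``: reference-population MAF <= 1% and
    sample AF <= 1%.
    """
    if mode == "strict":
        return ref_pop_af == 0.0 and sample_af <= sample_af_max
    if mode == "maf":
        return ref_pop_af <= 0.01 and sample_af <= sample_af_max
    raise ValueError(f"unknown frequency mode {mode!r}")


def recurrent_gene_filter(gene_id: str,
                          blocklist: Iterable[str] = DEFAULT_RECURRENT_GENES) -> bool:
    """Pass unless the gene is on the recurrently-mutated blocklist."""
    return gene_id not in set(blocklist)


def loftee_filter(loftee_flag: str, aux_flags: str = "") -> bool:
    """Pass only high-confidence Loftee calls with no auxiliary flag."""
    return loftee_flag == "high_confidence" and not aux_flags


def map_splice_to_exon(exon_index: int, splice_offset: int, model: GeneModel,
                       window: int = 3) -> tuple[int, int] | None:
    """Map a splice-site variant to its closest coding exon.

    ``splice_offset`` is the signed intronic distance from the exon boundary
    (negative = upstream of the exon start, positive = downstream of the
    exon end).  Within ``window`` bp (inclusive) the variant adopts that
    boundary's CDS coordinate as its effective position; beyond it the
    variant is unmappable and ``None`` is returned.
    """
    if abs(splice_offset) > window:
        return None
    if not 0 <= exon_index < len(model.exon_starts):
        raise ValueError(f"{model.gene_id}: exon index {exon_index} out of range")
    if splice_offset <= 0:
        return exon_index, int(model.exon_starts[exon_index])
    return exon_index, int(model.exon_ends[exon_index])


def brain_pext(exon_index: int, model: GeneModel) -> float:
    """Maximum pext across the exon's brain tissues (NaN tissues ignored).

    Raises ``ValueError`` only when every tissue value is missing.
    """
    values = model.exon_pext[exon_index]
    if np.all(np.isnan(values)):
        raise ValueError("missing_pext")
    return float(np.nanmax(values))


def truncated_fraction(cds_position: int, cds_length: int) -> float:
    """Fraction of the encoded protein truncated: 1 - position / length."""
    if cds_position > cds_length:
        raise ValueError("position_out_of_cds")
    if cds_position < 1:
        raise ValueError("position_out_of_cds")
    return 1.0 - cds_position / cds_length


def mnv_phase_filter(variant_ids: Sequence[str], mnv_pairs: pd.DataFrame | None,
                     window: int = 2) -> dict[str, bool]:
    """Per-variant retention under the in-phase MNV rescue rule.

    ``mnv_pairs`` has columns ``variant_id, partner_id, distance_bp, phase,
    joint_consequence``; an S-LoF candidate is dropped only when an in-phase
    partner within ``window`` bp changes the joint consequence away from LoF
    (for example a stop-gain rescued to missense).  Unknown phase retains the
    variant (a warning is logged); out-of-phase or distant partners never
    drop it.
    """
    retained = {v: True for v in variant_ids}
    if mnv_pairs is None or mnv_pairs.empty:
        return retained
    for row in mnv_pairs.itertuples(index=False):
        vid = row.variant_id
        if vid not in retained:
            continue
        if row.phase == "unknown":
            logger.warning("MNV pair (%s, %s) has unknown phase; retaining %s",
                           vid, row.partner_id, vid)
            continue
        if (row.phase == "in_phase" and row.distance_bp <= window
                and row.joint_consequence != "LoF"):
            retained[vid] = False
    return retained


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def classify_variant(variant: Mapping, call: Mapping | None, model: GeneModel,
                     config: FilterConfig = FilterConfig(),
                     mnv_retained: bool = True) -> VariantClass:
    """Classify one variant-call record into S_LOF / S_SYN / OTHER.

    All applicable filters are evaluated so that ``failed`` lists every
    reason at once.  The Loftee and MNV phase filters apply to LoF
    consequences only; synonymous candidates run the shared QC, frequency,
    recurrent-gene, exon-expression and truncation filters.
    """
    consequence = variant["consequence"]
    failed: list[str] = []

    if call is not None:
        ok, reason = qc_genotype(call)
        if not ok:
            failed.append(f"qc:{reason}")
    if not frequency_filter(variant["ref_pop_af"], variant["sample_af"],
                            config.frequency_mode, config.sample_af_max):
        failed.append("frequency")
    if not recurrent_gene_filter(variant["gene_id"], config.blocklist):
        failed.append("recurrent_gene")
    if consequence == "LoF":
        if not loftee_filter(variant.get("loftee_flag", ""), variant.get("loftee_aux_flags", "")):
            failed.append("loftee")
        if not mnv_retained:
            failed.append("mnv_phase")

    exon = int(variant["exon_index"])
    position = int(variant["cds_position"])
    if variant.get("is_splice_site", False):
        mapped = map_splice_to_exon(exon, int(variant.get("splice_offset", 0)),
                                    model, config.splice_window)
        if mapped is None:
            failed.append("unmapped_splice")
            exon = -1
        else:
            exon, position = mapped
    if exon >= 0:
        try:
            if not brain_pext(exon, model) > config.pext_min:
                failed.append("pext")
        except ValueError:
            failed.append("missing_pext")
        try:
            if not truncated_fraction(position, model.cds_length) > config.truncation_min:
                failed.append("truncation")
        except ValueError:
            failed.append("position_out_of_cds")

    if failed:
        return VariantClass("OTHER", tuple(failed))
    if consequence == "LoF":
        return VariantClass("S_LOF")
    if consequence == "synonymous":
        return VariantClass("S_SYN")
    return VariantClass("OTHER", ("consequence",))


def classify_table(variants: pd.DataFrame, calls: pd.DataFrame | None,
                   gene_models: Mapping[str, GeneModel],
                   config: FilterConfig = FilterConfig(),
                   mnv_pairs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Classify every row of an annotated variant table.

    ``calls`` (optional) is joined on ``(variant_id, individual_id)``.
    Returns the variant table with ``variant_class`` and ``failed_filters``
    (semicolon-joined reasons) columns appended.  Per-filter pass/fail
    counts are logged.
    """
    df = variants.copy()
    if calls is not None:
        metric_cols = ["depth", "genotype_quality", "allelic_fraction", "call_rate", "autosomal"]
        df = df.merge(calls[["variant_id", "individual_id"] + metric_cols],
                      on=["variant_id", "individual_id"], how="left")
    retained = mnv_phase_filter(df["variant_id"].tolist(), mnv_pairs, config.mnv_window)

    labels: list[str] = []
    reasons: list[str] = []
    for row in df.to_dict("records"):
        model = gene_models.get(row["gene_id"])
        if model is None:
            raise KeyError(f"no gene model for {row['gene_id']}")
        call = row if calls is not None else None
        vc = classify_variant(row, call, model, config, retained[row["variant_id"]])
        labels.append(vc.label)
        reasons.append(";".join(vc.failed))
    out = variants.copy()
    out["variant_class"] = labels
    out["failed_filters"] = reasons

    counts = out["variant_class"].value_counts()
    logger.info("classified %d variants: %s", len(out), counts.to_dict())
    fail_counts = pd.Series(
        [r for rs in reasons if rs for r in rs.split(";")]).value_counts()
    if len(fail_counts):
        logger.info("filter failures: %s", fail_counts.to_dict())
    return out


# ---------------------------------------------------------------------------
# Carrier matrix
# ---------------------------------------------------------------------------


class CarrierMatrix:
    """Binary gene x individual carrier structure for one variant class.

    Stored in long form (gene, individual, variant) so that the per-group
    singleton rule of the OR estimator can be applied at the variant level;
    an individual with several qualifying variants in one gene is still a
    single carrier.
    """

    def __init__(self, entries: pd.DataFrame, individuals: pd.Index,
                 genes: Sequence[str], variant_class: str = "S_LOF"):
        self.variant_class = variant_class
        self.individuals = pd.Index(individuals, name="individual_id")
        self.genes = pd.Index(genes, name="gene_id")
        entries = entries[["gene_id", "individual_id", "variant_id"]].copy()
        unknown = set(entries["individual_id"]) - set(self.individuals)
        if unknown:
            raise ValueError(f"carriers not in cohort: {sorted(unknown)[:5]}")
        self.entries = entries.reset_index(drop=True)
        self._indiv_codes = self.individuals.get_indexer(entries["individual_id"])
        self._gene_codes = self.genes.get_indexer(entries["gene_id"])
        _, self._var_codes = np.unique(entries["variant_id"], return_inverse=True)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(gene_codes, individual_codes, variant_codes) integer arrays."""
        return self._gene_codes, self._indiv_codes, self._var_codes

    def bool_matrix(self) -> np.ndarray:
        """Dense (n_individuals, n_genes) carrier indicator matrix."""
        mat = np.zeros((self.n_individuals, self.n_genes), dtype=bool)
        mat[self._indiv_codes, self._gene_codes] = True
        return mat

    def carrier_counts(self, mask: np.ndarray | None = None) -> pd.Series:
        """Carriers per gene, optionally restricted to a boolean individual mask."""
        keep = np.ones(len(self.entries), dtype=bool) if mask is None else mask[self._indiv_codes]
        pairs = np.unique(np.stack([self._gene_codes[keep], self._indiv_codes[keep]]), axis=1)
        counts = np.bincount(pairs[0], minlength=self.n_genes)
        return pd.Series(counts, index=self.genes, name="n_carriers")

    def genes_carried_by(self) -> pd.Series:
        """Number of distinct carried genes per individual."""
        pairs = np.unique(np.stack([self._gene_codes, self._indiv_codes]), axis=1)
        counts = np.bincount(pairs[1], minlength=self.n_individuals)
        return pd.Series(counts, index=self.individuals, name="n_genes_carried")

    def max_carriers_per_variant(self) -> int:
        if len(self.entries) == 0:
            return 0
        return int(np.bincount(self._var_codes).max())

    def to_long(self) -> pd.DataFrame:
        out = self.entries[["gene_id", "individual_id"]].drop_duplicates()
        out["variant_class"] = self.variant_class
        return out.reset_index(drop=True)


def carrier_matrix(classified: pd.DataFrame, cohort: pd.DataFrame,
                   variant_class: str = "S_LOF",
                   genes: Sequence[str] | None = None) -> CarrierMatrix:
    """Build the carrier matrix for one variant class from classified rows."""
    sel = classified[classified["variant_class"] == variant_class]
    if genes is None:
        genes = sorted(classified["gene_id"].unique())
    return CarrierMatrix(sel, pd.Index(cohort["individual_id"]), list(genes), variant_class)
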