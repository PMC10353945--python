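"""Tab-delimited and VCF 4.2 input/output.

Tables are written as TSV with a commented header block (``# key: value``)
recording the seed and configuration hash, so every stage output is
self-describing.  Variants can also round-trip through VCF 4.2 (via pysam)
with annotation carried in INFO (GENE, CSQ_CLASS, LOFTEE, LOFTEE_FLAGS,
PEXT_EXON, CDS_POS, REF_AF, SPLICE, SPLICE_OFFSET, AC) and per-sample
FORMAT fields GT, DP, GQ and VAF (AD-derived allelic fraction).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "write_table",
    "read_table",
    "write_vcf",
    "read_vcf",
    "read_variant_input",
    "REQUIRED_VARIANT_COLUMNS",
]

REQUIRED_VARIANT_COLUMNS = (
    "variant_id", "gene_id", "individual_id", "consequence", "loftee_flag",
    "loftee_aux_flags", "ref_pop_af", "allele_count", "sample_af",
    "cds_position", "exon_index", "is_splice_site", "splice_offset",
)


def write_table(df: pd.DataFrame, path: str | Path,
                meta: Mapping[str, object] | None = None) -> None:
    """Write a TSV with a ``# key: value`` metadata header."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (metadata in ``.attrs``)."""
    path = Path(path)
    meta: dict[str, str] = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
    df = pd.read_csv(path, sep="\t", skiprows=skip)
    df.attrs["meta"] = meta
    return df


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_INFO_FIELDS = [
    ("GENE", "1", "String", "Gene symbol"),
    ("CSQ_CLASS", "1", "String", "Consequence class (LoF/synonymous/other)"),
    ("LOFTEE", "1", "String", "Loftee confidence (high_confidence/low_confidence)"),
    ("LOFTEE_FLAGS", "1", "String", "Auxiliary Loftee flags"),
    ("PEXT_EXON", "1", "Integer", "0-based index of the assigned coding exon"),
    ("CDS_POS", "1", "Integer", "1-based CDS position"),
    ("REF_AF", "1", "Float", "Reference-population allele frequency"),
    ("AC", "A", "Integer", "Within-sample allele count"),
    ("SPLICE", "0", "Flag", "Splice-site variant"),
    ("SPLICE_OFFSET", "1", "Integer", "Signed bp offset from the exon boundary"),
]


def write_vcf(variants: pd.DataFrame, calls: pd.DataFrame | None,
              samples: list[str], path: str | Path) -> None:
    """Emit the annotated variant table as VCF 4.2.

    Each row becomes one biallelic record on a synthetic contig with the
    carrier genotyped 0/1 and every other sample 0/0; per-sample DP, GQ and
    VAF come from ``calls`` when given.
    """
    header = pysam.VariantHeader()
    header.add_meta("source", "lofburden")
    header.contigs.add("1", length=2_000_000_000)
    for name, number, vtype, desc in _INFO_FIELDS:
        header.info.add(name, number, vtype, desc)
    header.formats.add("GT", "1", "String", "Genotype")
    header.formats.add("DP", "1", "Integer", "Read depth")
    header.formats.add("GQ", "1", "Integer", "Genotype quality")
    header.formats.add("VAF", "1", "Float", "AD-derived allelic fraction")
    for s in samples:
        header.add_sample(s)

    call_map: dict[tuple[str, str], dict] = {}
    if calls is not None:
        for row in calls.to_dict("records"):
            call_map[(row["variant_id"], row["individual_id"])] = row

    sample_pos = {s: i for i, s in enumerate(samples)}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for pos0, row in enumerate(variants.to_dict("records")):
            rec = vcf.new_record(contig="1", start=pos0 * 10 + 100,
                                 alleles=("A", "T"), id=row["variant_id"])
            rec.info["GENE"] = row["gene_id"]
            rec.info["CSQ_CLASS"] = row["consequence"]
            rec.info["LOFTEE"] = row["loftee_flag"]
            rec.info["LOFTEE_FLAGS"] = row["loftee_aux_flags"] or "."
            rec.info["PEXT_EXON"] = int(row["exon_index"])
            rec.info["CDS_POS"] = int(row["cds_position"])
            rec.info["REF_AF"] = float(row["ref_pop_af"])
            rec.info["AC"] = (int(row["allele_count"]),)
            if row.get("is_splice_site", False):
                rec.info["SPLICE"] = True
                rec.info["SPLICE_OFFSET"] = int(row["splice_offset"])
            carrier = row["individual_id"]
            for s in samples:
                rec.samples[s]["GT"] = (0, 1) if s == carrier else (0, 0)
            call = call_map.get((row["variant_id"], carrier))
            if call is not None:
                rec.samples[carrier]["DP"] = int(call["depth"])
                rec.samples[carrier]["GQ"] = int(call["genotype_quality"])
                rec.samples[carrier]["VAF"] = float(call["allelic_fraction"])
            _ = sample_pos  # carrier lookup validated above
            vcf.write(rec)


def read_vcf(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a VCF written by :func:`write_vcf` back into (variants, calls)."""
    v_rows, c_rows = [], []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            carrier = None
            for sample, data in rec.samples.items():
                if data["GT"] == (0, 1):
                    carrier = sample
                    dp, gq = data.get("DP"), data.get("GQ")
                    vaf = data.get("VAF")
                    if dp is not None:
                        c_rows.append(dict(
                            variant_id=rec.id, individual_id=sample,
                            depth=float(dp), genotype_quality=float(gq),
                            allelic_fraction=float(vaf), call_rate=1.0,
                            autosomal=True))
                    break
            aux = rec.info.get("LOFTEE_FLAGS", ".")
            v_rows.append(dict(
                variant_id=rec.id,
                gene_id=rec.info["GENE"],
                individual_id=carrier,
                consequence=rec.info["CSQ_CLASS"],
                loftee_flag=rec.info["LOFTEE"],
                loftee_aux_flags="" if aux == "." else aux,
                ref_pop_af=float(rec.info["REF_AF"]),
                allele_count=int(rec.info["AC"][0]),
                sample_af=int(rec.info["AC"][0]) / (2 * len(rec.samples)),
                cds_position=int(rec.info["CDS_POS"]),
                exon_index=int(rec.info["PEXT_EXON"]),
                is_splice_site=bool(rec.info.get("SPLICE", False)),
                splice_offset=int(rec.info.get("SPLICE_OFFSET", 0)),
            ))
    return (pd.DataFrame(v_rows, columns=list(REQUIRED_VARIANT_COLUMNS)),
            pd.DataFrame(c_rows))


def read_variant_input(path: str | Path, fmt: str = "tabular") -> pd.DataFrame:
    """Read an annotated variant table from TSV or VCF.

    Raises ``ValueError`` listing any required column that is missing.
    """
    if fmt == "vcf":
        variants, _ = read_vcf(path)
    elif fmt == "tabular":
        variants = read_table(path)
    else:
        raise ValueError(f"unknown variant input format {fmt!r}")
    missing = [c for c in REQUIRED_VARIANT_COLUMNS if c not in variants.columns]
    if missing:
        raise ValueError(f"variant input {path} is missing columns: {missing}")
    variants["loftee_aux_flags"] = variants["loftee_aux_flags"].fillna("")
    return variants
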