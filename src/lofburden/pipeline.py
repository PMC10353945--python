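"""End-to-end orchestration: simulate -> classify -> OR -> stats -> models.

A :class:`PipelineConfig` (loadable from YAML) fixes every stage parameter
and a master seed; ``run_pipeline`` executes the stages, writes each output
as a self-describing TSV stamped with the seed and a configuration hash,
and ``report`` regenerates the machine-readable summary from the saved
stage outputs without recomputation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import burden, filters, io, models, odds, simulate

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "report"]


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run."""

    outdir: str = "lofburden_out"
    seed: int = 0
    # simulation
    n_diagnosed: int = 1000
    n_undiagnosed: int = 5000
    n_autism_genes: int = 30
    n_constrained_genes: int = 40
    n_other_genes: int = 10
    # filtering
    frequency_mode: str = "strict"
    pext_min: float = 0.10
    truncation_min: float = 0.10
    # OR estimation
    n_iterations: int = 100
    n_bootstraps: int = 1000
    singleton_mode: str = "per_group_singletons"
    # regressions: (outcome, family, preset, lof_column)
    regressions: list = field(default_factory=lambda: [
        ["diagnosed", "binary_logistic", "diagnosis", "lof_high"],
        ["fluid_intelligence", "linear", "population_trait", "lof_high"],
        ["townsend_reversed", "linear", "population_trait", "lof_high"],
        ["income_band", "ordinal_logistic", "socioeconomic_ordinal", "lof_high"],
    ])

    def __post_init__(self) -> None:
        if self.n_bootstraps < 1:
            raise ValueError("n_bootstraps must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        # the output location is not part of the analysis configuration
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _meta(config: PipelineConfig, stage: str) -> dict:
    return {"stage": stage, "seed": config.seed, "config_hash": config.hash()}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the result bundle into ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("simulate")
        cohort_spec = simulate.CohortSpec(config.n_diagnosed, config.n_undiagnosed, seed=seed)
        cohort = simulate.build_cohort(cohort_spec)
        genes = simulate.default_gene_panel(config.n_autism_genes,
                                            config.n_constrained_genes,
                                            config.n_other_genes, seed=seed + 1)
        variants, truth = simulate.simulate_variants(cohort, genes, seed=seed + 2)
        calls = simulate.simulate_genotype_metrics(variants, simulate.QCSimSpec(), seed=seed + 3)
        indicators = simulate.carrier_indicators(truth, genes, cohort)
        phenotypes = simulate.simulate_phenotypes(cohort, indicators, seed=seed + 4)
        io.write_table(cohort, out / "cohort.tsv", _meta(config, "simulate"))
        io.write_table(variants, out / "variants.tsv", _meta(config, "simulate"))
        io.write_table(calls, out / "genotype_metrics.tsv", _meta(config, "simulate"))
        io.write_table(phenotypes.reset_index(), out / "phenotypes.tsv", _meta(config, "simulate"))

        stage("classify")
        fcfg = filters.FilterConfig(pext_min=config.pext_min,
                                    truncation_min=config.truncation_min,
                                    frequency_mode=config.frequency_mode)
        gene_models = {g.gene_id: filters.GeneModel.from_gene_spec(g) for g in genes}
        classified = filters.classify_table(variants, calls, gene_models, fcfg)
        io.write_table(classified, out / "classified_variants.tsv", _meta(config, "classify"))
        slof = filters.carrier_matrix(classified, cohort, "S_LOF")
        ssyn = filters.carrier_matrix(classified, cohort, "S_SYN")
        io.write_table(slof.to_long(), out / "carriers_slof.tsv", _meta(config, "classify"))
        io.write_table(ssyn.to_long(), out / "carriers_ssyn.tsv", _meta(config, "classify"))

        stage("or-estimate")
        sub_cfg = odds.SubsamplingConfig(config.n_iterations, config.singleton_mode,
                                         seed=seed + 5)
        gene_or = odds.gene_or_table(slof, cohort, sub_cfg,
                                     n_bootstraps=config.n_bootstraps, seed=seed + 6)
        io.write_table(gene_or.reset_index(), out / "gene_or.tsv", _meta(config, "or"))

        stage("burden")
        diag = cohort["diagnosed"].to_numpy()
        gene_sets = {g.gene_id: g.gene_set for g in genes}
        aut_genes = [g for g, s in gene_sets.items() if s == "autism_associated"]
        rows = []
        for label, mask in (("diagnosed", diag), ("undiagnosed", ~diag)):
            carried = slof.carrier_counts(mask).loc[lambda s: s.index.isin(aut_genes)]
            member = slof.entries["gene_id"].isin(aut_genes).to_numpy()
            g_codes, i_codes, _ = slof.arrays()
            ids = np.unique(i_codes[member & mask[i_codes]]) if member.any() else []
            ci = burden.carrier_proportion_ci(len(ids), int(mask.sum()))
            rows.append(dict(group=label, gene_set="autism_associated",
                             k=ci.k, n=ci.n, proportion=ci.p, se=ci.se,
                             ci_low=ci.ci_low, ci_high=ci.ci_high))
        proportions = pd.DataFrame(rows)
        io.write_table(proportions, out / "proportions.tsv", _meta(config, "burden"))

        stage("regress")
        phen = phenotypes.copy()
        phen["townsend_reversed"] = models.reverse_townsend(phen["townsend_index"])
        frame = models.prepare_model_frame(cohort, indicators, phen)
        reg_rows = []
        for outcome, family, preset, lof_col in config.regressions:
            spec = models.RegressionSpec.from_preset(outcome, family, preset, lof_col)
            reg_rows.append(models.fit_model(frame, spec))
        regressions = models.fdr_adjust(pd.concat(reg_rows, ignore_index=True),
                                        group_cols=("term",))
        io.write_table(regressions, out / "regressions.tsv", _meta(config, "regress"))

        stage("report")
        summary = report(out)
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc


def report(results_dir: str | Path) -> dict:
    """Build the machine-readable + human-readable summary from saved outputs."""
    out = Path(results_dir)
    gene_or = io.read_table(out / "gene_or.tsv")
    proportions = io.read_table(out / "proportions.tsv")
    regressions = io.read_table(out / "regressions.tsv")
    observed = gene_or[gene_or["n_carriers_diagnosed"] > 0]
    summary = {
        "n_genes_reported": int(len(observed)),
        "n_genes_significant": int(observed["significant"].sum()),
        "median_capped_or": float(observed["capped_or"].median()) if len(observed) else float("nan"),
        "proportions": proportions.to_dict("records"),
        "regressions": regressions.to_dict("records"),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    lines = [
        "lofburden summary",
        f"  genes with >=1 diagnosed carrier: {summary['n_genes_reported']}",
        f"  genes significant (empirical P CI < 0.05): {summary['n_genes_significant']}",
        f"  median capped autism OR: {summary['median_capped_or']:.3g}",
    ]
    for row in summary["proportions"]:
        lines.append(
            f"  S-LoF carriers ({row['group']}): {row['k']}/{row['n']} = "
            f"{100 * row['proportion']:.2f}% (95% CI {100 * row['ci_low']:.2f}-"
            f"{100 * row['ci_high']:.2f}%)")
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return summary
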