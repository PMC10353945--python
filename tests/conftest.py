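import numpy as np
import pandas as pd
import pytest

import lofburden as lb
from lofburden.simulate import VariantSimConfig

# annotation-noise-free variant simulation: every signal carrier's record
# passes the classification cascade, so carrier recovery is exact
CLEAN_VARIANTS = VariantSimConfig(
    syn_carrier_freq=0.0, p_splice=0.0, p_low_confidence=0.0,
    p_loftee_flagged=0.0, p_nonzero_ref_af=0.0,
)


@pytest.fixture(scope="session")
def small_cohort():
    return lb.build_cohort(lb.CohortSpec(500, 2500, seed=1))


@pytest.fixture(scope="session")
def gene_panel():
    return lb.default_gene_panel(10, 10, 5, seed=2)


@pytest.fixture(scope="session")
def simulated(small_cohort, gene_panel):
    variants, truth = lb.simulate_variants(small_cohort, gene_panel, seed=3)
    calls = lb.simulate_genotype_metrics(variants, seed=4)
    return variants, truth, calls


@pytest.fixture(scope="session")
def classified(small_cohort, gene_panel, simulated):
    variants, _, calls = simulated
    models = {g.gene_id: lb.GeneModel.from_gene_spec(g) for g in gene_panel}
    return lb.classify_table(variants, calls, models)


def make_carrier_matrix(cohort, genes, seed, sim_config=CLEAN_VARIANTS):
    """Carrier matrix straight from the generative truth (no filter noise)."""
    variants, _ = lb.simulate_variants(cohort, genes, seed=seed, config=sim_config)
    return lb.CarrierMatrix(variants, pd.Index(cohort["individual_id"]),
                            [g.gene_id for g in genes])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
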