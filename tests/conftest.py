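import numpy as np
import pytest

import tetraqtl as tq


@pytest.fixture(scope="session")
def small_map():
    return tq.GeneticMap((("chr1", 100.0), ("chr2", 80.0)))


@pytest.fixture(scope="session")
def bivalent_config():
    return tq.MeiosisConfig()


@pytest.fixture(scope="session")
def demo_population(small_map, bivalent_config):
    """A moderate F1 with a planted additive QTL, shared across tests.

    150 individuals, bivalent meiosis, QTL of +0.3 per copy on homologue 2
    at chr1:40 cM, informativeness 0.95, single-year two-block trial.
    """
    truth = tq.simulate_population(
        150, small_map, bivalent_config, bivalent_config, seed=42
    )
    probs = tq.inheritance_to_probabilities(truth, 0.95)
    grid = probs.to_dosage()
    qtl = tq.PlantedQTL(
        "chr1", 40.0, np.array([0.0, 0.3, 0, 0, 0, 0, 0, 0]), mu=1.0
    )
    pheno = tq.simulate_phenotypes(
        truth,
        qtl,
        years=1,
        blocks_per_year=2,
        var_G_polygenic=0.0,
        var_GxY=0.0,
        var_E=0.05,
        var_year=0.0,
        var_block=0.001,
        seed=7,
    )
    y = pheno.groupby("clone")["protein_content"].mean()
    return {
        "truth": truth,
        "probs": probs,
        "grid": grid,
        "qtl": qtl,
        "pheno": pheno,
        "y": y,
    }
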