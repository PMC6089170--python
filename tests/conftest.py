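import numpy as np
import pandas as pd
import pytest

import germsoma as gs
from germsoma.simulate import make_synthetic_signatures


@pytest.fixture(scope="session")
def sigs() -> pd.DataFrame:
    """Deterministic 96 x 11 reference signature matrix."""
    return make_synthetic_signatures(11)


@pytest.fixture(scope="session")
def planted_cohort() -> gs.simulate.SyntheticCohort:
    """A small cohort with one planted effect per phenotype family."""
    cfg = gs.SimConfig(
        seed=424242,
        n_samples=400,
        n_pool_snps=300,
        n_genes=900,
        n_drivers=120,
        n_background_pathways=15,
        mutations_per_sample_mean=80,
        driver_planting_rate=0.0,
        mafs=[0.3] * 11,
    )
    sets = gs.simulate_annotation_and_sets(cfg)
    driver0 = sorted(sets.drivers)[0]
    # effect sizes chosen so each planted link clears BH within its own
    # phenotype family (the driver family alone holds 120 x 11 tests)
    cfg.planted_effects = [
        gs.PlantedEffect("rs100000", "KEY_PW_1", "pathway_truncation", -1.35, baseline=0.30),
        gs.PlantedEffect("rs100001", driver0, "driver_mutation", 1.6, baseline=0.25),
        gs.PlantedEffect("rs100002", sorted(sets.drivers)[1], "copy_number", 0.3),
        gs.PlantedEffect("rs100003", "Amp 1p1.1", "lesion", 1.2, baseline=0.20),
        gs.PlantedEffect("rs100004", "Signature.15", "signature", 0.25),
    ]
    gm = gs.simulate_genotypes(cfg)
    somatic = gs.simulate_somatic(cfg, gm, sets)
    cov = gs.simulate.simulate_covariates(cfg, list(gm.dosages.index))
    return gs.simulate.SyntheticCohort(
        config=cfg, sets=sets, genotypes=gm, somatic=somatic, covariates=cov
    )
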