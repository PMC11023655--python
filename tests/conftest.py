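import numpy as np
import pandas as pd
import pytest

import bwburden as b


@pytest.fixture(scope="session")
def small_cohort():
    """Reference five-gene cohort, 1500 duos, with read-level artifacts."""
    return b.simulate_cohort(b.default_config(n_duos=1500, seed=11))


@pytest.fixture(scope="session")
def clean_cohort():
    """Artifact-free cohort: reads filled but nothing degraded."""
    cfg = b.default_config(
        n_duos=800,
        seed=5,
        artifact_rates=b.ArtifactRates(0.0, 0.0, 0.0, 0.0),
    )
    return b.simulate_cohort(cfg)


def phenotype_only_table(values, ids, arm="fetal"):
    """Minimal covariate-free analysis table for direct regression tests."""
    df = pd.DataFrame({"phenotype": np.asarray(values, dtype=float)}, index=ids)
    return b.AnalysisTable(df, arm, [])


def carrier_vector(status, ids, gene="G", mask="PTV"):
    return b.CarrierVector(gene, mask, list(ids), np.asarray(status, dtype=np.int32), ())
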