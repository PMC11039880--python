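import numpy as np
import pandas as pd
import pytest

from cerna_weaver.model import (
    ExpressionMatrix,
    Knockdown,
    MoleculeClass,
    Sample,
    SampleDesign,
    Treatment,
)
from cerna_weaver.fixtures import make_published_fixtures
from cerna_weaver.synth import SyntheticConfig, generate_experiment


def make_design(n_replicates: int = 3) -> SampleDesign:
    samples = []
    for kd in (Knockdown.siNT, Knockdown.siOct4):
        for tr in (Treatment.DMSO, Treatment.POVPC):
            for r in range(1, n_replicates + 1):
                samples.append(Sample(f"{kd.value}_{tr.value}_r{r}", kd, tr, r))
    return SampleDesign(samples)


def make_matrix(values: np.ndarray, design: SampleDesign, feature_ids=None,
                molecule_class=MoleculeClass.mRNA) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    if feature_ids is None:
        feature_ids = [f"F{i:03d}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=feature_ids, columns=design.sample_ids)
    return ExpressionMatrix(df, design, molecule_class)


@pytest.fixture(scope="session")
def design():
    return make_design()


@pytest.fixture(scope="session")
def published_fixtures():
    return make_published_fixtures()


@pytest.fixture(scope="session")
def small_noiseless_experiment():
    """Small noiseless experiment used by exact-recovery tests."""
    cfg = SyntheticConfig(
        n_lnc=60, n_mrna=200, n_mir=40,
        noise_log2_sd=0.0, de_fraction=0.1,
        n_planted_triplets_up=3, n_planted_triplets_down=3, n_decoy_triplets=2,
        seed=11,
    )
    return cfg, generate_experiment(cfg)
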