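import numpy as np
import pandas as pd
import pytest

from lncfun.expression_io import ExpressionMatrix
from lncfun.synthetic_data import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A desk-scale experiment: 160 features, 3 vs 3, tight planted modules.

    Regulons are kept compact (few non-module fillers) so the trans screen
    stays well-powered in a universe of only 120 mRNAs.
    """
    return SimConfig(
        seed=7,
        n_lncrna=40,
        n_mrna=120,
        de_fraction=0.15,
        log2_effect=2.0,
        noise_sd=0.25,
        n_modules=3,
        module_r=0.95,
        cis_fraction=0.5,
        n_tfs=6,
        regulon_size=8,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture()
def toy_log2_matrix() -> ExpressionMatrix:
    """Six samples, hand-chosen log2 values, two groups of three."""
    samples = ["AR_1", "AR_2", "AR_3", "nonAR_1", "nonAR_2", "nonAR_3"]
    values = pd.DataFrame(
        {
            "lnc-A": [8.0, 8.2, 7.8, 6.0, 6.2, 5.8],
            "lnc-B": [5.0, 5.1, 4.9, 5.0, 5.1, 4.9],
            "GENE1": [10.0, 10.1, 9.9, 12.0, 12.1, 11.9],
            "GENE2": [7.0, 7.0, 7.0, 7.0, 7.0, 7.0],
        },
        index=samples,
    ).T
    classes = pd.Series(
        ["lncRNA", "lncRNA", "mRNA", "mRNA"], index=values.index
    )
    design = {s: ("AR" if s.startswith("AR") else "nonAR") for s in samples}
    return ExpressionMatrix(values=values, feature_class=classes, scale="log2", design=design)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
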