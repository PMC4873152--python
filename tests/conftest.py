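import numpy as np
import pytest

from aneuscreen.phenotype import SummaryStat

# Published fasting-glucose group summaries (mM): control vs model arm.
GLUCOSE_SUMMARIES = {
    "Ts65Dn": (SummaryStat(10.9, 0.9, 14), SummaryStat(8.0, 0.3, 17)),
    "Dp16": (SummaryStat(12.1, 0.9, 11), SummaryStat(9.7, 0.5, 10)),
    "Ts1Rhr": (SummaryStat(11.5, 0.4, 12), SummaryStat(11.1, 0.6, 18)),
    "Tc1": (SummaryStat(9.4, 0.5, 23), SummaryStat(13.6, 0.6, 23)),
}

# Published per-gene DE p-values for the five upregulated candidates.
PRINTED_DE_PVALUES = {
    "EVA1C": 0.038,
    "OLIG2": 0.009,
    "IFNAR1": 0.021,
    "RCAN1": 0.009,
    "RUNX1": 0.0003,
}

# Published per-site methylation summaries, beta percent: (ND, T2D).
METHYLATION_SUMMARIES = {
    "cg05156137": ((51.1, 1.8, 34), (40.2, 3.1, 15)),
    "cg21301258": ((57.9, 1.9, 34), (48.0, 3.2, 15)),
    "cg05056497": ((42.3, 1.5, 34), (29.5, 1.9, 15)),
}


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_921)


@pytest.fixture(scope="session")
def default_study():
    """One published-parameter synthetic study shared across tests."""
    from aneuscreen.synthetic import generate_study, published_default_config

    return generate_study(published_default_config(), seed=11)
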