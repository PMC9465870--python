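import numpy as np
import pandas as pd
import pytest

import sleepmr as smr


@pytest.fixture(scope="session")
def panel():
    return smr.make_panel(k=78, seed=11)


@pytest.fixture(scope="session")
def small_panel():
    return smr.make_panel(k=5, seed=3)


@pytest.fixture(scope="session")
def cohort20k(panel):
    """One medium cohort shared by read-only tests."""
    return smr.simulate_cohort(
        n=20_000,
        panel=panel,
        outcomes={
            "low_birthweight": smr.OutcomeSpec(
                family="binary",
                shape=smr.EffectShapeSpec("quadratic", {"curvature": 0.06}, 8.0),
                prevalence=0.08,
            ),
            "birthweight": smr.OutcomeSpec(
                family="continuous", shape=smr.EffectShapeSpec("null"), confounder_effect=30.0
            ),
        },
        seed=101,
    )


def make_hset(bx, sx, by, sy, snp_ids=None):
    """Hand-built harmonized instrument set for estimator tests."""
    k = len(bx)
    table = pd.DataFrame(
        {
            "snp_id": snp_ids if snp_ids is not None else [f"rs{i}" for i in range(k)],
            "effect_allele": "A",
            "other_allele": "G",
            "eaf_exposure": 0.3,
            "beta_exposure": np.asarray(bx, float),
            "se_exposure": np.asarray(sx, float),
            "eaf_outcome": 0.3,
            "beta_outcome": np.asarray(by, float),
            "se_outcome": np.asarray(sy, float),
        }
    )
    return smr.HarmonizedInstrumentSet(table)
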