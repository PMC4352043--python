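import numpy as np
import pandas as pd
import pytest

from illnessdeath import Cohort, RateSet, RateSurface


def constant_rates(i=0.0, r=0.0, mA=0.0, mB=0.0) -> RateSet:
    return RateSet(
        i=RateSurface.constant(i, name="i"),
        r=RateSurface.constant(r, name="r"),
        m_A=RateSurface.constant(mA, name="mA"),
        m_B=RateSurface.constant(mB, name="mB"),
    )


@pytest.fixture
def smooth_rates() -> RateSet:
    """Smooth, bounded, t- and a-dependent rates with r = 0 (irreversible state)."""
    i = RateSurface(lambda t, a: 0.05 + 0.0005 * np.asarray(a, float) + 1e-4 * (np.asarray(t, float) - 50), name="i")
    mA = RateSurface(lambda t, a: 1e-4 * np.exp(0.08 * np.asarray(a, float)), name="mA")
    mB = RateSurface(lambda t, a: 2e-4 * np.exp(0.08 * np.asarray(a, float)), name="mB")
    return RateSet(i=i, r=RateSurface.constant(0.0, name="r"), m_A=mA, m_B=mB)


def tiny_cohort(rows) -> Cohort:
    """Cohort from (birth_time, diagnosis_age-or-None, death_age) tuples."""
    df = pd.DataFrame(
        {
            "birth_time": [r[0] for r in rows],
            "diagnosis_age": [np.nan if r[1] is None else r[1] for r in rows],
            "death_age": [r[2] for r in rows],
        }
    )
    return Cohort(df)
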