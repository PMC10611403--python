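import numpy as np
import pandas as pd
import pytest

from mmjive.panel import FeaturePanel
from mmjive.synthetic import SyntheticSpec, simulate_multilevel

#: PA/gait block split proportional to block widths; with this setting both
#: blocks have the same planted composition, so per-block Frobenius scaling
#: inside the JIVE fits does not change variance fractions.
PROPORTIONAL_SPLIT = (13 / 24, 11 / 24)


def make_panel(rows, pa, gait, wear=None) -> FeaturePanel:
    """Build a FeaturePanel from (subject, day, *features) tuples."""
    cols = ["subject", "day"] + pa + gait
    df = pd.DataFrame(rows, columns=cols)
    if wear is not None:
        df.insert(2, "wear_hours", wear)
    return FeaturePanel(df, pa, gait)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_panel():
    """2 subjects x 2 days x (2 PA + 1 gait)."""
    return make_panel(
        [
            ("s1", 1, 1.0, 2.0, 3.0),
            ("s1", 2, 2.0, 1.0, 4.0),
            ("s2", 1, 0.0, 5.0, 1.0),
            ("s2", 2, 4.0, 3.0, 2.0),
        ],
        pa=["pa_a", "pa_b"],
        gait=["g_a"],
    )


def random_panel(rng, n_subjects=5, days=3, P=4, Q=3):
    rows = []
    for i in range(n_subjects):
        for j in range(days):
            rows.append((f"s{i}", j + 1, *rng.normal(size=P + Q)))
    return make_panel(
        rows, pa=[f"pa{k}" for k in range(P)], gait=[f"g{k}" for k in range(Q)]
    )


@pytest.fixture(scope="session")
def stryde_shaped():
    """65 subjects x ~8.8 days x (13 PA + 11 gait), default planted structure."""
    panel, truth = simulate_multilevel(SyntheticSpec(seed=7))
    return panel, truth
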