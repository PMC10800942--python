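import numpy as np
import pandas as pd
import pytest

from neuroexposome.predictor import GradientBooster, HyperParams
from neuroexposome.synthetic import gen_biomarkers, gen_cohort


@pytest.fixture(scope="session")
def small_cohort():
    return gen_cohort(n=30, female_frac=0.5, age_range=(13, 25), seed=11)


@pytest.fixture(scope="session")
def small_panel(small_cohort):
    return gen_biomarkers(None, small_cohort, corr=0.3, seed=12)


@pytest.fixture(scope="session")
def fitted_small_booster():
    """A small tree ensemble on 6 features with known structure.

    y depends on f0 (linear), f1 (step) and an f2*f3 interaction; f4 is
    noise, f5 is constant (never split on).
    """
    rng = np.random.default_rng(5)
    X = pd.DataFrame(rng.standard_normal((60, 6)), columns=[f"f{j}" for j in range(6)])
    X["f5"] = 1.0
    y = 2 * X["f0"] - 1.5 * (X["f1"] > 0.3) + X["f2"] * X["f3"] + rng.standard_normal(60) * 0.2
    hp = HyperParams(learning_rate=0.3, max_depth=3, n_rounds=20, alpha=0.0, subsample=1.0)
    booster = GradientBooster(hp, seed=3).fit(X, y.to_numpy())
    return booster, X
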