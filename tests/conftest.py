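import numpy as np
import pytest

from thymoselect import CategoryProbs, ControlFractions, EncounterModel


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def standard_model():
    """Single-contact endogenous model: lognormal(0, 1), no agonist, no nulls."""
    return EncounterModel(N=1)


@pytest.fixture
def control_fractions():
    """Strongly selecting control regime: 85% conventional, 3% regulatory."""
    return ControlFractions(0.85, 0.03)


def random_category_probs(rng, p0_zero=False):
    """Random point on the 4-simplex (optionally with p0 = 0)."""
    w = rng.dirichlet(np.ones(4))
    if p0_zero:
        w = np.concatenate([[0.0], rng.dirichlet(np.ones(3))])
    return CategoryProbs(*w)


def calibrated_category_probs(rng, budgets=(100.0, 1000.0, 10000.0)):
    """Per-encounter zone probabilities consistent with a strongly selecting
    baseline: control fractions with a large conventional share and a small
    regulatory share, decomposed over a realistic encounter budget."""
    n = float(rng.choice(budgets))
    frac_conv = rng.uniform(0.5, 0.95)
    frac_reg = rng.uniform(0.005, min(0.1, 0.98 - frac_conv))
    s1 = frac_conv ** (1.0 / n)
    s2 = (frac_conv + frac_reg) ** (1.0 / n)
    return CategoryProbs(0.0, s1, s2 - s1, 1.0 - s2), n
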