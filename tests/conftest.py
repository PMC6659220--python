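import numpy as np
import pytest
from scipy.special import expit

from gatedirt import ScenarioConfig, simulate_exam


def quadrature_p_cheater(
    y, b, exposed, theta_c_prior_mean=1.0, theta_c_prior_variance=2.0, n_grid=801
):
    """Brute-force posterior P(theta_t < theta_c) for a single student.

    Independent oracle: dense 2-D numerical integration over (theta_t,
    theta_c) of prior x gated likelihood, no MCMC involved.
    """
    y = np.asarray(y)
    b = np.asarray(b, dtype=float)
    exposed = np.asarray(exposed).astype(bool)
    tt = np.linspace(-8, 8, n_grid)
    tc = np.linspace(-8, 10, n_grid + 50)
    TT, TC = np.meshgrid(tt, tc, indexing="ij")
    cheat = TT < TC
    ll = np.zeros_like(TT)
    for i in range(y.size):
        ability = np.where(cheat & exposed[i], TC, TT)
        p = expit(ability - b[i])
        ll += np.log(p) if y[i] == 1 else np.log1p(-p)
    lp = (
        ll
        - 0.5 * TT**2
        - (TC - theta_c_prior_mean) ** 2 / (2 * theta_c_prior_variance)
    )
    w = np.exp(lp - lp.max())
    return float(w[cheat].sum() / w.sum())


@pytest.fixture(scope="session")
def toy_student():
    """One student, 20 known-difficulty items (5 exposed), true gain 3."""
    rng = np.random.default_rng(5)
    n_items = 20
    b = rng.standard_normal(n_items)
    exposed = np.zeros(n_items, dtype=int)
    exposed[:5] = 1
    theta_t, gain = -1.0, 3.0
    p = expit(np.where(exposed == 1, theta_t + gain, theta_t) - b)
    y = (rng.random(n_items) < p).astype(int)
    p_exact = quadrature_p_cheater(y, b, exposed)
    return {"y": y, "b": b, "exposed": exposed, "p_exact": p_exact}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250922)


@pytest.fixture(scope="session")
def small_exam():
    """A small mixed exam: 60 students, 50 items (10 exposed), 35% cheaters."""
    scen = ScenarioConfig(
        prop_cheaters=0.35,
        efficacy="high",
        n_students=60,
        n_items=50,
        n_exposed=10,
        seed=1234,
    )
    return simulate_exam(scen, 0)


@pytest.fixture(scope="session")
def honest_exam():
    """An all-honest exam at the design's 20%-exposed ratio."""
    scen = ScenarioConfig(
        prop_cheaters=0.0,
        efficacy="none",
        n_students=100,
        n_items=100,
        n_exposed=20,
        seed=1234,
    )
    return simulate_exam(scen, 0)
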