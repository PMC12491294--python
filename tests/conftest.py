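import numpy as np
import pytest

import phagedyn as pdn


@pytest.fixture(scope="session")
def passive_result() -> pdn.ScenarioResult:
    """Full pipeline run of the passive-defense outbreak scenario."""
    return pdn.run_scenario(pdn.passive_scenario())


@pytest.fixture(scope="session")
def active_result() -> pdn.ScenarioResult:
    """Full pipeline run of the active-defense outbreak scenario."""
    return pdn.run_scenario(pdn.active_scenario())


@pytest.fixture(scope="session")
def both_results(passive_result, active_result) -> dict[str, pdn.ScenarioResult]:
    return {"passive": passive_result, "active": active_result}


def draw_params_and_fp(rng: np.random.Generator) -> tuple[pdn.ModelParams, pdn.FixedPoint]:
    """One random valid parameter set plus a matching phage-free fixed point.

    Rates are drawn log-uniformly over two decades around 1/day, defense
    parameters uniformly; half the draws include logistic growth (mu > 0),
    in which case the fixed point sits at the carrying capacity.
    """
    loguni = lambda lo, hi: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    mu = loguni(0.01, 1.0) if rng.random() < 0.5 else 0.0
    Rm = loguni(0.5, 5.0)
    S0 = loguni(0.1, 3.0)
    params = pdn.ModelParams(
        beta0=loguni(0.1, 10.0),
        gamma=float(rng.uniform(0.0, 10.0)),
        alpha=float(rng.uniform(0.0, 2.0)),
        Rm=Rm,
        q=loguni(0.05, 5.0),
        k1=loguni(0.05, 5.0),
        k2=loguni(0.05, 5.0),
        mu=mu,
        K=S0 if mu > 0 else 1.0,
    )
    fp = pdn.phage_free_fixed_point(S0, float(rng.uniform(0.0, 0.9 * Rm)), params)
    return params, fp
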