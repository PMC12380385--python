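import numpy as np
import pytest

from phmm import PerceptionHMM, scenario_preset, simulate_dataset
from phmm.params import ModelSpec, ParameterSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_parameters(spec: ModelSpec, rng: np.random.Generator,
                      sigma_scale: float = 1.0) -> ParameterSet:
    """A random valid parameter set for a given spec."""

    def simplex(*shape):
        g = rng.gamma(1.0, size=shape)
        return g / g.sum(axis=-1, keepdims=True)

    pi1 = simplex(1, spec.C)
    pi = (np.broadcast_to(pi1, (spec.S, spec.C)).copy()
          if spec.share_initial else simplex(spec.S, spec.C))
    qshape = ((spec.S, spec.M, spec.C, spec.Cm)
              if spec.perception_mode == "arm_specific"
              else (spec.M, spec.C, spec.Cm))
    if spec.perception_mode == "identity":
        Q = np.broadcast_to(np.eye(spec.C), (spec.M, spec.C, spec.C)).copy()
    else:
        Q = simplex(*qshape)
    gamma = np.concatenate(
        [rng.uniform(0.5, 2.0, size=(spec.M, spec.J, 1)),
         rng.uniform(0.05, 0.5, size=(spec.M, spec.J, spec.Cm - 1))], axis=2)
    A = rng.normal(size=(spec.r, spec.r)) * sigma_scale
    Sigma = A @ A.T + np.eye(spec.r) * sigma_scale
    return ParameterSet(
        pi=pi, P=simplex(spec.S, spec.C, spec.C), Q=Q,
        tau=rng.normal(size=(spec.M, spec.J, spec.Cm)),
        beta=rng.normal(size=(spec.M, spec.J, spec.q)) * 0.1,
        gamma=gamma, Sigma=Sigma)


@pytest.fixture(scope="session")
def scenario2_panel():
    """One full-size panel generated under the shared-perception scenario."""
    preset = scenario_preset(2)
    panel, truth = simulate_dataset(preset, seed=1234)
    return preset, panel, truth


@pytest.fixture(scope="session")
def small_fit():
    """A short fit on a reduced panel, shared across diagnostic tests."""
    preset = scenario_preset(2)
    panel, truth = simulate_dataset(preset, seed=77, n_clusters=150)
    model = PerceptionHMM(panel, n_states=3, perception="shared")
    res = model.fit(phase1_iters=200, phase1_burnin=100,
                    phase2_iters=800, phase2_burnin=400, thin=2, seed=5)
    return preset, panel, truth, res
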