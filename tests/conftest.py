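import numpy as np
import pytest

from effortdm import model_space as ms
from effortdm import task_engine as te


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def full_parabolic():
    return ms.get_model("full_parabolic")


def make_cohort(n_subjects, seed, model=None, alpha=1.0, sd_alpha=0.0,
                beta_R=2.0, beta_E=2.0):
    """Small deterministic cohort of simulated sessions (trial frame)."""
    model = model or ms.get_model("full_parabolic")
    rng = np.random.default_rng(seed)
    sessions = []
    for i in range(n_subjects):
        a = rng.normal(alpha, sd_alpha) if sd_alpha else alpha
        agent = te.make_agent(f"s{i:03d}", ms.ParameterSet(a, beta_R, beta_E),
                              rng=rng)
        sessions.append(te.run_session(agent, model,
                                       seed=int(rng.integers(2**31))))
    return te.sessions_to_frame(sessions)


@pytest.fixture(scope="session")
def small_cohort(full_parabolic):
    return make_cohort(8, seed=7, model=full_parabolic, sd_alpha=0.5)
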