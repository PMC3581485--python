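import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from shoctscan.profile_hmm import ProfileHMM
from shoctscan.synthetic_data import ProteomeConfig, generate_proteome


def random_hmm(rng: np.random.Generator, M: int, reentry: float = 0.5) -> ProfileHMM:
    """A random but valid local multihit profile, for property tests."""
    match_em = rng.dirichlet(np.full(20, 0.5), size=M)
    insert_em = rng.dirichlet(np.full(20, 5.0), size=M + 1)
    exit_p = float(rng.uniform(0.05, 0.3))
    me = np.full(M, exit_p)
    me[M - 1] = 1.0
    t_core = np.zeros((M, 7))
    core = rng.dirichlet(np.ones(3), size=M)
    t_core[:, 0:3] = core * (1.0 - me)[:, None]
    t_core[:, 3:5] = rng.dirichlet(np.ones(2), size=M)
    t_core[:, 5:7] = rng.dirichlet(np.ones(2), size=M)
    t_core[M - 1, 0:3] = 0.0
    t_core[M - 1, 3:5] = (1.0, 0.0)
    t_core[M - 1, 5:7] = (1.0, 0.0)
    null = rng.dirichlet(np.full(20, 10.0))
    h = ProfileHMM(
        M=M,
        match_emissions=match_em,
        insert_emissions=insert_em,
        t_core=t_core,
        match_exit=me,
        entry=rng.dirichlet(np.ones(M)),
        reentry=reentry,
        null_freqs=null,
        name="random",
    )
    h.validate()
    return h


@pytest.fixture(scope="session")
def small_proteome():
    """A compact seeded proteome shared by search/decoy/census tests."""
    cfg = ProteomeConfig(
        n_background=400, n_family=30, n_weak=20, n_decoy_only=20
    )
    db, seed_aln, truth = generate_proteome(cfg, 42)
    return cfg, db, seed_aln, truth
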