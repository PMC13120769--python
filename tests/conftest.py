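import numpy as np
import pytest

import guildspec as gs


@pytest.fixture(scope="session")
def small_network():
    """N=6, M=30, two guilds, q=0.4 — the workhorse example community."""
    cfg = gs.GuildConfig(n_species=6, n_resources=30, n_guilds=2, guild_bias=0.4, seed=11)
    return gs.sample_network(cfg)


@pytest.fixture(scope="session")
def ou_realization(small_network):
    """One OU-driven trajectory of the workhorse community, z-scored."""
    drive = gs.DriveSpec.ou(30, omega=1.0, seed=7)
    params = gs.SimParams(t_final=5000.0, sampling_interval=1.0)
    traj = gs.simulate(small_network, drive, params)
    z = gs.log_zscore(traj.abundances)
    return small_network, traj, z


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
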