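import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from picoseason.hydro import CTDProfile
from picoseason.synth import (
    CommunityConfig,
    PhysicsConfig,
    simulate_community,
    simulate_physics,
)

ZERO_NOISE = dict(
    sigma_noise=1e-12,
    fluor_noise=0.0,
    par_noise=0.0,
    mld_jitter_m=0.0,
    dcm_center_jitter_m=0.0,
)


def make_profile(
    depths,
    sigma=None,
    fluor=None,
    par=None,
    pid="p1",
    ts="2017-06-01",
):
    depths = np.asarray(depths, dtype=float)
    return CTDProfile(
        profile_id=pid,
        timestamp=np.datetime64(pd.Timestamp(ts)),
        depth_m=depths,
        sigma_t=None if sigma is None else np.asarray(sigma, dtype=float),
        fluor_rfu=None if fluor is None else np.asarray(fluor, dtype=float),
        par=None if par is None else np.asarray(par, dtype=float),
    )


def exponential_par_profile(k=0.046, z_max=260.0, dz=0.5, par0=1500.0):
    z = np.arange(0.0, z_max, dz)
    return make_profile(z, sigma=np.full_like(z, 24.0), par=par0 * np.exp(-k * z))


@pytest.fixture(scope="session")
def synthetic_year():
    """One default-noise synthetic year: (ctd table, truth, community data)."""
    pcfg = PhysicsConfig()
    ctd, truth = simulate_physics(pcfg, seed=11)
    data = simulate_community(CommunityConfig(), truth, pcfg, seed=12)
    return ctd, truth, data


@pytest.fixture(scope="session")
def zero_noise_year():
    pcfg = PhysicsConfig(**ZERO_NOISE)
    ctd, truth = simulate_physics(pcfg, seed=7)
    return pcfg, ctd, truth


def ctd_roundtrip(ctd_df):
    """Write the CTD frame to CSV text and parse it back into profiles."""
    from picoseason.io import read_ctd_csv

    buf = io.StringIO()
    ctd_df.to_csv(buf, index=False)
    buf.seek(0)
    return read_ctd_csv(buf)
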