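import numpy as np
import pytest

from halfsibqg import (
    PhenotypeTable,
    SimulationConfig,
    log10_transform,
    simulate_design,
)


@pytest.fixture(scope="session")
def small_design():
    """One-population 10-sire split-brood dataset with known truth."""
    cfg = SimulationConfig(
        seed=42, populations=("SF",), n_sires=(10,), n_lines=(3,), rho_ge=0.0
    )
    ped, tab, truth = simulate_design(cfg)
    return cfg, ped, tab, truth


@pytest.fixture(scope="session")
def small_log(small_design):
    cfg, ped, tab, truth = small_design
    return cfg, ped, log10_transform(tab), truth


def single_pop_config(seed, n_sires, h2, c_frac=0.15, r_frac=0.0, T=None, **kw):
    """Single-population config with specified per-trait heritabilities."""
    T = np.ones(5) * 0.01 if T is None else np.asarray(T)
    h2 = np.asarray(h2, dtype=float)
    e_frac = 1.0 - h2 - c_frac - r_frac
    return SimulationConfig(
        seed=seed,
        populations=("SF",),
        n_sires=(n_sires,),
        n_lines=(3,),
        G0=np.diag(h2 * T),
        G7=np.diag(h2 * T),
        C=np.diag(c_frac * T),
        R=np.diag(r_frac * T),
        E=np.diag(e_frac * T),
        rho_ge=0.0,
        **kw,
    )
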