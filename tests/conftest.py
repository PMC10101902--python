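import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from itieskit import (
    CellGeometry,
    Conditions,
    SimConfig,
    TransferSpecies,
    simulate_macro_itv,
    simulate_micro_itv,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def conditions():
    return Conditions()


@pytest.fixture(scope="session")
def nit_species():
    """Nitrazepam-cation-like transferring ion at 20 uM."""
    return TransferSpecies(
        label="NIT+",
        charge=1,
        formal_potential=0.242,
        diffusion_aq=14.1e-6,
        diffusion_org=14.1e-6,
        concentration_aq=20e-6,
    )


@pytest.fixture(scope="session")
def clean_macro_cfg():
    """Fine-grid macro scan with no background and no noise."""
    return SimConfig(
        potential_start=-0.1,
        potential_vertex=0.5,
        n_space=800,
        noise_sd=0.0,
        wall_amplitude=0.0,
        double_layer_capacitance=0.0,
    )


@pytest.fixture(scope="session")
def clean_macro_itv(nit_species, clean_macro_cfg, conditions):
    return simulate_macro_itv([nit_species], clean_macro_cfg, conditions)


@pytest.fixture(scope="session")
def background_macro_itv(nit_species, conditions):
    """Fine-grid macro scan with walls and capacitance but no noise."""
    cfg = SimConfig(
        potential_start=-0.1, potential_vertex=0.5, n_space=800, noise_sd=0.0
    )
    return simulate_macro_itv([nit_species], cfg, conditions)


@pytest.fixture(scope="session")
def tma_species():
    """Reference-ion-like species for micro quality control (50 uM)."""
    return TransferSpecies(
        label="TMA+",
        charge=1,
        formal_potential=0.25,
        diffusion_aq=13.8e-6,
        diffusion_org=13.8e-6,
        concentration_aq=50e-6,
    )


@pytest.fixture(scope="session")
def clean_micro_itv(tma_species, conditions):
    cfg = SimConfig.micro_defaults(
        radius_cm=12e-4,
        noise_sd=0.0,
        wall_amplitude=0.0,
        double_layer_capacitance=0.0,
    )
    return simulate_micro_itv([tma_species], cfg, conditions)


@pytest.fixture()
def triangle_voltammogram():
    """Analytic noiseless triangular scan carrying a Gaussian peak pair."""

    def make(
        peak_amplitude=1e-6,
        peak_potential=0.25,
        noise_sd=0.0,
        seed=0,
        n=400,
        start=-0.2,
        vertex=0.6,
    ):
        from itieskit import Voltammogram

        up = np.linspace(start, vertex, n // 2)
        down = np.linspace(vertex, start, n // 2)
        pot = np.concatenate([up, down[1:]])
        rng = np.random.default_rng(seed)
        sign = np.concatenate([np.ones(n // 2), -np.ones(n // 2 - 1)])
        cur = sign * peak_amplitude * np.exp(
            -((pot - peak_potential) ** 2) / (2 * 0.02 ** 2)
        )
        if noise_sd > 0:
            cur = cur + rng.normal(0, noise_sd, cur.size)
        return Voltammogram(potential=pot, current=cur, scan_rate=0.02)

    return make
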