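"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import optimize

from micalkin import AssayDesign, GlobalKineticParams


def species_velocity(params: GlobalKineticParams, S: float, A: float, E: float) -> float:
    """Independent rate oracle: enumerate the four enzyme species.

    Under rapid equilibrium the relative abundances of E, ES, EA and ESA are
    1, S/K_M, A/K_act and S*A/(alpha*K_M*K_act); flux is k_cat per ES plus
    beta*k_cat per ESA.  This never touches the closed-form rate expression.
    """
    free = 1.0
    es = S / params.K_M
    ea = A / params.K_act
    esa = (S / (params.alpha * params.K_M)) * (A / params.K_act)
    total = free + es + ea + esa
    return E * params.k_cat * (es + params.beta * esa) / total


def oracle_apparent_kcat(params: GlobalKineticParams, A: float) -> float:
    """Apparent turnover via the species oracle at near-saturating substrate."""
    S = 1e9 * params.K_M
    return species_velocity(params, S, A, 1.0)


def oracle_apparent_km(params: GlobalKineticParams, A: float) -> float:
    """Apparent K_M via the species oracle: substrate level at half v_max."""
    vmax = oracle_apparent_kcat(params, A)
    f = lambda S: species_velocity(params, S, A, 1.0) - vmax / 2.0
    return optimize.brentq(f, 1e-9, 1e9 * params.K_M)


@pytest.fixture(scope="session")
def params_mo() -> GlobalKineticParams:
    """MO construct global parameters (alpha restrained to 1)."""
    return GlobalKineticParams(k_cat=0.68, K_M=28.8, K_act=9.3, alpha=1.0, beta=4.7)


@pytest.fixture(scope="session")
def params_moch() -> GlobalKineticParams:
    """MO-CH construct global parameters (alpha = 0.16, strong coupling)."""
    return GlobalKineticParams(k_cat=1.7, K_M=37.7, K_act=10.5, alpha=0.16, beta=7.43)


@pytest.fixture(scope="session")
def design_mo() -> AssayDesign:
    from micalkin.presets import DESIGN_MO

    return DESIGN_MO


@pytest.fixture(scope="session")
def design_moch() -> AssayDesign:
    from micalkin.presets import DESIGN_MO_CH

    return DESIGN_MO_CH


def random_params(rng: np.random.Generator) -> GlobalKineticParams:
    """Log-uniform draw of a valid parameter set over generous ranges."""
    return GlobalKineticParams(
        k_cat=10.0 ** rng.uniform(-2, 2),
        K_M=10.0 ** rng.uniform(-1, 3),
        K_act=10.0 ** rng.uniform(-1, 3),
        alpha=10.0 ** rng.uniform(-2, 2),
        beta=10.0 ** rng.uniform(-1, 2),
    )
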