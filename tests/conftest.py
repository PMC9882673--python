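"""Shared fixtures: controlled synthetic constructions used across modules."""

import numpy as np
import pytest

from nucarray.model import build_template
from nucarray.synthetic import (
    MixtureSpec,
    NormalSpec,
    SyntheticParams,
    generate_array,
    generate_population,
    load_preset,
)


def fixed_mixture(value: float) -> MixtureSpec:
    """Degenerate one-component mixture (effectively a constant)."""
    return MixtureSpec((1.0,), (value,), (1e-9,))


def fixed_params(
    n_ncp=1,
    alpha=39.0,
    beta=-9.0,
    delta_entry=None,
    delta_exit=None,
    noise=0.0,
    alpha_exit=None,
    beta_exit=None,
):
    """SyntheticParams with deterministic angles/deltas for round-trip tests."""
    return SyntheticParams(
        template=build_template(n_ncp),
        alpha_entry=fixed_mixture(alpha),
        alpha_exit=fixed_mixture(alpha if alpha_exit is None else alpha_exit),
        beta_entry=fixed_mixture(beta),
        beta_exit=fixed_mixture(beta if beta_exit is None else beta_exit),
        delta_entry=None if delta_entry is None else NormalSpec(delta_entry, 1e-9),
        delta_exit=None if delta_exit is None else NormalSpec(delta_exit, 1e-9),
        noise_sigma_A=noise,
        name="fixed",
    )


def random_rotation(rng) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix()


@pytest.fixture(scope="session")
def mono_template():
    return build_template(1)


@pytest.fixture(scope="session")
def ideal_mono():
    """Zero-noise fully wrapped mononucleosome (fixed arm angles)."""
    return generate_array(fixed_params(), rng_seed=1)


@pytest.fixture(scope="session")
def peeled_mono():
    """Zero-noise mononucleosome peeled 5 bp at entry, 11 bp at exit."""
    return generate_array(fixed_params(alpha=39.0, alpha_exit=14.0, beta=-9.0,
                                       beta_exit=5.0, delta_entry=-5, delta_exit=-11),
                          rng_seed=7)


@pytest.fixture(scope="session")
def tetra_population_30():
    """30 tetranucleosome models at the low-salt preset (sigma = 2 A)."""
    return generate_population(load_preset("tetra_5mM"), 30, seed=5)
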