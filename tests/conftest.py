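"""Shared fixtures: toy-oracle datasets, trained models, FD helpers."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from gpmlmm.envgen import EnvGenConfig
from gpmlmm.geometry import Geometry
from gpmlmm.gpr import train_environment, train_vacuum
from gpmlmm.oracle import build_dataset, default_toy_params

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")


def numerical_gradient(f, x, h=1e-5):
    """Central finite differences of scalar f over the flattened array x."""
    x = np.asarray(x, dtype=float)
    g = np.zeros(x.size)
    flat = x.reshape(-1)
    for i in range(x.size):
        xp = flat.copy()
        xm = flat.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (f(xp.reshape(x.shape)) - f(xm.reshape(x.shape))) / (2 * h)
    return g.reshape(x.shape)


@pytest.fixture(scope="session")
def toy_params():
    return default_toy_params()


@pytest.fixture(scope="session")
def envgen_config():
    # scaled-down point counts so each sample's environment stays small
    return EnvGenConfig(n_select=60, surface_density=0.3, rng_seed=7)


@pytest.fixture(scope="session")
def solvated_dataset(toy_params, envgen_config):
    """60 fully labelled samples with artificial environments."""
    return build_dataset(toy_params, envgen_config, 60, rng=11)


@pytest.fixture(scope="session")
def vacuum_dataset(toy_params):
    """80 vacuum-only samples."""
    return build_dataset(toy_params, None, 80, rng=12)


@pytest.fixture(scope="session")
def vacuum_model(vacuum_dataset):
    return train_vacuum(vacuum_dataset[:60], lengthscale=1.0, sigma_f=1e-4)


@pytest.fixture(scope="session")
def environment_model(solvated_dataset):
    return train_environment(
        solvated_dataset[:40], lengthscale=1.0, sigma_e=1e-3, sigma_q=1e-5
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_geometry(rng, n=4, symbols=("C", "O", "H", "H")):
    """A well-separated random geometry for derivative tests."""
    base = np.array(
        [[0, 0, 0], [1.6, 0, 0], [0, 1.6, 0], [1.6, 1.6, 0.8], [0.8, 0.8, 1.6],
         [2.4, 0.8, 1.6]],
        dtype=float,
    )
    coords = rng.normal(scale=0.4, size=(n, 3)) + base[:n]
    return Geometry(symbols[:n], coords)
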