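"""Shared fixtures: a fast toy universe for unit tests and the
full-scale trained runs reused by the acceptance suite."""

from __future__ import annotations

import warnings
from types import SimpleNamespace

import pytest
from hypothesis import HealthCheck, settings

from cgbscreen import cgbfp, cpi_model, synthetic_data

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

warnings.filterwarnings("ignore", category=FutureWarning)

TOY_CONFIG = dict(
    n_targets=6,
    n_compounds=400,
    noise_rate=0.05,
    min_binders=40,
    seed=11,
)


@pytest.fixture(scope="session")
def toy_universe():
    return synthetic_data.generate_universe(**TOY_CONFIG)


@pytest.fixture(scope="session")
def toy_split(toy_universe):
    train, test = synthetic_data.emit_training_set(
        toy_universe, holdout_fraction=0.25, seed=11, max_pos_per_target=40
    )
    return train, test


@pytest.fixture(scope="session")
def toy_model(toy_universe, toy_split):
    train, _ = toy_split
    return cpi_model.train(
        train, toy_universe.compounds, toy_universe.targets, seed=11
    )


@pytest.fixture(scope="session")
def toy_panel(toy_split):
    train, _ = toy_split
    return cgbfp.build_panel(train, min_count=20)


FULL_SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def full_runs():
    """Default-configuration universes and trained models, seeds 1-5.

    These are the study conditions for signal-recovery and
    scaffold-hopping checks; built once per session because each
    training takes tens of seconds.
    """
    runs = {}
    for seed in FULL_SEEDS:
        u = synthetic_data.generate_universe(seed=seed)
        train, test = synthetic_data.emit_training_set(u, holdout_fraction=0.25, seed=seed)
        model = cpi_model.train(train, u.compounds, u.targets, seed=seed)
        panel = cgbfp.build_panel(train, min_count=100)
        runs[seed] = SimpleNamespace(
            universe=u, train=train, test=test, model=model, panel=panel
        )
    return runs
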