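"""Shared fixtures: one default synthetic study and its pipeline run.

Session scope keeps the end-to-end objects computed once; every assertion
against planted truth reuses them.
"""

from __future__ import annotations

import pytest

from mirnaome import SimConfig, generate_dataset, run_on_dataset


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=20160)


@pytest.fixture(scope="session")
def dataset(default_config):
    return generate_dataset(default_config)


@pytest.fixture(scope="session")
def pipeline_result(dataset):
    return run_on_dataset(dataset)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A reduced study for tests that regenerate data repeatedly."""
    return SimConfig(
        seed=7,
        n_chromosomes=1,
        chromosome_length=30_000,
        n_known_mirnas=30,
        n_novel_hairpins=3,
        n_contaminant_features=4,
        library_depth=20_000,
        n_breed_de=1,
        n_decline=6,
        n_mrnas=40,
        n_true_targets=6,
        n_decoy_targets=10,
    )
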