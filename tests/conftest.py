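"""Shared fixtures: small synthetic datasets built once per session."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import nucleoff as nf

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from nucleoff.synthetic import synthetic_adapter_scores


@pytest.fixture(scope="session")
def small_config() -> nf.SyntheticConfig:
    return nf.SyntheticConfig(
        seed=7, n_studies=2, sites_per_study=150, genome_length=60_000
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    ds, truth = nf.generate_dataset(small_config)
    return ds, truth


@pytest.fixture(scope="session")
def scored_dataset(small_config):
    """A fully annotated copy: all 19 features (adapters synthetic)."""
    ds, truth = nf.generate_dataset(small_config)
    adapters = synthetic_adapter_scores(ds, seed=small_config.seed)
    nf.score_dataset(ds, adapter_scores=adapters)
    return ds, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_context(rng: np.random.Generator, length: int = 169) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
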