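"""Shared fixtures: small deterministic simulation setups."""
from __future__ import annotations

import numpy as np
import pytest

from twolayer.simdata import FragmentLengthModel, SimConfig


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def clean_sim_config() -> SimConfig:
    """Error-free, damage-free small library on a repeat-free genome."""
    return SimConfig(
        genome_length=8000,
        repeat_specs=(),
        target_coverage=25.0,
        fragment_length_model=FragmentLengthModel(),
        sequencing_error_rate=0.0,
        damage_rate_5p=0.0,
        seed=7,
    )
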