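"""Shared fixtures: a desk-scale default synthetic study (session-scoped,
generated once) and a small fast one for unit-level pipeline tests."""

from __future__ import annotations

import dataclasses

import pytest

from gfap4c.config import PipelineConfig, SyntheticConfig
from gfap4c.pipeline import run_screen
from gfap4c.synthetic import generate_bundle


def small_config(**overrides) -> SyntheticConfig:
    """A 3 x 2 Mb genome with a reduced planting plan (fast to generate)."""
    base = dict(
        n_chromosomes=3,
        chrom_length=2_000_000,
        n_genes=45,
        n_planted_assoc_genes=4,
        n_planted_expr_genes=4,
        n_planted_overlap=3,
        n_assoc_other=2,
        n_assoc_shared=1,
        n_expr_lifminus=2,
        n_expr_shared=2,
        n_bait_peaks=5,
        n_nuclei=50,
        seed=11,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def default_bundle():
    """The full default study conditions (30 Mb genome, 20 truth genes)."""
    return generate_bundle(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def default_screen(default_bundle):
    b = default_bundle
    return run_screen(
        b.e4c_signals,
        b.genes,
        b.chrom_sizes,
        b.expression_intensities,
        b.spikes,
        PipelineConfig(),
    )


@pytest.fixture(scope="session")
def small_bundle():
    return generate_bundle(small_config())


@pytest.fixture(scope="session")
def small_noiseless_bundle():
    return generate_bundle(small_config(noise_sd=0.0, expr_noise_sd=0.0))
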