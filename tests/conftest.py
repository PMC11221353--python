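"""Shared fixtures: small simulated studies reused across test modules."""

from __future__ import annotations

import pytest

from ivtkit.simulate import (
    SimulationConfig,
    generate_reference,
    generate_truth,
    simulate_sample,
    simulate_study,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale study: ~28x mean coverage over 2 contigs of 8 kb."""
    return SimulationConfig(
        n_contigs=2,
        contig_length=8_000,
        n_genes=16,
        n_genomic_snv=6,
        n_ivt_artifacts=4,
        n_modification_sites=4,
        modification_miscall_rate=0.5,
        background_error_rate=0.02,
        n_low_quality_kmers=12,
        reads_per_sample=1_500,
        read_length_mean=300,
        seed=7,
    )


@pytest.fixture(scope="session")
def study(small_config, tmp_path_factory):
    """A written study with 3 IVT samples and 1 biological sample."""
    out = tmp_path_factory.mktemp("study")
    result = simulate_study(small_config, out, n_ivt_samples=3, n_bio_samples=1)
    result["dir"] = out
    result["config"] = small_config
    return result


def full_coverage_config(**overrides) -> SimulationConfig:
    """One gene spanning one contig; every read covers (almost) every base.

    With ``read_length_mean`` equal to the contig length, read lengths clip to
    the single gene interval, so the depth at every gene position equals
    ``reads_per_sample`` — convenient for exact-coverage experiments.
    """
    defaults = dict(
        n_contigs=1,
        contig_length=2_000,
        n_genes=1,
        n_genomic_snv=0,
        n_ivt_artifacts=0,
        n_modification_sites=0,
        background_error_rate=0.0,
        n_low_quality_kmers=0,
        reads_per_sample=100,
        read_length_mean=2_000,
        seed=0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture()
def full_coverage():
    """Factory: (config overrides) -> (reference, genes, truth, config)."""

    def make(**overrides):
        config = full_coverage_config(**overrides)
        reference, genes = generate_reference(config)
        truth = generate_truth(config, reference, genes)
        return reference, genes, truth, config

    return make


__all__ = ["full_coverage_config", "simulate_sample"]
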