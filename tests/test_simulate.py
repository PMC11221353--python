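"""Synthetic-data generator: determinism, construction, and rate recovery."""

from __future__ import annotations

import numpy as np
import pytest

from ivtkit.errors import ConfigurationError, TruthSetError
from ivtkit.pileup import build_pileup
from ivtkit.simulate import (
    SimulationConfig,
    TruthEvent,
    TruthSet,
    de_bruijn_reference,
    generate_reference,
    generate_truth,
    simulate_sample,
    to_alignments,
    write_fasta,
    write_sam,
)

from conftest import full_coverage_config


def test_reference_is_deterministic_and_well_formed(tmp_path):
    config = SimulationConfig(n_contigs=2, contig_length=10_000, seed=1)
    ref1, genes1 = generate_reference(config)
    ref2, genes2 = generate_reference(config)
    assert ref1 == ref2 and genes1 == genes2
    assert len(ref1) == 2
    for seq in ref1.values():
        assert len(seq) == 10_000
        assert set(seq) <= set("ACGT")
    # byte-identical FASTA under a fixed seed
    write_fasta(ref1, tmp_path / "a.fasta")
    write_fasta(ref2, tmp_path / "b.fasta")
    assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()


def test_sam_output_byte_identical_for_fixed_seed(tmp_path):
    config = SimulationConfig(seed=3, reads_per_sample=50, contig_length=3000,
                              read_length_mean=200, n_genes=6)
    for name in ("x", "y"):
        reference, genes = generate_reference(config)
        truth = generate_truth(config, reference, genes)
        reads = simulate_sample(reference, truth, genes, "IVT", config, 1)
        write_sam(reads, reference, tmp_path / f"{name}.sam")
    assert (tmp_path / "x.sam").read_bytes() == (tmp_path / "y.sam").read_bytes()


def test_gene_intervals_are_pairwise_disjoint():
    config = SimulationConfig(n_genes=50, n_contigs=3, contig_length=15_000, seed=2)
    _, genes = generate_reference(config)
    assert len(genes) == 50
    # brute-force overlap check over all interval pairs
    for i, g in enumerate(genes):
        for h in genes[i + 1 :]:
            if g.contig != h.contig:
                continue
            assert g.end <= h.start or h.end <= g.start, (g, h)


def test_truth_positions_disjoint_and_consistent(study):
    truth, reference = study["truth"], study["reference"]
    events = truth.all_events()
    keys = {(e.contig, e.position) for e in events}
    assert len(keys) == len(events)
    for e in events:
        assert reference[e.contig][e.position] == e.ref_base
        assert e.alt_base != e.ref_base


def test_invalid_configs_rejected():
    with pytest.raises(ConfigurationError):
        SimulationConfig(background_error_rate=1.5)
    with pytest.raises(ConfigurationError):
        SimulationConfig(base_quality_low=30, base_quality_high=20)
    with pytest.raises(ConfigurationError):
        SimulationConfig(contig_length=100, read_length_mean=500)
    with pytest.raises(ConfigurationError):
        SimulationConfig(n_genes=0)


def test_truth_reference_inconsistency_rejected(full_coverage):
    reference, genes, _, config = full_coverage()
    contig = next(iter(reference))
    wrong_ref = "A" if reference[contig][100] != "A" else "C"
    bad = TruthSet(genomic_snvs=[TruthEvent(contig, 100, wrong_ref, "G", 1.0)])
    with pytest.raises(TruthSetError):
        simulate_sample(reference, bad, genes, "IVT", config)


def test_zero_error_limit_reads_match_reference(full_coverage):
    reference, genes, truth, config = full_coverage(reads_per_sample=40)
    for mode in ("IVT", "biological"):
        reads = simulate_sample(reference, truth, genes, mode, config)
        for r in reads:
            assert r.seq == reference[r.contig][r.start : r.start + len(r.seq)]


def test_forced_snv_has_alt_fraction_one(full_coverage):
    reference, genes, _, config = full_coverage(reads_per_sample=100)
    contig = next(iter(reference))
    pos, ref_base = 500, reference[contig][500]
    alt = "A" if ref_base != "A" else "G"
    truth = TruthSet(genomic_snvs=[TruthEvent(contig, pos, ref_base, alt, 1.0)])
    reads = simulate_sample(reference, truth, genes, "IVT", config)
    pile = build_pileup(to_alignments(reads, reference), reference)
    row = pile[(pile["contig"] == contig) & (pile["pos0"] == pos)].iloc[0]
    assert row["depth"] >= 90
    assert row[alt] == row["depth"] and row[ref_base] == 0


@pytest.mark.parametrize("coverage", [200, 800, 3200])
def test_event_rates_recovered_within_binomial_tolerance(full_coverage, coverage):
    """Empirical mismatch fractions converge to configured rates as depth grows."""
    miscall, bg = 0.4, 0.01
    reference, genes, _, config = full_coverage(
        reads_per_sample=coverage,
        modification_miscall_rate=miscall,
        background_error_rate=bg,
        seed=11,
    )
    contig = next(iter(reference))
    ref_base = reference[contig][600]
    alt = "T" if ref_base != "T" else "C"
    truth = TruthSet(
        modification_sites=[TruthEvent(contig, 600, ref_base, alt, miscall)]
    )
    bio = simulate_sample(reference, truth, genes, "biological", config, 1)
    pile = build_pileup(to_alignments(bio, reference), reference)
    row = pile[pile["pos0"] == 600].iloc[0]
    se = np.sqrt(miscall * (1 - miscall) / coverage)
    assert abs(row[alt] / row["depth"] - miscall) <= 3 * se
    # background positions: aggregate error rate within 3 SE of bg
    others = pile[pile["pos0"] != 600]
    nonref = sum(
        others[b][others["ref"] != b].sum() for b in "ACGT"
    )
    n = others["depth"].sum()
    assert abs(nonref / n - bg) <= 3 * np.sqrt(bg * (1 - bg) / n)


def test_mode_contrast_events_only_in_their_mode(full_coverage):
    """IVT artifacts are invisible in biological reads and vice versa."""
    reference, genes, _, config = full_coverage(reads_per_sample=400, seed=5)
    contig = next(iter(reference))
    mk = lambda p, frac: TruthEvent(
        contig, p, reference[contig][p],
        "A" if reference[contig][p] != "A" else "G", frac,
    )
    truth = TruthSet(ivt_artifacts=[mk(300, 1.0)], modification_sites=[mk(900, 0.5)])
    for mode, silent_pos in (("IVT", 900), ("biological", 300)):
        reads = simulate_sample(reference, truth, genes, mode, config, 1)
        pile = build_pileup(to_alignments(reads, reference), reference)
        row = pile[pile["pos0"] == silent_pos].iloc[0]
        assert row[row["ref"]] == row["depth"]  # zero background: fully reference


def test_base_qualities_follow_kmer_context(full_coverage):
    reference, genes, _, config = full_coverage(
        n_low_quality_kmers=10, reads_per_sample=20, seed=9
    )
    truth = generate_truth(config, reference, genes)
    assert len(truth.low_quality_kmers) == 10
    reads = simulate_sample(reference, truth, genes, "biological", config)
    h = config.kmer_size // 2
    low_seen = 0
    for r in reads[:5]:
        seq = reference[r.contig]
        for j, q in enumerate(r.quals):
            p = r.start + j
            kmer = seq[p - h : p + h + 1] if h <= p < len(seq) - h else None
            expected = (
                config.base_quality_low
                if kmer in truth.low_quality_kmers
                else config.base_quality_high
            )
            assert q == expected
            low_seen += q == config.base_quality_low
    assert low_seen > 0


def test_gene_labels_recorded_per_read(study):
    truth, samples = study["truth"], study["samples"]
    genes = {g.gene_id for g in study["genes"]}
    for reads in samples.values():
        for r in reads[:50]:
            assert truth.gene_of_read[r.name] == r.gene
            assert r.gene in genes


def test_de_bruijn_reference_contains_every_kmer_once():
    seq = de_bruijn_reference(5)
    assert len(seq) == 4**5 + 4
    seen = {seq[i : i + 5] for i in range(len(seq) - 4)}
    assert len(seen) == 4**5
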