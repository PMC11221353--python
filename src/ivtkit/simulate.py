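"""Synthetic aligned-read generator for IVT-control pipelines.

Direct RNA sequencing (DRS) of in vitro transcribed (IVT) RNA gives an
unmodified rendition of a transcriptome: genomic single-nucleotide variants
(SNVs) appear in both biological and IVT reads, RNA modifications manifest as
systematic miscalls in biological reads only, and IVT-specific artifacts
(polymerase or reverse-transcriptase errors) mismatch only in IVT reads. This
module generates a small multi-contig reference with gene intervals and
simulates pre-aligned read sets with exactly that statistical structure, so
every downstream stage of the pipeline can be tested without external data.

Reads are emitted already aligned (substitutions only by default; an optional
per-base deletion rate exercises deletion-aware counting). Per-base qualities
follow a two-level scheme: bases whose reference 9-mer context belongs to a
designated "low-quality" k-mer set get a depressed phred score, everything
else a high one. Gene identity of each read is carried in the ``GN`` SAM tag
and mirrored in a read-id-to-gene TSV.

Coordinates are 0-based half-open internally and in all BED/TSV output.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .errors import ConfigurationError, TruthSetError

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated study.

    Defaults mimic a desk-scale DRS experiment: a few thousand reads of a few
    hundred bases against kilobase-scale contigs, a ~3% per-base substitution
    background (the substitution component of nanopore DRS error), strong
    modification miscall rates, and the basecaller's quality range (Q7 floor,
    mid-20s typical).
    """

    n_contigs: int = 2
    contig_length: int = 20_000
    n_genes: int = 40
    gene_abundance_skew: float = 1.2
    n_genomic_snv: int = 12
    snv_allele_fraction: float = 1.0
    n_ivt_artifacts: int = 8
    n_modification_sites: int = 8
    modification_miscall_rate: float = 0.4
    background_error_rate: float = 0.03
    n_low_quality_kmers: int = 30
    abundance_jitter_sd: float = 0.4
    base_quality_high: int = 25
    base_quality_low: int = 7
    reads_per_sample: int = 4_000
    read_length_mean: int = 400
    deletion_rate: float = 0.0
    kmer_size: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "snv_allele_fraction",
            "modification_miscall_rate",
            "background_error_rate",
            "deletion_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        for name in (
            "n_contigs",
            "contig_length",
            "n_genes",
            "reads_per_sample",
            "read_length_mean",
        ):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in ("n_genomic_snv", "n_ivt_artifacts", "n_modification_sites",
                     "n_low_quality_kmers"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.abundance_jitter_sd < 0:
            raise ConfigurationError("abundance_jitter_sd must be >= 0")
        if self.base_quality_low >= self.base_quality_high:
            raise ConfigurationError("base_quality_low must be < base_quality_high")
        if self.contig_length < self.read_length_mean:
            raise ConfigurationError("contig_length must be >= read_length_mean")
        if self.kmer_size % 2 == 0 or self.kmer_size < 3:
            raise ConfigurationError("kmer_size must be odd and >= 3")


@dataclass(frozen=True)
class GeneInterval:
    """Half-open [start, end) interval of one gene on a contig."""

    gene_id: str
    contig: str
    start: int
    end: int


@dataclass(frozen=True)
class TruthEvent:
    """One injected substitution event (SNV, IVT artifact, or modification)."""

    contig: str
    position: int  # 0-based
    ref_base: str
    alt_base: str
    fraction: float  # allele fraction or miscall rate


@dataclass
class TruthSet:
    """Ground truth of a simulated study.

    Position lists are pairwise disjoint; ``gene_of_read`` is populated as
    samples are simulated (read ids are unique across samples).
    """

    genomic_snvs: list[TruthEvent] = field(default_factory=list)
    ivt_artifacts: list[TruthEvent] = field(default_factory=list)
    modification_sites: list[TruthEvent] = field(default_factory=list)
    low_quality_kmers: set[str] = field(default_factory=set)
    gene_of_read: dict[str, str] = field(default_factory=dict)

    def all_events(self) -> list[TruthEvent]:
        return [*self.genomic_snvs, *self.ivt_artifacts, *self.modification_sites]

    def validate(self, reference: Mapping[str, str]) -> None:
        seen: set[tuple[str, int]] = set()
        for ev in self.all_events():
            key = (ev.contig, ev.position)
            if key in seen:
                raise TruthSetError(f"duplicate truth position {key}")
            seen.add(key)
            if ev.contig not in reference:
                raise TruthSetError(f"truth contig {ev.contig!r} not in reference")
            seq = reference[ev.contig]
            if not 0 <= ev.position < len(seq):
                raise TruthSetError(f"truth position {key} outside contig")
            if seq[ev.position] != ev.ref_base:
                raise TruthSetError(
                    f"truth ref base {ev.ref_base} != reference "
                    f"{seq[ev.position]} at {key}"
                )
            if ev.alt_base == ev.ref_base:
                raise TruthSetError(f"alt base equals ref base at {key}")


@dataclass
class SimRead:
    """One simulated, pre-aligned read."""

    name: str
    contig: str
    start: int  # 0-based leftmost reference coordinate
    seq: str
    quals: list[int]
    cigar: list[tuple[int, int]]  # pysam cigartuples (op, length)
    gene: str


def generate_reference(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GeneInterval]]:
    """Generate a random ACGT reference and non-overlapping gene intervals.

    Genes tile part of each contig as half-open intervals separated by short
    intergenic gaps; output is deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    reference: dict[str, str] = {}
    for c in range(config.n_contigs):
        codes = rng.integers(0, 4, size=config.contig_length)
        reference[f"contig{c + 1}"] = "".join(BASES[i] for i in codes)

    genes: list[GeneInterval] = []
    per_contig = [config.n_genes // config.n_contigs] * config.n_contigs
    for c in range(config.n_genes % config.n_contigs):
        per_contig[c] += 1
    gid = 0
    for c, n_here in enumerate(per_contig):
        contig = f"contig{c + 1}"
        if n_here == 0:
            continue
        # slot width includes a gap so intervals never touch
        slot = config.contig_length // n_here
        gap = max(1, slot // 20)
        length = slot - gap
        if length < 1:
            raise ConfigurationError(
                "too many genes for contig length: empty gene intervals"
            )
        for j in range(n_here):
            start = j * slot
            gid += 1
            genes.append(GeneInterval(f"gene{gid}", contig, start, start + length))
    return reference, genes


def generate_truth(
    config: SimulationConfig,
    reference: Mapping[str, str],
    genes: Sequence[GeneInterval],
) -> TruthSet:
    """Draw disjoint truth positions inside gene intervals and low-quality k-mers.

    Event positions are kept at least ``kmer_size // 2`` bases from contig
    edges so their k-mer context is always defined, and low-quality k-mer
    contexts are sampled from positions disjoint from the event positions.
    """
    rng = np.random.default_rng(config.seed + 10_007)
    h = config.kmer_size // 2
    candidates = [
        (g.contig, p)
        for g in genes
        for p in range(max(g.start, h), min(g.end, len(reference[g.contig]) - h))
    ]
    n_events = config.n_genomic_snv + config.n_ivt_artifacts + config.n_modification_sites
    n_pick = n_events + config.n_low_quality_kmers
    if n_pick > len(candidates):
        raise ConfigurationError("not enough gene territory for requested truth events")
    idx = rng.choice(len(candidates), size=n_pick, replace=False)
    picks = [candidates[i] for i in idx]

    def make_events(pos_list: list[tuple[str, int]], fraction: float) -> list[TruthEvent]:
        out = []
        for contig, pos in pos_list:
            ref_base = reference[contig][pos]
            alts = [b for b in BASES if b != ref_base]
            alt = alts[rng.integers(0, 3)]
            out.append(TruthEvent(contig, pos, ref_base, alt, fraction))
        return out

    a = config.n_genomic_snv
    b = a + config.n_ivt_artifacts
    c = b + config.n_modification_sites
    truth = TruthSet(
        genomic_snvs=make_events(picks[:a], config.snv_allele_fraction),
        ivt_artifacts=make_events(picks[a:b], 1.0),
        modification_sites=make_events(picks[b:c], config.modification_miscall_rate),
    )
    for contig, pos in picks[c:]:
        truth.low_quality_kmers.add(reference[contig][pos - h : pos + h + 1])
    truth.validate(reference)
    return truth


def gene_abundance_weights(config: SimulationConfig, n_genes: int) -> np.ndarray:
    """Zipf-like abundance weights over a study-level random gene rank order.

    Deterministic in ``config.seed`` and independent of the per-sample RNG
    streams, so all samples of a study share one expression profile.
    """
    rng = np.random.default_rng(config.seed + 20_011)
    order = rng.permutation(n_genes)
    ranks = np.empty(n_genes, dtype=int)
    ranks[order] = np.arange(1, n_genes + 1)
    weights = ranks.astype(float) ** -config.gene_abundance_skew
    return weights / weights.sum()


def _low_quality_centers(
    reference: Mapping[str, str], low_kmers: set[str], k: int
) -> dict[str, np.ndarray]:
    """Boolean mask per contig: is the reference k-mer centered here low-quality?"""
    h = k // 2
    masks: dict[str, np.ndarray] = {}
    for contig, seq in reference.items():
        mask = np.zeros(len(seq), dtype=bool)
        if low_kmers:
            for p in range(h, len(seq) - h):
                if seq[p - h : p + h + 1] in low_kmers:
                    mask[p] = True
        masks[contig] = mask
    return masks


def simulate_sample(
    reference: Mapping[str, str],
    truth: TruthSet,
    genes: Sequence[GeneInterval],
    mode: str,
    config: SimulationConfig,
    sample_index: int = 0,
    sample_name: str | None = None,
) -> list[SimRead]:
    """Simulate one aligned read set in ``"IVT"`` or ``"biological"`` mode.

    Genomic SNVs are expressed in both modes at their allele fraction, IVT
    artifacts only in IVT mode, modification miscalls only in biological mode;
    independent background substitutions occur elsewhere at
    ``background_error_rate`` with the alternate base uniform over the three
    non-reference bases. Each sample uses its own RNG stream seeded
    ``config.seed + sample_index``, so adding a sample never perturbs others.
    """
    if mode not in ("IVT", "biological"):
        raise ConfigurationError(f"mode must be 'IVT' or 'biological', got {mode!r}")
    truth.validate(reference)
    if sample_name is None:
        sample_name = f"{mode.lower()}{sample_index}"
    rng = np.random.default_rng(config.seed + sample_index)

    # per-contig event lookup applicable to this mode
    events: dict[str, dict[int, TruthEvent]] = {c: {} for c in reference}
    active = list(truth.genomic_snvs)
    active += truth.ivt_artifacts if mode == "IVT" else truth.modification_sites
    for ev in active:
        events[ev.contig][ev.position] = ev
    # positions of *any* truth event are never hit by background error or deletion
    shielded: dict[str, set[int]] = {c: set() for c in reference}
    for ev in truth.all_events():
        shielded[ev.contig].add(ev.position)

    low_mask = _low_quality_centers(reference, truth.low_quality_kmers, config.kmer_size)

    # The expression profile belongs to the simulated cell line, so the
    # Zipf-like rank order is derived from the study seed and shared by every
    # sample; a per-sample lognormal jitter models library-prep variability
    # (e.g. RT-PCR amplification bias in the IVT arm).
    weights = gene_abundance_weights(config, len(genes))
    if config.abundance_jitter_sd > 0:
        weights = weights * rng.lognormal(0.0, config.abundance_jitter_sd, len(genes))
        weights /= weights.sum()

    reads: list[SimRead] = []
    gene_idx = rng.choice(len(genes), size=config.reads_per_sample, p=weights)
    for i in range(config.reads_per_sample):
        g = genes[gene_idx[i]]
        glen = g.end - g.start
        lo = min(30, glen)
        length = int(
            np.clip(rng.normal(config.read_length_mean, config.read_length_mean / 4),
                    lo, glen)
        )
        start = int(rng.integers(g.start, g.end - length + 1))
        ref_seg = reference[g.contig][start : start + length]
        base_codes = np.array([_BASE_IDX[x] for x in ref_seg], dtype=np.int8)

        # background substitutions
        err = rng.random(length) < config.background_error_rate
        # deletions (optional), disjoint from substitutions
        dele = (rng.random(length) < config.deletion_rate) & ~err
        for p in shielded[g.contig]:
            if start <= p < start + length:
                err[p - start] = False
                dele[p - start] = False
        for j in np.nonzero(err)[0]:
            base_codes[j] = (base_codes[j] + rng.integers(1, 4)) % 4
        # injected events
        for p, ev in events[g.contig].items():
            if start <= p < start + length and rng.random() < ev.fraction:
                base_codes[p - start] = _BASE_IDX[ev.alt_base]

        keep = ~dele
        kept_pos = np.nonzero(keep)[0]
        seq = "".join(BASES[base_codes[j]] for j in kept_pos)
        quals = [
            config.base_quality_low
            if low_mask[g.contig][start + j]
            else config.base_quality_high
            for j in kept_pos
        ]
        cigar = _runs_to_cigar(keep)
        name = f"{sample_name}_read{i:06d}"
        reads.append(SimRead(name, g.contig, start, seq, quals, cigar, g.gene_id))
        truth.gene_of_read[name] = g.gene_id
    return reads


def _runs_to_cigar(keep: np.ndarray) -> list[tuple[int, int]]:
    """Convert a per-reference-position kept/deleted mask to M/D cigartuples."""
    cigar: list[tuple[int, int]] = []
    if len(keep) == 0:
        return cigar
    cur_op = 0 if keep[0] else 2
    run = 1
    for flag in keep[1:]:
        op = 0 if flag else 2
        if op == cur_op:
            run += 1
        else:
            cigar.append((cur_op, run))
            cur_op, run = op, 1
    cigar.append((cur_op, run))
    # leading/trailing deletions are not representable: trim them
    while cigar and cigar[0][0] == 2:
        cigar.pop(0)
    while cigar and cigar[-1][0] == 2:
        cigar.pop()
    return cigar


# ---------------------------------------------------------------------------
# writers


def sam_header(reference: Mapping[str, str]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": c, "LN": len(s)} for c, s in reference.items()],
        }
    )


def to_alignments(
    reads: Sequence[SimRead], reference: Mapping[str, str]
) -> list[pysam.AlignedSegment]:
    """Convert simulated reads to in-memory pysam alignment records."""
    header = sam_header(reference)
    tid = {c: i for i, c in enumerate(reference)}
    out = []
    for r in reads:
        a = pysam.AlignedSegment(header)
        a.query_name = r.name
        a.query_sequence = r.seq
        a.flag = 0
        a.reference_id = tid[r.contig]
        a.reference_start = r.start
        a.mapping_quality = 60
        a.cigartuples = r.cigar
        a.query_qualities = pysam.qualitystring_to_array(
            "".join(chr(q + 33) for q in r.quals)
        )
        a.set_tag("GN", r.gene, "Z")
        out.append(a)
    return out


def write_sam(
    reads: Sequence[SimRead], reference: Mapping[str, str], path: str | Path
) -> None:
    """Write simulated reads as an uncompressed SAM file (gene in the GN tag)."""
    header = sam_header(reference)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for a in to_alignments(reads, reference):
            out.write(a)


def de_bruijn_reference(k: int) -> str:
    """A linear ACGT sequence containing every k-mer exactly once as a substring.

    Built from the cyclic de Bruijn sequence B(4, k) (Lyndon-word
    concatenation) with the first k-1 symbols appended to linearize it.
    Useful for constructing references in which every position has a unique
    k-mer context.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    a = [0] * (4 * k)
    seq: list[int] = []

    def db(t: int, p: int) -> None:
        if t > k:
            if k % p == 0:
                seq.extend(a[1 : p + 1])
        else:
            a[t] = a[t - p]
            db(t + 1, p)
            for j in range(a[t - p] + 1, 4):
                a[t] = j
                db(t + 1, t)

    db(1, 1)
    cyc = "".join(BASES[i] for i in seq)
    return cyc + cyc[: k - 1]


def write_fasta(reference: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for contig, seq in reference.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_truth_tables(truth: TruthSet, out_dir: str | Path) -> None:
    """Write truth events as TSV + BED (0-based half-open) and the k-mer set."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    classes = [
        ("genomic_snvs", truth.genomic_snvs),
        ("ivt_artifacts", truth.ivt_artifacts),
        ("modification_sites", truth.modification_sites),
    ]
    with open(out / "truth_events.tsv", "w") as fh:
        fh.write("class\tcontig\tpos0\tref\talt\tfraction\n")
        for cls, evs in classes:
            for ev in evs:
                fh.write(
                    f"{cls}\t{ev.contig}\t{ev.position}\t{ev.ref_base}\t"
                    f"{ev.alt_base}\t{ev.fraction}\n"
                )
    with open(out / "truth_events.bed", "w") as fh:
        for cls, evs in classes:
            for ev in sorted(evs, key=lambda e: (e.contig, e.position)):
                fh.write(
                    f"{ev.contig}\t{ev.position}\t{ev.position + 1}\t"
                    f"{cls}:{ev.ref_base}>{ev.alt_base}\n"
                )
    with open(out / "truth_low_quality_kmers.txt", "w") as fh:
        for kmer in sorted(truth.low_quality_kmers):
            fh.write(kmer + "\n")


def write_read_gene_tsv(reads: Sequence[SimRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tgene_id\n")
        for r in reads:
            fh.write(f"{r.name}\t{r.gene}\n")


def write_config_snapshot(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, sort_keys=True)
        fh.write("\n")


def simulate_study(
    config: SimulationConfig,
    out_dir: str | Path,
    n_ivt_samples: int = 6,
    n_bio_samples: int = 1,
) -> dict[str, object]:
    """Generate and write a full study: reference, truth, and all samples.

    IVT samples get stream indices ``1..n_ivt``; biological samples follow.
    Returns the in-memory reference, genes, truth, and per-sample read lists.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference, genes = generate_reference(config)
    truth = generate_truth(config, reference, genes)
    write_fasta(reference, out / "reference.fasta")
    write_truth_tables(truth, out)
    write_config_snapshot(config, out / "config.json")

    samples: dict[str, list[SimRead]] = {}
    idx = 1
    for _ in range(n_ivt_samples):
        name = f"ivt{idx}"
        reads = simulate_sample(reference, truth, genes, "IVT", config, idx, name)
        write_sam(reads, reference, out / f"{name}.sam")
        write_read_gene_tsv(reads, out / f"{name}.read_gene.tsv")
        samples[name] = reads
        idx += 1
    for _ in range(n_bio_samples):
        name = f"bio{idx}"
        reads = simulate_sample(reference, truth, genes, "biological", config, idx, name)
        write_sam(reads, reference, out / f"{name}.sam")
        write_read_gene_tsv(reads, out / f"{name}.read_gene.tsv")
        samples[name] = reads
        idx += 1
    return {"reference": reference, "genes": genes, "truth": truth, "samples": samples}
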