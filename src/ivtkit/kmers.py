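"""Low-confidence k-mer curation from per-base qualities.

Nanopore basecallers are systematically less confident in some sequence
contexts; mismatches inside such contexts are more likely basecalling noise
than genuine signal. This module profiles the mean phred quality of every
reference k-mer context (k = 9 by default) observed in a biological DRS
sample, selects the lowest quartile as the low-confidence set, and answers
membership queries for variant positions.

The quality attributed to one k-mer occurrence is, by default, the quality of
the read base aligned to the **center** of the reference k-mer (variant
positions are classified by their centered context). A mean-over-all-k
positions mode is available via ``mode="window"``.

Profiles are indexed by reference-sequence k-mers (not read-sequence), so
membership is stable across samples. The quartile rule is computed over k-mer
types, each counted once regardless of how often it occurs.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from .errors import ConfigurationError, InputError
from .pileup import is_primary

logger = logging.getLogger(__name__)

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

_MATCH_OPS = {0, 7, 8}


@dataclass
class KmerQualityProfile:
    """Mean center-base quality and occurrence count per reference k-mer."""

    k: int
    mean_quality: dict[str, float]
    occurrence_count: dict[str, int]

    def __len__(self) -> int:
        return len(self.mean_quality)


@dataclass(frozen=True)
class KmerConfidenceSet:
    """The curated low-confidence k-mer set and the cutoff that produced it."""

    kmers: frozenset[str]
    quartile_cutoff: float
    k: int

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.kmers

    def __len__(self) -> int:
        return len(self.kmers)


def _encode_contig(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_ids(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer id of the k-mer centered at each position; -1 where undefined.

    Ids encode the k-mer base-4 (A=0..T=3); positions within k//2 of a contig
    edge, or whose context contains a non-ACGT base, get -1.
    """
    n = len(codes)
    ids = np.full(n, -1, dtype=np.int64)
    if n < k:
        return ids
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    vals = windows @ powers
    h = k // 2
    ids[h : h + len(vals)][valid] = vals[valid]
    return ids


def _decode_kmer(kid: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[kid % 4])
        kid //= 4
    return "".join(reversed(out))


def profile_kmer_quality(
    alignments: str | Path | Iterable[pysam.AlignedSegment],
    reference: Mapping[str, str],
    k: int = 9,
    mode: str = "center",
) -> KmerQualityProfile:
    """Average read base qualities over every observed reference k-mer context.

    Parameters
    ----------
    alignments
        SAM/BAM path or iterable of primary-filterable aligned segments; reads
        must carry base qualities. Intended source: an independent
        *biological* DRS sample (IVT qualities do not reflect the contexts a
        modification analysis will encounter).
    k
        Context length, odd, >= 3.
    mode
        ``"center"`` (default): the quality of the read base aligned to the
        k-mer's center position. ``"window"``: the mean quality of the read
        bases aligned across all k positions (occurrences whose window spans
        an alignment gap are skipped).
    """
    if k < 3 or k % 2 == 0:
        raise ConfigurationError(f"k must be odd and >= 3, got {k}")
    if mode not in ("center", "window"):
        raise ConfigurationError(f"mode must be 'center' or 'window', got {mode!r}")

    kmer_ids: dict[str, np.ndarray] = {
        contig: _kmer_ids(_encode_contig(seq), k) for contig, seq in reference.items()
    }
    qsum = np.zeros(4**k, dtype=np.float64)
    qcnt = np.zeros(4**k, dtype=np.int64)
    h = k // 2

    def consume(reads: Iterable[pysam.AlignedSegment]) -> None:
        for read in reads:
            if not is_primary(read):
                continue
            quals = read.query_qualities
            if quals is None:
                raise InputError(f"read {read.query_name!r} has no base qualities")
            if read.reference_name not in reference:
                raise InputError(
                    f"read aligned to contig {read.reference_name!r} absent from reference"
                )
            ids = kmer_ids[read.reference_name]
            quals = np.asarray(quals, dtype=np.float64)
            rpos = read.reference_start
            qpos = 0
            for op, length in read.cigartuples:
                if op in _MATCH_OPS:
                    block_ids = ids[rpos : rpos + length]
                    if mode == "center":
                        block_q = quals[qpos : qpos + length]
                        ok = block_ids >= 0
                    else:  # window mean within one gapless block
                        ok = np.zeros(length, dtype=bool)
                        block_q = np.zeros(length)
                        if length >= k:
                            means = np.convolve(
                                quals[qpos : qpos + length], np.ones(k) / k, "valid"
                            )
                            ok[h : length - h] = block_ids[h : length - h] >= 0
                            block_q[h : length - h] = means
                    np.add.at(qsum, block_ids[ok], block_q[ok])
                    np.add.at(qcnt, block_ids[ok], 1)
                    rpos += length
                    qpos += length
                elif op == 2 or op == 3:
                    rpos += length
                elif op in (1, 4):
                    qpos += length

    if isinstance(alignments, (str, Path)):
        with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
            consume(fh)
    else:
        consume(alignments)

    seen = np.nonzero(qcnt)[0]
    mean_quality = {_decode_kmer(int(i), k): qsum[i] / qcnt[i] for i in seen}
    occurrence_count = {_decode_kmer(int(i), k): int(qcnt[i]) for i in seen}
    return KmerQualityProfile(k, mean_quality, occurrence_count)


def select_low_confidence(
    profile: KmerQualityProfile, quantile: float = 0.25
) -> KmerConfidenceSet:
    """Select the lowest-quality fraction of profiled k-mer types.

    The cutoff is the largest observed mean quality whose empirical CDF over
    k-mer types is <= ``quantile``; membership uses an inclusive
    ``mean <= cutoff`` rule. With all-distinct means and n divisible by 1/q
    this selects exactly the lowest q fraction. When even the smallest mean
    carries more than q of the mass (e.g. two-level quality data with a large
    low class, or all means identical), the entire minimum-value class is
    selected — ties at the boundary are never split.
    """
    if not 0 < quantile < 1:
        raise ConfigurationError(f"quantile must lie in (0, 1), got {quantile}")
    if len(profile) == 0:
        raise InputError("cannot select from an empty k-mer profile")
    means = np.fromiter(profile.mean_quality.values(), dtype=float)
    uniq, counts = np.unique(means, return_counts=True)
    cdf = np.cumsum(counts) / len(means)
    below = np.nonzero(cdf <= quantile)[0]
    cutoff = float(uniq[below[-1]]) if len(below) else float(uniq[0])
    members = frozenset(
        kmer for kmer, m in profile.mean_quality.items() if m <= cutoff
    )
    return KmerConfidenceSet(members, cutoff, profile.k)


def in_low_confidence(
    reference: Mapping[str, str],
    contig: str,
    position: int,
    conf_set: KmerConfidenceSet,
) -> bool:
    """Is the reference k-mer centered on ``position`` a low-confidence context?

    Positions within k//2 bases of a contig edge have no full context; they
    are logged and reported as not-low-confidence.
    """
    if contig not in reference:
        raise InputError(f"unknown contig {contig!r}")
    seq = reference[contig]
    h = conf_set.k // 2
    if position < h or position + h >= len(seq):
        logger.warning(
            "position %s:%d within %d bases of contig edge; no %d-mer context",
            contig, position, h, conf_set.k,
        )
        return False
    return seq[position - h : position + h + 1] in conf_set.kmers


def write_confidence_set(
    conf_set: KmerConfidenceSet, profile: KmerQualityProfile | None, path: str | Path
) -> None:
    """Write the set as TSV (kmer, mean_quality) with k and cutoff in the header."""
    with open(path, "w") as fh:
        fh.write(f"#k={conf_set.k}\tcutoff={conf_set.quartile_cutoff:.6g}\n")
        fh.write("kmer\tmean_quality\n")
        for kmer in sorted(conf_set.kmers):
            mq = profile.mean_quality[kmer] if profile is not None else float("nan")
            fh.write(f"{kmer}\t{mq:.6g}\n")


def read_confidence_set(path: str | Path) -> KmerConfidenceSet:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#k="):
            raise InputError(f"missing k/cutoff header in {path}")
        kpart, cutpart = header[1:].split("\t")
        k = int(kpart.split("=")[1])
        cutoff = float(cutpart.split("=")[1])
        fh.readline()  # column header
        kmers = frozenset(line.split("\t")[0] for line in fh if line.strip())
    return KmerConfidenceSet(kmers, cutoff, k)
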