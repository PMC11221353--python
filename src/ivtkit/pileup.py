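"""Per-position nucleotide and deletion counts from aligned reads.

The pileup is the unit of everything downstream: for each reference position
covered by at least one primary alignment it records how many reads called
A, C, G, T, or a deletion there. Depth is the number of reads spanning the
position, so ``A + C + G + T + del == depth`` at every row.

Conventions
-----------
* Coordinates are 0-based half-open internally and in the TSV output
  (column ``pos0``); human-readable reports render 1-based positions.
* Only primary alignments are counted: unmapped, secondary (flag 256) and
  supplementary (flag 2048) records are dropped, matching the usual
  ``samtools view -F 4 -F 256 -F 2048`` filter.
* Insertions relative to the reference occupy no reference coordinate and are
  ignored. Counting is strand-unaware on the reference forward strand.
* No mapping- or base-quality filtering is applied at this stage.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .errors import InputError, ReferenceMismatchError

PILEUP_COLUMNS = ["contig", "pos0", "ref", "A", "C", "G", "T", "del", "depth"]

# consumes-reference cigar ops: M=0, D=2, N=3, =7, X=8
_MATCH_OPS = {0, 7, 8}

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def is_primary(read: pysam.AlignedSegment) -> bool:
    return not (read.is_unmapped or read.is_secondary or read.is_supplementary)


def build_pileup(
    alignments: str | Path | Iterable[pysam.AlignedSegment],
    reference: Mapping[str, str],
) -> pd.DataFrame:
    """Count A/C/G/T/deletion per reference position over primary alignments.

    Parameters
    ----------
    alignments
        Path to a SAM/BAM file, or an iterable of ``pysam.AlignedSegment``.
    reference
        Mapping contig name -> uppercase sequence; every aligned contig must
        be present.

    Returns
    -------
    DataFrame with one row per position of depth >= 1, columns
    ``contig, pos0, ref, A, C, G, T, del, depth``.
    """
    counts: dict[str, np.ndarray] = {}  # contig -> (L, 5) A,C,G,T,del

    def contig_counts(contig: str) -> np.ndarray:
        if contig not in reference:
            raise InputError(f"read aligned to contig {contig!r} absent from reference")
        if contig not in counts:
            counts[contig] = np.zeros((len(reference[contig]), 5), dtype=np.int64)
        return counts[contig]

    if isinstance(alignments, (str, Path)):
        with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
            _accumulate(fh, contig_counts)
    else:
        _accumulate(alignments, contig_counts)

    frames = []
    for contig in reference:
        if contig not in counts:
            continue
        arr = counts[contig]
        depth = arr.sum(axis=1)
        pos = np.nonzero(depth)[0]
        if len(pos) == 0:
            continue
        seq = reference[contig]
        frames.append(
            pd.DataFrame(
                {
                    "contig": contig,
                    "pos0": pos,
                    "ref": [seq[p] for p in pos],
                    "A": arr[pos, 0],
                    "C": arr[pos, 1],
                    "G": arr[pos, 2],
                    "T": arr[pos, 3],
                    "del": arr[pos, 4],
                    "depth": depth[pos],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=PILEUP_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def _accumulate(reads, contig_counts) -> None:
    for read in reads:
        if not is_primary(read):
            continue
        arr = contig_counts(read.reference_name)
        seq = read.query_sequence
        rpos = read.reference_start
        qpos = 0
        for op, length in read.cigartuples:
            if op in _MATCH_OPS:
                codes = _BASE_CODE[
                    np.frombuffer(seq[qpos : qpos + length].encode(), dtype=np.uint8)
                ]
                valid = codes >= 0  # non-ACGT read bases are not counted
                np.add.at(arr, (rpos + np.nonzero(valid)[0], codes[valid]), 1)
                rpos += length
                qpos += length
            elif op == 2:  # deletion
                arr[rpos : rpos + length, 4] += 1
                rpos += length
            elif op == 3:  # reference skip
                rpos += length
            elif op in (1, 4):  # insertion, soft clip
                qpos += length
            # 5 (hard clip) and 6 (pad) consume nothing


def merge_pileups(pileups: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Sum pileups position-wise to form a pooled dataset.

    All inputs must agree on the reference base at shared coordinates; every
    count field at every position equals the sum over inputs.
    """
    if len(pileups) == 0:
        raise InputError("merge_pileups needs at least one pileup")
    if len(pileups) == 1:
        return pileups[0].copy()
    cat = pd.concat(pileups, ignore_index=True)
    refs = cat.groupby(["contig", "pos0"])["ref"].nunique()
    if (refs > 1).any():
        where = refs[refs > 1].index[0]
        raise ReferenceMismatchError(f"conflicting ref base at {where}")
    merged = (
        cat.groupby(["contig", "pos0", "ref"], as_index=False)[
            ["A", "C", "G", "T", "del", "depth"]
        ]
        .sum()
        .sort_values(["contig", "pos0"], ignore_index=True)
    )
    return merged[PILEUP_COLUMNS]


def write_pileup(pileup: pd.DataFrame, path: str | Path) -> None:
    pileup.to_csv(path, sep="\t", index=False, columns=PILEUP_COLUMNS)


def read_pileup(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "ref": str})
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"pileup file missing columns: {sorted(missing)}")
    return df[PILEUP_COLUMNS]
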