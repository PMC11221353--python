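"""Mismatch cataloging: flag non-reference positions and sweep occurrence thresholds.

A position enters the catalog when it has at least ``min_coverage`` reads and
at least one called nucleotide differing from the reference. The occurrence
fraction of a variant is its read count divided by the number of canonical
bases **plus deletions** at the location (deletions dilute every substitution
but are never themselves emitted as variants). The catalog is then filtered at
a ladder of occurrence thresholds — 30, 40, 50, 60, 70, 80, 95 percent by
default — producing nested variant sets and one BED track per threshold for
genome-browser review.

Thresholds are compared inclusively (``fraction >= t/100``), so a variant at
exactly 30% survives the 30% filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (30, 40, 50, 60, 70, 80, 95)

CATALOG_COLUMNS = [
    "contig",
    "pos0",
    "ref",
    "alt",
    "alt_count",
    "denom",
    "occurrence_fraction",
    "sample",
]


def call_candidates(
    pileup: pd.DataFrame,
    min_coverage: int = 10,
    sample: str = "sample",
    aggregate: bool = False,
) -> pd.DataFrame:
    """Flag every (position, alternate base) pair at sufficient coverage.

    Parameters
    ----------
    pileup
        Per-position counts with columns ``contig, pos0, ref, A, C, G, T,
        del, depth``.
    min_coverage
        Minimum depth (canonical bases + deletions) for a position to be
        considered; default 10.
    aggregate
        If True, emit one record per position whose fraction is the combined
        non-reference substitution fraction (the alternate base reported is
        the most abundant non-reference base). Default is one record per
        alternate base, each with its own fraction.

    Returns
    -------
    DataFrame with columns ``contig, pos0, ref, alt, alt_count, denom,
    occurrence_fraction, sample``.
    """
    if min_coverage < 1:
        raise ConfigurationError(f"min_coverage must be >= 1, got {min_coverage}")
    rows = pileup[pileup["depth"] >= min_coverage]
    records = []
    for row in rows.itertuples(index=False):
        ref = row.ref
        counts = {b: getattr(row, b) for b in "ACGT"}
        alt_counts = {b: n for b, n in counts.items() if b != ref and n > 0}
        if not alt_counts:
            continue
        denom = int(row.depth)  # canonical bases + deletions
        if aggregate:
            total_alt = sum(alt_counts.values())
            top = max(alt_counts, key=lambda b: (alt_counts[b], b))
            records.append(
                (row.contig, row.pos0, ref, top, total_alt, denom,
                 total_alt / denom, sample)
            )
        else:
            for alt, n in sorted(alt_counts.items()):
                records.append(
                    (row.contig, row.pos0, ref, alt, int(n), denom, n / denom, sample)
                )
    return pd.DataFrame(records, columns=CATALOG_COLUMNS)


@dataclass
class ThresholdSweepResult:
    """Variant catalogs retained at each occurrence threshold (percent).

    Sets are nested: every variant retained at a higher threshold is also
    retained at every lower one.
    """

    thresholds: tuple[int, ...]
    variants_at: dict[int, pd.DataFrame]

    def keys_at(self, threshold: int) -> set[tuple[str, int, str]]:
        df = self.variants_at[threshold]
        return set(zip(df["contig"], df["pos0"], df["alt"]))

    def positions_at(self, threshold: int) -> set[tuple[str, int]]:
        df = self.variants_at[threshold]
        return set(zip(df["contig"], df["pos0"]))


def threshold_sweep(
    candidates: pd.DataFrame,
    thresholds: tuple[int, ...] | list[int] = DEFAULT_THRESHOLDS,
) -> ThresholdSweepResult:
    """Filter the candidate catalog at each occurrence threshold (percent).

    Retention is inclusive: a record survives threshold ``t`` when its
    occurrence fraction is >= t/100. The resulting sets are checked for
    monotone nesting on every run.
    """
    thresholds = tuple(thresholds)
    if not thresholds:
        raise ConfigurationError("threshold list must be non-empty")
    if any(not 0 < t <= 100 for t in thresholds):
        raise ConfigurationError(f"thresholds must lie in (0, 100]: {thresholds}")
    if list(thresholds) != sorted(set(thresholds)):
        raise ConfigurationError(f"thresholds must be strictly increasing: {thresholds}")
    variants_at = {
        t: candidates[candidates["occurrence_fraction"] >= t / 100].reset_index(drop=True)
        for t in thresholds
    }
    result = ThresholdSweepResult(thresholds, variants_at)
    for lo, hi in zip(thresholds, thresholds[1:]):
        if not result.keys_at(hi) <= result.keys_at(lo):
            raise AssertionError(
                f"threshold nesting violated between {lo}% and {hi}%"
            )  # pragma: no cover - internal consistency check
    return result


def write_threshold_beds(
    sweep: ThresholdSweepResult, out_prefix: str | Path
) -> dict[int, Path]:
    """Emit one single-base BED file per threshold (0-based half-open).

    The name field encodes ``ref>alt|fraction``; an empty threshold bin still
    produces a valid (empty) BED file. Returns threshold -> path.
    """
    out_prefix = Path(out_prefix)
    if out_prefix.parent != Path(""):
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths: dict[int, Path] = {}
    for t in sweep.thresholds:
        path = out_prefix.parent / f"{out_prefix.name}_t{t}.bed"
        df = sweep.variants_at[t].sort_values(["contig", "pos0", "alt"])
        with open(path, "w") as fh:
            for row in df.itertuples(index=False):
                name = f"{row.ref}>{row.alt}|{row.occurrence_fraction:.4f}"
                score = min(1000, int(round(row.occurrence_fraction * 1000)))
                fh.write(f"{row.contig}\t{row.pos0}\t{row.pos0 + 1}\t{name}\t{score}\t+\n")
        paths[t] = path
    return paths


def read_variant_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED written by :func:`write_threshold_beds` back into a catalog.

    Returns columns ``contig, pos0, ref, alt, occurrence_fraction``.
    """
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise InputError(f"malformed BED line: {line!r}")
            contig, start, end, name = fields[:4]
            if int(end) != int(start) + 1:
                raise InputError(f"expected single-base BED interval: {line!r}")
            try:
                change, frac = name.split("|")
                ref, alt = change.split(">")
            except ValueError as exc:
                raise InputError(f"unparseable BED name field: {name!r}") from exc
            records.append((contig, int(start), ref, alt, float(frac)))
    return pd.DataFrame(
        records, columns=["contig", "pos0", "ref", "alt", "occurrence_fraction"]
    )


def write_catalog(catalog: pd.DataFrame, path: str | Path) -> None:
    catalog.to_csv(path, sep="\t", index=False)


def read_catalog(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "ref": str, "alt": str})
    missing = set(CATALOG_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"catalog file missing columns: {sorted(missing)}")
    return df
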