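"""Three-bin classification of flagged variants and multi-sample overlap.

Each flagged variant falls into exactly one of three disjoint bins, applied in
precedence order:

1. ``known_variant`` — the position (or position + allele, per the configured
   match mode) is documented in a supplied variant catalog;
2. ``low_confidence_kmer`` — the reference k-mer context centered on the
   position belongs to the curated low-confidence set;
3. ``novel`` — neither of the above.

The precedence makes the bins disjoint and exhaustive, so their counts always
sum to the catalog total. The overlap table counts, for each sample, how many
of its variants are shared with exactly 0, 1, ..., all of the other samples
(variant identity = contig, position, alternate base).
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import InputError
from .kmers import KmerConfidenceSet, in_low_confidence

BIN_KNOWN = "known_variant"
BIN_LOWCONF = "low_confidence_kmer"
BIN_NOVEL = "novel"
BINS = (BIN_KNOWN, BIN_LOWCONF, BIN_NOVEL)

MATCH_MODES = ("pos-alt", "pos")


@dataclass(frozen=True)
class KnownVariants:
    """A local known-variant resource keyed both ways.

    ``keys`` holds (contig, 0-based position, alt base) triples; ``positions``
    holds (contig, 0-based position) pairs for position-only matching.
    """

    keys: frozenset[tuple[str, int, str]]

    @property
    def positions(self) -> frozenset[tuple[str, int]]:
        return frozenset((c, p) for c, p, _ in self.keys)

    def __len__(self) -> int:
        return len(self.keys)


def load_known_variants(path: str | Path) -> KnownVariants:
    """Load a known-variant file: VCF (1-based) or 3-column TSV.

    The TSV form is ``contig <TAB> 1-based position <TAB> alt base`` with an
    optional header line. Multi-allelic VCF records are split into one key per
    alternate allele; non-SNV alleles are skipped.
    """
    path = Path(path)
    keys: set[tuple[str, int, str]] = set()
    if path.suffix in (".vcf",) or path.name.endswith(".vcf.gz"):
        import pysam

        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                for alt in rec.alts or ():
                    if alt is not None and len(alt) == 1 and alt in "ACGT" \
                            and len(rec.ref or "") == 1:
                        keys.add((rec.chrom, rec.pos - 1, alt))
    else:
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise InputError(f"{path}:{ln}: expected 3 columns, got {len(fields)}")
                contig, pos, alt = fields[0], fields[1], fields[2]
                if ln == 1 and not pos.isdigit():
                    continue  # header line
                if not pos.isdigit():
                    raise InputError(f"{path}:{ln}: non-numeric position {pos!r}")
                if alt not in "ACGT" or len(alt) != 1:
                    raise InputError(f"{path}:{ln}: invalid alt base {alt!r}")
                keys.add((contig, int(pos) - 1, alt))
    return KnownVariants(frozenset(keys))


@dataclass
class ClassifiedCatalog:
    """A variant catalog with a ``bin`` column, plus the context it was made in."""

    records: pd.DataFrame
    sample: str = "sample"
    threshold: int | None = None
    match_mode: str = "pos-alt"

    @property
    def n_total(self) -> int:
        return len(self.records)

    def bin_counts(self) -> dict[str, int]:
        counts = self.records["bin"].value_counts().to_dict()
        return {b: int(counts.get(b, 0)) for b in BINS}

    def keys(self) -> set[tuple[str, int, str]]:
        return set(zip(self.records["contig"], self.records["pos0"], self.records["alt"]))


def classify(
    records: pd.DataFrame,
    known: KnownVariants,
    lowconf: KmerConfidenceSet,
    reference: Mapping[str, str],
    match_mode: str = "pos-alt",
    sample: str = "sample",
    threshold: int | None = None,
) -> ClassifiedCatalog:
    """Assign each variant record to one of the three bins.

    Precedence is known_variant > low_confidence_kmer > novel, which keeps the
    bins disjoint and exhaustive. ``match_mode`` selects the known-variant key:
    ``"pos-alt"`` (contig, position, alt base; default) or ``"pos"`` (position
    only, for catalogs whose alleles may be reported on the opposite strand).
    """
    if match_mode not in MATCH_MODES:
        raise InputError(f"match_mode must be one of {MATCH_MODES}, got {match_mode!r}")
    out = records.copy().reset_index(drop=True)
    bins = []
    for row in out.itertuples(index=False):
        if match_mode == "pos-alt":
            hit = (row.contig, row.pos0, row.alt) in known.keys
        else:
            hit = (row.contig, row.pos0) in known.positions
        if hit:
            bins.append(BIN_KNOWN)
        elif in_low_confidence(reference, row.contig, row.pos0, lowconf):
            bins.append(BIN_LOWCONF)
        else:
            bins.append(BIN_NOVEL)
    out["bin"] = bins
    cat = ClassifiedCatalog(out, sample=sample, threshold=threshold, match_mode=match_mode)
    counts = cat.bin_counts()
    assert sum(counts.values()) == cat.n_total  # partition identity
    return cat


def overlap_table(catalogs: Mapping[str, set] | Sequence[tuple[str, set]]) -> pd.DataFrame:
    """Count variant sharing between samples.

    For each sample, each of its variants is counted once by the number of
    *other* samples that also contain it: column ``unique`` (no others),
    ``in_1_other`` ... and ``in_all`` (every other sample). Rows sum to the
    sample's variant count; the ``in_all`` column is the size of the common
    intersection and therefore identical across rows.

    ``catalogs`` maps sample name to a set of variant keys
    (contig, position, alt); :meth:`ClassifiedCatalog.keys` produces them.
    """
    items = list(catalogs.items()) if isinstance(catalogs, Mapping) else list(catalogs)
    names = [name for name, _ in items]
    if len(names) != len(set(names)):
        raise InputError("duplicate sample names in overlap table input")
    if len(items) < 2:
        raise InputError("overlap table needs at least 2 samples")
    n = len(items)
    sets = {name: set(keys) for name, keys in items}
    columns = ["unique"] + [f"in_{j}_other{'s' if j > 1 else ''}" for j in range(1, n - 1)]
    columns.append("in_all")
    rows = {}
    for name in names:
        hist = [0] * n
        for key in sets[name]:
            shared = sum(1 for other in names if other != name and key in sets[other])
            hist[shared] += 1
        rows[name] = hist
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)


def write_classified(cat: ClassifiedCatalog, path: str | Path) -> None:
    """Write the classified catalog TSV with its context in a comment header."""
    with open(path, "w") as fh:
        fh.write(
            f"#sample={cat.sample}\tthreshold={cat.threshold}\t"
            f"match_mode={cat.match_mode}\n"
        )
        cat.records.to_csv(fh, sep="\t", index=False)


def write_bin_beds(cat: ClassifiedCatalog, out_prefix: str | Path) -> dict[str, Path]:
    """One single-base BED track per bin (0-based half-open)."""
    out_prefix = Path(out_prefix)
    paths = {}
    for b in BINS:
        df = cat.records[cat.records["bin"] == b].sort_values(["contig", "pos0", "alt"])
        path = out_prefix.parent / f"{out_prefix.name}_{b}.bed"
        with open(path, "w") as fh:
            for row in df.itertuples(index=False):
                name = f"{row.ref}>{row.alt}|{row.occurrence_fraction:.4f}"
                fh.write(f"{row.contig}\t{row.pos0}\t{row.pos0 + 1}\t{name}\n")
        paths[b] = path
    return paths
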