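"""Candidate-site decision procedure for RNA-modification analysis.

A position is informative for modification detection when biological DRS
reads mismatch the reference while the unmodified IVT control matches it —
the signature of a systematic miscall induced by a modified nucleotide. The
decision procedure combines, per position:

* ``bio_mismatch`` — the biological sample mismatches the reference at or
  above the chosen occurrence threshold;
* ``ivt_mismatch`` — the IVT catalog contains the position at that threshold;
* ``ivt_covered`` — the IVT control has at least the minimum coverage there.

Verdicts:

* ``exclude`` — the IVT baseline itself mismatches the reference (genomic
  variant, IVT/basecalling artifact, or editing site): excluded regardless of
  category, since no modification inference is safe there.
* ``candidate`` — biological mismatch over a covered, reference-matching IVT
  baseline: nominated for downstream modification analysis.
* ``needs_orthogonal`` — biological mismatch but no usable IVT baseline
  (insufficient coverage); orthogonal evidence such as Sanger sequencing of
  gDNA is required. This verdict is this package's explicit convention for
  the uncovered case.
* ``no_evidence`` — no mismatch on either side; nothing to act on.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .catalog import ThresholdSweepResult
from .errors import ConfigurationError, InputError

VERDICT_CANDIDATE = "candidate"
VERDICT_EXCLUDE = "exclude"
VERDICT_NO_EVIDENCE = "no_evidence"
VERDICT_NEEDS_ORTHOGONAL = "needs_orthogonal"
VERDICTS = (
    VERDICT_CANDIDATE,
    VERDICT_EXCLUDE,
    VERDICT_NO_EVIDENCE,
    VERDICT_NEEDS_ORTHOGONAL,
)


@dataclass(frozen=True)
class SiteState:
    """Observed mismatch/coverage state of one genomic position."""

    contig: str
    position: int  # 0-based
    bio_mismatch: bool
    ivt_mismatch: bool
    ivt_covered: bool

    def __post_init__(self) -> None:
        if self.ivt_mismatch and not self.ivt_covered:
            raise InputError("ivt_mismatch implies ivt_covered")


@dataclass(frozen=True)
class SiteDecision:
    """Verdict for one site, with a short machine-readable reason code."""

    verdict: str
    reason: str


def decide(state: SiteState) -> SiteDecision:
    """Apply the inclusion decision tree to one site.

    Any IVT mismatch at the threshold excludes the position outright,
    regardless of its category. A biological mismatch over a covered,
    matching IVT baseline is a candidate; without IVT coverage the call is
    deferred to orthogonal evidence.
    """
    if state.ivt_mismatch:
        return SiteDecision(VERDICT_EXCLUDE, "ivt_baseline_mismatch")
    if state.bio_mismatch:
        if state.ivt_covered:
            return SiteDecision(VERDICT_CANDIDATE, "bio_mismatch_ivt_matches")
        return SiteDecision(VERDICT_NEEDS_ORTHOGONAL, "no_ivt_coverage")
    return SiteDecision(VERDICT_NO_EVIDENCE, "no_mismatch")


DECISION_COLUMNS = [
    "contig",
    "pos0",
    "verdict",
    "reason",
    "bio_fraction",
    "ivt_fraction",
    "ivt_depth",
]


def apply_decisions(
    bio_catalog: pd.DataFrame,
    ivt_sweep: ThresholdSweepResult,
    ivt_pileup: pd.DataFrame,
    threshold: int,
    min_coverage: int = 10,
    bio_threshold: int | None = None,
) -> pd.DataFrame:
    """Decide every biological-mismatch position against the IVT baseline.

    ``bio_catalog`` is the biological sample's candidate catalog (from
    :func:`ivtkit.catalog.call_candidates`); positions whose maximum
    occurrence fraction is below ``bio_threshold`` percent (default: the IVT
    ``threshold``) are not evaluated. Decisions are per position (any
    alternate base). Returns one row per evaluated position with the verdict,
    reason, and supporting numbers.
    """
    if bio_threshold is None:
        bio_threshold = threshold
    if threshold not in ivt_sweep.thresholds:
        raise ConfigurationError(
            f"threshold {threshold} not in sweep thresholds {ivt_sweep.thresholds}"
        )
    ivt_positions = ivt_sweep.positions_at(threshold)
    ivt_frac_at: dict[tuple[str, int], float] = {}
    for row in ivt_sweep.variants_at[threshold].itertuples(index=False):
        key = (row.contig, row.pos0)
        ivt_frac_at[key] = max(ivt_frac_at.get(key, 0.0), row.occurrence_fraction)
    depth_at = dict(zip(zip(ivt_pileup["contig"], ivt_pileup["pos0"]), ivt_pileup["depth"]))

    rows = []
    if len(bio_catalog) > 0:
        bio_pos = (
            bio_catalog[bio_catalog["occurrence_fraction"] >= bio_threshold / 100]
            .groupby(["contig", "pos0"])["occurrence_fraction"]
            .max()
        )
        for (contig, pos), bio_frac in bio_pos.items():
            key = (contig, pos)
            depth = int(depth_at.get(key, 0))
            state = SiteState(
                contig=contig,
                position=pos,
                bio_mismatch=True,
                ivt_mismatch=key in ivt_positions,
                ivt_covered=depth >= min_coverage or key in ivt_positions,
            )
            d = decide(state)
            rows.append(
                (contig, pos, d.verdict, d.reason, float(bio_frac),
                 ivt_frac_at.get(key, 0.0), depth)
            )
    table = pd.DataFrame(rows, columns=DECISION_COLUMNS)
    if len(table):
        table = table.sort_values(["contig", "pos0"], ignore_index=True)
    return table


def write_candidate_bed(decisions: pd.DataFrame, path: str | Path) -> None:
    """BED track (0-based half-open) of candidate-verdict sites only."""
    cand = decisions[decisions["verdict"] == VERDICT_CANDIDATE]
    with open(path, "w") as fh:
        for row in cand.itertuples(index=False):
            name = f"candidate|bio={row.bio_fraction:.4f}"
            fh.write(f"{row.contig}\t{row.pos0}\t{row.pos0 + 1}\t{name}\n")


def verdict_counts(decisions: pd.DataFrame) -> dict[str, int]:
    counts = decisions["verdict"].value_counts().to_dict() if len(decisions) else {}
    return {v: int(counts.get(v, 0)) for v in VERDICTS}
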