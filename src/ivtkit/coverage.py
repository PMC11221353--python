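"""Gene coverage, round-robin saturation curves, and naive TPM correlation.

These operations quantify how well an IVT control represents the genes of a
biological sample: the fraction of a gene universe covered at increasing
read-count cutoffs, rarefaction-style saturation of one sample's gene set by
reads subsampled from the others ("round robin"), and the squared Pearson
correlation of length-normalized abundances (TPM) between paired samples.

The TPM here is deliberately naive — primary-alignment counts divided by
effective length and rescaled to one million — rather than an EM-based
multi-mapping estimator; it is meant for coarse abundance comparison between
paired samples, not isoform quantification.
"""

from __future__ import annotations

import logging
from collections import Counter
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError, InsufficientDataError

logger = logging.getLogger(__name__)


def gene_read_counts(gene_labels: Sequence[str] | Mapping[str, str]) -> Counter:
    """Tally reads per gene from per-read gene labels (or a read->gene mapping)."""
    labels = gene_labels.values() if isinstance(gene_labels, Mapping) else gene_labels
    return Counter(labels)


def coverage_vs_cutoff(
    counts: Mapping[str, int],
    universe: set[str],
    cutoffs: Sequence[int],
) -> pd.DataFrame:
    """Fraction of a gene universe with at least ``cutoff`` reads, per cutoff.

    Genes counted but absent from the universe are ignored (their number is
    logged); fractions are non-increasing in the cutoff.
    """
    if not universe:
        raise ConfigurationError("gene universe must be non-empty")
    cutoffs = list(cutoffs)
    if cutoffs != sorted(set(cutoffs)) or any(c < 1 for c in cutoffs):
        raise ConfigurationError(f"cutoffs must be strictly increasing, >= 1: {cutoffs}")
    outside = [g for g in counts if g not in universe]
    if outside:
        logger.info("%d counted genes outside the universe ignored", len(outside))
    in_universe = np.array([counts.get(g, 0) for g in universe])
    rows = [(c, float((in_universe >= c).sum() / len(universe))) for c in cutoffs]
    return pd.DataFrame(rows, columns=["cutoff", "fraction"])


@dataclass
class SaturationCurve:
    """Mean covered-gene proportion vs reads drawn from the population."""

    target: str
    sample_sizes: np.ndarray  # combined reads drawn across the population
    mean_proportion: np.ndarray
    sd_proportion: np.ndarray
    n_repeats: int
    score: str  # "intersection" or "union"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "combined_reads": self.sample_sizes,
                "mean_proportion": self.mean_proportion,
                "sd_proportion": self.sd_proportion,
            }
        )


def _subsample(rng: np.random.Generator, labels: np.ndarray, size: int) -> np.ndarray:
    if size >= len(labels):
        return labels
    idx = rng.choice(len(labels), size=size, replace=False)
    return labels[idx]


def saturation_curve(
    target_reads: Sequence[str],
    population_reads: Mapping[str, Sequence[str]],
    target_draw: int = 1_000_000,
    step: int = 100_000,
    max_combined: int | None = None,
    repeats: int = 100,
    seed: int | None = None,
    score: str = "intersection",
    target_name: str = "target",
) -> SaturationCurve:
    """Round-robin gene saturation of one target sample by the others.

    The target gene set comes from a single draw of ``target_draw`` reads from
    the target sample (all reads, with a warning, if it has fewer). Then at
    each combined size ``k * step`` (up to ``max_combined``, default
    ``len(population) * target_draw``), ``k * step / n_population`` reads are
    drawn without replacement from each population sample, the union of their
    gene sets is formed, and the curve scores

    * ``"intersection"`` (default): |population genes ∩ target genes| /
      |target genes| — a proportion in [0, 1];
    * ``"union"``: |population genes ∪ target genes| / |target genes| — the
      literal union-over-target ratio, >= 1 once the population adds any gene.

    Draws are repeated ``repeats`` times and averaged; the curve starts at 0
    reads with proportion 0 (intersection mode).
    """
    if repeats < 1:
        raise ConfigurationError("repeats must be >= 1")
    if score not in ("intersection", "union"):
        raise ConfigurationError(f"score must be 'intersection' or 'union': {score!r}")
    if not population_reads:
        raise InputError("population must contain at least one sample")
    rng = np.random.default_rng(seed)

    target_arr = np.asarray(list(target_reads), dtype=object)
    if len(target_arr) < target_draw:
        logger.warning(
            "target has %d reads < requested draw %d; using all",
            len(target_arr), target_draw,
        )
    target_genes = set(_subsample(rng, target_arr, target_draw))
    if not target_genes:
        raise InputError("target gene set is empty")

    pop = {s: np.asarray(list(v), dtype=object) for s, v in population_reads.items()}
    n_pop = len(pop)
    for s, arr in pop.items():
        if len(arr) < step:
            logger.warning("population sample %s has %d reads < step %d", s, len(arr), step)
    if max_combined is None:
        max_combined = n_pop * target_draw
    sizes = np.arange(0, max_combined + 1, step)

    props = np.zeros((repeats, len(sizes)))
    for r in range(repeats):
        for i, size in enumerate(sizes):
            if size == 0:
                genes: set[str] = set()
            else:
                per = int(round(size / n_pop))
                genes = set()
                for arr in pop.values():
                    genes.update(_subsample(rng, arr, per))
            if score == "intersection":
                props[r, i] = len(genes & target_genes) / len(target_genes)
            else:
                props[r, i] = len(genes | target_genes) / len(target_genes)
    return SaturationCurve(
        target=target_name,
        sample_sizes=sizes,
        mean_proportion=props.mean(axis=0),
        sd_proportion=props.std(axis=0, ddof=0),
        n_repeats=repeats,
        score=score,
    )


def round_robin(
    samples: Mapping[str, Sequence[str]], **kwargs
) -> dict[str, SaturationCurve]:
    """One saturation curve per sample, each in turn acting as the target."""
    curves = {}
    for target in samples:
        population = {s: v for s, v in samples.items() if s != target}
        curves[target] = saturation_curve(
            samples[target], population, target_name=target, **kwargs
        )
    return curves


def naive_tpm(
    counts: Mapping[str, int], lengths: Mapping[str, float]
) -> dict[str, float]:
    """Length-normalized abundance: TPM_i = (c_i / L_i) / sum_j (c_j / L_j) * 1e6.

    Every counted transcript needs a positive effective length; the returned
    values sum to one million up to floating-point rounding.
    """
    missing = [t for t in counts if t not in lengths or lengths[t] <= 0]
    if missing:
        raise InputError(f"missing or non-positive length for: {missing[:5]}")
    total = sum(counts.values())
    if total == 0:
        raise InputError("zero total read count")
    rates = {t: c / lengths[t] for t, c in counts.items()}
    denom = sum(rates.values())
    return {t: r / denom * 1e6 for t, r in rates.items()}


def tpm_correlation(
    tpm_a: Mapping[str, float],
    tpm_b: Mapping[str, float],
    log_transform: bool = True,
) -> tuple[float, int]:
    """Squared Pearson correlation over transcripts present in both samples.

    With ``log_transform`` the correlation is computed on log10(TPM + 1),
    the usual scale for abundance scatter plots. Returns (r^2, n shared).
    """
    shared = sorted(set(tpm_a) & set(tpm_b))
    if len(shared) < 3:
        raise InsufficientDataError(
            f"only {len(shared)} shared transcripts; need at least 3"
        )
    a = np.array([tpm_a[t] for t in shared], dtype=float)
    b = np.array([tpm_b[t] for t in shared], dtype=float)
    if log_transform:
        a = np.log10(a + 1.0)
        b = np.log10(b + 1.0)
    r = stats.pearsonr(a, b).statistic
    return float(r**2), len(shared)
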