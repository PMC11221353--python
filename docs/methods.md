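# Methods

This note documents the models and conventions behind `ivtkit`: what each
stage computes, the parameters that matter, what the synthetic-data generator
does and does not emulate, and the design choices made where more than one
reasonable convention exists.

## Pileup and pooling

A pileup row records, for one reference position, the number of primary
alignments calling A, C, G, T, or a deletion there; `depth` is their sum.
Primary means not unmapped, not secondary (SAM flag 256), not supplementary
(flag 2048) — the standard `samtools view -F 4 -F 256 -F 2048` filter.
Insertions occupy no reference coordinate and are ignored; counting is
strand-unaware on the reference forward strand (DRS reads are sense-strand).
No mapping- or base-quality filter is applied at this stage: the only read
quality control assumed is the basecaller's own Q ≥ 7 pass filter upstream.

Pooling sums pileups position-wise after checking that all inputs agree on
the reference base; merging is associative and commutative, and pooled depth
dominates every single-sample depth. Pooling several IVT cell lines buys gene
and positional coverage at the cost of cell-line specificity — a variant
present in any contributing line enters the pooled catalog.

Coordinates are 0-based half-open everywhere internally and in BED/TSV
output; human-oriented strings such as `chr2:117817639` are 1-based.

## Mismatch catalog and threshold sweep

A position is cataloged when `depth ≥ min_coverage` (default 10) and at
least one called nucleotide differs from the reference. The **occurrence
fraction** of an alternate base is its count divided by the number of
canonical bases **plus deletions** at the location — deletions dilute every
substitution but are never emitted as variants themselves. One record is
produced per (position, alternate base); an aggregate mode (one record per
position, combined non-reference fraction) exists behind a flag for
sensitivity analysis, since public mismatch counts do not always state which
convention they use.

The sweep filters the catalog at 30/40/50/60/70/80/95 % by default.
Comparison is inclusive (`fraction ≥ t/100`): a variant at exactly 30 %
survives the 30 % filter. Sets at increasing thresholds are nested by
construction, and this invariant is asserted on every run. The coverage floor
can be applied per sample or to the pooled pileup, whichever dataset is being
cataloged.

## Low-confidence k-mer curation

Basecallers are systematically less confident in some sequence contexts, and
mismatches there are more likely noise than signal. The profile maps each
reference 9-mer (k configurable, odd) to the mean phred quality of read bases
aligned to its **center** position, accumulated over a biological DRS sample
— biological, not IVT, because the curated set must reflect the contexts a
modification analysis will encounter. A window mode averaging qualities
across all k aligned positions is available (`mode="window"`); center-base is
the default because variant positions are classified by their centered
context. Profiles are keyed by reference k-mers, so membership is stable
across samples, and the quartile is computed over k-mer **types**, each
counted once.

The lowest-quartile rule: the cutoff is the largest observed mean quality
whose empirical CDF over types is ≤ 0.25, and every k-mer with mean ≤ cutoff
is selected. With all-distinct means this selects the lowest quarter exactly.
Ties at the boundary are never split: when even the smallest mean carries
more than a quarter of the mass (two-level quality data with a large low
class, or all means identical) the entire minimum-value class is selected.
This convention keeps the selection aligned with the intuitive reading of
"lowest quartile" on strongly discrete quality data, where an
interpolated or nearest-rank percentile would land on the high-quality value
and degenerate to selecting everything.

Positions within ⌊k/2⌋ bases of a contig edge have no full context; they are
logged and treated as not-low-confidence.

## Three-bin classification and overlap

Each flagged variant is assigned exactly one bin with precedence
**known variant > low-confidence k-mer > novel**. The precedence is what
makes the bins disjoint and exhaustive, so
`n_known + n_lowconf + n_novel = n_total` always holds and is asserted.
Known-variant matching defaults to (contig, position, alt); a position-only
mode exists because public catalogs sometimes report alleles on the opposite
strand. VCF input (1-based, multi-allelics split, non-SNVs skipped) and
3-column TSV are both accepted; the match mode is recorded in output
metadata.

The overlap table counts each of a sample's variants once, by how many
*other* samples contain it (identity = contig, position, alt). Rows sum to
each sample's catalog size, and the "in all" column is the one shared
intersection, hence constant across rows.

## Coverage, saturation, and TPM

`coverage_vs_cutoff` reports the fraction of a caller-supplied gene universe
with at least c reads, for increasing c; it is non-increasing in c by
construction. The universe is explicit because "all genes" can mean the
annotation's protein-coding set, the observed set, or anything between.

The round-robin saturation curve asks how well the other samples' reads
reconstruct one target sample's gene set. The target gene set comes from a
single draw of `target_draw` reads; then, at each combined size (0 to
`max_combined` in steps of `step`), an equal number of reads is drawn without
replacement from each population sample, their gene sets are unioned, and the
score is |population genes ∩ target genes| / |target genes|, averaged over
`repeats` independent repetitions (default 100; recorded in the result).
The intersection-over-target score is the default because it is a proportion
in [0, 1] that converges to the attainable asymptote; the literal
union-over-target ratio (≥ 1 whenever the population contributes any gene
outside the target set) is available as `score="union"` for auditability.
Samples smaller than a requested draw contribute all their reads, with a
warning.

`naive_tpm` is deliberately simple: primary-alignment counts divided by
effective length, normalized to 10⁶. It is *not* an EM-based multi-mapping
abundance estimator and is intended for coarse abundance comparison between
paired samples, where it is adequate; `tpm_correlation` reports the squared
Pearson correlation over shared transcripts, by default on log10(TPM + 1),
the scale on which abundance scatter is usually judged.

## Site decision

Per position, three booleans: biological mismatch at ≥ the biological
occurrence threshold, IVT mismatch at ≥ the IVT threshold, and IVT coverage
≥ the minimum. Verdicts:

| state | verdict |
|---|---|
| IVT mismatch (any category) | `exclude` |
| bio mismatch, IVT covered and matching | `candidate` |
| bio mismatch, IVT not covered | `needs_orthogonal` |
| no mismatch on either side | `no_evidence` |

Exclusion on any IVT mismatch is deliberate: whether the underlying cause is
a genomic variant, an IVT/RT/PCR artifact or a context error, the position
cannot support a clean modification comparison. `needs_orthogonal` encodes
the manual follow-up (e.g. Sanger sequencing of gDNA from the same sample) as
an explicit verdict rather than attempting automatic resolution; it is this
package's convention for the no-baseline case, and a position with neither
mismatch is reported as `no_evidence` even when IVT coverage is absent, since
there is nothing to defer. Decisions are per position (any alternate base).
The biological threshold defaults to the IVT threshold but is independently
settable — raising only the IVT threshold removes exclusions and therefore
never decreases the candidate count, which is tested.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes,
pre-aligned (the pipeline begins after alignment, so reads are emitted with
perfect coordinates, substitutions only, plus an optional deletion rate to
exercise the deletion-aware denominator):

* **Genomic SNVs** appear in both IVT and biological reads, each read
  independently carrying the alternate base with the allele fraction.
* **IVT artifacts** appear only in IVT-mode reads (fraction 1.0 — a
  template-level change propagated through amplification).
* **Modification sites** appear only in biological-mode reads, each read
  miscalling with the configured rate.
* **Background errors** hit every other position independently, alternate
  base uniform over the three non-reference bases. Truth positions are
  shielded from background error and deletion so injected rates are exact.
* **Base qualities** are two-level: the low phred value whenever the
  reference 9-mer centered at the base belongs to the designated low-quality
  set, the high value otherwise.
* **Gene abundance** follows a Zipf-like law over a study-level random rank
  order (the expression profile belongs to the simulated cell line and is
  shared by all of its samples), with a per-sample lognormal jitter modeling
  library-prep variability such as RT-PCR amplification bias in the IVT arm.
  Each read carries its gene in the SAM `GN` tag and a read-to-gene TSV.

One RNG stream per sample, seeded `seed + sample_index`, so adding a sample
never perturbs the others; all outputs are byte-reproducible for a fixed
configuration.

Default study conditions (chosen once as a desk-scale caricature of a DRS
experiment): 2 contigs × 20 kb, 40 genes, Zipf exponent 1.2, abundance jitter
σ = 0.4, 4 000 reads/sample of mean length 400 (≈ 40× mean coverage,
strongly skewed across genes), background substitution rate 3 % (the
substitution component of ~90 % alignment identity typical of DRS),
modification miscall rate 0.4, SNV allele fraction 1.0, 12 SNVs / 8 IVT
artifacts / 8 modification sites / 30 low-quality 9-mers, qualities Q25/Q7
(the basecaller pass floor).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no signal-level (ionic current) structure, no
splicing or isoforms, no alignment errors or soft-clipping, no indel errors
beyond uniform deletions, no strand effects, no context-dependent
substitution spectrum, no quality miscalibration beyond the two-level 9-mer
scheme, and modification miscalls are independent across reads rather than
clustered by molecule. Results on synthetic data demonstrate the *counting,
thresholding and decision logic*, not basecaller or aligner behavior.

## Numerical and degenerate-input conventions

* Threshold comparison inclusive; thresholds validated as strictly
  increasing in (0, 100].
* Deletions counted in every denominator, never emitted as variants.
* Empty threshold bins still produce valid (empty) BED files.
* Reads with non-ACGT base calls contribute depth only at positions where
  their call is canonical.
* `merge_pileups` raises on conflicting reference bases; unknown contigs and
  missing qualities raise input errors rather than being skipped.
* TPM requires positive lengths and a positive total count;
  `tpm_correlation` requires ≥ 3 shared transcripts.
* The saturation curve's size-0 point is exactly 0 (intersection mode).

## Scaling of the bundled analyses

The test suite and the acceptance script run the pipeline on desk-scale
studies (thousands of reads against kilobase contigs, saturation with
thousands of labels and tens of repeats). These sizes are the package's
chosen demonstration scale; all operations are linear in aligned bases (or
in reads × curve points for saturation) and run unchanged on full-size
BAM/FASTA inputs.

## Known limitations

* The pileup engine does no realignment, indel left-alignment, or BAQ; it
  trusts the aligner's CIGAR.
* The naive TPM ignores multi-mapping ambiguity entirely (primary alignment
  only) and will diverge from EM-based estimators on paralog-rich gene sets.
* The window quality mode skips k-mer occurrences whose window spans an
  alignment gap, slightly biasing window-mode profiles toward gapless
  regions.
* The low-confidence set is only as good as the biological sample it is
  profiled from; sets built from shallow samples under-cover rare contexts.
* With `match_mode="pos"` a known variant masks any alternate base at that
  position, which is conservative for modification discovery.
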