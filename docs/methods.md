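# Methods

## Translation calling from P-site periodicity

A candidate ORF is every AUG…in-frame-stop pair wholly inside a transcript,
enumerated on the spliced sequence in all three frames. ORFs sharing a stop
codon are collapsed to the 5′-most AUG by default (`longest_per_stop`),
since periodicity evidence cannot distinguish nested same-stop starts.
Positions with non-ACGT characters are masked and ORFs spanning them are
dropped with a warning.

For one ORF and one sample, the per-codon P-site counts over the full span
`[start, end)` (stop codon included) are split into frames
`(f0, f1, f2)`. Codons with any signal are *informative*. The test statistic
is the one-sided Wilcoxon signed-rank on the paired differences
`f0 − max(f1, f2)`, zero differences dropped. Taking the off-frame
**maximum** rather than the mean makes the null conservative: under
frame-uniform noise the expected difference is negative. p-values are
Benjamini–Hochberg corrected across all ORFs within a sample and an ORF is
called at adjusted p < α (default 0.05). Minimum evidence of 5 informative
codons and 10 in-frame P-sites prevents 2-aa ORFs from being called on a
single read. An ORF is retained if called in ≥ 1 sample; supporting samples
and the minimum adjusted p are recorded.

Numerical choice: `scipy.stats.wilcoxon` is invoked with an explicit method
— exact for ≤ 25 untied differences, otherwise the normal approximation
with continuity correction. The library's automatic selection falls back to
a per-call permutation test in the tied small-n regime, which is two orders
of magnitude slower with no change in the calls at these sample sizes.

## Positional classification

Classification is a total function of the ORF interval and the transcript's
CDS interval (transcript coordinates, 0-based half-open, both spans
including the stop codon), evaluated in a fixed decision order: no CDS →
`novel`; bounds equal to the CDS → `annotated`; entirely upstream /
downstream → `uORF` / `dORF`; straddling the 5′ CDS boundary →
`Overlap_uORF`; straddling the 3′ boundary → `Overlap_dORF`; nested inside
the CDS in a shifted frame → `Internal`. Two deliberate resolutions where
the taxonomy is silent:

* an ORF spanning the entire CDS is `Overlap_uORF` (upstream start takes
  precedence);
* a same-frame ORF nested in the CDS is labelled `inframe_nested` and
  excluded from the seven-class output — it is indistinguishable from the
  main ORF by periodicity.

Upstream/downstream is measured on the ORF's own transcript; with multiple
transcripts per gene an ORF is classified per transcript.

An sORF is an ORF whose peptide is 2–100 aa, i.e. CDS 6–300 nt excluding
the stop codon. The inclusive 2-aa and 100-aa bounds follow the peptide
definition; a nucleotide-range phrasing ("3–300 nt") that cannot encode
2 aa is not used.

## Quantification

RPKM/FPKM use the literal formula `count · 10⁹ / (total · length)` with the
per-sample column totals of the supplied count table as the default
denominator. Feature length for an sORF is its CDS length in nt **including
the stop codon** (documented constant; the choice cancels in every contrast
because it is applied uniformly). TE is computed only where both assays pass
`min_expr = 0.5`; samples missing one assay (the generator supports dropped
libraries) contribute no TE records. Shannon entropy is computed across all
samples by default, matching how the tissue-specificity comparison is run;
a `collapse_replicates` flag averages replicates to tissues first, exposing
the per-tissue variant of the formula. All-zero expression vectors have
undefined entropy and propagate as NaN, excluded from contrasts.

## MS verification

Digestion is fully tryptic — cleave after K or R except before P — via
pyteomics with that explicit rule (no Keil WKP/MRP exceptions), default 2
missed cleavages and reportable peptides of 7–50 aa, common search-engine
defaults. Uniqueness is assessed against the sORF and canonical proteomes
**combined**: a peptide shared with any other entry evidences nothing. The
canonical proteome is the set of annotated proteins longer than 100 aa —
annotated-class sORFs are themselves part of the sORF database, and
re-listing them as canonical entries would veto their own evidence.
Isoleucine/leucine are distinct by default (`merge_il` flag to merge).
Monoisotopic masses are residue sums plus one water (pyteomics mass model).

## Downstream statistics

* Sequence context: ±5 bp around start and stop codons as 13-column base
  frequency matrices; positions outside the transcript are masked and drop
  out of that column's denominator. Two sets are contrasted per position by
  chi-square on the 4×2 count table, BH-corrected across positions.
* Rank-sum contrasts: Mann–Whitney U, exact when nA+nB ≤ 12 without ties,
  otherwise the normal approximation with tie and continuity corrections.
* Clustering: agglomerative, Euclidean distance on row-standardized
  log₂(FPKM+1), complete linkage — recorded as configuration (flags disable
  the log transform and the standardization) since only a plotting
  routine's defaults stand behind the original choice. scipy's linkage is
  deterministic on identical input; zero-variance features are dropped with
  a warning.
* Parent-gene correlation: Pearson r with permutation p
  `(1 + #{|r_perm| ≥ |r|}) / (1 + N)`, default N = 10,000 (consistent with
  p < 1e-4 granularity), seeded.
* Proportions: `100 · count / total` rounded to 2 decimals (1-decimal
  variant flag).

## The synthetic generator

`synthio` emulates the study design, not the sequencing process: P-site
tracks are emitted directly as position→count tables (no reads, no
alignment, no contaminant RNA), and RNA counts are fragments per transcript
— exactly the inputs the downstream formulas consume. Defaults are the
study conditions: 6 tissues × 2 replicates, 70 planted translated sORFs
(10 per class), frame-0 share (`periodicity_strength`) 0.9, coverage 30
reads/codon.

Transcripts are single-exon (splicing adds no statistical structure the
analysis tests; the caller's projection machinery handles multi-exon
models), randomly stranded, and laid out on 2 chromosomes; a
`telomere_bias` parameter draws transcript positions from a U-shaped Beta
to emulate end-of-chromosome enrichment. Each planted sORF is constructed
by rejection sampling so that it starts with ATG, ends at its first
in-frame stop, is maximal for that stop (so longest-per-stop collapsing
recovers its exact coordinates), and—for overlap and internal classes—
coexists with a valid host CDS in a shifted frame.

Noise model: independent Poisson counts per codon with multinomial frame
allocation `(ps, (1−ps)/2, (1−ps)/2)` inside translated ORFs; untranslated
positions receive frame-uniform background at `background_rate` (default
0). Expression is lognormal across tissues (σ = 0.8) with small replicate
noise (σ = 0.1), so replicates co-cluster while tissues separate. A
configurable fraction of planted sORFs (default 0.3) is translated in
exactly one tissue. sORF ribosome occupancy carries a 2× boost
(`sorf_te_boost`), reproducing the observed higher translation efficiency.
Per-class peptide-length ranges (annotated 50–100 aa, novel 3–12 aa, others
intermediate) reproduce the observed class length ordering, which in turn
drives the validation-rate ordering through the MS model.

MS detection is logistic:
`P(detect) = expit(β₀ + β_abund · log₂(abundance+1) + β_len · length)` with
defaults β₀ = −4, β_abund = 0.3, β_len = 0.04 — chosen once to give an
overall validation rate near the reported ~29% under default abundances
while staying well below saturation so both covariate effects remain
visible. Detected ORFs contribute 1–3 distinct reportable tryptic peptides;
an ORF whose digest has no 7–50 aa fragment can never be detected, which is
itself part of the length bias. Where neither the study design nor the
analysis fixes a value (library depth 50 fragments/kb, UTR lengths
150–400 nt, canonical CDS 120–280 aa), values were chosen once as realistic
for a plant transcriptome and are plain config fields.

What passing tests do and do not show: the generator has no sequencing
error, no multi-mapping, no isoform ambiguity, no P-site offset
miscalibration, and its noise is exactly the model the caller assumes, so
recovery rates here are an upper bound on real-data performance; the tests
demonstrate correctness of the statistics and bookkeeping, not robustness
to violated assumptions.

## Determinism

One seed fixes every stochastic choice: the generator derives independent
substreams for genome construction, tracks, and the MS table; permutation
tests and the acceptance script seed all their RNGs from the given seed.
Identical config + seed gives byte-identical output files.

## Problem sizes

Tests and the acceptance script run the generator at the defaults above
(95 transcripts, ~500k P-site rows), a 200-ORF frame-uniform null for
false-call control, a 600-ORF detection-bias experiment, exhaustive
classifier/oracle enumeration on transcripts of length ≤ 60 (~284k interval
pairs), and exhaustive rank-sum enumeration for pooled sizes ≤ 10.

## Known limitations

* AUG starts only; near-cognate starts are out of scope by design.
* No isoform deconvolution or multi-mapping resolution: counts are taken as
  given, and features are quantified per transcript.
* Spectral-level MS scoring (mass tolerances, FDR, score cutoffs) is out of
  scope; the peptide table is trusted input.
* The periodicity test treats codons as independent; run-length structure
  in real elongation (pausing, stacking) is not modelled.
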