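# Methods

`cmmltools` re-implements, as a tested library, the bespoke computational
procedures used in serial multi-omic studies of chronic myelomonocytic
leukaemia (CMML) under hypomethylating-agent therapy: tumour–normal somatic
filter cascades, mutation-spectrum and signature analysis, cross-patient
hotspot detection, serial VAF clonal tracking, and tile-based differential
methylation. This note documents the models, the defaults and why they hold,
the numerical choices, and what the synthetic generators do and do not show.

## Somatic filter cascades

Two cascades mirror the two sequencing designs.

**Exome-style (single caller).** A candidate call is somatic when its
caller somatic p-value is strictly below 1e-4 — relaxed to 1e-3 when the
sample's mean coverage is under 100× or the CD3⁺ control contamination
exceeds 15% — and the tumour-minus-normal VAF difference is at least 15%.
Annotation-based drops follow: dbSNP members, intergenic/intronic/UTR/ncRNA
variants, synonymous SNVs. The serial-sample *presence* rule is VAF ≥ 4%
(boundary inclusive). Comparison operators are applied exactly as each rule
is conventionally phrased: strict `<` for the p-value ("below"), inclusive
`≥` elsewhere; boundary cases are rare and the asymmetry is deliberate.

**Genome-style (three-caller consensus).** Depth/support minima (≥15× normal,
≥6× tumour, ≥3 alt reads), one caller-specific score rule each
(SomaticSniper score ≥ 30; VarScan2 somatic p ≤ 0.01; Strelka QSS/QSI ≥ 15),
FILTER-flag exclusions (SNVs: SpanDel/BCNoise/DP; indels:
OVERLAP/Repeat/iHpol/BCNoise/DP), VAF difference ≥ 20% and normal VAF < 15%.
A score absent from a record skips that rule rather than failing it —
callers do not all emit every field, and absence is not evidence. Region
masks (low-complexity, immunoglobulin loci, blacklisted genes) remove a
variant when its left-aligned anchor base falls inside any mask interval;
per-mask removal fractions are reported. Consensus is the **union** of
per-caller passing variants keyed by (chrom, pos, ref, alt) and tagged with
the supporting caller set; `require_callers=N` switches to an intersection.
Union is the default because per-caller totals differ and tagging preserves
the information needed to tighten later.

Every rejection carries exactly one reason — the first failing rule — so
per-reason counts telescope to the total removed.

## Spectrum and signatures

Substitutions are reported with the pyrimidine of the mutated base pair as
reference (six classes); trinucleotide contexts are read from the reference
plus strand and reverse-complemented when the reference base is a purine,
giving the conventional 96 channels ordered class-major, then 5′, then 3′
base. With gene models the matrix doubles to 192 channels by whether the
pyrimidine lies on the transcribed (template) or untranscribed (coding)
strand; variants outside genes or inside genes annotated on both strands are
tallied as discarded rather than guessed.

Signature extraction factorises the channel × sample count matrix V ≈ WH by
multiplicative updates minimising generalised Kullback–Leibler divergence,
with signature columns normalised to probability vectors. Defaults: random
uniform initialisation from the seeded generator, 10 restarts per fit (best
KL kept), up to 400 iterations with a 1e-6 relative tolerance. Stability is
assessed by multinomial bootstrap of each sample's counts: each replicate is
refactorised, its signatures paired to the base solution by greedy
best-pair-first cosine matching (optimal assignment available via
`hungarian=True`), and per-signature reproducibility is the mean silhouette
under cosine distance (cohesion to the base signature when k = 1). The
selected rank maximises mean reproducibility; ranks within 0.02 of the
maximum resolve to the smallest, a parsimony preference standing in for a
formal reconstruction-error elbow. A correctness check in the test suite
verifies the factorisation reaches a KL objective on par with scikit-learn's
`NMF(beta_loss="kullback-leibler")` on the same data; the library solver is
never used in the pipeline itself.

Transcriptional strand bias is an exact two-sided binomial test of
transcribed vs untranscribed counts per channel against 0.5, BH-corrected
across channels.

## Hotspots and the uniform-placement null

A hotspot is a single-linkage chain of variants on one chromosome with
adjacent distances ≤ 250 bp (so a chain's total span may exceed 250 bp),
carrying ≥ 2 variants from ≥ 2 distinct patients. `mode="span"` instead
emits greedy left-to-right groups of total span < 250 bp; both semantics are
tested. Distances are measured between left-aligned anchor positions.

The analytic null places N variants independently and uniformly into W
exchangeable 250-bp windows (default W = 6.82 × 10⁶, the non-repeat window
count of a masked human genome). Exact per-window probabilities are
reported for ≥ 1 variant, ≥ 2 variants, and ≥ 2 variants from ≥ 2 distinct
patients (by inclusion–exclusion over per-patient counts, an equal split by
default), together with the genome-wide expectation W·p and the family-wise
probability. These quantities differ by orders of magnitude and are all
reported rather than collapsed into a single "hotspot p-value"; edge effects
at mask boundaries are ignored (windows are treated as exchangeable cells).
An empirical null (`simulate_null_clusters`) throws the observed per-patient
counts uniformly over the unmasked genome and re-runs the cluster caller,
yielding a count distribution and an add-one-corrected empirical p.

The regulatory census builds strand-aware promoter windows (−2,000/+200 bp
around each gene's anchor — the anchor may be a transcription or translation
start; the caller decides which populates the gene model) and counts
enhancer hits; an enhancer hit is *active* only when the interval's
annotated activity is ≥ 5% in **all** requested tissues (blood and monocytes
by default).

## Serial dynamics and mutation allele burden

Per patient, the variant universe is the union of somatic-passing variants
over all timepoints; counts are looked up at every timepoint, with variants
absent from a timepoint's calls assigned zero alt reads at that timepoint's
median depth so losses remain countable. Presence follows the 4% rule;
trajectories classify as stable (present throughout), acquired(at t)
(absent at all earlier timepoints, present from t on), lost(at t), or
fluctuating. Reversing time maps acquired ↔ lost by construction. A
per-variant Fisher exact test on (alt, ref) counts between consecutive
timepoints, BH-corrected per patient, is this package's formal addition to
the otherwise descriptive classification and is labelled as such.

Clone grouping partitions trajectories by presence bitmask, then splits a
group when a member deviates from the group's mean trajectory by more than
10 VAF points at any timepoint **and** the deviation exceeds three binomial
standard errors at that member's local depth. The noise floor is essential:
at 100× depth the pairwise trajectory noise is ≈ 7 VAF points, and a bare
10-point rule fragments homogeneous clones, biasing everything downstream.
Splitting is recursive and two-sided around the mean (so retained-member
means stay unbiased under pure noise), with a bisection fallback when two
well-separated clones straddle the mean; a final merge pass recombines
clusters whose mean trajectories agree within the threshold at every
timepoint. The founder is the full-presence group with the highest
first-timepoint mean VAF among groups of non-negligible size (at least half
the largest full-presence group) — tiny groups are late noise split-offs or
minor clones, never the founding clone.

The mutated-allele-burden verdict takes last-minus-first VAF over founder
variants and asks whether the 95% CI of the mean, bootstrapping over
variants, contains zero. The **studentized bootstrap** (bootstrap-t, 2,000
resamples) is used rather than the plain percentile interval: a founder
clone typically carries 5–20 variants with depth-dependent heavy-tailed
noise, where the percentile interval covers ≈ 92% and studentizing restores
≈ 95%. Under a pure-noise null at 100× depth the "unchanged" verdict is
attained in ≈ 95% of simulated patients; fewer than two founder variants
flags the verdict low-confidence.

## Tile-based differential methylation

25-bp fixed-grid tiles are kept when coverage lies in [10, 500] in **both**
samples. Each tile is tested with a two-sided Fisher exact test on
(methylated, unmethylated) × (t1, t2) pooled counts; with single patients at
two timepoints there is no within-group replication from which to estimate a
beta-binomial dispersion, so the pooled-count exact test replaces a
dispersion-aware likelihood-ratio test (a different per-tile test can be
injected via `call_dmrs(test=...)`). A DMR requires |Δ| ≥ 25% and BH q
strictly < 0.10 over all tested tiles; swapping timepoint labels negates
every delta, preserves p-values, and maps gains ↔ losses exactly.

DMR gene annotation applies three ordered rules: (i) genes whose body
overlaps the tile by any bp; else (ii) all genes within a 50-kb window; else
(iii) the gene with the nearest TSS. Context enrichment compares DMR vs
non-DMR tiles in vs out of each region set with a 2×2 Fisher test (odds
ratio < 1 = depletion), BH across contexts.

## Integration with expression

Differential-expression lists are inputs (their upstream GLM fitting is out
of scope). The module computes exact Venn overlaps between uppercased DMR
gene symbols and up/down DE sets (no alias resolution — determinism over
recall), and pairwise 2×2 χ² tests without continuity correction of DE
proportions between arms over a shared tested-gene universe (24,563 genes by
default). Two arms with zero DE genes compare as χ² = 0, p = 1. Pairwise
tests (not a 3×2 omnibus) match the claim being made — that every pair of
arms differs.

## Synthetic generators

`simulate_cohort` fabricates both sequencing arms on a miniature genome
(default five 10-Mb contigs of seeded random sequence; tests and the
acceptance script use two 1-Mb contigs, which preserves every per-variant
statistic while keeping runtimes in seconds) with 45% of 50-kb blocks
masked. The exome arm draws 49 patients with truncated-normal(14, 5²)
coding-mutation counts clipped to [4, 23], 73.3% transitions, consequence
labels tuned so 75.7% of all coding variants are nonsynonymous, a founder
clone at fraction 0.9 plus 0–3 subclones (fractions uniform in [0.1, 0.9],
each acquired at a later timepoint with probability 0.3, else present
throughout), negative-binomial depths (mean 100, shape 10) and
Binomial(depth, clone-fraction/2) read counts under the heterozygous
diploid assumption — no copy-number events. Germline contaminants with
matched tumour/normal VAFs near 0.5 are planted alongside. The genome arm
draws 17 patients with uniform [27, 854] clonal variant counts (6.3%
indels, 66.3% transitions) thrown uniformly over the whole miniature genome
(so masking removes ≈ 45% of them), each reported by all three callers with
passing-range scores; planted hotspots place k patients' variants within a
given width at an unmasked locus. Every generator emits a truth table;
recovery tests read truth, never re-derive it.

`simulate_methylome` draws baseline tile methylation from a hypo/mid/hyper
beta mixture, plants true DMRs (responder profile: 5% of tiles, 90% losses,
|Δ| uniform in [0.25, 0.6], baselines re-drawn so the full change fits in
[0, 1]; stable profile: 1% small symmetric changes; untreated: none) and
emits Binomial(coverage, fraction) counts at negative-binomial coverages
(mean 60).

`simulate_context_mixture` builds channel count matrices from known
signatures with log-normal exposures (σ = 1.0 — real cohorts vary widely in
process activity, and near-constant exposure ratios make a mixture
unidentifiable for any factorisation) and multinomial counts.

**What passing these tests does not show.** The generators are exchangeable
and diploid: no copy-number alteration, no purity drift, no mappability or
GC structure, no correlated error modes between callers, no spatial
autocorrelation of methylation, and coding variants are placed uniformly
rather than in exons. Recovery on this synthetic structure demonstrates the
procedures implement their definitions; it does not certify performance on
real sequencing artefacts.

## Problem sizes

Defaults used by the test suite and `scripts/acceptance.py`: two 1–5 Mb
contigs, 49 + 17 synthetic patients, 4,000-tile methylomes, 120-patient
burden calibration, 10-bootstrap signature extraction on 12 samples, and
300-replicate Monte-Carlo null checks — sizes chosen so every statistic's
sampling error is well below its test tolerance.
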