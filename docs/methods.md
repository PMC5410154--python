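# Methods

## The problem and the model

Snake venom is a mixture of secreted toxin proteins whose relative
expression in the venom gland changes with age in many species. The
analysis here asks which individual toxin loci drive that ontogenetic
shift, given venom-gland RNA-seq from adult/juvenile pairs collected in
several populations with known geographic expression differences.

Expression in transcripts per million is compositional — each sample's
values sum to one million by construction, so only ratios carry
information. All expression comparisons therefore operate on the
centered log-ratio transform,

    clr_i(x) = ln x_i − (1/D) Σ_j ln x_j ,

computed per sample over all D transcripts supplied (toxins plus the
nontoxin background together, whenever both are available; on a
toxin-only table the transform is taken over toxins alone and results
must be read as toxin-relative). Zeros are floored at 1.0 TPM first so
logarithms exist; only exact zeros are touched.

### The outlier test and the consensus rule

For each population's adult/juvenile pair, the per-transcript difference
Δ_i = clr_i(adult) − clr_i(juvenile) is computed. Toxin expression is
under selection and cannot supply its own null, but the thousands of
nontoxin (housekeeping) transcripts can: the empirical 99th percentile of
|Δ| over nontoxins defines the pair's outlier threshold. A toxin is
flagged up (down) in that pair when Δ is strictly greater than the
threshold (strictly less than its negation). The percentile uses linear
interpolation between order statistics (the common type-7 definition;
configurable). A degenerate null — a non-positive threshold, which can
only arise when >99% of nontoxin differences are exactly zero — raises an
error rather than flagging everything.

A single pair cannot distinguish ontogeny from geography. The consensus
rule requires a toxin to be an outlier in at least 3 of the 5 population
pairs with at least 3 agreeing on direction; direction counts use only
the pairs where the toxin was an outlier, so n_up + n_down = n_outlier.
Flags and thresholds rescale identically under a change of logarithm
base, so calls are base-invariant (tested). Consensus calls may be
intersected with external differential-expression detections (DESeq and
DESeq2 adjusted p < 0.1, consumed as flag tables, never re-run):
"confirmed" means called by the consensus rule and detected by at least
one external method.

### Assembly

The assembler is a deliberately minimal greedy seed-extender for merged
(single-sequence) reads. Only reads whose every base has phred ≥ 30 are
used. A read extends a contig end when it overlaps that end exactly —
over at least 120 nt, with the entire overlap matching — and continues
beyond it; both orientations are considered. The long exact overlap is
the paralog-separation mechanism: toxin families carry many near-identical
gene copies, and at ~2% divergence a 120-nt window almost always contains
a diagnostic site, so reads from a sister paralog simply never match.
When candidate reads disagree beyond the overlap, each extended position
takes the majority base among still-consistent candidates; an exact vote
tie stops extension at that end and flags the contig instead of
fabricating a chimera. Contigs identical to or contained in longer ones
(either strand) are removed, and contigs supported by fewer than 200
exactly-mapping reads are discarded. Canonical (id-sorted) read ordering
makes output independent of input file order.

Paralog separation is only well-posed where the paralogs actually differ:
if two copies share an identity corridor of ≥ 120 nt, reads inside it are
literally identical and no assembler could assign them. The simulation
tests state this precondition explicitly and use paralog draws in which
every 120-nt window is diagnostic.

### Consensus transcriptome

Pairwise divergence is the p-distance of a global alignment (match +1,
mismatch −1, gap −2): mismatched plus gapped columns divided by alignment
length, with IUPAC ambiguity codes matching any compatible base.
Clustering is single linkage — sequences are linked at divergence ≤ t and
clusters are connected components — because the thresholds describe a
connectivity criterion; complete linkage is available behind a flag. The
two-stage procedure clusters within individuals at t = 0.01, then the
per-cluster consensus sequences across individuals at t = 0.015, which
operationally defines paralogs. Cluster consensus is the column-majority
over members aligned pairwise to the longest member, ties becoming IUPAC
codes; insertions relative to the reference are dropped, so consensus
length never exceeds the longest member. Chimeric assemblies are screened
by coverage shape: the transcript is dropped when the ratio of median
depths in adjacent 100-nt windows reaches 5 anywhere (both medians ≥ 1),
and the step position is reported.

### Presence/absence

Reads are aligned end-to-end against the consensus transcripts (edit
distance, infix mode, both strands) and discarded when the best alignment
has more than 2 mismatches counting gaps and substitutions. A read tying
across k references contributes depth 1/k to each (random single
assignment available), so near-identical paralogs are not artificially
emptied; a read matching both strands of one reference counts once. A
transcript is absent when the fraction of positions with depth < 5
exceeds 0.10 — both inequalities strict, so uniform depth exactly 5, or
exactly 10% low, is still present. The strictness approximates "could
this transcript have been assembled de novo from this sample", not "is it
expressed". Read-count equalization across samples is uniform subsampling
without replacement under a recorded seed. Group summaries use a
two-sided Welch t-test (unequal variances, Welch–Satterthwaite df) on
adult vs juvenile missing counts.

### LD50

The Spearman-Karber estimator integrates the empirical tolerance
distribution on log10 dose. With ascending log-doses x_i at constant
spacing d and mortality proportions p_i, the classical form is
x_max + d/2 − d Σ p_i; the implementation uses the equivalent trapezoid
integral over the completed series (p = 0 one dilution below the lowest
dose, p = 1 one above the highest), which also covers unequal spacing.
Completion beyond observed mortality is an extrapolation and attaches an
explicit warning. The standard error of log10 LD50 is
√(Σ p_i(1−p_i)/(n_i−1) · d²), defined when every group has more than one
animal. The estimator is untrimmed by default (trim 0–10% available) and
exactly scale-equivariant. Non-monotone mortality can optionally be
pooled by isotonic regression (PAVA, group-size weights) before
estimation; off by default.

## Synthetic data: what it emulates and what it does not

The expression generator draws a per-transcript baseline log-abundance
(Normal, mean 3, sd 2 on the natural-log scale — spanning the ~6 orders
of magnitude seen in venom-gland TPM), adds a shared population effect
(sd 0.5) per population, and gives each adult column a per-transcript
difference drawn N(0, log_noise_sd) plus any planted log-fold-change.
Columns are renormalized to one million TPM, so planted and null effects
interact exactly as they would in real compositional data. Defaults
follow the study design: 5 populations × (1 adult + 1 juvenile), 59
toxins, 2,000 nontoxins, pair noise sd 0.4 natural-log units. The noise
sd is a free parameter — no empirical dispersion for nontoxin
adult/juvenile differences is published — and a Student-t option
(configurable df, variance-matched) exists to probe the percentile null's
robustness to heavy tails. A truth table always accompanies planted
effects so recovery tests never re-derive ground truth from outputs.

Reads are sampled uniformly along each transcript with fragment starts
clamped at the termini, reproducing the boundary pileup of real
fragmentation and giving uniform expected coverage right to the ends
(without this, exact end-to-end assembly would be unattainable at
moderate depth). Reads are error-free with uniform phred 40 by default;
substitution errors are opt-in. No indels, no paired-end structure (the
pipeline operates on merged reads), no GC or fragment-length bias.
Paralog families are independent substitution draws from a shared random
ancestor, so pairwise divergence is ~2× the per-lineage rate,
binomially distributed. Dose-response tables are binomial deaths under a
logistic tolerance curve on log10 dose; the default design is a two-fold
series of 5 doses centered on the true LD50 (top dose 12, LD50 3 mg/kg,
slope 4 per log10 unit, 8 animals per group), the standard way such
assays are ranged. Passing tests on these generators demonstrates the
machinery is correct under the stated statistical structure; it does not
validate robustness to real-data pathologies (mapping bias, expression-
dependent dispersion, batch effects) that the generators do not model.

Every generator is a pure function of its spec including the seed; one
global seed fans out to per-component streams via CRC-hashed spawn keys,
so adding a generator never perturbs existing streams.

## Numerical and design choices

* Percentile definition, clr basis, linkage criterion, multimapper
  policy, chimera window/ratio, and SK trimming are all exposed as
  parameters with the defaults above.
* Extension tie-breaks: majority per position among consistent
  candidates; exact ties stop and flag. Deduplication and clustering
  apply canonical sorts before processing, making every stage
  order-invariant and byte-reproducible (manifest-verified in the CLI).
* Degenerate inputs error loudly: empty expression files, all-zero
  counts for TPM, zero outlier thresholds, LD50 with mortality never
  crossing 50%, seeds shorter than the overlap.
* Problem sizes in the test suite (1,000-nt transcripts, 8–20
  transcripts for mapping, 100 recovery seeds, 1,000 simulated dose
  tables) were chosen as the smallest scales at which the statistical
  assertions are stable.

## Known limitations

* The internal mapper is exhaustive over references (no FM-index); it is
  meant for consensus transcriptomes of tens of sequences, not genomes.
* The consensus sequence is reference-anchored (longest member), not a
  full multiple alignment; for highly gappy families a true MSA would
  differ.
* The published per-dose mortality counts behind the reported adult and
  juvenile LD50s are not available, so those two numbers serve as context
  only; the estimator is validated analytically and by simulation.
* Summing the published toxin-TPM table per individual does not reproduce
  the published mean total SVMP figures (the averaging basis there is not
  recoverable); a summation utility is provided but those figures are not
  asserted anywhere.
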