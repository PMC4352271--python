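# Methods

This note documents the models, conventions, defaults and numerical
choices behind `exindel`, and what the synthetic data does and does not
show about real exome INDEL calling.

## Coordinates and normalization

All records use the VCF anchored convention internally: `pos` is the
1-based coordinate of the anchor base preceding the event, both alleles
include the anchor, exactly one allele has length 1, and |length| < 100
bp. BED input is 0-based half-open and converted at the I/O boundary.
Sequence comparison is case-insensitive; pipeline outputs are
restricted to autosomes.

**Left alignment** iterates the rotation rule: an event with sequence
*S* anchored at *P* is equivalent to one anchored at *P−1* with
sequence `ref[P] + S[:-1]` whenever `ref[P] == S[-1]`. Iteration stops
at the contig start, at an `N` (ambiguity is handled conservatively:
the representation is left as-is), or after `max_shift` steps (default
300 bp — far beyond the <100 bp allele limit, so a bounded cost rather
than a behavioral limit). The operation is idempotent and preserves the
alternate haplotype; both properties are fuzz-tested against a
brute-force enumeration oracle.

**Complex-event splitting** trims equal bases from both ends of a
ref/alt pair, aligns the remaining cores from their right edge, emits
mismatching aligned bases as SNP components and the length difference
as one pure INDEL anchored at the base preceding the cores. Anchoring
the INDEL at the left edge (rather than after a left-aligned SNP block)
makes decomposition commute with left alignment, so records reach the
same matching key regardless of how a caller chose to join adjacent
events. Both decomposition conventions reconstruct the identical
alternate haplotype; the choice only fixes which of several valid
simple-INDEL representations is canonical. SNP components are discarded
downstream: the pipeline is INDEL-only, and carrying caller-specific
SNP fragments through an INDEL consensus would conflate two different
error processes.

**Matching keys.** Two normalized records denote the same allele iff
`(chrom, pos, ref, alt)` are equal. Multi-allelic lines are decomposed
into one record per alternate allele before any processing, because
consensus scoring operates on alleles, not sites.

## Union and quality normalization

Caller quality scores live on incomparable scales, so each caller's
qualities are rank-transformed to the empirical CDF in (0, 1] (ties
share the mean rank; a missing quality is flagged and assigned 0.5, the
median prior). The union annotation averages the ECDF values over
supporting callers only. Rank normalization rather than z-scoring: the
score distributions are heavy-tailed and a monotone transform is all
the downstream forest can use anyway.

Target-region filtering tests the anchor base as a point. This is
deterministic, matches the position-based comparison used for in-silico
matching, and avoids edge ambiguity for deletions straddling an
interval boundary.

## Consensus model

Six covariates per union allele: `n_callers`, `norm_qual_mean`,
`site_depth` (mean depth over carrier samples), `variant_read_ratio`
(aggregate alt reads / aggregate depth over carriers),
`homopolymer_run` (longest single-base run in the ±10 bp reference
context — the dominant INDEL artifact mode), and `abs_length`. The
classifier is a 500-tree random forest (scikit-learn defaults
otherwise) with a fixed, recorded seed; the reported probability is the
fraction of trees voting "true". Determinism was favored over
hyperparameter tuning: the operating point is set by the probability
cutoff, not by squeezing the forest.

Training labels come from key overlap with a truth call set. Because a
forest memorizes its training rows, the pipeline trains on a random
50% of the union (emulating a truth standard that covers only part of
the data, as an orthogonal platform would) and scores all alleles.
Alleles with probability **≥ 0.4** are kept — the boundary value is
retained, only strictly smaller probabilities are excluded.

**Regenotyping** assigns each (site, sample) the maximum-likelihood
genotype under `alt_reads ~ Binomial(depth, p)` with `p = ε` (0/0),
`0.5` (0/1), `1 − ε` (1/1), flat prior, `ε = 0.02`. Zero depth yields a
missing genotype. Sites where no sample retains a non-reference call
are pruned. Any calibrated binomial genotyper satisfies the same
contract; this one is chosen for transparency.

## CCC classification

`smallest_motif` returns the shortest prefix that tiles the allele
sequence an integer number of times; a sequence with no proper tiling
is its own motif (copy count 1), and a single adjacent reference copy
then still qualifies as CCC (copy count 1→2 or 2→1). The classifier
compares the `len(motif)` reference bases immediately left and right
of the event with the motif; either side matching ⇒ CCC. An `N` inside
the inspected context yields NCCC with an `ambiguous` flag.

Adjacency is tested on **both** sides even though left-aligned records
make the right side canonical: the symmetric rule is robust to
representation and costs one extra string comparison. The verdict is
defined on the left-aligned representation — phase-shifted encodings of
the same haplotype can flip the motif (e.g. deleting `AC` vs `CA` from
a `CACA` run), which is why classification is part of the normalized
pipeline, not a standalone record predicate.

The random control draws signed lengths i.i.d. from an empirical
histogram, places events uniformly in the target intervals (deletions
re-placed if they would cross an interval edge), takes deletion
sequences from the reference and insertion sequences i.i.d. uniform
over {A,C,G,T}. Uniform insertions give a clean analytic null — for
1-bp insertions the CCC rate is 1 − (3/4)² = 7/16 — at the cost of not
matching reference base composition; a GC-matched variant would shift
the null slightly but is not needed for the enrichment argument.

## Population statistics

All per-individual statistics are computed per individual and then
averaged. Density = calls / (region bp / 10⁶); the analyzed region
defaults to the full target size (per-sample callable-region BED masks
are supported as an option, but depth masks are data-dependent plumbing
the synthetic pipeline does not model). The 7 allele-frequency bins use
edges {0.1%, 0.5%, 1%, 5%, 10%, 50%} on (0, 1], left-open right-closed;
they are logarithmic-ish and every reporting threshold used elsewhere
(<1% rare, 1–10%, ≥10%) is a union of whole bins, so stratified
densities always sum to the total. MAF comparisons use the two-sided
Wilcoxon rank-sum test (normal approximation with tie correction;
exact enumeration for tiny tie-free samples). In the pipeline summary
"rare" means AAF ≤ 1%: with the default 50 samples (2N = 100)
singletons sit exactly at 1%, and a strict inequality would make the
statistic vacuous at this cohort size.

## Validation rules

Positional matching: same chromosome, exact same signed length, anchors
within 30 bp (5 bp for 1-bp INDELs). Status classification, with the
1-bp thresholds in parentheses: FAILED on design failure or fewer than
20 covering reads; CONFIRMED at variant-read ratio ≥ 20% (40%) **and**
mean base quality ≥ 10 (20); FALSE_POSITIVE at ratio < 3% (5%);
AMBIGUOUS otherwise — including sites that meet the confirmation ratio
but miss the quality floor, since the false-positive rule is stated
purely in terms of the ratio. `FDR = FP/(TP+FP)` over conclusive sites;
`S_consensus = TP_consensus/TP_union`; detectable INDELs
`= TP_union + (AMBG_consensus + FAIL_consensus)·(1 − S_consensus)`,
with an optional variant that additionally discounts the inconclusive
sites by (1 − consensus FDR) for users who prefer that reading of the
estimator. Site selection for validation stratifies by AF bin
(largest-remainder apportionment) so the assessed sample preserves the
union's frequency profile, then draws up to 5 carrier samples per site.

## Synthetic study conditions

Defaults (all overridable in `SimulationConfig`): 1 Mb reference on one
autosome; 6 repeat tracts/kb (homopolymers and 2–4 bp motifs, 6–30 bp
long, ≥20 bp apart); 400 bp target intervals covering 50% of the
contig; 50 samples; 2,000 true INDELs; signed-length histogram heavy at
±1 bp, enriched at multiples of 3, deletions ~1.6× insertions; planted
CCC fraction 0.60; site-frequency spectrum `P(count = c) ∝ c^−1.9`
(rare-skewed; most sites are singletons at this cohort size); read
depth Poisson(60) with error rate 0.02.

Three callers with sensitivities 0.90/0.85/0.80 and 820 false calls per
target Mb each, 30% of them drawn from a shared cross-caller artifact
pool (so some false alleles carry multi-caller support), false calls
3×-enriched in repeat tracts and dominated by ±1–2 bp events; true-call
qualities ~N(50, 12) vs false ~N(32, 12); 25% of true records emitted
right-shifted and 10% as complex events to exercise normalization.
These rates were chosen by expected-count arithmetic so the union
operates at ~35% false alleles — the regime in which a consensus step
is worth building. Validation evidence: Poisson(100) reads, 1% error,
5% design failures.

Sizes are what a laptop CPU handles in seconds while leaving every
statistic with usable precision (≈3,100-allele unions, 800 validated
sites); the full test suite runs in about half a minute.

## What the synthetic data does not show

The generator reproduces the *structure* of a multi-caller exome study
(representation heterogeneity, repeat-biased false calls, shared
artifacts, rare-skewed frequencies, validation read counts) but not the
*noise correlations* of real data: covariates are drawn from clean
parametric families, so the consensus forest separates true from false
alleles almost perfectly (consensus FDR ≈ 0, retention ≈ 1 under the
defaults). Real callers' quality scores, depths and allele balances are
mutually correlated and contaminated in ways that leave a consensus
FDR of several percent and a sensitivity cost of ~10–15%. Passing
tests here demonstrate correctness of the machinery and the direction
and bounds of the trade-off (consensus FDR strictly below union FDR at
≥70% retention), not field performance. Likewise the truth standard is
exact by construction; `truth_dropout` can degrade it, but no attempt
is made to model platform-specific truth biases. Read-level artifacts
(mapping, local realignment) are emulated only as representation
shifts, and the length histogram is a study condition, not an estimate
of human INDEL mutagenesis.

## Known limitations

- Structural variants (≥100 bp) and SNP calling are out of scope.
- Complex/disrupted repeats are not modeled as a third class: an
  insertion whose underlying repeat structure was broken by a SNP
  classifies as NCCC.
- The in-silico confirmation/rediscovery machinery assumes both call
  sets are restricted to shared samples and regions before comparison.
- `estimate_fdr` treats AMBIGUOUS and FAILED sites as uninformative;
  if ambiguity correlates with being a true positive (it mildly does —
  marginal-ratio hets), the FDR is very slightly overestimated.
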