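# Methods

## Coordinates and genotype coding

Positions are 1-based inclusive base pairs; the length of a run or tract is
`end_bp − start_bp` (the detectRUNS "to − from" convention), used everywhere
including the FROH numerator and the length-class bins.  Genotypes are held
as a dense samples × SNPs matrix over four states (HOM_A, HET, HOM_B,
MISSING).  On PED input, A is the lexicographically smaller allele observed
at the SNP (as in PLINK's data-derived A1/A2); detection only distinguishes
homozygous/heterozygous/missing, so the A/B labelling affects no result.  A
consequence worth knowing: a SNP at which only one allele is observed cannot
retain its A/B label through a PED write→read cycle; after the MAF filter
(which guarantees both alleles are seen) round-trips are exact.

## Quality control

SNP filters run in a fixed order: (1) drop non-autosomal SNPs (autosome
labels default to BTA 1–29), (2) drop SNPs with missing fraction above 5%,
(3) drop SNPs with minor allele frequency below 1%, computed from allele
counts over non-missing calls; a SNP with no non-missing calls has
undefined MAF and is dropped.  Each SNP is counted against the first filter
that removes it, so the attrition report balances exactly.  Samples are
never dropped.  Whether the thresholds are applied jointly or sequentially
is immaterial to which SNPs survive (the filters are independent
per-SNP predicates); the order only affects attrition bookkeeping.

## Consecutive-runs detection

Per sample and chromosome, a left-to-right scan grows a candidate run and
closes it when admitting the next SNP would exceed the heterozygous budget
(`max_het`, 0–2) or missing budget (`max_missing`, 0–4), when the gap to the
next SNP exceeds `max_gap_bp` (1 Mb default), or at the chromosome end.
Closed candidates are emitted iff they span ≥ `min_snp` SNPs (15 or 20) and
≥ `min_length_bp` (250 kb).  Missing calls count toward `n_snp` and
`max_missing`, never toward `n_het`.

The restart rule after a budget closure is not part of the published
parameter ledgers of the common callers, so it is fixed here by two
requirements: reported runs must be disjoint (FROH must not double-count),
and a single bad call must not shadow a downstream run.  After an *emitted*
closure the scan resumes just past the violating call.  After a *dropped*
closure (candidate failed the SNP-count or length filter) the scan
backtracks to just past the candidate's first tolerated het/missing call:
the dropped candidate reported nothing, so no overlap is at stake, and
freeing the budget there lets a longer passing run that the candidate had
swallowed be found.  Gap and chromosome-end closures never backtrack —
every sub-candidate is a subset and the filters are monotone in extent, so
nothing recoverable is lost.  With both budgets at zero the output is
provably the set of maximal all-homozygous stretches passing the filters,
which is what the brute-force oracle in the test suite enumerates.

Under this rule, the base-pair union of reported runs is non-decreasing in
either budget on all tested panels.  We note for completeness that *strict*
per-base monotonicity is not achievable by any detector with disjoint
output: raising the budget can bridge two runs across a het and then close
one SNP differently, uncovering the odd single-SNP sliver.  No such case
arises under the study conditions exercised here.

## Sliding-window detection

Each SNP's *support* is the fraction of `window_snp`-sized windows covering
it (slid one SNP at a time) that contain at most `window_max_het` HET and
`window_max_missing` MISSING calls; edge SNPs are normalised by their own
coverage (PLINK edge semantics), and a chromosome shorter than one window
has support 0 everywhere.  SNPs with support ≥ `window_threshold` (0.05)
are marked; maximal marked stretches are split at gaps > `max_gap_bp` and
emitted iff they pass `min_snp`, `min_length_bp`, and the density bound
`length_bp / n_snp ≤ max_bp_per_snp`.  Splitting precedes the length
filter.  All threshold comparisons are ≥.

Window callers are ambiguous about whether the het/missing allowance is per
window or per segment; this implementation budgets per window, and a HET
(resp. MISSING) *call* can sit inside a reported run only when the
corresponding window budget is positive — at budget zero a heterozygote can
never be inside a run, matching the strict reading of a run as a homozygous
sequence.

Two named presets bundle the standard parameterizations, differing only in
the density bound: `sliding-15`/`sliding-20` (detectRUNS-style, 1 SNP per
1 Mb) and `plink-paper` (PLINK-style, 1 SNP per 60 kb, window 20,
threshold 0.05).

## Downstream statistics

* **FROH** — summed run length over the autosome denominator, default
  2,508,706,681 bp (the mapped-autosome total of the emulated panel); a
  `from-map` mode sums per-chromosome mapped extents instead, needed for
  toy genomes.  Overlapping input segments raise an error rather than being
  merged silently — they indicate a caller bug.
* **Length classes** — left-closed bins [1,2), [2,4), [4,8), [8,16),
  [16,∞) Mb.  Runs in [250 kb, 1 Mb) are tallied in an explicit `<1Mb` bin
  but excluded from the five-class relative frequencies, since the minimum
  run length sits below the smallest tabulated class; the boundary
  convention (2.0 Mb → 2–4 Mb) is declared here because published tables
  never state it.
* **Chromosome ranking** — score = (share of all ROH on the chromosome) /
  (share of genome length); rank 1 is the largest score, ties broken by
  chromosome number.  The length-weighted mean of scores is exactly 1, an
  algebraic identity the tests enforce to 1e−12.
* **Herd summaries** — mean and SE = sd/√n (n−1 denominator); pairwise
  Welch two-sided t-tests with Welch–Satterthwaite df, chosen over the
  pooled-variance form because herd variances routinely differ.  No
  multiple-testing correction is applied, matching how such pairwise herd
  comparisons are conventionally reported; singleton herds get no SE and
  join no test.  A `exclude=` argument recomputes summaries without named
  animals (the leave-one-out probe for single extreme animals).
* **Sensitivity sweep** — the detector is fully re-run per cell of the
  het (0–2) × missing (0–4) grid, recording mean ROH count and mean FROH
  per sample.
* **Method agreement** — Spearman rank correlation (scipy, average ranks
  for ties, two-sided t-approximation p-value) between chromosome rankings;
  a perfect correlation reports the approximation's own floor, not an
  invented p.

## Synthetic panels

The generator emulates a medium-density bovine array study: 29 autosomes in
real BTA proportions rescaled to sum exactly to the 2,508,706,681 bp
denominator; a jittered grid of SNPs at 52 kb mean spacing (≈48k markers
genome-wide); per-SNP allele frequencies uniform on [0.05, 0.5]; background
genotypes drawn per SNP from Hardy–Weinberg proportions.  Autozygosity is
planted per animal as Poisson(55) tracts with log-uniform lengths on
[250 kb, 20 Mb] (mean ≈ 4.5 Mb), placed uniformly, overlaps merged so the
truth is canonical; every spanned SNP is set homozygous (allele drawn by
its frequency) before noise.  These defaults put mean planted autozygosity
near 0.10 of the genome, the FROH level typical of intensively selected
Holstein herds, and the default 0.5% missingness keeps the total genotyping
rate above 0.99.  Genotyping error renders a call HET (the only miscall
mode a run detector can see; hom→hom miscalls are invisible and not
modelled), then missingness is applied per call.

RNG streams are split per (seed, stage, sample), so one seed is
bit-reproducible and adding samples never perturbs earlier ones.

What the simulator does *not* model: linkage disequilibrium between
markers, realistic allele-frequency spectra, pedigree or coalescent
structure, herd differentiation (herds differ only by label unless
configured otherwise), and clustered missingness.  Passing recovery tests
therefore demonstrate the correctness of the detection and summary
machinery on panels of realistic scale and noise, not calibration of FROH
against any real population.  One visible consequence: with uniform
per-call missingness, SNPs carrying a few missing calls survive QC, so the
missing-call allowance has a small residual effect on simulated panels,
whereas array studies with clustered missingness concentrated in
QC-removed SNPs report none.

## Scoring detection against truth

A truth tract is matched when a called segment on the same sample and
chromosome has reciprocal overlap ≥ a threshold (default 0.5); precision is
the fraction of called segments matched to any tract; boundary error is the
mean of |start difference| + |end difference| over best matches; undefined
ratios are reported as absent, never 0/0.

A planted boundary is not directly observable: the tract's edge falls
between SNPs, and flanking background homozygotes extend the visible run
beyond it (expected overshoot ≈ (1−h)/h inter-SNP gaps per side for
background het fraction h), so raw boundary error against the planted
interval is dominated by this legitimate extension for *any* correct
detector.  `extend_tracts_to_homozygous_span` therefore snaps each tract to
its maximal containing run of homozygous calls — the most the genotype data
can say about it — and detector boundary accuracy is assessed against that
observable extent.  On error-free panels both detectors reproduce it
exactly.

## Problem sizes in the shipped tests and acceptance script

Oracle-equivalence checks use 1,000 random chromosomes of ≤ 60 SNPs;
planted-tract recovery uses 200 samples on five 40 Mb chromosomes at 52 kb
spacing with 1–16 Mb tracts (≈3.8k SNPs, ≈900 well-spanned tracts); the
simulated herd study runs 60 animals in six herds on the full ≈48k-SNP
genome.  These sizes give stable statistics (binomial tolerances in the
tests are 3 SE at the stated draws) while a complete run of the suite and
the acceptance script stays under a minute each on one core.
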