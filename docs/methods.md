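# Methods

This note documents the statistical model behind each stage, the synthetic
data the package generates to exercise them, and the numerical and design
choices that were genuinely open.

## Study design being modeled

A paired two-tissue factorial design: 22 females, each contributing one
maturing oocyte and one 24-h egg sample, split across four groups formed by
season of release (early/late) × maternal body condition (control/poor),
with per-tissue group sizes 6/4/6/6 and two field cages.  mRNA counts cover
~12,770 genes; the small-RNA arm yields ~75 curated miRNA loci (72 unique
mature sequences: three pairs of loci share a mature sequence at disjoint
genomic locations and are deliberately kept separate).  Oocyte and egg
samples are always analyzed separately; the driver refuses mixed-tissue
differential-expression designs.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions above.

**Count model.** Gene *g* in sample *s* has log₂ relative abundance
x_gs = μ_g + λ_g f_{m(g)}(s) + Δ_g(s), where μ_g ~ N(2, 3²) is a gene-wise
log-normal baseline, λ_g ~ N(1, 0.2²) a module loading, f_m the latent
factor (eigengene) of the gene's module, and Δ_g a planted
differential-expression offset.  Per-sample proportions
p_gs = 2^{x_gs}/Σ_g 2^{x_gs} are scaled by a library size that is
log-normal per tissue (log₂ mean 21.0 for oocytes, 21.5 for eggs, sd 0.25)
plus a female-level intercept (sd 0.10 log₂ units) shared by the paired
oocyte/egg samples, and counts are negative-binomial with common dispersion
0.05 (gamma–Poisson mixture) — a standard bulk-RNA-seq emulation consistent
with the TMM/CPM assumptions downstream.  The baseline spread (sd 3.0 log₂
units) was set so that the CPM filter retains roughly two-thirds to
three-quarters of genes at the full 12,770-gene scale, the regime the
pipeline is designed for.

**Planted modules.** Five modules of sizes 80/65/50/45/30.  Latent factors
are built on mutually orthogonal noise vectors, also orthogonal to the
season coding; a season-coupled module's factor is
f = r·z_season + √(1−r²)·ε, so its realized sample correlation with season
is exactly r.  Defaults couple modules 1–4 to season at r = 0.6, 0.5, 0.45,
0.45 (module 5 uncoupled), in oocytes only.  Orthogonalization is a
deliberate design choice: with only 22 samples, independent random factors
correlate at |r| ≈ 0.5 by chance alarmingly often, which genuinely fuses
two planted modules and makes the ground-truth partition unidentifiable —
the planted truth would then be wrong, not the detector.

**Cross-tissue map.** In the egg partition, 60% of the genes of oocyte
modules 2–4 are re-assigned together into egg module 1, planting the
convergence of several season-linked oocyte modules into one large egg
module; the remaining genes keep their labels (egg modules 2–4 consequently
drop below the 30-gene detection floor, which is intended: egg module
structure is dominated by the big module).

**Planted differential expression.** 30 up- and 20 down-regulated genes
(log₂FC ±2) on the season contrast in oocytes, drawn from *expressed*
background genes (baseline μ above the median): differential signal planted
below the detection floor is unobservable by construction and would only
blur the recovery contract.  Eggs receive no planted effects, mirroring the
design's expectation that maternal signatures vanish past the
maternal-to-zygotic transition.

**miRNA records, hit tables, target tables.** The miRNA generator emits per
sample × precursor records with genomic intervals, mature/star read counts,
randfold p, and rRNA/tRNA flags; 20% of loci are planted as two overlapping
precursors that must merge, 4% share a mature sequence at disjoint
locations (75 loci vs 72 unique matures), and 40% extra decoy precursors
fail exactly one quality filter.  The similarity-hit generator plants
mutual-best pairs with e-values ≤ 10⁻¹⁰ and decoys that always score worse
than a query's true hit (orphan queries' decoys point only at
ortholog-bearing targets, so no spurious reciprocal pair can form).  The
target-table generator plants a known consensus set plus single-predictor
and weak-p distractors.

All randomness flows from one integer seed through independently spawned
streams per table, so regenerating one table never perturbs another.

**What the generator does not emulate.** Sequence-level realism (no reads,
no quality scores, no mapping ambiguity), gene-length effects, GC bias,
batch effects beyond cage/female intercepts, gene-wise dispersion trends,
and correlated DE/module membership.  Passing tests therefore demonstrate
the statistics are implemented correctly and calibrated under a faithful
count model — not that the pipeline is robust to artifacts of real
sequencing data.

## Normalization

`filter_by_expression` re-specifies the standard CPM rule: keep a feature
iff CPM ≥ min_count/median(library)·10⁶ in at least *k* samples (*k* = the
smallest group size) and total count ≥ min_total; defaults min_count = 10,
min_total = 15.  TMM uses the published estimator: reference = the sample
whose upper-quartile CPM is closest to the mean upper-quartile (ties to the
first in input order), double rank-trimming of M (30% each side) and A (5%
each side), inverse-variance weights from the asymptotic binomial variance
(1−p)/(np) summed over both samples, and factors rescaled to geometric
mean 1.  Note a consequence of those weights: scaling one sample's counts
by a constant leaves M and A unchanged but not the reference sample's
variance term, so factors (and hence CPM) are invariant to depth only to
within ~1–2%, not exactly.  log-CPM uses a prior count of 0.5 with the
effective library inflated by twice the prior.

## Differential expression

Per-feature weighted least squares under ~0 + group with contrasts
season = (lateControl+latePoor)/2 − (earlyControl+earlyPoor)/2, condition
analogously, and interaction = (latePoor−lateControl) −
(earlyPoor−earlyControl).  Precision weights come from a lowess fit
(span 0.5) of √(residual sd) on mean log-CPM, evaluated at each
observation's fitted value and raised to the −4th power; with fewer than 10
features the trend is meaningless and weights fall back to 1 with a logged
warning.  The moderation prior (d₀, s0²) is estimated by Smyth-style moment
matching on log s² (digamma/trigamma closed forms; the trigamma inverse is
solved by Newton iteration); a non-positive moment estimate means the
variance spread is within sampling noise and d₀ = ∞ (full shrinkage).
Moderated t carries d₀ + d degrees of freedom; BH adjustment is applied per
contrast (matching per-contrast summary tables), two-sided throughout.
Under the generator's null the raw-p rate at 0.05 is calibrated to within
[0.035, 0.065] (tested).  An explicit `drop_samples` list handles outlier
removal; the judgment is not automated.

## Coexpression networks

Unsigned adjacency |cor|^β (pairwise-complete Pearson when values are
missing).  β defaults to 4 and remains a config input; `scale_free_scan`
reports the signed R² of log₁₀(frequency) on log₁₀(binned connectivity)
(10 equal-width bins, empty bins dropped, R² sign-flipped for positive
slopes, NaN when connectivity is degenerate) together with mean
connectivity, so the user can balance the two as the analysis intends.

TOM is computed exactly as defined above; the matrix product form subtracts
the u = i and u = j terms and symmetrizes against floating-point drift.

`cut_modules` is a deterministic variable-height branch cut, not a
re-implementation of the published dynamic-hybrid algorithm (a deliberate
scope decision; the recovery contract is adjusted-Rand-index against
planted truth, not label-for-label agreement with another implementation).
The average-linkage tree of 1 − TOM is traversed top-down: a branch with a
strong internal merge-height gap (relative gap ≥ τ, τ = 0.5/0.4/0.3/0.2/0.1
for deep-split 0–4) is cut at that gap and revisited; a gap-free branch is
accepted as a module if it is cohesive (mean internal dissimilarity
≤ 0.90) or bisected at its root otherwise; branches below the 30-gene
minimum stay unassigned (label 0).  Accepted branches are then refined by
topological-overlap connectivity: a member is kept only while its mean TOM
to the module is at least half the core connectivity (mean of the
best-connected 30 members), shedding background genes the dendrogram
attached on the way up — the TOM analogue of eigengene-connectivity module
membership.  Labels are ordered by descending size.  Module merging
iterates to a fixed point: while any two eigengenes correlate above
1 − cut_height (default 0.25), merge and recompute, so transitive chains
collapse.  Eigengenes are the first left singular vector of the per-gene
z-scored module submatrix, unit variance, sign-oriented to correlate
positively with members on average.

Sample outliers: average-linkage on Euclidean sample distance; singleton
branches joining above the 0.99 quantile of merge heights are flagged.

## Cross-tissue correspondence

Label matching is greedy on the smallest hypergeometric overlap p over the
shared universe (the published matching behaves greedily; exhaustive search
is used only as a test oracle on toys).  Unmatched source modules get fresh
labels; label 0 never matches.  The hypergeometric test reports
P(X ≥ k) for X ~ Hypergeom(N, n_target, n_source) and the representation
factor k·N/(n₁n₂).  The bootstrap null redraws module-sized gene sets
without replacement (vectorized random-key selection, which is
distributionally identical to sequential sampling) and counts strictly
greater overlap proportions; zero exceedances are reported as an upper
bound p < 1/n_iter, matching "p < 0.0001"-style reporting.  An optional
(k+1)/(n+1) estimator exists but is off by default.  The universe for both
tests defaults to genes assigned (label ≠ 0) in both partitions and is
configurable to include unassigned genes; both choices are recorded in the
output.  On synthetic truth partitions the assigned universe is small and
the big egg module fills most of it, so planted-flow significance is
evaluated over the full gene universe (`include_unassigned=True`) — with
the target module at ~65% of the assigned universe a 60% overlap is *below*
chance, which is a property of the universe choice, not of the statistic.

## miRNA curation

Quality filtering is strict on the boundaries: randfold p < 0.05 (0.05
itself fails), read floors ≥ 5 on both strands.  Locus merging groups by
exact mature sequence, then takes connected components of the
interval-overlap graph per chromosome+strand (transitive closure via a
sorted sweep), so chains merge and different strands never do; the result
is order-independent, idempotent, and count-conserving.  Coordinates are
0-based half-open internally; GFF3 I/O converts to/from 1-based closed.
Homology identity is matches/query-length over the best gapless sliding
alignment (mature miRNAs are short; counting "mismatches" implies no gaps),
mismatch positions are 1-based from the 5' end, and the seed region is
positions 2–7 inclusive.  Several precursors mapping within one individual
triggers a warning, not an error.

## Targets and orthologs

Consensus target calling enforces source-appropriate columns (a table
carrying a p column cannot be passed as predictor A — swapped arguments are
an error, not a silent wrong answer).  RBH "best" is lowest e-value with
ties broken by bitscore then lexicographic subject, both directions at or
below the e-value cutoff.  The cutoff notation "10 × 10⁻⁵" is ambiguous as
printed; the package defaults to the conventional 10⁻⁵ and exposes it as a
flag.

## Problem sizes and runtime

The TOM/dendrogram stage is cubic in gene count, so the package runs its
synthetic demonstrations at desk scale as its own choice of problem size:
module-recovery evaluations use 1,000 genes × 22 samples (planted modules
cover 270 genes), DE calibration/recovery 2,000 genes, filter-retention
checks the full 12,770, and the pipeline's simulate default is 2,000.
Module-recovery evaluations generate without planted DE effects: strongly
season-driven DE genes form a real season-correlated expression cluster
that the truth partition labels as background, so a correct clustering
would be penalized for finding it.  DE evaluations use the DE defaults.

## Known limitations

Cage and female pairing are generated but not modeled in the DE fit (no
random effects / duplicate correlation); the cut algorithm is not the
published dynamic hybrid and label boundaries can differ in detail even
when partitions agree; TMM depth-invariance is approximate (see above);
the bootstrap and hypergeometric tests share the universe but not the
finite-sample discreteness corrections; and nothing here validates against
real sequencing artifacts (adapter content, multimapping, batch effects).
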