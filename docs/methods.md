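# Methods

This note documents the models, parameter choices and numerical
decisions behind `ranetkit`, and what the synthetic benchmark does and
does not establish about real data.

## Preprocessing

Per study, log2 fold-changes are computed per probe as
`intensity − median(normal intensities)`, separately for each disease
condition, so one study with a primary-disease arm and a comparator arm
contributes two matrices. Probes collapse to genes by keeping the single
probe whose largest *absolute* fold-change across samples is maximal
(signed maxima would discard strong down-regulation; ties break to the
lexicographically smallest probe id). Each matrix is then flattened to a
vector, the vectors are quantile-normalized as a group, and the matrices
are combined column-wise over a gene-ID match (intersection by default;
union with missing-value flags is available). Unequal-length vectors are
handled by linearly interpolating each sorted vector onto a common grid
of `max(len)` quantiles and mapping values back through their average
ranks, which reduces to classical quantile normalization when lengths are
equal. Missing values are rejected on input rather than imputed.

A consequence worth knowing: quantile normalization equalizes whole
fold-change distributions, so arms with a heavier differential-expression
burden get compressed relative to lighter arms. In the synthetic
benchmark (primary arm carries twice the DE burden of the comparator) a
planted symmetric 2.0 log2 effect emerges as ≈1.74 in the primary and
≈2.17 in the comparator arm. This is a property of the method, not a
bug, and the downstream classification is designed to tolerate it.

## DEP discovery

**Folding.** NMF needs non-negative input. Each gene contributes an
"up" row `max(v, 0)` and a "down" row `max(−v, 0)`; the original row is
their difference. Folding preserves sparsity and sign semantics, unlike
value-shifting, and lets one factor carry coherent up- and
down-regulation (which co-occur in the same samples) simultaneously.

**Factorization.** Multiplicative updates minimize the Frobenius error;
the error is non-increasing at every iteration (asserted in tests), and
iteration stops when the relative error change falls below 1e-6 or after
500 iterations. Initialization is NNDSVDar: factors built from the
non-negative parts of the leading SVD components, with small random
values in place of zeros. One initialization is the default. Uniform
random restarts are available but not used by default, for a measured
reason: on matrices with a few strong patterns plus noise, random-init
runs sometimes reach a marginally lower Frobenius error through
fragmented, per-sample-subset factors, so selecting the best error over
random restarts can *reduce* scientific quality. After fitting, basis
columns are L2-normalized with the scale pushed into the activation
rows, making activation magnitudes comparable across independent
factorizations — a prerequisite for reusing permutation-derived
activation cutoffs on real factorizations.

**Choosing the rank.** The factorization rank must stay well below the
number of fold-change columns: with rank = columns an exact degenerate
factorization (activation = identity) exists and the factors collapse
toward single-sample indicators. The pipeline default is k=30, suitable
for compendia with dozens of samples and rich structure; the synthetic
benchmark (30 columns, four planted pattern classes) uses k=4. At k=5–6
the planted patterns still pass the screen but the shared pattern
fragments per study, degrading shared/dominant gene classification from
≈0.98 to ≈0.79 accuracy; the benchmark therefore fixes k=4 throughout.

**Membership.** Per cluster, basis weights are standardized,
`z = (w − m)/s`, where `m` and `s` are the mean and standard deviation
of the column *after excluding its top 2% of loadings*; members are
features with BH-adjusted upper-tail normal `P < 0.05` (alpha
configurable). The trim exists because a cluster's own members occupy
the extreme upper tail and inflate an untrimmed scale estimate enough to
mask their own weakest quintile (measured sensitivity ≈0.86 untrimmed vs
≈0.99 trimmed on the planted benchmark). A fully robust median/MAD scale
overshoots in the other direction and sweeps in the cross-loadings that
shared genes place on dominant clusters (FDR ≈0.5). 2% covers the
expected member share of one cluster under the default configuration.

**Significance screening.** Chance levels come from element
permutation: all matrix entries are globally shuffled, the folding and
factorization repeated (20 permutations by default, 200 iterations per
permutation fit), and two per-cluster counts recorded — member genes
under the *same* membership test as real clusters, and samples above
that permutation's 95th-percentile activation cutoff. The thresholds
estimate the joint chance event "many genes in many samples": the sample
threshold is the 95th percentile across permutations of the
per-permutation maximum sample count; the gene threshold is the same
percentile of the maximum member count *among chance clusters that
themselves exceed the sample threshold* (zero when no chance cluster
qualifies). Marginal aggregation would let chance clusters with hundreds
of members but one or two active samples set an unreachable gene
threshold; such a pattern is not a DEP. Real clusters must strictly
exceed both thresholds.

**Classification.** A cluster's sample support is the set of samples at
≥25% of its peak activation. Partial activation of a genuine pattern
measures ≈0.3–0.5 of peak (e.g. the primary-arm share of a shared
pattern after the quantile-normalization compression described above),
while a truly inactive arm sits near 0.01 of peak, so 0.25 separates the
regimes with an order-of-magnitude margin; the extreme-tail activation
cutoff stays in charge of the significance screen, where chance
calibration matters. Among support samples with disease conditions, a
cluster is *dominant* when the comparator fraction is below 0.2 and its
primary samples span at least two studies, *shared* when both disease
fractions reach 0.2, otherwise unclassified. The core gene set is the
union of member genes of significant dominant up-clusters. Gene-level
shared/dominant calls (`classify_genes`) let shared evidence override
dominant evidence for the same gene, mirroring the definition of
disease-dominance as absence of comparator sharing.

## Empirical enrichment

All enrichment-style tests share one engine: draw `B` query-sized gene
sets from the universe without replacement (random-key argpartition,
chunked, BLAS-accelerated counting), count exceedances `r`, report
`P = (r+1)/(B+1)` — never exactly zero, floored at `1/(B+1)`. Under this
null the overlap count is exactly hypergeometric; `scipy`'s
hypergeometric tail is used as an independent oracle in the tests, never
as the implementation. Defaults follow the pipeline's operating point:
`B = 100,000`, significance 0.05 for process/disease enrichment and 0.01
for TF and hub candidates; the `--fast` profile caps `B` at 10,000.
P-values are reported raw (the thresholds above are applied to raw
values); a BH column is emitted alongside for readers who want it.
`Z = Φ⁻¹(1−P)` with out-of-range values clamped to the floor.

## Perturbed network and module scores

Seeds are core genes annotated to at least one configured process
module; interactors are the remaining core genes directly adjacent to a
seed in the interaction graph — interactors are required to be core
genes themselves. The network is the induced subgraph on both. Annotated
nodes join every module whose term they carry; unannotated interactors
join the modal module(s) of their seed neighbors, ties keeping all tied
modules. The module enrichment score is implemented exactly as printed —
`(overlap/module_size) / (network_size/core_set_size)` — although that
background ratio is inverted relative to a conventional fold-enrichment;
a `conventional=True` variant computes the reciprocal-background form
for comparison. The sixteen default module labels (AP, TC, BC, IG, CA,
NK, IC, CK, CMH, TLR, AF, JS, CC, CDS, ECM, MR) are configuration, not
biology baked into code.

## Regulator candidates

The hub statistic counts core genes among a candidate's first and second
interaction neighbors (union, candidate excluded); the TF statistic
counts a TF's targets among the core genes. Both use the resampling
null above with alpha 0.01. The candidate pool defaults to all
interaction-network nodes and can be restricted. Ranking within a module
sorts by ascending empirical p, then larger statistic, then gene id —
the statistic tie-break matters in practice because strong candidates
often share the resampling floor `1/(B+1)`.

## Synthetic benchmark

The generator emulates a multi-cohort tissue compendium: per study and
gene a baseline `N(8, 1)` log2 intensity; five planted gene groups —
shared-up, dominant-up, shared-down, dominant-down (7% of genes each,
140 of 2000 by default) and null; condition offsets of ±2.0 log2 units
applied in both disease arms (shared) or the primary arm only
(dominant); per-measurement noise `N(0, 0.5²)`; and a per-study
multiplicative jitter `U(0.8, 1.25)` on the offsets so cross-study
normalization has real work to do. The interaction network is
preferential-attachment (Barabási–Albert, m=2) with five planted hubs
wired to the core group with probability 0.5 each and to each other
(regulator complexes); TF-target maps contain 20 TFs of 50 targets, four
of them drawing 40% of targets from the core group against a ≈7% base
rate; sixteen process modules of 15 genes draw 80% from the dominant-up
group; overlay signatures cover a configurable fraction of each module.

What the benchmark does *not* emulate: probe-level artifacts and
cross-hybridization, batch effects beyond scale jitter, correlated noise
between genes, heterogeneous per-study platforms or sample sizes, and
the diffuse polygenic differential expression of real tissue (planted
groups are clean blocks). Passing the planted-recovery tests shows the
machinery is correct and calibrated under its own assumptions; it does
not guarantee comparable sensitivity on real cohorts, where effect sizes
are smaller and structure is messier.

Known limitations: the shared/dominant classifier depends on the
factorization respecting arm structure, which is only guaranteed when
the rank is chosen sensibly relative to the sample count; the
permutation null is exchangeable across all matrix entries and does not
model gene-wise variance heterogeneity; and hub statistics saturate on
dense graphs where two-hop neighborhoods approach the whole network.

## Determinism

Every stochastic step takes an explicit seed; NMF restarts derive
per-restart generators from `SeedSequence(seed).spawn`, resampling uses
`default_rng(seed)`, and the pipeline writes SHA-256 checksums of every
output into its manifest. Two runs with the same configuration are
byte-identical (asserted in the test suite).
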