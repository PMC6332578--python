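# Methods

## Inputs and gene universe

Three tab-separated tables: a genes × cells RPKM matrix, a per-gene
annotation (chromosome, 1-based inclusive coordinates, housekeeping flag,
one-to-one chicken-ortholog flag with chicken location, X-syntenic-block
flag) and per-cell metadata (embryo, embryonic day E3–E7, lineage). Every
X-vs-autosome statistic is restricted to genes with one-to-one chicken
orthologs — genes that predate the mammalian X — and autosomes means
chromosomes 1–22 only; genes on MT or unrecognised contigs are kept in
files but never enter the contrasts. Unknown chromosome labels are mapped
to `other` with a warning rather than dropped, so a gene annotated to a
non-standard label (including dual X/Y placements encoded as such) is
excluded from both the X and Y sets without double counting.

## Sex calling and strata

A cell's sex score is the sum of its Y-linked RPKM values; the cell is male
when the score strictly exceeds τ = 1.0 RPKM. The sum is robust to dropout
of any single Y gene, and the default embryo-level majority vote (all cells
of an embryo share a karyotype; ties → unknown) suppresses residual
per-cell miscalls. Both τ and the vote are configurable. Analysis strata
are the observed (day, lineage, sex) combinations; E3/E4 cells predate
lineage segregation and carry the lineage label `prelineage`, forming their
own strata. Ratios need ≥ 1 cell, noise statistics ≥ 2 cells.

## Fraction-matched X:AA estimation

For a stratum, per-gene means are taken over its cells. With threshold
T ∈ {10, 5} RPKM, x% = (#X genes with mean ≥ T)/(#X genes); the X selection
is exactly those genes, and the autosomal selection is the top
round(x% · n_A) autosomal genes by mean (round half away from zero, minimum
1; ranking ties broken lexicographically by gene id so the selection is
deterministic). The estimate is median(X)/median(A), even-length medians
being the mean of the two central values. The per-cell variant repeats
selection and ratio inside each cell's own RPKM vector, skipping (with a
log entry) cells where no X gene reaches T; the per-autosome variant
matches the fraction against each single autosome's gene pool, reporting
autosomes with no qualifying genes as absent. The biased common-threshold
estimator (both classes cut at T) is provided for comparison; on synthetic
truth r = 0.5 it overshoots in essentially every run, which is the
methodological point the matched selection addresses.

The whole procedure is scale-invariant: multiplying the matrix and the
threshold by the same constant changes nothing.

## Uncertainty and testing

Confidence intervals are percentile bootstrap: the selected X and A gene
sets are resampled with replacement independently, B = 1000 times, the
median ratio (or comparison statistic) recomputed per replicate, and the
interval is the (5th, 95th) percentile pair using numpy's
linear-interpolation quantile rule. Resampling operates on the *selected*
sets; re-running selection per replicate is available behind a flag
(`reselect` is deliberately not the default, matching the primary
definition of the interval as uncertainty of the medians given the
selection). The Mann–Whitney U test comparing selected X and A values is
exact when both sides have ≤ 20 observations and no ties; otherwise the
normal approximation with tie correction and no continuity correction is
used, which returns exactly p = 1 for identical samples. Significance is
reported per stratum without multiple-testing correction, mirroring the
per-panel presentation this analysis style uses.

## Expression noise: CV and DM

CV is the sample standard deviation (n−1 denominator) over a stratum's
cells divided by the mean; zero-mean genes are dropped with a log entry.
Because CV falls with expression (the finite-number effect), DM subtracts
the local trend: genes are ranked by mean (ties broken by gene id), each
focal gene receives a window of the k genes nearest in rank excluding
itself — shifted inward at the ends of the ranking so it always holds
exactly k genes — and

    dm = focal CV − median(window CVs),

so larger DM means noisier than expected at that expression level. The
default k = 20, with 10 and 50 as sensitivity settings. The pooled ranking
for windows spans all analysis genes of the stratum (X and autosomal
together); restricting it is possible by passing a subset table. The gene
universe for noise statistics is the union of the matched selected sets at
the same threshold, so the expression-level composition matches the ratio
analysis. CV sets are compared by the ratio of medians (CV is a relative
quantity), DM sets by the difference of medians (DM is already a linear
distance); both carry the same bootstrap/rank-test machinery as the ratio.

## Housekeeping depletion

Five 2×2 chi-squared tests (focal vs reference, housekeeping vs not),
restricted to one-to-one ortholog genes: human X vs human autosomes;
chicken chr1 and chr4, complete chromosomes, vs the other chicken autosomes
(Z/W and unplaced contigs never count as autosomes, and the focal
chromosome is excluded from its reference); and the X-syntenic spans of
chr1/chr4 — all ortholog genes lying between the first and last
X-syntenic-flagged ortholog on that chromosome — against the same
references. Yates' continuity correction is on by default and switchable;
with the published counts, the corrected test reproduces every printed
p-value at one significant figure (1×10⁻⁴ for the human X, < 10⁻⁴ and
0.002 for chicken chr1/chr4, 0.0006 for both syntenic spans), whereas the
uncorrected statistic gives 8×10⁻⁵ and 5×10⁻⁴ for two of them.

## Synthetic data generator

The generator emulates the statistical shape of a preimplantation-embryo
single-cell RPKM study. Defaults: 22 autosomes × 662 genes, 450 X and 40 Y
genes with ortholog probability 0.8 (≈ 360 X-linked and ≈ 11.6k autosomal
orthologs in expectation); housekeeping probability 0.147 on X and 0.2365
on autosomes (the published depletion); the full E3–E7 × lineage × sex
grid at 70 cells per stratum (≈ 1.5k cells); true X:AA of 0.5 in males at
every day and declining linearly from 0.75 (E3) to 0.5 (E7) in females.

Per gene, a base mean is drawn from LogNormal(μ = 2.0, σ = 1.5 natural-log
units) — medians near 7 RPKM with a realistic multi-order-of-magnitude
spread. A cell's value is the sum over `ploidy` independent Gamma allele
draws (X: 1 allele in males, 2 in females; Y: 1/0; autosomes: 2) with
per-allele variance set so that total CV² = a/mean + 2b/ploidy, i.e.
CV² = a/mean + b at diploidy, with a = 10 RPKM and b = 0.25 by default and
b halved for housekeeping genes. Haploid genes therefore keep the full
per-allele variance while diploid genes average half of it away — the
ploidy-noise premise of the male-X comparisons — and a regression of
estimated CV² on 1/mean recovers (a, b). Y-linked genes are flat at
5 RPKM in males and exactly zero in females, which is what the sex caller
exploits. X-linked orthologs map into a syntenic block on chicken chr1
(70%) or chr4 (30%); autosomal orthologs scatter uniformly over ten
chicken autosomes. Gamma draws (continuous, non-negative) are used rather
than discrete counts because the pipeline consumes RPKM, not UMIs; dropout
is represented only through this continuous noise, which is adequate above
the 5–10 RPKM analysis floor. All randomness derives from one seed through
separate named streams for annotation and expression, so each table is
independently reproducible.

What the generator does *not* emulate: mapping artefacts, batch and embryo
effects beyond the embryo id grouping, zero-inflation, gene–gene
correlation, and any real linkage structure. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
model, not robustness to those real-data complications.

## Experiment sizes and numerical behaviour

The validation experiments use 2,000 X / 10,000 autosomal genes and 100
cells per stratum for recovery and bootstrap-coverage studies, 1,000 X /
5,000 autosomal genes and 50 cells for the estimator-bias runs, and 200
simulations for coverage. Two finite-sample effects are worth knowing.
First, the matched estimator is a ratio of medians of a few hundred
selected heavy-tailed gene means, so its per-run sampling spread at these
sizes is roughly 0.03–0.05; it is unbiased (averages over seeds recover
the planted ratio to well under 0.02 at 100 cells) but single runs
scatter accordingly. Second, with few cells (≲ 50) the threshold selects
on noisy means, which induces a small upward bias at high true ratios and
pushes bootstrap-CI coverage a few points below nominal (≈ 80% rather
than 90% at 40 cells); at 100 cells coverage is ≈ 83–87%. The bootstrap
cannot see the selection step by construction (it resamples the selected
sets), which is the documented trade-off of the default interval.

Degenerate inputs raise typed errors rather than returning placeholders: a
zero autosomal median, an empty selected set, a stratum of one cell for
noise, fewer than k+1 genes for DM, or a zero chi-squared marginal. CI
bounds that fail to bracket the point estimate (possible in pathological
bootstrap degeneracies) are logged, not silently clipped.
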