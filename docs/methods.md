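# Methods

## Mixture model

The methylation density of an allele-defined plasma fragment class at CpG
site *i* is modeled as a convex combination of reference tissue profiles,

x̄ᵢ = Σₖ pₖ Mᵢₖ,  Σₖ pₖ = 1,  pₖ ≥ 0,

where x̄ᵢ is the fraction of class molecules methylated at site *i* and
Mᵢₖ the methylation density of site *i* in reference tissue *k*. The
proportions p are estimated by weighted least squares over the marker
sites the class actually covers. The model assumes (a) the reference
panel spans the tissues that actually release the class molecules, (b)
per-molecule methylation states at a site are exchangeable draws from the
source tissue's density, and (c) the class assignment itself is correct —
misassigned fragments (sequencing error at the tagging SNP, chimeras) are
not modeled. Identifiability requires at least as many usable sites as
tissues and full column rank of M on those sites; with exactly K sites
the result is flagged `exactly_determined`.

## Marker CpG selection

A site enters the marker mask when every tissue covers it at depth ≥
`min_depth` (default 10) and

1. max density − min density > `diff_min` (default 0.25), and
2. after removing the tissue with the highest density, **or** the tissue
   with the lowest density, the coefficient of variation (sample sd /
   mean) of the remaining K−1 densities is < `cv_max` (default 0.3).

The either/or reading targets sites with exactly one outlier tissue of
either polarity; requiring both removals to pass would reject every
marker whose remaining tissues sit at a high baseline (removing the
minimum then leaves the outlier inside the CV computation). CV is defined
as 0 when the remaining densities are identical — in particular the
all-zero remainder, where 0/0 would otherwise reject a maximally
informative site. Ties at the extreme are broken by tissue order, so
selection is deterministic; it is also invariant to the order of the
input methylomes because only one tissue is removed per trial and tied
configurations fail the spread criterion anyway.

## Fragment classes and aggregation

Each fragment votes once per usable SNP/mutation observation
(maternal/recipient-specific allele → class A, fetal/donor-specific →
class B, shared allele at a B-specific locus → shared, mutant/reference
base at a mutation locus → mutant/wildtype). Fragments whose observations
vote for different classes are labeled CONFLICT and excluded from every
class — conservative, since multi-locus disagreement indicates error or
contamination. Observations whose allele pair is collapsed by bisulfite
conversion on the fragment's strand (C/T on the converted strand, G/A on
its complement) are dropped per observation, not per locus, because the
opposite-strand read of the same locus remains informative. Aggregation
counts each fragment at most once per CpG site; x̄ᵢ is a ratio of
molecule counts, so densities are exact rational numbers.

## Quadratic-program solver

The objective is a convex QP on the probability simplex. For K ≤ 12
tissues it is solved exactly: every non-empty support set yields an
equality-constrained least-squares KKT system (≤ 13×13); infeasible
solutions (negative entries) are discarded and the best feasible
stationary point is the global minimizer. This costs 2ᴷ−1 small solves —
negligible for the 5-tissue panels this problem meets — and is immune to
the tolerance drift of iterative solvers near simplex vertices, where
pure-tissue solutions live. Larger panels fall back to non-negative least
squares on the system augmented with a sum-to-one penalty row, polished
by SLSQP and a final KKT re-solve on the detected support. Site weights
are uniform by default; `weighting="coverage"` weights each site by its
covering-molecule count, since a density estimated from two molecules is
noisier than one from fifty. An exhaustive simplex-grid search
(`grid_search_oracle`, K ≤ 4) is kept as an independent check and is used
by the test suite, never by the pipeline.

## Somatic-variant rules

A plasma variant is a candidate somatic mutation when its alternate count
reaches the smallest c with P(X ≥ c | Binomial(depth, e)) < α — alternate
reads at a clean position are treated as independent sequencing errors at
rate e (default 0.003) and the observed count must be inconsistent with
error alone at level α (default 1e−6). The threshold is non-decreasing in
depth. Additional requirements: zero alternate reads in the buffy coat,
and survival of confirmatory realignment, which is an upstream boolean on
the input (alignment itself is out of scope). For the pregnancy-plus-
lymphoma triage, a plasma-specific variant that matches a common-SNP
catalog and is absent from tumor reads is fetal; one absent from the
catalog with ≥ 3 tumor reads is tumor-specific; everything else is
discarded. The three rules partition the input space.

Fetal (or graft) DNA fraction is estimated at loci where the host is
homozygous and the second genome heterozygous: F = 2s/(s+h) for s
specific- and h shared-allele molecules, the factor 2 arising because a
heterozygous second genome contributes the specific allele on only half
of its molecules.

## Synthetic data

`synthesize_reference_panel` emulates a reference methylome panel on a
shared CpG catalog. A `marker_fraction` of sites (default 0.2) are
designated markers, split evenly across tissues and alternating polarity:
hypomethylated outliers (marked tissue ~Beta mean 0.05, others ~0.85) and
hypermethylated outliers (marked ~0.95, others ~0.35). Baseline tissues
at a marker share a tight Beta concentration (400) reflecting the
between-tissue agreement the CV criterion demands; background sites place
all tissues near one shared Beta-drawn baseline in [0.3, 0.7] so they
fail the spread criterion. Per-site read totals are Poisson with mean
`depth` = 300 — reference methylomes pooled across consortium donors are
deep — and methylated counts are Binomial, so reference densities carry
realistic sampling noise and marker selection on the generated panel
recovers ≈ marker_fraction × n_sites.

Fragments are Bernoulli-sampled: source tissue from the mixture
proportions, CpG count per fragment from Poisson(mean 2) clamped to
[1, 10] (plasma cfDNA is ~170 bp and carries few CpGs), sites uniform
over the usable marker set, and each state methylated with probability
equal to the source density. This surrogate replaces resampling of real
bisulfite reads; it reproduces molecule-count statistics but not genomic
clustering of CpGs within fragments, linked methylation along a molecule,
bisulfite conversion failure, or sequencing error in base calls — so
passing tests demonstrate correctness of the estimation machinery under
the stated noise model, not performance on real plasma.

Scenario scales match the study medians of informative-molecule and
covered-CpG counts: cancer pairs 29,868 mutant-allele molecules with
18,193 CpG sites; pregnancy (53,039 sites) and transplant (141,794 sites)
publish no molecule totals, so their fragment counts reuse the cancer
scenario's ~1.64 molecules per distinct covered site (87,000 and 232,700
fragments). Routine runs and the acceptance script divide all counts by
10 so the full three-scenario, 30-replicate design completes in about a
minute on one CPU; the panel is 20,000 sites with 20% markers, which caps
the usable marker set at ~4,000 sites for the larger scenarios.

Replication is seeded throughout: replicate *r* of a tissue's experiment
uses `seed + r` within that tissue's seed stream (streams are offset by a
large stride so tissues draw independent sequences).

## Numerical choices and limitations

* Proportions are clipped at 0 and renormalized after solving; reported
  percentages sum to 100 within 1e−6.
* Sites with undefined density in any reference tissue are dropped before
  solving, not imputed.
* Density quantization in I/O uses integer methylated/covering counts;
  vectors constructed from exact densities in tests use a 1e9 denominator.
* Self-deconvolution at desk scale is not perfect: with ~5 covering
  molecules per marker site, zero-mean Bernoulli noise folded at the
  simplex boundary leaks a mean ~0.5% of a pure class to other tissues,
  so pure-placenta medians land near 99.4–99.5% rather than 100%. The
  leakage shrinks with fragment count and site count (verified by the
  monotone-trend tests) and is a property of the sampling scale, not of
  the solver, which is exact.
* The variant-calling threshold is a standard binomial error model with
  documented defaults; cohort-level variant counts from the original
  study design depend on controlled-access data and are out of scope.
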