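# Methods

This note records the models, parameter choices and numerical decisions
behind the package, and what the synthetic validation does and does not
establish.

## Coordinates and gene bisection

All coordinates are 0-based half-open internally (BED convention); GFF3/GTF
1-based inclusive starts are converted on read. Bisection operates on the
genomic gene span (the union of isoforms), not on transcript models —
transcript-resolved halving would require exon-aware arithmetic and is
deliberately out of scope. The 5′ half receives `ceil(L/2)` bases, so for
odd lengths the extra base goes to the 5′ side; on the − strand the 5′ half
is the right (higher-coordinate) side. Genes shorter than 2 bases cannot be
bisected and are rejected. Unstranded records are rejected because 5′/3′
orientation is undefined for them. Overlapping genes are all kept;
ambiguity is handled downstream (each fragment is counted independently per
gene it qualifies for) and an explicit adjacency filter is available for
metaprofiles.

## Fragment counting

A fragment (the outer genomic span of a read pair, strand decoded per the
library protocol: `yes` for sense, `reverse` for dUTP-style kits, `no` to
ignore strand) is assigned to the half-gene region containing its
*biological 5′-most base under the region's strand* — the lowest coordinate
for + genes, the highest for − genes. This rule is deterministic, assigns a
midpoint-straddling fragment to exactly one half, and guarantees that for
fragments inside a gene the half counts sum exactly to the whole-gene
count. Overlap-fraction assignment was rejected because it is ambiguous at
the midpoint and breaks that conservation property. Fragments whose anchor
base falls in no region, or that fail the strand filter, are uncounted but
tallied in the run report.

## Normalization and differential testing

Size factors are median-of-ratios (each sample's median ratio to the
per-region geometric mean across samples, computed over regions positive in
all samples, rescaled to geometric mean 1), falling back to library-size
ratios with a warning when no all-positive region exists.

Counts are modelled as negative binomial with `Var = μ + αμ²`. Per-region
dispersions are method-of-moments estimates on normalized counts — pooled
within-group residual variance against the grand mean — shrunk toward a
fitted trend `α(μ) = a0 + a1/μ` (nonlinear least squares on the log scale,
over regions with positive raw estimates) with weight `n/(n+4)`. All-zero
regions get the trend evaluated at the smallest positive region mean; with
a single replicate per group the trend is returned outright with a warning.

The test statistic is a Wald z on the log2 fold change of pseudocounted
group means (`pseudocount 0.5`, avoiding infinite fold changes), with the
standard error from the delta method. P-values use the standard normal
reference; BH correction is applied across all regions of one contrast
(never per-chromosome, never pooled across contrasts). Calls: a region is
UP/DOWN when `fdr ≤ alpha` and `|log2FC| ≥ lfc_min` (defaults 0.05 and 0,
both exposed). Selection of cold-specific 3′ depletion takes genes whose 3′
half is DOWN in the cold contrast and NS — under the same thresholds — in
the control contrast.

**Known limitation.** With very few replicates (2–3 per group) the normal
reference is anticonservative (the statistic is closer to a t with ~2(n−1)
degrees of freedom; at 3 v 3 the empirical size at nominal 0.05 is ~0.08–
0.10). Null calibration is therefore validated at 15 replicates per group,
where the measured size is ~0.05–0.065. At benchmark scale this
anticonservativeness is absorbed by the FDR step and the control-condition
screen, but single-region p-values at n=3 should be read accordingly.

## Metagene profiles

Each gene's per-base coverage is rescaled to 100 bins (configurable) by
base-weighted averaging computed from the cumulative coverage: a base
falling across a bin boundary contributes fractionally, so the binned mean
equals the per-base mean to machine precision at any length. Profiles are
reversed for − genes so bin 0 is always the biological 5′ end, averaged
within a genotype × condition group on size-factor-normalized coverage, and
then averaged across genes. The adjacency filter removes genes within a
configurable distance of any other annotated gene (default 0 = literal
overlap only), strand-blind, since an antisense neighbour distorts coverage
just as a sense one does.

## The termination simulator

One transcription event on a gene of length L terminates prematurely at
base x with probability `h(1−h)^(x−1)` and runs to completion with
probability `(1−h)^L`. A premature RNA (spanning `[0, x)` in gene
coordinates) survives degradation with probability `1−δ_pt`; full-length
RNA with `1−δ_fl`. Event counts per gene per library are gamma-Poisson with
mean `λ · κ` (κ applies to cold-induced genes in cold) and dispersion φ.
The closed-form per-base expected coverage,

    cov(x) = λ [ (1−δ_pt)((1−h)^x − (1−h)^L) + (1−δ_fl)(1−h)^L ],

is exposed alongside the sampler and is used both as a Monte-Carlo oracle
and to size benchmark effects exactly. Surviving RNAs are by default
sheared into ~100-base subfragments with uniform placement (so counting by
5′-anchor approximates coverage-proportional counting); unsheared mode
emits one fragment per RNA and is what the closed form describes.

Default magnitudes (not measured rates; chosen once to reproduce the
qualitative genotype contrasts): baseline hazard 5×10⁻⁴ per base (~37%
full-length output at 2 kb), λ = 50 events/gene/library, φ = 0.05,
κ = 4, WT δ_pt = 0.9, δ_fl = 0.05. Presets: *hen2* loses degradation
(δ_pt 0.2) and doubles the hazard in cold; core-exosome mutants lose
degradation only; *zcchc8a/b* carries a full-length-level modifier only
(δ_fl 0.15). The hen2-cold hazard elevation is deliberately moderate (2×):
the closed form shows that much larger elevations deplete the 5′ half as
well (full-length loss dominates everywhere), destroying the
5′-up/3′-down signature that defines the phenotype. An optional
5′-proximal elevated-hazard window exists for promoter-proximal termination
scenarios and is off by default.

## The benchmark

`make_benchmark` emits 600 genes (log-normal lengths around 2 kb, clipped
to 0.5–8 kb, spaced 10 kb apart across synthetic chromosomes), WT and
mutant at 22 °C and cold, 3 replicates each. Both genotypes share identical
baseline parameters; the mutant differs only at 60 truth genes, whose cold
hazard is solved per gene length (Brent root-finding on the closed form) so
the expected 3′-half coverage drops exactly 4-fold versus WT in cold. All
positives are cold-induced (κ = 4), as are 15% of null genes. This design
keeps null genes exact nulls — so empirical FDR against truth is well
defined and normalization is stable — at the cost of not exercising the
genome-wide 5′-fragment stabilization of the full presets inside the
benchmark; that phenotype is validated separately by the preset-contrast
checks.

What passing these checks shows: the pipeline's arithmetic is correct and
calibrated on data generated by its own working model. What it does not
show: robustness to features of real libraries the generator omits —
splicing (fragments are contiguous spans), positional coverage bias from
library chemistry, multimapping, genuinely overlapping gene models,
unequal per-genotype dispersions, and any mismatch between the geometric
hazard model and real termination kinetics.

## Assays

ΔΔCt: ΔCt = Ct(target) − mean Ct(references) (arithmetic mean of cycles =
geometric mean of linear quantities; the combination rule when two
reference genes are supplied), ΔΔCt = ΔCt(test) − ΔCt(reference sample),
fold change `2^−ΔΔCt`. Replicate fold changes are summarized by mean ± SEM
on the fold-change scale. No amplification-efficiency correction is
applied.

Electrolyte leakage: relative leakage = conductivity before / after total
kill, clipped to 1 with a warning if the ratio exceeds 1. Curves are fitted
with `leakage(T) = bottom + (top−bottom)/(1 + 10^((LogEC50 − T)·slope))` by
Levenberg–Marquardt least squares from a fixed 12-point multi-start grid
(4 slopes × 3 EC50 quantiles, asymptotes initialized from the data range),
making the fit deterministic; `bottom > top` solutions are re-expressed by
swapping asymptotes and negating the slope. Fits with dynamic range below
10⁻³ are flagged degenerate. The genotype comparison is the extra
sum-of-squares F-test between a full model (shared bottom/top/slope,
separate LogEC50; 5 parameters) and a nested null (one shared LogEC50; 4),
`F = ((RSS₀−RSS₁)/(df₀−df₁)) / (RSS₁/df₁)`; which parameters are shared is
the common dose-response recipe and is the package's choice. If the
optimizer leaves `RSS(full) > RSS(null)`, the full model is refitted from
the null solution before erroring.

## Validation scales

The self-validation runs at sizes chosen to finish in minutes on one CPU:
the default 600-gene benchmark (~3.5 M fragments), a 2,000-region null
matrix at 15 replicates per group for Wald calibration, 20 genes × 10
positions × 100 libraries for the sampler/closed-form comparison, 200
cold-induced genes for the preset contrasts (60 of them profiled), and
1,000 curve-pair simulations for the F-test null. In the sampler
comparison the probed positions of one gene share libraries, so their
z-scores are correlated: occasional whole-gene excursions beyond 3 SE
reflect that shared NB event-count draw, not a bias of the sampler.
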