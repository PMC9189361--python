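# Methods

This note documents the models, parameter choices and numerical decisions
behind `methmorph`, and what the synthetic-data generators do and do not
emulate.

## Methylation calling

**Model.** Bisulfite treatment deaminates unmethylated cytosine to uracil
(read as T); 5-methyl-cytosine in CpG context resists conversion and reads
as C.  Only the plus strand is modeled: the amplified region is annotated
"+strand" and bisulfite PCR primers target one converted strand, so a
single-strand model covers the assay.  CHH/CHG contexts, duplicate-read
removal and basecalling are out of scope.

**CpG islands.** The island definition follows the classic
length/GC/obs-exp criteria (defaults: ≥ 200 bp, GC ≥ 0.50,
obs/exp = N_CG·L/(N_C·N_G) ≥ 0.60, 200 bp window, 1 bp step), the de facto
standard implemented by common primer-design tools; all thresholds are
configurable on `IslandCriteria`.  Qualifying windows are merged, and each
merged interval is trimmed one base at a time — from whichever end most
improves the obs/exp ratio, right end on ties — until the interval meets
the criteria as a whole, which makes the output deterministic and maximal.

**Alignment.** Reads are aligned glocally (free reference overhangs,
linear gaps) against a converted reference in which every non-CpG C is T
and every CpG C is the pyrimidine ambiguity Y scoring as a match against
both C and T; this makes converted reads penalty-free at conversion sites
without an asymmetric substitution matrix.  Scoring defaults are match +1,
mismatch −1, gap −2: amplicon reads are near-exact copies, so simplicity
is preferred over sensitivity.  Among co-optimal alignments the aligner's
canonical first traceback is taken, which is deterministic; test suites
assert score equality against an independent quadratic-time dynamic
program rather than path identity.

**Calling and rates.** At each covered CpG site: C → M, T → U, any other
base or a gap → N; N is excluded from both numerator and denominator.  The
region rate r_m defaults to the pooled estimate Σn_M/Σ(n_M+n_U), which is
depth-weighted and well defined at uneven coverage; a per-site mode (mean
of site rates) is available because the phrase "methylated sites over
total sites" is also readable site-wise.  The two agree exactly at uniform
coverage.  Known artifact, asserted in tests: with conversion rate c < 1
and true probability p, the expected pooled rate is p + (1−p)(1−c).

**Coordinates.** 0-based half-open everywhere internally; 1-based
inclusive only at the genomic-span boundary (as printed in browsers),
converted at I/O.  The region's verbatim annotations that have no
computational meaning are carried as metadata, not interpreted.

## Synthetic promoter and reads

The promoter generator rejection-samples island segments (CG-dinucleotide
emission rate targeting the requested obs/exp, single-base emission at the
island GC) until each segment satisfies the island criteria on its own,
places them with at least one detection window of CpG-depleted background
between islands (background CG dinucleotides are broken, emulating
vertebrate CpG depletion and preventing spurious islands), and accepts an
assembly only when the island detector reports exactly the requested count
with ≥ 2 CpG sites per island.  Ground truth is therefore
detector-verified, not assumed.  Infeasible specs (island GC < 0.5,
obs/exp < 0.6, length < 200, or insufficient total length) error out
immediately; an admissibility cap bounds the rejection loop.

Reads default to full amplicon length starting at offset 0 — direct
amplicon sequencing reads every CpG site of the amplified region — with a
shorter `read_length` giving uniform random offsets.  Per read, each CpG
site is methylated independently with its profile probability; deamination
converts unmethylated Cs with probability `conversion_rate` (default 1.0);
substitution errors are applied per base at `seq_error_rate` (no indels —
the dominant amplicon artifact modeled is substitution noise).  Qualities
are constant Q30, or the Phred score of the error rate when an error model
is active, since no quality model is reported for the assay.  Depth is a
free parameter (the source work does not state one); the examples and
checks use depth 200, where the pooled-rate binomial error is ≪ 0.05.

What the simulator does **not** emulate: PCR amplification bias,
minus-strand or paired-end reads, indel errors, primer artifacts, and
within-specimen site-to-site methylation heterogeneity beyond the supplied
profile.  Passing recovery tests therefore demonstrates correctness of the
calling chain under clean amplicon conditions, not robustness to every
real-data artifact.

## Morphometry

**F-value.** The study's imaging procedure designates an enclosing region
around the tumor without defining it geometrically; here it is fixed as
the **minimum enclosing circle** of the tumor boundary (Welzl's algorithm
over convex-hull vertices, deterministic seeded point order).  Rationale:
it is parameter-free, guarantees A_selected ≥ A_tumor so F ∈ [0, 1), and
matches the statistic's reading as distance-from-circularity.  An
alternative reading — the circle on the long-axis diameter — coincides
with the minimum enclosing circle for the circles and ellipses used in
validation but differs for e.g. triangles; the choice is flagged, not
silently interchangeable.  The circle is fitted to boundary pixel centers
and its radius inflated by half a pixel to account for pixel extent,
keeping A_selected ≥ A_tumor on rasterized shapes (for a digital circle of
radius 50 this yields F ≈ 0.021 rather than a small negative value).

**Other metrics.** The long axis is the maximum Feret diameter (largest
pairwise distance between boundary pixel centers, computed on hull
vertices and verified against all-pairs search).  Perimeter is the outer
8-connected Moore contour chain with diagonal steps weighted √2; it is
reported but does not enter F.  Interior holes are filled before
measurement because gross tumor outlines are solid.  F is computed in
pixels and is scale-free; volume uses caliper millimetres only and is
never inferred from images.  Masks must contain exactly one 4-connected
foreground component.

**Report layout.** The per-tumor table keeps one row per animal and one
column per group, with missing tumors (animals that grew none) as NaN
rows excluded from the mean ± SD summary but preserved in the table,
mirroring how such outcomes are tabulated.

## Invasion

Depth is measured along a declared axis from a declared capsule edge —
the geometry of a cell-laden hydrogel drop adhered to the liver surface,
with invasion proceeding inward.  Total depth is the maximum per-line
liver extent; invaded depth is the maximum lesion-pixel distance from the
per-line liver edge (the front's deepest point, since "depth of the
lesions" reads as maximal extent; averaging over the width is the
alternative and was not chosen).  The section generator draws a smooth
random front profile and pins its maximum to the requested depth, so
RI round-trips exactly on noiseless sections.

## Cohort generator and associations

**Structure.** Five groups: the four MM stages — intraosseous (marrow),
blood (plasma-cell-leukemia-like), bone tumor, extraosseous tumor — at the
enrolled sizes n = 35, 42, 38, 21, plus a primary B-cell control (n = 20,
a free choice; only "n ≥ 3" is required of it).  Per sample: methylation
~ Normal(group mean, 0.05) truncated to [0, 1]; miR-23 and uPA are linear
in methylation plus Gaussian noise, with slopes and intercepts taken from
the per-stage fitted equations (miR-23 on methylation negative, uPA on
methylation positive).

**Group methylation means** (0.20, 0.68, 0.67, 0.80, B cells 0.05) are a
design choice: only a bar chart is reported, so means were fixed once to
satisfy its qualitative ordering — intraosseous lowest of the MM groups,
blood ≈ bone tumor, extraosseous highest, B cells lowest overall with the
highest miR-23.  The B-cell group reuses the intraosseous link slopes with
a lower uPA intercept, since no fitted equations are reported for it.

**Noise calibration.** Link-noise SDs are not reported; they are derived
so the expected slope t-statistic at each group's n reproduces the
reported P value (P < 0.0001 taken as P = 0.0001), via
s_resid = |a|·sd_x·√(n−2)/t.  One subtlety: both expression variables load
on methylation only, so their mutual correlation is the product of the two
direct-link correlations, and the three reported P values per stage are
not jointly attainable under this single-pathway model.  The
expression–expression P is treated as the binding constraint: both noise
SDs are tightened by a common per-stage factor until the implied
uPA–miR-23 relation reaches its reported significance, leaving the direct
links at least as significant as reported.  A `null_links` switch zeroes
all slopes (fixed noise) for null simulations, and `noise_scale=0` gives
noiseless cohorts for coefficient-recovery checks.

**Statistics.** Regression is ordinary least squares with the classical
two-sided slope t-test (n−2 df); the regression layer is exercised against
closed-form normal equations and calibrated under the null (empirical
type-I error ≈ 0.05).  Group comparisons use one-way ANOVA plus pairwise
**Welch** t-tests — the single-factor design the data actually have, and
unequal variances are expected at unequal group sizes — with Bonferroni
correction over the pairwise family within one analysis panel (the
smallest defensible family; the multiplier is exposed).  The degenerate
all-identical case returns F = 0, p = 1 rather than 0/0.  The sample-size
check uses the two-sample normal-approximation formula
n = ⌈2(z₁₋α/₂ + z₁₋β)²/Δ²⌉; at α = 0.05, power 0.8, Δ = 1 this gives 16
per group.

## Pipeline

`run_end_to_end` derives sub-stage seeds from the global seed by fixed
offsets, writes a resolved `config.json`, and records a SHA-256 of each
stage's configuration in `manifest.json`; a rerun with unchanged
configuration and existing outputs skips the stage.  Summary quantities
are always recomputed from the written files so fresh and resumed runs
report bitwise-identical numbers.  The summary's "any association
significant" flag applies Bonferroni over the twelve slope tests of the
association panel, consistent with the family rule above.

## Problem sizes and tolerances

Validation uses a 2 kb promoter (160–170 CpG sites), a ~260 bp amplicon
(~23 sites), read depths 50–1000, 64–160 px masks, and 200-replicate
cohort simulations; these sizes make every check sharp (binomial bounds
4/√depth for rate recovery; ±0.03 discretization tolerance on analytic
F-values at radii ≥ 20 px; 1e−6 agreement for the enclosing circle;
1e−10 relative agreement for OLS coefficients) while keeping the full
suite fast.  Known limitations: the island detector's trim rule is one
deterministic choice among several in circulation; the enclosing-region
definition is fixed by design rather than recovered from the original
imaging software; and cohort noise is Gaussian because only means ± SD
and P values are reported.
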