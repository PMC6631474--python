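# Methods

## Problem setting

Targeted kit assays report plasma phosphatidylcholines as bulk "PC sums"
(`PC aa Cx:y`, `PC ae Cx:y`) identified only by total side-chain carbons x
and double bonds y; side-chain-resolving platforms report individual
species `PC x1:y1_x2:y2` without sn-position or double-bond-position
information. `pccomp` decomposes the bulk measures into their measurable
constituents by running both data types through a common pipeline:
qualitative isobar enumeration, quantitative proportion estimation,
variation/replication testing, concordance analysis, and reference-based
imputation.

## Nomenclature and mass algebra

Labels from three dialects (kit sum, species, fatty-acid level) parse into
one entity type. The kit annotation `PC aa Cx:y` denotes the diacyl species
PC x:y, `PC ae Cx:y` the ether species PC O-x:y; this follows the kit's
labeling convention (measures are annotated assuming even-numbered chains,
so an even-x diacyl and an odd-(x−1) ether reading denote the same
underlying m/z). Chain pairs are unordered; the canonical printed order is
alkyl chain first, then ascending (carbons, double bonds). One deliberate
guard: a bare species label `PC x:y` with x < 20 is rejected as
"incomplete", because such a token is indistinguishable from a lone
fatty-acid shorthand (e.g. `PC 16:0` missing its second chain); every
legitimate species-level label in the kit universe has x ≥ 24.

Neutral sum formulas use standard glycerophosphocholine and sphingomyelin
chemistry — diacyl PC x:y = C(x+8) H(2x−2y+16) N O8 P, ether PC adds
+2H −O, SM x:y = C(x+5) H(2x−2y+13) N2 O6 P, and the [13C1] isotopologue
swaps one 12C for 13C. Monoisotopic atom weights are w(H)=1.007825,
w(C)=12, w(13C)=13.003355, w(O)=15.994915, w(N)=14.003074 Da; w(P) is the
standard 30.973762 Da. These formulas are validated two ways in the test
suite: the eight isobar-rule mass deltas reproduce the tabulated values to
1e-6 Da, and the floor of the monoisotopic mass (the "nominal mass")
matches the parenthesized neutral mass of all 38 reference species labels.

## Isobar catalogs

For each PC sum, the theoretical constituent set is the union of all chain
splits of every member of the anchor's isobaric series (diacyl anchor:
PC x:y, PC x+1:y+7, PC O-x+1:y, PC O-x+2:y+7; ether anchor: PC O-x:y,
PC O-x+1:y+7, PC x−1:y, PC x:y+7), plus the [13C1]SM isotopologue when the
corresponding SM is not itself quantified by the kit (if it is, the kit's
isotope correction already removes it from the sum; the SM enters the
catalog as a single species, with no chain enumeration). Enumeration
bounds are configurable; defaults are min 2 carbons per chain, max
x − 2, and a chemical double-bond cap of ⌊(c−1)/2⌋ per chain. With these
defaults the 38 reference sums get 240–657 theoretical constituents each;
the exact bounds behind any particular published catalog size are not
asserted, and enumeration is instead verified against a brute-force
double-loop oracle on randomized instances. Ether splits treat the alkyl
chain as distinguishable (exactly one per lipid), so `PC O-17:0_16:1` and
`PC O-16:1_17:0` are distinct; diacyl splits are unordered. Measured
analytes must partition across catalogs — an analyte matching zero or two
sums is an input error, not silently resolved.

## Cohort IO and QC

Concentration tables are wide TSV/CSV (samples × analytes, μmol/L) with
named metadata columns (subject, timepoint, cohort, challenge, phase, sex,
group, run day). Analyte headers are parsed and renamed to canonical
labels, so chain order in input files is irrelevant. QC follows
reference-replicate practice: analytes with CV > 25% in reference-sample
replicates are excluded, as are analytes with CV > 20% that correlate with
the run day. The run-day test is a two-sided Spearman rank correlation at
α = 0.05 — a choice this package makes (rank correlation is robust to the
drift shape); the underlying procedure is usually described without naming
a test. Coverage filtering keeps analytes quantified in ≥ 25% of samples
(inclusive). Missing values are never imputed at this stage; zero
denominators are treated as missing rather than infinite ratios.

## Composition estimation

q_ijst = conc(PC_j)/conc(PC_i) per sample where both values are present.
The characteristic proportion is the sample mean; variation is reported as
the empirical 5th/95th percentiles (linear interpolation between order
statistics — the convention chosen here, since "lowest/largest 5%" does
not pin down an estimator). Categories are strict step functions: II for
mean q > 0.8, I for > 0.2. The main constituent is the largest mean q,
with exact ties broken by canonical label order for deterministic
reporting. Per-sum proportion totals may exceed 1; that is a real
phenomenon of semi-quantitative platforms with different
extraction/ionization efficiencies, not an error. Within-platform
fractions (each constituent over the sum of measured constituents) are
also provided; samples missing part of the constituent set get fractions
over the remainder, flagged partial.

## Variation and replication

SD_challenges is the mean, over (sum, constituent, subject) cells, of the
SD of q across the baseline/intervention timepoints of the lipid-related
challenges; SD_subjects is the mean over (sum, constituent, timepoint)
cells of the SD across subjects. Cells with fewer than two observations
are skipped and counted. Challenge trends use the two-sided paired
Wilcoxon signed-rank test with zero-difference pairs dropped (the common
convention; an all-zero difference vector returns p = 1). Across-subject
comparisons gate on a Shapiro–Wilk test of the group-mean-centered
residuals at α = 0.05: pass → one-way ANOVA, fail → Kruskal–Wallis.
Cross-cohort replication compares, for each sum testable in both cohorts,
the main-constituent q distributions with Kruskal–Wallis at a Bonferroni
level α = 0.05/n_tests, where n_tests is recomputed from the data rather
than hard-coded; main-constituent agreement is only meaningful (and only
reported) where at least two constituents are measured.

## Concordance

The through-origin fit PC_i ~ b·Σ_j PC_j uses complete cases (samples
missing any mapped constituent are dropped, so the cumulated concentration
is never partial). R² is reported as the squared Pearson correlation of
observed and fitted values: the uncentered no-intercept variant is
systematically inflated (near 1 even for uncorrelated data) and could not
produce the low explained-variance values that motivate the statistic; it
is carried along under a separate field. Bland–Altman statistics use
d = conc_i − Σ conc_j against the pairwise mean; the classification
reference is the SD of the species-level measure itself (within 1 SD /
within 2 SD / beyond), with the conventional mean ± 1.96·SD(d) limits of
agreement additionally reported but not used for classification. Negative
mean differences mean the cumulated constituents exceed the bulk measure.

## Reference table and imputation

The packaged reference (`src/pccomp/data/reference_composition.tsv`)
stores, verbatim to four decimals, the published characteristic
compositions of 38 PC sums (69 constituent rows): mean q, 5%/95%
percentiles, category, per-sum R² (%) and proportion total. Loading
validates schema, category consistency, and per-sum proportion totals; one
source row (PC aa C36:3) is internally inconsistent by 1e-3 between its
printed members and its printed total, so the consistency tolerance is
1.5e-3 rather than the ~2.5e-4 that 4-decimal rounding alone would allow.
The `PC ae C40:1` sum keeps its printed label while its single measured
constituent (the diacyl PC 18:2_22:6, isobaric through the x:y+7 rule) is
stored under its diacyl identity. Imputation is the linear map
conc(PC_j) = mean_q(i,j) · conc(PC_i); outputs carry an `imputed`
provenance flag. Re-estimating proportions on imputed data returns the
table exactly (an algebraic identity, tested to machine precision).
Uncertainty is not propagated: percentile intervals are carried, not
combined.

## Synthetic cohorts

The generator draws, per sum and sample, a latent abundance
T = base·exp(u_s + v_st) with subject effect u ~ N(0, 0.3²) and
within-subject effect v ~ N(0, 0.2²) on the log scale; constituent
abundances are fixed proportions p_ij of T with remainder R = 1 − Σp
unmeasured. Platforms observe eff_sp·T and eff_fa·p_ij·T under
multiplicative log-normal noise with σ² = ln(1 + CV²), default CV 10% per
platform (plausible targeted-MS repeatability, below the 20–25% QC
ceilings). The expected ratio is
E[q_ij] = p_ij·(eff_fa/eff_sp)·exp((σ_sp² + σ_fa²)/2); the last factor is
the exact log-normal ratio bias (≈1.01 at CV 10%), folded into the
reported truth so recovery checks are exact in expectation and collapse to
the plain proportions at zero noise. Missingness is completely at random.
Challenge effects, when enabled, multiply constituent concentrations at
intervention timepoints so the ratio — not just the abundance — shifts.
All randomness flows from one seeded generator; equal seeds give
byte-identical cohorts.

Two design templates mirror the study layouts the analysis targets: a deep
design (4 subjects × 56 timepoints ≈ 224 samples, three challenges with
baseline/intervention pairs) and a wide cross-sectional design (305
single-sample subjects with crossed sex and disease-group labels).
`config_from_reference` converts the packaged table into generator truth:
proportion vectors totalling ≤ 0.9 are used directly (remainder = 1 − Σq,
efficiencies 1); larger totals are rescaled to 0.9 with remainder 0.1 and
the excess moved into the fatty-acid-platform efficiency Σq/0.9, so
expected ratios equal the printed values — including totals above 1 —
while true proportions plus remainder still sum to one.

What the generator does *not* emulate: correlated noise across analytes,
run-day drift, batch effects, censoring at detection limits
(missingness is MCAR, not concentration-dependent), isotope-pattern
interference beyond the single [13C1]SM term, and real biological
covariance between constituent proportions and total abundance. Passing
tests therefore demonstrate correctness of the estimators under the
stated model, not robustness to every artifact of real platform data.

## Problem sizes and numerical choices

The test suite and the acceptance script run the estimation stages at
n = 200–224 samples, the null-replication check at 200 simulated cohort
pairs of 25 subjects × 3 sums, and the enumeration oracle at 100
randomized instances — sizes at which the Monte-Carlo error of each check
is comfortably below its tolerance (e.g. the recovery check's ±0.02 band
is ≈2.7 standard errors at n = 200, CV 10%). Percentiles use linear
interpolation; Wilcoxon uses the exact distribution where scipy selects
it (small n, no ties); all tie-breaks are deterministic.

## Known limitations

sn-positions, double-bond positions and stereochemistry are out of scope,
as are lipid classes beyond PC/PC-O and the SM interference term; lysoPCs
are not modeled. The packaged reference derives from healthy-adult plasma
on one platform pair — compositions in other tissues, diseases or
platforms may differ, and the imputation inherits that scope. Proportions
from a single cohort can exceed 1 for efficiency reasons; imputation
applies them as-is without recalibration.
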