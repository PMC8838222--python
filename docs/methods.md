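# Methods

## Scope and data model

The package models the desk-analysis half of a plant cytogenetic study:
chromosome arm measurements from metaphase plates, fluorescence histograms
from propidium-iodide flow cytometry with an internal standard, and the
inference layer that links 2C DNA amounts to ploidy levels and chromosome
counts. Wet-lab steps (germination, staining, squashing, instrument
operation) and molecular phylogenetics are outside its scope; a Newick
tree, if supplied, is only annotated, never inferred.

A karyotype is stored as the haploid complement: one `ArmPair` per
chromosome with short arm q and long arm p in µm, normalised so q ≤ p
(misordered inputs are swapped silently; non-positive lengths are
rejected), ordered by total length descending. The somatic number 2n and
base number x (default 8) travel with it; 2n/x is the ploidy level when
the division is exact.

## Karyotype morphometrics

Centromere position is classified from the arm ratio r = p/q with
inclusive upper bounds: M for r ≤ 1 + t, m ≤ 1.7, sm ≤ 3.0, st ≤ 7.0,
else t. A strictly median centromere (r = 1) has measure zero in real
measurements, so the median band half-width t defaults to 0.05 and is
configurable; boundary values belong to the more symmetric class.

Indices: TF% = 100·Σq/Σ(q+p); AsK% = 100 − TF% (the two are exact
complements before rounding); Syi% = 100·q̄/p̄; S% = 100·min/max of total
chromosome lengths (defined as 100 for a single-chromosome complement);
R is the mean of per-chromosome ratios p_i/q_i (not the ratio of mean
arms — the two differ for heterogeneous complements); Ci is the mean of
q_i/(q_i+p_i), reported as a fraction. The Stebbins class combines the
largest/smallest total-length ratio (A < 2, B 2–4, C > 4) with the
proportion π of chromosomes with r ≥ 2 (1: π = 0, 2: π ≤ 0.5,
3: π < 1, 4: π = 1).

Report rounding follows the conventions evident in published karyotype
tables: lengths and ratios to 2 dp, TF/Syi/S to the nearest integer, and
AsK truncated to the integer below. Truncating AsK is what lets a table
print TF 45 next to AsK 54 (45.50 and 54.50 from the same arms); reference
tables we checked follow exactly this pattern. Because published integer
indices are computed from unrounded raw measurements while only 2-dp arm
means are printed, recomputation from printed means is expected to agree
only to ±1 integer point, and the regression tests encode that contract.
One packaged reference row (its printed long-arm mean contradicts the same
row's total length and all three indices) is retained as printed but
excluded from index-reproduction checks.

Multiple plates per individual: the default is one designated best plate,
matching common practice; `mean_karyotype` offers position-wise averaging
across equal-sized plates as a clearly labelled extension.

## Flow cytometry

Only the ratio of G1 peak positions carries information — instrument gain
and channel scale cancel — so 2C = 2C_standard · x̄_sample/x̄_standard with
maize (5.43 pg/2C) as default standard. Histograms are 1024-channel linear
by default.

Peaks are detected on a moving-average-smoothed histogram (odd window,
default 5 bins; edge-padded so flat regions stay flat) restricted to
channels at or above a debris floor (default 10), keeping local maxima
with prominence ≥ 5% of the regional maximum. Candidates within 5% of
twice a retained peak are set aside as G2 doublets. Peak statistics are
windowed moments — mean, sd, CV% = 100·sd/x̄ — iterated twice with a
±3.5 sd window capped by the initial half-window (15% of the centre
channel, or 45% of the gap to the nearest neighbour when peaks are close).
Moments slightly under-estimate sd under truncation (≈1% at a ±3.5 sd
window), which is immaterial next to instrument CVs. An optional
least-squares Gaussian refinement recovers the true width from curvature
when a neighbouring peak forces a window narrower than the peak; the full
pipeline uses it when assigning peak roles, because role assignment
compares abundances (height·sd·√2π), a quantity that raw truncated area
would bias.

Role assignment: with a channel hint the standard is the peak nearest the
hint; without one it is the larger-abundance peak, flagged
`ambiguous_assignment` when the two abundances are within 30% — a brighter
sample is then indistinguishable from the reverse, as happens in real
datasets where one individual's sample outshines the standard. QC flags:
`high_cv_standard`/`high_cv_sample` above 5% (silica-dried material
routinely exceeds this), `reject` above 16%, `g2_overlaps_standard` when
the sample's doublet lands on the standard.

## Ploidy inference

Cx is calibrated as half the mean 2C of individuals independently known to
be diploid (chromosome-counted 2n = 2x). A 2C value is assigned the
allowed level L (default even levels 2–8; odd levels can be enabled)
minimising |2C − L·Cx|/(L·Cx), provided that minimum is within a relative
tolerance, default 0.15 — wide enough to absorb the ≤5% within-species and
0–25% among-species variation seen within ploidy levels, narrow enough
that a genuinely anomalous value (e.g. 1.54 pg against Cx ≈ 1.14,
deviation 0.32) is left indeterminate. Assignment is monotone in 2C and
invariant to jointly rescaling 2C and Cx. Per-level aggregation reports
the population standard deviation (n denominator), which is the convention
that reproduces published per-ploidy spreads from their member values.

Concordance: an assignment and a chromosome count disagree when
2n ≠ L·x or the assignment is indeterminate; such pairs are flagged
`possible_cytotype_variation`. On the packaged tables with default
settings exactly one species is flagged — one individual as an outright
genome-size outlier, the other as diploid-sized against a tetraploid
count — which is the behaviour the inference layer exists to surface.

Tree annotation appends `|2C=<mean over individuals>|2n=<count>` (with `#`
for missing values) to every tip label by positional text editing after a
dendropy parse validates the input; since only insertions are made,
stripping the annotations restores the input byte for byte, and topology,
branch lengths and support values are untouched.

## Synthetic data

The generators are pure functions of their spec (seed included) and mirror
the study conditions: arm ratios drawn uniformly inside each requested
Levan class with a 5% margin from the class boundaries (so noise-free
output always classifies back to the requested formula), total lengths
around 2.2 µm; histograms as multinomial mixtures of two Gaussian G1
peaks (standard at channel 500 of 1024, CVs defaulting to 3.37% and
7.79%), optional G2 doublets at twice each mean (5%), and exponential
debris from channel 1 (5%, scale nbins/8); species tables with ploidy
levels 2x/4x/6x dominated by diploids, Cx = 1.14 pg, 1–4 individuals per
species and 5% within-species scatter. Throughout, CV is interpreted as
the sd/mean of the underlying event distribution, not of the binned
counts.

What the simulations do not model: non-linear instrument response, drift
between sample and standard, fluorochrome base-composition bias,
aggregates/doublet discrimination beyond simple 2× G2 peaks, and
tissue-preservation effects. Passing recovery tests therefore shows the
estimators are correct under the stated noise model, not that any
instrument artefact is handled.

## Numerical choices and problem sizes

Deterministic tie-breaks throughout: Levan boundaries go to the more
symmetric class; the Stebbins letter boundary 2 and 4 go to B; ploidy
assignment takes the lowest level on exact ties (argmin over ascending
levels). Validation failures raise typed exceptions; batch interfaces
(measurement CSV reading, the CLI commands) report malformed rows with
line numbers and continue.

Test problem sizes are chosen to run in seconds on one CPU: 10⁴-event
histograms for recovery checks (10⁶ for the law-of-large-numbers moment
check), 100-histogram batches for the 2C error distribution, 60-individual
species tables for ploidy recovery (≥95% at 5% noise, with no 2x/4x
confusion), and 17–64-row packaged tables for the published-value
regressions.

## Known limitations

Raw FCS ingestion is not implemented; histograms enter as `channel,count`
CSV (or are built from event arrays in memory). The S% definition
(shortest/longest total length) is a documented convention — published
tables do not state theirs, and theirs cannot be reverse-engineered from
means. Printed-table reproduction of R and Ci is approximate (±0.05)
because per-chromosome raw data are generally unpublished. The diploid
per-ploidy mean of a published study is reproducible only if the study
states its averaging set; the package reports whatever set it is given.
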