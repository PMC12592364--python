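# Methods

## Scope and data model

The package implements the downstream analysis of binned Hi-C contact maps
and binned sequencing coverage tracks. All intervals are 0-based half-open
(BED convention); bins are addressed by a global index over a genome's bin
table. Contact maps store one dense symmetric matrix per chromosome in cis;
trans contacts are kept only as a scalar total for the cis/trans QC ratio.
This reflects the analysis itself: every quantity computed here (expected,
O/E, EV1, saddle, insulation, differential maps) is a cis quantity.

## Balancing

Iterative correction solves for per-bin weights `w` with corrected counts
`c'_ij = c_ij·w_i·w_j`. One update divides each weight by its relative
corrected marginal and renormalises the weights to mean 1 per chromosome.
Two modes are exposed:

* `n_iter=1` (default) — a single update pass, `w_i ∝ 1/marginal_i`. This
  mirrors analyses that apply one correction pass only.
* `tol` mode — updates until the coefficient of variation of the unmasked
  marginals falls below the tolerance (default 1e-5), i.e. standard converged
  ICE.

Both are provided because a single pass is statistically unusual but is a
documented practice; the pipeline default is the converged mode. Bins with
zero marginal are added to the mask; masking is idempotent and balancing
never resurrects masked bins. Balancing is per chromosome since only cis
matrices are held.

## Expected, O/E and P(s)

The expected profile is the mean balanced contact at each bin distance over
all unmasked pairs, per chromosome arm; without an arm table each chromosome
is one arm (synthetic genomes have no centromeres). O/E divides balanced
values by the arm's expected at that distance; the diagonal, cross-arm pairs
and distances with zero expected are undefined. By construction the
per-distance mean of O/E against its own expected is exactly 1. P(s)
aggregates per-arm expected values weighted by valid-pair counts and smooths
into log-spaced distance bins (8 per decade; geometric-mean distance per
bin). The log-log slope over an interior distance range recovers the
generative decay exponent within ~0.1 at ≥10⁶ cis counts per chromosome.

## Compartments

EV1 is computed per chromosome: usable bins are unmasked with at least one
finite off-diagonal O/E entry; the Pearson correlation matrix of O/E columns
is double-centred (rows, columns, grand mean) and eigendecomposed; the
eigenvector with the largest |eigenvalue| is scaled by √|eigenvalue|.
Undefined O/E entries inside the usable submatrix (zero expected) are filled
with the neutral value 1 before correlation; the diagonal is excluded the
same way. The sign is flipped so the correlation with the GC track is
non-negative — the standard orientation convention, since compartment A is
GC-rich. EV1 exactly 0 is NA rather than a compartment; chromosomes with
fewer than 10 usable bins are NA with a warning.

Switching between conditions is called per bin and requires the same sign
change in both replicate cell lines; discordant changes count as unchanged,
and any NA among the four tracks makes the bin NA. The genome proportion is
taken over bins scored in all four tracks. This concordance rule is what the
decoy machinery in the simulator tests: flips planted in one line only must
never be called.

Saddle analysis assigns bins with defined EV1 to equal-count percentile
groups (stable sort, ties broken by genomic order), accumulates off-diagonal
O/E sums, sums of squares and pair counts per group pair per chromosome,
symmetrises, and aggregates genome-wide weighted by pair counts. Corner
means are count-weighted means of the 5×5 corner blocks. Per-cell standard
errors come from the within-cell variance; note that a 50×50 grid is a large
family, so under a null map a few cells will exceed ±3 SE purely by
multiplicity (the expected maximum |z| over ~1275 unique cells is ≈3.5).
Trimming of extreme EV1 values before grouping is available but off by
default, as no trimming rule is part of the analysis definition.

## Insulation and borders

The insulation score of bin *i* is the mean balanced contact over pairs
(a, b) with `i−w ≤ a < i < b ≤ i+w` (window 100 kb at 10 kb bins, so
w = 10). It is defined only where the full window fits in the chromosome and
at least 50% of window cells are unmasked (avoids masked-region artifacts),
and normalised per chromosome as log2 of the window mean over the mean of
window means — which cancels any global scaling of the map. Borders are
local minima with topographic prominence ≥ 0.2 (log2 units) found per
contiguous defined segment; the default is conservative and yields zero
borders on TAD-free simulations. Border overlap uses greedy one-to-one
nearest matching within an inclusive ±20 kb tolerance, preventing double
counting when borders cluster.

## Track pipeline

Unit tags (`counts → cpm → log2_ratio → zscore`, with `log2_cpm1` for RNA)
enforce the processing order; aggregation to coarser bins happens on counts
only. Fragments are assigned to the bin containing their midpoint — the
coverage rule is otherwise ambiguous at bin edges, and midpoint assignment
counts each fragment exactly once. Zero in either IP or input makes the log
ratio missing; no pseudocount is applied, treating zero-coverage bins as
no-data (consistent with smoothing only over non-zero bins). Z-scores are
per chromosome over non-missing bins; a constant chromosome becomes missing.
Non-zero smoothing takes the defined non-zero bins of a chromosome in
genomic order and replaces each with the mean of itself and its
(window−1)/2 non-zero neighbours per side, truncated at the ends; zeros and
missing bins pass through, so the zero set is invariant.

## Sites

Per-site mean EV1 re-bins the 50 kb EV1 track to 10 kb by value replication
(piecewise-constant; no interpolation) and averages over a site's
overlapping 10 kb bins. Sites with under 50% defined bins are NA
(configurable). Quadrant classification uses the sign pair of the two
condition means: (+,−) A-to-B, (−,+) B-to-A, (+,+)/(−,−) stable; zero or
missing in either condition is NA. Proportions are reported per cell line
and summarised as mean ± SD across lines. Stack-ups centre each site at the
bin containing `floor((start+end)/2)`, which makes centering deterministic.

Randomised controls preserve the exact length multiset and place intervals
uniformly over the genome proportional to chromosome length (the matching
contract is the size distribution, not the chromosome of origin), rejecting
overlaps with masked bins and with already-placed intervals; large sites are
placed first to ease packing. In compartment-matched mode placements are
additionally rejected until the A/B/NA label counts equal those of the input
set. Placement failure after a bounded number of tries raises rather than
silently relaxing constraints.

Group comparisons (e.g. sites that switched B-to-A vs those that stayed in
B) use two-tailed Mann-Whitney U tests across groups within each condition
and across conditions within each group, corrected jointly by
Benjamini-Hochberg within the invocation; the FDR family is per invocation,
since no global family is well-defined. Groups with fewer than two defined
values are skipped and flagged.

## Statistics

The U statistic counts `x_i > y_j` pairs plus half the ties. Exact
two-tailed p-values are `2·min(P(U≤u), P(U≥u))` capped at 1 — the standard
two-tail convention. Without ties the exact null distribution comes from the
counting recurrence `N(u; m, n) = N(u−n; m−1, n) + N(u; m, n−1)`, cheap for
any n₁·n₂ ≤ 400 (the auto-mode cutoff); with ties, exact mode enumerates all
C(n₁+n₂, n₁) group assignments when that count is ≤ 2·10⁵. Larger samples
use the normal approximation with tie correction and continuity correction
of ½, which matches the asymptotic two-sided test in scipy and keeps the
null rejection rate at the nominal 5% (measured 0.042–0.0495 over 2000
replicates). BH adjustment is the step-up formula
`q_(i) = min_{j≥i} m·p_(j)/j` capped at 1. Significance stars use inclusive
thresholds (≤0.05, ≤0.01, ≤0.001).

## Synthetic generator: what it emulates, and what it does not

Planted compartment profiles use alternating-sign blocks with geometric
lengths — a one-parameter family that reproduces a heavy-tailed domain-size
spectrum. Condition-2 profiles flip each bin independently with the switch
probability, concordantly across replicate lines or not; decoy flips in a
single line exercise the concordance rule. Contact counts are Poisson around
`C·d^(−α)·exp(κ·s_i·s_j)`; the multiplicative compartment term makes saddle
corners analytically checkable (same-sign/opposite-sign O/E ratio is
exp(2κ)). A negative-binomial option (gamma-Poisson with a size parameter)
is available but the default is Poisson — sufficient for planted-truth
recovery. Trans contacts are a uniform background total only (default
cis:trans 9:1) for the QC ratio; the generator does not model
restriction-fragment structure, read-level data, trans compartment signal,
mappability or copy-number variation. Consequently, passing tests show the
*algorithms* recover planted structure under the stated noise model; they do
not certify behaviour on artifacts specific to real libraries (repeats,
translocations, uneven coverage), which is what blacklist masking is for in
real analyses.

Default generative parameters are calibration choices, not claims about real
data: α = 1 (the classic mid-range contact-decay exponent), κ = 0.4 (gives
saddle corners in the empirically typical 1.4–1.6 range), sequencing depth
10⁶ cis contacts per 50 Mb chromosome at 50 kb bins (enough that EV1
recovery saturates, |r| > 0.95), IP effect β = 1 on the log scale, site
sizes log-uniform in 20–300 kb emulating initiation-zone scale. The
simulation sizes used in tests and in `scripts/acceptance.py` (two 50 Mb
chromosomes at 50 kb; one 20 Mb chromosome at 10 kb for insulation) were
chosen so every stage runs comfortably on a laptop-class single core while
keeping per-stage statistical power high.

## Numerical choices and degenerate inputs

* Equal-count quantile assignment and all sorts use stable order; every
  stochastic function is a pure function of its arguments including the seed,
  and the pipeline derives all stage seeds from one config seed, so a config
  run twice yields byte-identical text outputs.
* Distances for the cis/trans QC classification are measured between bin
  start coordinates with an inclusive ≤20 kb short-range threshold.
* Differential maps coarsen *balanced* values to 1 Mb by summation before
  the log ratio (the ratio is defined on normalised contacts); cells with a
  zero or undefined value in either map are missing, making the operation
  antisymmetric under argument swap.
* Degenerate inputs fail loudly: all-masked maps, zero library totals,
  mismatched bin tables, out-of-range p-values and infeasible site packing
  raise; short chromosomes or arms yield NA tracks with warnings.

## Known limitations

* EV1 is per chromosome in cis; genome-wide (trans) eigendecomposition and
  higher eigenvectors are out of scope, as are sub-compartments.
* Insulation border calling is single-scale; no nested/hierarchical TADs.
* The MWU exact mode with heavy ties falls back to the normal approximation
  beyond the enumeration bound rather than implementing the conditional
  tie-permutation distribution in closed form.
* Balancing is per chromosome; with real genome-wide matrices the weights
  would couple chromosomes through trans contacts.
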