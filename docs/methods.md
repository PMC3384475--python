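# Methods

This note documents the models and numerical choices behind `straincgh`,
and what the synthetic-data generator does and does not emulate.

## Study design being modeled

A two-channel CGH experiment: for each query strain, its genomic DNA (test
channel) and the reference strain's DNA (reference channel) are co-hybridized
to a whole-genome oligo array of the reference. The reference strain carries
every probe by construction, so presence calling is one-sided: a probe with
test-channel signal well above background is present in the query. The
default layout mirrors a CH34-like genome — 6205 CDS probes over CHR1
(3553), CHR2 (2270), pMOL28 (166) and pMOL30 (216) — a 7 + 9 strain panel in
two gene-content groups, 13 + 5 planted chromosomal islands of 5–150 genes,
both plasmids as always-carried backbone regions, and two plasmid-cured
derivative strains used only for cutoff calibration.

## Background correction (normexp)

Net intensity per spot and channel is `X = fg - bg`, modeled as
`X = B + S`, `B ~ N(mu, sigma^2)`, `S ~ Exp(mean alpha)`. The corrected
intensity is `E[S | X = x] + offset` with offset 50 (intensity units). Since
`S | X = x` is a normal truncated to (0, ∞) with location
`m = x - mu - sigma^2/alpha` and scale `sigma`,

    E[S | X = x] = m + sigma * phi(m/sigma) / Phi(m/sigma),

evaluated in the log domain via `log_ndtr`, so the far-left tail
(`m/sigma` of −40 and beyond) neither underflows nor loses the Mills-ratio
asymptotics; no separate asymptotic branch is needed. The corrector is
strictly increasing and maps the real line into (offset, ∞).

Two fits are provided:

- `normexp_fit` — full three-parameter MLE (Nelder–Mead on
  `(mu, log sigma, log alpha)` from method-of-moments starts). This is the
  textbook estimator and recovers the parameters well on data that actually
  follow the convolution (median relative error < 10% at n = 10,000).
- `normexp_fit_anchored` (default inside `correct_scan`) — `mu` pinned at 0,
  `sigma` from the measured background columns (√2 × MAD-based SD, since the
  net's background residual is a difference of two background draws), and
  only `alpha` fit by 1-D ML. Rationale: on arrays where nearly every probe
  hybridizes (an MGE-rich strain carries ~97% of probes), the bright-spot
  mass forms a tight mode that the three-parameter MLE prefers to explain
  with the *normal* component — verifiably a lower-NLL optimum, not an
  optimizer artifact — which then subtracts the signal level from every spot
  and destroys the calls. Pinning the background to what the scanner
  actually measured removes that degeneracy at no cost on well-behaved
  arrays. The background SD floor is 1e-3 to keep `sigma > 0` on noise-free
  synthetic input.

## Within-array normalization

M/A values are computed from the corrected channels on non-flagged spots and
M is centered on A within each print-tip group by robust local linear
regression (statsmodels lowess: tricube weights, span 0.3, 4 robustifying
iterations — the conventional defaults of this algorithm family). Groups
with fewer than 10 spots fall back to the whole-array fit. A and per-group
spot counts are preserved exactly. Presence calling operates on corrected
intensities (fold over background), not on loess-adjusted ratios: the
ratio normalization serves diagnostics and any downstream ratio analysis,
while centering M would, on low-A spots, actively cancel the absent-gene
signal the caller needs.

## Presence calling and calibration

Default fold change is per-spot: `corrected fg_test / (bg_test + offset)`;
an array-background mode (`corrected fg_test / (mu_hat + offset)`) is
available behind a flag. A gene is present iff fold ≥ cutoff (inclusive;
default 20). Flagged spots (negative quality flag, the GenePix convention)
yield "no data" — recorded as NA, never as absence. Multi-probe genes are
collapsed by majority vote, ties → NA. Calibration evaluates every cutoff
on a grid (default 1 to 100, step 0.5) against strains of known content:
fp(c) = known-absent probes with fold ≥ c, fn(c) = known-present probes
with fold < c, and picks the smallest grid point minimizing fp + fn — a
deterministic, sensitivity-leaning tie-break. On default synthetic data the
zero-error plateau is wide and flat, so the calibrated value sits at the
low end of the grid while the conventional 20-fold cutoff lies on the same
zero-error plateau; both are reported.

## Gene-content statistics

Core = genes called present in every strain; genes with any NA cell are
excluded from the core list but stay in the denominator (the array's probe
count). Shared-gene report matrix: counts below, percentages above the
diagonal, diagonal = each strain's detectable genes;
`pct = 100*shared/min(det_i, det_j)` (bounded by 100, containment = 100),
with a mean-denominator option. Occupancy = 100 × present members /
informative members per (set, strain); NA members leave both numerator and
denominator. All report percentages are one decimal, rounded half-up.

## Clustering

Clustering input: each strain's profile of shared-gene percentages with
every strain, using the **mean** denominator `200*shared/(det_i + det_j)`.
The min-denominator report convention is unsuitable here: whenever one
strain's content contains another's it saturates at exactly 100, so in a
clean two-block panel every profile is constant and the correlation is
undefined; the mean denominator keeps the group-level shape (MGE-rich rows
run high against MGE-rich columns and low against MGE-poor ones, and vice
versa) that the correlation distance then separates. Distance is
`1 - Pearson r` in [0, 2]; zero-variance profiles raise an error in direct
use and follow a documented degenerate rule inside bootstrap replicates
(equal constant profiles → 0, otherwise → 1). Complete linkage is
implemented directly with a deterministic tie-break (lexicographically
smallest min-member pair), making trees bit-reproducible; scipy's
implementation serves as an independent cross-check in the tests. Node
support is the ordinary bootstrap probability from resampling genes with
replacement (default n = 1000), not a multiscale/approximately-unbiased
value — a deliberate, fully specified and testable choice. The two main
groups come from removing the root merge; group I is the side with the
higher mean island occupancy when an occupancy table is supplied, else the
larger side.

## Island scanning

Genes are classified per presence pattern (counts ignore NA): conserved =
absent from no strain; variable = absent from ≥ `min_absent` (default 4)
and present in ≥ `min_present` (default 1); otherwise uninformative.
Candidate islands are maximal runs of consecutive loci that start and end
on a variable gene, contain no more than `max_gap` (2) consecutive
non-variable genes, span ≥ `min_genes` (5) loci and are ≥
`min_variable_frac` (0.8) variable. The implementation computes, per
start, the farthest qualifying endpoint; a window is maximal iff no
earlier start reaches at least as far — provably equivalent to exhaustive
enumeration, which the tests sweep on all instances up to 50 loci × 8
strains. Overlapping maximal windows resolve longest-first (then
leftmost); calls never cross replicon boundaries. All four knobs are
configuration; the defaults formalize, as an explicit reproducible rule,
the kind of block-wise presence/absence pattern that is otherwise read by
eye from strain-by-gene maps. Sizes are `(end - start + 1)/1000` kb,
half-up to one decimal, from 1-based inclusive coordinates; BED output
shifts to 0-based half-open. Merging an inversion-split island sums the
component sizes (the parts are non-contiguous, so the spanning interval
would overstate the element) and weights profiles by gene count.

## Synthetic data: what it emulates, and what it does not

Strain contents follow a lineage-style inheritance model: each group draws
an ancestral island-content template (island included with probability
`(p - eps)/(1 - 2 eps)`), and each strain copies the template with
per-island flip probability `eps` (default 0.05); the marginal per-strain
carriage is then exactly the configured group probability (0.9 / 0.2 by
default) while group members share most of their island complement, as
strains of common descent do. With fully independent carriage there is no
within-group correlation signal at all, and no correlation-based
clustering can recover the groups — the template model is therefore part
of the study conditions, not a tuning knob. Degenerate probabilities (0 or
1) stay deterministic. Carried regions lose individual loci at a 2%
dropout rate; 2% of spots are flagged bad uniformly at random.

Spot intensities: background draws are `N(100, 10^2)` (clipped at 1);
present loci add a signal that is lognormal with mean 20,000 (16-bit-like
bright spots) and log-SD 0.25. A tight, bright signal — rather than a
literal exponential — is what makes a 20-fold-over-background cutoff
meaningful: with an exponential signal at any realistic mean, a large
fraction of truly present spots falls below 20 × background and no cutoff
near 20 can be low-error. The exponential stays as the *fitting* model for
background correction (it governs the corrector, not the simulator). The
test channel is multiplied on the log2 scale by a per-print-tip offset
(±0.1) and a dye trend in A (intercept 0.1, slope 0.05), which the loess
stage removes; the array is a 4 × 4 print-tip grid, spots row-major.

Not emulated: cross-hybridization, probe GC/efficiency effects, spatial
gradients within a tip group, inter-array batch structure, scanner
saturation, or islands on the plasmids. Passing tests therefore
demonstrate the pipeline's correctness and its behavior under the stated
noise model, not robustness to every artifact of real scanner data; real
arrays with heavy spatial artifacts would lean harder on the loess and
flagging stages than the simulation does.

## Problem sizes and runtime choices

The test suite and acceptance script run the full default design (6205
probes, 16 strains + reference + 2 derivatives) for calling accuracy and
calibration; clustering recovery uses truth-derived presence matrices over
20 seeds with 200 bootstrap replicates (the check concerns the clustering
stage, and intensity noise is already covered by the calling checks); island recall at default noise runs the full scan → correct →
call path on a scaled single-replicon genome (800 loci, 8 islands) over 20
seeds. These sizes are the package's own benchmark choices and are stated
here so results are interpreted at the scale they were computed.

## Known limitations

- Bootstrap supports are plain bootstrap probabilities; they are known to
  be conservative for well-supported clades compared to AU p-values.
- The island scanner is purely pattern-based: it cannot see islands carried
  (or absent) uniformly across the panel, and reports runs, not mechanistic
  boundaries (no tRNA/direct-repeat/GC evidence).
- Calling uses a single global cutoff; no per-gene error model.
- The GEO/SOFT format is not parsed; real data enter through the
  GenePix-like spot table and annotation TSVs.
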