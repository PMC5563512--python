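# Methods

## Unzipping free-energy landscape

The landscape is written from the folded reference: opening bp `i` costs
its duplex stability `α_i` (kBT > 0) and gains the stretching free energy
of two released nucleotides, so `G_F(n) = Σ_{i≤n} α_i − 2 n g_ss(F)` and
consecutive values telescope exactly as `α_{n+1} − 2 g_ss(F)`.  The
end-loop formation free energy is a constant shared by all states the
assay compares (the loop persists until the final bp) and is therefore
omitted from the landscape; the `loop_penalty` field on `NNModel` (default
4 kBT) is retained as configuration for completeness but cancels in every
difference the package computes.

`α_i` is the unified nearest-neighbour free energy of the dinucleotide
step `(i, i+1)`, built from ΔH/ΔS at the working temperature (default
298.15 K) with the standard entropy salt correction
(+0.368·ln[Na⁺] cal mol⁻¹ K⁻¹ per step; default 100 mM NaCl), converted
to kBT and sign-flipped so stabilities are positive.  The bp adjoining the
loop has no Watson-Crick step ahead of it; it is assigned the
sequence-mean step energy — a neutral choice that keeps uniform sequences
uniform and makes the total duplex stability, and hence the coexistence
force, invariant under unzipping the duplex from the other end.  The table
is config-overridable through `NNModel.step_energies`.

ssDNA elasticity is a freely jointed chain, `x(F) = L_nt (coth u − 1/u)`
with `u = F b / kBT`, integrated in closed form to
`g_ss(F) = (L_nt/b) ln(sinh u / u)` per nucleotide.  Defaults `b = 1.5 nm`
and `L_nt = 0.59 nm` give 0.96 nm of tether per unzipped bp at 15 pN and
place coexistence forces of ~50% GC hairpins near 15 pN.  kBT at 25 °C is
taken as 4.114 pN·nm.

The coexistence force is found by bisection of `G_F(0) − G_F(N)` on
(0.001, 50] pN to 1e-9 pN; an explicit error names the bracket when no
root exists (e.g. a GC-only stem whose F_c exceeds the bracket).  The
"largest barrier" of a landscape is `max_{i<j} (G(j) − G(i))`, computed
with a running minimum in O(N).

## Hairpin design

The design target is a stem of length `N` whose length-`K` windows cover
every k-mer class at least once and not more than twice.  Classes identify
a window with its reverse complement by default, because the duplex
carries both strands; for `K = 4` this gives (256+16)/2 = 136 classes in a
170-bp stem (167 windows), which also bounds feasible lengths to
[139, 275].  Rejection sampling of random 170-mers essentially never
satisfies the constraint, so the initial sequence is built constructively:
a randomized greedy walk on the (K−1)-mer overlap graph that never lets a
class exceed two occurrences, always prefers a base covering a new class,
backtracks on dead ends and restarts when stuck.  This succeeds in
milliseconds.

Flattening then minimizes the roughness
`R = Σ_{j=1..N} (Σ_{i≤j} α_i − j ᾱ)²` (the inner sum runs to `j`
inclusive, so uniform sequences give exactly R = 0) by Metropolis Monte
Carlo with geometric cooling, followed by basin-hopping reheat/quench
rounds keeping the best state, and an optional polish stage that descends
directly on the largest forward rise of the cumulative step-energy
profile — the quantity that equals the unzipping barrier at coexistence.
Because one-base substitutions almost always violate the tight coverage
constraint (~0.3% acceptance), the move set adds two rearrangements that
conserve the window multiset exactly: excising the closed sub-walk between
two occurrences of the same (K−1)-mer and splicing it at another
occurrence, and reverse-complementing in place a segment flanked by
reverse-complementary (K−1)-mers (counts preserved under duplex class
counting; disabled in single-strand mode).  Ties (ΔR = 0) are accepted to
widen the explored plateau.  All randomness flows from `DesignSpec.seed`;
identical seeds give identical designs.

A floor on the achievable barrier exists: any covering sequence contains a
GCGC window, whose three internal steps (GC, CG, GC ≈ 11.4 kBT at
25 °C/100 mM) exceed three mean steps (≈ 7.2 kBT) by ≈ 4.2 kBT, and this
rise lower-bounds the maximal forward barrier regardless of ordering.  The
designer reliably reaches ≈ 4.1–4.6 kBT — at the floor, roughly a third of
the ≈ 12 kBT typical of random 170-bp sequences, and small enough that
sequence-induced pauses at the detection force last well under the
blockage-detection threshold.

## Synthetic traces

The generator emulates the five-phase force cycle: bind at F_low (6 pN),
detect at F_test (17 pN), strip at F_high (25 pN), re-reference at F_test,
refold at F_low, sampled at 30 Hz.  Unzipping between roadblocks is
treated as instantaneous at F_test ≫ F_c (intrinsic fork kinetics are not
modelled); a ligand blocks the fork at the first bp of its stabilized span
(default 4 bp, the XCGY geometry of a bis-intercalator), holding the
extension at `2 p x_ss(F_test)`.  Dwells are exponential with the
Bell-Evans rate at F_test; a dwell running into the end of the phase is
truncated there (right-censoring).  Per-cycle occupancy is Bernoulli with
probability `c/(c+Kd)` or a per-site override.  A cooperative adjacent
site pair binds jointly and unbinds as one composite block with doubled
X†.  F_high removes all ligands each cycle by default (`ligand_survival`
raises carryover).  Re-binding during the detection phase is neglected
(binding times at those forces far exceed the phase).

Extensions are recorded force-normalized to the detection force: phases
2–4 are all referenced to F_test elasticity, so the deterministic elastic
offset between force levels — which carries no information and is removed
by calibration in an experiment — does not appear, and the phase-3
subtraction aligns the open state to zero.  Measurement noise is white
Gaussian (default 1 nm per sample, chosen so the stated ~2 bp position
resolution is achievable rather than to match any instrument); drift is an
Ornstein-Uhlenbeck wander (correlation time 30 s, magnitude set by
`drift_rate`, default 0.05 nm/s) plus a static per-bead offset scaling
with the drift magnitude, so zero drift yields exactly clean levels.

Hopping traces are a nearest-neighbour continuous-time Markov chain over
the blocked configurations, with rates
`k(i→j) = attempt_rate · exp(−(G_j − G_i)/2)` satisfying detailed balance,
so long-run occupancies are Boltzmann in the configuration free energies
`G_F(p_i) − Σ_{bound} ΔG_int`.  A configuration counts as bound every
ligand at or beyond the fork.  `choose_hopping_sites` mimics the
experimental selection of a force window where hopping is visible: it
scans XCGY positions and picks the site combination minimizing the spread
of configuration free energies at F_hop.

What the generator does not emulate: bead Brownian dynamics and camera
blur, force-calibration error, sequence-dependent ssDNA elasticity,
intrinsic fork pausing, and re-binding during detection.  Tests passing on
these traces therefore validate the estimators under the stated model, not
instrument-specific artifacts.

## Trace analysis

Alignment subtracts each cycle's mean phase-3 extension from its phase-2
samples, collapsing cycles onto a common open-state reference and removing
drift slower than a cycle.  Conversion to bp is linear:
`position = N + aligned/(2 x_ss(F_test))`.  Plateaus are detected on a
5-sample median filter (suppressing single-sample excursions) as maximal
runs within ± tolerance/2 of the running mean, re-joining adjacent runs
whose means agree within the tolerance; a run's level is the median of its
raw samples (robust to boundary bleed), events shorter than `min_dwell`
(default 3 samples at 30 Hz) or at the open level are discarded, and runs
reaching the phase end are flagged censored with their observation limit
recorded.

Position histograms are fitted with Gaussian mixtures; the component count
is chosen as the smallest k whose BIC lies within 10 of the optimum
(parsimony guard against degenerate spikes).  Aggregation pools per-bead
peak centers, histograms them in 1-bp bins with error bars inversely
proportional to √count, and refits with a bin-scale variance floor so a
stray bead widens a peak rather than spawning one.  Motif probabilities
assign each event to its nearest bp (round half-up); the tallied motif is
the tetramer starting at the blocked bp, or the dinucleotide one bp into
the stabilized span (the CpG of an XCGY site).  Raw probabilities sum to 1
over motifs; the normalized variant divides by the motif's occurrence
count in the stem and renormalizes, which removes the spurious weight an
under-represented motif inherits from a neighbouring strong site.  Motifs
absent from the stem are reported as undefined, not zero.

## Kinetics and thermodynamics

The exponential dwell fit is the censoring-aware MLE
`k = events / total observed time`, with an exact chi-square confidence
interval.  The detector's `min_dwell` acts as a left truncation; by
memorylessness, subtracting it from every dwell restores an unbiased
rate (`left_truncation` argument).  Goodness of fit is a KS test; when
per-dwell observation limits are available, uncensored dwells are mapped
through the truncated probability-integral transform so the test stays
calibrated under censoring.  The Bell-Evans fit is weighted least squares
of `ln k` on `F` (weights from per-point standard errors when given),
slope × kBT = X†, intercept = ln k0, with the parameter covariance
reported.

The hopping estimator fits the requested number of Gaussians to the
extension histogram (scikit-learn mixture, initialized at the expected
levels when known; traces beyond 3·10⁵ samples are strided down for the
EM fit, which does not bias the weights); components closer than 1.5× the
sum of their widths raise an explicit collapse error.  The binding energy
is solved per adjacent configuration pair from
`kBT ln(p_j/p_i) = −ΔΔG⁰ + ΔG^ss − Δc·ΔG_int` (deeper fork ⇒ fewer bound
ligands; `bound_counts` overrides the default one-release-per-hop) and
reported as the mean and spread over pairs; an all-pairs mode exists.
Pairs with a zero population are excluded.

## Numerical choices and degenerate inputs

Energies are kBT throughout; forces pN; lengths nm.  FJC expressions use
series/log1p forms near zero force.  Bisection tolerances: 1e-9 pN (F_c).
The similarity scan includes the blockage bp itself in its windows; ties
at S = K are all returned, ranked by summed distance to the blockage
positions.  Blockage positions are rounded half-up before windowing.
Empty trace files round-trip; a single-bead aggregate reproduces that
bead's peak centers; an all-censored dwell set, a single blockage for
recognition search, and a spacer position for mirroring all fail with
explicit messages rather than guesses.

## Known limitations

The barrier floor above means "flat" is ≈ 4 kBT, not arbitrarily small,
under realistic step energies.  Dwell-rate estimates carry a residual few
percent bias from 30-Hz quantization and median-filter edge erosion —
well inside the tolerances used.  The NN table is fixed-temperature; loop
penalty is sequence-independent; the hopping estimator treats each block
as a single ligand unless told otherwise; concentration dependence of the
apparent binding energy is not modelled.
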