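# Methods

This note records the models implemented in `driftline`, the defaults
and why they were chosen, the numerical conventions, and what the
synthetic study system can and cannot establish about real data.

## Biophysical dispersal model

**Forcing.** A `VelocityField` is daily-mean surface currents on a
regular lon/lat grid (u, v in m/s) with a boolean raster land mask on
the same grid. Daily fields are held constant within each day; only
spatial interpolation is applied. NetCDF I/O follows the usual
lon/lat/time convention with land stored as missing values.

**Release scheme.** One raft per habitat site per day by default
(`particles_per_site_per_day = 1`), released at the site's cell centre.
The release ledger is plain calendar arithmetic: sites × days ×
particles; ten calendar years with three leap years give 3,653 release
days per site.

**Stepping.** Positions update every `dt = 1 h` (any divisor of 24 h is
accepted). Velocity at a position is the bilinear interpolation over
the four surrounding nodes of that day's field; land nodes get zero
weight and the remaining weights are renormalised over ocean nodes
(all-four-land samples return (0, 0) — a raft sitting in such a cell
simply stalls). Metres-to-degrees conversion uses a spherical earth,
R = 6371 km: `dlon = u·dt/(R cos φ)·180/π`, `dlat = v·dt/R·180/π`.
The default integrator is forward Euler at the stated hourly update;
an RK2 (midpoint) integrator is available and is used in the
convergence tests (first- vs second-order behaviour is asserted on
rigid-rotation fields, where the Euler map has a closed form).

**Fates.** A raft ends at the first of:

- *event* — an hourly position within the capture radius (default =
  the site-aggregation resolution) of a site. The source site becomes
  eligible only after the raft has first left the source's radius;
  a raft that reaches the maximum duration while still (or again)
  inside its source radius scores a retention event at the source.
  This permits self-recruitment without terminating every raft at
  step 0.
- *beached_no_site* — entering a land-masked cell (nearest-node test)
  away from any site; the land position is not reported, so recorded
  tracks never lie inside land cells.
- *lost_domain* — leaving the grid hull.
- *expired* — `max_days` (default 60, an extreme propagule viability
  estimate) without any of the above.

Checks are ordered lost → event → beached, so a raft that lands within
capture radius of a coastal site scores the event. Advection is fully
deterministic: there is no diffusion or random-walk term, and the
config seed is reserved for synthetic forcing. Rafts released near the
end of a forcing record that outlive it are advected with the last
available day's field (clamped), which only affects the final
`max_days` of a multi-year record.

The vectorised `run_period` advances all concurrently active rafts in
a single time-major loop and is asserted (in tests) to agree exactly,
fate by fate, with the single-particle reference tracker.

## Habitat sites

Occurrences are snapped to a fixed equal-angle grid: latitudinal step
= resolution/111.32 km-per-degree; longitudinal step scaled by
cos(latitude of the domain centre), rounded to the nearest degree so
that re-aggregating site centres is exactly idempotent. Cells are
0-based and half-open (a cell owns its lower/left edge) and anchored
at (−180°, −90°), making the result order-independent. Grid-cell
snapping was chosen over distance clustering because it matches a
stated "spaced 1 km apart" simulation resolution and has no seed or
iteration order. Occurrences whose cell centre is on land are snapped
to the nearest ocean-centred cell within 2 cells, else dropped and
counted. One site per occupied cell, at the cell centre; conservation
(Σ n_occ + dropped = input records) is asserted.

Because the grid origin and the aggregation algorithm behind any
particular published site count are rarely stated, the aggregation is
validated against constructed fixtures (k clusters in k known cells →
exactly k sites) and the origin/centre-latitude conventions are
explicit parameters, so sensitivity can be probed.

## Connectivity and its stepping-stone closure

`P_ij = n_ij / N_i` exactly, retention on the diagonal. Multi-year
climatologies are element-wise means of yearly `P` (counts are summed
for bookkeeping only). Event statistics follow the mean ± SD
convention: distances are haversine between site centres weighted by
the pair's event count; probability and event-count summaries are
taken, by default, over ordered pairs with ≥ 1 event, diagonal
included — conditioning on realised links is what makes a "mean
probability of connectivity" meaningful when most pairs are structural
zeros; the unconditional variant is a flag away. SDs are population
SDs over the event/link multiset. A run with no events returns a
flagged undefined result rather than NaNs.

The stepping-stone closure runs Floyd–Warshall on `w = -ln P` entirely
in log space (probabilities are re-exponentiated only on output, so
200-link chains at P = 0.05 — a product near 1e-260 — are exact).
`SS_ii = 1` by convention (the zero-length path); retention stays
available in the connectivity matrix. Unreachable pairs carry SS = 0
plus an explicit reachability flag, because "no connectivity events at
all" is a finding, not a distance. Ties between equal-weight paths are
broken deterministically: the strict `<` relaxation with ascending
intermediate index keeps the path through the lowest intermediate node
and keeps a direct edge over an equal-weight detour.

## Clonal discrimination

Two ramets share an MLG iff they match at every mutually scored locus
and neither is missing more than half its loci (missing entries act as
wildcards — herbarium-grade data motivates this; strictness is
configurable). Grouping is greedy in input order and deterministic.

`p_gen` is the Hardy–Weinberg probability of one sexual event
producing the MLG (`p²` / `2pq` per locus, product over scored loci),
with allele frequencies computed from genet-level data (one copy per
distinct MLG) of the population. `P_sex` is the unconditional binomial
upper tail `P(X ≥ n)`, `X ~ Bin(N, p_gen)` at the MLG's observed copy
number n in a sample of N ramets; copies with `P_sex < 0.01` merge
into one genet, otherwise they are treated as independent sexual
recruits. The conditional variant (n−1 of N−1) is available; the
unconditional form at the observed count is the default because the
bare 0.01-threshold convention in the clonal-plant literature
(GenClone/RClone lineage) does not pin the variant down. Re-running
discrimination on the genet-level dataset converges immediately on the
test fixtures, and this is asserted.

## Diversity and differentiation

- Clonal richness `R = (G−1)/(N−1)`; NaN for N = 1.
- Rarefaction is Hurlbert's expectation
  `Σ_a [1 − C(N−N_a, g)/C(N, g)]`, computed with exact rational
  arithmetic and verified against complete subsample enumeration.
  Default standardised size g = 2 × (minimum genet count over
  populations). Private alleles are rarefied the same way, restricted
  to alleles absent from every other population's full sample; both Â
  and PÂ are means over loci.
- `H_O` = fraction heterozygous among scored genets; `H_E` is Nei's
  unbiased `(ñ/(ñ−1))(1 − Σ p²)` with ñ scored gene copies; per-locus
  `F_IS = 1 − H_O/H_E` (undefined and flagged at monomorphic loci) and
  multilocus `F_IS = 1 − mean(H_O)/mean(H_E)`; the full per-locus
  distribution is retained because its spread is itself informative
  about clonal mating systems.
- F_ST is Weir–Cockerham θ: variance components a, b, c accumulated
  per locus per allele with per-locus sample sizes (missing data
  allowed), θ = Σa/Σ(a+b+c); negative estimates are reported as
  computed. Small populations are flagged, not dropped. The estimator
  is cross-checked against hand-computed components and, over
  replicate island-model simulations, against the parametric θ of the
  realised population frequencies.

## Genetics vs currents

Populations map to their nearest site (error beyond `max_km`). SS is
symmetrised (max by default — the stronger direction bounds what gene
flow could achieve; mean available) before `−log`, floored at 0.
Linearized differentiation `θ/(1−θ)` is the genetic matrix. The Mantel
test takes Pearson r over masked upper-triangle entries and permutes
rows/columns of the second matrix simultaneously (9,999 permutations
by default; two-sided p with the +1 correction; the mask stays fixed
in the first matrix's frame, and unreachable pairs are excluded and
counted rather than imputed). The permutation null is calibrated:
p-values are uniform under independence (KS-checked). The Mantel
operationalisation itself is this package's addition to what is
usually a qualitative comparison, and is labelled as such.

## Synthetic study system

`make_velocity_field` provides zero/uniform fields (closed-form
oracles), rigid rotation (exact Euler-map oracle; planar metric frozen
at the domain centre), and a double gyre derived from a stream
function by central differences — mixed discrete partials commute, so
the discrete central-difference divergence vanishes identically at
interior nodes. An optional periodic perturbation (`gyre_eps`,
`gyre_period_days`) swings the separatrix day by day, giving
release-date-dependent trajectories and probabilistic connectivity;
without it a steady field sends every raft from a site down the same
path. Land is an optional raster border.

`make_genotypes` draws per-population allele frequencies from a
Dirichlet centred on a global frequency vector with concentration
`(1−d)/d` — a single-knob island model in which d = 0 copies the
global frequencies and d = 1 fixes one allele per population. Ramets
follow a sequential urn: the first ramet founds a genet; each later
ramet is, with probability `clonality`, a copy of a uniformly chosen
resident genet, otherwise a fresh draw, capped at `genets_per_pop`
founders. The urn is the only scheme consistent with both required
endpoints (clonality 1 → one clone per population, R = 0; clonality 0
with cap = sample size → all-distinct draws, R = 1) and the
ramets ≥ genets invariant. Missing entries are blanked per
(ramet, locus) at the stated rate. `make_genotypes_chain` replaces the
island model with a frequency random walk along a chain
(isolation-by-distance), and `make_genotypes_from_distance` draws
logit-scale frequency perturbations from a Gaussian process whose
correlation decays with any supplied dispersal-cost matrix (e.g.
−log SS) — "gene flow follows the currents" — with a spectrum clip
because an arbitrary cost matrix need not induce a PSD kernel. All
generators split a single top-level seed per sub-stream and are
exactly reproducible.

**What the synthetic system does not emulate:** mesoscale turbulence
and eddy statistics of a real hindcast, tides, wind-wave forcing,
coastline geometry beyond a raster border, selection, mutation, null
alleles, and genotyping error. Passing tests therefore establish the
correctness of the algorithms and their statistical calibration under
known ground truth — not the realism of any particular ocean or
species.

## Problem sizes and numerical choices

The test suite and the acceptance script run the drift simulation on a
10°×10° basin at 0.25° with a ring of ~12 ten-km sites, 60–90 release
days and a 60-day pelagic limit (~10³ trajectories), and the genetic
analyses on 10–19 populations × 25–50 individuals × 8 loci — sizes
chosen so every oracle comparison (exhaustive enumeration, 100-replicate
recovery, 500-replicate Mantel calibration) completes in seconds to a
few minutes while keeping Monte-Carlo standard errors small. Rarefaction
uses exact rationals; stepping-stone stays in log space; Psex uses the
scipy binomial survival function; haversine distances use R = 6371 km
throughout. Degenerate inputs (no events, monomorphic loci, zero-variance
matrices, N = 1 populations) return flagged undefined values rather than
raising or silently producing NaN arithmetic.

## Known limitations

- Beaching uses the nearest-node raster land test, so sub-cell
  coastline geometry is invisible; a polygon-coastline reader could be
  added without touching the stepping core.
- The equal-angle site grid distorts cell widths far from the domain
  centre latitude; for basin-scale domains (> ~30° of latitude) a
  per-row grid would be more faithful.
- MLG wildcard matching is non-transitive in principle; the greedy
  deterministic grouping resolves ambiguity by input order, which can
  matter at high missingness.
- The Mantel test inherits the usual caveats of distance-matrix
  correlation (non-independence of pairs, low power against
  non-monotone structure); it is a calibrated summary, not a causal
  model.
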