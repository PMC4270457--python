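# Methods

`parspace` models how a *parABC* partitioning locus spaces low-copy plasmids
equally over the bacterial nucleoid. ParA is a P-loop ATPase whose ATP-bound
dimer binds nucleoid DNA nonspecifically; the plasmid-borne ParB–*parC*
complex stimulates ParA-ATP hydrolysis, releasing ParA from the nucleoid as
cytoplasmic ParA-ADP, which matures slowly back to a DNA-binding-competent
form. Because binding happens anywhere but release happens only at plasmids,
the nucleoid-bound ParA concentration self-organizes into gradients that
encode, in their local slopes, the distances to the neighbouring plasmids and
nucleoid ends. Any mechanism that lets a plasmid move toward the side with
more ParA then drives the population to equal spacing.

## 1. Analytic gradient model (`parspace.gradient`)

The nucleoid is the interval [0, L]. Nucleoid-bound ParA-ATP with linear
density A(x) obeys, between plasmids,

    D A''(x) + R = 0,          A'(0) = A'(L) = 0,

with R the uniform binding flux per unit length and D the diffusion constant
of the bound form. A plasmid at x_i is either an absorbing point
(A(x_i) = 0, the limit of fast hydrolysis) or a point sink with
J⁻ + J⁺ = k_B·A(x_i) for finite hydrolysis rate k_B, where J∓ are the
diffusive arrival fluxes from each side. The solution is piecewise quadratic
and is assembled by solving the 2(n_p+1)-unknown linear system of edge,
continuity, and sink conditions. Two exact identities anchor the tests:
the total arrival flux equals R·L (everything bound is eventually released),
and for a single plasmid J⁺ − J⁻ = R·(L − 2x₁). Fluxes balance at every
plasmid exactly at x_i = (2i−1)L/(2n_p): equal spacing L/n_p with half
spacing to the ends, so the two-plasmid separation is L/2 — slope 0.5 of
separation versus nucleoid length.

`flux_imbalance_relaxation` is a quasi-static fixed-point iteration, not a
physical equation of motion (the model deliberately leaves the plasmid-moving
mechanism open): each plasmid steps toward its larger arrival flux with a
per-plasmid step that grows 1.2× under a persistent sign and halves on a
sign flip, terminating at |Δx| < 1e-9·L. The finite-k_B branch treats the
plasmid as a point sink proportional to the local concentration; it converges
to the absorbing solution as k_B → ∞ (relative flux error < 1e-6 at
k_B = 1e9 for unit parameters, asserted in tests).

## 2. Stochastic engine (`parspace.engine`, `parspace._kernels`)

Both simulators are exact continuous-time Markov chains sampled with the
Gillespie direct method. The generic `run_ssa` loop (used for engine-level
contracts: birth–death stationarity, exponential inter-event times, lattice
diffusion recovering MSD = 2Dτ) re-evaluates propensities each step. The
production simulators are Numba-compiled loops that keep per-category
propensity sums updated incrementally and select weighted sites through
Fenwick trees (O(log n) selection). Three exactness devices are used:

* **Null events** — a hop whose target is a reflecting boundary or hard wall
  is included in the propensity but leaves the state unchanged. Adding
  self-loops to a CTMC (uniformization) does not change its law.
* **Thinning** — "leak" hops past a plasmid at fraction f of the normal rate
  are realised by accepting a full-rate hop with probability f.
* **Integer weights** — polymerization weights are integer products of site
  counts, so the maintained totals never drift.

Timed events interleave at exact times: nucleoid growth inserts two empty
lattice columns at a uniformly random position (all indices to the right
shift by two) and, by default, tops the cytoplasmic ParA-ADP pool up to
2400 ParA dimers per µm of long axis — newly synthesised ParA must mature
through the slow ADP→ATP step, which is why replenishment enters the ADP
pool. A fixed-copy-number mode is provided. Duplication copies a uniformly
chosen plasmid in place with zero bound ParA.

## 3. Diffusion/immobilization model (`parspace.immobilization`)

One-dimensional lattice, native site size dx = 5 nm. Nucleoid-bound
ParA-ATP hops at D_A/dx² per direction (D_A = 1e-2 µm²/s); a plasmid hops at
D_P/dx² (D_P = 1e-1 µm²/s) while fewer than two ParA-ATP are bound to it and
is immobile otherwise. ParA-ATP at the plasmid's site binds it at k_AB
(100 s⁻¹ at the native site size), up to 35 bound; bound ParA-ATP is
hydrolysed at k_B = 68.5 s⁻¹ per molecule to cytoplasmic ParA-ADP, which
matures at k_W = 1/15 s⁻¹ and rebinds anywhere at k_on = 50 s⁻¹ per
molecule. Initial condition: one quarter of total ParA as cytoplasmic
ParA-ADP, 11 ParA-ATP bound per plasmid (initial anchoring), the rest
uniform on the nucleoid.

**Coarsening.** Hop rates scale as 1/dx² automatically. Same-site binding is
mass action in the site count, which grows linearly with the site size, so
the effective k_AB is rescaled by (5 nm)/dx; this preserves the continuum
capture coefficient κ = k_AB·dx (µm/s) and hence the per-second capture
kinetics of a diffusing plasmid. Position distributions were checked to be
indistinguishable across dx = 50/25/12.5 nm.

**Operating regime.** At the default rates the per-plasmid ParA arrival flux
is limited by slow transport of bound ParA (D_A = 1e-2 µm²/s) toward the
plasmid sink. The resulting mean bound count sits near the immobilization
threshold (measured ≈ 2, with the plasmid anchored roughly half the time),
so single plasmids hold a mid-nucleoid *mode* while two-plasmid label
distributions are broad with means near L/4 and 3L/4. Tests assert the mode
for one plasmid and the means for two.

**Duplication assay.** Each replicate relaxes one plasmid from mid-nucleoid
on a fixed 3 µm nucleoid for 100 s (several maturation times; the geometry is
a package choice, recorded in the run config), duplicates it, and records the
maximal additional inter-plasmid separation within 20 s, sampled every 0.5 s.
The new plasmid starts with zero bound ParA inside the parent's depletion
hole, so at D_P = 1e-1 µm²/s nearly all replicates separate ≥ 0.8 µm before
recapture; at D_P ≤ 1e-3 µm²/s essentially none do.

## 4. Directed-motion model (`parspace.directed`)

Thin 2D strip lattice (native dx = 5 nm; short axis S = 30 nm short-polymer
variant, 25 nm long-polymer, 10 nm perturbed-long). Mobile nucleoid-bound
ParA-ATP (D_A = 1 µm²/s) hops in four directions. Two mobile molecules in
the same row at long-axis-adjacent polymer-free sites nucleate an immobile
polymer of two subunits at k_p; a mobile molecule at a polymer-free site
long-axis-adjacent to a polymeric site joins at k_p; each subunit
depolymerizes to a mobile molecule at the same site at k_dp. Interior
removal splits a polymer; a leftover isolated single subunit is reclassified
mobile (polymers have ≥ 2 subunits by the nucleation definition). The
short/long variants differ in k_p/k_dp (800/10 vs 1e6/1e-4 s⁻¹).

A plasmid occupies one long-axis column across the full width. It diffuses
(D_P = 3e-4 µm²/s) only when no polymeric subunit occupies its column or the
two adjacent columns; otherwise it is tethered. Polymeric subunits in its
column are hydrolysed at k_B = 68.5 s⁻¹; each polymeric subunit in an
adjacent column drives, at k_dm = 0.8 s⁻¹, a directed step: the plasmid
moves to that column and the subunit converts to cytoplasmic ParA-ADP (a
burnt-bridge ratchet). In wild type the plasmid's column is a hard wall to
mobile ParA-ATP: hops *into* the column are rejected (molecules deposited
there by cytoplasmic binding may leave). The perturbed-nucleoid variants
turn the wall into a leak (10% of the normal hop rate for short polymers,
100% for long) and reduce k_mB ten-fold.

**k_mB reach.** The mobile-ParA hydrolysis k_mB = 40 s⁻¹ acts on mobile
ParA-ATP in the plasmid's column *and the two adjacent columns* — the same
contact neighbourhood through which the tethering, k_B and k_dm reactions
act. With a strict own-column reading, the wild-type wall would leave k_mB
with almost nothing to act on, the only ParA sinks would be the slow
polymer-mediated ones, and ParA would pile up on the nucleoid into a
polymer-saturated state with nucleoid-length filament runs. With the
adjacent-column reach, k_mB is the dominant turnover route: a large
cytoplasmic ParA-ADP reservoir forms (≈ 60% of total at steady state), the
nucleoid stays unsaturated, and the short-polymer variant settles into
filaments of ~8 subunits mean length (measured as maximal contiguous runs,
which slightly over-count because independently nucleated filaments can
abut) — the intended short-filament regime. Tuning k_mB too high would
deplete ParA around the plasmid and starve directed motion, which is why the
rate matters at all.

**Scaled-down mode** (`scale_down`). Polymer occupancy is 0/1 per site, so
the lattice's polymer capacity per µm is n_short/dx. Coarsening to
dx = 30 nm with one row cuts that capacity 36-fold; the scaled mode shrinks
the total ParA density by the same capacity ratio (2400 → 66.7 dimers/µm),
preserving per-site mean occupancies and with them the polymerization
statistics and the positioning regime. At this coarsening the maximal
directed drift speed k_dm · (subunits per adjacent column) · dx = 24 nm/s
equals its native value. Polymer *physical* lengths are not preserved (a
subunit is 30 nm instead of 5 nm); subunit-count statistics approximately
are. The equal-spacing slope and all distribution-shape checks run in this
mode; filament-length statistics were additionally verified at the native
lattice on a short nucleoid.

**Asymmetry series.** For single-plasmid runs sampled every 5 s, the
nucleoid-bound ParA (mobile + polymeric) left and right of the plasmid
column is summed and divided by the side lengths, giving densities I_L and
I_R; cytoplasmic ParA is uniform and adds equally to both densities. The
reported series is |I_L − I_R|/(I_L + I_R). The wild-type median (~0.07) is
far below the sinusoidal-oscillator reference (below).

## 5. Trajectory statistics (`parspace.trajectories`)

MSD pooling uses every overlapping frame pair at each lag across all foci
and cells; lags are indexed on the frame-interval grid and pairs spanning
gaps survive. The fit is weighted nonlinear least squares of

    r²(τ) = 4 D τ^α + β      (weights 1/SEM(τ), τ = 0 excluded)

with the planar prefactor 4 and the offset β absorbing the time-independent
localization error: writing the measured position as the true one plus an
error ε, squaring and averaging leaves ⟨ε²⟩ as a constant additive term
(β ≈ 4σ² for i.i.d. noise of per-coordinate variance σ²). α is invariant to
the prefactor convention. Least-squares standard errors understate the
uncertainty of α because pooled-MSD points share trajectories and are
strongly correlated across lags; `bootstrap_subdiffusion` resamples whole
trajectories with replacement and reports a percentile CI, which is the
honest interval (typically ±0.05 at ~600 synthetic tracks, versus ±0.01
nominal). The estimator's bias is below 0.03 for α ∈ {0.5, 0.73, 1.0} at
500 tracks (tested).

Segregation events: two per-cell foci at most 0.3 µm apart (a merged focus
that splits enters at ~0) that move at least another 0.8 µm apart within
20 s (a 60 s relaxed window is selectable). The additional separation is the
pair distance minus its value at the event start, maximized over the window.
The mobility of an event set is scored by the mean of per-trajectory maximal
time-averaged MSDs against equally sized subsets resampled without
replacement, with the +1-corrected empirical p-value.

The analytic bound 4·D_f·τ with D_f = 10e-4 µm²/s dominates the fitted
subdiffusive MSD at all lags ≥ 4 s; conversely, relocations of 3–4 µm in
10 min would require D ≈ x²/(2t) ≈ 1e-2 µm²/s under unbiased 1D diffusion —
an order of magnitude above that bound, which is the quantitative argument
against a pure diffusion/immobilization mechanism.

## 6. Localization statistics (`parspace.localization`)

Nucleoid edges are the outermost crossings of half the profile maximum,
linearly interpolated between samples; lobes (contiguous above-half-max
regions) are counted separately. Focus positions are reported relative to
the edges and rank-labeled 1..n_p; the uniform null places n_p positions
i.i.d. uniform and rank-labels them, so label k has mean k/(n_p+1) — the
ordering alone induces structure, which is why the null matters.

The asymmetry measure sums intensity from each pole to the focus and divides
by the pole-to-focus distance; |I_L − I_R|/(I_L + I_R) is 0 for any uniform
profile and 1 for a fully one-sided one. The oscillator reference emulates a
MinD-like pole-to-pole oscillation: amplitude·|sin t| at 10³ uniform phases,
default amplitude 0.6 (mean 2/π·amplitude ≈ 0.38).

The in-focus band of a z-stack is the 9-consecutive-plane window maximizing
Σ I_max(z), ties to the lowest start. The first-harmonic score builds, per
plane, H(x) = I_max(z)·sin(π(x−x_L)/(x_R−x_L)) between the plane's
half-maximum edges and averages ((I−H)/I_maxcell)² over in-range (x, z); the
amplitude choice I_max(z) makes a half-sine of the plane's own peak height
score exactly 0 when its support is supplied as the edges. With automatic
half-max edges even a perfect half-sine scores a small positive constant
(the harmonic is re-fitted between the sin = 1/2 crossings; the constant has
a closed form asserted in tests); helically modulated profiles score higher
still, which is the discriminating direction. The residual is normalized to
I_maxcell *before* squaring, making the score comparable across expression
levels.

Colocalization: Pearson r_P over all (x, z) intensity pairs, and Manders
overlap M_A(T) = fraction of channel-A intensity where channel B, normalized
to its own cell maximum, is ≥ T (symmetrically M_B). The ≥ comparison makes
M(0) = 1 exactly by construction; both curves are non-increasing in T. A
channel nested inside the other's support has the larger overlap coefficient
at every positive threshold.

## 7. Synthetic data (`parspace.synthetic`)

Focus tracks are planar fractional Brownian motion, one exact fGn stream per
coordinate synthesised by circulant embedding (Davies–Harte; the embedding
eigenvalues are nonnegative for H ≤ 1 up to round-off, which is clipped),
scaled so the ensemble planar MSD is 4·D·τ^α. Degradations follow the
imaging chain: optional reflecting confinement (path folding), Gaussian
localization noise per coordinate, rounding to the 0.066 µm camera pixel.
`generate_mobility_dataset` pools a short-interval ensemble (1 min at 4 s)
with a long one (15 min at 30 s) on a common 2 s lag grid — the 2.5-decade
lag range is what pins the anomalous exponent.

Cell stacks are two-channel I(z, x) grids: a nucleoid envelope (half-sine or
flat top) between ground-truth edges, optional helical modulation
1 + a·cos(2πx/λ + φz), a second channel that is a copy or a support-shrunken
nested structure with Gaussian foci, a 9-plane in-focus band, and
Poisson-like noise (Gaussian with variance proportional to intensity) plus
baseline. Ground truth (half-max edges, support, in-focus band, foci) is
returned with the data.

What the generators do not emulate: photophysics (bleaching, blinking),
focus-detection failures, cell-outline segmentation error, drift beyond the
static localization term, and inter-cell heterogeneity. Passing the recovery
tests therefore shows the estimators are correct on data matching their
model assumptions, not that those assumptions hold for any particular
microscope.

## 8. Problem sizes and reproducibility

Simulation checks run on the coarsened lattices (diffusion/immobilization at
dx = 50 nm, directed motion in the scaled mode at dx = 30 nm), with
steady-state windows of 300–2000 s and 2–8 seeds per condition; the
acceptance script uses 8 seeds per nucleoid length for the spacing slope and
150 duplication replicates. Every stochastic component takes an explicit
integer seed and is exactly reproducible; CLI runs write their fully
resolved configuration and seed next to their outputs. Known limitations:
polymer identity is not tracked (filament statistics use contiguous runs);
the generic `run_ssa` surface is for small models and contracts, not
production-scale lattices; and the diffusion/immobilization model's marginal
anchoring regime (Section 3) makes its two-plasmid distributions broad, so
mode-based summaries of them are noisy at desk scale.
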