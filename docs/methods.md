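# Methods

This note documents the models, conventions and numerical choices behind
`dimerkin`, in the order the pipeline uses them.

## Order parameter and embedding

A protomer pair is described by (d, α1, α2): the minimal-image
centre-of-mass distance and, per protomer, the unsigned 3-point angle at its
COM between the direction to its TM1 COM and the direction to the partner's
COM. Angles live in [0, π]; we compute them in full 3D by default (a
membrane-plane projection is available via `compute_cvs(..., project_xy=True)`
— with planar or near-planar geometries the two agree). COMs use backbone
beads only, unweighted: this is stable under sidechain coarse-graining
choices. For clustering, frames are embedded as
(d sin α1, d cos α1, d sin α2, d cos α2); the embedding is invertible for
d > 0 and the norm of each coordinate pair equals d, which is used to apply
the far-field rule directly in embedded space.

Because the two protomers are identical, every trajectory is duplicated with
α1 and α2 exchanged before any statistics are collected. All downstream
count matrices are then exactly invariant under the swap permutation of
microstates.

## Synthetic worlds

The generator produces overdamped Langevin (Euler–Maruyama) dynamics of two
orientable points in a periodic square membrane patch, in reduced units
(kT = 1, nm, μs). Angles are never integrated directly: the state is
positions plus orientation angles, forces on (d, α1, α2) are mapped by the
chain rule, and the CVs are recomputed from the configuration, so the
non-Euclidean CV geometry is handled exactly. Determinism: trajectory i of a
world with seed s uses NumPy Generator seed s + i; noise is drawn outside
the jitted stepper, so results do not depend on the compiler.

Stated world defaults, and why:

- box 15 nm — a typical two-receptor coarse-grained membrane patch;
- translational diffusion 5 nm²/μs per protomer (relative 10 nm²/μs
  ≡ 10 μm²/s), the order observed for lipid-embedded receptors in
  coarse-grained membranes;
- rotational diffusion 15 rad²/μs for the two-basin benchmark world: fast
  enough that the unbound orientational relaxation (~0.03 μs) is far below
  the basin lifetimes (so the monomeric state is one kinetic entity), slow
  enough that a passage between differently-oriented basins cannot complete
  within one counting lag (see "Lags" below);
- bound basins are Gaussian wells on (d, α1, α2) (centres at d = 3 nm,
  depths 5–5.5 kT, widths 0.4 nm / 0.5 rad in the benchmark);
- an orientation-gated steric wall (`StericWall`): a half-harmonic repulsion
  whose contact distance relaxes from 4.6 nm to 2.5 nm inside a Gaussian
  opening (width 0.6 rad) around each well's orientation. This encodes shape
  complementarity — two receptors can only approach closely in compatible
  orientations — and is what makes bound basins *kinetically disconnected*:
  reorienting while in contact is sterically forbidden, so interconversion
  must pass through large separations, i.e. through the unbound state.

The equilibrium oracle integrates p(d, α1, α2) ∝ J(d) e^(−U/kT) on a grid,
with J the exact torus pair-distance Jacobian (2πd/L² for d ≤ L/2, clipped
arcs beyond), so free diffusion reproduces the ideal-gas pair-distance law
out to the box diagonal.

What the generator does **not** emulate: internal receptor conformational
dynamics, membrane deformations and lipid-mediated interactions, hydrodynamic
coupling, thermostat artifacts of real MD, and anomalous (crowded) diffusion.
A green end-to-end test therefore establishes that the *estimators* recover a
known CV-level truth — not that any particular receptor behaves this way.

Discrete truths are reversible chains built from symmetric weight matrices
with planted metastable blocks (π ∝ row sums by construction); biased
ensembles are Metropolis reweightings, reversible with respect to
π_i e^(−b_i). These are the unit-test substrate for the MSM, PCCA+ and TRAM
estimators.

## Markov state models

k-means (k-means++ seeding, fixed seed, ≤ 500 iterations) is fitted only on
frames with d < L/2; all farther frames share one reserved far-field
microstate. Transition counting is sliding-window, trajectories never
concatenated. The reversible maximum-likelihood transition matrix uses the
standard self-consistent edge-variable iteration, run to a max |ΔT| of 1e-12;
estimation is restricted to the largest strongly connected component of the
count graph (dropped states are reported). Eigenvalues are computed on the
π-symmetrized matrix (sorted by modulus, ties by real part), implied
timescales are t_i = −τ/ln λ_i with eigenvalue 1 beyond the Perron root
reported as ∞ and flagged. Uncertainties come from resampling whole
trajectories with replacement (means and 5/95% percentiles). The
Chapman–Kolmogorov test compares T(τ)^k set-occupation predictions with
models re-estimated at lag kτ.

### Lags

The pipeline uses two lags with the same discretization:

- a short **detection lag** (default 4 recorded frames) for the component
  decomposition. Connectivity between components is judged on the *support*
  of the count matrix, and any passage between components faster than one
  lag window produces a spurious direct count; the detection lag is chosen
  so such passages are essentially impossible (rotating by ~π within the
  window is a > 5σ event for the stated world);
- a longer **rate lag** (default 8× the detection lag) for quantitative
  kinetics, chosen where the implied timescales have converged — at desk
  scale the discretization error at the detection lag shortens the slow
  timescales noticeably. Rates are read from the coarse matrix via the exact
  matrix logarithm (with a p/lag fallback if the generator has negative
  entries). In the source system that motivated this design the slow
  processes are four orders of magnitude above the lag, so one lag serves
  both purposes there; at desk scale the separation is only ~100×.

## TRAM

The multi-ensemble estimator solves the standard TRAM fixed point (see the
docstring of `dimerkin.tram` for the equations) with log-space accumulation,
a gauge fixing that normalizes the unbiased state weights, and convergence
on max |Δf| (default 1e-9 kT, cap 100 000 iterations; tightening to 1e-12
changes the transition matrix by < 1e-7). Samples with identical
(microstate, bias-vector) are aggregated with multiplicities, which makes
state-wise-constant-bias problems (discrete truths) cheap without changing
the estimate. Ensembles whose bias energies agree on every frame are merged
before estimation — TRAM keeps one transition matrix per thermodynamic
state, so merging is what makes a zero-bias duplicate of the unbiased
ensemble exactly equivalent to pooling the data. With a single unbiased
ensemble the estimate coincides with the reversible MLE (verified to 1e-8).
Bias energies are always recomputed from frame CVs (U_b = ½k_d(d−d₀)² +
½k_α[(α1−α1₀)² + (α2−α2₀)²], reduced by kT; R = 0.0083145 kJ/mol/K for
physical units), never taken from stored simulation energies.

Unbound-state resampling: microstates of the preliminary unbound component
with no counts to or from the outside (either direction) are merged into a
small number of replacement states (k-means on their centres when
coordinates are given, one state otherwise), with the old→new mapping
returned and total frame count conserved.

## PCCA+, unbound detection, components

PCCA+ uses the dominant eigenvectors of the π-symmetrized transition matrix
and the Deuflhard–Weber inner-simplex vertex search; memberships are
barycentric coordinates clipped to the probability simplex, crisp labels by
argmax (ties to the lower index). The unbound cluster is found by scanning
n_clusters upward and accepting the first cluster whose members all have
d > 4.2 nm *and* a flat angular distribution. "Flat" is operationalized as:
circular resultant length (on doubled angles) below 0.3 for both α1 and α2,
and at least 3 of the 4 angular quadrants (split at π/2) each holding ≥ 2%
of the cluster's weight; the reserved far-field state carries NaN angles and
is excluded from the angular statistics.

Components are connected components of the bound clusters on the undirected
count-support graph. They are labelled by the π-weighted circular means of
their members' angles (mean < π/2 → "0", > π/2 → "π"); components below
0.5% of the bound weight are labelled "other". Macrostates merge each
cluster with its swap mirror (majority image of its members under the
nearest-neighbour α1↔α2 permutation); unpaired mirrors are kept unmerged
with a warning, and the pairing is an involution.

## Coarse-graining

The reduced transfer matrix solves
Σ_{i∈I,j∈J} A⁻¹_ij π_i = B⁻¹_IJ π̂_I, A = I + 1πᵀ − T, B = I + 1π̂ᵀ − T̂.
For reversible T, diag(π)·A is symmetric, and this convention yields a
coarse matrix that is exactly row-stochastic with stationary vector exactly
the aggregated π (the transpose-equivalent conventions do not; the identity
partition returns T unchanged either way, so the convention was fixed by the
stationarity test). Exactly disconnected chains are coarse-grained per
connected component and assembled block-diagonally. Negative entries beyond
a tolerance raise a "kinetically inconsistent partition" error; the default
tolerance is round-off (1e-10), and the pipeline relaxes it to 1e-3 because
sampled models routinely carry O(1e-4) negative entries that are noise, not
inconsistency.

A caution on scope: without a spectral gap, this construction does not
dominate naive flux projection in short-time occupation tracking (projection
reproduces the one-step aggregated propagator exactly). With metastable
structure — the regime coarse-graining is for — it tracks the aggregated
occupation curves at least as well as projection at every horizon, which is
what the tests assert.

## Transition path theory

Forward committors solve the standard restricted linear system; net reactive
flux f⁺_ij = max(0, f_ij − f_ji) with f_ij = π_i(1−q_i)T_ij q_j; pathways
are removed greedily by maximum-bottleneck (widest-path) search, reporting
per-pathway flux fractions. Umbrella positions are the microstates with
committor above 10% (sink excluded) toward each component's most probable
microstate.

## Contacts and interfaces

A contact is a residue pair (one residue per protomer) with any backbone
bead pair within 0.8 nm (minimal image), counted once per frame. Dimeric
microstates have P(≥ 10 contacts) ≥ 0.9 over their unbiased frames
(inclusive threshold; exactly 0.9 is dimeric). Macrostate contact maps are
π-weighted sums over dimeric microstates; the normalized version (divided by
the summed weight) is used for interface naming so macrostates of different
weight are comparable. Region-level counts are expected contacts per frame;
regions with more than 3 are primary, more than 0 and up to 3 parenthetical
(exactly 3 → parenthetical), rendered in sequence order with sides ordered
lexicographically for asymmetric interfaces. Per-residue averages pool the
two (identical) protomer sides.

## Reaction-diffusion model

Units: lengths nm, concentrations μm⁻², D in μm²/s, rates μs⁻¹ (note
1 nm²/μs = 1 μm²/s numerically). The diffusive rate is
k₊₁ = 4πD/ln(λ/r₀) with λ = (πc)^(−1/2) (natural logarithm), valid for
λ > r₁ > r₀; grid points violating this are flagged invalid. r₀ is the
π-weighted mean separation in the unbound cluster; the escape radius r₁
defaults to 7 nm; f_ass/f_esc are measured from excursions that start when d
crosses r₀ and end at association or at r₁. γ = f_ass/(1 − f_esc·p_ass)
with p_ass = 1 − ln(λ/r₁)/ln(λ/r₀); k₋₁ = (1−γ)/γ · Σ k_enter follows from
the definition of γ. Per-component capture probabilities partition γ in
proportion to the entry rates, so Σ_I k_on,I = γ·k₊₁. Equilibrium fractions
solve the full linear scheme unbound ⇌ encounter ⇌ component I (detailed
balance makes the conditional bound fractions exactly the reduced-matrix
stationary ratios). The effective first-order association rate composes the
diffusive supply and the chemical step in series,
k_eff = (1/(γ_I k₊₁ c) + 1/k_enter,I)⁻¹: it vanishes as c → 0 and saturates
at the reaction-limited entry rate at high density. The conventional ×4
coarse-grained-time factor is applied exactly once, when rates are extracted
from the reduced matrix (time_scale=1 for synthetic worlds).

The diffusion estimator fits Var[Δd] vs lag; the window must sit well below
L/2 — near the box diagonal the torus geometry compresses the radial
coordinate and biases D downward by tens of percent (measured ~30% for a
window straddling L/2 in a 15 nm box). Recovery is within 5% for a (4, 6) nm
window in that box.

## Lifetime semantics

T_off = 1/k_exit from the reduced matrix is the π-weighted exit rate of a
component. The matching independent observable is the component-indicator
autocorrelation relaxation λ (with k_off = λ(1−p) in the two-state
reduction), which the cross-relaxation-preserving coarse matrix is built to
reproduce. First-passage times from the basin core are systematically longer
and edge-entry dwell times shorter — all three differ by recrossing
conventions, so comparisons must match definitions.

## Known limitations

- The component detector is support-based; with extremely long trajectories
  the probability of a single faster-than-lag passage between components
  rises, so the detection lag must shrink as sampling grows.
- PCCA+ uses the index-search memberships without the optional simplex
  optimization; for strongly overlapping clusters the memberships are
  approximate (crisp labels are unaffected in all tested regimes).
- The TRAM transition-matrix output for states never visited in the unbiased
  ensemble is an identity-row placeholder (flagged by a warning).
- The reaction-diffusion scheme treats components as single kinetic species;
  intra-component structure enters only through the reduced matrix.
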