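# dimerkin

Dimerization kinetics of membrane receptors from trajectory data.

Two receptors diffusing in a membrane associate, form distinct dimer
interfaces, and dissociate again. `dimerkin` turns trajectories of such a
protomer pair — reduced to the order parameter (d, α1, α2): the
centre-of-mass separation and the two unsigned angles each protomer's TM1
direction makes with the partner — into a quantitative kinetic model:

1. **Markov state model.** Frames are embedded as
   (d sin α1, d cos α1, d sin α2, d cos α2), swap-duplicated (α1 ↔ α2, the two
   protomers are identical), discretized by k-means with a reserved far-field
   microstate (d ≥ L/2), and a reversible transition matrix is estimated by
   maximum likelihood, validated with implied timescales and the
   Chapman–Kolmogorov test.
2. **Multi-ensemble reweighting (TRAM).** Umbrella-restrained ensembles with
   per-frame bias energies are combined with the unbiased data into one
   statistically optimal estimate of the unbiased stationary distribution and
   transition matrix.
3. **Kinetic components.** PCCA+ clusters the microstates; the monomeric
   (unbound) cluster is the smallest clustering level exhibiting a cluster of
   purely large-separation, orientation-flat microstates. Removing it splits
   the bound states into kinetically disconnected components labelled by the
   orientation angles (C00, Cππ, C0π, Cπ0); clusters merge with their
   protomer-swap mirrors into macrostates.
4. **Coarse-graining.** The transfer matrix is reduced to macrostate or
   component level by the cross-relaxation-preserving construction
   Σ_{i∈I,j∈J} A⁻¹_ij π_i = B⁻¹_IJ π̂_I with A = I + 1πᵀ − T and
   B = I + 1π̂ᵀ − T̂, which reproduces the aggregated stationary law exactly.
   Transition-path theory (committors, net-flux pathway decomposition,
   umbrella-center selection) runs on either level.
5. **Contacts and interfaces.** Inter-protomer residue contacts (backbone
   beads within 0.8 nm, minimal image) define dimeric microstates
   (≥ 10 contacts with probability ≥ 0.9), stationary-weighted contact maps,
   and interface names such as `TM1,2,(H8)/TM1,2,(H8)`.
6. **Reaction-diffusion extrapolation.** The two-step scheme
   A + B ⇌ A·B ⇌ AB with the 2D dilute diffusive rate
   k₊₁ = 4πD / ln(λ/r₀), λ = (πc)^(−1/2), and the
   Northrup–Allison–McCammon capture probability
   γ = f_ass / (1 − f_esc·p_ass) predicts k_on(c), k_off, lifetimes and
   equilibrium dimer fractions at arbitrary 2D receptor concentrations.

A first-class **synthetic-data module** generates ground-truth systems at
desk scale — Brownian-dynamics trajectories of two orientable protomers in a
periodic membrane patch with orientation-gated excluded volume and planted
bound basins, umbrella-restrained counterparts, and discrete reversible
chains with known stationary laws and bias energies — so every stage of the
pipeline is testable against an independent oracle.

## Worked example

`examples/04_kinetic_components.py` simulates a world with two bound basins
(both angles ≈ 0, depth 5.5 kT; both angles ≈ π, depth 5 kT) and runs the
full pipeline:

```
simulated 16 x 120 us
unbound cluster found at n_clusters = 3
kinetically disconnected components: ['C00', 'Cpipi']
  C00: stationary weight 0.0845
  Cpipi: stationary weight 0.0646
macrostates: [('C00', [1]), ('Cpipi', [0])]
encounter distance r0 = 6.71 nm
component-level coarse-grained transfer matrix (lag 120 ns):
[[0.9755 0.0121 0.0124]
 [0.123  0.8756 0.0014]
 [0.1634 0.0018 0.8348]]
component  k_off_per_us  T_off_us
      C00      1.109094  0.901637
    Cpipi      1.508851  0.662756
```

The two planted basins are recovered as disconnected components with the
correct orientation labels; their stationary weights agree with numerical
Boltzmann integration of the world's potential within sampling error, and
the lifetimes T_off = 1/k_off agree with the independently measured
basin-indicator relaxation rate. The other examples cover the synthetic
worlds (`01`), MSM validation (`02`), TRAM reweighting against a planted
discrete truth (`03`), contact maps and interface naming (`05`) and the
concentration scan (`06`).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full analysis from scratch: it simulates the synthetic
two-basin world with the given seed, builds the Markov state model,
identifies the kinetic components and their lifetimes, and runs the
reaction-diffusion concentration scan, printing a summary and writing the
JSON result file.
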