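# Methods

## The model

`polyion` studies 30-residue homo-polypeptide polyelectrolytes (polyD,
polyE, polyK, polyR; neutral polyGS control) as coarse-grained bead-spring
chains with explicit ions in implicit solvent.  One bead represents one
residue and carries that residue's formal charge (−1 for D/E, +1 for K/R,
0 for G/S).  The energy, in units of kT, is

* **bonds**: harmonic, `U = ½ k (r − b)²` between consecutive beads, with
  stiffness `k = 100 kT/Å²` and rest length `b = 3.8 Å` (the Cα–Cα virtual
  bond).  The implied thermal bond-length width is 0.1 Å, so the chain is
  effectively freely rotating with near-fixed bond lengths.
* **excluded volume**: Weeks–Chandler–Andersen (purely repulsive,
  truncated-shifted Lennard-Jones, ε = 1 kT) between all non-bonded pairs.
  Per-species diameters combine by arithmetic mixing.  Defaults: charged
  beads 3.8 Å; the neutral control bead 1.0 Å (a deliberately weak excluded
  volume so the control samples a near-ideal coil, consistent with its
  measured scaling exponent ≈ 0.5); monovalent cations 2.3 Å, divalent
  cations 3.0 Å, anions 3.6 Å.
* **electrostatics**: pairwise Coulomb `U = λ_B q_i q_j / r` with the
  Bjerrum length `λ_B = e²/(4πε₀ ε_r k_B T)` ≈ 7.1 Å at T = 300 K and
  ε_r = 78.5, evaluated under the minimum-image convention and truncated
  at half the box edge.  Truncated minimum-image electrostatics (rather
  than Ewald/PME summation) is a deliberate desk-scale simplification: the
  observables analyzed here are ordinal screening and valency trends, not
  absolute energies.  Bonded neighbours interact through the bond and
  Coulomb terms but are excluded from WCA, the standard bead-spring
  convention (otherwise the WCA shoulder at 2^{1/6}·3.8 Å would fight the
  bond rest length).

Ion content derives from a `SaltSpec`: monovalent counterions first cancel
the chain's net charge exactly, then whole salt formula units are added —
`round(c·N_A·V)` units, one cation + one anion for 1:1 salt, one divalent
cation + two anions for 2:1 salt — so every configuration is exactly
charge-neutral.  The "0 M" condition is a counterion-only system.  The box
is cubic and periodic, default edge 75 Å, constant volume.

## Sampling

Metropolis Monte Carlo with two move types: single-particle displacements
(uniform in a cube of half-width `max_displacement`; ions are wrapped into
the box, chain beads stay unwrapped so the chain is always whole), and
chain pivots (a uniform random rotation of the shorter arm about a random
interior bead, which preserves all bond lengths).  A sweep is one attempted
move per particle; a chain-bead move is a pivot with probability
`pivot_probability` (default 0.2).  `max_displacement` is auto-tuned toward
30–50 % acceptance every 100 sweeps **during equilibration only** and then
frozen, so the production chain is strictly Markovian.  Acceptance rates
outside (0.05, 0.95) are recorded as warnings in the ensemble metadata.
Frames are stored every `sample_interval` sweeps after
`equilibration_sweeps`; frame spacing is therefore in sweeps, and
relaxation times from MC ensembles are reported in sweeps with no claim of
physical-time equivalence.

The initial configuration is a straight chain through the box centre with
ions placed uniformly at random (hard overlaps rejected).  For the charged
30-mer the measured Rg autocorrelation time is ≈ 600 sweeps, so the
default 10⁴ equilibration sweeps cover many relaxation times and a
5 × 10⁴-sweep production run yields ~60–80 effectively independent frames.

The Monte Carlo inner loop is compiled with numba; determinism is per-seed
exact (identical parameters and seed give bit-identical trajectories).

## Estimators

**Internal-distance scaling.**  For each sequence separation s, the
profile averages over all residue pairs (i, i+s) and all frames; the
default estimator is the RMS pair distance, which makes the rod limit
exactly ν = 1.  A subchain-Rg estimator (RMS Rg of contiguous segments)
is available because "Rg versus |i−j|" phrasing is common; for
self-similar ensembles the two agree to within 0.05.  ν is the OLS slope
of log R(s) vs log s.  The default window for a 30-mer is s ∈ [2, 15]:
s = 1 is fixed by the bond length and carries no scaling information, and
separations beyond half the chain have few pairs and end effects.  The
window is a parameter and is always reported with the fit, together with
R², the OLS standard error of the slope, and the prefactor.

**Relaxation time.**  The Rg autocorrelation uses the biased (1/n)
normalization.  τ comes from nonlinear least squares of exp(−Δ/τ) over
lags 1 … the first lag where the ACF drops below 0.05, capped at 20 % of
the series length (long lags are noise-dominated; the cap bounds the
variance of the fit).  The initial guess is the 1/e crossing.  The
residual RMSE is reported so multi-exponential decay is visible; τ below
one frame spacing is flagged unresolved rather than trusted.

**Ion adsorption.**  An ion is adsorbed when its minimum-image,
centre-to-centre distance to any chain bead is ≤ 4 Å (boundary inclusive).
The cutoff is configurable and always recorded.  At one-bead-per-residue
resolution there is no "any peptide atom" surface, so centre-to-centre
distance is the only meaningful choice; absolute counts are therefore not
comparable to atomistic values, while trends across conditions are.  The
default species filter counts counterions (charge sign opposite the
chain's net charge); "all", "cations" and "anions" modes exist, and the
joint (Rg, count) histogram uses 1 Å × 1-ion bins.

**PCA.**  Frames are superposed by centroid removal and Kabsch proper
rotation (det +1, so mirror images are never matched) onto the mean
structure, with the mean recomputed and the alignment repeated once.  PCA
is an SVD of the centred, flattened 3N coordinates; eigenvalues use the
1/(F−1) normalization so they sum to the total coordinate variance.
Component signs are fixed (largest-magnitude loading positive).  For
cross-ensemble displays the components are fitted on one ensemble and the
other is aligned to the same mean structure and projected; fitting on the
union of both ensembles is also supported, and the union is the fairer
shared space when neither ensemble is privileged — projections onto one
ensemble's own leading components systematically understate the spread of
the other.  Occupied conformational area is summarized as the product of
central 95 % spans of PC1 and PC2 (robust to single outlier frames).

**Homorepeat census.**  Repeats are maximal runs over {D,E} or {K,R};
any other character breaks a run; minimum length 10 by default.  The
protein-count curve counts each protein once via its longest run, in two
declared modes: `cumulative` (min ≤ r ≤ L, matching a
"cumulative value up to L" reading) and `at_least` (r ≥ L).  Composition
ratios (e.g. n(E)/n(D)) are totals across hits, with an infinite-ratio
flag when the denominator member is absent.

## What the synthetic ensembles do and do not emulate

The reference generators (rod, 3-D Hilbert-curve compact chain, freely
jointed chain, pivot-algorithm self-avoiding walk, AR(1)/OU series) have
exactly known scaling exponents and relaxation times and anchor every
estimator to a closed form.  The CG Monte Carlo ensembles reproduce the
*statistical structure* of polyelectrolyte conformational ensembles —
extended scaling (ν ≈ 0.8–0.9) for fully charged chains, near-ideal
behaviour for the neutral control, monotone compaction with added salt,
stronger compaction by divalent cations, counterion enrichment at the
chain anticorrelated with chain size, and negligible adsorption on the
uncharged control.

They do **not** encode atomistic chemistry: side-chain geometry, specific
solvation, and hydration thermodynamics are absent, so chemically distinct
residues with equal charge (D vs E, K vs R) are indistinguishable here,
and absolute Å or ion-count values are not comparable to all-atom
simulations.  Passing tests demonstrate correctness of the estimators and
the ordinal electrostatic physics, not chemical specificity.

## Problem sizes and numerical choices

Chains are 30 beads (512 for the compact reference); boxes 75 Å;
desk-scale runs use 5 × 10⁴–2.2 × 10⁵ sweeps with 5 independent seeds for
condition comparisons, sizes at which the tested effects exceed their
seed-to-seed spread (charged-chain mean Rg: 0 M 19.4 ± 0.4 Å,
0.25 M 17.9 ± 1.5 Å, 0.125 M 2:1 salt 15.9 ± 1.3 Å).  Replicate seeds are
derived from a single global seed by `numpy.random.SeedSequence` mixing of
(seed, system, condition, replicate).  Statistical acceptance checks use
one-sided paired tests across seeds at α = 0.05, and χ² Boltzmann checks
thin the Markov chain to approximately independent samples first.
Degenerate inputs fail loudly: zero-variance series, collinear PCA
references (fallback with warning), wrapped chains (bond > box/2), and
non-neutral ion assignments all raise.

## Known limitations

* Truncated minimum-image electrostatics; no Ewald summation.  An
  extended chain (contour 110 Å) in a 75 Å periodic box interacts weakly
  with its own images; this is accepted at desk scale.
* Constant-volume sampling only; no pressure coupling.
* Uniform bead masses in Rg (no atomic-mass weighting exists at this
  resolution).
* The relaxation-time model is single-exponential by construction;
  multi-exponential decay shows up only through the reported RMSE.
* Proteome-scale repeat statistics depend on the proteome release used;
  the scanner is tested against a regular-expression oracle on synthetic
  sequences, not against any fixed public proteome.
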