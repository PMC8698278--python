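# Methods

## Scope and intent

`gomelt` is a desk-scale surrogate for a class of protein-stability
studies that combine (i) replica exchange with solute scaling (REST2)
to measure thermal melting of a β-barrel protein and its destabilised
point mutant, (ii) two-state thermodynamic fits of native-contact
melting curves, and (iii) bidirectional alchemical free-energy
estimates over a folded/unfolded thermodynamic cycle.  The package
reproduces the *machinery* of such a study — the estimators, the
exchange scheme, the fitting and the cycle algebra — on a synthetic
system small enough to sample exhaustively on one CPU in minutes.  It
does not attempt atomistic accuracy: explicit solvent, all-atom force
fields and secondary-structure assignment (DSSP) are out of scope by
design, and a contact-based proxy stands in for per-strand secondary
structure.

## The synthetic system

The default structure is an idealised antiparallel β-barrel: 8 strands
of 8 residues on a cylinder of radius 6.5 Å (Cα spacing 3.8 Å along
each strand, alternating direction), joined by 3-residue loops that
bulge outward and past the barrel ends, 85 residues in total.  At a
contact cutoff of 8 Å with a minimum sequence separation of 3 the
barrel has 232 native Cα contacts: every cyclically adjacent strand
pair shares contacts, so the barrel is closed (strand 8 packs against
strand 1).  The two sheets of the barrel are taken as strands
(β1, β2, β3, β6) and (β4, β5, β7, β8), following the standard
partition for the SOD1 barrel family this geometry emulates.

### Hamiltonian

Energies in kJ/mol, distances in Å, kB = R = 0.0083145 kJ/mol/K.

* Native contacts: 12-10 Gō well, `w·ε·[5(r0/r)^12 − 6(r0/r)^10]`,
  minimum −w·ε exactly at the native distance r0.  ε defaults to
  4.5 kJ/mol, calibrated once so the barrel's melting midpoint falls
  inside the 300–698 K ladder (see below).
* Bonds: harmonic, ½·k·(r−b0)², k = 40 kJ/mol/Å², with per-bond b0
  taken from the native structure (scalar 3.8 Å fallback when no
  native reference exists, e.g. for toy chains).
* Bending: ½·k_a·(cosθ − cosθ0)² on every virtual bond angle, with
  native reference angles; k_a defaults to 15 kJ/mol and the term is
  disabled when no native reference is supplied.  This term is a
  deliberate design choice: without chain stiffness the barrel melts
  by gradual, strand-by-strand fraying, the melting curve is so soft
  that the fitted T_m fluctuates by tens of kelvin between runs, and a
  single-residue contact perturbation is undetectable.  Real β-strands
  are stiff; restraining the virtual angles makes strands behave as
  cooperative units and produces the two-state-like melting the
  pipeline is meant to analyse.
* Excluded volume: truncated-shifted repulsion `ε·[(σ/r)^12 − 1]` for
  non-native, non-bonded pairs closer than σ = 3.0 Å.  σ sits just
  below the closest non-native approach in the native barrel (3.2 Å),
  so the native state is unstrained.

### Monte-Carlo sampling

Single-bead Metropolis moves: a Gaussian displacement (SD 0.35 Å) or a
crankshaft rotation of one bead about the axis through its two
neighbours (angle uniform in ±1.5 rad), chosen with equal probability;
one sweep = N attempted moves.  Both moves are symmetric proposals, so
detailed balance holds; the test suite verifies Boltzmann sampling
against closed-form and importance-sampling oracles on enumerable toy
systems.  Time is measured in sweeps and stands in for nanoseconds in
the emulated protocol; the protocol's proportions (exchange cadence ≪
block length ≪ run length) are preserved rather than its absolute
times.

### The mutation surrogate

A destabilising point mutation is modelled at contact resolution: the
native contacts of one residue lose their well depth.  The default is
`scale` mode with factor 0 on residue 46 — a well-packed position in
strand β5 (8 contacts, reaching β4 and β6), analogous to a buried
side-chain truncation adjacent to sheet 2.  The site matters for the
strand-resolved readout: in a closed barrel every strand touches one
same-sheet and one cross-sheet neighbour, and sheet 1's within-sheet
pairs involve only β1–β3, so a β5 mutation damages sheet 2's
within-sheet contacts (β4–β5) while its cross-sheet damage lands on
β6, leaving sheet 1's within-sheet content untouched — a clean
"sheet 2 unfolds first" signature.  Scaling to zero rather
than deleting the pairs keeps the contact *list* intact, so Q_N is
evaluated over the same native set for both variants; deleting the
pairs would silently redefine the mutant's reaction coordinate (the
removed, fraying-prone pairs leave the denominator) and bias the
mutant's apparent stability upward.  `delete` mode is available for
users who want map-level removal.

## REST2 scheme

The solute-temperature ladder spans T0 = 300 K to T_max = 698 K
(12 rungs by default) with λ_m = T0/T_m.  Plain geometric spacing
places no extra rungs where the heat capacity peaks, and the pair
straddling the cooperative transition then falls below useful exchange
rates; the pipeline therefore tunes the spacing by default: short
warm-started pilot runs measure per-pair acceptance and rung
temperatures are redistributed in ln T so the estimated difficulty
−ln(acceptance) accumulates evenly (endpoints fixed).  Two to three
iterations lift the worst pair to ≈ 0.2, comfortably above the 0.15
operating point.  Each rung is
propagated at the base temperature with its Hamiltonian scaled by λ
(the whole Gō energy is "solute"; the surrogate has no solvent terms,
so the effective temperature is exactly T0/λ).  Exchanges between
adjacent rungs are attempted every 10 sweeps, alternating even and odd
pairs, with the standard REST2 Metropolis criterion
Δ = β0(λa−λb)(E_b−E_a).  One master seed spawns independent per-rung
move streams and one exchange stream, so runs are bit-reproducible.
The mean-field effective-temperature estimate (energy matching against
an unscaled temperature scan) is implemented for completeness and
reduces to T0/λ for a harmonic solute.

## Observables and errors

Q_N counts a native pair as formed when its distance is ≤ 1.2·r0.
Melting curves discard the first 40% of each rung's time series as
burn-in and report block means over 12 contiguous blocks with the SEM
of block means — mirroring the burn-in/block-analysis conventions of
the emulated protocol.  Per-strand content is the formed fraction of
native contacts touching a strand, normalised so the native structure
scores 1; per-sheet content uses only contacts with both members
inside one sheet, which is where a within-sheet perturbation is
visible without dilution by cross-sheet pairs.  Free-energy surfaces
are −kB·T·ln of the normalised 2D histogram of the two within-sheet
contact counts, minimum shifted to zero, empty bins masked.

## Two-state fits

Q_N(T) is fitted as f_F·(qf0+qf1·T) + (1−f_F)·(qu0+qu1·T) with
f_F = 1/(1+exp(−ΔG_u/RT)) and Gibbs–Helmholtz
ΔG_u(T) = ΔH_vH(1−T/T_m) (+ optional ΔC_p term, default off — the
curves are near-sigmoidal and 12 points cannot constrain ΔC_p).
Weights are 1/sem with zero-sem points given the median sem.  Baseline
intercepts are bounded to [−1, 2] and slopes to ±0.01 K⁻¹ to keep the
sigmoid identifiable on broad transitions.  When two variants are
measured on the same observable the pipeline fits them *jointly* with
shared baselines (T_m and ΔH_vH per curve, one baseline pair): the
baselines are physically common, and freeing them per-variant lets the
baseline/enthalpy trade-off dominate the extrapolated ΔΔG_u(310 K).
By default the paired fit also ties ΔH_vH across the two variants:
a single-residue contact perturbation changes the transition's
cooperativity by a few percent at most, far below what 12-point curves
resolve (fitted ΔH differences of ±15 kJ/mol are pure noise), and an
unresolved ΔH difference dominates — and can flip the sign of — the
Gibbs–Helmholtz extrapolation to 310 K.  With a shared ΔH the
comparison reduces to the classic melting-shift estimate
ΔΔG_u(T) = ΔH·T·(T_m^mut − T_m^wt)/(T_m^wt·T_m^mut).
ΔΔG_u(T) = ΔG_u^mut − ΔG_u^wt (negative = destabilising) carries a
first-order uncertainty from the per-fit covariances; with a shared
ΔH this is conservative (the ΔH contribution largely cancels in the
difference but is counted twice).

## Paired replicates and the null control

One pipeline run samples several (default 3) independent replicate
pairs: within a pair, the wildtype and mutant branches share one
sampling seed (common random numbers), and each rung contributes its
post-burn-in block means to a pooled melting curve, so the statistical
error of the fitted T_m shrinks with both run length and replication —
a single pair's paired ΔT_m noise (~7 K at the default length) is
comparable to the shift being measured, while the pooled estimate
resolves it.  The null branch applies
`scale` with factor 1 — a no-op Hamiltonian — seed-matched to
wildtype replicate 0, and must reproduce that branch bit-for-bit; the
pipeline records the identity, which doubles as an end-to-end
determinism check of the whole REST2 stack.  Consequence: the null
ΔT_m is exactly 0.

## Alchemical stage

The pmx/GROMACS transition machinery of the emulated protocol is out
of scope; the alchemy module works on *work values*.  The synthetic
generator draws the unique equal-variance Gaussian pair consistent
with the Crooks fluctuation theorem: forward work N(ΔG+βσ²/2, σ²),
negated-reverse N(ΔG−βσ²/2, σ²).  Defaults mirror the emulated
protocol's shape: 10 folded and 10 unfolded geometries, 50 work values
per direction per geometry, work SD 4 kJ/mol (typical of ~100 ps
alchemical transitions), per-geometry ΔG scatter SD 3 kJ/mol, and
endpoint means 20 (folded) and 9 (unfolded) kJ/mol so the cycle closes
near ΔΔG_u ≈ −11 kJ/mol, the magnitude class of a strongly
destabilising point mutation.  CGI takes the crossing of the two
fitted Gaussians (midpoint closed form for equal variances, otherwise
the quadratic root between the means; no root between the means is a
hard error); a percentile bootstrap gives the CI.  BAR is solved
self-consistently by bracketing + Brent and serves as the independent
cross-check.  The cycle closes per-geometry-first:
ΔΔG_u = ⟨ΔG⟩_unfolded − ⟨ΔG⟩_folded, SEM over geometries in
quadrature (SD reported alongside, since conventions differ).
Folded/unfolded geometry extraction from the REST2 run uses Q_N
thresholds (≥0.8 at the bottom rung, ≤0.2 at the top rung),
config-exposed.

## Problem sizes and numerical choices

The default experiment (85 residues, 12 rungs, 2×10⁵ sweeps per
branch, 3 replicate pairs, exchange every 10 sweeps, recording every
50) is the package's desk-scale operating point: all three branches and the estimator
checks complete in well under half an hour on one CPU, with the MC
kernel JIT-compiled via numba.  Fits use `scipy.optimize.least_squares`
(trf, xtol = ftol = 10⁻¹²); BAR bisection tolerance 10⁻⁶ kJ/mol;
histogram overflow is counted, never dropped; landscape bins with zero
samples are masked, not zeroed; a single occupied bin is a warning,
not an error.  The kernel uses fastmath; determinism is per-platform
(same machine, same seed → same trajectory), which is the
reproducibility contract the pipeline reports.

## What passing tests do and do not show

The synthetic generator emulates two-state melting with controllable
stability, a contact-level destabilising mutation, and CFT-consistent
work distributions.  It does not emulate solvent, side chains,
misfolded off-pathway states, force-field error, or the kinetic
heterogeneity of real unfolding; passing tests therefore validate the
*analysis machinery* — estimator correctness, exchange statistics,
fit recovery, cycle algebra, and the qualitative destabilisation
phenotype of a contact-deletion mutant — not any biological claim
about a specific protein.  Real deposited data (native-contact melting
curves derived from atomistic REST2 trajectories) can be imported as
TSV and pushed through the same fits and comparisons.

## Known limitations

* The Cα resolution cannot express side-chain-specific effects; the
  mutation surrogate removes whole-residue contact energetics.
* The two-state fit's T_m carries model-form uncertainty when the
  transition has intermediates; the pipeline reports fit covariance
  but cannot detect model misspecification by itself.
* Exchange acceptance dips at the rung pair straddling the transition
  (the usual replica-exchange bottleneck near a cooperative
  transition); acceptance tuning keeps every pair above the 0.15
  operating point, but replica round trips through the transition are
  still limited by basin-change kinetics, not by acceptance — at the
  default run length replicas traverse the ladder without completing
  full round trips.  A much sharper transition (larger k_a or ε) would
  require more rungs.
* Sweeps are not physical time; kinetic quantities are out of scope.
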