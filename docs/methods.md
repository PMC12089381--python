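# Methods

## The model

`phosdyn` simulates enzymatic phosphorylation of intrinsically disordered
proteins with a one-bead-per-residue, implicit-solvent coarse-grained model,
and provides the statistical machinery to certify that the chemically driven
simulation is thermodynamically consistent.

### Force field

Non-bonded interactions between beads are the sum of three terms:

* **Ashbaugh–Hatch (AH)**: a hydropathy-scaled 12-6 Lennard-Jones.  For
  `r ≤ 2^{1/6}σ_ij` the potential is `U_LJ(r) + (1−λ_ij)ε`; beyond the
  minimum it is `λ_ij·U_LJ(r)`, truncated at 2.0 nm.  σ and λ combine by
  arithmetic means.  Well depth ε = 0.8368 kJ/mol (0.2 kcal/mol).
* **Yukawa**: screened Coulomb `q_i q_j k_e/(ε_r) · e^{−r/λ_D}/r` with
  ε_r = 80, Debye length λ_D = 1 nm (≈100 mM ionic strength), truncated at
  3.5 nm.
* **Cation-π** (modified variant only): an additional 12-6 well of depth
  3.138 kJ/mol between Arg/Lys and Phe/Trp/Tyr, using the AH σ-combination.

Bonded neighbours interact through a harmonic bond
`U = ½k(r−r₀)²`, k = 8033 kJ/(mol·nm²), r₀ = 0.38 nm, and are excluded
from the non-bonded sum.  Residue parameters (mass, σ, λ, charge) are the
standard hydropathy-scale (HPS) table, shipped as
`data/hps_residues.tsv` with a source column; every constant above is a
field of `ParameterSet` and can be overridden.

Phospho-serine is a first-class bead type: charge −2 e, mass 167.05 amu
(Ser + HPO₃), σ = 0.56 nm, λ = 0.45.  These are package defaults chosen
once — a heavier, slightly larger, less hydrophobic and strongly acidic
version of serine — and are deliberately exposed for override since
published phospho-residue parameterizations differ.

Beads belonging to a rigid folded domain interact with every partner with
the attractive (hydropathy-scaled) part of AH and the cation-π well reduced
by 30% (`folded_scale = 0.7`); electrostatics are not scaled.

Engineered sequence variants: `no_charge` zeroes every charge except
phospho-serine; `average_lambda` replaces all non-Ser residues by a single
neutral bead carrying the chain-averaged mass/σ/λ (for the bundled TDP-43
low-complexity domain: 98.957 amu, 0.54331 nm, 0.64039, averaged over all
154 residues — averaging over non-Ser residues only gives 101.148 amu and
does not reproduce the reference bead, which settles how the average is
defined); `average_lambda_equi_ser` additionally redistributes the same
number of serines at equal spacing (ties toward the N-terminus).

### Dynamics

Langevin dynamics with the BAOAB splitting, default timestep 0.01 ps at
300 K.  The friction coefficient is per unit mass (units ps⁻¹).  Rigid
bodies (folded domains) translate with their total mass and rotate about
their principal axes; the body-frame angular velocity gets an
Ornstein-Uhlenbeck thermostat with a per-axis rotational drag (default
4 ps⁻¹).  Body bead positions are recomputed from the centre/quaternion
pose each step, so intra-body geometry is preserved to machine precision
by construction.  The inner loop is JIT-compiled (numba); Gaussian noise is
pre-generated per MD block by a `numpy` `Generator`, so a single seed
determines the entire run bit-for-bit.

Pair interactions are evaluated over all pairs with minimum-image
distances.  At the system sizes this package validates (toy systems of
~10 beads, fragment systems of ~60, small condensates of ~100) an exact
all-pairs kernel is faster than maintaining a cell list; the kernel is
isolated so a neighbour-list variant can be substituted for larger systems.

Stability safeguard: at strong driving an accepted swap can deposit tens
of kJ/mol of locally strained energy (the acceptance rule tolerates up to
|Δμ_P| of configurational uphill), and at low friction such a hot spot can
occasionally grow until the bond vibration is under-resolved.  When any
free-bead speed exceeds 10 nm/ps — roughly 65 thermal standard deviations,
never a thermal fluctuation — the engine redraws *all* momenta from the
Maxwell-Boltzmann distribution.  A momentum refresh is an exact canonical
operation, so it cannot bias the configurational ensemble; it is counted
(`n_thermal_resets`), and more than 50 refreshes, or non-finite
coordinates, abort the run with a diagnostic, since that means the
timestep is genuinely too large for the system.  The equilibrium and
toy-validation runs trigger zero refreshes.

### Chemistry: hybrid MD/MC

Every `mc_interval` MD steps (default 200) the engine tests whether a
phosphosite is *in contact* with the enzyme's catalytic triad: all three
distances to the active-site beads below 1 nm, minimum-image convention.
If several sites qualify, only the closest (smallest mean distance,
ties toward the lower residue number) is considered.

For the contacting site a Metropolis swap Ser⇌pSer is attempted.  With
`ΔU_P = U(pSer) − U(Ser)` computed over the terms involving the swapped
bead (exactly the full-system difference, verified to 1e-9 kJ/mol in the
tests), the forward move accepts with `min(1, e^{−β(ΔU_P+Δμ_P)})` and the
reverse with the sign-flipped exponent.  Δμ_P is the ADP−ATP chemical
potential difference; ATP/ADP are implicit.  Presets: 0, −5, −10 kJ/mol for
validation and −48 kJ/mol for the physiological ATP/ADP ratio (stored as a
named constant rather than derived from concentrations).  A negative Δμ_P
drives the cycle and breaks detailed balance.  An accepted swap changes the
bead's non-bonded parameters and mass; its velocity is redrawn from the
Maxwell-Boltzmann distribution at the new mass so the configurational
ensemble remains canonical.

In validation runs a *reservoir exchange* closes the cycle: when all three
site-triad distances exceed half the box (configurable), the site identity
is swapped with plain Metropolis acceptance `min(1, e^{−βΔU})` — a
detailed-balance move that models exchanging the substrate with an
equilibrated reservoir, as a phosphatase would.  It is restricted to
single-phosphosite systems and off by default; production runs do not use
it.

## Markov-state-model consistency check

The trajectory is discretized into four states — 1 unbound·Ser, 2
bound·Ser, 3 bound·pSer, 4 unbound·pSer.  Bound/unbound labels come from a
pluggable assigner: a distance threshold with a logistic soft probability,
or a linear VAMP projection (dominant singular function of the whitened
time-lagged covariance) with a two-component Gaussian mixture for soft
probabilities.  Frames whose soft probability falls in (0.30, 0.70) are
relabelled by transition-based assignment: they inherit the previous firm
state up to the transition midpoint.  The assigner is an interface; a
neural backend could be added without touching anything downstream.

The transition matrix is the non-reversible maximum-likelihood estimate
(sliding-window counts at lag τ, row-normalized).  First-order rates
`k_ij = T_ij(τ)/τ` live behind one function so a matrix-logarithm
estimator could be swapped in.  The dissipated heat per forward cycle
follows from local detailed balance,

    Δμ_cycle = −RT ln[(k₁₂k₂₃k₃₄k₄₁)/(k₁₄k₄₃k₃₂k₂₁)],

which is invariant under uniform rescaling of all rates, hence independent
of the MC attempt frequency.  Model quality is monitored through implied
timescales `t_i = −τ/ln|λ_i|` and the Chapman-Kolmogorov test
(`T(nτ)` vs `[T(τ)]ⁿ` with 95% bootstrap bands; agreement = overlapping
bands).  Uncertainties come from a circular block bootstrap over the state
sequence; the block length must exceed the chain's correlation time — the
default is 10τ, and the validation protocol uses 2000 frames.

Sign conventions worth spelling out: on the chemical edge, local detailed
balance gives `RT ln(k₂₃/k₃₂) = −(F₃−F₂) − Δμ_P`, so lowering Δμ_P from 0
to −10 kJ/mol *raises* that edge's log-ratio by +10 kJ/mol, and the
leading minus sign in Δμ_cycle converts this into the −10 kJ/mol of
dissipated heat.  The other three edges are driving-independent.

### Toy validation system and protocol

The desk-scale system is a G-S-G-like tri-bead substrate (inert linkers,
one reactive serine) and a rigid tetrahedral enzyme whose three sticky,
weakly negative (−0.3 e) beads form the catalytic triad; the fourth bead is
inert.  The negative triad makes phosphorylation *destabilize* the bound
complex (product release), which keeps both reaction directions
well-sampled at strong driving.  Box 8 nm, friction 0.1 ps⁻¹, MC check
every 20 steps, reservoir trigger at half the box.

Protocol (chosen once, encoded in `phosdyn.validation`): 10⁷ MD steps per
driving, one frame per MC check (0.2 ps Markov step), threshold assignment
at 1.6 nm — deliberately wider than the 1 nm catalytic contact, so the
bound·Ser state survives between contact and reaction — lag τ = 100 frames
(2 ps), 30 bootstrap replicates of 2000-frame blocks.  The lag was chosen
from an implied-timescale/affinity plateau: shorter lags under-resolve the
fast recrossings at the state boundary and bias the affinity toward zero.
At these settings the recovered Δμ_cycle matches the applied 0, −5 and
−10 kJ/mol within (typically) one bootstrap SEM.

## Kinetics

Phosphorylation rates use the exponential maximum-likelihood estimator
with uniform prior: `r = (n+1)/Θ`, `var = (n+1)/Θ²`, where the exposure Θ
sums observed first-passage times plus the full replica length per
censored replica.  Survival curves are normalized inverse cumulative
histograms; fits are least squares with either a single exponential or the
binding-conditioned model

    1 − P_c(t) = r_B r_P/(r_B−r_P) · (e^{−r_P t}/r_P − e^{−r_B t}/r_B),

whose exchange symmetry is resolved by labelling the larger rate r_B, with
the analytic `(1+rt)e^{−rt}` limit at r_B ≈ r_P.  A caveat the test suite
makes explicit: a single 500-replica dataset determines r_B only to ~40%
(few early events carry the fast-rate information), so recovery accuracy
is asserted on the estimator's mean over replicate datasets.

Order statistics: `p(t_i < t_j)` counts, per ordered pair, replicas where
site i fired first among replicas where the order is decidable; when
exactly one of the two is observed, the observed one counts as first (the
choice is flagged in reports); pairs with both censored are excluded.
Arrival-order histograms count how many other sites fired before a given
site, excluding replicas where it never fired.  Contact rates count rising
edges of the all-three-distances condition per unit time, averaged over
replicas with a replica SEM.

## Condensate analysis

Clustering is DBSCAN (ε = 1 nm, n_min = 2 neighbours by default) on
minimum-image distances, implemented in-package over a periodic k-d tree —
periodic boundaries are the reason for not calling an off-the-shelf
implementation, which serves instead as the test oracle on precomputed
distance matrices.  A chain belongs to a cluster if any of its beads does
(a majority rule is available); the condensate is the largest cluster by
chain count, ties toward the lower label.  When classifying enzymes, the
largest cluster is determined among substrate chains only, so a detached
enzyme pair can never count as the condensate.  The droplet centre is the
per-axis circular mean, which makes centring and the radial density
profiles (counts per spherical shell / shell volume, default bin 0.5 nm)
invariant under lattice translations.  Per-residue energy decompositions
split group-partner interaction energies into AH, Yukawa and cation-π
terms; the component sums reproduce the total exactly.  Dissolution onset
is reported as the first frame below 97.5% of the initial plateau
(threshold exposed).

## Synthetic generators and what they do (not) show

`synthetic` provides ground-truth inputs: an exact-jump-chain Markov ring
with a stored analytic affinity, telegraph contact signals, censored
(optionally binding-conditioned) exponential first-passage tables, and
droplet-plus-gas bead configurations with known membership (with a
straddle option that wraps the droplet across the periodic boundary).
These validate the estimators against their generating truth.  They do not
emulate conformational correlations, non-exponential waiting times, or
finite-size interfacial fluctuations of real condensates — so passing
tests certify the statistical machinery and the engine's sampling, not the
biological accuracy of the coarse-grained force field.

## Desk-scale study systems

Two reduced systems stand in for cluster-scale campaigns:

* **Sequence dependence**: the bundled TDP-43 LCD is split into matched
  50-residue fragments (261-310 vs 365-414) and simulated with a generic
  rigid enzyme whose uniformly sticky, positively charged triad caricatures
  the kinase's aromatic-philic, cationic catalytic cleft.  Three replicas
  of 8×10⁵ steps per fragment in a 6.5 nm box at Δμ_P = −48 kJ/mol give a
  pooled C-terminal/N-terminal first-phosphorylation rate ratio of ~4: the
  aromatic-rich C-terminal segment binds the triad and reacts far more
  readily, the cationic N-terminal segment is electrostatically repelled.
* **Dissolution**: eight 12-bead methionine-rich sticker chains with three
  serines each condense into a droplet at ε = 2.0 kJ/mol.  Imposing a pSer
  level before an equilibrium run (4×10⁵ steps, 10 nm box) weakens
  cohesion through the −2 e charges and reduced hydropathy; the fraction
  of chains in the largest cluster decreases monotonically with the level
  and collapses at full phosphorylation.

Problem sizes throughout (10⁷-step toy runs, 50-residue fragments,
8-chain droplets) are the package's validation scale: large enough for
every estimator to resolve its target with the quoted uncertainties,
small enough to run routinely.

## Known limitations

* The bundled CK1δ FASTA is a synthetic stand-in (correct length and
  active-site triad only); supply the real UniProt P48730 sequence and
  PDB 6RU7 / AlphaFold coordinates for production use.
* No neighbour list: system sizes beyond a few hundred beads will be slow.
* The VAMP assigner is linear; strongly non-linear bound/unbound
  boundaries would need a neural backend behind the same interface.
* pSer parameters and the cation-π depth are package defaults, not a
  published parameterization; override them for quantitative work.
* Reservoir exchange supports exactly one phosphosite per system.
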