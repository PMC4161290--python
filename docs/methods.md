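# Methods

This note records the models implemented in `esipred`, their
assumptions, the defaults that matter, and what the synthetic test
systems do and do not establish.

## Protonation microstates

An ionizable site is either proton-holding (occupancy 1: a cationic
base or a neutral acid) or not (occupancy 0: a neutral base or an
anionic acid). With `n_base` proton-accepting and `n_acid`
deprotonatable sites the net charge is

    q = (#occupied bases) − (#unoccupied acids) = k − n_acid,

where `k` is the total number of occupied sites. The microstate count
at fixed q is therefore the single binomial C(n_base + n_acid,
q + n_acid), evaluated in exact integer arithmetic (the insulin dimer
reaches ~1.2 × 10⁸ states at 1+, and larger inventories overflow
64-bit intermediates). The equivalent double sum
Σ_d C(n_base, q+d)·C(n_acid, d) is kept in the test suite as an
independent oracle.

Gas-phase rule: N-terminus, C-terminus, R, K, H, Q, D, E may gain or
lose a proton (the glutamine amide is proton-accepting in vacuo).
Solution rule: the conventional titratable set (Q excluded). For the
human insulin dimer sequence the gas-phase rule gives 18 bases
(4 N-termini + 2 R + 2 K + 4 H + 6 Q) and 12 acids (4 C-termini +
8 E; insulin contains no aspartate).

## Energy model

The ranking of microstates at fixed q is governed by Coulomb
repulsion of the placed charges versus the intrinsic gas-phase
basicity of the sites holding protons:

    E_corr = E_FF + E_GB,   E_GB = − Σ_occupied GB(site).

GB is the negative free-energy change of protonation in vacuo, so
attaching a proton to a site lowers the energy by its GB and
higher-GB sites are favoured. The additive per-site form is this
module's defining assumption.

`E_FF` is by default the reduced-model non-bonded energy: ±1e point
charges on the sites' anchor atoms (side-chain charged-group terminal
heavy atoms: NZ for K, CZ for R, NE2 for H/Q, CG/CD for D/E, backbone
N/C for termini; Cα fallback for coarse models), vacuum Coulomb with
k = 138.935 kJ·mol⁻¹·nm·e⁻² and **no cutoff** — long-range
electrostatics are the physics of interest in the gas phase — plus an
optional generic 12-6 Lennard-Jones term (off by default; on a rigid
structure it is a state-independent offset). A full force-field or MD
engine can replace this through the relaxer contract
`relax(structure, state, rng) → (structure′, E_FF)`.

The shipped GB table (`data/gb_intrinsic.tsv`, kJ/mol) uses the
standard gas-phase basicity scale for the basic residues
(R 1006.6, K 951.0, H 950.2, Q 937.8, N-terminal amine 886.6); acidic
sites carry the basicity of their carboxylate conjugate base
(~1400–1450), which correctly keeps acids neutral in positively
charged gas-phase ions except when the charge balance forces
deprotonation. Users may override the table per run or per site.

## Monte Carlo sampler

Proposals relocate a single proton from a uniformly chosen occupied
site to a uniformly chosen unoccupied site. Because q depends only on
the occupancy count, any relocation — including base ↔ acid — is
charge-preserving, and the kernel is symmetric and ergodic over the
fixed-q space. Acceptance is the standard Metropolis rule at 300 K
(R = 8.314 × 10⁻³ kJ·mol⁻¹·K⁻¹); on a small three-state system the
chain's empirical frequencies match Boltzmann weights (χ² check in
the acceptance suite).

A sampling chain ends when `patience` (default 10) consecutive
iterations fail to accept a new state. Because GB differences are
tens of kJ/mol ≫ RT, a single chain is nearly greedy and stops at the
first local minimum; `run_mc` therefore launches fresh random-start
chains until the `max_steps` budget (default 5000) is spent and
reports the best state over all chains. This multi-start reading
follows from the protocol's random generation of initial protonation
states and is what makes the sampler recover the
exhaustive-enumeration minimum in 100/100 seeded runs on rugged 10-
and 12-site test systems; `multi_start=False` restores the
single-chain behaviour and `patience=None` runs one chain for the
full budget (used for the stationarity check). One seeded generator
drives proposal and acceptance draws in a documented order, so runs
are exactly reproducible. Equal-energy ties keep the incumbent best
state.

## Main-charge prediction

The apparent gas-phase basicity of an ion in microstate s is

    GB_app(s) = max over unoccupied basic sites i of
                [ GB(i) − ΔE_Coul(+1e at i | charges of s) ],

i.e. the best remaining proton-attachment free energy after paying
the Coulomb work against the charges already present (anionic acids
*raise* GB_app). This Coulomb-corrected max-over-sites form is the
package's documented stand-in for the protocol's supplementary
definition, which is not publicly printed.

For each charge q the lowest-energy state from the MC sweep is
evaluated over a small ensemble of conformer snapshots (default 10;
Gaussian coordinate jitter of 0.02 nm when no relaxer trajectory is
available), giving mean ± std per q. An unweighted least-squares line
GB_app = a + b·q (inverse-variance weighting optional) is intersected
with the solvent GB — water, 660.3 kJ/mol by default — and the
crossing is rounded to the nearest integer (`floor` available for a
strict "maximum charge not exceeding the crossing" reading). A
non-negative fitted slope is rejected as unphysical.

## Collision cross sections

The projection approximation inflates every atom by a probe radius
(default 0.10 nm, helium), projects along uniformly random
orientations (random rotations from uniformly sampled unit
quaternions) and estimates the area of the disk union by rejection
sampling in the bounding box; the mean ± SE over orientations is
reported. A fine-grid rasterization of the same projection serves as
the independent oracle route in the tests (agreement ≤ 1% on 20-atom
fixtures). PA systematically underestimates scattering-based cross
sections for large ions; a multiplicative `calibration_factor`
(default 1.0) can absorb this, and results are labelled `PA` or
`PA_calibrated` accordingly. Per-element collision radii (Bondi van
der Waals scale) ship as a versioned TSV. Trajectory profiles reuse
one sample stream across frames (common random numbers) so
frame-to-frame differences reflect structure, not Monte Carlo noise.

## Trajectory observables

* **Superposition/RMSD** — Kabsch SVD with proper-rotation
  correction; collinear inputs fall back to a translation-only fit
  with a warning.
* **RMSF/B-factor** — fluctuations about the mean structure after
  superposition; B = (8π²/3)·RMSF² with RMSF in Å.
* **Hydrogen bonds** — geometric criterion: donor–acceptor distance
  ≤ 0.35 nm and H–D–A angle ≤ 30° (a widely used default, exposed as
  configuration since criteria differ between analysis packages);
  same-residue pairs excluded; group filters support whole-complex
  and inter-monomer counts.
* **Contacts** — inter-monomer carbon pairs within 0.60 nm.
* **Secondary structure** — a DSSP-like assigner: Kabsch–Sander
  electrostatic H-bond energy 0.084·(1/r_ON + 1/r_CH − 1/r_OH −
  1/r_CN)·332 kcal/mol with bonds below −0.5 kcal/mol, amide
  hydrogens placed 1.0 Å from N opposite the preceding carbonyl when
  absent; helices from two consecutive i→i+4 turns, strands from
  parallel/antiparallel bridge patterns; the label set is reduced to
  {H, E, C}.
* **Essential dynamics** — iterative superposition onto the converged
  mean (tolerance 10⁻⁶ nm), covariance eigendecomposition, per-frame
  projections; eigenvalue sum equals total positional variance.
* **Cosine content** — c_i = (2/T)·(∫cos(iπt/T)p dt)²/∫p² dt by the
  trapezoid rule; values near 1 indicate diffusive, unconverged
  sampling (random-walk fixtures reproduce this regime).

## Synthetic systems and what they show

`fixtures` provides analytically controlled systems: charged shells
(Fibonacci-sphere sites; GB_app computable by direct Coulomb sums),
toy dimers with constructed site/contact counts, ideal-geometry
helices and antiparallel β-pairs built by internal-coordinate chain
construction (the β-pair's inter-strand placement is optimised at
build time against the Kabsch–Sander bond count), and trajectory
generators for the rigid-motion null, single-mode signal, Gaussian
jitter and random-walk regimes.

The insulin-dimer model used by the end-to-end charge-prediction test
is a **synthetic coarse-grained surface model**: one bead per residue
of the real dimer sequence on a sphere of radius 2.1 nm (the
equivalent-sphere radius of the complex's aqueous radius of gyration,
1.37 nm → 1.77 nm, plus ~0.35 nm for side-chain arms), with a small
seeded jitter. It carries the exact sequence-derived ionizable-site
inventory, so the combinatorics are those of the real complex, and
its size sets a realistic Coulomb scale — but it has no native
topology, secondary structure or packing. The predicted main charge
(6+, stable across seeds) therefore demonstrates that the GB scale
plus Coulomb physics at the correct molecular size reproduces the
observed charge state; it does not validate conformer-level detail.
CCS values computed on coarse models are likewise not comparable to
experimental absolute values; the CCS machinery is validated against
analytic and grid oracles instead.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen for exhaustive
verifiability: ≤ 12-site inventories for enumeration oracles, 800–
1,500-step MC budgets, 10³–10⁴-frame synthetic trajectories, and 10⁵
draws for acceptance-rate estimates. Degenerate inputs fail loudly:
empty structures, zero-variance series, infeasible charges,
coincident charged atoms, non-finite relaxer energies and unphysical
(non-decreasing) GB_app curves all raise with specific messages.

## Known limitations

* The per-site additive GB correction ignores polarization,
  conformational relaxation upon protonation and proton tautomerism
  within a site.
* The reduced E_FF has no bonded terms; structural relaxation beyond
  jitter-plus-descent requires an external relaxer plugin.
* PA cross sections carry a systematic offset relative to
  trajectory-method values; only calibrated comparisons are
  meaningful.
* The DSSP-like assigner implements the H/E/C reduction only (no
  3₁₀/π helices, turns or bends).
* Solvent-accessible surface area is not implemented.
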