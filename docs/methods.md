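# Methods

## The model

`evccp` implements an extended-variable, coupled sampler for molecular
crystal structure prediction (CSP).  Two systems share one set of
collective variables (CVs): a crystal of Z' rigid molecules, described
by packing coordinates **X** (per molecule: Cartesian centre of mass in
Å and intrinsic ZYZ Euler angles in degrees) together with the six cell
parameters **H**; and a reference system of extended variables (EVs)
**S** with the same layout as **X**, living in a large orthogonal box
and carrying no self-energy, U(**S**) = 0.  The two are tied by a
harmonic coupling

    U(X, H, S) = U(X, H) + (k_com/2) Σ_i ||com_i − s_com,i||²
                         + (k_eul/2) Σ_i wrap(eul_i − s_eul,i)²

with angle differences wrapped to (−180°, 180°].  The joint partition
function factorizes the sampling problem: for fixed **S** the crystal
side is explored by a *mini-batch* of M structure generations (random
cell **H** within sampler bounds, packing seeded at **X**₀ = **S**,
local minimization of the biased energy), and the batch minimum

    U(X, H | S) = min_m [ U_adb(X_m, H_m | S) + penalty_m ]

is the conditional configuration energy used to propagate **S** by
Metropolis Monte Carlo at bath temperature T.  Every generated
polymorph is archived whether or not the proposal was accepted.  A
log-sum-exp soft-min over the batch (at a configurable smoothing
temperature) is available behind `EvccpConfig.batch_smoothing_T`; the
default is the hard argmin.

On top of single chains, a *modified replica exchange* (MRE) swaps only
the EV vector (with its cached conditional energy) between temperature
baths.  Variant moves: MRE1 deposits Gaussian kernels along the
accepted EV path (metadynamics-style history penalty against
revisiting); MRE2 resets each bath's EVs to its best basin at the start
of every MC cycle ("forced relaxation"); MRE3 re-converges archived
candidates with tight tolerances after each cycle and restarts all
baths from the global *unbiased* minimum.  A caller-supplied history
bias may be combined with any variant (the history + forced-relaxation
combination is the configuration that most strongly re-generates a
designated rare structure).

Free-energy differences between generator ensembles (e.g. Z' = 2
vs Z' = 1) are estimated by feeding the EV trajectory of the base
ensemble back through the alternate generator and Zwanzig-averaging the
per-molecule energy differences, ΔF = −kB T ln⟨exp(−ΔU/kB T)⟩, with
log-sum-exp stabilization; ⟨ΔU⟩ is carried as the error proxy and the
Gibbs–Bogoliubov bound ΔF ≤ ⟨ΔU⟩ is asserted on every run.  The
temperature dependence is summarized by an ordinary least-squares line
whose intercept plays the role of a zero-point-energy difference, in
analogy with the harmonic vibrational free energy
F(T) = Σ_i [ħω_i/2 + kB T ln(1 − e^(−ħω_i/kB T))] implemented in
`evccp.fep.vib_free_energy`.

## The potential

The crystal PES is a site–site Lennard-Jones + Coulomb rigid-body
potential: U = Σ 4ε_ij[(σ_ij/r)¹² − (σ_ij/r)⁶] + kc q_i q_j / r over
distinct intermolecular pairs within a real-space cutoff, halved for
double counting and normalized per molecule.  Lorentz–Berthelot
combination, plain truncation (no tail shift), no Ewald sum — shipped
fixtures keep charges zero or small so the real-space cutoff suffices.
The backend is deliberately simple and pluggable: the sampler only ever
sees energies through the module surface, so a production force field
can replace it.  Default cutoff 8 Å; the search fixtures use 6 Å (5 Å
for the cheapest scans).  Because the dispersion tail of a lattice sum
decays only as r⁻³, converged absolute energies need cutoffs around
20 Å; all comparisons inside a search use one fixed cutoff, so ranking
is unaffected.

Pairs closer than 0.1 Å mark an unphysical overlap: the public
`lattice_energy` returns +inf (the configuration is rejected), while
the minimization objective floors distances at 0.05 Å so the surface
stays finite and strongly repulsive — a quasi-Newton step can always
escape an overlapping start.

## Minimization

Local minimization is L-BFGS-B over the free coordinates: the Z'·6
packing CVs plus the symmetry-free cell parameters (lengths bounded to
[1.5, 60] Å, free angles to [30°, 150°]).  Gradients are central finite
differences evaluated inside the compiled kernel; central (not forward)
differences are required for reliable line searches on the stiff r⁻¹²
wall.  Two convergence regimes are used deliberately:

* **on-the-fly** (Monte Carlo inner loops): maxiter ≈ 30–80, gradient
  tolerance 1e-2 — structure generation during sampling does not need
  full convergence, which is deferred to post-processing;
* **reference / post-processing** (fixture minima, MRE3 restarts):
  maxiter 400–500, gradient tolerance 1e-4.

During biased minimizations the optimized COMs are *not* wrapped back
into the cell: the tether to **S** breaks translation symmetry and the
stored penalty must equal the objective's.  Unbiased results are
wrapped fractionally for presentation; the energy is unaffected either
way.

## Duplicate identification

Two minimized structures are duplicates when their unbiased energies
agree within tol_E (default 0.1 kJ/mol, 0.3 for loose hit counting),
and either (a) their cell parameters agree in the same setting within
(0.1 Å, 0.5°) *and* the best COM RMSD over symmetry images, molecule
permutations and lattice translations is below tol_r (0.3 Å), or
(b) their Niggli-reduced cells agree — the same lattice routinely
reappears in permuted settings, especially in P1, and reduced-cell
comparison is the setting-independent test.  Deduplication keeps the
lowest-energy representative and is idempotent.

## Synthetic fixtures and what they show

Toy rigid molecules (ε = 1 kJ/mol, σ = 3.4 Å, charges 0; a ±0.2 e
variant covers the Coulomb path): a 1-site "atom", a 3-site bent
triatomic, and a 5-site planar pentad.  Bundled systems pair them with
space groups and sampler bounds chosen for specific behaviours:

* `atom_p1` — the energy depends only on **H** (no symmetry mates), so
  the k = 0, M = 1 EVCCP stream is *exactly* the PR stream in
  distribution: the reduction-law fixture.
* `atom_p21` / `bent3_p21` — the 2₁ screw makes the COM energetically
  meaningful at Z' = 1; `bent3_p21` adds orientational frustration and
  is the fixture for the coupling-bias and conditional-enrichment
  checks.
* `bent3_p1_z2` — two independent molecules; relative COMs carry
  forces.
* analytic EV surrogates — quadratic (Boltzmann variance kB T/k),
  double well (replica-exchange marginals), rough quadratic (seeded,
  enumerable minima), gaussian_pair (closed-form ΔF(T)), and
  `rare_well`, a corrugated landscape with one deep narrow minimum.

These fixtures reproduce the *structural* features the method assumes —
multiple minima, basin-volume asymmetry, orientation-coupled packing —
but not the energetics of any real force field: absolute energies,
probabilities and landscape statistics here say nothing quantitative
about real molecular crystals.  In particular the toy LJ landscapes are
glassy (hundreds of near-degenerate minima), which is realistic for
rigid-molecule CSP but means no *crystal* fixture at this scale has a
stable, re-identifiable rare global minimum; the variant-ordering
behaviour (random search ≤ plain replica exchange ≤ history +
forced-relaxation) is therefore validated on the `rare_well` EV
surrogate, whose designated minimum has a tiny basin (rare under
random-start descent, ~4% of a 2000-draw budget) yet dominates the
Boltzmann weight once found — the landscape topology of a rare
low-energy polymorph, with every method given the same descent budget.

## Defaults and units

All energies kJ/mol (lattice energies per molecule), lengths Å, angles
degrees, kB = 0.0083144621 kJ/mol/K, Coulomb constant
1389.35 kJ mol⁻¹ Å e⁻², wavenumber→energy 0.0119627 kJ/mol per cm⁻¹.
Spring constants carry inverse-square units (kJ mol⁻¹ Å⁻²,
kJ mol⁻¹ deg⁻²).  Sampler defaults: M = 10, |ΔS|_max = 0.5 Å / 15°
per class (an optional flag scales steps by kB T), E_threshold floating
at (running best + 1000 kJ/mol), exchange every 5 steps over
nearest-neighbour pairs with alternating parity, default bath ladder
263/370/574/1142 K (roughly geometric; `tune_ladder` adjusts the rung
ratio from short pilots until the mean swap acceptance is near 0.5).
History-bias defaults: w = 2 kJ/mol, σ = 0.5 Å / 10°, kernels deposited
at accepted states, FIFO-capped at 2000.  Exchange swaps cached
conditional energies by default; a strict mode re-evaluates both
swapped states through the generators.

## Problem sizes

The shipped test suite and the results script run deliberately small
study sizes — reference searches of 60–800 draws, Monte Carlo chains of
10³–10⁵ steps, mini-batch sizes 1–5, rare-minimum budgets of 2000
structures per run — with loose on-the-fly minimization in the inner
loops.  These sizes give stable statistics for every qualitative claim
while keeping a full run on a single CPU in the tens of minutes; all
are parameters, and scale up directly.

## Known limitations

* No Ewald electrostatics: strongly charged systems are outside the
  shipped potential's validity.
* Gradients are finite-difference; analytic derivatives would speed the
  inner loops several-fold.
* Duplicate detection keys on energy + lattice + COM geometry; it does
  not compare full atomic environments (no packing-similarity
  fingerprint), so distinct structures that are degenerate in all three
  can in principle merge.
* The reference system is strictly non-interacting; self-interacting
  EV potentials (U(S) ≠ 0) are plumbed but not implemented.
* Exchange of non-ordinal variables (space group, Z') is not
  implemented; each run holds both fixed.
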