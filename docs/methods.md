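# Methods

`ssmech` is a desk-scale model of a single-molecule pulling experiment on a
disulfide-crosslinked protein. A coarse-grained chain held together by a
structure-based potential is stretched at constant velocity under Langevin
dynamics while its disulfide bonds are treated in one of four ways that
encode the redox environment. This note records the model, its parameters,
the numerical choices, and what the synthetic test systems can and cannot
show.

## Chain representation

Each residue carries two interaction centers: a backbone center (Cα) and a
side center. For synthetic folds the side center sits 1.8 Å off the
backbone; for PDB-derived topologies it is the side-chain heavy-atom
centroid, with the Cβ coordinate retained separately because the
bond-presence criterion used throughout the analysis is a *Cβ* distance
below 5.5 Å. Residues without side-chain heavy atoms (glycine) get a
pseudo side center 0.9 Å off the backbone so every bead has finite bonded
geometry. Residue ordinals are 0-based internally and 1-based in all
user-facing output (Cys26 etc.).

Each bead has a uniform mass of 55 amu — the ~110 amu of an average
residue split evenly between its two centers. Masses enter only the
Langevin dynamics; none of the analysed observables depend on the split.

## Background (Gō) potential

The folded state is maintained by a minimal structure-based potential:

* harmonic backbone bonds, k = 100 kcal/mol/Å², b₀ = 3.8 Å;
* two harmonic side-attachment bonds per side center (to its own and the
  next backbone bead), which fix the side-bead geometry without angle
  terms;
* 12-10 native-contact wells, ε = 1.0 kcal/mol, one per backbone pair
  within 8 Å (|i−j| ≥ 3) and per side-center pair within 6 Å in the
  native conformation, with the native distance as the well position;
* a quartic excluded-volume repulsion ε_ev (1 − r²/σ²)² for r < σ = 4 Å
  (ε_ev = 3 kcal/mol) between all pairs not bonded, not in contact, and
  more than one residue apart;
* cosine pseudo-dihedrals k(1 − cos(φ − φ₀)) on backbone quadruplets,
  k = 0.3 kcal/mol, φ₀ from the native conformation.

This deliberately simple background stands in for a full transferable
coarse-grained force field, which is far outside the scope of this
package: its single job is to provide a fold that is stable at 300 K,
unfolds under piconewton-scale forces, and has element-resolved contacts
(helix blocks H1…, strand blocks B1…, strand pairings "B1-B2", tertiary
"T", crosslink side-center contacts "SS") so secondary-structure loss can
be tracked as native-contact fractions. DSSP-style assignment is
intentionally not used on the coarse-grained beads.

## Disulfide treatments (the redox model)

Four modes, selectable per run:

* **none** — reducing environment; no disulfide term at all. Cysteine
  side centers still interact through whatever generic contacts the
  native structure gives them.
* **dynamic** — a distance double-well between *every* cysteine pair
  (native or not):

  U(r) = A/r¹² − D_bond·exp(−(r−r_b)²/2σ_b²) − D_contact·exp(−(r−r_c)²/2σ_c²)

  with r_b = 4.0 Å, σ_b = 0.4 Å, r_c = 6.5 Å, σ_c = 0.8 Å,
  D_contact = 1.0 kcal/mol, and A sized so the core contributes
  0.05 kcal/mol at r_b (keeping U(r_b) within 2% of −D_bond). The bonded
  depth D_bond is the redox dial: 5.5 kcal/mol for a weakly and
  11.0 kcal/mol for a highly oxidizing environment. Changing it leaves
  the contact minimum untouched (well under 1%), so doubling D_bond
  doubles the rupture barrier. The potential is distance-only; an
  orientation-dependent refinement exists in the literature but its form
  and parameters are not public, so it is not modelled here.

  On top of the pair terms, a triplet repulsion forbids one cysteine
  from bonding two partners at once:

  U_SSS = a·s(r_ki)·s(r_kj),  s(r) = (1 + exp(b(r − c)))^(−d)

  evaluated for every cysteine k and unordered partner pair {i, j}. The
  four parameters are user-settable; the defaults (a = 30 kcal/mol,
  b = 4 Å⁻¹, c = 5 Å, d = 1) make a doubly-bonded geometry cost more
  than one bonded well even at D_bond = 11, while a single bonded
  partner incurs < 10⁻³ kcal/mol. The functional form is this package's
  own: the published description fixes only the qualitative behaviour
  ("repulsion preventing triple disulfide bonds", parameters
  "user-defined"), not the closed form.
* **static** — native crosslinks as permanent harmonic bonds
  (k = 100 kcal/mol/Å², equilibrium at the native side-center distance),
  the very-high-oxidation limit.
* **restraint** — the all-atom-style breaking restraint on native
  crosslinks: harmonic below r₁, zero on [r₁, r₂], harmonic on [r₂, r₃],
  and *linear* beyond r₃, i.e. a constant force 2k(r₃ − r₂). With
  k = 4.0 kcal/mol/Å², r₁/r₂/r₃ = 1.8/3.0/4.0 Å the tail force is
  8.0 kcal/mol/Å = 555.8 pN (reported as 556 pN). The below-r₁ branch is
  a parabola with the same k; excluded volume dominates there anyway.
  The analysis provides the matching correction that subtracts 555.8 pN
  per permanently broken pair from subsequent force readings.

Internal units are kcal/mol and Å throughout; forces are converted with
1 kcal/mol/Å = 69.479 pN only at the reporting boundary.

## Dynamics and pulling

Langevin dynamics uses the BAOAB splitting with a fixed time step of
0.489 fs (one hundredth of the 4.89 fs molecular time unit, MTU). With
the thermostat off it reduces to velocity Verlet and conserves energy to
better than 0.1% over 10⁴ steps (tested). The friction coefficient is a
base value of 5 ps⁻¹ scaled by 1/100 — the conventional coarse-grained
friction reduction — giving a weak thermostat coupling chosen so that at
the fastest pulling speed the aggregate viscous drag on the chain
(N·γ·m·v) stays below the disulfide rupture-force scale; with water-like
friction the drag at desk-scale speeds would swamp the very redox
contrast the model exists to show. Thermal sampling is unaffected (the
stationary distribution is γ-independent), only kinetic relaxation times
are; starting velocities are drawn from the Maxwell–Boltzmann
distribution, so the short thermalization suffices.

Preparation mirrors the usual protocol: 1000 steps of energy
minimization, then a seeded 10⁴-step thermalization at the run
temperature. Pulling tethers one anchor (harmonic spring, default
k = 1 kcal/mol/Å²) to a fixed point and the other to a point moving at
the protocol speed along the *native* anchor–anchor axis. Anchors default
to the second and second-to-last residues. **Extension** is defined as
the current anchor–anchor distance minus its native value — zero at the
start and comparable across modes. The source experiments never define
their extension axis (their static-mode force rise near 120 Å cannot be
reconciled with any inextensibility bound under this convention), so no
quantitative extension value from them is used as a target; one visible
consequence is that observables such as the rupture-extension shift with
pulling speed can carry the opposite sign here than a different extension
convention would give. What is convention-independent — and what the
tests assert — is that forces grow with pulling speed and that lowering
the temperature shifts ruptures the same way as pulling faster.

Per saved frame (every 200 steps) the logs carry the coordinates, the
signed spring force (pN), the extension, the potential and disulfide
energies, and the distance of every cysteine pair. The binary bond state
applies the 5.5 Å criterion with a two-saved-frame hysteresis to suppress
flicker at the cutoff; break/form events are derived from the debounced
states, so events strictly alternate per pair.

## Analysis pipeline

* **Force–extension profiles**: 1 Å bins; each bin pools every
  observation from every trajectory and reports mean, SEM
  (sd/√n, pooled — well-defined when trajectories populate bins
  unevenly), and n; empty bins are absent, not zero.
* **Peak detection**: moving-average smoothing (5 bins) then a local
  maximum scan with prominence threshold 2 × median SEM; interior minima
  between adjacent maxima. The published analyses read peaks by eye; a
  deterministic rule is required here, and this is it.
* **Bond fractions**: per pair and 1 Å bin, the fraction of observations
  with raw distance < 5.5 Å (no hysteresis — fractions are ensemble
  statistics, the debouncing is event bookkeeping).
* **Contact fractions by element**: fraction of an element's native
  contacts within 1.2 × the native distance, per bin — the
  secondary-structure proxy.
* **Breaking order**: per trajectory the *final* break extension per pair
  (a reformation voids earlier breaks, matching the observation that a
  bond's fraction can drop several times before disappearing); consensus
  by median rank with vote counts; never-broken pairs rank last as
  "unbroken".
* **Representative conformers**: all frames within ±1 Å of a target
  extension (typically a force minimum); exact all-pairs Kabsch RMSD
  (SVD, reflections disallowed); the member with the lowest RMSD sum
  wins, ties to the lowest frame id.
* **Rg / Rgmax / RMSF**: mass-uniform radius of gyration; Rgmax is the
  maximum bead distance from the geometric center (the quantity is not
  defined in the source; this is this package's definition); RMSF about
  the iterated mean structure after superposition, using only the second
  half of the frames.

## Synthetic test systems

`default_toy_spec` (40 residues: helix, two paired strands, two
crosslinks) and `rnase_mimic_spec` (124 residues, three helices, seven
strand blocks, crosslinks at the ribonuclease A cysteine positions
26–84, 40–95, 58–110, 65–72 with the native nesting, anchors at residues
2 and 123) are built deterministically: serpentine block layout, staged
minimization that closes the crosslinks with ramped harmonic scaffolds,
contact/dihedral harvesting, and a final relaxation so the returned
conformation is a true local minimum of its own Gō energy (max gradient
component < 10⁻³ kcal/mol/Å). Element boundaries in the mimic are nudged
by 1–2 residues from the real protein so every cysteine sits in a loop
or strand block, a generator constraint. Identical spec + seed gives
bitwise-identical output.

The mimic reproduces the *architecture* of RNase A, not its energetics:
native-contact counts, not transferable interactions; uniform contact
strengths; no electrostatics or solvent. Passing tests therefore
demonstrate that the machinery — bond bookkeeping, redox ordering,
profile/peak analysis — behaves correctly on a fold of realistic size
and crosslink nesting; they do not reproduce protein-specific force-peak
positions or heights, which require the full published force fields and
are out of scope. The same applies to the real-structure path:
offline environments use the mimic written/reloaded as PDB (a synthetic
stand-in with the true cysteine topology); pointing `load_structure` at
an actual RNase A entry gives the real geometry.

## Problem sizes, thresholds, and other numerical choices

* Test and acceptance ensembles run at desk scale: 8 (tests) or 4
  (acceptance script) replicas per condition, pulls of 1.3–2.5 × 10⁵
  steps at 0.005–0.02 Å/MTU on the mimic and toy folds. These sizes give
  reproducible medians for the qualitative orderings being asserted.
* Equilibrium stability threshold: backbone RMSD < 3.5 Å over 10⁵
  unbiased steps on the toy fold — calibrated once from a three-seed
  sweep (max observed 3.01 Å) and frozen.
* The Boltzmann-occupancy validation of the thermostat uses a shallower
  bonded well (D_bond = 2.5 kcal/mol) so the two wells exchange many
  times within 10⁶ saved samples; standard errors are batch-means over
  50 blocks (floored by the binomial SE), the statistically honest error
  for correlated samples.
* L-BFGS is used for all minimizations (gtol 10⁻⁴–10⁻⁶); degenerate
  dihedrals (collinear bonds) contribute zero force; beads closer than
  0.1 Å raise an error naming the pair; trajectories abort with a
  diagnostic if any coordinate exceeds 10⁶ Å.
* The excluded-volume term runs over an explicit pair list; inside the
  integrator the list is distance-pruned every 50 steps with a 1.2 Å
  skin, far beyond the possible per-interval drift.
* Randomness: one integer seed per trajectory drives both the
  Maxwell–Boltzmann draw and the thermostat noise (an inline
  xorshift128+/Box–Muller stream inside the compiled kernel, validated
  against the Boltzmann occupancy test); identical protocol + seed gives
  identical trajectories. Pipeline-level seeds are derived from the
  master seed by hashing the condition label and replica index.

## Known limitations

* The background potential is native-centric: non-native *contacts*
  cannot form (non-native disulfide bonds can, in dynamic mode).
* The dynamic disulfide potential is distance-only; no orientation
  dependence.
* Single chains only; no solvent, electrostatics, or hydrogen-bond
  terms; no constant-force mode; no free-energy reconstruction.
* The restraint mode applies the flat-bottom function to the native
  crosslink pairs only, as in the all-atom protocol it mirrors.
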