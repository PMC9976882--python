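# Methods

## Model

`dnabind` samples the posterior distribution of protein–DNA configurations

p(x|D) ∝ p(D|x) · p(x)

where the prior p(x) is the Boltzmann distribution of a physical energy
(the *backend*) and the likelihood p(D|x) scores agreement with ambiguous
or noisy contact data.  The likelihood is realized as an energy added to
the backend energy, so the effective potential of replica k is

U_k(x) = U_backend(x) + s_k · U_data(x) + U_scaffold(x)

with s_k the replica's restraint scale.  Sampling U_k by Metropolis Monte
Carlo (or Langevin dynamics) at temperature T_k and exchanging
configurations between neighboring rungs with the standard two-Hamiltonian
Metropolis rule gives each rung a well-defined stationary distribution;
the lowest rung (T = 1, s = 1) is the posterior ensemble analyzed for
binding modes.

### Restraint likelihood

A single datum is a flat-bottom distance restraint with parameters
0 ≤ r1 ≤ r2 ≤ r3 ≤ r4 and force constant k: zero on [r2, r3], half-harmonic
½k(r−r3)² on (r3, r4] (mirrored below r2), and linear beyond r4 (below r1)
with the slope of the wall at the matching point, offset so the energy is
C¹ everywhere.  Linear tails keep forces bounded at the ≥ 30 Å initial
separations.  Defaults: data contacts (0, 0, 6, 8) Å, k = 1; scaffold
contacts (d₀−1, d₀−0.5, d₀+0.5, d₀+1) around the bound-state distance d₀,
k = 2; base-pair N1–N1 restraints (0, 0, 3.2, 3.6) Å, k = 5.

Ambiguity and noise are handled by two levels of lowest-energy-subset
selection: a *group* counts only its `n_active` cheapest member restraints,
a *collection* only its `n_active_groups` cheapest groups.  Because the
individual terms are independent, summing the k smallest members is exactly
the minimum over all k-subsets (the test suite verifies this against
exhaustive enumeration).  Selection is re-evaluated at every energy call —
no hysteresis — and ties break by ascending index so replays are
deterministic.  The active fraction of data groups defaults to 0.5 and is
exposed in the run configuration; it trades exploration (small f) against
constraint strength (large f).

Collections are labelled `data`, `scaffold` or `duplex-separation`.  Only
`data` collections are scaled down the ladder; scaffold restraints
(protein native Cα contacts, DNA base-pair registers) and the
duplex-separation floor of competitive runs stay on at every rung, because
their job — keeping the molecules folded and the duplexes apart — does not
depend on the sampling temperature.

Protein secondary structure is maintained implicitly: the native-contact
collection includes every Cα pair within 8 Å at sequence separation ≥ 3,
which covers helical i,i+4 and cross-strand pairs, so no torsion terms are
needed at bead resolution.

### Coarse-grained backend

Reduced units: kT at the lowest replica ≡ 1, distances in Å.  The bead
model has

- harmonic bonds (k = 100 energy/Ų) along each chain at built lengths;
- Weeks–Chandler–Andersen excluded volume between molecules,
  σ_ij = radius_i + radius_j, ε = 1;
- Debye–Hückel electrostatics U = l_B q_i q_j exp(−r/λ)/r with Bjerrum
  length l_B = 7 Å (water at room temperature) and screening length
  λ = 10 Å (physiological-ish ionic strength); phosphates carry −1 e,
  Lys/Arg +1 e, Asp/Glu −1 e at Cα.

DUMMY sites are ghosts: excluded from all non-bonded terms, tied rigidly to
their parent purine N1.  Intra-molecular non-bonded terms are omitted
(bonds plus the scaffold restraints govern internal geometry at this
resolution).

Two propagators are available.  Rigid-molecule Metropolis MC — Gaussian
translation (σ_t = 1.5 Å at T = 1, scaled by √T) plus rotation
(σ_r = 0.25 rad) of one molecule per move — is the workhorse for binding
runs, since the scaffold keeps each molecule internally near-rigid anyway;
it replays bit-identically from a seed.  BAOAB Langevin dynamics
(dt = 0.005, γ = 1) integrates the flexible bead model and is used for
backend validation.  Competitive runs add a *partner-swap* move: a π
rotation of the protein about the assembly's two-fold axis, proposed with
probability 0.1 and Metropolis-accepted on the energy change.  The
competitive builder places the two duplexes as exact C2 images, so for
identical duplexes the move is energy-preserving and the bound-duplex
identity decorrelates between consecutive frames; for different duplexes
it is an ordinary (valid) proposal with energy-dependent acceptance.  This
is what makes frame-count binomial statistics on A-vs-B populations
meaningful at desk scale.

### Replica ladder

Default: geometric temperatures between t_min = 1 and t_max = 3 in reduced
units; restraint scale 1 over the lowest third of the ladder, then linear
to 0 at the top rung.  Production-style runs in the literature this
package emulates use 30 replicas; the desk-scale defaults here use 6–8,
which suffices for the fixture systems' barriers.  Exchanges sweep
nearest neighbors with even/odd alternation each round.  Per-replica
random streams are spawned from the master seed, so results are
independent of execution order.

## Synthetic systems

The fixture generator builds a 12-residue "clamp": two stacked 6-residue
Cα arcs (a hairpin-like fold) wrapping an 8-bp GCGATCGC duplex at 12.5 Å
radius, middle six residues arginine (+1 e, the binding domain), residue 1
glycine (no Cβ), the rest alanine.  The bound pose is clash-free, has zero
scaffold energy by construction, and makes four inter-molecular residue
contacts at the 5 Å criterion.  The palindromic sequence means both duplex
orientations are equally consistent with the data — ensembles genuinely
contain flipped binding modes, as they should.

What the fixtures emulate: the charge complementarity of a basic binding
domain against the phosphate backbone, ambiguous contact data with only a
fraction satisfiable at once, unbound initialization at ≥ 30 Å, and an
exactly symmetric competition control.  What they do not emulate:
sequence-dependent DNA shape and deformability (the built duplex is ideal
B-form regardless of sequence), side-chain packing, solvation structure,
and the scale of real interfaces (46–227 contacts in experimental
complexes vs 4 here).  Passing tests therefore validate the machinery —
selection optimality, exchange correctness, population statistics — not
force-field realism.

At bead resolution the Cα-to-N1 data window (0, 0, 6, 8) Å is not fully
reachable: the dummy sites sit at 4 Å from the helix axis behind the
phosphate shell, so a docked Cα rests ~9 Å from its nearest dummy and the
bound state retains a small residual data energy.  The restraints still
act as the intended funnel (energy decreases monotonically toward
contact); only the zero-energy plateau is unreachable.  This mirrors the
intended use with noisy data, where exact satisfaction of all data is not
expected either.

## Analysis conventions

- Interface RMSD: interface residues are those of either molecule with any
  site within 10 Å of the partner in the reference; the model is superposed
  on the reference over the interface sites and their RMSD reported
  (CAPRI-style).  Superposition is the SVD-based Kabsch construction,
  proper rotations only.
- fnat: native contacts are inter-molecular residue pairs with any site
  pair within 5 Å in the reference; fnat is the fraction preserved in the
  model.  Bead pairs stand in for heavy-atom pairs.
- Clustering: frames at the lowest replica, metric = protein RMSD after
  superposing each frame pair on the DNA (a binding-mode distance),
  hierarchical average linkage cut at 3 Å, clusters ranked by population,
  medoid representative.  At most 400 frames enter the O(n²) metric
  (evenly subsampled).
- Success call: a < 5 Å interface-RMSD representative among the top five
  clusters by population.
- Competitive populations: a lowest-replica frame counts as bound to a
  duplex when ≥ ⌈n/2⌉ of the n binding-domain Cα sites are within 8 Å of
  that duplex and fewer than that of the other; frames near both are
  ambiguous (warned, pooled with unbound).  The A-share of bound frames is
  reported with a Wilson 95% binomial CI.  Populations are frame fractions
  at the lowest replica only; no multistate reweighting across rungs is
  attempted.

## Numerical choices and degenerate inputs

- Tie-breaks in subset selection: ascending index (stable sort).
- Coincident restraint endpoints (r = 0): zero force by convention.
- Kabsch superposition requires ≥ 3 non-collinear sites; degenerate
  selections raise.
- Exchange acceptance exponents are clipped at 700 before exponentiation
  to avoid overflow; identical neighbors give acceptance exactly 1.
- Langevin aborts with a diagnostic when the energy explodes (step-size
  instability); MC needs no such guard.
- Protocol-1 pruning: residue pairs farther than 20 Å apart in the bound
  protein cannot plausibly contact the same base; their shared-dummy pick
  combinations are recorded as exclusions and resolved greedily (cheapest
  active group picks first, later groups take their best non-conflicting
  restraint).  With no exclusions the greedy path reduces to plain k-of-n
  selection.
- Apo/holo conformational freezing is implemented as flat-bottom
  positional restraints (width 1 Å, k = 10) to anchor coordinates rather
  than frozen degrees of freedom, leaving the propagator unchanged.  With
  the built-in B-form generator both freeze targets coincide; supplying a
  bent (holo) duplex structure separates them.

## Problem sizes

Statistical checks run at sizes chosen for tight oracles at interactive
turnaround: the double-well ladder check uses 8 replicas × 4000 rounds
(~3·10⁵ frames) against quadrature-integrated well weights; the
information-effect comparison uses 25-round windows from the unbound start
(an acceleration readout — longer windows saturate because the charged
system eventually binds without data too); the self-competition control
pools three seeds × 700 rounds (≥ 2000 lowest-replica frames).

## Known limitations

- The backend is a stand-in at bead resolution; no claim of force-field
  accuracy is made, and sequence readout beyond charge complementarity is
  absent (base identity affects only purine dummy placement).
- Populations are raw frame counts at the lowest rung; relative binding
  affinities are qualitative without reweighting.
- Rigid-molecule MC cannot show induced fit; Langevin mode can, but the
  desk-scale demonstrations do not exercise DNA bending.
- The PDB reader keeps the first model of multi-model files and ignores
  insertion codes and alternate locations.
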