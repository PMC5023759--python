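# Methods

`dimerscan` implements a population-based protocol for predicting the
dimerization interface of a class-A G-protein-coupled receptor (GPCR)
from a monomer structure, together with the trajectory diagnostics used
to judge an inactive-state model.  Everything runs on synthetic,
idealized 7-TM helical bundles, so the full protocol is testable without
any experimental structure.  This note records the model, the defaults,
and the design choices that were genuinely open.

## The protocol

1. **Pose enumeration.**  A dimer of two upright membrane proteins is
   membrane-compatible only if both protomers keep their membrane-normal
   (+z) orientation; the remaining degrees of freedom are each protomer's
   rotation about its own z-axis and the in-plane separation.  The
   starting population is the full rotational grid: protomer A rotated by
   360·i/steps_a, protomer B by 360·j/steps_b, with B slid along the
   inter-axis direction until the closest heavy-atom contact reaches
   `d_contact`.  Defaults: 12 × 12 grid (144 poses, 30° per protomer) and
   `d_contact` = 4.0 Å.  The contact placement is computed in closed
   form: for every atom pair that overlaps in the yz-projection the
   contact shift is `a_x − b_x + sqrt(d² − d_yz²)`, and the placement is
   the maximum over pairs — exact, no line search.

2. **Rigid-body refinement ("refine only").**  Each starting pose seeds
   `n_outputs` (default 10) independent Metropolis Monte Carlo chains
   over the rigid placement of protomer B: z-rotation (σ = 5°), in-plane
   translation (σ = 1.0 Å) and a bounded membrane-normal shift
   (σ = 0.25 Å).  The temperature is set so a 1-unit energy increase is
   accepted with p ≈ e⁻¹.  Each chain reports its best-visited pose.
   Crucially, chains are confined to the parent pose's basin
   (|Δθ| ≤ 25°, in-plane ≤ 3 Å, |Δz| ≤ 3 Å): the stage's role is local
   sampling around a fixed interface, and unbounded chains would simply
   re-dock every pose onto the single best face, erasing the
   interface-population structure the consensus stage depends on.

3. **Four-parameter scoring.**  Per dimer:
   * *interface score* — cross-protomer Lennard-Jones + screened Coulomb
     energy;
   * *interface area* — solvent-accessible surface area (SASA) buried on
     complexation, `SASA(A) + SASA(B) − SASA(AB)`;
   * *binding-energy surrogate* — `E(AB) − E(A) − E(B)`; for rigid
     protomers this equals the sum of all cross terms including hydrogen
     bonds;
   * *hydrogen-bond energy* — the directional H-bond component alone.

   Each dimer also gets an interface class `pq_rs`: per protomer, the
   sequentially adjacent TM pair (12, 23, …, 67, 71) with the largest
   summed buried area, the two pair labels ordered canonically.  Seven
   symmetric plus 21 mixed labels give a 28-class alphabet.  Interfaces
   dominated by non-adjacent helices are collapsed onto the best-covering
   adjacent pair.  When the burial is confined to a single helix, the two
   pairs containing it tie with zero information from area alone; the tie
   is resolved, in order, by (1) cross-chain consistency — the candidate
   pair that also covers the partner protomer's dominant contact helix,
   since the two labels describe one interface and a TM4-against-TM5
   contact should read 45 on both sides; (2) the azimuthal lean of the
   burial-weighted centroid, which names the neighbor helix on the side
   the buried surface actually faces; (3) the lower TM index.  A fixed
   lower-index tie-break was rejected because it assigns every
   single-helix contact of a given helix to the same label regardless of
   which face touches the partner.  No unique collapse rule exists; this
   convention is flagged here.

4. **Consensus ranking.**  The four parameters are affinely normalized to
   [0, 1] with 1 = better (energies: minimum → 1; area: maximum → 1; a
   constant parameter carries no information and is set to 0.5).  Two
   consensus methods rank classes over the population:
   * *value averaging* — per parameter, the mean normalized score of each
     class's members within the global top-N (N = 100), classes absent
     from the top-N scoring 0; combined = the same rule applied to the
     unweighted mean of the four normalized parameters;
   * *frequency* — per parameter, each class's share of the top-N;
     combined = the mean of the four shares, ties broken by the value
     consensus, then label order.

   "Top-N with respect to each interface" is ambiguous between a global
   top-N and each class's own best members; the global reading is the
   default and the per-class variant is available (`per_class=True`).

## Surrogate energy model

The protocol's contribution is the population/consensus logic, which
needs a self-contained, deterministic energy — not a reproduction of any
production force field.  The surrogate is:

* **Lennard-Jones 6-12** with per-element radii (C 1.9, N 1.7, O 1.6,
  S 1.8 Å) and well depths (0.10–0.15), combined by sum/geometric mean.
* **Coulomb** with distance-dependent dielectric ε(r) = 4r (332·qᵢqⱼ/4r²)
  — the standard implicit-screening shortcut for membrane-interior
  electrostatics.  Coarse partial charges: backbone N/O ±0.2, carboxylate
  oxygens −0.5, guanidinium nitrogens +0.33, hydroxyl oxygens −0.2;
  planted decoration sites carry the charge stored in their B-factor.
* **Hydrogen bonds** between typed heavy-atom donors and acceptors (the
  synthetic structures have no hydrogens): donor–acceptor distance
  ≤ 3.5 Å, antecedent–donor–acceptor alignment angle ≥ 120°, energy
  −ε·cos²(180° − θ)·ramp(d) with ε = 2.0 and a linear ramp from 1 at
  2.9 Å to 0 at 3.5 Å.  The antecedent is the nearest same-residue atom,
  a bonded-neighbor proxy that is exact for the generator's minimal side
  chains.
* 10 Å cutoff with KD-tree neighbor search; atom pairs closer than 0.5 Å
  raise a clash flag and the energy is capped.

Energies are in kcal/mol-like units; only comparisons and ranks matter.

## SASA

Own Shrake–Rupley implementation: deterministic Fibonacci-sphere
quadrature (default 92 points, probe 1.4 Å, vdW radii C 1.70 / N 1.55 /
O 1.52 / S 1.80 Å).  Interface burial uses an exact locality argument:
only atoms whose inflated sphere can touch an inflated sphere of the
other chain can change SASA on complexation, so isolated and complexed
surfaces are evaluated for that interface shell only and the burial is
exactly zero elsewhere.  This makes the burial difference identical to
the full three-term computation while scoring a 1440-dimer population in
well under the time of a naive implementation.  At 92 points the
quadrature error on a single sphere is below 2%; oracle comparisons in
the tests use 480 points (≈0.1% error).

## The synthetic monomer

Seven ideal α-helices (rise 1.5 Å/residue, twist 100°, CA radius 2.3 Å;
26 residues each) stand on an ellipse (13 × 11 Å semi-axes) with
alternating up/down orientation and ±10° tilts; short loops and 4-residue
tails are interpolated.  Residues are poly-alanine (backbone + CB) except
the functionally designated positions, named by Ballesteros–Weinstein
generic numbers through a sidecar annotation table (never inferred from
coordinates): the orthosteric pocket residues 3.32/6.48/6.55 face the
central axis, Tyr 5.42 carries an outward hydroxyl, and the ionic-lock
partners are built as interaction-site side chains — a guanidinium-like
triplet on Arg 3.50 and a carboxylate-like pair on Glu 6.30, planted
facing each other at `lock_gap` (default 3.5 Å, a formed lock).  The x.50
references place 3.50 near the intracellular end of TM3 and 6.30 at the
intracellular start of TM6, as in class-A receptors.  All dimensions are
artifact conventions for an idealized bundle; they do not reproduce any
receptor's geometry, and distances measured on this bundle (e.g. between
orthosteric sites of a dimer) are properties of the synthetic model only.

**Planted interface.**  `plant_interface_patch` decorates a chosen helix
pair (default TM4/TM5) so that one interface class is energetically
favorable by construction — the recovery ground truth.  The decoration
emulates a complementary ion-pair/H-bond ring with shape complementarity:

* a rail of 6 positively charged donor sites along TM4 and 6 negative
  acceptor sites along TM5 (±1 e), aimed at the TM4/TM5 mid-face and
  placed flush with the CB surface so they contact without holding the
  backbones apart; in the symmetric pose each protomer's donors meet the
  partner's acceptors head-on;
* neutral steric rim ridges on the outer edges of the pair, making the
  face a groove: only a face-on approach nests between the rims, oblique
  approaches are held at standoff.

This design was reached iteratively: weak protruding point charges left
the planted face indistinguishable from the Lennard-Jones background,
and without the rims the neighboring grid cells engaged the face
obliquely and fragmented the class labels.  The defaults are fixed; the
monotonicity contract (larger `charge_magnitude` never weakens the
matched-face binding) is under test.

**Trajectories.**  `simulate_trajectory` produces reference coordinates
plus i.i.d. Gaussian jitter (default σ = 0.2 Å) and planted step events
(persistent displacements of an atom group from a given frame onward).
It is a noise model, not dynamics: no inertia, no correlations, no
solvent.  What passing diagnostics show is that the analysis code
recovers planted signals at their planted frames and magnitudes — not
that any force field or sampling protocol is correct.

## Trajectory diagnostics

* *Ionic lock*: minimum distance between Arg 3.50 {NE, NH1, NH2} and
  Glu 6.30 {OE1, OE2} per frame; "formed" below 4.5 Å (salt-bridge
  convention).
* *H-bond persistence*: per frame, any selected donor–acceptor pair
  meeting the same geometric criteria as the scoring module; occupancy =
  fraction of frames.
* *Water bridges*: waters (HOH/WAT oxygens) within 3.5 Å of both atom
  sets.
* *RMSD stability*: Kabsch-superposed RMSD to frame 0 (proper rotation
  enforced via SVD sign correction); "stable" iff the maximum stays at or
  below 4.0 Å.

## Problem sizes

The default study conditions are the 12 × 12 grid, 10 replicates per
pose (1440 refined dimers) and top-100 consensus.  The test suite
exercises end-to-end recovery at a 6 × 6 grid with 5 replicates and a
proportionally reduced top-N, which preserves the top-N-to-population
ratio; the acceptance script runs the full-size population once and the
recovery property across 5 seeds.  Monte Carlo chain length defaults to
200 steps; recovery runs use shorter chains (the planted basin is deep
and is typically found within ~100 steps).

## Known limitations

* The surrogate energy has no solvation, no side-chain flexibility and
  coarse charges; absolute energies are meaningless outside this package.
* The 28-label collapse of multi-helix interfaces is a convention; real
  interfaces can genuinely straddle three helices.
* The extracellular-path site distance is a two-segment waypoint
  surrogate (via a point 5 Å above the highest atom on the dimer axis),
  not a surface geodesic.
* Generic numbers come solely from the user-supplied (or generated)
  annotation table; no sequence-based assignment is attempted.
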