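# Methods

`polyplexmc` simulates the condensation of a linear DNA molecule by
generation-2 (G2) PAMAM dendrimers, free peptides, and peptide–dendrimer
conjugates, using coarse-grained bead models sampled by Metropolis Monte
Carlo, and computes the conformational statistics used to characterise
the resulting polyplexes.

## The model

**Beads.** All species are built from charged hard spheres in a
continuum dielectric (a primitive-model electrolyte):

| species              | beads | radius (Å) | charge per bead |
|----------------------|------:|-----------:|-----------------|
| DNA                  |  120  | 4.0        | −1 (every bead) |
| amino-acid residue   | 24–25 per tail | 1.5 | +1 (lysine, `P`), −1 (aspartate, `N`), 0 (`0`) |
| G2 dendrimer         |   57  | 1.5        | +1 on the 16 terminal beads, 0 elsewhere |
| counterions          | one per charged bead | 1.2 | ∓1 |

The dendrimer is a hierarchical tree: four two-bead arms ("dimers")
bonded to a central bead, then two further doubling generations, giving
1 + 8 + 16 + 32 = 57 beads with 16 terminal tips (the protonated primary
amines). Peptide tails are parsed from compact charge-pattern tokens
such as `(0P)12 0` (12 repeats of neutral–cationic, then one neutral
residue; net +12). Conjugates attach one or two tails by a harmonic bond
from a tail's first bead to a dendrimer terminal; with two tails the two
terminals are chosen at maximal graph distance (opposite branches),
deterministically. Attached terminals keep their +1 charge in the
simulation convention; the experimental charge convention
(`experimental_vector_charge`) instead subtracts 2.3 linker-neutralised
amines and counts 2.3 tails per dendrimer, matching how conjugate doses
were converted to charge ratios in the wet-lab assays the model
accompanies.

**Charge ratio.** Mixtures are characterised by the nominal charge ratio

    r_charge = (n_vector · Z_vector) / (n_DNA · Z_DNA),

with `Z_DNA` the magnitude of the DNA charge (120 for the model chain,
2 per base pair for a plasmid) — the N/P ratio of the formulation
literature. `r_molar` is the corresponding molecule-number ratio.

**Energy.** In units of kT,

* hard-sphere exclusion between every non-bonded pair (+∞ on overlap);
* Coulomb, `u_ij = λ_B z_i z_j exp(−r/λ_D) / r`, with Bjerrum length
  λ_B = 7.14 Å (water, 298 K) and an optional Debye screening length
  λ_D (`None` = bare 1/r, the package default);
* harmonic bonds, `½ k (r − r₀)²`, with `k` = 0.4 N/m ≈ 0.97 kT/Å² and
  per-bond rest lengths `r₀` defaulting to the contact distance of the
  bonded beads;
* a hard spherical wall confining every bead centre to the cell radius
  R_cell = 1200 Å.

The system is a single finite cell with explicit counterions, so the
Coulomb sum is evaluated exactly (no cutoff, no Ewald).

**Sub-contact springs.** A bond whose rest length is set *below* the
contact distance is treated as a spring anchored inside the hard core:
that pair — and second neighbours along such springs, the usual 1-2/1-3
non-bonded exclusion of bead-spring force fields — is exempt from
hard-sphere exclusion, with the spring providing the restoring force.
The study systems use this for the dendrimer's internal bonds (r₀ = 0;
bonds equilibrate near 2.1 Å), which is what makes the 57-bead scaffold
as compact as the molecule it represents; see *Calibration*. DNA and
peptide bonds always keep contact rest lengths and full hard cores — a
bonded cationic–anionic residue pair without a hard core would collapse
into the Coulomb singularity.

## Calibration of the two undetermined parameters

The bead geometry, charges, cell, temperature and run lengths above are
all fixed by the study design. Two quantities are not determined by it
— the effective electrostatic screening and the dendrimer bond rest
length — and were fixed once, against the study's own structural
anchors, before any acceptance evaluation; they are not tuning knobs
and are never revisited per experiment.

**Screening length λ_D = 12 Å.** With bare unscreened Coulomb at
λ_B = 7.14 Å, a 120-bead chain of unit charges at 8 Å spacing in a
dilute cell is almost a rigid rod (measured ensemble asphericity ≈ 0.92,
consistent with classic dilute-polyelectrolyte simulations). The
behaviour this package targets — a free DNA only slightly stiffer than
an athermal self-avoiding chain (mean asphericity ≈ 0.58 vs 0.53), a
~15 Å dendrimer, and a condensation transition at r_charge ≈ 1 — is
that of a *screened* polyelectrolyte. A Debye factor with λ_D scanned
over {8, 15, 30, 60} Å gave free-DNA mean asphericities
{0.58, 0.61, 0.66, 0.77}; λ_D in the 8–15 Å window satisfies the shape
anchor. Within that window, a stability probe (a pre-condensed polyplex
relaxed for 8×10⁵ moves) showed the condensed state is thermodynamically
stable throughout, but dispersed-start runs at desk budgets only reach
the condensed branch for λ_D ≳ 12 Å. λ_D = 12 Å — the Debye length of a
~65 mM 1:1 electrolyte, within the buffered conditions of the
accompanying experiments — satisfies both anchors jointly:
free-DNA ⟨A⟩ = 0.597 ± 0.009 (6 replicates), condensation at
r_charge ≈ 1 present. `InteractionParams` defaults to bare Coulomb;
`polyplexmc.fixtures.study_params()` carries the study value.

**Dendrimer bond rest length r₀ = 0.** With contact-length bonds
(3 Å), each centre-to-terminal arm is a six-bond tangent-sphere string;
its most probable extension puts the RDF peak near 14 Å regardless of
electrostatics — a geometric floor twice the anchored size. Centre-
anchored springs (r₀ = 0 with the same 0.4 N/m constant, sub-contact
exclusions as above) let the bonds settle at ≈ 2.1 Å and give an
RDF-peak diameter of 15.5–16.5 Å. The dendrimer diameter is reported as
twice the position of the maximum of the shell-normalised g(r) between
the central bead and the 16 terminals (the terminals trace the
molecular envelope; raw pair counts would weight the peak upward by the
r² shell volume).

## Monte Carlo sampling

Canonical-ensemble Metropolis with three move types:

* single-particle displacement (80% of attempts): uniform cube moves,
  amplitude 2.5 Å for bonded beads and 60 Å for free counterions;
* rigid whole-molecule translation (10%), amplitude 40 Å;
* pivot (10%): a random bond is chosen; the sub-chain (linear molecule)
  or subtree (branched molecule) beyond it rotates rigidly about a
  random axis through the pivot bead, angle uniform in (−π, π].

Amplitudes were tuned once against two diagnostics — acceptance in the
30–55% band for displacement moves, and vector–DNA mixing (with small
molecule steps, a dendrimer needs ~10⁴ accepted translations to cross
the 1200 Å cell, which silently rate-limits binding at reduced
budgets) — and then frozen; measured acceptance on the mixed systems is
≈ 38% for bead moves and ≈ 55% for molecule translations.

An "MC step" is one attempted elementary move. All moves displace a
subset rigidly, so the energy difference reduces
to cross-pair Coulomb terms, boundary-crossing bonds, hard-core and
wall checks, evaluated incrementally in a compiled (numba) kernel; the
incremental evaluation agrees with a full recomputation to < 1e-10 kT
(property-tested).

Initial states are built by self-avoiding growth of each molecule
(beads placed at bond contact distance in random directions, with
overlap rejection), random rigid placement in the cell, and uniform
counterion insertion; equilibration then precedes production. A run is
fully reproducible from (composition, config, seed); replicate `k` of
an ensemble uses seed `base + k`.

**Study conditions.** 2.0×10⁶ equilibration and 3.0×10⁶ production
attempted moves per replicate, at least six replicates, frames sampled
every 10³ moves. The `scale` parameter of `make_paper_system` and
`SimulationConfig.scaled` shrinks the step budgets only — never the
molecular model, whose bead counts are structural.

## Observables

* **Radius of gyration** `Rg = √(⟨|r_i − r_CM|²⟩)` over a bead
  selection (unweighted). Condensation curves report the rms Rg over
  frames and replicates, normalised by the free-DNA rms Rg.
* **Asphericity** from the sorted eigenvalues L₁² ≤ L₂² ≤ L₃² of the
  unit-mass gyration tensor:

      A = [(L₁²−L₂²)² + (L₂²−L₃²)² + (L₃²−L₁²)²] / [2 (L₁²+L₂²+L₃²)²].

  A = 0 for spherical symmetry, exactly ¼ for a thin ring (toroid), 1
  for a straight rod. Per-frame ratios classify morphologies
  (toroidlike 0.15–0.25, rodlike > 0.6). *Ensemble-mean* asphericities
  — per replicate and pooled — are the ratio of ensemble-averaged
  invariants ⟨num⟩/⟨den⟩, the convention under which an ideal chain
  gives exactly 10/19 = 0.526 (verified here against exact
  freely-jointed sampling) and long self-avoiding chains ≈ 0.53–0.55;
  averaging per-frame ratios instead gives systematically lower values
  (0.39 ideal, 0.45 SAW) because the denominator fluctuates with
  instantaneous size. The gyration-tensor convention is used throughout
  because the limiting values above (ring ¼, rod 1, sphere 0) are its
  signatures; a literal moment-of-inertia tensor would give 1/16, ¼ and
  0 instead.
* **RDF** between two bead groups: shell-volume-normalised histogram;
  when a container volume is supplied, normalised by the ideal pair
  density (a uniform gas then reads 1 − 3r/4R + O((r/R)³), the exact
  finite-ball depletion, which the tests assert).
* **Contact profiles**: time-averaged number of dendrimer end groups
  and of peptide beads within a 20 Å centre-to-centre cutoff of each
  DNA monomer, resolved along the chain.
* **Morphology densities**: Gaussian KDE (Silverman bandwidth by
  default) over per-replicate mean asphericities, with local maxima
  reported — a bimodal density with one peak in the toroid band and
  one above 0.6 signals coexisting condensate shapes.

## Synthetic references

`polyplexmc.fixtures` generates every validation input with no external
data: rings, rods, Fibonacci-sphere shells and cubic lattices with
closed-form Rg and A; exact freely-jointed chains
(⟨Rg²⟩ = b²(N²−1)/6N); pivot-equilibrated athermal self-avoiding chains
(compiled sampler, rigid tangent bonds); a charged-sphere/counterion
pair in a small cell whose mean separation reduces to a 1-D Boltzmann
quadrature over the exact two-point separation density of a ball; and
the full study compositions at configurable charge ratio. These
fixtures emulate the *statistics* the analyses assume — they do not
emulate experimental data (gels, light scattering, AFM), so passing
tests validate the simulator and estimators, not the mapping from model
to wet-lab observables.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run reduced versions of the
study conditions chosen to keep a full desk run in minutes while
leaving each estimate's sampling error well inside its comparison band:
free-DNA asphericity from 4–6 replicates at 8–12% of the study step
budget (replicate spread ≈ 0.01); the SAW reference from 10⁴
pivot-thinned configurations; the dendrimer RDF from 3 replicates of
4.5×10⁵ moves; trend checks at 15–30% step budgets with 2–3
replicates. Replicate means at these sizes are stable to ≈ 0.01 in A
and a few percent in Rg ratios.

## Known limitations

* The condensed branch at r_charge ≈ 1 is thermodynamically stable but
  kinetically hard to reach: dispersed random starts nucleate
  condensation unreliably at reduced step budgets, so near-transition
  Rg ratios have large replicate dispersion (the same dispersion is a
  feature of the transition region itself), and tightly condensed
  toroids (A < 0.3) are rarely reached at a tenth of the study budget.
  Cluster or bridging moves would accelerate nucleation; they are out
  of scope.
* Debye screening plus explicit counterions double-counts the small-ion
  atmosphere at second order; at 65 mM effective salt and the bead
  charge densities used here the explicit-ion correlations near
  contact (the counterion-release driving force) dominate, which is
  why the explicit ions are kept.
* No bending potential: chain stiffness is emergent from electrostatics
  and excluded volume.
* The hard wall acts on bead centres; a bead can protrude up to its
  radius beyond R_cell. At R_cell = 1200 Å this is negligible.
* Single-DNA cell: aggregation of several DNA molecules into one
  polyplex — visible in the accompanying experiments — is outside the
  model.
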