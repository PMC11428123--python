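# Methods

This note documents the models implemented in `xtalloy`, the choices made
where the design was genuinely open, and what the synthetic fixtures do and
do not establish about real crystals.

## Crystal model

Structures are stored as a unit cell (lengths in Å, angles in degrees), a
list of symmetry operations as xyz triplets, and the full unit-cell
molecule content; the leading molecules form the asymmetric unit and
expanding them with the operations reproduces the cell (checked on
construction and after CIF reads).  Fractional coordinates are used
internally; the fractional→Cartesian basis is the standard column matrix
with *a* along x and *b* in the x–y plane, so one convention covers all
geometry.  CIF input goes through gemmi's tokenizer; molecules are
assembled from symmetry-expanded atom sites by covalent-distance bonding
(Cordero radii sum × 1.15, the common heuristic) with connected components
unwrapped across periodic boundaries.  Partial occupancies are rejected —
disorder is out of scope.  d-spacings come from the triclinic reciprocal
metric, `d = (h·G*·h)^(-1/2)`.

## Solid solutions

Substitution places a guest template on a host site by least-squares
rigid-body superposition (Kabsch, proper rotations only) over the scaffold
atoms the two molecules share — for purines the nine ring heavy atoms plus
the keto oxygen; "maximum atom overlap" is thus operationalized as the
optimal rotation/translation over the shared ring.  The reversed scaffold
order is tried as well and kept only when it lowers the RMSD (a planar
molecule can superpose face-down); a substitution whose scaffold RMSD
exceeds 0.75 Å is refused.

Configuration ensembles at fixed stoichiometry enumerate all site
combinations of the supercell and deduplicate them under **lattice
translations only** (point-group reduction would be stricter; translations
match the supercell's periodicity and are what the orbit-counting oracle
verifies).  When the combination space exceeds 2×10⁴ the ensemble falls
back to seeded rejection sampling of distinct canonical patterns; the cap
(default 64, usually 4–12 in the pipeline) and seed are recorded in the
ensemble provenance.  Ensembles are reduced to a single energy per
composition by minimum (default), mean, or Boltzmann weight — the choice is
exposed because the upstream protocol does not pin it down; with the
noise-free pairwise fixture all members are degenerate and the choice is
immaterial.

## Thermodynamics

Per-molecule lattice energy of a doped supercell:

    E_latt = (E_cell − N_h·E_h − N_g·E_g) / N_cell        [kJ/mol]

with gas-phase reference energies per species.  Ideal mixing entropy
`ΔS_mix = −R (x_h ln x_h + x_g ln x_g)` (J·mol⁻¹·K⁻¹, 0·ln 0 = 0), a
degree-3 least-squares trendline for the vibrational contribution sampled
at a few compositions (`numpy.polyfit`), and

    G(x) = E_latt(x) + F_vib(x) − T·ΔS_mix(x),   T = 300 K default.

Helmholtz and Gibbs energies are treated as interchangeable (PΔV ≈ 0 for
substitutional doping).  Stability is judged against the linear physical
mixture of the most stable pure solids; the accessibility threshold is
2RT evaluated exactly (≈ 4.99 kJ/mol at 300 K) rather than a rounded
4 kJ/mol, and both the margin and the threshold are reported so either
reading can be applied.  The α↔β host polymorph gap and the pure-guest
energy are never available from first principles here; they are
configuration inputs (fixture: gap 1.5 kJ/mol, guest offset +1.0 kJ/mol).
The default composition grid stops at x_g = 0.5, the experimentally
relevant doping range.

## Interactions

Two molecules are neighbors when their minimum atom–atom distance over
periodic images is ≤ 3.8 Å (the solvation-partitioning convention; centroid
distance would undercount π-stacked planar molecules).  The image search
range grows automatically with the cutoff plus molecular extents, so small
cells never error.  Two contacts share an interaction type iff a symmetry
operation of the structure, composed with central↔neighbor exchange, maps
one molecular pair onto the other (union-find over the contact orbit
graph; centroid matching tolerance 0.05 fractional).  Multiplicity is the
directed contact count per molecule, and Σ multiplicities equals the
neighbor count — an invariant the tests enforce.

Energies attach to types with the **half-bond convention** (per-molecule
share = dimer energy / 2) and the sign convention that
`ΔG_cryst = ΔG_vacuum − ΔG_desolv` is **positive when crystallizing the
interaction is favorable**.  The upstream solvation-partitioning
literature uses the opposite sign internally; the sign is stated here and
on the dataclasses to prevent silent inversion.

## Synthetic data

`make_toy_structure("beta")` builds a Z = 2 monoclinic cell (a = 3.6 Å,
b = 6.0 Å, c = 7.0 Å, β = 96°) of planar 5-atom cross molecules whose
contact graph reproduces the β-guanine motif qualitatively: π-stacking
along the short *a* axis (×2), a chain contact along *b* (×2, the
"3H-bond"), and four diagonal dimer contacts in the *bc* plane (the
"2H-bond").  The second molecule is generated by a centering translation
operation so both sublattices are symmetry-equivalent and classification
yields 4 unique types from 8 neighbors.  The packaged
`beta_guanine_synthetic.cif` is the same motif with a doubled *c* axis
(Z = 4, cyclic translation group of order 4); its header states that it is
a synthetic approximation, not the experimental structure.  The real
β-guanine coordination (12 neighbors, 8 unique types) requires the
published CSD structure, which is not redistributed here; the neighbor and
classification code paths are instead validated against brute-force
oracles on randomized cells.

Fixture energies are **qualitative by construction**: they encode only
documented orderings, never digitized figure values.  Host vacuum wells
(kJ/mol, half-bond): π-stack 5, 3H-bond 9.5, 2H-bond 9 — the required
ordering 3H > 2H > π with a deliberately modest 3H:2H margin so the
in-plane hexagonal habit survives at desk-scale crystal sizes.
Desolvation offsets: water {π −8, 3H +5.5, 2H +3.5} (π strengthened,
H-bonds weakened), toluene {π +9, 3H +1.5, 2H +1} (π-stack ΔG_cryst
negative, in-plane almost solid-state).  Guest perturbations scale
ΔG_vacuum: hpx-like {3H ×0.5, 2H ×0.85, π ×1.0}, xan-like {3H ×0.45,
2H ×0.70, π ×1.05}.  The pairwise energy model subtracts per-species,
per-label penalties from each contact well; a guest's lattice-energy
increment is therefore exactly its summed contact penalties (11 kJ/mol for
the hpx-like set, 22 for the xan-like set — a 2:1 slope ratio the fixtures
assert), the supercell energy is extensive, and E_latt(x) is exactly
linear, which is what makes the parameter-recovery test sharp.

Passing tests on these fixtures establish that the *pipeline machinery* is
correct (bookkeeping, classification, detailed balance, classification of
shapes), and that the *encoded qualitative physics* (orderings, slope
ratios) propagates to the expected conclusions.  They do not validate DFT
energetics, real solvation free energies, or quantitative morphologies of
real guanine crystals.

## Speciation

Neutral fraction by the Henderson–Hasselbalch partition
`f = 1/(1 + 10^(pH−pKa_acid) + 10^(pKa_base−pH))`, terms omitted when a
pKa is absent; tautomer populations are Boltzmann weights of relative
energies.  pKa values are configuration, not constants: the fixture uses
literature values (guanine 9.4/3.3, hypoxanthine 8.94, xanthine 7.44),
which reproduce uncharged fractions of ≈0.71/0.47/0.03 at pH 9.  The
fixture tautomer energies are placeholders ordered per qualitative
gas/water statements and are flagged non-authoritative in the source.

## Growth engine

Coarse-grained KMC on the perfect-crystal site lattice (cells × molecules
per cell): whole-molecule growth units, no bulk vacancies, no surface
reconstruction.  Each cycle draws a site uniformly from the union of
attachment candidates (empty sites adjacent to the crystal) and detachment
candidates (occupied surface sites) — a single-pool proposal rather than a
50/50 coin between the two sets, which removes proposal asymmetry so the
single-site logistic equilibrium `p = e^{βU'}/(1+e^{βU'})` holds exactly
(verified to 3σ at five energies).  Acceptance is the Metropolis pair
`P_attach = min(1, e^{+β(U+Δμ)})`, `P_detach = min(1, e^{−β(U+Δμ)})` with
`U = Σ ΔG_cryst` over occupied neighbors, giving the rate ratio
`e^{β(U+Δμ)}` and single-site detailed balance.  Detachments that would
disconnect the crystal are rejected (local early-exit BFS); a debug mode
re-verifies global connectivity after every event.

**Equilibrium reference.**  Because ΔG_cryst > 0 for every contact, a
literal Δμ = 0 still drives growth everywhere.  The engine therefore
supports two references: `fixed_zero` applies the schedule unchanged, and
the default `solubility_matched` offsets it by the kink (half-crystal)
energy `U_kink = ½ Σ mult·ΔG_cryst`, the energy at which a self-replicating
kink site is neutral — so a schedule value of 0 means solid–solution
coexistence.  At exact coexistence a *finite* crystal slowly dissolves
(the Gibbs–Thomson effect; confirmed empirically), which the test suite
exercises with a box-spanning bulk slab whose net drift is statistically
zero, and which motivates the desk-scale protocol below.

**Driving-force schedule.**  Constant at the initial supersaturation, then
a linear descent (the simplest monotone choice) between two breakpoints,
then equilibrium.  The reference-protocol defaults — 10⁶ cycles, initial
driving force 100 kcal/mol = 418.4 kJ/mol (the unit is explicit because
prose and methodology sources disagree between kJ and kcal), descent from
cycle 5×10⁵ to 6×10⁵ — sit on `GrowthConfig` unchanged.

**Desk-scale protocol.**  At 418 kJ/mol every attachment is accepted and
shape selectivity would rely entirely on a long annealing tail that a
desk-scale run cannot afford (and that dissolves finite crystals at
coexistence).  The pipeline presets therefore grow *kinetic* morphologies:
a constant supersaturation of 0.20–0.28 × U_kink (scaled per table via
`dmu_relative`, since each solvent's energy scale differs — the per-solvent
value is a growth condition, with the aqueous tables needing 0.28 for the
3³-cell seed nucleus to be supercritical), 1–1.5×10⁵ cycles in a
44×56×30-cell box, stopping at 3500 sites or at the box margin.  These
conditions yield the expected solvent/guest morphology matrix reproducibly
across seeds (hexagonal (100) plates in vacuum, rods along *a* in water,
(100)-free needles for H-bond-weakened guests in water, flat plates in
toluene) in seconds per run.

**Facets.**  A surface site's raw outward direction is the sum of unit
vectors toward its empty neighbors on the molecular contact graph; the
local normal averages these over surface sites within 6 Å (with the
central site double-weighted), and the site votes for the candidate plane
family — coprime (hkl) with |h|,|k|,|l| ≤ 2, ±(hkl) identified — nearest
in angle.  Relative facet areas are vote fractions.  Edges and corners of
small crystals genuinely belong to no facet, so a perfect cuboid reports
{100} as the three leading families with the remainder scattered, rather
than 100% {100}.

**Morphology metrics.**  Extents are spans of occupied-site centroids
along the a, b, c directions, padded by one site spacing so a single unit
cell reports its cell edges.  The cross-section is the convex hull of the
projection onto the plane ⊥ a; hull edges are merged at 28° and clustered
by direction mod 180°, and a direction is dominant when its (antiparallel
pair of) edges carries ≥ 20% of the perimeter — equivalent to the
"dominant edges ≥ 10% each" rule but robust to ragged kinetic surfaces.
3 dominant directions → hexagonal, 2 → rectangle (in-plane aspect ≤ 2) or
lath (> 2), 1 → lath, else irregular.  The habit label compares the
a-extent to the principal in-plane extent: ≥ 3 needle, ≥ 1.5 rod, ≤ 0.6
plate, else prism; the thresholds are package conventions.

**In-plane anisotropy caveat.**  On the toy lattice the *b* axis carries
both the chain contact and the diagonal contacts, so equal per-contact
energies (3H:2H ratio 1) still favor *b* mildly (b/c extent ≈ 1.4); exact
in-plane isotropy is a property of the energy *and* topology, not the
energies alone.  The sweep asserts monotone trends (the a-axis aspect
strictly increases with the π-stack scale) rather than exact in-plane
symmetry at ratio 1.

**Guest occupancy mode.**  Alongside whole-structure guest replacement
(which preserves the crystal symmetry and is the default for morphology
comparisons), an occupancy-resolved mode attaches guests with probability
`guest_fraction`, guest sites drawing their energies from the perturbed
table.

## Reproducibility

All stochastic components consume a `numpy` `default_rng` seed carried in
the run configuration; identical configurations reproduce occupancy
lattices bit-for-bit (asserted in the tests).  Pipeline runs write a
manifest (config snapshot, seeds, stage timings, package version).

## Known limitations

* Fixture energetics are ordinal, not quantitative; no force field or
  electronic-structure backend is included.
* Crystal twinning (the experimental "chevron" habit), spiral/dislocation
  growth, and solution transport are not modeled.
* Non-ideal (regular-solution) mixing, charged-species substitution, and
  microspeciation with site-resolved protonation are out of scope.
* The packaged β-guanine fixture reproduces contact topology, not the
  published geometry; quantitative lattice-parameter trends vs doping are
  therefore not a test surface.
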