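# Methods

This note documents the models implemented in `cttaccess`, the
assumptions behind them, the tunable parameters, and what the synthetic
data generator does and does not establish.

## Coordinate and numbering conventions

All coordinates are in Å, right-handed. After lattice building the
microtubule axis is +z and the plus end is at higher z, so "toward the
minus end" means decreasing ring index / z. Author residue numbering is
authoritative and never rewritten: all site residues (β R390…, α K112…)
and tail residues (E441…Y451) are addressed in author numbering, and the
tail builder numbers only residues actually present — the tyrosinated
TubA1A tail `SVEGEGEEEGEEY` starting at 439 puts a glycine at 448, so
the glutamate subset of 445–450 is {445, 446, 447, 449, 450} and any
selection must filter by residue name, not numbering contiguity.

## Lattice model

The microtubule wall is modelled as a 13-protofilament, 3-start (13_3)
helical lattice. Its `LatticeSpec` carries:

* `pf_transform` — the rigid screw motion taking the dimer of
  protofilament *j* onto protofilament *j+1* within a ring;
* `dimer_repeat` — the axial rise per dimer along one protofilament
  (monomer repeat = half of it);
* the seam identity — composing `pf_transform` 13 times must equal a
  pure axial translation of 3 monomer repeats. Seam-closure tolerances
  default to 0.5 Å translation and 0.5° rotation residual (real
  cryo-EM lattices close imperfectly); both are configurable.

`infer_lattice_spec` recovers these parameters from any template
lattice by Kabsch least-squares superposition of backbone atoms
(N, CA, C, O; all-heavy-atom optional) between a named seed dimer and
its lateral and axial neighbours. The user names the seed chains
explicitly — deposited entries do not identify which chains to use.
Helical parameters are always inferred at runtime, never hard-coded;
the synthetic fixture uses an exactly seam-closing spec with arbitrary
documented values (dimer repeat 120 Å, ring radius 60 Å — chosen for
geometric clarity of the toy, not realism; the real dimer repeat is
~80 Å). Spec equality under a global rigid motion of the template is
judged on the frame-independent `geometry_signature` (protofilament
count, start number, twist per lateral step, rise per step, dimer
repeat), since the transform matrices themselves conjugate with the
frame.

Ring building applies `pf_transform^j` to the seed; stacking translates
the ring by multiples of the dimer repeat. Both are rigid-body
isometries per dimer. Chain identifiers are re-assigned from a
deterministic scheme (single characters up to 62 chains, a
two-character scheme beyond — a 39-dimer lattice has 156 chains); the
PDB writer places two-character identifiers in columns 21–22, the
common large-assembly extension.

The "infinite" microtubule is a bookkeeping step: the 3-ring fragment
is given an axially periodic box of length `n_rings × dimer_repeat`,
under which each protofilament continues into its own image. This is
only valid for a seam-closing (untwisted) lattice; an inherently
twisted lattice — the expanded GTP form — fails validation and is
directed to the padded box instead (20 Å padding on each side by
convention). Distances under axial periodicity use the single-axis
minimum-image convention; the implementation augments one side of a
neighbour search with ±1 axial images, exact whenever the cutoff is far
below the axial length (4 Å versus 360 Å here).

GMPCPP→GTP conversion is template bookkeeping, not chemistry: the
α,β-bridging methylene carbon (C3A and its hydrogens) is replaced by a
bridging oxygen at the carbon's position; every other ligand atom is
kept. The packaged ligand templates are synthetic stand-ins with the
correct topology of the phosphate chain, not the full chemical
component dictionary entries. Residue-name dialects GCP/CPP/G2P are
normalised to one internal GMPCPP code.

`fit_to_reference` superposes each mobile dimer onto its mapped
reference dimer independently (per-dimer mode, the default — the only
mode that guarantees the mobile model acquires the reference's lattice
geometry); a single global superposition is available as an option.

## Tail construction

Tails are built residue by residue with ideal peptide geometry
(Engh–Huber-like bond lengths and angles; NeRF internal→Cartesian
placement) and backbone dihedrals drawn uniformly from the extended
β/PPII region (φ ∈ [−150°, −60°], ψ ∈ [100°, 170°]). A placement is
accepted only when every new heavy atom is at least `clash_cutoff`
(default 2.5 Å) from all existing heavy atoms; the two residues
covalently adjacent to the growing end are exempt, since a peptide bond
is 1.33 Å by construction. Rejection sampling retries each residue up
to `max_attempts` times and backtracks one residue when a position is
geometrically blocked, within a bounded total budget. The builder is
deterministic per seed; different seeds give different conformations
with identical sequence and numbering.

Side chains are minimal: glutamate gets its full carboxylate
(CB–CG–CD–OE1/OE2, with random χ angles) because those oxygens are the
salt-bridge acceptors downstream; every other non-glycine residue gets
CB only. OXT is added to the final residue. Tails of different chains
are not clash-checked against one another (each chain is checked
against the body and its own earlier residues); the ensemble is an
extended coil, not a Boltzmann sample — downstream users equilibrate.
The β-tail sequence is a required user input with no default (isotype
dependent).

## Salt-bridge criterion and statistics

A salt bridge is any basic side-chain nitrogen (Lys NZ; Arg NE, NH1,
NH2) within `cutoff` of any carboxylate oxygen (Glu OE1/OE2, Asp
OD1/OD2, or OXT plus the backbone O on an OXT-bearing residue — the
C-terminal carboxylate). The default cutoff is 4.0 Å, the common
convention for N–O salt bridges; no geometric criterion is prescribed
by the source study, so the cutoff is configurable and every statistic
can be re-derived at other values. Multiple qualifying atom pairs
between two residues count as one contact.

Site assignment uses the host relation: *cis* sites (3, 4) must be on
the very α chain bearing the tail; *trans* sites (1, 2) must be on the
β chain of the dimer one ring toward the minus end on the same
protofilament, wrapping across the boundary when the box is periodic.
Contacts with basic residues outside all sites are labelled "other" and
retained (a census of unregistered contacts is the only site-discovery
aid; the four-site registry itself is an input). In a non-periodic box
the minus-most ring has no trans partner; those (tail, site-1/2) cells
are excluded from rate denominators.

The interaction rate is fractional frame occupancy — the fraction of
(frame, tail) samples with ≥1 salt bridge — not events per time;
an events-per-ns variant is exposed secondarily (`events_per_ns=True`).
Fig-style occupancy is the reproducible default because it needs no
time calibration. Multiple trajectories are averaged with equal weight.

Inaccessibility defaults to per-tail mode over glutamates E445–E450:
the fraction of tails with at least one salt bridge among those
residues at any of sites 1–4, per frame, optionally smoothed with a
trailing moving average (default window 1 = none). A variant counting
residues E445–Y451 (tyrosine contributing through its terminal
carboxylate) is available via `residues=INACCESSIBLE_RESIDUES_WITH_TERMINUS`
and `mode="per_residue"` — the two published descriptions of the
statistic differ, so both are implemented rather than guessing. The
registry ships the discussion-section site lists verbatim; note the
recorded discrepancy that the running text speaks of five basic
residues in sites 2, 3 and 4 while the site-3 list has four.

## Synthetic trajectories

`simulate_binding` plants an independent two-state Markov chain per
(tail, glutamate, site) triple: per-frame transition probabilities
`p_on` (unbound→bound) and `p_off` (bound→unbound), stationary
occupancy `q = p_on/(p_on+p_off)`, initial state drawn from the
stationary distribution by default (so short runs are unbiased) or
all-unbound (`start_stationary=False`, emulating a rising occupancy
curve). Geometry is emitted so that every bound pair's closest
donor–acceptor distance is `d_bound` (3.0 Å) plus a uniform jitter
(< cutoff − d_bound), and every unbound acceptor rests at a fixed
per-residue point ≥ `d_unbound` (8.0 Å) from all donors. The toy dimer
places its site residue blocks ≥ 10 Å apart so a bound oxygen can never
sit within the cutoff of the wrong site. Under periodicity the donor
image nearest the tail's anchor is targeted, so ring-0 tails genuinely
contact the top ring across the boundary.

Deliberate non-physicalities, chosen so the planted state is verifiable
from distances alone: unbound acceptors sit at a fixed rest point
rather than diffusing; a glutamate bound to two sites at once has OE1
and OE2 placed independently near the two donors (a stretched
carboxylate); at most two simultaneous sites are realisable per residue
and any excess bound state is dropped (highest site id first). The
returned `GroundTruth` records the *realised* tensor after this
resolution, so it matches the emitted coordinates exactly — the
analysis pipeline is expected to reproduce it frame for frame, and the
tests assert exactly that. The presets never plant more than two sites
per residue, so planted-versus-recovered comparisons are unaffected.

Determinism: the chain states use one seeded generator; per-frame
jitter derives from a (seed, frame) seed sequence, so lazily
regenerated frames are identical on every iteration and the text
trajectory is byte-for-byte reproducible per seed.

### Presets

Occupancies are documented arbitrary choices echoing the qualitative
compacted (GDP) versus expanded (GTP) contrast, not measured data:

| cell | gdp_like q | gtp_like q |
|------|-----------|-----------|
| (E441, site 1) | 0.45 | 0.45 |
| (E443, site 1) | 0.35 | 0.35 |
| (E445–E450, site 2) | 0.06 each | 0.004 each |
| (E449/E450, site 4) | 0.06 each | — (0) |
| (E445–E447, site 3) | 0.03 each | 0.03 each |

with `p_off = 0.02` per frame throughout (mean bound dwell 5 ns at the
default 0.1 ns frame interval). Under the closed form
`1 − Π(1 − q)` these give an expected per-tail inaccessibility of
≈ 0.41 (gdp_like) and ≈ 0.10 (gtp_like). What a green test on these
presets establishes is that the *pipeline* — detection, site
assignment, occupancy accounting — recovers planted kinetics exactly
and reproduces the expected orderings; it does not establish anything
about real tubulin dynamics, which require hundreds of nanoseconds of
all-atom MD of the 39-dimer system and are out of desk scale.

## Numerical choices

* Superposition: scipy `Rotation.align_vectors` (Kabsch); backbone
  atoms by default; atom matching by (chain rank, residue number, atom
  name) with a 90% coverage floor.
* Neighbour search: `scipy.spatial.cKDTree` over donors (±1 axial
  images when periodic), radius query from acceptors; equivalence with
  the all-pairs minimum-image computation is asserted in tests.
* Statistical tolerances in tests use the two-state chain's integrated
  autocorrelation: SE² = q(1−q)/(n_frames · n_tails) · (1+ρ)/(1−ρ)
  with ρ = 1 − p_on − p_off; stochastic assertions use 3 SE with fixed
  seeds.
* Degenerate inputs: a spec with zero dimer repeat fails validation; a
  non-closing (twisted) spec cannot be made periodic; an empty model
  cannot be written; coordinates outside the fixed-width PDB field
  raise with a pointer at mmCIF.
* Zero-frame trajectories and empty residue sets raise rather than
  returning empty statistics.

## Known limitations

* The PDB two-character chain extension (columns 21–22) is non-standard;
  third-party readers may mis-parse chains of >62-chain models (mmCIF
  output avoids the issue for interchange).
* Subunit-role inference on read pairs protein chains alternately
  (α, β) in file order, matching the builders' output; arbitrary
  downloaded entries need an explicit `role_map`.
* The tail builder produces a single extended-coil conformer per seed,
  not an ensemble with realistic statistics.
* Site discovery is out of scope: the registry is an input, and only
  the "other" census hints at unregistered contacts.
* Interaction rates are stationary occupancies; no kinetic or
  free-energy estimation is attempted.
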