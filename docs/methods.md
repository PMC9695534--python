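# Methods

## Scope and model

`raftbind` analyzes configurations and trajectories of phase-separated
model membranes (rafts) with bound amyloidogenic peptides. It does not
integrate dynamics or evaluate force fields: coordinates come from
upstream simulation output (GRO/PDB/multi-frame GRO), energies from
tabulated nonbonded time series (XVG), and validation inputs from the
package's own synthetic generator, which plants the quantities the
analyses are supposed to recover.

Three raft systems are modelled, following the standard three-component
raft design: a control raft (CO) of DPPC/DLPC/cholesterol with
coexisting liquid-ordered (Lo), liquid-disordered (Ld) and boundary
(Lod) domains; a GM-raft with GM1 clusters confined to one leaflet; and
a PS-raft with POPS clusters confined to one leaflet. Default molecule
counts are the published system sizes (CO: 828/540/576 DPPC/DLPC/CHOL;
GM: 36 GM1 + 709/407/410; PS: 162 POPS + 666/540/576) in a
22 × 22 × 20 nm³ orthorhombic box.

## Domain classification

The classifier implements the distance-rule definition of raft domains:
a DPPC belongs to Lo when at least one of its atoms lies within the
contact cutoff (default 0.5 nm) of an atom of *another* DPPC; DLPC
likewise defines Ld; PC lipids in neither core are Lod. Cholesterol is
attached to the domain of its nearest PC lipid; when its minimum
distance exceeds the cutoff it is still labelled by the nearest PC but
flagged. GM1 and POPS carry cluster labels by species — the lipids of
one species on one leaflet *are* the cluster, so no additional
clustering step is defined or invented.

Decisions where the rule as stated leaves freedom:

- **Same-leaflet restriction.** Domains are leaflet-resolved, so PC–PC
  contacts are restricted to lipids of the same leaflet. Cross-leaflet
  0.5 nm contacts are geometrically implausible for head or upper-chain
  beads but are excluded explicitly for determinism.
- **Leaflet assignment** is by head-bead z relative to the midplane
  (the mean head-bead z over all lipids). A frame whose head beads are
  all at one z has no midplane and is rejected.
- **Cholesterol tie-break.** On an exact distance tie across domains
  the fixed priority Lo > Lod > Ld applies, guaranteeing exclusive
  labels.
- **All atoms versus head atoms.** The contact search uses all lipid
  atoms by default ("one atom of each lipid"); a head-only variant is
  available as an option.
- Classification is per frame; reported compositions are time and
  replicate averages of counts, never temporally smoothed labels.

Distances are minimum-image on the orthorhombic box in all three
dimensions. The production path uses a periodic `cKDTree`; a
brute-force all-pairs path is kept alongside and the test suite asserts
bit-equality of the two on randomized frames (mindist, shells,
domains).

## Annular shells

A lipid is annular (AL) at cutoff *c* when any of its atoms lies within
*c* of any protein atom; the non-annular set (nAL) is the complement
over the analyzed lipids. Both leaflets are eligible — single-leaflet
selection is an observed outcome of bound geometries, not a rule — and
a leaflet filter is available for reporting. Water and ions are never
shell members. Compositions are species percentages of the AL
membership, averaged over window frames within each replicate with the
SEM across replicates; an entirely empty shell is returned flagged with
undefined percentages rather than zeros.

## Binding kinetics

The mindist of a protein–group pair is the minimum over all cross-pair
atom distances under periodic boundaries; the contact count is the
number of group molecules with any atom within the 2 nm interaction
threshold. The per-residue spectrum averages each residue's minimum
distance to the group over a trailing window, with residues numbered by
accumulated index (1–130 for chain A, 131–260 for chain B, and so on —
the mutation markers fall at 45/66/76 plus 130 per chain). Difference
spectra subtract two spectra residue-wise; dips are strict local minima
below a 1.0 nm threshold.

The binding-time detector formalizes the qualitative "abrupt decline to
a small, stabilized mindist": the binding time is the earliest *t* with
mindist(*t*) ≤ `d_bind` and mindist ≤ `d_hold` throughout
[*t*, *t* + `t_persist`]. Defaults are `d_bind` = 0.6 nm,
`d_hold` = 0.8 nm and `t_persist` = 0.5 µs on the coarse-grained time
scale (10 ns is the natural atomistic analogue); all three are exposed
in the configuration. A persistence window running past the end of the
series is evaluated on the available frames and flagged truncated.

## Chain order

For carbon *i* (numbered from 1 beside the headgroup), the order
parameter is S(*i*) = ⟨½(3 cos²θᵢ − 1)⟩ with θᵢ the tilt of the
flanking vector — from carbon *i−1* to carbon *i+1* — against the
bilayer normal, taken as the fixed z-axis of these planar bilayers
(no local-normal fitting). Terminal carbons carry no value. Averages
pool both acyl chains, lipids and window frames; the SEM is across
replicates when several are given, otherwise across lipids, and the
profile records which. S is bounded in [−0.5, 1]: 1 for normal-aligned
all-trans chains, 0 at the magic angle (cos²θ = 1/3) or for an
isotropic ensemble, −0.5 for in-plane chains. The flanking-vector
(three-atom) convention is the primary definition; coarse-grained beads
are treated as carbons.

## Energetics

Energy tables carry a time column plus (species, term) tagged columns
with term ∈ {Lennard-Jones, Coulomb} in kJ/mol. Aggregation takes the
trailing-window mean per replicate and the mean ± SEM across
replicates; totals are LJ + Coulomb per species and species totals sum
to the all-lipid total. The Coulomb fraction is |Coulomb|/|total| (a
sign mismatch between terms is flagged separately since the ratio is
then not a share). Normalized binding energy divides the species total
by the *time-averaged* 1.2 nm annular lipid count — a single division,
not per-frame — because 1.2 nm is the energy-calculation threshold the
tables were produced with. SEM is across replicates of window means,
matching how replicate uncertainties are quoted.

## Contact maps

Cell (*i*, *j*) of the residue contact map is the minimum distance
between atoms of accumulated residues *i* and *j*; the map carries a
time-mean and a standard-deviation layer over the window. Distances
are plain Euclidean (chains are kept whole, never split across
periodic images). The continuous map is primary; a thresholded contact
fraction (default 0.5 nm) is provided for summaries.

## Sequence descriptors

The packaged K18 reference is the 130-residue tau fragment at 2N4R
numbering 243–372, shipped as a FASTA fixture; the test suite fails
loudly if its charge counts drift from the documented (+21, −11). The
charge model counts side chains only — Lys/Arg +1, Asp/Glu −1, His
neutral, termini uncharged — the only convention consistent with those
printed counts; charged termini would give (+22, −12) with the same
net. Hydropathy uses the Kyte–Doolittle scale with a centered 5-point
moving average, truncating (and flagging) windows at the termini so the
profile keeps the sequence length. Repeat boundaries follow the
standard 2N4R convention (R1 244–274, R2 275–305, R3 306–336,
R4 337–368); position 243 precedes R1. The two in-text fragment
lengths ("73-residue" 308–372, "57-residue" 243–307) are inconsistent
with their own ranges (65 each); the ranges, which sum to 130, are
authoritative here. Accumulated residue numbering is 1-based and
contiguous (130 per chain); published chain-C/D mutation markers that
disagree with the +260/+390 offsets are treated as typos and the
arithmetic is followed.

## Synthetic generator

The generator's purpose is recoverable ground truth, not physical
realism. Lipids are stick figures — one head bead plus a linear chain
(default 7 beads at 0.24 nm spacing) — and the lateral layout is
lattice-planted so the 0.5 nm contact rule reproduces it exactly:

- Lo core: DPPC on a 0.45 nm square lattice disc (every lipid has a
  same-species contact under the cutoff);
- Ld core: DLPC on an equally dense disc centered half a box away;
- Lod: remaining DPPC/DLPC interleaved on a 0.55 nm lattice ring
  around the Lo core (no same-species pair within the cutoff), with
  0.7 nm clearance between regions;
- cholesterol: single beads 0.25 nm outside a host PC's head bead,
  hosts drawn at the planted Lo/Ld/Lod fractions — 60/10/30 by default
  (the distribution reported for control and GM rafts; 50/15/35 for
  the PS raft);
- GM1/POPS: dense discs on one designated leaflet only (region
  exclusion is minimum-image aware so clusters stay clear of the Lod
  ring across periodic boundaries);
- placement jitter is uniform ±0.015 nm per lipid plus ±0.005 nm per
  frame, small enough that the dense/sparse margins (0.49 vs 0.51 nm
  worst case against the 0.5 nm cutoff) are never crossed.

The DPPC Lo-core fraction (0.33) and DLPC Ld-core fraction (0.25)
reproduce the reported domain shares in which roughly 20% of PC lipids
sit in Lo, 10% in Ld and the Lod boundary accounts for the large
remainder. Defaults keep chains vertical (S = 1); planting sub-unity
order tilts chains, which wander laterally and void the lattice
separation guarantees, so order-planting (`plant_chain_order`) is for
order fixtures, not classification fixtures.

The binding script holds the protein (a compact serpentine blob of
130-bead chains, one bead per residue) at its initial height — default
5 nm, the published initial placement — and drops it at the first frame
whose time reaches the scripted binding time to a bound gap (default
0.4 nm) above the PC head-bead plane, with bounded jitter. The drop is
abrupt by construction, mirroring the abrupt mindist declines the
detector is designed for; outward-protruding beads (cholesterol, GM1
headgroups) can make the realized all-lipid mindist slightly smaller
than the scripted gap, which stays well inside the bound regime.
Chain-order targets are realized by a two-point tilt mixture (perfect
alignment vs the magic angle for S ≥ 0, magic angle vs 90° for S < 0),
giving the exact expectation with known Monte-Carlo variance; flanking
vectors are set independently by exploiting that even- and odd-indexed
beads form two interleaved subchains. Time stamps are microseconds for
coarse-grained-style fixtures (nanoseconds are the atomistic
convention). An optional thin water slab supports protein–water
mindist curves and is off by default. All randomness flows from the
spec/script seed; identical seeds give bit-identical output.

What the generator does *not* emulate: thermal lipid diffusion, domain
boundary fluctuations, membrane undulations, realistic area per lipid,
or emergent phase behavior. Passing the planted-truth suites shows the
analysis operators invert the generator's construction under noise —
it does not validate force fields or sampling of real trajectories.

## Problem sizes and numerics

Validation suites run at sizes chosen to exercise the full published
system where it is cheap (domain classification on the 1944-lipid CO
raft) and scaled-down fixtures where ensembles are needed (20 seeded
binding scripts on ~120-lipid rafts of 40 frames; 5000-chain order
ensembles; randomized ≤60-lipid frames for the 100-frame oracle
equivalence sweep). Oracle equality is asserted to 1e-9 nm for
distances and exactly for set memberships and labels. Percentages per
species sum to 100 within floating rounding; SEM with a single
replicate is reported as NaN and flagged rather than silently computed
across a different axis.

## Known limitations

- Orthorhombic boxes only; triclinic inputs are rejected at parse time.
- Binary trajectory formats (XTC/TRR/DCD) are not read; trajectories
  are frame-concatenated GRO or per-frame files.
- The energetics module never computes energies from coordinates.
- The binding-time detector is a threshold rule, not a changepoint
  estimator; heavily fluctuating series near the thresholds inherit
  its sensitivity to `d_hold`/`t_persist`.
- Secondary structure (DSSP-style) analysis and resolution
  transformations between bead and atomistic representations are out
  of scope.
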