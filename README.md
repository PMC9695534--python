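# raftbind

Trajectory analysis of tau-K18 oligomers binding to phase-separated
lipid rafts.

Misfolded tau aggregates interact with the raft domains of neuronal
membranes, and characterizing *where* and *how strongly* a disordered
oligomer engages a phase-separated bilayer takes a specific stack of
trajectory analyses. `raftbind` packages that stack as a tested Python
library for structural bioinformaticians working with coarse-grained or
atomistic membrane simulations of raft models built from DPPC, DLPC,
cholesterol, GM1 and POPS:

- **Domain classification** — every DPPC with an atom within 0.5 nm of
  another DPPC (same leaflet, minimum image) is liquid-ordered (Lo);
  DLPC likewise defines liquid-disordered (Ld); the remaining PC lipids
  form the mixed boundary (Lod). Each cholesterol inherits the domain
  of its nearest PC lipid; GM1/POPS carry their one-leaflet cluster
  labels.
- **Annular shells** — a lipid with any atom within a cutoff (0.5 or
  1.2 nm) of any protein atom is an annular lipid (AL); compositions
  are reported as mean ± SEM per species over windows and replicates.
- **Binding kinetics** — protein–group minimum distance ("mindist")
  and 2 nm contact counts versus time, per-residue mindist spectra with
  accumulated residue numbering (130 per chain), difference spectra and
  sub-1 nm dip finding, and a threshold-persistence binding-time
  detector (bound from the earliest time the mindist drops below
  `d_bind` = 0.6 nm and holds below `d_hold` = 0.8 nm for `t_persist`).
- **Chain order** — the orientational order parameter
  `S(i) = ⟨½(3 cos²θᵢ − 1)⟩`, with θᵢ the angle between the vector
  joining carbons *i−1* and *i+1* and the bilayer normal; paired AL/nAL
  profiles quantify protein-induced chain disruption.
- **Energetics** — Lennard-Jones + Coulomb protein–lipid energy tables
  (XVG) aggregated per species with SEM across replicates, Coulomb
  fractions, and totals normalized by the 1.2 nm annular lipid count.
- **Sequence tools** — WT-K18 (tau 243–372, net +10e) and the
  membrane-binding-deficient MBD-K18 (V287E/I308E/V318E, net +7e),
  formal charges, Kyte–Doolittle hydropathy, and tau repeat (R1–R4)
  annotation.
- **Synthetic membranes** — a generator that plants CO-, GM- and
  PS-raft layouts (at the published molecule counts), cholesterol
  splits, one-leaflet GM1/POPS clusters, scripted binding events and
  per-carbon chain order as recoverable ground truth, so every analysis
  is validated against known answers.

## Worked example

Classify a synthetic control raft and recover its planted composition
(`examples/02_domain_classification.py`):

```python
import raftbind as rb

frame, truth = rb.generate_raft(rb.raft_spec("CO", seed=1))
assignment = rb.classify_frame(frame, cutoff=0.5)
print(f"{100 * rb.label_agreement(assignment, truth.domain_label):.1f}%")
```

which prints, together with the composition table:

```
lipids classified : 1944
planted-label agreement: 100.0%

species  domain    share
  DPPC   Lo         33.1%
  DPPC   Lod        66.9%
  DLPC   Ld         25.2%
  DLPC   Lod        74.8%
  CHOL   Ld-CHOL    10.1%
  CHOL   Lo-CHOL    60.1%
  CHOL   Lod-CHOL   29.9%
```

The 1944 lipids are the control raft's published counts (828 DPPC,
540 DLPC, 576 CHOL); the cholesterol shares recover the planted
60/10/30 Lo/Ld/Lod split. Detecting a scripted binding event
(`examples/03_binding_kinetics.py`) prints

```
scripted binding time : 5.10 us
detected binding time : 5.10 us
contacts before/after : 0 -> 93

0.5 nm annular shell (31.0 lipids):
  CHOL   33.6%
  DLPC   24.0%
  DPPC   42.4%
```

— the detector lands on the scripted frame, and a protein bound over
the Lod boundary sees both PC species in its shell. The other
`examples/` scripts cover sequences, order parameters, energetics and
contact maps, each printing a short annotated result.

A `raftbind` command-line tool wraps the same operations
(`generate`, `classify`, `shells`, `kinetics`, `order`, `energy`,
`contacts`, `report`) for shell pipelines; see `raftbind --help`.

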