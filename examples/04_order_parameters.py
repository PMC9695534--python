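"""Acyl-chain order parameters: closed forms and AL/nAL comparison.

The orientational order parameter S = <0.5 (3 cos^2 theta - 1)> of the
flanking-carbon vector is 1 for chains aligned with the bilayer
normal, 0 at the magic angle, and recovers an intermediate planted
target within Monte-Carlo error.  Disordering the chains inside the
annular shell (AL) relative to the rest (nAL) reproduces the kind of
protein-induced order perturbation seen around membrane-bound
oligomers.
"""

import numpy as np

import raftbind as rb
from raftbind import order, shells
from raftbind.synthetic import plant_chain_order

for target in (1.0, 0.0, 0.4):
    chains = rb.generate_chain_ensemble(target, 5000, chain_length=9, seed=2)
    _, s, sem = rb.order_from_chains(chains)
    print(f"target S = {target:4.1f} -> measured {s.mean():+.3f} "
          f"(max SEM {sem.max():.3f})")

# AL/nAL perturbation on a bound-protein frame
spec = rb.RaftSpec(counts={"DPPC": 120, "DLPC": 80, "CHOL": 40},
                   box=(14, 14, 20), seed=3)
script = rb.BindingScript(binding_time=0.2, seed=3, n_chains=1,
                          lateral_offset=(2.5, 0.0))
traj, _ = rb.generate_trajectory(spec, script, n_frames=4, dt=0.5)
last = traj[-1]
sel = shells.select_annular(last, 0.8)
al_dppc = [m for m in sel.annular if sel.species[m] == "DPPC"]
nal_dppc = [m for m in sel.non_annular if sel.species[m] == "DPPC"]
frame = plant_chain_order(last, al_dppc, 0.65, seed=3)
frame = plant_chain_order(frame, nal_dppc, 0.95, seed=4)
comparison = order.shell_order_comparison(
    rb.Trajectory([frame]), cutoff=0.8, window=1.0)
al = comparison["DPPC"]["AL"]
nal = comparison["DPPC"]["nAL"]
print(f"\nDPPC shells: {len(al_dppc)} AL vs {len(nal_dppc)} nAL lipids")
print("carbon   S(AL)   S(nAL)  difference")
for c, a, n in zip(al.carbons, al.values, nal.values):
    print(f"  {c}     {a:+.3f}  {n:+.3f}   {a - n:+.3f}")

# A negative AL - nAL difference at every carbon is the signature of
# chain-order disruption localized to the protein's lipid shell.
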