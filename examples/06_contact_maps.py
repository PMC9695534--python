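"""Residue-contact map of a K18 dimer with mean and fluctuation layers.

The map holds, per residue pair, the time-mean minimum distance and
its standard deviation over the analysis window; compact oligomers
show large low-distance blocks, and rigid motion leaves the SD layer
at zero.
"""

import numpy as np

import raftbind as rb
from raftbind.contacts import residue_contact_map

spec = rb.RaftSpec(counts={"DPPC": 40, "DLPC": 30, "CHOL": 10},
                   box=(10, 10, 20), seed=6)
script = rb.BindingScript(binding_time=0.5, seed=6, n_chains=2)
traj, _ = rb.generate_trajectory(spec, script, n_frames=6, dt=0.5)

cmap = residue_contact_map(traj, window=2.0)
print(f"map size      : {cmap.n_residues} x {cmap.n_residues} residues")
print(f"frames used   : {cmap.n_frames}")
print(f"mean distance : {cmap.mean[np.triu_indices(cmap.n_residues, 1)].mean():.2f} nm")
print(f"max SD        : {cmap.sd.max():.3f} nm")
print(f"contact fraction (<= 0.5 nm): {cmap.contact_fraction(0.5):.3f}")

# The two 130-residue diagonal blocks are the intra-chain maps of
# chains A and B; near-zero SD reflects the rigid scripted motion.
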