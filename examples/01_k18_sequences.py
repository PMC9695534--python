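"""Build WT-K18 and MBD-K18 and compare their charge and hydropathy.

K18 is the four-repeat microtubule-binding fragment of tau (residues
243-372).  The membrane-binding-deficient mutant swaps three
hydrophobic residues (V287, I308, V318) for glutamate, removing three
positive units of net charge and cutting hydropathy at each site.
"""

import raftbind as rb

wt = rb.build_k18("wild_type")
mbd = rb.build_k18("mbd")

cw, cm = rb.formal_charges(wt), rb.formal_charges(mbd)
print(f"WT-K18 : length {len(wt)}, charges +{cw.positive_count}e / "
      f"{cw.negative_count}e, net {cw.net:+d}e")
print(f"MBD-K18: length {len(mbd)}, charges +{cm.positive_count}e / "
      f"{cm.negative_count}e, net {cm.net:+d}e")

prof_wt = rb.hydropathy_profile(wt, window=5)
prof_mbd = rb.hydropathy_profile(mbd, window=5)
print("\nmutation site, repeat context, local index, hydropathy WT -> MBD")
for pos in (287, 308, 318):
    print(f"  {wt.at(pos)}{pos}E  {rb.repeat_context(wt, pos):12s}"
          f"  {wt.local_index(pos):3d}"
          f"  {prof_wt.value_at(pos):+5.2f} -> {prof_mbd.value_at(pos):+5.2f}")

# Charges count side chains only (His neutral, termini uncharged);
# each V/I -> E substitution lowers the net charge by one.
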