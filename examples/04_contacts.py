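"""Residue contact statistics between a pore ring and a cargo protein.

The demo system moves a small cargo through a hexagonal dimer ring; residue
pairs within 6.5 A count as contacts, aggregated as frame fractions, and
contacting pairs are classified by polarity.
"""

from poremap import contact_matrix, contact_number_profiles, polarity_contact_fractions, recenter
from poremap.pipeline import generate_demo

demo = generate_demo(seed=0)
traj = recenter(demo.trajectory, demo.pore_selection, demo.po4_selection)

cm = contact_matrix(traj, demo.pore_selection, demo.cargo_selection, cutoff=6.5)
pore_profile, cargo_profile = contact_number_profiles(cm)
fractions = polarity_contact_fractions(cm, demo.topology)

print(f"contact matrix: {cm.values.shape[0]} pore x {cm.values.shape[1]} "
      f"cargo residues over {cm.n_frames} frames")
print(f"pore residues ever in contact: {(pore_profile > 0).sum()}")
print(f"max contact persistence: {cm.values.max():.2f} (fraction of frames)")
for k, v in fractions.items():
    print(f"  {k}: {v:.1f}%")
# Hydrophilic-hydrophilic pairs dominating the interface indicates that
# polar/charged residues, not hydrophobic packing, steer the association.
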