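"""Coarse-grained to all-atom back-mapping of a two-helix assembly.

A known two-helix structure is forward-mapped to one backbone bead per
residue, then reconstructed by rigid-fitting the reference helices onto the
bead trace; the round-trip backbone RMSD measures the fidelity.
"""

import numpy as np

from poremap import (
    Frame,
    FragmentLibrary,
    SegmentDefinition,
    Topology,
    backmap_assembly,
    coarse_grain_backbone,
    make_helix,
)

top1, fr1 = make_helix(12, chain_id="A", start_resid=1)
top2, fr2 = make_helix(12, chain_id="A", start_resid=17)
fr2 = Frame(fr2.coordinates + np.array([15.0, 0.0, 0.0]), fr2.box)
aa_top = Topology.concatenate([top1, top2])
aa_frame = Frame(np.vstack([fr1.coordinates, fr2.coordinates]), fr1.box)

cg_top, cg_frame = coarse_grain_backbone(aa_top, aa_frame)
library = FragmentLibrary({"h1": (top1, fr1), "h2": (top2, fr2)})
segments = [SegmentDefinition("A", 1, 12, "h1"),
            SegmentDefinition("A", 17, 28, "h2")]

out_top, out_frame, report = backmap_assembly(cg_top, cg_frame, segments,
                                              library)
print(f"coarse-grained beads: {len(cg_top)}; rebuilt atoms: {len(out_top)}")
for seg, rmsd in report.segment_rmsd.items():
    print(f"segment {seg}: fit RMSD = {rmsd:.3f} A")
print(f"placeholder loop residues: {len(report.placeholder_residues)}; "
      f"steric clashes: {len(report.clashes)}")
# Fit RMSD near 0 means each reference helix sits exactly on its bead trace;
# loops between helices are straight-line placeholders awaiting refinement.
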