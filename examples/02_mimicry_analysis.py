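"""Cross-RMSD mimicry analysis of a parent/retro-D ensemble pair.

Generates two synthetic conformer-ensemble pairs for HAIYPRH — one whose
retro-D ensemble geometrically mimics the parent (retro-construction +
0.5 Å noise) and one sampled independently — and compares every parent
frame against every retro-D frame over the reversed-residue atom map.
A low matrix minimum means the two molecules can adopt the same 3D
arrangement.
"""

import numpy as np

from retromimic import (
    build_retro_atom_map,
    count_clusters,
    cross_rmsd_matrix,
    parse_sequence,
    retro_d_transform,
    self_rmsd_matrix,
)
from retromimic.synthetic import make_mimic_pair

parent_seq = parse_sequence("HAIYPRH")
retro_seq = retro_d_transform(parent_seq)

for mode in ("mimic", "independent"):
    parent, retro, _ = make_mimic_pair(
        parent_seq, overlap_mode=mode, noise_sigma=0.5, n_frames=60, seed=1
    )
    amap = build_retro_atom_map(parent_seq, retro_seq, parent, retro)
    res = cross_rmsd_matrix(parent, retro, amap)
    i, j, best = res.best_pair
    print(f"{mode:12s}: min cross-RMSD {best:.2f} Å at frame pair ({i}, {j}); "
          f"median {np.median(res.matrix):.2f} Å over {res.matrix.size} pairs")

# 2D self-RMSD of the parent ensemble: how many conformational clusters
# were visited (single linkage at 2 Å instead of a by-eye call)?
parent, _, _ = make_mimic_pair(parent_seq, "mimic", 0.5, n_frames=60, seed=1)
n_clusters, labels = count_clusters(self_rmsd_matrix(parent), cutoff=2.0)
print(f"parent ensemble visits {n_clusters} clusters "
      f"(largest holds {np.bincount(labels).max()} of {len(labels)} frames)")
# A mimic-mode minimum well below the independent one is the hallmark of
# genuine topological mimicry.
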