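"""Essential-dynamics overlap between parent and retro-D ensembles.

After mapping the retro-D coordinates into the parent's index space via
the reversed-residue correspondence, each ensemble's positional
covariance is diagonalized. RMSIP compares the 10 leading eigenvector
subspaces (1 = identical directions); the covariance overlap also
weighs amplitudes (1 = identical covariances).
"""

from retromimic import (
    build_retro_atom_map,
    covariance_modes,
    covariance_overlap,
    mapped_coordinates,
    parse_sequence,
    retro_d_transform,
    rmsip,
)
from retromimic.synthetic import make_mimic_pair

seq = parse_sequence("HAIYPRH")
retro_seq = retro_d_transform(seq)

for mode in ("mimic", "independent"):
    parent, retro, _ = make_mimic_pair(seq, mode, 0.5, n_frames=60, seed=2)
    amap = build_retro_atom_map(seq, retro_seq, parent, retro)
    modes_a = covariance_modes(mapped_coordinates(parent, amap, "A"))
    modes_b = covariance_modes(mapped_coordinates(retro, amap, "B"))
    print(
        f"{mode:12s}: RMSIP(k=10) = {rmsip(modes_a, modes_b, 10):.3f}, "
        f"covariance overlap = {covariance_overlap(modes_a, modes_b):.3f}"
    )
# Mimicking pairs score high on both metrics; independently sampled pairs
# (whose D-residues prefer mirrored torsion basins) score visibly lower.
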