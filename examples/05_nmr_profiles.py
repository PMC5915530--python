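"""NMR chemical-shift-deviation profiling of a parent/retro-D pair.

Generates synthetic shift tables with an imposed CSD pattern that the
retro-D peptide mirrors on the type-aligned residues, then recovers the
deviations, aligns the two profiles by amino-acid type, fits amide
temperature coefficients, and estimates cis/trans populations.
"""

import numpy as np

from retromimic import (
    align_profiles_by_type,
    cis_trans_populations,
    compute_csd,
    parse_sequence,
    retro_d_transform,
    temperature_coefficients,
)
from retromimic.synthetic import gen_shift_table

parent_seq = parse_sequence("HAIYPRH")
retro_seq = retro_d_transform(parent_seq)

rng = np.random.default_rng(0)
true_csd = {(i, "CA"): v for i, v in enumerate(rng.normal(0, 0.8, 7), 1)}
retro_csd = {(8 - i, "CA"): v for (i, _), v in true_csd.items()}

parent_table, intensities = gen_shift_table(
    parent_seq, true_csd=true_csd, cis_fraction=0.15, noise_sigma=0.02, seed=1
)
retro_table, _ = gen_shift_table(
    retro_seq, true_csd=retro_csd, noise_sigma=0.02, seed=2
)

p = compute_csd(parent_table[parent_table.temperature_K == 298.0])
r = compute_csd(retro_table[retro_table.temperature_K == 298.0])
paired = align_profiles_by_type(p, r, parent_seq, retro_seq)
ca = paired[paired.nucleus == "CA"]
corr = np.corrcoef(ca.parent_csd_ppm, ca.retro_csd_ppm)[0, 1]
print(f"CA CSD correlation across type-aligned residues: {corr:.3f}")

tempco = temperature_coefficients(parent_table)
shielded = tempco[tempco.shielded_flag]["residue_index"].tolist()
print(
    f"amide temperature coefficients: "
    f"{[round(s, 1) for s in tempco.slope_ppb_per_K]} ppb/K; "
    f"residues flagged shielded: {shielded or 'none'}"
)

pops = cis_trans_populations(intensities, method="amide-1d")
print(f"cis/trans populations: {pops['cis']:.0%} / {pops['trans']:.0%}")
# A high aligned-CSD correlation says the two peptides share local
# conformational preferences residue by residue; slopes shallower than
# -4.6 ppb/K would suggest hydrogen-bonded amides.
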