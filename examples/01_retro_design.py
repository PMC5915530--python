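"""Design retro-D versions of two blood-brain-barrier shuttle peptides.

The retro-D transformation reverses the sequence and inverts every
residue to the D-configuration (lowercase in the case convention), which
preserves side-chain topology while conferring protease resistance.
"""

from retromimic import parse_sequence, retro_d_transform, to_string

for name, text in (("HAI", "HAIYPRH"), ("THR", "THRPPMWSPVWP")):
    parent = parse_sequence(text)
    retro = retro_d_transform(parent)
    print(f"{name}: {to_string(parent)}  ->  retro-D: {to_string(retro)}")
    back = retro_d_transform(retro)
    print(f"     applying the transform twice returns: {to_string(back)}")

# Residue i of the parent carries the same side chain as residue N+1-i of
# the retro-D peptide; that correspondence drives every downstream analysis.
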