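"""Sequence descriptors for prenylated membrane-anchor (PIDR) sequences.

Builds the descriptor table for the six built-in small-GTPase anchors:
polybasic-domain (PBD) size and Lys:Arg balance, the hydrophobic fraction
and basic:acidic balance of the region N-terminal to the PBD, and the
spacing S between the PBD and the prenylated cysteine.
"""

from pidrtools.descriptors import builtin_descriptor_table

table = builtin_descriptor_table()
print(table.to_string(index=False))
print()
print(
    "Np is the number of Lys/Arg in the PBD (runs of basic residues\n"
    "separated by at most two others, minimum four).  Rheb carries a single\n"
    "lysine and therefore no PBD -- its PBD-relative fields are empty.\n"
    "S = 0 means the PBD runs directly into the prenylated cysteine."
)
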