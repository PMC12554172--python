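"""Static-structure interface contacts by van der Waals overlap.

Builds a small synthetic two-chain structure and reports cross-chain
residue contacts using the overlap criterion r_i + r_j - d >= -0.40 Å —
atoms count as contacting while their van der Waals surfaces are within
0.4 Å of touching.
"""

import numpy as np

from degronmap import StaticStructure, static_contacts

# synthetic toy interface: chain A backbone atoms facing three chain B residues
coords = np.array(
    [
        [0.0, 0.0, 0.0],  # A res 234, C
        [0.0, 3.5, 0.0],  # A res 235, C
        [0.0, 7.0, 0.0],  # A res 236, C
        [3.6, 0.0, 0.0],  # B res 13, S  (gap 3.6 -> overlap -0.1: contact)
        [3.9, 3.5, 0.0],  # B res 14, C  (overlap -0.5: no contact)
        [3.3, 7.0, 0.0],  # B res 15, N  (overlap -0.05: contact)
    ]
)
structure = StaticStructure(
    elements=np.array(["C", "C", "C", "S", "C", "N"]),
    coords=coords,
    chains=np.array(["A", "A", "A", "B", "B", "B"]),
    resids=np.array([234, 235, 236, 13, 14, 15]),
    resnames=np.array(["TYR", "TRP", "ALA", "CYS", "ARG", "PRO"]),
)

contacts = static_contacts(structure)
print("Cross-chain residue contacts (vdW overlap >= -0.40 Å):")
print(contacts.to_string(index=False))
print()
print(
    "Residue pairs appear when any of their atom pairs satisfies the overlap\n"
    "criterion; max_overlap_A is the tightest approach (positive = interpenetrating)."
)
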