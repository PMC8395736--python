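"""Published reference inputs for the four blood proteins.

Per-residue-type contact percentages (binding-site composition on a
MUS-capped 2.2 nm gold core) and size descriptors for hemoglobin,
serum albumin, α1-antiproteinase and complement C3. These are inputs
to the class-aggregation and capacity comparisons, not quantities this
package computes.
"""

from .capacity import BLOOD_PROTEIN_GEOMETRIES  # noqa: F401

BLOOD_PROTEINS = (
    "hemoglobin",
    "serum_albumin",
    "alpha1_antiproteinase",
    "complement_c3",
)

#: binding-site composition, percent of binding-site residues per type,
#: columns ordered as BLOOD_PROTEINS
CONTACT_TYPE_PERCENTAGES: dict[str, tuple[int, int, int, int]] = {
    "A": (13, 11, 7, 7), "C": (2, 13, 0, 3), "D": (2, 2, 4, 2),
    "E": (0, 5, 9, 1), "F": (10, 4, 11, 6), "G": (2, 0, 0, 5),
    "H": (3, 5, 0, 2), "I": (0, 4, 9, 4), "K": (8, 4, 4, 5),
    "L": (3, 16, 20, 10), "M": (3, 2, 4, 4), "N": (3, 4, 4, 2),
    "P": (10, 5, 2, 7), "Q": (7, 4, 0, 7), "R": (3, 2, 0, 5),
    "S": (7, 2, 9, 9), "T": (5, 2, 4, 6), "V": (15, 9, 7, 11),
    "W": (2, 0, 2, 2), "Y": (2, 7, 4, 4),
}

#: published class-row percentages, same column order
CONTACT_CLASS_PERCENTAGES: dict[str, tuple[int, int, int, int]] = {
    "hydrophobic": (48, 53, 64, 46),
    "charged": (14, 12, 17, 14),
    "polar": (22, 11, 17, 23),
    "others": (17, 24, 2, 17),
}

#: mean binding strength per protein over its binding sites, kcal/mol
BINDING_STRENGTH_KCAL: dict[str, tuple[float, float]] = {
    "hemoglobin": (-41.0, 11.0),
    "serum_albumin": (-36.0, 12.0),
    "alpha1_antiproteinase": (-36.0, 8.0),
    "complement_c3": (-47.0, 15.0),
}
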