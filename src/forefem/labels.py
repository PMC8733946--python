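"""Region label codes shared by the voxel, mesh and solver layers.

A single integer label array describes a dressed forefoot model.  Bones are
labelled per structure (the morphometrics and boundary-condition layers need
to tell MH1 and the sesamoids apart); everything else is one code per
material region.  Helper sets group the structure codes into the material
categories of the constitutive table.
"""

from __future__ import annotations

BACKGROUND = 0

# Bones: five metatarsals (incl. fused phalanx stubs) and two sesamoids.
MH1, MH2, MH3, MH4, MH5 = 11, 12, 13, 14, 15
SESAMOID_MEDIAL, SESAMOID_LATERAL = 21, 22

SOFT_TISSUE = 3
SKIN = 4
SOCK = 5
ORTHOSIS = 6
SOLE = 7
UPPER = 8

METATARSALS = (MH1, MH2, MH3, MH4, MH5)
SESAMOIDS = (SESAMOID_MEDIAL, SESAMOID_LATERAL)
BONES = METATARSALS + SESAMOIDS

#: label -> material-region name used by :class:`forefem.materials.MaterialLibrary`
REGION_OF_LABEL = {
    **{b: "bone" for b in BONES},
    SOFT_TISSUE: "soft_tissue",
    SKIN: "skin",
    SOCK: "sock",
    ORTHOSIS: "orthosis",
    SOLE: "sole",
    UPPER: "upper",
}

#: labels belonging to the foot body (bonded to each other); the shoe body
#: (orthosis, sole, upper) interacts with the sock only through contact.
FOOT_BODY = BONES + (SOFT_TISSUE, SKIN, SOCK)
SHOE_BODY = (ORTHOSIS, SOLE, UPPER)

NAME_OF_LABEL = {
    BACKGROUND: "background",
    MH1: "mh1", MH2: "mh2", MH3: "mh3", MH4: "mh4", MH5: "mh5",
    SESAMOID_MEDIAL: "sesamoid_medial", SESAMOID_LATERAL: "sesamoid_lateral",
    SOFT_TISSUE: "soft_tissue", SKIN: "skin", SOCK: "sock",
    ORTHOSIS: "orthosis", SOLE: "sole", UPPER: "upper",
}
LABEL_OF_NAME = {v: k for k, v in NAME_OF_LABEL.items()}


def is_bone(label: int) -> bool:
    return label in BONES
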