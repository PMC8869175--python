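"""Reference per-class image counts of the three-source bone-marrow /
peripheral-blood cytology collection this tool was designed around.

Source 1 is a clinical laboratory bone-marrow aspirate-smear set, source 2
a peripheral-blood single-cell set from an automated slide analyzer, and
source 3 a bone-marrow set from an AML cohort archive.  Counts are images
per morphological label per source; ``None`` marks a label absent from a
source.  These tables drive manifest arithmetic (merging, balancing) in
tests and examples without shipping any image data.
"""

from __future__ import annotations

# label -> (source 1, source 2, source 3)
SOURCE_COUNTS: dict[str, tuple[int | None, int | None, int | None]] = {
    "basophil": (570, 420, 234),
    "eosinophil": (1061, 1356, 1121),
    "erythroblast": (540, 500, 507),
    "immature_granulocytes": (1266, 1615, None),
    "lymphocyte": (None, 1213, None),
    "lymphocyte_atypical": (4, None, 3),
    "lymphocyte_typical": (1790, None, 2028),
    "metamyelocyte": (8, None, 5),
    "monoblast": (14, None, 12),
    "monocyte": (912, 1013, 658),
    "myeloblast": (1246, None, 1858),
    "myelocyte": (22, None, 17),
    "neutrophil": (None, 3316, None),
    "neutrophil_band": (42, None, 40),
    "neutrophil_segmented": (3588, None, 3758),
    "platelet": (1650, 689, None),
    "promyelocyte": (26, None, 43),
    "promyelocyte_bilobed": (10, None, 8),
    "smudge_cells": (7, None, 8),
}

# per-class totals after merging cell families and one expert removal
# (a single neutrophil image was excluded during curation)
MERGED_COUNTS: dict[str, int] = {
    "basophil": 1224,
    "eosinophil": 3538,
    "erythroblast": 1547,
    "immature_granulocytes": 2933,
    "lymphocyte": 5038,
    "monoblast": 26,
    "monocyte": 2583,
    "myeloblast": 3104,
    "neutrophil": 10743,
    "platelet": 2339,
    "promyelocyte": 87,
    "smudge_cells": 15,
}

MERGED_TOTAL = 33177


def totals_by_label() -> dict[str, int]:
    """Pre-merge totals summed across the three sources."""
    return {label: sum(c for c in counts if c is not None)
            for label, counts in SOURCE_COUNTS.items()}
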