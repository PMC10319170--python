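"""Default antibody-panel definition for the myeloid Ki-67/Bcl-2 assay.

The assay stains each bone-marrow aspirate in seven tubes.  Two tube
groups share backbone markers so that tubes within a group can be merged
event-wise: tubes 1/2/5 share FSC, SSC, CD13, CD34, CD45, CD117 and
HLA-DR, and tubes 3/4/6/7 share FSC, SSC, CD33, CD45, CD117 and HLA-DR.
Tubes 1 and 7 carry IgG1 isotype controls on the Ki-67 (FITC) and Bcl-2
(PE-CF594) detectors; the remaining tubes carry the Ki-67/Bcl-2 stains
plus the lineage markers needed by the hierarchical gating strategy
(CD36/CD71/CD235a for erythroid work-up, CD14/CD10/CD11b for the
monocyte backgate).
"""

from __future__ import annotations

from .fcs_io import PanelDefinition

__all__ = ["default_panel", "SCATTER_CHANNELS", "GROUP_A_BACKBONE", "GROUP_B_BACKBONE"]

SCATTER_CHANNELS = [
    ("FSC", "INT", "FSC-INT"),
    ("SSC", "INT", "SSC-INT"),
    ("FS", "PEAK", "FS-PEAK"),
]

GROUP_A_BACKBONE = {"FSC", "SSC", "CD13", "CD34", "CD45", "CD117", "HLA-DR"}
GROUP_B_BACKBONE = {"FSC", "SSC", "CD33", "CD45", "CD117", "HLA-DR"}

_COMMON = [
    ("CD45", "KO", "CD45-KO"),
    ("CD117", "PC5.5", "CD117-PC5.5"),
    ("HLA-DR", "PB", "HLA-DR-PB"),
]
_GROUP_A = _COMMON + [
    ("CD34", "ECD", "CD34-ECD"),
    ("CD13", "APC-A700", "CD13-APC-A700"),
]
_GROUP_B = _COMMON + [("CD33", "APC", "CD33-APC")]

_KI_BCL = [
    ("Ki-67", "FITC", "Ki-67-FITC"),
    ("Bcl-2", "PE-CF594", "Bcl-2-PE-CF594"),
]
_ISOTYPE = [
    ("IgG1", "FITC", "IgG1-FITC"),
    ("IgG1-PE", "PE-CF594", "IgG1-PE-CF594"),
]


def default_panel() -> PanelDefinition:
    """The package's default 7-tube panel (markers × fluorochromes × channels)."""
    scatter = SCATTER_CHANNELS
    tubes = {
        "1": scatter + _GROUP_A + _ISOTYPE,
        "2": scatter + _GROUP_A + _KI_BCL,
        "5": scatter + _GROUP_A + _KI_BCL + [("CD11b", "APC", "CD11b-APC-A750")],
        "3": scatter + _GROUP_B + _KI_BCL + [
            ("CD36", "PE-Cy7", "CD36-PE-Cy7"),
            ("CD71", "APC-A750", "CD71-APC-A750"),
            ("CD235a", "APC-A700", "CD235a-APC-A700"),
        ],
        "4": scatter + _GROUP_B + _KI_BCL + [
            ("CD14", "APC-A750", "CD14-APC-A750"),
            ("CD10", "PE-Cy7", "CD10-PE-Cy7"),
            ("CD11b", "APC-A700", "CD11b-APC-A700"),
            ("CD13", "ECD", "CD13-ECD"),
        ],
        "6": scatter + _GROUP_B + _KI_BCL + [("CD14", "APC-A750", "CD14-APC-A750")],
        "7": scatter + _GROUP_B + _ISOTYPE,
    }
    groups = {
        "A": ({"1", "2", "5"}, set(GROUP_A_BACKBONE)),
        "B": ({"3", "4", "6", "7"}, set(GROUP_B_BACKBONE)),
    }
    return PanelDefinition(tubes=tubes, backbone_groups=groups)
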