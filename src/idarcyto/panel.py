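"""Panel, population and condition vocabulary shared across the pipeline.

The assay is a single 8-color tube read on a conventional cytometer:
three scatter parameters plus eight fluorescence channels, one per
surface marker (CD14, CD16, CD45, CD64, CD91, CD123, HLA-DR and the
integrin beta-7 subunit).  Gating resolves seven monocyte subsets
(M1..M7), two dendritic-cell subsets and the neutrophil/mononuclear
backbone populations.
"""

from __future__ import annotations

SCATTER_CHANNELS: tuple[str, ...] = ("FSC-A", "FSC-H", "SSC-A")

#: Fluorescence channels in fixed panel order (spillover matrix rows/cols).
FLUORO_CHANNELS: tuple[str, ...] = (
    "CD14",
    "CD16",
    "CD45",
    "CD64",
    "CD91",
    "CD123",
    "HLADR",
    "ITGB7",
)

ALL_CHANNELS: tuple[str, ...] = SCATTER_CHANNELS + FLUORO_CHANNELS

#: Clinical conditions a sample can come from.  H2/H24/H48 are hours after
#: cardiac surgery (noninfectious inflammation model); BSI is a documented
#: bloodstream infection; LOCAL_INF is a localized infection without
#: positive blood culture (validation-cohort style).
CONDITIONS: tuple[str, ...] = ("HEALTHY", "H2", "H24", "H48", "LOCAL_INF", "BSI")

#: Conditions labelled infectious in the binary score construction.
INFECTIOUS_CONDITIONS: frozenset[str] = frozenset({"LOCAL_INF", "BSI"})

#: Monocyte subsets in gate order.
MONOCYTE_SUBSETS: tuple[str, ...] = ("M1", "M2", "M3", "M4", "M5", "M6", "M7")

#: Human-readable phenotype of each terminal population.
POPULATION_PHENOTYPES: dict[str, str] = {
    "MONONUCLEAR": "low-SSC CD45-bright mononuclear cells",
    "NEUTROPHILS": "high-SSC CD45-intermediate granulocytes",
    "MONOCYTES_TOTAL": "all CD14/CD16-defined monocytes",
    "M1": "CD14+ b7- CD16- classical monocytes",
    "M2": "CD14+ b7- CD16low monocytes",
    "M3": "CD14+ b7- CD16+ monocytes",
    "M4": "CD14+ b7+ CD16- monocytes",
    "M5": "CD14+ b7+ CD16+ monocytes",
    "M6": "CD14low b7- CD16+ nonclassical monocytes",
    "M7": "CD14+ CD91low monocytes",
    "MDC": "myeloid dendritic cells (HLA-DR+ CD14- CD16- CD91+)",
    "PDC": "plasmacytoid dendritic cells (HLA-DR+ CD14- CD16- CD123+)",
}

#: Terminal populations reported by the gate tree.
TERMINAL_POPULATIONS: tuple[str, ...] = tuple(POPULATION_PHENOTYPES)

#: Populations simulated by the generator (FILLER = residual lymphoid cells).
GENERATOR_POPULATIONS: tuple[str, ...] = (
    "NEUTROPHILS",
    *MONOCYTE_SUBSETS,
    "MDC",
    "PDC",
    "FILLER",
)
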