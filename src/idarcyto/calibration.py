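"""Generator calibration: condition-dependent abundances and marker intensities.

The shipped calibration (`default_calibration`) encodes, per clinical
condition, the expected leukocyte composition and geometric-mean surface
marker intensities of each simulated population.  Absolute cell
concentrations for the three leukocyte lineages are anchored to published
hematology means (healthy monocytes 561 cells/ul, etc.); monocyte-subset
and dendritic-cell redistribution is expressed as fold-changes relative to
healthy, with classical (M1) monocytes taken as the remainder so per-
condition total monocyte concentrations are matched exactly.  Marker
intensity shifts (e.g. threefold neutrophil CD64 in bloodstream infection)
are multiplicative on the healthy geometric means.  Values stated only
graphically in the source material are interpolated; see docs/methods.md.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .panel import (
    CONDITIONS,
    FLUORO_CHANNELS,
    GENERATOR_POPULATIONS,
    MONOCYTE_SUBSETS,
)

#: Channels drawn directly from lognormal population distributions
#: (FSC-H is derived from FSC-A by a tight multiplicative ratio).
DRAWN_CHANNELS: tuple[str, ...] = ("FSC-A", "SSC-A") + FLUORO_CHANNELS


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic event-level generator.

    Attributes
    ----------
    conditions : list of condition labels.
    abundance : ``abundance[condition][population]`` expected fraction of
        leukocyte events (dimensionless, in [0, 1]; the per-condition sum
        must be <= 1 with the remainder implicitly FILLER).
    marker_mu : ``marker_mu[condition][population][channel]`` geometric-mean
        intensity in linear arbitrary units (> 0).
    marker_cv : ``marker_cv[population][channel]`` lognormal coefficient of
        variation (> 0).
    subject_sd : SD (log scale) of the shared per-subject multiplicative
        random effect applied per marker (and to WBC).
    wbc_mu, wbc_cv : per-condition white-blood-cell concentration
        (arithmetic mean, cells/ul) and lognormal CV.
    spillover : 8x8 non-negative matrix with unit diagonal; entry (i, j) is
        the fraction of channel i signal detected in channel j.
    acquisition_target : monocyte events to record per sample.
    max_events : hard cap on recorded events per sample.
    singlet_ratio_sd : log-scale SD of the FSC-H/FSC-A ratio.
    """

    conditions: list[str] = field(default_factory=lambda: list(CONDITIONS))
    abundance: dict[str, dict[str, float]] = field(default_factory=dict)
    marker_mu: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    marker_cv: dict[str, dict[str, float]] = field(default_factory=dict)
    subject_sd: float = 0.15
    wbc_mu: dict[str, float] = field(default_factory=dict)
    wbc_cv: dict[str, float] = field(default_factory=dict)
    spillover: np.ndarray = field(default_factory=lambda: np.eye(len(FLUORO_CHANNELS)))
    acquisition_target: int = 6000
    max_events: int = 200_000

    singlet_ratio_sd: float = 0.05

    def validate(self) -> None:
        for cond in self.conditions:
            ab = self.abundance[cond]
            total = sum(ab.values())
            if total > 1.0 + 1e-9:
                raise ValueError(f"abundances for {cond} sum to {total:.4f} > 1")
            if any(v < 0 for v in ab.values()):
                raise ValueError(f"negative abundance in {cond}")
            if self.wbc_mu[cond] <= 0:
                raise ValueError(f"wbc_mu[{cond}] must be positive")
            for pop, mus in self.marker_mu[cond].items():
                for ch, mu in mus.items():
                    if mu <= 0:
                        raise ValueError(f"marker_mu[{cond}][{pop}][{ch}] <= 0")
        for pop, cvs in self.marker_cv.items():
            for ch, cv in cvs.items():
                if cv <= 0:
                    raise ValueError(f"marker_cv[{pop}][{ch}] <= 0")
        s = np.asarray(self.spillover, dtype=float)
        if s.shape != (len(FLUORO_CHANNELS),) * 2:
            raise ValueError("spillover must be 8x8")
        if not np.allclose(np.diag(s), 1.0):
            raise ValueError("spillover diagonal entries must equal 1")
        if (s < 0).any():
            raise ValueError("spillover entries must be non-negative")

    # -- serialization ---------------------------------------------------
    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["spillover"] = np.asarray(self.spillover).tolist()
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        d["spillover"] = np.asarray(d["spillover"], dtype=float)
        cfg = cls(**d)
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# Shipped calibration
# ---------------------------------------------------------------------------

#: Lineage concentrations, cells/ul (arithmetic means per condition).
_LINEAGE_CONC: dict[str, dict[str, float]] = {
    #            neutrophils  lymphoid   monocytes(total)
    "HEALTHY": {"NEUT": 3368, "LYMPH": 2016, "MONO": 561},
    "H2": {"NEUT": 8687, "LYMPH": 1792, "MONO": 682},
    "H24": {"NEUT": 9944, "LYMPH": 922, "MONO": 1071},
    "H48": {"NEUT": 8706, "LYMPH": 1296, "MONO": 1173},
    "LOCAL_INF": {"NEUT": 11000, "LYMPH": 1100, "MONO": 900},
    "BSI": {"NEUT": 13543, "LYMPH": 999, "MONO": 1040},
}

#: Healthy monocyte-subset and DC concentrations, cells/ul.
_HEALTHY_SUBSET_CONC: dict[str, float] = {
    "M2": 15.0,
    "M3": 20.0,
    "M4": 12.0,
    "M5": 8.0,
    "M6": 25.0,
    "M7": 6.0,
    "MDC": 12.0,
    "PDC": 6.0,
}
# M1 (classical) healthy concentration is the remainder of the 561 total.

#: Count fold-changes vs healthy for the non-classical subsets and DCs.
#: M7 peaks 20x at H24 and stays >10x in BSI; M3 reaches ~10x at H48 and is
#: slightly larger in BSI; M5 peaks 7x in BSI; M2 6x at H24 / 4x in BSI;
#: both DC subsets fall to one quarter in BSI.  H2 and LOCAL_INF values are
#: interpolations.
_COUNT_FOLD: dict[str, dict[str, float]] = {
    "M2": {"H2": 2.0, "H24": 6.0, "H48": 4.0, "LOCAL_INF": 3.0, "BSI": 4.0},
    "M3": {"H2": 2.0, "H24": 6.0, "H48": 10.0, "LOCAL_INF": 6.0, "BSI": 11.0},
    "M4": {"H2": 1.2, "H24": 2.0, "H48": 2.0, "LOCAL_INF": 1.5, "BSI": 2.0},
    "M5": {"H2": 1.5, "H24": 3.0, "H48": 4.0, "LOCAL_INF": 4.0, "BSI": 7.0},
    "M6": {"H2": 1.5, "H24": 3.0, "H48": 3.0, "LOCAL_INF": 3.0, "BSI": 5.0},
    "M7": {"H2": 6.0, "H24": 20.0, "H48": 12.0, "LOCAL_INF": 8.0, "BSI": 12.0},
    "MDC": {"H2": 0.7, "H24": 0.5, "H48": 0.5, "LOCAL_INF": 0.4, "BSI": 0.25},
    "PDC": {"H2": 0.7, "H24": 0.5, "H48": 0.5, "LOCAL_INF": 0.4, "BSI": 0.25},
}

#: Healthy geometric-mean intensities (linear arbitrary units) per
#: population and channel.  Scatter means are instrument-scale surrogates.
_HEALTHY_MU: dict[str, dict[str, float]] = {
    "NEUTROPHILS": {
        "FSC-A": 80_000, "SSC-A": 150_000,
        "CD14": 300, "CD16": 15_000, "CD45": 3_000, "CD64": 300,
        "CD91": 300, "CD123": 100, "HLADR": 60, "ITGB7": 100,
    },
    "M1": {
        "FSC-A": 90_000, "SSC-A": 40_000,
        "CD14": 20_000, "CD16": 80, "CD45": 15_000, "CD64": 1_500,
        "CD91": 4_000, "CD123": 100, "HLADR": 8_000, "ITGB7": 80,
    },
    "M2": {
        "FSC-A": 90_000, "SSC-A": 40_000,
        "CD14": 20_000, "CD16": 1_000, "CD45": 15_000, "CD64": 1_500,
        "CD91": 4_000, "CD123": 100, "HLADR": 8_000, "ITGB7": 80,
    },
    "M3": {
        "FSC-A": 90_000, "SSC-A": 40_000,
        "CD14": 20_000, "CD16": 8_000, "CD45": 15_000, "CD64": 1_500,
        "CD91": 4_000, "CD123": 100, "HLADR": 9_000, "ITGB7": 80,
    },
    "M4": {
        "FSC-A": 90_000, "SSC-A": 40_000,
        "CD14": 20_000, "CD16": 80, "CD45": 15_000, "CD64": 1_500,
        "CD91": 4_000, "CD123": 100, "HLADR": 8_000, "ITGB7": 4_000,
    },
    "M5": {
        "FSC-A": 90_000, "SSC-A": 40_000,
        "CD14": 20_000, "CD16": 8_000, "CD45": 15_000, "CD64": 1_500,
        "CD91": 4_000, "CD123": 100, "HLADR": 9_000, "ITGB7": 4_000,
    },
    "M6": {
        "FSC-A": 85_000, "SSC-A": 35_000,
        "CD14": 1_200, "CD16": 10_000, "CD45": 15_000, "CD64": 1_200,
        "CD91": 4_000, "CD123": 100, "HLADR": 9_000, "ITGB7": 80,
    },
    "M7": {
        "FSC-A": 90_000, "SSC-A": 40_000,
        "CD14": 15_000, "CD16": 300, "CD45": 15_000, "CD64": 1_500,
        "CD91": 300, "CD123": 100, "HLADR": 6_000, "ITGB7": 300,
    },
    "MDC": {
        "FSC-A": 70_000, "SSC-A": 20_000,
        "CD14": 80, "CD16": 80, "CD45": 20_000, "CD64": 800,
        "CD91": 5_000, "CD123": 300, "HLADR": 15_000, "ITGB7": 500,
    },
    "PDC": {
        "FSC-A": 70_000, "SSC-A": 20_000,
        "CD14": 80, "CD16": 80, "CD45": 20_000, "CD64": 200,
        "CD91": 300, "CD123": 15_000, "HLADR": 15_000, "ITGB7": 300,
    },
    "FILLER": {
        "FSC-A": 60_000, "SSC-A": 15_000,
        "CD14": 50, "CD16": 60, "CD45": 25_000, "CD64": 60,
        "CD91": 100, "CD123": 80, "HLADR": 60, "ITGB7": 300,
    },
}

#: MFI fold-changes vs healthy: (population, channel) -> condition -> fold.
#: Prose-stated anchors: neutrophil CD64 3x and M6 CD64 6x in BSI; M6 CD14
#: 2x postoperative / 4x BSI; M3/M5 CD14 2x at H24-H48 but unchanged in BSI;
#: HLA-DR depression on M5/M7 through H48 and in BSI; the rest interpolated.
_MFI_FOLD: dict[tuple[str, str], dict[str, float]] = {
    ("NEUTROPHILS", "CD64"): {"H2": 1.2, "H24": 1.5, "H48": 1.4, "LOCAL_INF": 2.0, "BSI": 3.0},
    ("M6", "CD64"): {"H2": 1.2, "H24": 2.0, "H48": 2.0, "LOCAL_INF": 3.0, "BSI": 6.0},
    ("M6", "CD14"): {"H2": 1.5, "H24": 2.0, "H48": 2.0, "LOCAL_INF": 3.0, "BSI": 4.0},
    ("M3", "CD14"): {"H2": 1.2, "H24": 2.0, "H48": 2.0, "LOCAL_INF": 1.5, "BSI": 1.0},
    ("M5", "CD14"): {"H2": 1.2, "H24": 2.0, "H48": 2.0, "LOCAL_INF": 1.5, "BSI": 1.0},
    ("M5", "HLADR"): {"H2": 0.8, "H24": 0.6, "H48": 0.5, "LOCAL_INF": 0.5, "BSI": 0.5},
    ("M7", "HLADR"): {"H2": 0.9, "H24": 0.7, "H48": 0.5, "LOCAL_INF": 0.5, "BSI": 0.5},
    ("M5", "CD16"): {"H2": 0.7, "H24": 1.3, "H48": 1.3, "LOCAL_INF": 1.3, "BSI": 1.5},
    ("NEUTROPHILS", "CD123"): {"H2": 0.7, "H24": 1.3, "H48": 1.3, "LOCAL_INF": 1.3, "BSI": 1.6},
    ("M1", "CD91"): {"H2": 1.0, "H24": 0.7, "H48": 1.0, "LOCAL_INF": 0.8, "BSI": 0.7},
    ("M7", "ITGB7"): {"H2": 0.7, "H24": 0.7, "H48": 1.0, "LOCAL_INF": 1.0, "BSI": 1.0},
}

#: Default lognormal CVs by channel class.
_DEFAULT_CV = {"FSC-A": 0.12, "SSC-A": 0.15}
_FLUORO_CV = 0.30


def population_concentrations(condition: str) -> dict[str, float]:
    """Expected cells/ul of every generator population for one condition."""
    lin = _LINEAGE_CONC[condition]
    conc: dict[str, float] = {"NEUTROPHILS": lin["NEUT"]}
    subset_sum = 0.0
    for pop, healthy in _HEALTHY_SUBSET_CONC.items():
        fold = 1.0 if condition == "HEALTHY" else _COUNT_FOLD[pop][condition]
        conc[pop] = healthy * fold
        if pop in MONOCYTE_SUBSETS:
            subset_sum += conc[pop]
    conc["M1"] = lin["MONO"] - subset_sum
    if conc["M1"] <= 0:
        raise ValueError(f"calibration leaves no classical monocytes for {condition}")
    conc["FILLER"] = lin["LYMPH"] - conc["MDC"] - conc["PDC"]
    return conc


def total_wbc(condition: str) -> float:
    """Expected total leukocyte concentration, cells/ul."""
    lin = _LINEAGE_CONC[condition]
    return lin["NEUT"] + lin["LYMPH"] + lin["MONO"]


def default_calibration() -> GeneratorConfig:
    """Build the shipped paper-anchored generator calibration."""
    abundance: dict[str, dict[str, float]] = {}
    marker_mu: dict[str, dict[str, dict[str, float]]] = {}
    wbc_mu: dict[str, float] = {}
    wbc_cv: dict[str, float] = {}
    for cond in CONDITIONS:
        wbc = total_wbc(cond)
        conc = population_concentrations(cond)
        abundance[cond] = {pop: conc[pop] / wbc for pop in GENERATOR_POPULATIONS}
        wbc_mu[cond] = wbc
        wbc_cv[cond] = 0.20
        mus: dict[str, dict[str, float]] = {}
        for pop in GENERATOR_POPULATIONS:
            base = dict(_HEALTHY_MU[pop])
            if cond != "HEALTHY":
                for (fpop, ch), folds in _MFI_FOLD.items():
                    if fpop == pop:
                        base[ch] = base[ch] * folds[cond]
            mus[pop] = base
        marker_mu[cond] = mus

    marker_cv = {
        pop: {ch: _DEFAULT_CV.get(ch, _FLUORO_CV) for ch in DRAWN_CHANNELS}
        for pop in GENERATOR_POPULATIONS
    }
    cfg = GeneratorConfig(
        abundance=abundance,
        marker_mu=marker_mu,
        marker_cv=marker_cv,
        wbc_mu=wbc_mu,
        wbc_cv=wbc_cv,
    )
    cfg.validate()
    return cfg


def example_spillover() -> np.ndarray:
    """A non-trivial 8x8 spillover example (unit diagonal, modest bleed).

    The bead-derived instrument matrix is not public; this synthetic
    example couples spectrally adjacent detectors for round-trip tests.
    """
    n = len(FLUORO_CHANNELS)
    s = np.eye(n)
    rng = np.random.default_rng(20210)
    for i in range(n):
        for j in range(n):
            if i != j:
                s[i, j] = 0.08 * rng.random() / (1 + abs(i - j))
    return s
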