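"""The 101-variable phenotype vector: MFIs, percentages, absolute counts.

The registry comprises 80 MFI variables (8 markers x 10 populations:
mononuclear cells, neutrophils, total monocytes and the 7 monocyte
subsets), 9 percentage variables (mDC, pDC and the 7 monocyte subsets),
10 absolute-count variables (mDC, pDC, total monocytes and the 7 monocyte
subsets), plus two reconciliation entries (CNT.NEUTROPHILS and
PCT.MONOCYTES_TOTAL) that bring the enumerated 99 up to the stated 101.
No MFI variable exists for dendritic cells.

MFIs are arithmetic means of linear (compensated, untransformed)
fluorescence; a population below ``min_events`` events yields MISSING.
Percentages of monocyte subsets are relative to total monocytes; DC
percentages are relative to mononuclear cells.  Absolute counts anchor
gated event fractions to the hematology-analyzer WBC concentration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .gating import GateTree, PopulationMap, apply_compensation, apply_gate_tree, auto_adjust_gates
from .panel import FLUORO_CHANNELS, MONOCYTE_SUBSETS

#: Populations carrying MFI variables, in registry order.
MFI_POPULATIONS: tuple[str, ...] = (
    "MONONUCLEAR",
    "NEUTROPHILS",
    "MONOCYTES_TOTAL",
    *MONOCYTE_SUBSETS,
)

#: Default minimum events for a valid MFI.
DEFAULT_MIN_EVENTS = 30


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    kind: str  # "MFI" | "PCT" | "CNT"
    population: str
    marker: str | None = None
    denominator: str | None = None

    def __post_init__(self):
        if self.kind == "MFI" and self.marker is None:
            raise ValueError(f"{self.name}: MFI spec requires a marker")
        if self.kind == "PCT" and self.denominator is None:
            raise ValueError(f"{self.name}: PCT spec requires a denominator")


def feature_registry() -> list[FeatureSpec]:
    """The fixed, ordered list of the 101 feature specifications."""
    specs: list[FeatureSpec] = []
    for pop in MFI_POPULATIONS:
        for marker in FLUORO_CHANNELS:
            specs.append(FeatureSpec(f"MFI.{marker}.{pop}", "MFI", pop, marker=marker))
    for pop in ("MDC", "PDC"):
        specs.append(FeatureSpec(f"PCT.{pop}", "PCT", pop, denominator="MONONUCLEAR"))
    for pop in MONOCYTE_SUBSETS:
        specs.append(FeatureSpec(f"PCT.{pop}", "PCT", pop, denominator="MONOCYTES_TOTAL"))
    for pop in ("MDC", "PDC", "MONOCYTES_TOTAL", *MONOCYTE_SUBSETS):
        specs.append(FeatureSpec(f"CNT.{pop}", "CNT", pop))
    # reconciliation entries: the enumerated variable groups yield 99
    specs.append(FeatureSpec("CNT.NEUTROPHILS", "CNT", "NEUTROPHILS"))
    specs.append(FeatureSpec("PCT.MONOCYTES_TOTAL", "PCT", "MONOCYTES_TOTAL",
                             denominator="LEUKOCYTES"))
    return specs


FEATURE_NAMES: tuple[str, ...] = tuple(s.name for s in feature_registry())


@dataclass
class FeatureVector:
    """One sample's named feature values (NaN encodes MISSING)."""

    sample_id: str
    values: dict[str, float]
    flags: list[str]

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(FEATURE_NAMES), dtype=float)


def extract_features(
    events: pd.DataFrame,
    pops: PopulationMap,
    wbc: float,
    sample_id: str = "S0",
    min_events: int = DEFAULT_MIN_EVENTS,
) -> FeatureVector:
    """Compute the 101 features for one gated sample.

    ``events`` must hold compensated linear intensities from the same
    table the `PopulationMap` was derived from.
    """
    if wbc <= 0:
        raise ValueError("wbc must be positive")
    n_leuk = pops.count("LEUKOCYTES")
    if n_leuk == 0:
        raise ValueError(f"{sample_id}: no leukocyte events; unusable sample")
    flags = list(pops.flags)
    n_mono = pops.count("MONOCYTES_TOTAL")
    if n_mono == 0:
        flags.append("no_monocyte_events")

    fluoro = events[list(FLUORO_CHANNELS)].to_numpy()
    col = {ch: i for i, ch in enumerate(FLUORO_CHANNELS)}
    values: dict[str, float] = {}
    for spec in feature_registry():
        idx = pops[spec.population]
        if spec.kind == "MFI":
            if len(idx) < min_events:
                values[spec.name] = np.nan
            else:
                values[spec.name] = float(fluoro[idx, col[spec.marker]].mean())
        elif spec.kind == "PCT":
            denom = pops.count(spec.denominator)
            if denom == 0:
                values[spec.name] = np.nan
            else:
                values[spec.name] = 100.0 * len(idx) / denom
        else:  # CNT
            values[spec.name] = wbc * len(idx) / n_leuk
    return FeatureVector(sample_id=sample_id, values=values, flags=flags)


def cohort_feature_table(
    samples: Iterable,
    tree: GateTree,
    auto_adjust: bool = True,
    spillover: np.ndarray | None = None,
    min_events: int = DEFAULT_MIN_EVENTS,
) -> pd.DataFrame:
    """Gate and featurize a cohort into one row per sample.

    Columns: subject_id, condition, time_h, label, then the 101 registry
    features in fixed order.  ``samples`` may be any iterable of
    `SubjectSample` (a generator keeps peak memory at one sample).
    When ``spillover`` is given, compensation is applied before gating.
    """
    rows = []
    meta = []
    n = 0
    for s in samples:
        n += 1
        try:
            ev = s.events
            if spillover is not None:
                ev = apply_compensation(ev, spillover)
            t = auto_adjust_gates(ev, tree) if auto_adjust else tree
            pops = apply_gate_tree(ev, t)
            fv = extract_features(ev, pops, s.wbc, sample_id=s.subject_id,
                                  min_events=min_events)
        except ValueError as err:
            raise ValueError(f"sample {s.subject_id} ({s.condition}): {err}") from err
        meta.append((s.subject_id, s.condition, s.sampling_time, s.label))
        rows.append(fv.as_series())
    if n == 0:
        raise ValueError("empty sample list")
    feat = pd.DataFrame(rows).reset_index(drop=True)
    head = pd.DataFrame(meta, columns=["subject_id", "condition", "time_h", "label"])
    return pd.concat([head, feat], axis=1)


# ---------------------------------------------------------------------------
# CSV round trip (MISSING serialized as an empty cell)
# ---------------------------------------------------------------------------

def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, na_rep="")


def read_feature_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing[:5]}...")
    return table
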