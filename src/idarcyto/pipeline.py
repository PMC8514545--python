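"""End-to-end helpers binding simulation, gating, features and scoring.

These are the entry points the examples, CLI and acceptance checks use:
simulate a cohort straight into a feature table (streaming, one sample in
memory at a time), or carry score series per subject for longitudinal
monitoring with the infection / systemic-infection cutoffs annotated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibration import GeneratorConfig, default_calibration
from .features import cohort_feature_table
from .gating import GateTree, build_default_gate_tree
from .model import IdarModel
from .synth import CohortDesign, discovery_design, iter_cohort

#: Score cutoffs used when annotating monitor output: above the first a
#: sample is called infected; above the second, systemically infected.
INFECTION_CUTOFF = 54.5
SYSTEMIC_CUTOFF = 98.4


def simulate_feature_table(
    design: CohortDesign,
    config: GeneratorConfig | None = None,
    tree: GateTree | None = None,
    auto_adjust: bool = True,
) -> pd.DataFrame:
    """Generate a cohort and run gating + feature extraction sample by sample."""
    config = config or default_calibration()
    tree = tree or build_default_gate_tree()
    return cohort_feature_table(
        iter_cohort(design, config, keep_truth=False), tree, auto_adjust=auto_adjust
    )


def discovery_feature_table(seed: int = 0, **kwargs) -> pd.DataFrame:
    """Feature table for the 46/22/80/43/59 discovery-style cohort."""
    return simulate_feature_table(discovery_design(seed), **kwargs)


def monitor_series(
    model: IdarModel,
    feature_table: pd.DataFrame,
    infection_cutoff: float = INFECTION_CUTOFF,
    systemic_cutoff: float = SYSTEMIC_CUTOFF,
) -> pd.DataFrame:
    """Per-subject longitudinal score series with cutoff annotations."""
    scores = model.score_table(feature_table)
    out = feature_table[["subject_id", "condition", "time_h", "label"]].copy()
    out["idar"] = scores["idar"].to_numpy()
    out["infected_call"] = out["idar"] > infection_cutoff
    out["systemic_call"] = out["idar"] > systemic_cutoff
    return out.sort_values(["subject_id", "time_h"], kind="stable").reset_index(drop=True)
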