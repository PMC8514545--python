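"""Synthetic event-level cytometry cohorts.

Each simulated sample emulates one stained whole-blood tube: events are
drawn population-by-population from condition-specific abundance vectors,
marker intensities are lognormal around population geometric means (with a
shared per-subject multiplicative random effect), fluorescence is mixed
through a spillover matrix, and acquisition stops once the target number
of true monocyte events (default 6000) has been recorded.  Ground-truth
per-event population labels are retained so gating and feature extraction
can be validated against the generator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import DRAWN_CHANNELS, GeneratorConfig
from .panel import (
    ALL_CHANNELS,
    FLUORO_CHANNELS,
    GENERATOR_POPULATIONS,
    INFECTIOUS_CONDITIONS,
    MONOCYTE_SUBSETS,
)

_MONOCYTE_SET = frozenset(MONOCYTE_SUBSETS)


class DegenerateSampleWarning(UserWarning):
    """Raised (as a warning) when acquisition or gating hits a fallback."""


@dataclass
class SubjectSample:
    """One acquired sample: recorded events plus generator ground truth."""

    subject_id: str
    condition: str
    sampling_time: float | None
    events: pd.DataFrame              # recorded (post-spillover) intensities
    wbc: float                        # cells/ul from the hematology analyzer
    truth: np.ndarray                 # per-event population label (str array)
    true_fluorescence: pd.DataFrame | None = None  # pre-spillover intensities
    flags: list[str] = field(default_factory=list)

    @property
    def label(self) -> int:
        """Binary class: 1 = infectious, 0 = noninfectious."""
        return int(self.condition in INFECTIOUS_CONDITIONS)


@dataclass
class CohortDesign:
    """Subject counts per condition plus repeated-measure structure.

    ``n_subjects`` maps condition -> number of distinct subjects sampled
    once at that condition.  ``surgery_series`` adds subjects sampled
    repeatedly along the postoperative time course (conditions H2/H24/H48
    at 2/24/48 h) sharing one subject effect.
    """

    n_subjects: dict[str, int] = field(default_factory=dict)
    surgery_series: int = 0
    seed: int = 0

    def validate(self) -> None:
        if any(v < 0 for v in self.n_subjects.values()):
            raise ValueError("subject counts must be >= 0")
        if self.surgery_series < 0:
            raise ValueError("surgery_series must be >= 0")


_SURGERY_TIMES = {"H2": 2.0, "H24": 24.0, "H48": 48.0}


def discovery_design(seed: int = 0) -> CohortDesign:
    """The discovery-cohort layout: 46 healthy, 22 H2, 80 H24, 43 H48
    cardiac-surgery samples and 59 blood-culture-positive samples."""
    return CohortDesign(
        n_subjects={"HEALTHY": 46, "H2": 22, "H24": 80, "H48": 43, "BSI": 59},
        seed=seed,
    )


def draw_subject_effect(config: GeneratorConfig, rng: np.random.Generator) -> dict[str, float]:
    """Per-subject multiplicative effects, one per drawn channel plus WBC.

    Effects are mean-one lognormal (log-sd = ``config.subject_sd``) and are
    shared across all of a subject's samples, inducing the within-subject
    correlation that grouped cross-validation must respect.
    """
    sd = config.subject_sd
    names = list(DRAWN_CHANNELS) + ["WBC"]
    draws = np.exp(rng.normal(-0.5 * sd * sd, sd, size=len(names)))
    return dict(zip(names, draws))


def neutral_effect() -> dict[str, float]:
    return {name: 1.0 for name in list(DRAWN_CHANNELS) + ["WBC"]}


def sample_subject(
    condition: str,
    config: GeneratorConfig,
    subject_effect: dict[str, float] | None = None,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    subject_id: str = "S0",
    sampling_time: float | None = None,
    keep_truth: bool = True,
) -> SubjectSample:
    """Simulate acquisition of one stained sample.

    Events are recorded in stream order until ``config.acquisition_target``
    true monocyte events have been seen or ``config.max_events`` is hit
    (the latter flags the sample as degenerate instead of raising).
    """
    if condition not in config.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(seed)
    if subject_effect is None:
        subject_effect = neutral_effect()

    flags: list[str] = []

    # --- WBC draw (arithmetic-mean anchored lognormal) -----------------
    cv = config.wbc_cv[condition]
    sigma2 = np.log1p(cv * cv)
    mu_log = np.log(config.wbc_mu[condition]) - 0.5 * sigma2
    wbc = float(np.exp(rng.normal(mu_log, np.sqrt(sigma2)))) * subject_effect["WBC"]

    # --- event population labels + acquisition stopping rule -----------
    pops = list(GENERATOR_POPULATIONS)
    probs = np.array([config.abundance[condition].get(p, 0.0) for p in pops])
    filler_extra = 1.0 - probs.sum()
    if filler_extra > 1e-12:
        probs[pops.index("FILLER")] += filler_extra
    probs = probs / probs.sum()
    cum = np.cumsum(probs)

    codes = np.searchsorted(cum, rng.random(config.max_events), side="right")
    codes = np.minimum(codes, len(pops) - 1).astype(np.int16)
    mono_mask_full = np.isin(codes, [pops.index(p) for p in MONOCYTE_SUBSETS])
    mono_cum = np.cumsum(mono_mask_full)
    hit = np.searchsorted(mono_cum, config.acquisition_target, side="left")
    if hit >= config.max_events:
        n_rec = config.max_events
        flags.append("acquisition_target_unreached")
        warnings.warn(
            f"{subject_id}/{condition}: acquisition target "
            f"{config.acquisition_target} monocytes not reached within "
            f"{config.max_events} events",
            DegenerateSampleWarning,
            stacklevel=2,
        )
    else:
        n_rec = int(hit) + 1
    codes = codes[:n_rec]

    # --- intensities ----------------------------------------------------
    true_vals = np.empty((n_rec, len(DRAWN_CHANNELS)))
    for ci, pop in enumerate(pops):
        mask = codes == ci
        n = int(mask.sum())
        if n == 0:
            continue
        mus = config.marker_mu[condition][pop]
        cvs = config.marker_cv[pop]
        for ki, ch in enumerate(DRAWN_CHANNELS):
            sig = np.sqrt(np.log1p(cvs[ch] ** 2))
            gm = mus[ch] * subject_effect[ch]
            true_vals[mask, ki] = np.exp(rng.normal(np.log(gm), sig, size=n))

    # FSC-H tracks FSC-A with a tight ratio (singlets; doublets not modelled)
    fsc_a = true_vals[:, DRAWN_CHANNELS.index("FSC-A")]
    ratio_sd = config.singlet_ratio_sd
    fsc_h = fsc_a * np.exp(rng.normal(-0.5 * ratio_sd**2, ratio_sd, size=n_rec))

    fluoro_idx = [DRAWN_CHANNELS.index(ch) for ch in FLUORO_CHANNELS]
    true_fluoro = true_vals[:, fluoro_idx]
    spill = np.asarray(config.spillover, dtype=float)
    recorded_fluoro = true_fluoro @ spill.T if not np.allclose(spill, np.eye(len(FLUORO_CHANNELS))) else true_fluoro

    events = pd.DataFrame(
        np.column_stack([fsc_a, fsc_h, true_vals[:, DRAWN_CHANNELS.index("SSC-A")], recorded_fluoro]),
        columns=list(ALL_CHANNELS),
    )
    truth = np.asarray(pops, dtype=object)[codes]
    true_fl_df = None
    if keep_truth:
        true_fl_df = pd.DataFrame(true_fluoro, columns=list(FLUORO_CHANNELS))
    return SubjectSample(
        subject_id=subject_id,
        condition=condition,
        sampling_time=sampling_time,
        events=events,
        wbc=wbc,
        truth=truth,
        true_fluorescence=true_fl_df,
        flags=flags,
    )


def iter_cohort(design: CohortDesign, config: GeneratorConfig, keep_truth: bool = True):
    """Yield `SubjectSample`s for a design, deterministically from its seed.

    Repeated-measure (surgery-series) subjects share one subject effect
    across their H2/H24/H48 samples.
    """
    design.validate()
    config.validate()
    root = np.random.SeedSequence(design.seed)
    # spawn order is fixed: single-shot conditions in declared order, then series
    n_single = sum(design.n_subjects.values())
    n_series = design.surgery_series
    children = root.spawn(n_single + n_series)
    idx = 0
    for cond in design.n_subjects:
        for k in range(design.n_subjects[cond]):
            ss = children[idx]
            idx += 1
            rng = np.random.default_rng(ss)
            effect = draw_subject_effect(config, rng)
            sid = f"{cond}_{k:03d}"
            t = _SURGERY_TIMES.get(cond)
            yield sample_subject(
                cond, config, effect, rng, subject_id=sid,
                sampling_time=t, keep_truth=keep_truth,
            )
    for k in range(n_series):
        ss = children[idx]
        idx += 1
        rng = np.random.default_rng(ss)
        effect = draw_subject_effect(config, rng)
        sid = f"SURG_{k:03d}"
        for cond, t in _SURGERY_TIMES.items():
            yield sample_subject(
                cond, config, effect, rng, subject_id=sid,
                sampling_time=t, keep_truth=keep_truth,
            )


def generate_cohort(design: CohortDesign, config: GeneratorConfig, keep_truth: bool = True) -> list[SubjectSample]:
    """Materialize the whole cohort as a list (see `iter_cohort`)."""
    return list(iter_cohort(design, config, keep_truth=keep_truth))
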