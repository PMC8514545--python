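"""Validation machinery: grouped CV, randomization nulls, ROC, statistics.

Cross-validation assigns whole subjects (or temporal strata) to folds so
that repeated samples from one subject never straddle the train/test
boundary.  The randomization null refits the full CV under subject-level
label permutation.  ROC confidence intervals use a stratified percentile
bootstrap; operating points use the strict "positive iff score > cutoff"
convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, spearmanr
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import GroupKFold, StratifiedGroupKFold, StratifiedKFold

from .model import IdarModel, TrainConfig, fit_idar


@dataclass
class CVScheme:
    k: int = 10
    grouping: str = "SUBJECT"  # SUBJECT | TEMPORAL | RECORD
    repeats: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.grouping not in ("SUBJECT", "TEMPORAL", "RECORD"):
            raise ValueError(f"unknown grouping {self.grouping}")


@dataclass
class CVResult:
    scores: np.ndarray          # pooled out-of-fold scores, first repeat
    labels: np.ndarray
    fold_of_record: np.ndarray  # fold index per record, first repeat
    auroc: float                # pooled AUROC, first repeat
    ci: tuple[float, float]
    per_repeat_auroc: np.ndarray
    warnings: list[str] = field(default_factory=list)

    @property
    def mean_auroc(self) -> float:
        return float(self.per_repeat_auroc.mean())

    @property
    def sd_auroc(self) -> float:
        return float(self.per_repeat_auroc.std(ddof=1)) if len(self.per_repeat_auroc) > 1 else 0.0


def _temporal_folds(y, subjects, times, k, rng):
    """Distribute subjects to folds within sampling-time strata."""
    df = pd.DataFrame({"y": y, "subject": subjects,
                       "t": ["NONE" if t is None or (isinstance(t, float) and np.isnan(t))
                             else t for t in times]})
    fold = np.full(len(df), -1, dtype=int)
    counter = 0
    for _, stratum in df.groupby("t", sort=True):
        subs = pd.unique(stratum["subject"])
        order = rng.permutation(len(subs))
        for j, si in enumerate(order):
            f = (counter + j) % k
            fold[(df["subject"] == subs[si]).to_numpy() & (df["t"] == stratum["t"].iloc[0]).to_numpy()] = f
        counter += len(subs)
    for f in range(k):
        yield np.flatnonzero(fold != f), np.flatnonzero(fold == f)


def _folds(y, subjects, times, scheme: CVScheme, seed: int):
    if scheme.grouping == "RECORD":
        splitter = StratifiedKFold(n_splits=scheme.k, shuffle=True, random_state=seed)
        yield from splitter.split(np.zeros(len(y)), y)
    elif scheme.grouping == "SUBJECT":
        # stratify folds by class at subject level when possible; with
        # more folds than minority-class subjects (e.g. leave-one-subject
        # -out) fall back to plain grouped folds
        _, counts = np.unique(
            [y[subjects == u][0] for u in pd.unique(subjects)], return_counts=True
        )
        if scheme.k <= counts.min():
            splitter = StratifiedGroupKFold(n_splits=scheme.k, shuffle=True,
                                            random_state=seed)
        else:
            splitter = GroupKFold(n_splits=scheme.k)
        yield from splitter.split(np.zeros(len(y)), y, groups=subjects)
    else:
        rng = np.random.default_rng(seed)
        yield from _temporal_folds(y, subjects, times, scheme.k, rng)


def cross_validate(
    features: pd.DataFrame,
    labels: np.ndarray,
    subjects: np.ndarray,
    times=None,
    config: TrainConfig | None = None,
    scheme: CVScheme | None = None,
) -> CVResult:
    """Out-of-fold scoring with a fresh ensemble per fold."""
    config = config or TrainConfig()
    scheme = scheme or CVScheme()
    scheme.validate()
    y = np.asarray(labels, dtype=int)
    subjects = np.asarray(subjects)
    if times is None:
        times = [None] * len(y)
    if scheme.grouping in ("SUBJECT", "TEMPORAL") and subjects is None:
        raise ValueError("grouped CV requires subject identifiers")

    warns: list[str] = []
    per_repeat = []
    first_scores = None
    first_folds = None
    for rep in range(scheme.repeats):
        rep_seed = scheme.seed + 1000 * rep
        oof = np.full(len(y), np.nan)
        fold_idx = np.full(len(y), -1, dtype=int)
        for f, (tr, te) in enumerate(_folds(y, subjects, times, scheme, rep_seed)):
            if len(np.unique(y[tr])) < 2:
                warns.append(f"repeat {rep} fold {f}: single-class training set, skipped")
                continue
            cfg = TrainConfig(**{**config.__dict__, "seed": config.seed + 101 * rep + f})
            model = fit_idar(features.iloc[tr], y[tr], cfg, subjects=subjects[tr])
            oof[te] = model.score(features.iloc[te])
            fold_idx[te] = f
        scored = ~np.isnan(oof)
        per_repeat.append(roc_auc_score(y[scored], oof[scored]))
        if rep == 0:
            first_scores, first_folds = oof, fold_idx
    per_repeat = np.asarray(per_repeat)
    scored = ~np.isnan(first_scores)
    _, _, _, ci = roc(first_scores[scored], np.asarray(y)[scored], n_boot=500,
                      seed=scheme.seed)
    return CVResult(
        scores=first_scores, labels=y, fold_of_record=first_folds,
        auroc=float(per_repeat[0]), ci=ci, per_repeat_auroc=per_repeat,
        warnings=warns,
    )


def randomization_null(
    features: pd.DataFrame,
    labels: np.ndarray,
    subjects: np.ndarray,
    config: TrainConfig | None = None,
    scheme: CVScheme | None = None,
    n_shuffles: int = 30,
    seed: int = 0,
) -> np.ndarray:
    """Null AUROC distribution from subject-level label shuffles.

    Labels are permuted across subjects (every record of a subject gets
    the subject's permuted label), then the full grouped CV is re-run.
    Returns the per-shuffle pooled AUROCs.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    scheme = scheme or CVScheme()
    y = np.asarray(labels, dtype=int)
    subjects = np.asarray(subjects)
    uniq = pd.unique(subjects)
    subj_label = {u: y[subjects == u][0] for u in uniq}
    base = np.array([subj_label[u] for u in uniq])
    rng = np.random.default_rng(seed)
    aurocs = []
    for s in range(n_shuffles):
        perm = rng.permutation(len(uniq))
        mapping = dict(zip(uniq, base[perm]))
        y_perm = np.array([mapping[u] for u in subjects])
        sub_scheme = CVScheme(k=scheme.k, grouping=scheme.grouping,
                              repeats=1, seed=scheme.seed + 7919 * (s + 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = cross_validate(features, y_perm, subjects, None, config, sub_scheme)
        aurocs.append(res.auroc)
    return np.asarray(aurocs)


# ---------------------------------------------------------------------------
# ROC and operating points
# ---------------------------------------------------------------------------

def roc(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float, tuple[float, float]]:
    """Empirical ROC curve, trapezoidal AUROC, stratified-bootstrap 95% CI.

    Returns ``(fpr, tpr, auroc, (ci_lo, ci_hi))``.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes")
    fpr, tpr, _ = roc_curve(y, scores)
    auroc = float(np.trapezoid(tpr, fpr))
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bp = rng.choice(pos, size=len(pos), replace=True)
        bn = rng.choice(neg, size=len(neg), replace=True)
        idx = np.concatenate([bp, bn])
        boots[i] = roc_auc_score(y[idx], scores[idx])
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return fpr, tpr, auroc, ci


@dataclass
class OperatingPoint:
    cutoff: float
    sensitivity: float  # percent; NaN when undefined
    specificity: float
    ppv: float
    npv: float


def operating_point(scores, labels, cutoff: float) -> OperatingPoint:
    """2x2-table metrics at a cutoff (positive call iff score > cutoff)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    call = scores > cutoff
    tp = int(np.sum(call & (y == 1)))
    fp = int(np.sum(call & (y == 0)))
    fn = int(np.sum(~call & (y == 1)))
    tn = int(np.sum(~call & (y == 0)))

    def pct(num, den):
        return 100.0 * num / den if den > 0 else float("nan")

    return OperatingPoint(
        cutoff=cutoff,
        sensitivity=pct(tp, tp + fn),
        specificity=pct(tn, tn + fp),
        ppv=pct(tp, tp + fp),
        npv=pct(tn, tn + fn),
    )


def cutoff_sweep(scores, labels, cutoffs) -> pd.DataFrame:
    rows = [operating_point(scores, labels, c).__dict__ for c in cutoffs]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort statistics
# ---------------------------------------------------------------------------

def cohort_statistics(
    values_by_group: dict[str, np.ndarray],
    paired: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
) -> dict:
    """Mann-Whitney tests per group pair plus Spearman rho per variable pair.

    No multiple-testing correction is applied; p-values are reported raw.
    Groups of size 0 are skipped with a warning entry.
    """
    report: dict = {"mann_whitney": {}, "spearman": {}, "warnings": []}
    names = list(values_by_group)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            va = np.asarray(values_by_group[a], dtype=float)
            vb = np.asarray(values_by_group[b], dtype=float)
            if len(va) == 0 or len(vb) == 0:
                report["warnings"].append(f"group pair ({a}, {b}) skipped: empty group")
                continue
            u, p = mannwhitneyu(va, vb, alternative="two-sided")
            report["mann_whitney"][(a, b)] = {"U": float(u), "p": float(p)}
    for name, (x, y) in (paired or {}).items():
        rho, p = spearmanr(x, y)
        report["spearman"][name] = {"rho": float(rho), "p": float(p)}
    return report
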