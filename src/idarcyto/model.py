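"""Bootstrap-aggregated gradient-boosted ensemble and the 0-100 score.

Thirty-two XGBoost classifiers are each fit on a subject-level bootstrap
resample of the training table (all of a subject's samples enter or leave
together) with influence trimming: after an initial fit, the most
confidently classified ``ceil(fraction * n)`` rows are removed and the
booster is refit on the remainder.

Each booster's raw margin m_b is the log-odds of the infectious class;
the oriented half-log-odds response is s_b = -m_b / 2 and the ensemble
response r is their mean.  The score is

    p = exp(-2r) / (1 + exp(-2r)),    score = 100 * p,

which decreases in r and, with the orientation above, equals the mean
ensemble log-odds passed through a sigmoid: an infection-risk score on a
0-100 scale.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.special import expit

from .features import FEATURE_NAMES


@dataclass
class TrainConfig:
    n_bootstrap: int = 32
    n_estimators: int = 300
    max_depth: int = 3
    learning_rate: float = 0.1
    subsample: float = 0.8
    influence_trim_fraction: float = 0.10
    trim_near_threshold: bool = False  # unconventional alternative reading
    bootstrap_unit: str = "SUBJECT"    # or "RECORD"
    seed: int = 0

    def validate(self) -> None:
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not 0 <= self.influence_trim_fraction < 1:
            raise ValueError("influence_trim_fraction must be in [0, 1)")
        if self.bootstrap_unit not in ("SUBJECT", "RECORD"):
            raise ValueError("bootstrap_unit must be SUBJECT or RECORD")


@dataclass
class ScoreResult:
    r: float
    p: float
    idar: float
    responses: np.ndarray | None = None


def influence_trim_mask(probs: np.ndarray, fraction: float) -> np.ndarray:
    """Inclusion mask dropping the ceil(fraction*n) most confident rows.

    Confidence is |p - 0.5|; ties are broken by stable row order.  With
    ``fraction == 0`` every row is kept.
    """
    probs = np.asarray(probs, dtype=float)
    n = len(probs)
    k = int(np.ceil(fraction * n))
    mask = np.ones(n, dtype=bool)
    if k == 0:
        return mask
    dist = np.abs(probs - 0.5)
    order = np.argsort(-dist, kind="stable")
    mask[order[:k]] = False
    return mask


def _near_threshold_mask(probs: np.ndarray, fraction: float) -> np.ndarray:
    probs = np.asarray(probs, dtype=float)
    n = len(probs)
    k = int(np.ceil(fraction * n))
    mask = np.ones(n, dtype=bool)
    if k == 0:
        return mask
    order = np.argsort(np.abs(probs - 0.5), kind="stable")
    mask[order[:k]] = False
    return mask


def _make_booster(config: TrainConfig, seed: int) -> xgb.XGBClassifier:
    return xgb.XGBClassifier(
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        learning_rate=config.learning_rate,
        subsample=config.subsample,
        objective="binary:logistic",
        base_score=0.5,
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        verbosity=0,
    )


@dataclass
class IdarModel:
    """Fitted ensemble: boosters + feature registry snapshot + config."""

    boosters: list[xgb.XGBClassifier]
    feature_names: list[str]
    config: TrainConfig
    bootstrap_indices: list[np.ndarray] = field(default_factory=list)

    # -- prediction ------------------------------------------------------
    def _matrix(self, x: pd.DataFrame | pd.Series | np.ndarray) -> np.ndarray:
        if isinstance(x, pd.Series):
            x = x.to_frame().T
        if isinstance(x, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in x.columns]
            if missing:
                raise ValueError(f"feature columns missing: {missing[:5]}")
            x = x[self.feature_names].to_numpy(dtype=float)
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != len(self.feature_names):
            raise ValueError("column count mismatch with feature registry")
        return x

    def ensemble_response(self, x) -> tuple[np.ndarray, np.ndarray]:
        """Per-model half-log-odds responses s_b = -m_b/2 and their mean r.

        Returns ``(responses, r)`` with responses of shape (n, B).
        """
        if not self.boosters:
            raise ValueError("model has no fitted boosters")
        mat = self._matrix(x)
        dmat = xgb.DMatrix(mat, missing=np.nan)
        margins = np.column_stack(
            [b.get_booster().predict(dmat, output_margin=True) for b in self.boosters]
        )
        responses = -margins / 2.0
        return responses, responses.mean(axis=1)

    def score_table(self, x) -> pd.DataFrame:
        """r, p and the 0-100 score for each row of ``x``."""
        _, r = self.ensemble_response(x)
        p = expit(-2.0 * r)  # == e^{-2r} / (1 + e^{-2r}), overflow-safe
        return pd.DataFrame({"r": r, "p": p, "idar": 100 * p})

    def score(self, x) -> np.ndarray:
        return self.score_table(x)["idar"].to_numpy()

    # -- persistence -----------------------------------------------------
    def save(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "feature_names": self.feature_names,
            "boosters": [
                b.get_booster().save_raw("json").decode("utf-8")
                for b in self.boosters
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "IdarModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        config = TrainConfig(**payload["config"])
        boosters = []
        for raw in payload["boosters"]:
            clf = _make_booster(config, 0)
            booster = xgb.Booster()
            booster.load_model(bytearray(raw.encode("utf-8")))
            clf._Booster = booster
            boosters.append(clf)
        return cls(boosters=boosters, feature_names=payload["feature_names"],
                   config=config)


def idar_score(r: float) -> ScoreResult:
    """Map an ensemble response r to probability and 0-100 score."""
    r = float(r)
    if not np.isfinite(r):
        raise ValueError("r must be finite")
    p = float(expit(-2.0 * r))  # == e^{-2r} / (1 + e^{-2r}), overflow-safe
    return ScoreResult(r=r, p=p, idar=100.0 * p)


def fit_idar(
    features: pd.DataFrame,
    labels: np.ndarray,
    config: TrainConfig | None = None,
    subjects: np.ndarray | None = None,
) -> IdarModel:
    """Fit the bootstrap ensemble on a feature table.

    ``features`` must carry the 101 registry columns (extra metadata
    columns are ignored); NaN encodes MISSING and is routed natively by
    the boosters.  ``subjects`` enables subject-level bootstrap; without
    it rows are resampled individually.
    """
    config = config or TrainConfig()
    config.validate()
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    cols = [c for c in FEATURE_NAMES if c in features.columns]
    if len(cols) == len(FEATURE_NAMES):
        feature_names = list(FEATURE_NAMES)
    else:
        # toy tables: use all non-metadata columns as-is
        feature_names = [c for c in features.columns
                         if c not in ("subject_id", "condition", "time_h", "label")]
    x = features[feature_names].to_numpy(dtype=float)

    if config.bootstrap_unit == "SUBJECT" and subjects is not None:
        units = np.asarray(subjects)
    else:
        units = np.arange(len(y))
    uniq = pd.unique(units)

    rng = np.random.default_rng(config.seed)
    boosters: list[xgb.XGBClassifier] = []
    chosen_indices: list[np.ndarray] = []
    for b in range(config.n_bootstrap):
        for _attempt in range(20):
            pick = rng.choice(len(uniq), size=len(uniq), replace=True)
            sel_units = uniq[pick]
            rows = np.concatenate([np.flatnonzero(units == u) for u in sel_units])
            if len(np.unique(y[rows])) == 2:
                break
        else:
            raise ValueError("could not draw a two-class bootstrap resample")
        seed_b = int(rng.integers(0, 2**31 - 1))
        clf = _make_booster(config, seed_b)
        clf.fit(x[rows], y[rows])
        if config.influence_trim_fraction > 0:
            probs = clf.predict_proba(x[rows])[:, 1]
            if config.trim_near_threshold:
                keep = _near_threshold_mask(probs, config.influence_trim_fraction)
            else:
                keep = influence_trim_mask(probs, config.influence_trim_fraction)
            kept_rows = rows[keep]
            if len(np.unique(y[kept_rows])) == 2:
                clf = _make_booster(config, seed_b)
                clf.fit(x[kept_rows], y[kept_rows])
                rows = kept_rows
        boosters.append(clf)
        chosen_indices.append(rows)
    return IdarModel(boosters=boosters, feature_names=feature_names,
                     config=config, bootstrap_indices=chosen_indices)
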