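"""Decode group identity from boolean receptor-transcription profiles.

A random forest (200 trees, depth 10, balanced class weights) is evaluated
with stratified 5-fold cross-validation: per-fold balanced accuracy, a
true-label-normalized confusion matrix built from out-of-fold predictions,
and a per-class precision/recall/F1 report.  Feature attribution is a
class x gene matrix of mean absolute Shapley values estimated by Monte
Carlo permutation sampling over the forest's predicted class probabilities,
computed on a model refit on the full table (accuracy comes from the CV
loop, attribution from the single full fit).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score, classification_report, confusion_matrix
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DecoderSpec:
    n_estimators: int = 200
    max_depth: int = 10
    class_weight: str = "balanced"
    n_splits: int = 5
    seed: int = 0
    attribution_sample: int = 10_000
    attribution_background: int = 50
    attribution_permutations: int = 8
    baseline_models: tuple[str, ...] = ("logistic", "lda")

    def __post_init__(self):
        if self.n_splits < 2:
            raise ValueError("n_splits must be >= 2")


@dataclass
class DecodingResult:
    mean_balanced_accuracy: float  # fraction in [0, 1]
    per_fold: list[float]
    chance_level: float  # percent
    confusion: pd.DataFrame  # true x predicted, rows sum to 1
    per_class_report: dict
    model: RandomForestClassifier  # refit on the full feature table
    dropped_classes: list[str]


def make_feature_table(
    mask: pd.DataFrame, cells: pd.DataFrame, target_level: str
) -> tuple[pd.DataFrame, pd.Series]:
    """Boolean cells x genes features plus one label per cell.

    Column order follows the mask's gene order; rows whose label is missing
    are dropped with a logged count.
    """
    if target_level not in cells.columns:
        raise KeyError(f"unknown target level: {target_level!r}")
    labels = cells.set_index("cell_label")[target_level].reindex(mask.index)
    valid = labels.notna()
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.warning("make_feature_table: dropped %d cells with missing labels", n_dropped)
    return mask.loc[valid].astype(bool), labels[valid]


def chance_level(labels) -> float:
    """Uniform-guessing chance level: 100 / number of distinct labels."""
    k = pd.Series(labels).nunique()
    if k < 1:
        raise ValueError("need at least one label")
    return 100.0 / k


def _drop_small_classes(X: pd.DataFrame, y: pd.Series, n_splits: int):
    counts = y.value_counts()
    small = counts[counts < n_splits].index.tolist()
    if small:
        logger.warning(
            "dropping %d class(es) with fewer than %d members: %s",
            len(small), n_splits, small,
        )
        keep = ~y.isin(small)
        X, y = X[keep], y[keep]
    return X, y, [str(s) for s in small]


def _make_forest(spec: DecoderSpec) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=spec.n_estimators,
        max_depth=spec.max_depth,
        class_weight=spec.class_weight,
        random_state=spec.seed,
        n_jobs=1,
    )


def _cross_validate(model_factory, X: np.ndarray, y: np.ndarray, spec: DecoderSpec):
    """One CV pass yielding both per-fold scores and out-of-fold predictions."""
    skf = StratifiedKFold(n_splits=spec.n_splits, shuffle=True, random_state=spec.seed)
    oof = np.empty(len(y), dtype=object)
    scores = []
    for train, test in skf.split(X, y):
        model = model_factory()
        model.fit(X[train], y[train])
        pred = model.predict(X[test])
        oof[test] = pred
        scores.append(float(balanced_accuracy_score(y[test], pred)))
    return scores, oof.astype(str)


def run_decoder(X: pd.DataFrame, y: pd.Series, spec: DecoderSpec = DecoderSpec()) -> DecodingResult:
    """Cross-validated random-forest decoding of ``y`` from ``X``.

    Classes smaller than ``n_splits`` are dropped with a warning (never
    silently merged).  The returned model is refit on the full table for
    attribution.
    """
    X, y, dropped = _drop_small_classes(X, y, spec.n_splits)
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes after filtering")
    Xa, ya = X.to_numpy(dtype=bool), y.to_numpy(dtype=str)
    scores, oof = _cross_validate(lambda: _make_forest(spec), Xa, ya, spec)
    cm = confusion_matrix(ya, oof, labels=classes, normalize="true")
    report = classification_report(ya, oof, labels=classes, output_dict=True, zero_division=0)
    full = _make_forest(spec).fit(Xa, ya)
    return DecodingResult(
        mean_balanced_accuracy=float(np.mean(scores)),
        per_fold=scores,
        chance_level=chance_level(y),
        confusion=pd.DataFrame(cm, index=classes, columns=classes),
        per_class_report=report,
        model=full,
        dropped_classes=dropped,
    )


def _class_weighted_sample(
    y: pd.Series, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Stratified row sample with probability inversely proportional to
    class frequency, capped at each class's size."""
    counts = y.value_counts()
    inv = 1.0 / counts
    target = (inv / inv.sum() * size).round().astype(int)
    idx_parts = []
    positions = pd.Series(np.arange(len(y)), index=y.index)
    for cls, want in target.items():
        pool = positions[(y == cls).to_numpy()].to_numpy()
        take = min(int(want), len(pool))
        if take > 0:
            idx_parts.append(rng.choice(pool, size=take, replace=False))
    return np.concatenate(idx_parts) if idx_parts else np.arange(min(size, len(y)))


def attribution_matrix(
    model: RandomForestClassifier,
    X: pd.DataFrame,
    y: pd.Series,
    spec: DecoderSpec = DecoderSpec(),
) -> pd.DataFrame:
    """Class x gene mean absolute Shapley attribution of the fitted model.

    Shapley values of the predicted class probabilities are estimated by
    Monte Carlo permutation sampling against a background sample: for each
    random feature ordering, features of a background row are switched one
    at a time to the explained row's values and the marginal change in the
    background-averaged class probability is credited to the switched
    feature.  Explained rows are a class-weight-balanced sample of
    min(n, attribution_sample) rows.  All entries are >= 0; a feature that
    is constant across the data receives exactly 0.
    """
    rng = np.random.default_rng(spec.seed)
    n, n_feat = X.shape
    sample_idx = _class_weighted_sample(y, min(n, spec.attribution_sample), rng)
    E = X.to_numpy(dtype=float)[sample_idx]  # explained rows (m, g)
    labels_e = y.to_numpy(dtype=str)[sample_idx]
    bg_idx = rng.choice(n, size=min(n, spec.attribution_background), replace=False)
    B = X.to_numpy(dtype=float)[bg_idx]  # background (b, g)
    m, b = len(E), len(B)
    classes = list(model.classes_)
    k = len(classes)

    phi = np.zeros((m, n_feat, k))
    for _ in range(spec.attribution_permutations):
        order = rng.permutation(n_feat)
        cur = np.tile(B, (m, 1))  # (m*b, g), row blocks per explained row
        v_prev = model.predict_proba(cur).reshape(m, b, k).mean(axis=1)
        for j in order:
            if np.all(E[:, j][:, None] == B[None, :, j]):
                continue  # constant feature: switching changes nothing
            cur[:, j] = np.repeat(E[:, j], b)
            v = model.predict_proba(cur).reshape(m, b, k).mean(axis=1)
            phi[:, j, :] += v - v_prev
            v_prev = v
    phi /= spec.attribution_permutations

    out = np.zeros((k, n_feat))
    for ci, cls in enumerate(classes):
        out[ci] = np.abs(phi[:, :, ci]).mean(axis=0)
    return pd.DataFrame(out, index=classes, columns=list(X.columns))


_BASELINES = {
    "logistic": lambda spec: LogisticRegression(
        max_iter=2000, class_weight="balanced", random_state=spec.seed
    ),
    # lsqr + shrinkage stays defined when within-class scatter is singular,
    # which boolean profiles with deterministic genes routinely produce
    "lda": lambda spec: LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto"),
}


def run_baselines(X: pd.DataFrame, y: pd.Series, spec: DecoderSpec = DecoderSpec()) -> dict[str, float]:
    """Mean balanced accuracy of each baseline under the same CV protocol."""
    X, y, _ = _drop_small_classes(X, y, spec.n_splits)
    Xa, ya = X.to_numpy(dtype=float), y.to_numpy(dtype=str)
    out = {}
    for name in spec.baseline_models:
        if name not in _BASELINES:
            raise KeyError(f"unknown baseline model: {name!r}")
        scores, _ = _cross_validate(lambda: _BASELINES[name](spec), Xa, ya, spec)
        out[name] = float(np.mean(scores))
    return out
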