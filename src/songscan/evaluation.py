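"""Evaluation machinery: balanced accuracy, ROC/AUC, repeated holdout,
learning curves and detector-vs-truth matching.

Balanced accuracy follows the two-class definition

    BAC = (P(A) + P(B)) / 2 * 100

where P(A) and P(B) are the proportions of presence and absence examples
classified correctly. Repeated holdout draws stratified 70/30 splits; the
random stream for repetition ``i`` is derived from ``(seed, i)`` so that
changing ``n_reps`` never reshuffles earlier repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import classifier as clf
from .annotations import Selection

__all__ = [
    "EvaluationResult",
    "LearningCurveResult",
    "DetectorScore",
    "balanced_accuracy",
    "roc_auc",
    "repeated_holdout",
    "learning_curve",
    "match_detections",
    "DEFAULT_FRACTIONS",
]

DEFAULT_FRACTIONS = (0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1)


@dataclass
class EvaluationResult:
    """Summary of a repeated-holdout evaluation (percent-scale BAC)."""

    bac_mean: float
    bac_sd: float
    p_a: float
    p_b: float
    auc: float
    n_reps: int
    train_fraction: float
    seed: int
    per_class_accuracy: dict[int, float] = field(default_factory=dict)
    bac_values: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    def to_dict(self) -> dict:
        out = {
            "bac_mean": self.bac_mean,
            "bac_sd": self.bac_sd,
            "p_a": self.p_a,
            "p_b": self.p_b,
            "auc": self.auc,
            "n_reps": self.n_reps,
            "train_fraction": self.train_fraction,
            "seed": self.seed,
        }
        if self.per_class_accuracy:
            out["per_class_accuracy"] = {str(k): v for k, v in self.per_class_accuracy.items()}
        return out


@dataclass
class LearningCurveResult:
    """BAC mean/SD as a function of the training-data fraction."""

    fractions: tuple[float, ...]
    bac_mean: tuple[float, ...]
    bac_sd: tuple[float, ...]
    n_reps: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fraction": self.fractions, "bac_mean": self.bac_mean, "bac_sd": self.bac_sd}
        )


@dataclass
class DetectorScore:
    """Recall/precision of detections against ground-truth selections."""

    recall: float
    precision: float
    n_truth: int
    n_detected: int
    n_matched: int
    overlap_threshold: float
    precision_defined: bool = True


def _validate_two_class(truth: np.ndarray) -> None:
    if not ((truth == 1).any() and (truth == 0).any()):
        raise ValueError("truth must contain both presence (1) and absence (0)")


def balanced_accuracy(pred, truth) -> tuple[float, float, float]:
    """Return ``(bac_percent, p_a, p_b)`` for binary labels (1 = presence)."""
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    _validate_two_class(truth)
    p_a = float((pred[truth == 1] == 1).mean())
    p_b = float((pred[truth == 0] == 0).mean())
    return (p_a + p_b) / 2.0 * 100.0, p_a, p_b


def roc_auc(scores, truth) -> float:
    """Area under the ROC curve (Mann-Whitney formulation, ties count 1/2)."""
    truth = np.asarray(truth, dtype=int)
    _validate_two_class(truth)
    return float(roc_auc_score(truth, np.asarray(scores, dtype=float)))


def _stratified_split(y: np.ndarray, train_fraction: float, rng: np.random.Generator):
    train_idx, test_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_train = int(round(train_fraction * len(idx)))
        if n_train < 1 or n_train >= len(idx):
            raise ValueError(
                f"class {cls} has too few examples ({len(idx)}) to stratify at "
                f"train_fraction={train_fraction}"
            )
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def repeated_holdout(
    features,
    labels,
    svm_cfg: clf.SVMConfig | None = None,
    train_fraction: float = 0.7,
    n_reps: int = 1000,
    seed: int = 0,
    class_labels=None,
) -> EvaluationResult:
    """Repeated stratified holdout evaluation of the SVM.

    Per repetition: split ``train_fraction`` / rest, train, evaluate BAC and
    AUC on the held-out part. ``class_labels`` (0-3 per row, optional)
    enables the per-class accuracy diagnostic.
    """
    svm_cfg = svm_cfg or clf.SVMConfig()
    if isinstance(features, pd.DataFrame):
        x = features
    else:
        x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    _validate_two_class(y)
    cls4 = None if class_labels is None else np.asarray(class_labels, dtype=int)

    bacs, pas, pbs, aucs = [], [], [], []
    class_correct: dict[int, int] = {}
    class_total: dict[int, int] = {}
    for rep in range(n_reps):
        rng = np.random.default_rng(np.random.SeedSequence((seed, rep)))
        tr, te = _stratified_split(y, train_fraction, rng)
        x_tr = x.iloc[tr] if isinstance(x, pd.DataFrame) else x[tr]
        x_te = x.iloc[te] if isinstance(x, pd.DataFrame) else x[te]
        model = clf.train(x_tr, y[tr], svm_cfg)
        scores = clf.decision_scores(model, x_te)
        pred = (scores > 0).astype(int)
        bac, p_a, p_b = balanced_accuracy(pred, y[te])
        bacs.append(bac)
        pas.append(p_a)
        pbs.append(p_b)
        aucs.append(roc_auc(scores, y[te]))
        if cls4 is not None:
            for c in np.unique(cls4[te]):
                mask = cls4[te] == c
                expected = 0 if c == 0 else 1
                class_correct[c] = class_correct.get(c, 0) + int((pred[mask] == expected).sum())
                class_total[c] = class_total.get(c, 0) + int(mask.sum())

    per_class = {
        int(c): class_correct[c] / class_total[c] for c in sorted(class_total)
    }
    bacs = np.asarray(bacs)
    return EvaluationResult(
        bac_mean=float(bacs.mean()),
        bac_sd=float(bacs.std(ddof=1)) if n_reps > 1 else 0.0,
        p_a=float(np.mean(pas)),
        p_b=float(np.mean(pbs)),
        auc=float(np.mean(aucs)),
        n_reps=n_reps,
        train_fraction=train_fraction,
        seed=seed,
        per_class_accuracy=per_class,
        bac_values=bacs,
    )


def learning_curve(
    features,
    labels,
    svm_cfg: clf.SVMConfig | None = None,
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
    n_reps: int = 100,
    seed: int = 0,
    train_fraction: float = 0.7,
) -> LearningCurveResult:
    """Repeated holdout on stratified subsamples of the data.

    Fraction 1.0 uses all rows in their original order, so its result is
    identical to :func:`repeated_holdout` with the same seed.
    """
    y = np.asarray(labels, dtype=int)
    means, sds = [], []
    for frac in fractions:
        if not 0 < frac <= 1:
            raise ValueError(f"fractions must lie in (0, 1], got {frac}")
        rng = np.random.default_rng(np.random.SeedSequence((seed, int(round(frac * 1e6)))))
        rows = []
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            n_keep = max(2, int(round(frac * len(idx))))
            if frac >= 1.0:
                rows.append(idx)
            else:
                rows.append(rng.choice(idx, size=n_keep, replace=False))
        rows = np.sort(np.concatenate(rows))
        x_sub = (
            features.iloc[rows]
            if isinstance(features, pd.DataFrame)
            else np.asarray(features)[rows]
        )
        result = repeated_holdout(
            x_sub, y[rows], svm_cfg, train_fraction=train_fraction, n_reps=n_reps, seed=seed
        )
        means.append(result.bac_mean)
        sds.append(result.bac_sd)
    return LearningCurveResult(
        fractions=tuple(fractions),
        bac_mean=tuple(means),
        bac_sd=tuple(sds),
        n_reps=n_reps,
        seed=seed,
    )


def match_detections(
    detected: list[Selection],
    truth: list[Selection],
    overlap_threshold: float = 0.5,
) -> DetectorScore:
    """Greedy one-to-one matching of detections to truth selections.

    A pair is matchable when temporal intersection / truth duration >=
    ``overlap_threshold``; pairs are taken in order of descending overlap
    fraction. With no detections, precision is reported as 0.0 and flagged
    undefined.
    """
    pairs = []
    for ti, t in enumerate(truth):
        for di, d in enumerate(detected):
            frac = t.overlap_seconds(d) / t.duration
            if frac >= overlap_threshold:
                pairs.append((-frac, ti, di))
    pairs.sort()
    used_t, used_d = set(), set()
    n_matched = 0
    for _, ti, di in pairs:
        if ti in used_t or di in used_d:
            continue
        used_t.add(ti)
        used_d.add(di)
        n_matched += 1
    n_truth, n_detected = len(truth), len(detected)
    recall = n_matched / n_truth if n_truth else 0.0
    precision_defined = n_detected > 0
    precision = n_matched / n_detected if precision_defined else 0.0
    return DetectorScore(
        recall=recall,
        precision=precision,
        n_truth=n_truth,
        n_detected=n_detected,
        n_matched=n_matched,
        overlap_threshold=overlap_threshold,
        precision_defined=precision_defined,
    )
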