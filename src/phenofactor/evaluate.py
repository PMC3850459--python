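"""Similarity-cutoff classification of encounters and its evaluation.

Workflow: factor the training term-by-encounter matrix (l1 LRMD, NMF or
truncated SVD) into k term-space feature vectors; score each test encounter
by its best cosine similarity to any feature (negative cosines clipped to
0, so the score lives in [0, 1] with 1 = perfect correlation); call an
encounter positive when its score strictly exceeds a cutoff.  Performance
is summarized by sensitivity/specificity per cutoff, the ROC curve and its
area, pooled over the folds of a seeded k-fold cross-validation in which
the vocabulary, idf weights and features are always computed from training
folds only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .factorization import (DegenerateInputError, lrmd_decompose,
                            nmf_decompose, svd_truncate)
from .features import (FIELD_PREFIXES, TermEncounterMatrix, TermVocabulary,
                       build_matrix)

__all__ = [
    "FeatureSet",
    "EvalReport",
    "FoldSplit",
    "extract_features",
    "score_encounter",
    "score_matrix",
    "classify",
    "confusion_metrics",
    "roc_curve",
    "make_folds",
    "cross_validate",
    "dominant_terms_report",
]

DEFAULT_CUTOFFS = (0.65, 0.75, 0.85, 0.90)


@dataclass
class FeatureSet:
    """k term-space feature vectors tied to the vocabulary they live in."""

    feature_vectors: np.ndarray      # M x k
    vocabulary: TermVocabulary
    method: str                      # lrmd / nmf / svd
    training_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.feature_vectors = np.atleast_2d(
            np.asarray(self.feature_vectors, dtype=float))
        if self.feature_vectors.shape[0] != len(self.vocabulary):
            raise ValueError("feature vector length must equal the "
                             "vocabulary size")
        if self.k < 1:
            raise ValueError("need at least one feature")

    @property
    def k(self) -> int:
        return self.feature_vectors.shape[1]


@dataclass
class FoldSplit:
    """Assignment of encounter ids to cross-validation folds."""

    n_folds: int
    assignments: dict                # encounter id -> fold index
    seed: int

    def fold_ids(self, fold: int) -> list:
        return [e for e, f in self.assignments.items() if f == fold]


@dataclass
class EvalReport:
    """Cutoff table, ROC curve and (optionally) per-fold reports."""

    cutoffs: list
    sensitivity: list
    specificity: list
    counts: list                     # per cutoff: dict tp/fp/tn/fn
    roc_points: list                 # (fpr, tpr) vertices
    auc: float
    per_fold: list = field(default_factory=list)
    scores: Optional[np.ndarray] = None
    truth: Optional[np.ndarray] = None

    def cutoff_table(self) -> pd.DataFrame:
        rows = []
        for c, se, sp, ct in zip(self.cutoffs, self.sensitivity,
                                 self.specificity, self.counts):
            rows.append({"cutoff": c, "sensitivity": se, "specificity": sp,
                         **ct})
        return pd.DataFrame(rows)


def extract_features(train_matrix: TermEncounterMatrix, k: int,
                     method: str = "lrmd", seed: int = 0,
                     **kwargs) -> FeatureSet:
    """Factor the training matrix and keep the k term-space vectors.

    lrmd -> u columns of the l1 decomposition; nmf -> W columns;
    svd -> left singular vectors.
    """
    X = train_matrix.matrix
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds min{X.shape}")
    if method == "lrmd":
        pair, _ = lrmd_decompose(X, k, **kwargs)
        vectors = pair.u
    elif method == "nmf":
        W, _, _ = nmf_decompose(X, k, seed=seed, **kwargs)
        vectors = W
    elif method == "svd":
        pair, _ = svd_truncate(X, k)
        vectors = pair.u
    else:
        raise ValueError(f"unknown method {method!r}")
    return FeatureSet(vectors, train_matrix.vocabulary, method,
                      list(train_matrix.encounter_ids))


def score_matrix(features: FeatureSet, X: np.ndarray,
                 zero_score: float = 0.0) -> np.ndarray:
    """Similarity score for every column of ``X`` (M x N).

    All-zero columns (encounters with no in-vocabulary terms) receive
    ``zero_score``; they carry no evidence of similarity.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    U = features.feature_vectors
    u_norms = np.linalg.norm(U, axis=0)
    x_norms = np.linalg.norm(X, axis=0)
    if np.any(u_norms == 0):
        raise DegenerateInputError("a feature vector is zero")
    cos = (U.T @ X) / np.outer(u_norms, np.maximum(x_norms, 1e-300))
    scores = np.clip(cos.max(axis=0), 0.0, 1.0)
    scores[x_norms == 0] = zero_score
    return scores


def score_encounter(features: FeatureSet, x) -> float:
    """Best cosine similarity of one encounter column to the feature set,
    clipped to [0, 1]; exactly 1 iff x is parallel to some feature."""
    x = np.asarray(x, dtype=float).ravel()
    if not np.any(x):
        raise DegenerateInputError("cannot score an all-zero encounter")
    return float(score_matrix(features, x[:, None])[0])


def classify(scores, cutoff: float) -> np.ndarray:
    """Positive iff score strictly exceeds the cutoff."""
    return (np.asarray(scores, dtype=float) > cutoff).astype(int)


def _require_two_classes(truth: np.ndarray, context: str = "truth") -> None:
    if truth.min() == truth.max():
        missing = "positive" if truth.max() == 0 else "negative"
        raise ValueError(f"{context} contains no {missing} examples; "
                         "sensitivity/specificity are undefined")


def confusion_metrics(predicted, truth):
    """(sensitivity, specificity, counts) for binary predictions."""
    predicted = np.asarray(predicted, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth lengths differ")
    _require_two_classes(truth)
    tp = int(np.sum((predicted == 1) & (truth == 1)))
    fn = int(np.sum((predicted == 0) & (truth == 1)))
    tn = int(np.sum((predicted == 0) & (truth == 0)))
    fp = int(np.sum((predicted == 1) & (truth == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return sens, spec, {"tp": tp, "fp": fp, "tn": tn, "fn": fn}


def roc_curve(scores, truth):
    """ROC vertices (one per distinct score, ties grouped) and trapezoidal
    AUC; the curve always includes (0, 0) and (1, 1)."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    _require_two_classes(truth)
    fpr, tpr, _ = _skm.roc_curve(truth, scores, drop_intermediate=False)
    auc = float(_skm.auc(fpr, tpr))
    points = list(zip(fpr.tolist(), tpr.tolist()))
    if points[-1] != (1.0, 1.0):  # pragma: no cover - sklearn guarantees it
        points.append((1.0, 1.0))
    return points, auc


def make_folds(encounter_ids: Sequence[str], n_folds: int = 4,
               seed: int = 0) -> FoldSplit:
    """Seeded uniform shuffle + round-robin assignment; fold sizes differ
    by at most one."""
    ids = list(encounter_ids)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if len(ids) < n_folds:
        raise ValueError("fewer encounters than folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    assignments = {ids[j]: int(i % n_folds) for i, j in enumerate(perm)}
    return FoldSplit(n_folds, assignments, seed)


def _fold_report(scores, truth, cutoffs):
    sens, spec, counts = [], [], []
    for c in cutoffs:
        se, sp, ct = confusion_metrics(classify(scores, c), truth)
        sens.append(se)
        spec.append(sp)
        counts.append(ct)
    points, auc = roc_curve(scores, truth)
    return EvalReport(list(cutoffs), sens, spec, counts, points, auc,
                      scores=np.asarray(scores, dtype=float),
                      truth=np.asarray(truth, dtype=int))


def cross_validate(records, labels, k: int = 4, n_folds: int = 4,
                   cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
                   method: str = "lrmd", weighting: str = "binary",
                   seed: int = 0, train_on: str = "positives",
                   age_bin_width: float = 0.5,
                   fold_split: Optional[FoldSplit] = None) -> EvalReport:
    """k-fold cross-validated evaluation of the similarity classifier.

    Per fold: build the vocabulary and weighted matrix from training
    records only (``train_on="positives"`` restricts feature extraction to
    positive-class training encounters, mirroring a detector trained on the
    phenotype of interest; ``"all"`` uses the full training fold), extract
    features, project test records through the training vocabulary (and
    training idf), and score them.  The default binary weighting keeps
    similarity scores on the interpretable shared-term-correlation scale
    that the customary cutoff grid (0.65-0.9) presumes; tf-idf compresses
    cosines toward 0 and suits factor discovery more than cutoff scoring.
    Confusion counts are pooled (micro-averaged) across folds for the
    cutoff table and ROC; per-fold reports are kept alongside.  Supplying ``fold_split`` lets two methods be
    compared on identical partitions.
    """
    labels = np.asarray(labels, dtype=int)
    if len(records) != len(labels):
        raise ValueError("records and labels lengths differ")
    if train_on not in ("positives", "all"):
        raise ValueError(f"unknown train_on {train_on!r}")
    ids = [r.encounter_id for r in records]
    split = fold_split or make_folds(ids, n_folds=n_folds, seed=seed)
    by_id = {r.encounter_id: (r, l) for r, l in zip(records, labels)}

    pooled_scores, pooled_truth, per_fold = [], [], []
    for fold in range(split.n_folds):
        test_ids = set(split.fold_ids(fold))
        train = [(r, l) for i, (r, l) in by_id.items() if i not in test_ids]
        test = [(r, l) for i, (r, l) in by_id.items() if i in test_ids]
        fold_truth = np.array([l for _, l in test])
        try:
            _require_two_classes(fold_truth, context=f"fold {fold}")
            _require_two_classes(np.array([l for _, l in train]),
                                 context=f"training folds for fold {fold}")
        except ValueError as err:
            raise ValueError(str(err)) from None
        feat_records = ([r for r, l in train if l == 1]
                        if train_on == "positives" else [r for r, _ in train])
        train_matrix = build_matrix(feat_records, weighting=weighting,
                                    age_bin_width=age_bin_width)
        feats = extract_features(train_matrix, k, method=method, seed=seed)
        test_matrix = build_matrix([r for r, _ in test], weighting=weighting,
                                   age_bin_width=age_bin_width,
                                   vocabulary=train_matrix.vocabulary,
                                   idf=train_matrix.idf, drop_empty=False)
        fold_scores = score_matrix(feats, test_matrix.matrix)
        pooled_scores.append(fold_scores)
        pooled_truth.append(fold_truth)
        per_fold.append(_fold_report(fold_scores, fold_truth, cutoffs))

    report = _fold_report(np.concatenate(pooled_scores),
                          np.concatenate(pooled_truth), cutoffs)
    report.per_fold = per_fold
    return report


def dominant_terms_report(features: FeatureSet, top_m: int = 5,
                          age_fraction: float = 0.25) -> pd.DataFrame:
    """Per-feature table of dominant terms grouped by clinical field.

    For each feature the ``top_m`` terms by absolute loading are reported
    within every field; fields with no nonzero loading show "N/A".  Age-bin
    terms are collapsed to a min-max range string spanning the bins whose
    loading is at least ``age_fraction`` of the strongest age-bin loading.
    """
    if top_m < 1:
        raise ValueError("top_m must be >= 1")
    vocab = features.vocabulary
    rows = {name: [] for pref, name in FIELD_PREFIXES.items()}
    for i in range(features.k):
        loadings = features.feature_vectors[:, i]
        by_field = {pref: [] for pref in FIELD_PREFIXES}
        for term, idx in vocab.index.items():
            pref, _, value = term.partition(":")
            if pref in by_field and abs(loadings[idx]) > 1e-12:
                by_field[pref].append((abs(loadings[idx]), value))
        for pref, name in FIELD_PREFIXES.items():
            entries = sorted(by_field[pref], reverse=True)
            if not entries:
                rows[name].append("N/A")
            elif pref == "age":
                # the range is defined by every sufficiently loaded bin,
                # not by the top_m truncation used for listed terms
                best = entries[0][0]
                keep = [v for a, v in entries if a >= age_fraction * best]
                lo = min(float(v.split("-")[0]) for v in keep)
                hi = max(float(v.split("-")[1]) for v in keep)
                rows[name].append(f"{lo:g}-{hi:g}")
            else:
                rows[name].append("; ".join(v for _, v in entries[:top_m]))
    cols = [f"feature_{i + 1}" for i in range(features.k)]
    df = pd.DataFrame(rows, index=cols).T
    df.index.name = "variable"
    return df
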