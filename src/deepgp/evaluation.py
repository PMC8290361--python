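"""Labeled-dataset construction, cross-validation and ranking metrics.

Positives are the curated disease-gene pairs; negatives are drawn uniformly
without replacement from the unlabeled complement of (genes x diseases), one
per positive, so the dataset is balanced. Negative sampling happens once on
the full dataset before fold splitting — the protocol the training procedure
describes — and folds are stratified by label so every test fold carries both
classes. AUC is the Mann-Whitney probability that a random positive outscores
a random negative (ties 0.5); AUPR is step-integrated average precision.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .io import ValidationError

Pair = tuple[str, str]  # (disease_id, gene_id)


@dataclasses.dataclass
class LabeledDataset:
    positives: list[Pair]
    negatives: list[Pair]
    seed: int

    def __post_init__(self) -> None:
        if set(self.positives) & set(self.negatives):
            raise ValidationError("positives and negatives overlap")

    @property
    def pairs(self) -> list[Pair]:
        return list(self.positives) + list(self.negatives)

    @property
    def labels(self) -> np.ndarray:
        return np.r_[np.ones(len(self.positives)), np.zeros(len(self.negatives))]


def enumerate_candidate_negatives(
    genes: Sequence[str], diseases: Sequence[str], positives: Sequence[Pair]
) -> list[Pair]:
    """(genes x diseases) minus the curated positives, in canonical order.

    Canonical order is panel order over diseases, then the supplied gene
    order. Size is |genes| * |diseases| - |positives|.
    """
    gene_set, disease_set = set(genes), set(diseases)
    pos = set()
    for d, g in positives:
        if g not in gene_set or d not in disease_set:
            raise ValidationError(
                f"positive pair ({d!r}, {g!r}) references an unknown gene/disease"
            )
        pos.add((d, g))
    return [(d, g) for d in diseases for g in genes if (d, g) not in pos]


def sample_negatives(
    candidates: Sequence[Pair], n: int, seed: int
) -> list[Pair]:
    """Uniform sample without replacement; exhaustive n keeps canonical order."""
    if n > len(candidates):
        raise ValidationError(
            f"cannot sample {n} negatives from {len(candidates)} candidates"
        )
    if n == len(candidates):
        return list(candidates)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n, replace=False)
    return [candidates[i] for i in sorted(idx)]


def build_labeled_dataset(
    genes: Sequence[str],
    diseases: Sequence[str],
    positives: Sequence[Pair],
    seed: int,
) -> LabeledDataset:
    """Balanced dataset: curated positives plus an equal-size negative sample."""
    positives = sorted(set(positives))
    candidates = enumerate_candidate_negatives(genes, diseases, positives)
    negatives = sample_negatives(candidates, len(positives), seed)
    return LabeledDataset(positives=positives, negatives=negatives, seed=seed)


def kfold_split(
    dataset: LabeledDataset, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Label-stratified k-fold partition over the dataset's pair indices.

    Test folds are disjoint, cover every pair exactly once, differ in size by
    at most one, and each contains both classes.
    """
    n = len(dataset.pairs)
    if k < 2:
        raise ValidationError("k must be at least 2")
    if n < k:
        raise ValidationError(f"cannot split {n} samples into {k} folds")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (train, test) for train, test in splitter.split(np.zeros(n), dataset.labels)
    ]


def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).reshape(-1)
    if len(np.unique(labels)) < 2:
        raise ValidationError("metrics require both classes present")
    return labels


def compute_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (Mann-Whitney statistic, ties count 0.5)."""
    labels = _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float).reshape(-1)))


def compute_aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve by step integration."""
    labels = _check_two_classes(labels)
    return float(
        average_precision_score(labels, np.asarray(scores, dtype=float).reshape(-1))
    )


@dataclasses.dataclass
class CvResult:
    folds: pd.DataFrame  # columns: repeat, fold, auc, aupr
    assignments: list[list[tuple[np.ndarray, np.ndarray]]]
    dataset: LabeledDataset

    @property
    def mean_auc(self) -> float:
        return float(self.folds["auc"].mean())

    @property
    def mean_aupr(self) -> float:
        return float(self.folds["aupr"].mean())

    def report(self) -> pd.DataFrame:
        """Per-fold rows plus a mean summary row, ready for TSV export."""
        rows = self.folds.copy()
        rows["fold"] = rows["fold"].astype(str)
        summary = pd.DataFrame(
            [{"repeat": "", "fold": "mean", "auc": self.mean_auc,
              "aupr": self.mean_aupr}]
        )
        return pd.concat([rows, summary], ignore_index=True)


def run_cv(
    fit_score,
    dataset: LabeledDataset,
    k: int = 10,
    cv_seed: int = 0,
    n_repeats: int = 1,
) -> CvResult:
    """k-fold cross-validation of an arbitrary fit/score routine.

    ``fit_score(train_pairs, train_labels, test_pairs, fold_seed)`` must
    return scores for the test pairs. Per fold we record AUC and AUPR of the
    held-out scores; the default protocol is a single 10-fold round, with
    ``n_repeats`` re-running the split under shifted seeds.
    """
    pairs = dataset.pairs
    labels = dataset.labels
    records = []
    assignments = []
    for rep in range(n_repeats):
        folds = kfold_split(dataset, k, cv_seed + rep)
        assignments.append(folds)
        for fi, (train_idx, test_idx) in enumerate(folds):
            fold_seed = (cv_seed + rep) * 1009 + fi
            scores = fit_score(
                [pairs[i] for i in train_idx],
                labels[train_idx],
                [pairs[i] for i in test_idx],
                fold_seed,
            )
            records.append(
                {
                    "repeat": rep,
                    "fold": fi,
                    "auc": compute_auc(scores, labels[test_idx]),
                    "aupr": compute_aupr(scores, labels[test_idx]),
                }
            )
    return CvResult(
        folds=pd.DataFrame(records), assignments=assignments, dataset=dataset
    )


def screen_predictions(
    scores: pd.DataFrame, threshold: float = 0.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep pairs with score > threshold; summarize counts per disease.

    Returns (screened pairs, summary with disease_id, n_screened,
    n_candidates).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError("threshold must lie in [0, 1]")
    screened = scores[scores["score"] > threshold].reset_index(drop=True)
    summary = (
        scores.groupby("disease_id", sort=True)
        .agg(n_candidates=("score", "size"))
        .reset_index()
    )
    counts = screened.groupby("disease_id").size()
    summary["n_screened"] = (
        summary["disease_id"].map(counts).fillna(0).astype(int)
    )
    return screened, summary[["disease_id", "n_screened", "n_candidates"]]
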