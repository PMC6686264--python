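"""AUC, repeated stratified cross-validation, and repeated external testing.

The evaluation protocol mirrors the study design the package targets:
5-fold cross-validation repeated 20 times (100 sub-models per endpoint),
and external testing in which the classifier is retrained on the full
training set under 100 different seeds and scored on a fixed held-out set.
Results carry the full per-unit AUC list plus mean and standard deviation,
the "mean(sd)" presentation of the field's benchmark tables.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .classifier import ClassifierSpec, predict_proba, train_classifier
from .encoders import LatentFeatures
from .io_data import EndpointLabels

# keep derived seeds well under 2**31
_SEED_MOD = 2 ** 31 - 1


@dataclass
class CVConfig:
    n_folds: int = 5
    n_repeats: int = 20
    base_seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        if self.n_repeats < 1:
            raise ValueError("need at least 1 repeat")


@dataclass
class EvalResult:
    endpoint: str
    feature_set: str
    aucs: list[float]
    base_seed: int = 0

    def __post_init__(self):
        if any(not 0.0 <= a <= 1.0 for a in self.aucs):
            raise ValueError("every AUC must lie in [0, 1]")

    @property
    def mean(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def sd(self) -> float:
        return float(np.std(self.aucs, ddof=0)) if len(self.aucs) > 1 else 0.0

    def summary(self) -> str:
        return f"{self.mean:.3f}({self.sd:.3f})"


def auc(scores, labels) -> float:
    """Area under the ROC curve.

    Equals the probability that a random positive outscores a random
    negative, with ties credited 0.5 (the Mann-Whitney convention).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC is undefined with a single class")
    return float(roc_auc_score(labels, scores))


def _fold_partitions(labels: np.ndarray, cv: CVConfig) -> list[list[np.ndarray]]:
    """One list of test-index arrays per repeat; each repeat covers all samples."""
    partitions = []
    for r in range(cv.n_repeats):
        seed = (cv.base_seed + r) % _SEED_MOD
        if cv.stratified:
            if np.bincount(labels, minlength=2).min() < cv.n_folds:
                raise ValueError(
                    "smallest class is below n_folds; use stratified=False "
                    "or fewer folds"
                )
            splitter = StratifiedKFold(cv.n_folds, shuffle=True, random_state=seed)
        else:
            splitter = KFold(cv.n_folds, shuffle=True, random_state=seed)
        partitions.append([test for _, test in splitter.split(labels, labels)])
    return partitions


def _fit_score(features, y, train_idx, test_idx, clf_spec, seed):
    spec = ClassifierSpec(**{**asdict(clf_spec), "seed": int(seed)})
    sub = EndpointLabels("fold", [str(i) for i in train_idx], y[train_idx])
    clf = train_classifier(features[train_idx], sub, spec)
    proba = predict_proba(clf, features[test_idx])
    return auc(proba[:, 1], y[test_idx])


def cross_validate(features: np.ndarray, labels: EndpointLabels,
                   clf_spec: ClassifierSpec, cv: CVConfig) -> EvalResult:
    """Repeated k-fold CV: one classifier per fold per repeat.

    Repeat r uses fold partition seed base_seed + r, so the full run builds
    n_folds x n_repeats sub-models and every sample is tested exactly once
    per repeat.
    """
    features = np.asarray(features, dtype=float)
    y = labels.labels
    aucs = []
    for r, folds in enumerate(_fold_partitions(y, cv)):
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
            seed = (cv.base_seed + 9973 * r + f) % _SEED_MOD
            aucs.append(_fit_score(features, y, train_idx, test_idx, clf_spec, seed))
    return EvalResult(labels.name, "cv", aucs, cv.base_seed)


def external_evaluate(train_features, train_labels: EndpointLabels,
                      test_features, test_labels: EndpointLabels,
                      clf_spec: ClassifierSpec, n_runs: int = 100,
                      base_seed: int = 0) -> EvalResult:
    """Retrain on the full training set n_runs times; score a fixed test set.

    Run i uses classifier seed base_seed + i. Train and test sample ids must
    be disjoint (leakage guard).
    """
    overlap = set(train_labels.sample_ids) & set(test_labels.sample_ids)
    if overlap:
        raise ValueError(f"train/test sample ids overlap: {sorted(overlap)[:5]} ...")
    train_features = np.asarray(train_features, dtype=float)
    test_features = np.asarray(test_features, dtype=float)
    aucs = []
    for i in range(n_runs):
        spec = ClassifierSpec(**{**asdict(clf_spec), "seed": (base_seed + i) % _SEED_MOD})
        clf = train_classifier(train_features, train_labels, spec)
        proba = predict_proba(clf, test_features)
        aucs.append(auc(proba[:, 1], test_labels.labels))
    return EvalResult(train_labels.name, "external", aucs, base_seed)


def ablation_compare(features: LatentFeatures, labels: EndpointLabels,
                     clf_spec: ClassifierSpec, cv: CVConfig,
                     subsets: list[tuple[str, ...]] | None = None) -> dict[tuple[str, ...], EvalResult]:
    """CV each feature-block subset on identical fold partitions.

    Defaults to every single block plus all blocks together, the paired
    design needed to attribute performance to individual encoding networks.
    """
    if subsets is None:
        singles = [(name,) for name in features.blocks]
        subsets = singles + [tuple(features.blocks)]
    sub = features.subset_samples(labels.sample_ids)
    y = labels.labels
    partitions = _fold_partitions(y, cv)
    results: dict[tuple[str, ...], EvalResult] = {}
    for subset in subsets:
        mat = np.concatenate([sub.blocks[name] for name in subset], axis=1)
        spec = ClassifierSpec(**{**asdict(clf_spec), "input_dim": mat.shape[1]})
        aucs = []
        for r, folds in enumerate(partitions):
            for f, test_idx in enumerate(folds):
                train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
                seed = (cv.base_seed + 9973 * r + f) % _SEED_MOD
                aucs.append(_fit_score(mat, y, train_idx, test_idx, spec, seed))
        results[tuple(subset)] = EvalResult(labels.name, "+".join(subset), aucs, cv.base_seed)
    return results


def write_results(results: list[EvalResult], long_path, summary_path) -> None:
    """Long-format per-unit AUCs plus a mean(sd) summary table."""
    long_rows = [
        {"endpoint": r.endpoint, "feature_set": r.feature_set,
         "unit_index": i, "auc": a}
        for r in results for i, a in enumerate(r.aucs)
    ]
    pd.DataFrame(long_rows).to_csv(long_path, sep="\t", index=False)
    summary_rows = [
        {"endpoint": r.endpoint, "feature_set": r.feature_set, "n_units": len(r.aucs),
         "mean_auc": r.mean, "sd_auc": r.sd, "mean_sd": r.summary(),
         "base_seed": r.base_seed}
        for r in results
    ]
    pd.DataFrame(summary_rows).to_csv(summary_path, sep="\t", index=False)
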