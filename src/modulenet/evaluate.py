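"""Downstream evaluation of functional modules.

Two complementary checks of whether a module's genes carry outcome
signal: (i) unsupervised — hierarchically cluster patients on the
module's expression profiles into two groups and compare their survival
by the log-rank test, against a Monte-Carlo null of random same-size
gene sets; (ii) supervised — repeated re-sampling classification with an
SVM on an SVM-RFE-selected gene signature, scored by sensitivity,
specificity, accuracy and Matthews correlation.

All randomness flows from a single master seed through
``numpy.random.SeedSequence`` spawning, so every report is reproducible.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .errors import DataError
from .expression_io import ExpressionMatrix, SampleAnnotation

POSITIVE_LABEL = "high"  # high-risk patients are the positive class throughout


# --------------------------------------------------------------------------
# confusion-matrix metrics

@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise DataError("confusion-matrix counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class Metrics:
    """SEN/SPC/ACC/MCC; a metric with zero denominator is None (undefined)."""

    sen: float | None
    spc: float | None
    acc: float | None
    mcc: float | None


def metrics(cm: ConfusionMatrix) -> Metrics:
    """SEN=TP/(TP+FN), SPC=TN/(TN+FP), ACC=(TP+TN)/total,
    MCC=(TP*TN-FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))."""
    if cm.total == 0:
        raise DataError("confusion matrix is empty")
    sen = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else None
    spc = cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp else None
    acc = (cm.tp + cm.tn) / cm.total
    denom = (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    mcc = (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom) if denom else None
    return Metrics(sen=sen, spc=spc, acc=acc, mcc=mcc)


def confusion_from_predictions(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    positive: str = POSITIVE_LABEL,
) -> ConfusionMatrix:
    if len(y_true) != len(y_pred):
        raise DataError("prediction and label vectors differ in length")
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == positive and p == positive)
    tn = sum(1 for t, p in zip(y_true, y_pred) if t != positive and p != positive)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t != positive and p == positive)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == positive and p != positive)
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


# --------------------------------------------------------------------------
# clustering + survival

@dataclass
class ClusterSurvivalResult:
    assignment: dict[str, int]          # sample -> cluster 1/2
    risk_by_cluster: dict[int, str] | None  # cluster -> high/low, if survival known
    statistic: float | None
    p_value: float | None


def cluster_two_groups(
    mat: ExpressionMatrix,
    ann: Sequence[SampleAnnotation] | None = None,
    method: str = "average",
    metric: str = "correlation",
) -> ClusterSurvivalResult:
    """Cut an agglomerative sample dendrogram into two patient groups.

    Samples are clustered on the module genes' expression profiles
    (correlation distance, average linkage by default). When annotation
    is supplied the cluster with the smaller median survival among
    observed deaths is designated high risk and a two-group log-rank
    test is run.
    """
    if mat.n_samples < 4:
        raise DataError("clustering needs at least 4 samples")
    if mat.n_genes < 2:
        raise DataError("clustering needs at least 2 genes")
    x = mat.values.T  # samples x genes
    if np.allclose(x, x[0]):
        raise DataError("expression matrix is constant across samples; no structure to cluster")
    d = pdist(x, metric=metric)
    if not np.isfinite(d).all():
        raise DataError(
            f"{metric} distances are undefined (constant sample profiles?); "
            "try metric='euclidean'"
        )
    labels = fcluster(linkage(d, method=method), 2, criterion="maxclust")
    if len(set(labels)) < 2:
        raise DataError("dendrogram could not be cut into 2 clusters")
    assignment = {s: int(c) for s, c in zip(mat.sample_ids, labels)}

    if ann is None:
        return ClusterSurvivalResult(assignment, None, None, None)
    stat, p = logrank(assignment, ann)
    by_sample = {a.sample_id: a for a in ann}
    med: dict[int, float] = {}
    for c in (1, 2):
        samples = [by_sample[s] for s in assignment if assignment[s] == c and s in by_sample]
        event_days = [a.survival_days for a in samples if a.event]
        all_days = [a.survival_days for a in samples if a.survival_days is not None]
        # median survival among events; clusters without events fall back to all times
        med[c] = float(np.median(event_days if event_days else all_days))
    high = min(med, key=lambda c: (med[c], c))
    risk = {high: "high", 3 - high: "low"}
    return ClusterSurvivalResult(assignment, risk, stat, p)


def logrank(
    groups: Mapping[str, int],
    ann: Sequence[SampleAnnotation],
) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) on survival days and events."""
    by_sample = {a.sample_id: a for a in ann}
    missing = [s for s in groups if s not in by_sample]
    if missing:
        raise DataError(f"samples without annotation: {missing[:10]}")
    ids = sorted(groups)
    incomplete = [s for s in ids if by_sample[s].survival_days is None or by_sample[s].event is None]
    if incomplete:
        raise DataError(f"samples missing survival_days/event: {incomplete[:10]}")
    levels = sorted(set(groups.values()))
    if len(levels) != 2:
        raise DataError(f"log-rank needs exactly 2 groups, got {len(levels)}")
    a = [s for s in ids if groups[s] == levels[0]]
    b = [s for s in ids if groups[s] == levels[1]]
    res = logrank_test(
        [by_sample[s].survival_days for s in a],
        [by_sample[s].survival_days for s in b],
        event_observed_A=[int(by_sample[s].event) for s in a],
        event_observed_B=[int(by_sample[s].event) for s in b],
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass
class NullComparison:
    p_values: list[float]
    mean_p: float
    observed_p: float | None
    frac_below_observed: float | None


def random_geneset_null(
    mat: ExpressionMatrix,
    ann: Sequence[SampleAnnotation],
    network_genes: Sequence[str],
    m: int,
    reps: int = 100,
    seed: int = 0,
    module_genes: Sequence[str] | None = None,
    method: str = "average",
    metric: str = "correlation",
) -> NullComparison:
    """Monte-Carlo null for module survival signal.

    ``reps`` random size-``m`` gene sets drawn without replacement from
    the network genes are each run through clustering + log-rank; the
    resulting p-values are compared with the observed module p when
    ``module_genes`` is given.
    """
    network_genes = list(network_genes)
    if m > len(network_genes):
        raise DataError(f"m={m} exceeds the {len(network_genes)} network genes")
    observed_p = None
    if module_genes is not None:
        observed_p = cluster_two_groups(
            mat.subset_genes(list(module_genes)), ann, method=method, metric=metric
        ).p_value
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    p_values = []
    for _ in range(reps):
        genes = list(rng.choice(network_genes, size=m, replace=False))
        res = cluster_two_groups(mat.subset_genes(genes), ann, method=method, metric=metric)
        p_values.append(res.p_value)
    frac = None
    if observed_p is not None:
        frac = sum(1 for p in p_values if p < observed_p) / len(p_values)
    return NullComparison(
        p_values=p_values,
        mean_p=float(np.mean(p_values)),
        observed_p=observed_p,
        frac_below_observed=frac,
    )


# --------------------------------------------------------------------------
# SVM-RFE and re-sampling classification

def _as_xy(
    mat: ExpressionMatrix, labels: Mapping[str, str]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    samples = [s for s in mat.sample_ids if s in labels]
    idx = {s: j for j, s in enumerate(mat.sample_ids)}
    x = mat.values[:, [idx[s] for s in samples]].T  # samples x genes
    y = np.array([1 if labels[s] == POSITIVE_LABEL else 0 for s in samples])
    return x, y, samples


def svm_rfe_select(
    mat: ExpressionMatrix,
    labels: Mapping[str, str],
    n_features: int = 30,
    step_frac: float = 0.1,
    C: float = 1.0,
) -> list[str]:
    """Rank genes by recursive elimination of linear-SVM weights.

    Each round fits a linear SVM on the surviving genes and removes the
    10% (of remaining, floor 1) with smallest |weight|, ties broken by
    gene id; elimination stops when ``n_features`` genes survive, which
    are returned ordered by final |weight| descending. Training data
    only — callers must pass the training split.
    """
    x, y, _ = _as_xy(mat, labels)
    if len(set(y)) < 2 or min(np.bincount(y)) < 2:
        raise DataError("SVM-RFE needs >=2 samples in each class")
    genes = list(mat.gene_ids)
    if n_features > len(genes):
        raise DataError(f"n_features={n_features} exceeds {len(genes)} genes")
    if n_features == len(genes):
        return genes
    mu, sd = x.mean(axis=0), x.std(axis=0)
    sd[sd == 0] = 1.0
    x = (x - mu) / sd

    remaining = list(range(len(genes)))
    while len(remaining) > n_features:
        clf = SVC(kernel="linear", C=C, max_iter=_SVC_MAX_ITER)
        clf.fit(x[:, remaining], y)
        w = np.abs(clf.coef_[0])
        n_remove = min(max(1, int(step_frac * len(remaining))), len(remaining) - n_features)
        order = sorted(range(len(remaining)), key=lambda i: (w[i], genes[remaining[i]]))
        drop = {remaining[i] for i in order[:n_remove]}
        remaining = [i for i in remaining if i not in drop]
    clf = SVC(kernel="linear", C=C, max_iter=_SVC_MAX_ITER)
    clf.fit(x[:, remaining], y)
    w = np.abs(clf.coef_[0])
    ranked = sorted(range(len(remaining)), key=lambda i: (-w[i], genes[remaining[i]]))
    return [genes[remaining[i]] for i in ranked]


# libsvm can iterate almost indefinitely at huge C on non-separable data;
# the cap keeps grid search bounded without affecting well-posed fits
_SVC_MAX_ITER = 20_000


def default_svm_grid() -> list[dict]:
    """Linear and RBF SVMs over a coarse power-of-two C / gamma lattice."""
    cs = [2.0 ** e for e in range(-5, 16, 4)]
    gammas = [2.0 ** e for e in range(-15, 4, 4)]
    return [
        {"kernel": ["linear"], "C": cs},
        {"kernel": ["rbf"], "C": cs, "gamma": gammas},
    ]


@dataclass
class IterationResult:
    seed: int
    train_ids: list[str]
    valid_ids: list[str]
    selected_genes: list[str]
    best_params: dict
    cm: ConfusionMatrix
    metrics: Metrics


@dataclass
class ResamplingReport:
    per_iteration: list[IterationResult]
    averages: dict[str, float | None]

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "iteration": i,
                "tp": it.cm.tp, "tn": it.cm.tn, "fp": it.cm.fp, "fn": it.cm.fn,
                "sen": it.metrics.sen, "spc": it.metrics.spc,
                "acc": it.metrics.acc, "mcc": it.metrics.mcc,
            }
            for i, it in enumerate(self.per_iteration)
        ]
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "averages": self.averages,
            "per_iteration": [
                {
                    "seed": it.seed,
                    "train_ids": it.train_ids,
                    "valid_ids": it.valid_ids,
                    "selected_genes": it.selected_genes,
                    "best_params": it.best_params,
                    "confusion": asdict(it.cm),
                    "metrics": asdict(it.metrics),
                }
                for it in self.per_iteration
            ],
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _mean_defined(values: list[float | None]) -> float | None:
    defined = [v for v in values if v is not None]
    return float(np.mean(defined)) if defined else None


def resample_evaluate(
    mat: ExpressionMatrix,
    labels: Mapping[str, str],
    reps: int = 100,
    train_frac: float = 0.8,
    seed: int = 0,
    n_features: int = 30,
    step_frac: float = 0.1,
    param_grid: list[dict] | None = None,
    cv: int = 5,
) -> ResamplingReport:
    """Repeated re-sampling classification of high vs low risk.

    Each iteration: subsample the majority class to a 1:1 ratio, split
    4:1 into training and validation (stratified), run SVM-RFE gene
    selection on the training split only, grid-search SVM
    hyperparameters by stratified 5-fold cross-validation on the
    training split, then score the refit model on the validation split.
    Averages are arithmetic means of the per-iteration metrics (over
    iterations where the metric is defined).
    """
    if param_grid is None:
        param_grid = default_svm_grid()
    if not 0 < train_frac < 1:
        raise DataError(f"train_frac must be in (0, 1), got {train_frac}")
    pos = sorted(s for s in mat.sample_ids if labels.get(s) == POSITIVE_LABEL)
    neg = sorted(s for s in mat.sample_ids if labels.get(s) == "low")
    if len(pos) < 5 or len(neg) < 5:
        raise DataError(f"each class needs >=5 samples (high={len(pos)}, low={len(neg)})")
    n_min = min(len(pos), len(neg))
    n_train = int(round(train_frac * n_min))
    if n_train < cv or n_train >= n_min:
        raise DataError(
            f"per-class training size {n_train} incompatible with {cv}-fold CV "
            f"and a nonempty validation split (class size {n_min})"
        )
    n_feat = min(n_features, mat.n_genes)

    children = np.random.SeedSequence(seed).spawn(reps)
    iterations: list[IterationResult] = []
    for child in children:
        it_seed = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(child)
        pos_s = sorted(rng.choice(pos, size=n_min, replace=False))
        neg_s = sorted(rng.choice(neg, size=n_min, replace=False))
        train_ids, valid_ids = [], []
        for cls in (pos_s, neg_s):
            perm = list(rng.permutation(cls))
            train_ids += perm[:n_train]
            valid_ids += perm[n_train:]
        train_ids, valid_ids = sorted(train_ids), sorted(valid_ids)

        train_mat = mat.subset_samples(train_ids)
        selected = svm_rfe_select(train_mat, labels, n_features=n_feat, step_frac=step_frac)

        x_tr, y_tr, _ = _as_xy(train_mat.subset_genes(selected), labels)
        mu, sd = x_tr.mean(axis=0), x_tr.std(axis=0)
        sd[sd == 0] = 1.0
        x_tr = (x_tr - mu) / sd
        search = GridSearchCV(
            SVC(max_iter=_SVC_MAX_ITER),
            param_grid,
            scoring="accuracy",
            cv=StratifiedKFold(n_splits=cv, shuffle=True, random_state=it_seed),
            n_jobs=None,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            search.fit(x_tr, y_tr)

        valid_mat = mat.subset_samples(valid_ids).subset_genes(selected)
        x_va, y_va, va_samples = _as_xy(valid_mat, labels)
        x_va = (x_va - mu) / sd
        y_hat = search.best_estimator_.predict(x_va)
        truth = [POSITIVE_LABEL if v else "low" for v in y_va]
        pred = [POSITIVE_LABEL if v else "low" for v in y_hat]
        cm = confusion_from_predictions(truth, pred)
        iterations.append(
            IterationResult(
                seed=it_seed,
                train_ids=train_ids,
                valid_ids=valid_ids,
                selected_genes=selected,
                best_params={k: (v if isinstance(v, str) else float(v))
                             for k, v in search.best_params_.items()},
                cm=cm,
                metrics=metrics(cm),
            )
        )
    averages = {
        "sen": _mean_defined([it.metrics.sen for it in iterations]),
        "spc": _mean_defined([it.metrics.spc for it in iterations]),
        "acc": _mean_defined([it.metrics.acc for it in iterations]),
        "mcc": _mean_defined([it.metrics.mcc for it in iterations]),
    }
    return ResamplingReport(per_iteration=iterations, averages=averages)
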