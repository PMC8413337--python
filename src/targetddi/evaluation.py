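"""Classification metrics and the cross-validation / independent-test protocol.

The metric suite is computed from a 2x2 confusion matrix M with class order
(positive, negative) and M[i][j] = count of class i classified as class j.
With the per-class intermediates

    p_l = M[l,l]            (correct for class l)
    q_l = sum_{i!=l, j!=l} M[i,j]
    r_l = sum_{i!=l} M[i,l] (pulled into class l from elsewhere)
    s_l = sum_{j!=l} M[l,j] (leaked out of class l)

per-class precision, sensitivity and Matthews correlation are

    PR_l = p_l / (p_l + r_l),  SE_l = p_l / (p_l + s_l),
    MCC_l = (p_l q_l - r_l s_l) / sqrt((p_l+r_l)(p_l+s_l)(q_l+r_l)(q_l+s_l)),

overall accuracy is trace/total, overall MCC uses the pooled p, q, r, s, and
F1 is the harmonic mean of PR and SE on the positive class. Zero denominators
yield NaN (rendered "NA" in reports) rather than a silent 0.

The k-fold protocol samples negatives once (same cardinality as the
positives, uniform over unordered non-self pairs of the drug roster,
excluding known positives), stratifies pairs into k folds, and rebuilds the
gene universe per fold from training-fold drugs only so no feature
information leaks from held-out pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import classifier
from .io import (NEGATIVE, POSITIVE, DrugTargetMap, InteractionSet,
                 canonical_pair)
from .profiles import GeneUniverse, build_design_matrix, build_universe

NA = float("nan")


def _fmt(x: float) -> str:
    return "NA" if isinstance(x, float) and math.isnan(x) else f"{x:.4f}"


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts, rows = true class, columns = predicted, order (+1, -1)."""

    m: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=np.int64)
        if m.shape != (2, 2):
            raise ValueError(f"confusion matrix must be 2x2, got {m.shape}")
        if (m < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")
        object.__setattr__(self, "m", m)

    @property
    def total(self) -> int:
        return int(self.m.sum())


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("true and predicted label vectors differ in length")
    if y_true.size == 0:
        raise ValueError("cannot build a confusion matrix from empty input")
    for arr, name in ((y_true, "true"), (y_pred, "predicted")):
        bad = set(np.unique(arr).tolist()) - {POSITIVE, NEGATIVE}
        if bad:
            raise ValueError(f"{name} labels outside {{-1,+1}}: {sorted(bad)}")
    idx = {POSITIVE: 0, NEGATIVE: 1}
    m = np.zeros((2, 2), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        m[idx[int(t)], idx[int(p)]] += 1
    return ConfusionMatrix(m)


def _intermediates(cm: ConfusionMatrix) -> tuple[np.ndarray, np.ndarray,
                                                 np.ndarray, np.ndarray]:
    m = cm.m
    L = m.shape[0]
    p = np.array([m[l, l] for l in range(L)], dtype=np.float64)
    q = np.array([sum(m[i, j] for i in range(L) for j in range(L)
                      if i != l and j != l) for l in range(L)],
                 dtype=np.float64)
    r = np.array([sum(m[i, l] for i in range(L) if i != l) for l in range(L)],
                 dtype=np.float64)
    s = np.array([sum(m[l, j] for j in range(L) if j != l) for l in range(L)],
                 dtype=np.float64)
    return p, q, r, s


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else NA


def per_class_metrics(cm: ConfusionMatrix) -> dict[str, tuple[float, float]]:
    """PR_l, SE_l, MCC_l for the (positive, negative) classes."""
    p, q, r, s = _intermediates(cm)
    pr, se, mcc = [], [], []
    for l in range(2):
        pr.append(_safe_div(p[l], p[l] + r[l]))
        se.append(_safe_div(p[l], p[l] + s[l]))
        den = math.sqrt((p[l] + r[l]) * (p[l] + s[l]) *
                        (q[l] + r[l]) * (q[l] + s[l]))
        mcc.append(_safe_div(p[l] * q[l] - r[l] * s[l], den) if den > 0 else NA)
    return {"PR": tuple(pr), "SE": tuple(se), "MCC": tuple(mcc)}


def overall_metrics(cm: ConfusionMatrix) -> tuple[float, float]:
    """(accuracy, overall MCC from the pooled intermediates)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    acc = float(np.trace(cm.m)) / cm.total
    p, q, r, s = (float(v.sum()) for v in _intermediates(cm))
    den = math.sqrt((p + r) * (p + s) * (q + r) * (q + s))
    mcc = _safe_div(p * q - r * s, den) if den > 0 else NA
    return acc, mcc


def f1_positive(cm: ConfusionMatrix) -> float:
    pcm = per_class_metrics(cm)
    pr, se = pcm["PR"][0], pcm["SE"][0]
    if math.isnan(pr) or math.isnan(se):
        return NA
    return _safe_div(2.0 * pr * se, pr + se)


def roc_auc(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """Probability a random positive outscores a random negative (ties = 1/2)."""
    y_true = np.asarray(y_true, dtype=np.int64)
    if len(set(np.unique(y_true).tolist())) < 2:
        raise ValueError("ROC-AUC requires both classes present")
    return float(roc_auc_score(y_true, np.asarray(scores, dtype=np.float64)))


@dataclass(frozen=True)
class MetricsReport:
    """One evaluation's metric suite (per-class and overall)."""

    pr_pos: float
    pr_neg: float
    se_pos: float
    se_neg: float
    mcc_pos: float
    mcc_neg: float
    acc: float
    mcc: float
    auc: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


REPORT_COLUMNS = ("PR+", "PR-", "SE+", "SE-", "MCC+", "MCC-",
                  "Acc", "MCC", "AUC", "F1")
_FIELD_BY_COLUMN = dict(zip(REPORT_COLUMNS,
                            ("pr_pos", "pr_neg", "se_pos", "se_neg",
                             "mcc_pos", "mcc_neg", "acc", "mcc", "auc", "f1")))


def evaluate(y_true: Sequence[int], proba: Sequence[float],
             threshold: float = 0.5) -> MetricsReport:
    """Full metric suite from true labels and positive-class probabilities."""
    proba = np.asarray(proba, dtype=np.float64)
    y_pred = np.where(proba >= threshold, POSITIVE, NEGATIVE)
    cm = confusion(y_true, y_pred)
    pcm = per_class_metrics(cm)
    acc, mcc = overall_metrics(cm)
    return MetricsReport(
        pr_pos=pcm["PR"][0], pr_neg=pcm["PR"][1],
        se_pos=pcm["SE"][0], se_neg=pcm["SE"][1],
        mcc_pos=pcm["MCC"][0], mcc_neg=pcm["MCC"][1],
        acc=acc, mcc=mcc,
        auc=roc_auc(y_true, proba), f1=f1_positive(cm))


# ---------------------------------------------------------------------------
# Negative sampling and cross validation
# ---------------------------------------------------------------------------

def sample_negative_pairs(drugs: Sequence[str],
                          exclude: Iterable[tuple[str, str]],
                          n: int,
                          rng: np.random.Generator) -> list[tuple[str, str]]:
    """Uniformly sample *n* unordered non-self drug pairs outside *exclude*."""
    roster = sorted(set(drugs))
    d = len(roster)
    excluded = set(exclude)
    space = d * (d - 1) // 2 - len(excluded)
    if n > space:
        raise ValueError(
            f"requested {n} negative pairs but only {space} unordered pairs "
            "are available outside the excluded set")
    chosen: set[tuple[str, str]] = set()
    out: list[tuple[str, str]] = []
    # rejection sampling; the pair space is much larger than n in practice
    while len(out) < n:
        i, j = rng.integers(0, d, size=2)
        if i == j:
            continue
        pair = canonical_pair(roster[int(i)], roster[int(j)])
        if pair in excluded or pair in chosen:
            continue
        chosen.add(pair)
        out.append(pair)
    return out


def assemble_training_set(targets: DrugTargetMap, positives: InteractionSet,
                          seed: int = 0,
                          n_negatives: int | None = None,
                          exclude_pairs: Iterable[tuple[str, str]] = ()
                          ) -> InteractionSet:
    """Positives plus once-sampled negatives (default: equal cardinality).

    *exclude_pairs* keeps additional pairs (e.g. an independent test set)
    out of the sampled negatives.
    """
    positives.resolve_in(targets)
    pos_pairs = positives.pair_keys()
    if any(label != POSITIVE for label in positives.labels()):
        raise ValueError("the positive interaction set contains -1 labels")
    n = len(positives) if n_negatives is None else n_negatives
    rng = np.random.default_rng(seed)
    negatives = sample_negative_pairs(targets.drugs,
                                      pos_pairs | set(exclude_pairs), n, rng)
    records = [(a, b, POSITIVE) for a, b, _ in positives]
    records += [(a, b, NEGATIVE) for a, b in negatives]
    return InteractionSet.from_records(records)


@dataclass(frozen=True)
class CVResult:
    folds: tuple[MetricsReport, ...]
    mean: MetricsReport
    sd: MetricsReport

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, rep in enumerate(self.folds, start=1):
            rows.append({"fold": str(i), **{c: rep.as_dict()[_FIELD_BY_COLUMN[c]]
                                            for c in REPORT_COLUMNS}})
        for name, rep in (("mean", self.mean), ("sd", self.sd)):
            rows.append({"fold": name, **{c: rep.as_dict()[_FIELD_BY_COLUMN[c]]
                                          for c in REPORT_COLUMNS}})
        return pd.DataFrame(rows)

    def write(self, path: str | Path) -> None:
        df = self.to_frame()
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(df.columns) + "\n")
            for _, row in df.iterrows():
                cells = [row["fold"]] + [_fmt(row[c]) for c in REPORT_COLUMNS]
                fh.write("\t".join(cells) + "\n")


def _aggregate(reports: Sequence[MetricsReport]) -> tuple[MetricsReport,
                                                          MetricsReport]:
    names = [f.name for f in fields(MetricsReport)]
    mean = {}
    sd = {}
    for name in names:
        vals = np.array([getattr(r, name) for r in reports], dtype=np.float64)
        mean[name] = float(np.nanmean(vals)) if not np.all(np.isnan(vals)) else NA
        sd[name] = float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else NA
    return MetricsReport(**mean), MetricsReport(**sd)


def kfold_cv(targets: DrugTargetMap,
             positives: InteractionSet,
             k: int = 5,
             seed: int = 0,
             C: float = 1.0,
             threshold: float = 0.5,
             dataset: InteractionSet | None = None,
             **train_kwargs) -> CVResult:
    """Stratified k-fold cross validation with per-fold universes.

    *dataset* may supply a pre-assembled labeled pair set (e.g. with labels
    shuffled for a null control); otherwise negatives are sampled once from
    the drug roster with the given seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if dataset is None:
        dataset = assemble_training_set(targets, positives, seed=seed)
    else:
        dataset.resolve_in(targets)
    pairs = list(dataset)
    y = np.asarray(dataset.labels(), dtype=np.int64)
    counts = {c: int((y == c).sum()) for c in (POSITIVE, NEGATIVE)}
    if min(counts.values()) < k:
        raise ValueError(f"k={k} exceeds the size of the smaller class {counts}")

    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports: list[MetricsReport] = []
    for train_idx, test_idx in splitter.split(np.zeros(len(y)), y):
        train_pairs = [pairs[i] for i in train_idx]
        test_pairs = [pairs[i] for i in test_idx]
        train_drugs = sorted({d for a, b, _ in train_pairs for d in (a, b)})
        universe = build_universe(targets, train_drugs)
        X_tr, y_tr = build_design_matrix(train_pairs, targets, universe)
        X_te, y_te = build_design_matrix(test_pairs, targets, universe)
        model = classifier.train(X_tr, y_tr, C=C, universe=universe,
                                 seed=seed, **train_kwargs)
        proba = classifier.predict_proba(model, X_te, universe)
        reports.append(evaluate(y_te, proba, threshold=threshold))
    mean, sd = _aggregate(reports)
    return CVResult(tuple(reports), mean, sd)


def independent_recall(model: classifier.TrainedModel,
                       universe: GeneUniverse,
                       test_pairs: InteractionSet,
                       targets: DrugTargetMap,
                       training_pairs: InteractionSet,
                       threshold: float = 0.5) -> float:
    """Fraction of a single-class external test set recovered by the model.

    The test set must be disjoint from the training pairs; overlap is an
    error (it would inflate the recall estimate).
    """
    if len(test_pairs) == 0:
        raise ValueError("empty independent test set")
    labels = set(test_pairs.labels())
    if len(labels) != 1:
        raise ValueError("independent recall is defined for a single-class "
                         "test set (all +1 or all -1)")
    overlap = sorted(test_pairs.pair_keys() & training_pairs.pair_keys())
    if overlap:
        raise ValueError(
            f"test pairs overlap the training set: {overlap[:10]}"
            + (" ..." if len(overlap) > 10 else ""))
    test_pairs.resolve_in(targets)
    X, y = build_design_matrix(test_pairs, targets, universe)
    predicted = classifier.classify(model, X, threshold=threshold,
                                    universe=universe)
    return float(np.mean(predicted == y))
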