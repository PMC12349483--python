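"""Repeated stratified-split evaluation, metrics, and paired statistical
comparison of configurations.

The protocol: for each of ``n_runs`` runs, stratify the trials into a 70%
training / 30% testing split (per-class rounding, split seed =
``base_seed + r``), train on the training subset only, evaluate once on the
held-out subset, and aggregate accuracy, weighted F1 and macro-averaged
one-vs-rest AUC as mean +/- SD across runs.  Two configurations evaluated
on the same seed schedule are compared pairwise: Shapiro-Wilk decides
normality of both metric vectors at alpha, gating a paired t-test versus a
Wilcoxon signed-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import f1_score, roc_auc_score, roc_curve

from .containers import FunctionalTrialSet, N_CLASSES

__all__ = [
    "RunMetrics",
    "ComparisonResult",
    "EvaluationResult",
    "stratified_split",
    "weighted_f1",
    "one_vs_rest_auc",
    "repeated_evaluation",
    "compare_configurations",
    "leakage_overlap",
]


def stratified_split(labels, train_fraction: float, seed: int):
    """Per-class stratified train/test indices.

    Train counts are round-half-up of ``train_fraction * N_c`` per class
    (clipped so both sides keep at least one trial), with any remainder
    against the overall rounded total adjusted on the largest class.
    """
    labels = np.asarray(labels)
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 2):
        raise ValueError("every class needs at least two trials")
    n_train = {c: int(np.floor(train_fraction * n + 0.5))
               for c, n in zip(classes, counts)}
    for c, n in zip(classes, counts):
        n_train[c] = min(max(n_train[c], 1), n - 1)
    target_total = int(np.floor(train_fraction * labels.size + 0.5))
    largest = classes[np.argmax(counts)]
    diff = target_total - sum(n_train.values())
    n_large = counts[np.argmax(counts)]
    n_train[largest] = min(max(n_train[largest] + diff, 1), n_large - 1)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        train_idx.append(idx[: n_train[c]])
        test_idx.append(idx[n_train[c]:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def grouped_split(labels, groups, train_fraction: float, seed: int):
    """Per-group (e.g. per-subject) train/test split, off by default in the
    shipped protocol: whole groups are assigned to one side, stratifying
    groups by their majority class.  Guards against within-subject leakage
    at the cost of coarser stratification."""
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    uniq = np.unique(groups)
    maj = np.array([np.bincount(labels[groups == g]).argmax() for g in uniq])
    g_train, _ = stratified_split(maj, train_fraction, seed)
    train_groups = set(uniq[g_train])
    in_train = np.array([g in train_groups for g in groups])
    return np.flatnonzero(in_train), np.flatnonzero(~in_train)


def weighted_f1(y_true, y_pred) -> float:
    """Per-class F1 averaged with weights proportional to class prevalence
    in ``y_true``; degenerate per-class F1 counts as 0."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    return float(f1_score(y_true, y_pred, labels=list(range(N_CLASSES)),
                          average="weighted", zero_division=0))


def one_vs_rest_auc(y_true, probs) -> float:
    """Unweighted mean over classes of the one-vs-rest ROC AUC (midrank tie
    handling); classes absent from ``y_true`` are skipped with a warning."""
    y_true = np.asarray(y_true)
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 2 or probs.shape != (y_true.size, N_CLASSES):
        raise ValueError("probs must be n x 3")
    if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("probability rows must sum to 1")
    aucs = []
    for c in range(N_CLASSES):
        pos = y_true == c
        if pos.all() or not pos.any():
            warnings.warn(f"class {c} absent from y_true; skipped in AUC")
            continue
        aucs.append(roc_auc_score(pos, probs[:, c]))
    return float(np.mean(aucs))


@dataclass(frozen=True)
class RunMetrics:
    run_id: int
    accuracy: float
    weighted_f1: float
    auc: float
    per_class_precision: tuple
    per_class_recall: tuple
    split_seed: int


@dataclass
class EvaluationResult:
    per_run: pd.DataFrame
    summary: dict
    roc_best: dict
    best_run: int
    splits: list = field(default_factory=list)
    failures: list = field(default_factory=list)


def _default_fit(train_set: FunctionalTrialSet, seed: int, model_spec, cfg):
    from dataclasses import replace

    from .training import train_model

    model, _ = train_model(train_set, model_spec, replace(cfg, seed=seed))
    return model


def repeated_evaluation(dataset: FunctionalTrialSet, model_spec=None, cfg=None,
                        n_runs: int = 100, base_seed: int = 0,
                        train_fraction: float = 0.7,
                        fit=None) -> EvaluationResult:
    """Run the repeated stratified-split protocol.

    ``fit(train_set, seed)`` must return an object with a
    ``predict(trial_set) -> (labels, probs)`` method; by default the
    Multi-AdaFNN is trained with ``cfg`` reseeded per run.  Run r uses split
    seed ``base_seed + r``.  The ROC coordinates of the run with the highest
    weighted F1 are kept for plotting.
    """
    if fit is None:
        if model_spec is None or cfg is None:
            raise ValueError("either pass fit= or both model_spec and cfg")

        def fit(train_set, seed):
            return _default_fit(train_set, seed, model_spec, cfg)

    rows, splits, failures = [], [], []
    best_f1, best_run, roc_best = -np.inf, -1, {}
    for r in range(n_runs):
        split_seed = base_seed + r
        tr, te = stratified_split(dataset.labels, train_fraction, split_seed)
        splits.append((tr, te))
        try:
            model = fit(dataset.subset(tr), split_seed)
            pred, probs = model.predict(dataset.subset(te))
        except (FloatingPointError, ValueError) as exc:  # recorded, not fatal
            failures.append((r, repr(exc)))
            continue
        y = dataset.labels[te]
        prec, rec = [], []
        for c in range(N_CLASSES):
            tp = np.sum((pred == c) & (y == c))
            prec.append(tp / max(np.sum(pred == c), 1))
            rec.append(tp / max(np.sum(y == c), 1))
        m = RunMetrics(
            run_id=r,
            accuracy=float(np.mean(pred == y)),
            weighted_f1=weighted_f1(y, pred),
            auc=one_vs_rest_auc(y, probs),
            per_class_precision=tuple(prec),
            per_class_recall=tuple(rec),
            split_seed=split_seed,
        )
        rows.append(m.__dict__)
        if m.weighted_f1 > best_f1:
            best_f1, best_run = m.weighted_f1, r
            roc_best = {}
            for c in range(N_CLASSES):
                pos = y == c
                if pos.any() and not pos.all():
                    fpr, tpr, _ = roc_curve(pos, probs[:, c])
                    roc_best[c] = (fpr, tpr)
    per_run = pd.DataFrame(rows)
    summary = {"n_runs": n_runs, "completed": len(rows),
               "incomplete": len(failures) > 0}
    for metric in ("accuracy", "weighted_f1", "auc"):
        vals = per_run[metric].to_numpy() if len(rows) else np.array([])
        summary[f"{metric}_mean"] = float(np.mean(vals)) if vals.size else np.nan
        summary[f"{metric}_sd"] = (
            float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan
        )
    return EvaluationResult(per_run, summary, roc_best, best_run, splits,
                            failures)


def leakage_overlap(result: EvaluationResult) -> int:
    """Total number of indices shared between train and test across runs."""
    return sum(np.intersect1d(tr, te).size for tr, te in result.splits)


@dataclass(frozen=True)
class ComparisonResult:
    pair: tuple
    normality_p: tuple
    test_used: str
    statistic: float
    p_value: float
    alpha: float
    significant: bool


def compare_configurations(metrics_a, metrics_b, alpha: float = 0.05,
                           pair=("a", "b")) -> ComparisonResult:
    """Shapiro-Wilk-gated paired comparison of per-run metric vectors.

    If both vectors pass Shapiro-Wilk at ``alpha`` the paired two-sided
    t-test is used; otherwise the Wilcoxon signed-rank test on the paired
    differences.  Identically-zero differences are a degenerate case
    reported as "no difference".
    """
    a = np.asarray(metrics_a, dtype=np.float64)
    b = np.asarray(metrics_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired metric vectors must have equal length")
    p_a = stats.shapiro(a).pvalue
    p_b = stats.shapiro(b).pvalue
    diffs = b - a
    if np.all(diffs == 0.0):
        return ComparisonResult(tuple(pair), (p_a, p_b), "degenerate",
                                np.nan, 1.0, alpha, False)
    if p_a > alpha and p_b > alpha:
        res = stats.ttest_rel(a, b)
        used = "paired_t"
    else:
        res = stats.wilcoxon(a, b)
        used = "wilcoxon_signed_rank"
    return ComparisonResult(tuple(pair), (p_a, p_b), used,
                            float(res.statistic), float(res.pvalue), alpha,
                            bool(res.pvalue < alpha))
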