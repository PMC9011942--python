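"""Classification metrics, ROC AUC with DeLong confidence intervals, and the
training-size ablation harness.

AUC is the Mann–Whitney statistic (ties get half credit).  The DeLong
variance uses the placement-value structural components with midranks, so it
runs in O(n log n); an independent brute-force oracle lives in the test
suite.  Undefined metrics (0/0) are reported as ``None``, never coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm, rankdata

from . import attention_rnn as arnn


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    accuracy: float | None
    precision: float | None
    recall: float | None
    f1: float | None


@dataclass(frozen=True)
class RocResult:
    auc: float
    delong_variance: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    alpha: float = 0.05
    n_pos: int = 0
    n_neg: int = 0


def confusion(truth: Sequence[int], predicted: Sequence[int]) -> ConfusionCounts:
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError(f"length mismatch: {truth.shape} vs {predicted.shape}")
    tp = int(np.sum((truth == 1) & (predicted == 1)))
    fp = int(np.sum((truth == 0) & (predicted == 1)))
    tn = int(np.sum((truth == 0) & (predicted == 0)))
    fn = int(np.sum((truth == 1) & (predicted == 0)))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(c: ConfusionCounts) -> MetricSet:
    """Accuracy = (TP+TN)/total, precision = TP/(TP+FP), recall = TP/(TP+FN),
    F1 = harmonic mean of precision and recall; 0/0 cases are None."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    accuracy = (c.tp + c.tn) / c.total
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return MetricSet(accuracy=accuracy, precision=precision, recall=recall, f1=f1)


def _placements(scores: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    m, n = len(pos), len(neg)
    all_ranks = rankdata(np.concatenate([pos, neg]))
    # fraction of negatives scored below each positive (ties half credit)
    v01 = (all_ranks[:m] - rankdata(pos)) / n
    # fraction of positives scored above each negative
    v10 = 1.0 - (all_ranks[m:] - rankdata(neg)) / m
    return v01, v10


def roc_auc(scores: Sequence[float], truth: Sequence[int]) -> RocResult:
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth)
    m = int(np.sum(truth == 1))
    n = int(np.sum(truth == 0))
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    v01, _ = _placements(scores, truth)
    return RocResult(auc=float(v01.mean()), n_pos=m, n_neg=n)


def delong_ci(
    scores: Sequence[float], truth: Sequence[int], alpha: float = 0.05
) -> RocResult:
    """AUC with DeLong variance and the (1 - alpha) normal-approximation CI."""
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth)
    m = int(np.sum(truth == 1))
    n = int(np.sum(truth == 0))
    if m < 2 or n < 2:
        raise ValueError(f"need >= 2 per class, got {m} positives / {n} negatives")
    v01, v10 = _placements(scores, truth)
    auc = float(v01.mean())
    variance = float(np.var(v01, ddof=1) / m + np.var(v10, ddof=1) / n)
    z = norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(max(variance, 0.0))
    return RocResult(
        auc=auc,
        delong_variance=variance,
        ci_low=float(np.clip(auc - half, 0.0, 1.0)),
        ci_high=float(np.clip(auc + half, 0.0, 1.0)),
        alpha=alpha,
        n_pos=m,
        n_neg=n,
    )


def per_label_roc(
    scores: np.ndarray, truth: np.ndarray, label_names: Sequence[str],
    alpha: float = 0.05,
) -> dict[str, RocResult | None]:
    """DeLong AUC per label column; single-class labels come back as None."""
    out: dict[str, RocResult | None] = {}
    for j, name in enumerate(label_names):
        try:
            out[name] = delong_ci(scores[:, j], truth[:, j], alpha=alpha)
        except ValueError:
            out[name] = None
    return out


# ---------------------------------------------------------------------------
# training-size ablation

@dataclass
class AblationResult:
    fractions: tuple[float, ...]
    results: dict[float, dict[str, RocResult | None]] = field(default_factory=dict)

    def to_rows(self) -> list[dict[str, object]]:
        rows = []
        for fraction in self.fractions:
            for label, roc in self.results[fraction].items():
                row: dict[str, object] = {"fraction": fraction, "label": label}
                if roc is None:
                    row.update(auc=None, ci_low=None, ci_high=None, n_pos=None)
                else:
                    row.update(
                        auc=roc.auc, ci_low=roc.ci_low, ci_high=roc.ci_high,
                        n_pos=roc.n_pos,
                    )
                rows.append(row)
        return rows


def ablate(
    X_pool: np.ndarray,
    y_pool: np.ndarray,
    subjects_pool: Sequence[str],
    X_val: np.ndarray,
    y_val: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    label_names: Sequence[str],
    config: "arnn.ModelConfig",
    fractions: Sequence[float] = (0.2, 0.4, 0.6, 0.8, 1.0),
    seed: int = 0,
    nested: bool = True,
) -> AblationResult:
    """Train at increasing training-pool fractions and measure per-label AUC.

    Subsampling is by subject so the subject-wise discipline of the main
    split carries over; with ``nested`` (default) smaller fractions are
    subsets of larger ones, otherwise each fraction is an independent draw.
    """
    for f in fractions:
        if not 0.0 < f <= 1.0:
            raise ValueError(f"fraction {f} outside (0, 1]")
    subjects_pool = np.asarray(subjects_pool)
    unique_subjects = sorted(set(subjects_pool.tolist()))
    rng = np.random.default_rng(seed)
    base_order = rng.permutation(unique_subjects)
    result = AblationResult(fractions=tuple(fractions))
    for fraction in fractions:
        k = max(int(round(fraction * len(unique_subjects))), 1)
        if nested:
            chosen = set(base_order[:k].tolist())
        else:
            chosen = set(rng.permutation(unique_subjects)[:k].tolist())
        take = np.isin(subjects_pool, list(chosen))
        X_frac, y_frac = X_pool[take], y_pool[take]
        per_label: dict[str, RocResult | None] = {}
        try:
            pos_weight = arnn.class_weights(y_frac)
        except ValueError:
            pos_weight = None
        if pos_weight is None:
            # some label is degenerate at this fraction: weight evaluable
            # labels only, mark the rest unevaluable afterwards
            counts = y_frac.sum(axis=0)
            safe = np.clip((len(y_frac) - counts), 1, None) / np.clip(counts, 1, None)
            pos_weight = np.clip(safe, 1.0, 50.0)
        model = arnn.build_model(config)
        arnn.train(model, X_frac, y_frac, X_val, y_val, pos_weight=pos_weight)
        probs = model.predict_ids(X_test)
        per_label = per_label_roc(probs, y_test, label_names)
        counts = y_frac.sum(axis=0)
        for j, name in enumerate(label_names):
            if counts[j] == 0:
                per_label[name] = None
        result.results[fraction] = per_label
    return result


def plot_ablation(result: AblationResult, path: str, title: str = "") -> None:
    """AUC vs training fraction with CI error bars, one line per label."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = list(next(iter(result.results.values())).keys())
    fig, ax = plt.subplots(figsize=(6, 4))
    for label in labels:
        xs, ys, lo, hi = [], [], [], []
        for fraction in result.fractions:
            roc = result.results[fraction][label]
            if roc is None:
                continue
            xs.append(fraction)
            ys.append(roc.auc)
            lo.append(roc.auc - (roc.ci_low if roc.ci_low is not None else roc.auc))
            hi.append((roc.ci_high if roc.ci_high is not None else roc.auc) - roc.auc)
        if xs:
            ax.errorbar(xs, ys, yerr=[lo, hi], marker="o", capsize=3, label=label)
    ax.set_xlabel("training fraction")
    ax.set_ylabel("AUC")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
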