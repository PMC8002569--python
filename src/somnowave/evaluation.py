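"""Cross-validated evaluation and agreement metrics.

The protocol mirrors the study: stratified 10-fold cross-validation
repeated five times with reshuffled folds; the per-trial accuracy is
the mean over folds, and trials are aggregated as mean +/- population
standard deviation (divide by n, not n-1 -- this is what reproduces
the study's printed spreads, e.g. trial accuracies 76.26, 77.66,
79.06, 79.66, 78.86 -> 78.3 +/- 1.21).  Cohen's kappa is computed per
trial from the trial's pooled predictions and aggregated the same way.

Confusion matrices use the fixed class order (W, S1, S2, S3, S4, REM)
with true classes on rows; the row-percent view divides each row by
its row sum.  "Individual per-stage accuracy" is one-vs-rest accuracy:
(TP + TN) / total after collapsing the matrix to stage-versus-rest,
which is how per-stage figures like 95.84% for wake coexist with a
68.8% wake row diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skm
from sklearn.model_selection import StratifiedKFold

from .ensemble import _decode, _encode, make_bagging
from .stages import STAGES


@dataclass
class ConfusionMatrix:
    """6x6 count matrix, rows = true stage, columns = predicted."""

    counts: np.ndarray
    classes: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"expected {k}x{k} counts, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        counts = skm.confusion_matrix(list(y_true), list(y_pred), labels=list(STAGES))
        return cls(counts=counts)

    @classmethod
    def from_row_percent(cls, row_percent, row_totals) -> "ConfusionMatrix":
        """Reconstruct counts from a printed row-percent table.

        Printed rows rarely sum to exactly 100 after rounding.  The
        diagonal cell is taken at its printed share of the row total
        (it drives every metric of interest); the off-diagonal cells
        absorb the remaining mass by largest-remainder rounding, so
        every row sums exactly to its stated total.
        """
        rp = np.asarray(row_percent, dtype=float)
        totals = np.asarray(row_totals)
        counts = np.zeros_like(rp, dtype=int)
        for i, (row, total) in enumerate(zip(rp, totals)):
            total = int(total)
            diag = int(np.rint(row[i] / 100.0 * total))
            off_idx = [j for j in range(len(row)) if j != i]
            off = row[off_idx]
            remaining = total - diag
            if off.sum() > 0:
                exact = off / off.sum() * remaining
            else:
                exact = np.zeros_like(off)
            base = np.floor(exact).astype(int)
            short = remaining - base.sum()
            order = np.argsort(-(exact - base))
            base[order[:short]] += 1
            counts[i, off_idx] = base
            counts[i, i] = diag
        return cls(counts=counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_percent(self) -> np.ndarray:
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        sums[sums == 0] = 1.0
        return 100.0 * self.counts / sums

    def to_frame(self, percent: bool = False) -> pd.DataFrame:
        data = self.row_percent() if percent else self.counts
        return pd.DataFrame(data, index=list(self.classes), columns=list(self.classes))

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts, self.classes)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """100 x trace / total."""
    if cm.total == 0:
        return 0.0
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def per_class_ovr_accuracy(cm: ConfusionMatrix, stage: str) -> float:
    """One-vs-rest accuracy of ``stage`` in percent: (TP + TN) / total."""
    i = cm.classes.index(stage)
    tp = cm.counts[i, i]
    tn = cm.total - cm.counts[i, :].sum() - cm.counts[:, i].sum() + tp
    if cm.total == 0:
        return 0.0
    return 100.0 * float(tp + tn) / cm.total


def f1_per_class(cm: ConfusionMatrix, stage: str) -> float:
    """Harmonic mean of precision and recall; 0 when undefined."""
    i = cm.classes.index(stage)
    tp = float(cm.counts[i, i])
    fp = float(cm.counts[:, i].sum()) - tp
    fn = float(cm.counts[i, :].sum()) - tp
    denom = 2 * tp + fp + fn
    return 0.0 if denom == 0 else 2 * tp / denom


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e)."""
    n = cm.total
    if n == 0:
        return 0.0
    counts = cm.counts.astype(float)
    p_o = np.trace(counts) / n
    p_e = float(counts.sum(axis=1) @ counts.sum(axis=0)) / n**2
    if p_e >= 1.0:
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def aggregate_trials(values) -> tuple[float, float]:
    """Mean and *population* standard deviation of per-trial values."""
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=0))


def roc_ovr(scores: np.ndarray, y_true) -> dict[str, dict]:
    """One-vs-rest ROC curve and trapezoid AUC per stage.

    ``scores`` has one column per stage in canonical order.  Stages
    absent from ``y_true`` are skipped.
    """
    scores = np.asarray(scores, dtype=float)
    codes = _encode(y_true)
    out: dict[str, dict] = {}
    for i, stage in enumerate(STAGES):
        pos = codes == i
        if pos.all() or not pos.any():
            continue
        fpr, tpr, thr = skm.roc_curve(pos.astype(int), scores[:, i])
        out[stage] = {"fpr": fpr, "tpr": tpr, "auc": float(skm.auc(fpr, tpr))}
    return out


@dataclass
class CVResult:
    """Aggregated repeated-CV metrics."""

    per_trial_accuracy: list[float]
    mean_accuracy: float
    std_accuracy: float
    per_trial_kappa: list[float]
    kappa_mean: float
    kappa_error: float
    confusion: ConfusionMatrix  # pooled over folds and trials
    per_class: pd.DataFrame  # ovr accuracy, F1, AUC per stage
    auc: dict[str, float] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"accuracy = {self.mean_accuracy:.1f} +/- {self.std_accuracy:.2f} %",
            f"kappa    = {self.kappa_mean:.4f} +/- {self.kappa_error:.4f}",
        ]
        return "\n".join(lines)


def repeated_cv(
    X,
    y,
    n_learners: int = 50,
    max_splits: int | None = None,
    k: int = 10,
    trials: int = 5,
    seed: int = 0,
    train_balance_target: int | None = None,
) -> CVResult:
    """Repeated stratified k-fold CV of the bagged-tree classifier.

    Every class must have at least ``k`` members (stratified folds need
    one per fold).  Folds are reshuffled per trial from ``seed``.  When
    ``train_balance_target`` is set, each training fold is resampled to
    that many epochs per class before fitting (leakage-free "strict"
    balancing); the test fold is never resampled.
    """
    X = np.asarray(X, dtype=float)
    codes = _encode(y)
    present, counts = np.unique(codes, return_counts=True)
    small = [STAGES[c] for c, n in zip(present, counts) if n < k]
    if small:
        raise ValueError(
            f"classes {small} have fewer than k={k} members; reduce k, merge data "
            "or balance the classes first"
        )

    per_trial_acc: list[float] = []
    per_trial_kappa: list[float] = []
    pooled = ConfusionMatrix(np.zeros((len(STAGES), len(STAGES)), dtype=int))
    all_scores = []
    all_true = []
    for t in range(trials):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=(seed + 7919 * t) & 0x7FFFFFFF)
        fold_acc = []
        trial_cm = ConfusionMatrix(np.zeros((len(STAGES), len(STAGES)), dtype=int))
        for fold_id, (tr, te) in enumerate(skf.split(X, codes)):
            if train_balance_target is not None:
                from .balancing import BalanceSpec, _balanced_indices

                sub = _balanced_indices(
                    [STAGES[c] for c in codes[tr]],
                    BalanceSpec(train_balance_target,
                                seed=seed + 7919 * t + 101 * fold_id),
                )
                tr = tr[sub]
            est = make_bagging(n_learners, max_splits,
                               seed + 7919 * t + 101 * fold_id)
            est.fit(X[tr], codes[tr])
            pred = est.predict(X[te])
            fold_acc.append(100.0 * float(np.mean(pred == codes[te])))
            cm = ConfusionMatrix.from_predictions(_decode(codes[te]), _decode(pred))
            trial_cm = trial_cm + cm
            proba = np.zeros((len(te), len(STAGES)))
            p = est.predict_proba(X[te])
            for j, cls in enumerate(est.classes_):
                proba[:, int(cls)] = p[:, j]
            all_scores.append(proba)
            all_true.extend(_decode(codes[te]))
        per_trial_acc.append(float(np.mean(fold_acc)))
        per_trial_kappa.append(cohens_kappa(trial_cm))
        pooled = pooled + trial_cm

    mean_acc, std_acc = aggregate_trials(per_trial_acc)
    kappa_mean, kappa_err = aggregate_trials(per_trial_kappa)
    roc = roc_ovr(np.vstack(all_scores), all_true)
    per_class = pd.DataFrame(
        {
            "ovr_accuracy": [per_class_ovr_accuracy(pooled, s) for s in STAGES],
            "f1": [f1_per_class(pooled, s) for s in STAGES],
            "auc": [roc.get(s, {}).get("auc", float("nan")) for s in STAGES],
        },
        index=list(STAGES),
    )
    return CVResult(
        per_trial_accuracy=per_trial_acc,
        mean_accuracy=mean_acc,
        std_accuracy=std_acc,
        per_trial_kappa=per_trial_kappa,
        kappa_mean=kappa_mean,
        kappa_error=kappa_err,
        confusion=pooled,
        per_class=per_class,
        auc={s: d["auc"] for s, d in roc.items()},
    )
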