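"""Outcome dichotomization, classification metrics and cohort statistics.

The positive class for F1 and the confusion matrix is the unfavourable
outcome (the alarm class). The decision rule at the patient level is
strict: a mean score must exceed the threshold to be called unfavourable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .types import OUTCOME_FAV, OUTCOME_UNFAV

__all__ = ["EvalReport", "dichotomize", "classification_report", "cohort_compare"]


@dataclass
class EvalReport:
    """Patient-level classification summary at a fixed threshold."""

    auc: float
    accuracy: float
    f1: float
    confusion: np.ndarray  # rows: true (fav, unfav); cols: predicted
    n_patients: int
    threshold: float

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "confusion": self.confusion.tolist(),
            "n_patients": self.n_patients,
            "threshold": self.threshold,
        }


def dichotomize(scale: str, value: int) -> str:
    """Dichotomize an outcome score: GOS 4-5 / GOS-E 5-8 are favourable."""
    scale = scale.upper().replace("-", "")
    if scale == "GOS":
        if not 1 <= value <= 5:
            raise ValueError(f"GOS must be in 1-5, got {value}")
        return OUTCOME_FAV if value >= 4 else OUTCOME_UNFAV
    if scale == "GOSE":
        if not 1 <= value <= 8:
            raise ValueError(f"GOS-E must be in 1-8, got {value}")
        return OUTCOME_FAV if value >= 5 else OUTCOME_UNFAV
    raise ValueError(f"unknown outcome scale {scale!r}")


def classification_report(
    scores: Sequence[float],
    labels: Sequence[str],
    threshold: float = 0.5,
) -> EvalReport:
    """AUC (rank statistic, ties averaged), accuracy, F1 and confusion.

    Scores are P(unfavourable); predicted unfavourable iff score > threshold
    (strict). F1 is computed for the unfavourable class.
    """
    scores = np.asarray(scores, float)
    y = np.asarray([1 if lab == OUTCOME_UNFAV else 0 for lab in labels])
    if scores.size == 0:
        raise ValueError("empty input")
    auc = float(roc_auc_score(y, scores)) if len(np.unique(y)) == 2 else float("nan")
    pred = (scores > threshold).astype(int)
    conf = np.zeros((2, 2), dtype=int)
    for t, p in zip(y, pred):
        conf[t, p] += 1
    tp = conf[1, 1]
    fp = conf[0, 1]
    fn = conf[1, 0]
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    acc = conf.trace() / conf.sum()
    return EvalReport(
        auc=auc, accuracy=float(acc), f1=float(f1), confusion=conf,
        n_patients=len(y), threshold=threshold,
    )


def _fmt_med_iqr(x: np.ndarray) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.2f} ({q1:.2f}-{q3:.2f})"


def cohort_compare(
    features: pd.DataFrame,
    label_col: str = "label",
    continuous: Optional[Sequence[str]] = None,
    categorical: Sequence[str] = (),
    exact_n_threshold: int = 8,
) -> pd.DataFrame:
    """Per-variable class comparison: median (Q1-Q3) per class and p-values.

    Continuous variables: Shapiro-Wilk normality per class is recorded and
    medians compared by the two-sided Mann-Whitney U test (exact when both
    groups have <= ``exact_n_threshold`` patients, asymptotic otherwise).
    Categorical variables: Pearson chi-squared, falling back to Fisher's
    exact test when any expected cell count is below 5. Alpha = 0.05 by
    field convention; no multiplicity correction is applied.
    """
    labels = features[label_col]
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError("need exactly two outcome classes")
    groups = {c: features[labels == c] for c in classes}
    if any(len(g) < 2 for g in groups.values()):
        raise ValueError("need >= 2 patients per class")
    if continuous is None:
        continuous = [
            c for c in features.columns
            if c != label_col and c not in categorical
            and np.issubdtype(features[c].dtype, np.number)
        ]

    rows: List[dict] = []
    for col in continuous:
        a = groups[classes[0]][col].dropna().to_numpy(float)
        b = groups[classes[1]][col].dropna().to_numpy(float)
        method = "exact" if max(len(a), len(b)) <= exact_n_threshold else "asymptotic"
        u = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        sw_p = min(
            stats.shapiro(a).pvalue if len(a) >= 3 else np.nan,
            stats.shapiro(b).pvalue if len(b) >= 3 else np.nan,
        )
        rows.append({
            "variable": col,
            classes[0]: _fmt_med_iqr(a),
            classes[1]: _fmt_med_iqr(b),
            "test": f"mann-whitney ({method})",
            "p_value": float(u.pvalue),
            "shapiro_min_p": float(sw_p),
        })
    for col in categorical:
        tab = pd.crosstab(features[col], labels)
        chi2 = stats.chi2_contingency(tab.to_numpy())
        if (chi2.expected_freq < 5).any() and tab.shape == (2, 2):
            p = float(stats.fisher_exact(tab.to_numpy()).pvalue)
            test = "fisher exact"
        else:
            p = float(chi2.pvalue)
            test = "chi-squared"
        counts = {
            c: " / ".join(str(v) for v in tab[c].tolist()) for c in classes
        }
        rows.append({
            "variable": col, **counts, "test": test, "p_value": p,
            "shapiro_min_p": np.nan,
        })
    return pd.DataFrame(rows)


def render_roc(scores, labels, path) -> None:
    """ROC curve PNG for a score/label set."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    y = np.asarray([1 if lab == OUTCOME_UNFAV else 0 for lab in labels])
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, float))
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr, lw=2, label=f"AUC = {roc_auc_score(y, scores):.2f}")
    ax.plot([0, 1], [0, 1], "k--", lw=1)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
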