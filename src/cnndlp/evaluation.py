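"""Ranking metrics and method comparison.

AUC is the area under the ROC curve with ties counted as half-concordant
(equivalently the Mann-Whitney statistic); AUPR uses the step-wise
precision convention (no linear interpolation), the conservative choice
under heavy class imbalance. Recall@k is the fraction of all true
positives appearing among the top-k ranked candidates. All three are
computed per disease over that disease's test pairs and averaged
unweighted over diseases with at least one test positive; pooled values
over all pairs are reported alongside, since candidate lists are screened
per disease but a pooled number summarizes the whole matrix.

Method comparison uses the two-sided paired Wilcoxon signed-rank test on
per-disease metric differences (exact null for n <= 25 after dropping
zeros, normal approximation above).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "EvalReport",
    "roc_auc",
    "pr_aupr",
    "recall_at_k",
    "paired_wilcoxon",
    "per_disease_report",
]

DEFAULT_KS = (30, 60, 90, 120, 240)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve; ties count as 0.5 concordance."""
    scores, labels = _as_arrays(scores, labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("roc_auc requires at least one positive and one negative")
    return float(roc_auc_score(labels, scores))


def pr_aupr(scores, labels) -> float:
    """Area under the precision-recall curve (step-wise precision)."""
    scores, labels = _as_arrays(scores, labels)
    if labels.sum() < 1:
        raise ValueError("pr_aupr requires at least one positive")
    return float(average_precision_score(labels, scores))


def recall_at_k(ranked_labels, k: int) -> float:
    """Fraction of all positives found in the top k of a ranked label list."""
    if k < 1:
        raise ValueError("k must be >= 1")
    labels = np.asarray(ranked_labels, float)
    total = labels.sum()
    if total == 0:
        return float("nan")
    return float(labels[:k].sum() / total)


def paired_wilcoxon(metric_a, metric_b) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test on per-disease metrics.

    Zero differences are dropped; exact p-values for n <= 25 surviving
    pairs, normal approximation above. All-zero differences give p = 1
    with a warning.
    """
    a, b = np.asarray(metric_a, float), np.asarray(metric_b, float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 5:
        raise ValueError("need equal-length 1-D metric vectors of length >= 5")
    diffs = a - b
    nonzero = diffs[diffs != 0]
    if len(nonzero) == 0:
        warnings.warn("all paired differences are zero; test is uninformative")
        return 0.0, 1.0
    method = "exact" if len(nonzero) <= 25 else "approx"
    res = stats.wilcoxon(nonzero, zero_method="wilcox", alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclasses.dataclass
class EvalReport:
    """Per-disease and averaged metrics with fold provenance."""

    per_disease: pd.DataFrame  # columns: fold, disease, n_pos, n_neg, auc, aupr, recall@k...
    averaged: dict[str, float]
    pooled: dict[str, float]
    ks: tuple[int, ...]
    seed: int
    n_folds: int

    def to_dict(self) -> dict:
        return {
            "averaged": self.averaged,
            "pooled": self.pooled,
            "ks": list(self.ks),
            "seed": self.seed,
            "n_folds": self.n_folds,
            "per_disease": self.per_disease.to_dict(orient="records"),
        }


def per_disease_report(
    diseases: np.ndarray,
    scores: np.ndarray,
    labels: np.ndarray,
    ks: tuple[int, ...] = DEFAULT_KS,
    fold: int = 0,
) -> pd.DataFrame:
    """Metrics per disease over that disease's column of test pairs.

    Diseases with no test positive are skipped (their AUC/AUPR are
    undefined); AUC additionally needs one negative.
    """
    diseases = np.asarray(diseases)
    rows = []
    for d in np.unique(diseases):
        mask = diseases == d
        s, y = np.asarray(scores)[mask], np.asarray(labels)[mask]
        if y.sum() == 0:
            continue
        order = np.argsort(-s, kind="stable")
        ranked = y[order]
        row: dict = {
            "fold": fold,
            "disease": d,
            "n_pos": int(y.sum()),
            "n_neg": int(len(y) - y.sum()),
            "aupr": pr_aupr(s, y),
        }
        row["auc"] = roc_auc(s, y) if row["n_neg"] > 0 else np.nan
        for k in ks:
            row[f"recall@{k}"] = recall_at_k(ranked, k)
        rows.append(row)
    return pd.DataFrame(rows)


def summarize(
    per_disease: pd.DataFrame,
    diseases: np.ndarray,
    scores: np.ndarray,
    labels: np.ndarray,
    ks: tuple[int, ...],
    seed: int,
    n_folds: int,
) -> EvalReport:
    """Average the per-disease table and add pooled all-pair metrics."""
    metric_cols = [c for c in per_disease.columns if c not in ("fold", "disease", "n_pos", "n_neg")]
    averaged = {c: float(per_disease[c].mean()) for c in metric_cols}
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    pooled = {
        "auc": roc_auc(scores, labels),
        "aupr": pr_aupr(scores, labels),
    }
    order = np.argsort(-scores, kind="stable")
    for k in ks:
        pooled[f"recall@{k}"] = recall_at_k(labels[order], k)
    return EvalReport(
        per_disease=per_disease,
        averaged=averaged,
        pooled=pooled,
        ks=tuple(ks),
        seed=seed,
        n_folds=n_folds,
    )


def _as_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, float)
    y = np.asarray(labels, float)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    return s, y
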