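"""Clinical-style and assay-style evaluation metrics.

Scores are oriented so that higher means more pathogenic / more
functionally abnormal; adapters flip the sign of predictors with the
opposite convention before evaluation.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .io import LabeledVariantSet


def roc_auc(labels, scores) -> float:
    """AUROC: probability a random pathogenic variant outranks a random benign one.

    Ties count one half (rank / Mann-Whitney formulation).  Returns NaN
    when only one class is present.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have the same length")
    if len(np.unique(labels)) < 2:
        return math.nan
    return float(roc_auc_score(labels, scores))


def specificity_at_sensitivity(labels, scores, s: float) -> float:
    """Specificity at the most stringent threshold reaching sensitivity >= s.

    A variant is called pathogenic when its score is at or above the
    threshold; the threshold is the largest score value whose sensitivity
    on the pathogenic class is still >= s, and specificity is the benign
    fraction strictly below it.
    """
    if not 0 < s <= 1:
        raise ValueError("target sensitivity must lie in (0, 1]")
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        return math.nan
    best = math.nan
    for t in np.unique(scores):  # ascending candidate thresholds
        sens = np.mean(pos >= t)
        if sens >= s:
            best = float(np.mean(neg < t))  # most stringent feasible t so far
    return best


def per_gene_auroc(data: LabeledVariantSet, scores,
                   min_benign: int = 4, min_pathogenic: int = 4) -> dict[str, float]:
    """AUROC within each gene having enough variants of both classes."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(data):
        raise ValueError("scores length must match the variant set")
    by_gene: dict[str, list[int]] = {}
    for i, k in enumerate(data.keys):
        by_gene.setdefault(k.gene, []).append(i)
    out: dict[str, float] = {}
    for gene, idx in by_gene.items():
        y = data.labels[idx]
        if (y == 0).sum() < min_benign or (y == 1).sum() < min_pathogenic:
            continue
        out[gene] = roc_auc(y, scores[idx])
    return out


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average ranks for ties; NaN if degenerate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors must have the same length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan
    return float(stats.spearmanr(x, y).statistic)


@dataclass
class EvaluationReport:
    """Bundle of clinical-style metrics for one score vector."""

    global_auroc: float
    per_gene_auroc: dict[str, float] = field(default_factory=dict)
    spec_at_sens: dict[str, float] = field(default_factory=dict)
    spearman: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=1, allow_nan=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def evaluate(data: LabeledVariantSet, scores,
             sensitivities: tuple[float, ...] = (0.90, 0.95, 0.99),
             min_benign: int = 4, min_pathogenic: int = 4,
             spearman_data: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
             ) -> EvaluationReport:
    """Full clinical-style evaluation of one score vector.

    ``spearman_data`` optionally maps dataset names to (assay score,
    prediction) pairs for assay-style rank correlation.
    """
    scores = np.asarray(scores, dtype=float)
    report = EvaluationReport(
        global_auroc=roc_auc(data.labels, scores),
        per_gene_auroc=per_gene_auroc(data, scores, min_benign, min_pathogenic),
        spec_at_sens={
            f"{s:.2f}": specificity_at_sensitivity(data.labels, scores, s)
            for s in sensitivities
        },
    )
    if spearman_data:
        report.spearman = {
            name: spearman_rho(a, p) for name, (a, p) in spearman_data.items()
        }
    return report
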