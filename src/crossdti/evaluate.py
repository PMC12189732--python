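"""Evaluation metrics and group comparisons.

PR AUC is the step-wise average-precision estimator (no interpolation):
AP = Σ_n (R_n − R_{n−1}) P_n over the thresholds induced by the scores; with
uninformative constant scores it equals the positive prevalence.  ROC AUC is
the probability that a random positive outscores a random negative, ties
counted half (the Mann–Whitney statistic).  Group comparisons use Welch's
unequal-variance t-test; "group a interacts more strongly" means its latent
distances are smaller, i.e. a one-sided test with alternative "less".
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score, precision_recall_curve, roc_curve

from .featurize import FeatureSet
from .model import ModelState, forward, sigmoid


def _check_binary(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels).ravel()
    classes = set(np.unique(y).tolist())
    if not classes <= {0, 1} or len(classes) != 2:
        raise ValueError("labels must contain both classes 0 and 1")
    return y


def pr_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve (step-wise average precision)."""
    y = _check_binary(labels)
    return float(average_precision_score(y, np.asarray(scores).ravel()))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """P(random positive outscores random negative), ties counted half."""
    y = _check_binary(labels)
    return float(roc_auc_score(y, np.asarray(scores).ravel()))


def curve_points(scores: np.ndarray, labels: np.ndarray) -> dict[str, np.ndarray]:
    """Per-threshold PR and ROC curve points, exportable for plotting."""
    y = _check_binary(labels)
    s = np.asarray(scores).ravel()
    precision, recall, pr_thresh = precision_recall_curve(y, s)
    fpr, tpr, roc_thresh = roc_curve(y, s)
    return {"precision": precision, "recall": recall, "fpr": fpr, "tpr": tpr}


@dataclass
class EvalReport:
    split: str
    pr_auc: float
    roc_auc: float
    n_pos: int
    n_neg: int
    degenerate_scores: bool = False

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    def to_csv(self, path: str | Path) -> None:
        with Path(path).open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["split", "pr_auc", "roc_auc", "n_pos", "n_neg", "degenerate_scores"])
            writer.writerow([self.split, self.pr_auc, self.roc_auc, self.n_pos, self.n_neg, self.degenerate_scores])


def evaluate_split(state: ModelState, dataset, features: FeatureSet, split: str = "test") -> EvalReport:
    """Score a split with sigmoid(logits) and report PR/ROC AUC with class counts."""
    pairs = [p for p in dataset.split(split)
             if p.compound_id in features.compound and p.target_id in features.target]
    if not pairs:
        raise ValueError(f"split {split!r} is empty")
    y = _check_binary(np.array([p.label for p in pairs]))
    E1 = np.stack([features.target[p.target_id].vector for p in pairs])
    E2 = np.stack([features.compound[p.compound_id].vector for p in pairs])
    scores = sigmoid(forward(E1, E2, state))
    degenerate = bool(np.allclose(scores, scores[0]))
    return EvalReport(
        split=split,
        pr_auc=pr_auc(scores, y),
        roc_auc=roc_auc(scores, y),
        n_pos=int(y.sum()),
        n_neg=int(len(y) - y.sum()),
        degenerate_scores=degenerate,
    )


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    t_statistic: float
    p_value: float
    alternative: str


def compare_groups(
    distances_a: np.ndarray,
    distances_b: np.ndarray,
    alternative: str = "stronger",
    group_a: str = "a",
    group_b: str = "b",
) -> GroupComparison:
    """Welch one-sided t-test on two latent-distance samples.

    ``alternative="stronger"`` tests whether group a interacts more strongly,
    i.e. whether its distances are smaller (one-sided "less"); ``"weaker"``
    tests the opposite direction.
    """
    a = np.asarray(distances_a, dtype=np.float64).ravel()
    b = np.asarray(distances_b, dtype=np.float64).ravel()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    scipy_alt = {"stronger": "less", "weaker": "greater"}[alternative]
    res = stats.ttest_ind(a, b, equal_var=False, alternative=scipy_alt)
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alternative=alternative,
    )
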