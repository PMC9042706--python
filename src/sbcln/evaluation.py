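"""Operational performance metrics and tumor-purity cutoff calibration.

Note the operational definitions used throughout, which follow diagnostic
practice for a classifier with a rejection ("undetermined") option rather
than the epidemiological true-negative rate:

* sensitivity = correct calls / all samples — an "undetermined" sample
  counts against sensitivity;
* specificity = correct calls / assigned samples — only samples that
  received an entity call enter the denominator, so rejections do not hurt
  specificity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cascade import PredictionResult
from .core_io import UNDETERMINED

DEFAULT_TARGET_FRACTION = 0.9
DEFAULT_PROB_THRESHOLD = 0.5


@dataclass
class EvaluationReport:
    n_total: int
    n_assigned: int
    n_correct: int
    sensitivity: float
    specificity: float | None  # None when nothing was assigned
    per_entity: pd.DataFrame
    misclassified: list[str]
    undetermined: list[str]

    def rounded(self) -> tuple[str, str]:
        """2-decimal presentation of (sensitivity, specificity)."""
        spec = "undefined" if self.specificity is None else f"{self.specificity:.2f}"
        return f"{self.sensitivity:.2f}", spec


def _calls(predictions: Sequence[PredictionResult] | Mapping[str, str]) -> dict[str, str]:
    if isinstance(predictions, Mapping):
        return dict(predictions)
    return {p.sample_id: p.final_call for p in predictions}


def sensitivity_specificity(
    predictions: Sequence[PredictionResult] | Mapping[str, str],
    truth: Mapping[str, str] | pd.Series,
) -> EvaluationReport:
    """Compute the operational sensitivity/specificity report."""
    calls = _calls(predictions)
    truth = dict(truth)
    missing = [s for s in calls if s not in truth]
    if missing:
        raise ValueError(f"samples without truth labels: {missing}")

    n_total = len(calls)
    if n_total == 0:
        raise ValueError("no predictions")
    mis, und = [], []
    n_correct = n_assigned = 0
    per_entity_rows: dict[str, dict[str, int]] = {}
    for sample, call in calls.items():
        t = truth[sample]
        row = per_entity_rows.setdefault(t, {"n": 0, "correct": 0, "misclassified": 0, "undetermined": 0})
        row["n"] += 1
        if call == UNDETERMINED:
            und.append(sample)
            row["undetermined"] += 1
            continue
        n_assigned += 1
        if call == t:
            n_correct += 1
            row["correct"] += 1
        else:
            mis.append(sample)
            row["misclassified"] += 1

    return EvaluationReport(
        n_total=n_total,
        n_assigned=n_assigned,
        n_correct=n_correct,
        sensitivity=n_correct / n_total,
        specificity=(n_correct / n_assigned) if n_assigned else None,
        per_entity=pd.DataFrame(per_entity_rows).T.rename_axis("entity"),
        misclassified=mis,
        undetermined=und,
    )


@dataclass
class CutoffResult:
    cutoff: float
    attainable: bool
    n_at_cutoff: int  # samples with content >= cutoff


def purity_cutoff(
    probabilities: Sequence[float],
    tumor_contents: Sequence[float],
    target_fraction: float = DEFAULT_TARGET_FRACTION,
    prob_threshold: float = DEFAULT_PROB_THRESHOLD,
    grid: Sequence[float] | None = None,
) -> CutoffResult:
    """Minimal tumor-content cutoff for one entity.

    Returns the smallest candidate cutoff c such that strictly more than
    ``target_fraction`` of the samples with content >= c have true-entity
    probability strictly above ``prob_threshold``. Candidates default to the
    observed content values; pass ``grid`` for a fixed scan. When no cutoff
    satisfies the condition the maximum observed content is returned flagged
    not attainable.
    """
    p = np.asarray(probabilities, dtype=float)
    rho = np.asarray(tumor_contents, dtype=float)
    if p.size == 0 or p.size != rho.size:
        raise ValueError("need equal-length nonempty probability and content lists")
    candidates = np.unique(rho) if grid is None else np.unique(np.asarray(grid, dtype=float))
    hit = p > prob_threshold
    for c in np.sort(candidates):
        sel = rho >= c
        if sel.sum() == 0:
            continue
        if hit[sel].mean() > target_fraction:
            return CutoffResult(float(c), True, int(sel.sum()))
    c = float(rho.max())
    return CutoffResult(c, False, int((rho >= c).sum()))


def purity_cutoffs_by_entity(
    predictions: Sequence[PredictionResult],
    truth: Mapping[str, str] | pd.Series,
    tumor_contents: Mapping[str, float] | pd.Series,
    target_fraction: float = DEFAULT_TARGET_FRACTION,
    prob_threshold: float = DEFAULT_PROB_THRESHOLD,
) -> pd.DataFrame:
    """Per-entity cutoff table from cascade predictions.

    The probability of the *true* entity is read from each sample's step
    profile (0 when the cascade stopped before reaching that entity's step).
    """
    truth = dict(truth)
    contents = dict(tumor_contents)
    groups: dict[str, list[tuple[float, float]]] = {}
    for r in predictions:
        t = truth.get(r.sample_id)
        if t in (None, UNDETERMINED, "control", "unknown"):
            continue
        rho = contents.get(r.sample_id)
        if rho is None:
            continue
        p_true = r.probabilities.get(t, 0.0)
        groups.setdefault(t, []).append((rho, p_true))

    rows = {}
    for entity, pairs in sorted(groups.items()):
        rho, p = zip(*pairs)
        res = purity_cutoff(p, rho, target_fraction, prob_threshold)
        rows[entity] = {
            "cutoff": res.cutoff,
            "attainable": res.attainable,
            "n_samples": len(pairs),
            "n_at_cutoff": res.n_at_cutoff,
        }
    return pd.DataFrame(rows).T.rename_axis("entity")


def cumulative_metrics(
    predictions: Sequence[PredictionResult] | Mapping[str, str],
    truth: Mapping[str, str] | pd.Series,
    tumor_contents: Mapping[str, float] | pd.Series,
) -> pd.DataFrame:
    """Sensitivity/specificity curves over content-thresholded suffix subsets.

    For each threshold t (the sorted unique observed contents) the metrics
    are recomputed on the samples with content >= t.
    """
    calls = _calls(predictions)
    truth = dict(truth)
    contents = dict(tumor_contents)
    missing = [s for s in calls if s not in contents]
    if missing:
        raise ValueError(f"samples without tumor content: {missing}")

    rows = []
    for t in np.unique(list(contents[s] for s in calls)):
        subset = {s: c for s, c in calls.items() if contents[s] >= t}
        if not subset:
            continue
        rep = sensitivity_specificity(subset, truth)
        rows.append(
            {
                "threshold": float(t),
                "n": rep.n_total,
                "sensitivity": rep.sensitivity,
                "specificity": rep.specificity,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GroupTestResult:
    table: np.ndarray  # 2x2: rows correct/incorrect, cols group A/B
    odds_ratio: float
    p_value: float
    degenerate: bool = False


def group_accuracy_test(
    predictions: Sequence[PredictionResult] | Mapping[str, str],
    truth: Mapping[str, str] | pd.Series,
    group_labels: Mapping[str, str] | pd.Series,
) -> GroupTestResult:
    """Two-sided Fisher exact test of accuracy between two sample groups
    (e.g. FFPE vs fresh-frozen)."""
    calls = _calls(predictions)
    truth = dict(truth)
    group_labels = dict(group_labels)
    group_names = sorted(set(group_labels[s] for s in calls))
    if len(group_names) != 2:
        raise ValueError(f"need exactly 2 groups, got {group_names}")

    table = np.zeros((2, 2), dtype=int)
    for s, call in calls.items():
        col = group_names.index(group_labels[s])
        row = 0 if call == truth[s] else 1
        table[row, col] += 1

    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        return GroupTestResult(table, float("nan"), 1.0, degenerate=True)
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return GroupTestResult(table, float(odds), float(p))
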