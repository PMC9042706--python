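"""Differential-expression screening and the clustering feasibility check.

Candidate markers are screened on a labeled log2 expression matrix by
one-vs-rest or one-vs-one contrasts: a gene is selected when its absolute
log2 fold change exceeds 1 and its Benjamini-Hochberg FDR is below 0.05
(both strict). A global one-way ANOVA F statistic across all groups is
reported alongside the per-contrast Welch t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .normalization import NormalizedMatrix

DEFAULT_LFC = 1.0
DEFAULT_FDR = 0.05


@dataclass
class DEResult:
    gene: str
    contrast: str  # "<entity>_vs_rest" or "<a>_vs_<b>"
    log2fc: float
    p_value: float
    fdr: float
    anova_p: float | None = None

    def selected(self, lfc_threshold: float = DEFAULT_LFC, fdr_threshold: float = DEFAULT_FDR) -> bool:
        # strict inequalities on both thresholds
        return abs(self.log2fc) > lfc_threshold and self.fdr < fdr_threshold


def _values(matrix: NormalizedMatrix | pd.DataFrame) -> pd.DataFrame:
    return matrix.values if isinstance(matrix, NormalizedMatrix) else matrix


def _two_group_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch t per gene; exact-equality shortcut when both groups are constant."""
    lfc = a.mean() - b.mean()
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return lfc, (1.0 if a.mean() == b.mean() else 0.0)
    p = stats.ttest_ind(a, b, equal_var=False).pvalue
    return lfc, float(p)


def differential_expression(
    matrix: NormalizedMatrix | pd.DataFrame,
    labels: pd.Series,
    strategy: str = "one_vs_rest",
    lfc_threshold: float = DEFAULT_LFC,
    fdr_threshold: float = DEFAULT_FDR,
) -> list[DEResult]:
    """Screen genes by group contrasts on log2 expression.

    ``labels`` maps sample id -> group. Strategy ``one_vs_rest`` contrasts
    each group against the pooled others; ``one_vs_one`` contrasts every
    group pair. BH FDR is applied within each contrast.
    """
    values = _values(matrix)
    labels = labels.reindex(values.columns)
    if labels.isna().any():
        raise ValueError("every sample needs a label")
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    counts = labels.value_counts()
    small = counts[counts < 2]
    if not small.empty:
        raise ValueError(f"groups with <2 samples: {list(small.index)}")

    X = values.to_numpy()
    group_masks = {g: (labels == g).to_numpy() for g in groups}

    # global one-way ANOVA F across all groups, reported per gene
    anova_p = np.empty(X.shape[0])
    for i in range(X.shape[0]):
        arrays = [X[i, group_masks[g]] for g in groups]
        if all(a.std(ddof=1) == 0 for a in arrays):
            means = [a.mean() for a in arrays]
            anova_p[i] = 1.0 if len(set(means)) == 1 else 0.0
        else:
            anova_p[i] = stats.f_oneway(*arrays).pvalue

    if strategy in ("one_vs_rest", "ovr"):
        contrasts = [(g, None) for g in groups]
    elif strategy in ("one_vs_one", "ovo"):
        contrasts = list(combinations(groups, 2))
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    results: list[DEResult] = []
    for pair in contrasts:
        if pair[1] is None:
            g = pair[0]
            name = f"{g}_vs_rest"
            mask_a, mask_b = group_masks[g], ~group_masks[g]
        else:
            a, b = pair
            name = f"{a}_vs_{b}"
            mask_a, mask_b = group_masks[a], group_masks[b]
        lfcs = np.empty(X.shape[0])
        pvals = np.empty(X.shape[0])
        for i in range(X.shape[0]):
            lfcs[i], pvals[i] = _two_group_test(X[i, mask_a], X[i, mask_b])
        fdrs = multipletests(pvals, method="fdr_bh")[1]
        for i, gene in enumerate(values.index):
            results.append(
                DEResult(
                    gene=gene,
                    contrast=name,
                    log2fc=float(lfcs[i]),
                    p_value=float(pvals[i]),
                    fdr=float(fdrs[i]),
                    anova_p=float(anova_p[i]),
                )
            )
    return results


def de_results_table(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "contrast": [r.contrast for r in results],
            "log2fc": [r.log2fc for r in results],
            "p_value": [r.p_value for r in results],
            "fdr": [r.fdr for r in results],
            "anova_p": [r.anova_p for r in results],
        }
    )


def assemble_candidate_panel(
    de_results: Sequence[DEResult],
    literature_supplements: Sequence[str] = (),
    lfc_threshold: float = DEFAULT_LFC,
    fdr_threshold: float = DEFAULT_FDR,
) -> list[str]:
    """Union of DE-selected genes and literature supplements.

    DE genes come first, ordered by their best (lowest) FDR over contrasts,
    then the supplements; duplicates counted once.
    """
    best_fdr: dict[str, float] = {}
    for r in de_results:
        if r.selected(lfc_threshold, fdr_threshold):
            if r.gene not in best_fdr or r.fdr < best_fdr[r.gene]:
                best_fdr[r.gene] = r.fdr
    panel: dict[str, None] = {}
    for g in sorted(best_fdr, key=lambda g: (best_fdr[g], g)):
        panel.setdefault(g, None)
    for g in literature_supplements:
        panel.setdefault(g, None)
    return list(panel)


def cluster_feasibility(
    matrix: NormalizedMatrix | pd.DataFrame,
    labels: pd.Series,
    n_branches: int,
    method: str = "ward",
    metric: str = "euclidean",
) -> float:
    """Fraction of samples 'appropriately clustered' by hierarchical clustering.

    Samples are clustered (default Ward linkage, Euclidean distance on log2
    values), the tree is cut into ``n_branches``, and a sample counts as
    appropriately clustered when the majority label of its branch equals its
    own label.
    """
    values = _values(matrix)
    labels = labels.reindex(values.columns)
    if labels.isna().any():
        raise ValueError("every sample needs a label")
    n_samples = values.shape[1]
    if n_branches > n_samples:
        raise ValueError(f"n_branches={n_branches} exceeds n_samples={n_samples}")
    if n_branches < labels.nunique():
        raise ValueError("n_branches must be at least the number of distinct labels")

    X = values.to_numpy().T  # samples x genes
    Z = hierarchy.linkage(X, method=method, metric=metric)
    branches = hierarchy.fcluster(Z, t=n_branches, criterion="maxclust")

    correct = 0
    lab = labels.to_numpy()
    for b in np.unique(branches):
        members = lab[branches == b]
        majority = pd.Series(members).mode().iloc[0]
        correct += int((members == majority).sum())
    return correct / n_samples
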