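"""Housekeeping-gene selection and geometric-mean normalization.

Raw digital counts are normalized per cohort against the geometric mean of a
set of stably expressed housekeeping genes, then log2 transformed. Candidate
housekeeping genes are ranked by the geNorm pairwise-stability statistic M
(mean, over partner genes, of the standard deviation across samples of the
log2 expression ratio; lower M = more stable) and filtered on expression
level and coefficient of variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import CountMatrix

DEFAULT_MIN_EXPRESSION = 64.0  # geometric-mean raw counts
DEFAULT_MAX_CV = 0.5
DEFAULT_K = 4


@dataclass
class StabilityReport:
    """Per-candidate housekeeping stability metrics."""

    table: pd.DataFrame  # index gene; columns: M, cv, geomean

    @property
    def ranked(self) -> list[str]:
        """Candidates sorted by ascending geNorm M (stable first)."""
        return list(self.table.sort_values("M", kind="stable").index)


@dataclass
class NormalizedMatrix:
    """Log2-scale normalized expression for one cohort."""

    values: pd.DataFrame  # genes x samples, log2(count * factor + 1)
    housekeeping_used: list[str]
    cohort_id: str = "all"
    factors: pd.Series | None = None  # per-sample normalization factors

    def __post_init__(self) -> None:
        if not self.housekeeping_used:
            raise ValueError("housekeeping_used must be nonempty")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("normalized values must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def _candidate_counts(
    counts: CountMatrix | pd.DataFrame, candidates: Sequence[str], pseudocount: float
) -> pd.DataFrame:
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    missing = [g for g in candidates if g not in df.index]
    if missing:
        raise ValueError(f"candidate genes absent from matrix: {missing}")
    sub = df.loc[list(candidates)].astype(float)
    if pseudocount:
        sub = sub + pseudocount
    if (sub.to_numpy() <= 0).any():
        raise ValueError("zero counts among candidates; supply a pseudocount")
    return sub


def genorm_rank(
    counts: CountMatrix | pd.DataFrame,
    candidates: Sequence[str],
    pseudocount: float = 0.0,
) -> StabilityReport:
    """Rank candidate housekeeping genes by the geNorm stability value M.

    M_g is the mean over all other candidates k of the standard deviation
    (ddof=1) across samples of log2(c_g / c_k). Also reports each candidate's
    coefficient of variation (sd/mean of raw counts) and geometric mean.
    """
    if len(candidates) < 2:
        raise ValueError("geNorm needs at least 2 candidate genes")
    sub = _candidate_counts(counts, candidates, pseudocount)
    log2c = np.log2(sub.to_numpy())  # candidates x samples

    n = len(candidates)
    m_values = np.empty(n)
    for i in range(n):
        ratios = log2c[i] - np.delete(log2c, i, axis=0)  # (n-1) x samples
        m_values[i] = ratios.std(axis=1, ddof=1).mean()

    raw = sub.to_numpy()
    table = pd.DataFrame(
        {
            "M": m_values,
            "cv": raw.std(axis=1, ddof=1) / raw.mean(axis=1),
            "geomean": np.exp2(log2c.mean(axis=1)),
        },
        index=pd.Index(list(candidates), name="gene"),
    )
    return StabilityReport(table)


def genorm_iterative_exclusion(
    counts: CountMatrix | pd.DataFrame,
    candidates: Sequence[str],
    keep: int = 2,
    pseudocount: float = 0.0,
) -> list[str]:
    """Classic geNorm stepwise variant: repeatedly drop the least stable
    candidate (highest M) and re-rank, until ``keep`` genes remain.

    Returns candidates in exclusion order, most stable last.
    """
    remaining = list(candidates)
    excluded: list[str] = []
    while len(remaining) > max(keep, 2):
        report = genorm_rank(counts, remaining, pseudocount=pseudocount)
        worst = report.table["M"].idxmax()
        remaining.remove(worst)
        excluded.append(worst)
    return excluded + remaining


def select_housekeeping(
    counts: CountMatrix | pd.DataFrame,
    candidates: Sequence[str],
    min_expression: float = DEFAULT_MIN_EXPRESSION,
    max_cv: float = DEFAULT_MAX_CV,
    k: int = DEFAULT_K,
    pseudocount: float = 0.0,
) -> list[str]:
    """Pick the final housekeeping set.

    Candidates with geometric-mean count below ``min_expression`` or CV above
    ``max_cv`` are dropped; of the survivors the ``k`` with lowest CV are
    returned (input order breaks ties; all survivors if fewer than k).
    """
    report = genorm_rank(counts, candidates, pseudocount=pseudocount)
    t = report.table
    survivors = t[(t["geomean"] >= min_expression) & (t["cv"] <= max_cv)]
    if survivors.empty:
        raise ValueError(
            "no housekeeping candidate passed the filters; relax min_expression "
            f"(={min_expression}) or max_cv (={max_cv})"
        )
    ordered = survivors.sort_values("cv", kind="stable").index
    return list(ordered[:k])


def normalize_counts(
    counts: CountMatrix,
    housekeeping_set: Sequence[str],
    cohort_partition: Mapping[str, Sequence[str]] | None = None,
    pseudocount: float = 1.0,
    reference: float | None = None,
) -> dict[str, NormalizedMatrix]:
    """Housekeeping geometric-mean normalization with log2 transform, per cohort.

    Within each cohort the per-sample factor is

        f_s = reference / (HK geometric mean of sample s)

    and the normalized value is log2(count * f_s + pseudocount). ``reference``
    defaults to the arithmetic mean of the per-sample housekeeping geometric
    means of the cohort, which keeps normalized counts on the raw count scale;
    after scaling, every sample of a cohort has the same housekeeping
    geometric mean (the reference). Because the default reference is itself a
    cohort statistic, rescaling one sample's library nudges every sample's
    values through it; pass a fixed ``reference`` for exact per-sample scale
    invariance. Cohorts are normalized independently — the factors of one
    cohort never depend on the samples of another.
    """
    hk = list(housekeeping_set)
    if not hk:
        raise ValueError("housekeeping set is empty")
    missing = [g for g in hk if g not in counts.counts.index]
    if missing:
        raise ValueError(f"housekeeping genes absent from matrix: {missing}")

    if cohort_partition is None:
        cohort_partition = {"all": counts.sample_ids}

    out: dict[str, NormalizedMatrix] = {}
    for cohort_id, sample_ids in cohort_partition.items():
        sample_ids = list(sample_ids)
        sub = counts.counts[sample_ids].astype(float)
        hk_counts = sub.loc[hk]
        zero_samples = hk_counts.columns[(hk_counts <= 0).any(axis=0)]
        geomeans = np.exp2(np.log2(hk_counts.where(hk_counts > 0)).mean(axis=0))
        if len(zero_samples):
            raise ValueError(
                f"cohort {cohort_id!r}: zero housekeeping counts in sample(s) "
                f"{list(zero_samples)}; cannot form geometric mean"
            )
        ref = geomeans.mean() if reference is None else float(reference)
        factors = ref / geomeans
        values = np.log2(sub.mul(factors, axis=1) + pseudocount)
        out[cohort_id] = NormalizedMatrix(
            values=values,
            housekeeping_used=hk,
            cohort_id=cohort_id,
            factors=factors,
        )
    return out


def normalize_single_cohort(
    counts: CountMatrix,
    housekeeping_set: Sequence[str],
    pseudocount: float = 1.0,
    reference: float | None = None,
) -> NormalizedMatrix:
    """Convenience wrapper: normalize all samples as one cohort."""
    return normalize_counts(counts, housekeeping_set, None, pseudocount, reference)["all"]
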