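"""Genetic-marker integration and the variant-table filter.

Four lesions supplement the expression model: the IGH-BCL2 translocation
(hallmark of FL), MYD88 L265P (LPL/WM), BRAF V600E (HCL — an entity outside
the expression cascade entirely) and EZH2 Y646 (FL). Variant tables arrive
pre-annotated (effect class, supporting reads, gnomAD population frequency,
lymphoma-relevance flag); no database lookup is performed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .cascade import PredictionResult
from .core_io import ENTITIES, HCL, UNDETERMINED, SampleAnnotation

MIN_READS = 20
MAX_POPULATION_FREQUENCY = 1e-4
RETAINED_EFFECTS = ("exonic nonsynonymous", "splice-site")

OVERRIDE_UNDETERMINED_ONLY = "override_undetermined_only"
OVERRIDE_ALL = "override_all"

#: conflict priority when several markers are positive (most specific first)
MARKER_PRIORITY = ("BRAF_V600E", "MYD88_L265P", "IGH_BCL2", "EZH2_Y646")


@dataclass(frozen=True)
class IntegrationRule:
    marker: str
    entity: str
    precedence: str = OVERRIDE_UNDETERMINED_ONLY

    def __post_init__(self) -> None:
        if self.entity not in (*ENTITIES, HCL):
            raise ValueError(f"rule maps to unknown entity {self.entity!r}")
        if self.precedence not in (OVERRIDE_UNDETERMINED_ONLY, OVERRIDE_ALL):
            raise ValueError(f"unknown precedence {self.precedence!r}")


#: default rule set; BRAF→HCL always overrides because HCL has no expression step
DEFAULT_RULES: tuple[IntegrationRule, ...] = (
    IntegrationRule("IGH_BCL2", "FL", OVERRIDE_UNDETERMINED_ONLY),
    IntegrationRule("MYD88_L265P", "LPL/WM", OVERRIDE_UNDETERMINED_ONLY),
    IntegrationRule("BRAF_V600E", HCL, OVERRIDE_ALL),
    IntegrationRule("EZH2_Y646", "FL", OVERRIDE_UNDETERMINED_ONLY),
)


@dataclass
class VariantRecord:
    gene: str
    effect: str  # 'exonic nonsynonymous' / 'splice-site' / anything else
    reads: int
    population_frequency: float
    lymphoma_relevant: bool = False

    def __post_init__(self) -> None:
        if self.reads < 0:
            raise ValueError(f"{self.gene}: negative read support")
        if not (0.0 <= self.population_frequency <= 1.0):
            raise ValueError(f"{self.gene}: population frequency outside [0,1]")


def filter_variants(records: Sequence[VariantRecord]) -> list[VariantRecord]:
    """Apply the targeted-sequencing variant filter.

    A variant is retained iff it is exonic nonsynonymous or splice-site,
    has >= 20 supporting reads, and is either rare in the population
    (frequency <= 1e-4) or flagged lymphoma-relevant.
    """
    kept = []
    for rec in records:
        if rec.effect not in RETAINED_EFFECTS:
            continue
        if rec.reads < MIN_READS:
            continue
        if rec.population_frequency > MAX_POPULATION_FREQUENCY and not rec.lymphoma_relevant:
            continue
        kept.append(rec)
    return kept


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a TSV variant table (columns gene, effect, reads, popfreq,
    lymphoma_relevant)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "effect", "reads", "popfreq", "lymphoma_relevant"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        if row.isna().any():
            raise ValueError(f"{path}: missing field(s) in row {i}")
        records.append(
            VariantRecord(
                gene=str(row["gene"]),
                effect=str(row["effect"]),
                reads=int(row["reads"]),
                population_frequency=float(row["popfreq"]),
                lymphoma_relevant=str(row["lymphoma_relevant"]).strip().lower()
                in ("true", "1", "yes"),
            )
        )
    return records


def _positive_markers(ann: SampleAnnotation, rules: Sequence[IntegrationRule]) -> list[IntegrationRule]:
    fired = [r for r in rules if ann.marker(r.marker) == "positive"]
    order = {m: i for i, m in enumerate(MARKER_PRIORITY)}
    return sorted(fired, key=lambda r: order.get(r.marker, len(order)))


def integrate_markers(
    predictions: Sequence[PredictionResult],
    annotations: Mapping[str, SampleAnnotation],
    rules: Sequence[IntegrationRule] = DEFAULT_RULES,
) -> list[PredictionResult]:
    """Revise cascade calls with genetic-marker rules.

    Under ``override_undetermined_only`` a rule fires only for samples the
    expression model left undetermined; ``override_all`` replaces any call.
    At most one rule fires per sample; multi-positive conflicts resolve by
    marker specificity (BRAF > MYD88 > IGH-BCL2) with a warning. Samples with
    unknown or negative markers are returned untouched.
    """
    revised = []
    for pred in predictions:
        ann = annotations.get(pred.sample_id)
        if ann is None:
            revised.append(pred)
            continue
        fired = _positive_markers(ann, rules)
        applicable = [
            r for r in fired
            if r.precedence == OVERRIDE_ALL or pred.final_call == UNDETERMINED
        ]
        if not applicable:
            revised.append(pred)
            continue
        if len(fired) > 1:
            warnings.warn(
                f"sample {pred.sample_id}: multiple positive markers "
                f"{[r.marker for r in fired]}; applying {applicable[0].marker}",
                stacklevel=2,
            )
        revised.append(replace(pred, final_call=applicable[0].entity))
    return revised


def select_combined_markers(
    candidate_rules: Sequence[IntegrationRule],
    predictions: Sequence[PredictionResult],
    truth: Mapping[str, str] | pd.Series,
    annotations: Mapping[str, SampleAnnotation],
    min_reclassified: int = 2,
) -> list[IntegrationRule]:
    """Admit a candidate rule iff applying it alone correctly reclassifies at
    least ``min_reclassified`` samples (default 2)."""
    truth = dict(truth)
    admitted = []
    for rule in candidate_rules:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            revised = integrate_markers(predictions, annotations, [rule])
        gained = sum(
            1
            for before, after in zip(predictions, revised)
            if after.final_call != before.final_call
            and after.final_call == truth.get(after.sample_id)
        )
        if gained >= min_reclassified:
            admitted.append(rule)
    return admitted
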