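"""The cascade classifier: DBI-ordered one-vs-rest binary random forests.

Multiclass discrimination is decomposed into an ordered sequence of binary
random-forest classifiers, one per entity. The order is decided by the
Davies-Bouldin index (more separable entities first). Each step is trained
on the full candidate panel against a "rest" class of all other entity
samples plus all nonmalignant controls, then refined to the top-k genes by
Gini importance among genes upregulated in the target entity, and retrained
on the refined set. At prediction time the steps fire in order: the first
step whose probability reaches the threshold (default 0.5, boundary
inclusive) names the entity; if no step fires the sample is reported as
"undetermined" — the cascade never asserts an entity it has no evidence for.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .core_io import CONTROL, ENTITIES, UNDETERMINED, GenePanel
from .normalization import NormalizedMatrix

#: the step order of the published reference six-entity model
PUBLISHED_ORDER: tuple[str, ...] = ENTITIES

#: refined marker sets of the published reference model (CCND1 is shared by
#: the two mantle-cell steps, so the union counts 35 genes)
REFERENCE_MARKERS: dict[str, tuple[str, ...]] = {
    "CLL/SLL": ("BTLA", "ARHGAP44", "ZBTB24", "CLNK", "CD200"),
    "cMCL": ("SOX11", "PLEKHG4B", "ZNF711", "CCND1", "FAM129C", "ABCA6"),
    "FL": ("BCL2", "EML6", "ELL3", "CTLA4", "FCER2", "IGF2BP3", "RGS13", "EBF1"),
    "nnMCL": ("CCND1", "ZNF331", "PAX5", "CNR1"),
    "MZL": ("FCRLA", "HDAC9", "MS4A1", "SIGLEC6", "ZBTB32", "BHLHE41"),
    "LPL/WM": ("CCR2", "HOPX", "FKBP11", "ANK3", "ZNF226", "MFAP5", "MEF2A"),
}

#: default refined-marker count per entity, matching the reference model
DEFAULT_K_TABLE: dict[str, int] = {e: len(g) for e, g in REFERENCE_MARKERS.items()}

DEFAULT_THRESHOLD = 0.5


@dataclass
class CascadeConfig:
    """Hyperparameters of the cascade fit.

    ``markers_per_entity`` may be an int (same k for every entity), a mapping
    entity -> k, or ``"auto"`` (per-step leave-one-out Youden-index search
    over k in [3, 10]). ``entity_order`` is ``"dbi"``, ``"published"`` or an
    explicit entity list.
    """

    n_estimators: int = 100  # forests with scikit-learn standard parameters
    max_features: str | int | float = "sqrt"
    markers_per_entity: int | Mapping[str, int] | str = field(
        default_factory=lambda: dict(DEFAULT_K_TABLE)
    )
    entity_order: str | Sequence[str] = "dbi"
    threshold: float = DEFAULT_THRESHOLD
    seed: int = 0
    auto_k_range: tuple[int, int] = (3, 10)

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0,1)")

    def k_for(self, entity: str) -> int | None:
        if self.markers_per_entity == "auto":
            return None
        if isinstance(self.markers_per_entity, int):
            return self.markers_per_entity
        k = self.markers_per_entity.get(entity)
        if k is None:
            raise ValueError(
                f"no marker count configured for entity {entity!r}; "
                "pass an int or 'auto' in markers_per_entity"
            )
        return k


@dataclass
class CascadeStep:
    entity: str
    marker_genes: list[str]
    classifier: RandomForestClassifier
    gini_importances: pd.Series  # over the genes the classifier was fitted on
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.marker_genes:
            raise ValueError(f"step {self.entity}: empty marker list")

    def probability(self, values: pd.DataFrame) -> np.ndarray:
        """Probability of the target entity as the fraction of trees voting it."""
        missing = [g for g in self.marker_genes if g not in values.index]
        if missing:
            raise ValueError(f"step {self.entity}: marker gene(s) missing from matrix: {missing}")
        X = values.loc[self.marker_genes].to_numpy().T
        target_idx = int(np.flatnonzero(self.classifier.classes_ == 1)[0])
        votes = np.stack([tree.predict(X) for tree in self.classifier.estimators_])
        return (votes == target_idx).mean(axis=0)


@dataclass
class CascadeModel:
    steps: list[CascadeStep]
    threshold: float = DEFAULT_THRESHOLD
    dbi_values: dict[str, float] = field(default_factory=dict)
    housekeeping_set: list[str] = field(default_factory=list)
    panel: GenePanel | None = None
    config: CascadeConfig | None = None

    def __post_init__(self) -> None:
        entities = [s.entity for s in self.steps]
        if len(set(entities)) != len(entities):
            raise ValueError("duplicate entities in cascade steps")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0,1)")

    @property
    def entity_order(self) -> list[str]:
        return [s.entity for s in self.steps]

    @property
    def marker_union(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.steps:
            for g in s.marker_genes:
                seen.setdefault(g, None)
        return list(seen)


@dataclass
class PredictionResult:
    sample_id: str
    probabilities: dict[str, float]  # entity -> p, in step order as evaluated
    final_call: str  # entity or "undetermined"
    stopped_at_step: int | None  # 0-based index of the firing step


# ---------------------------------------------------------------------------
# Davies-Bouldin ordering
# ---------------------------------------------------------------------------

def entity_dbi_order(
    matrix: NormalizedMatrix | pd.DataFrame,
    labels: pd.Series,
    entities: Sequence[str] | None = None,
) -> list[tuple[str, float]]:
    """Order entities by ascending Davies-Bouldin index.

    For entity e, S_e is the mean Euclidean distance of its samples to the
    entity centroid and D_e = max over other entities f of
    (S_e + S_f) / ||centroid_e - centroid_f||. Lower D = more separable.
    Control samples are excluded. Ties broken alphabetically.
    """
    values = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    labels = labels.reindex(values.columns)
    if entities is None:
        entities = sorted(set(labels.unique()) - {CONTROL})
    entities = list(entities)
    if len(entities) < 2:
        raise ValueError("DBI ordering needs at least 2 entities")

    X = values.to_numpy().T  # samples x genes
    centroids, scatters = {}, {}
    for e in entities:
        mask = (labels == e).to_numpy()
        if mask.sum() < 1:
            raise ValueError(f"entity {e!r} has no samples")
        pts = X[mask]
        c = pts.mean(axis=0)
        centroids[e] = c
        scatters[e] = float(np.linalg.norm(pts - c, axis=1).mean())

    dbi: dict[str, float] = {}
    for e in entities:
        ratios = []
        for f in entities:
            if f == e:
                continue
            dist = float(np.linalg.norm(centroids[e] - centroids[f]))
            if dist == 0.0:
                raise ValueError(
                    f"entities {e!r} and {f!r} have coincident centroids; "
                    "Davies-Bouldin ratio undefined (check labels / features)"
                )
            ratios.append((scatters[e] + scatters[f]) / dist)
        dbi[e] = max(ratios)

    ordered = sorted(entities, key=lambda e: (dbi[e], e))
    return [(e, dbi[e]) for e in ordered]


# ---------------------------------------------------------------------------
# Step training and refinement
# ---------------------------------------------------------------------------

def _make_forest(config: CascadeConfig, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=config.n_estimators,
        max_features=config.max_features,
        random_state=seed,
        n_jobs=1,
    )


def _binary_xy(
    values: pd.DataFrame, labels: pd.Series, target_entity: str, genes: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    missing = [g for g in genes if g not in values.index]
    if missing:
        raise ValueError(f"genes missing from matrix: {missing}")
    X = values.loc[list(genes)].to_numpy().T
    y = (labels.reindex(values.columns) == target_entity).to_numpy().astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(f"single-class input for target {target_entity!r}")
    return X, y


def train_step(
    matrix: NormalizedMatrix | pd.DataFrame,
    labels: pd.Series,
    target_entity: str,
    candidate_genes: Sequence[str],
    config: CascadeConfig | None = None,
    seed: int | None = None,
) -> CascadeStep:
    """Fit the pre-refinement one-vs-rest forest for one entity.

    The rest class is every non-target sample in the matrix — other entities
    and all controls.
    """
    config = config or CascadeConfig()
    seed = config.seed if seed is None else seed
    values = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    X, y = _binary_xy(values, labels, target_entity, candidate_genes)
    clf = _make_forest(config, seed)
    clf.fit(X, y)
    importances = pd.Series(clf.feature_importances_, index=list(candidate_genes))
    total = importances.sum()
    if total > 0:
        importances = importances / total
    return CascadeStep(
        entity=target_entity,
        marker_genes=list(candidate_genes),
        classifier=clf,
        gini_importances=importances,
        seed=seed,
    )


def _upregulated_mask(
    values: pd.DataFrame, labels: pd.Series, target_entity: str, genes: Sequence[str]
) -> pd.Series:
    labels = labels.reindex(values.columns)
    in_target = (labels == target_entity).to_numpy()
    sub = values.loc[list(genes)]
    return pd.Series(
        sub.to_numpy()[:, in_target].mean(axis=1) > sub.to_numpy()[:, ~in_target].mean(axis=1),
        index=list(genes),
    )


def refine_markers(
    step: CascadeStep,
    matrix: NormalizedMatrix | pd.DataFrame,
    labels: pd.Series,
    k: int,
    config: CascadeConfig | None = None,
) -> CascadeStep:
    """Keep the top-k upregulated genes by Gini importance and retrain."""
    config = config or CascadeConfig()
    values = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    up = _upregulated_mask(values, labels, step.entity, step.marker_genes)
    ranked = step.gini_importances.sort_values(ascending=False, kind="stable").index
    refined = [g for g in ranked if up[g]][:k]
    if not refined:
        raise ValueError(f"step {step.entity}: no upregulated gene among candidates")
    X, y = _binary_xy(values, labels, step.entity, refined)
    clf = _make_forest(config, step.seed)
    clf.fit(X, y)
    importances = pd.Series(clf.feature_importances_, index=refined)
    total = importances.sum()
    if total > 0:
        importances = importances / total
    return CascadeStep(
        entity=step.entity,
        marker_genes=refined,
        classifier=clf,
        gini_importances=importances,
        seed=step.seed,
    )


def _step_loo_youden(
    values: pd.DataFrame,
    labels: pd.Series,
    entity: str,
    genes: Sequence[str],
    config: CascadeConfig,
    seed: int,
) -> float:
    """Leave-one-out Youden index (sens + spec - 1) of a single binary step."""
    labels = labels.reindex(values.columns)
    y_true = (labels == entity).to_numpy().astype(int)
    calls = np.empty(len(y_true), dtype=int)
    for i, sample in enumerate(values.columns):
        rest = [s for s in values.columns if s != sample]
        X, y = _binary_xy(values[rest], labels[rest], entity, genes)
        clf = _make_forest(config, seed)
        clf.fit(X, y)
        step = CascadeStep(entity, list(genes), clf, pd.Series(1.0, index=list(genes)), seed)
        calls[i] = int(step.probability(values[[sample]])[0] >= config.threshold)
    tp = int(((calls == 1) & (y_true == 1)).sum())
    tn = int(((calls == 0) & (y_true == 0)).sum())
    sens = tp / max(y_true.sum(), 1)
    spec = tn / max((1 - y_true).sum(), 1)
    return sens + spec - 1.0


def _choose_k_auto(
    step: CascadeStep,
    values: pd.DataFrame,
    labels: pd.Series,
    config: CascadeConfig,
) -> int:
    up = _upregulated_mask(values, labels, step.entity, step.marker_genes)
    ranked = [g for g in step.gini_importances.sort_values(ascending=False, kind="stable").index if up[g]]
    lo, hi = config.auto_k_range
    best_k, best_j = lo, -np.inf
    for k in range(lo, min(hi, len(ranked)) + 1):
        j = _step_loo_youden(values, labels, step.entity, ranked[:k], config, step.seed)
        if j > best_j:  # ties keep the smaller (more parsimonious) k
            best_k, best_j = k, j
    return best_k


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------

def fit_cascade(
    matrix: NormalizedMatrix | pd.DataFrame,
    labels: pd.Series,
    candidate_genes: Sequence[str],
    config: CascadeConfig | None = None,
) -> CascadeModel:
    """Train the full cascade: order entities, train + refine each step."""
    config = config or CascadeConfig()
    values = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    labels = labels.reindex(values.columns)
    entities_present = sorted(set(labels.unique()) - {CONTROL})
    if not entities_present:
        raise ValueError("no entity samples in labels")

    dbi_values: dict[str, float] = {}
    if isinstance(config.entity_order, str) and config.entity_order == "dbi":
        if len(entities_present) >= 2:
            ordered = entity_dbi_order(values.loc[list(candidate_genes)], labels, entities_present)
            order = [e for e, _ in ordered]
            dbi_values = dict(ordered)
        else:
            order = entities_present
    elif isinstance(config.entity_order, str) and config.entity_order == "published":
        order = [e for e in PUBLISHED_ORDER if e in entities_present]
    else:
        order = list(config.entity_order)
        missing = [e for e in order if e not in entities_present]
        if missing:
            raise ValueError(f"entities in forced order absent from labels: {missing}")

    steps: list[CascadeStep] = []
    for i, entity in enumerate(order):
        step_seed = config.seed + i
        pre = train_step(values, labels, entity, candidate_genes, config, seed=step_seed)
        k = config.k_for(entity)
        if k is None:
            k = _choose_k_auto(pre, values, labels, config)
        steps.append(refine_markers(pre, values, labels, k, config))

    hk = matrix.housekeeping_used if isinstance(matrix, NormalizedMatrix) else []
    return CascadeModel(
        steps=steps,
        threshold=config.threshold,
        dbi_values=dbi_values,
        housekeeping_set=list(hk),
        config=config,
    )


def predict(
    model: CascadeModel,
    matrix: NormalizedMatrix | pd.DataFrame,
    full_profile: bool = False,
) -> list[PredictionResult]:
    """Run the cascade on every sample of the matrix.

    Steps are evaluated in order; the first step with probability >= threshold
    (boundary inclusive) names the entity and later steps are skipped unless
    ``full_profile`` requests the complete probability profile for diagnostics.
    """
    values = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    step_probs = np.full((len(model.steps), values.shape[1]), np.nan)

    # probabilities are computed step-by-step; a fired sample needs no later steps
    n = values.shape[1]
    active = np.ones(n, dtype=bool)
    for i, step in enumerate(model.steps):
        if not (full_profile or active.any()):
            break
        idx = np.arange(n) if full_profile else np.flatnonzero(active)
        p = step.probability(values.iloc[:, idx])
        step_probs[i, idx] = p
        fired = np.zeros(n, dtype=bool)
        fired[idx] = p >= model.threshold
        active &= ~fired

    results = []
    for j, sample in enumerate(values.columns):
        probs: dict[str, float] = {}
        call, stopped = UNDETERMINED, None
        for i, step in enumerate(model.steps):
            p = step_probs[i, j]
            if np.isnan(p):
                continue
            probs[step.entity] = float(p)
            if stopped is None and p >= model.threshold:
                call, stopped = step.entity, i
        results.append(PredictionResult(sample, probs, call, stopped))
    return results


def predictions_table(results: Sequence[PredictionResult], entity_order: Sequence[str]) -> pd.DataFrame:
    rows = []
    for r in results:
        row: dict = {"sample_id": r.sample_id}
        for e in entity_order:
            row[f"p_{e}"] = r.probabilities.get(e)
        row["final_call"] = r.final_call
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class LOOSummary:
    n_entity_samples: int
    n_correct: int
    n_misclassified: int
    n_undetermined: int

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_entity_samples if self.n_entity_samples else float("nan")


def loo_evaluate(
    matrix: NormalizedMatrix | pd.DataFrame,
    labels: pd.Series,
    candidate_genes: Sequence[str],
    config: CascadeConfig | None = None,
    reselect_markers: bool = False,
) -> tuple[list[PredictionResult], LOOSummary]:
    """Leave-one-out evaluation of the whole cascade.

    By default the step order and refined marker sets are frozen from the fit
    on all samples and only the forests are refit per fold; full per-fold
    marker re-selection is available with ``reselect_markers=True``.
    """
    config = config or CascadeConfig()
    values = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    labels = labels.reindex(values.columns)
    entity_counts = labels[labels != CONTROL].value_counts()
    small = entity_counts[entity_counts < 2]
    if not small.empty:
        raise ValueError(f"entities with <2 samples: {list(small.index)}")

    full_model = fit_cascade(values, labels, candidate_genes, config)
    frozen_config = replace(config, entity_order=full_model.entity_order)

    results: list[PredictionResult] = []
    for sample in values.columns:
        rest_cols = [s for s in values.columns if s != sample]
        sub_values, sub_labels = values[rest_cols], labels[rest_cols]
        if reselect_markers:
            fold = fit_cascade(sub_values, sub_labels, candidate_genes, frozen_config)
            results.extend(predict(fold, values[[sample]]))
            continue
        # frozen marker sets: refit step forests lazily — a later step is only
        # needed (and only fitted) when no earlier step fired for this sample
        probs: dict[str, float] = {}
        call, stopped = UNDETERMINED, None
        held_out = values[[sample]]
        for i, step in enumerate(full_model.steps):
            X, y = _binary_xy(sub_values, sub_labels, step.entity, step.marker_genes)
            clf = _make_forest(config, step.seed)
            clf.fit(X, y)
            imp = pd.Series(clf.feature_importances_, index=step.marker_genes)
            if imp.sum() > 0:
                imp = imp / imp.sum()
            fold_step = CascadeStep(step.entity, list(step.marker_genes), clf, imp, step.seed)
            p = float(fold_step.probability(held_out)[0])
            probs[step.entity] = p
            if p >= config.threshold:
                call, stopped = step.entity, i
                break
        results.append(PredictionResult(sample, probs, call, stopped))

    is_entity = labels != CONTROL
    n_entity = int(is_entity.sum())
    n_correct = n_mis = n_und = 0
    for r in results:
        truth = labels[r.sample_id]
        if truth == CONTROL:
            continue
        if r.final_call == truth:
            n_correct += 1
        elif r.final_call == UNDETERMINED:
            n_und += 1
        else:
            n_mis += 1
    return results, LOOSummary(n_entity, n_correct, n_mis, n_und)
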