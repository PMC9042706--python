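"""Synthetic NanoString-like cohorts with the structure the classifier assumes.

The generator emulates the data-generating process the cascade is built
for: each lymphoma entity upregulates a private block of marker genes on a
shared background; housekeeping genes are flat across all classes; every
sample carries a log-normal library-size factor; counts are negative
binomial (overdispersed Poisson); and tumor purity dilutes the malignant
expression profile linearly toward the nonmalignant background at the mean
level, as in a bulk mixture of tumor and bystander cells. Genetic-marker
status is drawn per sample at entity-conditional prevalences.

Entities listed in ``no_signature_entities`` (HCL by default) receive no
expression signature — their profile equals the background — mirroring
entities that the expression model cannot see and only genetics can call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    CONTROL,
    ENDOGENOUS,
    ENTITIES,
    GENETIC_MARKERS,
    HOUSEKEEPING,
    CountMatrix,
    GenePanel,
    SampleAnnotation,
)

#: entity-conditional genetic-marker prevalences; "default" covers the rest
DEFAULT_PREVALENCES: dict[str, dict[str, float]] = {
    "IGH_BCL2": {"FL": 0.8, "default": 0.03},
    "MYD88_L265P": {"LPL/WM": 0.9, "default": 0.05},
    "BRAF_V600E": {"HCL": 0.9, "default": 0.05},
    "EZH2_Y646": {"default": 0.05},
}


@dataclass
class SyntheticConfig:
    """Study-condition parameters of the simulated cohort."""

    entities: tuple[str, ...] = ENTITIES
    samples_per_entity: int = 20
    n_controls: int = 40
    markers_per_entity: int = 8
    n_background_genes: int = 60
    n_housekeeping_genes: int = 6
    effect_size: float = 2.0  # log2 upregulation of an entity's markers
    baseline_mean: float = 100.0  # endogenous background mean counts
    housekeeping_mean: float = 500.0
    dispersion: float = 20.0  # NB size r: var = mu + mu^2 / r
    library_sd: float = 0.3  # sd of log library-size factor
    purity: float | tuple[float, float] | Sequence[float] = (0.9, 1.0)
    prevalences: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {m: dict(v) for m, v in DEFAULT_PREVALENCES.items()}
    )
    no_signature_entities: tuple[str, ...] = ("HCL", "other_SBCLN")
    cohort: str = "training"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")
        if self.samples_per_entity < 1 or (self.n_controls < 1 and self.entities):
            raise ValueError("need at least 1 sample per class")
        if self.dispersion <= 0 or self.baseline_mean <= 0:
            raise ValueError("dispersion and baseline_mean must be > 0")
        for marker, table in self.prevalences.items():
            for key, p in table.items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"prevalence {marker}/{key} outside [0,1]")

    def marker_genes_for(self, entity: str) -> list[str]:
        if entity in self.no_signature_entities:
            return []
        tag = entity.replace("/", "")
        return [f"{tag}_mk{j + 1}" for j in range(self.markers_per_entity)]

    @property
    def background_genes(self) -> list[str]:
        return [f"BG{j + 1:03d}" for j in range(self.n_background_genes)]

    @property
    def housekeeping_genes(self) -> list[str]:
        return [f"HK{j + 1}" for j in range(self.n_housekeeping_genes)]

    @property
    def planted_markers(self) -> dict[str, list[str]]:
        return {e: self.marker_genes_for(e) for e in self.entities if self.marker_genes_for(e)}

    def panel(self) -> GenePanel:
        candidates = [g for gs in self.planted_markers.values() for g in gs] + self.background_genes
        return GenePanel(
            candidate_genes=candidates,
            housekeeping_candidates=self.housekeeping_genes,
            refined_markers={},
        )


def _purities(config: SyntheticConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    p = config.purity
    if isinstance(p, (int, float)):
        return np.full(n, float(p))
    p = tuple(p) if not isinstance(p, tuple) else p
    if len(p) == 2 and all(isinstance(x, (int, float)) for x in p) and not isinstance(config.purity, list):
        lo, hi = float(p[0]), float(p[1])
        return rng.uniform(lo, hi, size=n)
    arr = np.asarray(config.purity, dtype=float)
    if arr.size != n:
        raise ValueError(f"per-sample purity list has {arr.size} values, need {n}")
    return arr


def _nb_draw(mu: np.ndarray, r: float, rng: np.random.Generator) -> np.ndarray:
    # negative binomial with mean mu and size r (var = mu + mu^2/r)
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_cohort(config: SyntheticConfig) -> tuple[CountMatrix, list[SampleAnnotation]]:
    """Draw a full cohort of raw counts plus annotations, seed-reproducibly."""
    rng = np.random.default_rng(config.seed)
    planted = config.planted_markers
    marker_genes = [g for gs in planted.values() for g in gs]
    genes = marker_genes + config.background_genes + config.housekeeping_genes
    n_endo = len(marker_genes) + len(config.background_genes)
    roles = [ENDOGENOUS] * n_endo + [HOUSEKEEPING] * config.n_housekeeping_genes

    # entity-profile means on the endogenous genes (tumor at purity 1)
    base = np.full(n_endo, config.baseline_mean)
    profiles: dict[str, np.ndarray] = {}
    for e in config.entities:
        mu = base.copy()
        for g in planted.get(e, []):
            mu[genes.index(g)] = config.baseline_mean * 2.0 ** config.effect_size
        profiles[e] = mu

    columns: dict[str, np.ndarray] = {}
    annotations: list[SampleAnnotation] = []

    def draw_sample(sample_id: str, entity: str | None, rho: float | None) -> None:
        lib = float(np.exp(rng.normal(0.0, config.library_sd)))
        if entity is None:
            mu_endo = base
        else:
            mu_endo = rho * profiles[entity] + (1.0 - rho) * base
        mu = np.concatenate([mu_endo, np.full(config.n_housekeeping_genes, config.housekeeping_mean)])
        columns[sample_id] = _nb_draw(lib * mu, config.dispersion, rng)
        annotations.append(
            SampleAnnotation(
                sample_id=sample_id,
                cohort=config.cohort,
                label=CONTROL if entity is None else entity,
                tumor_cell_content=rho,
            )
        )

    # per-sample purity lists run over all entity samples in entity order
    all_rhos = _purities(config, len(config.entities) * config.samples_per_entity, rng)
    for ei, e in enumerate(config.entities):
        rhos = all_rhos[ei * config.samples_per_entity : (ei + 1) * config.samples_per_entity]
        tag = e.replace("/", "")
        for i in range(config.samples_per_entity):
            draw_sample(f"{tag}_s{i + 1:03d}", e, float(rhos[i]))
    for i in range(config.n_controls):
        draw_sample(f"CTRL_s{i + 1:03d}", None, None)

    counts = pd.DataFrame(columns, index=pd.Index(genes, name="gene"), dtype=np.int64)
    matrix = CountMatrix(counts, pd.Series(roles, index=genes, name="gene_role"))
    return matrix, annotations


def simulate_marker_status(
    annotations: Sequence[SampleAnnotation],
    config: SyntheticConfig,
    seed: int | None = None,
) -> list[SampleAnnotation]:
    """Fill genetic-marker status by independent Bernoulli draws at the
    configured entity-conditional prevalences. Controls stay negative."""
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    out = []
    for ann in annotations:
        status: dict[str, str] = {}
        for marker in GENETIC_MARKERS:
            table = config.prevalences.get(marker, {"default": 0.0})
            if ann.label == CONTROL:
                prev = 0.0
            else:
                prev = table.get(ann.label, table.get("default", 0.0))
            status[marker] = "positive" if rng.random() < prev else "negative"
        out.append(replace(ann, marker_status=status))
    return out
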