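"""Domain types and readers/writers for counts, panels, annotations and models.

The central container is :class:`CountMatrix` — a genes x samples table of
raw nonnegative integer NanoString-style counts, with a per-gene role tag
(endogenous / housekeeping candidate / positive control / negative control).
Positive/negative control probes are retained in the object but excluded
from all downstream mathematics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
import yaml

# gene roles
ENDOGENOUS = "endogenous"
HOUSEKEEPING = "housekeeping_candidate"
POSITIVE_CTRL = "positive_control"
NEGATIVE_CTRL = "negative_control"
GENE_ROLES = (ENDOGENOUS, HOUSEKEEPING, POSITIVE_CTRL, NEGATIVE_CTRL)

# sample labels
ENTITIES = ("CLL/SLL", "cMCL", "FL", "nnMCL", "MZL", "LPL/WM")
CONTROL = "control"
UNDETERMINED = "undetermined"
HCL = "HCL"

GENETIC_MARKERS = ("IGH_BCL2", "MYD88_L265P", "BRAF_V600E", "EZH2_Y646")

_RCC_ROLE_MAP = {
    "endogenous": ENDOGENOUS,
    "housekeeping": HOUSEKEEPING,
    "positive": POSITIVE_CTRL,
    "negative": NEGATIVE_CTRL,
}

MODEL_FORMAT_VERSION = 1


class RCCParseError(ValueError):
    """Raised when an RCC file is malformed."""


@dataclass
class CountMatrix:
    """Raw digital-expression counts, genes x samples, with gene roles."""

    counts: pd.DataFrame  # genes x samples, nonnegative integers
    gene_role: pd.Series  # indexed by gene, values in GENE_ROLES

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if self.counts.columns.duplicated().any():
            dups = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        self.gene_role = self.gene_role.reindex(self.counts.index)
        if self.gene_role.isna().any():
            missing = self.gene_role.index[self.gene_role.isna()].tolist()
            raise ValueError(f"genes without a role: {missing}")
        bad = set(self.gene_role.unique()) - set(GENE_ROLES)
        if bad:
            raise ValueError(f"unknown gene roles: {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def genes_with_role(self, role: str) -> list[str]:
        return list(self.gene_role.index[self.gene_role == role])

    @property
    def housekeeping_candidates(self) -> list[str]:
        return self.genes_with_role(HOUSEKEEPING)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)], self.gene_role.copy())

    @staticmethod
    def column_bind(matrices: Sequence["CountMatrix"]) -> "CountMatrix":
        """Merge single/multi-sample matrices sharing an identical gene set.

        Gene order of the first matrix is preserved.
        """
        if not matrices:
            raise ValueError("nothing to bind")
        first = matrices[0]
        for m in matrices[1:]:
            if set(m.gene_ids) != set(first.gene_ids):
                raise ValueError("gene sets differ between matrices")
        frames = [m.counts.reindex(first.counts.index) for m in matrices]
        return CountMatrix(pd.concat(frames, axis=1), first.gene_role.copy())


@dataclass
class SampleAnnotation:
    """Per-sample clinical annotation."""

    sample_id: str
    cohort: str = "other"  # training / validation / other
    label: str = "unknown"  # entity, control, or unknown
    tumor_cell_content: float | None = None
    sample_type: str | None = None  # FFPE / fresh_frozen
    marker_status: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tumor_cell_content is not None:
            if not (0.0 <= self.tumor_cell_content <= 1.0):
                raise ValueError(
                    f"tumor_cell_content {self.tumor_cell_content} outside [0,1] "
                    f"for sample {self.sample_id}"
                )
        for marker, status in self.marker_status.items():
            if status not in ("positive", "negative", "unknown"):
                raise ValueError(f"bad marker status {status!r} for {marker}")

    def marker(self, name: str) -> str:
        return self.marker_status.get(name, "unknown")


@dataclass
class GenePanel:
    """The screening panel: candidate genes, housekeeping candidates and the
    per-entity refined marker lists."""

    candidate_genes: list[str] = field(default_factory=list)
    housekeeping_candidates: list[str] = field(default_factory=list)
    refined_markers: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.candidate_genes) & set(self.housekeeping_candidates)
        if overlap:
            raise ValueError(f"genes in both candidate and housekeeping sets: {sorted(overlap)}")
        for entity, genes in self.refined_markers.items():
            stray = set(genes) - set(self.candidate_genes)
            if stray:
                raise ValueError(f"refined markers for {entity} not in candidate panel: {sorted(stray)}")

    @property
    def marker_union(self) -> list[str]:
        """Union of all refined marker lists, first occurrence order."""
        seen: dict[str, None] = {}
        for genes in self.refined_markers.values():
            for g in genes:
                seen.setdefault(g, None)
        return list(seen)


# ---------------------------------------------------------------------------
# RCC reading
# ---------------------------------------------------------------------------

def _split_rcc_line(line: str) -> list[str]:
    # RCC dialects in the wild are comma- or tab-delimited
    return line.split("\t") if "\t" in line else line.split(",")


def read_rcc(path: str | Path) -> tuple[CountMatrix, dict]:
    """Parse a NanoString RCC raw file into a single-sample :class:`CountMatrix`.

    Returns the matrix plus a metadata dict with the header and sample/lane
    attributes. The sample id is taken from the Sample_Attributes ``ID`` row
    (file stem as fallback).
    """
    path = Path(path)
    sections: dict[str, list[list[str]]] = {}
    current: str | None = None
    for raw_line in path.read_text().splitlines():
        line = raw_line.strip()
        if not line:
            continue
        if line.startswith("</"):
            current = None
            continue
        if line.startswith("<") and line.endswith(">"):
            current = line[1:-1]
            sections.setdefault(current, [])
            continue
        if current is not None:
            sections[current].append(_split_rcc_line(line))

    if "Code_Summary" not in sections or not sections["Code_Summary"]:
        raise RCCParseError(f"{path}: missing Code_Summary section")

    meta = {
        name: {row[0]: (row[1] if len(row) > 1 else "") for row in rows}
        for name, rows in sections.items()
        if name != "Code_Summary"
    }
    sample_id = meta.get("Sample_Attributes", {}).get("ID") or path.stem

    rows = sections["Code_Summary"]
    header = [h.strip() for h in rows[0]]
    try:
        i_class = header.index("CodeClass")
        i_name = header.index("Name")
        i_count = header.index("Count")
    except ValueError as exc:
        raise RCCParseError(f"{path}: Code_Summary header must contain CodeClass, Name, Count") from exc

    genes, roles, counts = [], [], []
    for row in rows[1:]:
        if len(row) <= max(i_class, i_name, i_count):
            raise RCCParseError(f"{path}: short Code_Summary row {row!r}")
        code_class = row[i_class].strip().lower()
        role = _RCC_ROLE_MAP.get(code_class)
        if role is None:
            raise RCCParseError(f"{path}: unknown CodeClass {row[i_class]!r}")
        count_str = row[i_count].strip()
        try:
            count = int(count_str)
        except ValueError:
            raise ValueError(f"{path}: non-integer count {count_str!r} for gene {row[i_name]!r}") from None
        genes.append(row[i_name].strip())
        roles.append(role)
        counts.append(count)

    cm = CountMatrix(
        pd.DataFrame({sample_id: counts}, index=pd.Index(genes, name="gene")),
        pd.Series(roles, index=genes, name="gene_role"),
    )
    return cm, meta


# ---------------------------------------------------------------------------
# Count tables and annotations
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_count_table(path: str | Path, panel: GenePanel | None = None) -> CountMatrix:
    """Read a TSV/CSV count table (first column gene id, remaining samples).

    Gene roles are assigned from panel membership; genes absent from the panel
    are tagged endogenous.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, comment="#")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate gene ids {dups}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"{path}: non-numeric counts")
    if (values < 0).any():
        raise ValueError(f"{path}: negative counts")
    if not np.allclose(values, np.round(values)):
        raise ValueError(f"{path}: non-integer counts")
    df = df.round().astype(np.int64)

    hk = set(panel.housekeeping_candidates) if panel else set()
    roles = pd.Series(
        [HOUSEKEEPING if g in hk else ENDOGENOUS for g in df.index],
        index=df.index,
        name="gene_role",
    )
    return CountMatrix(df, roles)


def write_count_table(matrix: CountMatrix, path: str | Path) -> None:
    path = Path(path)
    matrix.counts.to_csv(path, sep=_sep_for(path))


def read_annotations(path: str | Path) -> list[SampleAnnotation]:
    """Read a TSV/CSV annotation table.

    Required column: sample_id. Optional: cohort, label, tumor_cell_content,
    sample_type, and one column per genetic marker (positive/negative/unknown).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, comment="#")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing sample_id column")
    anns = []
    for _, row in df.iterrows():
        tcc = row.get("tumor_cell_content")
        tcc = float(tcc) if tcc not in (None, "", "NA") and pd.notna(tcc) else None
        markers = {
            m: (row[m] if pd.notna(row.get(m)) else "unknown")
            for m in GENETIC_MARKERS
            if m in df.columns
        }
        anns.append(
            SampleAnnotation(
                sample_id=row["sample_id"],
                cohort=row.get("cohort") if pd.notna(row.get("cohort")) else "other",
                label=row.get("label") if pd.notna(row.get("label")) else "unknown",
                tumor_cell_content=tcc,
                sample_type=row.get("sample_type") if pd.notna(row.get("sample_type")) else None,
                marker_status=markers,
            )
        )
    return anns


def write_annotations(annotations: Sequence[SampleAnnotation], path: str | Path) -> None:
    path = Path(path)
    rows = []
    for a in annotations:
        row = {
            "sample_id": a.sample_id,
            "cohort": a.cohort,
            "label": a.label,
            "tumor_cell_content": a.tumor_cell_content,
            "sample_type": a.sample_type,
        }
        for m in GENETIC_MARKERS:
            row[m] = a.marker(m)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


def annotations_by_id(annotations: Sequence[SampleAnnotation]) -> dict[str, SampleAnnotation]:
    return {a.sample_id: a for a in annotations}


def labels_series(annotations: Sequence[SampleAnnotation]) -> pd.Series:
    return pd.Series({a.sample_id: a.label for a in annotations}, name="label")


# ---------------------------------------------------------------------------
# Panels
# ---------------------------------------------------------------------------

def read_panel(path: str | Path) -> GenePanel:
    """Read a panel definition from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return GenePanel(
        candidate_genes=list(data.get("candidate_genes", [])),
        housekeeping_candidates=list(data.get("housekeeping_candidates", [])),
        refined_markers={k: list(v) for k, v in (data.get("refined_markers") or {}).items()},
    )


def write_panel(panel: GenePanel, path: str | Path) -> None:
    path = Path(path)
    data = {
        "candidate_genes": panel.candidate_genes,
        "housekeeping_candidates": panel.housekeeping_candidates,
        "refined_markers": panel.refined_markers,
    }
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# Model serialization
# ---------------------------------------------------------------------------

def save_model(model, path: str | Path) -> None:
    """Serialize a fitted cascade model (joblib bundle with a version tag)."""
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, path)


def load_model(path: str | Path):
    path = Path(path)
    try:
        bundle = joblib.load(path)
    except Exception as exc:
        raise ValueError(f"{path}: cannot read model bundle ({exc})") from exc
    if not isinstance(bundle, dict) or "format_version" not in bundle:
        raise ValueError(f"{path}: not a model bundle")
    if bundle["format_version"] != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"{path}: model format version {bundle['format_version']} != {MODEL_FORMAT_VERSION}"
        )
    return bundle["model"]
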