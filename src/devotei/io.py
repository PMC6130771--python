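"""Domain types and readers/writers for expression, annotation and timeline files.

The canonical interchange formats are deliberately narrow:

* expression — TSV, genes as rows, ordered stages as columns, '.' decimal;
* annotation — TSV with columns ``gene_id, omega0, phylostratum,
  paralog_count, connectivity, is_retrogene`` (empty cell = missing);
* stage timeline — YAML/JSON ``{stages: [{id, period}]}``.

The expression *scale* is always declared by the caller, never inferred:
microarray series typically arrive already log-transformed while RNA-seq
arrives as counts or normalized linear values, and silent inference risks
double-transformation.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SCALES",
    "PERIOD_ORDER",
    "ExpressionMatrix",
    "StageTimeline",
    "TissuePanel",
    "read_expression",
    "write_expression",
    "read_timeline",
    "write_timeline",
    "read_annotation",
    "write_annotation",
    "validate_annotation",
    "read_tissue_panel",
    "write_tissue_panel",
    "resolve_omega0",
]

SCALES = ("raw_count", "normalized_linear", "log_transformed")
PERIOD_ORDER = ("preMZT", "early", "middle", "late")

ANNOTATION_COLUMNS = (
    "omega0",
    "phylostratum",
    "paralog_count",
    "connectivity",
    "is_retrogene",
)


@dataclass
class ExpressionMatrix:
    """Gene-by-stage expression with a declared measurement scale.

    ``data`` is a genes × stages DataFrame; column order is the stage
    order and is preserved through the whole pipeline.  On linear scales
    every value must be ≥ 0 and absence is encoded as 0; on the
    ``log_transformed`` scale negative values are legitimate.
    """

    data: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.isfinite(values).all():
            raise ValueError("expression values must be finite (no missing cells)")
        if self.scale != "log_transformed" and (values < 0).any():
            raise ValueError(f"negative value on linear scale {self.scale!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def stage_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def with_data(self, data: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(data=data, scale=scale if scale is not None else self.scale)


@dataclass
class StageTimeline:
    """Ordered developmental stages, each labelled with a broad period.

    Periods must occur as contiguous blocks in developmental order
    preMZT → early → middle → late.  preMZT and late may be absent, but
    the early-vs-middle contrast needs at least one stage in each of the
    early and middle periods, so both are mandatory.
    """

    stage_ids: list[str]
    periods: list[str]

    def __post_init__(self) -> None:
        if len(self.stage_ids) != len(self.periods):
            raise ValueError("stage_ids and periods must have equal length")
        if len(set(self.stage_ids)) != len(self.stage_ids):
            raise ValueError("duplicate stage ids in timeline")
        bad = sorted(set(self.periods) - set(PERIOD_ORDER))
        if bad:
            raise ValueError(f"unknown period labels: {bad}")
        # contiguity: collapse runs and require the collapsed sequence to be a
        # subsequence of the canonical order with no repeats
        runs: list[str] = []
        for p in self.periods:
            if not runs or runs[-1] != p:
                runs.append(p)
        if len(runs) != len(set(runs)):
            raise ValueError(f"period blocks are not contiguous: {self.periods}")
        order = [PERIOD_ORDER.index(p) for p in runs]
        if order != sorted(order):
            raise ValueError(f"periods out of developmental order: {runs}")
        for required in ("early", "middle"):
            if required not in runs:
                raise ValueError(f"timeline lacks a {required!r} stage block")

    def stages_in(self, period: str) -> list[str]:
        return [s for s, p in zip(self.stage_ids, self.periods) if p == period]

    @property
    def period_of(self) -> dict[str, str]:
        return dict(zip(self.stage_ids, self.periods))


@dataclass
class TissuePanel:
    """Gene-by-tissue log-scale expression with one designated testis column."""

    data: pd.DataFrame
    testis: str = "testis"

    def __post_init__(self) -> None:
        if self.data.shape[1] < 2:
            raise ValueError("tissue panel requires at least 2 tissues")
        if self.testis not in self.data.columns:
            raise ValueError(f"testis tissue {self.testis!r} not among panel columns")
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValueError("tissue panel values must be finite")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def tissue_ids(self) -> list[str]:
        return list(self.data.columns)


def read_expression(path: str | Path, scale: str) -> ExpressionMatrix:
    """Read a genes-as-rows TSV with a header row of stage ids.

    Raises on duplicate gene ids, non-numeric cells and (on linear scales)
    negative values — these are data errors, not conditions to repair.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric expression cell in {path}: {exc}") from exc
    return ExpressionMatrix(data=df, scale=scale)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    out = m.data.copy()
    out.index.name = "gene_id"
    # repr round-trips float64 exactly
    out.to_csv(path, sep="\t", float_format=None)


def read_timeline(path: str | Path) -> StageTimeline:
    """Read a YAML/JSON timeline config of the form ``stages: [{id, period}]``."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "stages" not in doc:
        raise ValueError(f"timeline file {path} lacks a 'stages' key")
    stages = doc["stages"]
    return StageTimeline(
        stage_ids=[str(s["id"]) for s in stages],
        periods=[str(s["period"]) for s in stages],
    )


def write_timeline(timeline: StageTimeline, path: str | Path) -> None:
    doc = {
        "stages": [
            {"id": s, "period": p} for s, p in zip(timeline.stage_ids, timeline.periods)
        ]
    }
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate and coerce a per-gene annotation table (index = gene_id).

    Any field may be missing (NaN) for any gene; each downstream index uses
    only genes with that field present.
    """
    if ann.index.duplicated().any():
        dups = ann.index[ann.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in annotation: {dups}")
    ann = ann.copy()
    for col in ("omega0", "phylostratum", "paralog_count", "connectivity"):
        if col in ann.columns:
            ann[col] = pd.to_numeric(ann[col], errors="raise")
    if "omega0" in ann.columns and (ann["omega0"].dropna() < 0).any():
        raise ValueError("omega0 must be nonnegative")
    if "phylostratum" in ann.columns and (ann["phylostratum"].dropna() < 1).any():
        raise ValueError("phylostratum must be >= 1 (1 = oldest)")
    for col in ("paralog_count", "connectivity"):
        if col in ann.columns and (ann[col].dropna() < 0).any():
            raise ValueError(f"{col} must be nonnegative")
    if "is_retrogene" in ann.columns:
        ann["is_retrogene"] = ann["is_retrogene"].map(
            {True: True, False: False, "True": True, "False": False, 1: True, 0: False,
             "1": True, "0": False, "true": True, "false": False}
        )
    return ann


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col="gene_id")
    return validate_annotation(ann)


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    out = ann.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_tissue_panel(path: str | Path, testis: str = "testis") -> TissuePanel:
    df = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    return TissuePanel(data=df, testis=testis)


def write_tissue_panel(panel: TissuePanel, path: str | Path) -> None:
    out = panel.data.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


BRANCH_RELATIONS = ("pre_duplication", "post_duplication", "unique")


def resolve_omega0(records: Iterable[tuple[str, str, float]]) -> pd.Series:
    """Collapse per-branch ω₀ records to one value per gene.

    A gene that overlaps a duplication node carries two branch values; the
    branch *following* the duplication reflects the gene's own recent
    selective regime, so the post-duplication value is kept and the
    pre-duplication value discarded.  Genes without a duplication carry a
    single ``unique`` record.  More than two records per gene (nested
    duplications) are rejected rather than guessed at.
    """
    by_gene: dict[str, dict[str, float]] = {}
    for gene_id, relation, value in records:
        if relation not in BRANCH_RELATIONS:
            raise ValueError(f"unknown branch relation {relation!r} for {gene_id}")
        slot = by_gene.setdefault(gene_id, {})
        if relation in slot:
            raise ValueError(
                f"gene {gene_id} has two {relation!r} records; at most one allowed"
            )
        slot[relation] = float(value)

    resolved: dict[str, float] = {}
    for gene_id, slot in by_gene.items():
        if len(slot) > 2:
            raise ValueError(f"gene {gene_id} has more than two branch records")
        if "post_duplication" in slot:
            resolved[gene_id] = slot["post_duplication"]
        elif "unique" in slot:
            if "pre_duplication" in slot:
                raise ValueError(
                    f"gene {gene_id} mixes 'unique' and 'pre_duplication' records"
                )
            resolved[gene_id] = slot["unique"]
        else:
            raise ValueError(
                f"gene {gene_id} has only a pre-duplication record; no usable value"
            )
    return pd.Series(resolved, name="omega0", dtype=float)
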