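"""TSV readers and writers for every pipeline artifact.

All files are tab-separated with a single header row; writers prepend a
comment line recording the processing stage and pipeline version so a file
is self-describing. Readers reject malformed input atomically — no partial
ingestion.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .errors import ParseError, SchemaError
from .types import (
    ExpressionMatrix,
    IHCRecord,
    SampleAnnotation,
    Stage,
    TargetPair,
    validate_annotations,
)

logger = logging.getLogger(__name__)

_ANNOTATION_COLUMNS = ["sample_id", "group", "run_id", "chip_id"]
_TARGET_COLUMNS = ["mirna_id", "gene_id"]
_IHC_COLUMNS = [
    "case_id",
    "cohort",
    "truth_group",
    "marker",
    "intensity",
    "percent_category",
    "evaluable",
]


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", comment="#", **kwargs)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"{path}: malformed TSV: {exc}") from exc
    if frame.shape[0] == 0 and frame.shape[1] == 0:
        raise ParseError(f"{path}: no data rows")
    return frame


def _header_comment(stage: str | None = None) -> str:
    tag = f" stage={stage}" if stage else ""
    return f"# basalmir v{__version__}{tag}\n"


# -- expression matrices ---------------------------------------------------

def read_expression_matrix(path, stage: Stage | str) -> ExpressionMatrix:
    """Read a features x samples TSV (first column feature ids, header row
    sample ids) and validate it at the given stage."""
    frame = _read_tsv(path, index_col=0)
    for col in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            bad = frame[col][pd.to_numeric(frame[col], errors="coerce").isna()]
            line = bad.index[0] if len(bad) else "?"
            raise ParseError(
                f"{path}: non-numeric value in sample {col!r} at feature {line!r}"
            )
    return ExpressionMatrix(frame, stage)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_comment(matrix.stage.value))
        out = matrix.frame.copy()
        out.index.name = "feature_id"
        out.to_csv(fh, sep="\t", float_format="%.17g")


# -- sample annotations ----------------------------------------------------

def read_annotations(path) -> list[SampleAnnotation]:
    """Read per-sample annotations (sample_id, group, run_id, chip_id)."""
    frame = _read_tsv(path, dtype=str)
    missing = [c for c in _ANNOTATION_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    annotations = [
        SampleAnnotation(
            sample_id=row.sample_id,
            group=row.group,
            run_id=row.run_id,
            chip_id=row.chip_id,
        )
        for row in frame.itertuples()
    ]
    validate_annotations(annotations)
    return annotations


def write_annotations(annotations: Sequence[SampleAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment())
        frame = pd.DataFrame([a.__dict__ for a in annotations])
        frame.to_csv(fh, sep="\t", index=False)


# -- target-prediction tables ----------------------------------------------

def read_target_table(path, source_name: str) -> list[TargetPair]:
    """Read a (mirna_id, gene_id) prediction table for one source.

    Exact duplicate rows are dropped (the count is logged); an empty table
    yields a warning and an empty list rather than an error.
    """
    try:
        frame = _read_tsv(path, dtype=str)
    except ParseError:
        raise
    missing = [c for c in _TARGET_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if len(frame) == 0:
        logger.warning("%s: empty target table for source %r", path, source_name)
        return []
    n_before = len(frame)
    frame = frame.drop_duplicates(subset=_TARGET_COLUMNS)
    dropped = n_before - len(frame)
    if dropped:
        logger.info("%s: dropped %d duplicate target pairs", path, dropped)
    return [
        TargetPair(mirna_id=row.mirna_id, gene_id=row.gene_id, source=source_name)
        for row in frame.itertuples()
    ]


def write_target_table(pairs: Sequence[TargetPair], path) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment())
        frame = pd.DataFrame(
            {"mirna_id": [p.mirna_id for p in pairs], "gene_id": [p.gene_id for p in pairs]}
        )
        frame.to_csv(fh, sep="\t", index=False)


# -- immunohistochemistry tables -------------------------------------------

def read_ihc_table(path) -> list[IHCRecord]:
    """Read per-case per-marker IHC scores; invariants are enforced at
    ingestion (a violating row aborts the whole read)."""
    frame = _read_tsv(path, dtype=str)
    missing = [c for c in _IHC_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    records = []
    for row in frame.itertuples():
        try:
            intensity = int(row.intensity)
            percent = int(row.percent_category)
        except ValueError as exc:
            raise ParseError(
                f"{path}: case {row.case_id!r}: non-integer score"
            ) from exc
        records.append(
            IHCRecord(
                case_id=row.case_id,
                cohort=row.cohort,
                truth_group=row.truth_group,
                marker=row.marker,
                intensity=intensity,
                percent_category=percent,
                evaluable=str(row.evaluable).strip().lower() in ("1", "true", "yes"),
            )
        )
    return records


def write_ihc_table(records: Sequence[IHCRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment())
        frame = pd.DataFrame([r.__dict__ for r in records])
        frame.to_csv(fh, sep="\t", index=False)
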