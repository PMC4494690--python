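"""Domain types shared by every pipeline stage.

The central container is :class:`ExpressionMatrix`, a features x samples
intensity grid tagged with a processing stage. Stages advance only in the
documented order (raw -> filtered -> shifted -> log2 -> quantile_normalized
-> standardized), which lets each operation state its precondition as a
stage check rather than re-validating numeric properties.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, StageError, ValidationError


class Stage(enum.Enum):
    """Processing stage of an expression matrix."""

    RAW = "raw"
    FILTERED = "filtered"
    SHIFTED = "shifted"
    LOG2 = "log2"
    QUANTILE_NORMALIZED = "quantile_normalized"
    STANDARDIZED = "standardized"

    @property
    def order(self) -> int:
        return _STAGE_ORDER[self]


_STAGE_ORDER = {
    Stage.RAW: 0,
    Stage.FILTERED: 1,
    Stage.SHIFTED: 2,
    Stage.LOG2: 3,
    Stage.QUANTILE_NORMALIZED: 4,
    Stage.STANDARDIZED: 5,
}

#: Sample groups recognised by the pipeline. Fixed vocabulary: the study's
#: five biological groups plus a technical ``control`` group.
GROUPS = (
    "normal",
    "luminal",
    "basal_sporadic",
    "basal_brca1",
    "cell_line",
    "control",
)


class ExpressionMatrix:
    """Features x samples intensity grid with a processing-stage tag.

    Parameters
    ----------
    values
        DataFrame with feature ids as index and sample ids as columns, or
        anything :func:`pandas.DataFrame` accepts together with
        ``feature_ids`` / ``sample_ids``.
    stage
        Processing stage of the values.
    """

    def __init__(
        self,
        values,
        stage: Stage | str,
        feature_ids: Sequence[str] | None = None,
        sample_ids: Sequence[str] | None = None,
    ) -> None:
        if isinstance(values, pd.DataFrame):
            frame = values.copy()
        else:
            frame = pd.DataFrame(
                np.asarray(values, dtype=float),
                index=list(feature_ids) if feature_ids is not None else None,
                columns=list(sample_ids) if sample_ids is not None else None,
            )
        frame.index = frame.index.astype(str)
        frame.columns = frame.columns.astype(str)
        self._frame = frame.astype(float)
        self.stage = Stage(stage)
        self._validate()

    # -- container protocol -------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def values(self) -> np.ndarray:
        return self._frame.to_numpy()

    @property
    def feature_ids(self) -> list[str]:
        return list(self._frame.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._frame.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._frame.shape

    def _validate(self) -> None:
        if self._frame.index.has_duplicates:
            dupes = self._frame.index[self._frame.index.duplicated()].unique()
            raise ValidationError(f"duplicate feature ids: {list(dupes)[:5]}")
        if self._frame.columns.has_duplicates:
            dupes = self._frame.columns[self._frame.columns.duplicated()].unique()
            raise ValidationError(f"duplicate sample ids: {list(dupes)[:5]}")
        if self._frame.shape[0] == 0 or self._frame.shape[1] == 0:
            raise ValidationError("expression matrix must have at least one feature and one sample")
        if self.stage.order >= Stage.SHIFTED.order and self._frame.isna().any().any():
            raise ValidationError(f"missing values are not allowed at stage {self.stage.value!r}")

    def require_stage(self, stage: Stage) -> None:
        if self.stage is not stage:
            raise StageError(
                f"operation requires stage {stage.value!r}, matrix is at {self.stage.value!r}"
            )

    def advance(self, values, stage: Stage) -> "ExpressionMatrix":
        """Return a new matrix at ``stage``, enforcing the documented order."""
        stage = Stage(stage)
        if stage.order != self.stage.order + 1:
            raise StageError(
                f"illegal stage transition {self.stage.value!r} -> {stage.value!r}"
            )
        if isinstance(values, pd.DataFrame):
            return ExpressionMatrix(values, stage)
        return ExpressionMatrix(
            values, stage, feature_ids=self.feature_ids, sample_ids=self.sample_ids
        )

    def subset_features(self, feature_ids: Iterable[str], stage: Stage | None = None) -> "ExpressionMatrix":
        frame = self._frame.loc[list(feature_ids)]
        return ExpressionMatrix(frame, stage if stage is not None else self.stage)

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.stage is other.stage and self._frame.equals(other._frame)

    def __repr__(self) -> str:  # pragma: no cover - convenience
        nf, ns = self.shape
        return f"ExpressionMatrix({nf} features x {ns} samples, stage={self.stage.value})"


@dataclass(frozen=True)
class SampleAnnotation:
    """Per-sample group label and hybridisation batch identifiers."""

    sample_id: str
    group: str
    run_id: str
    chip_id: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise SchemaError(
                f"unknown group label {self.group!r}; expected one of {GROUPS}"
            )


def validate_annotations(
    annotations: Sequence[SampleAnnotation],
    sample_ids: Sequence[str] | None = None,
) -> None:
    """Check annotation invariants: unique samples, run constant within chip,
    and (optionally) exact coverage of a matrix's samples."""
    seen: dict[str, SampleAnnotation] = {}
    chip_run: dict[str, str] = {}
    for ann in annotations:
        if ann.sample_id in seen:
            raise ValidationError(f"duplicate annotation for sample {ann.sample_id!r}")
        seen[ann.sample_id] = ann
        prev = chip_run.setdefault(ann.chip_id, ann.run_id)
        if prev != ann.run_id:
            raise ValidationError(
                f"chip {ann.chip_id!r} spans runs {prev!r} and {ann.run_id!r}; "
                "run_id must be constant within a chip"
            )
    if sample_ids is not None:
        missing = [s for s in sample_ids if s not in seen]
        if missing:
            raise ValidationError(f"samples without annotation: {missing[:5]}")


def annotations_to_frame(annotations: Sequence[SampleAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [a.sample_id for a in annotations],
            "group": [a.group for a in annotations],
            "run_id": [a.run_id for a in annotations],
            "chip_id": [a.chip_id for a in annotations],
        }
    ).set_index("sample_id", drop=False)


@dataclass(frozen=True)
class TargetPair:
    """A (miRNA, gene) prediction edge from one prediction source."""

    mirna_id: str
    gene_id: str
    source: str


@dataclass(frozen=True)
class IHCRecord:
    """One marker scored on one case: staining intensity 0-3 plus stained
    tumour-cell proportion category 0-4 (composite score out of 7)."""

    case_id: str
    cohort: str
    truth_group: str
    marker: str
    intensity: int
    percent_category: int
    evaluable: bool = True

    def __post_init__(self) -> None:
        if self.cohort not in ("initial", "validation"):
            raise ValidationError(
                f"case {self.case_id!r}: unknown cohort {self.cohort!r}"
            )
        if self.truth_group not in ("brca1", "sporadic"):
            raise ValidationError(
                f"case {self.case_id!r}: unknown truth group {self.truth_group!r}"
            )
        if not 0 <= self.intensity <= 3:
            raise ValidationError(
                f"case {self.case_id!r}: intensity {self.intensity} outside 0-3"
            )
        if not 0 <= self.percent_category <= 4:
            raise ValidationError(
                f"case {self.case_id!r}: percent category {self.percent_category} outside 0-4"
            )
        if (self.intensity == 0) != (self.percent_category == 0):
            raise ValidationError(
                f"case {self.case_id!r}: intensity {self.intensity} and percent "
                f"category {self.percent_category} disagree on absence of staining"
            )


@dataclass
class ConsensusGene:
    """A gene supported by >= min_support differentially expressed miRNAs."""

    gene_id: str
    supporting_mirnas: frozenset[str]
    predicted_protein_direction: str  # "up_in_A" | "down_in_A"
    in_both_lists: bool = False
    cleavage_flag: bool = False

    @property
    def support(self) -> int:
        return len(self.supporting_mirnas)


@dataclass(frozen=True)
class PrevalenceAssumptions:
    """Population assumptions from which the BRCA1 prevalence among basal
    cancers is derived: P(mutation) x P(basal | mutation) / P(basal)."""

    p_mutation_in_breast_cancer: float = 0.02
    p_basal_phenotype: float = 0.15
    p_basal_given_mutation: float = 0.69

    @property
    def derived_prevalence(self) -> float:
        from .errors import AssumptionError

        prev = (
            self.p_mutation_in_breast_cancer
            * self.p_basal_given_mutation
            / self.p_basal_phenotype
        )
        if not 0.0 < prev < 1.0:
            raise AssumptionError(
                f"derived prevalence {prev:.4f} outside (0, 1); check assumptions"
            )
        return prev


@dataclass(frozen=True)
class PanelRule:
    """Call a case BRCA1 when >= k of the panel markers stain negative."""

    markers: tuple[str, ...] = ("FOXP1", "CCND1", "NRP1")
    k: int = 2

    def __post_init__(self) -> None:
        if not 1 <= self.k <= len(self.markers):
            raise ValidationError(
                f"panel rule requires 1 <= k <= {len(self.markers)}, got k={self.k}"
            )
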