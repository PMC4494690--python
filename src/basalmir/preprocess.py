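"""Raw-intensity preprocessing: probe filtering, per-sample shift, log2
transform, quantile normalisation and per-run feature standardisation.

The stage chain mirrors the array-analysis protocol: probes whose maximum
background-subtracted intensity never reaches 150 units are discarded, each
sample is shifted so its minimum intensity is exactly 1, values are log2
transformed (so every sample's minimum becomes 0) and quantile normalised
against the mean-of-sorted-values reference. For clustering, each feature
is standardised to mean 0 / sd 1 — separately per hybridisation run, since
the two runs differ systematically in probe intensity.

Each step exists both as a plain function operating on
:class:`~basalmir.types.ExpressionMatrix` and through the sklearn-style
:class:`ArrayPreprocessor` / :class:`RunStandardizer` transformers.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ValidationError
from .types import ExpressionMatrix, SampleAnnotation, Stage, annotations_to_frame

logger = logging.getLogger(__name__)

#: Default probe-intensity floor: a probe is kept only if some sample
#: reaches at least this raw intensity ("less than 150 units ... excluded",
#: so exactly 150 is retained).
DEFAULT_INTENSITY_THRESHOLD = 150.0

#: Default detection-score cutoff for the mRNA matrix (strict inequality).
DEFAULT_DETECTION_THRESHOLD = 0.95


def filter_low_intensity(
    matrix: ExpressionMatrix, threshold: float = DEFAULT_INTENSITY_THRESHOLD
) -> ExpressionMatrix:
    """Drop features whose maximum intensity across samples is below
    ``threshold``. Features with any missing value are dropped as well
    (missing raw measurements are treated as absent)."""
    matrix.require_stage(Stage.RAW)
    frame = matrix.frame
    complete = ~frame.isna().any(axis=1)
    keep = complete & (frame.max(axis=1) >= threshold)
    if not keep.any():
        raise ValidationError(
            f"intensity filter at threshold {threshold} removed every feature"
        )
    logger.info(
        "intensity filter: retained %d / %d features (threshold %g)",
        int(keep.sum()),
        len(keep),
        threshold,
    )
    return matrix.advance(frame.loc[keep], Stage.FILTERED)


def filter_by_detection(
    matrix: ExpressionMatrix,
    detection_scores: pd.DataFrame,
    threshold: float = DEFAULT_DETECTION_THRESHOLD,
) -> ExpressionMatrix:
    """Keep features whose detection score exceeds ``threshold`` (strictly)
    in at least one sample — the detection filter used for the mRNA matrix."""
    matrix.require_stage(Stage.RAW)
    scores = detection_scores.reindex(index=matrix.feature_ids, columns=matrix.sample_ids)
    if scores.isna().any().any():
        raise ValidationError("detection scores do not cover the matrix")
    keep = (scores > threshold).any(axis=1)
    if not keep.any():
        raise ValidationError("detection filter removed every feature")
    return matrix.advance(matrix.frame.loc[keep], Stage.FILTERED)


def shift_min_to_one(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Add a per-sample constant so each sample's minimum intensity is 1.

    Idempotent: applying it to already-shifted input is a no-op.
    """
    if matrix.stage is not Stage.SHIFTED:
        matrix.require_stage(Stage.FILTERED)
    values = matrix.values
    shifts = 1.0 - values.min(axis=0)
    shifted = values + shifts[np.newaxis, :]
    if matrix.stage is Stage.SHIFTED:
        return ExpressionMatrix(
            shifted, Stage.SHIFTED, feature_ids=matrix.feature_ids, sample_ids=matrix.sample_ids
        )
    return matrix.advance(shifted, Stage.SHIFTED)


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2; valid after the shift (all values >= 1)."""
    matrix.require_stage(Stage.SHIFTED)
    values = matrix.values
    if (values <= 0).any():
        raise ValidationError("log2 transform requires strictly positive values")
    return matrix.advance(np.log2(values), Stage.LOG2)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the mean-of-sorted-values reference
    distribution.

    Each sample's values are replaced by the reference value at the value's
    within-sample rank; tied values within a sample receive the mean of the
    reference values spanning their rank range, so ranks are preserved and
    ties stay tied. Idempotent: normalising an already-normalised matrix
    leaves it unchanged.
    """
    if matrix.stage is not Stage.QUANTILE_NORMALIZED:
        matrix.require_stage(Stage.LOG2)
    values = matrix.values
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        sorted_col = col[order]
        i = 0
        while i < n:
            k = i
            while k + 1 < n and sorted_col[k + 1] == sorted_col[i]:
                k += 1
            out[order[i : k + 1], j] = reference[i : k + 1].mean()
            i = k + 1
    if matrix.stage is Stage.QUANTILE_NORMALIZED:
        return ExpressionMatrix(
            out,
            Stage.QUANTILE_NORMALIZED,
            feature_ids=matrix.feature_ids,
            sample_ids=matrix.sample_ids,
        )
    return matrix.advance(out, Stage.QUANTILE_NORMALIZED)


def standardize_features(
    matrix: ExpressionMatrix,
    annotations: Sequence[SampleAnnotation],
    within: str = "run",
) -> tuple[ExpressionMatrix, list[str]]:
    """Standardise each feature to mean 0 / sd 1 (sample sd, n-1 denominator),
    separately per run when ``within='run'`` or over all samples when
    ``within='all'``.

    Returns the standardised matrix and the ids of features that were
    constant within some stratum; those values are set to 0 rather than
    dropped so feature sets stay aligned across runs.
    """
    matrix.require_stage(Stage.QUANTILE_NORMALIZED)
    if within not in ("run", "all"):
        raise ValidationError(f"within must be 'run' or 'all', got {within!r}")
    ann = annotations_to_frame(annotations).reindex(matrix.sample_ids)
    if ann["sample_id"].isna().any():
        missing = [s for s, v in ann["sample_id"].isna().items() if v]
        raise ValidationError(f"samples without annotation: {missing[:5]}")

    values = matrix.values.astype(float).copy()
    flagged: set[str] = set()
    if within == "run":
        strata = [np.flatnonzero((ann["run_id"] == r).to_numpy()) for r in ann["run_id"].unique()]
    else:
        strata = [np.arange(values.shape[1])]
    for cols in strata:
        block = values[:, cols]
        mean = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=1, keepdims=True) if len(cols) > 1 else np.zeros_like(mean)
        zero = (sd == 0).ravel()
        sd[zero.reshape(-1, 1)] = 1.0
        values[:, cols] = (block - mean) / sd
        values[np.ix_(zero, cols)] = 0.0
        flagged.update(np.asarray(matrix.feature_ids)[zero])
    out = matrix.advance(values, Stage.STANDARDIZED)
    return out, sorted(flagged)


class ArrayPreprocessor(BaseEstimator, TransformerMixin):
    """Composite raw -> quantile-normalised transformer.

    ``fit`` learns the retained feature set and the quantile reference from
    the training matrix; ``transform`` replays filter, per-sample shift,
    log2 and quantile normalisation. Fitting and transforming the same
    matrix reproduces the plain-function chain exactly.

    Parameters
    ----------
    intensity_threshold : float, default 150
        Probe-intensity floor for the max-across-samples filter.
    """

    def __init__(self, intensity_threshold: float = DEFAULT_INTENSITY_THRESHOLD):
        self.intensity_threshold = intensity_threshold

    def fit(self, X: ExpressionMatrix, y=None):
        filtered = filter_low_intensity(X, self.intensity_threshold)
        self.retained_features_ = filtered.feature_ids
        self.n_features_in_ = X.shape[0]
        logged = log2_transform(shift_min_to_one(filtered))
        self.reference_distribution_ = np.sort(logged.values, axis=0).mean(axis=1)
        return self

    def transform(self, X: ExpressionMatrix) -> ExpressionMatrix:
        if not hasattr(self, "retained_features_"):
            raise ValidationError("ArrayPreprocessor must be fitted before transform")
        X.require_stage(Stage.RAW)
        filtered = X.subset_features(self.retained_features_, Stage.FILTERED)
        return quantile_normalize(log2_transform(shift_min_to_one(filtered)))

    def fit_transform(self, X: ExpressionMatrix, y=None) -> ExpressionMatrix:
        return self.fit(X).transform(X)


class RunStandardizer(BaseEstimator, TransformerMixin):
    """Per-feature, per-run standardisation transformer.

    Parameters
    ----------
    annotations : sequence of SampleAnnotation
        Sample -> run mapping (stateless w.r.t. the data; passed at
        construction because sklearn transforms carry no side table).
    within : {'run', 'all'}, default 'run'
    """

    def __init__(self, annotations: Sequence[SampleAnnotation] = (), within: str = "run"):
        self.annotations = annotations
        self.within = within

    def fit(self, X: ExpressionMatrix, y=None):
        self.n_features_in_ = X.shape[0]
        return self

    def transform(self, X: ExpressionMatrix) -> ExpressionMatrix:
        out, flagged = standardize_features(X, list(self.annotations), self.within)
        self.zero_variance_features_ = flagged
        return out
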