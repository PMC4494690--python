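"""Per-feature differential expression with the hybridisation chip as a
covariate, Benjamini-Hochberg adjustment, signed fold changes and top-N
signature selection.

The model is a per-feature two-way fixed-effects linear model
``log2 intensity ~ group + chip`` (no interaction). The group effect is
tested with a partial F test: the residual sum of squares of the reduced
model (intercept + chip) is compared with the full model's, and the p-value
comes from the F distribution at the corresponding degrees of freedom.
Fitting is vectorised across features via projection matrices, so a whole
array is tested in one pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .errors import ConfoundingError, ValidationError
from .types import ExpressionMatrix, SampleAnnotation, Stage, annotations_to_frame

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class DifferentialResult:
    """One feature's test result for one contrast."""

    feature_id: str
    fold_change: float
    f_statistic: float
    p_raw: float
    p_adjusted: float
    direction: str  # "up_in_A" | "down_in_A"
    contrast: tuple[str, ...]
    degenerate: bool = False


@dataclass(frozen=True)
class SignatureConfig:
    """Top-N-by-|fold change| signature selection.

    Defaults mirror the headline analysis: 75 features per contrast for the
    basal-vs-luminal comparison, 100 for BRCA1-vs-sporadic; report
    thresholds |fold change| > 2.5 at adjusted p < 0.05.
    """

    top_n_per_contrast: tuple[int, ...] = (75, 100)
    report_fold_change: float = 2.5
    report_p_adjusted: float = 0.05


def _dummies(labels: pd.Series) -> tuple[np.ndarray, list[str]]:
    levels = sorted(labels.unique())
    cols = [(labels == lv).to_numpy(float) for lv in levels[1:]]  # drop first level
    return (np.column_stack(cols) if cols else np.empty((len(labels), 0))), levels[1:]


def _build_designs(ann: pd.DataFrame, groups: Sequence[str]):
    """Intercept + chip (reduced) and intercept + chip + group (full) designs.

    Chip dummy columns that do not increase the design rank are dropped
    (aliased chip levels); if a group dummy then fails to increase rank the
    group factor is confounded with chips and the model is not estimable.
    """
    n = len(ann)
    intercept = np.ones((n, 1))
    chip_cols, chip_names = _dummies(ann["chip_id"])
    base = intercept
    kept_chips = []
    for j, name in enumerate(chip_names):
        cand = np.column_stack([base, chip_cols[:, j]])
        if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(base):
            base = cand
            kept_chips.append(name)
    group_cols, group_names = _dummies(ann["group"])
    full = base
    for j, name in enumerate(group_names):
        cand = np.column_stack([full, group_cols[:, j]])
        if np.linalg.matrix_rank(cand) <= np.linalg.matrix_rank(full):
            chips_of_group = sorted(ann.loc[ann["group"] == name, "chip_id"].unique())
            raise ConfoundingError(
                f"group level {name!r} is aliased with chip level(s) {chips_of_group}; "
                "the group effect is not estimable"
            )
        full = cand
    return base, full, kept_chips


def _normalize_side(side) -> tuple[str, ...]:
    """A contrast side may be one group label or a set of pooled labels."""
    if isinstance(side, str):
        return (side,)
    return tuple(side)


def fit_group_model(
    matrix: ExpressionMatrix,
    annotations: Sequence[SampleAnnotation],
    groups: Sequence[str],
    covariate: str = "chip",
    pool: Sequence[Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Test every feature for a group effect, adjusting for chip.

    Parameters
    ----------
    matrix
        Quantile-normalised log2 matrix.
    groups
        Group labels defining the factor; samples outside these groups are
        ignored. Each retained level needs >= 2 samples.
    covariate
        ``'chip'`` (default) or ``'none'`` to drop the batch covariate.
    pool
        Optional partition of ``groups`` into factor levels; labels pooled
        together count as one level (e.g. both basal groups vs. luminal).

    Returns
    -------
    DataFrame indexed by feature id with columns ``f_statistic``, ``p_raw``
    and ``degenerate`` (True where both effect and residual sums of squares
    vanish; such features get p = 1).
    """
    matrix.require_stage(Stage.QUANTILE_NORMALIZED)
    ann = annotations_to_frame(annotations)
    ann = ann[ann["group"].isin(groups)]
    ann = ann.loc[[s for s in matrix.sample_ids if s in ann.index]]
    if pool is not None:
        level_of = {}
        for i, labels in enumerate(pool):
            for label in _normalize_side(labels):
                level_of[label] = f"level{i}"
        ann = ann.assign(group=ann["group"].map(level_of))
        if ann["group"].isna().any():
            raise ValidationError("pool must cover every selected group label")
    counts = ann["group"].value_counts()
    small = counts[counts < 2]
    if len(ann["group"].unique()) < 2:
        raise ValidationError(f"need >= 2 group levels among {list(groups)}")
    if len(small):
        raise ValidationError(f"groups with < 2 samples: {dict(small)}")

    if covariate == "none":
        ann = ann.assign(chip_id="all")
    reduced, full, _ = _build_designs(ann, groups)
    y = matrix.frame[ann.index.tolist()].to_numpy().T  # samples x features

    def rss(design: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        return (resid**2).sum(axis=0)

    rank_full = np.linalg.matrix_rank(full)
    rank_red = np.linalg.matrix_rank(reduced)
    df1 = rank_full - rank_red
    df2 = len(ann) - rank_full
    if df2 <= 0:
        raise ValidationError("no residual degrees of freedom for the group model")
    rss_full = rss(full)
    rss_red = rss(reduced)
    effect = np.maximum(rss_red - rss_full, 0.0)

    scale = np.maximum(np.abs(y).max(axis=0) ** 2, 1.0)
    zero_resid = rss_full < _EPS * scale
    zero_effect = effect < _EPS * scale
    degenerate = zero_resid & zero_effect

    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = (effect / df1) / (rss_full / df2)
    p = stats.f.sf(f_stat, df1, df2)
    f_stat = np.where(degenerate, 0.0, f_stat)
    p = np.where(degenerate, 1.0, p)
    # zero residual but a real effect: perfect separation, p -> 0
    p = np.where(zero_resid & ~zero_effect, 0.0, p)
    f_stat = np.where(zero_resid & ~zero_effect, np.inf, f_stat)
    return pd.DataFrame(
        {"f_statistic": f_stat, "p_raw": p, "degenerate": degenerate},
        index=matrix.feature_ids,
    )


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(
    matrix: ExpressionMatrix,
    annotations: Sequence[SampleAnnotation],
    contrast: tuple[str, str],
) -> pd.Series:
    """Signed fold change of group A over group B on the raw scale.

    With r = 2^(mean log2 A - mean log2 B), the signed convention is
    fc = r when r >= 1 and -1/r otherwise, so |fc| >= 1 always and swapping
    the contrast negates the value.
    """
    matrix.require_stage(Stage.QUANTILE_NORMALIZED)
    side_a, side_b = _normalize_side(contrast[0]), _normalize_side(contrast[1])
    ann = annotations_to_frame(annotations)
    a_samples = [s for s in matrix.sample_ids if s in ann.index and ann.loc[s, "group"] in side_a]
    b_samples = [s for s in matrix.sample_ids if s in ann.index and ann.loc[s, "group"] in side_b]
    if not a_samples or not b_samples:
        raise ValidationError(f"contrast {contrast} has an empty group")
    diff = matrix.frame[a_samples].mean(axis=1) - matrix.frame[b_samples].mean(axis=1)
    ratio = np.power(2.0, diff)
    return pd.Series(
        np.where(ratio >= 1.0, ratio, -1.0 / ratio), index=matrix.feature_ids, name="fold_change"
    )


def differential_expression(
    matrix: ExpressionMatrix,
    annotations: Sequence[SampleAnnotation],
    contrast: tuple,
    covariate: str = "chip",
) -> list[DifferentialResult]:
    """Full per-feature analysis for one two-sided contrast; either side
    may pool several group labels."""
    side_a, side_b = _normalize_side(contrast[0]), _normalize_side(contrast[1])
    fit = fit_group_model(
        matrix,
        annotations,
        list(side_a + side_b),
        covariate=covariate,
        pool=(side_a, side_b),
    )
    fc = fold_change(matrix, annotations, contrast)
    p_adj = adjust_bh(fit["p_raw"].to_numpy())
    results = []
    for i, feature in enumerate(fit.index):
        f = float(fc.loc[feature])
        results.append(
            DifferentialResult(
                feature_id=feature,
                fold_change=f,
                f_statistic=float(fit["f_statistic"].iloc[i]),
                p_raw=float(fit["p_raw"].iloc[i]),
                p_adjusted=float(p_adj[i]),
                direction="up_in_A" if f >= 1.0 else "down_in_A",
                contrast=contrast,
                degenerate=bool(fit["degenerate"].iloc[i]),
            )
        )
    return results


def results_to_frame(results: Sequence[DifferentialResult]) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "fold_change": [r.fold_change for r in results],
            "f_statistic": [r.f_statistic for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "direction": [r.direction for r in results],
        }
    )
    return frame.set_index("feature_id", drop=False)


def select_signature(
    result_lists: Sequence[Sequence[DifferentialResult]],
    top_n_per_contrast: Sequence[int],
) -> list[str]:
    """Union of the top-N features by |fold change| from each contrast.

    Ties at rank N break by feature id ascending; the returned list is
    sorted by (max |fold change| across contrasts desc, feature id asc), so
    the selection is deterministic under any input permutation.
    """
    if len(result_lists) != len(top_n_per_contrast):
        raise ValidationError("one top-N value is required per contrast")
    best: dict[str, float] = {}
    for results, n in zip(result_lists, top_n_per_contrast):
        ranked = sorted(results, key=lambda r: (-abs(r.fold_change), r.feature_id))
        for r in ranked[: max(int(n), 0)]:
            best[r.feature_id] = max(best.get(r.feature_id, 0.0), abs(r.fold_change))
    return sorted(best, key=lambda f: (-best[f], f))


class GroupDifferentialExpression(BaseEstimator):
    """sklearn-style estimator for one two-group contrast.

    Parameters
    ----------
    contrast : (group A, group B)
    covariate : {'chip', 'none'}, default 'chip'

    Attributes
    ----------
    results_ : list of DifferentialResult
    results_frame_ : DataFrame view of ``results_``
    significant_ : feature ids with adjusted p < alpha
    """

    def __init__(
        self,
        contrast: tuple[str, str] = ("basal_brca1", "basal_sporadic"),
        covariate: str = "chip",
        alpha: float = 0.05,
    ):
        self.contrast = contrast
        self.covariate = covariate
        self.alpha = alpha

    def fit(self, X: ExpressionMatrix, y: Sequence[SampleAnnotation]):
        self.results_ = differential_expression(
            X, list(y), tuple(self.contrast), covariate=self.covariate
        )
        self.results_frame_ = results_to_frame(self.results_)
        self.significant_ = [
            r.feature_id for r in self.results_ if r.p_adjusted < self.alpha
        ]
        return self
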