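"""Immunohistochemistry scoring, per-marker group comparisons and the
k-of-n negative-marker BRCA1 classifier.

Each marker on each case carries a staining intensity (0 = negative to
3 = strong) and a stained-proportion category (0 = 0 % up to 4 = 81-100 %);
their sum is the composite score out of 7. A case is positive for a marker
when any staining is present (intensity >= 1, proportion >= 1). Groups are
compared marker-wise with a Pearson chi-square on positivity (df = 1, no
continuity correction) and a Mann-Whitney U test on the composite scores.

The diagnostic rule calls a case BRCA1 when at least k of the panel
markers (default 2 of FOXP1, cyclin D1, NRP1) stain negative. Cohort
predictive values follow from the confusion table; population predictive
values are re-derived by Bayes' theorem at the BRCA1 prevalence among
basal cancers implied by the stated population assumptions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import ValidationError
from .types import IHCRecord, PanelRule, PrevalenceAssumptions


@dataclass
class MarkerComparison:
    marker: str
    counts: tuple[tuple[int, int], tuple[int, int]]  # (brca1, sporadic) x (pos, neg)
    chi2_statistic: float
    p_chi2: float
    mannwhitney_u: float
    p_mw: float
    positivity_brca1: float
    positivity_sporadic: float


@dataclass
class PanelResult:
    rule: PanelRule
    tp: int
    fp: int
    tn: int
    fn: int
    n_excluded: int
    sensitivity: float
    specificity: float
    cohort_ppv: float
    cohort_npv: float
    adjusted_ppv: float
    adjusted_npv: float
    derived_prevalence: float
    assumptions: PrevalenceAssumptions


def composite_score(intensity: int, percent_category: int) -> int:
    """Intensity (0-3) plus proportion category (0-4): a score out of 7."""
    if not 0 <= intensity <= 3:
        raise ValidationError(f"intensity {intensity} outside 0-3")
    if not 0 <= percent_category <= 4:
        raise ValidationError(f"percent category {percent_category} outside 0-4")
    return intensity + percent_category


def positivity(record: IHCRecord) -> bool:
    """Presence of any staining."""
    return record.intensity >= 1 and record.percent_category >= 1


def chisq_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table [[a, b], [c, d]], df = 1, without
    continuity correction; p from the upper tail."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValidationError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("chi-square undefined: a row or column margin is zero")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def _exact_mannwhitney_p(u: float, n1: int, n2: int) -> float:
    """Two-sided exact p by enumeration of all C(n1+n2, n1) rank splits
    (valid without ties)."""
    n = n1 + n2
    total = math.comb(n, n1)
    mean_u = n1 * n2 / 2.0
    dev = abs(u - mean_u)
    count = 0
    for combo in itertools.combinations(range(1, n + 1), n1):
        u1 = sum(combo) - n1 * (n1 + 1) / 2
        if abs(u1 - mean_u) >= dev - 1e-9:
            count += 1
    return count / total


def mannwhitney(scores_a: Sequence[float], scores_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    The exact null distribution is enumerated when both samples have at
    most 8 observations and there are no ties; otherwise the normal
    approximation with tie correction is used (without continuity
    correction, so identical samples give p = 1 exactly).

    Returns (U of the first sample, p).
    """
    a = np.asarray(list(scores_a), dtype=float)
    b = np.asarray(list(scores_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    r1 = ranks[: a.size].sum()
    u1 = r1 - a.size * (a.size + 1) / 2.0
    n1, n2 = a.size, b.size
    has_ties = np.unique(combined).size < combined.size
    if n1 <= 8 and n2 <= 8 and not has_ties:
        return float(u1), float(_exact_mannwhitney_p(u1, n1, n2))
    mean_u = n1 * n2 / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    n = n1 + n2
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return float(u1), 1.0
    z = (u1 - mean_u) / math.sqrt(var_u)
    return float(u1), float(2.0 * stats.norm.sf(abs(z)))


def compare_marker(records: Sequence[IHCRecord], marker: str) -> MarkerComparison:
    """Per-marker BRCA1 vs sporadic comparison on evaluable records only."""
    rel = [r for r in records if r.marker == marker and r.evaluable]
    brca1 = [r for r in rel if r.truth_group == "brca1"]
    sporadic = [r for r in rel if r.truth_group == "sporadic"]
    if not brca1 or not sporadic:
        raise ValidationError(
            f"marker {marker!r}: need evaluable cases in both groups "
            f"(brca1 n={len(brca1)}, sporadic n={len(sporadic)})"
        )
    pos_b = sum(positivity(r) for r in brca1)
    pos_s = sum(positivity(r) for r in sporadic)
    counts = ((pos_b, len(brca1) - pos_b), (pos_s, len(sporadic) - pos_s))
    stat, p_chi2 = chisq_2x2(*counts[0], *counts[1])
    u, p_mw = mannwhitney(
        [composite_score(r.intensity, r.percent_category) for r in brca1],
        [composite_score(r.intensity, r.percent_category) for r in sporadic],
    )
    return MarkerComparison(
        marker=marker,
        counts=counts,
        chi2_statistic=stat,
        p_chi2=p_chi2,
        mannwhitney_u=u,
        p_mw=p_mw,
        positivity_brca1=pos_b / len(brca1),
        positivity_sporadic=pos_s / len(sporadic),
    )


def marker_table(records: Sequence[IHCRecord], markers: Sequence[str]) -> pd.DataFrame:
    """Per-marker comparison table in the shape of a cohort results table."""
    rows = []
    for marker in markers:
        cmp = compare_marker(records, marker)
        (pb, nb), (ps, ns) = cmp.counts
        rows.append(
            {
                "marker": marker,
                "positive_brca1": pb,
                "n_brca1": pb + nb,
                "positive_sporadic": ps,
                "n_sporadic": ps + ns,
                "pct_positive_brca1": 100.0 * cmp.positivity_brca1,
                "pct_positive_sporadic": 100.0 * cmp.positivity_sporadic,
                "chi2": cmp.chi2_statistic,
                "p_chi2": cmp.p_chi2,
                "mannwhitney_u": cmp.mannwhitney_u,
                "p_mw": cmp.p_mw,
            }
        )
    return pd.DataFrame(rows).set_index("marker")


def case_positivity(records: Sequence[IHCRecord]) -> pd.DataFrame:
    """Case x marker positivity grid (NaN where not evaluable), with the
    case's truth group attached."""
    rows: dict[str, dict] = {}
    for r in records:
        entry = rows.setdefault(r.case_id, {"truth_group": r.truth_group})
        if entry["truth_group"] != r.truth_group:
            raise ValidationError(f"case {r.case_id!r} has conflicting truth groups")
        entry[r.marker] = positivity(r) if r.evaluable else np.nan
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def panel_classify(
    marker_positivity: Mapping[str, bool], rule: PanelRule = PanelRule()
) -> str:
    """Predict 'brca1' when >= k of the rule's markers are negative."""
    missing = [m for m in rule.markers if m not in marker_positivity]
    if missing:
        raise ValidationError(f"case is missing panel markers {missing}")
    n_negative = sum(not bool(marker_positivity[m]) for m in rule.markers)
    return "brca1" if n_negative >= rule.k else "sporadic"


def evaluate_panel(
    predictions: Sequence[str],
    truth: Sequence[str],
    rule: PanelRule = PanelRule(),
    assumptions: PrevalenceAssumptions = PrevalenceAssumptions(),
    n_excluded: int = 0,
) -> PanelResult:
    """Confusion counts, cohort rates, and prevalence-adjusted PPV/NPV."""
    if len(predictions) != len(truth):
        raise ValidationError("predictions and truth must align")
    tp = sum(p == "brca1" and t == "brca1" for p, t in zip(predictions, truth))
    fp = sum(p == "brca1" and t == "sporadic" for p, t in zip(predictions, truth))
    tn = sum(p == "sporadic" and t == "sporadic" for p, t in zip(predictions, truth))
    fn = sum(p == "sporadic" and t == "brca1" for p, t in zip(predictions, truth))
    if tp + fn == 0 or tn + fp == 0:
        raise ValidationError("both truth classes must be present to evaluate the panel")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    cohort_ppv = tp / (tp + fp) if tp + fp else float("nan")
    cohort_npv = tn / (tn + fn) if tn + fn else float("nan")
    adj_ppv, adj_npv, prev = prevalence_adjusted_pv(sens, spec, assumptions)
    return PanelResult(
        rule=rule,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        n_excluded=n_excluded,
        sensitivity=sens,
        specificity=spec,
        cohort_ppv=cohort_ppv,
        cohort_npv=cohort_npv,
        adjusted_ppv=adj_ppv,
        adjusted_npv=adj_npv,
        derived_prevalence=prev,
        assumptions=assumptions,
    )


def prevalence_adjusted_pv(
    sensitivity: float,
    specificity: float,
    assumptions: PrevalenceAssumptions = PrevalenceAssumptions(),
) -> tuple[float, float, float]:
    """PPV and NPV at the BRCA1 prevalence among basal cancers derived from
    the population assumptions: prev = P(mut) * P(basal|mut) / P(basal)."""
    if not 0 <= sensitivity <= 1 or not 0 <= specificity <= 1:
        raise ValidationError("sensitivity and specificity must lie in [0, 1]")
    prev = assumptions.derived_prevalence
    ppv_num = sensitivity * prev
    ppv_den = ppv_num + (1.0 - specificity) * (1.0 - prev)
    npv_num = specificity * (1.0 - prev)
    npv_den = npv_num + (1.0 - sensitivity) * prev
    ppv = ppv_num / ppv_den if ppv_den else float("nan")
    npv = npv_num / npv_den if npv_den else float("nan")
    return ppv, npv, prev


class NegativeMarkerPanel(BaseEstimator, ClassifierMixin):
    """sklearn-style classifier wrapping the k-of-n negative-marker rule.

    The rule is fixed a priori (no fitting beyond recording classes); it
    exists as an estimator so the panel can sit in sklearn model-selection
    machinery for cohort evaluation.

    Parameters
    ----------
    markers : tuple of marker names, default ("FOXP1", "CCND1", "NRP1")
    k : int, default 2
        Number of negative markers required to call BRCA1.
    """

    def __init__(self, markers: tuple[str, ...] = ("FOXP1", "CCND1", "NRP1"), k: int = 2):
        self.markers = markers
        self.k = k

    @property
    def rule(self) -> PanelRule:
        return PanelRule(markers=tuple(self.markers), k=self.k)

    def fit(self, X: pd.DataFrame, y=None):
        missing = [m for m in self.markers if m not in X.columns]
        if missing:
            raise ValidationError(f"positivity table lacks panel markers {missing}")
        self.classes_ = np.array(["brca1", "sporadic"])
        self.n_features_in_ = len(self.markers)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        rule = self.rule
        out = []
        for _, row in X.iterrows():
            out.append(panel_classify({m: row[m] for m in self.markers}, rule))
        return np.array(out)

    def evaluate(
        self,
        X: pd.DataFrame,
        y: Sequence[str],
        assumptions: PrevalenceAssumptions = PrevalenceAssumptions(),
    ) -> PanelResult:
        """Classify evaluable cases (rows with any missing panel marker are
        excluded and counted) and compute the full panel report."""
        usable = X[list(self.markers)].notna().all(axis=1)
        preds = self.predict(X.loc[usable])
        truth = np.asarray(list(y))[usable.to_numpy()]
        return evaluate_panel(
            preds,
            truth,
            rule=self.rule,
            assumptions=assumptions,
            n_excluded=int((~usable).sum()),
        )
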