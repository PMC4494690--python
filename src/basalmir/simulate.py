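"""Seeded generators for every pipeline input, with planted, recoverable
structure.

Each generator emulates the statistical shape of one real input:

* :func:`gen_expression` — a raw miRNA intensity matrix over the study's
  four-group design (normal / luminal / sporadic-basal / BRCA1-basal) with
  planted log2 group effects, additive per-chip offsets, a multiplicative
  run-level distortion and log-normal residual noise. Defaults mirror the
  profiled cohort: 1145 probes (of which ~108 sit below the 150-unit
  intensity floor), 13 normal, 17 luminal, 16 sporadic-basal and 11
  BRCA1-basal samples hybridised on one chip in run 1 and five chips in
  run 2, with samples randomised across chips.
* :func:`gen_target_tables` — per-source miRNA->gene prediction tables in
  which the configured fraction of emitted pairs is true (mirroring the
  44 % / 61 % pSILAC specificities of the two real algorithms).
* :func:`gen_gene_expression` — an mRNA matrix in which a seeded subset
  (default 20 %, the approximate RISC-cleavage fraction) of true target
  genes shifts opposite in sign to its targeting miRNAs.
* :func:`gen_ihc_cohort` — per-case marker staining records with planted
  group-conditional positivity; within-case correlation of marker
  negativity enters through a shared latent case factor (Gaussian copula).

Every generator derives independent sub-streams from its single seed, so
enlarging one component never perturbs the draws of another.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .types import ExpressionMatrix, IHCRecord, SampleAnnotation, Stage

_DEFAULT_GROUPS = {
    "normal": 13,
    "luminal": 17,
    "basal_sporadic": 16,
    "basal_brca1": 11,
}


# --------------------------------------------------------------------------
# expression simulation
# --------------------------------------------------------------------------

@dataclass
class ExpressionSimConfig:
    """Planted-effect miRNA array simulation.

    ``log2_effect`` is the group shift in log2 units; ``chip_effect_sd``
    the spread of additive per-chip log2 offsets; ``run_scale`` the
    multiplicative raw-scale distortion applied to run 2; ``noise_sd`` the
    residual log2 sd. ``negative_offset`` (default off) subtracts a raw
    constant so sample minima can go negative, the way background
    subtraction produces negative intensities.
    """

    n_features: int = 1145
    n_per_group: Mapping[str, int] = field(default_factory=lambda: dict(_DEFAULT_GROUPS))
    de_features: int = 50
    log2_effect: float = 2.0
    chip_effect_sd: float = 0.25
    run_scale: float = 1.3
    noise_sd: float = 0.5
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.0
    n_low_features: int = 108
    low_baseline_log2_mean: float = 4.0
    negative_offset: float = 0.0
    run1_size: int = 11
    chip_capacity: int = 12
    randomize_layout: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1 or any(n < 1 for n in self.n_per_group.values()):
            raise ConfigError("all counts must be >= 1")
        if 2 * self.de_features + self.n_low_features > self.n_features:
            raise ConfigError(
                "de_features (per contrast, two contrasts) plus low features "
                "must fit within n_features"
            )
        for name in ("chip_effect_sd", "noise_sd", "baseline_log2_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass
class ExpressionTruth:
    """Planted truth: DE feature directions per contrast (+1 = up in the
    contrast's first group), sub-threshold features, chip offsets."""

    de_basal: dict[str, int]
    de_brca1: dict[str, int]
    low_features: list[str]
    chip_offsets: dict[str, list[float]]  # per-feature offset vector per chip
    groups: dict[str, str]


def _streams(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def gen_expression(
    config: ExpressionSimConfig,
) -> tuple[ExpressionMatrix, list[SampleAnnotation], ExpressionTruth]:
    """Simulate a raw miRNA array with planted group, chip and run effects.

    Raw intensity = 2^(baseline + group effect + chip offset + noise)
    x run scale - negative offset. The truth record lists the DE features
    of both contrasts with their directions.
    """
    rng = _streams(config.seed, ["baseline", "select", "layout", "chips"])
    n_regular = config.n_features - config.n_low_features
    feature_ids = [f"miR-{i:04d}" for i in range(config.n_features)]
    baselines = np.empty(config.n_features)
    baselines[:n_regular] = rng["baseline"].normal(
        config.baseline_log2_mean, config.baseline_log2_sd, n_regular
    )
    baselines[n_regular:] = rng["baseline"].normal(
        config.low_baseline_log2_mean, 0.5, config.n_low_features
    )
    low_features = feature_ids[n_regular:]

    # disjoint DE sets for the two contrasts, drawn from well-expressed probes
    pick = rng["select"].choice(n_regular, size=2 * config.de_features, replace=False)
    basal_idx = pick[: config.de_features]
    brca1_idx = pick[config.de_features :]
    dir_basal = rng["select"].choice([-1, 1], size=config.de_features)
    dir_brca1 = rng["select"].choice([-1, 1], size=config.de_features)

    # sample layout: run 1 fills one chip, run 2 fills the rest
    sample_ids, groups = [], []
    for group, n in config.n_per_group.items():
        for i in range(n):
            sample_ids.append(f"{group}_{i:02d}")
            groups.append(group)
    # randomised layout mirrors the study design; the sequential layout
    # aligns chips with groups to study chip-group confounding
    if config.randomize_layout:
        order = rng["layout"].permutation(len(sample_ids))
    else:
        order = np.arange(len(sample_ids))
    annotations: list[SampleAnnotation] = []
    chip_of = {}
    for pos, idx in enumerate(order):
        if pos < config.run1_size:
            run, chip = "run1", "chip1"
        else:
            chip_no = 2 + (pos - config.run1_size) // config.chip_capacity
            run, chip = "run2", f"chip{chip_no}"
        annotations.append(
            SampleAnnotation(
                sample_id=sample_ids[idx], group=groups[idx], run_id=run, chip_id=chip
            )
        )
        chip_of[sample_ids[idx]] = (run, chip)
    annotations.sort(key=lambda a: a.sample_id)

    # probe-specific chip offsets: batch effects on bead arrays hit probes
    # unevenly, so a chip's offset is a vector over features (a constant
    # per-sample shift would be removed entirely by quantile normalisation)
    chip_ids = sorted({a.chip_id for a in annotations})
    offsets = {
        chip: rng["chips"].normal(0.0, config.chip_effect_sd, config.n_features)
        for chip in chip_ids
    }

    ordered_samples = [a.sample_id for a in annotations]
    group_of = {a.sample_id: a.group for a in annotations}
    log2 = np.tile(baselines[:, None], (1, len(ordered_samples)))
    for j, sample in enumerate(ordered_samples):
        grp = group_of[sample]
        if grp in ("basal_sporadic", "basal_brca1"):
            log2[basal_idx, j] += dir_basal * config.log2_effect
        if grp == "basal_brca1":
            log2[brca1_idx, j] += dir_brca1 * config.log2_effect
        log2[:, j] += offsets[chip_of[sample][1]]  # vector over features
    # per-sample noise sub-streams: adding samples never perturbs earlier draws
    noise_parent = np.random.SeedSequence(config.seed).spawn(5)[4]
    for j, child in enumerate(noise_parent.spawn(len(ordered_samples))):
        log2[:, j] += np.random.default_rng(child).normal(0.0, config.noise_sd, config.n_features)

    raw = np.power(2.0, log2)
    run2 = np.array([chip_of[s][0] == "run2" for s in ordered_samples])
    raw[:, run2] *= config.run_scale
    raw -= config.negative_offset

    matrix = ExpressionMatrix(raw, Stage.RAW, feature_ids=feature_ids, sample_ids=ordered_samples)
    truth = ExpressionTruth(
        de_basal={feature_ids[i]: int(d) for i, d in zip(basal_idx, dir_basal)},
        de_brca1={feature_ids[i]: int(d) for i, d in zip(brca1_idx, dir_brca1)},
        low_features=list(low_features),
        chip_offsets={chip: [float(v) for v in off] for chip, off in offsets.items()},
        groups=group_of,
    )
    return matrix, annotations, truth


# --------------------------------------------------------------------------
# target-prediction simulation
# --------------------------------------------------------------------------

@dataclass
class TargetSimConfig:
    """Per-source prediction tables with configurable true-pair fraction.

    ``source_specificities`` gives, per prediction source, the fraction of
    its emitted pairs that are true; defaults mirror the benchmark
    specificities of the study's two algorithms. ``n_consensus_genes``
    genes are planted with >= ``min_consensus_support`` true targeting
    miRNAs of a common direction, so consensus filtering has structure to
    recover.
    """

    n_genes: int = 2000
    true_targets_per_mirna: int = 10
    source_specificities: tuple[float, ...] = (0.44, 0.61)
    n_consensus_genes: int = 50
    min_consensus_support: int = 3
    max_consensus_support: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.source_specificities:
            raise ConfigError("at least one source specificity required")
        for q in self.source_specificities:
            if not 0.0 < q <= 1.0:
                raise ConfigError(f"specificity {q} outside (0, 1]")


def gene_universe(config: TargetSimConfig) -> list[str]:
    return [f"GENE{i:05d}" for i in range(config.n_genes)]


def gen_truth_map(
    config: TargetSimConfig, mirna_directions: Mapping[str, str]
) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Plant a true miRNA->target map.

    Consensus genes are each assigned several miRNAs of one direction
    (support drawn in [min, max]); every miRNA is then topped up with
    random private targets to ``true_targets_per_mirna``.

    Returns (truth map, consensus gene -> supporting-miRNA direction).
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])
    genes = gene_universe(config)
    mirnas = sorted(mirna_directions)
    if not mirnas:
        raise ConfigError("mirna_directions must be non-empty")
    consensus_pool = rng.choice(len(genes), size=config.n_consensus_genes, replace=False)
    truth: dict[str, set[str]] = {m: set() for m in mirnas}
    consensus_direction: dict[str, str] = {}
    by_dir = {
        "up_in_A": [m for m in mirnas if mirna_directions[m] == "up_in_A"],
        "down_in_A": [m for m in mirnas if mirna_directions[m] == "down_in_A"],
    }
    for gi in consensus_pool:
        gene = genes[gi]
        direction = "up_in_A" if rng.random() < 0.5 and by_dir["up_in_A"] else "down_in_A"
        pool = by_dir[direction] or by_dir["up_in_A" if direction == "down_in_A" else "down_in_A"]
        direction = mirna_directions[pool[0]]
        support = int(
            rng.integers(config.min_consensus_support, config.max_consensus_support + 1)
        )
        support = min(support, len(pool))
        for m in rng.choice(len(pool), size=support, replace=False):
            truth[pool[m]].add(gene)
        consensus_direction[gene] = direction
    for m in mirnas:
        deficit = config.true_targets_per_mirna - len(truth[m])
        while deficit > 0:
            cand = genes[int(rng.integers(len(genes)))]
            if cand not in truth[m]:
                truth[m].add(cand)
                deficit -= 1
    return truth, consensus_direction


def gen_target_tables(
    config: TargetSimConfig,
    mirna_ids: Sequence[str],
    truth_map: Mapping[str, set[str]],
) -> list[list]:
    """Emit one prediction table per source: all true pairs of each miRNA
    diluted with false pairs so the true fraction equals the source's
    specificity within rounding."""
    from .types import TargetPair

    missing = [m for m in mirna_ids if m not in truth_map]
    if missing:
        raise ConfigError(f"truth_map does not cover miRNAs {missing[:5]}")
    genes = gene_universe(config)
    streams = np.random.SeedSequence(config.seed).spawn(2)[1].spawn(
        len(config.source_specificities)
    )
    tables: list[list[TargetPair]] = []
    for s_idx, (specificity, stream) in enumerate(zip(config.source_specificities, streams)):
        rng = np.random.default_rng(stream)
        source = f"source{s_idx + 1}"
        table: list[TargetPair] = []
        for mirna in mirna_ids:
            true_genes = sorted(truth_map[mirna])
            n_true = len(true_genes)
            n_false = round(n_true * (1.0 - specificity) / specificity)
            candidates = [g for g in genes if g not in truth_map[mirna]]
            false_genes = [
                candidates[i]
                for i in rng.choice(len(candidates), size=n_false, replace=False)
            ]
            for gene in true_genes + false_genes:
                table.append(TargetPair(mirna_id=mirna, gene_id=gene, source=source))
        tables.append(table)
    return tables


# --------------------------------------------------------------------------
# mRNA (cleavage) simulation
# --------------------------------------------------------------------------

@dataclass
class CleavageSimConfig:
    """mRNA matrix for the consensus genes: a seeded ``cleavage_fraction``
    subset of true targets shifts opposite in sign to its miRNAs."""

    cleavage_fraction: float = 0.20
    mrna_log2_effect: float = 1.0
    noise_sd: float = 0.5
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cleavage_fraction <= 1.0:
            raise ConfigError("cleavage_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


def gen_gene_expression(
    config: CleavageSimConfig,
    consensus_direction: Mapping[str, str],
    annotations: Sequence[SampleAnnotation],
    gene_ids: Sequence[str],
) -> tuple[ExpressionMatrix, dict[str, str]]:
    """Simulate a raw mRNA matrix over the annotated samples.

    Exactly ``round(cleavage_fraction * n_consensus)`` consensus genes
    (seeded sampling without replacement) receive a log2 shift in the
    BRCA1-basal group opposite to their supporting miRNAs' direction; all
    other genes carry no planted shift. Returns the matrix and the planted
    gene -> mRNA direction map.
    """
    rng = _streams(config.seed, ["pick", "noise", "baseline"])
    targets = sorted(consensus_direction)
    n_cleaved = round(config.cleavage_fraction * len(targets))
    cleaved_idx = rng["pick"].choice(len(targets), size=n_cleaved, replace=False)
    cleaved = {
        targets[i]: ("down_in_A" if consensus_direction[targets[i]] == "up_in_A" else "up_in_A")
        for i in cleaved_idx
    }
    samples = [a.sample_id for a in annotations]
    in_a = np.array([a.group == "basal_brca1" for a in annotations])
    baselines = rng["baseline"].normal(
        config.baseline_log2_mean, config.baseline_log2_sd, len(gene_ids)
    )
    log2 = np.tile(baselines[:, None], (1, len(samples)))
    for i, gene in enumerate(gene_ids):
        direction = cleaved.get(gene)
        if direction is not None:
            shift = config.mrna_log2_effect if direction == "up_in_A" else -config.mrna_log2_effect
            log2[i, in_a] += shift
    log2 += rng["noise"].normal(0.0, config.noise_sd, log2.shape)
    matrix = ExpressionMatrix(
        np.power(2.0, log2), Stage.RAW, feature_ids=list(gene_ids), sample_ids=samples
    )
    return matrix, cleaved


def gen_gene_annotations(n_brca1: int = 14, n_sporadic: int = 10) -> list[SampleAnnotation]:
    """Single-run, single-chip annotations for the mRNA cohort (defaults
    mirror the 14 BRCA1 / 10 non-BRCA1 basal comparison)."""
    out = []
    for i in range(n_brca1):
        out.append(SampleAnnotation(f"mB{i:02d}", "basal_brca1", "run1", "chip1"))
    for i in range(n_sporadic):
        out.append(SampleAnnotation(f"mS{i:02d}", "basal_sporadic", "run1", "chip1"))
    return out


# --------------------------------------------------------------------------
# IHC cohort simulation
# --------------------------------------------------------------------------

_DEFAULT_POSITIVITY = {
    # planted per-evaluable-case positivity rates, BRCA1 vs sporadic,
    # mirroring the validation-cohort marker percentages
    "FOXP1": {"brca1": 0.52, "sporadic": 0.94},
    "CCND1": {"brca1": 0.57, "sporadic": 0.89},
    "NRP1": {"brca1": 0.41, "sporadic": 0.72},
}

_DEFAULT_INTENSITY = {1: 0.40, 2: 0.35, 3: 0.25}
_DEFAULT_PERCENT = {1: 0.25, 2: 0.30, 3: 0.25, 4: 0.20}


@dataclass
class IHCCohortSimConfig:
    """Two-group IHC cohort with planted marker positivity.

    ``panel_negative_corr`` is the latent (Gaussian-copula) correlation of
    marker negativity within a case; marginal positivity rates are exact
    regardless. ``p_evaluable`` thins records to emulate uninterpretable
    TMA cores.
    """

    n_brca1: int = 82
    n_sporadic: int = 65
    positivity: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {m: dict(v) for m, v in _DEFAULT_POSITIVITY.items()}
    )
    intensity_dist: Mapping[int, float] = field(default_factory=lambda: dict(_DEFAULT_INTENSITY))
    percent_dist: Mapping[int, float] = field(default_factory=lambda: dict(_DEFAULT_PERCENT))
    panel_negative_corr: float = 0.3
    p_evaluable: float = 0.95
    cohort: str = "validation"
    seed: int = 0

    def __post_init__(self) -> None:
        for marker, probs in self.positivity.items():
            for grp, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"positivity[{marker}][{grp}] = {p} outside [0, 1]")
        for name, dist in (("intensity_dist", self.intensity_dist), ("percent_dist", self.percent_dist)):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1")
            if 0 in dist:
                raise ConfigError(f"{name} is conditional on positivity; category 0 is implicit")
        if not 0.0 <= self.panel_negative_corr < 1.0:
            raise ConfigError("panel_negative_corr must lie in [0, 1)")


def gen_ihc_cohort(
    config: IHCCohortSimConfig,
) -> tuple[list[IHCRecord], dict]:
    """Simulate per-case marker records for both truth groups.

    Marker negativity is drawn through a shared latent case factor:
    z_marker = sqrt(rho) z_case + sqrt(1-rho) eps, negative iff z_marker
    falls below the marginal negativity quantile. Positive cases draw
    intensity >= 1 and percent category >= 1 from the configured
    distributions; negative cases are (0, 0).
    """
    from scipy import stats as _stats

    rng = _streams(config.seed, ["latent", "scores", "evaluable"])
    markers = sorted(config.positivity)
    records: list[IHCRecord] = []
    truth_labels: dict[str, str] = {}
    rho = config.panel_negative_corr
    int_cats = sorted(config.intensity_dist)
    int_probs = [config.intensity_dist[c] for c in int_cats]
    pct_cats = sorted(config.percent_dist)
    pct_probs = [config.percent_dist[c] for c in pct_cats]

    for group, prefix, n in (
        ("brca1", "B", config.n_brca1),
        ("sporadic", "S", config.n_sporadic),
    ):
        z_case = rng["latent"].normal(size=n)
        for i in range(n):
            case_id = f"{prefix}{i:04d}"
            truth_labels[case_id] = group
            for marker in markers:
                p_neg = 1.0 - config.positivity[marker][group]
                z = np.sqrt(rho) * z_case[i] + np.sqrt(1.0 - rho) * rng["latent"].normal()
                negative = z < _stats.norm.ppf(p_neg)
                if negative:
                    intensity, percent = 0, 0
                else:
                    intensity = int(rng["scores"].choice(int_cats, p=int_probs))
                    percent = int(rng["scores"].choice(pct_cats, p=pct_probs))
                evaluable = bool(rng["evaluable"].random() < config.p_evaluable)
                records.append(
                    IHCRecord(
                        case_id=case_id,
                        cohort=config.cohort,
                        truth_group=group,
                        marker=marker,
                        intensity=intensity,
                        percent_category=percent,
                        evaluable=evaluable,
                    )
                )
    truth = {
        "positivity": {m: dict(v) for m, v in config.positivity.items()},
        "labels": truth_labels,
        "panel_negative_corr": rho,
    }
    return records, truth


def kofn_rule_performance(
    negativity_probs: Sequence[float], k: int
) -> float:
    """Closed-form probability that >= k of n independent markers are
    negative — the oracle for panel sensitivity/specificity under the
    independence model."""
    n = len(negativity_probs)
    total = 0.0
    for flags in itertools.product([0, 1], repeat=n):
        if sum(flags) >= k:
            p = 1.0
            for f, q in zip(flags, negativity_probs):
                p *= q if f else (1.0 - q)
            total += p
    return total
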