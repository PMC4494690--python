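"""Consensus filtering of miRNA-target predictions.

Individual prediction algorithms are noisy (pSILAC benchmarking puts their
specificity near 44-61 %), so predictions from all sources are pooled with
a union search and a gene is retained only when at least ``min_support``
distinct differentially expressed miRNAs target it. Support is counted
per miRNA direction: targets of up-regulated miRNAs form the predicted
protein-DOWN list, targets of down-regulated miRNAs the predicted
protein-UP list, and genes reaching support in both directions appear in
both lists with ``in_both_lists`` set.

Because only a minority of targets (~20 %) are degraded by RISC-mediated
cleavage, an optional cross-reference against mRNA differential expression
flags the consensus genes whose mRNA itself shifts (in the direction
opposite to their miRNAs, by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError
from .types import ConsensusGene, TargetPair


@dataclass(frozen=True)
class ConsensusConfig:
    min_support: int = 3
    require_opposite_mrna_direction: bool = True

    def __post_init__(self) -> None:
        if self.min_support < 1:
            raise ValidationError("min_support must be >= 1")


def union_targets(tables: Sequence[Sequence[TargetPair]]) -> dict[tuple[str, str], set[str]]:
    """Union of all prediction tables: (miRNA, gene) -> set of sources."""
    union: dict[tuple[str, str], set[str]] = {}
    for table in tables:
        for pair in table:
            union.setdefault((pair.mirna_id, pair.gene_id), set()).add(pair.source)
    return union


def consensus_genes(
    pairs: Mapping[tuple[str, str], set[str]] | Iterable[tuple[str, str]],
    de_mirnas: Mapping[str, str],
    config: ConsensusConfig = ConsensusConfig(),
) -> list[ConsensusGene]:
    """Genes targeted by >= min_support distinct DE miRNAs, per direction.

    Parameters
    ----------
    pairs
        Union of (miRNA, gene) prediction edges.
    de_mirnas
        miRNA id -> direction ("up_in_A" or "down_in_A") for the
        differentially expressed miRNAs of the contrast.
    """
    if not de_mirnas:
        raise ValidationError("de_mirnas must be non-empty")
    bad = {d for d in de_mirnas.values() if d not in ("up_in_A", "down_in_A")}
    if bad:
        raise ValidationError(f"unknown miRNA directions: {sorted(bad)}")
    support: dict[str, dict[str, set[str]]] = {}
    for mirna, gene in pairs:
        direction = de_mirnas.get(mirna)
        if direction is None:
            continue
        support.setdefault(gene, {"up_in_A": set(), "down_in_A": set()})[direction].add(mirna)

    out: list[ConsensusGene] = []
    for gene in sorted(support):
        by_dir = support[gene]
        up_m, down_m = by_dir["up_in_A"], by_dir["down_in_A"]
        hit_up = len(up_m) >= config.min_support  # up miRNAs -> protein down
        hit_down = len(down_m) >= config.min_support  # down miRNAs -> protein up
        both = hit_up and hit_down
        if hit_up:
            out.append(
                ConsensusGene(
                    gene_id=gene,
                    supporting_mirnas=frozenset(up_m),
                    predicted_protein_direction="down_in_A",
                    in_both_lists=both,
                )
            )
        if hit_down:
            out.append(
                ConsensusGene(
                    gene_id=gene,
                    supporting_mirnas=frozenset(down_m),
                    predicted_protein_direction="up_in_A",
                    in_both_lists=both,
                )
            )
    return out


def cleavage_subset(
    consensus: Sequence[ConsensusGene],
    mrna_de: Mapping[str, tuple[float, str]],
    config: ConsensusConfig = ConsensusConfig(),
    alpha: float = 0.05,
) -> list[ConsensusGene]:
    """Flag consensus genes whose mRNA is itself differentially expressed.

    ``mrna_de`` maps gene id -> (BH-adjusted p, mRNA direction). A gene is
    flagged when its mRNA q-value is below ``alpha`` and — if the config
    requires it — the mRNA moves opposite to its supporting miRNAs, i.e.
    the mRNA direction equals the predicted protein direction.
    """
    flagged = []
    for gene in consensus:
        entry = mrna_de.get(gene.gene_id)
        flag = False
        if entry is not None:
            q, direction = entry
            if q < alpha:
                flag = (
                    direction == gene.predicted_protein_direction
                    if config.require_opposite_mrna_direction
                    else True
                )
        flagged.append(
            ConsensusGene(
                gene_id=gene.gene_id,
                supporting_mirnas=gene.supporting_mirnas,
                predicted_protein_direction=gene.predicted_protein_direction,
                in_both_lists=gene.in_both_lists,
                cleavage_flag=flag,
            )
        )
    return flagged


def overlap_stats(consensus: Sequence[ConsensusGene]) -> dict[str, float]:
    """Counts of the predicted-up and predicted-down lists, their overlap,
    and the overlap fraction.

    ``n_total`` sums the two list sizes (a gene reaching support in both
    directions is counted in each list), so the overlap fraction is
    n_overlap / (n_up + n_down); ``n_distinct`` counts unique genes.
    """
    up = {g.gene_id for g in consensus if g.predicted_protein_direction == "up_in_A"}
    down = {g.gene_id for g in consensus if g.predicted_protein_direction == "down_in_A"}
    overlap = up & down
    n_total = len(up) + len(down)
    return {
        "n_total": n_total,
        "n_distinct": len(up | down),
        "n_up": len(up),
        "n_down": len(down),
        "n_overlap": len(overlap),
        "overlap_fraction": (len(overlap) / n_total) if n_total else 0.0,
    }
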