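"""Chromosomal distribution accounting and positional gene-cluster detection.

A cluster is a maximal chain of >= ``cluster_min_genes`` same-family genes on
one chromosome in which each consecutive gene lies within
``cluster_max_gap_bp`` of the previous one (gap anchored start-to-start by
default).  Chaining, not total span, is the rule: cluster spans may exceed
the gap threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

from .io_formats import (
    SUBGENOME_A,
    SUBGENOME_B,
    SUBGENOME_NONE,
    UNPLACED,
    AnalysisConfig,
    GeneModel,
)
from .rga_classifier import family_of


@dataclass
class GeneCluster:
    """A positional grouping of >=3 same-family genes on one chromosome."""

    cluster_id: str
    chromosome: str
    member_ids: list[str]
    span_bp: int
    homogeneous: bool | None = None
    tandem: bool | None = None

    def __len__(self) -> int:
        return len(self.member_ids)


@dataclass
class ClusterSummary:
    n_clusters: int
    n_genes: int
    mean_genes_per_subgenome: dict[str, float]
    min_span_kb: Decimal
    max_span_kb: Decimal
    mean_span_kb: Decimal


def assign_subgenome(gene: GeneModel, cfg: AnalysisConfig) -> str:
    """Regex-based chromosome -> sub-genome mapping."""
    return cfg.subgenome_of(gene.chromosome)


def distribution_table(
    genes: Iterable[GeneModel], classes: Mapping[str, str]
) -> dict:
    """Per-chromosome counts by class, plus the mapped/unassigned split.

    Returns a dict with keys ``per_chromosome`` (chromosome -> class ->
    count), ``mapped`` (class -> count), ``unassigned`` (class -> count) and
    ``total`` (class -> count); mapped + unassigned = total per class.
    """
    per_chrom: dict[str, dict[str, int]] = {}
    mapped: dict[str, int] = {}
    unassigned: dict[str, int] = {}
    total: dict[str, int] = {}
    for g in genes:
        cls = classes.get(g.gene_id, "NON_RGA")
        total[cls] = total.get(cls, 0) + 1
        if g.placed:
            mapped[cls] = mapped.get(cls, 0) + 1
            per_chrom.setdefault(g.chromosome, {})
            per_chrom[g.chromosome][cls] = per_chrom[g.chromosome].get(cls, 0) + 1
        else:
            unassigned[cls] = unassigned.get(cls, 0) + 1
    return {
        "per_chromosome": per_chrom,
        "mapped": mapped,
        "unassigned": unassigned,
        "total": total,
    }


def family_counts(table: dict, family_classes: Sequence[str]) -> dict[str, int]:
    """Collapse a distribution table onto one family (mapped/unassigned/total)."""
    return {
        key: sum(table[key].get(c, 0) for c in family_classes)
        for key in ("mapped", "unassigned", "total")
    }


def detect_clusters(
    family_genes_on_one_chromosome: Sequence[GeneModel],
    cfg: AnalysisConfig,
    cluster_prefix: str = "C",
) -> list[GeneCluster]:
    """Maximal <=gap chains of length >= cluster_min_genes on one chromosome.

    Input must be sorted by start and restricted to one chromosome and one
    family; unsorted input is a hard error.
    """
    genes = list(family_genes_on_one_chromosome)
    if not genes:
        return []
    chroms = {g.chromosome for g in genes}
    if len(chroms) > 1:
        raise ValueError(f"genes span multiple chromosomes: {sorted(chroms)}")
    starts = [g.start for g in genes]
    if starts != sorted(starts):
        raise ValueError("input genes are not sorted by start")

    clusters: list[GeneCluster] = []
    chain: list[GeneModel] = [genes[0]]
    idx = 0

    def flush(chain: list[GeneModel]) -> None:
        nonlocal idx
        if len(chain) >= cfg.cluster_min_genes:
            idx += 1
            clusters.append(
                GeneCluster(
                    cluster_id=f"{cluster_prefix}{chain[0].chromosome}.{idx}",
                    chromosome=chain[0].chromosome,
                    member_ids=[g.gene_id for g in chain],
                    span_bp=chain[-1].end - chain[0].start,
                )
            )

    for prev, cur in zip(genes, genes[1:]):
        anchor = prev.start if cfg.gap_anchor == "start-start" else prev.end
        if cur.start - anchor <= cfg.cluster_max_gap_bp:
            chain.append(cur)
        else:
            flush(chain)
            chain = [cur]
    flush(chain)
    return clusters


def detect_family_clusters(
    genes: Iterable[GeneModel],
    classes: Mapping[str, str],
    family: str,
    cfg: AnalysisConfig,
) -> list[GeneCluster]:
    """Run cluster detection for one family across all chromosomes."""
    members = [
        g
        for g in genes
        if g.placed and family_of(classes.get(g.gene_id, "NON_RGA")) == family
    ]
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in members:
        by_chrom.setdefault(g.chromosome, []).append(g)
    clusters: list[GeneCluster] = []
    for chrom in sorted(by_chrom):
        chrom_genes = sorted(by_chrom[chrom], key=lambda g: (g.start, g.gene_id))
        clusters.extend(
            detect_clusters(chrom_genes, cfg, cluster_prefix=f"{family}-")
        )
    return clusters


def _kb(value_bp: float) -> Decimal:
    return (Decimal(value_bp) / Decimal(1000)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )


def cluster_statistics(
    clusters: Sequence[GeneCluster], cfg: AnalysisConfig | None = None
) -> ClusterSummary:
    """Count/span summary for one family's clusters (spans in kb, 2 dp)."""
    cfg = cfg or AnalysisConfig()
    if not clusters:
        zero = Decimal("0.00")
        return ClusterSummary(0, 0, {}, zero, zero, zero)
    spans = [c.span_bp for c in clusters]
    by_sg: dict[str, list[int]] = {}
    for c in clusters:
        sg = cfg.subgenome_of(c.chromosome)
        by_sg.setdefault(sg, []).append(len(c))
    mean_genes = {sg: sum(v) / len(v) for sg, v in sorted(by_sg.items())}
    return ClusterSummary(
        n_clusters=len(clusters),
        n_genes=sum(len(c) for c in clusters),
        mean_genes_per_subgenome=mean_genes,
        min_span_kb=_kb(min(spans)),
        max_span_kb=_kb(max(spans)),
        mean_span_kb=_kb(sum(spans) / len(spans)),
    )


def label_homogeneity(
    cluster: GeneCluster, classes: Mapping[str, str]
) -> bool:
    """True iff every member shares one subfamily (e.g. all LRR_RLK)."""
    member_classes = {classes[m] for m in cluster.member_ids}
    return len(member_classes) == 1


def label_cluster_homogeneity(
    clusters: Iterable[GeneCluster], classes: Mapping[str, str]
) -> list[GeneCluster]:
    for c in clusters:
        c.homogeneous = label_homogeneity(c, classes)
    return list(clusters)
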