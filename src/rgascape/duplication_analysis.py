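"""Duplicate-pair calling and typing (tandem/segmental/dispersed, intra/inter).

A pair is a duplicate when some hit between the two genes passes the
identity/dual-coverage thresholds.  Same-chromosome pairs split at the
tandem distance: within it TANDEM, beyond it SEGMENTAL; cross-chromosome
(or unplaced) pairs are DISPERSED.  Events are unique unordered pairs — no
transitive closure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .genome_landscape import GeneCluster
from .io_formats import (
    SUBGENOME_A,
    SUBGENOME_B,
    AnalysisConfig,
    GeneModel,
    SimilarityHit,
)

TANDEM = "TANDEM"
SEGMENTAL = "SEGMENTAL"
DISPERSED = "DISPERSED"

INTRA_A = "INTRA_A"
INTRA_B = "INTRA_B"
INTER = "INTER"
SCOPE_OTHER = "OTHER"


@dataclass
class DuplicatePair:
    """One duplication event between two genes (gene_a < gene_b)."""

    gene_a: str
    gene_b: str
    positional_type: str | None = None
    genome_scope: str | None = None
    evidence: SimilarityHit | None = None

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise ValueError("pair must be ordered gene_a < gene_b")

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def _better(a: SimilarityHit, b: SimilarityHit) -> SimilarityHit:
    """Lower E-value wins, then higher bitscore."""
    if (a.evalue, -a.bitscore) <= (b.evalue, -b.bitscore):
        return a
    return b


def call_duplicates(
    hits: Iterable[SimilarityHit], cfg: AnalysisConfig
) -> list[DuplicatePair]:
    """Unordered duplicate pairs passing identity and dual-coverage thresholds.

    Reciprocal hits collapse onto one pair; the best passing hit (lowest
    E-value, then highest bitscore) is stored as evidence.  Self-hits are
    ignored.
    """
    best: dict[tuple[str, str], SimilarityHit] = {}
    for h in hits:
        if h.is_self:
            continue
        if not (
            cfg.passes_min(h.pct_identity, cfg.dup_identity_min)
            and cfg.passes_min(h.query_cov, cfg.dup_coverage_min)
            and cfg.passes_min(h.subject_cov, cfg.dup_coverage_min)
        ):
            continue
        key = tuple(sorted((h.query_id, h.subject_id)))
        best[key] = h if key not in best else _better(best[key], h)
    return [
        DuplicatePair(gene_a=a, gene_b=b, evidence=best[(a, b)])
        for a, b in sorted(best)
    ]


def type_pair(
    pair: DuplicatePair,
    gene_positions: Mapping[str, GeneModel],
    cfg: AnalysisConfig,
) -> tuple[str, str]:
    """Positional type from start-to-start distance; scope from sub-genomes."""
    ga = gene_positions[pair.gene_a]
    gb = gene_positions[pair.gene_b]

    if ga.placed and gb.placed and ga.chromosome == gb.chromosome:
        distance = abs(ga.start - gb.start)
        positional = TANDEM if distance <= cfg.tandem_max_distance_bp else SEGMENTAL
    else:
        positional = DISPERSED

    sgs = {ga.sub_genome, gb.sub_genome}
    if sgs == {SUBGENOME_A}:
        scope = INTRA_A
    elif sgs == {SUBGENOME_B}:
        scope = INTRA_B
    elif sgs == {SUBGENOME_A, SUBGENOME_B}:
        scope = INTER
    else:
        scope = SCOPE_OTHER
    return positional, scope


def type_pairs(
    pairs: Iterable[DuplicatePair],
    gene_positions: Mapping[str, GeneModel],
    cfg: AnalysisConfig,
) -> list[DuplicatePair]:
    out = []
    for p in pairs:
        p.positional_type, p.genome_scope = type_pair(p, gene_positions, cfg)
        out.append(p)
    return out


@dataclass
class DuplicationSummary:
    n_events: int
    n_duplicated_genes: int
    n_tandem_genes: int
    n_segmental_genes: int
    n_mapped_genes: int
    events_by_type: dict[str, int]
    events_by_scope: dict[str, int]


def duplication_summary(
    pairs: Sequence[DuplicatePair], mapped_genes: Sequence[str] | int
) -> DuplicationSummary:
    """Per-family tallies: events = pairs, gene counts = distinct members.

    Scope tallies partition the events (INTRA_A + INTRA_B + INTER [+ OTHER]
    = total).
    """
    genes: set[str] = set()
    tandem_genes: set[str] = set()
    segmental_genes: set[str] = set()
    by_type: dict[str, int] = {TANDEM: 0, SEGMENTAL: 0, DISPERSED: 0}
    by_scope: dict[str, int] = {INTRA_A: 0, INTRA_B: 0, INTER: 0, SCOPE_OTHER: 0}
    for p in pairs:
        genes.update(p.key)
        if p.positional_type is not None:
            by_type[p.positional_type] += 1
            if p.positional_type == TANDEM:
                tandem_genes.update(p.key)
            elif p.positional_type == SEGMENTAL:
                segmental_genes.update(p.key)
        if p.genome_scope is not None:
            by_scope[p.genome_scope] += 1
    n_mapped = mapped_genes if isinstance(mapped_genes, int) else len(set(mapped_genes))
    return DuplicationSummary(
        n_events=len(pairs),
        n_duplicated_genes=len(genes),
        n_tandem_genes=len(tandem_genes),
        n_segmental_genes=len(segmental_genes),
        n_mapped_genes=n_mapped,
        events_by_type=by_type,
        events_by_scope=by_scope,
    )


def call_paralogs(
    hits: Iterable[SimilarityHit],
    cfg: AnalysisConfig,
    gene_positions: Mapping[str, GeneModel] | None = None,
) -> set[tuple[str, str]]:
    """Within-genome paralog pairs: E-value rule only (no identity/coverage).

    Genes must occupy distinct genomic positions; with positions available,
    co-located records (same chromosome and start) are rejected.
    """
    out: set[tuple[str, str]] = set()
    for h in hits:
        if h.is_self or h.evalue > cfg.paralog_evalue_max:
            continue
        if gene_positions is not None:
            ga = gene_positions.get(h.query_id)
            gb = gene_positions.get(h.subject_id)
            if (
                ga is not None
                and gb is not None
                and ga.chromosome == gb.chromosome
                and ga.start == gb.start
            ):
                continue
        out.add(tuple(sorted((h.query_id, h.subject_id))))
    return out


def paralog_groups(pairs: Iterable[tuple[str, str]]) -> list[set[str]]:
    """Connected components of the paralog-pair graph."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pairs:
        parent.setdefault(a, a)
        parent.setdefault(b, b)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    groups: dict[str, set[str]] = {}
    for node in parent:
        groups.setdefault(find(node), set()).add(node)
    return sorted(groups.values(), key=lambda s: sorted(s)[0])


def label_tandem_clusters(
    clusters: Iterable[GeneCluster], pairs: Iterable[DuplicatePair]
) -> list[GeneCluster]:
    """Set ``tandem`` on clusters whose every consecutive member pair is a
    TANDEM duplicate pair."""
    tandem_pairs = {
        p.key for p in pairs if p.positional_type == TANDEM
    }
    labelled = []
    for c in clusters:
        consecutive = zip(c.member_ids, c.member_ids[1:])
        c.tandem = all(
            tuple(sorted(ab)) in tandem_pairs for ab in consecutive
        )
        labelled.append(c)
    return labelled
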