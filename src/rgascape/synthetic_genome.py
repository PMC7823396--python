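"""Synthetic allotetraploid + progenitor worlds with planted ground truth.

Two generators are provided:

* :func:`simulate_world` — a seeded, configurable generator used for property
  and robustness testing.  Hit tables are synthesised directly (identity,
  coverage and E-value planted) rather than produced by a real aligner, so
  every planted relationship separates cleanly from background at the
  analysis thresholds.
* :func:`paper_counts_fixture` — a deterministic, hand-laid-out world whose
  planted tallies equal a published allotetraploid receptor-gene survey's
  headline counts, so summary percentages can be string-compared against
  printed values.

The E-value model is ``evalue = 10**-(identity - 30)`` clamped to
[1e-180, 1.0]: monotone in identity, and chosen so the threshold tiers
(1e-5 / 1e-20 / 1e-45) separate planted tiers from background.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import (
    SUBGENOME_A,
    SUBGENOME_B,
    AnalysisConfig,
    DomainRecord,
    GeneModel,
    SimilarityHit,
    make_hit,
    write_domain_table,
    write_gene_models,
    write_similarity_hits,
)

GENE_LEN = 999  # end - start; a gene occupies [s, s + GENE_LEN]
PROT_LEN = 500
PAD_BP = 400_000  # spacing between planted structures (> cluster gap)
FILLER_SPACING = 2_000
LOOSE_TANDEM_GAP = 1_000_000  # < tandem distance, > cluster gap
SEGMENTAL_GAP = 6_000_000  # > tandem distance

TETRAPLOID = "tetraploid"
PROGENITOR_A = "progenitor_A"
PROGENITOR_B = "progenitor_B"

RGA_DB_REF = "RGAdb_ref"


def evalue_from_identity(identity: float) -> float:
    return float(min(1.0, max(1e-180, 10.0 ** (-(identity - 30.0)))))


def planted_hit(
    qid: str,
    sid: str,
    identity: float = 85.0,
    coverage: float = 95.0,
    qlen: int = PROT_LEN,
    slen: int = PROT_LEN,
) -> SimilarityHit:
    span_q = int(round(coverage / 100.0 * qlen))
    span_s = int(round(coverage / 100.0 * slen))
    return make_hit(
        query_id=qid,
        subject_id=sid,
        pct_identity=round(identity, 3),
        aln_length=max(span_q, span_s),
        evalue=evalue_from_identity(identity),
        bitscore=round(identity * 10.0, 1),
        query_len=qlen,
        subject_len=slen,
        query_span=span_q,
        subject_span=span_s,
    )


def reciprocal_hits(a: str, b: str, identity: float = 85.0, coverage: float = 95.0):
    return [
        planted_hit(a, b, identity, coverage),
        planted_hit(b, a, identity, coverage),
    ]


_CLASS_DOMAINS = {
    "LRR_RLK": ["SIGNAL_PEPTIDE"] + ["LRR"] * 4 + ["TM", "KINASE_STTK"],
    "LYSM_RLK": ["SIGNAL_PEPTIDE", "LYSM", "TM", "KINASE_STTK"],
    "LRR_RLP": ["SIGNAL_PEPTIDE"] + ["LRR"] * 3 + ["TM"],
    "LYSM_RLP": ["SIGNAL_PEPTIDE", "LYSM", "TM"],
}


def domains_for(gene_id: str, rga_class: str) -> list[DomainRecord]:
    """The planted domain records implying the given class."""
    recs = []
    pos = 1
    for dom in _CLASS_DOMAINS.get(rga_class, []):
        recs.append(
            DomainRecord(
                gene_id=gene_id,
                domain_class=dom,
                p_start=pos,
                p_end=pos + 20,
                evalue=1e-10,
                source="simulated",
            )
        )
        pos += 25
    return recs


# ---------------------------------------------------------------------------
# Layout
# ---------------------------------------------------------------------------


class LayoutError(ValueError):
    """Planted structures do not fit on a chromosome."""


class _Layout:
    """Sequential placement of planted structures along chromosomes."""

    def __init__(self, chromosome_length_bp: int):
        self.length = chromosome_length_bp
        self.cursors: dict[str, int] = {}

    def _take(self, chrom: str, extent_bp: int, pad: int = PAD_BP) -> int:
        start = self.cursors.get(chrom, 100_001)
        if start + extent_bp > self.length:
            raise LayoutError(
                f"structure of {extent_bp} bp does not fit on {chrom} "
                f"(cursor {start}, length {self.length})"
            )
        self.cursors[chrom] = start + extent_bp + pad
        return start

    def cluster(self, chrom: str, n: int, span_bp: int) -> list[tuple[int, int]]:
        if n < 2 or span_bp <= GENE_LEN:
            raise LayoutError("cluster needs >=2 genes and span > gene length")
        p = self._take(chrom, span_bp)
        starts = [p + (i * (span_bp - GENE_LEN)) // (n - 1) for i in range(n)]
        return [(s, s + GENE_LEN) for s in starts]

    def pair(self, chrom: str, gap_bp: int) -> list[tuple[int, int]]:
        p = self._take(chrom, gap_bp + GENE_LEN)
        return [(p, p + GENE_LEN), (p + gap_bp, p + gap_bp + GENE_LEN)]

    def single(self, chrom: str) -> tuple[int, int]:
        p = self._take(chrom, GENE_LEN)
        return (p, p + GENE_LEN)

    def filler(self, chrom: str) -> tuple[int, int]:
        p = self._take(chrom, GENE_LEN, pad=FILLER_SPACING)
        return (p, p + GENE_LEN)


# ---------------------------------------------------------------------------
# World containers
# ---------------------------------------------------------------------------


@dataclass
class SpeciesData:
    genes: list[GeneModel] = field(default_factory=list)
    domains: list[DomainRecord] = field(default_factory=list)
    prescreen_hits: list[SimilarityHit] = field(default_factory=list)
    self_hits: list[SimilarityHit] = field(default_factory=list)


@dataclass
class GroundTruth:
    """Everything planted, keyed so every pipeline stage can be scored."""

    classes: dict[str, dict[str, str]] = field(default_factory=dict)
    clusters: dict[tuple[str, str], list[list[str]]] = field(default_factory=dict)
    cluster_spans: dict[tuple[str, str], list[int]] = field(default_factory=dict)
    tandem_cluster_idx: dict[tuple[str, str], set[int]] = field(default_factory=dict)
    # (species, family) -> {(gene_a, gene_b): (positional_type, scope)}
    pairs: dict[tuple[str, str], dict[tuple[str, str], tuple[str, str]]] = field(
        default_factory=dict
    )
    orthologs: dict[tuple[str, str], set[tuple[str, str]]] = field(default_factory=dict)
    conserved_tet: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    conserved_prog: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    syntenic: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    # -- derived tallies ----------------------------------------------------
    def duplicated_genes(self, species: str, family: str) -> set[str]:
        return {g for pair in self.pairs.get((species, family), {}) for g in pair}

    def genes_of_type(self, species: str, family: str, ptype: str) -> set[str]:
        return {
            g
            for pair, (pt, _) in self.pairs.get((species, family), {}).items()
            for g in pair
            if pt == ptype
        }

    def events_by_scope(self, species: str, family: str) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, (_, scope) in self.pairs.get((species, family), {}).items():
            out[scope] = out.get(scope, 0) + 1
        return out

    def validate(self, positions: Mapping[str, GeneModel], cfg: AnalysisConfig) -> None:
        for (species, family), pairmap in self.pairs.items():
            for (a, b), (ptype, scope) in pairmap.items():
                ga, gb = positions[a], positions[b]
                if ptype == "TANDEM":
                    assert ga.chromosome == gb.chromosome and ga.placed
                    assert abs(ga.start - gb.start) <= cfg.tandem_max_distance_bp
                elif ptype == "SEGMENTAL":
                    assert ga.chromosome == gb.chromosome and ga.placed
                    assert abs(ga.start - gb.start) > cfg.tandem_max_distance_bp
                else:
                    assert (not ga.placed) or (not gb.placed) or (
                        ga.chromosome != gb.chromosome
                    )
                if scope == "INTER":
                    assert {ga.sub_genome, gb.sub_genome} == {SUBGENOME_A, SUBGENOME_B}
                elif scope == "INTRA_A":
                    assert ga.sub_genome == gb.sub_genome == SUBGENOME_A
                elif scope == "INTRA_B":
                    assert ga.sub_genome == gb.sub_genome == SUBGENOME_B
        for (species, family), clusters in self.clusters.items():
            for members in clusters:
                assert len(members) >= cfg.cluster_min_genes
                genes = [positions[m] for m in members]
                assert len({g.chromosome for g in genes}) == 1
                starts = [g.start for g in genes]
                assert starts == sorted(starts)
                for s0, s1 in zip(starts, starts[1:]):
                    assert s1 - s0 <= cfg.cluster_max_gap_bp
        for key, pairs in self.orthologs.items():
            tets = {t for t, _ in pairs}
            assert self.conserved_tet[key] <= tets


@dataclass
class World:
    species: dict[str, SpeciesData]
    cross_hits: dict[tuple[str, str], list[SimilarityHit]]
    pairings: list[tuple[str, str, str]]  # (tetraploid, progenitor, sub_genome)
    ground_truth: GroundTruth
    cfg: AnalysisConfig = field(default_factory=AnalysisConfig)

    def species_inputs(self) -> dict[str, dict]:
        out: dict[str, dict] = {}
        for name, data in self.species.items():
            out[name] = {
                "genes": data.genes,
                "domains": data.domains,
                "prescreen_hits": data.prescreen_hits,
                "self_hits": data.self_hits,
                "cross_hits": {},
            }
        for (tet, prog), hits in self.cross_hits.items():
            out[tet]["cross_hits"][prog] = hits
        return out

    def positions(self) -> dict[str, GeneModel]:
        return {
            g.gene_id: g for data in self.species.values() for g in data.genes
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, data in self.species.items():
            write_gene_models(data.genes, out / f"{name}.gff3")
            write_domain_table(data.domains, out / f"{name}.domains.tsv")
            write_similarity_hits(data.prescreen_hits, out / f"{name}.rga_hits.tsv")
            write_similarity_hits(data.self_hits, out / f"{name}.self_hits.tsv")
        for (tet, prog), hits in self.cross_hits.items():
            write_similarity_hits(hits, out / f"{tet}_vs_{prog}.hits.tsv")
        manifest = {
            "species": sorted(self.species),
            "pairings": self.pairings,
            "planted_counts": {
                f"{sp}:{fam}:duplicated": len(
                    self.ground_truth.duplicated_genes(sp, fam)
                )
                for (sp, fam) in self.ground_truth.pairs
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# World builder (shared by both generators)
# ---------------------------------------------------------------------------


class _WorldBuilder:
    def __init__(self, species: str, layout: _Layout, cfg: AnalysisConfig):
        self.species = species
        self.layout = layout
        self.cfg = cfg
        self.data = SpeciesData()
        self.classes: dict[str, str] = {}
        self._counter = itertools.count()
        self._scaffold = itertools.count(1)

    def _new_id(self, prefix: str) -> str:
        return f"{prefix}{next(self._counter):05d}"

    def add_gene(
        self, prefix: str, chrom: str, start: int, end: int, rga_class: str
    ) -> str:
        gid = self._new_id(prefix)
        self.data.genes.append(
            GeneModel(
                gene_id=gid,
                species=self.species,
                chromosome=chrom,
                start=start,
                end=end,
                strand="+",
                sub_genome=self.cfg.subgenome_of(chrom),
            )
        )
        self.classes[gid] = rga_class
        if rga_class != "NON_RGA":
            self.data.domains.extend(domains_for(gid, rga_class))
            self.data.prescreen_hits.append(
                planted_hit(gid, RGA_DB_REF, identity=85.0)
            )
        return gid

    def add_unplaced(self, prefix: str, rga_class: str) -> str:
        from .io_formats import UNPLACED

        gid = self._new_id(prefix)
        self.data.genes.append(
            GeneModel(
                gene_id=gid,
                species=self.species,
                chromosome=UNPLACED,
                start=1,
                end=1 + GENE_LEN,
                strand="+",
                sub_genome="NONE",
            )
        )
        self.classes[gid] = rga_class
        if rga_class != "NON_RGA":
            self.data.domains.extend(domains_for(gid, rga_class))
            self.data.prescreen_hits.append(
                planted_hit(gid, RGA_DB_REF, identity=85.0)
            )
        return gid

    def add_cluster(
        self, prefix: str, chrom: str, sizes_classes: Sequence[str], span_bp: int
    ) -> list[str]:
        coords = self.layout.cluster(chrom, len(sizes_classes), span_bp)
        return [
            self.add_gene(prefix, chrom, s, e, cls)
            for (s, e), cls in zip(coords, sizes_classes)
        ]

    def add_pair(
        self, prefix: str, chrom: str, gap_bp: int, rga_class: str
    ) -> tuple[str, str]:
        (s1, e1), (s2, e2) = self.layout.pair(chrom, gap_bp)
        return (
            self.add_gene(prefix, chrom, s1, e1, rga_class),
            self.add_gene(prefix, chrom, s2, e2, rga_class),
        )

    def add_single(self, prefix: str, chrom: str, rga_class: str) -> str:
        s, e = self.layout.single(chrom)
        return self.add_gene(prefix, chrom, s, e, rga_class)

    def add_filler(self, prefix: str, chrom: str) -> str:
        s, e = self.layout.filler(chrom)
        return self.add_gene(prefix, chrom, s, e, "NON_RGA")


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


def _cross_chrom_pairs(
    genes: Sequence[str],
    positions: Mapping[str, GeneModel],
    n_pairs: int,
) -> list[tuple[str, str]]:
    """Disjoint pairs of genes on different chromosomes, taken greedily from
    the front of the list."""
    pool = list(genes)
    pairs: list[tuple[str, str]] = []
    while len(pairs) < n_pairs:
        if len(pool) < 2:
            raise LayoutError("not enough genes for requested dispersed pairs")
        a = pool.pop(0)
        partner_idx = next(
            (
                i
                for i, b in enumerate(pool)
                if positions[b].chromosome != positions[a].chromosome
            ),
            None,
        )
        if partner_idx is None:
            raise LayoutError("cannot form a cross-chromosome pair")
        b = pool.pop(partner_idx)
        pairs.append(_pair_key(a, b))
    return pairs


def _round_robin(by_chrom: Mapping[str, Sequence[str]]) -> list[str]:
    """Interleave per-chromosome lists so consecutive entries usually sit on
    different chromosomes."""
    iters = [iter(by_chrom[c]) for c in sorted(by_chrom)]
    out: list[str] = []
    for batch in itertools.zip_longest(*iters):
        out.extend(g for g in batch if g is not None)
    return out


# ---------------------------------------------------------------------------
# Generic simulator
# ---------------------------------------------------------------------------


def _default_class_counts() -> dict[str, int]:
    return {
        "LRR_RLK": 80,
        "LYSM_RLK": 4,
        "LRR_RLP": 40,
        "LYSM_RLP": 2,
        "NON_RGA": 150,
    }


def _default_pair_counts() -> dict[str, dict[str, int]]:
    return {
        "RLK": {"tandem": 8, "segmental": 3, "dispersed": 6, "inter": 8},
        "RLP": {"tandem": 4, "segmental": 1, "dispersed": 3, "inter": 4},
    }


@dataclass
class SimConfig:
    """Parameters of the generic world generator."""

    rng_seed: int = 0
    n_chromosomes_a: int = 10
    n_chromosomes_b: int = 8
    chromosome_length_bp: int = 60_000_000
    class_counts: dict[str, int] = field(default_factory=_default_class_counts)
    n_clusters: dict[str, int] = field(
        default_factory=lambda: {"RLK": 4, "RLP": 2}
    )
    cluster_sizes: tuple[int, ...] = (3, 4, 5)
    pair_counts: dict[str, dict[str, int]] = field(default_factory=_default_pair_counts)
    ortholog_retention_prob: dict[str, float] = field(
        default_factory=lambda: {"A": 0.8, "B": 0.8}
    )
    n_lost: dict[str, int] = field(default_factory=lambda: {"A": 5, "B": 5})
    identity_dup_range: tuple[float, float] = (75.0, 95.0)
    identity_background_max: float = 40.0
    unplaced_fraction: float = 0.05

    def validate(self) -> None:
        if any(v < 0 for v in self.class_counts.values()):
            raise ValueError("class counts must be nonnegative")
        if self.identity_dup_range[0] <= self.identity_background_max:
            raise ValueError(
                "identity_dup_range must sit above identity_background_max "
                "in the noiseless regime"
            )
        if not 0.0 <= self.unplaced_fraction < 1.0:
            raise ValueError("unplaced_fraction must be in [0, 1)")


_FAMILY_LRR = {"RLK": "LRR_RLK", "RLP": "LRR_RLP"}
_FAMILY_LYSM = {"RLK": "LYSM_RLK", "RLP": "LYSM_RLP"}


def simulate_world(cfg: SimConfig) -> World:
    """Generate a tetraploid + two progenitors with planted ground truth.

    Deterministic for a fixed seed; planted count totals depend only on the
    config, never on the seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    acfg = AnalysisConfig(rng_seed=cfg.rng_seed)
    chroms_a = [f"A{i:02d}" for i in range(1, cfg.n_chromosomes_a + 1)]
    chroms_b = [f"B{i:02d}" for i in range(1, cfg.n_chromosomes_b + 1)]
    layout = _Layout(cfg.chromosome_length_bp)
    b = _WorldBuilder(TETRAPLOID, layout, acfg)
    gt = GroundTruth()

    def rand_chrom(pool: Sequence[str]) -> str:
        return pool[int(rng.integers(len(pool)))]

    def dup_identity() -> float:
        lo, hi = cfg.identity_dup_range
        return float(rng.uniform(lo, hi))

    self_hits = b.data.self_hits
    all_chroms = chroms_a + chroms_b

    for family in ("RLK", "RLP"):
        lrr = _FAMILY_LRR[family]
        lysm = _FAMILY_LYSM[family]
        n_lrr = cfg.class_counts.get(lrr, 0)
        n_lysm = cfg.class_counts.get(lysm, 0)
        pairmap: dict[tuple[str, str], tuple[str, str]] = {}
        planted_lrr = 0

        # clusters (alternate sub-genomes); every cluster is tandem-planted
        clusters: list[list[str]] = []
        spans: list[int] = []
        tandem_idx: set[int] = set()
        for ci in range(cfg.n_clusters.get(family, 0)):
            # sizes cycle through the configured choices so planted totals
            # depend on the config only, never on the seed
            size = int(cfg.cluster_sizes[ci % len(cfg.cluster_sizes)])
            gaps = rng.integers(20_000, 150_000, size=size - 1)
            span = int(gaps.sum()) + GENE_LEN
            chrom = rand_chrom(chroms_a if ci % 2 == 0 else chroms_b)
            members = b.add_cluster("Tg", chrom, [lrr] * size, span)
            clusters.append(members)
            spans.append(span)
            tandem_idx.add(ci)
            planted_lrr += size
            for x, y in zip(members, members[1:]):
                key = _pair_key(x, y)
                scope = "INTRA_A" if chrom in chroms_a else "INTRA_B"
                pairmap[key] = ("TANDEM", scope)
                self_hits.extend(reciprocal_hits(x, y, dup_identity()))
        gt.clusters[(TETRAPLOID, family)] = clusters
        gt.cluster_spans[(TETRAPLOID, family)] = spans
        gt.tandem_cluster_idx[(TETRAPLOID, family)] = tandem_idx

        counts = cfg.pair_counts.get(family, {})
        for i in range(counts.get("tandem", 0)):
            chrom = rand_chrom(all_chroms)
            gap = int(rng.integers(300_000, acfg.tandem_max_distance_bp - 100_000))
            x, y = b.add_pair("Tg", chrom, gap, lrr)
            scope = "INTRA_A" if chrom in chroms_a else "INTRA_B"
            pairmap[_pair_key(x, y)] = ("TANDEM", scope)
            self_hits.extend(reciprocal_hits(x, y, dup_identity()))
            planted_lrr += 2
        for i in range(counts.get("segmental", 0)):
            chrom = rand_chrom(all_chroms)
            gap = int(
                rng.integers(
                    acfg.tandem_max_distance_bp + 500_000,
                    acfg.tandem_max_distance_bp + 3_000_000,
                )
            )
            x, y = b.add_pair("Tg", chrom, gap, lrr)
            scope = "INTRA_A" if chrom in chroms_a else "INTRA_B"
            pairmap[_pair_key(x, y)] = ("SEGMENTAL", scope)
            self_hits.extend(reciprocal_hits(x, y, dup_identity()))
            planted_lrr += 2
        for i in range(counts.get("dispersed", 0)):
            pool = chroms_a if i % 2 == 0 else chroms_b
            c1, c2 = rng.choice(len(pool), size=2, replace=False)
            x = b.add_single("Tg", pool[int(c1)], lrr)
            y = b.add_single("Tg", pool[int(c2)], lrr)
            scope = "INTRA_A" if pool is chroms_a else "INTRA_B"
            pairmap[_pair_key(x, y)] = ("DISPERSED", scope)
            self_hits.extend(reciprocal_hits(x, y, dup_identity()))
            planted_lrr += 2
        for _ in range(counts.get("inter", 0)):
            x = b.add_single("Tg", rand_chrom(chroms_a), lrr)
            y = b.add_single("Tg", rand_chrom(chroms_b), lrr)
            pairmap[_pair_key(x, y)] = ("DISPERSED", "INTER")
            self_hits.extend(reciprocal_hits(x, y, dup_identity()))
            planted_lrr += 2

        if planted_lrr > n_lrr:
            raise LayoutError(
                f"{family}: planted structures need {planted_lrr} {lrr} genes "
                f"but class_counts allows {n_lrr}"
            )
        n_unplaced = int((n_lrr - planted_lrr) * cfg.unplaced_fraction)
        for _ in range(n_lrr - planted_lrr - n_unplaced):
            b.add_single("Tg", rand_chrom(all_chroms), lrr)
        for _ in range(n_unplaced):
            b.add_unplaced("Tg", lrr)
        for _ in range(n_lysm):
            b.add_single("Tg", rand_chrom(all_chroms), lysm)
        gt.pairs[(TETRAPLOID, family)] = pairmap

    for _ in range(cfg.class_counts.get("NON_RGA", 0)):
        b.add_filler("Tf", rand_chrom(all_chroms))

    # background hits (reject at every threshold)
    family_genes = [g for g, c in b.classes.items() if c != "NON_RGA"]
    for i, gid in enumerate(family_genes):
        other = family_genes[(i + 7) % len(family_genes)]
        if other != gid:
            ident = float(rng.uniform(20.0, cfg.identity_background_max))
            self_hits.append(planted_hit(gid, other, ident, coverage=50.0))

    gt.classes[TETRAPLOID] = dict(b.classes)
    positions = {g.gene_id: g for g in b.data.genes}

    # progenitors: one per sub-genome; A-progenitor placed collinearly,
    # B-progenitor on unanchored scaffolds (excluded from synteny)
    species = {TETRAPLOID: b.data}
    cross: dict[tuple[str, str], list[SimilarityHit]] = {}
    for sg, prog_name, placed in (
        (SUBGENOME_A, PROGENITOR_A, True),
        (SUBGENOME_B, PROGENITOR_B, False),
    ):
        pb = _WorldBuilder(prog_name, _Layout(cfg.chromosome_length_bp), acfg)
        hits: list[SimilarityHit] = []
        for family in ("RLK", "RLP"):
            lrr = _FAMILY_LRR[family]
            tet_members = sorted(
                (
                    g
                    for g in b.data.genes
                    if gt.classes[TETRAPLOID][g.gene_id]
                    in (_FAMILY_LRR[family], _FAMILY_LYSM[family])
                    and g.sub_genome == sg
                ),
                key=lambda g: (g.chromosome, g.start),
            )
            # a fixed fraction is retained (count depends only on config);
            # the seed only decides which genes
            n_keep = int(round(cfg.ortholog_retention_prob[sg] * len(tet_members)))
            keep_idx = set(
                int(i)
                for i in rng.choice(len(tet_members), size=n_keep, replace=False)
            )
            keep = [i in keep_idx for i in range(len(tet_members))]
            conserved_tet: set[str] = set()
            conserved_prog: set[str] = set()
            opairs: set[tuple[str, str]] = set()
            syntenic: set[str] = set()
            for g, retained in zip(tet_members, keep):
                if not retained:
                    continue
                if placed:
                    pg = pb.add_single("Pg", g.chromosome, lrr)
                    syntenic.add(g.gene_id)
                else:
                    pg = pb.add_unplaced("Pg", lrr)
                conserved_tet.add(g.gene_id)
                conserved_prog.add(pg)
                opairs.add((g.gene_id, pg))
                hits.extend(reciprocal_hits(g.gene_id, pg, dup_identity()))
            for _ in range(cfg.n_lost.get(sg, 0)):
                if placed:
                    pg = pb.add_single(
                        "Pg", chroms_a[0] if sg == SUBGENOME_A else chroms_b[0], lrr
                    )
                else:
                    pg = pb.add_unplaced("Pg", lrr)
                conserved_prog.discard(pg)
            key = (family, sg)
            gt.orthologs[key] = opairs
            gt.conserved_tet[key] = conserved_tet
            gt.conserved_prog[key] = conserved_prog
            gt.syntenic[key] = syntenic if placed else set()
        gt.classes[prog_name] = dict(pb.classes)
        species[prog_name] = pb.data
        cross[(TETRAPLOID, prog_name)] = hits
        positions.update({g.gene_id: g for g in pb.data.genes})

    world = World(
        species=species,
        cross_hits=cross,
        pairings=[
            (TETRAPLOID, PROGENITOR_A, SUBGENOME_A),
            (TETRAPLOID, PROGENITOR_B, SUBGENOME_B),
        ],
        ground_truth=gt,
        cfg=acfg,
    )
    gt.validate(positions, acfg)
    return world


def perturb_world(
    world: World, noise_sd: float, dropout_rate: float, seed: int
) -> World:
    """Jitter hit identities (Gaussian, clamped to [0, 100]) and drop hit rows.

    Ground truth is untouched so recall/precision can be scored.
    """
    if not 0.0 <= dropout_rate <= 1.0:
        raise ValueError("dropout_rate must be in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)

    def perturb_hits(hits: list[SimilarityHit]) -> list[SimilarityHit]:
        out = []
        for h in hits:
            if dropout_rate and rng.random() < dropout_rate:
                continue
            ident = h.pct_identity
            if noise_sd:
                ident = float(np.clip(ident + rng.normal(0.0, noise_sd), 0.0, 100.0))
            out.append(
                SimilarityHit(
                    query_id=h.query_id,
                    subject_id=h.subject_id,
                    pct_identity=ident,
                    aln_length=h.aln_length,
                    evalue=h.evalue,
                    bitscore=h.bitscore,
                    query_len=h.query_len,
                    subject_len=h.subject_len,
                    query_cov=h.query_cov,
                    subject_cov=h.subject_cov,
                )
            )
        return out

    species = {
        name: SpeciesData(
            genes=data.genes,
            domains=data.domains,
            prescreen_hits=data.prescreen_hits,
            self_hits=perturb_hits(data.self_hits),
        )
        for name, data in world.species.items()
    }
    cross = {k: perturb_hits(v) for k, v in world.cross_hits.items()}
    return World(
        species=species,
        cross_hits=cross,
        pairings=world.pairings,
        ground_truth=world.ground_truth,
        cfg=world.cfg,
    )


# ---------------------------------------------------------------------------
# Deterministic fixture sized to the published headline tallies
# ---------------------------------------------------------------------------

# tetraploid per-chromosome family totals
_T_RLK_A = {"A01": 30, "A02": 25, "A03": 29, "A04": 16, "A05": 22,
            "A06": 31, "A07": 26, "A08": 12, "A09": 23, "A10": 22}
_T_RLK_B = {"B01": 27, "B02": 36, "B03": 30, "B04": 30, "B05": 33,
            "B06": 20, "B07": 16, "B08": 30}
_T_RLP_A = {"A01": 12, "A02": 5, "A03": 17, "A04": 9, "A05": 6,
            "A06": 7, "A07": 11, "A08": 8, "A09": 17, "A10": 3}
_T_RLP_B = {"B01": 6, "B02": 10, "B03": 19, "B04": 23, "B05": 18,
            "B06": 11, "B07": 16, "B08": 14}

# (chromosome, size, span_bp, tandem, index of a LysM member or None)
_RLK_CLUSTERS = [
    ("A01", 3, 112_690, True, None),
    ("A01", 3, 112_690, True, None),
    ("A02", 3, 112_690, True, None),
    ("A02", 3, 112_690, True, None),
    ("A03", 3, 29_450, True, None),
    ("A03", 3, 112_690, True, None),
    ("A05", 3, 112_690, False, None),
    ("A06", 4, 112_690, False, 1),  # the single heterogeneous cluster
    ("A09", 4, 112_690, False, None),
    ("A10", 4, 112_690, False, None),
    ("B02", 5, 112_690, False, None),
    ("B02", 4, 112_750, False, None),
    ("B03", 3, 293_950, False, None),
    ("B04", 6, 112_690, False, None),
    ("B05", 6, 112_690, False, None),
    ("B08", 5, 112_690, False, None),
]
_RLP_CLUSTERS = [
    ("A03", 3, 33_380, True, None),
    ("A07", 3, 73_380, True, None),
    ("A08", 3, 73_380, False, None),
    ("B03", 3, 73_380, True, None),
    ("B04", 5, 73_380, True, None),
    ("B06", 3, 186_320, True, None),
    ("B07", 5, 73_380, True, None),
]

_RLK_LOOSE_TANDEM = {"A04": 1, "A05": 2, "A06": 2, "A07": 3, "A09": 1, "A10": 1,
                     "B01": 2, "B03": 2, "B05": 1, "B06": 2, "B07": 2, "B08": 1}
_RLP_LOOSE_TANDEM = {"A01": 2, "A06": 1, "A09": 2,
                     "B01": 1, "B02": 2, "B03": 2, "B04": 2, "B05": 2, "B08": 1}
_RLK_SEGMENTAL = ["A01", "A02", "A07", "A09", "B02", "B05", "B06", "B07"]
_RLP_SEGMENTAL = ["A03", "B05"]
_RLK_LYSM_SINGLES = {"A04": 2, "A05": 1, "A08": 1, "B01": 2, "B04": 1}
_RLP_LYSM_SINGLES = {"A06": 1, "B03": 1}

_N_UNPLACED_RLK_LRR, _N_UNPLACED_RLK_LYSM = 34, 1
_N_UNPLACED_RLP_LRR = 16
_TET_GENE_CONTENT = 80_430

# dispersed intra-genomic LRR pair counts per family
_RLK_DISP_INTRA = {"A": 56, "B": 66}
_RLP_DISP_INTRA = {"A": 10, "B": 9}
_RLK_DISP_ONLY = {"A": 159, "B": 173}
_RLP_DISP_ONLY = {"A": 33, "B": 21}
_RLK_INTER_LRR = 304
_RLP_INTER_LRR = 57

# progenitor A (placed, collinear) layout and conservation
_P_RLK_A = {"A01": 36, "A02": 28, "A03": 38, "A04": 16, "A05": 25,
            "A06": 49, "A07": 37, "A08": 19, "A09": 26, "A10": 21}
_P_RLP_A = {"A01": 10, "A02": 7, "A03": 9, "A04": 1, "A05": 6,
            "A06": 10, "A07": 4, "A08": 7, "A09": 9, "A10": 2}
_P_RLK_A_LYSM = {"A04": 1, "A06": 1, "A08": 1}
_P_RLP_A_LYSM = {"A06": 1, "A08": 1}
_P_A_RLK_UNPLACED = 5
_P_A_GENE_CONTENT = 46_098

_CONS_RLK_A = {"A01": 24, "A02": 17, "A03": 26, "A04": 13, "A05": 18,
               "A06": 27, "A07": 22, "A08": 12, "A09": 17, "A10": 18}  # 194
_CONS_RLP_A = {"A01": 6, "A02": 2, "A03": 1, "A04": 1, "A05": 1,
               "A06": 2, "A07": 2, "A08": 3, "A09": 5, "A10": 1}  # 24
# chromosomes carrying one conserved-but-displaced (non-syntenic) RLK anchor
_DISPLACED_RLK_A = {"A01": 5, "A02": 5}
_EXTRA_PROG_RLK_A = ("A06", 20)  # extra progenitor-side conserved genes -> 214
_EXTRA_PROG_RLP_A = ("A01", 3)  # -> 27

# progenitor B (scaffold-only): totals and conservation
_P_B_RLK_TOTAL, _P_B_RLK_LYSM = 317, 5
_P_B_RLP_TOTAL, _P_B_RLP_LYSM = 176, 1
_P_B_GENE_CONTENT = 49_826
_CONS_RLK_B = {"B01": 24, "B02": 30, "B03": 27, "B04": 23, "B05": 28,
               "B06": 17, "B07": 16, "B08": 24}  # 189
_CONS_RLP_B = {"B01": 6, "B02": 3, "B03": 13, "B04": 11, "B05": 11,
               "B06": 6, "B07": 9, "B08": 6}  # 65
_EXTRA_PROG_RLK_B = 38  # -> 227 conserved in the B progenitor
_EXTRA_PROG_RLP_B = 7  # -> 72


def _fixture_family(
    b: _WorldBuilder,
    gt: GroundTruth,
    family: str,
    totals: Mapping[str, int],
    cluster_specs,
    loose_tandem: Mapping[str, int],
    segmental: Sequence[str],
    lysm_singles: Mapping[str, int],
    disp_intra: Mapping[str, int],
    disp_only: Mapping[str, int],
    n_inter_lrr: int,
    lysm_intra_pairs,
    lysm_inter_pairs,
    n_unplaced_lrr: int,
    n_unplaced_lysm: int,
) -> None:
    """Plant one family of the deterministic fixture into the builder."""
    lrr, lysm = _FAMILY_LRR[family], _FAMILY_LYSM[family]
    used: dict[str, int] = {c: 0 for c in totals}
    pairmap: dict[tuple[str, str], tuple[str, str]] = {}
    lysm_by_slot: dict[str, list[str]] = {c: [] for c in totals}

    def scope_of(chrom: str) -> str:
        return "INTRA_A" if chrom.startswith("A") else "INTRA_B"

    clusters: list[list[str]] = []
    spans: list[int] = []
    tandem_idx: set[int] = set()
    nontandem_cluster_members: dict[str, list[str]] = {}
    for ci, (chrom, size, span, tandem, lysm_at) in enumerate(cluster_specs):
        member_classes = [lysm if i == lysm_at else lrr for i in range(size)]
        members = b.add_cluster("Tg", chrom, member_classes, span)
        used[chrom] += size
        clusters.append(members)
        spans.append(span)
        if tandem:
            tandem_idx.add(ci)
            for x, y in zip(members, members[1:]):
                pairmap[_pair_key(x, y)] = ("TANDEM", scope_of(chrom))
                b.data.self_hits.extend(reciprocal_hits(x, y))
        else:
            for m, cls in zip(members, member_classes):
                if cls == lrr:
                    nontandem_cluster_members.setdefault(chrom, []).append(m)
        if lysm_at is not None:
            lysm_by_slot[chrom].append(members[lysm_at])
    gt.clusters[(TETRAPLOID, family)] = clusters
    gt.cluster_spans[(TETRAPLOID, family)] = spans
    gt.tandem_cluster_idx[(TETRAPLOID, family)] = tandem_idx

    for chrom, n_pairs in loose_tandem.items():
        for _ in range(n_pairs):
            x, y = b.add_pair("Tg", chrom, LOOSE_TANDEM_GAP, lrr)
            used[chrom] += 2
            pairmap[_pair_key(x, y)] = ("TANDEM", scope_of(chrom))
            b.data.self_hits.extend(reciprocal_hits(x, y))
    for chrom in segmental:
        x, y = b.add_pair("Tg", chrom, SEGMENTAL_GAP, lrr)
        used[chrom] += 2
        pairmap[_pair_key(x, y)] = ("SEGMENTAL", scope_of(chrom))
        b.data.self_hits.extend(reciprocal_hits(x, y))
    for chrom, n in lysm_singles.items():
        for _ in range(n):
            gid = b.add_single("Tg", chrom, lysm)
            used[chrom] += 1
            lysm_by_slot[chrom].append(gid)

    singles_by_chrom: dict[str, list[str]] = {}
    for chrom in sorted(totals):
        n_singles = totals[chrom] - used[chrom]
        if n_singles < 0:
            raise LayoutError(f"{family}: structures overflow {chrom}")
        singles_by_chrom[chrom] = [
            b.add_single("Tg", chrom, lrr) for _ in range(n_singles)
        ]

    # LysM duplication relationships are planted explicitly
    for (c1, i1), (c2, i2) in lysm_intra_pairs:
        x, y = lysm_by_slot[c1][i1], lysm_by_slot[c2][i2]
        pairmap[_pair_key(x, y)] = ("DISPERSED", scope_of(c1))
        b.data.self_hits.extend(reciprocal_hits(x, y))
    for (c1, i1), (c2, i2) in lysm_inter_pairs:
        x, y = lysm_by_slot[c1][i1], lysm_by_slot[c2][i2]
        pairmap[_pair_key(x, y)] = ("DISPERSED", "INTER")
        b.data.self_hits.extend(reciprocal_hits(x, y))

    # dispersed-only LRR genes: drawn round-robin from singles plus
    # non-tandem cluster members, per sub-genome
    positions = {g.gene_id: g for g in b.data.genes}
    disp_lists: dict[str, list[str]] = {}
    for sg in ("A", "B"):
        pool_by_chrom = {
            c: singles_by_chrom.get(c, []) + nontandem_cluster_members.get(c, [])
            for c in totals
            if c.startswith(sg)
        }
        ordered = _round_robin(pool_by_chrom)
        if len(ordered) < disp_only[sg]:
            raise LayoutError(
                f"{family}/{sg}: pool {len(ordered)} < required {disp_only[sg]}"
            )
        chosen = ordered[: disp_only[sg]]
        disp_lists[sg] = chosen
        for x, y in _cross_chrom_pairs(chosen, positions, disp_intra[sg]):
            pairmap[_pair_key(x, y)] = ("DISPERSED", f"INTRA_{sg}")
            b.data.self_hits.extend(reciprocal_hits(x, y))

    la, lb = disp_lists["A"], disp_lists["B"]
    seen_inter: set[tuple[str, str]] = set()
    for i in range(n_inter_lrr):
        key = _pair_key(la[i % len(la)], lb[i % len(lb)])
        if key in seen_inter:
            raise LayoutError("duplicate inter-genomic pair generated")
        seen_inter.add(key)
        pairmap[key] = ("DISPERSED", "INTER")
        b.data.self_hits.extend(reciprocal_hits(*key))

    for _ in range(n_unplaced_lrr):
        b.add_unplaced("Tu", lrr)
    for _ in range(n_unplaced_lysm):
        b.add_unplaced("Tu", lysm)

    gt.pairs[(TETRAPLOID, family)] = pairmap


def _fixture_progenitor_a(gt: GroundTruth, acfg: AnalysisConfig):
    """Placed, collinear progenitor of the A sub-genome."""
    pb = _WorldBuilder(PROGENITOR_A, _Layout(60_000_000), acfg)
    by_chrom: dict[tuple[str, str], list[str]] = {}
    for family, per_chrom, lysm_chroms in (
        ("RLK", _P_RLK_A, _P_RLK_A_LYSM),
        ("RLP", _P_RLP_A, _P_RLP_A_LYSM),
    ):
        lrr, lysm = _FAMILY_LRR[family], _FAMILY_LYSM[family]
        for chrom in sorted(per_chrom):
            n_lysm = lysm_chroms.get(chrom, 0)
            classes = [lysm] * n_lysm + [lrr] * (per_chrom[chrom] - n_lysm)
            by_chrom[(family, chrom)] = [
                pb.add_single("Pa", chrom, cls) for cls in classes
            ]
    for _ in range(_P_A_RLK_UNPLACED):
        pb.add_unplaced("Pu", "LRR_RLK")
    for _ in range(_P_A_GENE_CONTENT - 300 - 65):
        chrom = f"A{(_ % 10) + 1:02d}"
        pb.add_filler("Pf", chrom)
    gt.classes[PROGENITOR_A] = dict(pb.classes)
    return pb, by_chrom


def _fixture_progenitor_b(gt: GroundTruth, acfg: AnalysisConfig):
    """Scaffold-only progenitor of the B sub-genome."""
    pb = _WorldBuilder(PROGENITOR_B, _Layout(60_000_000), acfg)
    genes: dict[str, list[str]] = {}
    for family, total, n_lysm in (
        ("RLK", _P_B_RLK_TOTAL, _P_B_RLK_LYSM),
        ("RLP", _P_B_RLP_TOTAL, _P_B_RLP_LYSM),
    ):
        lrr, lysm = _FAMILY_LRR[family], _FAMILY_LYSM[family]
        genes[family] = [pb.add_unplaced("Pb", lrr) for _ in range(total - n_lysm)]
        genes[family] += [pb.add_unplaced("Pb", lysm) for _ in range(n_lysm)]
    for _ in range(_P_B_GENE_CONTENT - _P_B_RLK_TOTAL - _P_B_RLP_TOTAL):
        pb.add_unplaced("Pf", "NON_RGA")
    gt.classes[PROGENITOR_B] = dict(pb.classes)
    return pb, genes


def paper_counts_fixture() -> World:
    """A deterministic world whose planted tallies equal the published
    headline counts (mapped/unplaced genes, clusters, duplication events,
    conservation and synteny), so report percentages can be compared against
    printed values."""
    acfg = AnalysisConfig()
    layout = _Layout(60_000_000)
    b = _WorldBuilder(TETRAPLOID, layout, acfg)
    gt = GroundTruth()

    _fixture_family(
        b,
        gt,
        "RLK",
        {**_T_RLK_A, **_T_RLK_B},
        _RLK_CLUSTERS,
        _RLK_LOOSE_TANDEM,
        _RLK_SEGMENTAL,
        _RLK_LYSM_SINGLES,
        _RLK_DISP_INTRA,
        _RLK_DISP_ONLY,
        _RLK_INTER_LRR,
        # one intra-genomic LysM event: A04 gene 0 with the A05 gene
        lysm_intra_pairs=[(("A04", 0), ("A05", 0))],
        # four inter-genomic LysM events (A06 slot holds the cluster member)
        lysm_inter_pairs=[
            (("A04", 1), ("B01", 0)),
            (("A06", 0), ("B04", 0)),
            (("A04", 0), ("B01", 1)),
            (("A05", 0), ("B04", 0)),
        ],
        n_unplaced_lrr=_N_UNPLACED_RLK_LRR,
        n_unplaced_lysm=_N_UNPLACED_RLK_LYSM,
    )
    _fixture_family(
        b,
        gt,
        "RLP",
        {**_T_RLP_A, **_T_RLP_B},
        _RLP_CLUSTERS,
        _RLP_LOOSE_TANDEM,
        _RLP_SEGMENTAL,
        _RLP_LYSM_SINGLES,
        _RLP_DISP_INTRA,
        _RLP_DISP_ONLY,
        _RLP_INTER_LRR,
        lysm_intra_pairs=[],
        lysm_inter_pairs=[(("A06", 0), ("B03", 0))],
        n_unplaced_lrr=_N_UNPLACED_RLP_LRR,
        n_unplaced_lysm=0,
    )

    all_chroms = sorted({**_T_RLK_A, **_T_RLK_B})
    n_filler = _TET_GENE_CONTENT - len(b.data.genes)
    for i in range(n_filler):
        b.add_filler("Tf", all_chroms[i % len(all_chroms)])
    gt.classes[TETRAPLOID] = dict(b.classes)

    # background within-species hits that must be rejected everywhere
    fam_genes = sorted(g for g, c in b.classes.items() if c != "NON_RGA")
    for i in range(0, 60):
        b.data.self_hits.append(
            planted_hit(fam_genes[i], fam_genes[i + 61], identity=35.0, coverage=50.0)
        )

    pa, pa_by_chrom = _fixture_progenitor_a(gt, acfg)
    pb, pb_genes = _fixture_progenitor_b(gt, acfg)

    tet_by = {
        (family, chrom): []
        for family in ("RLK", "RLP")
        for chrom in all_chroms
    }
    for g in b.data.genes:
        cls = b.classes[g.gene_id]
        if cls == "NON_RGA" or not g.placed:
            continue
        family = "RLK" if cls.endswith("RLK") else "RLP"
        tet_by[(family, g.chromosome)].append(g)
    for key in tet_by:
        tet_by[key].sort(key=lambda g: g.start)

    cross_a: list[SimilarityHit] = []
    cross_b: list[SimilarityHit] = []

    # --- A pairing: collinear anchors, two displaced RLK anchors, extra
    # progenitor-side conserved genes
    for family, cons, displaced, extra in (
        ("RLK", _CONS_RLK_A, _DISPLACED_RLK_A, _EXTRA_PROG_RLK_A),
        ("RLP", _CONS_RLP_A, {}, _EXTRA_PROG_RLP_A),
    ):
        opairs: set[tuple[str, str]] = set()
        conserved_tet: set[str] = set()
        conserved_prog: set[str] = set()
        syntenic: set[str] = set()
        for chrom, k in sorted(cons.items()):
            tet_genes = [g.gene_id for g in tet_by[(family, chrom)][:k]]
            prog_genes = pa_by_chrom[(family, chrom)]
            disp = displaced.get(chrom)
            if disp is None:
                partners = dict(zip(tet_genes, prog_genes[:k]))
            else:
                partners = {}
                normal = [t for i, t in enumerate(tet_genes) if i != disp]
                for t, p in zip(normal, prog_genes[1:k]):
                    partners[t] = p
                partners[tet_genes[disp]] = prog_genes[0]
            for t, p in partners.items():
                opairs.add((t, p))
                conserved_tet.add(t)
                conserved_prog.add(p)
                cross_a.extend(reciprocal_hits(t, p))
            if k - (1 if disp is not None else 0) >= acfg.synteny_min_chain:
                syntenic.update(t for i, t in enumerate(tet_genes) if i != disp)
        extra_chrom, n_extra = extra
        hub = tet_by[(family, extra_chrom)][0].gene_id
        k0 = cons[extra_chrom]
        for p in pa_by_chrom[(family, extra_chrom)][k0 : k0 + n_extra]:
            opairs.add((hub, p))
            conserved_prog.add(p)
            cross_a.extend(reciprocal_hits(hub, p))
        key = (family, SUBGENOME_A)
        gt.orthologs[key] = opairs
        gt.conserved_tet[key] = conserved_tet
        gt.conserved_prog[key] = conserved_prog
        gt.syntenic[key] = syntenic

    # --- B pairing: scaffold progenitor, conservation only
    for family, cons, n_extra in (
        ("RLK", _CONS_RLK_B, _EXTRA_PROG_RLK_B),
        ("RLP", _CONS_RLP_B, _EXTRA_PROG_RLP_B),
    ):
        opairs = set()
        conserved_tet = set()
        conserved_prog = set()
        prog_pool = pb_genes[family]
        cursor = 0
        for chrom, k in sorted(cons.items()):
            tet_genes = [g.gene_id for g in tet_by[(family, chrom)][:k]]
            for t in tet_genes:
                p = prog_pool[cursor]
                cursor += 1
                opairs.add((t, p))
                conserved_tet.add(t)
                conserved_prog.add(p)
                cross_b.extend(reciprocal_hits(t, p))
        hub = tet_by[(family, sorted(cons)[0])][0].gene_id
        for p in prog_pool[cursor : cursor + n_extra]:
            opairs.add((hub, p))
            conserved_prog.add(p)
            cross_b.extend(reciprocal_hits(hub, p))
        key = (family, SUBGENOME_B)
        gt.orthologs[key] = opairs
        gt.conserved_tet[key] = conserved_tet
        gt.conserved_prog[key] = conserved_prog
        gt.syntenic[key] = set()

    # failing cross-species hits (below ortholog thresholds)
    for i in range(20):
        cross_a.append(
            planted_hit(fam_genes[i], f"Pa{i:05d}", identity=60.0, coverage=95.0)
        )

    world = World(
        species={TETRAPLOID: b.data, PROGENITOR_A: pa.data, PROGENITOR_B: pb.data},
        cross_hits={
            (TETRAPLOID, PROGENITOR_A): cross_a,
            (TETRAPLOID, PROGENITOR_B): cross_b,
        },
        pairings=[
            (TETRAPLOID, PROGENITOR_A, SUBGENOME_A),
            (TETRAPLOID, PROGENITOR_B, SUBGENOME_B),
        ],
        ground_truth=gt,
        cfg=acfg,
    )
    _check_fixture_tallies(world)
    world.ground_truth.validate(world.positions(), acfg)
    return world


def _check_fixture_tallies(world: World) -> None:
    gt = world.ground_truth
    assert len(gt.duplicated_genes(TETRAPLOID, "RLK")) == 413
    assert len(gt.duplicated_genes(TETRAPLOID, "RLP")) == 112
    assert len(gt.genes_of_type(TETRAPLOID, "RLK", "TANDEM")) == 58
    assert len(gt.genes_of_type(TETRAPLOID, "RLK", "SEGMENTAL")) == 16
    assert len(gt.genes_of_type(TETRAPLOID, "RLP", "TANDEM")) == 52
    assert len(gt.genes_of_type(TETRAPLOID, "RLP", "SEGMENTAL")) == 4
    assert gt.events_by_scope(TETRAPLOID, "RLK") == {
        "INTRA_A": 83,
        "INTRA_B": 80,
        "INTER": 308,
    }
    assert gt.events_by_scope(TETRAPLOID, "RLP") == {
        "INTRA_A": 20,
        "INTRA_B": 32,
        "INTER": 58,
    }
    assert sum(len(c) for c in gt.clusters[(TETRAPLOID, "RLK")]) == 62
    assert sum(len(c) for c in gt.clusters[(TETRAPLOID, "RLP")]) == 25
    assert len(gt.clusters[(TETRAPLOID, "RLK")]) == 16
    assert len(gt.clusters[(TETRAPLOID, "RLP")]) == 7
    assert len(gt.tandem_cluster_idx[(TETRAPLOID, "RLK")]) == 6
    assert len(gt.tandem_cluster_idx[(TETRAPLOID, "RLP")]) == 6
    assert len(gt.conserved_tet[("RLK", "A")]) == 194
    assert len(gt.conserved_tet[("RLK", "B")]) == 189
    assert len(gt.conserved_tet[("RLP", "A")]) == 24
    assert len(gt.conserved_tet[("RLP", "B")]) == 65
    assert len(gt.conserved_prog[("RLK", "A")]) == 214
    assert len(gt.conserved_prog[("RLK", "B")]) == 227
    assert len(gt.conserved_prog[("RLP", "A")]) == 27
    assert len(gt.conserved_prog[("RLP", "B")]) == 72
    assert len(gt.syntenic[("RLK", "A")]) == 192
    tet_classes = gt.classes[TETRAPLOID]
    assert len(tet_classes) == _TET_GENE_CONTENT
    n_rlk = sum(1 for c in tet_classes.values() if c.endswith("RLK"))
    n_rlp = sum(1 for c in tet_classes.values() if c.endswith("RLP"))
    assert (n_rlk, n_rlp) == (493, 228)
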