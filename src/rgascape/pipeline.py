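"""End-to-end orchestration: per-species stages plus cross-species comparison.

This is thin glue over the analysis modules; it exists so the CLI, the test
suite and the acceptance script all exercise the same code path.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from .comparative_orthology import (
    call_orthologs,
    conservation_ledger,
    synteny_chains,
)
from .duplication_analysis import (
    call_duplicates,
    call_paralogs,
    duplication_summary,
    label_tandem_clusters,
    type_pairs,
)
from .genome_landscape import (
    cluster_statistics,
    detect_family_clusters,
    distribution_table,
    family_counts,
    label_cluster_homogeneity,
)
from .io_formats import AnalysisConfig, GeneModel, SimilarityHit, exclude_self_hits
from .rga_classifier import (
    RLK_CLASSES,
    RLP_CLASSES,
    classify_proteome,
    family_of,
)
from .summary_report import ResultBundle, SpeciesResult

FAMILIES = ("RLK", "RLP")
_FAMILY_CLASSES = {"RLK": RLK_CLASSES, "RLP": RLP_CLASSES}


def analyse_species(
    species: str,
    genes: Sequence[GeneModel],
    domains,
    prescreen_hits: Iterable[SimilarityHit],
    self_hits: Iterable[SimilarityHit],
    cfg: AnalysisConfig,
) -> SpeciesResult:
    """Run classification, distribution, clustering and duplication analysis
    for one species."""
    classification = classify_proteome(genes, domains, prescreen_hits, cfg)
    positions = {g.gene_id: g for g in genes}
    result = SpeciesResult(
        species=species,
        genes=list(genes),
        classification=classification,
        distribution=distribution_table(genes, classification),
    )

    clean_hits = exclude_self_hits(self_hits)
    for family in FAMILIES:
        members = {
            gid for gid, cls in classification.items() if family_of(cls) == family
        }
        fam_hits = [
            h
            for h in clean_hits
            if h.query_id in members and h.subject_id in members
        ]
        clusters = detect_family_clusters(genes, classification, family, cfg)
        label_cluster_homogeneity(clusters, classification)
        pairs = type_pairs(call_duplicates(fam_hits, cfg), positions, cfg)
        label_tandem_clusters(clusters, pairs)
        mapped = family_counts(result.distribution, _FAMILY_CLASSES[family])["mapped"]
        result.clusters[family] = clusters
        result.cluster_stats[family] = cluster_statistics(clusters, cfg)
        result.duplicate_pairs[family] = pairs
        result.dup_summary[family] = duplication_summary(pairs, mapped)
        result.paralogs[family] = call_paralogs(fam_hits, cfg, positions)
    return result


def compare_to_progenitor(
    bundle: ResultBundle,
    tetraploid: str,
    progenitor: str,
    sub_genome: str,
    cross_hits: Iterable[SimilarityHit],
    cfg: AnalysisConfig,
) -> None:
    """Ortholog calling, conservation ledger and synteny for one
    sub-genome <-> progenitor pairing; results land in the bundle."""
    tet = bundle.species[tetraploid]
    prog = bundle.species[progenitor]
    cross_hits = list(cross_hits)
    tet_ids = {g.gene_id for g in tet.genes}
    positions = {g.gene_id: g for g in tet.genes} | {
        g.gene_id: g for g in prog.genes
    }

    for family in FAMILIES:
        tet_members = {
            gid
            for gid, cls in tet.classification.items()
            if family_of(cls) == family
        }
        prog_members = {
            gid
            for gid, cls in prog.classification.items()
            if family_of(cls) == family
        }
        fam_hits = [
            h
            for h in cross_hits
            if (h.query_id in tet_members and h.subject_id in prog_members)
            or (h.query_id in prog_members and h.subject_id in tet_members)
        ]
        orthologs = call_orthologs(fam_hits, cfg, tetraploid_ids=tet_ids)
        bundle.orthologs[(family, sub_genome)] = orthologs

        tet_side = [
            g
            for g in tet.genes
            if g.gene_id in tet_members and g.sub_genome == sub_genome and g.placed
        ]
        prog_side = [g for g in prog.genes if g.gene_id in prog_members]
        bundle.conservation.append(
            conservation_ledger(
                tet_side,
                prog_side,
                orthologs,
                sub_genome=sub_genome,
                progenitor_species=progenitor,
                family=family,
            )
        )
        chains, syntenic = synteny_chains(orthologs, positions, cfg)
        bundle.synteny[(family, sub_genome)] = (chains, syntenic)


def run_pipeline(
    species_inputs: Mapping[str, dict],
    pairings: Sequence[tuple[str, str, str]],
    cfg: AnalysisConfig,
) -> ResultBundle:
    """Full pipeline.

    ``species_inputs`` maps species -> dict with keys genes, domains,
    prescreen_hits, self_hits; ``pairings`` lists (tetraploid, progenitor,
    sub_genome, cross_hits) via (tet, prog, sub_genome) keys into
    ``species_inputs[tet]['cross_hits'][prog]``.
    """
    bundle = ResultBundle()
    for species, data in species_inputs.items():
        bundle.species[species] = analyse_species(
            species,
            data["genes"],
            data.get("domains", []),
            data.get("prescreen_hits", []),
            data.get("self_hits", []),
            cfg,
        )
    for tetraploid, progenitor, sub_genome in pairings:
        cross = species_inputs[tetraploid].get("cross_hits", {}).get(progenitor, [])
        compare_to_progenitor(bundle, tetraploid, progenitor, sub_genome, cross, cfg)
    return bundle
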