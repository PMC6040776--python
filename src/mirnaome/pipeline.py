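"""End-to-end orchestration: tags -> annotation -> TPM -> DE screens ->
ordination and model profiles -> miRNA-mRNA network."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from . import annotate, diffexpr, network, patterns, quantify
from .annotate import GenomeAnnotation, HairpinCandidate, LibraryMeta, TagSet
from .quantify import ExpressionMatrix


@dataclass
class PipelineResult:
    """Everything the pipeline computes, stage by stage."""

    alignments: list
    annotation_summary: pd.DataFrame
    expression: ExpressionMatrix  # full (unfiltered) matrix with TPM
    filtered: ExpressionMatrix  # the >28 TPM analysis universe
    hairpins: list[HairpinCandidate]
    de_breed: pd.DataFrame
    breed_de_sets: dict[int, set[str]]
    de_stage: pd.DataFrame
    stage_de_sets: dict[str, set[str]]
    pca: patterns.OrdinationResult
    hca: patterns.OrdinationResult
    profiles: dict[str, list[patterns.ModelProfile]]
    pairs: list = field(default_factory=list)
    final_pairs: list = field(default_factory=list)
    network: nx.Graph | None = None


def run_pipeline(
    genome: GenomeAnnotation,
    libraries: list[tuple[LibraryMeta, TagSet]],
    mrna_matrix: pd.DataFrame | None = None,
    predicted_pairs: list[tuple[str, str]] | None = None,
    breed_de_mrnas: set[str] | None = None,
    tpm_threshold: float = quantify.DEFAULT_TPM_THRESHOLD,
    fold_threshold: float = diffexpr.DEFAULT_FOLD,
    p_threshold: float = diffexpr.DEFAULT_P,
    rho_threshold: float = network.DEFAULT_RHO,
    max_profiles: int = patterns.DEFAULT_MAX_PROFILES,
    hub_degree: int = network.HUB_DEGREE,
) -> PipelineResult:
    """Run every analysis stage on one study's libraries.

    The network stage runs only when a predicted-target list, an mRNA matrix
    and a breed-DE mRNA set are all supplied.
    """
    # preprocessing + mapping + annotation (on the union of unique tags)
    processed = [
        (meta, annotate.preprocess_tags(tags)) for meta, tags in libraries
    ]
    all_tags = sorted({t for _, tags in processed for t in tags})
    index = annotate.GenomeIndex(genome.chromosomes)
    alignments = annotate.map_tags(all_tags, genome, index=index)
    alignments = annotate.annotate_tags(alignments, genome)
    summary = annotate.annotation_summary(alignments, processed)

    # quantification and normalisation
    matrix = annotate.quantify_known_mirnas(alignments, genome, processed)
    matrix = quantify.tpm_normalize(matrix)
    filtered = quantify.high_expression_filter(matrix, threshold=tpm_threshold)

    # novel hairpin candidates from unannotated mapped tags
    hairpins = annotate.detect_novel_hairpins(alignments, genome)

    # differential expression
    de_breed = diffexpr.screen_de(
        filtered, mode="breed", fold_threshold=fold_threshold,
        p_threshold=p_threshold,
    )
    de_stage = diffexpr.screen_de(
        filtered, mode="stage", fold_threshold=fold_threshold,
        p_threshold=p_threshold,
    )
    bde_sets = diffexpr.breed_de_sets(de_breed)
    sde_sets = diffexpr.stage_de_sets(de_stage)

    # ordination on the z-scored filtered matrix
    standardized = patterns.zscore(filtered.tpm)
    pca = patterns.pca_libraries(standardized)
    hca = patterns.hcluster_libraries(standardized)

    # model-profile clustering, one panel per breed
    breeds = sorted({m.breed for m in filtered.metas.values()})
    profiles = {
        breed: patterns.run_stem(
            filtered.stage_matrix(breed), max_profiles=max_profiles
        )
        for breed in breeds
    }

    result = PipelineResult(
        alignments=alignments,
        annotation_summary=summary,
        expression=matrix,
        filtered=filtered,
        hairpins=hairpins,
        de_breed=de_breed,
        breed_de_sets=bde_sets,
        de_stage=de_stage,
        stage_de_sets=sde_sets,
        pca=pca,
        hca=hca,
        profiles=profiles,
    )

    if (
        mrna_matrix is not None
        and predicted_pairs is not None
        and breed_de_mrnas is not None
    ):
        mirna_traj = {b: filtered.stage_matrix(b) for b in breeds}
        mrna_traj = {}
        for breed in breeds:
            libs = sorted(
                (m for m in filtered.metas.values() if m.breed == breed),
                key=lambda m: m.stage,
            )
            cols = [m.library_id for m in libs]
            sub = mrna_matrix[cols].copy()
            sub.columns = [m.stage for m in libs]
            mrna_traj[breed] = sub
        pairs = network.pair_breed_de(
            bde_sets, predicted_pairs, mirna_traj, mrna_traj,
            rho_threshold=rho_threshold,
        )
        final = network.intersect_breed_de_mrna(pairs, breed_de_mrnas)
        result.pairs = pairs
        result.final_pairs = final
        result.network = network.build_network(final, hub_degree=hub_degree)
    return result


def run_on_dataset(dataset, **kwargs) -> PipelineResult:
    """Convenience entry point for a generator SyntheticDataset."""
    return run_pipeline(
        dataset.genome,
        dataset.libraries,
        mrna_matrix=dataset.mrna_matrix,
        predicted_pairs=[
            (r.mirna_id, r.mrna_id) for r in dataset.target_table.itertuples()
        ],
        breed_de_mrnas=set(dataset.truth.breed_de_mrnas),
        **kwargs,
    )


def write_outputs(result: PipelineResult, outdir) -> None:
    """Write the pipeline's tables: annotation composition, count and TPM
    matrices, DE tables, ordination scores, profile tables, hairpin report,
    pair table, SIF/GraphML network and degree table."""
    from . import io as mio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.annotation_summary.to_csv(outdir / "annotation_summary.tsv", sep="\t")
    mio.write_matrix_tsv(outdir / "counts.tsv", result.expression.counts)
    mio.write_matrix_tsv(outdir / "tpm.tsv", result.expression.tpm)
    mio.write_matrix_tsv(outdir / "tpm_filtered.tsv", result.filtered.tpm)
    result.de_breed.to_csv(outdir / "de_breed.tsv", sep="\t", index=False)
    result.de_stage.to_csv(outdir / "de_stage.tsv", sep="\t", index=False)
    result.pca.scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
    result.pca.variance_ratio.to_csv(
        outdir / "pca_variance.tsv", sep="\t", header=["fraction"]
    )
    pd.DataFrame(
        result.hca.linkage_matrix,
        columns=["left", "right", "height", "size"],
    ).to_csv(outdir / "dendrogram.tsv", sep="\t", index=False)
    for breed, profiles in result.profiles.items():
        patterns.profile_table(profiles).to_csv(
            outdir / f"profiles_{breed}.tsv", sep="\t"
        )
        rows = [
            {"mirna_id": mir, "profile_id": p.profile_id}
            for p in profiles
            for mir in p.assigned
        ]
        pd.DataFrame(rows).to_csv(
            outdir / f"assignments_{breed}.tsv", sep="\t", index=False
        )
    mio.write_hairpin_bed(outdir / "hairpins.bed", result.hairpins)
    if result.network is not None:
        pd.DataFrame(
            [
                {
                    "mirna_id": p.mirna_id,
                    "mrna_id": p.mrna_id,
                    **{f"rho_{b}": r for b, r in p.rho.items()},
                }
                for p in result.final_pairs
            ]
        ).to_csv(outdir / "pairs.tsv", sep="\t", index=False)
        network.export_network(
            result.network, outdir / "network.sif", outdir / "network.graphml"
        )
        network.degree_table(result.network).to_csv(
            outdir / "degrees.tsv", sep="\t", index=False
        )
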