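"""Plain-text readers and writers: FASTA (genome, catalog, collapsed tags),
BED features, library tables and matrices.

Collapsed tag FASTA uses the "id_x<count>" header dialect; BED is 0-based,
half-open, with "category:name" in the name column. Every writer emits
records in a deterministic order so identical inputs give identical bytes.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import (
    Feature,
    GenomeAnnotation,
    HairpinCandidate,
    LibraryMeta,
    MatureMiRNA,
    TagSet,
)

_COUNT_RE = re.compile(r"_x(\d+)$")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_genome_fasta(path, chromosomes: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(chromosomes[cid]), id=cid, description="")
        for cid in sorted(chromosomes)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_genome_fasta(path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_tag_fasta(path, tags: TagSet) -> None:
    """Collapsed tags with headers "tag<serial>_x<count>", most abundant first."""
    ordered = sorted(tags.items(), key=lambda kv: (-kv[1], kv[0]))
    records = [
        SeqRecord(Seq(seq), id=f"tag{i + 1:06d}_x{count}", description="")
        for i, (seq, count) in enumerate(ordered)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_tag_fasta(path) -> TagSet:
    """Parse the "id_x<count>" dialect; duplicate sequences are summed."""
    counts: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _COUNT_RE.search(rec.id)
        if m is None:
            raise ValueError(f"tag header without _x<count> suffix: {rec.id!r}")
        seq = str(rec.seq).upper()
        counts[seq] = counts.get(seq, 0) + int(m.group(1))
    return TagSet(counts)


def write_catalog_fasta(
    path, catalog: list[MatureMiRNA], genome: GenomeAnnotation
) -> None:
    """Mature + precursor records; loci are encoded in the description as
    "locus=chrom:start-end(strand)"."""
    records = []
    for m in sorted(catalog, key=lambda m: m.mirna_id):
        desc = (
            f"mature locus={m.chrom}:{m.start}-{m.end}({m.strand}) "
            f"precursor={m.pre_start}-{m.pre_end} category={m.category}"
        )
        records.append(SeqRecord(Seq(m.mature_seq), id=m.mirna_id, description=desc))
        pre_seq = genome.locus_seq(m.chrom, m.pre_start, m.pre_end, m.strand)
        records.append(
            SeqRecord(
                Seq(pre_seq),
                id=f"{m.mirna_id}_pre",
                description=f"precursor locus={m.chrom}:{m.pre_start}-{m.pre_end}({m.strand})",
            )
        )
    SeqIO.write(records, str(path), "fasta")


_LOCUS_RE = re.compile(
    r"locus=(\S+):(\d+)-(\d+)\(([+-])\) precursor=(\d+)-(\d+) category=(\S+)"
)


def read_catalog_fasta(path) -> list[MatureMiRNA]:
    catalog = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id.endswith("_pre"):
            continue
        m = _LOCUS_RE.search(rec.description)
        if m is None:
            raise ValueError(f"unparseable catalog description: {rec.description!r}")
        catalog.append(
            MatureMiRNA(
                mirna_id=rec.id,
                mature_seq=str(rec.seq).upper(),
                chrom=m.group(1),
                start=int(m.group(2)),
                end=int(m.group(3)),
                strand=m.group(4),
                pre_start=int(m.group(5)),
                pre_end=int(m.group(6)),
                category=m.group(7),
            )
        )
    return catalog


# ---------------------------------------------------------------------------
# BED and tables
# ---------------------------------------------------------------------------


def write_bed(path, features: Iterable[Feature]) -> None:
    lines = [
        f"{f.chrom}\t{f.start}\t{f.end}\t{f.category}:{f.name}\t0\t{f.strand}"
        for f in sorted(features, key=lambda f: (f.chrom, f.start, f.end, f.name))
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bed(path) -> list[Feature]:
    features = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        chrom, start, end, name, _score, strand = line.split("\t")[:6]
        category, _, fname = name.partition(":")
        features.append(
            Feature(chrom, int(start), int(end), strand, category, fname)
        )
    return features


def write_hairpin_bed(path, candidates: list[HairpinCandidate]) -> None:
    lines = [
        f"{c.chrom}\t{c.start}\t{c.end}\t"
        f"hairpin:{c.mature_tag}_{c.arm}\t{c.paired_bases}\t{c.strand}"
        for c in sorted(candidates, key=lambda c: (c.chrom, c.start))
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_library_table(path, metas: list[LibraryMeta]) -> None:
    pd.DataFrame(
        {
            "library_id": [m.library_id for m in metas],
            "breed": [m.breed for m in metas],
            "stage": [m.stage for m in metas],
            "total_clean_reads": [m.total_clean_reads for m in metas],
        }
    ).to_csv(path, sep="\t", index=False)


def read_library_table(path) -> list[LibraryMeta]:
    df = pd.read_csv(path, sep="\t")
    return [
        LibraryMeta(
            library_id=str(r.library_id),
            breed=str(r.breed),
            stage=int(r.stage),
            total_clean_reads=int(r.total_clean_reads),
        )
        for r in df.itertuples()
    ]


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(path, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path, sep="\t")


def read_target_table(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return [
        (str(r.mirna_id), str(r.mrna_id)) for r in df.itertuples()
    ]


def read_term_annotation(path) -> dict[str, set[str]]:
    """Two-column TSV (term, gene) -> term -> gene-set mapping."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(str(r[0]), set()).add(str(r[1]))
    return out


def read_truth_json(path) -> dict:
    return json.loads(Path(path).read_text())


def read_dataset_dir(path):
    """Reconstruct generator artefacts written by write_dataset."""
    from .simulate import GroundTruth, PlantedHairpin

    path = Path(path)
    chromosomes = read_genome_fasta(path / "genome.fa")
    features = read_bed(path / "features.bed")
    catalog = read_catalog_fasta(path / "catalog.fa")
    genome = GenomeAnnotation(
        chromosomes=chromosomes, features=features, catalog=catalog
    )
    metas = read_library_table(path / "libraries.tsv")
    libraries = [
        (m, read_tag_fasta(path / f"tags_{m.library_id}.fa")) for m in metas
    ]
    raw = read_truth_json(path / "truth.json")
    truth = GroundTruth(
        breed_de={int(k): v for k, v in raw["breed_de"].items()},
        declining=list(raw["declining"]),
        novel_hairpins=[PlantedHairpin(**h) for h in raw["novel_hairpins"]],
        target_pairs=list(raw["target_pairs"]),
        breed_de_mrnas=list(raw["breed_de_mrnas"]),
    )
    mrna_matrix = read_matrix_tsv(path / "mrna_matrix.tsv")
    target_table = pd.read_csv(path / "target_table.tsv", sep="\t")
    return genome, libraries, truth, mrna_matrix, target_table
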