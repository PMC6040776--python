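"""Synthetic study generator: a miniature genome with annotated features,
known and novel miRNA loci, ten collapsed tag libraries (two breeds x five
prenatal stages) and a matched mRNA matrix, all with recorded ground truth.

The generator emulates the study design this pipeline targets — pooled
small-RNA libraries for two pig breeds (TC, YK) sampled at 40, 55, 63, 70
and 90 days post coitum — and plants the effects the downstream stages must
recover: a monotone-decline expression cluster, per-stage breed effects
with fold > 2, inverted-repeat hairpin loci carrying novel mature tags,
contaminant tags from non-miRNA feature categories, and miRNA->mRNA
regulatory pairs with negatively correlated trajectories.

Counts can be deterministic (rounded means, the default: planted effects
are then exactly recoverable), Poisson, or negative binomial with
configurable dispersion (the Poisson limit as dispersion -> 0); the paper
design pools three fetuses per library, so biological dispersion is left as
a free parameter of the pool.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import (
    CATEGORY_PRIORITY,
    Feature,
    GenomeAnnotation,
    LibraryMeta,
    MatureMiRNA,
    TagSet,
    revcomp,
)

CONTAMINANT_CATEGORIES = tuple(
    c for c in CATEGORY_PRIORITY if c != "known_miRNA"
)
_SLOT = 400  # one planted feature per slot keeps intervals non-overlapping
_MATURE_LEN = 22
_ARM_LEN = 25


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for the synthetic generator.

    Defaults give a 2 x 100 kb genome, 150 known miRNAs and ~50,000 tags
    per library — a desk-scale analogue of the 10-library design.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 100_000
    n_known_mirnas: int = 150
    n_novel_hairpins: int = 10
    n_contaminant_features: int = 20  # per category
    library_depth: int = 50_000
    breeds: tuple[str, str] = ("TC", "YK")
    stages: tuple[int, ...] = (40, 55, 63, 70, 90)
    n_breed_de: int = 3  # planted breed-DE miRNAs per stage
    breed_de_fold: float = 4.0
    n_decline: int = 30
    noise_model: str = "none"  # "none" | "poisson" | "nb"
    dispersion: float = 0.0
    contaminant_fraction: float = 0.30
    n_mrnas: int = 300
    n_true_targets: int = 20
    n_decoy_targets: int = 40
    other_mammal_every: int = 10  # every k-th known miRNA flagged other-mammal

    def __post_init__(self) -> None:
        if self.breed_de_fold <= 2:
            raise ValueError("planted breed fold must exceed 2")
        if list(self.stages) != sorted(set(self.stages)):
            raise ValueError("stages must be strictly increasing")
        if self.library_depth <= 0:
            raise ValueError("library depth must be positive")
        for name in (
            "n_chromosomes",
            "chromosome_length",
            "n_known_mirnas",
            "n_novel_hairpins",
            "n_contaminant_features",
            "n_decline",
            "n_mrnas",
            "n_true_targets",
            "n_decoy_targets",
            "n_breed_de",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.noise_model not in ("none", "poisson", "nb"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if not 0 <= self.contaminant_fraction < 1:
            raise ValueError("contaminant fraction must be in [0, 1)")


@dataclass
class PlantedHairpin:
    chrom: str
    start: int
    end: int
    strand: str
    mature_seq: str
    arm: str


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream auditing."""

    breed_de: dict[int, dict[str, dict]] = field(default_factory=dict)
    declining: list[str] = field(default_factory=list)
    novel_hairpins: list[PlantedHairpin] = field(default_factory=list)
    target_pairs: list[dict] = field(default_factory=list)
    breed_de_mrnas: list[str] = field(default_factory=list)

    def qualifying_pairs(self) -> set[tuple[str, str]]:
        """Planted pairs whose mRNA is also flagged breed-DE — exactly the
        edges the network stage should return."""
        flagged = set(self.breed_de_mrnas)
        return {
            (p["mirna_id"], p["mrna_id"])
            for p in self.target_pairs
            if p["mrna_id"] in flagged
        }


@dataclass
class SyntheticDataset:
    config: SimConfig
    genome: GenomeAnnotation
    truth: GroundTruth
    libraries: list[tuple[LibraryMeta, TagSet]]
    mirna_means: dict[str, pd.DataFrame]  # breed -> miRNA x stage mean counts
    mrna_matrix: pd.DataFrame  # mRNA x library expression values
    target_table: pd.DataFrame  # predicted (mirna_id, mrna_id) rows


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, n_mut: int) -> str:
    """Substitute n_mut positions with a different base."""
    chars = list(seq)
    for pos in rng.choice(len(chars), size=n_mut, replace=False):
        chars[pos] = rng.choice([b for b in "ACGT" if b != chars[pos]])
    return "".join(chars)


def _build_hairpin(
    rng: np.random.Generator, arm_mismatches: int
) -> tuple[str, str]:
    """(precursor sequence, mature sequence): 5' arm carrying the mature,
    an 8-20 nt loop, and a 3' arm that is the arm's reverse complement with
    ``arm_mismatches`` substitutions (>= 90% arm complementarity)."""
    arm5 = _random_seq(rng, _ARM_LEN)
    loop = _random_seq(rng, int(rng.integers(8, 21)))
    arm3 = _mutate(rng, revcomp(arm5), arm_mismatches)
    return arm5 + loop + arm3, arm5[:_MATURE_LEN]


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------


def generate_reference(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GenomeAnnotation, GroundTruth]:
    """Build the genome, its feature annotation, the known-miRNA catalog and
    the planted novel hairpins.

    Features are planted one per fixed-width slot, so intervals never
    overlap; exceeding the slot capacity raises a sizing error naming the
    offending category.
    """
    rng = rng or np.random.default_rng(config.seed)
    chrom_ids = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chroms = {
        cid: list(_random_seq(rng, config.chromosome_length))
        for cid in chrom_ids
    }

    slots = [
        (cid, pos)
        for cid in chrom_ids
        for pos in range(0, config.chromosome_length - _SLOT + 1, _SLOT)
    ]
    slot_order = list(rng.permutation(len(slots)))

    def take_slot(category: str) -> tuple[str, int]:
        if not slot_order:
            raise ValueError(
                f"genome too small to place requested {category} features"
            )
        cid, pos = slots[slot_order.pop()]
        return cid, pos + 20  # margin inside the slot

    features: list[Feature] = []
    catalog: list[MatureMiRNA] = []
    truth = GroundTruth()

    def plant(seq: str, category_hint: str) -> tuple[str, int, int, str]:
        """Write seq into a free slot on a random strand; returns its locus."""
        cid, start = take_slot(category_hint)
        strand = "+" if rng.random() < 0.5 else "-"
        genomic = seq if strand == "+" else revcomp(seq)
        chroms[cid][start : start + len(seq)] = list(genomic)
        return cid, start, start + len(seq), strand

    # known miRNA precursors
    for i in range(config.n_known_mirnas):
        mirna_id = f"mir-{i + 1:04d}"
        pre, mature = _build_hairpin(rng, arm_mismatches=2)
        cid, pstart, pend, strand = plant(pre, "known_miRNA")
        if strand == "+":
            mstart, mend = pstart, pstart + _MATURE_LEN
        else:  # mature occupies the precursor's 5' arm read on the minus strand
            mstart, mend = pend - _MATURE_LEN, pend
        category = (
            "other_mammal"
            if config.other_mammal_every
            and (i + 1) % config.other_mammal_every == 0
            else "known_porcine"
        )
        features.append(
            Feature(cid, pstart, pend, strand, "known_miRNA", mirna_id)
        )
        catalog.append(
            MatureMiRNA(
                mirna_id=mirna_id,
                mature_seq=mature,
                chrom=cid,
                start=mstart,
                end=mend,
                strand=strand,
                pre_start=pstart,
                pre_end=pend,
                category=category,
            )
        )

    # novel hairpins: planted but absent from both the annotation and catalog
    for i in range(config.n_novel_hairpins):
        pre, mature = _build_hairpin(rng, arm_mismatches=2)
        cid, pstart, pend, strand = plant(pre, "novel_hairpin")
        truth.novel_hairpins.append(
            PlantedHairpin(
                chrom=cid,
                start=pstart,
                end=pend,
                strand=strand,
                mature_seq=mature,
                arm="5p",
            )
        )

    # contaminant features label stretches of genomic background
    for category in CONTAMINANT_CATEGORIES:
        for i in range(config.n_contaminant_features):
            cid, start = take_slot(category)
            length = int(rng.integers(100, 301))
            strand = "+" if rng.random() < 0.5 else "-"
            features.append(
                Feature(
                    cid,
                    start,
                    start + length,
                    strand,
                    category,
                    f"{category}-{i + 1:03d}",
                )
            )

    genome = GenomeAnnotation(
        chromosomes={cid: "".join(chars) for cid, chars in chroms.items()},
        features=features,
        catalog=catalog,
    )
    return genome, truth


# ---------------------------------------------------------------------------
# expression design
# ---------------------------------------------------------------------------


def _design_means(
    config: SimConfig, truth: GroundTruth, rng: np.random.Generator,
    mirna_ids: list[str],
) -> dict[str, pd.DataFrame]:
    """Per-breed miRNA x stage mean tag counts with the planted effects."""
    n_stages = len(config.stages)
    order = rng.permutation(len(mirna_ids))
    n_bde = config.n_breed_de * n_stages
    bde_idx = order[:n_bde]
    decline_idx = order[n_bde : n_bde + config.n_decline]
    if n_bde + config.n_decline > len(mirna_ids):
        raise ValueError("more planted miRNAs requested than catalog entries")

    means = {
        breed: np.zeros((len(mirna_ids), n_stages)) for breed in config.breeds
    }
    # null miRNAs: flat across stages and identical between breeds
    base_null = rng.lognormal(mean=np.log(60.0), sigma=0.8, size=len(mirna_ids))
    base_null = np.clip(base_null, 3.0, 500.0)
    for breed in config.breeds:
        means[breed][:] = base_null[:, None]

    # monotone decline cluster: shared geometric decay in both breeds
    t = np.arange(n_stages)
    for idx in decline_idx:
        base = rng.uniform(150.0, 600.0)
        factor = rng.uniform(0.42, 0.48)
        profile = base * factor**t
        for breed in config.breeds:
            means[breed][idx] = profile
        truth.declining.append(mirna_ids[idx])

    # breed-DE miRNAs: decline-shaped baseline (so trajectories are strictly
    # monotone with distinct values) plus a fold effect in the first breed
    # at the designated stage
    tc, yk = config.breeds
    for s, stage in enumerate(config.stages):
        truth.breed_de.setdefault(stage, {})
        for k in range(config.n_breed_de):
            idx = bde_idx[s * config.n_breed_de + k]
            base = rng.uniform(200.0, 600.0)
            factor = rng.uniform(0.42, 0.48)
            profile = base * factor**t
            direction = "up" if rng.random() < 0.5 else "down"
            means[yk][idx] = profile
            means[tc][idx] = profile.copy()
            if direction == "up":
                means[tc][idx, s] *= config.breed_de_fold
            else:
                means[tc][idx, s] /= config.breed_de_fold
            truth.breed_de[stage][mirna_ids[idx]] = {
                "direction": direction,
                "fold": config.breed_de_fold,
                "stage": stage,
            }

    # scale so miRNA reads average (1 - contaminant share) of library depth
    target = (1 - config.contaminant_fraction) * config.library_depth
    grand = np.mean(
        [means[breed][:, s].sum() for breed in config.breeds
         for s in range(n_stages)]
    )
    scale = target / grand
    out = {}
    for breed in config.breeds:
        out[breed] = pd.DataFrame(
            means[breed] * scale, index=mirna_ids, columns=list(config.stages)
        )
    return out


def draw_counts(
    means: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Counts from the configured noise model around the given means."""
    means = np.asarray(means, dtype=float)
    if config.noise_model == "none":
        return np.rint(means).astype(int)
    if config.noise_model == "poisson" or config.dispersion <= 1e-9:
        return rng.poisson(means)
    # negative binomial with Var = m + dispersion * m^2
    size = 1.0 / config.dispersion
    p = size / (size + means)
    return rng.negative_binomial(size, p)


# ---------------------------------------------------------------------------
# libraries
# ---------------------------------------------------------------------------


def _isoform(genome: GenomeAnnotation, m: MatureMiRNA) -> str | None:
    """A +1 nt 3'-extended isomiR read from the genomic context."""
    if m.strand == "+":
        start, end = m.start, m.end + 1
    else:
        start, end = m.start - 1, m.end
    if start < 0 or end > len(genome.chromosomes[m.chrom]):
        return None
    return genome.locus_seq(m.chrom, start, end, m.strand)


def generate_libraries(
    config: SimConfig,
    genome: GenomeAnnotation,
    truth: GroundTruth,
    rng: np.random.Generator,
    mirna_means: dict[str, pd.DataFrame],
) -> list[tuple[LibraryMeta, TagSet]]:
    """Emit one collapsed TagSet per (breed, stage) library.

    Each known miRNA contributes its mature tag (70% of its mean) plus one
    3'-extended isomiR (30%); planted novel hairpins contribute their mature
    tag; contaminant tags are substrings of non-miRNA features. The recorded
    total clean reads N equals the emitted tag-count sum exactly.
    """
    if config.library_depth <= 0:  # guarded again for direct callers
        raise ValueError("library depth must be positive")

    mirna_ids = [m.mirna_id for m in genome.catalog]
    isoforms = {
        m.mirna_id: _isoform(genome, m) for m in genome.catalog
    }
    matures = {m.mirna_id: m.mature_seq for m in genome.catalog}

    # contaminant tag pool with fixed per-library mean counts
    contaminant: list[tuple[str, float]] = []
    by_cat: dict[str, list[Feature]] = {}
    for f in genome.features:
        if f.category != "known_miRNA":
            by_cat.setdefault(f.category, []).append(f)
    budget_per_cat = (
        config.contaminant_fraction * config.library_depth / len(by_cat)
        if by_cat
        else 0.0
    )
    for category in sorted(by_cat):
        feats = by_cat[category]
        raw = []
        for f in feats:
            for _ in range(3):
                length = int(rng.integers(19, 26))
                offset = int(rng.integers(0, f.end - f.start - length))
                seq = genome.chromosomes[f.chrom][
                    f.start + offset : f.start + offset + length
                ]
                raw.append((seq, rng.lognormal(0.0, 1.0)))
        weight = sum(w for _, w in raw)
        contaminant.extend(
            (seq, w / weight * budget_per_cat) for seq, w in raw
        )

    novel_mean = 60.0

    libraries = []
    for breed in config.breeds:
        for s, stage in enumerate(config.stages):
            tag_means: dict[str, float] = {}
            stage_means = mirna_means[breed].iloc[:, s]
            for mir in mirna_ids:
                m = float(stage_means[mir])
                tag_means[matures[mir]] = tag_means.get(matures[mir], 0.0) + 0.7 * m
                iso = isoforms[mir]
                if iso is not None:
                    tag_means[iso] = tag_means.get(iso, 0.0) + 0.3 * m
            for hp in truth.novel_hairpins:
                tag_means[hp.mature_seq] = (
                    tag_means.get(hp.mature_seq, 0.0) + novel_mean
                )
            for seq, mean in contaminant:
                tag_means[seq] = tag_means.get(seq, 0.0) + mean

            seqs = sorted(tag_means)
            counts = draw_counts(
                np.array([tag_means[q] for q in seqs]), config, rng
            )
            tagset = TagSet(
                {q: int(c) for q, c in zip(seqs, counts) if c > 0}
            )
            meta = LibraryMeta(
                library_id=f"{breed}{stage}",
                breed=breed,
                stage=stage,
                total_clean_reads=tagset.total(),
            )
            libraries.append((meta, tagset))
    return libraries


# ---------------------------------------------------------------------------
# mRNA profiles and target table
# ---------------------------------------------------------------------------


def random_trend(
    rng: np.random.Generator, n_stages: int, base: float = 50.0
) -> np.ndarray:
    """Independent stage effects (exchangeable across stages): the null
    trajectory model used for decoy mRNAs."""
    return base * np.exp(rng.normal(0.0, 0.6, size=n_stages))


def generate_mrna_profiles(
    config: SimConfig,
    truth: GroundTruth,
    rng: np.random.Generator,
    mirna_means: dict[str, pd.DataFrame],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """mRNA expression over the ten libraries plus the predicted-target table.

    Planted pairs: the target mRNA's per-breed stage means are a strictly
    decreasing function (K / x) of its miRNA's mean trajectory, so the
    noise-free Spearman correlation is exactly -1 in each breed. About 60%
    of planted-pair mRNAs (plus a few extras) are flagged breed-DE in the
    truth; decoy rows pair breed-DE miRNAs with independent-trend mRNAs that
    are never flagged, and null miRNAs with flagged mRNAs, so decoys cannot
    survive the conjunctive pairing under noise-free settings.
    """
    n_stages = len(config.stages)
    gene_ids = [f"gene-{i + 1:04d}" for i in range(config.n_mrnas)]
    lib_ids = [
        f"{breed}{stage}" for breed in config.breeds for stage in config.stages
    ]
    values = pd.DataFrame(0.0, index=gene_ids, columns=lib_ids)

    # background: independent trends per breed
    for gene in gene_ids:
        for breed in config.breeds:
            trend = random_trend(rng, n_stages)
            for s, stage in enumerate(config.stages):
                values.loc[gene, f"{breed}{stage}"] = trend[s]

    de_mirnas = sorted(
        {mir for stage in truth.breed_de.values() for mir in stage}
    )
    rows = []
    if config.n_true_targets and not de_mirnas:
        raise ValueError("cannot plant targets without breed-DE miRNAs")
    for j in range(config.n_true_targets):
        # the first planted miRNA collects six targets (a designed hub);
        # the rest rotate round-robin
        mir = de_mirnas[0] if j < 6 else de_mirnas[(j - 6) % len(de_mirnas)]
        gene = gene_ids[j]
        scale = float(rng.uniform(1e4, 1e5))
        for breed in config.breeds:
            traj = mirna_means[breed].loc[mir].to_numpy()
            for s, stage in enumerate(config.stages):
                values.loc[gene, f"{breed}{stage}"] = scale / traj[s]
        flagged = j % 5 != 4  # ~80% of planted-pair mRNAs are breed-DE
        if flagged:
            truth.breed_de_mrnas.append(gene)
        truth.target_pairs.append(
            {"mirna_id": mir, "mrna_id": gene, "effect": "repression"}
        )
        rows.append({"mirna_id": mir, "mrna_id": gene})

    # decoys: half DE-miRNA x independent mRNA, half null-miRNA x flagged mRNA
    null_mirnas = [
        m
        for m in mirna_means[config.breeds[0]].index
        if m not in de_mirnas and m not in truth.declining
    ]
    decoy_genes = gene_ids[config.n_true_targets :]
    for j in range(config.n_decoy_targets):
        gene = decoy_genes[j % len(decoy_genes)]
        if j % 2 == 0 and de_mirnas:
            mir = de_mirnas[j % len(de_mirnas)]
        else:
            mir = null_mirnas[j % len(null_mirnas)]
            if gene not in truth.breed_de_mrnas:
                truth.breed_de_mrnas.append(gene)
        rows.append({"mirna_id": mir, "mrna_id": gene})

    target_table = pd.DataFrame(rows, columns=["mirna_id", "mrna_id"])
    if config.noise_model != "none":
        noise = rng.lognormal(0.0, 0.1, size=values.shape)
        values = values * noise
    return values, target_table


# ---------------------------------------------------------------------------
# orchestration + file output
# ---------------------------------------------------------------------------


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Run the full generator: reference, libraries, mRNA matrix, truth."""
    rng = np.random.default_rng(config.seed)
    genome, truth = generate_reference(config, rng)
    mirna_ids = [m.mirna_id for m in genome.catalog]
    mirna_means = _design_means(config, truth, rng, mirna_ids)
    libraries = generate_libraries(config, genome, truth, rng, mirna_means)
    mrna_matrix, target_table = generate_mrna_profiles(
        config, truth, rng, mirna_means
    )
    return SyntheticDataset(
        config=config,
        genome=genome,
        truth=truth,
        libraries=libraries,
        mirna_means=mirna_means,
        mrna_matrix=mrna_matrix,
        target_table=target_table,
    )


def truth_to_dict(truth: GroundTruth) -> dict:
    return {
        "breed_de": {
            str(stage): entries for stage, entries in truth.breed_de.items()
        },
        "declining": list(truth.declining),
        "novel_hairpins": [dataclasses.asdict(h) for h in truth.novel_hairpins],
        "target_pairs": list(truth.target_pairs),
        "breed_de_mrnas": list(truth.breed_de_mrnas),
    }


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write every generator artefact as plain text.

    genome FASTA; features BED (0-based half-open, name column
    "category:name"); catalog FASTA (mature + precursor records with loci in
    the description); one collapsed tag FASTA per library with headers
    "tag<serial>_x<count>"; mRNA matrix and target-table TSV; ground-truth
    and config JSON. Identical configs produce byte-identical files.
    """
    from . import io as mio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mio.write_genome_fasta(outdir / "genome.fa", dataset.genome.chromosomes)
    mio.write_bed(outdir / "features.bed", dataset.genome.features)
    mio.write_catalog_fasta(
        outdir / "catalog.fa", dataset.genome.catalog, dataset.genome
    )
    for meta, tags in dataset.libraries:
        mio.write_tag_fasta(outdir / f"tags_{meta.library_id}.fa", tags)
    mio.write_library_table(
        outdir / "libraries.tsv", [m for m, _ in dataset.libraries]
    )
    dataset.mrna_matrix.to_csv(outdir / "mrna_matrix.tsv", sep="\t")
    dataset.target_table.to_csv(
        outdir / "target_table.tsv", sep="\t", index=False
    )
    (outdir / "truth.json").write_text(
        json.dumps(truth_to_dict(dataset.truth), indent=1, sort_keys=True)
    )
    (outdir / "config.json").write_text(
        json.dumps(dataclasses.asdict(dataset.config), indent=1, sort_keys=True)
    )
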