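"""Small-RNA tag preprocessing, genome mapping, priority-rule annotation,
known-miRNA quantification and novel hairpin candidate calling.

Collapsed tag libraries (unique sequence -> occurrence count) are mapped to
the genome by exact full-length matching on both strands. Every mapped tag
is then given exactly one annotation by the priority rule

    rRNAetc (GenBank > Rfam) > known miRNA > repeat > exon > intron,

tags overlapping nothing become "unann". Tags annotated as known miRNA are
quantified against the mature-miRNA catalog with a +/-2 nt end tolerance
(absorbing isomiR ends); unannotated mapped tags are folded with their
flanking sequence and accepted as novel hairpin candidates when they sit on
one arm of a well-paired stem-loop.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left, bisect_right
from collections import Counter, defaultdict
from collections.abc import Mapping
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import pandas as pd
from intervaltree import IntervalTree

from . import fold

CATEGORY_PRIORITY: tuple[str, ...] = (
    "rRNAetc_genbank",
    "rRNAetc_rfam",
    "known_miRNA",
    "repeat",
    "exon",
    "intron",
)
UNANNOTATED = "unann"
MIN_TAG_LENGTH = 18
DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LibraryMeta:
    """One sequencing library: breed x developmental stage, with its total
    clean-read count N (the denominator of TPM and of the exact test)."""

    library_id: str
    breed: str
    stage: int
    total_clean_reads: int

    def __post_init__(self) -> None:
        if self.total_clean_reads <= 0:
            raise ValueError(
                f"library {self.library_id}: total clean reads must be > 0"
            )


def check_library_design(metas: Iterable[LibraryMeta]) -> None:
    """(breed, stage) must be unique across libraries."""
    seen: set[tuple[str, int]] = set()
    for m in metas:
        key = (m.breed, m.stage)
        if key in seen:
            raise ValueError(f"duplicate (breed, stage) cell: {key}")
        seen.add(key)


class TagSet(Mapping):
    """Collapsed small-RNA tags: unique uppercase sequence -> count >= 1."""

    def __init__(self, counts: Mapping[str, int]):
        clean: dict[str, int] = {}
        for seq, count in counts.items():
            if not isinstance(count, (int,)) or count < 1:
                raise ValueError(f"tag {seq!r}: count must be an integer >= 1")
            clean[seq.upper()] = int(count)
        self._counts = clean

    def __getitem__(self, seq: str) -> int:
        return self._counts[seq]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def total(self) -> int:
        """Total read count (sum over tags)."""
        return sum(self._counts.values())

    def __repr__(self) -> str:
        return f"TagSet({len(self)} tags, {self.total()} reads)"


@dataclass(frozen=True)
class Feature:
    """Stranded, categorised genomic interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    strand: str
    category: str
    name: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class MatureMiRNA:
    """Catalog entry: a mature miRNA and the precursor locus embedding it."""

    mirna_id: str
    mature_seq: str
    chrom: str
    start: int
    end: int
    strand: str
    pre_start: int
    pre_end: int
    category: str = "known_porcine"  # or "other_mammal"


@dataclass
class GenomeAnnotation:
    """Chromosome sequences plus categorised features and the miRNA catalog."""

    chromosomes: dict[str, str]
    features: list[Feature]
    catalog: list[MatureMiRNA]

    def __post_init__(self) -> None:
        for f in self.features:
            if f.category not in CATEGORY_PRIORITY:
                raise ValueError(f"unknown feature category: {f.category!r}")
            if f.chrom not in self.chromosomes:
                raise ValueError(f"feature on unknown chromosome {f.chrom}")
            if f.end > len(self.chromosomes[f.chrom]):
                raise ValueError(
                    f"feature {f.chrom}:{f.start}-{f.end} exceeds chromosome"
                )
        for m in self.catalog:
            if not (m.pre_start <= m.start < m.end <= m.pre_end):
                raise ValueError(f"{m.mirna_id}: mature locus outside precursor")

    def locus_seq(self, chrom: str, start: int, end: int, strand: str) -> str:
        """Strand-aware sequence of a locus (minus strand returns revcomp)."""
        s = self.chromosomes[chrom][start:end]
        return s if strand == "+" else revcomp(s)


@dataclass
class TagAlignment:
    """All exact-match loci of one tag, plus its single annotation category.

    category is one of CATEGORY_PRIORITY, "unann" (mapped, no overlapping
    feature) or None (unmapped / not yet annotated).
    """

    tag: str
    hits: list[tuple[str, int, int, str]] = field(default_factory=list)
    category: str | None = None

    @property
    def is_mapped(self) -> bool:
        return bool(self.hits)


@dataclass
class HairpinCandidate:
    """A novel miRNA precursor candidate called from an unannotated tag."""

    chrom: str
    start: int
    end: int
    strand: str
    mature_tag: str
    arm: str  # "5p" or "3p"
    paired_bases: int  # tag bases paired within the stem-loop
    loop_length: int

    def __post_init__(self) -> None:
        if self.loop_length < fold.MIN_LOOP:
            raise ValueError("hairpin loop shorter than the minimum loop")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def preprocess_tags(raw: TagSet, min_length: int = MIN_TAG_LENGTH) -> TagSet:
    """Drop tags shorter than ``min_length`` or containing non-ACGT characters.

    Counts of surviving tags are preserved. Adaptor trimming and quality
    filtering are assumed already done on the collapsed input; this hook only
    enforces the minimum-length and alphabet rules.
    """
    kept = {
        seq: count
        for seq, count in raw.items()
        if len(seq) >= min_length and set(seq) <= DNA_ALPHABET
    }
    if not kept:
        warnings.warn("no tags survived preprocessing", stacklevel=2)
    return TagSet(kept)


def length_histogram(tags: TagSet) -> pd.Series:
    """Read counts by tag length (the length-distribution table)."""
    hist: Counter[int] = Counter()
    for seq, count in tags.items():
        hist[len(seq)] += count
    return pd.Series(dict(sorted(hist.items())), name="reads", dtype=int)


# ---------------------------------------------------------------------------
# exact-match mapping
# ---------------------------------------------------------------------------


class GenomeIndex:
    """Exact-match index: seed k-mer lookup plus full-length verification."""

    def __init__(self, chromosomes: Mapping[str, str], k: int = MIN_TAG_LENGTH):
        self.k = k
        self.chromosomes = dict(chromosomes)
        index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom in sorted(self.chromosomes):
            seq = self.chromosomes[chrom]
            for pos in range(len(seq) - k + 1):
                index[seq[pos : pos + k]].append((chrom, pos))
        self._index = dict(index)

    def _forward_hits(self, query: str) -> list[tuple[str, int, int]]:
        if len(query) < self.k:
            # short queries fall back to a direct scan
            out = []
            for chrom in sorted(self.chromosomes):
                seq = self.chromosomes[chrom]
                p = seq.find(query)
                while p != -1:
                    out.append((chrom, p, p + len(query)))
                    p = seq.find(query, p + 1)
            return out
        out = []
        for chrom, pos in self._index.get(query[: self.k], ()):
            if self.chromosomes[chrom][pos : pos + len(query)] == query:
                out.append((chrom, pos, pos + len(query)))
        return out

    def hits(self, tag: str) -> list[tuple[str, int, int, str]]:
        """All exact full-length matches of a tag on both strands."""
        found = {(c, s, e, "+") for c, s, e in self._forward_hits(tag)}
        rc = revcomp(tag)
        found |= {(c, s, e, "-") for c, s, e in self._forward_hits(rc)}
        return sorted(found)


def map_tags(
    tags: Iterable[str], genome: GenomeAnnotation, index: GenomeIndex | None = None
) -> list[TagAlignment]:
    """Map tags to the genome by exact full-length matching (both strands)."""
    if index is None:
        index = GenomeIndex(genome.chromosomes)
    return [TagAlignment(tag=t, hits=index.hits(t)) for t in tags]


def mapping_summary(
    alignments: list[TagAlignment], tags: TagSet
) -> dict[str, float]:
    """Mapped-tag and mapped-read fractions for one library."""
    mapped = [a for a in alignments if a.is_mapped and a.tag in tags]
    n_tags = sum(1 for t in tags if t)
    total = tags.total()
    mapped_reads = sum(tags[a.tag] for a in mapped)
    return {
        "tags": n_tags,
        "mapped_tags": len(mapped),
        "mapped_tag_fraction": len(mapped) / n_tags if n_tags else 0.0,
        "reads": total,
        "mapped_reads": mapped_reads,
        "mapped_read_fraction": mapped_reads / total if total else 0.0,
    }


# ---------------------------------------------------------------------------
# priority-rule annotation
# ---------------------------------------------------------------------------


class FeatureIndex:
    """Interval lookup of categorised features, one tree per chromosome."""

    def __init__(self, features: Iterable[Feature]):
        trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for f in features:
            if f.category not in CATEGORY_PRIORITY:
                raise ValueError(f"unknown feature category: {f.category!r}")
            trees[f.chrom].addi(f.start, f.end, f)
        self._trees = dict(trees)

    def overlapping(self, chrom: str, start: int, end: int) -> list[Feature]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]


def annotate_tags(
    alignments: list[TagAlignment],
    genome: GenomeAnnotation,
    feature_index: FeatureIndex | None = None,
) -> list[TagAlignment]:
    """Assign each mapped tag its single highest-priority category.

    The miRNA category is strand-specific (a hit must lie on the precursor's
    strand); the remaining categories match on either strand, since rRNA and
    repeat annotations are commonly unstranded. Mapped tags overlapping no
    feature become "unann"; unmapped tags keep category None.
    """
    if feature_index is None:
        feature_index = FeatureIndex(genome.features)
    rank = {cat: i for i, cat in enumerate(CATEGORY_PRIORITY)}
    out = []
    for aln in alignments:
        if not aln.is_mapped:
            out.append(replace(aln, category=None))
            continue
        best: str | None = None
        for chrom, start, end, strand in aln.hits:
            for f in feature_index.overlapping(chrom, start, end):
                if f.category == "known_miRNA" and f.strand != strand:
                    continue
                if best is None or rank[f.category] < rank[best]:
                    best = f.category
        out.append(replace(aln, category=best if best is not None else UNANNOTATED))
    return out


def annotation_summary(
    alignments: list[TagAlignment],
    libraries: list[tuple[LibraryMeta, TagSet]],
) -> pd.DataFrame:
    """Per-library read counts by annotation category (the composition table)."""
    by_tag = {a.tag: a for a in alignments}
    rows = {}
    cats = list(CATEGORY_PRIORITY) + [UNANNOTATED, "unmapped"]
    for meta, tags in libraries:
        counts = dict.fromkeys(cats, 0)
        for seq, count in tags.items():
            aln = by_tag.get(seq)
            if aln is None or not aln.is_mapped:
                counts["unmapped"] += count
            else:
                counts[aln.category] += count
        rows[meta.library_id] = counts
    return pd.DataFrame(rows).T[cats]


def chromosome_distribution(
    alignments: list[TagAlignment],
    libraries: list[tuple[LibraryMeta, TagSet]],
) -> pd.DataFrame:
    """Per-library mapped read counts by chromosome (multi-hit tags count
    once per distinct chromosome)."""
    by_tag = {a.tag: a for a in alignments}
    rows: dict[str, Counter] = {}
    for meta, tags in libraries:
        counts: Counter[str] = Counter()
        for seq, count in tags.items():
            aln = by_tag.get(seq)
            if aln is None or not aln.is_mapped:
                continue
            for chrom in {h[0] for h in aln.hits}:
                counts[chrom] += count
        rows[meta.library_id] = counts
    return pd.DataFrame(rows).fillna(0).astype(int).sort_index().T


# ---------------------------------------------------------------------------
# known-miRNA quantification
# ---------------------------------------------------------------------------


def match_tags_to_matures(
    alignments: list[TagAlignment],
    genome: GenomeAnnotation,
    tolerance: int = 2,
) -> dict[str, str]:
    """Map tag sequence -> mature miRNA id under the +/-tolerance end rule.

    A hit matches a mature locus when it lies on the mature strand and both
    its start and end are within ``tolerance`` nt of the mature's. A tag with
    several candidate matures is assigned to the one with the smallest total
    |start offset| + |end offset|, ties broken by lexicographic miRNA id.
    """
    by_locus: dict[tuple[str, str], list[MatureMiRNA]] = defaultdict(list)
    for m in genome.catalog:
        by_locus[(m.chrom, m.strand)].append(m)
    for key in by_locus:
        by_locus[key].sort(key=lambda m: m.start)
    starts = {key: [m.start for m in ms] for key, ms in by_locus.items()}

    assignment: dict[str, str] = {}
    for aln in alignments:
        if aln.category != "known_miRNA":
            continue
        candidates: list[tuple[int, str]] = []
        for chrom, start, end, strand in aln.hits:
            key = (chrom, strand)
            if key not in by_locus:
                continue
            pos = starts[key]
            lo = bisect_left(pos, start - tolerance)
            hi = bisect_right(pos, start + tolerance)
            for m in by_locus[key][lo:hi]:
                ds, de = start - m.start, end - m.end
                if abs(ds) <= tolerance and abs(de) <= tolerance:
                    candidates.append((abs(ds) + abs(de), m.mirna_id))
        if candidates:
            candidates.sort()
            assignment[aln.tag] = candidates[0][1]
    return assignment


def quantify_known_mirnas(
    alignments: list[TagAlignment],
    genome: GenomeAnnotation,
    libraries: list[tuple[LibraryMeta, TagSet]],
    tolerance: int = 2,
):
    """Raw per-library counts per mature miRNA (returns an ExpressionMatrix).

    A tag's count accrues to at most one miRNA (see match_tags_to_matures).
    Catalog miRNAs with no matching tag keep zero rows.
    """
    from .quantify import ExpressionMatrix  # local import avoids a cycle

    check_library_design(m for m, _ in libraries)
    tag2mir = match_tags_to_matures(alignments, genome, tolerance=tolerance)
    mirna_ids = [m.mirna_id for m in genome.catalog]
    lib_ids = [meta.library_id for meta, _ in libraries]
    counts = pd.DataFrame(0, index=mirna_ids, columns=lib_ids, dtype=int)
    for meta, tags in libraries:
        for seq, count in tags.items():
            mir = tag2mir.get(seq)
            if mir is not None:
                counts.loc[mir, meta.library_id] += count
    totals = pd.Series(
        {meta.library_id: meta.total_clean_reads for meta, _ in libraries}
    )
    categories = pd.Series({m.mirna_id: m.category for m in genome.catalog})
    metas = {meta.library_id: meta for meta, _ in libraries}
    return ExpressionMatrix(
        counts=counts, totals=totals, categories=categories, metas=metas
    )


# ---------------------------------------------------------------------------
# novel hairpin candidates
# ---------------------------------------------------------------------------


def _window(genome: GenomeAnnotation, chrom, start, end, strand, flank):
    """Flanking window around a tag hit, in fold orientation.

    Returns (window sequence, tag start, tag end) with tag coordinates in
    window space; windows at chromosome ends are truncated.
    """
    length = len(genome.chromosomes[chrom])
    ws, we = max(0, start - flank), min(length, end + flank)
    seq = genome.chromosomes[chrom][ws:we]
    if strand == "+":
        return seq, start - ws, end - ws, ws, we
    return revcomp(seq), we - end, we - start, ws, we


def _best_arm_chain(
    touching: list[tuple[int, int]], max_bulge: int
) -> list[tuple[int, int]]:
    """Longest compact sub-chain of nested tag-touching pairs.

    ``touching`` is sorted by tag position; consecutive chain members may be
    separated by at most ``max_bulge`` unpaired bases on either side (the
    bulge/internal-loop tolerance of a single helix). Classic longest-chain
    dynamic programme, O(k^2) on the handful of tag pairs.
    """
    k = len(touching)
    if k == 0:
        return []
    best_len = [1] * k
    prev = [-1] * k
    for b in range(k):
        for a in range(b):
            (ia, ja), (ib, jb) = touching[a], touching[b]
            gap_tag = abs(ib - ia) - 1
            gap_partner = abs(ja - jb) - 1
            if gap_tag < 0 or gap_partner < 0:
                continue
            if gap_tag <= max_bulge and gap_partner <= max_bulge:
                if best_len[a] + 1 > best_len[b]:
                    best_len[b] = best_len[a] + 1
                    prev[b] = a
    end = max(range(k), key=lambda b: best_len[b])
    chain = []
    while end != -1:
        chain.append(touching[end])
        end = prev[end]
    return chain[::-1]


def evaluate_hairpin(
    window: str,
    tag_lo: int,
    tag_hi: int,
    min_paired: int = 16,
    max_loop: int = 50,
    max_bulge: int = 6,
) -> tuple[str, int, int, tuple[int, int]] | None:
    """Score a tag-in-window for hairpin structure.

    Folds the window to a maximum-pairing structure and asks whether the tag
    sits on one arm of a stem: the pairs involving tag bases whose partners
    lie on a single side of the tag must form a compact helix chain
    (consecutive pairs separated by at most ``max_bulge`` nt on either
    strand) of at least ``min_paired`` pairs, whose innermost pair spans at
    most ``max_loop`` + 2 tag-side bases of loop. Returns (arm,
    paired_bases, loop_length, (stem_start, stem_end)) in window
    coordinates for the better arm, or None.
    """
    pairs = fold.max_pairing(window)
    in_tag = lambda p: tag_lo <= p < tag_hi
    best = None
    for arm in ("5p", "3p"):
        if arm == "5p":
            touching = sorted(
                (i, j) for (i, j) in pairs if in_tag(i) and j >= tag_hi
            )
        else:
            touching = sorted(
                (j, i) for (i, j) in pairs if in_tag(j) and i < tag_lo
            )
        chain = _best_arm_chain(touching, max_bulge)
        if len(chain) < min_paired:
            continue
        inner_tag, inner_partner = chain[-1]
        loop_len = abs(inner_partner - inner_tag) - 1
        if loop_len > max_loop:
            continue
        outer_tag, outer_partner = chain[0]
        extent = (
            min(outer_tag, outer_partner),
            max(outer_tag, outer_partner) + 1,
        )
        if best is None or len(chain) > best[1]:
            best = (arm, len(chain), loop_len, extent)
    return best


def evaluate_hairpin_window(
    window: str,
    tag_lo: int,
    tag_hi: int,
    min_paired: int = 16,
    max_loop: int = 50,
    max_bulge: int = 6,
    strict_min_paired: int = 19,
    scan_sizes: tuple[int, ...] = (60, 80),
) -> tuple[str, int, int, tuple[int, int]] | None:
    """Hairpin evaluation with local refolds.

    The full window is folded first. Maximum-pairing structures are highly
    degenerate, and pairing opportunities in the flanks can pull tag bases
    out of a genuine stem, so two refinements are also folded: (1) the
    one-sided subwindows (tag plus downstream context for a 5p arm,
    upstream context plus tag for a 3p arm) at the standard paired-base
    bar, and (2) precursor-scale scan windows (``scan_sizes`` nt anchored
    at the tag) which remove far-flank interference entirely but, being
    deliberately permissive contexts, must clear the stricter
    ``strict_min_paired`` bar. The best qualifying arm is returned with its
    extent in full-window coordinates.
    """
    hit = evaluate_hairpin(window, tag_lo, tag_hi, min_paired, max_loop, max_bulge)
    candidates = [(hit, 0)] if hit is not None else []
    subwindows: list[tuple[str, int, int, str, int, int]] = [
        (window[tag_lo:], 0, tag_hi - tag_lo, "5p", min_paired, tag_lo),
        (window[:tag_hi], tag_lo, tag_hi, "3p", min_paired, 0),
    ]
    for size in scan_sizes:
        s0 = max(0, tag_hi - size)
        subwindows.append(
            (window[tag_lo : tag_lo + size], 0, tag_hi - tag_lo, "5p",
             strict_min_paired, tag_lo)
        )
        subwindows.append(
            (window[s0:tag_hi], tag_lo - s0, tag_hi - s0, "3p",
             strict_min_paired, s0)
        )
    for sub, lo, hi, want_arm, bar, offset in subwindows:
        res = evaluate_hairpin(sub, lo, hi, bar, max_loop, max_bulge)
        if res is not None and res[0] == want_arm:
            candidates.append((res, offset))
    if not candidates:
        return None
    (arm, paired, loop_len, (lo, hi)), offset = max(
        candidates, key=lambda c: c[0][1]
    )
    return arm, paired, loop_len, (lo + offset, hi + offset)


def detect_novel_hairpins(
    alignments: list[TagAlignment],
    genome: GenomeAnnotation,
    flank: int = 100,
    min_paired: int = 16,
    max_loop: int = 50,
    max_bulge: int = 6,
    strict_min_paired: int = 19,
) -> list[HairpinCandidate]:
    """Call novel hairpin candidates from unannotated mapped tags.

    Only tags with category "unann" are considered; each hit locus is folded
    with +/-flank nt of context. One candidate (the best-paired) is reported
    per tag.
    """
    out = []
    for aln in alignments:
        if aln.category != UNANNOTATED:
            continue
        best: HairpinCandidate | None = None
        for chrom, start, end, strand in aln.hits:
            window, tag_lo, tag_hi, ws, we = _window(
                genome, chrom, start, end, strand, flank
            )
            hit = evaluate_hairpin_window(
                window, tag_lo, tag_hi, min_paired, max_loop, max_bulge,
                strict_min_paired=strict_min_paired,
            )
            if hit is None:
                continue
            arm, paired, loop_len, (lo, hi) = hit
            if strand == "+":
                g_lo, g_hi = ws + lo, ws + hi
            else:
                g_lo, g_hi = we - hi, we - lo
            cand = HairpinCandidate(
                chrom=chrom,
                start=g_lo,
                end=g_hi,
                strand=strand,
                mature_tag=aln.tag,
                arm=arm,
                paired_bases=paired,
                loop_length=loop_len,
            )
            if best is None or cand.paired_bases > best.paired_bases:
                best = cand
        if best is not None:
            out.append(best)
    return out
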