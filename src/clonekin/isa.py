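"""Lentiviral integration-site clone calling from LTR-junction reads.

Each sequencing read from the junction amplification protocol is the 3'
end of the provirus LTR, followed by the genomic fragment flanking the
integration site, followed by the ligated linker. The pipeline:

1. LTR filter — reads whose best LTR fit is below 90% identity are
   discarded; the matched LTR span (and, when a linker sequence is
   supplied, the trailing linker) is trimmed off.
2. Vector filter — trimmed inserts matching the vector sequence at >= 80%
   identity (internal amplification products rather than genomic
   junctions) are discarded.
3. Genome alignment — k-mer-seeded local alignment of each insert; the
   top-scoring alignment and all alignments within 95% of the top score
   are kept. Reads whose best alignment is shorter than 30 bp or starts
   more than 10 bp into the insert are moved to the unaligned pool.
4. Grouping and consensus — reads sharing an identical alignment set are
   grouped (largest groups first); each group gets a majority-vote
   consensus built from a centre-star multiple alignment; unaligned reads
   at >= 90% identity to a consensus are rescued into that group.
5. Merging — groups with >= 90% consensus similarity are merged (highest
   count against lowest count); across samples of one subject, groups
   with exact alignment-set matches, exact consensus matches, or
   multi-align-ratio >= 0.9 with >= 90% similar consensus are merged into
   one clone id.
6. Reporting — per-sample clone frequencies (reads of the clone / all
   clone-assigned reads), ribbon tables with clones < 1% pooled into an
   "other" bin, exon/intron/intergenic annotation of each site against a
   gene model, and >= 5-fold expanded/contracted site lists between the
   infusion product and post-infusion samples.

The multi-align-ratio of a group is second-best / best alignment score of
its representative read: 0 means uniquely mapped, near 1 means the insert
maps equally well to several loci.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .alignment import (
    GenomeAlignment,
    KmerGenomeAligner,
    global_identity,
    infix_search,
    local_identity,
    prefix_identity,
)
from .errors import CoordinateError, EmptyRepertoireError

__all__ = [
    "IsaParams",
    "IsaRead",
    "ReadGroup",
    "IsaClone",
    "GeneModel",
    "IsaResult",
    "filter_ltr",
    "filter_vector",
    "filter_alignments",
    "multi_align_ratio",
    "build_consensus",
    "group_and_consensus",
    "merge_clones",
    "clone_frequencies",
    "ribbon_table",
    "annotate_site",
    "fold_change_sites",
    "call_integration_sites",
]


@dataclass(frozen=True)
class IsaParams:
    """Thresholds of the clone-calling pipeline (documented defaults)."""

    min_ltr_identity: float = 0.90
    max_vector_identity: float = 0.80
    min_vector_overlap: int = 30
    min_align_length: int = 30
    max_align_start: int = 10
    top_score_frac: float = 0.95
    merge_identity: float = 0.90
    multi_align_threshold: float = 0.90
    ribbon_min_freq: float = 0.01
    fold_change: float = 5.0
    seed_k: int = 11
    seed_step: int = 5
    max_kmer_occurrences: int = 64


_EPS = 1e-12


@dataclass
class IsaRead:
    """A read that passed the LTR filter, with its trimmed genomic insert."""

    read_id: str
    sequence: str
    ltr_identity: float
    trimmed_insert: str
    vector_identity: float = 0.0
    sample: str = "sample"


def filter_ltr(
    read_id: str,
    sequence: str,
    ltr_seq: str,
    min_identity: float = 0.90,
    linker_seq: str | None = None,
    sample: str = "sample",
) -> IsaRead | None:
    """LTR filter: fit the LTR inside the read and trim it off.

    Identity is matches / aligned columns of the best fit of the whole
    LTR within the read. Reads under ``min_identity`` (90% default) are
    rejected (returns None). On pass, everything through the matched LTR
    span is trimmed; if ``linker_seq`` is given and found at >= 80%
    identity downstream of the LTR, the linker and anything after it is
    trimmed as well.
    """
    if not ltr_seq:
        raise ValueError("LTR sequence must be non-empty")
    if not sequence:
        return None
    identity, _, ltr_end = infix_search(ltr_seq.upper(), sequence.upper())
    if identity < min_identity - _EPS:
        return None
    insert = sequence.upper()[ltr_end:]
    if linker_seq:
        link_id, link_start, _ = infix_search(linker_seq.upper(), insert)
        if link_id >= 0.80 and link_start > 0:
            insert = insert[:link_start]
    return IsaRead(
        read_id=read_id,
        sequence=sequence,
        ltr_identity=identity,
        trimmed_insert=insert,
        sample=sample,
    )


def filter_vector(
    read: IsaRead,
    vector_seq: str,
    max_identity: float = 0.80,
    min_overlap: int = 30,
) -> bool:
    """Vector filter: True when the read is kept.

    The insert is locally aligned to the vector sequence; the read is
    rejected when the best local alignment spans at least ``min_overlap``
    columns at >= ``max_identity`` identity. The span floor prevents a
    chance handful of matching bases from counting as vector identity.
    Side effect: records the measured identity on the read.
    """
    identity, cols = local_identity(read.trimmed_insert, vector_seq.upper())
    read.vector_identity = identity if cols >= min_overlap else 0.0
    return read.vector_identity < max_identity - _EPS


def filter_alignments(
    alignments: Sequence[GenomeAlignment],
    min_align_length: int = 30,
    max_align_start: int = 10,
) -> list[GenomeAlignment]:
    """Alignment-quality filter applied to one read's alignment set.

    The whole read is discarded (empty list) when its best alignment is
    shorter than ``min_align_length`` columns or starts more than
    ``max_align_start`` bases into the insert; otherwise the set is
    returned unchanged.
    """
    if not alignments:
        return []
    best = max(alignments, key=lambda a: a.score)
    if best.align_length < min_align_length or best.align_start > max_align_start:
        return []
    return list(alignments)


def multi_align_ratio(alignments: Sequence[GenomeAlignment]) -> float:
    """Second-best / best alignment score; 0 for a uniquely mapped read."""
    if not alignments:
        raise ValueError("multi_align_ratio is undefined for an empty alignment set")
    if len(alignments) == 1:
        return 0.0
    scores = sorted((a.score for a in alignments), reverse=True)
    return scores[1] / scores[0]


@dataclass
class ReadGroup:
    """Reads sharing one alignment set, with their consensus insert."""

    alignments: tuple[GenomeAlignment, ...]
    reads: list[IsaRead]
    consensus: str = ""
    multi_align: float = 0.0

    @property
    def read_count(self) -> int:
        return len(self.reads)

    @property
    def site_key(self) -> tuple[tuple[str, int, str], ...]:
        return tuple(sorted(a.site for a in self.alignments))

    @property
    def best_site(self) -> tuple[str, int, str]:
        return max(self.alignments, key=lambda a: (a.score, a.site)).site


def _center_star_alignments(center: str, others: Iterable[str]):
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    for other in others:
        yield aligner.align(center, other)[0]


def build_consensus(sequences: Sequence[str]) -> str:
    """Majority-vote consensus of a read group.

    Centre-star multiple alignment: the most frequent sequence (ties to
    the lexicographically smallest) is the centre; every other distinct
    sequence is globally aligned to it; each centre column is called by
    weighted majority vote with ties resolved to the centre's base.
    Insertions relative to the centre are ignored and a majority deletion
    removes the column, so with substitution-dominated errors the
    consensus recovers the true insert.
    """
    if not sequences:
        raise ValueError("cannot build a consensus from zero sequences")
    tally = Counter(sequences)
    center, _ = min(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(tally) == 1:
        return center
    votes: list[Counter] = [Counter() for _ in center]
    for i, base in enumerate(center):
        votes[i][base] += tally[center]
    others = [s for s in sorted(tally) if s != center]
    for seq, aln in zip(others, _center_star_alignments(center, others)):
        weight = tally[seq]
        covered = [False] * len(center)
        for (cstart, cend), (ostart, _) in zip(*aln.aligned):
            for offset in range(cend - cstart):
                votes[cstart + offset][seq[ostart + offset]] += weight
                covered[cstart + offset] = True
        for i, was_covered in enumerate(covered):
            if not was_covered:
                votes[i]["-"] += weight  # deletion vote
    out = []
    for i, base in enumerate(center):
        top = max(votes[i].values())
        if votes[i][base] == top:
            winner = base  # tie goes to the centre read
        else:
            winner = min(b for b, v in votes[i].items() if v == top)
        if winner != "-":
            out.append(winner)
    return "".join(out)


def group_and_consensus(
    aligned_reads: Sequence[tuple[IsaRead, Sequence[GenomeAlignment]]],
    unaligned_pool: Sequence[IsaRead] = (),
    rescue_identity: float = 0.90,
) -> list[ReadGroup]:
    """Group reads by alignment set, build consensus, rescue unaligned reads.

    Reads with identical alignment sets (including multi-mapped reads,
    which are grouped by their full set of sites) form one group; groups
    are processed largest first. Each group's consensus is the majority
    vote of its members' inserts. Reads the genome aligner could not
    place are then compared against every consensus in descending group
    order and merged into the best-identity group at >= ``rescue_identity``
    (group counts grow; consensus is not rebuilt). Output order is
    (read count desc, consensus lexicographic) for determinism.
    """
    by_key: dict[tuple, ReadGroup] = {}
    for read, alignments in aligned_reads:
        if not alignments:
            continue
        key = tuple(sorted(a.site for a in alignments))
        group = by_key.get(key)
        if group is None:
            ordered = tuple(sorted(alignments, key=lambda a: (-a.score, a.site)))
            by_key[key] = ReadGroup(alignments=ordered, reads=[read])
        else:
            group.reads.append(read)
    groups = list(by_key.values())
    for group in groups:
        group.reads.sort(key=lambda r: r.read_id)
        group.consensus = build_consensus([r.trimmed_insert for r in group.reads])
        group.multi_align = multi_align_ratio(group.alignments)
    groups.sort(key=lambda g: (-g.read_count, g.consensus))

    for read in sorted(unaligned_pool, key=lambda r: r.read_id):
        best_group, best_identity = None, 0.0
        for group in groups:
            identity = prefix_identity(read.trimmed_insert, group.consensus)
            if identity > best_identity:
                best_group, best_identity = group, identity
        if best_group is not None and best_identity >= rescue_identity - _EPS:
            best_group.reads.append(read)
    groups.sort(key=lambda g: (-g.read_count, g.consensus))
    return groups


@dataclass
class IsaClone:
    """A merged integration-site clone across all samples of one subject."""

    clone_id: str
    chromosome: str | None
    locus: int | None  # 0-based internally; reports are 1-based
    strand: str | None
    consensus: str
    multi_align: float
    sample_counts: dict[str, int] = field(default_factory=dict)
    site_key: tuple = ()

    @property
    def read_count(self) -> int:
        return sum(self.sample_counts.values())

    @property
    def is_multi_aligned(self) -> bool:
        return self.multi_align >= 0.90


def _groups_to_clones(groups: Sequence[ReadGroup]) -> list[IsaClone]:
    clones = []
    for group in groups:
        chrom, locus, strand = group.best_site
        counts: dict[str, int] = {}
        for read in group.reads:
            counts[read.sample] = counts.get(read.sample, 0) + 1
        clones.append(
            IsaClone(
                clone_id="",
                chromosome=chrom,
                locus=locus,
                strand=strand,
                consensus=group.consensus,
                multi_align=group.multi_align,
                sample_counts=counts,
                site_key=group.site_key,
            )
        )
    return clones


def _absorb(winner: IsaClone, loser: IsaClone) -> None:
    for sample, n in loser.sample_counts.items():
        winner.sample_counts[sample] = winner.sample_counts.get(sample, 0) + n


def merge_clones(
    clones: Sequence[IsaClone],
    merge_identity: float = 0.90,
    multi_align_threshold: float = 0.90,
) -> list[IsaClone]:
    """Merge clone candidates within one subject into final clone ids.

    Four rules, applied in order; merged counts sum and the representative
    locus/consensus come from the higher-count member:

    1. consensus similarity >= 90%, comparing highest-count clones against
       lowest-count clones;
    2. exact alignment-set match (same site or same multi-map set);
    3. exact consensus sequence match;
    4. both multi-aligned (multi-align-ratio >= 0.9) with >= 90% similar
       consensus ("reference") sequences.
    """

    def order(cs: list[IsaClone]) -> list[IsaClone]:
        return sorted(cs, key=lambda c: (-c.read_count, c.consensus))

    live = order([replace(c, sample_counts=dict(c.sample_counts)) for c in clones])

    # rule 1: highest-count vs lowest-count consensus similarity
    i = 0
    while i < len(live):
        j = len(live) - 1
        while j > i:
            if prefix_identity(live[i].consensus, live[j].consensus) >= merge_identity - _EPS:
                _absorb(live[i], live.pop(j))
            j -= 1
        i += 1
        live = order(live)

    def merge_pass(key_fn) -> None:
        nonlocal live
        seen: dict = {}
        merged: list[IsaClone] = []
        for clone in order(live):
            key = key_fn(clone)
            if key is not None and key in seen:
                _absorb(seen[key], clone)
            else:
                if key is not None:
                    seen[key] = clone
                merged.append(clone)
        live = merged

    # rule 2: exact alignment-set match; rule 3: exact consensus match
    merge_pass(lambda c: c.site_key or None)
    merge_pass(lambda c: c.consensus or None)

    # rule 4: multi-aligned clones with similar consensus
    multi = [c for c in order(live) if c.multi_align >= multi_align_threshold]
    for a in multi:
        for b in multi:
            if (
                a is not b
                and b in live
                and a in live
                and a.read_count >= b.read_count
                and prefix_identity(a.consensus, b.consensus) >= merge_identity - _EPS
            ):
                _absorb(a, b)
                live.remove(b)

    live = order(live)
    for n, clone in enumerate(live, start=1):
        if clone.is_multi_aligned and len(clone.site_key) > 1:
            clone.clone_id = f"clone{n:04d}_multi"
        else:
            clone.clone_id = f"clone{n:04d}_{clone.chromosome}_{clone.locus + 1}_{clone.strand}"
    return live


def clone_frequencies(clones: Sequence[IsaClone], sample: str) -> pd.Series:
    """Per-clone read-fraction within one sample (sums to 1)."""
    counts = pd.Series(
        {c.clone_id: c.sample_counts.get(sample, 0) for c in clones}, dtype=float
    )
    total = counts.sum()
    if total == 0:
        raise EmptyRepertoireError(f"no clone-assigned reads in sample {sample!r}")
    return counts / total


def ribbon_table(
    clones: Sequence[IsaClone],
    samples: Sequence[str],
    min_freq: float = 0.01,
) -> pd.DataFrame:
    """Long table for stacked-ribbon plots of clone contributions.

    A clone keeps its own ribbon when it reaches ``min_freq`` (1% default)
    in at least one sample of the subject; all remaining clones are pooled
    into a single ``other`` ribbon per sample.
    """
    freqs = {s: clone_frequencies(clones, s) for s in samples}
    colored = {
        c.clone_id
        for c in clones
        if any(freqs[s][c.clone_id] >= min_freq for s in samples)
    }
    rows = []
    for s in samples:
        other = 0.0
        for clone_id, f in freqs[s].items():
            if clone_id in colored:
                rows.append((s, clone_id, f))
            else:
                other += f
        rows.append((s, "other", other))
    return pd.DataFrame(rows, columns=["sample", "clone_id", "frequency"])


class GeneModel:
    """Gene/exon intervals for exon-intron-intergenic site annotation.

    Built from per-gene exon lists with 0-based half-open coordinates;
    :meth:`from_bed12` parses the standard 12-column BED gene model where
    blocks are exons.
    """

    def __init__(self, genes: Mapping[str, tuple[str, list[tuple[int, int]]]]):
        # genes: gene_id -> (chromosome, [(exon_start, exon_end), ...])
        self._gene_trees: dict[str, IntervalTree] = {}
        self._exon_trees: dict[str, IntervalTree] = {}
        self.genes = dict(genes)
        for gene_id, (chrom, exons) in self.genes.items():
            if not exons:
                raise ValueError(f"gene {gene_id!r} has no exons")
            span = (min(s for s, _ in exons), max(e for _, e in exons))
            if span[0] < 0:
                raise ValueError(f"gene {gene_id!r} has negative coordinates")
            self._gene_trees.setdefault(chrom, IntervalTree()).addi(*span, gene_id)
            for start, end in exons:
                self._exon_trees.setdefault(chrom, IntervalTree()).addi(start, end, gene_id)

    @classmethod
    def from_bed12(cls, path) -> "GeneModel":
        genes: dict[str, tuple[str, list[tuple[int, int]]]] = {}
        with open(path) as fh:
            for line_no, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 12:
                    raise ValueError(
                        f"{path}:{line_no}: expected 12 BED columns, got {len(fields)}"
                    )
                chrom, start, name = fields[0], int(fields[1]), fields[3]
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
                exons = [(start + s, start + s + sz) for s, sz in zip(starts, sizes)]
                genes[name] = (chrom, exons)
        return cls(genes)

    def genes_at(self, chromosome: str, locus: int) -> list[str]:
        tree = self._gene_trees.get(chromosome)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.at(locus))

    def classify(self, chromosome: str, locus: int) -> str:
        if locus < 0:
            raise CoordinateError(f"negative locus {locus}")
        exon_tree = self._exon_trees.get(chromosome)
        if exon_tree is not None and exon_tree.at(locus):
            return "exon"
        return "intron" if self.genes_at(chromosome, locus) else "intergenic"


def annotate_site(
    site: tuple[str, int, str],
    gene_model: GeneModel,
    chrom_lengths: Mapping[str, int] | None = None,
) -> str:
    """Classify a site as exon / intron / intergenic (strand-agnostic)."""
    chrom, locus, _ = site
    if chrom_lengths is not None:
        if chrom not in chrom_lengths or not 0 <= locus < chrom_lengths[chrom]:
            raise CoordinateError(f"locus {chrom}:{locus} outside chromosome bounds")
    return gene_model.classify(chrom, locus)


def fold_change_sites(
    ip_freqs: pd.Series,
    post_freqs: pd.Series,
    fold: float = 5.0,
    gene_lookup=None,
    pseudo_freq: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sites >= ``fold``-fold expanded or contracted between two samples.

    Frequencies of 0 (a clone undetected in one sample) are replaced by a
    floor so the ratio stays defined: ``pseudo_freq`` when given (half the
    reciprocal sample depth is the natural choice when depths are known),
    otherwise half the smallest nonzero frequency in that sample.
    ``gene_lookup`` maps a clone_id to its host gene(s); when given, a
    ``genes`` column is attached.

    Returns (expanded, contracted) DataFrames with columns
    ``freq_ip``, ``freq_post``, ``ratio`` (and ``genes``).
    """
    ids = sorted(set(ip_freqs.index) | set(post_freqs.index))
    ip = ip_freqs.reindex(ids).fillna(0.0)
    post = post_freqs.reindex(ids).fillna(0.0)

    def floor(series: pd.Series) -> float:
        if pseudo_freq is not None:
            return pseudo_freq
        nonzero = series[series > 0]
        return float(nonzero.min()) / 2 if len(nonzero) else 1.0

    ratio = post.where(post > 0, floor(post)) / ip.where(ip > 0, floor(ip))
    df = pd.DataFrame({"freq_ip": ip, "freq_post": post, "ratio": ratio})
    if gene_lookup is not None:
        df["genes"] = [",".join(gene_lookup(i)) for i in ids]
    expanded = df[df["ratio"] >= fold].sort_values("ratio", ascending=False)
    contracted = df[df["ratio"] <= 1.0 / fold].sort_values("ratio")
    return expanded, contracted


@dataclass
class IsaResult:
    """End-to-end clone-calling output plus per-stage read accounting."""

    clones: list[IsaClone]
    samples: list[str]
    stats: dict[str, int]
    params: IsaParams

    def clone_table(self) -> pd.DataFrame:
        """Wide clone table; coordinates 1-based, one count/freq pair per sample."""
        rows = []
        for c in self.clones:
            row = {
                "clone_id": c.clone_id,
                "chromosome": c.chromosome,
                "position": (c.locus + 1) if c.locus is not None else pd.NA,
                "strand": c.strand,
                "multi_align_ratio": c.multi_align,
                "read_count": c.read_count,
                "consensus": c.consensus,
            }
            rows.append(row)
        df = pd.DataFrame(rows)
        for s in self.samples:
            freqs = clone_frequencies(self.clones, s)
            df[f"count_{s}"] = [c.sample_counts.get(s, 0) for c in self.clones]
            df[f"freq_{s}"] = [freqs[c.clone_id] for c in self.clones]
        return df

    def frequencies(self, sample: str) -> pd.Series:
        return clone_frequencies(self.clones, sample)

    def ribbons(self) -> pd.DataFrame:
        return ribbon_table(self.clones, self.samples, self.params.ribbon_min_freq)


def call_integration_sites(
    reads_by_sample: Mapping[str, Sequence[tuple[str, str]]],
    genome: Mapping[str, str],
    ltr_seq: str,
    vector_seq: str,
    linker_seq: str | None = None,
    params: IsaParams = IsaParams(),
) -> IsaResult:
    """Run the full clone-calling pipeline for one subject.

    Parameters
    ----------
    reads_by_sample
        Mapping sample name -> iterable of (read_id, sequence) from
        stitched junction reads.
    genome
        Mapping chromosome name -> reference sequence.
    """
    aligner = KmerGenomeAligner(
        genome,
        k=params.seed_k,
        step=params.seed_step,
        max_kmer_occurrences=params.max_kmer_occurrences,
        top_score_frac=params.top_score_frac,
    )
    stats = {
        "input_reads": 0,
        "ltr_rejected": 0,
        "vector_rejected": 0,
        "unaligned": 0,
        "grouped_reads": 0,
    }
    aligned: list[tuple[IsaRead, list[GenomeAlignment]]] = []
    pool: list[IsaRead] = []
    for sample in sorted(reads_by_sample):
        for read_id, sequence in reads_by_sample[sample]:
            stats["input_reads"] += 1
            read = filter_ltr(
                read_id, sequence, ltr_seq, params.min_ltr_identity, linker_seq, sample
            )
            if read is None:
                stats["ltr_rejected"] += 1
                continue
            if not filter_vector(
                read, vector_seq, params.max_vector_identity, params.min_vector_overlap
            ):
                stats["vector_rejected"] += 1
                continue
            alignments = filter_alignments(
                aligner.align(read.trimmed_insert),
                params.min_align_length,
                params.max_align_start,
            )
            if alignments:
                aligned.append((read, alignments))
            else:
                stats["unaligned"] += 1
                pool.append(read)
    groups = group_and_consensus(aligned, pool, params.merge_identity)
    stats["grouped_reads"] = sum(g.read_count for g in groups)
    stats["rescued"] = stats["grouped_reads"] - len(aligned)
    clones = merge_clones(
        _groups_to_clones(groups), params.merge_identity, params.multi_align_threshold
    )
    return IsaResult(
        clones=clones, samples=sorted(reads_by_sample), stats=stats, params=params
    )
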