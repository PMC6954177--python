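"""Pairwise-identity helpers and a k-mer-seeded local genome aligner.

Identity is defined uniformly across the pipeline as matched columns
divided by aligned columns, with gap columns counting as mismatches.
Bulk identity computations (read rescue, clone merging) run through
edlib; scored local alignment (vector screening, seed extension) runs
through Bio.Align.PairwiseAligner.

The genome aligner replaces an external whole-genome mapper at desk
scale: genome k-mers (length 11, indexed every 5 bases, mirroring the
tile/step sizes of BLAT-style mapping) seed candidate windows, which are
then resolved by Smith-Waterman extension. Over-represented k-mers are
masked by a simple occurrence cap.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
from Bio import Align

__all__ = [
    "GenomeAlignment",
    "prefix_identity",
    "KmerGenomeAligner",
    "global_identity",
    "infix_search",
    "local_identity",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")
_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _cigar_columns(cigar: str) -> int:
    return sum(int(n) for n, _ in _CIGAR_RE.findall(cigar))


def global_identity(a: str, b: str) -> float:
    """End-to-end identity between two sequences.

    Matched columns / aligned columns of a minimum-edit-distance global
    alignment; insertions and deletions count as mismatched columns.
    """
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW", task="path")
    cols = _cigar_columns(res["cigar"])
    return (cols - res["editDistance"]) / cols


def prefix_identity(a: str, b: str) -> float:
    """Identity with the shorter sequence aligned as a prefix of the longer.

    Junction-anchored fragments from one integration site share their
    start but end wherever the linker ligated, so similarity between two
    of them (or a read and a consensus) is judged over the shared prefix:
    the shorter sequence is aligned end-gap-free against the longer and
    identity is matches / aligned columns of that span.
    """
    if not a or not b:
        return 0.0
    query, target = (a, b) if len(a) <= len(b) else (b, a)
    res = edlib.align(query, target, mode="SHW", task="path")
    cols = _cigar_columns(res["cigar"])
    return (cols - res["editDistance"]) / cols


def infix_search(query: str, target: str) -> tuple[float, int, int]:
    """Best alignment of the whole ``query`` inside ``target``.

    Returns ``(identity, start, end)`` where ``target[start:end]`` is the
    matched span and identity is matches / aligned columns. Used to fit
    the LTR against the read and to locate the linker.
    """
    if not query or not target:
        return 0.0, 0, 0
    res = edlib.align(query, target, mode="HW", task="path")
    cols = _cigar_columns(res["cigar"])
    identity = (cols - res["editDistance"]) / cols
    start, end = res["locations"][0]
    return identity, start, end + 1


def _make_local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner

_LOCAL = _make_local_aligner()


def _alignment_stats(aln) -> tuple[int, int]:
    """(matched columns, aligned columns incl. internal gaps)."""
    c = aln.counts()
    return c.identities, c.identities + c.mismatches + c.gaps


def local_identity(a: str, b: str) -> tuple[float, int]:
    """Identity over the aligned span of the best-scoring local alignment.

    Returns ``(identity, aligned_columns)``; (0.0, 0) when no positive-
    scoring local alignment exists.
    """
    if not a or not b:
        return 0.0, 0
    alns = _LOCAL.align(a, b)
    if len(alns) == 0 or alns.score <= 0:
        return 0.0, 0
    matches, cols = _alignment_stats(alns[0])
    if cols == 0:
        return 0.0, 0
    return matches / cols, cols


@dataclass(frozen=True)
class GenomeAlignment:
    """One local alignment of a trimmed insert against the genome.

    ``locus`` is the 0-based genomic position of the first insert base
    (the vector-genome junction), extrapolated from the alignment ends
    when the first few insert bases did not align; ``align_start`` is the
    0-based offset within the insert where the alignment begins.
    """

    chromosome: str
    locus: int
    strand: str
    score: float
    align_length: int
    align_start: int

    @property
    def site(self) -> tuple[str, int, str]:
        return (self.chromosome, self.locus, self.strand)

    def label(self) -> str:
        """1-based site label, e.g. ``chr1_8020175_+``."""
        return f"{self.chromosome}_{self.locus + 1}_{self.strand}"


class KmerGenomeAligner:
    """Seed-and-extend local aligner over a small reference genome.

    Parameters
    ----------
    genome
        Mapping chromosome name -> sequence.
    k, step
        Seed k-mer length and genome indexing stride (defaults 11 and 5).
    max_kmer_occurrences
        Genome k-mers occurring more often than this are masked from the
        seed index (repeat masking at toy-genome scale).
    top_score_frac
        All alignments scoring within this fraction of the best are
        reported alongside it (default 0.95).
    """

    def __init__(
        self,
        genome: dict[str, str],
        k: int = 11,
        step: int = 5,
        max_kmer_occurrences: int = 64,
        top_score_frac: float = 0.95,
    ) -> None:
        self.genome = {name: seq.upper() for name, seq in genome.items()}
        self.k = k
        self.step = step
        self.top_score_frac = top_score_frac
        self._aligner = _make_local_aligner()
        index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.genome.items():
            for pos in range(0, len(seq) - k + 1, step):
                index.setdefault(seq[pos : pos + k], []).append((name, pos))
        self._index = {
            kmer: hits
            for kmer, hits in index.items()
            if len(hits) <= max_kmer_occurrences and "N" not in kmer
        }

    def _candidate_windows(self, query: str) -> dict[tuple[str, int], list[int]]:
        """Seed hits grouped by (chromosome, banded diagonal)."""
        band = 2 * self.step + self.k
        windows: dict[tuple[str, int], list[int]] = {}
        for qpos in range(0, len(query) - self.k + 1):
            for chrom, gpos in self._index.get(query[qpos : qpos + self.k], ()):
                diag = gpos - qpos
                windows.setdefault((chrom, diag // band), []).append(diag)
        return windows

    def _extend(self, query: str, chrom: str, diags: list[int]) -> GenomeAlignment | None:
        seq = self.genome[chrom]
        pad = 20
        start = max(0, min(diags) - pad)
        end = min(len(seq), max(diags) + len(query) + pad)
        window = seq[start:end]
        alns = self._aligner.align(query, window)
        if len(alns) == 0 or alns.score <= 0:
            return None
        aln = alns[0]
        matches, cols = _alignment_stats(aln)
        qstart = int(aln.aligned[0][0][0])
        qend = int(aln.aligned[0][-1][1])
        tstart = start + int(aln.aligned[1][0][0])
        tend = start + int(aln.aligned[1][-1][1])
        return GenomeAlignment(
            chromosome=chrom,
            locus=tstart - qstart,  # '+' orientation; '-' fixed up by caller
            strand="+",
            score=float(alns.score),
            align_length=cols,
            align_start=qstart,
        ), qend, tend

    def align(self, insert: str) -> list[GenomeAlignment]:
        """All retained alignments of an insert, best first.

        Both orientations are searched; for a reverse-strand hit the
        reported locus is the genomic base pairing with the first insert
        base and ``align_start`` stays in original insert coordinates.
        Alignments scoring below ``top_score_frac`` of the best, and
        duplicate sites, are dropped. Empty list when nothing seeds.
        """
        insert = insert.upper()
        if len(insert) < self.k:
            return []
        results: list[GenomeAlignment] = []
        for strand, query in (("+", insert), ("-", revcomp(insert))):
            for (chrom, _), diags in self._candidate_windows(query).items():
                hit = self._extend(query, chrom, diags)
                if hit is None:
                    continue
                aln, qend, tend = hit
                if strand == "+":
                    results.append(aln)
                else:
                    align_start = len(insert) - qend
                    results.append(
                        GenomeAlignment(
                            chromosome=chrom,
                            locus=tend - 1 + align_start,
                            strand="-",
                            score=aln.score,
                            align_length=aln.align_length,
                            align_start=align_start,
                        )
                    )
        if not results:
            return []
        best = max(a.score for a in results)
        kept: dict[tuple[str, int, str], GenomeAlignment] = {}
        for aln in sorted(results, key=lambda a: (-a.score, a.site)):
            if aln.score >= self.top_score_frac * best and aln.site not in kept:
                kept[aln.site] = aln
        return list(kept.values())
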