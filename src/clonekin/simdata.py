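"""Synthetic inputs with the statistical structure the analyses assume.

Three generators stand in for the patient data so every downstream stage
is testable without any download:

* :func:`simulate_repertoire_timeline` — a heavy-tailed (power-law)
  baseline clonotype distribution observed multinomially at each
  timepoint, with designated clones planted on increasing / transient /
  decreasing frequency trajectories.
* :func:`simulate_isa_reads` — LTR-junction reads of the form
  ``LTR + genomic fragment + linker`` from integration sites planted in
  a random toy genome, with i.i.d. substitution errors and an optional
  fraction of vector-carryover contaminant reads.
* :func:`simulate_cell_table` — single-cell records (QC scalars,
  clonotype, infusion-product cluster label) where the cells of planted
  expanding clonotypes are enriched in designated clusters.

One integer seed is split into independent per-purpose streams via
``numpy.random.SeedSequence``, so each generator is byte-deterministic
given its config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidConfigError
from .repertoire import RepertoireSample

__all__ = [
    "PlantedClone",
    "SimRepertoireConfig",
    "SimIsaConfig",
    "SimCellConfig",
    "SimulatedTimeline",
    "SimulatedIsaReads",
    "simulate_repertoire_timeline",
    "simulate_isa_reads",
    "simulate_cell_table",
    "random_dna",
    "write_reads_fasta",
    "write_genome_fasta",
    "write_repertoire_tsv",
]

_PATTERNS = ("increasing", "transient", "decreasing")
_TIMEPOINT_LABELS = ("IP", "early", "late", "very_late")
_BASES = np.array(list("ACGT"))


def random_dna(length: int, rng: np.random.Generator) -> str:
    """Uniform random DNA string of the given length."""
    return "".join(rng.choice(_BASES, size=length))


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass(frozen=True)
class PlantedClone:
    """A clone planted on a known frequency trajectory."""

    clone_index: int
    pattern: str  # increasing | transient | decreasing
    fold_per_step: float = 4.0

    def __post_init__(self) -> None:
        if self.pattern not in _PATTERNS:
            raise InvalidConfigError(f"unknown pattern {self.pattern!r}")
        if self.fold_per_step <= 1:
            raise InvalidConfigError("fold_per_step must be > 1")


@dataclass(frozen=True)
class SimRepertoireConfig:
    """Configuration of the repertoire-timeline generator.

    Baseline clone frequencies follow rank^(-abundance_exponent); each
    timepoint's observed sample is a multinomial draw of
    ``sequencing_depth`` templates from that timepoint's true frequency
    vector (so observed counts sum exactly to the depth).
    """

    n_clonotypes: int
    abundance_exponent: float = 1.0
    n_timepoints: int = 4
    planted_dynamics: tuple[PlantedClone, ...] = ()
    sequencing_depth: int | tuple[int, ...] = 100_000
    cdr3_length: int = 45
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clonotypes < 1:
            raise InvalidConfigError("n_clonotypes must be positive")
        if self.abundance_exponent <= 0:
            raise InvalidConfigError("abundance_exponent must be positive")
        if self.n_timepoints < 2:
            raise InvalidConfigError("n_timepoints must be >= 2")
        depths = self.depths
        if any(d < 1 for d in depths):
            raise InvalidConfigError("sequencing_depth must be positive")
        indices = [p.clone_index for p in self.planted_dynamics]
        if len(set(indices)) != len(indices):
            raise InvalidConfigError("planted clone indices must be unique")
        if any(i < 0 or i >= self.n_clonotypes for i in indices):
            raise InvalidConfigError("planted clone index out of range")

    @property
    def depths(self) -> tuple[int, ...]:
        if isinstance(self.sequencing_depth, int):
            return (self.sequencing_depth,) * self.n_timepoints
        if len(self.sequencing_depth) != self.n_timepoints:
            raise InvalidConfigError("one sequencing depth per timepoint required")
        return tuple(self.sequencing_depth)


@dataclass
class SimulatedTimeline:
    """Samples plus ground truth from one repertoire simulation."""

    samples: list[RepertoireSample]
    truth: pd.DataFrame  # clonotype_id, clone_index, pattern, cdr3_nt
    true_freqs: np.ndarray  # shape (n_timepoints, n_clonotypes)
    config: SimRepertoireConfig

    @property
    def clonotype_ids(self) -> list[str]:
        return list(self.truth["clonotype_id"])


def _pattern_multiplier(pattern: str, fold: float, t: int) -> float:
    # transient clones rise to the early (second) timepoint then decay
    # symmetrically: multipliers 1, f, 1, 1/f, ... over timepoints 0,1,2,3.
    if pattern == "increasing":
        return fold**t
    if pattern == "decreasing":
        return fold**-t
    return fold ** (min(t, 2 - t))


def timepoint_label(t: int, n_timepoints: int) -> str:
    if n_timepoints <= len(_TIMEPOINT_LABELS):
        return _TIMEPOINT_LABELS[t]
    return f"t{t}"


def simulate_repertoire_timeline(
    config: SimRepertoireConfig, patient_id: str = "SIM-1"
) -> SimulatedTimeline:
    """Generate per-timepoint repertoire samples with planted dynamics."""
    rng_seq, rng_sample = _streams(config.seed, 2)
    n = config.n_clonotypes
    baseline = np.arange(1, n + 1, dtype=float) ** -config.abundance_exponent
    baseline /= baseline.sum()

    planted = {p.clone_index: p for p in config.planted_dynamics}
    true_freqs = np.empty((config.n_timepoints, n))
    for t in range(config.n_timepoints):
        w = baseline.copy()
        for idx, p in planted.items():
            w[idx] = baseline[idx] * _pattern_multiplier(p.pattern, p.fold_per_step, t)
        true_freqs[t] = w / w.sum()

    ids = [f"CT{i:06d}" for i in range(n)]
    cdr3 = [random_dna(config.cdr3_length, rng_seq) for _ in range(n)]
    truth = pd.DataFrame(
        {
            "clonotype_id": ids,
            "clone_index": np.arange(n),
            "pattern": [planted[i].pattern if i in planted else "background" for i in range(n)],
            "fold_per_step": [planted[i].fold_per_step if i in planted else np.nan for i in range(n)],
            "cdr3_nt": cdr3,
        }
    )
    for t in range(config.n_timepoints):
        truth[f"true_freq_{timepoint_label(t, config.n_timepoints)}"] = true_freqs[t]

    samples = []
    for t, depth in enumerate(config.depths):
        counts = rng_sample.multinomial(depth, true_freqs[t])
        observed = {ids[i]: int(c) for i, c in enumerate(counts) if c > 0}
        samples.append(
            RepertoireSample(
                counts=observed,
                patient_id=patient_id,
                timepoint=timepoint_label(t, config.n_timepoints),
                compartment="CAR_pos",
            )
        )
    return SimulatedTimeline(samples=samples, truth=truth, true_freqs=true_freqs, config=config)


@dataclass(frozen=True)
class SimIsaConfig:
    """Configuration of the integration-site read generator.

    Reads are ``LTR + fragment + linker`` with i.i.d. substitutions at
    ``substitution_rate`` per base; ``contaminant_fraction`` of reads
    carry a vector fragment instead of a genomic one. Per-site read
    counts are Poisson(``mean_reads_per_site``) clipped below at
    ``min_reads_per_site``. When LTR/linker/vector sequences are not
    supplied they are generated from the seed (60 / 24 / 1000 bp).
    """

    genome_length: int = 100_000
    n_sites: int = 50
    mean_reads_per_site: float = 20.0
    min_reads_per_site: int = 5
    ltr_seq: str | None = None
    linker_seq: str | None = None
    vector_seq: str | None = None
    fragment_length_range: tuple[int, int] = (60, 150)
    substitution_rate: float = 0.0
    indel_rate: float = 0.0
    contaminant_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.fragment_length_range
        if lo < 30 or hi < lo:
            raise InvalidConfigError(
                "fragment lengths must be >= 30 and min <= max (alignment-length filter)"
            )
        if hi > self.genome_length:
            raise InvalidConfigError("fragment range exceeds genome length")
        if self.n_sites < 1 or self.genome_length < 1:
            raise InvalidConfigError("n_sites and genome_length must be positive")
        for name in ("substitution_rate", "indel_rate", "contaminant_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0, 1]")
        for name in ("ltr_seq", "linker_seq", "vector_seq"):
            v = getattr(self, name)
            if v is not None and len(v) == 0:
                raise InvalidConfigError(f"{name} must be non-empty when given")


@dataclass
class SimulatedIsaReads:
    """Reads, toy genome, and truth tables from one simulation."""

    reads: list[tuple[str, str]]  # (read_id, sequence)
    genome: dict[str, str]
    ltr_seq: str
    linker_seq: str
    vector_seq: str
    truth_sites: pd.DataFrame  # chromosome, locus (0-based), strand, read_count
    truth_reads: pd.DataFrame  # read_id, site_index (-1 for contaminants)
    config: SimIsaConfig


def _mutate(seq: str, rate: float, indel_rate: float, rng: np.random.Generator) -> str:
    if rate <= 0 and indel_rate <= 0:
        return seq
    out = []
    for base in seq:
        if indel_rate > 0 and rng.random() < indel_rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(str(rng.choice(_BASES)))  # insertion before base
        if rate > 0 and rng.random() < rate:
            out.append(str(rng.choice(_BASES[_BASES != base])))
        else:
            out.append(base)
    return "".join(out)


def simulate_isa_reads(config: SimIsaConfig, chromosome: str = "chr1") -> SimulatedIsaReads:
    """Generate junction reads and their planted-site truth table.

    The site locus is the 0-based position of the first genomic base
    after the LTR junction; a '+' site reads rightward from the locus, a
    '-' site reads leftward along the reverse complement. Loci keep a
    margin of the maximal fragment length from the chromosome ends so
    every fragment stays in bounds.
    """
    rng_genome, rng_sites, rng_reads = _streams(config.seed, 3)
    genome = random_dna(config.genome_length, rng_genome)
    ltr = config.ltr_seq or random_dna(60, rng_genome)
    linker = config.linker_seq or random_dna(24, rng_genome)
    vector = config.vector_seq or random_dna(1000, rng_genome)

    lo, hi = config.fragment_length_range
    margin = hi
    if config.genome_length <= 2 * margin:
        raise InvalidConfigError("genome too short for the fragment length range")
    loci = rng_sites.choice(
        np.arange(margin, config.genome_length - margin),
        size=config.n_sites,
        replace=False,
    )
    loci.sort()
    strands = rng_sites.choice(["+", "-"], size=config.n_sites)
    n_reads = np.maximum(
        rng_sites.poisson(config.mean_reads_per_site, size=config.n_sites),
        config.min_reads_per_site,
    )

    from .alignment import revcomp

    reads: list[tuple[str, str]] = []
    read_truth: list[tuple[str, int]] = []
    counter = 0
    for j in range(config.n_sites):
        locus, strand = int(loci[j]), strands[j]
        for _ in range(int(n_reads[j])):
            flen = int(rng_reads.integers(lo, hi + 1))
            if strand == "+":
                fragment = genome[locus : locus + flen]
            else:
                fragment = revcomp(genome[locus - flen + 1 : locus + 1])
            if config.contaminant_fraction > 0 and rng_reads.random() < config.contaminant_fraction:
                vstart = int(rng_reads.integers(0, max(1, len(vector) - flen)))
                fragment = vector[vstart : vstart + flen]
                site_index = -1
            else:
                site_index = j
            raw = ltr + fragment + linker
            read_id = f"read{counter:06d}"
            reads.append(
                (read_id, _mutate(raw, config.substitution_rate, config.indel_rate, rng_reads))
            )
            read_truth.append((read_id, site_index))
            counter += 1

    truth_reads = pd.DataFrame(read_truth, columns=["read_id", "site_index"])
    genomic_counts = truth_reads[truth_reads["site_index"] >= 0].groupby("site_index").size()
    truth_sites = pd.DataFrame(
        {
            "site_index": np.arange(config.n_sites),
            "chromosome": chromosome,
            "locus": loci,
            "strand": strands,
            "read_count": genomic_counts.reindex(np.arange(config.n_sites), fill_value=0).to_numpy(),
        }
    )
    return SimulatedIsaReads(
        reads=reads,
        genome={chromosome: genome},
        ltr_seq=ltr,
        linker_seq=linker,
        vector_seq=vector,
        truth_sites=truth_sites,
        truth_reads=truth_reads,
        config=config,
    )


@dataclass(frozen=True)
class SimCellConfig:
    """Configuration of the single-cell table generator.

    ``irf_cluster_bias`` is the probability that an infusion-product cell
    of a planted expanding (increasing) clonotype is assigned to one of
    the ``designated_clusters``; all other infusion-product cells follow
    ``cluster_mixture``. ``qc_outlier_rate`` of cells are planted to
    violate exactly one QC gate (gene count < 200, mito fraction > 20%,
    or > 40,000 UMIs).
    """

    n_cells_per_timepoint: int = 2000
    n_clusters: int = 4
    cluster_mixture: tuple[float, ...] | None = None
    designated_clusters: tuple[int, ...] = (2, 4)
    irf_cluster_bias: float = 0.85
    qc_outlier_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_per_timepoint < 1 or self.n_clusters < 1:
            raise InvalidConfigError("cell and cluster counts must be positive")
        if not 0.0 <= self.irf_cluster_bias <= 1.0:
            raise InvalidConfigError("irf_cluster_bias must be in [0, 1]")
        if not 0.0 <= self.qc_outlier_rate <= 1.0:
            raise InvalidConfigError("qc_outlier_rate must be in [0, 1]")
        mix = self.mixture
        if len(mix) != self.n_clusters or abs(sum(mix) - 1.0) > 1e-9 or min(mix) < 0:
            raise InvalidConfigError("cluster mixture must be a distribution over clusters")
        if not set(self.designated_clusters) <= set(range(1, self.n_clusters + 1)):
            raise InvalidConfigError("designated clusters must be valid cluster labels")

    @property
    def mixture(self) -> tuple[float, ...]:
        if self.cluster_mixture is None:
            return (1.0 / self.n_clusters,) * self.n_clusters
        return self.cluster_mixture


def simulate_cell_table(
    config: SimCellConfig,
    timeline: SimulatedTimeline,
    patient_id: str = "SIM-1",
) -> pd.DataFrame:
    """Generate a cell-level table consistent with a simulated timeline.

    One row per cell: ``cell_barcode, patient_id, timepoint,
    clonotype_id, cluster_label, n_genes_detected, mito_fraction,
    n_umis``. Clonotypes are drawn per cell from the timeline's true
    frequency vector at that timepoint; cluster labels (1-based) are
    assigned to infusion-product cells only.
    """
    (rng,) = _streams(config.seed, 1)
    clusters = np.arange(1, config.n_clusters + 1)
    mixture = np.asarray(config.mixture)
    designated = np.asarray(sorted(config.designated_clusters))
    non_designated = np.asarray([c for c in clusters if c not in set(designated)])
    non_mix = mixture[non_designated - 1]
    non_mix = non_mix / non_mix.sum() if non_mix.sum() > 0 else None

    expanding = set(
        timeline.truth.loc[timeline.truth["pattern"] == "increasing", "clonotype_id"]
    )
    ids = np.asarray(timeline.clonotype_ids)
    n_tp = timeline.true_freqs.shape[0]

    rows = []
    counter = 0
    for t in range(n_tp):
        label = timepoint_label(t, n_tp)
        draws = rng.choice(ids, size=config.n_cells_per_timepoint, p=timeline.true_freqs[t])
        for ct in draws:
            cluster = pd.NA
            if t == 0:
                if ct in expanding and rng.random() < config.irf_cluster_bias:
                    cluster = int(rng.choice(designated))
                elif ct in expanding and non_mix is not None:
                    cluster = int(rng.choice(non_designated, p=non_mix))
                else:
                    cluster = int(rng.choice(clusters, p=mixture))
            n_genes = int(rng.integers(800, 4001))
            mito = float(rng.uniform(0.01, 0.12))
            umis = int(rng.integers(2000, 20001))
            if config.qc_outlier_rate > 0 and rng.random() < config.qc_outlier_rate:
                kind = rng.integers(0, 3)
                if kind == 0:
                    n_genes = int(rng.integers(0, 200))
                elif kind == 1:
                    mito = float(rng.uniform(0.21, 0.6))
                else:
                    umis = int(rng.integers(40_001, 80_001))
            rows.append(
                (
                    f"CELL{counter:06d}",
                    patient_id,
                    label,
                    ct,
                    cluster,
                    n_genes,
                    mito,
                    umis,
                )
            )
            counter += 1
    return pd.DataFrame(
        rows,
        columns=[
            "cell_barcode",
            "patient_id",
            "timepoint",
            "clonotype_id",
            "cluster_label",
            "n_genes_detected",
            "mito_fraction",
            "n_umis",
        ],
    )


def write_repertoire_tsv(sample: RepertoireSample, truth: pd.DataFrame, path) -> None:
    """Write one sample as a clonotype TSV (clonotype_id, cdr3_nt, count, productive)."""
    cdr3 = dict(zip(truth["clonotype_id"], truth["cdr3_nt"]))
    df = pd.DataFrame(
        {
            "clonotype_id": list(sample.counts),
            "cdr3_nt": [cdr3.get(c, "") for c in sample.counts],
            "count": list(sample.counts.values()),
            "productive": True,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_reads_fasta(reads: Sequence[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f">{read_id}\n{seq}\n")


def write_genome_fasta(genome: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
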