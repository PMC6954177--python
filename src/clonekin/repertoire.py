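"""Diversity, overlap, and rank statistics on TCRB clonotype count tables.

A repertoire sample is the clonotype -> template-count table obtained by
high-throughput sequencing of the TCRB CDR3 region in a sorted cell
population (here CD8+ CAR-T cells from the infusion product or blood).
Clone frequency is the fraction of total templates occupied by a clonotype.

The statistics implemented here are the ones used to characterise how the
CAR-T repertoire changes after adoptive transfer:

* Shannon entropy ``H = -sum p_i ln p_i`` as the clonal-diversity index,
  compared across samples of unequal depth by repeated downsampling to a
  common depth and taking the median entropy.
* The Morisita-Horn overlap index between two repertoires, 0 for disjoint
  clonotype sets and exactly 1 for identical composition.
* Top-N clonotype fractions and capped competition ranks used to track
  dominant clones over time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DownsampleDepthError, EmptyRepertoireError

__all__ = [
    "RepertoireSample",
    "shannon_entropy",
    "median_downsampled_entropy",
    "morisita_index",
    "top_n_fraction",
    "rank_clonotypes",
    "rank_tracks",
]


@dataclass
class RepertoireSample:
    """Clonotype -> count table for one patient/timepoint/compartment.

    Parameters
    ----------
    counts
        Mapping from clonotype identifier to a non-negative integer
        template count. Zero-count entries are dropped on construction.
    patient_id, timepoint, compartment
        Free-form labels; ``timepoint`` is typically one of
        ``IP``/``early``/``late``/``very_late`` or a day number, and
        ``compartment`` distinguishes CAR+ from CAR- sorted cells.
    """

    counts: dict[str, int]
    patient_id: str | None = None
    timepoint: str | None = None
    compartment: str | None = None

    def __post_init__(self) -> None:
        cleaned: dict[str, int] = {}
        for clonotype, count in self.counts.items():
            if count < 0 or int(count) != count:
                raise ValueError(
                    f"count for {clonotype!r} must be a non-negative integer, got {count!r}"
                )
            if count > 0:
                cleaned[str(clonotype)] = int(count)
        self.counts = cleaned

    @property
    def total(self) -> int:
        """Total number of templates in the sample."""
        return sum(self.counts.values())

    @property
    def richness(self) -> int:
        """Number of distinct clonotypes with at least one template."""
        return len(self.counts)

    def frequencies(self) -> pd.Series:
        """Relative clonotype frequencies, summing to 1."""
        _require_nonempty(self)
        s = pd.Series(self.counts, dtype=float)
        return s / s.sum()

    def frequency(self, clonotype_id: str) -> float:
        """Relative frequency of one clonotype (0 if absent)."""
        _require_nonempty(self)
        return self.counts.get(clonotype_id, 0) / self.total


def _require_nonempty(sample: RepertoireSample) -> None:
    if sample.total < 1:
        raise EmptyRepertoireError("repertoire sample contains no templates")


def _count_vector(sample: RepertoireSample) -> np.ndarray:
    return np.asarray(list(sample.counts.values()), dtype=np.int64)


def shannon_entropy(sample: RepertoireSample, *, base: float | None = None) -> float:
    """Shannon entropy of the clonotype frequency distribution.

    ``H = -sum_i p_i log p_i`` over clonotypes with ``p_i > 0``. Natural
    log by default; pass ``base=2`` for bits.
    """
    _require_nonempty(sample)
    counts = _count_vector(sample)
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    # clamp the -0.0 that a single-clonotype sample produces
    return max(h, 0.0)


def median_downsampled_entropy(
    sample: RepertoireSample,
    depth: int,
    n_reps: int = 1000,
    seed: int | np.random.Generator | None = None,
    *,
    base: float | None = None,
) -> float:
    """Median Shannon entropy over repeated without-replacement subsamples.

    Samples of unequal sequencing depth are compared by downsampling each
    to a common number of templates (the minimum across the samples being
    compared), ``n_reps`` times, and summarising each sample by the median
    entropy of its subsamples. Subsampling without replacement from the
    count table is a multivariate hypergeometric draw.

    Parameters
    ----------
    depth
        Number of templates per subsample; must not exceed the sample total.
    n_reps
        Number of independent subsamples (1000 by default).
    seed
        Integer seed or an existing :class:`numpy.random.Generator`.
    """
    _require_nonempty(sample)
    counts = _count_vector(sample)
    total = int(counts.sum())
    if depth < 1:
        raise DownsampleDepthError(f"depth must be >= 1, got {depth}")
    if depth > total:
        raise DownsampleDepthError(
            f"downsample depth {depth} exceeds sample total {total}"
        )
    rng = np.random.default_rng(seed)
    log_base = math.log(base) if base is not None else 1.0
    entropies = np.empty(n_reps)
    for r in range(n_reps):
        sub = rng.multivariate_hypergeometric(counts, depth)
        sub = sub[sub > 0]
        p = sub / depth
        entropies[r] = -(p * np.log(p)).sum() / log_base
    return float(np.median(entropies))


def morisita_index(a: RepertoireSample, b: RepertoireSample) -> float:
    """Morisita-Horn overlap between two repertoires.

    ``C = 2 sum_i p_i q_i / (sum_i p_i^2 + sum_i q_i^2)`` on relative
    frequencies, where the sum runs over the union of clonotypes. Bounded
    in [0, 1]: 0 when no clonotype is shared, exactly 1 when both samples
    contain the same clonotypes in the same proportions.
    """
    _require_nonempty(a)
    _require_nonempty(b)
    ids = sorted(set(a.counts) | set(b.counts))
    ta, tb = a.total, b.total
    p = np.asarray([a.counts.get(i, 0) for i in ids], dtype=float) / ta
    q = np.asarray([b.counts.get(i, 0) for i in ids], dtype=float) / tb
    denom = float(p @ p) + float(q @ q)
    return float(2.0 * (p @ q) / denom)


def top_n_fraction(sample: RepertoireSample, n: int = 10) -> float:
    """Summed relative frequency of the ``n`` highest-count clonotypes.

    Returns 1.0 when richness < ``n``. Ties at the membership boundary are
    broken lexicographically by clonotype id so the result is deterministic.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    _require_nonempty(sample)
    ordered = sorted(sample.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    top = sum(count for _, count in ordered[:n])
    return top / sample.total


def rank_clonotypes(
    sample: RepertoireSample,
    cap: int = 100,
    clonotypes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Competition ranks and relative frequencies of clonotypes.

    Ranks are assigned by descending count; tied counts share the minimum
    rank of the tied block ("1224" ranking). Ranks above ``cap`` are
    reported as ``cap + 1``, matching the convention of plotting every
    rank > 100 at position 101. When ``clonotypes`` is given, clonotypes
    absent from the sample are included with rank ``cap + 1`` and
    frequency 0, which is how a clone is tracked across samples where it
    was not detected.

    Returns
    -------
    DataFrame indexed by clonotype_id with columns ``rank`` and ``frequency``.
    """
    _require_nonempty(sample)
    counts = pd.Series(sample.counts, dtype=float)
    ranks = counts.rank(method="min", ascending=False).astype(int)
    ranks[ranks > cap] = cap + 1
    freqs = counts / counts.sum()
    df = pd.DataFrame({"rank": ranks, "frequency": freqs})
    if clonotypes is not None:
        wanted = list(dict.fromkeys(clonotypes))
        df = df.reindex(wanted)
        df["rank"] = df["rank"].fillna(cap + 1).astype(int)
        df["frequency"] = df["frequency"].fillna(0.0)
    df.index.name = "clonotype_id"
    return df


def rank_tracks(
    samples: Sequence[RepertoireSample],
    clonotypes: Iterable[str],
    cap: int = 100,
) -> pd.DataFrame:
    """Track ranks and frequencies of chosen clonotypes across samples.

    One row per clonotype; per-sample ``rank_<tp>`` and ``freq_<tp>``
    columns named by each sample's timepoint label (or position if the
    label is missing).
    """
    wanted = list(dict.fromkeys(clonotypes))
    out = pd.DataFrame(index=pd.Index(wanted, name="clonotype_id"))
    for i, sample in enumerate(samples):
        label = sample.timepoint if sample.timepoint is not None else str(i)
        ranked = rank_clonotypes(sample, cap=cap, clonotypes=wanted)
        out[f"rank_{label}"] = ranked["rank"]
        out[f"freq_{label}"] = ranked["frequency"]
    return out
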