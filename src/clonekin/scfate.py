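"""Single-cell QC filtering and clonotype-fate (IRF/DRF) analysis.

Paired V(D)J sequencing assigns each single CD8+ CAR-T cell a clonotype,
which lets the post-infusion fate of each infused clone be read off cell
counts. A clonotype whose relative abundance is significantly higher at
the early post-infusion timepoint than in the infusion product is an IRF
(increased relative frequency) clonotype; significantly lower, a DRF
(decreased relative frequency) clonotype. Significance is a two-sided
Fisher exact test on the 2x2 table

    [[cells of clonotype, other cells]   (infusion product)
     [cells of clonotype, other cells]]  (early timepoint)

with Benjamini-Hochberg control at FDR 5% across clonotypes.

Downstream summaries link the labels to the transcriptional clusters of
the infusion product (which clusters IRF clones come from) and to
persistence (what fraction of IRF/DRF clonotypes is still detected at
the late and very-late timepoints).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Set

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .errors import EmptyTimepointError

__all__ = [
    "QC_MIN_GENES",
    "QC_MAX_MITO",
    "QC_MAX_UMIS",
    "qc_filter",
    "clonotype_fate_test",
    "fate_summary",
    "persistence_proportions",
    "cluster_attribution",
    "detected_cluster_composition",
]

# Cell-level QC gates: cells with fewer detected genes, a higher
# mitochondrial fraction, or more UMIs than these are removed.
QC_MIN_GENES = 200
QC_MAX_MITO = 0.20
QC_MAX_UMIS = 40_000

_CELL_QC_COLUMNS = ("n_genes_detected", "mito_fraction", "n_umis")


def qc_filter(cells: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Remove low-quality cells; returns (kept cells, number removed).

    A cell is kept iff ``n_genes_detected >= 200``, ``mito_fraction <=
    0.20`` and ``n_umis <= 40000``. Idempotent.
    """
    for col in _CELL_QC_COLUMNS:
        if col not in cells.columns:
            raise KeyError(f"cell table lacks required QC column {col!r}")
    keep = (
        (cells["n_genes_detected"] >= QC_MIN_GENES)
        & (cells["mito_fraction"] <= QC_MAX_MITO)
        & (cells["n_umis"] <= QC_MAX_UMIS)
    )
    return cells.loc[keep].copy(), int((~keep).sum())


def _clonotype_counts(cells: pd.DataFrame) -> pd.Series:
    with_ct = cells.dropna(subset=["clonotype_id"])
    return with_ct.groupby("clonotype_id").size()


def clonotype_fate_test(
    ip_cells: pd.DataFrame,
    early_cells: pd.DataFrame,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Label clonotypes IRF/DRF/unchanged between infusion product and early.

    Cells without a clonotype are ignored. Every clonotype seen at either
    timepoint is tested with a two-sided Fisher exact test on cell counts;
    p-values are Benjamini-Hochberg adjusted across clonotypes, and a
    clonotype is labelled IRF (DRF) when its adjusted q <= ``fdr`` and its
    early-timepoint cell proportion is above (below) its infusion-product
    proportion.

    Returns
    -------
    DataFrame with one row per tested clonotype: ``ip_count``,
    ``early_count``, ``ip_total``, ``early_total``, ``odds_direction``
    (up/down/flat), ``p_value``, ``q_value``, ``label``.
    """
    ip_counts = _clonotype_counts(ip_cells)
    early_counts = _clonotype_counts(early_cells)
    n_ip = int(ip_counts.sum())
    n_early = int(early_counts.sum())
    if n_ip == 0 or n_early == 0:
        raise EmptyTimepointError(
            "fate test needs clonotype-bearing cells at both timepoints"
        )
    clonotypes = sorted(set(ip_counts.index) | set(early_counts.index))

    records = []
    for ct in clonotypes:
        k_ip = int(ip_counts.get(ct, 0))
        k_early = int(early_counts.get(ct, 0))
        table = [[k_ip, n_ip - k_ip], [k_early, n_early - k_early]]
        p = float(fisher_exact(table, alternative="two-sided")[1])
        prop_ip, prop_early = k_ip / n_ip, k_early / n_early
        if prop_early > prop_ip:
            direction = "up"
        elif prop_early < prop_ip:
            direction = "down"
        else:
            direction = "flat"
        records.append((ct, k_ip, k_early, direction, p))

    df = pd.DataFrame.from_records(
        records,
        columns=["clonotype_id", "ip_count", "early_count", "odds_direction", "p_value"],
    ).set_index("clonotype_id")
    df.insert(2, "ip_total", n_ip)
    df.insert(3, "early_total", n_early)
    df["q_value"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    significant = df["q_value"] <= fdr
    df["label"] = "unchanged"
    df.loc[significant & (df["odds_direction"] == "up"), "label"] = "IRF"
    df.loc[significant & (df["odds_direction"] == "down"), "label"] = "DRF"
    return df


def fate_summary(labels: pd.DataFrame) -> pd.DataFrame:
    """One-line-per-label summary of a fate-test result table."""
    return (
        labels.groupby("label")
        .agg(
            n_clonotypes=("p_value", "size"),
            ip_cells=("ip_count", "sum"),
            early_cells=("early_count", "sum"),
            min_q=("q_value", "min"),
        )
        .sort_index()
    )


def persistence_proportions(
    labels: pd.DataFrame | Mapping[str, str],
    detected: Mapping[str, Set[str]],
) -> pd.DataFrame:
    """Fraction of IRF/DRF clonotypes still detected at later timepoints.

    Parameters
    ----------
    labels
        Fate-test result frame (uses its ``label`` column) or a plain
        clonotype -> label mapping.
    detected
        Mapping timepoint name -> set of clonotypes detected there (a
        clonotype counts as detected when >= 1 QC-passing cell carries it).

    Returns
    -------
    Long DataFrame (label, timepoint, n_detected, n_total, percent) with
    ``percent = round(100 * n_detected / n_total)``; NA for an empty
    label class rather than 0.
    """
    if isinstance(labels, pd.DataFrame):
        label_map = labels["label"]
    else:
        label_map = pd.Series(dict(labels))
    rows = []
    for label in ("IRF", "DRF"):
        members = set(label_map.index[label_map == label])
        for timepoint, present in detected.items():
            n_total = len(members)
            if n_total == 0:
                rows.append((label, timepoint, pd.NA, 0, pd.NA))
                continue
            n_det = len(members & set(present))
            rows.append((label, timepoint, n_det, n_total, round(100 * n_det / n_total)))
    return pd.DataFrame(
        rows, columns=["label", "timepoint", "n_detected", "n_total", "percent"]
    )


def _ip_cells_with_label(
    labels: pd.DataFrame | Mapping[str, str], ip_cells: pd.DataFrame
) -> pd.DataFrame:
    if isinstance(labels, pd.DataFrame):
        label_map = labels["label"]
    else:
        label_map = pd.Series(dict(labels))
    cells = ip_cells.dropna(subset=["clonotype_id", "cluster_label"]).copy()
    cells["label"] = cells["clonotype_id"].map(label_map)
    return cells


def cluster_attribution(
    labels: pd.DataFrame | Mapping[str, str],
    ip_cells: pd.DataFrame,
) -> pd.DataFrame:
    """Per-cluster fractions of infusion-product cells of IRF/DRF clones.

    Among infusion-product cells whose clonotype carries a given fate
    label, the fraction sitting in each transcriptional cluster; fractions
    sum to 1 per label. This is the quantity that shows which infused
    clusters the expanding clones originate from.
    """
    cells = _ip_cells_with_label(labels, ip_cells)
    cells = cells[cells["label"].isin(["IRF", "DRF"])]
    if cells.empty:
        raise EmptyTimepointError("no labelled, clustered infusion-product cells")
    counts = cells.groupby(["label", "cluster_label"]).size().unstack(fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)


def detected_cluster_composition(
    ip_cells: pd.DataFrame,
    detected: Mapping[str, Set[str]],
) -> pd.DataFrame:
    """Cluster composition of infusion-product cells by later detection.

    For each later timepoint, infusion-product cells are partitioned by
    whether their clonotype is detected at that timepoint ("yes"/"no");
    within each partition the per-cluster cell fractions sum to 1. A
    rising cluster share in the "yes" partition over successive
    timepoints indicates preferential persistence of clones from that
    cluster.

    Returns
    -------
    Long DataFrame (timepoint, detected, cluster_label, n_cells, fraction).
    """
    cells = ip_cells.dropna(subset=["clonotype_id", "cluster_label"])
    rows = []
    for timepoint, present in detected.items():
        is_detected = cells["clonotype_id"].isin(set(present))
        for flag, part in (("yes", cells[is_detected]), ("no", cells[~is_detected])):
            if part.empty:
                continue
            counts = part.groupby("cluster_label").size()
            total = int(counts.sum())
            for cluster, n in counts.items():
                rows.append((timepoint, flag, cluster, int(n), n / total))
    return pd.DataFrame(
        rows, columns=["timepoint", "detected", "cluster_label", "n_cells", "fraction"]
    )
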