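"""Readers and writers for the plain-text formats the pipeline consumes.

Clonotype tables are tab-separated with columns ``clonotype_id, cdr3_nt,
count`` and an optional boolean ``productive`` column (honoured when
present: non-productive rows are dropped). AIRR-style column aliases are
accepted (``junction`` for cdr3_nt, ``duplicate_count`` for count).
FASTA goes through Biopython; patient metadata is YAML; cell tables are
CSV; gene models are BED12.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from .kinetics import PatientMeta
from .repertoire import RepertoireSample

__all__ = [
    "read_repertoire_tsv",
    "write_metrics_tsv",
    "write_morisita_matrix",
    "read_fasta",
    "read_single_fasta",
    "read_patient_meta",
    "read_cell_table",
]

_CDR3_ALIASES = ("cdr3_nt", "junction")
_COUNT_ALIASES = ("count", "duplicate_count")
_TRUTHY = {"true", "t", "yes", "y", "1", "productive"}


def _pick(columns, aliases, path):
    for alias in aliases:
        if alias in columns:
            return alias
    raise ValueError(f"{path}: none of the columns {aliases} found (got {list(columns)})")


def read_repertoire_tsv(
    path,
    patient_id: str | None = None,
    timepoint: str | None = None,
    compartment: str | None = None,
) -> RepertoireSample:
    """Load a clonotype count table into a :class:`RepertoireSample`.

    Rows flagged non-productive are dropped; rows without a productive
    column are assumed pre-filtered to productive rearrangements. When no
    ``clonotype_id`` column exists the CDR3 nucleotide sequence is the
    clonotype key. Duplicate clonotype ids have their counts summed.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    count_col = _pick(df.columns, _COUNT_ALIASES, path)
    if "clonotype_id" in df.columns:
        id_col = "clonotype_id"
    else:
        id_col = _pick(df.columns, _CDR3_ALIASES, path)
    if "productive" in df.columns:
        keep = df["productive"].astype(str).str.strip().str.lower().isin(_TRUTHY)
        df = df.loc[keep]
    counts = (
        df.assign(**{count_col: pd.to_numeric(df[count_col]).astype(int)})
        .groupby(id_col)[count_col]
        .sum()
    )
    return RepertoireSample(
        counts=counts.to_dict(),
        patient_id=patient_id,
        timepoint=timepoint,
        compartment=compartment,
    )


def write_metrics_tsv(metrics: pd.DataFrame, path) -> None:
    """Write the per-timepoint diversity metrics table."""
    metrics.to_csv(path, sep="\t", index=False)


def write_morisita_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a pairwise Morisita-Horn overlap matrix."""
    matrix.to_csv(path, sep="\t", index=True)


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> {record id: uppercase sequence}, order preserved."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_single_fasta(path) -> str:
    """Read a FASTA expected to hold exactly one sequence (e.g. the LTR)."""
    seqs = read_fasta(path)
    if len(seqs) != 1:
        raise ValueError(f"{path}: expected exactly one sequence, found {len(seqs)}")
    return next(iter(seqs.values()))


def read_patient_meta(path) -> PatientMeta:
    """Load patient enumeration metadata from YAML.

    Expected keys: ``patient_id, weight, sex, infused_cd8_car_dose,
    abs_car_counts`` (mapping day -> cells/ul).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PatientMeta(
        patient_id=str(raw["patient_id"]),
        weight=float(raw["weight"]),
        sex=str(raw["sex"]),
        infused_cd8_car_dose=float(raw["infused_cd8_car_dose"]),
        abs_car_counts={int(k): float(v) for k, v in raw.get("abs_car_counts", {}).items()},
    )


def read_cell_table(path) -> pd.DataFrame:
    """Load a cell-level CSV table, normalising missing clonotype/cluster to NA."""
    df = pd.read_csv(path)
    for col in ("clonotype_id", "cluster_label"):
        if col in df.columns:
            df[col] = df[col].replace({"": pd.NA, "NA": pd.NA})
    return df
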