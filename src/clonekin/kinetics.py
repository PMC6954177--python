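"""Absolute clone counts in blood and per-clone kinetic classification.

Relative clonotype frequencies say nothing about whether a clone is
actually growing or shrinking in the patient; for that the frequency is
converted to an absolute count of cells per microlitre of blood:

* at post-infusion timepoints, clone count = clonotype frequency x the
  measured absolute CD8+ CAR-T cell count (cells/ul) on that day;
* at day 0, no measurement exists, so the infused dose is assumed evenly
  distributed through the estimated total blood volume
  (``BloodVol = weight x 65 ml/kg`` for women, ``x 75 ml/kg`` for men),
  and the clone's share is its frequency in the infusion product.

Tracks over (day 0, early, late) are classified into the three observed
kinetic regimes — progressively increasing, transiently increasing then
contracting, progressively decreasing — with an explicit fold-change rule
(2-fold by default), since the regimes are defined visually in the source
material. The rule is scale invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidMetaError
from .repertoire import RepertoireSample, rank_clonotypes

__all__ = [
    "PatientMeta",
    "AVG_BLOOD_VOL_ML_PER_KG",
    "blood_volume",
    "day0_clone_count",
    "clone_abs_count",
    "classify_kinetics",
    "build_clone_tracks",
]

#: Average blood volume per kg body weight, by sex.
AVG_BLOOD_VOL_ML_PER_KG = {"female": 65.0, "male": 75.0}


@dataclass
class PatientMeta:
    """Enumeration metadata needed to convert frequencies to absolute counts.

    Attributes
    ----------
    weight : float
        Body weight in kg; must be positive.
    sex : str
        ``"female"`` or ``"male"`` (selects the blood-volume constant).
    infused_cd8_car_dose : float
        Number of CD8+ CAR-T cells infused.
    abs_car_counts : dict[int, float]
        Measured absolute CD8+ CAR-T cells per ul blood, keyed by day
        post infusion.
    """

    patient_id: str
    weight: float
    sex: str
    infused_cd8_car_dose: float
    abs_car_counts: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise InvalidMetaError(f"weight must be positive, got {self.weight}")
        if self.sex not in AVG_BLOOD_VOL_ML_PER_KG:
            raise InvalidMetaError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.infused_cd8_car_dose < 0:
            raise InvalidMetaError("infused dose must be >= 0")
        if any(v < 0 for v in self.abs_car_counts.values()):
            raise InvalidMetaError("absolute CAR-T counts must be >= 0")

    @property
    def blood_volume_ml(self) -> float:
        return blood_volume(self.weight, self.sex)


def blood_volume(weight: float, sex: str) -> float:
    """Estimated total blood volume in ml: weight x 65 (female) or 75 (male)."""
    if weight <= 0:
        raise InvalidMetaError(f"weight must be positive, got {weight}")
    try:
        per_kg = AVG_BLOOD_VOL_ML_PER_KG[sex]
    except KeyError:
        raise InvalidMetaError(f"sex must be 'female' or 'male', got {sex!r}") from None
    return weight * per_kg


def day0_clone_count(rel_freq: float, dose: float, blood_volume_ml: float) -> float:
    """Modelled day-0 clone count (cells/ul) immediately after infusion.

    The infused dose is assumed uniformly distributed in blood, so a clone
    at relative frequency ``f`` in the infusion product contributes
    ``dose * f / (blood_volume_ml * 1000)`` cells per microlitre.
    """
    if not 0.0 <= rel_freq <= 1.0:
        raise ValueError(f"relative frequency must be in [0, 1], got {rel_freq}")
    if blood_volume_ml <= 0:
        raise InvalidMetaError(f"blood volume must be positive, got {blood_volume_ml}")
    return dose * rel_freq / (blood_volume_ml * 1000.0)


def clone_abs_count(rel_freq: float, car_count: float) -> float:
    """Clone count in cells/ul: clonotype frequency x absolute CAR-T count."""
    if not 0.0 <= rel_freq <= 1.0:
        raise ValueError(f"relative frequency must be in [0, 1], got {rel_freq}")
    if car_count < 0:
        raise ValueError(f"absolute CAR-T count must be >= 0, got {car_count}")
    return rel_freq * car_count


def classify_kinetics(counts: Sequence[float], fold_threshold: float = 2.0) -> str:
    """Classify a clone's absolute-count track into a kinetic pattern.

    ``counts`` is an ordered track with at least (day 0, early, late);
    longer tracks are classified on (first, second, last). With
    ``fold = fold_threshold``:

    * ``increasing``  — early > day0*fold and late >= early;
    * ``transient``   — early > day0*fold and late < early/fold;
    * ``decreasing``  — early <= day0/fold;
    * ``indeterminate`` otherwise (including an all-zero track).

    The rule is invariant to multiplying the whole track by a positive
    constant, so it can be applied to relative frequencies when the total
    CAR-T count is stable.
    """
    if len(counts) < 3:
        raise InsufficientDataError(
            f"need >= 3 timepoints (day0, early, late), got {len(counts)}"
        )
    if fold_threshold <= 1:
        raise ValueError(f"fold_threshold must be > 1, got {fold_threshold}")
    if any(c < 0 for c in counts):
        raise ValueError("absolute counts must be >= 0")
    day0, early, late = float(counts[0]), float(counts[1]), float(counts[-1])
    if day0 == early == late == 0.0:
        return "indeterminate"
    fold = float(fold_threshold)
    if early > day0 * fold:
        if late >= early:
            return "increasing"
        if late < early / fold:
            return "transient"
        return "indeterminate"
    if early <= day0 / fold:
        return "decreasing"
    return "indeterminate"


def build_clone_tracks(
    ip_sample: RepertoireSample,
    post_samples: Mapping[int, RepertoireSample],
    meta: PatientMeta,
    top_n: int = 30,
    fold_threshold: float = 2.0,
) -> pd.DataFrame:
    """Absolute-count tracks and kinetic labels for the dominant clones.

    Clones tracked are the union of the top-``top_n`` ranked clonotypes of
    the infusion product and of every post-infusion sample. Day 0 counts
    come from the infusion-dose model; post-infusion counts from the
    measured absolute CAR-T count for that day (``meta.abs_car_counts``).

    Parameters
    ----------
    post_samples
        Mapping day (int > 0) -> repertoire sample drawn on that day.

    Returns
    -------
    DataFrame with one row per tracked clonotype: ``abs_day0``, one
    ``abs_day<d>`` column per post-infusion day in ascending order, and
    ``pattern``.
    """
    days = sorted(post_samples)
    if len(days) < 2:
        raise InsufficientDataError("need at least two post-infusion samples")
    missing = [d for d in days if d not in meta.abs_car_counts]
    if missing:
        raise InvalidMetaError(f"no absolute CAR-T count for day(s) {missing}")

    tracked: list[str] = []
    for sample in [ip_sample, *(post_samples[d] for d in days)]:
        ranked = rank_clonotypes(sample, cap=top_n)
        tracked.extend(ranked.index[ranked["rank"] <= top_n])
    tracked = list(dict.fromkeys(tracked))

    vol = meta.blood_volume_ml
    rows = {}
    for ct in tracked:
        track = [day0_clone_count(ip_sample.frequency(ct), meta.infused_cd8_car_dose, vol)]
        track += [
            clone_abs_count(post_samples[d].frequency(ct), meta.abs_car_counts[d])
            for d in days
        ]
        rows[ct] = track + [classify_kinetics(track, fold_threshold=fold_threshold)]

    columns = ["abs_day0"] + [f"abs_day{d}" for d in days] + ["pattern"]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    df.index.name = "clonotype_id"
    return df
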