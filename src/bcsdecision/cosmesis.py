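"""Tumor/breast volume ratio and panel-based cosmetic-result scoring.

The continuous predictor of the cosmesis model is the tumor volume divided
by the breast volume, multiplied by 1000 (the "TV/BV ratio").  The observed
outcome is a dichotomised multi-rater panel score: a panel of raters scores
a fixed questionnaire (11 items, each 0 = excellent ... 3 = poor) from
post-treatment photographs, and the unweighted mean over all (rater, item)
cells is cut at 1.5 — a mean at or below 1.5 counts as a *good* cosmetic
result, above 1.5 as *poor*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "TumorLocation",
    "PatientPresentation",
    "PanelAssessment",
    "CosmesisOutcome",
    "GOOD_COSMESIS_CUTOFF",
    "tv_bv_ratio",
    "panel_score",
    "read_presentations",
    "read_panel_scores",
]

#: Panel mean score at or below this value counts as a good cosmetic result.
GOOD_COSMESIS_CUTOFF = 1.5

#: Admissible item scores (0 = excellent, 1 = good, 2 = moderate, 3 = poor).
_VALID_SCORES = (0, 1, 2, 3)


class TumorLocation(str, Enum):
    """One of the four breast quadrants or a central position.

    ``UPPER_LATERAL`` is the reference category of the logistic model.
    """

    UPPER_LATERAL = "upper_lateral"
    UPPER_MEDIAL = "upper_medial"
    LOWER_LATERAL = "lower_lateral"
    LOWER_MEDIAL = "lower_medial"
    CENTRAL = "central"


@dataclass(frozen=True)
class PatientPresentation:
    """Per-patient model input: tumor volume, breast volume (cm^3), location."""

    tumor_volume: float
    breast_volume: float
    location: TumorLocation

    def __post_init__(self) -> None:
        if not np.isfinite(self.tumor_volume) or self.tumor_volume <= 0:
            raise ValueError(f"tumor_volume must be positive, got {self.tumor_volume}")
        if not np.isfinite(self.breast_volume) or self.breast_volume <= 0:
            raise ValueError(f"breast_volume must be positive, got {self.breast_volume}")
        if self.tumor_volume > self.breast_volume:
            raise ValueError(
                "tumor_volume cannot exceed breast_volume "
                f"({self.tumor_volume} > {self.breast_volume})"
            )
        if not isinstance(self.location, TumorLocation):
            object.__setattr__(self, "location", TumorLocation(self.location))


@dataclass(frozen=True)
class PanelAssessment:
    """A (rater x item) grid of 4-point scores; ``nan`` marks a missing cell."""

    scores: np.ndarray
    n_items: int = 11
    n_raters: int = field(default=6)

    def __post_init__(self) -> None:
        arr = np.asarray(self.scores, dtype=float)
        if arr.ndim != 2:
            raise ValueError("scores must be a 2-D (rater x item) grid")
        object.__setattr__(self, "scores", arr)
        object.__setattr__(self, "n_raters", arr.shape[0])
        object.__setattr__(self, "n_items", arr.shape[1])
        observed = arr[~np.isnan(arr)]
        if not np.isin(observed, _VALID_SCORES).all():
            bad = observed[~np.isin(observed, _VALID_SCORES)]
            raise ValueError(f"scores must be in {{0,1,2,3}}; got {bad[:5]}")


@dataclass(frozen=True)
class CosmesisOutcome:
    """Mean panel score with its dichotomised label."""

    mean_score: float
    label: str  # "good" | "poor"

    def __post_init__(self) -> None:
        expected = "good" if self.mean_score <= GOOD_COSMESIS_CUTOFF else "poor"
        if self.label != expected:
            raise ValueError(
                f"label {self.label!r} inconsistent with mean {self.mean_score} "
                f"and cutoff {GOOD_COSMESIS_CUTOFF}"
            )


def tv_bv_ratio(presentation: PatientPresentation) -> float:
    """Tumor volume / breast volume x 1000 (dimensionless, in (0, 1000])."""
    return presentation.tumor_volume / presentation.breast_volume * 1000.0


def panel_score(assessment: PanelAssessment) -> CosmesisOutcome:
    """Dichotomise the unweighted mean over all non-missing panel cells.

    Raters and items carry equal weight; missing cells are excluded from the
    mean.  A mean at or below 1.5 is labelled ``good``, otherwise ``poor``.
    """
    arr = assessment.scores
    if arr.size == 0 or np.isnan(arr).all():
        raise ValueError("panel grid has no observed scores")
    mean = float(np.nanmean(arr))
    label = "good" if mean <= GOOD_COSMESIS_CUTOFF else "poor"
    return CosmesisOutcome(mean_score=mean, label=label)


def read_presentations(path) -> dict[str, PatientPresentation]:
    """Read patient presentations from a tidy CSV.

    Expected columns: patient_id, tumor_volume_cm3, breast_volume_cm3,
    location (lowercase token, e.g. ``upper_lateral``).
    """
    df = pd.read_csv(path)
    required = {"patient_id", "tumor_volume_cm3", "breast_volume_cm3", "location"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"presentation CSV missing columns: {sorted(missing)}")
    return {
        str(row.patient_id): PatientPresentation(
            tumor_volume=float(row.tumor_volume_cm3),
            breast_volume=float(row.breast_volume_cm3),
            location=TumorLocation(row.location),
        )
        for row in df.itertuples(index=False)
    }


def read_panel_scores(path) -> dict[str, PanelAssessment]:
    """Read tidy panel scores (patient_id, rater_id, item_id, score) into grids."""
    df = pd.read_csv(path)
    required = {"patient_id", "rater_id", "item_id", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel CSV missing columns: {sorted(missing)}")
    out: dict[str, PanelAssessment] = {}
    for pid, grp in df.groupby("patient_id"):
        grid = grp.pivot_table(
            index="rater_id", columns="item_id", values="score", aggfunc="first"
        )
        out[str(pid)] = PanelAssessment(scores=grid.to_numpy(dtype=float))
    return out
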