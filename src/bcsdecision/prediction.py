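"""Logistic model for the probability of good cosmesis after breast-conserving surgery.

The model is a plain logistic regression on the TV/BV ratio (continuous,
on the x1000 scale) and tumor location (categorical, upper-lateral
reference):

    logit P(good cosmesis) = intercept + ratio_coef * ratio + offset[location]

The original study printed only derived quantities of its fitted model —
the five per-location ratio cut-offs at the treatment threshold plus one
worked-example prediction — so the default coefficients shipped here are
reconstructed exactly from those six published constraints by solving the
corresponding 6x6 linear system (:func:`calibrate_from_printed_values`).

Also provided: intercept updating for a shifted outcome prevalence,
confusion counts / predictive values at a probability threshold, and a
rank-based AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, logit
from scipy.stats import rankdata

from .cosmesis import PatientPresentation, TumorLocation, tv_bv_ratio

__all__ = [
    "CosmesisLogisticModel",
    "ConfusionCounts",
    "CalibrationError",
    "predict_good_cosmesis",
    "calibrate_from_printed_values",
    "update_intercept",
    "confusion_at_threshold",
    "auc",
]


class CalibrationError(ValueError):
    """The printed constraints do not determine a unique, valid model."""


@dataclass(frozen=True)
class CosmesisLogisticModel:
    """Coefficients of the good-cosmesis logistic model.

    ``location_offsets`` holds the log-odds offset of every location;
    the upper-lateral reference is fixed at 0.  ``ratio_coef`` must be
    negative: a larger tumor relative to the breast can only lower the
    chance of a good cosmetic result.
    """

    intercept: float
    ratio_coef: float
    location_offsets: Mapping[TumorLocation, float]

    def __post_init__(self) -> None:
        offsets = {TumorLocation(k): float(v) for k, v in self.location_offsets.items()}
        offsets.setdefault(TumorLocation.UPPER_LATERAL, 0.0)
        if offsets[TumorLocation.UPPER_LATERAL] != 0.0:
            raise ValueError("upper_lateral is the reference category; its offset must be 0")
        missing = set(TumorLocation) - set(offsets)
        if missing:
            raise ValueError(f"missing location offsets: {sorted(m.value for m in missing)}")
        if not self.ratio_coef < 0:
            raise ValueError(f"ratio_coef must be negative, got {self.ratio_coef}")
        object.__setattr__(self, "location_offsets", offsets)

    def linear_predictor(self, location: TumorLocation, ratio: float) -> float:
        return self.intercept + self.ratio_coef * ratio + self.location_offsets[TumorLocation(location)]

    def predict(self, location: TumorLocation, ratio: float) -> float:
        """P(good cosmesis) at a given location and TV/BV ratio."""
        if ratio <= 0:
            raise ValueError(f"ratio must be positive, got {ratio}")
        return float(expit(self.linear_predictor(location, ratio)))

    def to_dict(self) -> dict[str, float]:
        d = {"intercept": self.intercept, "ratio_coef": self.ratio_coef}
        for loc in TumorLocation:
            if loc is not TumorLocation.UPPER_LATERAL:
                d[f"offset_{loc.value}"] = self.location_offsets[loc]
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "CosmesisLogisticModel":
        offsets = {TumorLocation.UPPER_LATERAL: 0.0}
        for loc in TumorLocation:
            if loc is not TumorLocation.UPPER_LATERAL:
                offsets[loc] = float(d[f"offset_{loc.value}"])
        return cls(
            intercept=float(d["intercept"]),
            ratio_coef=float(d["ratio_coef"]),
            location_offsets=offsets,
        )


def predict_good_cosmesis(
    model: CosmesisLogisticModel, presentation: PatientPresentation
) -> float:
    """Predicted probability of good cosmesis after BCS for one patient."""
    return model.predict(presentation.location, tv_bv_ratio(presentation))


def calibrate_from_printed_values(
    cutoffs: Mapping[TumorLocation, float],
    threshold_prob: float,
    anchor: tuple[TumorLocation, float, float],
) -> CosmesisLogisticModel:
    """Reconstruct the logistic coefficients from published cut-offs and one anchor.

    Each per-location ratio cut-off pins the model to the treatment
    threshold (``P = threshold_prob`` at that location and ratio); the
    anchor ``(location, ratio, probability)`` supplies the sixth equation.
    The six constraints are linear in (intercept, ratio_coef, four
    offsets) on the logit scale, so the solution is exact.

    Raises :class:`CalibrationError` if the system is singular (for
    instance when the anchor ratio coincides with its location's cut-off)
    or the solution violates the model invariants.
    """
    if not 0 < threshold_prob < 1:
        raise ValueError(f"threshold_prob must be in (0,1), got {threshold_prob}")
    cutoffs = {TumorLocation(k): float(v) for k, v in cutoffs.items()}
    if set(cutoffs) != set(TumorLocation):
        raise ValueError("a cut-off is required for each of the five locations")
    anchor_loc, anchor_ratio, anchor_prob = TumorLocation(anchor[0]), float(anchor[1]), float(anchor[2])
    if not 0 < anchor_prob < 1:
        raise ValueError(f"anchor probability must be in (0,1), got {anchor_prob}")

    # Unknown vector: (intercept, ratio_coef, offset_UM, offset_LL, offset_LM, offset_C)
    free = [loc for loc in TumorLocation if loc is not TumorLocation.UPPER_LATERAL]
    col = {loc: 2 + i for i, loc in enumerate(free)}
    rows, rhs = [], []
    for loc in TumorLocation:
        row = np.zeros(6)
        row[0] = 1.0
        row[1] = cutoffs[loc]
        if loc in col:
            row[col[loc]] = 1.0
        rows.append(row)
        rhs.append(logit(threshold_prob))
    row = np.zeros(6)
    row[0] = 1.0
    row[1] = anchor_ratio
    if anchor_loc in col:
        row[col[anchor_loc]] = 1.0
    rows.append(row)
    rhs.append(logit(anchor_prob))

    a = np.array(rows)
    b = np.array(rhs)
    try:
        sol = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:
        raise CalibrationError(f"printed constraints are singular: {exc}") from exc
    if not np.allclose(a @ sol, b, rtol=0, atol=1e-9):
        raise CalibrationError("printed constraints are inconsistent")

    offsets = {TumorLocation.UPPER_LATERAL: 0.0}
    offsets.update({loc: float(sol[col[loc]]) for loc in free})
    try:
        return CosmesisLogisticModel(
            intercept=float(sol[0]), ratio_coef=float(sol[1]), location_offsets=offsets
        )
    except ValueError as exc:
        raise CalibrationError(f"calibrated solution violates model invariants: {exc}") from exc


def update_intercept(
    model: CosmesisLogisticModel, old_prior: float, new_prior: float
) -> CosmesisLogisticModel:
    """Shift the intercept for a new outcome prevalence, keeping all effects.

    Standard prevalence (intercept) updating: the intercept moves by
    ``logit(new_prior) - logit(old_prior)``; slope and offsets — hence all
    between-patient odds ratios — are unchanged.
    """
    for name, p in (("old_prior", old_prior), ("new_prior", new_prior)):
        if not 0 < p < 1:
            raise ValueError(f"{name} must be in (0,1), got {p}")
    shift = float(logit(new_prior) - logit(old_prior))
    return replace(model, intercept=model.intercept + shift)


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts of predicted-positive (good predicted) vs observed cosmesis."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def ppv(self) -> float | None:
        """Positive predictive value; None when no positive predictions exist."""
        denom = self.tp + self.fp
        return self.tp / denom if denom else None

    @property
    def npv(self) -> float | None:
        denom = self.tn + self.fn
        return self.tn / denom if denom else None


def confusion_at_threshold(
    predicted: Sequence[float], observed: Sequence[str], threshold: float
) -> ConfusionCounts:
    """Classify predictions at a probability threshold and cross-tabulate.

    A prediction is positive only when it strictly exceeds the threshold
    (equality is negative).  Observed labels are ``good`` / ``poor``.
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=object)
    if pred.size == 0:
        raise ValueError("empty prediction list")
    if pred.shape != obs.shape:
        raise ValueError("predicted and observed must have equal length")
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    bad = set(obs) - {"good", "poor"}
    if bad:
        raise ValueError(f"observed labels must be 'good' or 'poor'; got {bad}")
    positive = pred > threshold
    good = obs == "good"
    return ConfusionCounts(
        tp=int(np.sum(positive & good)),
        fp=int(np.sum(positive & ~good)),
        tn=int(np.sum(~positive & ~good)),
        fn=int(np.sum(~positive & good)),
    )


def auc(predicted: Sequence[float], observed: Sequence[str]) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve; ties count 1/2."""
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=object)
    if pred.shape != obs.shape:
        raise ValueError("predicted and observed must have equal length")
    good = obs == "good"
    n_good = int(good.sum())
    n_poor = int((~good).sum())
    if n_good == 0 or n_poor == 0:
        raise ValueError("AUC requires at least one good and one poor outcome")
    ranks = rankdata(pred)  # average ranks handle ties as 1/2
    u = ranks[good].sum() - n_good * (n_good + 1) / 2
    return float(u / (n_good * n_poor))
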