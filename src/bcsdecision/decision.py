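"""Treatment decision tree, harm/benefit threshold, and recommendations.

With equal survival across arms, the choice between breast-conserving
surgery (BCS) and mastectomy (MST) reduces to expected quality-of-life
utility.  The BCS arm is a lottery over good/poor cosmesis with success
probability ``p_good`` from the prediction model; the MST arm is its
reconstruction-pooled expectation:

    EU_BCS = p_good * u_bcs_good + (1 - p_good) * u_bcs_poor
    EU_MST = p_recon * u_mst_recon + (1 - p_recon) * u_mst_only

Setting the two equal yields the classic harm/benefit treatment threshold
(Pauker-Kassirer form)

    threshold = harm / (harm + benefit),
    benefit   = u_bcs_good - EU_MST,   harm = EU_MST - u_bcs_poor,

so BCS is preferred exactly when p_good exceeds the threshold.  Because
the logistic model is monotone in the TV/BV ratio, the threshold maps to
one ratio cut-off per tumor location: BCS below the cut-off, MST above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logit

from .cosmesis import PatientPresentation, TumorLocation, tv_bv_ratio
from .prediction import CosmesisLogisticModel, predict_good_cosmesis
from .utilities import HealthStateUtilities, OrderingError, pooled_mst_utility

__all__ = [
    "DecisionResult",
    "expected_utility_bcs",
    "benefit",
    "harm",
    "treatment_threshold",
    "ratio_cutoff",
    "recommend",
    "decision_graph",
]

#: Default utility tolerance below which the two arms are called indifferent.
DEFAULT_TOLERANCE = 1e-12


@dataclass(frozen=True)
class DecisionResult:
    """Outcome of the decision model for one patient."""

    p_good: float
    eu_bcs: float
    eu_mst: float
    threshold: float
    recommendation: str  # "BCS" | "MST" | "indifferent"
    margin: float  # eu_bcs - eu_mst


def expected_utility_bcs(p_good: float, utils: HealthStateUtilities) -> float:
    """Expected utility of the BCS arm at a given chance of good cosmesis."""
    if not 0 <= p_good <= 1:
        raise ValueError(f"p_good must be in [0,1], got {p_good}")
    return float(p_good * utils.u_bcs_good + (1.0 - p_good) * utils.u_bcs_poor)


def benefit(utils: HealthStateUtilities) -> float:
    """Utility gained by BCS with good cosmesis over pooled mastectomy."""
    b = utils.u_bcs_good - pooled_mst_utility(utils)
    if b <= 0:
        raise OrderingError(
            f"benefit must be positive: u_bcs_good ({utils.u_bcs_good}) does not exceed "
            f"the pooled MST utility ({pooled_mst_utility(utils):.6f})"
        )
    return float(b)


def harm(utils: HealthStateUtilities) -> float:
    """Utility lost by BCS with poor cosmesis relative to pooled mastectomy."""
    h = pooled_mst_utility(utils) - utils.u_bcs_poor
    if h <= 0:
        raise OrderingError(
            f"harm must be positive: pooled MST utility ({pooled_mst_utility(utils):.6f}) "
            f"does not exceed u_bcs_poor ({utils.u_bcs_poor})"
        )
    return float(h)


def treatment_threshold(utils: HealthStateUtilities) -> float:
    """Chance of good cosmesis at which the two arms' expected utilities are equal."""
    h, b = harm(utils), benefit(utils)
    return h / (h + b)


def ratio_cutoff(
    model: CosmesisLogisticModel, threshold: float, location: TumorLocation
) -> float:
    """TV/BV ratio at which the predicted probability equals the threshold.

    Analytic inversion of the logistic linear predictor.  The result can be
    non-positive (the threshold is never reached at any realisable ratio for
    that location) or above 1000; callers should report such values as
    "always MST" / "always BCS" regions rather than clamp them.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    if model.ratio_coef == 0:
        raise ValueError("ratio_coef is zero; no ratio cut-off exists")
    loc = TumorLocation(location)
    return float(
        (logit(threshold) - model.intercept - model.location_offsets[loc]) / model.ratio_coef
    )


def recommend(
    presentation: PatientPresentation,
    model: CosmesisLogisticModel,
    utils: HealthStateUtilities,
    tolerance: float = DEFAULT_TOLERANCE,
) -> DecisionResult:
    """Full decision-model evaluation for one patient.

    The arms are compared on expected utility; a margin within ``tolerance``
    is reported as ``indifferent`` (at the threshold the arms are equal by
    construction, so a strict rule would be arbitrary there).  When the
    margin is indifferent because the utilities themselves are degenerate
    (no positive benefit or harm), no threshold exists and ``nan`` is
    reported for it; ordering violations with a decisive margin still raise.
    """
    p_good = predict_good_cosmesis(model, presentation)
    eu_bcs = expected_utility_bcs(p_good, utils)
    eu_mst = pooled_mst_utility(utils)
    margin = eu_bcs - eu_mst
    if abs(margin) <= tolerance:
        rec = "indifferent"
        try:
            thr = treatment_threshold(utils)
        except OrderingError:
            thr = float("nan")
    else:
        utils.validate()
        thr = treatment_threshold(utils)
        rec = "BCS" if margin > 0 else "MST"
    return DecisionResult(
        p_good=p_good,
        eu_bcs=eu_bcs,
        eu_mst=eu_mst,
        threshold=thr,
        recommendation=rec,
        margin=margin,
    )


def decision_graph(
    model: CosmesisLogisticModel,
    utils: HealthStateUtilities,
    ratio_grid,
    locations=tuple(TumorLocation),
) -> pd.DataFrame:
    """Tabulate p_good and the recommendation over a (location x ratio) grid.

    One row per combination; for each location the recommendation flips from
    BCS to MST exactly once, at that location's ratio cut-off.
    """
    grid = np.asarray(list(ratio_grid), dtype=float)
    if grid.size and (grid <= 0).any():
        raise ValueError("ratio grid values must be positive")
    thr = treatment_threshold(utils.validate())
    rows = []
    for loc in locations:
        loc = TumorLocation(loc)
        for r in grid:
            p = model.predict(loc, float(r))
            rows.append(
                {
                    "location": loc.value,
                    "ratio": float(r),
                    "p_good": p,
                    "recommendation": "BCS" if p > thr else "MST",
                }
            )
    return pd.DataFrame(rows, columns=["location", "ratio", "p_good", "recommendation"])
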