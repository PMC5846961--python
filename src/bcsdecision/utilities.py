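"""Health-state utilities and instrument-to-utility linear maps.

The decision model compares four terminal health states — BCS with good
cosmesis, BCS with poor cosmesis, mastectomy only, mastectomy with
reconstruction — each valued by an EQ-5D-compatible utility on [0, 1].
Instrument scores (e.g. EORTC QLQ-C30 or FACT-G scale scores) are turned
into utilities through published linear "mapping" (crosswalk) regressions,
supplied as configuration since their coefficients come from the mapping
literature, not from this package.

BCS utilities are built by anchoring: the cohort-specific gain/loss of a
good/poor cosmetic result relative to the pooled cohort mean is added to a
large-sample external mean utility after BCS.  The two mastectomy states
are pooled by the probability of breast reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "LinearUtilityMap",
    "HealthStateUtilities",
    "OrderingError",
    "map_to_utility",
    "anchored_bcs_utilities",
    "pooled_mst_utility",
]


class OrderingError(ValueError):
    """The utilities violate the ordering the decision model relies on."""


@dataclass(frozen=True)
class LinearUtilityMap:
    """Affine map from instrument scale scores to a single-index utility."""

    intercept: float
    coefficients: Mapping[str, float]
    clamp: bool = True
    instrument: str = ""

    def __post_init__(self) -> None:
        if not self.coefficients:
            raise ValueError("a utility map needs at least one scale coefficient")
        object.__setattr__(self, "coefficients", dict(self.coefficients))


@dataclass(frozen=True)
class HealthStateUtilities:
    """Utilities of the four terminal states plus the reconstruction rate.

    The decision model requires the ordering
    ``u_bcs_good > pooled MST utility > u_bcs_poor``; ``validate()``
    raises :class:`OrderingError` naming the violated inequality.
    """

    u_bcs_good: float
    u_bcs_poor: float
    u_mst_only: float
    u_mst_recon: float
    p_recon: float

    def __post_init__(self) -> None:
        for name in ("u_bcs_good", "u_bcs_poor", "u_mst_only", "u_mst_recon"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not 0 <= self.p_recon <= 1:
            raise ValueError(f"p_recon must be in [0,1], got {self.p_recon}")

    def validate(self) -> "HealthStateUtilities":
        pooled = pooled_mst_utility(self)
        if not self.u_bcs_good > pooled:
            raise OrderingError(
                f"u_bcs_good ({self.u_bcs_good}) must exceed the pooled MST utility ({pooled:.6f})"
            )
        if not pooled > self.u_bcs_poor:
            raise OrderingError(
                f"pooled MST utility ({pooled:.6f}) must exceed u_bcs_poor ({self.u_bcs_poor})"
            )
        return self


def map_to_utility(utility_map: LinearUtilityMap, scores: Mapping[str, float]) -> float:
    """Apply a linear instrument-to-utility map to a set of scale scores."""
    missing = set(utility_map.coefficients) - set(scores)
    if missing:
        raise ValueError(f"scores missing scales required by the map: {sorted(missing)}")
    value = utility_map.intercept + sum(
        coef * float(scores[name]) for name, coef in utility_map.coefficients.items()
    )
    if utility_map.clamp:
        value = min(1.0, max(0.0, value))
    return float(value)


def anchored_bcs_utilities(
    anchor_utility: float,
    cohort_good: Sequence[float],
    cohort_poor: Sequence[float],
) -> tuple[float, float]:
    """Anchor cohort good/poor utility deltas onto an external BCS mean.

    The gain (loss) of a good (poor) cosmetic result is measured relative
    to the pooled cohort mean and added to the anchor, so the
    prevalence-weighted recombination of the two outputs reproduces the
    anchor exactly.  Outputs are clamped to [0, 1].
    """
    good = np.asarray(cohort_good, dtype=float)
    poor = np.asarray(cohort_poor, dtype=float)
    if good.size == 0 or poor.size == 0:
        raise ValueError("both cohort utility lists must be non-empty")
    if not 0 <= anchor_utility <= 1:
        raise ValueError(f"anchor utility must be in [0,1], got {anchor_utility}")
    pooled_mean = float(np.concatenate([good, poor]).mean())
    u_good = anchor_utility + (float(good.mean()) - pooled_mean)
    u_poor = anchor_utility + (float(poor.mean()) - pooled_mean)
    clamp = lambda u: min(1.0, max(0.0, u))  # noqa: E731
    return clamp(u_good), clamp(u_poor)


def pooled_mst_utility(utils: HealthStateUtilities) -> float:
    """Expected mastectomy utility over the reconstruction chance node."""
    return float(
        utils.p_recon * utils.u_mst_recon + (1.0 - utils.p_recon) * utils.u_mst_only
    )
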