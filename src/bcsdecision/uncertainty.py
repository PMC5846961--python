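"""Probabilistic sensitivity analysis (PSA) and expected value of perfect information.

Every model parameter lives on [0, 1] (four health-state utilities, the
reconstruction probability, optionally the predicted chance of good
cosmesis), so uncertainty is expressed with beta distributions,
parameterised by mean and standard error via the method of moments.  The
PSA redraws all parameters independently, re-evaluates both arms of the
decision tree for a reference patient, and summarises how often each arm
is optimal.  The expected value of perfect information (EVPI) is the mean
opportunity loss of sticking with the baseline-optimal arm across draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cosmesis import PatientPresentation
from .prediction import CosmesisLogisticModel, predict_good_cosmesis
from .utilities import HealthStateUtilities

__all__ = [
    "ParamDistribution",
    "PsaResult",
    "beta_from_moments",
    "run_psa",
    "evpi",
    "PSA_PARAMETER_ORDER",
]

#: Fixed draw order for the parameter streams, so results are
#: bit-reproducible for a given seed regardless of caller bookkeeping.
PSA_PARAMETER_ORDER = (
    "u_bcs_good",
    "u_bcs_poor",
    "u_mst_only",
    "u_mst_recon",
    "p_recon",
    "p_good",
)


@dataclass(frozen=True)
class ParamDistribution:
    """Beta distribution on [0, 1] given by its mean and standard error.

    ``se == 0`` denotes an explicit point mass at the mean (used for
    degenerate, no-uncertainty analyses); the beta shape parameters are
    then undefined and sampling returns the mean.
    """

    mean: float
    se: float
    alpha: Optional[float] = None
    beta: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 < self.mean < 1:
            raise ValueError(f"mean must be in (0,1), got {self.mean}")
        if self.se < 0:
            raise ValueError(f"se must be non-negative, got {self.se}")
        if self.se > 0:
            if self.alpha is None or self.beta is None:
                d = beta_from_moments(self.mean, self.se)
                object.__setattr__(self, "alpha", d.alpha)
                object.__setattr__(self, "beta", d.beta)
            elif self.alpha <= 0 or self.beta <= 0:
                raise ValueError("beta shape parameters must be positive")

    @property
    def degenerate(self) -> bool:
        return self.se == 0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.degenerate:
            return np.full(n, self.mean)
        return rng.beta(self.alpha, self.beta, size=n)


def beta_from_moments(mean: float, se: float) -> ParamDistribution:
    """Method-of-moments beta: alpha = mean*nu, beta = (1-mean)*nu, nu = mean(1-mean)/se^2 - 1."""
    if not 0 < mean < 1:
        raise ValueError(f"mean must be in (0,1), got {mean}")
    if se <= 0:
        raise ValueError(f"se must be positive, got {se}")
    var = se * se
    if var >= mean * (1.0 - mean):
        raise ValueError(
            f"no beta distribution exists: se^2 ({var:.6g}) must be below "
            f"mean*(1-mean) ({mean * (1 - mean):.6g})"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return ParamDistribution(mean=mean, se=se, alpha=mean * nu, beta=(1.0 - mean) * nu)


@dataclass(frozen=True)
class PsaResult:
    """Monte-Carlo draws of the two arms' expected utilities and summaries."""

    n_samples: int
    eu_bcs_samples: np.ndarray
    eu_mst_samples: np.ndarray
    p_bcs_optimal: float
    evpi: float
    baseline: str
    seed: int

    def summary(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "seed": self.seed,
            "baseline": self.baseline,
            "p_bcs_optimal": self.p_bcs_optimal,
            "evpi": self.evpi,
            "eu_bcs_mean": float(self.eu_bcs_samples.mean()),
            "eu_mst_mean": float(self.eu_mst_samples.mean()),
        }


def run_psa(
    utils: HealthStateUtilities,
    ses: dict,
    presentation: PatientPresentation,
    model: CosmesisLogisticModel,
    n: int = 10_000,
    seed: int = 0,
    p_good_se: float = 0.0,
) -> PsaResult:
    """Joint Monte-Carlo propagation of parameter uncertainty for one patient.

    Parameters
    ----------
    utils
        Point estimates of the health-state utilities and reconstruction
        probability; each becomes the mean of its beta distribution.
    ses
        Standard errors keyed by parameter name (any of ``u_bcs_good``,
        ``u_bcs_poor``, ``u_mst_only``, ``u_mst_recon``, ``p_recon``);
        a missing or zero entry makes that parameter a point mass.
    presentation
        The reference ("average") patient whose arm utilities are recomputed
        per draw.
    p_good_se
        Standard error of the model's predicted probability of good
        cosmesis; 0 (default) holds the prediction fixed, a positive value
        gives it a beta distribution of its own.

    Draws are taken in the fixed order :data:`PSA_PARAMETER_ORDER` from a
    single ``numpy`` generator seeded with ``seed``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    unknown = set(ses) - set(PSA_PARAMETER_ORDER[:-1])
    if unknown:
        raise ValueError(f"unknown PSA parameter names: {sorted(unknown)}")
    p_good_hat = predict_good_cosmesis(model, presentation)
    means = {
        "u_bcs_good": utils.u_bcs_good,
        "u_bcs_poor": utils.u_bcs_poor,
        "u_mst_only": utils.u_mst_only,
        "u_mst_recon": utils.u_mst_recon,
        "p_recon": utils.p_recon,
        "p_good": p_good_hat,
    }
    all_ses = dict(ses)
    all_ses["p_good"] = p_good_se

    rng = np.random.default_rng(seed)
    draws = {}
    for name in PSA_PARAMETER_ORDER:
        dist = ParamDistribution(mean=means[name], se=float(all_ses.get(name, 0.0)))
        draws[name] = dist.sample(rng, n)

    eu_bcs = draws["p_good"] * draws["u_bcs_good"] + (1 - draws["p_good"]) * draws["u_bcs_poor"]
    eu_mst = draws["p_recon"] * draws["u_mst_recon"] + (1 - draws["p_recon"]) * draws["u_mst_only"]
    p_bcs_optimal = float(np.mean(eu_bcs > eu_mst))
    baseline = "BCS" if eu_bcs.mean() >= eu_mst.mean() else "MST"
    result = PsaResult(
        n_samples=n,
        eu_bcs_samples=eu_bcs,
        eu_mst_samples=eu_mst,
        p_bcs_optimal=p_bcs_optimal,
        evpi=0.0,
        baseline=baseline,
        seed=seed,
    )
    return PsaResult(**{**result.__dict__, "evpi": evpi(result, baseline)})


def evpi(result: PsaResult, baseline: str) -> float:
    """Mean opportunity loss of the baseline arm: E[max(arms) - EU_baseline].

    ``baseline`` must be the arm with the higher mean expected utility
    across the draws; the result is then non-negative and equals
    ``mean(max(arms)) - max(mean(arms))``.
    """
    if baseline not in ("BCS", "MST"):
        raise ValueError(f"baseline must be 'BCS' or 'MST', got {baseline!r}")
    bcs, mst = result.eu_bcs_samples, result.eu_mst_samples
    means = {"BCS": bcs.mean(), "MST": mst.mean()}
    if means[baseline] < max(means.values()):
        raise ValueError(
            f"baseline {baseline} is not the arm with the higher mean expected utility"
        )
    eu_baseline = bcs if baseline == "BCS" else mst
    return float(np.mean(np.maximum(bcs, mst) - eu_baseline))
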