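"""Synthetic cohorts with the statistical structure of the original 69-patient study.

No per-patient data were ever deposited, so testing the pipeline requires a
generator that emulates the published cohort summaries: the location mix
(47.8 / 20.3 / 18.8 / 4.3 / 8.7 % for upper-lateral / upper-medial /
lower-lateral / lower-medial / central), a log-normal TV/BV ratio matched
to the printed median 2.47 and IQR 1.25-5.54, binary cosmesis outcomes
drawn from the logistic model itself, label-consistent panel mean scores,
and state utilities with clamped Gaussian noise.  Breast volumes are drawn
uniformly on a plausible clinical range purely to make the volumes
concrete — only the ratio enters the model.

``fit_logistic`` refits the generating model by maximum likelihood
(statsmodels Newton) for parameter-recovery checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import log
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .cosmesis import GOOD_COSMESIS_CUTOFF, TumorLocation
from .prediction import CosmesisLogisticModel
from .utilities import HealthStateUtilities

__all__ = [
    "CohortSpec",
    "SeparationError",
    "LogisticFit",
    "generate_cohort",
    "fit_logistic",
    "DEFAULT_LOCATION_PROBS",
    "RATIO_LOG_MEAN",
    "RATIO_LOG_SD",
]

#: Published location frequencies of the study cohort.
DEFAULT_LOCATION_PROBS: dict[TumorLocation, float] = {
    TumorLocation.UPPER_LATERAL: 0.478,
    TumorLocation.UPPER_MEDIAL: 0.203,
    TumorLocation.LOWER_LATERAL: 0.188,
    TumorLocation.LOWER_MEDIAL: 0.043,
    TumorLocation.CENTRAL: 0.088,
}

#: Log-normal ratio parameters matched to the printed median 2.47 and
#: IQR 1.25-5.54: median fixes the log-mean; the IQR spans 2 * 0.6745 sd.
RATIO_LOG_MEAN = log(2.47)
RATIO_LOG_SD = (log(5.54) - log(1.25)) / (2 * 0.674489750196082)

#: Plausible clinical breast-volume range (cm^3) for concreteness only.
BREAST_VOLUME_RANGE = (200.0, 1500.0)


class SeparationError(RuntimeError):
    """The logistic fit is degenerate (perfectly separated outcomes)."""


@dataclass(frozen=True)
class CohortSpec:
    """Generating parameters of a synthetic cohort."""

    n: int
    model: CosmesisLogisticModel
    utils: Optional[HealthStateUtilities] = None
    location_probs: Mapping[TumorLocation, float] = field(
        default_factory=lambda: dict(DEFAULT_LOCATION_PROBS)
    )
    ratio_log_mean: float = RATIO_LOG_MEAN
    ratio_log_sd: float = RATIO_LOG_SD
    qol_noise_sd: float = 0.02
    panel_noise_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        probs = {TumorLocation(k): float(v) for k, v in self.location_probs.items()}
        if set(probs) != set(TumorLocation) or any(p < 0 for p in probs.values()):
            raise ValueError("location_probs must cover all five locations with p >= 0")
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"location_probs must sum to 1, got {total}")
        if self.ratio_log_sd < 0 or self.qol_noise_sd < 0 or self.panel_noise_sd < 0:
            raise ValueError("spread parameters must be non-negative")
        object.__setattr__(self, "location_probs", probs)


def _panel_scores(rng, labels: np.ndarray, noise_sd: float) -> np.ndarray:
    """Label-first panel means: centre of the label's score interval plus
    truncated noise, so label and score never disagree."""
    centers = np.where(labels, 0.75, 2.25)
    if noise_sd == 0:
        return centers
    scores = centers + rng.normal(0.0, noise_sd, size=labels.size)
    lo = np.where(labels, 0.0, np.nextafter(GOOD_COSMESIS_CUTOFF, 3.0))
    hi = np.where(labels, GOOD_COSMESIS_CUTOFF, 3.0)
    return np.clip(scores, lo, hi)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one synthetic cohort; fully reproducible from ``spec.seed``.

    Returns a tidy frame with columns: patient_id, location, tumor_volume,
    breast_volume, ratio, p_good_true, cosmesis_label, panel_mean_score,
    qol_utility.
    """
    rng = np.random.default_rng(spec.seed)
    locs = list(TumorLocation)
    probs = np.array([spec.location_probs[l] for l in locs])
    loc_idx = rng.choice(len(locs), size=spec.n, p=probs)
    ratio = rng.lognormal(spec.ratio_log_mean, spec.ratio_log_sd, size=spec.n)
    ratio = np.minimum(ratio, 1000.0)  # a tumor cannot exceed its breast
    breast = rng.uniform(*BREAST_VOLUME_RANGE, size=spec.n)
    tumor = ratio * breast / 1000.0

    p_good = np.array(
        [spec.model.predict(locs[i], r) for i, r in zip(loc_idx, ratio)]
    )
    good = rng.uniform(size=spec.n) < p_good
    panel = _panel_scores(rng, good, spec.panel_noise_sd)

    if spec.utils is not None:
        base = np.where(good, spec.utils.u_bcs_good, spec.utils.u_bcs_poor)
    else:
        base = np.where(good, 0.908, 0.843)
    if spec.qol_noise_sd > 0:
        qol = np.clip(base + rng.normal(0.0, spec.qol_noise_sd, size=spec.n), 0.0, 1.0)
    else:
        qol = base

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(spec.n)],
            "location": [locs[i].value for i in loc_idx],
            "tumor_volume": tumor,
            "breast_volume": breast,
            "ratio": ratio,
            "p_good_true": p_good,
            "cosmesis_label": np.where(good, "good", "poor"),
            "panel_mean_score": panel,
            "qol_utility": qol,
        }
    )


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood refit of the cosmesis model with standard errors.

    Coefficient keys are ``intercept``, ``ratio_coef`` and
    ``offset_<location>``; ``conf_int`` maps each key to its 95% Wald
    interval.  Unlike :class:`CosmesisLogisticModel`, no sign constraint is
    imposed — a refit can legitimately land on either side of zero.
    """

    params: dict[str, float]
    bse: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    converged: bool

    def to_model(self) -> CosmesisLogisticModel:
        """Coerce the fit into a model object (requires a negative ratio slope)."""
        offsets = {TumorLocation.UPPER_LATERAL: 0.0}
        for loc in TumorLocation:
            if loc is not TumorLocation.UPPER_LATERAL:
                offsets[loc] = self.params.get(f"offset_{loc.value}", 0.0)
        return CosmesisLogisticModel(
            intercept=self.params["intercept"],
            ratio_coef=self.params["ratio_coef"],
            location_offsets=offsets,
        )


def fit_logistic(cohort: pd.DataFrame) -> LogisticFit:
    """Refit the logistic model of cosmesis on ratio + location dummies.

    Upper-lateral is the reference category.  Raises
    :class:`SeparationError` on perfect separation and ``ValueError`` when a
    single outcome class is present.  Locations absent from the cohort are
    simply absent from the returned coefficients.
    """
    y = (cohort["cosmesis_label"] == "good").to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present to fit the model")

    cols = {"ratio_coef": cohort["ratio"].to_numpy(dtype=float)}
    for loc in TumorLocation:
        if loc is TumorLocation.UPPER_LATERAL:
            continue
        dummy = (cohort["location"] == loc.value).to_numpy(dtype=float)
        if dummy.any():
            cols[f"offset_{loc.value}"] = dummy
    x = pd.DataFrame(cols)
    x.insert(0, "intercept", 1.0)

    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Logit(y, x).fit(method="newton", disp=0, tol=1e-10, maxiter=200)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise SeparationError(f"perfect separation in logistic fit: {exc}") from exc
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix: {exc}") from exc

    ci = res.conf_int(alpha=0.05)
    return LogisticFit(
        params={k: float(v) for k, v in res.params.items()},
        bse={k: float(v) for k, v in res.bse.items()},
        conf_int={k: (float(ci.loc[k, 0]), float(ci.loc[k, 1])) for k in res.params.index},
        converged=bool(res.mle_retvals.get("converged", True)),
    )
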