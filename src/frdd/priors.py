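"""Prior elicitation for the dog-population capture-recapture model.

Four priors feed the model, each built from survey-design numbers or
questionnaire records collected during the door-to-door marking campaign:

* **recapture probability** -- a uniform prior whose bounds are the products
  of the minimum/maximum transect coverage, dog-encountering and recording
  probabilities;
* **confinement probability** -- a uniform prior whose bounds are
  count-weighted means of per-roaming-category confinement limits;
* **ownerless:owned ratio** -- a log-normal prior (location ``mu``,
  precision ``tau`` = 1/variance of the log, the BUGS convention) fitted to
  per-respondent ratio estimates;
* **owned-dog count** -- a discrete uniform prior from the number of dogs
  collared up to a generous cap.

The module also computes the collar-loss probability schedule ``lm(t)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from ._util import round_half_up

logger = logging.getLogger(__name__)

#: Roaming categories recorded in the owner questionnaire.
ROAMING_CATEGORIES = ("never", "always", "day_only", "night_only", "few_hours")

#: Lower/upper confinement probability assigned to each roaming category
#: during the hours the transects are walked. Categories with a range
#: (day_only, night_only) contribute their interval endpoints to the
#: elicited uniform prior; the others are fixed values.
CONFINEMENT_LOW: Mapping[str, float] = {
    "never": 1.0,
    "always": 0.0,
    "day_only": 0.0,
    "few_hours": 0.5,
    "night_only": 0.75,
}
CONFINEMENT_HIGH: Mapping[str, float] = {
    "never": 1.0,
    "always": 0.0,
    "day_only": 0.25,
    "few_hours": 0.5,
    "night_only": 1.0,
}


# ---------------------------------------------------------------------------
# prior containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UniformPrior:
    """Continuous uniform prior on a probability, ``low <= x <= high``."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.low <= self.high <= 1.0):
            raise ValueError(
                f"uniform prior bounds must satisfy 0 <= low <= high <= 1, "
                f"got ({self.low}, {self.high})"
            )

    @property
    def width(self) -> float:
        return self.high - self.low

    def contains(self, x: float) -> bool:
        return self.low <= x <= self.high

    def logpdf(self, x: float) -> float:
        if not self.contains(x):
            return -math.inf
        if self.width == 0.0:
            return 0.0  # point mass convention
        return -math.log(self.width)

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.uniform(self.low, self.high))


@dataclass(frozen=True)
class LogNormalPrior:
    """Log-normal prior with location ``mu`` and precision ``tau``.

    ``tau`` is the inverse variance of log(x) (BUGS parameterisation), so
    ``sigma = tau ** -0.5`` and the distribution mean is
    ``exp(mu + 1/(2 tau))``.
    """

    mu: float
    tau: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.mu):
            raise ValueError(f"mu must be finite, got {self.mu}")
        if not (self.tau > 0.0 and math.isfinite(self.tau)):
            raise ValueError(f"tau must be a positive precision, got {self.tau}")

    @property
    def sigma(self) -> float:
        return self.tau ** -0.5

    @property
    def mean(self) -> float:
        """E[x] = exp(mu + 1/(2 tau))."""
        return math.exp(self.mu + 0.5 / self.tau)

    def logpdf_log(self, log_x: float) -> float:
        """Log density of log(x), which is Normal(mu, 1/tau)."""
        z = (log_x - self.mu) / self.sigma
        return -0.5 * z * z - math.log(self.sigma) - 0.5 * math.log(2.0 * math.pi)

    def sample(self, rng: np.random.Generator) -> float:
        return float(np.exp(rng.normal(self.mu, self.sigma)))


@dataclass(frozen=True)
class GammaRatioPrior:
    """Gamma prior on the ownerless:owned ratio, for sensitivity analysis.

    Allows substantially more mass on large ratios than the log-normal
    elicited from owner interviews.
    """

    shape: float
    rate: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.rate <= 0:
            raise ValueError("gamma shape and rate must be positive")

    @property
    def mean(self) -> float:
        return self.shape / self.rate

    def logpdf_log(self, log_x: float) -> float:
        """Log density of log(x) when x ~ Gamma(shape, rate)."""
        x = math.exp(log_x)
        return float(stats.gamma.logpdf(x, a=self.shape, scale=1.0 / self.rate)) + log_x

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.gamma(self.shape, 1.0 / self.rate))


@dataclass(frozen=True)
class DiscreteUniformPrior:
    """Discrete uniform prior on an integer count, inclusive bounds."""

    low: int
    high: int

    def __post_init__(self) -> None:
        if self.low != int(self.low) or self.high != int(self.high):
            raise ValueError("discrete uniform bounds must be integers")
        if not (0 <= self.low <= self.high):
            raise ValueError(
                f"discrete uniform bounds must satisfy 0 <= low <= high, "
                f"got ({self.low}, {self.high})"
            )

    def contains(self, n: int) -> bool:
        return self.low <= n <= self.high

    def logpmf(self, n: int) -> float:
        if not self.contains(n):
            return -math.inf
        return -math.log(self.high - self.low + 1)

    def sample(self, rng: np.random.Generator) -> int:
        return int(rng.integers(self.low, self.high + 1))


@dataclass(frozen=True)
class MarkingSummary:
    """Totals from the collaring campaign: dogs collared ``n_collared``
    (Mc), collars lost over the study ``n_lost`` (Ml), and the number of
    transect rounds ``n_transects`` (T)."""

    n_collared: int
    n_lost: int
    n_transects: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_lost <= self.n_collared):
            raise ValueError(
                f"collars lost must satisfy 0 <= Ml <= Mc, got "
                f"Ml={self.n_lost}, Mc={self.n_collared}"
            )
        if self.n_transects < 1:
            raise ValueError(f"need at least one transect, got {self.n_transects}")


# ---------------------------------------------------------------------------
# elicitation operations
# ---------------------------------------------------------------------------

def recapture_prior(
    coverage_min: float,
    coverage_max: float,
    encounter_min: float,
    encounter_max: float,
    record_min: float,
    record_max: float,
    report_decimals: int | None = 2,
) -> UniformPrior:
    """Combine coverage, encountering and recording bounds into the
    recapture-probability uniform prior.

    The lower bound is the product of the three minima, the upper bound the
    product of the three maxima, each rounded half-up to ``report_decimals``
    (pass ``None`` to keep full precision).
    """
    components = {
        "coverage": (coverage_min, coverage_max),
        "encounter": (encounter_min, encounter_max),
        "record": (record_min, record_max),
    }
    for name, (lo, hi) in components.items():
        if not (0.0 <= lo <= 1.0) or not (0.0 <= hi <= 1.0):
            raise ValueError(f"{name} probabilities must lie in [0, 1], got ({lo}, {hi})")
        if lo > hi:
            raise ValueError(f"{name} min {lo} exceeds its max {hi}")
    low = coverage_min * encounter_min * record_min
    high = coverage_max * encounter_max * record_max
    if report_decimals is not None:
        low = round_half_up(low, report_decimals)
        high = round_half_up(high, report_decimals)
    return UniformPrior(low, high)


def confinement_prior(categories: Mapping[str, int]) -> UniformPrior:
    """Elicit the owned-dog confinement prior from roaming-category counts.

    Each category contributes its lower/upper confinement limit weighted by
    the number of dogs reported in it; the weighted means form the bounds of
    the uniform prior.
    """
    unknown = set(categories) - set(ROAMING_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown roaming categories: {sorted(unknown)}")
    counts = {k: int(categories.get(k, 0)) for k in ROAMING_CATEGORIES}
    if any(v < 0 for v in counts.values()):
        raise ValueError("category counts must be non-negative")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no dogs to weight: all roaming-category counts are zero")
    low = sum(counts[k] * CONFINEMENT_LOW[k] for k in ROAMING_CATEGORIES) / total
    high = sum(counts[k] * CONFINEMENT_HIGH[k] for k in ROAMING_CATEGORIES) / total
    return UniformPrior(low, high)


def fit_ownerless_ratio_prior(
    owned_estimates: Sequence[float],
    ownerless_estimates: Sequence[float],
    tau_cap: float = 1e6,
) -> LogNormalPrior:
    """Fit the log-normal ownerless:owned ratio prior to respondent data.

    Each respondent contributes the ratio of their ownerless-dog estimate to
    their owned-dog estimate; respondents with a zero in either estimate are
    excluded (the log-ratio is undefined) and counted in a log message.
    ``mu`` is the mean of the log ratios and ``tau`` the inverse of their
    unbiased variance, capped at ``tau_cap`` to keep degenerate (constant)
    data usable downstream.
    """
    owned = np.asarray(owned_estimates, dtype=float)
    ownerless = np.asarray(ownerless_estimates, dtype=float)
    if owned.shape != ownerless.shape or owned.ndim != 1:
        raise ValueError("owned and ownerless estimate vectors must be 1-d and equal length")
    if np.any(owned < 0) or np.any(ownerless < 0):
        raise ValueError("estimates must be non-negative")
    usable = (owned > 0) & (ownerless > 0)
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.info(
            "ratio prior fit: excluded %d/%d respondents with a zero estimate",
            n_excluded, owned.size,
        )
    log_ratios = np.log(ownerless[usable] / owned[usable])
    if log_ratios.size < 2:
        raise ValueError(
            f"need at least 2 respondents with positive owned and ownerless "
            f"estimates, got {log_ratios.size}"
        )
    mu = float(np.mean(log_ratios))
    s2 = float(np.var(log_ratios, ddof=1))
    if s2 == 0.0:
        logger.warning(
            "ratio prior fit: all %d log ratios identical; precision capped at %g",
            log_ratios.size, tau_cap,
        )
        tau = tau_cap
    else:
        tau = min(1.0 / s2, tau_cap)
    return LogNormalPrior(mu=mu, tau=tau)


def collar_loss_probability(marking: MarkingSummary, t: int) -> float:
    """Probability that a marked dog no longer carries its collar at
    transect ``t`` (1-based): lm(t) = (Ml/Mc) * (t/T), growing linearly over
    the survey. Zero by convention when no dog was collared."""
    if not (1 <= t <= marking.n_transects):
        raise ValueError(
            f"transect index {t} outside 1..{marking.n_transects}"
        )
    if marking.n_collared == 0:
        return 0.0
    return (marking.n_lost / marking.n_collared) * (t / marking.n_transects)


def owned_count_prior(n_collared: int, cap: int = 1000) -> DiscreteUniformPrior:
    """Non-informative prior on the owned-dog count: uniform from the number
    of dogs collared (a hard minimum -- every collared dog is owned) to a cap
    set well above any plausible village population."""
    if cap < n_collared:
        raise ValueError(f"cap {cap} is below the number of dogs collared {n_collared}")
    return DiscreteUniformPrior(int(n_collared), int(cap))
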