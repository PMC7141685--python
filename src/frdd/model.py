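"""Bayesian capture-recapture model for free-roaming dog populations.

The survey marks ``Mc`` owned dogs with collars, then walks ``T`` transects
counting marked (``m_t``) and unmarked (``u_t``) dogs. The model estimates
the number of owned free-roaming dogs ``N_o``, the expected number of
ownerless dogs ``lambda_u = r * N_o`` (with ``r`` the ownerless:owned
ratio), and hence the total free-roaming population.

Observation model, per transect ``t``:

* collars are lost over time with probability ``lm(t) = (Ml/Mc)(t/T)``, so
  ``M_t = round(Mc * (1 - lm(t)))`` dogs still carry a collar;
* marked sightings  ``m_t ~ Binomial(M_t, p(1-c))``;
* unmarked sightings ``u_t = A_t + B_t`` with owned-unmarked
  ``A_t ~ Binomial(N_o - M_t, p(1-c))`` and ownerless
  ``B_t ~ Poisson(lambda_u * p)`` (ownerless dogs are never confined);

where ``p`` is the per-transect recapture probability and ``c`` the
probability an owned dog is confined (hence invisible) during the transect.
The ownerless detections use a Poisson law, the small-expectation limit of
the binomial, which also yields the continuous ownerless summaries the
survey reports.

Inference is Metropolis-within-Gibbs: random-walk proposals for ``p`` and
``c`` on the logit scale rescaled to their uniform prior support, for
``log r`` on the log scale, and an integer random walk for ``N_o``. Step
sizes adapt toward a 44% acceptance rate during burn-in only, so the kept
draws come from a fixed Markov kernel.

Usage follows the Model/Results convention::

    model = CaptureRecaptureModel(observations, priors)
    res = model.fit(n_chains=4, n_iter=50_000, n_burn=10_000, seed=17)
    print(res.summary())
    res.posterior_summary().as_report()
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit, logsumexp
from scipy.stats import poisson

from ._util import round_half_up, round_half_up_int
from .priors import (
    DiscreteUniformPrior,
    GammaRatioPrior,
    LogNormalPrior,
    MarkingSummary,
    UniformPrior,
    collar_loss_probability,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CRObservations",
    "CRPriorSet",
    "CRParameters",
    "PosteriorSummary",
    "CaptureRecaptureModel",
    "CaptureRecaptureResults",
    "unmarked_count_log_pmf",
    "log_posterior",
    "fit_cr_model",
    "summarize_posterior",
    "prior_sensitivity",
    "available_marked",
    "chapman_estimate",
]


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CRObservations:
    """Per-site transect counts plus the marking summary."""

    marking: MarkingSummary
    marked_counts: tuple[int, ...]
    unmarked_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        m = tuple(int(x) for x in self.marked_counts)
        u = tuple(int(x) for x in self.unmarked_counts)
        object.__setattr__(self, "marked_counts", m)
        object.__setattr__(self, "unmarked_counts", u)
        T = self.marking.n_transects
        if len(m) != T or len(u) != T:
            raise ValueError(
                f"count vectors must have length T={T}, got {len(m)} marked "
                f"and {len(u)} unmarked"
            )
        if any(x < 0 for x in m + u):
            raise ValueError("counts must be non-negative")
        if any(x > self.marking.n_collared for x in m):
            raise ValueError(
                "a transect reports more marked dogs than were ever collared"
            )


@dataclass(frozen=True)
class CRPriorSet:
    """The four priors of the capture-recapture model."""

    recapture: UniformPrior
    confinement: UniformPrior
    ratio: LogNormalPrior | GammaRatioPrior
    owned: DiscreteUniformPrior

    def replace(self, **kwargs) -> "CRPriorSet":
        """Return a copy with named components swapped (used by the prior
        sensitivity analysis)."""
        valid = {"recapture", "confinement", "ratio", "owned"}
        unknown = set(kwargs) - valid
        if unknown:
            raise ValueError(f"unknown prior components: {sorted(unknown)}")
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CRParameters:
    """One point in parameter space: recapture probability ``p``, owned-dog
    confinement probability ``c``, ownerless:owned ratio ``r`` and owned
    count ``n_owned``."""

    p: float
    c: float
    r: float
    n_owned: int

    @property
    def lambda_u(self) -> float:
        """Expected number of ownerless dogs."""
        return self.r * self.n_owned


@dataclass(frozen=True)
class IntervalSummary:
    mean: float
    cri_low: float
    cri_high: float


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior means and equal-tailed 95% credibility intervals for the
    owned, ownerless and total free-roaming dog counts."""

    owned: IntervalSummary
    ownerless: IntervalSummary
    total: IntervalSummary
    ess: Mapping[str, float] = field(default_factory=dict)
    rhat: Mapping[str, float] = field(default_factory=dict)

    def as_report(self) -> dict:
        """Rounded figures as a survey report prints them: whole dogs for
        owned and total, two decimals for the (small) ownerless mean."""
        def _iv(iv: IntervalSummary, dec: int) -> dict:
            if dec == 0:
                rnd = round_half_up_int
            else:
                rnd = lambda x: round_half_up(x, dec)  # noqa: E731
            return {"mean": rnd(iv.mean), "cri_low": rnd(iv.cri_low),
                    "cri_high": rnd(iv.cri_high)}

        return {
            "owned": _iv(self.owned, 0),
            "ownerless": _iv(self.ownerless, 2),
            "total": _iv(self.total, 0),
        }


# ---------------------------------------------------------------------------
# likelihood primitives
# ---------------------------------------------------------------------------

def _binom_logpmf(k: np.ndarray | int, n: int, q: float) -> np.ndarray | float:
    """Binomial log pmf with exact handling of q = 0 and q = 1."""
    k = np.asarray(k)
    if n < 0:
        return np.where(k == k, -np.inf, -np.inf)
    if q <= 0.0:
        out = np.where(k == 0, 0.0, -np.inf)
    elif q >= 1.0:
        out = np.where(k == n, 0.0, -np.inf)
    else:
        valid = (k >= 0) & (k <= n)
        ks = np.where(valid, k, 0)
        out = np.where(
            valid,
            gammaln(n + 1) - gammaln(ks + 1) - gammaln(n - ks + 1)
            + ks * math.log(q) + (n - ks) * math.log1p(-q),
            -np.inf,
        )
    return out if out.ndim else float(out)


def _poisson_logpmf(k: np.ndarray | int, lam: float) -> np.ndarray | float:
    k = np.asarray(k)
    if lam <= 0.0:
        out = np.where(k == 0, 0.0, -np.inf)
    else:
        valid = k >= 0
        ks = np.where(valid, k, 0)
        out = np.where(valid, -lam + ks * math.log(lam) - gammaln(ks + 1), -np.inf)
    return out if out.ndim else float(out)


def unmarked_count_log_pmf(
    k: int,
    n_owned_unmarked: int,
    q_owned: float,
    lambda_detect: float,
    tail_eps: float = 1e-12,
) -> float:
    """Log probability of seeing ``k`` unmarked dogs on one transect.

    The count is the sum of owned-unmarked detections
    ``A ~ Binomial(n_owned_unmarked, q_owned)`` and ownerless detections
    ``B ~ Poisson(lambda_detect)``; the convolution is evaluated exactly
    over the feasible binomial contribution, truncating Poisson terms whose
    upper-tail mass is below ``tail_eps``.
    """
    k = int(k)
    n = int(n_owned_unmarked)
    if k < 0:
        raise ValueError(f"count k must be non-negative, got {k}")
    if n < 0:
        raise ValueError(f"owned-unmarked pool must be non-negative, got {n}")
    if not (0.0 <= q_owned <= 1.0):
        raise ValueError(f"detection probability must lie in [0, 1], got {q_owned}")
    if lambda_detect < 0:
        raise ValueError(f"Poisson rate must be non-negative, got {lambda_detect}")

    if lambda_detect == 0.0:
        return float(_binom_logpmf(k, n, q_owned)) if k <= n else -math.inf

    a_max = min(k, n)
    b_cap = _poisson_tail_cap(lambda_detect, tail_eps)
    a_min = max(0, k - b_cap)
    if a_min > a_max:  # truncation removed everything; fall back to exact
        a_min = 0
    a = np.arange(a_min, a_max + 1)
    terms = _binom_logpmf(a, n, q_owned) + _poisson_logpmf(k - a, lambda_detect)
    return float(logsumexp(terms))


def _poisson_tail_cap(lam: float, tail_eps: float = 1e-12) -> int:
    """Smallest count above which the Poisson upper tail is safely below
    ``tail_eps`` (conservative mean + 12 sd + 30 bound; exact quantiles are
    much slower and unnecessary here)."""
    cap = int(lam + 12.0 * math.sqrt(lam) + 30.0)
    # guard: the analytic bound is generous, but verify once when feasible
    if poisson.sf(cap, lam) > tail_eps:  # pragma: no cover - defensive
        cap = int(poisson.isf(tail_eps, lam))
    return cap


def available_marked(marking: MarkingSummary) -> np.ndarray:
    """Number of dogs still carrying a collar at each transect,
    ``M_t = round(Mc * (1 - lm(t)))`` with ties rounded half-up. Dogs that
    lost their collar move into the owned-unmarked detection pool."""
    Mc = marking.n_collared
    return np.array(
        [
            round_half_up_int(Mc * (1.0 - collar_loss_probability(marking, t)))
            for t in range(1, marking.n_transects + 1)
        ],
        dtype=int,
    )


def chapman_estimate(n_marked: int, n_seen: int, n_seen_marked: int) -> float:
    """Chapman's bias-corrected two-sample abundance estimator,
    (Mc+1)(n+1)/(m+1) - 1. Serves as a closed-form cross-check for
    single-transect fits without confinement or ownerless dogs."""
    return (n_marked + 1) * (n_seen + 1) / (n_seen_marked + 1) - 1


class _LogPosterior:
    """Precomputed evaluator for one (observations, priors) pair."""

    def __init__(self, obs: CRObservations, priors: CRPriorSet):
        self.obs = obs
        self.priors = priors
        self.M = available_marked(obs.marking)
        self.m = np.asarray(obs.marked_counts, dtype=int)
        self.u = np.asarray(obs.unmarked_counts, dtype=int)
        self.T = obs.marking.n_transects
        # gammaln lookup table over every factorial index the likelihood can
        # touch (counts, pools up to the owned-prior cap); avoids repeated
        # scipy calls inside the sampler's inner loop
        limit = int(priors.owned.high) + int(self.u.max(initial=0)) + int(self.M.max(initial=0)) + 64
        self._G = gammaln(np.arange(limit + 2, dtype=float))

    def data_impossible(self) -> bool:
        """True when some transect reports more marked dogs than still carry
        a collar; no parameter value gives the data positive probability."""
        return bool(np.any(self.m > self.M))

    def loglike(self, p: float, c: float, r: float, n_owned: int) -> float:
        q = p * (1.0 - c)
        if n_owned < int(self.M.max()):
            return -math.inf
        lam = r * n_owned * p
        G = self._G
        if q <= 0.0 or q >= 1.0:  # degenerate detection; exact limits
            total = 0.0
            for t in range(self.T):
                total += float(_binom_logpmf(self.m[t], int(self.M[t]), q))
                total += unmarked_count_log_pmf(
                    int(self.u[t]), n_owned - int(self.M[t]), q, lam
                )
                if total == -math.inf:
                    return -math.inf
            return total
        logq = math.log(q)
        log1mq = math.log1p(-q)
        if lam > 0.0:
            log_lam = math.log(lam)
            b_cap = int(lam + 12.0 * math.sqrt(lam) + 30.0)
        total = 0.0
        for t in range(self.T):
            m = int(self.m[t])
            M = int(self.M[t])
            if m > M:
                return -math.inf
            total += (G[M + 1] - G[m + 1] - G[M - m + 1]
                      + m * logq + (M - m) * log1mq)
            k = int(self.u[t])
            n = n_owned - M
            if lam <= 0.0:
                if k > n:
                    return -math.inf
                total += (G[n + 1] - G[k + 1] - G[n - k + 1]
                          + k * logq + (n - k) * log1mq)
                continue
            a_hi = min(k, n)
            a_lo = max(0, k - b_cap)
            if a_lo > a_hi:
                a_lo = 0
            a = np.arange(a_lo, a_hi + 1)
            terms = (
                G[n + 1] - G[a + 1] - G[n - a + 1]
                + a * logq + (n - a) * log1mq
                - lam + (k - a) * log_lam - G[k - a + 1]
            )
            mx = terms.max()
            total += mx + math.log(np.exp(terms - mx).sum())
        return total

    def __call__(self, p: float, c: float, log_r: float, n_owned: int) -> float:
        pri = self.priors
        if not pri.recapture.contains(p):
            return -math.inf
        if not pri.confinement.contains(c):
            return -math.inf
        if not pri.owned.contains(n_owned):
            return -math.inf
        if not math.isfinite(log_r):
            return -math.inf
        lp = (
            pri.recapture.logpdf(p)
            + pri.confinement.logpdf(c)
            + pri.ratio.logpdf_log(log_r)
            + pri.owned.logpmf(n_owned)
        )
        if lp == -math.inf:
            return -math.inf
        return lp + self.loglike(p, c, math.exp(log_r), n_owned)


def log_posterior(
    params: CRParameters, obs: CRObservations, priors: CRPriorSet
) -> float:
    """Unnormalised log posterior density of one parameter point.

    Returns ``-inf`` for parameters outside the prior support and for data
    configurations the model cannot produce (e.g. more marked dogs seen than
    still carry collars).
    """
    ev = _LogPosterior(obs, priors)
    if ev.data_impossible():
        return -math.inf
    if params.r <= 0:
        return -math.inf
    return ev(params.p, params.c, math.log(params.r), params.n_owned)


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

class _Component:
    """One Metropolis-within-Gibbs update block with burn-in adaptation."""

    TARGET_RATE = 0.44
    WINDOW = 50

    def __init__(self, name: str, step: float):
        self.name = name
        self.step = step
        self.accepted_window = 0
        self.proposed_window = 0
        self.accepted_post_burn = 0
        self.proposed_post_burn = 0

    def record(self, accepted: bool, adapting: bool) -> None:
        if adapting:
            self.proposed_window += 1
            self.accepted_window += int(accepted)
            if self.proposed_window >= self.WINDOW:
                rate = self.accepted_window / self.proposed_window
                self.step *= math.exp(0.3 * (rate - self.TARGET_RATE))
                self.accepted_window = 0
                self.proposed_window = 0
        else:
            self.proposed_post_burn += 1
            self.accepted_post_burn += int(accepted)


@dataclass
class _ChainState:
    p: float
    c: float
    log_r: float
    n_owned: int
    lp: float


class CaptureRecaptureResults:
    """Posterior draws and summaries from a fitted capture-recapture model.

    Draw arrays have shape ``(n_chains, n_kept)`` and are exposed through
    :attr:`draws` under the keys ``p``, ``c``, ``r``, ``n_owned`` and the
    derived ``lambda_u``.
    """

    def __init__(
        self,
        model: "CaptureRecaptureModel",
        draws: Mapping[str, np.ndarray],
        seed: int,
        n_burn: int,
        acceptance: Mapping[str, float],
        step_sizes: Mapping[str, float],
    ):
        self.model = model
        self.draws = dict(draws)
        self.draws["lambda_u"] = self.draws["r"] * self.draws["n_owned"]
        self.seed = seed
        self.n_burn = n_burn
        self.acceptance = dict(acceptance)
        self.step_sizes = dict(step_sizes)
        self.warnings: list[str] = []
        self._idata = None

    # -- diagnostics --------------------------------------------------------

    def to_inference_data(self):
        """Posterior draws as an ``arviz.InferenceData`` object."""
        if self._idata is None:
            import arviz as az

            self._idata = az.from_dict(posterior={
                k: np.asarray(v, dtype=float) for k, v in self.draws.items()
            })
        return self._idata

    def _diagnostics(self) -> tuple[dict, dict]:
        import arviz as az

        idata = self.to_inference_data()

        def _clean(x: float) -> float | None:
            # single-chain or constant draws give NaN; None keeps reports
            # JSON-valid and comparable
            return float(x) if np.isfinite(x) else None

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ess = {k: _clean(az.ess(idata, var_names=[k])[k]) for k in ("n_owned", "lambda_u")}
            rhat = {k: _clean(az.rhat(idata, var_names=[k])[k]) for k in ("n_owned", "lambda_u")}
        return ess, rhat

    # -- summaries ----------------------------------------------------------

    def posterior_summary(self) -> PosteriorSummary:
        ess, rhat = self._diagnostics()
        summ = summarize_posterior(self.draws, ess=ess, rhat=rhat)
        for k, v in rhat.items():
            if v is not None and v > 1.1:
                msg = (
                    f"split-chain convergence statistic for {k} is {v:.3f} > 1.1; "
                    f"chains may not have mixed"
                )
                if msg not in self.warnings:
                    self.warnings.append(msg)
                    warnings.warn(msg, RuntimeWarning, stacklevel=2)
        return summ

    def summary(self) -> pd.DataFrame:
        """Posterior summary table (means, 95% CrI, diagnostics)."""
        rows = {}
        for k in ("p", "c", "r", "n_owned", "lambda_u"):
            x = np.asarray(self.draws[k], dtype=float).ravel()
            rows[k] = {
                "mean": x.mean(),
                "sd": x.std(ddof=1),
                "2.5%": np.percentile(x, 2.5),
                "97.5%": np.percentile(x, 97.5),
            }
        total = (np.asarray(self.draws["n_owned"], dtype=float)
                 + np.asarray(self.draws["lambda_u"], dtype=float)).ravel()
        rows["total"] = {
            "mean": total.mean(),
            "sd": total.std(ddof=1),
            "2.5%": np.percentile(total, 2.5),
            "97.5%": np.percentile(total, 97.5),
        }
        df = pd.DataFrame(rows).T
        ess, rhat = self._diagnostics()
        df["ess"] = pd.Series(ess)
        df["r_hat"] = pd.Series(rhat)
        return df

    # -- plotting -----------------------------------------------------------

    def plot_trace(self, var_names: Sequence[str] = ("n_owned", "lambda_u")):
        """Trace and density plots via arviz (returns the axes array)."""
        import arviz as az

        return az.plot_trace(self.to_inference_data(), var_names=list(var_names))

    def plot_posterior(self, var_names: Sequence[str] = ("n_owned", "lambda_u")):
        import arviz as az

        return az.plot_posterior(self.to_inference_data(), var_names=list(var_names))


class CaptureRecaptureModel:
    """Mark-resight model of a village dog population.

    Parameters
    ----------
    observations
        Marked/unmarked transect counts plus the marking summary.
    priors
        Recapture, confinement, ratio and owned-count priors, typically
        elicited with :mod:`frdd.priors`.
    """

    def __init__(self, observations: CRObservations, priors: CRPriorSet):
        if observations.marking.n_collared < 1:
            raise ValueError(
                "capture-recapture requires at least one marked dog (Mc >= 1)"
            )
        self._ev = _LogPosterior(observations, priors)
        if self._ev.data_impossible():
            raise ValueError(
                "observed marked counts exceed the number of dogs still "
                "carrying a collar under the collar-loss schedule"
            )
        self.observations = observations
        self.priors = priors

    # -- construction helpers ----------------------------------------------

    @classmethod
    def from_counts(
        cls,
        marking: MarkingSummary,
        marked_counts: Sequence[int],
        unmarked_counts: Sequence[int],
        priors: CRPriorSet,
    ) -> "CaptureRecaptureModel":
        obs = CRObservations(marking, tuple(marked_counts), tuple(unmarked_counts))
        return cls(obs, priors)

    # -- densities ----------------------------------------------------------

    def loglike(self, params: CRParameters) -> float:
        """Data log likelihood at one parameter point (no priors)."""
        return self._ev.loglike(params.p, params.c, params.r, params.n_owned)

    def logposterior(self, params: CRParameters) -> float:
        return log_posterior(params, self.observations, self.priors)

    # -- fitting ------------------------------------------------------------

    def _initial_state(self, rng: np.random.Generator) -> _ChainState:
        pri = self.priors
        for _ in range(200):
            p = pri.recapture.sample(rng)
            c = pri.confinement.sample(rng)
            r = pri.ratio.sample(rng)
            n = pri.owned.sample(rng)
            n = max(n, int(self._ev.M.max()))
            if not pri.owned.contains(n):
                continue
            lp = self._ev(p, c, math.log(r), n)
            if math.isfinite(lp):
                return _ChainState(p, c, math.log(r), n, lp)
        raise RuntimeError(
            "could not find a starting point with finite posterior density; "
            "check that the priors are compatible with the observed counts"
        )

    def _run_chain(
        self,
        rng: np.random.Generator,
        n_iter: int,
        n_burn: int,
    ) -> tuple[dict, dict, dict]:
        pri = self.priors
        ev = self._ev
        state = self._initial_state(rng)

        free_p = pri.recapture.width > 0
        free_c = pri.confinement.width > 0
        free_n = pri.owned.high > pri.owned.low
        if not free_p:
            state.p = pri.recapture.low
        if not free_c:
            state.c = pri.confinement.low

        comp = {
            "p": _Component("p", 0.8),
            "c": _Component("c", 0.8),
            "log_r": _Component("log_r", max(0.5, 1.5 / math.sqrt(getattr(pri.ratio, "tau", 1.0)))),
            "n_owned": _Component("n_owned", max(2.0, (pri.owned.high - pri.owned.low) / 20.0)),
        }
        n_keep = n_iter - n_burn
        kept = {k: np.empty(n_keep) for k in ("p", "c", "r", "n_owned")}

        def _logit_jac(u: float) -> float:
            # log |du/dz| for u = expit(z); guards the support edges
            return math.log(u) + math.log1p(-u)

        for it in range(n_iter):
            adapting = it < n_burn

            if free_p:
                lo, w = pri.recapture.low, pri.recapture.width
                u = min(max((state.p - lo) / w, 1e-12), 1 - 1e-12)
                z = logit(u)
                u_new = float(expit(z + rng.normal(0.0, comp["p"].step)))
                p_new = lo + u_new * w
                lp_new = ev(p_new, state.c, state.log_r, state.n_owned)
                log_acc = lp_new - state.lp + _logit_jac(u_new) - _logit_jac(u)
                ok = math.log(rng.uniform()) < log_acc
                if ok:
                    state.p, state.lp = p_new, lp_new
                comp["p"].record(ok, adapting)

            if free_c:
                lo, w = pri.confinement.low, pri.confinement.width
                u = min(max((state.c - lo) / w, 1e-12), 1 - 1e-12)
                z = logit(u)
                u_new = float(expit(z + rng.normal(0.0, comp["c"].step)))
                c_new = lo + u_new * w
                lp_new = ev(state.p, c_new, state.log_r, state.n_owned)
                log_acc = lp_new - state.lp + _logit_jac(u_new) - _logit_jac(u)
                ok = math.log(rng.uniform()) < log_acc
                if ok:
                    state.c, state.lp = c_new, lp_new
                comp["c"].record(ok, adapting)

            x_new = state.log_r + rng.normal(0.0, comp["log_r"].step)
            lp_new = ev(state.p, state.c, x_new, state.n_owned)
            ok = math.log(rng.uniform()) < lp_new - state.lp
            if ok:
                state.log_r, state.lp = x_new, lp_new
            comp["log_r"].record(ok, adapting)

            if free_n:
                step = max(1, int(round(comp["n_owned"].step)))
                delta = int(rng.integers(1, step + 1)) * (1 if rng.uniform() < 0.5 else -1)
                n_new = state.n_owned + delta
                if pri.owned.contains(n_new):
                    lp_new = ev(state.p, state.c, state.log_r, n_new)
                    ok = math.log(rng.uniform()) < lp_new - state.lp
                else:
                    ok = False  # moves outside the support are rejected
                if ok:
                    state.n_owned, state.lp = n_new, lp_new
                comp["n_owned"].record(ok, adapting)

            if it >= n_burn:
                j = it - n_burn
                kept["p"][j] = state.p
                kept["c"][j] = state.c
                kept["r"][j] = math.exp(state.log_r)
                kept["n_owned"][j] = state.n_owned

        accept = {
            k: (v.accepted_post_burn / v.proposed_post_burn if v.proposed_post_burn else math.nan)
            for k, v in comp.items()
        }
        steps = {k: v.step for k, v in comp.items()}
        stalled = [
            k for k, v in comp.items()
            if v.proposed_post_burn > 0 and v.accepted_post_burn == 0
        ]
        return kept, accept, steps, stalled

    def fit(
        self,
        n_chains: int = 4,
        n_iter: int = 50_000,
        n_burn: int = 10_000,
        seed: int | None = None,
    ) -> CaptureRecaptureResults:
        """Draw from the posterior by Metropolis-within-Gibbs.

        ``seed`` is mandatory: the sampler is stochastic and runs must be
        reproducible.
        """
        if seed is None:
            raise ValueError("a seed is required for a reproducible fit")
        if n_iter <= n_burn:
            raise ValueError(f"n_iter ({n_iter}) must exceed n_burn ({n_burn})")
        ss = np.random.SeedSequence(seed)
        chain_rngs = [np.random.default_rng(s) for s in ss.spawn(n_chains)]
        draws = {k: [] for k in ("p", "c", "r", "n_owned")}
        accept_all: dict[str, list[float]] = {}
        steps_last: dict[str, float] = {}
        stalled_all: set[str] = set()
        for rng in chain_rngs:
            kept, accept, steps, stalled = self._run_chain(rng, n_iter, n_burn)
            for k in draws:
                draws[k].append(kept[k])
            for k, v in accept.items():
                accept_all.setdefault(k, []).append(v)
            steps_last = steps
            stalled_all.update(stalled)
        draws_arr = {k: np.vstack(v) for k, v in draws.items()}
        stall_warnings = []
        for k in sorted(stalled_all):
            key = "r" if k == "log_r" else k
            # a component that never moves is acceptable only when every
            # chain agrees on a single value (a point-mass posterior, e.g.
            # perfect detection pinning the owned count); otherwise the
            # sampler is genuinely stuck
            if np.unique(draws_arr[key]).size > 1:
                raise RuntimeError(
                    f"sampler stalled: zero post-burn-in acceptance for "
                    f"component {k!r} with chains stuck at different values"
                )
            msg = (
                f"zero post-burn-in acceptance for component {k!r}: the "
                f"posterior is a point mass there"
            )
            warnings.warn(msg, RuntimeWarning, stacklevel=2)
            stall_warnings.append(msg)
        accept_mean = {
            k: (float(np.nanmean(v)) if not np.all(np.isnan(v)) else math.nan)
            for k, v in accept_all.items()
        }
        results = CaptureRecaptureResults(
            self, draws_arr, seed=seed, n_burn=n_burn,
            acceptance=accept_mean, step_sizes=steps_last,
        )
        results.warnings.extend(stall_warnings)
        return results

    # -- sensitivity --------------------------------------------------------

    def prior_sensitivity(
        self,
        perturbations: Mapping[str, Mapping[str, object]],
        n_chains: int = 2,
        n_iter: int = 8000,
        n_burn: int = 2500,
        seed: int = 0,
    ) -> pd.DataFrame:
        """Refit under perturbed priors and report percent changes.

        ``perturbations`` maps a label to a dict of prior-component
        replacements, e.g. ``{"wide_conf": {"confinement": UniformPrior(0.1,
        0.5)}, "gamma_ratio": {"ratio": GammaRatioPrior(1.0, 10.0)}}``. An
        empty dict is the identity perturbation. Returns percent change of
        the posterior owned / ownerless / total means relative to the
        baseline fit (same seed and chain settings throughout).
        """
        _FAMILIES = {
            "recapture": UniformPrior,
            "confinement": UniformPrior,
            "ratio": (LogNormalPrior, GammaRatioPrior),
            "owned": DiscreteUniformPrior,
        }
        for label, repl in perturbations.items():
            for comp_name, prior in repl.items():
                if comp_name not in _FAMILIES:
                    raise ValueError(
                        f"perturbation {label!r}: unknown prior component {comp_name!r}"
                    )
                if not isinstance(prior, _FAMILIES[comp_name]):
                    raise ValueError(
                        f"perturbation {label!r}: {comp_name!r} expects "
                        f"{_FAMILIES[comp_name]}, got {type(prior).__name__}"
                    )

        def _means(priors: CRPriorSet) -> tuple[float, float, float]:
            mod = CaptureRecaptureModel(self.observations, priors)
            res = mod.fit(n_chains=n_chains, n_iter=n_iter, n_burn=n_burn, seed=seed)
            owned = float(np.mean(res.draws["n_owned"]))
            ownerless = float(np.mean(res.draws["lambda_u"]))
            return owned, ownerless, owned + ownerless

        base = _means(self.priors)
        rows = {}
        for label, repl in perturbations.items():
            pert = _means(self.priors.replace(**repl))
            rows[label] = {
                f"{name}_pct_change": (
                    100.0 * (new - old) / old if old != 0 else math.nan
                )
                for name, new, old in zip(
                    ("owned", "ownerless", "total"), pert, base
                )
            }
        out = pd.DataFrame(rows).T
        out.attrs["baseline_means"] = dict(zip(("owned", "ownerless", "total"), base))
        return out


# ---------------------------------------------------------------------------
# functional front-ends
# ---------------------------------------------------------------------------

def fit_cr_model(
    obs: CRObservations,
    priors: CRPriorSet,
    n_chains: int = 4,
    n_iter: int = 50_000,
    n_burn: int = 10_000,
    seed: int | None = None,
) -> CaptureRecaptureResults:
    """Convenience wrapper: build a :class:`CaptureRecaptureModel` and fit it."""
    return CaptureRecaptureModel(obs, priors).fit(
        n_chains=n_chains, n_iter=n_iter, n_burn=n_burn, seed=seed
    )


def summarize_posterior(
    draws: Mapping[str, np.ndarray],
    ess: Mapping[str, float] | None = None,
    rhat: Mapping[str, float] | None = None,
) -> PosteriorSummary:
    """Posterior means and equal-tailed 95% CrIs from draw arrays.

    ``draws`` must contain ``n_owned`` and either ``lambda_u`` or both ``r``
    and ``n_owned`` from which it is derived. Percentiles use linear
    interpolation (the BUGS-style equal-tailed summary).
    """
    if "n_owned" not in draws:
        raise ValueError("draws must contain 'n_owned'")
    n_owned = np.asarray(draws["n_owned"], dtype=float).ravel()
    if n_owned.size == 0:
        raise ValueError("empty draws")
    if n_owned.size < 1000:
        warnings.warn(
            f"only {n_owned.size} draws; summaries may be unstable",
            RuntimeWarning, stacklevel=2,
        )
    if "lambda_u" in draws:
        lam = np.asarray(draws["lambda_u"], dtype=float).ravel()
    elif "r" in draws:
        lam = np.asarray(draws["r"], dtype=float).ravel() * n_owned
    else:
        raise ValueError("draws must contain 'lambda_u' or 'r'")
    total = n_owned + lam

    def _iv(x: np.ndarray) -> IntervalSummary:
        return IntervalSummary(
            mean=float(x.mean()),
            cri_low=float(np.percentile(x, 2.5)),
            cri_high=float(np.percentile(x, 97.5)),
        )

    return PosteriorSummary(
        owned=_iv(n_owned), ownerless=_iv(lam), total=_iv(total),
        ess=dict(ess or {}), rhat=dict(rhat or {}),
    )


def prior_sensitivity(
    obs: CRObservations,
    priors: CRPriorSet,
    perturbations: Mapping[str, Mapping[str, object]],
    **fit_kwargs,
) -> pd.DataFrame:
    """Functional front-end to :meth:`CaptureRecaptureModel.prior_sensitivity`."""
    return CaptureRecaptureModel(obs, priors).prior_sensitivity(
        perturbations, **fit_kwargs
    )
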