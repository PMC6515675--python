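"""Posterior predictive probabilities of end-of-trial success.

Two quantities drive sequential stopping:

* ``P_curr`` — probability that the trial would be declared successful at
  the *current* sample size once every already-enrolled patient completes
  the 30-day follow-up.  Patients enrolled but without an observed outcome
  ("in transit") are integrated out under the beta-binomial posterior
  predictive distribution.  ``P_curr`` above a success boundary stops
  accrual for success.
* ``P_max`` — probability of success if accrual instead continues to the
  maximum sample size, additionally integrating over the outcomes of all
  future patients (allocated deterministically between arms and thinned by
  the anticipated dropout rate).  ``P_max`` below a futility boundary stops
  the trial for futility.

Both are posterior predictive quantities: each draw first samples the arm
event rates from their current posteriors and then outcomes given those
rates, so parameter uncertainty propagates into the imputation.  When few
outcomes are outstanding the Monte-Carlo estimate is replaced by exact
enumeration over the beta-binomial predictive mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._boundary import get_boundary
from .inference import ArmCounts

__all__ = [
    "InterimSnapshot",
    "PredictiveResult",
    "predictive_prob_current",
    "predictive_prob_max",
    "split_future_patients",
    "EXACT_ENUMERATION_LIMIT",
]

#: exact enumeration replaces Monte Carlo when at most this many outcomes
#: are outstanding (and dropout thinning plays no role)
EXACT_ENUMERATION_LIMIT = 20


@dataclass(frozen=True)
class InterimSnapshot:
    """Per-arm randomised / complete / death counts at an interim look.

    ``complete`` counts patients with an observed 30-day outcome; ``deaths``
    are events among those complete.  ``randomised - complete`` patients are
    in transit (enrolled, outcome pending or ultimately missing).
    """

    randomised_control: int
    randomised_treatment: int
    complete_control: int
    complete_treatment: int
    deaths_control: int
    deaths_treatment: int

    def __post_init__(self) -> None:
        for arm in ("control", "treatment"):
            r = getattr(self, f"randomised_{arm}")
            c = getattr(self, f"complete_{arm}")
            d = getattr(self, f"deaths_{arm}")
            if not 0 <= d <= c <= r:
                raise ValueError(
                    f"{arm}: require 0 <= deaths <= complete <= randomised, "
                    f"got {d}/{c}/{r}"
                )

    @property
    def randomised_total(self) -> int:
        return self.randomised_control + self.randomised_treatment

    @property
    def in_transit_control(self) -> int:
        return self.randomised_control - self.complete_control

    @property
    def in_transit_treatment(self) -> int:
        return self.randomised_treatment - self.complete_treatment

    @property
    def counts_control(self) -> ArmCounts:
        return ArmCounts(self.deaths_control, self.complete_control)

    @property
    def counts_treatment(self) -> ArmCounts:
        return ArmCounts(self.deaths_treatment, self.complete_treatment)


@dataclass(frozen=True)
class PredictiveResult:
    probability: float
    n_draws: int
    seed: int | None
    kind: str  # "P_curr" | "P_max"
    exact: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability outside [0, 1]")


def split_future_patients(
    remaining: int, allocation: tuple[int, int] = (1, 1)
) -> tuple[int, int]:
    """Deterministic split of future slots between (control, treatment).

    Largest-remainder allocation; with 1:1 allocation an odd remainder goes
    to the control arm.
    """
    if remaining < 0:
        raise ValueError("remaining patients cannot be negative")
    c, t = allocation
    if c <= 0 or t <= 0:
        raise ValueError("allocation ratio parts must be positive")
    future_t = int(remaining * t // (c + t))
    return remaining - future_t, future_t


def _posteriors(
    snapshot: InterimSnapshot,
    prior: tuple[float, float],
    prior_treatment: tuple[float, float] | None,
):
    a0c, b0c = prior
    a0t, b0t = prior_treatment or prior
    return (
        (a0c + snapshot.deaths_control, b0c + snapshot.complete_control - snapshot.deaths_control),
        (a0t + snapshot.deaths_treatment, b0t + snapshot.complete_treatment - snapshot.deaths_treatment),
    )


def _enumerate(
    snapshot, post_c, post_t, extra_c, extra_t, n_final_c, n_final_t, boundary
) -> float:
    """Exact predictive probability by beta-binomial enumeration of the
    outstanding death totals in each arm."""
    pmf_c = stats.betabinom.pmf(np.arange(extra_c + 1), extra_c, *post_c)
    pmf_t = stats.betabinom.pmf(np.arange(extra_t + 1), extra_t, *post_t)
    d_c = snapshot.deaths_control + np.arange(extra_c + 1)
    cut = boundary.cutoffs(n_final_c, n_final_t, int(d_c[0]), int(d_c[-1]))
    # P(treatment deaths <= cutoff - observed) per control configuration
    k = cut - snapshot.deaths_treatment  # max additional treatment deaths
    cdf_t = np.concatenate([[0.0], np.cumsum(pmf_t)])
    k_clip = np.clip(k + 1, 0, extra_t + 1)
    # rounding in the pmf sums can overshoot the unit interval by an ulp
    return float(np.clip(np.dot(pmf_c, cdf_t[k_clip]), 0.0, 1.0))


def _monte_carlo(
    snapshot,
    post_c,
    post_t,
    transit_c,
    transit_t,
    future_c,
    future_t,
    dropout,
    dropout_in_transit,
    n_draws,
    rng,
    boundary,
) -> float:
    p_c = rng.beta(*post_c, size=n_draws)
    p_t = rng.beta(*post_t, size=n_draws)
    kept_transit_c, kept_transit_t = transit_c, transit_t
    if dropout_in_transit and dropout > 0.0:
        kept_transit_c = transit_c - rng.binomial(transit_c, dropout, size=n_draws)
        kept_transit_t = transit_t - rng.binomial(transit_t, dropout, size=n_draws)
    x_c = rng.binomial(kept_transit_c, p_c)
    x_t = rng.binomial(kept_transit_t, p_t)
    kept_future_c, kept_future_t = future_c, future_t
    if dropout > 0.0 and (future_c or future_t):
        kept_future_c = future_c - rng.binomial(future_c, dropout, size=n_draws)
        kept_future_t = future_t - rng.binomial(future_t, dropout, size=n_draws)
    y_c = rng.binomial(kept_future_c, p_c)
    y_t = rng.binomial(kept_future_t, p_t)
    d_final_c = snapshot.deaths_control + x_c + y_c
    d_final_t = snapshot.deaths_treatment + x_t + y_t
    n_final_c = snapshot.complete_control + kept_transit_c + kept_future_c
    n_final_t = snapshot.complete_treatment + kept_transit_t + kept_future_t
    ok = boundary.success(d_final_c, n_final_c, d_final_t, n_final_t)
    return float(np.mean(ok))


def _resolve_rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed, None
    return np.random.default_rng(seed), (int(seed) if seed is not None else None)


def predictive_prob_current(
    snapshot: InterimSnapshot,
    prior: tuple[float, float] = (1.0, 1.0),
    final_threshold: float = 0.975,
    n_draws: int = 10_000,
    *,
    seed: int | np.random.Generator,
    prior_treatment: tuple[float, float] | None = None,
    exact_limit: int = EXACT_ENUMERATION_LIMIT,
) -> PredictiveResult:
    """``P_curr``: predictive probability of success at the current sample size.

    In-transit patients are imputed as eventually observed (no dropout
    thinning: they are already enrolled and being followed), so the final
    denominators equal the randomised counts at the interim.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be at least 1")
    post_c, post_t = _posteriors(snapshot, prior, prior_treatment)
    boundary = get_boundary(
        (prior[0], prior[1]), prior_treatment or prior, final_threshold
    )
    m_c, m_t = snapshot.in_transit_control, snapshot.in_transit_treatment
    n_c, n_t = snapshot.randomised_control, snapshot.randomised_treatment
    if m_c + m_t <= exact_limit:
        p = _enumerate(snapshot, post_c, post_t, m_c, m_t, n_c, n_t, boundary)
        return PredictiveResult(p, n_draws, None, "P_curr", exact=True)
    rng, seed_out = _resolve_rng(seed)
    p = _monte_carlo(
        snapshot, post_c, post_t, m_c, m_t, 0, 0, 0.0, False, n_draws, rng, boundary
    )
    return PredictiveResult(p, n_draws, seed_out, "P_curr", exact=False)


def predictive_prob_max(
    snapshot: InterimSnapshot,
    prior: tuple[float, float] = (1.0, 1.0),
    n_max: int = 1006,
    allocation: tuple[int, int] = (1, 1),
    dropout: float = 0.03,
    final_threshold: float = 0.975,
    n_draws: int = 10_000,
    *,
    seed: int | np.random.Generator,
    prior_treatment: tuple[float, float] | None = None,
    dropout_in_transit: bool = False,
    exact_limit: int = EXACT_ENUMERATION_LIMIT,
) -> PredictiveResult:
    """``P_max``: predictive probability of success at the maximum sample size.

    The ``n_max - randomised`` future patients are split between arms by the
    allocation ratio (deterministic largest-remainder split, odd patient to
    control under 1:1) and each is lost to follow-up with the anticipated
    ``dropout`` probability before contributing an outcome.  In-transit
    patients are imputed as observed unless ``dropout_in_transit`` is set.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be at least 1")
    if not 0.0 <= dropout < 1.0:
        raise ValueError("dropout must lie in [0, 1)")
    remaining = n_max - snapshot.randomised_total
    if remaining < 0:
        raise ValueError(
            f"n_max={n_max} below randomised total {snapshot.randomised_total}"
        )
    future_c, future_t = split_future_patients(remaining, allocation)
    post_c, post_t = _posteriors(snapshot, prior, prior_treatment)
    boundary = get_boundary(
        (prior[0], prior[1]), prior_treatment or prior, final_threshold
    )
    m_c, m_t = snapshot.in_transit_control, snapshot.in_transit_treatment
    outstanding = m_c + m_t + remaining
    dropout_matters = (dropout > 0.0 and remaining > 0) or (
        dropout_in_transit and dropout > 0.0 and m_c + m_t > 0
    )
    if outstanding <= exact_limit and not dropout_matters:
        n_final_c = snapshot.randomised_control + future_c
        n_final_t = snapshot.randomised_treatment + future_t
        p = _enumerate(
            snapshot, post_c, post_t, m_c + future_c, m_t + future_t,
            n_final_c, n_final_t, boundary,
        )
        return PredictiveResult(p, n_draws, None, "P_max", exact=True)
    rng, seed_out = _resolve_rng(seed)
    p = _monte_carlo(
        snapshot, post_c, post_t, m_c, m_t, future_c, future_t,
        dropout, dropout_in_transit, n_draws, rng, boundary,
    )
    return PredictiveResult(p, n_draws, seed_out, "P_max", exact=False)
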