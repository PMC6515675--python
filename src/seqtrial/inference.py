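"""Conjugate beta-binomial inference for two-arm trials with a binary endpoint.

The primary outcome is a binary event (here: death within 30 days of
randomisation).  Each arm's event rate ``p`` carries an independent
``Beta(alpha0, beta0)`` prior; observing ``d`` events among ``n`` analysed
patients yields the conjugate posterior ``Beta(alpha0 + d, beta0 + n - d)``.
The quantity that drives all trial decisions is the posterior probability
that the treatment arm has the *lower* event rate,

    P(p_T < p_C | data),

with ``p_T`` and ``p_C`` independent beta variables.  This module computes
that probability exactly (closed-form finite sum for integer shape
parameters, adaptive quadrature otherwise), applies the final success rule
(probability strictly above a threshold, 0.975 by default), and provides the
frequentist relative risk with its log-normal (Katz) confidence interval and
the continuity-corrected two-proportion sample-size formula used to plan
fixed designs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, special, stats

__all__ = [
    "ArmCounts",
    "BetaPosterior",
    "SuperiorityResult",
    "RelativeRiskResult",
    "SampleSizeInputs",
    "SampleSizeResult",
    "ConvergenceError",
    "ZeroCellError",
    "posterior_from_counts",
    "prob_superiority",
    "final_success",
    "relative_risk",
    "sample_size_two_proportions",
]


class ConvergenceError(RuntimeError):
    """Raised when numerical integration cannot certify the requested accuracy."""


class ZeroCellError(ValueError):
    """Raised when a contingency cell required by an estimator is zero."""


@dataclass(frozen=True)
class ArmCounts:
    """Event counts for one arm: ``deaths`` events among ``analysed`` patients."""

    deaths: int
    analysed: int

    def __post_init__(self) -> None:
        if self.deaths != int(self.deaths) or self.analysed != int(self.analysed):
            raise ValueError("counts must be integers")
        if not 0 <= self.deaths <= self.analysed:
            raise ValueError(
                f"require 0 <= deaths <= analysed, got {self.deaths}/{self.analysed}"
            )

    @property
    def survivors(self) -> int:
        return self.analysed - self.deaths

    @property
    def rate(self) -> float:
        if self.analysed == 0:
            raise ZeroDivisionError("rate undefined with zero analysed patients")
        return self.deaths / self.analysed


@dataclass(frozen=True)
class BetaPosterior:
    """Beta distribution for an arm's event rate (prior or posterior)."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("beta parameters must be positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


@dataclass(frozen=True)
class SuperiorityResult:
    """Posterior probability that the treatment event rate is the lower one."""

    prob_superior: float
    method: str  # "quadrature" | "closed_form" | "monte_carlo"

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob_superior <= 1.0:
            raise ValueError("probability outside [0, 1]")


@dataclass(frozen=True)
class RelativeRiskResult:
    """Relative risk (treatment rate / control rate) with a two-sided CI."""

    rr: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not self.ci_low <= self.rr <= self.ci_high:
            raise ValueError("interval must contain the point estimate")


def posterior_from_counts(
    counts: ArmCounts, prior_alpha: float = 1.0, prior_beta: float = 1.0
) -> BetaPosterior:
    """Conjugate update: ``Beta(a0 + deaths, b0 + survivors)``."""
    if not (prior_alpha > 0 and prior_beta > 0):
        raise ValueError("prior parameters must be positive")
    return BetaPosterior(prior_alpha + counts.deaths, prior_beta + counts.survivors)


def _is_integer(x: float) -> bool:
    return abs(x - round(x)) < 1e-9


def _prob_less_closed(a1: float, b1: float, a2: float, b2: float) -> float:
    """P(X < Y) for X ~ Beta(a1, b1), Y ~ Beta(a2, b2), ``a2`` a positive integer.

    Finite sum over the ``a2`` terms of the beta-binomial tail identity; all
    factors are evaluated on the log scale for stability.
    """
    m = round(a2)
    j = np.arange(m, dtype=np.float64)
    log_terms = (
        special.betaln(a1 + j, b1 + b2)
        - np.log(b2 + j)
        - special.betaln(1.0 + j, b2)
        - special.betaln(a1, b1)
    )
    return float(min(1.0, np.exp(log_terms).sum()))


def _prob_less_quad(a1: float, b1: float, a2: float, b2: float, tol: float) -> float:
    """P(X < Y) by adaptive quadrature of E_Y[F_X(Y)]."""

    def integrand(y: float) -> float:
        return special.betainc(a1, b1, y) * stats.beta.pdf(y, a2, b2)

    mode = (a2 - 1) / (a2 + b2 - 2) if a2 > 1 and b2 > 1 else a2 / (a2 + b2)
    value, abserr = integrate.quad(
        integrand, 0.0, 1.0, points=[mode], epsabs=tol / 10.0, epsrel=0.0, limit=500
    )
    if abserr > tol:
        raise ConvergenceError(
            f"quadrature error estimate {abserr:.2e} exceeds tolerance {tol:.2e}"
        )
    return float(min(1.0, max(0.0, value)))


# closed-form sums longer than this fall back to quadrature
_MAX_CLOSED_TERMS = 100_000


def prob_superiority(
    post_treatment: BetaPosterior,
    post_control: BetaPosterior,
    tol: float = 1e-8,
    method: str = "auto",
    n_draws: int = 1_000_000,
    seed: int | np.random.Generator | None = None,
) -> SuperiorityResult:
    """Posterior probability that the treatment rate is below the control rate.

    Computes ``P(p_T < p_C)`` for independent beta posteriors.  With
    ``method="auto"`` the exact finite sum is used whenever a shape parameter
    is a (moderate) integer, otherwise adaptive quadrature certified to
    absolute accuracy ``tol``.  The Monte-Carlo path exists as an independent
    cross-check, not as a default.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    a1, b1 = post_treatment.alpha, post_treatment.beta
    a2, b2 = post_control.alpha, post_control.beta

    if method == "monte_carlo":
        rng = np.random.default_rng(seed)
        x = rng.beta(a1, b1, size=n_draws)
        y = rng.beta(a2, b2, size=n_draws)
        return SuperiorityResult(float(np.mean(x < y)), "monte_carlo")

    if method in ("auto", "closed_form"):
        candidates = []
        if _is_integer(a2) and round(a2) <= _MAX_CLOSED_TERMS:
            candidates.append(("direct", round(a2)))
        if _is_integer(a1) and round(a1) <= _MAX_CLOSED_TERMS:
            candidates.append(("complement", round(a1)))
        if candidates:
            kind, _ = min(candidates, key=lambda c: c[1])
            if kind == "direct":
                p = _prob_less_closed(a1, b1, a2, b2)
            else:
                p = 1.0 - _prob_less_closed(a2, b2, a1, b1)
            return SuperiorityResult(p, "closed_form")
        if method == "closed_form":
            raise ValueError("closed form requires an integer alpha parameter")

    if method not in ("auto", "quadrature"):
        raise ValueError(f"unknown method {method!r}")
    return SuperiorityResult(_prob_less_quad(a1, b1, a2, b2, tol), "quadrature")


def final_success(
    counts_control: ArmCounts,
    counts_treatment: ArmCounts,
    prior: tuple[float, float] = (1.0, 1.0),
    threshold: float = 0.975,
    prior_treatment: tuple[float, float] | None = None,
) -> bool:
    """Final success rule: posterior probability of superiority strictly above
    the threshold (default 0.975).

    ``prior`` applies to both arms unless ``prior_treatment`` overrides the
    treatment arm.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    pc = posterior_from_counts(counts_control, *prior)
    pt = posterior_from_counts(counts_treatment, *(prior_treatment or prior))
    return prob_superiority(pt, pc).prob_superior > threshold


def relative_risk(
    counts_control: ArmCounts, counts_treatment: ArmCounts, level: float = 0.95
) -> RelativeRiskResult:
    """Relative risk with the log-normal (Katz) confidence interval.

    RR = (d_T / n_T) / (d_C / n_C); the CI is computed on the log scale with
    variance ``1/d_T - 1/n_T + 1/d_C - 1/n_C``.  Any zero cell (no events or
    no survivors in an arm) makes the interval undefined and raises
    :class:`ZeroCellError`; no continuity correction is applied silently.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    d_c, n_c = counts_control.deaths, counts_control.analysed
    d_t, n_t = counts_treatment.deaths, counts_treatment.analysed
    if n_c == 0 or n_t == 0 or d_c == 0:
        raise ZeroCellError("point estimate requires non-zero denominators and control events")
    rr = (d_t / n_t) / (d_c / n_c)
    if min(d_t, n_t - d_t, d_c, n_c - d_c) == 0:
        raise ZeroCellError("confidence interval undefined with a zero cell")
    se_log = math.sqrt(1.0 / d_t - 1.0 / n_t + 1.0 / d_c - 1.0 / n_c)
    z = stats.norm.ppf(0.5 + level / 2.0)
    return RelativeRiskResult(
        rr=rr,
        ci_low=rr * math.exp(-z * se_log),
        ci_high=rr * math.exp(z * se_log),
        level=level,
    )


@dataclass(frozen=True)
class SampleSizeInputs:
    """Inputs to the two-proportion sample-size calculation.

    ``absolute_reduction`` is the targeted drop in the event rate from
    ``p_control``; ``dropout`` inflates the corrected per-arm size by
    ``1 / (1 - dropout)``.
    """

    p_control: float
    absolute_reduction: float
    alpha_two_sided: float = 0.05
    power: float = 0.80
    dropout: float = 0.0

    def __post_init__(self) -> None:
        p2 = self.p_control - self.absolute_reduction
        if not 0.0 < p2 < self.p_control < 1.0:
            raise ValueError("require 0 < p_control - reduction < p_control < 1")
        if not 0.0 < self.power < 1.0:
            raise ValueError("power must lie in (0, 1)")
        if not 0.0 < self.alpha_two_sided < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


@dataclass(frozen=True)
class SampleSizeResult:
    per_arm: int
    total: int
    n_uncorrected: float
    n_corrected: float


def sample_size_two_proportions(inputs: SampleSizeInputs) -> SampleSizeResult:
    """Continuity-corrected (Fleiss / Casagrande-Pike-Smith) two-proportion
    sample size, inflated for dropout.

    The uncorrected normal-approximation size per arm is

        n = (z_{1-a/2} sqrt(2 p q) + z_{power} sqrt(p1 q1 + p2 q2))^2 / d^2

    with ``p`` the pooled rate and ``d`` the absolute difference; the
    continuity correction is ``n_cc = n/4 (1 + sqrt(1 + 4/(n d)))^2``.  The
    per-arm size is ``ceil(n_cc / (1 - dropout))`` and the total is twice
    that.
    """
    p1 = inputs.p_control
    p2 = inputs.p_control - inputs.absolute_reduction
    d = inputs.absolute_reduction
    z_a = stats.norm.ppf(1.0 - inputs.alpha_two_sided / 2.0)
    z_b = stats.norm.ppf(inputs.power)
    p_bar = (p1 + p2) / 2.0
    q_bar = 1.0 - p_bar
    n = (z_a * math.sqrt(2.0 * p_bar * q_bar) + z_b * math.sqrt(p1 * (1 - p1) + p2 * (1 - p2))) ** 2 / d**2
    n_cc = n / 4.0 * (1.0 + math.sqrt(1.0 + 4.0 / (n * d))) ** 2
    per_arm = math.ceil(n_cc / (1.0 - inputs.dropout) - 1e-12)
    return SampleSizeResult(per_arm=per_arm, total=2 * per_arm, n_uncorrected=n, n_corrected=n_cc)
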