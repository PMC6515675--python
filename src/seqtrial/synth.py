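"""Synthetic patient-level streams for sequential-trial analysis.

Two generators are provided.  :func:`generate_stream` draws a stream with
the statistical structure every analysis in this package assumes: Poisson
accrual at a mean weekly rate, fair-coin 1:1 allocation, Bernoulli 30-day
outcomes at the scenario's per-arm event rates, and independent loss to
follow-up (missing outcome) at the dropout probability.  Outcomes are fixed
at generation time and revealed to analyses only once 30 days of follow-up
have elapsed.

:func:`generate_fixture` instead builds a stream under *exact count
constraints*: at each constrained trigger (a cumulative recruit count) the
interim snapshot recomputed from the stream — per-arm randomised, complete
and death counts — equals the constraint exactly.  Completeness is
controlled mechanically through recruit-time placement: patients required
to be complete at a trigger are recruited at least one follow-up window
before the trigger patient, in-transit patients inside the trailing window.
This makes the re-execution engine testable against published interim
tables without access to the underlying patient data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import ScenarioSpec

__all__ = [
    "CountConstraint",
    "InfeasibleConstraintError",
    "generate_stream",
    "generate_fixture",
    "load_constraints",
    "dump_constraints",
]

_TIME_EPS = 1e-6  # weeks; separates completeness cutoffs from recruit times


class InfeasibleConstraintError(ValueError):
    """Raised when no stream can satisfy the requested count constraints."""


@dataclass(frozen=True)
class CountConstraint:
    """Exact snapshot counts required at a cumulative recruit total."""

    at_total: int
    randomised_control: int
    randomised_treatment: int
    complete_control: int
    complete_treatment: int
    deaths_control: int
    deaths_treatment: int

    def __post_init__(self) -> None:
        if self.randomised_control + self.randomised_treatment != self.at_total:
            raise ValueError(
                f"arm totals {self.randomised_control}+{self.randomised_treatment} "
                f"do not sum to trigger total {self.at_total}"
            )
        for arm in ("control", "treatment"):
            r = getattr(self, f"randomised_{arm}")
            c = getattr(self, f"complete_{arm}")
            d = getattr(self, f"deaths_{arm}")
            if not 0 <= d <= c <= r:
                raise ValueError(
                    f"{arm}: require 0 <= deaths <= complete <= randomised"
                )


def _finalize_frame(arm, week, outcome) -> pd.DataFrame:
    n = len(arm)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:05d}" for i in range(n)],
            "arm": np.where(np.asarray(arm) == 1, "treatment", "control"),
            "recruit_week": np.asarray(week, dtype=float),
            "outcome": np.asarray(outcome, dtype=float),
        }
    )


def stream_arrays(
    scenario: ScenarioSpec, n_patients: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw (arm, recruit_week, outcome) arrays; arm 0=control, 1=treatment,
    outcome NaN = missing.  The randomness consumption order is fixed so a
    given generator state always yields the same stream."""
    if n_patients < 1:
        raise ValueError("n_patients must be at least 1")
    gaps = rng.exponential(1.0 / scenario.accrual_rate, size=n_patients)
    week = np.cumsum(gaps)
    arm = rng.integers(0, 2, size=n_patients)
    p = np.where(arm == 1, scenario.p_treatment, scenario.p_control)
    dead = rng.random(n_patients) < p
    missing = rng.random(n_patients) < scenario.dropout
    outcome = np.where(missing, np.nan, dead.astype(float))
    return arm, week, outcome


def generate_stream(
    scenario: ScenarioSpec, n_patients: int, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Patient stream in recruitment order as a DataFrame with columns
    ``patient_id, arm, recruit_week, outcome`` (outcome 0/1/NaN)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arm, week, outcome = stream_arrays(scenario, n_patients, rng)
    return _finalize_frame(arm, week, outcome)


# ---------------------------------------------------------------------------
# constrained fixtures
# ---------------------------------------------------------------------------


def _arm_series(constraints, final, arm: str):
    """Cumulative (R, M, D) per trigger for one arm, final appended last."""
    seq = [
        (
            getattr(c, f"randomised_{arm}"),
            getattr(c, f"complete_{arm}"),
            getattr(c, f"deaths_{arm}"),
        )
        for c in constraints
    ]
    if final is not None:
        seq.append(
            (
                getattr(final, f"randomised_{arm}"),
                getattr(final, f"complete_{arm}"),
                getattr(final, f"deaths_{arm}"),
            )
        )
    return seq


def _check_monotone(constraints, final) -> None:
    totals = [c.at_total for c in constraints]
    if totals != sorted(set(totals)):
        raise InfeasibleConstraintError("trigger totals must be strictly increasing")
    if final is not None and constraints and final.at_total < totals[-1]:
        raise InfeasibleConstraintError(
            f"final total {final.at_total} below last trigger {totals[-1]}"
        )
    for arm in ("control", "treatment"):
        seq = _arm_series(constraints, final, arm)
        prev = (0, 0, 0)
        for k, cur in enumerate(seq, start=1):
            for what, a, b in zip(("randomised", "complete", "deaths"), prev, cur):
                if b < a:
                    raise InfeasibleConstraintError(
                        f"{arm} {what} decreases at constraint {k}: {b} < {a}"
                    )
            prev = cur


def generate_fixture(
    constraints: list[CountConstraint],
    final: CountConstraint | None,
    scenario: ScenarioSpec,
    seed: int | np.random.Generator,
    n_patients: int | None = None,
) -> pd.DataFrame:
    """Stream whose recomputed snapshot at every constrained trigger equals
    the constraint exactly.

    ``final`` describes the dataset after full follow-up of everyone
    randomised (``complete`` fields = analysed denominators; patients absent
    from them are dropouts with missing outcomes).  With no constraints and
    no final, the call reduces to :func:`generate_stream` (``n_patients``
    then required).  Infeasible constraint sets raise
    :class:`InfeasibleConstraintError` naming the first violated inequality.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    constraints = sorted(constraints, key=lambda c: c.at_total)
    if not constraints and final is None:
        if n_patients is None:
            raise ValueError("n_patients required without any constraints")
        return generate_stream(scenario, n_patients, rng)
    _check_monotone(constraints, final)

    rate = scenario.accrual_rate
    fw = scenario.followup_weeks
    trigger_times = [c.at_total / rate for c in constraints]
    for k in range(len(trigger_times)):
        prev_t = trigger_times[k - 1] if k else 0.0
        if trigger_times[k] - fw <= prev_t:
            raise InfeasibleConstraintError(
                f"trigger {k + 1} less than one follow-up window after the "
                "previous trigger at the scenario accrual rate"
            )

    K = len(constraints)
    # per arm: cohorts[(k, kind)] with kind "complete" (complete at trigger k)
    # or "transit" (in the trailing window at trigger k); k = K for the
    # post-trigger tail.  Each cohort: dict(size, deaths, missing).
    plan: dict[str, dict] = {}
    for arm in ("control", "treatment"):
        seq = _arm_series(constraints, None, arm)
        fin = (
            (
                getattr(final, f"randomised_{arm}"),
                getattr(final, f"complete_{arm}"),
                getattr(final, f"deaths_{arm}"),
            )
            if final is not None
            else None
        )
        cohorts = {}
        prev_R = prev_M = prev_D = 0
        prev_transit = 0
        for k, (R, M, D) in enumerate(seq):
            dR = R - prev_R
            m_new = M - prev_R  # newly complete among this block's recruits
            if m_new < 0:
                raise InfeasibleConstraintError(
                    f"{arm} complete count {M} at constraint {k + 1} below the "
                    f"{prev_R} patients already recruited before the block"
                )
            if m_new > dR:
                raise InfeasibleConstraintError(
                    f"{arm} complete count {M} at constraint {k + 1} requires "
                    f"{m_new} newly complete but only {dR} newly recruited"
                )
            transit = dR - m_new
            dD = D - prev_D
            if dD > prev_transit + m_new:
                raise InfeasibleConstraintError(
                    f"{arm} deaths increase by {dD} at constraint {k + 1} but "
                    f"only {prev_transit + m_new} patients newly complete"
                )
            # greedy: earliest newly-complete cohort absorbs deaths first
            d_prev = min(prev_transit, dD)
            if k > 0:
                cohorts[(k - 1, "transit")]["deaths"] = d_prev
            cohorts[(k, "complete")] = {"size": m_new, "deaths": dD - d_prev, "missing": 0}
            cohorts[(k, "transit")] = {"size": transit, "deaths": 0, "missing": 0}
            prev_R, prev_M, prev_D = R, M, D
            prev_transit = transit
        # resolve after full follow-up
        if fin is not None:
            R_F, M_F, D_F = fin
            tail = R_F - prev_R
            if tail < 0:
                raise InfeasibleConstraintError(
                    f"{arm} final randomised {R_F} below last trigger count {prev_R}"
                )
            miss = R_F - M_F
            if miss < 0:
                raise InfeasibleConstraintError(
                    f"{arm} final complete {M_F} exceeds final randomised {R_F}"
                )
            cohorts[(K, "tail")] = {"size": tail, "deaths": 0, "missing": 0}
            # place missing patients as late as possible: tail first, then the
            # last in-transit cohort (they are incomplete at every trigger)
            miss_tail = min(miss, tail)
            cohorts[(K, "tail")]["missing"] = miss_tail
            miss_left = miss - miss_tail
            if miss_left > prev_transit:
                raise InfeasibleConstraintError(
                    f"{arm} requires {miss} dropouts but only "
                    f"{tail + prev_transit} patients are never complete at a trigger"
                )
            if K > 0:
                cohorts[(K - 1, "transit")]["missing"] = miss_left
            dD = D_F - prev_D
            observable_transit = prev_transit - miss_left
            if dD > observable_transit + (tail - miss_tail):
                raise InfeasibleConstraintError(
                    f"{arm} final deaths increase by {dD} but only "
                    f"{observable_transit + tail - miss_tail} outcomes remain unobserved"
                )
            d_transit = min(observable_transit, dD)
            if K > 0:
                cohorts[(K - 1, "transit")]["deaths"] = d_transit
            cohorts[(K, "tail")]["deaths"] = dD - d_transit
        else:
            # unconstrained tail: fill the last in-transit cohort from the scenario
            c = cohorts.get((K - 1, "transit"))
            if c is not None and c["size"] > 0:
                p = scenario.p_treatment if arm == "treatment" else scenario.p_control
                alive_mask = rng.random(c["size"]) < scenario.dropout
                c["missing"] = int(alive_mask.sum())
                c["deaths"] = int(
                    (rng.random(c["size"] - c["missing"]) < p).sum()
                )
        plan[arm] = cohorts

    # at least one in-transit patient must exist at each trigger: the trigger
    # patient is recruited at the trigger time itself
    for k in range(K):
        n_transit = sum(plan[a].get((k, "transit"), {"size": 0})["size"] for a in plan)
        if n_transit == 0:
            raise InfeasibleConstraintError(
                f"constraint {k + 1} leaves no in-transit patients, but the "
                "trigger patient cannot have completed follow-up at the trigger"
            )

    # materialise patients block by block
    def cohort_patients(arm_code: int, cohort: dict) -> list[tuple[int, float]]:
        out = (
            [(arm_code, 1.0)] * cohort["deaths"]
            + [(arm_code, 0.0)] * (cohort["size"] - cohort["deaths"] - cohort["missing"])
            + [(arm_code, np.nan)] * cohort["missing"]
        )
        return out

    arms: list[int] = []
    weeks: list[float] = []
    outcomes: list[float] = []
    for k in range(K):
        t_k = trigger_times[k]
        t_prev = trigger_times[k - 1] if k else 0.0
        comp = cohort_patients(0, plan["control"][(k, "complete")]) + cohort_patients(
            1, plan["treatment"][(k, "complete")]
        )
        trans = cohort_patients(0, plan["control"][(k, "transit")]) + cohort_patients(
            1, plan["treatment"][(k, "transit")]
        )
        rng.shuffle(comp)
        rng.shuffle(trans)
        if comp:
            times = np.linspace(t_prev + _TIME_EPS, t_k - fw, num=len(comp))
            for (a, o), w in zip(comp, times):
                arms.append(a), weeks.append(w), outcomes.append(o)
        times = np.linspace(t_k - fw + _TIME_EPS, t_k, num=len(trans))
        for (a, o), w in zip(trans, times):
            arms.append(a), weeks.append(w), outcomes.append(o)
    tail = []
    for arm_code, arm in ((0, "control"), (1, "treatment")):
        cohort = plan[arm].get((K, "tail"))
        if cohort and cohort["size"]:
            tail.extend(cohort_patients(arm_code, cohort))
    rng.shuffle(tail)
    t_start = trigger_times[-1] if K else 0.0
    for i, (a, o) in enumerate(tail, start=1):
        arms.append(a), weeks.append(t_start + i / rate), outcomes.append(o)
    return _finalize_frame(arms, weeks, outcomes)


# ---------------------------------------------------------------------------
# constraint config IO
# ---------------------------------------------------------------------------

_FIELDS = (
    "at_total",
    "randomised_control",
    "randomised_treatment",
    "complete_control",
    "complete_treatment",
    "deaths_control",
    "deaths_treatment",
)


def load_constraints(path: str | Path) -> tuple[list[CountConstraint], CountConstraint | None]:
    """Read ``{interims: [...], final: {...}}`` from YAML."""
    d = yaml.safe_load(Path(path).read_text())
    cons = [CountConstraint(**{f: int(c[f]) for f in _FIELDS}) for c in d.get("interims", [])]
    fin = d.get("final")
    final = CountConstraint(**{f: int(fin[f]) for f in _FIELDS}) if fin else None
    return cons, final


def dump_constraints(
    constraints: list[CountConstraint],
    final: CountConstraint | None,
    path: str | Path,
) -> None:
    d = {
        "interims": [{f: getattr(c, f) for f in _FIELDS} for c in constraints],
        "final": {f: getattr(final, f) for f in _FIELDS} if final else None,
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
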