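"""Virtual execution of a sequential design over a patient-level stream.

The engine replays a design's decision rules over patients in recruitment
order.  At each scheduled look (a cumulative recruit count) it builds the
interim snapshot from the patients whose 30-day window has elapsed by the
trigger patient's recruitment time, evaluates the predictive probabilities
and applies the stopping rules:

* futility first — stop if ``P_max`` falls strictly below ``F_i``;
* then success, where allowed — stop if ``P_curr`` strictly exceeds ``S_i``.

Futility is evaluated before success because a trial that is predictively
doomed at the maximum sample size should not be declared an early success
on the same look; the ordering only matters in boundary cases.

On stopping (or on reaching the maximum sample size) every randomised
patient is followed to 30 days and the final analysis is run on all
non-missing outcomes: posterior probability of superiority, relative risk
with confidence interval, and death totals.  A trial stopped for futility
is counted as unsuccessful regardless of its final posterior.  Accrual
duration is the recruitment time of the trigger patient — a futility stop
is assumed to end the trial immediately.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DesignSpec
from .inference import (
    ArmCounts,
    RelativeRiskResult,
    ZeroCellError,
    posterior_from_counts,
    prob_superiority,
    relative_risk,
)
from .predictive import (
    InterimSnapshot,
    predictive_prob_current,
    predictive_prob_max,
)

__all__ = [
    "InterimDecision",
    "ReexecutionReport",
    "PatientDataError",
    "TruncatedStreamError",
    "interim_decision",
    "reexecute",
    "snapshot_at",
    "load_patients",
    "save_patients",
    "patients_to_arrays",
]

CONTROL, TREATMENT = 0, 1


class PatientDataError(ValueError):
    """Raised for malformed patient-level input; names the offending row."""


class TruncatedStreamError(RuntimeError):
    """Raised when the stream ends before ``n_max`` without any stop."""


@dataclass(frozen=True)
class InterimDecision:
    """Outcome of one scheduled look (``interim_index`` is 0-based)."""

    interim_index: int
    action: str  # "continue" | "stop_success" | "stop_futility"
    p_superior: float
    p_curr: float | None
    p_max: float
    snapshot: InterimSnapshot


@dataclass(frozen=True)
class ReexecutionReport:
    design_name: str
    n_max: int
    decisions: tuple[InterimDecision, ...]
    stopped_at: int | None  # interim index, None if run to schedule end
    stop_reason: str  # "completed" | "success_stop" | "futility_stop"
    n_randomised: int
    counts_control: ArmCounts
    counts_treatment: ArmCounts
    deaths_total: int
    final_prob_superior: float
    final_rr: RelativeRiskResult | None
    successful: bool
    accrual_duration_weeks: float
    truncated: bool = False

    @property
    def savings_vs_n_max(self) -> int:
        return self.n_max - self.n_randomised


# ---------------------------------------------------------------------------
# patient table IO
# ---------------------------------------------------------------------------

_ARMS = {"control": CONTROL, "treatment": TREATMENT}


def load_patients(path: str | Path) -> pd.DataFrame:
    """Read the patient CSV dialect: header ``patient_id,arm,recruit_week,
    outcome``; arm in {control, treatment}; outcome in {0, 1, NA}; rows in
    ascending recruitment order.  Errors name the offending CSV line."""
    df = pd.read_csv(
        path,
        dtype={"patient_id": str, "arm": str},
        na_values=["NA"],
        keep_default_na=False,
        float_precision="round_trip",
    )
    expected = ["patient_id", "arm", "recruit_week", "outcome"]
    if list(df.columns) != expected:
        raise PatientDataError(
            f"expected columns {expected}, found {list(df.columns)}"
        )
    df["recruit_week"] = pd.to_numeric(df["recruit_week"], errors="coerce").astype(float)
    df["outcome"] = pd.to_numeric(df["outcome"], errors="coerce").astype(float)
    validate_patients(df)
    return df


def validate_patients(df: pd.DataFrame) -> None:
    arm_ok = df["arm"].isin(_ARMS)
    if not arm_ok.all():
        row = int(np.flatnonzero(~arm_ok.to_numpy())[0])
        raise PatientDataError(
            f"line {row + 2}: arm must be 'control' or 'treatment', "
            f"got {df['arm'].iloc[row]!r}"
        )
    weeks = df["recruit_week"].to_numpy(dtype=float)
    bad = ~np.isfinite(weeks) | (weeks < 0)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise PatientDataError(f"line {row + 2}: recruit_week must be a non-negative number")
    if np.any(np.diff(weeks) < 0):
        row = int(np.flatnonzero(np.diff(weeks) < 0)[0]) + 1
        raise PatientDataError(f"line {row + 2}: recruit_week must be non-decreasing")
    out = df["outcome"].to_numpy(dtype=float)
    bad = ~np.isnan(out) & ~np.isin(out, (0.0, 1.0))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise PatientDataError(f"line {row + 2}: outcome must be 0, 1 or NA")


def save_patients(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["outcome"] = out["outcome"].map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    out.to_csv(path, index=False)


def patients_to_arrays(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    arm = df["arm"].map(_ARMS).to_numpy(dtype=np.int64)
    week = df["recruit_week"].to_numpy(dtype=float)
    outcome = df["outcome"].to_numpy(dtype=float)
    return arm, week, outcome


# ---------------------------------------------------------------------------
# snapshots and decisions
# ---------------------------------------------------------------------------


def _snapshot_arrays(
    arm: np.ndarray, week: np.ndarray, outcome: np.ndarray,
    n_trigger: int, followup_weeks: float,
) -> InterimSnapshot:
    t = week[n_trigger - 1]
    a = arm[:n_trigger]
    o = outcome[:n_trigger]
    complete = ~np.isnan(o) & (week[:n_trigger] + followup_weeks <= t)
    dead = complete & (o == 1.0)
    return InterimSnapshot(
        randomised_control=int(np.sum(a == CONTROL)),
        randomised_treatment=int(np.sum(a == TREATMENT)),
        complete_control=int(np.sum(complete & (a == CONTROL))),
        complete_treatment=int(np.sum(complete & (a == TREATMENT))),
        deaths_control=int(np.sum(dead & (a == CONTROL))),
        deaths_treatment=int(np.sum(dead & (a == TREATMENT))),
    )


def snapshot_at(
    patients: pd.DataFrame, n_trigger: int, followup_days: int = 30
) -> InterimSnapshot:
    """Interim snapshot after ``n_trigger`` recruits, outcomes revealed only
    once 30 days (``followup_days``) have elapsed by the trigger time."""
    arm, week, outcome = patients_to_arrays(patients)
    if n_trigger > len(arm):
        raise ValueError(f"stream has {len(arm)} patients, trigger at {n_trigger}")
    return _snapshot_arrays(arm, week, outcome, n_trigger, followup_days / 7.0)


def interim_decision(
    snapshot: InterimSnapshot,
    design: DesignSpec,
    interim_index: int,
    n_draws: int = 10_000,
    *,
    seed: int | np.random.Generator,
    dropout: float = 0.03,
) -> InterimDecision:
    """Apply the design's stopping rules at one look.

    ``dropout`` is the design-time assumption used when projecting future
    patients for ``P_max`` (the anticipated loss to follow-up, matching the
    sample-size inflation), not an observed quantity.
    """
    if not 0 <= interim_index < len(design.interims):
        raise IndexError(f"interim index {interim_index} outside schedule")
    it = design.interims[interim_index]
    if snapshot.randomised_total != it.n:
        raise ValueError(
            f"snapshot totals {snapshot.randomised_total} do not match the "
            f"scheduled trigger {it.n}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    post_c = posterior_from_counts(snapshot.counts_control, *design.prior_control)
    post_t = posterior_from_counts(snapshot.counts_treatment, *design.prior_treatment)
    p_sup = prob_superiority(post_t, post_c).prob_superior
    p_max = predictive_prob_max(
        snapshot,
        prior=design.prior_control,
        prior_treatment=design.prior_treatment,
        n_max=design.n_max,
        allocation=design.allocation,
        dropout=dropout,
        final_threshold=design.final_threshold,
        n_draws=n_draws,
        seed=rng,
    ).probability
    p_curr = None
    if it.success is not None:
        p_curr = predictive_prob_current(
            snapshot,
            prior=design.prior_control,
            prior_treatment=design.prior_treatment,
            final_threshold=design.final_threshold,
            n_draws=n_draws,
            seed=rng,
        ).probability
    if p_max < it.futility:
        action = "stop_futility"
    elif p_curr is not None and p_curr > it.success:
        action = "stop_success"
    else:
        action = "continue"
    return InterimDecision(
        interim_index=interim_index,
        action=action,
        p_superior=p_sup,
        p_curr=p_curr,
        p_max=p_max,
        snapshot=snapshot,
    )


# ---------------------------------------------------------------------------
# full re-execution
# ---------------------------------------------------------------------------


def reexecute_arrays(
    arm: np.ndarray,
    week: np.ndarray,
    outcome: np.ndarray,
    design: DesignSpec,
    n_draws: int = 10_000,
    *,
    rng: np.random.Generator,
    dropout: float = 0.03,
    followup_weeks: float = 30.0 / 7.0,
    allow_truncation: bool = False,
) -> ReexecutionReport:
    """Array-level core of :func:`reexecute` (used directly by the simulator)."""
    n_total = len(arm)
    decisions: list[InterimDecision] = []
    stopped_at: int | None = None
    stop_reason = "completed"
    for i, it in enumerate(design.interims):
        if it.n > n_total:
            raise TruncatedStreamError(
                f"stream has {n_total} patients but interim {i + 1} triggers at {it.n}"
            )
        snap = _snapshot_arrays(arm, week, outcome, it.n, followup_weeks)
        dec = interim_decision(
            snap, design, i, n_draws, seed=rng, dropout=dropout
        )
        decisions.append(dec)
        if dec.action != "continue":
            stopped_at = i
            stop_reason = (
                "futility_stop" if dec.action == "stop_futility" else "success_stop"
            )
            break

    truncated = False
    if stopped_at is not None:
        n_stop = design.interims[stopped_at].n
    else:
        if n_total < design.n_max:
            if not allow_truncation:
                raise TruncatedStreamError(
                    f"stream ends at {n_total} patients before n_max={design.n_max} "
                    "with no stopping rule met"
                )
            truncated = True
            n_stop = n_total
        else:
            n_stop = design.n_max

    a = arm[:n_stop]
    o = outcome[:n_stop]
    observed = ~np.isnan(o)
    counts_c = ArmCounts(
        int(np.sum(observed & (o == 1.0) & (a == CONTROL))),
        int(np.sum(observed & (a == CONTROL))),
    )
    counts_t = ArmCounts(
        int(np.sum(observed & (o == 1.0) & (a == TREATMENT))),
        int(np.sum(observed & (a == TREATMENT))),
    )
    post_c = posterior_from_counts(counts_c, *design.prior_control)
    post_t = posterior_from_counts(counts_t, *design.prior_treatment)
    p_final = prob_superiority(post_t, post_c).prob_superior
    try:
        rr = relative_risk(counts_c, counts_t)
    except ZeroCellError:
        rr = None
    return ReexecutionReport(
        design_name=design.name,
        n_max=design.n_max,
        decisions=tuple(decisions),
        stopped_at=stopped_at,
        stop_reason=stop_reason,
        n_randomised=n_stop,
        counts_control=counts_c,
        counts_treatment=counts_t,
        deaths_total=counts_c.deaths + counts_t.deaths,
        final_prob_superior=p_final,
        final_rr=rr,
        successful=(stop_reason != "futility_stop")
        and (p_final > design.final_threshold),
        accrual_duration_weeks=float(week[n_stop - 1]),
        truncated=truncated,
    )


def reexecute(
    patients: pd.DataFrame,
    design: DesignSpec,
    n_draws: int = 10_000,
    *,
    seed: int | np.random.Generator,
    dropout: float = 0.03,
    followup_days: int = 30,
    allow_truncation: bool = False,
) -> ReexecutionReport:
    """Re-execute ``design`` over a patient stream in recruitment order.

    ``seed`` drives the Monte-Carlo imputation inside the predictive
    probabilities; the decision trail is deterministic given (stream,
    design, seed).
    """
    validate_patients(patients)
    arm, week, outcome = patients_to_arrays(patients)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return reexecute_arrays(
        arm,
        week,
        outcome,
        design,
        n_draws,
        rng=rng,
        dropout=dropout,
        followup_weeks=followup_days / 7.0,
        allow_truncation=allow_truncation,
    )
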