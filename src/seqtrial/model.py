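"""Model/results front for applying a sequential design to patient data.

:class:`SequentialTrial` is constructed from a patient-level table and a
:class:`~seqtrial.design.DesignSpec`; calling :meth:`SequentialTrial.fit`
replays the design's interim decision rules over the stream and returns a
:class:`SequentialTrialResults` carrying the decision trail, the final
posterior and relative-risk estimates, and a formatted summary table.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .design import DesignSpec
from .engine import ReexecutionReport, load_patients, reexecute, validate_patients

__all__ = ["SequentialTrial", "SequentialTrialResults"]


class SequentialTrial:
    """A Bayesian sequential two-arm trial applied to a patient stream.

    Parameters
    ----------
    data
        Patient-level table with columns ``patient_id, arm, recruit_week,
        outcome`` (outcome 0 = alive at 30 days, 1 = dead, NaN = missing),
        sorted by recruitment time.
    design
        The sequential design whose stopping rules are replayed.
    followup_days
        Outcome lag: a patient's outcome is visible at an interim only once
        this many days have elapsed since their recruitment.
    dropout
        Design-time anticipated loss to follow-up, used when projecting
        future patients for the futility probability.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        design: DesignSpec,
        followup_days: int = 30,
        dropout: float = 0.03,
    ) -> None:
        validate_patients(data)
        self.data = data.reset_index(drop=True)
        self.design = design
        self.followup_days = followup_days
        self.dropout = dropout

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        design: DesignSpec,
        followup_days: int = 30,
        dropout: float = 0.03,
    ) -> "SequentialTrial":
        return cls(load_patients(path), design, followup_days, dropout)

    def fit(
        self,
        *,
        seed: int | np.random.Generator,
        n_draws: int = 10_000,
        allow_truncation: bool = False,
    ) -> "SequentialTrialResults":
        """Replay the design and return the fitted results.

        ``seed`` drives the Monte-Carlo imputation in the predictive
        probabilities; the decision trail is deterministic given it.
        """
        report = reexecute(
            self.data,
            self.design,
            n_draws,
            seed=seed,
            dropout=self.dropout,
            followup_days=self.followup_days,
            allow_truncation=allow_truncation,
        )
        return SequentialTrialResults(self, report)


class SequentialTrialResults:
    """Decision trail and final analysis of a :class:`SequentialTrial` fit."""

    def __init__(self, model: SequentialTrial, report: ReexecutionReport) -> None:
        self.model = model
        self.report = report

    # convenience accessors -------------------------------------------------
    @property
    def decisions(self):
        return self.report.decisions

    @property
    def stopped_at(self):
        return self.report.stopped_at

    @property
    def stop_reason(self) -> str:
        return self.report.stop_reason

    @property
    def n_randomised(self) -> int:
        return self.report.n_randomised

    @property
    def prob_superior(self) -> float:
        return self.report.final_prob_superior

    @property
    def rr(self):
        return self.report.final_rr

    @property
    def successful(self) -> bool:
        return self.report.successful

    def interim_frame(self) -> pd.DataFrame:
        """One row per performed look, mirroring an interim-analysis report."""
        rows = []
        for dec in self.report.decisions:
            s = dec.snapshot
            rows.append(
                {
                    "interim": dec.interim_index + 1,
                    "n_trigger": s.randomised_total,
                    "randomised_control": s.randomised_control,
                    "randomised_treatment": s.randomised_treatment,
                    "deaths_control": s.deaths_control,
                    "complete_control": s.complete_control,
                    "deaths_treatment": s.deaths_treatment,
                    "complete_treatment": s.complete_treatment,
                    "prob_superior": dec.p_superior,
                    "p_curr": dec.p_curr,
                    "p_max": dec.p_max,
                    "decision": dec.action,
                }
            )
        return pd.DataFrame(rows)

    def final_dict(self) -> dict:
        """Final-analysis block with full-precision values."""
        r = self.report
        return {
            "design": r.design_name,
            "deaths_control": r.counts_control.deaths,
            "analysed_control": r.counts_control.analysed,
            "deaths_treatment": r.counts_treatment.deaths,
            "analysed_treatment": r.counts_treatment.analysed,
            "rr": None if r.final_rr is None else r.final_rr.rr,
            "rr_ci_low": None if r.final_rr is None else r.final_rr.ci_low,
            "rr_ci_high": None if r.final_rr is None else r.final_rr.ci_high,
            "prob_superior": r.final_prob_superior,
            "deaths_total": r.deaths_total,
            "n_randomised": r.n_randomised,
            "stop_reason": r.stop_reason,
            "successful": r.successful,
            "accrual_duration_weeks": r.accrual_duration_weeks,
            "savings_vs_n_max": r.savings_vs_n_max,
            "truncated": r.truncated,
        }

    def summary(self) -> str:
        """Human-readable report: per-look rows then the final analysis.

        Probabilities are rendered to 4 decimal places and relative risks to
        2, matching how such trial reports are usually printed; use
        :meth:`final_dict` / :meth:`interim_frame` for full precision.
        """
        r = self.report
        lines = [
            f"Sequential trial re-execution: {r.design_name} "
            f"(n_max={r.n_max}, final threshold {self.model.design.final_threshold})",
            "",
        ]
        actions = {
            "continue": "Stopping criteria not met",
            "stop_futility": "Stop for futility",
            "stop_success": "Stop for success",
        }
        for dec in r.decisions:
            s = dec.snapshot
            lines.append(
                f"Interim {dec.interim_index + 1} (n={s.randomised_total})  "
                f"allocation {s.randomised_control}:{s.randomised_treatment}  "
                f"outcomes {s.deaths_control}/{s.complete_control}; "
                f"{s.deaths_treatment}/{s.complete_treatment}"
            )
            p_curr = "NA" if dec.p_curr is None else f"{dec.p_curr:.4f}"
            lines.append(
                f"  P(superior)={dec.p_superior:.4f}  P_curr={p_curr}  "
                f"P_max={dec.p_max:.4f}  -> {actions[dec.action]}"
            )
        if not r.decisions:
            lines.append("No interim analyses (fixed design).")
        lines.append("")
        lines.append(
            f"Final analysis  control {r.counts_control.deaths}/{r.counts_control.analysed} "
            f"({r.counts_control.rate:.1%}); treatment {r.counts_treatment.deaths}/"
            f"{r.counts_treatment.analysed} ({r.counts_treatment.rate:.1%})"
        )
        if r.final_rr is not None:
            lines.append(
                f"  RR (95% CI): {r.final_rr.rr:.2f} "
                f"({r.final_rr.ci_low:.2f}, {r.final_rr.ci_high:.2f})"
            )
        lines.append(f"  Posterior probability treatment superior: {r.final_prob_superior:.4f}")
        lines.append(f"  Deaths in trial: {r.deaths_total}")
        lines.append(f"  Number randomised: {r.n_randomised}")
        lines.append(f"  Accrual duration (weeks): {r.accrual_duration_weeks:.1f}")
        lines.append(f"  Recruitment savings vs n_max: {r.savings_vs_n_max}")
        lines.append(
            f"  Trial {'successful' if r.successful else 'not successful'} "
            f"({r.stop_reason.replace('_', ' ')})"
        )
        return "\n".join(lines)

    def __repr__(self) -> str:
        r = self.report
        return (
            f"<SequentialTrialResults {r.design_name!r} stop_reason={r.stop_reason!r} "
            f"n={r.n_randomised} successful={r.successful}>"
        )
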