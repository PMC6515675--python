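"""Whole-trial simulation and operating characteristics.

Each replicate draws a fresh patient stream under a scenario (Poisson
accrual, fair-coin allocation, Bernoulli outcomes, independent dropout),
replays the design's stopping rules over it, and records the final sample
size, duration, stop reason and success status.  Aggregating replicates
gives the design's operating characteristics: the type I error is the
proportion of successful trials under a no-difference scenario, the power
the same proportion under the target difference, alongside the expected
sample size and early-stopping proportions.

Randomness is organised as one child ``SeedSequence`` per replicate spawned
from the master seed, so results are reproducible, independent of
evaluation order, and shared across threshold-grid points (common random
numbers) during calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignSpec, ScenarioSpec
from .engine import reexecute_arrays
from .synth import stream_arrays

__all__ = [
    "TrialResult",
    "OCTable",
    "simulate_trial",
    "operating_characteristics",
    "calibrate_thresholds",
]


@dataclass(frozen=True)
class TrialResult:
    stop_reason: str  # "success_stop" | "futility_stop" | "completed"
    n_randomised: int
    duration_weeks: float
    successful: bool
    deaths: int

    def __post_init__(self) -> None:
        if self.successful and self.stop_reason == "futility_stop":
            raise ValueError("a futility-stopped trial cannot be successful")


@dataclass(frozen=True)
class OCTable:
    """Operating characteristics averaged over ``n_sims`` simulated trials."""

    design_name: str
    scenario_label: str
    mean_n: float
    sd_n: float
    mean_duration_weeks: float
    prop_stop_success: float
    prop_stop_futility: float
    prop_successful: float
    n_sims: int
    seed: int

    @property
    def prop_completed(self) -> float:
        return 1.0 - self.prop_stop_success - self.prop_stop_futility

    def mc_se(self, p: float) -> float:
        return math.sqrt(max(p * (1.0 - p), 0.0) / self.n_sims)

    def to_dict(self) -> dict:
        return {
            "design": self.design_name,
            "scenario": self.scenario_label,
            "mean_duration_weeks": self.mean_duration_weeks,
            "mean_n": self.mean_n,
            "sd_n": self.sd_n,
            "prop_stop_success": self.prop_stop_success,
            "prop_successful": self.prop_successful,
            "prop_stop_futility": self.prop_stop_futility,
            "mc_se_stop_success": self.mc_se(self.prop_stop_success),
            "mc_se_successful": self.mc_se(self.prop_successful),
            "mc_se_stop_futility": self.mc_se(self.prop_stop_futility),
            "n_sims": self.n_sims,
            "seed": self.seed,
        }


def simulate_trial(
    design: DesignSpec,
    scenario: ScenarioSpec,
    rng_seed: int | np.random.SeedSequence,
    n_draws: int = 10_000,
) -> TrialResult:
    """Simulate one trial: generate a stream of ``n_max`` patients and replay
    the design over it.

    The stream and the interim imputation draws use separate child
    generators of ``rng_seed``, so designs whose boundaries are never hit
    reproduce the fixed design's result bit-for-bit on the same seed.
    """
    ss = (
        rng_seed
        if isinstance(rng_seed, np.random.SeedSequence)
        else np.random.SeedSequence(rng_seed)
    )
    stream_seed, analysis_seed = ss.spawn(2)
    arm, week, outcome = stream_arrays(
        scenario, design.n_max, np.random.default_rng(stream_seed)
    )
    report = reexecute_arrays(
        arm,
        week,
        outcome,
        design,
        n_draws,
        rng=np.random.default_rng(analysis_seed),
        dropout=scenario.dropout,
        followup_weeks=scenario.followup_weeks,
    )
    if report.stop_reason == "futility_stop":
        # the trial ceases immediately on a futility stop
        duration = report.accrual_duration_weeks
    else:
        duration = report.accrual_duration_weeks + scenario.followup_weeks
    return TrialResult(
        stop_reason=report.stop_reason,
        n_randomised=report.n_randomised,
        duration_weeks=duration,
        successful=report.successful,
        deaths=report.deaths_total,
    )


def operating_characteristics(
    design: DesignSpec,
    scenario: ScenarioSpec,
    n_sims: int = 10_000,
    seed: int = 0,
    n_draws: int = 10_000,
) -> OCTable:
    """Aggregate ``n_sims`` independent replicates into an :class:`OCTable`.

    Deterministic and bit-identical for identical inputs: replicate ``i``
    always runs on the ``i``-th spawned child of the master seed.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be at least 1")
    children = np.random.SeedSequence(seed).spawn(n_sims)
    n = np.empty(n_sims)
    dur = np.empty(n_sims)
    succ = np.zeros(n_sims, dtype=bool)
    stop_s = np.zeros(n_sims, dtype=bool)
    stop_f = np.zeros(n_sims, dtype=bool)
    for i, child in enumerate(children):
        res = simulate_trial(design, scenario, child, n_draws)
        n[i] = res.n_randomised
        dur[i] = res.duration_weeks
        succ[i] = res.successful
        stop_s[i] = res.stop_reason == "success_stop"
        stop_f[i] = res.stop_reason == "futility_stop"
    return OCTable(
        design_name=design.name,
        scenario_label=scenario.label or f"{scenario.p_control:.0%} vs {scenario.p_treatment:.0%}",
        mean_n=float(n.mean()),
        sd_n=float(n.std(ddof=1)) if n_sims > 1 else 0.0,
        mean_duration_weeks=float(dur.mean()),
        prop_stop_success=float(stop_s.mean()),
        prop_stop_futility=float(stop_f.mean()),
        prop_successful=float(succ.mean()),
        n_sims=n_sims,
        seed=seed,
    )


def calibrate_thresholds(
    design_template: DesignSpec,
    s_grid: list,
    f_grid: list,
    scenarios: list[ScenarioSpec],
    n_sims: int = 1_000,
    seed: int = 0,
    n_draws: int = 10_000,
    type1_cap: float = 0.03,
    power_floor: float = 0.75,
) -> pd.DataFrame:
    """Evaluate a success/futility threshold grid over scenarios.

    Grid entries may be scalars (applied uniformly over the applicable
    looks) or per-look sequences.  Every grid point reuses the same master
    seed (common random numbers), so differences between points reflect the
    thresholds, not Monte-Carlo noise.  A candidate is flagged when its
    worst type I error over the null scenarios (equal rates) stays at or
    below ``type1_cap`` and its worst power over the beneficial scenarios
    (treatment rate below control) reaches ``power_floor``.
    """
    if not s_grid or not f_grid:
        raise ValueError("threshold grids must be non-empty")
    rows = []
    for s in s_grid:
        for f in f_grid:
            variant = design_template.with_thresholds(success=s, futility=f)
            type1: list[float] = []
            power: list[float] = []
            ocs = []
            for sc in scenarios:
                oc = operating_characteristics(variant, sc, n_sims, seed, n_draws)
                ocs.append(oc)
                if sc.p_treatment == sc.p_control:
                    type1.append(oc.prop_successful)
                elif sc.p_treatment < sc.p_control:
                    power.append(oc.prop_successful)
            flagged = (not type1 or max(type1) <= type1_cap) and (
                not power or min(power) >= power_floor
            )
            for oc in ocs:
                rows.append(
                    {
                        "success_thresholds": repr(s),
                        "futility_thresholds": repr(f),
                        **oc.to_dict(),
                        "flagged": flagged,
                    }
                )
    return pd.DataFrame(rows)
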