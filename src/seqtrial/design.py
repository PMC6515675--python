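"""Design and scenario specifications for Bayesian sequential two-arm trials.

A :class:`DesignSpec` fixes everything decided before the trial starts: the
maximum sample size, the interim-analysis schedule (by number of recruits),
the per-interim success and futility boundaries on the predictive
probabilities, the final-analysis threshold on the posterior probability of
superiority, the per-arm priors and the allocation ratio.  A
:class:`ScenarioSpec` fixes the simulation truth: the per-arm event rates,
the accrual rate, the dropout probability and the follow-up length.

Six built-in designs reproduce the candidate set studied for the OSCAR
trial (ventilation strategies in acute respiratory distress syndrome, 30-day
mortality endpoint, maximum 1006 patients), ranging from a fixed design with
a Bayesian final analysis to three-look sequential designs.  Built-in
scenarios cover the matching null / target / small / large / harmful effect
sizes around a 45% control event rate.

Both spec types round-trip through YAML/JSON mappings via ``to_dict`` /
``from_dict`` and ``load`` / ``dump`` helpers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import yaml

__all__ = [
    "Interim",
    "DesignSpec",
    "ScenarioSpec",
    "builtin_designs",
    "get_design",
    "builtin_scenarios",
    "get_scenario",
    "load_design",
    "dump_design",
    "load_scenario",
    "dump_scenario",
]


@dataclass(frozen=True)
class Interim:
    """One scheduled look: trigger recruit count, optional success boundary
    ``S`` on ``P_curr`` (``None`` means success stopping is not allowed at
    this look) and futility boundary ``F`` on ``P_max``."""

    n: int
    success: float | None
    futility: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("interim trigger must be a positive recruit count")
        if self.success is not None and not 0.0 <= self.success <= 1.0:
            raise ValueError("success boundary outside [0, 1]")
        if not 0.0 <= self.futility <= 1.0:
            raise ValueError("futility boundary outside [0, 1]")


@dataclass(frozen=True)
class DesignSpec:
    name: str
    n_max: int = 1006
    interims: tuple[Interim, ...] = ()
    final_threshold: float = 0.975
    prior_control: tuple[float, float] = (1.0, 1.0)
    prior_treatment: tuple[float, float] = (1.0, 1.0)
    allocation: tuple[int, int] = (1, 1)

    def __post_init__(self) -> None:
        if self.n_max < 2:
            raise ValueError("n_max must allow at least one patient per arm")
        if not 0.0 < self.final_threshold < 1.0:
            raise ValueError("final threshold must lie in (0, 1)")
        ns = [it.n for it in self.interims]
        if ns != sorted(set(ns)):
            raise ValueError("interim schedule must be strictly increasing")
        if ns and ns[-1] >= self.n_max:
            raise ValueError("all interims must precede n_max")
        for pr in (self.prior_control, self.prior_treatment):
            if not (pr[0] > 0 and pr[1] > 0):
                raise ValueError("prior parameters must be positive")
        if self.allocation[0] <= 0 or self.allocation[1] <= 0:
            raise ValueError("allocation ratio parts must be positive")

    @property
    def schedule(self) -> tuple[int, ...]:
        return tuple(it.n for it in self.interims)

    @property
    def is_fixed(self) -> bool:
        return not self.interims

    def with_thresholds(self, success=None, futility=None) -> "DesignSpec":
        """Copy with replaced boundaries (for threshold calibration grids).

        ``success`` / ``futility`` may be a scalar (applied uniformly —
        success only at looks where success stopping is allowed) or a
        sequence with one value per applicable look.
        """
        interims = list(self.interims)
        if success is not None:
            slots = [i for i, it in enumerate(interims) if it.success is not None]
            vals = [success] * len(slots) if _is_scalar(success) else list(success)
            if len(vals) != len(slots):
                raise ValueError("success grid length does not match schedule")
            for i, v in zip(slots, vals):
                interims[i] = replace(interims[i], success=float(v))
        if futility is not None:
            vals = [futility] * len(interims) if _is_scalar(futility) else list(futility)
            if len(vals) != len(interims):
                raise ValueError("futility grid length does not match schedule")
            interims = [replace(it, futility=float(v)) for it, v in zip(interims, vals)]
        return replace(self, interims=tuple(interims))

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_max": self.n_max,
            "interims": [
                {"n": it.n, "S": it.success, "F": it.futility} for it in self.interims
            ],
            "final_threshold": self.final_threshold,
            "prior": {
                "control": list(self.prior_control),
                "treatment": list(self.prior_treatment),
            },
            "allocation": list(self.allocation),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSpec":
        prior = d.get("prior", {})
        if isinstance(prior, (list, tuple)):  # shared prior shorthand
            prior = {"control": prior, "treatment": prior}
        return cls(
            name=d["name"],
            n_max=int(d.get("n_max", 1006)),
            interims=tuple(
                Interim(
                    n=int(it["n"]),
                    success=None if it.get("S") is None else float(it["S"]),
                    futility=float(it["F"]),
                )
                for it in d.get("interims", [])
            ),
            final_threshold=float(d.get("final_threshold", 0.975)),
            prior_control=tuple(map(float, prior.get("control", (1.0, 1.0)))),
            prior_treatment=tuple(map(float, prior.get("treatment", (1.0, 1.0)))),
            allocation=tuple(map(int, d.get("allocation", (1, 1)))),
        )


def _is_scalar(x) -> bool:
    return isinstance(x, (int, float))


@dataclass(frozen=True)
class ScenarioSpec:
    """Simulation truth for one scenario.

    Rates are 30-day event proportions; ``accrual_rate`` is the mean number
    of patients recruited per week; ``dropout`` is the probability that a
    randomised patient's outcome is never observed; ``followup`` is the
    outcome lag in days.
    """

    p_control: float
    p_treatment: float
    accrual_rate: float = 5.5
    dropout: float = 0.03
    followup: int = 30
    label: str = ""

    def __post_init__(self) -> None:
        for r in (self.p_control, self.p_treatment):
            if not 0.0 < r < 1.0:
                raise ValueError("event rates must lie in (0, 1)")
        if self.accrual_rate <= 0:
            raise ValueError("accrual rate must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.followup < 0:
            raise ValueError("follow-up cannot be negative")

    @property
    def followup_weeks(self) -> float:
        return self.followup / 7.0

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "p_control": self.p_control,
            "p_treatment": self.p_treatment,
            "accrual_rate": self.accrual_rate,
            "dropout": self.dropout,
            "followup": self.followup,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        return cls(
            p_control=float(d["p_control"]),
            p_treatment=float(d["p_treatment"]),
            accrual_rate=float(d.get("accrual_rate", 5.5)),
            dropout=float(d.get("dropout", 0.03)),
            followup=int(d.get("followup", 30)),
            label=str(d.get("label", "")),
        )


# ---------------------------------------------------------------------------
# built-in candidate designs and scenarios
# ---------------------------------------------------------------------------


def builtin_designs() -> list[DesignSpec]:
    """The six candidate designs (maximum 1006 patients, uniform priors).

    Design 1 is the fixed comparator with a Bayesian final analysis; Designs
    2-6 differ in number and timing of looks and in their boundaries.  Looks
    before half the maximum sample size never allow success stopping.
    """
    return [
        DesignSpec(name="Design 1"),
        DesignSpec(
            name="Design 2",
            interims=(
                Interim(250, None, 0.05),
                Interim(500, 0.99, 0.10),
                Interim(750, 0.98, 0.15),
            ),
        ),
        DesignSpec(
            name="Design 3",
            interims=(Interim(335, None, 0.05), Interim(670, 0.99, 0.10)),
        ),
        DesignSpec(
            name="Design 4",
            interims=(
                Interim(335, None, 0.05),
                Interim(500, 0.99, 0.10),
                Interim(670, 0.98, 0.15),
            ),
        ),
        DesignSpec(
            name="Design 5",
            interims=(Interim(503, 0.99, 0.05), Interim(755, 0.98, 0.10)),
        ),
        DesignSpec(
            name="Design 6",
            interims=(
                Interim(503, 0.99, 0.05),
                Interim(755, 0.98, 0.10),
                Interim(880, 0.98, 0.15),
            ),
        ),
    ]


def get_design(name: str) -> DesignSpec:
    for d in builtin_designs():
        if d.name.lower() in (name.lower(), f"design {name.lower()}"):
            return d
    raise KeyError(f"no built-in design named {name!r}")


def builtin_scenarios(p_control: float = 0.45) -> list[ScenarioSpec]:
    """Null / target / small / large / harmful scenarios around ``p_control``."""
    pc = p_control

    def mk(p_t, label):
        return ScenarioSpec(pc, round(p_t, 10), label=label)

    return [
        mk(pc, f"No difference: {pc:.0%} vs {pc:.0%}"),
        mk(pc - 0.09, f"Target difference: {pc:.0%} vs {pc - 0.09:.0%}"),
        mk(pc - 0.05, f"Small difference: {pc:.0%} vs {pc - 0.05:.0%}"),
        mk(pc - 0.15, f"Large difference: {pc:.0%} vs {pc - 0.15:.0%}"),
        mk(pc + 0.05, f"Treatment harmful: {pc:.0%} vs {pc + 0.05:.0%}"),
    ]


_SCENARIO_ALIASES = {
    "null": 0,
    "no-difference": 0,
    "target": 1,
    "small": 2,
    "large": 3,
    "harmful": 4,
}


def get_scenario(name: str, p_control: float = 0.45) -> ScenarioSpec:
    key = name.lower()
    if key not in _SCENARIO_ALIASES:
        raise KeyError(f"no built-in scenario named {name!r}")
    return builtin_scenarios(p_control)[_SCENARIO_ALIASES[key]]


# ---------------------------------------------------------------------------
# config file IO (YAML or JSON by extension)
# ---------------------------------------------------------------------------


def _read_mapping(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _write_mapping(d: dict, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2, sort_keys=False) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def load_design(path: str | Path) -> DesignSpec:
    return DesignSpec.from_dict(_read_mapping(path))


def dump_design(design: DesignSpec, path: str | Path) -> None:
    _write_mapping(design.to_dict(), path)


def load_scenario(path: str | Path) -> ScenarioSpec:
    return ScenarioSpec.from_dict(_read_mapping(path))


def dump_scenario(scenario: ScenarioSpec, path: str | Path) -> None:
    _write_mapping(scenario.to_dict(), path)
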