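"""Published OSCAR trial summaries bundled as example inputs.

The OSCAR trial (conventional ventilation vs high-frequency oscillatory
ventilation in acute respiratory distress syndrome; primary outcome 30-day
mortality; 795 patients randomised) published the interim snapshots its
Bayesian re-analysis would have seen at each candidate design's looks, and
the final analysis datasets those looks imply.  The patient-level data are
not public, so this module exposes the printed per-look counts and pairs
them with :func:`seqtrial.synth.generate_fixture` to rebuild synthetic
patient streams whose recomputed snapshots equal the published ones
exactly.  The streams are synthetic; only their interim and final count
summaries match the real trial.
"""

from __future__ import annotations

import pandas as pd

from .design import ScenarioSpec, get_design
from .inference import ArmCounts
from .predictive import InterimSnapshot
from .synth import CountConstraint, generate_fixture

__all__ = [
    "oscar_snapshots",
    "oscar_final_counts",
    "oscar_constraints",
    "oscar_fixture",
    "OSCAR_TRIAL_COUNTS",
]

# (at_total, randomised (C, T), complete (C, T), deaths (C, T)) per look
_SNAPSHOTS: dict[str, list[tuple]] = {
    "Design 2": [
        (250, (129, 121), (118, 113), (49, 44)),
        (500, (249, 251), (230, 239), (96, 93)),
        (750, (377, 373), (372, 363), (154, 152)),
    ],
    "Design 3": [
        (335, (174, 161), (165, 153), (70, 57)),
        (670, (339, 331), (330, 322), (136, 129)),
    ],
    "Design 4": [
        (335, (174, 161), (165, 153), (70, 57)),
        (500, (249, 251), (230, 239), (96, 93)),
        (670, (339, 331), (330, 322), (136, 129)),
    ],
    "Design 5": [
        (503, (251, 252), (233, 240), (98, 93)),
        (755, (380, 375), (375, 364), (154, 152)),
    ],
}

# final analysed counts after full follow-up: (total, (d_C, n_C), (d_T, n_T))
_FINALS: dict[str, tuple] = {
    "Design 2": (750, (154, 377), (156, 373)),
    "Design 3": (670, (138, 339), (134, 331)),
    "Design 4": (670, (138, 339), (134, 331)),
    "Design 5": (755, (156, 380), (157, 375)),
}

#: the trial as actually run: 163/397 control vs 166/398 treatment deaths
OSCAR_TRIAL_COUNTS = (ArmCounts(163, 397), ArmCounts(166, 398))


def oscar_snapshots(design_name: str) -> list[InterimSnapshot]:
    """Published interim snapshots for one candidate design."""
    rows = _SNAPSHOTS[get_design(design_name).name]
    return [
        InterimSnapshot(
            randomised_control=r[0],
            randomised_treatment=r[1],
            complete_control=c[0],
            complete_treatment=c[1],
            deaths_control=d[0],
            deaths_treatment=d[1],
        )
        for _, r, c, d in rows
    ]


def oscar_final_counts(design_name: str) -> tuple[ArmCounts, ArmCounts]:
    """Final (control, treatment) analysed counts for one candidate design."""
    _, (d_c, n_c), (d_t, n_t) = _FINALS[get_design(design_name).name]
    return ArmCounts(d_c, n_c), ArmCounts(d_t, n_t)


def oscar_constraints(
    design_name: str,
) -> tuple[list[CountConstraint], CountConstraint]:
    """Snapshot constraints + final constraint for fixture generation."""
    name = get_design(design_name).name
    cons = [
        CountConstraint(
            at_total=total,
            randomised_control=r[0],
            randomised_treatment=r[1],
            complete_control=c[0],
            complete_treatment=c[1],
            deaths_control=d[0],
            deaths_treatment=d[1],
        )
        for total, r, c, d in _SNAPSHOTS[name]
    ]
    total, (d_c, n_c), (d_t, n_t) = _FINALS[name]
    rand_c, rand_t = _final_randomised(name)
    final = CountConstraint(
        at_total=total,
        randomised_control=rand_c,
        randomised_treatment=rand_t,
        complete_control=n_c,
        complete_treatment=n_t,
        deaths_control=d_c,
        deaths_treatment=d_t,
    )
    return cons, final


def _final_randomised(name: str) -> tuple[int, int]:
    # every randomised patient reached the final analysis in the published
    # datasets, so final randomised counts equal the analysed denominators
    _, (_, n_c), (_, n_t) = _FINALS[name]
    return n_c, n_t


def oscar_fixture(design_name: str, seed: int = 0) -> pd.DataFrame:
    """Synthetic patient stream reproducing the published snapshots of one
    candidate design at every look (and the final analysed counts)."""
    cons, final = oscar_constraints(design_name)
    scenario = ScenarioSpec(0.45, 0.41, label="fixture fill")
    return generate_fixture(cons, final, scenario, seed)
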