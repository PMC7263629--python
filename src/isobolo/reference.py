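"""Published summary values from a mouse 6-Hz two-drug isobolographic study.

A reference table of the printed results of one published preclinical study
of five antiseizure drugs (gabapentin GBP, lacosamide LCM, levetiracetam
LEV, pregabalin PGB, retigabine RTG) evaluated singly and in all ten
fixed-ratio 1:1 combinations against 6-Hz corneal-stimulation seizures.
These are *inputs* for worked examples and cross-checks — single-drug ED50s,
per-pair experimental and additive ED50 summaries (value ± SEM with
effective animal counts), mixture half-doses, grip-strength summaries and
the animal bookkeeping — not outputs of this package.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "SINGLE_ED50_MG_PER_KG",
    "SINGLE_ED50_CI95",
    "SINGLE_DOSE_GRIDS",
    "PairSummary",
    "PAIR_SUMMARIES",
    "HALF_ED50_COMPONENT_DOSES",
    "GRIP_STRENGTH_SUMMARY",
    "ANIMALS_PER_GROUP",
    "TOTAL_ANIMALS",
]

#: Single-drug median effective doses (mg/kg).  These equal twice the
#: published half-ED50 component doses of the 1:1 mixtures.
SINGLE_ED50_MG_PER_KG: dict[str, float] = {
    "GBP": 72.12,
    "LCM": 4.56,
    "LEV": 14.42,
    "PGB": 31.66,
    "RTG": 29.04,
}

#: Published 95% confidence limits where printed (mg/kg).
SINGLE_ED50_CI95: dict[str, tuple[float, float]] = {
    "GBP": (53.8, 96.7),
    "LCM": (2.5, 8.5),
}

#: Single-drug dose grids (mg/kg) used in the study.
SINGLE_DOSE_GRIDS: dict[str, tuple[float, ...]] = {
    "GBP": (50.0, 75.0, 100.0),
    "LCM": (3.0, 5.0, 10.0, 15.0),
    "LEV": (10.0, 15.0, 20.0),
    "PGB": (15.0, 25.0, 50.0),
    "RTG": (20.0, 30.0, 35.0, 40.0),
}


@dataclass(frozen=True)
class PairSummary:
    """Printed per-pair summary row.

    For parallel pairs ``ed50_add``/``sem_add`` hold the single additive
    value; for non-parallel pairs the lower and upper additive bounds are
    given instead (``lower_add``, ``upper_add`` with their SEMs) and the
    interaction index refers to the lower bound.
    """

    agent_a: str
    agent_b: str
    parallel: bool
    ed50_exp: float
    sem_exp: float
    n_exp: int
    n_add: int
    interaction_index: float
    classification: str
    ed50_add: float | None = None
    sem_add: float | None = None
    lower_add: float | None = None
    sem_lower: float | None = None
    upper_add: float | None = None
    sem_upper: float | None = None

    @property
    def label(self) -> str:
        return f"{self.agent_a}+{self.agent_b}"


#: The ten combinations in reporting order (parallel table first).
PAIR_SUMMARIES: tuple[PairSummary, ...] = (
    PairSummary("PGB", "LCM", True, 8.17, 2.40, 24, 36, 0.45, "synergy",
                ed50_add=18.11, sem_add=4.42),
    PairSummary("GBP", "LEV", True, 15.06, 5.03, 16, 44, 0.35, "synergy",
                ed50_add=43.27, sem_add=6.47),
    PairSummary("PGB", "LEV", True, 7.20, 2.39, 16, 36, 0.31, "synergy",
                ed50_add=23.04, sem_add=4.78),
    PairSummary("GBP", "RTG", True, 12.62, 3.81, 8, 52, 0.25, "synergy",
                ed50_add=50.57, sem_add=7.30),
    PairSummary("LEV", "RTG", True, 3.24, 0.55, 16, 52, 0.15, "synergy",
                ed50_add=21.73, sem_add=2.99),
    PairSummary("PGB", "GBP", True, 44.36, 5.51, 16, 36, 0.86, "additivity",
                ed50_add=51.88, sem_add=9.09),
    PairSummary("PGB", "RTG", True, 12.41, 3.32, 16, 44, 0.41, "synergy",
                ed50_add=30.34, sem_add=5.61),
    PairSummary("GBP", "LCM", False, 19.20, 5.78, 8, 44, 0.65, "additivity",
                lower_add=29.33, sem_lower=10.56, upper_add=47.35, sem_upper=11.56),
    PairSummary("LEV", "LCM", False, 1.73, 0.26, 24, 44, 0.24, "synergy",
                lower_add=7.26, sem_lower=3.36, upper_add=11.73, sem_upper=3.90),
    PairSummary("RTG", "LCM", False, 12.12, 1.81, 24, 52, 0.97, "additivity",
                lower_add=12.45, sem_lower=4.22, upper_add=21.15, sem_upper=4.82),
)

#: Half-ED50 component doses (mg/kg) of each 1:1 mixture as administered in
#: the grip-strength arm.
HALF_ED50_COMPONENT_DOSES: dict[str, tuple[float, float]] = {
    "PGB+LCM": (15.83, 2.28),
    "GBP+LEV": (36.06, 7.21),
    "PGB+LEV": (15.83, 7.21),
    "GBP+RTG": (36.06, 14.52),
    "LEV+RTG": (7.21, 14.52),
    "PGB+GBP": (15.83, 36.06),
    "PGB+RTG": (15.83, 14.52),
    "GBP+LCM": (36.06, 2.28),
    "LEV+LCM": (7.21, 2.28),
    "RTG+LCM": (14.52, 2.28),
}

#: Grip-strength summaries: mean force in newtons ± SEM (8 animals/group).
GRIP_STRENGTH_SUMMARY: dict[str, tuple[float, float]] = {
    "vehicle": (0.901, 0.050),
    "PGB+LCM": (0.887, 0.055),
    "GBP+LEV": (0.892, 0.058),
    "PGB+LEV": (0.896, 0.049),
    "GBP+RTG": (0.902, 0.050),
    "LEV+RTG": (0.898, 0.051),
    "PGB+GBP": (0.892, 0.057),
    "PGB+RTG": (0.907, 0.049),
    "GBP+LCM": (0.903, 0.052),
    "LEV+LCM": (0.892, 0.055),
    "RTG+LCM": (0.905, 0.057),
}

ANIMALS_PER_GROUP = 8
TOTAL_ANIMALS = 416
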