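"""Synthetic quantal datasets with known ground truth.

Emulates the structure of a mouse 6-Hz psychomotor-seizure protection study:
cohorts of 8 animals per dose group, 2-4 dose levels per agent bracketing
the ED50, binomial protected/not-protected outcomes driven by a latent
log10-dose probit curve, and fixed-ratio mixtures whose latent potency is a
scaled Loewe-additive total dose (scale kappa < 1 synergy, = 1 additivity,
> 1 antagonism — the same semantics as the interaction index).

What the generator does *not* emulate: litter effects, inter-day drift,
tolerance/kindling dynamics, or any pharmacokinetic interaction between the
mixture components; every animal is an independent Bernoulli draw from the
latent curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import DoseGroup, DoseResponseDataset

__all__ = [
    "AgentModel",
    "CombinationModel",
    "StudyFixture",
    "simulate_single",
    "simulate_combination",
    "make_study_fixture",
]


@dataclass(frozen=True)
class AgentModel:
    """Latent single-agent dose-response: probit-linear in log10 dose."""

    agent_id: str
    true_ed50: float
    true_slope: float  # probits per log10(mg/kg)

    def __post_init__(self) -> None:
        if self.true_ed50 <= 0 or self.true_slope <= 0:
            raise ValueError("true_ed50 and true_slope must be positive")

    def protection_probability(self, dose):
        d = np.asarray(dose, dtype=float)
        z = self.true_slope * (np.log10(d) - np.log10(self.true_ed50))
        out = stats.norm.cdf(z)
        return float(out) if np.isscalar(dose) else out


@dataclass(frozen=True)
class CombinationModel:
    """Latent fixed-ratio mixture model.

    The latent mixture ED50 (total dose) is ``kappa`` times the
    Loewe-additive total ``f*ED50_a + (1-f)*ED50_b``.  The mixture's own
    probit slope defaults to the effect-weighted mean of the component
    slopes.
    """

    agent_a: AgentModel
    agent_b: AgentModel
    fixed_fraction_f: float = 0.5
    interaction_kappa: float = 1.0
    mixture_slope: float | None = None

    def __post_init__(self) -> None:
        if self.interaction_kappa <= 0:
            raise ValueError("interaction_kappa must be positive")
        if not 0.0 < self.fixed_fraction_f < 1.0:
            raise ValueError("fixed_fraction_f must lie in (0, 1)")

    @property
    def combo_id(self) -> str:
        return f"{self.agent_a.agent_id}+{self.agent_b.agent_id}"

    @property
    def additive_total(self) -> float:
        f = self.fixed_fraction_f
        return f * self.agent_a.true_ed50 + (1.0 - f) * self.agent_b.true_ed50

    @property
    def latent_ed50(self) -> float:
        return self.interaction_kappa * self.additive_total

    @property
    def slope(self) -> float:
        if self.mixture_slope is not None:
            return self.mixture_slope
        f = self.fixed_fraction_f
        return f * self.agent_a.true_slope + (1.0 - f) * self.agent_b.true_slope

    def protection_probability(self, total_dose):
        d = np.asarray(total_dose, dtype=float)
        z = self.slope * (np.log10(d) - np.log10(self.latent_ed50))
        out = stats.norm.cdf(z)
        return float(out) if np.isscalar(total_dose) else out


def _binomial_dataset(agent_id, doses, probs, n_per_group, rng) -> DoseResponseDataset:
    groups = tuple(
        DoseGroup(agent_id, float(d), int(rng.binomial(n_per_group, p)), n_per_group)
        for d, p in zip(doses, probs)
    )
    return DoseResponseDataset(agent_id, groups)


def simulate_single(
    model: AgentModel,
    doses,
    n_per_group: int = 8,
    seed: int | np.random.Generator = 0,
) -> DoseResponseDataset:
    """Draw binomial protection counts for one agent at the given doses."""
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0) or n_per_group < 1:
        raise ValueError("doses must be positive and n_per_group >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return _binomial_dataset(
        model.agent_id, doses, model.protection_probability(doses), n_per_group, rng
    )


def simulate_combination(
    model: CombinationModel,
    total_doses,
    n_per_group: int = 8,
    seed: int | np.random.Generator = 0,
) -> DoseResponseDataset:
    """Draw binomial protection counts for a fixed-ratio mixture.

    The dataset records *total* doses; component doses follow from the
    design's fixed ratio.
    """
    total_doses = np.asarray(total_doses, dtype=float)
    if np.any(total_doses <= 0) or n_per_group < 1:
        raise ValueError("doses must be positive and n_per_group >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return _binomial_dataset(
        model.combo_id,
        total_doses,
        model.protection_probability(total_doses),
        n_per_group,
        rng,
    )


# -- the reference study layout ---------------------------------------------

#: Latent single-agent parameters of the bundled study fixture.  ED50s are
#: the published single-drug medians (mg/kg); slopes (probits per log10
#: dose) are not published and are chosen so that the parallelism pattern of
#: the study reproduces: LCM's line is much shallower than GBP/LEV/RTG
#: (non-parallel) but close enough to PGB to pass the LW test.
FIXTURE_AGENTS: tuple[AgentModel, ...] = (
    AgentModel("GBP", true_ed50=72.12, true_slope=6.0),
    AgentModel("LCM", true_ed50=4.56, true_slope=1.8),
    AgentModel("LEV", true_ed50=14.42, true_slope=6.0),
    AgentModel("PGB", true_ed50=31.66, true_slope=3.5),
    AgentModel("RTG", true_ed50=29.04, true_slope=6.0),
)

#: Single-agent dose grids (mg/kg) of the reference study design.
FIXTURE_DOSES: dict[str, tuple[float, ...]] = {
    "GBP": (50.0, 75.0, 100.0),
    "LCM": (3.0, 5.0, 10.0, 15.0),
    "LEV": (10.0, 15.0, 20.0),
    "PGB": (15.0, 25.0, 50.0),
    "RTG": (20.0, 30.0, 35.0, 40.0),
}

#: The ten pairs in reporting order with the latent interaction strength
#: kappa set to the published interaction indices.
FIXTURE_PAIRS: tuple[tuple[str, str, float], ...] = (
    ("PGB", "LCM", 0.45),
    ("GBP", "LEV", 0.35),
    ("PGB", "LEV", 0.31),
    ("GBP", "RTG", 0.25),
    ("LEV", "RTG", 0.15),
    ("PGB", "GBP", 0.86),
    ("PGB", "RTG", 0.41),
    ("GBP", "LCM", 0.65),
    ("LEV", "LCM", 0.24),
    ("RTG", "LCM", 0.97),
)

#: Relative dose grids (multiples of the latent mixture ED50).  The first
#: five pairs get 4 dose levels and the rest 3, giving the study's 35
#: mixture groups in total.
_GRID4 = (0.5, 0.8, 1.25, 2.0)
_GRID3 = (0.6, 1.0, 1.67)

#: Reference grip-strength generator settings: common mean force (N) and
#: within-group SD for a vehicle group plus one group per mixture.
FIXTURE_GRIP_MEAN_N = 0.9
FIXTURE_GRIP_SD_N = 0.15


@dataclass(frozen=True)
class StudyFixture:
    """Complete synthetic inputs for one study run, with ground truth."""

    agents: tuple[AgentModel, ...]
    combinations: tuple[CombinationModel, ...]
    single_datasets: dict[str, DoseResponseDataset]
    mixture_datasets: dict[str, DoseResponseDataset]
    mixture_pairs: dict[str, tuple[str, str]]
    mixture_doses: dict[str, tuple[float, ...]]
    grip_forces: dict[str, list[float]]
    single_doses: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(FIXTURE_DOSES)
    )


def make_study_fixture(
    seed: int = 0,
    n_per_group: int = 8,
    grip_n_per_group: int = 8,
) -> StudyFixture:
    """Generate the full reference-study inputs from one seed.

    Five agents on their published dose grids, ten fixed-ratio 1:1 mixtures
    with latent kappa equal to the published interaction indices (17 single
    and 35 mixture groups of ``n_per_group`` animals), plus raw grip-strength
    forces (a null treatment effect) for a vehicle group and each mixture.
    """
    rng = np.random.default_rng(seed)
    agents = {m.agent_id: m for m in FIXTURE_AGENTS}

    singles = {
        aid: simulate_single(agents[aid], FIXTURE_DOSES[aid], n_per_group, rng)
        for aid in sorted(agents)
    }

    combos = []
    mixtures = {}
    pairs = {}
    mix_doses = {}
    for i, (a, b, kappa) in enumerate(FIXTURE_PAIRS):
        model = CombinationModel(agents[a], agents[b], 0.5, kappa)
        combos.append(model)
        rel = _GRID4 if i < 5 else _GRID3
        doses = tuple(model.latent_ed50 * r for r in rel)
        mixtures[model.combo_id] = simulate_combination(
            model, doses, n_per_group, rng
        )
        pairs[model.combo_id] = (a, b)
        mix_doses[model.combo_id] = doses

    grip = {
        "vehicle": list(
            rng.normal(FIXTURE_GRIP_MEAN_N, FIXTURE_GRIP_SD_N, grip_n_per_group)
        )
    }
    for combo in mixtures:
        grip[combo] = list(
            rng.normal(FIXTURE_GRIP_MEAN_N, FIXTURE_GRIP_SD_N, grip_n_per_group)
        )
    # forces must be positive; the normal tail below zero is negligible at
    # these settings but clip defensively
    grip = {k: [max(v, 1e-3) for v in vals] for k, vals in grip.items()}

    return StudyFixture(
        agents=tuple(FIXTURE_AGENTS),
        combinations=tuple(combos),
        single_datasets=singles,
        mixture_datasets=mixtures,
        mixture_pairs=pairs,
        mixture_doses=mix_doses,
        grip_forces=grip,
    )
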