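"""Whole-study orchestration: fits, parallelism routing, report assembly.

``run_study`` reproduces the complete analysis workflow of a fixed-ratio
isobolographic study: fit every single agent by log-probit regression, test
each configured pair for parallelism, route the pair to the straight-line
or bounded (non-parallel) additive engine, fit the experimental mixture,
classify the interaction with the Welch comparison, run the compromise
power analysis, tally the animal ledger, optionally run the grip-strength
one-way ANOVA, and assemble everything into a serializable
:class:`StudyReport`.

No multiple-testing correction is applied across pairs: each combination is
reported with its own per-pair test, matching standard practice in this
assay literature.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__ as _pkg_version
from .data import DoseResponseDataset
from .isobole import (
    AdditivePrediction,
    InteractionResult,
    MixtureDesign,
    PowerReport,
    additive_nonparallel,
    additive_parallel,
    compare_exp_vs_add,
    compromise_power,
)
from .probit import ParallelismResult, ProbitFit, fit_log_probit, test_parallelism
from .viz import build_polygonogram_spec

__all__ = [
    "StudyConfig",
    "AnimalLedger",
    "GripStrengthGroup",
    "AnovaResult",
    "StudyReport",
    "StudyInputError",
    "run_study",
    "count_animals",
    "grip_strength_anova",
    "grip_strength_summary",
    "default_study_config",
]


class StudyInputError(ValueError):
    """A configured agent or pair has no matching dataset."""


def pair_label(agent_a: str, agent_b: str) -> str:
    return f"{agent_a}+{agent_b}"


@dataclass(frozen=True)
class StudyConfig:
    """Declarative description of a fixed-ratio combination study."""

    agents: dict[str, tuple[float, ...]]  # agent -> single-drug dose list
    pairs: tuple[tuple[str, str], ...]
    mixture_doses: dict[str, tuple[float, ...]] = field(default_factory=dict)
    fixed_fraction_f: float = 0.5
    alpha: float = 0.05
    animals_per_group: int = 8
    seed: int = 0
    beta_alpha_ratio_q: float = 1.0
    #: optional per-pair routing override: label -> True (force parallel
    #: engine) or False (force the bounded non-parallel engine)
    force_parallelism: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.fixed_fraction_f < 1.0:
            raise ValueError("fixed_fraction_f must lie in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        for a, b in self.pairs:
            for agent in (a, b):
                if agent not in self.agents:
                    raise ValueError(f"pair references undeclared agent {agent!r}")
        for agent, doses in self.agents.items():
            if len(doses) == 0:
                raise ValueError(f"agent {agent!r} has an empty dose list")


@dataclass(frozen=True)
class AnimalLedger:
    """Bookkeeping of groups and animals implied by the study design."""

    single_drug_groups: int
    mixture_groups: int
    animals_per_group: int
    animals_single: int
    animals_mixture: int
    animals_total: int


@dataclass(frozen=True)
class GripStrengthGroup:
    """Raw per-animal forelimb grip forces (newtons) for one treatment."""

    treatment_label: str
    forces: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "forces", tuple(float(f) for f in self.forces))
        if any(f <= 0 for f in self.forces):
            raise ValueError("forces must be positive")

    @property
    def mean(self) -> float:
        return float(np.mean(self.forces))

    @property
    def sem(self) -> float:
        return float(np.std(self.forces, ddof=1) / math.sqrt(len(self.forces)))


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float


@dataclass(frozen=True)
class StudyReport:
    """Complete, serializable outcome of one study run."""

    fits: dict[str, ProbitFit]
    parallelism: dict[str, ParallelismResult]
    interactions: dict[str, InteractionResult]
    power: dict[str, PowerReport]
    ledger: AnimalLedger
    grip_anova: AnovaResult | None
    grip_summary: dict[str, tuple[float, float]] | None
    polygonogram: dict
    provenance: dict

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    k: clean(v) for k, v in dataclasses.asdict(obj).items()
                }
            if isinstance(obj, dict):
                return {str(k): clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, float) and not math.isfinite(obj):
                return None
            return obj

        return clean(
            {
                "fits": self.fits,
                "parallelism": self.parallelism,
                "interactions": self.interactions,
                "power": self.power,
                "ledger": self.ledger,
                "grip_anova": self.grip_anova,
                "grip_summary": self.grip_summary,
                "polygonogram": self.polygonogram,
                "provenance": self.provenance,
            }
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def interaction_table(self) -> pd.DataFrame:
        """Per-pair table mirroring the standard report layout (2-decimal mg/kg)."""
        rows = []
        for label, res in self.interactions.items():
            add = res.additive
            row = {
                "combination": label,
                "kind": add.kind,
                "ed50_exp": round(res.ed50_exp, 2),
                "sem_exp": round(res.sem_exp, 2),
                "n_exp": res.n_exp,
                "ed50_add": None if add.ed50_add is None else round(add.ed50_add, 2),
                "sem_add": None if add.sem_add is None else round(add.sem_add, 2),
                "lower_ed50_add": None
                if add.lower_ed50_add is None
                else round(add.lower_ed50_add, 2),
                "upper_ed50_add": None
                if add.upper_ed50_add is None
                else round(add.upper_ed50_add, 2),
                "n_add": add.n_add,
                "t_statistic": round(res.t_statistic, 3),
                "df": round(res.df, 1),
                "p_value": res.p_value,
                "i_index": round(res.interaction_index, 2),
                "classification": res.classification,
            }
            rows.append(row)
        return pd.DataFrame(rows)

    def ledger_table(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(self.ledger)])


def count_animals(config: StudyConfig) -> AnimalLedger:
    """Group and animal totals implied by the configured dose lists."""
    single_groups = sum(len(d) for d in config.agents.values())
    mixture_groups = sum(len(d) for d in config.mixture_doses.values())
    n = config.animals_per_group
    return AnimalLedger(
        single_drug_groups=single_groups,
        mixture_groups=mixture_groups,
        animals_per_group=n,
        animals_single=single_groups * n,
        animals_mixture=mixture_groups * n,
        animals_total=(single_groups + mixture_groups) * n,
    )


def grip_strength_anova(groups: Sequence[GripStrengthGroup]) -> AnovaResult:
    """One-way ANOVA on raw per-animal grip forces across treatments."""
    if len(groups) < 2:
        raise ValueError("need at least 2 treatment groups")
    samples = [np.asarray(g.forces, dtype=float) for g in groups]
    if any(s.size < 2 for s in samples):
        raise ValueError("each group needs at least 2 observations")
    k = len(samples)
    n_total = sum(s.size for s in samples)
    allvals = np.concatenate(samples)
    if np.allclose(allvals, allvals[0]):
        return AnovaResult(0.0, k - 1, n_total - k, 1.0)
    f, p = stats.f_oneway(*samples)
    return AnovaResult(float(f), k - 1, n_total - k, float(p))


def grip_strength_summary(
    groups: Sequence[GripStrengthGroup],
) -> dict[str, tuple[float, float]]:
    """Mean force (N) ± SEM per treatment ("summary mode")."""
    return {g.treatment_label: (g.mean, g.sem) for g in groups}


def run_study(
    config: StudyConfig,
    single_data: Mapping[str, DoseResponseDataset],
    mixture_data: Mapping[str, DoseResponseDataset],
    grip_data: Mapping[str, Sequence[float]] | None = None,
) -> StudyReport:
    """Execute the full isobolographic analysis for a configured study.

    ``mixture_data`` is keyed by the pair label ``"A+B"`` in the order the
    pair is declared.  Deterministic for fixed inputs and config.
    """
    for agent in config.agents:
        if agent not in single_data:
            raise StudyInputError(f"no single-agent dataset for {agent!r}")

    fits = {
        agent: fit_log_probit(single_data[agent])
        for agent in sorted(config.agents)
    }

    parallelism: dict[str, ParallelismResult] = {}
    interactions: dict[str, InteractionResult] = {}
    power: dict[str, PowerReport] = {}

    for a, b in config.pairs:
        label = pair_label(a, b)
        if label not in mixture_data:
            raise StudyInputError(f"no mixture dataset for pair {label!r}")
        verdict = test_parallelism(fits[a], fits[b])
        parallelism[label] = verdict
        use_parallel = config.force_parallelism.get(label, verdict.parallel)

        f = config.fixed_fraction_f
        if use_parallel:
            additive = additive_parallel(fits[a], fits[b], f)
        else:
            additive = additive_nonparallel(fits[a], fits[b], f)

        mix_fit = fit_log_probit(mixture_data[label])
        design = MixtureDesign(a, b, fits[a].ed50, fits[b].ed50, f)
        try:
            res = compare_exp_vs_add(
                mix_fit.ed50,
                mix_fit.sem_ed50,
                mix_fit.n_effective,
                additive,
                alpha=config.alpha,
                design=design,
            )
        except ValueError as exc:
            raise StudyInputError(f"pair {label!r}: {exc}") from exc
        interactions[label] = res
        power[label] = compromise_power(
            res.ed50_exp,
            res.sem_exp,
            res.n_exp,
            additive.reference_ed50,
            additive.reference_sem,
            additive.n_add,
            q=config.beta_alpha_ratio_q,
        )

    grip_anova = None
    grip_summ = None
    if grip_data is not None:
        groups = [
            GripStrengthGroup(label, tuple(forces))
            for label, forces in sorted(grip_data.items())
        ]
        grip_anova = grip_strength_anova(groups)
        grip_summ = grip_strength_summary(groups)

    polygonogram = build_polygonogram_spec(interactions).to_dict()

    provenance = {
        "config": {
            "agents": {a: list(d) for a, d in config.agents.items()},
            "pairs": [list(p) for p in config.pairs],
            "mixture_doses": {k: list(v) for k, v in config.mixture_doses.items()},
            "fixed_fraction_f": config.fixed_fraction_f,
            "alpha": config.alpha,
            "animals_per_group": config.animals_per_group,
            "seed": config.seed,
        },
        "seed": config.seed,
        "version": _pkg_version,
    }

    return StudyReport(
        fits=fits,
        parallelism=parallelism,
        interactions=interactions,
        power=power,
        ledger=count_animals(config),
        grip_anova=grip_anova,
        grip_summary=grip_summ,
        polygonogram=polygonogram,
        provenance=provenance,
    )


def default_study_config(seed: int = 0) -> StudyConfig:
    """Config matching the bundled reference-study layout (17+35 groups)."""
    from .simulate import FIXTURE_DOSES, FIXTURE_PAIRS, make_study_fixture

    fixture = make_study_fixture(seed)
    return StudyConfig(
        agents={a: tuple(d) for a, d in FIXTURE_DOSES.items()},
        pairs=tuple((a, b) for a, b, _ in FIXTURE_PAIRS),
        mixture_doses=dict(fixture.mixture_doses),
        seed=seed,
    )
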