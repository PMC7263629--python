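"""Quantal dose-response containers and CSV input/output.

The atomic observation in a quantal protection assay is a *dose group*: a
cohort of animals given the same dose of one agent (or one fixed-ratio
mixture, in which case the dose is the *total* dose of the mixture), with a
count of how many were protected.  A :class:`DoseResponseDataset` collects the
groups for a single agent or mixture.

CSV schemas
-----------
Single agents::

    agent_id,dose_mg_per_kg,n_protected,n_total

Fixed-ratio mixtures::

    combo_id,agent_a,agent_b,total_dose_mg_per_kg,n_protected,n_total

Grip-strength raw forces::

    treatment,force_newton

All files are comma-separated UTF-8 with ``.`` as the decimal mark.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "DoseGroup",
    "DoseResponseDataset",
    "SchemaError",
    "read_single_agent_csv",
    "read_mixture_csv",
    "read_grip_csv",
    "write_single_agent_csv",
    "write_mixture_csv",
]

SINGLE_COLUMNS = ["agent_id", "dose_mg_per_kg", "n_protected", "n_total"]
MIXTURE_COLUMNS = [
    "combo_id",
    "agent_a",
    "agent_b",
    "total_dose_mg_per_kg",
    "n_protected",
    "n_total",
]
GRIP_COLUMNS = ["treatment", "force_newton"]


class SchemaError(ValueError):
    """A CSV row violates the expected schema; carries the offending line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class DoseGroup:
    """One cohort of animals at one dose.

    ``dose`` is in mg/kg; for a mixture group it is the total dose of both
    components.  ``n_protected`` of ``n_total`` animals were protected.
    """

    agent_id: str
    dose: float
    n_protected: int
    n_total: int

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise ValueError(f"dose must be positive, got {self.dose}")
        if self.n_total < 1:
            raise ValueError(f"n_total must be >= 1, got {self.n_total}")
        if not 0 <= self.n_protected <= self.n_total:
            raise ValueError(
                f"n_protected must be in [0, n_total], got "
                f"{self.n_protected}/{self.n_total}"
            )

    @property
    def proportion(self) -> float:
        return self.n_protected / self.n_total


@dataclass(frozen=True)
class DoseResponseDataset:
    """Quantal outcome groups for one agent or one fixed-ratio mixture."""

    agent_id: str
    groups: tuple[DoseGroup, ...]
    route: str = "i.p."
    pretreatment_min: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        if any(g.agent_id != self.agent_id for g in self.groups):
            raise ValueError("all groups must share the dataset agent_id")
        if len(self.distinct_doses()) < 2:
            raise ValueError(
                f"dataset {self.agent_id!r} needs >= 2 distinct dose levels"
            )

    def distinct_doses(self) -> list[float]:
        return sorted({g.dose for g in self.groups})

    @property
    def n_animals(self) -> int:
        return sum(g.n_total for g in self.groups)

    def pooled(self) -> "DoseResponseDataset":
        """Merge duplicate-dose groups by summing counts (order by dose)."""
        agg: dict[float, list[int]] = {}
        for g in self.groups:
            a = agg.setdefault(g.dose, [0, 0])
            a[0] += g.n_protected
            a[1] += g.n_total
        groups = tuple(
            DoseGroup(self.agent_id, d, k, n) for d, (k, n) in sorted(agg.items())
        )
        return replace(self, groups=groups)

    @classmethod
    def from_counts(
        cls,
        agent_id: str,
        doses: Iterable[float],
        n_protected: Iterable[int],
        n_total: Iterable[int] | int,
        **meta,
    ) -> "DoseResponseDataset":
        doses = list(doses)
        n_protected = list(n_protected)
        if isinstance(n_total, int):
            n_total = [n_total] * len(doses)
        else:
            n_total = list(n_total)
        if not len(doses) == len(n_protected) == len(n_total):
            raise ValueError("doses, n_protected and n_total must align")
        groups = tuple(
            DoseGroup(agent_id, d, k, n)
            for d, k, n in zip(doses, n_protected, n_total)
        )
        return cls(agent_id, groups, **meta)


def _require_columns(df: pd.DataFrame, expected: list[str], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}", line=1)


def _int_field(value, name: str, line: int) -> int:
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise SchemaError(f"{name} is not a number: {value!r}", line=line) from None
    if f != int(f):
        raise SchemaError(f"{name} must be an integer count: {value!r}", line=line)
    return int(f)


def read_single_agent_csv(path) -> dict[str, DoseResponseDataset]:
    """Read a single-agent CSV into one dataset per ``agent_id``.

    Raises :class:`SchemaError` naming the 1-based file line of the first
    offending row.
    """
    df = pd.read_csv(path)
    _require_columns(df, SINGLE_COLUMNS, path)
    by_agent: dict[str, list[DoseGroup]] = {}
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        agent = str(row["agent_id"])
        k = _int_field(row["n_protected"], "n_protected", line)
        n = _int_field(row["n_total"], "n_total", line)
        try:
            group = DoseGroup(agent, float(row["dose_mg_per_kg"]), k, n)
        except (TypeError, ValueError) as exc:
            raise SchemaError(str(exc), line=line) from None
        by_agent.setdefault(agent, []).append(group)
    out = {}
    for agent, groups in by_agent.items():
        try:
            out[agent] = DoseResponseDataset(agent, tuple(groups))
        except ValueError as exc:
            raise SchemaError(f"agent {agent!r}: {exc}") from None
    return out


def read_mixture_csv(path) -> dict[str, DoseResponseDataset]:
    """Read a mixtures CSV into one dataset per ``combo_id``.

    Each dataset's ``agent_id`` is the combo id and its doses are total
    mixture doses.  Callers that need the component agent pair for a combo
    should use :func:`read_mixture_pairs` on the same file.
    """
    df = pd.read_csv(path)
    _require_columns(df, MIXTURE_COLUMNS, path)
    by_combo: dict[str, list[DoseGroup]] = {}
    for i, row in df.iterrows():
        line = i + 2
        combo = str(row["combo_id"])
        k = _int_field(row["n_protected"], "n_protected", line)
        n = _int_field(row["n_total"], "n_total", line)
        try:
            group = DoseGroup(combo, float(row["total_dose_mg_per_kg"]), k, n)
        except (TypeError, ValueError) as exc:
            raise SchemaError(str(exc), line=line) from None
        by_combo.setdefault(combo, []).append(group)
    out = {}
    for combo, groups in by_combo.items():
        try:
            out[combo] = DoseResponseDataset(combo, tuple(groups))
        except ValueError as exc:
            raise SchemaError(f"combination {combo!r}: {exc}") from None
    return out


def read_mixture_pairs(path) -> dict[str, tuple[str, str]]:
    """Map each ``combo_id`` in a mixtures CSV to its (agent_a, agent_b)."""
    df = pd.read_csv(path)
    _require_columns(df, MIXTURE_COLUMNS, path)
    pairs: dict[str, tuple[str, str]] = {}
    for i, row in df.iterrows():
        combo = str(row["combo_id"])
        pair = (str(row["agent_a"]), str(row["agent_b"]))
        if pairs.setdefault(combo, pair) != pair:
            raise SchemaError(
                f"combination {combo!r} maps to conflicting agent pairs", line=i + 2
            )
    return pairs


def read_grip_csv(path) -> dict[str, list[float]]:
    """Read per-animal grip forces, keyed by treatment label."""
    df = pd.read_csv(path)
    _require_columns(df, GRIP_COLUMNS, path)
    out: dict[str, list[float]] = {}
    for i, row in df.iterrows():
        force = float(row["force_newton"])
        if force <= 0:
            raise SchemaError(f"force_newton must be positive: {force}", line=i + 2)
        out.setdefault(str(row["treatment"]), []).append(force)
    return out


def write_single_agent_csv(datasets: Mapping[str, DoseResponseDataset], path) -> None:
    rows = [
        {
            "agent_id": g.agent_id,
            "dose_mg_per_kg": g.dose,
            "n_protected": g.n_protected,
            "n_total": g.n_total,
        }
        for ds in datasets.values()
        for g in ds.groups
    ]
    pd.DataFrame(rows, columns=SINGLE_COLUMNS).to_csv(path, index=False)


def write_mixture_csv(
    datasets: Mapping[str, DoseResponseDataset],
    pairs: Mapping[str, tuple[str, str]],
    path,
) -> None:
    rows = [
        {
            "combo_id": combo,
            "agent_a": pairs[combo][0],
            "agent_b": pairs[combo][1],
            "total_dose_mg_per_kg": g.dose,
            "n_protected": g.n_protected,
            "n_total": g.n_total,
        }
        for combo, ds in datasets.items()
        for g in ds.groups
    ]
    pd.DataFrame(rows, columns=MIXTURE_COLUMNS).to_csv(path, index=False)
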