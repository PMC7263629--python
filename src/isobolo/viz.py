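"""Isobolograms and the polygonogram.

Rendering is split into two layers so tests can check structure without
touching pixels: ``build_*_spec`` functions produce plain declarative scene
descriptions (points, lines, edges), and ``render_*`` functions draw a spec
with matplotlib (SVG primary, PNG also supported).

Isobologram conventions: the first-declared drug of the pair sits on the
abscissa and the second on the ordinate, each axis anchored by that drug's
ED50 with its SEM error bar.  Parallel pairs show one straight line of
additivity and two labelled points — A (the additive prediction) and M (the
experimental mixture ED50), both on the fixed-ratio ray with SEM bars.
Non-parallel pairs show the lower and upper additivity bounds with points
A' and A'' plus M.

Polygonogram: the complete graph over the study's agents, a solid edge for
synergy, dashed for additivity, and dotted for antagonism (an extension of
the usual two-style legend, since antagonism is representable even when a
given study never observes it), with a companion column chart of the
interaction indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .isobole import InteractionResult, mixture_component_doses

__all__ = [
    "IsobologramSpec",
    "PolygonogramSpec",
    "build_isobologram_spec",
    "build_polygonogram_spec",
    "render_isobologram",
    "render_polygonogram",
]

EDGE_STYLE = {"synergy": "solid", "additivity": "dashed", "antagonism": "dotted"}


@dataclass(frozen=True)
class LabelledPoint:
    label: str  # "A", "A'", "A''" or "M"
    x: float  # dose of the abscissa drug (mg/kg)
    y: float  # dose of the ordinate drug (mg/kg)
    total: float
    sem_total: float


@dataclass(frozen=True)
class IsobologramSpec:
    """Declarative scene for one pair's isobologram."""

    agent_x: str
    agent_y: str
    ed50_x: float
    sem_x: float
    ed50_y: float
    sem_y: float
    kind: str  # "parallel" | "nonparallel"
    additivity_lines: tuple[tuple[tuple[float, float], ...], ...]
    points: tuple[LabelledPoint, ...]
    ray: tuple[tuple[float, float], tuple[float, float]]

    def to_dict(self) -> dict:
        return {
            "agent_x": self.agent_x,
            "agent_y": self.agent_y,
            "ed50_x": self.ed50_x,
            "ed50_y": self.ed50_y,
            "kind": self.kind,
            "n_additivity_lines": len(self.additivity_lines),
            "points": [
                {"label": p.label, "x": p.x, "y": p.y, "total": p.total}
                for p in self.points
            ],
        }


@dataclass(frozen=True)
class PolygonogramSpec:
    """Complete-graph summary of all pairwise interactions."""

    nodes: tuple[str, ...]
    edges: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"nodes": list(self.nodes), "edges": dict(self.edges)}

    def edge_count(self, style: str) -> int:
        return sum(1 for e in self.edges.values() if e["style"] == style)


def _ray_point(result: InteractionResult, label: str, total: float, sem: float):
    dx, dy = mixture_component_doses(result.design, total)
    return LabelledPoint(label=label, x=dx, y=dy, total=total, sem_total=sem)


def build_isobologram_spec(result: InteractionResult) -> IsobologramSpec:
    """Scene description for one interaction result.

    Requires the result to carry its :class:`~isobolo.isobole.MixtureDesign`
    (fits produced by ``run_study`` always do).
    """
    design = result.design
    if design is None:
        raise ValueError("isobologram needs the result's MixtureDesign")
    add = result.additive
    A, B = design.ed50_a, design.ed50_b

    if add.kind == "parallel":
        lines = (((A, 0.0), (0.0, B)),)
        points = (
            _ray_point(result, "A", add.ed50_add, add.sem_add),
            _ray_point(result, "M", result.ed50_exp, result.sem_exp),
        )
    else:
        lines = tuple(
            _trace_bound(design, total, which)
            for total, which in (
                (add.lower_ed50_add, "lower"),
                (add.upper_ed50_add, "upper"),
            )
        )
        points = (
            _ray_point(result, "A'", add.lower_ed50_add, add.sem_lower),
            _ray_point(result, "A''", add.upper_ed50_add, add.sem_upper),
            _ray_point(result, "M", result.ed50_exp, result.sem_exp),
        )

    far = max(p.total for p in points)
    ray_end = mixture_component_doses(design, 1.25 * far)
    return IsobologramSpec(
        agent_x=design.agent_a,
        agent_y=design.agent_b,
        ed50_x=A,
        sem_x=0.0,
        ed50_y=B,
        sem_y=0.0,
        kind=add.kind,
        additivity_lines=lines,
        points=points,
        ray=((0.0, 0.0), ray_end),
    )


def _trace_bound(design, total: float, which: str, n: int = 64):
    """Curved dose-equivalence isobole through a known ray intersection.

    Each bound has the form ``u + v**rho = 1`` (or its mirror) in reduced
    coordinates ``u = d_a/ED50_a``, ``v = d_b/ED50_b``; the exponent is
    recovered from the intersection point so the drawn curve passes exactly
    through both single-drug anchors and the bound's labelled point.
    """
    A, B = design.ed50_a, design.ed50_b
    da, db = mixture_component_doses(design, total)
    u0, v0 = min(da / A, 1.0 - 1e-12), min(db / B, 1.0 - 1e-12)
    us = np.linspace(0.0, 1.0, n)
    if which == "lower":
        rho = math.log(1.0 - u0) / math.log(v0) if v0 > 0 else 1.0
        vs = (1.0 - us) ** (1.0 / rho)
    else:
        rho = math.log(1.0 - v0) / math.log(u0) if u0 > 0 else 1.0
        vs = 1.0 - us**rho
    return tuple(zip((A * us).tolist(), (B * vs).tolist()))


def build_polygonogram_spec(
    interactions: Mapping[str, InteractionResult]
) -> PolygonogramSpec:
    """Adjacency structure over agents with styled interaction edges."""
    nodes: list[str] = []
    edges: dict[str, dict] = {}
    seen_pairs: set[frozenset] = set()
    for label, res in interactions.items():
        if res.design is not None:
            a, b = res.design.agent_a, res.design.agent_b
        else:
            a, b = label.split("+", 1)
        key = frozenset((a, b))
        if key in seen_pairs:
            raise ValueError(f"duplicate pair in polygonogram: {label}")
        seen_pairs.add(key)
        for agent in (a, b):
            if agent not in nodes:
                nodes.append(agent)
        edges[label] = {
            "agents": [a, b],
            "style": EDGE_STYLE[res.classification],
            "classification": res.classification,
            "interaction_index": res.interaction_index,
        }
    return PolygonogramSpec(nodes=tuple(nodes), edges=edges)


# -- matplotlib rendering ----------------------------------------------------


def _get_axes():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def render_isobologram(result: InteractionResult, path) -> IsobologramSpec:
    """Draw one pair's isobologram to ``path`` (format from the suffix)."""
    spec = build_isobologram_spec(result)
    plt = _get_axes()
    fig, ax = plt.subplots(figsize=(5, 5))
    for line in spec.additivity_lines:
        xs, ys = zip(*line)
        ax.plot(xs, ys, color="black", lw=1)
    rx, ry = zip(*spec.ray)
    ax.plot(rx, ry, ls=":", color="gray", lw=1)
    for p in spec.points:
        frac = p.x / p.total if p.total else 0.0
        ax.errorbar(
            p.x, p.y,
            xerr=p.sem_total * frac,
            yerr=p.sem_total * (1 - frac),
            marker="o", capsize=3, color="black",
        )
        ax.annotate(p.label, (p.x, p.y), textcoords="offset points", xytext=(6, 6))
    ax.set_xlabel(f"{spec.agent_x} dose (mg/kg)")
    ax.set_ylabel(f"{spec.agent_y} dose (mg/kg)")
    ax.set_xlim(left=0)
    ax.set_ylim(bottom=0)
    ax.set_title(f"{spec.agent_x} + {spec.agent_y} ({spec.kind})")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return spec


def render_polygonogram(
    interactions: Mapping[str, InteractionResult], path
) -> PolygonogramSpec:
    """Draw the polygonogram plus an interaction-index column chart."""
    spec = build_polygonogram_spec(interactions)
    plt = _get_axes()
    fig, (ax_g, ax_c) = plt.subplots(1, 2, figsize=(10, 5))

    n = len(spec.nodes)
    angles = {
        node: (2 * math.pi * i / n + math.pi / 2) for i, node in enumerate(spec.nodes)
    }
    pos = {node: (math.cos(a), math.sin(a)) for node, a in angles.items()}
    for label, e in spec.edges.items():
        a, b = e["agents"]
        (x1, y1), (x2, y2) = pos[a], pos[b]
        ax_g.plot([x1, x2], [y1, y2], ls={"solid": "-", "dashed": "--",
                                          "dotted": ":"}[e["style"]],
                  color="black", lw=1.5)
    for node, (x, y) in pos.items():
        ax_g.scatter([x], [y], s=600, color="white", edgecolor="black", zorder=3)
        ax_g.annotate(node, (x, y), ha="center", va="center", zorder=4)
    ax_g.set_aspect("equal")
    ax_g.axis("off")
    ax_g.set_title("interaction polygonogram")

    labels = list(spec.edges)
    idx = [spec.edges[k]["interaction_index"] for k in labels]
    hatches = [
        "" if spec.edges[k]["classification"] == "synergy" else "///" for k in labels
    ]
    bars = ax_c.bar(range(len(labels)), idx, color="white", edgecolor="black")
    for bar, h in zip(bars, hatches):
        bar.set_hatch(h)
    ax_c.axhline(1.0, ls=":", color="gray")
    ax_c.set_xticks(range(len(labels)))
    ax_c.set_xticklabels(labels, rotation=60, ha="right", fontsize=8)
    ax_c.set_ylabel("interaction index")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return spec
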