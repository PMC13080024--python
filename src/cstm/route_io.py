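"""Simplified synthesis-route dialect: read/write, classify, scale.

Real synthesis procedures, once executed on automated platforms, are
step lists in a chemical description language.  This module ships a
deliberately small stand-in dialect (YAML/JSON): a route names a
target and an ordered list of steps, each tagged with the 1-based
reaction step it belongs to and a free-form operation name.

Steps are classified into the machine's instruction categories: a name
found in the unit-operation registry is *composite* (annotated with
its primitive-expansion length), otherwise a default mapping table
sends common verbs to single primitives (add/transfer → AM,
filter/separate/evaporate → SM, heat/stir → AE, cool/crystallize →
SE).  The default table is a package stand-in, not a reproduction of
any deposited classification, and callers may override it.

:func:`cumulative_step_curve` aggregates classified routes into the
cumulative expanded-step count per reaction step and fits a line to
the mean curve — the desk-scale analogue of the observation that
executable procedure length grows approximately linearly with the
number of reaction steps.  :func:`generate_fixture_routes` produces a
seeded synthetic corpus (117 routes of one to three reaction steps by
default) for exercising that analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .core import CSTMError
from .unit_ops import UnitOpRegistry, default_registry


class RouteParseError(CSTMError):
    """Route file violates the dialect schema."""


#: default free-verb → primitive-category table (package stand-in,
#: user-overridable via ``category_map=``)
DEFAULT_CATEGORY_MAP: dict[str, str] = {
    "add": "AM",
    "add reagent": "AM",
    "transfer": "AM",
    "filter": "SM",
    "separate": "SM",
    "evaporate": "SM",
    "heat": "AE",
    "stir": "AE",
    "cool": "SE",
    "crystallize": "SE",
}

CATEGORIES = ("AM", "SM", "AE", "SE", "composite")


@dataclass(frozen=True)
class RouteStep:
    reaction_step: int
    op_name: str
    category: str | None = None
    expansion_len: int | None = None

    def expanded_count(self) -> int:
        """Primitive-expanded weight of this step (1 for non-composites)."""
        return self.expansion_len if self.category == "composite" else 1


@dataclass
class RouteFile:
    route_id: str
    target: str
    steps: list[RouteStep] = field(default_factory=list)
    metadata: dict[str, Any] = field(default_factory=dict)

    def n_reaction_steps(self) -> int:
        return max((s.reaction_step for s in self.steps), default=0)

    def to_dict(self) -> dict[str, Any]:
        return {
            "route_id": self.route_id,
            "target": self.target,
            "metadata": self.metadata,
            "steps": [
                {"reaction_step": s.reaction_step, "op": s.op_name}
                for s in self.steps
            ],
        }


def route_from_dict(doc: Mapping[str, Any], source: str = "<dict>") -> RouteFile:
    try:
        steps_raw = doc["steps"]
        route = RouteFile(
            route_id=str(doc["route_id"]),
            target=str(doc["target"]),
            metadata=dict(doc.get("metadata") or {}),
        )
    except (KeyError, TypeError) as exc:
        raise RouteParseError(f"{source}: missing required field: {exc}") from exc
    previous = 0
    for i, raw in enumerate(steps_raw):
        try:
            reaction_step = int(raw["reaction_step"])
            op = str(raw["op"])
        except (KeyError, TypeError, ValueError) as exc:
            raise RouteParseError(f"{source}: step {i}: {exc}") from exc
        if reaction_step < 1:
            raise RouteParseError(f"{source}: step {i}: reaction_step must be ≥ 1")
        if reaction_step < previous:
            raise RouteParseError(
                f"{source}: step {i}: reaction_step decreases ({previous} → {reaction_step})"
            )
        previous = reaction_step
        route.steps.append(RouteStep(reaction_step, op))
    return route


def read_route(path: str) -> RouteFile:
    """Read one route file (YAML or JSON by extension)."""
    with open(path) as fh:
        doc = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise RouteParseError(f"{path}: not a route document")
    return route_from_dict(doc, source=path)


def write_route(route: RouteFile, path: str) -> None:
    doc = route.to_dict()
    with open(path, "w") as fh:
        if path.endswith(".json"):
            json.dump(doc, fh, indent=2)
        else:
            yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


@dataclass
class ClassificationReport:
    route: RouteFile
    unclassified: list[str] = field(default_factory=list)

    @property
    def n_unclassified(self) -> int:
        return len(self.unclassified)


def classify_steps(route: RouteFile, registry: UnitOpRegistry | None = None,
                   category_map: Mapping[str, str] | None = None) -> ClassificationReport:
    """Assign every step a primitive category (or report it unclassified)."""
    registry = registry or default_registry()
    category_map = DEFAULT_CATEGORY_MAP if category_map is None else dict(category_map)
    classified: list[RouteStep] = []
    unclassified: list[str] = []
    for step in route.steps:
        name = step.op_name.lower()
        if name in registry:
            op = registry.get(name)
            classified.append(replace(step, category="composite",
                                      expansion_len=len(op.kinds)))
        elif name in category_map:
            classified.append(replace(step, category=category_map[name]))
        else:
            classified.append(replace(step, category=None))
            unclassified.append(step.op_name)
    out = RouteFile(route.route_id, route.target, classified, dict(route.metadata))
    return ClassificationReport(out, unclassified)


# ---------------------------------------------------------------------------
# scaling analysis
# ---------------------------------------------------------------------------


@dataclass
class StepCurve:
    """Cumulative expanded-step scaling across a route corpus."""

    curve: pd.DataFrame      # reaction_step, mean_cumulative, std, n_routes
    totals: pd.DataFrame     # route_id, n_reaction_steps, total_expanded
    slope: float
    intercept: float
    r_squared: float


def cumulative_step_curve(routes: Sequence[RouteFile]) -> StepCurve:
    """Mean cumulative expanded-step count per reaction step, plus a fit.

    Unclassified steps count 1 (they are still one executable step).
    The linear fit is over the mean cumulative curve; its slope is the
    average expanded steps added per reaction step.
    """
    if not routes:
        return StepCurve(
            pd.DataFrame(columns=["reaction_step", "mean_cumulative", "std", "n_routes"]),
            pd.DataFrame(columns=["route_id", "n_reaction_steps", "total_expanded"]),
            float("nan"), float("nan"), float("nan"),
        )
    per_route_cumulative: list[dict[int, int]] = []
    totals_rows = []
    for route in routes:
        by_step: dict[int, int] = {}
        for step in route.steps:
            by_step[step.reaction_step] = by_step.get(step.reaction_step, 0) + step.expanded_count()
        cumulative: dict[int, int] = {}
        running = 0
        for rs in range(1, route.n_reaction_steps() + 1):
            running += by_step.get(rs, 0)
            cumulative[rs] = running
        per_route_cumulative.append(cumulative)
        totals_rows.append({
            "route_id": route.route_id,
            "n_reaction_steps": route.n_reaction_steps(),
            "total_expanded": running,
        })
    max_steps = max((r.n_reaction_steps() for r in routes), default=0)
    rows = []
    for rs in range(1, max_steps + 1):
        values = [c[rs] for c in per_route_cumulative if rs in c]
        rows.append({
            "reaction_step": rs,
            "mean_cumulative": float(np.mean(values)),
            "std": float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
            "n_routes": len(values),
        })
    curve = pd.DataFrame(rows)
    if len(curve) >= 2:
        fit = stats.linregress(curve["reaction_step"], curve["mean_cumulative"])
        slope, intercept, r2 = fit.slope, fit.intercept, fit.rvalue ** 2
    else:
        slope = float(curve["mean_cumulative"].iloc[0]) if len(curve) else float("nan")
        intercept, r2 = 0.0, 1.0
    return StepCurve(curve, pd.DataFrame(totals_rows), float(slope), float(intercept), float(r2))


# ---------------------------------------------------------------------------
# synthetic route corpus
# ---------------------------------------------------------------------------

#: default per-step operation mix: a typical bench rhythm of additions,
#: conditioning, and work-up, with composite unit operations mixed in
DEFAULT_OP_MIX: dict[str, float] = {
    "add reagent": 0.30,
    "heat": 0.15,
    "stir": 0.10,
    "separate": 0.10,
    "evaporate": 0.05,
    "cool": 0.05,
    "drying": 0.10,
    "crystallization": 0.05,
    "liquid-liquid extraction": 0.10,
}


def generate_fixture_routes(seed: int, n_routes: int = 117,
                            steps_per_route_range: tuple[int, int] = (1, 3),
                            op_mix: Mapping[str, float] | None = None,
                            ops_per_step: int = 6,
                            registry: UnitOpRegistry | None = None,
                            category_map: Mapping[str, float] | None = None) -> list[RouteFile]:
    """Seeded synthetic route corpus with a fixed per-step operation mix.

    Each reaction step draws ``ops_per_step`` operation names from
    ``op_mix`` (a categorical distribution over registered/classifiable
    names, validated to sum to 1), so expanded step counts scale
    linearly in the number of reaction steps by construction.
    """
    registry = registry or default_registry()
    mix = dict(DEFAULT_OP_MIX if op_mix is None else op_mix)
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError(f"op_mix must sum to 1, got {sum(mix.values()):.6f}")
    cmap = DEFAULT_CATEGORY_MAP if category_map is None else dict(category_map)
    for name in mix:
        if name.lower() not in registry and name.lower() not in cmap:
            raise ValueError(f"op_mix entry {name!r} is neither registered nor classifiable")
    lo, hi = steps_per_route_range
    if not 1 <= lo <= hi:
        raise ValueError("steps_per_route_range must satisfy 1 <= lo <= hi")

    rng = np.random.default_rng(seed)
    names = sorted(mix)
    probs = np.array([mix[n] for n in names])
    routes: list[RouteFile] = []
    for i in range(n_routes):
        n_steps = int(rng.integers(lo, hi + 1))
        steps: list[RouteStep] = []
        for rs in range(1, n_steps + 1):
            drawn = rng.choice(len(names), size=ops_per_step, p=probs)
            steps.extend(RouteStep(rs, names[j]) for j in drawn)
        routes.append(RouteFile(
            route_id=f"route_{i:03d}",
            target=f"compound_{i:03d}",
            steps=steps,
            metadata={"generator_seed": seed},
        ))
    return routes
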