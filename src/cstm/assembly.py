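"""Assembly-theory calculus: index bounds, detectability, copy depletion.

The assembly index ``ai`` of a molecular graph is the minimal number of
joining operations needed to construct it from single bonds, allowing
recursive reuse of already-built parts.  For a graph with B bonds it is
bounded below by ceil(log2 B) (each join at most doubles the largest
part) and above by B − 1 (one bond at a time).

Detectability couples that intrinsic complexity to synthesis fidelity:
with per-step error probabilities ε_k, the flawless fraction after ai
steps is Π(1 − ε_k), so confirming a molecule that needs φ perfect
copies for detection requires synthesizing at least
``N_min = φ / Π(1 − ε_k)`` copies — exponentially many as ai grows or
fidelity drops.

:func:`simulate_copy_depletion` is the Monte-Carlo companion: starting
from N₀ copies (Avogadro's number by default), each assembly step i
removes a fraction ε_i = clip(ε₀·e^{k·i} + E_i, 0, 1−δ) with a
per-step systematic Gaussian term E_i ~ N(0, σ).  Trajectories
randomize the error *sequence*, not individual molecules: within a
trajectory the copy number is the continuous expectation
N_i = N_{i−1}(1 − ε_i).  With σ = 0 and k = 0 the mean collapses to
the closed form N₀(1 − ε₀)^i exactly.

General-purpose assembly-index computation is a hard search problem
and is out of scope; :func:`brute_force_assembly_index` is an exact
oracle for tiny graphs (B ≤ ~8) used to check the bounds.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

#: Avogadro's number: default initial copy population
N_AVOGADRO = 6.022e23

#: the ten baseline per-step error probabilities of the default grid
DEFAULT_EPSILON0_GRID = (0.01, 0.015, 0.02, 0.03, 0.05, 0.06, 0.08, 0.10, 0.20, 0.50)

#: per-step errors are clipped into [0, 1 − CLIP_DELTA]
CLIP_DELTA = 1e-9


def assembly_index_bounds(B: int) -> tuple[int, int]:
    """Theoretical (lower, upper) assembly-index bounds for B bonds.

    lower = ceil(log2 B), computed in integer arithmetic to avoid
    floating-point edge cases at powers of two; upper = B − 1.
    """
    if B < 2:
        raise ValueError(f"bounds require at least 2 bonds, got B={B}")
    return (B - 1).bit_length(), B - 1


@dataclass(frozen=True)
class AssemblyRecord:
    """A molecule summarized by bond count and assembly index."""

    bond_count: int
    assembly_index: int

    def __post_init__(self) -> None:
        lo, hi = assembly_index_bounds(self.bond_count)
        if not lo <= self.assembly_index <= hi:
            raise ValueError(
                f"assembly index {self.assembly_index} outside [{lo}, {hi}] "
                f"for B={self.bond_count}"
            )


def flawless_fraction(epsilon: float, ai: int) -> float:
    """Fraction of copies assembled without error: (1 − ε)^ai."""
    if not 0.0 <= epsilon < 1.0:
        raise ValueError(f"epsilon must lie in [0, 1), got {epsilon}")
    if ai < 0:
        raise ValueError("assembly index must be non-negative")
    return (1.0 - epsilon) ** ai


def n_min(phi: float, epsilons: Sequence[float]) -> float:
    """Minimum copies to synthesize so that φ flawless ones survive.

    ``phi / Π(1 − ε_k)``; monotone non-decreasing in every ε and in the
    number of steps.  Any ε = 1 makes the requirement infinite.
    """
    if phi <= 0:
        raise ValueError("phi must be positive")
    frac = 1.0
    for eps in epsilons:
        if not 0.0 <= eps <= 1.0:
            raise ValueError(f"per-step error {eps} outside [0, 1]")
        if eps == 1.0:
            return math.inf
        frac *= 1.0 - eps
    return phi / frac


def realizable(N: float, phi: float, epsilons: Sequence[float]) -> bool:
    """Detectability: is the expected flawless-copy count N ≥ N_min?"""
    if N < 0:
        raise ValueError("copy count must be non-negative")
    return N >= n_min(phi, epsilons)


@dataclass(frozen=True)
class DetectabilitySpec:
    """Detection threshold φ plus the per-step error schedule."""

    phi: float = 1e6  # typical reported range is 1e6–1e8
    epsilons: tuple[float, ...] = ()

    def n_min(self) -> float:
        return n_min(self.phi, self.epsilons)

    def realizable(self, N: float) -> bool:
        return realizable(N, self.phi, self.epsilons)


# ---------------------------------------------------------------------------
# Monte-Carlo copy depletion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ErrorModel:
    """Per-step error law ε_i = clip(ε₀·e^{k·i} + E_i, 0, 1−δ).

    ``epsilon0`` is the baseline per-step error, ``growth_rate`` the
    exponential growth constant with assembly depth, and
    ``systematic_sigma`` the standard deviation of the additive
    zero-mean Gaussian systematic term, resampled at every step of
    every trajectory.
    """

    epsilon0: float = 0.05
    growth_rate: float = 0.02
    systematic_sigma: float = 0.005
    clip_delta: float = CLIP_DELTA

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon0 < 1.0:
            raise ValueError("epsilon0 must lie in [0, 1)")
        if self.growth_rate < 0 or self.systematic_sigma < 0:
            raise ValueError("growth_rate and systematic_sigma must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    """Copy-depletion simulation settings (defaults: the stated world)."""

    N0: float = N_AVOGADRO
    ai_max: int = 120
    epsilon0_grid: tuple[float, ...] = DEFAULT_EPSILON0_GRID
    n_trajectories: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ai_max < 1 or self.n_trajectories < 1:
            raise ValueError("ai_max and n_trajectories must be ≥ 1")


def simulate_copy_depletion(config: SimulationConfig,
                            model: ErrorModel | None = None) -> pd.DataFrame:
    """Mean flawless copies vs assembly step for each baseline error.

    Seeding policy: one root ``SeedSequence(config.seed)`` spawns one
    child stream per ε₀ grid entry; within a stream the systematic
    terms are drawn as a single (n_trajectories, ai_max) normal block.
    Returns a tidy frame with columns ``epsilon0``, ``step``
    (1..ai_max), and ``mean_N``.
    """
    model = model if model is not None else ErrorModel()
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(len(config.epsilon0_grid))
    steps = np.arange(1, config.ai_max + 1)
    baseline = np.exp(model.growth_rate * steps)  # shape (ai_max,)
    frames = []
    for eps0, child in zip(config.epsilon0_grid, children):
        rng = np.random.default_rng(child)
        systematic = rng.normal(
            0.0, model.systematic_sigma, size=(config.n_trajectories, config.ai_max)
        )
        eps = np.clip(eps0 * baseline[None, :] + systematic, 0.0, 1.0 - model.clip_delta)
        survival = np.cumprod(1.0 - eps, axis=1)
        mean_n = config.N0 * survival.mean(axis=0)
        frames.append(pd.DataFrame(
            {"epsilon0": eps0, "step": steps, "mean_N": mean_n}
        ))
    return pd.concat(frames, ignore_index=True)


def closed_form_mean(config: SimulationConfig, epsilon0: float) -> np.ndarray:
    """Noise-free, growth-free limit: N₀(1 − ε₀)^i for i = 1..ai_max."""
    steps = np.arange(1, config.ai_max + 1)
    return config.N0 * (1.0 - epsilon0) ** steps


def plot_copy_depletion(table: pd.DataFrame, path: str) -> None:
    """Log-scale copy number vs assembly step, one line per ε₀."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for eps0, grp in table.groupby("epsilon0"):
        ax.plot(grp["step"], grp["mean_N"], label=f"$\\epsilon_0$={eps0:g}")
    ax.set_yscale("log")
    ax.set_xlabel("assembly index $a_i$")
    ax.set_ylabel("mean flawless copies $N$")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# brute-force assembly index for tiny graphs
# ---------------------------------------------------------------------------


def _connected_edge_subsets(G: nx.Graph) -> list[frozenset]:
    edges = [tuple(sorted(e)) for e in G.edges()]
    subsets = []
    for r in range(1, len(edges) + 1):
        for combo in itertools.combinations(edges, r):
            sub = nx.Graph(list(combo))
            if nx.is_connected(sub):
                subsets.append(frozenset(combo))
    return subsets


def brute_force_assembly_index(G: nx.Graph) -> int:
    """Exact shortest-assembly-path length for a tiny connected graph.

    Assembly model: the primitive objects are single bonds; one step
    joins two already-available structures along edge-disjoint
    embeddings into the target.  Once built, a structure may be reused
    any number of times (recursive reuse of parts), and structures are
    identified up to isomorphism.  The search restricts intermediates
    to connected subgraphs of the target, which preserves both the
    log2 lower bound (a join at most doubles the edge count) and the
    B − 1 upper bound (grow one bond at a time), so the returned index
    always lies within :func:`assembly_index_bounds`.

    Complexity is exponential in the bond count; intended for B ≤ ~8.
    """
    if G.number_of_edges() < 1:
        raise ValueError("graph must have at least one bond")
    if not nx.is_connected(G):
        raise ValueError("graph must be connected")
    B = G.number_of_edges()
    if B == 1:
        return 0

    subsets = _connected_edge_subsets(G)
    # group subsets into isomorphism classes
    class_reps: list[nx.Graph] = []
    subset_class: dict[frozenset, int] = {}
    for sub in subsets:
        g = nx.Graph(list(sub))
        for ci, rep in enumerate(class_reps):
            if (g.number_of_edges() == rep.number_of_edges()
                    and g.number_of_nodes() == rep.number_of_nodes()
                    and nx.is_isomorphic(g, rep)):
                subset_class[sub] = ci
                break
        else:
            subset_class[sub] = len(class_reps)
            class_reps.append(g)
    class_size = [rep.number_of_edges() for rep in class_reps]
    by_class: dict[int, list[frozenset]] = {}
    for sub, ci in subset_class.items():
        by_class.setdefault(ci, []).append(sub)

    target_class = subset_class[frozenset(tuple(sorted(e)) for e in G.edges())]
    bond_class = subset_class[next(s for s in subsets if len(s) == 1)]

    # joinable: (class a, class b) -> set of result classes via disjoint unions
    join: dict[tuple[int, int], set[int]] = {}
    for s1 in subsets:
        for s2 in subsets:
            if s1 & s2:
                continue
            union = s1 | s2
            res = subset_class.get(union)
            if res is None:
                continue  # disjoint union is disconnected
            key = tuple(sorted((subset_class[s1], subset_class[s2])))
            join.setdefault(key, set()).add(res)

    lo, hi = assembly_index_bounds(B)
    failed: set[tuple[frozenset, int]] = set()

    def search(pool: frozenset, depth: int) -> bool:
        if target_class in pool:
            return True
        if depth == 0:
            return False
        if max(class_size[c] for c in pool) * (2 ** depth) < B:
            return False
        key = (pool, depth)
        if key in failed:
            return False
        results: set[int] = set()
        for a in pool:
            for b in pool:
                if a <= b:
                    results |= join.get((a, b), set())
        # try larger intermediates first: fastest route to the target
        for r in sorted(results - pool, key=lambda c: -class_size[c]):
            if search(pool | {r}, depth - 1):
                return True
        failed.add(key)
        return False

    for depth in range(lo, hi + 1):
        if search(frozenset({bond_class}), depth):
            return depth
    # unreachable: one-bond-at-a-time growth always succeeds at depth B-1
    raise RuntimeError("assembly search failed to terminate within the upper bound")
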