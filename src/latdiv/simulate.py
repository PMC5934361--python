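"""Synthetic data with the statistical structure the analysis assumes.

Generates birth–death trees, binary latitudinal-affinity characters
evolving under Mk2 (optionally with an epoch rate shift), latitudinal
ranges consistent with the affinity, clade-structured tip diversification
rates with an optional latitude effect, and species-by-polygon incidence
records.  Every generator is deterministic under a fixed seed, and each
returns the ground truth needed for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import treeio
from .treeio import MutableNode, Phylogeny, from_nodes, node_ages
from .traitmodels import TROPIC_BOUNDARY, EpochMkParams

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "simulate_tree",
    "scale_to_age",
    "simulate_binary_trait",
    "simulate_ranges",
    "simulate_tip_rates",
    "simulate_incidence",
    "simulate_brownian",
]

_MAX_RETRIES = 1000

#: Default half-width range (degrees) for simulated latitudinal ranges;
#: narrow enough that most species fall entirely inside or outside the
#: tropics, as in the empirical data the generator emulates.
HALF_WIDTH_RANGE = (0.5, 15.0)


@dataclass
class SimulationConfig:
    """Bundled generator settings for the pipeline driver.

    Defaults describe the study conditions: a clock-scale tree of a few
    hundred tips with a root on the order of 100-150 my, slow binary
    trait evolution (q ~ 0.01 per my), and clade-structured tip rates
    with no latitude effect (beta = 0, the null the rate-latitude tests
    are calibrated against).
    """

    birth: float = 0.04
    death: float = 0.0
    n_tips: int | None = 200
    crown_age: float | None = None
    root_age: float | None = 140.0  # rescale target; None keeps simulated depth
    q01: float = 0.01
    q10: float = 0.01
    epoch_tau: float | None = None
    q_old: float | None = None
    q_young: float | None = None
    root_state: int = 0
    band_half_width: tuple[float, float] = HALF_WIDTH_RANGE
    n_regimes: int = 4
    regime_rates: tuple | None = None
    beta: float = 0.0
    rate_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.birth <= self.death or self.death < 0:
            raise ValueError("requires birth > death >= 0")
        if self.q01 < 0 or self.q10 < 0:
            raise ValueError("trait rates must be >= 0")


@dataclass
class TruthRecord:
    """Ground truth emitted alongside simulated data."""

    node_states: np.ndarray | None = None
    n_transitions: int | None = None
    tip_rates: pd.DataFrame | None = None
    regimes: dict | None = field(default=None)


# ----------------------------------------------------------------------
# trees


class _Lineage:
    __slots__ = ("node", "birth_time")

    def __init__(self, node, birth_time):
        self.node = node
        self.birth_time = birth_time


def simulate_tree(
    n_tips: int | None = None,
    crown_age: float | None = None,
    birth: float = 0.1,
    death: float = 0.0,
    seed: int | None = None,
    n_start: int = 1,
) -> Phylogeny:
    """Constant-rate birth–death tree conditioned on survival.

    Exactly one of ``n_tips`` (stop when that many lineages are extant;
    the tree is cut uniformly within the following inter-event wait) or
    ``crown_age`` (run ``n_start`` independent lineages for a fixed
    duration) must be given.  Full extinction triggers resimulation up
    to a bounded number of retries.  Tips are labeled ``t1..tn`` in tree
    order, deterministically under the seed.
    """
    if (n_tips is None) == (crown_age is None):
        raise ValueError("specify exactly one of n_tips or crown_age")
    if n_tips is not None and n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if crown_age is not None and crown_age <= 0:
        raise ValueError("crown_age must be > 0")
    if birth <= 0 or death < 0:
        raise ValueError("requires birth > 0 and death >= 0")
    rng = np.random.default_rng(seed)
    for _ in range(_MAX_RETRIES):
        tree = _simulate_once(n_tips, crown_age, birth, death, rng, n_start)
        if tree is not None:
            return tree
    raise RuntimeError(f"all lineages went extinct in {_MAX_RETRIES} attempts")


def _simulate_once(n_tips, crown_age, birth, death, rng, n_start):
    roots = [MutableNode() for _ in range(max(1 if n_tips is not None else n_start, 1))]
    active: list[_Lineage] = [_Lineage(r, 0.0) for r in roots]
    t = 0.0
    total = birth + death
    while active:
        n = len(active)
        dt = rng.exponential(1.0 / (n * total))
        if n_tips is not None and n == n_tips:
            # cut uniformly inside the waiting interval to the next event
            t_cut = t + rng.random() * dt
            for lin in active:
                lin.node.length = t_cut - lin.birth_time
            return _reconstruct(roots, active)
        if crown_age is not None and t + dt >= crown_age:
            for lin in active:
                lin.node.length = crown_age - lin.birth_time
            return _reconstruct(roots, active)
        t += dt
        k = rng.integers(n)
        lin = active.pop(k)
        lin.node.length = t - lin.birth_time
        if rng.random() < birth / total:
            for _ in range(2):
                child = lin.node.add(MutableNode())
                active.append(_Lineage(child, t))
        # else: death — lineage simply removed
    return None  # total extinction


def _reconstruct(roots, active):
    """Prune extinct lineages, suppress unifurcations, root at the crown."""
    alive = {id(lin.node) for lin in active}
    if len(alive) < 2:
        return None

    def rec(node):
        if not node.children:
            return node if id(node) in alive else None
        kept = [rec(c) for c in node.children]
        kept = [c for c in kept if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            kept[0].length += node.length
            return kept[0]
        node.children = kept
        return node

    pruned = [rec(r) for r in roots]
    pruned = [r for r in pruned if r is not None]
    if not pruned:
        return None
    if len(pruned) == 1:
        crown = pruned[0]
    else:
        crown = MutableNode()
        crown.children = pruned
    # descend to the first branching node (drop the stem)
    while len(crown.children) == 1:
        crown = crown.children[0]
    if not crown.children:
        return None
    crown.length = 0.0
    tree = from_nodes(crown)
    tree = Phylogeny(tree.parent, tree.length, [f"t{i+1}" for i in range(tree.n_tips)])
    return tree


def scale_to_age(tree: Phylogeny, root_age: float) -> Phylogeny:
    """Rescale all branch lengths so the root age equals ``root_age`` my."""
    cur = tree.root_age()
    if cur <= 0:
        raise ValueError("tree has zero depth")
    return Phylogeny(tree.parent.copy(), tree.length * (root_age / cur),
                     list(tree.tip_labels))


# ----------------------------------------------------------------------
# traits


def simulate_binary_trait(
    tree: Phylogeny,
    q01: float,
    q10: float,
    root_state: int = 0,
    seed: int | None = None,
    epoch: EpochMkParams | None = None,
) -> tuple[pd.Series, TruthRecord]:
    """Exact Gillespie simulation of a binary trait along the tree.

    With ``epoch`` given, the (symmetric) rate switches from
    ``epoch.q_old`` to ``epoch.q_young`` when a lineage crosses age
    ``epoch.tau``; otherwise the homogeneous rates ``q01``/``q10``
    apply.  Returns tip states (a Series indexed by tip label) and a
    :class:`TruthRecord` with every node state and the total transition
    count.
    """
    if q01 < 0 or q10 < 0:
        raise ValueError("rates must be >= 0")
    if root_state not in (0, 1):
        raise ValueError("root_state must be 0 or 1")
    rng = np.random.default_rng(seed)
    ages = node_ages(tree)
    states = np.empty(tree.n_nodes, dtype=np.int64)
    states[tree.root] = root_state
    n_trans = 0
    preorder = list(tree.postorder)[::-1]
    for v in preorder:
        for c in tree.children[v]:
            s = int(states[v])
            a = float(ages[v])  # older endpoint
            a_end = float(ages[c])
            while a > a_end:
                if epoch is not None:
                    # symmetric epoch rate applies in both directions
                    q = epoch.q_old if a > epoch.tau else epoch.q_young
                    horizon = epoch.tau if a > epoch.tau > a_end else a_end
                else:
                    q = q01 if s == 0 else q10
                    horizon = a_end
                if q <= 0.0:
                    a = horizon
                    continue
                wait = rng.exponential(1.0 / q)
                if a - wait <= horizon:
                    a = horizon
                else:
                    a -= wait
                    s = 1 - s
                    n_trans += 1
            states[c] = s
    tips = pd.Series(states[: tree.n_tips], index=tree.tip_labels, name="state")
    return tips, TruthRecord(node_states=states, n_transitions=n_trans)


# ----------------------------------------------------------------------
# geography


def simulate_ranges(
    tip_states: pd.Series,
    seed: int | None = None,
    half_width: tuple[float, float] = HALF_WIDTH_RANGE,
    boundary: float = TROPIC_BOUNDARY,
) -> pd.DataFrame:
    """Latitudinal ranges consistent with binary affinity states.

    Each species gets a half-width drawn uniformly from ``half_width``
    and a midpoint drawn inside the tropics (state 0) or poleward of the
    boundary (state 1), constrained so min/max stay within +-90 degrees.
    ``classify_affinity`` on the output recovers the input states
    exactly.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sp, s in tip_states.items():
        hw = rng.uniform(*half_width)
        if int(s) == 0:
            mid = rng.uniform(-boundary, boundary)
            # resampling at the closed boundary keeps the coding exact
            while abs(mid) >= boundary:
                mid = rng.uniform(-boundary, boundary)
        else:
            mag = rng.uniform(boundary, 90.0 - hw)
            mid = mag if rng.random() < 0.5 else -mag
        rows.append((sp, mid - hw, mid + hw))
    return pd.DataFrame(rows, columns=["species", "min_lat", "max_lat"])


# ----------------------------------------------------------------------
# diversification rates


def clade_partition(tree: Phylogeny, k: int) -> dict[int, list[str]]:
    """Partition tips into ``k`` disjoint monophyletic blocks.

    Found by repeatedly splitting the block with the most tips into its
    two child clades; deterministic for a given tree.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sizes = _clade_sizes(tree)
    blocks = [tree.root]
    while len(blocks) < k:
        cand = [b for b in blocks if tree.children[b]]
        if not cand:
            raise ValueError(f"k={k} exceeds the number of available disjoint clades")
        big = max(cand, key=lambda b: sizes[b])
        blocks.remove(big)
        blocks.extend(tree.children[big])
    return {b: _tips_under(tree, b) for b in blocks}


def _clade_sizes(tree: Phylogeny) -> np.ndarray:
    sizes = np.zeros(tree.n_nodes, dtype=np.int64)
    for v in tree.postorder:
        if not tree.children[v]:
            sizes[v] = 1
        else:
            sizes[v] = sum(sizes[c] for c in tree.children[v])
    return sizes


def _tips_under(tree: Phylogeny, v: int) -> list[str]:
    out = []
    stack = [v]
    while stack:
        x = stack.pop()
        if not tree.children[x]:
            out.append(tree.tip_labels[x])
        else:
            stack.extend(tree.children[x])
    return sorted(out)


def simulate_tip_rates(
    tree: Phylogeny,
    k: int,
    regime_rates,
    beta: float,
    ranges: pd.DataFrame,
    seed: int | None = None,
    noise_sd: float = 0.0,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Per-tip net diversification rates with a clade-regime structure.

    ``tip rate = regime rate * exp(beta * |midpoint latitude| / 90)``
    with multiplicative lognormal noise of log-sd ``noise_sd``.
    ``beta = 0`` makes rates latitude-independent (the null of the
    rate–latitude tests); negative ``beta`` depresses extratropical
    rates.
    """
    regime_rates = list(regime_rates)
    if len(regime_rates) != k:
        raise ValueError("need one rate per regime")
    rng = np.random.default_rng(seed)
    blocks = clade_partition(tree, k)
    mid = dict(zip(ranges["species"],
                   (ranges["min_lat"].to_numpy() + ranges["max_lat"].to_numpy()) / 2))
    rows = []
    for rid, (node, tips) in enumerate(sorted(blocks.items())):
        base = regime_rates[rid]
        for sp in tips:
            lat = abs(mid[sp])
            noise = math.exp(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 1.0
            rows.append((sp, base * math.exp(beta * lat / 90.0) * noise, rid))
    df = pd.DataFrame(rows, columns=["species", "rate", "regime"])
    truth = TruthRecord(tip_rates=df.copy(),
                        regimes={rid: tips for rid, (_, tips)
                                 in enumerate(sorted(blocks.items()))})
    return df, truth


# ----------------------------------------------------------------------
# incidence


def simulate_incidence(
    ranges: pd.DataFrame,
    polygons: pd.DataFrame,
    seed: int | None = None,
) -> pd.DataFrame:
    """Species-by-polygon incidence from latitudinal interval overlap.

    ``polygons`` needs columns ``polygon, min_lat, max_lat``; a species
    is present in every polygon whose latitude interval intersects its
    range (closed intervals).  The result is a binary DataFrame indexed
    by species with one column per polygon.  ``seed`` is accepted for
    interface uniformity; the operation is deterministic.
    """
    if len(polygons) == 0:
        raise ValueError("empty polygon set")
    smin = ranges["min_lat"].to_numpy()[:, None]
    smax = ranges["max_lat"].to_numpy()[:, None]
    pmin = polygons["min_lat"].to_numpy()[None, :]
    pmax = polygons["max_lat"].to_numpy()[None, :]
    inc = (smin <= pmax) & (smax >= pmin)
    return pd.DataFrame(inc.astype(int), index=ranges["species"].to_numpy(),
                        columns=polygons["polygon"].to_numpy())


# ----------------------------------------------------------------------
# Brownian motion (used for regression calibration)


def simulate_brownian(tree: Phylogeny, sigma: float = 1.0,
                      seed: int | None = None) -> pd.Series:
    """Brownian-motion tip values (root value 0, variance sigma^2 per my)."""
    rng = np.random.default_rng(seed)
    vals = np.zeros(tree.n_nodes)
    for v in list(tree.postorder)[::-1]:
        p = tree.parent[v]
        if p >= 0:
            vals[v] = vals[p] + rng.normal(0.0, sigma * math.sqrt(tree.length[v]))
    return pd.Series(vals[: tree.n_tips], index=tree.tip_labels)
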