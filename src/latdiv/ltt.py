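"""State-specific lineages-through-time curves from marginal probabilities.

Node marginal probabilities of the extratropical state are interpolated
linearly in time along each branch; at every 1-my grid point a lineage
is counted as high-confidence tropical or extratropical when the
interpolated probability clears a threshold (strictly greater than 0.90
by default).  Expected counts sum the probabilities themselves, so
expected tropical + expected extratropical equals the plain LTT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traitmodels import MarginalReconstruction
from .treeio import Phylogeny, node_ages

__all__ = ["StateLtt", "branch_state_prob", "state_ltt", "plain_ltt"]

DEFAULT_THRESHOLD = 0.90


@dataclass
class StateLtt:
    """Per-time-point lineage counts by reconstructed state."""

    table: pd.DataFrame  # time_my, n_total, n_hc_tropical, n_hc_extratropical,
    #                      e_tropical, e_extratropical

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def branch_state_prob(
    p_parent: float,
    p_child: float,
    age_parent: float,
    age_child: float,
    t: float,
) -> float:
    """Linear-in-time interpolation of a state probability along a branch.

    ``t`` must lie within [age_child, age_parent]; a zero-length branch
    returns the child's probability.
    """
    if not (age_child <= t <= age_parent):
        raise ValueError(
            f"time {t} outside branch interval [{age_child}, {age_parent}]"
        )
    dt = age_parent - age_child
    if dt <= 0:
        return p_child
    return p_child + (p_parent - p_child) * (t - age_child) / dt


def plain_ltt(tree: Phylogeny, times: np.ndarray) -> np.ndarray:
    """Number of branches crossing each time point (age_child <= t < age_parent)."""
    ages = node_ages(tree)
    counts = np.zeros(len(times), dtype=np.int64)
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        a_c, a_p = ages[v], ages[int(tree.parent[v])]
        counts += (times >= a_c) & (times < a_p)
    return counts


def state_ltt(
    tree: Phylogeny,
    marginals: MarginalReconstruction,
    threshold: float = DEFAULT_THRESHOLD,
    grid_step: float = 1.0,
) -> StateLtt:
    """State-specific LTT on a grid from the present to the root age.

    The grid runs from 0 to ceil(root age) in steps of ``grid_step`` my.
    Each branch spanning a grid time contributes its interpolated
    probability of being extratropical; a lineage is counted
    high-confidence extratropical when p > threshold and high-confidence
    tropical when 1 - p > threshold (strict inequalities, so p exactly
    at the threshold counts in neither class).  Terminal branches use
    the observed tip state as their young endpoint.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must be in (0.5, 1]")
    ages = node_ages(tree)
    p = marginals.p_extratropical
    if len(p) != tree.n_nodes:
        raise ValueError("marginals must cover all nodes")
    times = np.arange(0.0, math.ceil(tree.root_age()) + 0.5 * grid_step, grid_step)
    n_t = len(times)
    n_total = plain_ltt(tree, times)
    hc_trop = np.zeros(n_t, dtype=np.int64)
    hc_extra = np.zeros(n_t, dtype=np.int64)
    e_extra = np.zeros(n_t)
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        par = int(tree.parent[v])
        a_c, a_p = float(ages[v]), float(ages[par])
        mask = (times >= a_c) & (times < a_p)
        if not mask.any():
            continue
        tt = times[mask]
        if a_p > a_c:
            pv = p[v] + (p[par] - p[v]) * (tt - a_c) / (a_p - a_c)
        else:
            pv = np.full(len(tt), p[v])
        hc_extra[mask] += pv > threshold
        hc_trop[mask] += (1.0 - pv) > threshold
        e_extra[mask] += pv
    table = pd.DataFrame(
        {
            "time_my": times,
            "n_total": n_total,
            "n_hc_tropical": hc_trop,
            "n_hc_extratropical": hc_extra,
            "e_tropical": n_total - e_extra,
            "e_extratropical": e_extra,
        }
    )
    return StateLtt(table)
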