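"""Grafting unresolved terminal clades onto a dated backbone tree.

Backbone tips act as placeholders for named terminal clades (species
lists without internal resolution).  Each placeholder is replaced at
its stem by a randomly resolved ultrametric subtree containing the
clade's species, leaving every backbone node age untouched; iterating
over seeds and backbone trees yields an all-taxon posterior tree set.

Within-clade randomization: the topology is built by uniform random
joins (the Yule / labeled-history distribution); the crown age is drawn
uniform on (0, stem age) and the remaining internal-node ages i.i.d.
uniform on (0, crown age), ranked so successive joins are strictly
older.  Cross-clade patristic distances depend only on the backbone, so
assemblage-level diversity statistics are insensitive to these
within-clade details.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .treeio import MutableNode, Phylogeny, from_nodes, to_nodes

__all__ = ["CladeAssignment", "resolve_clade", "graft_all", "read_assignments"]


@dataclass
class CladeAssignment:
    """A terminal clade to graft: which backbone tip it replaces and the
    species it contains."""

    clade_id: str
    placeholder: str
    species: list[str]

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError(f"clade {self.clade_id!r} has an empty species list")


def read_assignments(path_or_df) -> list[CladeAssignment]:
    """Load assignments from a CSV with columns clade_id, placeholder,
    species (one row per species)."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    out = []
    for (cid, ph), grp in df.groupby(["clade_id", "placeholder"], sort=False):
        out.append(CladeAssignment(str(cid), str(ph), [str(s) for s in grp["species"]]))
    return out


def resolve_clade(
    n: int,
    stem_age: float,
    seed=None,
    labels: list[str] | None = None,
) -> Phylogeny:
    """Random ultrametric subtree of ``n`` species below a stem of age
    ``stem_age``.

    For ``n == 1`` the result is a single tip whose branch spans the
    whole stem.  Otherwise the crown age is uniform on (0, stem_age)
    and the topology follows the uniform-join (Yule) distribution.
    """
    root = _resolve_nodes(n, stem_age, np.random.default_rng(seed), labels)
    return from_nodes(root)


def _resolve_nodes(n, stem_age, rng, labels=None) -> MutableNode:
    if n < 1:
        raise ValueError("clade must contain at least one species")
    if stem_age <= 0:
        raise ValueError("stem age must be > 0")
    if labels is None:
        labels = [f"s{i+1}" for i in range(n)]
    if len(labels) != n:
        raise ValueError("labels length must equal n")
    if n == 1:
        return MutableNode(length=stem_age, label=labels[0])
    crown = rng.uniform(0.0, stem_age)
    inner = np.sort(rng.uniform(0.0, crown, size=n - 2)) if n > 2 else np.empty(0)
    heights = np.append(inner, crown)  # ascending join ages, last = crown
    active = [(MutableNode(label=lab), 0.0) for lab in labels]
    for h in heights:
        i, j = rng.choice(len(active), size=2, replace=False)
        (a, ha), (b, hb) = active[i], active[j]
        a.length = h - ha
        b.length = h - hb
        join = MutableNode()
        join.children = [a, b]
        active = [x for k, x in enumerate(active) if k not in (i, j)]
        active.append((join, h))
    root, h = active[0]
    root.length = stem_age - h
    return root


def graft_all(
    backbone: Phylogeny,
    assignments: list[CladeAssignment],
    seed=None,
) -> Phylogeny:
    """Replace every placeholder tip of the backbone by its resolved clade.

    Backbone internal-node ages are preserved exactly (surgery touches
    only the placeholder tips); the result is ultrametric and contains
    every assigned species exactly once.  Missing placeholders and
    species duplicated across assignments are errors.
    """
    if not backbone.is_ultrametric():
        raise ValueError("backbone must be ultrametric")
    tipset = set(backbone.tip_labels)
    missing = [a.placeholder for a in assignments if a.placeholder not in tipset]
    if missing:
        raise KeyError(f"placeholders not on backbone: {missing}")
    seen: set[str] = set()
    for a in assignments:
        dup = seen.intersection(a.species)
        if dup:
            raise ValueError(f"species assigned to multiple clades: {sorted(dup)}")
        seen.update(a.species)
    if not assignments:
        return backbone.copy()

    rng = np.random.default_rng(seed)
    by_placeholder = {a.placeholder: a for a in assignments}
    root = to_nodes(backbone)
    stack = [root]
    while stack:
        v = stack.pop()
        if not v.children:
            a = by_placeholder.get(v.label)
            if a is None:
                continue
            sub = _resolve_nodes(len(a.species), v.length, rng, list(a.species))
            v.label = sub.label  # None for n > 1, species name for n == 1
            v.length = sub.length
            v.children = sub.children
        else:
            stack.extend(v.children)
    return from_nodes(root)
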