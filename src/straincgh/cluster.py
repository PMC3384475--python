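"""Correlation-based complete-linkage clustering of strains with
gene-resampling bootstrap supports.

Strains are compared by the Pearson correlation of their gene-content
profiles (by default each strain's vector of shared-gene percentages with
every other strain); distance d = 1 - r in [0, 2]. Agglomeration is
complete linkage with a deterministic tie-break, so trees are
bit-reproducible. Node support is the ordinary bootstrap probability: the
percentage of gene-resampled replicates in which the node's exact strain
set reappears as a clade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator

import numpy as np
import pandas as pd

from ._utils import EstimationError, child_rng
from .io import PresenceMatrix


@dataclass
class Node:
    """A dendrogram node; leaves carry a strain name, internal nodes a
    merge height and (optionally) a bootstrap support percentage."""

    members: frozenset
    height: float = 0.0
    name: str | None = None
    left: "Node | None" = None
    right: "Node | None" = None
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def walk(self) -> Iterator["Node"]:
        yield self
        if not self.is_leaf:
            yield from self.left.walk()
            yield from self.right.walk()

    def internal_clades(self) -> list[frozenset]:
        return [n.members for n in self.walk() if not n.is_leaf]


def profile_distance(profiles: pd.DataFrame, on_constant: str = "raise") -> pd.DataFrame:
    """1 - Pearson correlation between strain profile rows.

    ``on_constant`` controls zero-variance profiles: "raise" (the contract
    for user-facing calls) or "degenerate" (used inside bootstrap
    replicates, where a resample can produce a constant profile): two equal
    constant profiles get distance 0, any other pairing distance 1.
    """
    x = profiles.to_numpy(dtype=float)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 strains with profiles of length >= 2")
    sd = x.std(axis=1)
    constant = sd == 0.0
    if constant.any():
        if on_constant == "raise":
            bad = profiles.index[np.flatnonzero(constant)[0]]
            raise EstimationError(f"strain {bad!r} has a zero-variance profile")
        if on_constant != "degenerate":
            raise ValueError(f"unknown on_constant mode {on_constant!r}")
    centered = x - x.mean(axis=1, keepdims=True)
    norm = np.sqrt((centered**2).sum(axis=1))
    safe = np.where(norm == 0, 1.0, norm)
    unit = centered / safe[:, None]
    r = unit @ unit.T
    d = 1.0 - np.clip(r, -1.0, 1.0)
    if constant.any():
        for i in np.flatnonzero(constant):
            for j in range(x.shape[0]):
                same = constant[j] and np.array_equal(x[i], x[j])
                d[i, j] = d[j, i] = 0.0 if same else 1.0
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


def complete_linkage(dist: pd.DataFrame) -> Node:
    """Agglomerative complete-linkage tree over a distance matrix.

    Inter-cluster distance is the maximum pairwise member distance. Ties
    are broken by the lexicographically smallest (min-member, min-member)
    strain-id pair, so the tree is deterministic; merge heights are
    non-decreasing (the complete-linkage ultrametric property).
    """
    d = dist.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    names = [str(s) for s in dist.index]
    if len(names) < 2:
        raise ValueError("need at least 2 strains")
    clusters: dict[int, Node] = {
        i: Node(members=frozenset([n]), name=n) for i, n in enumerate(names)
    }
    cur = {(i, j): d[i, j] for i in range(len(names)) for j in range(i + 1, len(names))}
    next_id = len(names)
    while len(clusters) > 1:
        best_key = min(
            cur,
            key=lambda k: (
                cur[k],
                tuple(sorted((min(clusters[k[0]].members), min(clusters[k[1]].members)))),
            ),
        )
        i, j = best_key
        h = cur[best_key]
        a, b = clusters.pop(i), clusters.pop(j)
        left, right = sorted((a, b), key=lambda n: min(n.members))
        merged = Node(members=a.members | b.members, height=h, left=left, right=right)
        new_dist = {}
        for k in clusters:
            dk = max(
                cur[tuple(sorted((i, k)))],
                cur[tuple(sorted((j, k)))],
            )
            new_dist[k] = dk
        cur = {
            key: v
            for key, v in cur.items()
            if i not in key and j not in key
        }
        for k, v in new_dist.items():
            cur[tuple(sorted((k, next_id)))] = v
        clusters[next_id] = merged
        next_id += 1
    return next(iter(clusters.values()))


def bootstrap_support(
    matrix: PresenceMatrix,
    n_boot: int = 1000,
    seed: int = 0,
    profile_fn: Callable[[PresenceMatrix], pd.DataFrame] | None = None,
) -> Node:
    """Complete-linkage tree with gene-resampling bootstrap supports.

    Genes (matrix rows) are resampled with replacement ``n_boot`` times;
    each replicate is re-profiled, re-distanced and re-clustered, and every
    internal node of the original tree is scored by the percentage of
    replicates containing its exact strain set as a clade.
    """
    from .content import shared_pct_profiles

    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if len(matrix.genes) < 2:
        raise ValueError("need at least 2 genes to resample")
    if profile_fn is None:
        profile_fn = shared_pct_profiles
    tree = complete_linkage(profile_distance(profile_fn(matrix)))
    clades = tree.internal_clades()
    counts = {c: 0 for c in clades}
    rng = child_rng(seed, 3)
    n_genes = len(matrix.genes)
    for _ in range(n_boot):
        idx = rng.integers(0, n_genes, size=n_genes)
        boot = PresenceMatrix(calls=matrix.calls.iloc[idx])
        dist = profile_distance(profile_fn(boot), on_constant="degenerate")
        boot_clades = set(complete_linkage(dist).internal_clades())
        for c in counts:
            if c in boot_clades:
                counts[c] += 1
    for node in tree.walk():
        if not node.is_leaf:
            node.support = 100.0 * counts[node.members] / n_boot
    return tree


def cut_two_groups(
    tree: Node, island_occupancy: pd.DataFrame | None = None
) -> tuple[set, set]:
    """Split the panel at the root merge into the two main content groups.

    With an occupancy table (regions x strains), the group with the higher
    mean island occupancy is labeled I (the MGE-rich group); otherwise the
    larger group is I, ties broken by smallest strain id.
    """
    if tree.is_leaf:
        raise ValueError("cannot cut a single-leaf tree")
    a, b = set(tree.left.members), set(tree.right.members)

    def mean_occ(group: set) -> float:
        cols = [s for s in group if s in island_occupancy.columns]
        if not cols:
            return float("-inf")
        return float(np.nanmean(island_occupancy[cols].to_numpy(dtype=float)))

    if island_occupancy is not None:
        key_a, key_b = mean_occ(a), mean_occ(b)
    else:
        key_a, key_b = len(a), len(b)
    if key_a > key_b:
        return a, b
    if key_b > key_a:
        return b, a
    return (a, b) if min(a) <= min(b) else (b, a)
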