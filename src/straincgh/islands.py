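"""Genomic-island discovery from presence/absence patterns.

A genomic island shows up in a strain panel as a run of consecutive genes
that are absent from several strains while the flanking backbone is
conserved everywhere. The scanner formalizes that visual pattern: genes
are classified conserved / variable / uninformative by how many strains
lack them, and candidate islands are maximal runs of consecutive loci that
(i) start and end on a variable gene, (ii) contain no more than ``max_gap``
consecutive non-variable genes, (iii) are at least ``min_genes`` long and
(iv) are mostly variable (fraction >= ``min_variable_frac``). Overlapping
candidates are resolved by keeping the longer run.

Sizes are 1-based inclusive: (end - start + 1)/1000 kb, half-up to one
decimal. Islands split in two by a chromosomal inversion can be merged;
the merged size is the sum of the parts, not the spanning interval.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._utils import round_half_up
from .io import GeneTable, PresenceMatrix

CONSERVED = "conserved"
VARIABLE = "variable"
UNINFORMATIVE = "uninformative"


@dataclass
class IslandCall:
    """A detected run of variably-present consecutive genes."""

    name: str
    replicon: str
    first_index: int  # position within the replicon's locus order
    last_index: int
    start: int  # bp, 1-based inclusive
    end: int
    n_genes: int
    size_kb: float
    score: float  # fraction of variable loci in the run
    profile: pd.Series  # per-strain mean presence over the run's genes
    group_concordance: float | None = None

    def overlaps(self, other: "IslandCall") -> bool:
        return (
            self.replicon == other.replicon
            and self.first_index <= other.last_index
            and other.first_index <= self.last_index
        )


def gene_variability(
    matrix: PresenceMatrix, min_absent: int = 4, min_present: int = 1
) -> pd.Series:
    """Classify each gene as conserved, variable or uninformative.

    Counting ignores no-data cells. Conserved: absent from no strain.
    Variable: absent from >= min_absent strains and present in
    >= min_present. Anything else (including genes with no informative
    cell) is uninformative.
    """
    present = matrix.calls.eq(True).fillna(False).sum(axis=1).to_numpy(dtype=int)
    absent = matrix.calls.eq(False).fillna(False).sum(axis=1).to_numpy(dtype=int)
    cls = np.full(len(matrix.genes), UNINFORMATIVE, dtype=object)
    informative = (present + absent) > 0
    cls[informative & (absent == 0)] = CONSERVED
    cls[(absent >= min_absent) & (present >= min_present)] = VARIABLE
    return pd.Series(cls, index=matrix.calls.index, name="variability")


def island_size_kb(start: int, end: int) -> float:
    """Island size in kb from 1-based inclusive coordinates, one decimal."""
    if start < 1 or start > end:
        raise ValueError(f"invalid coordinates {start}-{end}")
    return round_half_up((end - start + 1) / 1000.0, 1)


def _qualifying_windows(
    var: np.ndarray, min_genes: int, max_gap: int, min_variable_frac: float
) -> list[tuple[int, int]]:
    """All maximal qualifying windows over one replicon's variable mask,
    resolved to a disjoint set (longer runs win, then leftmost)."""
    n = var.size
    vpos = np.flatnonzero(var)
    if vpos.size == 0:
        return []
    # blocks: variable positions separated by runs of <= max_gap non-variables
    blocks: list[np.ndarray] = []
    cut = np.flatnonzero(np.diff(vpos) - 1 > max_gap)
    start = 0
    for c in cut:
        blocks.append(vpos[start : c + 1])
        start = c + 1
    blocks.append(vpos[start:])

    cum = np.concatenate([[0], np.cumsum(var)])
    maximal: list[tuple[int, int]] = []
    for blk in blocks:
        k = blk.size
        # farthest qualifying endpoint per start; a window (s, e) is maximal
        # iff e is s's farthest endpoint and no earlier start reaches >= e
        best_so_far = -1
        for a in range(k):
            s = int(blk[a])
            far = -1
            for b in range(a, k):
                e = int(blk[b])
                length = e - s + 1
                if length < min_genes:
                    continue
                if (cum[e + 1] - cum[s]) / length >= min_variable_frac:
                    far = e
            if far > best_so_far:
                maximal.append((s, far))
                best_so_far = far
    # overlapping maximal windows: keep the longer (then leftmost) run
    maximal.sort(key=lambda w: (-(w[1] - w[0]), w[0]))
    kept: list[tuple[int, int]] = []
    for s, e in maximal:
        if all(e < s2 or e2 < s for s2, e2 in kept):
            kept.append((s, e))
    kept.sort()
    return kept


def scan_islands(
    matrix: PresenceMatrix,
    table: GeneTable,
    min_genes: int = 5,
    max_gap: int = 2,
    min_variable_frac: float = 0.8,
    min_absent: int = 4,
    min_present: int = 1,
    groups: tuple[set, set] | None = None,
) -> list[IslandCall]:
    """Detect candidate genomic islands on every replicon.

    The annotation must be sorted by start within each replicon. When a
    two-group partition is supplied, each call's group-concordance is the
    Pearson correlation between its per-strain mean presence and the
    group-I indicator.
    """
    records = table.records
    for rep, grp in records.groupby("replicon", sort=False):
        if not grp["start"].is_monotonic_increasing:
            raise ValueError(f"annotation not sorted by start on replicon {rep}")
    missing = [t for t in records["locus_tag"] if t not in matrix.calls.index]
    if missing:
        raise KeyError(f"locus {missing[0]!r} missing from the presence matrix")

    variability = gene_variability(matrix, min_absent=min_absent, min_present=min_present)
    present = matrix.calls.eq(True).fillna(False)
    informative = matrix.informative()

    calls: list[IslandCall] = []
    for rep, grp in records.groupby("replicon", sort=False):
        tags = grp["locus_tag"].to_numpy()
        var = (variability.loc[tags] == VARIABLE).to_numpy()
        windows = _qualifying_windows(var, min_genes, max_gap, min_variable_frac)
        for k, (s, e) in enumerate(windows):
            run_tags = tags[s : e + 1]
            n_run = e - s + 1
            pres = present.loc[run_tags]
            info = informative.loc[run_tags]
            with np.errstate(invalid="ignore"):
                prof = pres.sum(axis=0) / info.sum(axis=0)
            profile = pd.Series(prof, index=matrix.strains, dtype=float)
            start_bp = int(grp["start"].to_numpy()[s])
            end_bp = int(grp["end"].to_numpy()[e])
            concordance = None
            if groups is not None:
                indicator = np.array(
                    [1.0 if st in groups[0] else 0.0 for st in matrix.strains]
                )
                pv = profile.to_numpy(dtype=float)
                if np.nanstd(pv) > 0 and indicator.std() > 0:
                    ok = np.isfinite(pv)
                    concordance = float(np.corrcoef(pv[ok], indicator[ok])[0, 1])
                else:
                    concordance = float("nan")
            calls.append(
                IslandCall(
                    name=f"{rep}-isl{k + 1:02d}",
                    replicon=str(rep),
                    first_index=s,
                    last_index=e,
                    start=start_bp,
                    end=end_bp,
                    n_genes=n_run,
                    size_kb=island_size_kb(start_bp, end_bp),
                    score=float(var[s : e + 1].mean()),
                    profile=profile,
                    group_concordance=concordance,
                )
            )
    return calls


def merge_split_island(a: IslandCall, b: IslandCall) -> IslandCall:
    """Merge the two parts of an inversion-split island.

    The merged size is the sum of the parts' sizes (the parts are
    non-contiguous, so the spanning interval would overstate it); gene
    counts add and the profile is the gene-count-weighted mean. Merging
    with a zero-length placeholder returns the other part unchanged.
    """
    if a.n_genes == 0 and a.size_kb == 0:
        return replace(b)
    if b.n_genes == 0 and b.size_kb == 0:
        return replace(a)
    if a.replicon != b.replicon:
        raise ValueError("cannot merge islands on different replicons")
    if a.overlaps(b):
        raise ValueError("cannot merge overlapping islands")
    w = np.array([a.n_genes, b.n_genes], dtype=float)
    prof = (
        a.profile.to_numpy(dtype=float) * w[0] + b.profile.to_numpy(dtype=float) * w[1]
    ) / w.sum()
    score = (a.score * w[0] + b.score * w[1]) / w.sum()
    return IslandCall(
        name=f"{a.name}+{b.name}",
        replicon=a.replicon,
        first_index=min(a.first_index, b.first_index),
        last_index=max(a.last_index, b.last_index),
        start=min(a.start, b.start),
        end=max(a.end, b.end),
        n_genes=a.n_genes + b.n_genes,
        size_kb=round_half_up(a.size_kb + b.size_kb, 1),
        score=float(score),
        profile=pd.Series(prof, index=a.profile.index),
        group_concordance=None,
    )
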