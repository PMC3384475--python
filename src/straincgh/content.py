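"""Core-genome, pairwise shared-gene and region-occupancy statistics.

The core genome is the set of genes called present in every strain of the
panel. Pairwise shared-gene counts and percentages summarize how much gene
content two strains have in common (the percentage is taken over the
smaller strain's detectable gene count, so containment gives 100%).
Region occupancy is the percent of a named gene set's informative probes
called present in each strain; flagged/no-data probes drop out of both
numerator and denominator so they never masquerade as absence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import round_half_up
from .io import GeneTable, OccupancyTable, PresenceMatrix


@dataclass
class SharedGeneMatrix:
    """Pairwise shared-gene counts and percentages between strains.

    ``counts`` is symmetric with each strain's detectable-gene total on the
    diagonal; ``pct`` holds 100 * shared / min(detectable_i, detectable_j)
    rounded to one decimal (or the mean-denominator variant).
    """

    strains: list[str]
    counts: pd.DataFrame
    pct: pd.DataFrame

    @property
    def detectable(self) -> pd.Series:
        return pd.Series(np.diag(self.counts.to_numpy()), index=self.strains)


def fraction_pct(numerator: int, denominator: int) -> float:
    """Percentage at one decimal, half-up — the report-table convention."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round_half_up(100.0 * numerator / denominator, 1)


def core_set(matrix: PresenceMatrix) -> tuple[list[str], float]:
    """Genes present in every strain, and their percentage of all probes.

    A gene with any no-data cell cannot be certified core and is excluded
    from the core list, but stays in the percentage's denominator (the
    denominator is the probe count of the array).
    """
    if len(matrix.strains) == 0 or len(matrix.genes) == 0:
        raise ValueError("empty presence matrix")
    all_present = matrix.calls.eq(True).all(axis=1) & matrix.informative().all(axis=1)
    core = list(matrix.calls.index[all_present.to_numpy(dtype=bool)])
    return core, fraction_pct(len(core), len(matrix.genes))


def pairwise_overlap(matrix: PresenceMatrix, denominator: str = "min") -> SharedGeneMatrix:
    """Shared-gene counts/percentages for every strain pair.

    shared_count(i, j) = genes called present in both strains; the diagonal
    is each strain's detectable-gene count. ``denominator`` selects the
    percentage convention: "min" (default) or "mean" of the two diagonals.
    """
    if len(matrix.strains) < 2:
        raise ValueError("need at least 2 strains")
    b = matrix.present().to_numpy(dtype=float)
    counts = b.T @ b
    det = np.diag(counts)
    if denominator == "min":
        denom = np.minimum.outer(det, det)
    elif denominator == "mean":
        denom = (np.add.outer(det, det)) / 2.0
    else:
        raise ValueError(f"unknown denominator convention {denominator!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(denom > 0, 100.0 * counts / denom, 0.0)
    pct_rounded = np.vectorize(lambda v: round_half_up(v, 1))(pct)
    strains = matrix.strains
    return SharedGeneMatrix(
        strains=strains,
        counts=pd.DataFrame(counts.astype(int), index=strains, columns=strains),
        pct=pd.DataFrame(pct_rounded, index=strains, columns=strains),
    )


def shared_pct_profiles(matrix: PresenceMatrix) -> pd.DataFrame:
    """Unrounded shared-gene percentage profiles (strains x strains), the
    clustering input: row i is strain i's percentage of overlap with every
    strain.

    Uses the mean-detectable denominator 200*shared/(det_i + det_j): the
    min-denominator report convention saturates at 100 whenever one
    strain's content contains another's, which erases exactly the
    between-group signal clustering needs.
    """
    b = matrix.present().to_numpy(dtype=float)
    counts = b.T @ b
    det = np.diag(counts)
    denom = np.add.outer(det, det) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(denom > 0, 100.0 * counts / denom, 0.0)
    return pd.DataFrame(pct, index=matrix.strains, columns=matrix.strains)


def region_occupancy(
    matrix: PresenceMatrix,
    table: GeneTable,
    sets: list[str] | None = None,
) -> OccupancyTable:
    """Percent of each named gene set called present, per strain.

    Per (set, strain): 100 * present members / informative members, one
    decimal half-up; NaN when no member is informative. The detail table
    lists the present member genes of every cell.
    """
    names = list(table.gene_sets) if sets is None else list(sets)
    for name in names:
        if name not in table.gene_sets:
            raise KeyError(f"unknown gene set {name!r}")
        if not table.gene_sets[name]:
            raise ValueError(f"gene set {name!r} is empty")
    values = {}
    detail_rows = []
    present = matrix.calls.eq(True)
    informative = matrix.informative()
    for name in names:
        members = [m for m in table.gene_sets[name]]
        missing = [m for m in members if m not in matrix.calls.index]
        if missing:
            raise KeyError(f"gene set {name!r} member {missing[0]!r} not in matrix")
        row = {}
        for strain in matrix.strains:
            info = [m for m in members if informative.at[m, strain]]
            pres = [m for m in info if present.at[m, strain]]
            row[strain] = fraction_pct(len(pres), len(info)) if info else np.nan
            detail_rows.append(
                {
                    "set_name": name,
                    "strain": strain,
                    "n_present": len(pres),
                    "n_informative": len(info),
                    "pct": row[strain],
                    "present_genes": ",".join(pres),
                }
            )
        values[name] = row
    frame = pd.DataFrame.from_dict(values, orient="index")
    frame = frame.reindex(index=names, columns=matrix.strains)
    return OccupancyTable(values=frame, detail=pd.DataFrame(detail_rows))
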