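"""Fold-over-background presence/absence calling with cutoff calibration.

A gene is called present in a strain when its background-corrected
test-channel intensity exceeds the background level by at least a fixed
fold-change cutoff (default 20-fold, inclusive). The cutoff can be
calibrated on strains of exactly known gene content (plasmid-cured
derivatives): for every candidate cutoff on a grid the false-positive and
false-negative counts are tallied and the smallest cutoff minimizing their
sum is chosen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import EstimationError
from .io import ArrayScan, PresenceMatrix
from .normalize import DEFAULT_OFFSET, NormexpParams

DEFAULT_CUTOFF = 20.0


@dataclass
class FoldChangeVector:
    """Per-probe fold-over-background ratios for one strain.

    ``fold`` is indexed by probe_id, NaN for flagged spots; ``valid`` marks
    probes with a usable measurement.
    """

    strain_id: str
    fold: pd.Series
    valid: pd.Series


@dataclass
class CutoffCalibration:
    """fp/fn trade-off across a cutoff grid, with the chosen optimum."""

    grid: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    cutoff: float
    n_known_present: int
    n_known_absent: int

    @property
    def total(self) -> np.ndarray:
        return self.fp + self.fn


def fold_change(
    scan: ArrayScan,
    mode: str = "per-spot",
    offset: float = DEFAULT_OFFSET,
    params_test: NormexpParams | None = None,
) -> FoldChangeVector:
    """Fold of corrected test intensity over the background level.

    per-spot mode divides by the spot's own local background (bg_test +
    offset); array-background mode divides by the fitted global background
    mean (mu + offset), which requires the test-channel normexp fit.
    """
    if "corr_test" not in scan.spots.columns:
        raise ValueError("scan is not background-corrected; run correct_scan first")
    spots = scan.spots
    if mode == "per-spot":
        denom = spots["bg_test"].to_numpy() + offset
    elif mode == "array-background":
        if params_test is None:
            raise ValueError("array-background mode needs the test-channel normexp fit")
        level = params_test.mu + offset
        if level <= 0:
            raise ValueError(f"non-positive array background level {level}")
        denom = np.full(len(spots), level)
    else:
        raise ValueError(f"unknown fold mode {mode!r}")
    fold = spots["corr_test"].to_numpy() / denom
    valid = (spots["flag"] >= 0).to_numpy()
    fold = np.where(valid, fold, np.nan)
    idx = pd.Index(spots["probe_id"], name="probe_id")
    return FoldChangeVector(
        strain_id=scan.strain_id,
        fold=pd.Series(fold, index=idx),
        valid=pd.Series(valid, index=idx),
    )


def call_presence(
    folds: FoldChangeVector,
    cutoff: float = DEFAULT_CUTOFF,
    probe_to_locus: pd.Series | None = None,
) -> pd.Series:
    """Per-gene presence calls (nullable boolean, NA = no data).

    A probe votes present iff fold >= cutoff (inclusive). With a
    probe->locus map, multi-probe genes are collapsed by majority vote;
    ties (including all-flagged genes) become NA.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    fold = folds.fold
    probe_call = pd.Series(pd.NA, index=fold.index, dtype="boolean")
    ok = folds.valid.to_numpy()
    probe_call[ok] = fold[ok] >= cutoff
    if probe_to_locus is None:
        return probe_call
    locus = probe_to_locus.reindex(fold.index)
    if locus.isna().any():
        missing = fold.index[locus.isna()][0]
        raise KeyError(f"probe {missing!r} absent from the annotation")
    out = {}
    for tag, grp in probe_call.groupby(locus.to_numpy(), sort=False):
        votes = grp.dropna()
        n_yes = int(votes.sum())
        n_no = len(votes) - n_yes
        out[tag] = pd.NA if n_yes == n_no else n_yes > n_no
    return pd.Series(out, dtype="boolean").rename_axis("locus_tag")


def presence_matrix(
    calls_by_strain: Mapping[str, pd.Series],
    folds_by_strain: Mapping[str, pd.Series] | None = None,
    gene_order: Sequence[str] | None = None,
) -> PresenceMatrix:
    """Assemble per-strain call vectors into a genes x strains matrix."""
    calls = pd.DataFrame(dict(calls_by_strain), dtype="boolean")
    fold = pd.DataFrame(dict(folds_by_strain)) if folds_by_strain else None
    if gene_order is not None:
        calls = calls.reindex(list(gene_order))
        if fold is not None:
            fold = fold.reindex(list(gene_order))
    if fold is not None:
        fold = fold.reindex(columns=calls.columns)
    return PresenceMatrix(calls=calls, fold=fold)


def calibrate_cutoff(
    derivative_scans: Iterable[tuple[FoldChangeVector, Mapping[str, bool]]],
    grid: np.ndarray | None = None,
) -> CutoffCalibration:
    """Choose the cutoff minimizing false positives + false negatives.

    ``derivative_scans`` pairs each fold-change vector with the truth for
    its strain (probe_id -> truly present). fp(c) counts known-absent
    probes with fold >= c; fn(c) counts known-present probes with fold < c.
    The chosen cutoff is the smallest grid point attaining the minimum.
    """
    if grid is None:
        grid = np.arange(1.0, 100.0 + 0.25, 0.5)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("cutoff grid must be non-empty and strictly increasing")
    present_folds: list[np.ndarray] = []
    absent_folds: list[np.ndarray] = []
    for folds, truth in derivative_scans:
        truth_s = pd.Series(truth)
        common = folds.fold.index.intersection(truth_s.index)
        f = folds.fold.loc[common]
        t = truth_s.loc[common].astype(bool)
        ok = folds.valid.loc[common].to_numpy()
        present_folds.append(f[ok & t.to_numpy()].to_numpy())
        absent_folds.append(f[ok & ~t.to_numpy()].to_numpy())
    present = np.sort(np.concatenate(present_folds)) if present_folds else np.array([])
    absent = np.sort(np.concatenate(absent_folds)) if absent_folds else np.array([])
    if present.size + absent.size == 0:
        raise EstimationError("empty truth: no known-present or known-absent probes")
    # fold >= c counted via sorted search; fp non-increasing, fn non-decreasing in c
    fp = absent.size - np.searchsorted(absent, grid, side="left")
    fn = np.searchsorted(present, grid, side="left")
    best = int(np.argmin(fp + fn))  # argmin takes the first (smallest) optimum
    return CutoffCalibration(
        grid=grid,
        fp=fp.astype(int),
        fn=fn.astype(int),
        cutoff=float(grid[best]),
        n_known_present=int(present.size),
        n_known_absent=int(absent.size),
    )
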