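"""Island scanner vs exhaustive window enumeration; coordinate arithmetic."""

import numpy as np
import pandas as pd
import pytest

from straincgh.io import GeneTable, PresenceMatrix
from straincgh.islands import (
    IslandCall,
    gene_variability,
    island_size_kb,
    merge_split_island,
    scan_islands,
)
from straincgh.islands import _qualifying_windows


def enumerate_windows_bruteforce(var, min_genes, max_gap, min_frac):
    """Oracle: all qualifying windows by direct enumeration, maximality
    filter, then longest-first disjoint resolution."""
    var = list(var)
    n = len(var)
    qualifying = []
    for s in range(n):
        for e in range(s, n):
            w = var[s : e + 1]
            if not (w[0] and w[-1]):
                continue
            if len(w) < min_genes:
                continue
            if sum(w) / len(w) < min_frac:
                continue
            run = worst = 0
            for v in w:
                run = 0 if v else run + 1
                worst = max(worst, run)
            if worst > max_gap:
                continue
            qualifying.append((s, e))
    maximal = [
        w
        for w in qualifying
        if not any(o != w and o[0] <= w[0] and w[1] <= o[1] for o in qualifying)
    ]
    maximal.sort(key=lambda w: (-(w[1] - w[0]), w[0]))
    kept = []
    for s, e in maximal:
        if all(e < s2 or e2 < s for s2, e2 in kept):
            kept.append((s, e))
    return sorted(kept)


def make_matrix_and_table(calls_2d, replicon="C1"):
    n_genes, n_strains = calls_2d.shape
    genes = [f"g{i:03d}" for i in range(n_genes)]
    calls = pd.DataFrame(
        calls_2d, index=genes, columns=[f"s{j}" for j in range(n_strains)],
        dtype="boolean",
    )
    records = pd.DataFrame(
        {
            "locus_tag": genes,
            "replicon": replicon,
            "start": np.arange(n_genes) * 1000 + 1,
            "end": np.arange(n_genes) * 1000 + 900,
            "strand": "+",
            "probe_id": [f"P{i}" for i in range(n_genes)],
        }
    )
    return PresenceMatrix(calls=calls), GeneTable(records=records)


def pattern_matrix(var_mask, n_strains=8, n_absent=5):
    """Genes flagged variable are absent in ``n_absent`` strains, others in none."""
    rows = []
    for v in var_mask:
        if v:
            rows.append([False] * n_absent + [True] * (n_strains - n_absent))
        else:
            rows.append([True] * n_strains)
    return np.array(rows)


class TestVariability:
    def test_classes_follow_counts(self):
        calls = pd.DataFrame(
            {
                f"s{j}": [True, j < 7, True if j else pd.NA, pd.NA]
                for j in range(16)
            },
            index=["conserved_gene", "variable_gene", "one_na", "all_na"],
            dtype="boolean",
        )
        out = gene_variability(PresenceMatrix(calls=calls))
        assert out["conserved_gene"] == "conserved"
        assert out["variable_gene"] == "variable"  # absent in 9 of 16
        assert out["one_na"] == "conserved"
        assert out["all_na"] == "uninformative"

    def test_matches_direct_counting(self):
        rng = np.random.default_rng(0)
        raw = rng.random((40, 16))
        calls = pd.DataFrame(
            np.where(raw < 0.45, True, np.where(raw < 0.9, False, None)),
            index=[f"g{i}" for i in range(40)],
            columns=[f"s{j}" for j in range(16)],
        ).astype("boolean")
        out = gene_variability(PresenceMatrix(calls=calls), min_absent=4, min_present=1)
        for g in calls.index:
            vals = [v for v in calls.loc[g] if v is not pd.NA]
            n_pres = sum(bool(v) for v in vals)
            n_abs = len(vals) - n_pres
            if not vals:
                want = "uninformative"
            elif n_abs == 0:
                want = "conserved"
            elif n_abs >= 4 and n_pres >= 1:
                want = "variable"
            else:
                want = "uninformative"
            assert out[g] == want


class TestSizeArithmetic:
    @pytest.mark.parametrize(
        "start,end,kb",
        [
            (2_895_950, 2_905_048, 9.1),
            (813_173, 900_292, 87.1),
            (1_217_667, 1_358_908, 141.2),
            (2_202_142, 2_322_293, 120.2),
            (1_075_185, 1_094_655, 19.5),
            (1, 1000, 1.0),
        ],
    )
    def test_one_decimal_inclusive_sizes(self, start, end, kb):
        assert island_size_kb(start, end) == kb

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(ValueError):
            island_size_kb(10, 9)
        with pytest.raises(ValueError):
            island_size_kb(0, 9)


def call_of(start, end, n_genes=10, replicon="CHR2", name="x",
            profile=None, first=0, last=9, score=1.0):
    return IslandCall(
        name=name, replicon=replicon, first_index=first, last_index=last,
        start=start, end=end, n_genes=n_genes,
        size_kb=island_size_kb(start, end), score=score,
        profile=profile if profile is not None else pd.Series({"a": 1.0, "b": 0.0}),
    )


class TestMerge:
    def test_inversion_split_island_sums_sizes(self):
        a = call_of(1_075_185, 1_094_655, n_genes=18, first=0, last=17)
        b = call_of(1_217_667, 1_358_908, n_genes=104, first=120, last=223)
        merged = merge_split_island(a, b)
        assert merged.size_kb == 160.7
        assert merged.n_genes == 122
        assert merged.name == "x+x"

    def test_commutative(self):
        a = call_of(100, 999, first=0, last=9, profile=pd.Series({"a": 1.0, "b": 0.2}))
        b = call_of(5000, 6999, first=20, last=29, profile=pd.Series({"a": 0.5, "b": 0.1}))
        m1, m2 = merge_split_island(a, b), merge_split_island(b, a)
        assert m1.size_kb == m2.size_kb and m1.n_genes == m2.n_genes
        assert np.allclose(m1.profile.to_numpy(), m2.profile.to_numpy())

    def test_zero_length_placeholder_is_identity(self):
        a = call_of(100, 999)
        empty = IslandCall(
            name="", replicon="CHR2", first_index=0, last_index=0, start=1, end=1,
            n_genes=0, size_kb=0.0, score=0.0, profile=pd.Series(dtype=float),
        )
        assert merge_split_island(a, empty) == a

    def test_overlapping_inputs_rejected(self):
        a = call_of(100, 999, first=0, last=9)
        b = call_of(500, 1999, first=5, last=19)
        with pytest.raises(ValueError):
            merge_split_island(a, b)


class TestScan:
    def test_all_conserved_yields_nothing(self):
        m, t = make_matrix_and_table(pattern_matrix([False] * 30))
        assert scan_islands(m, t) == []

    def test_planted_run_recovered_exactly(self):
        mask = [False] * 10 + [True] * 10 + [False] * 10
        m, t = make_matrix_and_table(pattern_matrix(mask))
        (call,) = scan_islands(m, t)
        assert (call.first_index, call.last_index) == (10, 19)
        assert call.n_genes == 10
        assert call.score == 1.0

    def test_two_runs_separated_by_wide_gap_stay_split(self):
        mask = [True] * 6 + [False] * 3 + [True] * 6  # gap of max_gap+1
        m, t = make_matrix_and_table(pattern_matrix(mask))
        calls = scan_islands(m, t, max_gap=2)
        assert [(c.first_index, c.last_index) for c in calls] == [(0, 5), (9, 14)]

    def test_small_gap_is_bridged(self):
        mask = [True] * 6 + [False] * 2 + [True] * 6
        m, t = make_matrix_and_table(pattern_matrix(mask))
        (call,) = scan_islands(m, t, max_gap=2, min_variable_frac=0.8)
        assert (call.first_index, call.last_index) == (0, 13)
        assert call.score == pytest.approx(12 / 14)

    def test_calls_never_cross_replicons(self):
        mask = [True] * 8
        upper = pattern_matrix(mask)
        m, _ = make_matrix_and_table(np.vstack([upper, upper]))
        genes = list(m.calls.index)
        records = pd.DataFrame(
            {
                "locus_tag": genes,
                "replicon": ["C1"] * 8 + ["C2"] * 8,
                "start": list(np.arange(8) * 1000 + 1) * 2,
                "end": list(np.arange(8) * 1000 + 900) * 2,
                "strand": "+",
                "probe_id": [f"P{i}" for i in range(16)],
            }
        )
        calls = scan_islands(m, GeneTable(records=records))
        assert len(calls) == 2
        assert {c.replicon for c in calls} == {"C1", "C2"}

    def test_unsorted_annotation_rejected(self):
        m, t = make_matrix_and_table(pattern_matrix([True] * 6))
        t.records.loc[0, "start"] = 10_000_000
        with pytest.raises(ValueError, match="sorted"):
            scan_islands(m, t)

    def test_group_concordance_sign(self):
        mask = [False] * 5 + [True] * 8 + [False] * 5
        m, t = make_matrix_and_table(pattern_matrix(mask, n_strains=8, n_absent=4))
        carriers = {f"s{j}" for j in range(4, 8)}
        others = {f"s{j}" for j in range(4)}
        (call,) = scan_islands(m, t, groups=(carriers, others))
        assert call.group_concordance == pytest.approx(1.0)

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_exhaustive_enumeration(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(5, 51))
        p_var = rng.uniform(0.2, 0.8)
        var_mask = rng.random(n) < p_var
        min_genes = int(rng.integers(3, 7))
        max_gap = int(rng.integers(1, 4))
        min_frac = float(rng.uniform(0.6, 0.95))
        got = _qualifying_windows(var_mask.astype(bool), min_genes, max_gap, min_frac)
        want = enumerate_windows_bruteforce(var_mask, min_genes, max_gap, min_frac)
        assert got == want

    def test_scan_agrees_with_oracle_on_called_matrices(self):
        # full path: matrix -> variability -> windows, vs oracle on the same mask
        rng = np.random.default_rng(7)
        for _ in range(8):
            raw = rng.random((40, 8))
            calls_2d = raw < np.where(rng.random(40) < 0.4, 0.45, 0.995)[:, None]
            m, t = make_matrix_and_table(calls_2d)
            var = gene_variability(m) == "variable"
            want = enumerate_windows_bruteforce(var.tolist(), 5, 2, 0.8)
            got = [(c.first_index, c.last_index) for c in scan_islands(m, t)]
            assert got == want
            # disjointness
            for (a1, b1), (a2, b2) in zip(got, got[1:]):
                assert b1 < a2
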