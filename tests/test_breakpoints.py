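"""Roaming-score windows, candidate scoring and breakpoint resolution."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from skimbin.breakpoints import (
    BreakpointConfig,
    crossovers_only,
    detect_breakpoints,
    resolve_breakpoints,
    roaming_scan,
    summarize_recombination,
    window_profile,
)
from skimbin.codes import HET, NA, P1, P2


def _line(codes, spacing=100_000, start=100_000):
    codes = np.asarray(codes, dtype=np.int8)
    pos = start + spacing * np.arange(len(codes))
    return pos, codes


class TestWindowProfile:
    def test_pure_window(self):
        pos, codes = _line([P1] * 20)
        prof = window_profile(pos, codes, x=pos[-1] + 1, side="left",
                             cfg=BreakpointConfig(window_bp=6_500_000))
        assert prof.klass == P1 and prof.p == 1.0 and prof.n_p1 == 20

    def test_near_even_window_is_heterozygous(self):
        pos, codes = _line([P1] * 11 + [P2] * 9)
        prof = window_profile(pos, codes, x=pos[-1] + 1, side="left")
        assert prof.p == pytest.approx(0.55)
        assert prof.klass == HET

    def test_sparse_window_is_na(self):
        pos, codes = _line([P1] * 5)
        prof = window_profile(pos, codes, x=pos[-1] + 1, side="left")
        assert prof.klass == NA

    def test_intermediate_purity_is_na(self):
        pos, codes = _line([P1] * 15 + [P2] * 5)  # p = 0.75
        prof = window_profile(pos, codes, x=pos[-1] + 1, side="left")
        assert prof.klass == NA


class TestRoamingScan:
    def test_homogeneous_line_has_no_candidates(self):
        pos, codes = _line([P1] * 50)
        assert roaming_scan(pos, codes).empty

    def test_perfect_switch_peaks_at_the_switch_midpoint(self):
        pos, codes = _line([P1] * 30 + [P2] * 30)
        cands = roaming_scan(pos, codes)
        assert len(cands) == 1  # only one differing-code adjacency
        expected_mid = 0.5 * (pos[29] + pos[30])
        assert cands["x"].iloc[0] == expected_mid
        # exhaustive oracle: score at EVERY inter-site midpoint via the
        # public one-window API; the switch midpoint must be the argmax
        cfg = BreakpointConfig()
        best_x, best_s = None, -1.0
        for i in range(len(pos) - 1):
            x = 0.5 * (pos[i] + pos[i + 1])
            L = window_profile(pos, codes, x, "left", cfg)
            R = window_profile(pos, codes, x, "right", cfg)
            if L.klass == NA or R.klass == NA:
                s = 0.0
            else:
                nl, nr = L.n_p1 + L.n_p2, R.n_p1 + R.n_p2
                s = abs(L.p - R.p) * np.sqrt(nl * nr / (nl + nr)) / np.sqrt(cfg.min_sites)
            if s > best_s:
                best_x, best_s = x, s
        assert best_x == expected_mid
        assert cands["score"].iloc[0] == pytest.approx(best_s)

    def test_single_flipped_site_scores_below_threshold(self):
        codes = [P1] * 30 + [P2] + [P1] * 30
        pos, codes = _line(codes)
        cfg = BreakpointConfig()
        cands = roaming_scan(pos, codes, cfg)
        assert len(cands) == 2
        assert (cands["score"] < cfg.min_score).all()

    def test_score_symmetric_under_parent_relabeling(self):
        rng = np.random.default_rng(4)
        codes = rng.choice([P1, P2], size=80).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 10_000_000), 80, replace=False))
        a = roaming_scan(pos, codes)
        b = roaming_scan(pos, np.where(codes == P1, P2, P1).astype(np.int8))
        np.testing.assert_allclose(a["score"], b["score"])


class TestResolveBreakpoints:
    def test_no_candidates_no_breakpoints(self):
        pos, codes = _line([P1] * 40)
        out = resolve_breakpoints(roaming_scan(pos, codes), pos, codes,
                                  chrom_length=10_000_000)
        assert out.empty

    def test_well_separated_crossovers_recovered_exactly(self):
        # switches at 20 Mb and 60 Mb on a 90-Mb chromosome, 100-kb spacing
        n = 900
        pos = 100_000 * np.arange(1, n + 1)
        codes = np.where(pos <= 20_000_000, P1, np.where(pos <= 60_000_000, P2, P1)).astype(np.int8)
        out = resolve_breakpoints(roaming_scan(pos, codes), pos, codes,
                                  chrom_length=90_000_000)
        xo = out[(out["left_state"] != out["right_state"])]
        assert len(xo) == 2
        assert xo["left_bp"].tolist() == [20_000_000, 60_000_000]
        assert xo["right_bp"].tolist() == [20_100_000, 60_100_000]
        assert (xo["interval_bp"] == 100_000).all()

    def test_close_double_crossover_recovered(self):
        # island of the opposite parent well inside one window width
        rng = np.random.default_rng(7)
        recovered = 0
        n_lines = 100
        for _ in range(n_lines):
            pos = np.sort(rng.choice(np.arange(1, 40_000_001), 2000, replace=False))
            a = rng.uniform(10e6, 25e6)
            b = a + rng.uniform(1.5e6, 3.0e6)
            codes = np.where((pos > a) & (pos <= b), P2, P1).astype(np.int8)
            out = resolve_breakpoints(roaming_scan(pos, codes), pos, codes,
                                      chrom_length=40_000_000)
            xo = out[(out["left_state"].isin([P1, P2]))
                     & (out["right_state"].isin([P1, P2]))]
            ok = (
                len(xo) == 2
                and xo["left_bp"].iloc[0] <= a <= xo["right_bp"].iloc[0]
                and xo["left_bp"].iloc[1] <= b <= xo["right_bp"].iloc[1]
            )
            recovered += ok
        assert recovered >= 0.9 * n_lines

    def test_het_boundaries_are_state_changes_not_crossovers(self):
        rng = np.random.default_rng(9)
        pos = 20_000 * np.arange(1, 1001)
        codes = np.where(
            pos <= 10_000_000, P1, rng.choice([P1, P2], size=1000)
        ).astype(np.int8)[: len(pos)]
        out = resolve_breakpoints(roaming_scan(pos, codes), pos, codes,
                                  chrom_length=20_000_000)
        assert (out["left_state"] == HET).any() or (out["right_state"] == HET).any()
        assert crossovers_only(out).empty


class TestSummarize:
    def test_reverse_map_length_scale(self):
        bps = pd.DataFrame(
            {
                "line": ["L1"] * 4, "chrom": ["c1"] * 4,
                "left_bp": [1, 2, 3, 4], "right_bp": [5, 6, 7, 8],
                "midpoint": [3, 4, 5, 6],
                "left_state": [P1, P2, P1, P2], "right_state": [P2, P1, P2, P1],
                "interval_bp": [4, 4, 4, 4], "score": [1.0] * 4,
            }
        )
        s = summarize_recombination(bps, n_lines=2, lengths={"c1": 100})
        assert s.reverse_map_cm == pytest.approx(100.0 * 4 / 2)

    def test_no_breakpoints(self):
        empty = pd.DataFrame(
            columns=["line", "chrom", "left_bp", "right_bp", "midpoint",
                     "left_state", "right_state", "interval_bp", "score"]
        )
        s = summarize_recombination(empty, n_lines=10, lengths={"c1": 100})
        assert s.reverse_map_cm == 0.0 and np.isnan(s.median_interval_bp)

    def test_zero_lines_rejected(self):
        with pytest.raises(ValueError):
            summarize_recombination(pd.DataFrame(), n_lines=0, lengths={})


class TestPopulationLevel:
    def test_reverse_map_matches_truth_junction_count(self, small_population, small_genome):
        _, truth, calls = small_population
        bps = detect_breakpoints(calls, small_genome.length_map)
        s = summarize_recombination(bps, len(truth.lines), small_genome.length_map)
        expected = 100.0 * len(truth.crossovers()) / len(truth.lines)
        assert s.reverse_map_cm == pytest.approx(expected, rel=0.25)

    def test_desert_shows_in_histogram(self, small_population, small_genome):
        _, truth, calls = small_population
        bps = detect_breakpoints(calls, small_genome.length_map)
        s = summarize_recombination(bps, len(truth.lines), small_genome.length_map)
        for chrom in ("c1", "c2"):
            h = np.array(s.histogram[chrom])
            assert h.sum() > 0
            central = h[5:15].sum()  # slices covering 25%-75%
            assert central <= 0.05 * h.sum()
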