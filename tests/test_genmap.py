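"""Marker filtering, recombination fractions, Kosambi map distances."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from skimbin.bins import BinConfig, bin_matrix, make_bins
from skimbin.codes import HET, NA, P1, P2
from skimbin.genmap import (
    MapConfig,
    adjacent_recombination_fraction,
    build_map,
    filter_markers,
    haldane_waddington,
    kosambi_cm,
)
from skimbin.simulate import (
    GenomeSpec,
    SimConfig,
    simulate_ril_population,
    simulate_parents,
    truth_bin_genotypes,
)


def _binmat_from_codes(codes: np.ndarray, chrom_len: int):
    """Build a BinGenotypeMatrix whose consensus equals ``codes`` exactly."""
    n_lines, n_bins = codes.shape
    rows = []
    for i in range(n_lines):
        for j in range(n_bins):
            c = codes[i, j]
            if c == NA:
                continue
            for k in range(5):  # five agreeing sites per informative bin
                rows.append((f"L{i:03d}", "c1", j * 1_000_000 + 1000 + k, c))
    coded = pd.DataFrame(rows, columns=["line", "chrom", "pos", "code"])
    coded["code"] = coded["code"].astype(np.int8)
    return bin_matrix(coded, make_bins({"c1": chrom_len}), BinConfig())


class TestFilterMarkers:
    def test_balanced_marker_retained(self):
        codes = np.tile([P1, P2], 50)[:, None].astype(np.int8)  # 50:50
        mat = _binmat_from_codes(codes, 1_000_000)
        retained, log = filter_markers(mat)
        assert retained == mat.bin_labels
        assert log["p_value"].iloc[0] == pytest.approx(1.0)

    def test_distorted_marker_removed_with_exact_chi_square(self):
        codes = np.array([P1] * 500 + [P2] * 312, dtype=np.int8)[:, None]
        mat = _binmat_from_codes(codes, 1_000_000)
        retained, log = filter_markers(mat)
        assert retained == []
        chi2 = (500 - 406) ** 2 / 406 + (312 - 406) ** 2 / 406
        assert log["chi2"].iloc[0] == pytest.approx(chi2)
        assert log["p_value"].iloc[0] == pytest.approx(stats.chi2.sf(chi2, 1))
        assert log["p_value"].iloc[0] < 1e-9

    def test_gappy_marker_removed_despite_balance(self):
        # bin 1: balanced but 25% missing; bin 2: balanced and complete
        col1 = np.array([P1, P2] * 30 + [NA] * 20, dtype=np.int8)
        col2 = np.array([P1, P2] * 40, dtype=np.int8)
        mat = _binmat_from_codes(np.column_stack([col1, col2]), 2_000_000)
        retained, log = filter_markers(mat)
        assert retained == ["c1:1000000"]
        assert log.set_index("bin").loc["c1:0", "reason"] == "missing"

    def test_uninformative_marker_removed(self):
        codes = np.full((10, 1), HET, dtype=np.int8)
        mat = _binmat_from_codes(codes, 1_000_000)
        retained, log = filter_markers(mat, MapConfig(max_missing=1.0))
        assert retained == [] and log["reason"].iloc[0] == "uninformative"


class TestClosedForms:
    @pytest.mark.parametrize("R,r", [(0.0, 0.0), (0.04, 0.04 / (2 * 0.96)), (1 / 3, 0.25)])
    def test_haldane_waddington(self, R, r):
        assert haldane_waddington(R) == pytest.approx(r, rel=1e-12)

    def test_haldane_waddington_domain(self):
        with pytest.raises(ValueError):
            haldane_waddington(0.5)

    @pytest.mark.parametrize(
        "r,d",
        [(0.0, 0.0),
         (0.2, 25.0 * math.log(1.4 / 0.6)),
         (0.01, 25.0 * math.log(1.02 / 0.98))],
    )
    def test_kosambi(self, r, d):
        assert kosambi_cm(r) == pytest.approx(d, rel=1e-12)

    def test_kosambi_small_r_limit(self):
        assert kosambi_cm(0.01) == pytest.approx(1.00013337, rel=1e-7)
        assert kosambi_cm(0.01) == pytest.approx(100 * 0.01, rel=1e-3)

    def test_kosambi_domain(self):
        with pytest.raises(ValueError):
            kosambi_cm(0.5)


class TestAdjacentR:
    def test_toy_fraction(self):
        codes = np.column_stack(
            [np.repeat([P1, P2], 50), np.repeat([P1, P2], 50)]
        ).astype(np.int8)
        codes[:4, 1] = np.where(codes[:4, 0] == P1, P2, P1)  # 4 recombinants
        mat = _binmat_from_codes(codes, 2_000_000)
        R = adjacent_recombination_fraction(mat, *mat.bin_labels)
        assert R == pytest.approx(0.04)

    def test_identical_columns_give_zero(self):
        codes = np.column_stack([np.repeat([P1, P2], 20)] * 2).astype(np.int8)
        mat = _binmat_from_codes(codes, 2_000_000)
        assert adjacent_recombination_fraction(mat, *mat.bin_labels) == 0.0

    def test_simulated_R_matches_selfed_ril_expectation(self):
        # adjacent 1-Mb bins at L Morgans per 100 Mb: r = L/100 per Mb
        g = GenomeSpec(names=["c1"], lengths=[100_000_000], snp_density=1 / 20_000)
        cfg = SimConfig(n_lines=1000, map_length_morgans=1.0, desert_fraction=0.0,
                        generations=10, seed=53)
        key = simulate_parents(g, seed=53)
        truth = simulate_ril_population(key, cfg, g)
        wide = truth_bin_genotypes(truth)
        a = wide.to_numpy()
        # pool R over all adjacent bin pairs
        ok = np.isin(a[:, :-1], (P1, P2)) & np.isin(a[:, 1:], (P1, P2))
        R_emp = float((a[:, :-1] != a[:, 1:])[ok].mean())
        r = 1.0 / 100
        expect = 2 * r / (1 + 2 * r)
        n = int(ok.sum())
        se = math.sqrt(expect * (1 - expect) / n)
        assert abs(R_emp - expect) < 3 * se + 0.0005  # small finite-g allowance


class TestBuildMap:
    def test_identical_columns_give_zero_length(self):
        codes = np.column_stack([np.repeat([P1, P2], 20)] * 5).astype(np.int8)
        gm = build_map(_binmat_from_codes(codes, 5_000_000))
        assert gm.total_cm == 0.0

    def test_orientation_invariance(self):
        rng = np.random.default_rng(3)
        base = np.repeat(rng.choice([P1, P2], size=(60, 1)), 8, axis=1)
        flip = rng.random(base.shape) < 0.05
        codes = np.where(flip, np.where(base == P1, P2, P1), base).astype(np.int8)
        gm_fwd = build_map(_binmat_from_codes(codes, 8_000_000))
        gm_rev = build_map(_binmat_from_codes(codes[:, ::-1], 8_000_000))
        assert gm_fwd.total_cm == pytest.approx(gm_rev.total_cm)

    def test_uncorrected_roughly_twice_corrected_for_small_R(self):
        rng = np.random.default_rng(5)
        base = np.repeat(rng.choice([P1, P2], size=(400, 1)), 10, axis=1)
        flip = rng.random(base.shape) < 0.01
        codes = np.where(flip, np.where(base == P1, P2, P1), base).astype(np.int8)
        gm = build_map(_binmat_from_codes(codes, 10_000_000))
        assert gm.total_cm_uncorrected == pytest.approx(2 * gm.total_cm, rel=0.06)

    def test_simulated_map_length_near_generating_length(self):
        g = GenomeSpec(names=["c1", "c2"], lengths=[100_000_000] * 2,
                       snp_density=1 / 20_000)
        cfg = SimConfig(n_lines=400, map_length_morgans=0.7, generations=8, seed=59)
        key = simulate_parents(g, seed=59)
        truth = simulate_ril_population(key, cfg, g)
        rows = []
        wide = truth_bin_genotypes(truth)
        coded = wide.stack().rename("code").reset_index()
        coded.columns = ["line", "bin", "code"]
        coded["chrom"] = coded["bin"].str.split(":").str[0]
        coded["pos"] = coded["bin"].str.split(":").str[1].astype(int) + 1000
        coded = coded[coded["code"] != NA][["line", "chrom", "pos", "code"]]
        coded["code"] = coded["code"].astype(np.int8)
        # five agreeing sites per bin so the consensus equals the truth code
        coded = pd.concat(
            [coded.assign(pos=coded["pos"] + k) for k in range(5)], ignore_index=True
        )
        mat = bin_matrix(coded, make_bins({"c1": 100_000_000, "c2": 100_000_000}))
        gm = build_map(mat)
        assert gm.total_cm == pytest.approx(2 * 70.0, rel=0.15)

    def test_null_distortion_filter_calibration(self):
        # under a fair 1:1 the filter should remove ~0.1% of markers
        rng = np.random.default_rng(61)
        n_bins, n_lines = 20_000, 500
        n1 = rng.binomial(n_lines, 0.5, size=n_bins)
        chi2 = (2 * n1 - n_lines) ** 2 / n_lines
        p = stats.chi2.sf(chi2, 1)
        frac = float((p < 0.001).mean())
        se = math.sqrt(0.001 * 0.999 / n_bins)
        assert abs(frac - 0.001) < 3 * se + 2e-4
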