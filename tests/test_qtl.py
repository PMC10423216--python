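"""LOD scans, permutation thresholds, epistasis, site associations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from skimbin.codes import HET, NA, P1, P2
from skimbin.qtl import (
    ScanConfig,
    benjamini_hochberg,
    encode_genotypes,
    epistasis_scan,
    permutation_threshold,
    pool_phenotype,
    single_marker_scan,
    site_association_scan,
)
from skimbin.simulate import (
    GenomeSpec,
    QTLSpec,
    SimConfig,
    simulate_parents,
    simulate_phenotypes,
    simulate_ril_population,
    truth_bin_genotypes,
)


def _toy_genotypes(n=8, m=3, seed=0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    codes = rng.choice([P1, P2], size=(n, m)).astype(np.int8)
    return pd.DataFrame(
        codes, index=[f"L{i}" for i in range(n)],
        columns=[f"c1:{j * 1_000_000}" for j in range(m)],
    )


def _oracle_lod(g: np.ndarray, y: np.ndarray) -> float:
    """Two-model regression LOD via an independent lstsq fit."""
    ok = ~np.isnan(g)
    g, y = g[ok], y[ok]
    n = len(y)
    X0 = np.ones((n, 1))
    X1 = np.column_stack([np.ones(n), g])
    rss0 = float(((y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]) ** 2).sum())
    rss1 = float(((y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]) ** 2).sum())
    return (n / 2) * np.log10(rss0 / rss1)


class TestSingleMarkerScan:
    def test_lod_matches_regression_oracle(self):
        G = _toy_genotypes(n=30, m=4, seed=1)
        rng = np.random.default_rng(2)
        y = pd.Series(rng.normal(size=30), index=G.index)
        res = single_marker_scan(G, y, ScanConfig(min_informative=10))
        enc = encode_genotypes(G)
        for j, b in enumerate(G.columns):
            want = _oracle_lod(enc.iloc[:, j].to_numpy(), y.to_numpy())
            got = res.table.set_index("bin").loc[b, "lod"]
            assert got == pytest.approx(want, rel=1e-10)

    def test_affine_invariance(self):
        G = _toy_genotypes(n=40, m=3, seed=3)
        rng = np.random.default_rng(4)
        y = pd.Series(rng.normal(size=40), index=G.index)
        cfg = ScanConfig(min_informative=10)
        a = single_marker_scan(G, y, cfg).table["lod"]
        b = single_marker_scan(G, 3.0 * y + 7.0, cfg).table["lod"]
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_parent_relabeling_flips_effect_sign_only(self):
        G = _toy_genotypes(n=40, m=3, seed=5)
        rng = np.random.default_rng(6)
        y = pd.Series(rng.normal(size=40), index=G.index)
        cfg = ScanConfig(min_informative=10)
        a = single_marker_scan(G, y, cfg).table
        swapped = G.replace({P1: P2, P2: P1}).astype(np.int8)
        b = single_marker_scan(swapped, y, cfg).table
        np.testing.assert_allclose(a["lod"], b["lod"], rtol=1e-9)
        np.testing.assert_allclose(a["effect"], -b["effect"], rtol=1e-9)

    def test_perfect_fit_is_capped(self):
        G = _toy_genotypes(n=24, m=1, seed=7)
        enc = encode_genotypes(G).iloc[:, 0]
        y = pd.Series(enc.to_numpy(), index=G.index)
        res = single_marker_scan(G, y, ScanConfig(min_informative=10))
        assert res.table["lod"].iloc[0] == 300.0
        assert res.table["pve"].iloc[0] == pytest.approx(1.0)

    def test_constant_phenotype_rejected(self):
        G = _toy_genotypes()
        y = pd.Series(np.ones(len(G)), index=G.index)
        with pytest.raises(ValueError, match="constant"):
            single_marker_scan(G, y, ScanConfig(min_informative=5))

    def test_sparse_bin_reports_nan(self):
        G = _toy_genotypes(n=30, m=2, seed=8)
        G.iloc[5:, 1] = NA
        rng = np.random.default_rng(9)
        y = pd.Series(rng.normal(size=30), index=G.index)
        res = single_marker_scan(G, y, ScanConfig(min_informative=20))
        assert np.isnan(res.table["lod"].iloc[1])
        assert not np.isnan(res.table["lod"].iloc[0])


class TestPermutationThreshold:
    def test_order_statistic_definition(self):
        G = _toy_genotypes(n=60, m=5, seed=10)
        rng = np.random.default_rng(11)
        y = pd.Series(rng.normal(size=60), index=G.index)
        cfg = ScanConfig(permutations=200, alpha=0.05, min_informative=10, seed=12)
        thr, maxima = permutation_threshold(G, y, cfg)
        assert len(maxima) == 200
        assert thr == np.sort(maxima)[int(np.ceil(0.95 * 200)) - 1]

    def test_seed_reproducibility(self):
        G = _toy_genotypes(n=60, m=5, seed=13)
        rng = np.random.default_rng(14)
        y = pd.Series(rng.normal(size=60), index=G.index)
        cfg = ScanConfig(permutations=150, min_informative=10, seed=15)
        assert permutation_threshold(G, y, cfg)[0] == permutation_threshold(G, y, cfg)[0]


@pytest.fixture(scope="module")
def sim():
    g = GenomeSpec(names=["c1", "c2"], lengths=[100_000_000] * 2,
                   snp_density=1 / 20_000)
    cfg = SimConfig(n_lines=600, seed=71)
    key = simulate_parents(g, seed=71)
    truth = simulate_ril_population(key, cfg, g)
    return truth, truth_bin_genotypes(truth)


class TestEpistasis:
    def test_negative_interaction_recovered_with_sign(self, sim):
        truth, bins_g = sim
        qtl = QTLSpec(
            loci=[("c1", 12_000_000), ("c2", 88_000_000)],
            additive_effects=[0.0, 0.0],
            epistatic_pairs=[(0, 1, -0.5)],
            residual_sd=1.0,
        )
        pheno = simulate_phenotypes(truth, qtl, seed=72, trait="epi")
        y = pool_phenotype(pheno, "epi")
        cands = ["c1:12000000", "c2:88000000", "c1:81000000", "c2:15000000"]
        res = epistasis_scan(bins_g, y, cands, ScanConfig(seed=72))
        top = res.iloc[0]
        assert {top["bin_a"], top["bin_b"]} == {"c1:12000000", "c2:88000000"}
        assert top["sign"] == -1

    def test_additive_trait_shows_no_strong_interactions(self, sim):
        truth, bins_g = sim
        qtl = QTLSpec(loci=[("c1", 12_000_000)], additive_effects=[0.5],
                      residual_sd=1.0)
        pheno = simulate_phenotypes(truth, qtl, seed=73, trait="add")
        y = pool_phenotype(pheno, "add")
        cands = ["c1:12000000", "c2:88000000", "c2:15000000"]
        res = epistasis_scan(bins_g, y, cands, ScanConfig(seed=73))
        # pairwise interaction F-test p-values stay unremarkable
        assert (res["p_value"] > 1e-3).all()


@pytest.fixture(scope="module")
def mendelian():
    g = GenomeSpec(names=["c1"], lengths=[60_000_000], snp_density=1 / 30_000)
    cfg = SimConfig(n_lines=300, seed=81)
    key = simulate_parents(g, seed=81)
    truth = simulate_ril_population(key, cfg, g)
    # scored 1/2/3 single-locus trait, fully penetrant
    qtl = QTLSpec(loci=[("c1", 8_000_000)], additive_effects=[1.0],
                  residual_sd=0.1, qualitative_thresholds=[-0.5, 0.5])
    pheno = simulate_phenotypes(truth, qtl, seed=81, trait="rc")
    y = pool_phenotype(pheno, "rc")
    # idealised imputed matrix straight from truth blocks
    pos = key["pos"].to_numpy()
    rows = []
    for line in truth.lines:
        state = truth.state_at(line, "c1", pos)
        rows.append(pd.DataFrame(
            {"line": line, "chrom": "c1", "pos": pos, "code": state}
        ))
    imputed = pd.concat(rows, ignore_index=True)
    return imputed, y


class TestSiteAssociation:
    def test_benjamini_hochberg_matches_reference_formula(self):
        rng = np.random.default_rng(20)
        p = rng.uniform(size=100)
        q = benjamini_hochberg(p)
        # step-up reference: q_(i) = min_{j>=i} p_(j) * m / j
        order = np.argsort(p)
        m = len(p)
        ref = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            running = min(running, p[order[rank - 1]] * m / rank)
            ref[order[rank - 1]] = running
        np.testing.assert_allclose(q, ref)

    def test_mendelian_trait_peaks_at_the_locus(self, mendelian):
        imputed, y = mendelian
        res = site_association_scan(
            imputed, y, ScanConfig(subsample_fraction=0.2, seed=82)
        )
        top = res.loc[res["p_value"].idxmin()]
        assert abs(top["pos"] - 8_000_000) <= 1_000_000
        assert top["significant"]

    def test_full_scan_contains_subsample_sites(self, mendelian):
        imputed, y = mendelian
        sub = site_association_scan(
            imputed, y, ScanConfig(subsample_fraction=0.2, seed=83)
        )
        full = site_association_scan(
            imputed, y, ScanConfig(subsample_fraction=1.0, seed=83)
        )
        assert set(sub["site"]) <= set(full["site"])
        sig_sub = sub[sub["significant"]]["site"]
        assert full.set_index("site").loc[sig_sub, "significant"].all()

    def test_too_small_subsample_rejected(self, mendelian):
        imputed, y = mendelian
        with pytest.raises(ValueError, match="below the 100-site minimum"):
            site_association_scan(imputed, y, ScanConfig(subsample_fraction=0.01))

    def test_null_phenotype_yields_no_discoveries(self, mendelian):
        imputed, _ = mendelian
        rng = np.random.default_rng(84)
        lines = imputed["line"].unique()
        discoveries = []
        for rep in range(5):
            y = pd.Series(rng.normal(size=len(lines)), index=lines)
            res = site_association_scan(
                imputed, y, ScanConfig(subsample_fraction=0.15, seed=85 + rep)
            )
            discoveries.append(int(res["significant"].sum()))
        assert int(np.median(discoveries)) == 0
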