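"""Simplified trait mapping: single-marker LOD scans, permutation
thresholds, digenic epistasis and a site-level association scan.

In a biparental RIL population single-marker regression on dense 1-Mb bins
approximates interval mapping (adjacent-bin recombination is ~1%), and no
population-structure correction is needed beyond the genome-wide relatedness
absorbed by permutation thresholds.  The scans use the two-model LOD

    LOD = (n/2) log10(RSS0 / RSS1)

with genotypes coded P1 -> +1, P2 -> -1 (heterozygous excluded by default
or coded 0), permutation-based genome-wide thresholds, PVE = 1 - RSS1/RSS0,
pairwise interaction F-tests on candidate bins, and per-site regression with
Benjamini-Hochberg control for the marker-trait association scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from scipy import stats

from skimbin.codes import HET, NA, P1, P2
from skimbin.bins import BinGenotypeMatrix

__all__ = [
    "ScanConfig",
    "ScanResult",
    "encode_genotypes",
    "pool_phenotype",
    "single_marker_scan",
    "permutation_threshold",
    "epistasis_scan",
    "site_association_scan",
    "benjamini_hochberg",
]

_LOD_CAP = 300.0


class ScanConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    permutations: int = Field(default=1000, ge=100)
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    major_pve: float = Field(default=0.10, gt=0.0, lt=1.0)
    h_mode: str = Field(default="exclude", pattern="^(exclude|code-zero)$")
    subsample_fraction: float = Field(default=0.10, gt=0.0, le=1.0)
    fdr_level: float = Field(default=0.05, gt=0.0, lt=1.0)
    min_informative: int = Field(default=20, ge=3)
    seed: int = 0


@dataclass
class ScanResult:
    table: pd.DataFrame  # bin, n, effect, lod, pve
    threshold: Optional[float] = None
    significant: Optional[pd.DataFrame] = None
    perm_max_lods: Optional[np.ndarray] = None


def encode_genotypes(
    codes: Union[BinGenotypeMatrix, pd.DataFrame], h_mode: str = "exclude"
) -> pd.DataFrame:
    """Code matrix -> numeric doses: P1 +1, P2 -1, H 0 or NaN, NA NaN."""
    if isinstance(codes, BinGenotypeMatrix):
        codes = codes.codes
    c = codes.to_numpy()
    g = np.full(c.shape, np.nan)
    g[c == P1] = 1.0
    g[c == P2] = -1.0
    if h_mode == "code-zero":
        g[c == HET] = 0.0
    return pd.DataFrame(g, index=codes.index, columns=codes.columns)


def pool_phenotype(pheno: pd.DataFrame, trait: str) -> pd.Series:
    """Pooled phenotype per line: the arithmetic mean over years."""
    sub = pheno[pheno["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no phenotype rows for trait {trait!r}")
    return sub.groupby("line")["value"].mean()


def _lod_matrix(
    G: np.ndarray, Y: np.ndarray, min_informative: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form per-marker regression for all phenotype columns at once.

    G: (n x m) doses with NaN missing; Y: (n x q) phenotype columns.
    Returns (lod, pve, beta, n_informative) each of shape (m x q) (n: m,).
    Missing phenotype entries are not supported (drop lines first).
    """
    M = ~np.isnan(G)
    G0 = np.where(M, G, 0.0)
    n_j = M.sum(axis=0).astype(float)  # (m,)
    Sg = G0.sum(axis=0)
    Sgg = (G0 * G0).sum(axis=0)
    Sy = M.T @ Y  # (m x q)
    Syy = M.T @ (Y * Y)
    Sgy = G0.T @ Y
    with np.errstate(invalid="ignore", divide="ignore"):
        Sxx = Sgg - Sg * Sg / n_j  # (m,)
        Sxy = Sgy - (Sg / n_j)[:, None] * Sy
        Syy_c = Syy - Sy * Sy / n_j[:, None]
        beta = np.where(Sxx[:, None] > 0, Sxy / Sxx[:, None], 0.0)
        rss1 = Syy_c - np.where(Sxx[:, None] > 0, Sxy * Sxy / Sxx[:, None], 0.0)
        rss1 = np.maximum(rss1, 0.0)
        ratio = np.where(rss1 > 0, Syy_c / np.maximum(rss1, 1e-300), np.inf)
        lod = 0.5 * n_j[:, None] * np.log10(np.maximum(ratio, 1.0))
        pve = np.where(Syy_c > 0, 1.0 - rss1 / np.maximum(Syy_c, 1e-300), 0.0)
    lod = np.minimum(np.nan_to_num(lod, nan=0.0), _LOD_CAP)
    bad = n_j < min_informative
    lod[bad] = np.nan
    pve[bad] = np.nan
    beta[bad] = np.nan
    return lod, pve, beta, n_j


def _prepare(genotypes, y, cfg: ScanConfig):
    G = encode_genotypes(genotypes, cfg.h_mode)
    y = pd.Series(y)
    common = G.index.intersection(y.index)
    y = y.loc[common].astype(float)
    y = y.dropna()
    G = G.loc[y.index]
    if len(y) < cfg.min_informative:
        raise ValueError("too few lines with both genotype and phenotype")
    if float(np.var(y)) == 0.0:
        raise ValueError("constant phenotype")
    return G, y


def single_marker_scan(
    genotypes: Union[BinGenotypeMatrix, pd.DataFrame],
    y: pd.Series,
    cfg: ScanConfig | None = None,
    threshold: Optional[float] = None,
) -> ScanResult:
    """Per-bin least-squares scan of one phenotype.

    ``y`` is indexed by line (e.g. from :func:`pool_phenotype`).  Bins with
    fewer informative lines than ``min_informative`` report NaN.  If a
    genome-wide ``threshold`` is given, significant bins (with the major-QTL
    flag at PVE > major_pve) are attached to the result.
    """
    cfg = cfg or ScanConfig()
    G, yv = _prepare(genotypes, y, cfg)
    lod, pve, beta, n_j = _lod_matrix(
        G.to_numpy(), yv.to_numpy()[:, None], cfg.min_informative
    )
    table = pd.DataFrame(
        {
            "bin": G.columns,
            "n": n_j.astype(int),
            "effect": beta[:, 0],
            "lod": lod[:, 0],
            "pve": pve[:, 0],
        }
    )
    res = ScanResult(table=table, threshold=threshold)
    if threshold is not None:
        sig = table[table["lod"] > threshold].copy()
        sig["major"] = sig["pve"] > cfg.major_pve
        res.significant = sig.reset_index(drop=True)
    return res


def permutation_threshold(
    genotypes: Union[BinGenotypeMatrix, pd.DataFrame],
    y: pd.Series,
    cfg: ScanConfig | None = None,
) -> Tuple[float, np.ndarray]:
    """Genome-wide LOD threshold from seeded phenotype permutations.

    Permutes the phenotype across lines, records the genome-wide maximum
    LOD per permutation, and returns the empirical (1 - alpha) quantile as
    the ceil((1-alpha) P)-th order statistic, plus the per-permutation
    maxima.
    """
    cfg = cfg or ScanConfig()
    G, yv = _prepare(genotypes, y, cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 55_117]))
    yarr = yv.to_numpy()
    Y = np.column_stack(
        [rng.permutation(yarr) for _ in range(cfg.permutations)]
    )
    lod, _, _, _ = _lod_matrix(G.to_numpy(), Y, cfg.min_informative)
    max_lod = np.nanmax(lod, axis=0)
    k = int(np.ceil((1.0 - cfg.alpha) * cfg.permutations)) - 1
    thr = float(np.sort(max_lod)[k])
    return thr, max_lod


def epistasis_scan(
    genotypes: Union[BinGenotypeMatrix, pd.DataFrame],
    y: pd.Series,
    candidates: Sequence[str],
    cfg: ScanConfig | None = None,
) -> pd.DataFrame:
    """Pairwise digenic interaction tests over candidate bins.

    For each pair, the full model y ~ g1 + g2 + g1*g2 is compared with the
    additive model by an interaction LOD (and F-test p-value); the sign of
    the interaction coefficient is reported.  Nearly collinear pairs (no
    variance left in the interaction after the additive terms) are skipped.
    """
    cfg = cfg or ScanConfig()
    G, yv = _prepare(genotypes, y, cfg)
    rows = []
    yarr = yv.to_numpy()
    for ai in range(len(candidates)):
        for bi in range(ai + 1, len(candidates)):
            a, b = candidates[ai], candidates[bi]
            g1 = G[a].to_numpy()
            g2 = G[b].to_numpy()
            ok = ~np.isnan(g1) & ~np.isnan(g2)
            n = int(ok.sum())
            if n < cfg.min_informative:
                continue
            x1, x2, yy = g1[ok], g2[ok], yarr[ok]
            X_add = np.column_stack([np.ones(n), x1, x2])
            X_full = np.column_stack([np.ones(n), x1, x2, x1 * x2])
            if np.linalg.matrix_rank(X_full) < 4:
                continue
            beta_add, rss_add = _ols(X_add, yy)
            beta_full, rss_full = _ols(X_full, yy)
            if rss_add <= 0:
                continue
            lod = 0.5 * n * np.log10(max(rss_add / max(rss_full, 1e-300), 1.0))
            df2 = n - 4
            F = ((rss_add - rss_full) / 1.0) / max(rss_full / df2, 1e-300)
            rows.append(
                {
                    "bin_a": a,
                    "bin_b": b,
                    "n": n,
                    "gamma": beta_full[3],
                    "interaction_lod": min(lod, _LOD_CAP),
                    "F": F,
                    "p_value": float(stats.f.sf(F, 1, df2)) if df2 > 0 else np.nan,
                    "sign": int(np.sign(beta_full[3])),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["bin_a", "bin_b", "n", "gamma", "interaction_lod", "F", "p_value", "sign"],
    ).sort_values("interaction_lod", ascending=False, ignore_index=True)


def _ols(X: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, float]:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values (monotone step-up adjustment)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def site_association_scan(
    imputed: pd.DataFrame,
    y: pd.Series,
    cfg: ScanConfig | None = None,
) -> pd.DataFrame:
    """Marker-trait association on (a random subset of) imputed sites.

    ``imputed`` is the long (line, chrom, pos, code) matrix from the
    imputer.  A seeded uniform subsample of sites at
    ``cfg.subsample_fraction`` is scanned with per-site regression; the
    returned table carries p-values, Benjamini-Hochberg q-values and a
    significance flag at ``cfg.fdr_level``.
    """
    cfg = cfg or ScanConfig()
    sites = imputed[["chrom", "pos"]].drop_duplicates().sort_values(
        ["chrom", "pos"], kind="mergesort"
    )
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 90_871]))
    n_sites = len(sites)
    n_take = int(round(cfg.subsample_fraction * n_sites))
    if n_take < 100:
        raise ValueError(
            f"subsample of {n_take} sites is below the 100-site minimum"
        )
    take = np.sort(rng.choice(n_sites, size=n_take, replace=False))
    chosen = sites.iloc[take]
    sub = imputed.merge(chosen, on=["chrom", "pos"], how="inner")
    sub = sub.assign(site=sub["chrom"].astype(str) + ":" + sub["pos"].astype(str))
    wide = sub.pivot_table(
        index="line", columns="site", values="code", aggfunc="first"
    )
    # preserve genomic order of columns
    order = (chosen["chrom"].astype(str) + ":" + chosen["pos"].astype(str)).tolist()
    wide = wide[[c for c in order if c in wide.columns]]
    G, yv = _prepare(wide, y, cfg)
    lod, pve, beta, n_j = _lod_matrix(
        G.to_numpy(), yv.to_numpy()[:, None], cfg.min_informative
    )
    n = n_j
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = pve[:, 0]
        F = r2 * (n - 2) / np.maximum(1.0 - r2, 1e-300)
    pvals = np.where(
        np.isnan(lod[:, 0]), np.nan, stats.f.sf(F, 1, np.maximum(n - 2, 1))
    )
    valid = ~np.isnan(pvals)
    q = np.full(len(pvals), np.nan)
    if valid.any():
        q[valid] = benjamini_hochberg(pvals[valid])
    chroms = [c.split(":")[0] for c in G.columns]
    poss = [int(c.split(":")[1]) for c in G.columns]
    out = pd.DataFrame(
        {
            "site": G.columns,
            "chrom": chroms,
            "pos": poss,
            "n": n.astype(int),
            "effect": beta[:, 0],
            "p_value": pvals,
            "q_value": q,
        }
    )
    out["significant"] = out["q_value"] <= cfg.fdr_level
    return out
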