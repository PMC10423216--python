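"""Bin-marker filtering, recombination fractions and the Kosambi map.

Bin markers are screened for segregation distortion (chi-square against the
1:1 expectation of a biparental inbred population) and missingness; adjacent
retained bins give an observed recombination fraction R, corrected to the
meiotic fraction r through the selfed-RIL (Haldane-Waddington) relation
R = 2r/(1+2r), and converted to centiMorgans with the Kosambi function
d = 25 ln((1+2r)/(1-2r)).  Physical bin order is used throughout: bins are
anchored on the assembly, so no de novo grouping or ordering is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from scipy import stats

from skimbin.codes import HET, NA, P1, P2
from skimbin.bins import BinGenotypeMatrix

__all__ = [
    "MapConfig",
    "GeneticMap",
    "filter_markers",
    "adjacent_recombination_fraction",
    "haldane_waddington",
    "kosambi_cm",
    "build_map",
]

_R_CAP = 0.4999


class MapConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    distortion_p: float = Field(default=0.001, gt=0.0, lt=1.0)
    max_missing: float = Field(default=0.20, ge=0.0, le=1.0)
    ril_correction: bool = True


def filter_markers(
    binmat: BinGenotypeMatrix, cfg: MapConfig | None = None
) -> Tuple[List[str], pd.DataFrame]:
    """Remove distorted and gappy bin markers.

    Per bin, a 1-df chi-square goodness-of-fit of the P1:P2 line counts
    against 1:1 (H and NA excluded); bins with p below the threshold, with
    missing fraction above the cap, or with no informative lines are
    removed.  Returns (retained bin labels, per-bin log with p-values).
    """
    cfg = cfg or MapConfig()
    codes = binmat.codes.to_numpy()
    n1 = (codes == P1).sum(axis=0).astype(float)
    n2 = (codes == P2).sum(axis=0).astype(float)
    n_lines = codes.shape[0]
    miss_frac = (codes == NA).sum(axis=0) / max(n_lines, 1)
    n = n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.divide((n1 - n2) ** 2, n, out=np.zeros_like(n), where=n > 0)
    pval = stats.chi2.sf(chi2, df=1)
    uninformative = n == 0
    distorted = (~uninformative) & (pval < cfg.distortion_p)
    gappy = miss_frac > cfg.max_missing
    removed = uninformative | distorted | gappy
    reason = np.where(
        uninformative,
        "uninformative",
        np.where(distorted, "distorted", np.where(gappy, "missing", "")),
    )
    log = pd.DataFrame(
        {
            "bin": binmat.bin_labels,
            "n_p1": n1.astype(int),
            "n_p2": n2.astype(int),
            "chi2": chi2,
            "p_value": pval,
            "missing_fraction": miss_frac,
            "removed": removed,
            "reason": reason,
        }
    )
    retained = [b for b, r in zip(binmat.bin_labels, removed) if not r]
    return retained, log


def adjacent_recombination_fraction(
    binmat: BinGenotypeMatrix, bin_a: str, bin_b: str
) -> float:
    """Observed recombination fraction between two adjacent bins.

    R = (# lines with differing non-missing, non-H codes) / (# lines
    informative at both), capped just below 0.5 for map conversion.  NaN if
    no line is informative at both bins.
    """
    a = binmat.codes[bin_a].to_numpy()
    b = binmat.codes[bin_b].to_numpy()
    ok = np.isin(a, (P1, P2)) & np.isin(b, (P1, P2))
    n = int(ok.sum())
    if n == 0:
        return float("nan")
    return min(float((a[ok] != b[ok]).mean()), _R_CAP)


def haldane_waddington(R: float) -> float:
    """Meiotic recombination fraction r from the selfed-RIL observed R.

    In a selfed RIL the observed fraction saturates at R = 2r/(1+2r);
    inverting gives r = R / (2 (1 - R)).
    """
    R = float(R)
    if not 0.0 <= R < 0.5:
        raise ValueError("R must lie in [0, 0.5)")
    return R / (2.0 * (1.0 - R))


def kosambi_cm(r: float) -> float:
    """Kosambi map distance (cM) for meiotic recombination fraction r."""
    r = float(r)
    if not 0.0 <= r < 0.5:
        raise ValueError("r must lie in [0, 0.5)")
    return 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


@dataclass
class GeneticMap:
    """Per-interval and cumulative Kosambi positions over retained bins."""

    table: pd.DataFrame  # chrom, bin, R, r, interval_cM, cumulative_cM
    totals: Dict[str, float]  # per chromosome, corrected scale
    total_cm: float
    total_cm_uncorrected: float
    removal_log: pd.DataFrame


def build_map(binmat: BinGenotypeMatrix, cfg: MapConfig | None = None) -> GeneticMap:
    """Filter markers and accumulate the Kosambi map in physical bin order.

    Totals are reported on both scales: with the selfed-RIL correction
    (r = R/(2(1-R)) before Kosambi) and without (R fed to Kosambi
    directly).  Chromosomes with fewer than two retained bins contribute
    zero length.
    """
    cfg = cfg or MapConfig()
    retained, log = filter_markers(binmat, cfg)
    idx = binmat.index.set_index("bin")
    rows = []
    totals: Dict[str, float] = {}
    total_unc = 0.0
    by_chrom: Dict[str, List[str]] = {}
    for b in retained:
        by_chrom.setdefault(idx.loc[b, "chrom"], []).append(b)
    for chrom, bins_here in by_chrom.items():
        cum = 0.0
        rows.append(
            {"chrom": chrom, "bin": bins_here[0], "R": np.nan, "r": np.nan,
             "interval_cM": 0.0, "cumulative_cM": 0.0}
        )
        for a, b in zip(bins_here[:-1], bins_here[1:]):
            R = adjacent_recombination_fraction(binmat, a, b)
            if np.isnan(R):
                r = np.nan
                d = 0.0
                d_unc = 0.0
            else:
                r = haldane_waddington(R) if cfg.ril_correction else R
                d = kosambi_cm(min(r, _R_CAP))
                d_unc = kosambi_cm(min(R, _R_CAP))
            cum += d
            total_unc += d_unc
            rows.append(
                {"chrom": chrom, "bin": b, "R": R, "r": r,
                 "interval_cM": d, "cumulative_cM": cum}
            )
        totals[chrom] = cum
    table = pd.DataFrame(
        rows, columns=["chrom", "bin", "R", "r", "interval_cM", "cumulative_cM"]
    )
    return GeneticMap(
        table=table,
        totals=totals,
        total_cm=float(sum(totals.values())),
        total_cm_uncorrected=float(total_unc),
        removal_log=log,
    )
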