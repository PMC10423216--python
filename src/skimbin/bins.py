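"""1-Mb bin consensus genotyping.

Sparse per-site parental codes are collapsed into non-overlapping physical
windows (default 1 Mb, 0-based half-open starts).  Within a window the
consensus is driven by the proportion of P1 among parental codes: a window
with nP1/(nP1+nP2) >= 0.7 is called P1, with the complement >= 0.7 called
P2, otherwise heterozygous; windows with too few informative sites are NA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from skimbin.codes import HET, NA, P1, P2, codes_to_str_array

__all__ = ["BinConfig", "BinGenotypeMatrix", "make_bins", "call_bin_consensus", "bin_matrix"]


class BinConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    threshold: float = Field(default=0.7, gt=0.5, le=1.0)
    min_sites: int = Field(default=5, ge=1)
    bin_size: int = Field(default=1_000_000, gt=0)


@dataclass
class BinGenotypeMatrix:
    """Lines x bins consensus codes with the underlying site counts.

    ``codes`` is an int8 DataFrame (index = line, columns = "chrom:start"),
    ``n_p1``/``n_p2``/``n_h`` the matching count matrices, and ``index`` the
    bin table (chrom, start, end, bin).
    """

    codes: pd.DataFrame
    n_p1: pd.DataFrame
    n_p2: pd.DataFrame
    n_h: pd.DataFrame
    index: pd.DataFrame
    config: BinConfig

    @property
    def lines(self):
        return list(self.codes.index)

    @property
    def bin_labels(self):
        return list(self.codes.columns)

    def to_tsv(self, path: str) -> None:
        out = self.codes.map(lambda c: {P1: "A", P2: "B", HET: "H", NA: "NA"}[c])
        with open(path, "w") as fh:
            fh.write("# bin consensus codes; legend: A=P1, B=P2, H=het, NA=missing\n")
            fh.write("# bins are 0-based half-open [start, start+size)\n")
            out.to_csv(fh, sep="\t")

    def counts_to_tsv(self, path: str) -> None:
        long = []
        for name, mat in (("n_p1", self.n_p1), ("n_p2", self.n_p2), ("n_h", self.n_h)):
            m = mat.stack().rename(name)
            long.append(m)
        df = pd.concat(long, axis=1).reset_index()
        df.columns = ["line", "bin", "n_p1", "n_p2", "n_h"]
        df.to_csv(path, sep="\t", index=False)


def make_bins(lengths: Dict[str, int], cfg: BinConfig | None = None) -> pd.DataFrame:
    """Tile each chromosome with fixed-size half-open bins (last bin partial)."""
    cfg = cfg or BinConfig()
    rows = []
    for chrom, L in lengths.items():
        if L <= 0:
            raise ValueError(f"non-positive length for {chrom}")
        starts = np.arange(0, L, cfg.bin_size, dtype=np.int64)
        for s in starts:
            rows.append((chrom, int(s), int(min(s + cfg.bin_size, L))))
    idx = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    idx["bin"] = idx["chrom"].astype(str) + ":" + idx["start"].astype(str)
    return idx


def call_bin_consensus(
    n_p1: int, n_p2: int, cfg: BinConfig | None = None, n_h: int = 0
) -> int:
    """Consensus code for one window from its parental-code counts.

    Let n = nP1 + nP2.  n < min_sites -> NA; p = nP1/n >= threshold -> P1;
    1-p >= threshold -> P2; otherwise H.  A window dominated by observed
    heterozygous calls (nH > nP1 + nP2) is coded H outright rather than
    forced to a parent.
    """
    cfg = cfg or BinConfig()
    n = n_p1 + n_p2
    if n_h > n:
        return HET if (n + n_h) >= cfg.min_sites else NA
    if n < cfg.min_sites:
        return NA
    p = n_p1 / n
    if p >= cfg.threshold:
        return P1
    if (1.0 - p) >= cfg.threshold:
        return P2
    return HET


def bin_matrix(
    coded: pd.DataFrame, bin_index: pd.DataFrame, cfg: BinConfig | None = None
) -> BinGenotypeMatrix:
    """Aggregate a sparse coded call matrix into the bin genotype matrix."""
    cfg = cfg or BinConfig()
    lengths = bin_index.groupby("chrom", sort=False)["end"].max().to_dict()
    lines = sorted(coded["line"].unique().tolist()) if len(coded) else []
    bins = bin_index["bin"].tolist()
    shape = (len(lines), len(bins))
    n_p1 = np.zeros(shape, dtype=np.int32)
    n_p2 = np.zeros(shape, dtype=np.int32)
    n_h = np.zeros(shape, dtype=np.int32)
    if len(coded):
        bad = ~coded["chrom"].isin(lengths)
        if bad.any():
            raise ValueError(
                f"site on chromosome outside the bin index: "
                f"{coded.loc[bad, 'chrom'].iloc[0]!r}"
            )
        over = coded["pos"] > coded["chrom"].map(lengths)
        if over.any():
            t = coded.loc[over].iloc[0]
            raise ValueError(f"site beyond chromosome end: {t['chrom']}:{t['pos']}")
        line_idx = pd.Categorical(coded["line"], categories=lines).codes
        bin_label = (
            coded["chrom"].astype(str)
            + ":"
            + (((coded["pos"] - 1) // cfg.bin_size) * cfg.bin_size).astype(str)
        )
        bin_idx = pd.Categorical(bin_label, categories=bins).codes
        code = coded["code"].to_numpy()
        for target, c in ((n_p1, P1), (n_p2, P2), (n_h, HET)):
            m = code == c
            np.add.at(target, (line_idx[m], bin_idx[m]), 1)
    n = n_p1 + n_p2
    total = n + n_h
    codes = np.full(shape, NA, dtype=np.int8)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.divide(n_p1, n, out=np.zeros(shape), where=n > 0)
    informative = n >= cfg.min_sites
    codes[informative & (p >= cfg.threshold)] = P1
    codes[informative & ((1.0 - p) >= cfg.threshold)] = P2
    codes[informative & (p < cfg.threshold) & ((1.0 - p) < cfg.threshold)] = HET
    het_dom = (n_h > n) & (total >= cfg.min_sites)
    codes[het_dom] = HET
    codes[(n_h > n) & (total < cfg.min_sites)] = NA
    line_index = pd.Index(lines, name="line")
    return BinGenotypeMatrix(
        codes=pd.DataFrame(codes, index=line_index, columns=bins),
        n_p1=pd.DataFrame(n_p1, index=line_index, columns=bins),
        n_p2=pd.DataFrame(n_p2, index=line_index, columns=bins),
        n_h=pd.DataFrame(n_h, index=line_index, columns=bins),
        index=bin_index,
        config=cfg,
    )
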