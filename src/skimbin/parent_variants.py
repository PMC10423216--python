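"""Filter high-depth parental variant calls into the segregating key.

Two deeply sequenced parents define which allele at each biallelic SNP
belongs to which parent.  A site enters the key only when both parents are
confidently homozygous for different alleles, so that any single error-free
progeny read identifies its parental origin.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["FilterConfig", "filter_parent_sites", "parent_allele_proportions"]


class FilterConfig(BaseModel):
    """Depth filters applied to each parent at each candidate site.

    Defaults follow the skim-seq protocol: total filtered depth within
    [6, 100] and the called (supporting) allele covered by >= 3 reads.
    """

    model_config = ConfigDict(extra="forbid")

    min_depth: int = Field(default=6, gt=0)
    max_depth: int = Field(default=100, gt=0)
    min_allele_depth: int = Field(default=3, ge=1)

    @model_validator(mode="after")
    def _check(self) -> "FilterConfig":
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth must not exceed max_depth")
        return self


def _parent_passes(
    gt: np.ndarray, dp: np.ndarray, ad_ref: np.ndarray, ad_alt: np.ndarray,
    cfg: FilterConfig,
) -> np.ndarray:
    """Homozygous, non-missing, depth in range, called allele supported.

    The supporting-allele rule applies to the allele the parent is called
    for; reads of the other allele are permitted but cannot rescue a site.
    """
    hom = (gt == 0) | (gt == 1)
    depth_ok = (dp >= cfg.min_depth) & (dp <= cfg.max_depth)
    support = np.where(gt == 0, ad_ref, ad_alt)
    return hom & depth_ok & (support >= cfg.min_allele_depth)


def filter_parent_sites(records: pd.DataFrame, cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Reduce parent site records to the segregating ParentKey.

    ``records`` is the DataFrame produced by ``vcfio.read_parent_vcf`` (one
    row per biallelic SNP with per-parent genotype class and depths).  A
    site is retained iff both parents pass the depth/homozygosity filters
    and their called alleles differ.  Returns the key sorted by chromosome
    then position with columns chrom, pos, ref, alt, p1, p2 (allele indices).

    Raises on missing depth columns or duplicated coordinates — duplicate
    records are ambiguous, not silently resolvable.
    """
    cfg = cfg or FilterConfig()
    required = {
        "chrom", "pos", "ref", "alt",
        "p1_gt", "p1_dp", "p1_ad_ref", "p1_ad_alt",
        "p2_gt", "p2_dp", "p2_ad_ref", "p2_ad_alt",
    }
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"malformed parent records: missing fields {sorted(missing)}")
    dup = records.duplicated(subset=["chrom", "pos"])
    if dup.any():
        t = records.loc[dup.idxmax()]
        raise ValueError(f"duplicate coordinate {t['chrom']}:{t['pos']}")
    ok1 = _parent_passes(
        records["p1_gt"].to_numpy(), records["p1_dp"].to_numpy(),
        records["p1_ad_ref"].to_numpy(), records["p1_ad_alt"].to_numpy(), cfg,
    )
    ok2 = _parent_passes(
        records["p2_gt"].to_numpy(), records["p2_dp"].to_numpy(),
        records["p2_ad_ref"].to_numpy(), records["p2_ad_alt"].to_numpy(), cfg,
    )
    segregating = records["p1_gt"].to_numpy() != records["p2_gt"].to_numpy()
    kept = records.loc[ok1 & ok2 & segregating].copy()
    key = pd.DataFrame(
        {
            "chrom": kept["chrom"].to_numpy(),
            "pos": kept["pos"].astype(np.int64).to_numpy(),
            "ref": kept["ref"].to_numpy(),
            "alt": kept["alt"].to_numpy(),
            "p1": kept["p1_gt"].astype(np.int8).to_numpy(),
            "p2": kept["p2_gt"].astype(np.int8).to_numpy(),
        }
    )
    key = key.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return key


def parent_allele_proportions(key: pd.DataFrame) -> Dict[str, float]:
    """Per-parent proportion of key sites on the reference allele.

    Mirrors the reference/alternate allele balance plot used to confirm
    which parent the reference assembly resembles: a wild parent aligned to
    a wild-type assembly carries mostly reference alleles.
    """
    if len(key) == 0:
        raise ValueError("empty parental key")
    return {
        "p1_ref": float((key["p1"] == 0).mean()),
        "p2_ref": float((key["p2"] == 0).mean()),
    }
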