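"""Readers and writers for the pipeline's plain-file interfaces.

VCF is read through cyvcf2 (htslib); output VCF is written uncompressed so
that simulated datasets remain plain text.  Tabular interchange uses TSV
with the P1/P2/H/NA code legend (bin matrices use A/B/H/NA, with the legend
stated in a header comment).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, Optional

import numpy as np
import pandas as pd

from skimbin.codes import HET, NA, P1, P2, codes_to_str_array, str_array_to_codes

__all__ = [
    "read_parent_vcf",
    "read_progeny_vcf_calls",
    "write_key_tsv",
    "read_key_tsv",
    "write_key_vcf",
    "write_progeny_vcf",
    "write_coded_tsv",
    "read_coded_tsv",
    "write_lengths_tsv",
    "read_lengths_tsv",
    "write_phenotypes_tsv",
    "read_phenotypes_tsv",
    "write_json",
]

# --------------------------------------------------------------------------- #
# parent VCF
# --------------------------------------------------------------------------- #

def read_parent_vcf(path: str, p1: str, p2: str) -> pd.DataFrame:
    """Read a two-parent VCF into per-site parent records.

    Returns one row per biallelic SNP with, per parent, the genotype class
    (0 hom-ref, 1 hom-alt, 2 het, -1 missing), total depth and ref/alt
    allele depths.  Multi-allelic and indel records are dropped (counted in
    the DataFrame attribute ``dropped_non_biallelic_snv``).
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    for name in (p1, p2):
        if name not in samples:
            raise ValueError(f"sample {name!r} not present in {path}")
    i1, i2 = samples.index(p1), samples.index(p2)
    rows = []
    dropped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            dropped += 1
            continue
        ad = v.format("AD")
        if ad is None:
            raise ValueError(
                f"malformed record at {v.CHROM}:{v.POS}: AD field absent"
            )
        gt_types = v.gt_types  # 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        depths = v.gt_depths
        rec = [v.CHROM, v.POS, v.REF, v.ALT[0]]
        for idx in (i1, i2):
            g = int(gt_types[idx])
            gclass = {0: 0, 3: 1, 1: 2, 2: -1}[g]
            ad_ref = max(int(ad[idx][0]), 0)
            ad_alt = max(int(ad[idx][1]), 0) if ad.shape[1] > 1 else 0
            dp = int(depths[idx])
            if dp < 0:
                dp = ad_ref + ad_alt
            rec += [gclass, dp, ad_ref, ad_alt]
        rows.append(rec)
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt",
            "p1_gt", "p1_dp", "p1_ad_ref", "p1_ad_alt",
            "p2_gt", "p2_dp", "p2_ad_ref", "p2_ad_alt",
        ],
    )
    df.attrs["dropped_non_biallelic_snv"] = dropped
    return df


def read_progeny_vcf_calls(path: str) -> pd.DataFrame:
    """Read a multi-sample progeny VCF into long (line, chrom, pos, gt) rows.

    ``gt`` is 0 hom-ref, 1 hom-alt, 2 het; uncalled genotypes are omitted
    (they are the implicit NA of the sparse matrix).
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = np.array(vcf.samples, dtype=object)
    lines, chroms, poss, gts = [], [], [], []
    for v in vcf:
        gt_types = np.asarray(v.gt_types)
        called = gt_types != 2  # 2 == UNKNOWN
        if not called.any():
            continue
        g = gt_types[called]
        gclass = np.where(g == 0, 0, np.where(g == 3, 1, 2)).astype(np.int8)
        lines.append(samples[called])
        chroms.append(np.repeat(v.CHROM, called.sum()))
        poss.append(np.full(called.sum(), v.POS, dtype=np.int64))
        gts.append(gclass)
    if not lines:
        return pd.DataFrame(columns=["line", "chrom", "pos", "gt"])
    return pd.DataFrame(
        {
            "line": np.concatenate(lines),
            "chrom": np.concatenate(chroms),
            "pos": np.concatenate(poss),
            "gt": np.concatenate(gts),
        }
    )


# --------------------------------------------------------------------------- #
# parental key
# --------------------------------------------------------------------------- #

def write_key_tsv(key: pd.DataFrame, path: str) -> None:
    out = key.copy()
    out["p1_allele"] = np.where(out["p1"] == 0, out["ref"], out["alt"])
    out["p2_allele"] = np.where(out["p2"] == 0, out["ref"], out["alt"])
    out[["chrom", "pos", "ref", "alt", "p1_allele", "p2_allele"]].to_csv(
        path, sep="\t", index=False
    )


def read_key_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    p1 = np.where(df["p1_allele"] == df["ref"], 0, 1).astype(np.int8)
    return pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"].astype(np.int64),
            "ref": df["ref"],
            "alt": df["alt"],
            "p1": p1,
            "p2": (1 - p1).astype(np.int8),
        }
    )


def _vcf_header(lengths: Optional[Dict[str, int]], samples: Iterable[str]) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=skimbin"]
    if lengths:
        for chrom, L in lengths.items():
            lines.append(f"##contig=<ID={chrom},length={L}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">'
    )
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    cols += list(samples)
    lines.append("\t".join(cols))
    return "\n".join(lines) + "\n"


def write_key_vcf(
    key: pd.DataFrame,
    path: str,
    p1_name: str = "P1",
    p2_name: str = "P2",
    lengths: Optional[Dict[str, int]] = None,
    depth: int = 30,
) -> None:
    """Write the parental key as a two-sample VCF (idealised depths)."""
    with open(path, "w") as fh:
        fh.write(_vcf_header(lengths, [p1_name, p2_name]))
        for row in key.itertuples(index=False):
            gts = []
            for allele in (row.p1, row.p2):
                ad = [0, 0]
                ad[allele] = depth
                gts.append(f"{allele}/{allele}:{ad[0]},{ad[1]}")
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\t"
                f"GT:AD\t{gts[0]}\t{gts[1]}\n"
            )


def write_progeny_vcf(key: pd.DataFrame, calls: pd.DataFrame, path: str,
                      lengths: Optional[Dict[str, int]] = None) -> None:
    """Write sparse coded calls as a multi-sample VCF over the key's sites.

    Codes are translated back to REF/ALT genotypes through the key (P1 means
    "carries the P1 parent's allele").  AD is taken from ad_p1/ad_p2 columns
    when present, else a single supporting read is recorded.  Sites with no
    calls in any line are written as all-missing.
    """
    lines = sorted(calls["line"].unique().tolist())
    idx_of = {l: i for i, l in enumerate(lines)}
    # map (chrom,pos) -> row of key
    key = key.reset_index(drop=True)
    has_ad = "ad_p1" in calls.columns
    cell: Dict[tuple, Dict[int, str]] = {}
    for t in calls.itertuples(index=False):
        cell.setdefault((t.chrom, t.pos), {})[idx_of[t.line]] = t
    with open(path, "w") as fh:
        fh.write(_vcf_header(lengths, lines))
        for row in key.itertuples(index=False):
            filled = cell.get((row.chrom, row.pos), {})
            fields = []
            for i in range(len(lines)):
                t = filled.get(i)
                if t is None:
                    fields.append("./.:.")
                    continue
                code = t.code
                if code == HET:
                    gt = "0/1"
                elif code == P1:
                    gt = f"{row.p1}/{row.p1}"
                else:
                    gt = f"{row.p2}/{row.p2}"
                if has_ad:
                    ad = [0, 0]
                    ad[row.p1] += int(t.ad_p1)
                    ad[row.p2] += int(t.ad_p2)
                else:
                    ad = [0, 0]
                    if code == HET:
                        ad = [1, 1]
                    elif code == P1:
                        ad[row.p1] = 1
                    else:
                        ad[row.p2] = 1
                fields.append(f"{gt}:{ad[0]},{ad[1]}")
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\t"
                f"GT:AD\t" + "\t".join(fields) + "\n"
            )


# --------------------------------------------------------------------------- #
# coded matrices, lengths, phenotypes
# --------------------------------------------------------------------------- #

def write_coded_tsv(coded: pd.DataFrame, path: str) -> None:
    out = coded[["line", "chrom", "pos"]].copy()
    out["code"] = codes_to_str_array(coded["code"].to_numpy())
    out.to_csv(path, sep="\t", index=False)


def read_coded_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"line": str, "chrom": str})
    df["code"] = str_array_to_codes(df["code"].to_numpy())
    df["pos"] = df["pos"].astype(np.int64)
    return df


def write_lengths_tsv(lengths: Dict[str, int], path: str) -> None:
    pd.DataFrame(
        {"chrom": list(lengths), "length": list(lengths.values())}
    ).to_csv(path, sep="\t", index=False)


def read_lengths_tsv(path: str) -> Dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return dict(zip(df["chrom"], df["length"].astype(int)))


def write_phenotypes_tsv(pheno: pd.DataFrame, path: str) -> None:
    pheno.to_csv(path, sep="\t", index=False)


def read_phenotypes_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"line": str, "trait": str, "year": str})


def write_json(obj, path: str) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
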