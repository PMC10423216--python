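"""Code low-coverage progeny calls against the parental key.

Each progeny genotype call is translated to the parent whose allele it
matches (P1/P2), heterozygous calls to H; sites outside the key, uncalled
sites, and third-allele noise are dropped.  Lines with excessive residual
heterozygosity are screened out before mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd

from skimbin.codes import HET, P1, P2

log = logging.getLogger(__name__)

__all__ = ["assign_parental_codes", "screen_heterozygous_lines"]


def assign_parental_codes(progeny: pd.DataFrame, key: pd.DataFrame) -> pd.DataFrame:
    """Convert progeny genotype calls into parental codes.

    ``progeny`` is long-format (line, chrom, pos, gt) with gt in
    {0 hom-ref, 1 hom-alt, 2 het} as produced by
    ``vcfio.read_progeny_vcf_calls``.  A hom call matching P1's allele codes
    P1, matching P2's allele codes P2; het calls code H.  Calls at
    coordinates absent from the key are dropped; a hom call matching neither
    key allele cannot occur for biallelic gt classes, but sites whose
    REF/ALT disagree with the key are dropped upstream.

    Returns the sparse coded matrix (line, chrom, pos, code).
    """
    merged = progeny.merge(
        key[["chrom", "pos", "p1", "p2"]], on=["chrom", "pos"], how="inner"
    )
    n_dropped = len(progeny) - len(merged)
    if n_dropped:
        log.warning("dropped %d progeny calls at coordinates outside the key", n_dropped)
    gt = merged["gt"].to_numpy()
    code = np.full(len(merged), HET, dtype=np.int8)
    hom = gt != 2
    code[hom & (gt == merged["p1"].to_numpy())] = P1
    code[hom & (gt == merged["p2"].to_numpy())] = P2
    out = merged[["line", "chrom", "pos"]].copy()
    out["code"] = code
    return out.sort_values(["line", "chrom", "pos"], kind="mergesort").reset_index(
        drop=True
    )


def screen_heterozygous_lines(
    coded: pd.DataFrame,
    max_h_fraction: float = 0.10,
    all_lines: "list[str] | None" = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Flag lines whose heterozygous-call fraction exceeds the threshold.

    In a selfed population most residual heterozygosity should have decayed;
    a line with an H fraction strictly above ``max_h_fraction`` among its
    typed sites indicates outcrossing or sample contamination and is
    removed.  A line at exactly the threshold is retained.

    Returns ``(line_qc, filtered_coded)`` where line_qc has columns
    line, n_typed, h_fraction, retained, reason.  ``all_lines`` may list the
    expected line ids so that lines with no typed site at all are still
    reported (reason "untyped") rather than silently absent.
    """
    grp = coded.groupby("line", sort=True)["code"]
    n_typed = grp.size()
    h_frac = grp.apply(lambda c: float((c == HET).mean()))
    if all_lines is not None:
        n_typed = n_typed.reindex(sorted(all_lines), fill_value=0)
        h_frac = h_frac.reindex(sorted(all_lines), fill_value=0.0)
    qc = pd.DataFrame(
        {
            "line": n_typed.index,
            "n_typed": n_typed.to_numpy(),
            "h_fraction": h_frac.to_numpy(),
        }
    ).reset_index(drop=True)
    untyped = qc["n_typed"] == 0
    too_het = qc["h_fraction"] > max_h_fraction
    qc["retained"] = ~(untyped | too_het)
    qc["reason"] = np.where(
        untyped, "untyped", np.where(too_het, "heterozygous", "")
    )
    keep = set(qc.loc[qc["retained"], "line"])
    filtered = coded[coded["line"].isin(keep)].reset_index(drop=True)
    return qc, filtered
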