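"""Integer parental-origin codes shared by every module.

Codes are stored as small ints in DataFrames/arrays: P1 and P2 are the two
parental homozygous states, HET a heterozygous call, NA missing.  TSV output
uses the strings P1/P2/H/NA (bin matrices additionally offer the A/B/H/NA
legend common in bin-map files).
"""

from __future__ import annotations

import numpy as np

P1: int = 0
P2: int = 1
HET: int = 2
NA: int = -1

_TO_STR = {P1: "P1", P2: "P2", HET: "H", NA: "NA"}
_FROM_STR = {"P1": P1, "P2": P2, "H": HET, "NA": NA, "A": P1, "B": P2}


def code_to_str(code: int) -> str:
    return _TO_STR[int(code)]


def str_to_code(s: str) -> int:
    try:
        return _FROM_STR[s]
    except KeyError:
        raise ValueError(f"unknown genotype code {s!r}") from None


def codes_to_str_array(codes: np.ndarray) -> np.ndarray:
    """Vectorised code -> string conversion."""
    out = np.empty(len(codes), dtype=object)
    for c, s in _TO_STR.items():
        out[np.asarray(codes) == c] = s
    return out


def str_array_to_codes(strings) -> np.ndarray:
    arr = np.asarray(strings, dtype=object)
    out = np.empty(len(arr), dtype=np.int8)
    seen = np.zeros(len(arr), dtype=bool)
    for s, c in _FROM_STR.items():
        m = arr == s
        out[m] = c
        seen |= m
    if not seen.all():
        bad = arr[~seen][0]
        raise ValueError(f"unknown genotype code {bad!r}")
    return out
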