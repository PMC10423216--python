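"""Roaming-score crossover-breakpoint detection.

A pair of sliding windows (default 6.5 Mb each) flanks every candidate
position; each window is classified from its typed parental-code content as
P1, P2, heterozygous (near a 1:1 ratio) or NA (too few sites).  The score of
a candidate grows with the contrast between the two windows:

    s(x) = |p_left - p_right| * sqrt(nL * nR / (nL + nR)) / sqrt(n_min)

with p the P1 proportion and n the parental-code count of each window.
Because the score is piecewise constant between typed sites, candidates are
evaluated only at midpoints between consecutive differing-code sites.  A
recursive selection keeps the highest-scoring candidates whose flanking
classes differ, suppressing neighbours within an exclusion radius; a second
pass rescans every inter-breakpoint segment with the largest window width
the surrounding accepted breakpoints allow, recovering close double
crossovers.  Transitions into or out of heterozygous regions are emitted as
state changes but excluded from crossover counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from skimbin.codes import HET, NA, P1, P2, code_to_str

__all__ = [
    "BreakpointConfig",
    "WindowProfile",
    "RecombinationSummary",
    "window_profile",
    "roaming_scan",
    "resolve_breakpoints",
    "detect_breakpoints",
    "crossovers_only",
    "summarize_recombination",
]


class BreakpointConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    window_bp: int = Field(default=6_500_000, gt=0)
    min_sites: int = Field(default=10, ge=1)
    purity: float = Field(default=0.9, gt=0.5, le=1.0)
    het_band: Tuple[float, float] = (0.4, 0.6)
    min_score: float = Field(default=0.5, ge=0.0)
    exclusion_radius: Optional[int] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "BreakpointConfig":
        lo, hi = self.het_band
        if not (0.0 < lo < hi < 1.0) or abs((lo + hi) / 2 - 0.5) > 1e-9:
            raise ValueError("het_band must be symmetric about 0.5")
        return self

    @property
    def radius(self) -> int:
        return self.exclusion_radius or self.window_bp


@dataclass
class WindowProfile:
    side: str
    n_p1: int
    n_p2: int
    p: float
    klass: int  # P1/P2/HET/NA


def _classify(n_p1: np.ndarray, n_p2: np.ndarray, cfg: BreakpointConfig, min_sites=None):
    """Vectorised four-way window classification.

    ``min_sites`` may be an array of per-window requirements (used when a
    window is truncated by the chromosome boundary); default is the
    configured minimum.
    """
    n = n_p1 + n_p2
    if min_sites is None:
        min_sites = cfg.min_sites
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.divide(n_p1, n, out=np.full(np.shape(n), np.nan), where=n > 0)
    klass = np.full(np.shape(n), NA, dtype=np.int8)
    ok = n >= min_sites
    lo, hi = cfg.het_band
    klass[ok & (p >= cfg.purity)] = P1
    klass[ok & (p <= 1.0 - cfg.purity)] = P2
    klass[ok & (p >= lo) & (p <= hi)] = HET
    return klass, p


class _LineData:
    """Prefix-count view of one line's sorted codes on one chromosome."""

    def __init__(self, positions: np.ndarray, codes: np.ndarray):
        order = np.argsort(positions, kind="mergesort")
        self.pos = positions[order].astype(np.int64)
        self.codes = codes[order]
        self.cum_p1 = np.concatenate([[0], np.cumsum(self.codes == P1)])
        self.cum_p2 = np.concatenate([[0], np.cumsum(self.codes == P2)])

    def counts(self, lo, hi):
        """Parental-code counts over the half-open-from-left interval (lo, hi]."""
        i = np.searchsorted(self.pos, lo, side="right")
        j = np.searchsorted(self.pos, hi, side="right")
        return self.cum_p1[j] - self.cum_p1[i], self.cum_p2[j] - self.cum_p2[i]


def window_profile(
    positions: np.ndarray,
    codes: np.ndarray,
    x: float,
    side: str,
    cfg: BreakpointConfig | None = None,
) -> WindowProfile:
    """Classify the window on one side of a candidate position.

    The left window covers (x - w, x], the right window (x, x + w]; counts
    run over typed P1/P2 sites only (H and other codes are ignored).
    """
    cfg = cfg or BreakpointConfig()
    d = _LineData(np.asarray(positions), np.asarray(codes))
    if side == "left":
        n1, n2 = d.counts(x - cfg.window_bp, x)
    elif side == "right":
        n1, n2 = d.counts(x, x + cfg.window_bp)
    else:
        raise ValueError("side must be 'left' or 'right'")
    klass, p = _classify(np.array(n1), np.array(n2), cfg)
    return WindowProfile(side, int(n1), int(n2), float(p), int(klass))


def _edge_min_sites(
    xs: np.ndarray, w: np.ndarray, avail: np.ndarray, cfg: BreakpointConfig
) -> np.ndarray:
    """Per-window site minimum, relaxed where the chromosome boundary
    truncates the window.

    A window that asks for width ``w`` but only has ``avail`` < w of
    chromosome to draw from cannot be held to the full minimum; the
    requirement scales with the available fraction, floored at 3 sites so a
    terminal crossover remains callable without admitting single-site noise.
    """
    frac = np.clip(np.asarray(avail, dtype=float) / np.maximum(w, 1.0), 0.0, 1.0)
    return np.maximum(np.ceil(cfg.min_sites * frac), 3.0)


def _score_candidates(
    d: _LineData,
    xs: np.ndarray,
    widths,
    cfg: BreakpointConfig,
    widths_right=None,
    chrom_length: Optional[float] = None,
) -> pd.DataFrame:
    """Windows, classes and scores at candidate positions (vectorised).

    ``widths`` (and optionally ``widths_right``) give per-candidate window
    widths for the left/right side; with ``chrom_length`` set, windows
    truncated by the chromosome boundary get a relaxed site minimum.
    """
    wL = np.broadcast_to(np.asarray(widths, dtype=float), xs.shape)
    wR = (
        np.broadcast_to(np.asarray(widths_right, dtype=float), xs.shape)
        if widths_right is not None
        else wL
    )
    iL = np.searchsorted(d.pos, xs - wL, side="right")
    im = np.searchsorted(d.pos, xs, side="right")
    iR = np.searchsorted(d.pos, xs + wR, side="right")
    nL1 = d.cum_p1[im] - d.cum_p1[iL]
    nL2 = d.cum_p2[im] - d.cum_p2[iL]
    nR1 = d.cum_p1[iR] - d.cum_p1[im]
    nR2 = d.cum_p2[iR] - d.cum_p2[im]
    if chrom_length is not None:
        mL = _edge_min_sites(xs, wL, xs, cfg)
        mR = _edge_min_sites(xs, wR, chrom_length - xs, cfg)
    else:
        mL = mR = None
    kL, pL = _classify(nL1, nL2, cfg, mL)
    kR, pR = _classify(nR1, nR2, cfg, mR)
    nL = nL1 + nL2
    nR = nR1 + nR2
    with np.errstate(invalid="ignore", divide="ignore"):
        eff = np.divide(nL * nR, nL + nR, out=np.zeros(xs.shape), where=(nL + nR) > 0)
        score = np.abs(pL - pR) * np.sqrt(eff) / np.sqrt(cfg.min_sites)
    score = np.where((kL == NA) | (kR == NA), 0.0, np.nan_to_num(score))
    return pd.DataFrame(
        {
            "x": xs,
            "n_l_p1": nL1, "n_l_p2": nL2, "p_l": pL, "class_l": kL,
            "n_r_p1": nR1, "n_r_p2": nR2, "p_r": pR, "class_r": kR,
            "score": score,
        }
    )


def roaming_scan(
    positions: np.ndarray, codes: np.ndarray, cfg: BreakpointConfig | None = None
) -> pd.DataFrame:
    """Score every candidate position on one line/chromosome.

    Candidates are midpoints between consecutive typed sites of differing
    code (the score is piecewise constant between typed sites, so these
    suffice).  Homogeneous lines yield an empty table.
    """
    cfg = cfg or BreakpointConfig()
    d = _LineData(np.asarray(positions), np.asarray(codes))
    if len(d.pos) < 2:
        return _score_candidates(d, np.empty(0), cfg.window_bp, cfg)
    diff = np.flatnonzero(d.codes[:-1] != d.codes[1:])
    xs = 0.5 * (d.pos[diff] + d.pos[diff + 1])
    return _score_candidates(d, xs, cfg.window_bp, cfg)


def _greedy_accept(
    rescored: pd.DataFrame,
    accepted_x: List[float],
    radii: np.ndarray,
    cfg: BreakpointConfig,
) -> List[int]:
    """Accept candidates highest-score-first with exclusion suppression.

    Suppression uses each *candidate's* own radius (its effective window
    width), so rescans at narrowed widths can place a breakpoint near an
    already accepted one without being vetoed by the wider first pass.
    """
    xs = rescored["x"].to_numpy()
    scores = rescored["score"].to_numpy()
    cl = rescored["class_l"].to_numpy()
    cr = rescored["class_r"].to_numpy()
    new: List[int] = []
    order = np.lexsort((xs, -scores))
    for k in order:
        if scores[k] < cfg.min_score or scores[k] <= 0:
            break
        if cl[k] == NA or cr[k] == NA or cl[k] == cr[k]:
            continue
        # strict inequality: a breakpoint exactly one effective width away
        # (the far edge of an already-resolved island) stays eligible
        r_k = float(radii[k])
        if any(abs(xs[k] - ax) < r_k for ax in accepted_x):
            continue
        accepted_x.append(float(xs[k]))
        new.append(int(k))
    return new


def resolve_breakpoints(
    candidates: pd.DataFrame,
    positions: np.ndarray,
    codes: np.ndarray,
    cfg: BreakpointConfig | None = None,
    chrom_length: Optional[int] = None,
) -> pd.DataFrame:
    """Reduce scored candidates to the final breakpoint list for one line.

    Selection is recursive over window scales.  At the full window width the
    highest-scoring candidates whose flanking window classes differ (both
    non-NA) and whose score reaches the minimum are accepted greedily,
    suppressing neighbours within the exclusion radius; every accepted
    breakpoint then bounds later searches.  The scan is repeated with the
    window width clipped to whatever the surroundings allow — the distance
    to the chromosome ends and to already accepted breakpoints — and then at
    successively halved maximum widths, which recovers double crossovers
    whose full-width windows contaminate each other and crossovers close to
    the telomeres.  Score and class thresholds are identical at every scale,
    so a narrowed acceptance still needs ``min_sites`` informative sites per
    window.

    Returns a DataFrame (left_bp, right_bp, midpoint, left_state,
    right_state, interval_bp, score) sorted by position; flanking positions
    are the last site consistent with the left class and the first site
    consistent with the right class.
    """
    cfg = cfg or BreakpointConfig()
    d = _LineData(np.asarray(positions), np.asarray(codes))
    if chrom_length is None:
        chrom_length = int(d.pos[-1]) + 1 if len(d.pos) else 0
    cands = candidates.reset_index(drop=True)
    all_x = cands["x"].to_numpy()
    accepted: List[dict] = []
    accepted_x: List[float] = []

    scale = float(cfg.window_bp)
    min_span = float(np.median(np.diff(d.pos))) if len(d.pos) > 2 else 1.0
    while scale >= max(cfg.min_sites * min_span / 2.0, 1.0):
        for _ in range(8):  # to fixpoint at this scale
            edges = [0.0] + sorted(accepted_x) + [float(chrom_length)]
            new_any = False
            for a, b in zip(edges[:-1], edges[1:]):
                inner = (all_x > a) & (all_x < b)
                if not inner.any():
                    continue
                xs = all_x[inner]
                # clip only at accepted breakpoints; the chromosome boundary
                # truncates counts naturally and relaxes the site minimum
                w_l = np.minimum(xs - a, scale) if a > 0 else np.full(xs.shape, scale)
                w_r = (
                    np.minimum(b - xs, scale)
                    if b < chrom_length
                    else np.full(xs.shape, scale)
                )
                radii = np.minimum(w_l, w_r)
                if (radii <= 0).all():
                    continue
                rescored = _score_candidates(
                    d, xs, w_l, cfg, w_r, float(chrom_length)
                )
                picked = _greedy_accept(rescored, accepted_x, radii, cfg)
                for k in picked:
                    accepted.append(dict(rescored.iloc[k]))
                    new_any = True
            if not new_any:
                break
        scale /= 1.5

    accepted = _island_rescue(d, all_x, accepted, accepted_x, cfg, float(chrom_length))

    # refinement: with the full breakpoint set known, re-derive each
    # breakpoint's flanking classes from the widest windows its accepted
    # neighbours allow; intermediate-scale acceptances may have classified a
    # half-contaminated window as heterozygous.  Breakpoints whose refined
    # classes coincide are spurious and dropped.
    for _ in range(3):
        if not accepted:
            break
        accepted.sort(key=lambda r: r["x"])
        xs = np.array([r["x"] for r in accepted])
        w = float(cfg.window_bp)
        w_l = np.minimum(np.concatenate([[w], np.diff(xs)]), w)
        w_r = np.minimum(np.concatenate([np.diff(xs), [w]]), w)
        refined = _score_candidates(d, xs, w_l, cfg, w_r, float(chrom_length))
        changed = False
        kept = []
        for r, (_, row) in zip(accepted, refined.iterrows()):
            if row["class_l"] == row["class_r"] and row["class_l"] != NA:
                changed = True
                continue  # both sides look the same: spurious
            if (
                row["class_l"] != NA
                and row["class_r"] != NA
                and (row["class_l"] != r["class_l"] or row["class_r"] != r["class_r"])
            ):
                r = dict(row)
                changed = True
            kept.append(r)
        accepted = kept
        if not changed:
            break

    rows = []
    xs_sorted = sorted(a["x"] for a in accepted)
    for a in accepted:
        if a["class_l"] == a["class_r"]:
            raise RuntimeError("inconsistent segmentation: equal flanking classes")
        x = a["x"]
        # search bounds: never cross a neighbouring accepted breakpoint
        others = [v for v in xs_sorted if v != x]
        lo = max([v for v in others if v < x], default=0.0)
        hi = min([v for v in others if v > x], default=float(chrom_length))
        left = _flank(d, x, int(a["class_l"]), "left", lo)
        right = _flank(d, x, int(a["class_r"]), "right", hi)
        rows.append(
            {
                "left_bp": left,
                "right_bp": right,
                "midpoint": (left + right) // 2,
                "left_state": int(a["class_l"]),
                "right_state": int(a["class_r"]),
                "interval_bp": right - left,
                "score": float(a["score"]),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "left_bp", "right_bp", "midpoint",
            "left_state", "right_state", "interval_bp", "score",
        ],
    )
    return out.sort_values("midpoint", kind="mergesort").reset_index(drop=True)


def _island_rescue(
    d: _LineData,
    all_x: np.ndarray,
    accepted: List[dict],
    accepted_x: List[float],
    cfg: BreakpointConfig,
    chrom_length: float,
) -> List[dict]:
    """Accept close double crossovers as candidate pairs with fitted windows.

    The scale ladder can miss an island (a short run of opposite parental
    code between two crossovers) when no rung falls between the island's
    width and the onset of contamination.  Here every candidate pair whose
    inner interval is a pure parental run of typed sites is tested with the
    windows fitted exactly to the island: outer windows at full width
    (clipped by accepted breakpoints, site minimum relaxed at chromosome
    ends), inner window the island itself.  Both outer windows must carry
    the *same* parental class, opposite to the island's — that double
    anchoring is what licenses a reduced inner site minimum (half the
    configured one, floor 3): a run of k consecutive opposite-parent calls
    inside a parental block has probability ~error^k, while the
    coin-flip runs that arise inside residual heterozygous blocks are
    rejected because their flanking windows classify heterozygous, not
    parental.  Both junctions must still clear the score threshold.
    """
    if len(all_x) < 2:
        return accepted
    w = float(cfg.window_bp)
    inner_min = max(3, cfg.min_sites // 2)
    im_all = np.searchsorted(d.pos, all_x, side="right")
    pair_rows = []
    for i in range(len(all_x) - 1):
        x1 = float(all_x[i])
        hi = int(np.searchsorted(all_x, x1 + w, side="right"))
        js = np.arange(i + 1, hi)
        if len(js) == 0:
            continue
        ni1 = d.cum_p1[im_all[js]] - d.cum_p1[im_all[i]]
        ni2 = d.cum_p2[im_all[js]] - d.cum_p2[im_all[i]]
        n_in = ni1 + ni2
        with np.errstate(invalid="ignore", divide="ignore"):
            p_in = np.divide(ni1, n_in, out=np.full(js.shape, np.nan), where=n_in > 0)
        cand = (n_in >= inner_min) & (
            (p_in >= cfg.purity) | (p_in <= 1.0 - cfg.purity)
        )
        for k in np.flatnonzero(cand):
            j = int(js[k])
            x2 = float(all_x[j])
            if any(x1 <= ax <= x2 for ax in accepted_x):
                continue
            inner_class = P1 if p_in[k] >= cfg.purity else P2
            left_acc = max((ax for ax in accepted_x if ax < x1), default=None)
            right_acc = min((ax for ax in accepted_x if ax > x2), default=None)
            w_l = w if left_acc is None else min(w, x1 - left_acc)
            w_r = w if right_acc is None else min(w, right_acc - x2)
            nl1, nl2 = d.counts(x1 - w_l, x1)
            nr1, nr2 = d.counts(x2, x2 + w_r)
            mL = float(_edge_min_sites(np.array([x1]), np.array([w_l]), np.array([x1]), cfg)[0])
            mR = float(
                _edge_min_sites(
                    np.array([x2]), np.array([w_r]), np.array([chrom_length - x2]), cfg
                )[0]
            )
            kL, pL = _classify(np.array(nl1), np.array(nl2), cfg, mL)
            kR, pR = _classify(np.array(nr1), np.array(nr2), cfg, mR)
            kL, pL, kR, pR = int(kL), float(pL), int(kR), float(pR)
            # same-parent anchoring on both sides, opposite to the island
            if kL != kR or kL not in (P1, P2) or kL == inner_class:
                continue
            nl = nl1 + nl2
            nr = nr1 + nr2
            ni = int(n_in[k])
            s1 = abs(pL - p_in[k]) * np.sqrt(nl * ni / (nl + ni)) / np.sqrt(cfg.min_sites)
            s2 = abs(p_in[k] - pR) * np.sqrt(ni * nr / (ni + nr)) / np.sqrt(cfg.min_sites)
            if min(s1, s2) < cfg.min_score:
                continue
            pair_rows.append(
                (
                    float(s1 + s2),
                    {"x": x1, "class_l": kL, "class_r": inner_class,
                     "p_l": pL, "p_r": float(p_in[k]), "score": float(s1)},
                    {"x": x2, "class_l": inner_class, "class_r": kR,
                     "p_l": float(p_in[k]), "p_r": pR, "score": float(s2)},
                )
            )
    for _, r1, r2 in sorted(pair_rows, key=lambda t: -t[0]):
        g = r2["x"] - r1["x"]
        lo, hi = r1["x"] - 0.5 * g, r2["x"] + 0.5 * g
        if any(lo <= ax <= hi for ax in accepted_x):
            continue
        accepted.append(r1)
        accepted.append(r2)
        accepted_x.extend([r1["x"], r2["x"]])
    return accepted


def _flank(d: _LineData, x: float, klass: int, side: str, bound: float) -> int:
    """Nearest typed site on one side of x consistent with the window class.

    Parental classes require a matching code; a heterozygous class accepts
    any code (an H region's typed sites are single-read parental draws).
    Falls back to the immediately adjacent site when no consistent site
    exists inside the search bound.
    """
    if side == "left":
        idx = np.arange(np.searchsorted(d.pos, x, side="right") - 1, -1, -1)
        idx = idx[d.pos[idx] > bound]
    else:
        idx = np.arange(np.searchsorted(d.pos, x, side="right"), len(d.pos))
        idx = idx[d.pos[idx] < bound]
    if len(idx) == 0:  # pathological; take nearest site regardless of bound
        i = np.searchsorted(d.pos, x, side="right")
        return int(d.pos[max(i - 1, 0)]) if side == "left" else int(d.pos[min(i, len(d.pos) - 1)])
    if klass in (P1, P2):
        match = idx[d.codes[idx] == klass]
        if len(match):
            return int(d.pos[match[0]])
    return int(d.pos[idx[0]])


def detect_breakpoints(
    coded: pd.DataFrame,
    lengths: Dict[str, int],
    cfg: BreakpointConfig | None = None,
) -> pd.DataFrame:
    """Run the roaming-score detector over every line and chromosome.

    ``coded`` is the sparse (line, chrom, pos, code) matrix.  Returns all
    detected state changes with line/chrom columns; P1<->P2 rows are the
    crossovers, H-involving rows are residual-heterozygosity boundaries.
    """
    cfg = cfg or BreakpointConfig()
    frames = []
    for (line, chrom), g in coded.groupby(["line", "chrom"], sort=True):
        pos = g["pos"].to_numpy()
        cod = g["code"].to_numpy()
        cands = roaming_scan(pos, cod, cfg)
        if cands.empty:
            continue
        bp = resolve_breakpoints(cands, pos, cod, cfg, lengths.get(chrom))
        if bp.empty:
            continue
        bp.insert(0, "chrom", chrom)
        bp.insert(0, "line", line)
        frames.append(bp)
    if not frames:
        return pd.DataFrame(
            columns=[
                "line", "chrom", "left_bp", "right_bp", "midpoint",
                "left_state", "right_state", "interval_bp", "score",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def crossovers_only(breakpoints: pd.DataFrame) -> pd.DataFrame:
    """Restrict detected state changes to parental P1<->P2 crossovers."""
    m = breakpoints["left_state"].isin([P1, P2]) & breakpoints["right_state"].isin(
        [P1, P2]
    )
    return breakpoints[m].reset_index(drop=True)


@dataclass
class RecombinationSummary:
    n_lines: int
    n_crossovers: int
    reverse_map_cm: float
    median_interval_bp: float
    mean_interval_bp: float
    histogram: Dict[str, List[int]] = field(default_factory=dict)
    n_slices: int = 20

    def to_dict(self) -> dict:
        return {
            "n_lines": self.n_lines,
            "n_crossovers": self.n_crossovers,
            "reverse_map_cm": self.reverse_map_cm,
            "median_interval_bp": self.median_interval_bp,
            "mean_interval_bp": self.mean_interval_bp,
            "n_slices": self.n_slices,
            "histogram": self.histogram,
        }


def summarize_recombination(
    breakpoints: pd.DataFrame,
    n_lines: int,
    lengths: Dict[str, int],
    n_slices: int = 20,
) -> RecombinationSummary:
    """Population recombination summary.

    The reverse genetic-map length treats each crossover as 1/n_lines of a
    recombination event per 100 map units: map_cM = 100 * B / n.  Interval
    statistics and the positional histogram (``n_slices`` equal
    chromosome-relative slices, revealing the pericentromeric desert) are
    computed over P1<->P2 crossovers only.
    """
    if n_lines <= 0:
        raise ValueError("n_lines must be positive")
    xo = crossovers_only(breakpoints) if len(breakpoints) else breakpoints
    B = len(xo)
    hist: Dict[str, List[int]] = {}
    for chrom, L in lengths.items():
        sub = xo[xo["chrom"] == chrom] if B else xo
        rel = np.clip(sub["midpoint"].to_numpy() / L, 0, 1 - 1e-12) if len(sub) else []
        counts, _ = np.histogram(rel, bins=n_slices, range=(0.0, 1.0))
        hist[chrom] = counts.astype(int).tolist()
    return RecombinationSummary(
        n_lines=n_lines,
        n_crossovers=B,
        reverse_map_cm=100.0 * B / n_lines,
        median_interval_bp=float(np.median(xo["interval_bp"])) if B else float("nan"),
        mean_interval_bp=float(np.mean(xo["interval_bp"])) if B else float("nan"),
        histogram=hist,
        n_slices=n_slices,
    )
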