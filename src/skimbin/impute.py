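"""Parental-origin HMM imputation of low-coverage genotypes.

A three-state hidden Markov model (P1, P2, H) runs along each line's typed
sites on each chromosome.  Emissions allow a genotyping-error rate; the
switch probability between the parental states over an inter-site distance
d is the map-style t(d) = (1 - exp(-2 d / D)) / 2 with the recombination
distance scale D (default 1 Mb), entry into the heterozygous state scaled
by a small prior.  The Viterbi path (deterministic, log-domain, ties broken
toward the previous state) assigns every key site inside a line's typed
span; hold-out masking of a fraction of the non-missing calls measures
imputation accuracy per line and chromosome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from skimbin.codes import HET, NA, P1, P2

__all__ = [
    "ImputeConfig",
    "HoldoutReport",
    "viterbi_decode",
    "impute_matrix",
    "holdout_accuracy",
]

_STATES = (P1, P2, HET)


class ImputeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    error_rate: float = Field(default=0.01, gt=0.0, lt=0.5)
    recomb_distance_bp: float = Field(default=1_000_000.0, gt=0.0)
    het_prior: float = Field(default=0.03, ge=0.0, lt=0.5)
    het_obs_prob: float = Field(default=0.05, gt=0.0, lt=1.0)
    resolve_conflicts: bool = True
    mask_fraction: float = Field(default=0.03, gt=0.0, lt=1.0)
    seed: int = 0


def _log_emissions(cfg: ImputeConfig) -> np.ndarray:
    """log P(observed code | state), rows = states, cols = observed P1/P2/H."""
    e = cfg.error_rate
    ph = cfg.het_obs_prob
    em = np.array(
        [
            [1.0 - e - e * e, e, e * e],          # state P1
            [e, 1.0 - e - e * e, e * e],          # state P2
            [(1 - ph) / 2, (1 - ph) / 2, ph],     # state H
        ]
    )
    return np.log(em)


def _switch_prob(d: np.ndarray, cfg: ImputeConfig) -> np.ndarray:
    """Map-style parental switch probability over distance d (bp)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d, dtype=float) / cfg.recomb_distance_bp))


def _log_transitions(d: float, cfg: ImputeConfig) -> np.ndarray:
    """3x3 log transition matrix for one inter-site gap.

    From a parental state the total switch mass t(d) splits into the other
    parent ((1 - pi_H) t) and the heterozygous state (pi_H t); from H the
    exits to each parent carry t(d) each.  Rows sum to one.
    """
    t = float(_switch_prob(d, cfg))
    pih = cfg.het_prior
    a = np.empty((3, 3))
    a[P1] = [1.0 - t, (1.0 - pih) * t, pih * t]
    a[P2] = [(1.0 - pih) * t, 1.0 - t, pih * t]
    a[HET] = [t, t, 1.0 - 2.0 * t]
    tiny = 1e-300
    return np.log(np.maximum(a, tiny))


def viterbi_decode(
    positions: np.ndarray, codes: np.ndarray, cfg: ImputeConfig | None = None
) -> np.ndarray:
    """Maximum-probability state path over one line's typed sites.

    ``positions`` must be strictly increasing; ``codes`` observed P1/P2/H.
    Uniform initial distribution; ties broken toward the previous state so
    decoding is deterministic.
    """
    cfg = cfg or ImputeConfig()
    pos = np.asarray(positions, dtype=np.int64)
    obs = np.asarray(codes)
    n = len(pos)
    if n == 0:
        raise ValueError("empty input: at least one typed site required")
    if n > 1 and not (np.diff(pos) > 0).all():
        raise ValueError("positions must be strictly increasing")
    log_em = _log_emissions(cfg)
    delta = log_em[:, obs[0]] + math.log(1.0 / 3.0)
    back = np.zeros((n, 3), dtype=np.int8)
    for i in range(1, n):
        la = _log_transitions(float(pos[i] - pos[i - 1]), cfg)
        cand = delta[:, None] + la  # cand[prev, cur]
        # argmax over prev with ties toward staying in the same state
        best_prev = cand.argmax(axis=0)
        for s in range(3):
            if cand[s, s] >= cand[best_prev[s], s] - 1e-12:
                best_prev[s] = s
        delta = cand[best_prev, np.arange(3)] + log_em[:, obs[i]]
        back[i] = best_prev
    path = np.empty(n, dtype=np.int8)
    path[-1] = int(delta.argmax())
    for i in range(n - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return path


def _fill_span(
    key_pos: np.ndarray, typed_pos: np.ndarray, states: np.ndarray,
    extrapolate: bool = False,
) -> Tuple[np.ndarray, np.ndarray]:
    """States at all key sites within the typed span.

    Between two consecutive typed sites with different decoded states the
    change is placed at their midpoint.  With ``extrapolate`` the terminal
    states are carried past the span ends (used for hold-out scoring, where
    masking may have removed a span-edge site); otherwise out-of-span
    positions are excluded.  Returns (mask_in_span, codes).
    """
    lo, hi = typed_pos[0], typed_pos[-1]
    if extrapolate:
        in_span = np.ones(len(key_pos), dtype=bool)
    else:
        in_span = (key_pos >= lo) & (key_pos <= hi)
    kp = key_pos[in_span]
    # index of the typed site governing each key position: nearest change
    right = np.searchsorted(typed_pos, kp, side="left")
    right = np.clip(right, 0, len(typed_pos) - 1)
    left = np.clip(right - 1, 0, len(typed_pos) - 1)
    exact = typed_pos[right] == kp
    take_right = exact | (
        (typed_pos[right] - kp) <= (kp - typed_pos[left])
    )
    idx = np.where(take_right, right, left)
    return in_span, states[idx]


def impute_matrix(
    coded: pd.DataFrame,
    key: pd.DataFrame,
    cfg: ImputeConfig | None = None,
) -> Tuple[pd.DataFrame, int]:
    """Impute every key site inside each line/chromosome typed span.

    Returns ``(imputed, n_conflicts)``: a long (line, chrom, pos, code)
    DataFrame covering all in-span key sites, and the number of observed
    codes that disagreed with the decoded state.  With resolve_conflicts on,
    disagreeing observations are replaced by the decoded state; off, they
    are preserved verbatim (and only counted).  Key sites outside a typed
    span remain absent (NA).
    """
    cfg = cfg or ImputeConfig()
    key_by_chrom = {c: g["pos"].to_numpy() for c, g in key.groupby("chrom", sort=False)}
    frames = []
    conflicts = 0
    for (line, chrom), g in coded.groupby(["line", "chrom"], sort=True):
        g = g.sort_values("pos", kind="mergesort")
        tpos = g["pos"].to_numpy()
        tcod = g["code"].to_numpy()
        states = viterbi_decode(tpos, tcod, cfg)
        disagreement = states != tcod
        conflicts += int(disagreement.sum())
        kp = key_by_chrom.get(chrom)
        if kp is None:
            raise ValueError(f"coded sites on chromosome {chrom!r} absent from key")
        in_span, filled = _fill_span(kp, tpos, states)
        out_pos = kp[in_span]
        out_code = filled.astype(np.int8)
        if not cfg.resolve_conflicts:
            # restore the observed codes at typed sites
            j = np.searchsorted(out_pos, tpos)
            out_code[j] = tcod
        frames.append(
            pd.DataFrame(
                {"line": line, "chrom": chrom, "pos": out_pos, "code": out_code}
            )
        )
    imputed = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["line", "chrom", "pos", "code"])
    )
    return imputed, conflicts


@dataclass
class HoldoutReport:
    """Masked-site imputation accuracy, per line/chromosome and overall."""

    per_cell: pd.DataFrame  # line, chrom, n_masked, n_correct
    mean_accuracy: float
    skipped: List[Tuple[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mean_accuracy": self.mean_accuracy,
            "n_masked_total": int(self.per_cell["n_masked"].sum()),
            "n_correct_total": int(self.per_cell["n_correct"].sum()),
            "n_skipped_cells": len(self.skipped),
        }


def holdout_accuracy(
    coded: pd.DataFrame,
    key: pd.DataFrame,
    cfg: ImputeConfig | None = None,
) -> HoldoutReport:
    """Hold-out validation: mask, impute, score.

    Independently for each line and chromosome, ``mask_fraction`` of the
    non-missing calls (floor, seeded uniform sampling) are hidden, the HMM
    is run on the remaining calls, and the decoded state at each masked
    position is compared with the original observed call.  The overall
    accuracy is the unweighted mean of per-line accuracies, each line pooling
    its chromosomes.
    """
    cfg = cfg or ImputeConfig()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 40_993]))
    rows = []
    skipped: List[Tuple[str, str]] = []
    for (line, chrom), g in coded.groupby(["line", "chrom"], sort=True):
        g = g.sort_values("pos", kind="mergesort")
        tpos = g["pos"].to_numpy()
        tcod = g["code"].to_numpy()
        n_mask = int(len(tpos) * cfg.mask_fraction)
        if n_mask < 1 or len(tpos) - n_mask < 2:
            skipped.append((line, chrom))
            continue
        mask_idx = np.sort(rng.choice(len(tpos), size=n_mask, replace=False))
        keep = np.ones(len(tpos), dtype=bool)
        keep[mask_idx] = False
        states = viterbi_decode(tpos[keep], tcod[keep], cfg)
        _, imputed = _fill_span(tpos[mask_idx], tpos[keep], states, extrapolate=True)
        imputed = imputed.astype(np.int8)
        correct = int((imputed == tcod[mask_idx]).sum())
        rows.append((line, chrom, n_mask, correct))
    per_cell = pd.DataFrame(rows, columns=["line", "chrom", "n_masked", "n_correct"])
    if per_cell.empty:
        raise ValueError("no line/chromosome had enough sites to mask")
    per_line = per_cell.groupby("line")[["n_masked", "n_correct"]].sum()
    acc = float((per_line["n_correct"] / per_line["n_masked"]).mean())
    return HoldoutReport(per_cell=per_cell, mean_accuracy=acc, skipped=skipped)
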