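"""Synthetic biparental RIL skim-seq populations with known truth.

The simulator emulates the statistical structure of a wild x domesticated
diploid selfing population genotyped by skim sequencing:

* a dense biallelic parental key (every site homozygous-different between
  the parents), placed by a Poisson process along each chromosome;
* explicit selfing from the F1 for ``g`` generations, with per-meiosis
  crossover counts Poisson in the chromosome's map length, a central
  pericentromeric "recombination desert" with zero crossover density, and
  distal (telomere-oriented Beta) crossover placement on each arm;
* Poisson read sampling at nominal coverage with a per-read error rate,
  collapsed to per-site calls (mixed-allele reads call heterozygous);
* quantitative and scored phenotypes from additive + digenic-epistatic QTL
  with year effects and Gaussian residuals.

Truth (haplotype blocks, crossover positions, realized QTL variances) is
retained per line so downstream detectors can be validated exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from skimbin.codes import HET, P1, P2

__all__ = [
    "GenomeSpec",
    "SimConfig",
    "QTLSpec",
    "TruthSet",
    "scaled_preset",
    "full_scale_preset",
    "simulate_parents",
    "simulate_ril_population",
    "simulate_skim_calls",
    "simulate_phenotypes",
    "truth_bin_genotypes",
]


# --------------------------------------------------------------------------- #
# configuration types
# --------------------------------------------------------------------------- #

class GenomeSpec(BaseModel):
    """Chromosome names/lengths, key-site density and centromere positions."""

    model_config = ConfigDict(extra="forbid")

    names: List[str]
    lengths: List[int]
    snp_density: float = Field(gt=0.0, description="key sites per base pair")
    centromeres: Optional[List[int]] = None

    @model_validator(mode="after")
    def _check(self) -> "GenomeSpec":
        if len(self.names) != len(self.lengths) or not self.names:
            raise ValueError("names and lengths must be non-empty and equal length")
        if any(L <= 0 for L in self.lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.centromeres is None:
            self.centromeres = [L // 2 for L in self.lengths]
        if len(self.centromeres) != len(self.names):
            raise ValueError("one centromere position per chromosome required")
        for c, L in zip(self.centromeres, self.lengths):
            if not 0 < c < L:
                raise ValueError("centromere position must lie inside the chromosome")
        return self

    @property
    def length_map(self) -> Dict[str, int]:
        return dict(zip(self.names, self.lengths))

    @property
    def centromere_map(self) -> Dict[str, int]:
        return dict(zip(self.names, self.centromeres))


class SimConfig(BaseModel):
    """Population and sequencing parameters for one simulated RIL panel."""

    model_config = ConfigDict(extra="forbid")

    n_lines: int = Field(default=300, ge=1)
    generations: int = Field(default=6, ge=2, description="filial generation g (F_g)")
    map_length_morgans: float = Field(default=1.0, ge=0.0)
    desert_fraction: float = Field(default=0.5, ge=0.0, lt=1.0)
    # crossover placement along each arm, 0 = telomere: Beta(a, b) with the
    # default mode near 20% of the arm, emulating distal crossover
    # localization with negligible mass at the pericentric desert edge
    arm_shape_a: float = Field(default=1.5, gt=0.0)
    arm_shape_b: float = Field(default=3.0, gt=0.0)
    coverage: float = Field(default=0.03, gt=0.0)
    read_error: float = Field(default=0.002, ge=0.0, lt=0.5)
    obligate_crossover: bool = False
    seed: int = 0


class QTLSpec(BaseModel):
    """Genetic architecture for simulated traits.

    ``loci`` are (chromosome, position) anchors; additive effects apply to the
    parental dose x in {-1, +1} (heterozygous -> 0); ``epistatic_pairs`` are
    (i, j, effect) index pairs into ``loci`` contributing effect * x_i * x_j.
    ``qualitative_thresholds`` optionally turns the latent value of a
    single-locus trait into 1/2/3 scores (e.g. coleoptile colour scoring).
    """

    model_config = ConfigDict(extra="forbid")

    loci: List[Tuple[str, int]]
    additive_effects: List[float]
    epistatic_pairs: List[Tuple[int, int, float]] = Field(default_factory=list)
    residual_sd: float = Field(default=1.0, ge=0.0)
    year_effects: Dict[str, float] = Field(default_factory=dict)
    intercept: float = 0.0
    qualitative_thresholds: Optional[List[float]] = None

    @model_validator(mode="after")
    def _check(self) -> "QTLSpec":
        if len(self.additive_effects) != len(self.loci):
            raise ValueError("one additive effect per locus required")
        k = len(self.loci)
        for i, j, _ in self.epistatic_pairs:
            if not (0 <= i < k and 0 <= j < k and i != j):
                raise ValueError("epistatic pair indices must reference distinct loci")
        return self


# --------------------------------------------------------------------------- #
# truth container
# --------------------------------------------------------------------------- #

@dataclass
class TruthSet:
    """Per-line haplotype-block truth plus phenotype bookkeeping.

    ``blocks[(line, chrom)]`` is ``(bounds, labels)``: ``bounds`` are the
    internal block boundaries in bp (strictly increasing, open interval ends),
    ``labels`` the parental-origin codes of the ``len(bounds)+1`` blocks.
    Adjacent labels always differ, and blocks tile [0, chrom length).
    """

    lines: List[str]
    genome: GenomeSpec
    config: SimConfig
    blocks: Dict[Tuple[str, str], Tuple[np.ndarray, np.ndarray]]
    phenotypes: Optional[pd.DataFrame] = None
    realized_pve: Optional[pd.DataFrame] = None
    seed: int = 0

    def state_at(self, line: str, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Parental-origin code of ``line`` at each bp position on ``chrom``."""
        bounds, labels = self.blocks[(line, chrom)]
        return labels[np.searchsorted(bounds, positions, side="right")]

    def crossovers(self, parental_only: bool = True) -> pd.DataFrame:
        """All block junctions as (line, chrom, pos, left_state, right_state).

        With ``parental_only`` the table is restricted to P1<->P2 junctions,
        the events counted as crossovers downstream; junctions into or out of
        residual-heterozygous blocks are then excluded.
        """
        rows = []
        for (line, chrom), (bounds, labels) in self.blocks.items():
            for k, pos in enumerate(bounds):
                left, right = labels[k], labels[k + 1]
                if parental_only and {left, right} != {P1, P2}:
                    continue
                rows.append((line, chrom, int(pos), int(left), int(right)))
        return pd.DataFrame(
            rows, columns=["line", "chrom", "pos", "left_state", "right_state"]
        )

    def het_fraction(self, line: str) -> float:
        """Genome fraction of ``line`` in residual heterozygous blocks."""
        het = tot = 0
        for chrom, L in self.genome.length_map.items():
            bounds, labels = self.blocks[(line, chrom)]
            edges = np.concatenate([[0], bounds, [L]])
            widths = np.diff(edges)
            het += widths[labels == HET].sum()
            tot += L
        return float(het / tot)


# --------------------------------------------------------------------------- #
# presets
# --------------------------------------------------------------------------- #

def scaled_preset() -> GenomeSpec:
    """Desk-scale default: 7 chromosomes x 100 Mb, 1 key site per 20 kb."""
    return GenomeSpec(
        names=[f"chr{i}A" for i in range(1, 8)],
        lengths=[100_000_000] * 7,
        snp_density=1.0 / 20_000,
    )


def full_scale_preset() -> GenomeSpec:
    """Full-scale preset: 7 chromosomes totalling ~5.1 Gb at ~1 site/307 bp.

    Matches the study regime (~16.6 M segregating sites over 5.1 Gb); far too
    large for routine tests and provided for completeness.
    """
    return GenomeSpec(
        names=[f"chr{i}A" for i in range(1, 8)],
        lengths=[728_600_000] * 7,
        snp_density=1.0 / 307,
    )


# --------------------------------------------------------------------------- #
# parental key
# --------------------------------------------------------------------------- #

_BASES = np.array(list("ACGT"))


def simulate_parents(
    genome: GenomeSpec,
    seed: int = 0,
    p1_ref_fraction: float = 0.875,
) -> pd.DataFrame:
    """Simulate the filtered, segregating parental variant key.

    Sites are placed by a Poisson process at ``genome.snp_density``; every
    site is homozygous-different between the parents, so any error-free read
    from a progeny line identifies its parental origin.  ``p1_ref_fraction``
    is the probability that P1 carries the reference allele, emulating a
    wild parent aligned to a wild-type reference assembly (the remaining
    sites have P1 on the alternate allele).

    Returns a DataFrame with columns chrom, pos (1-based), ref, alt, p1, p2
    where p1/p2 are allele indices (0=ref, 1=alt), sorted by chrom then pos.
    """
    rng = np.random.default_rng(seed)
    expected = genome.snp_density * sum(genome.lengths)
    if expected < 10:
        raise ValueError(
            f"degenerate genome: expected site count {expected:.1f} < 10"
        )
    frames = []
    for chrom, L in genome.length_map.items():
        n = rng.poisson(genome.snp_density * L)
        pos = np.unique(rng.integers(1, L + 1, size=n))
        ref_idx = rng.integers(0, 4, size=len(pos))
        alt_idx = (ref_idx + rng.integers(1, 4, size=len(pos))) % 4
        p1 = (rng.random(len(pos)) > p1_ref_fraction).astype(np.int8)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos.astype(np.int64),
                    "ref": _BASES[ref_idx],
                    "alt": _BASES[alt_idx],
                    "p1": p1,
                    "p2": (1 - p1).astype(np.int8),
                }
            )
        )
    key = pd.concat(frames, ignore_index=True)
    return key


# --------------------------------------------------------------------------- #
# meiosis and selfing
# --------------------------------------------------------------------------- #

def _crossover_positions(
    rng: np.random.Generator,
    L: int,
    centromere: int,
    cfg: SimConfig,
) -> np.ndarray:
    """Draw one meiosis' crossover positions on a chromosome.

    Count ~ Poisson(map length in Morgans); each position falls on an arm
    (chosen proportional to arm length outside the desert) at a Beta(a, b)
    relative position measured from the telomere, concentrating crossovers
    in the distal part of the arm with vanishing density at the
    pericentric edge.  The desert is the central ``desert_fraction`` of the
    chromosome centred on the centromere (clipped to the chromosome).
    """
    n = rng.poisson(cfg.map_length_morgans)
    if cfg.obligate_crossover and n == 0:
        n = 1
    if n == 0:
        return np.empty(0)
    half = 0.5 * cfg.desert_fraction * L
    left_hi = max(min(centromere - half, L), 0.0)
    right_lo = min(max(centromere + half, 0.0), L)
    arm_len = np.array([left_hi, L - right_lo])
    if arm_len.sum() <= 0:  # desert covers everything: no viable positions
        return np.empty(0)
    arm = rng.random(n) < arm_len[0] / arm_len.sum()
    u = rng.beta(cfg.arm_shape_a, cfg.arm_shape_b, size=n)
    pos = np.where(arm, u * arm_len[0], L - u * arm_len[1])
    return np.sort(pos)


def _segment_label(ends: np.ndarray, labels: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Label of the segment containing each x, for segments ending at ``ends``."""
    return labels[np.searchsorted(ends, x, side="right")]


def _merge(ends: np.ndarray, labels: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Coalesce adjacent equal-label segments."""
    if len(labels) <= 1:
        return ends, labels
    keep = np.flatnonzero(labels[:-1] != labels[1:])
    keep = np.append(keep, len(labels) - 1)
    return ends[keep], labels[keep]


def _recombine(
    hapA: Tuple[np.ndarray, np.ndarray],
    hapB: Tuple[np.ndarray, np.ndarray],
    xovers: np.ndarray,
    start_with_A: bool,
    L: int,
) -> Tuple[np.ndarray, np.ndarray]:
    """Form one gamete from two haplotypes given crossover positions."""
    endsA, labA = hapA
    endsB, labB = hapB
    cut = np.unique(np.concatenate([endsA[:-1], endsB[:-1], xovers]))
    cut = cut[(cut > 0) & (cut < L)]
    ends = np.append(cut, L)
    starts = np.concatenate([[0.0], cut])
    mid = 0.5 * (starts + ends)
    from_A = (np.searchsorted(xovers, mid) % 2 == 0) == start_with_A
    lab = np.where(
        from_A, _segment_label(endsA, labA, mid), _segment_label(endsB, labB, mid)
    ).astype(np.int8)
    return _merge(ends, lab)


def _genotype_blocks(
    hap0: Tuple[np.ndarray, np.ndarray],
    hap1: Tuple[np.ndarray, np.ndarray],
    L: int,
) -> Tuple[np.ndarray, np.ndarray]:
    """Diploid genotype mosaic: P1/P1 -> P1, P2/P2 -> P2, mixed -> H."""
    e0, l0 = hap0
    e1, l1 = hap1
    cut = np.unique(np.concatenate([e0[:-1], e1[:-1]]))
    ends = np.append(cut, L)
    starts = np.concatenate([[0.0], cut])
    mid = 0.5 * (starts + ends)
    a = _segment_label(e0, l0, mid)
    b = _segment_label(e1, l1, mid)
    lab = np.where(a == b, a, HET).astype(np.int8)
    ends, lab = _merge(ends, lab)
    bounds = np.round(ends[:-1]).astype(np.int64)
    # rounding can merge sub-bp segments; re-merge defensively
    keep = np.concatenate([[True], np.diff(bounds) > 0]) if len(bounds) else np.array([], bool)
    if len(bounds) and not keep.all():
        bounds = bounds[keep]
        lab = np.append(lab[:-1][keep], lab[-1])
        bounds, tail = _merge(np.append(bounds, L), lab)
        return bounds[:-1], tail
    return bounds, lab


def simulate_ril_population(key: pd.DataFrame, cfg: SimConfig, genome: GenomeSpec) -> TruthSet:
    """Self an F1 for ``cfg.generations - 1`` rounds and record block truth.

    Each line descends independently: starting from the F1 (one pure-P1 and
    one pure-P2 haplotype per chromosome), each generation draws two
    independent meioses of the current plant and selfs.  Residual
    heterozygosity therefore decays naturally as ~(1/2)^(g-1) and the
    long-run junction density approaches the selfed-RIL expectation of 2
    junctions per Morgan per chromosome.
    """
    rng = np.random.default_rng(cfg.seed)
    n_digits = max(4, len(str(cfg.n_lines)))
    lines = [f"RIL{str(i + 1).zfill(n_digits)}" for i in range(cfg.n_lines)]
    blocks: Dict[Tuple[str, str], Tuple[np.ndarray, np.ndarray]] = {}
    for chrom, L in genome.length_map.items():
        cent = genome.centromere_map[chrom]
        for line in lines:
            hap0 = (np.array([float(L)]), np.array([P1], dtype=np.int8))
            hap1 = (np.array([float(L)]), np.array([P2], dtype=np.int8))
            for _ in range(cfg.generations - 1):
                g0 = _recombine(
                    hap0, hap1, _crossover_positions(rng, L, cent, cfg),
                    bool(rng.integers(2)), L,
                )
                g1 = _recombine(
                    hap0, hap1, _crossover_positions(rng, L, cent, cfg),
                    bool(rng.integers(2)), L,
                )
                hap0, hap1 = g0, g1
            blocks[(line, chrom)] = _genotype_blocks(hap0, hap1, L)
    return TruthSet(
        lines=lines, genome=genome, config=cfg, blocks=blocks, seed=cfg.seed
    )


# --------------------------------------------------------------------------- #
# skim-seq read sampling
# --------------------------------------------------------------------------- #

def simulate_skim_calls(
    truth: TruthSet,
    key: pd.DataFrame,
    cfg: SimConfig,
    keep_read_counts: bool = False,
) -> pd.DataFrame:
    """Sample skim-seq calls: Poisson reads per site, per-read error.

    A site is called only when it receives >= 1 read.  All reads agreeing on
    one parental allele call that parent; mixed reads call heterozygous.  In
    truly heterozygous blocks each read carries either allele with equal
    probability.  Returns the sparse coded call matrix as a long DataFrame
    (line, chrom, pos, code); with ``keep_read_counts`` the per-site allele
    read depths (ad_p1, ad_p2) are included so VCF output can carry AD.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7_611]))
    eps = cfg.read_error
    out_line, out_chrom, out_pos, out_code = [], [], [], []
    out_a1, out_a2 = [], []
    by_chrom = {c: g["pos"].to_numpy() for c, g in key.groupby("chrom", sort=False)}
    for line in truth.lines:
        for chrom, pos in by_chrom.items():
            reads = rng.poisson(cfg.coverage, size=len(pos))
            typed = reads > 0
            if not typed.any():
                continue
            r = reads[typed]
            p = pos[typed]
            state = truth.state_at(line, chrom, p)
            # reads carrying the P1 allele, by true state
            n_p1 = np.empty(len(r), dtype=np.int64)
            for s, prob in ((P1, 1.0 - eps), (P2, eps), (HET, 0.5)):
                m = state == s
                if m.any():
                    n_p1[m] = rng.binomial(r[m], prob)
            code = np.full(len(r), HET, dtype=np.int8)
            code[n_p1 == r] = P1
            code[n_p1 == 0] = P2
            out_line.append(np.repeat(line, len(r)))
            out_chrom.append(np.repeat(chrom, len(r)))
            out_pos.append(p)
            out_code.append(code)
            if keep_read_counts:
                out_a1.append(n_p1)
                out_a2.append(r - n_p1)
    data = {
        "line": np.concatenate(out_line) if out_line else np.array([], object),
        "chrom": np.concatenate(out_chrom) if out_chrom else np.array([], object),
        "pos": np.concatenate(out_pos) if out_pos else np.array([], np.int64),
        "code": np.concatenate(out_code) if out_code else np.array([], np.int8),
    }
    if keep_read_counts:
        data["ad_p1"] = np.concatenate(out_a1) if out_a1 else np.array([], np.int64)
        data["ad_p2"] = np.concatenate(out_a2) if out_a2 else np.array([], np.int64)
    return pd.DataFrame(data)


# --------------------------------------------------------------------------- #
# phenotypes
# --------------------------------------------------------------------------- #

def _qtl_doses(truth: TruthSet, qtl: QTLSpec) -> np.ndarray:
    """Parental dose x in {-1, 0, +1} per line per QTL locus (P1 -> +1)."""
    lengths = truth.genome.length_map
    doses = np.empty((len(truth.lines), len(qtl.loci)))
    for k, (chrom, pos) in enumerate(qtl.loci):
        if chrom not in lengths:
            raise ValueError(f"QTL locus on unknown chromosome {chrom!r}")
        if not 1 <= pos <= lengths[chrom]:
            raise ValueError(f"QTL locus {chrom}:{pos} outside the chromosome")
        for i, line in enumerate(truth.lines):
            s = truth.state_at(line, chrom, np.array([pos]))[0]
            doses[i, k] = {P1: 1.0, P2: -1.0, HET: 0.0}[int(s)]
    return doses


def simulate_phenotypes(
    truth: TruthSet,
    qtl: QTLSpec,
    seed: int = 0,
    trait: str = "trait",
    years: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Additive + digenic-epistatic phenotypes with year effects.

    y = mu + sum_k a_k x_k + sum_(i,j) aa_ij x_i x_j + year + N(0, sigma^2).
    With ``qualitative_thresholds`` the latent y is cut into ordinal scores
    1..(len(thresholds)+1), emulating visually scored traits.  Realized
    per-locus variance explained (on the latent genetic scale, against total
    phenotypic variance of the first year) is stored in ``truth.realized_pve``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 22_993]))
    doses = _qtl_doses(truth, qtl)
    genetic = qtl.intercept + doses @ np.asarray(qtl.additive_effects)
    for i, j, eff in qtl.epistatic_pairs:
        genetic = genetic + eff * doses[:, i] * doses[:, j]
    if years is None:
        years = list(qtl.year_effects) or ["Y1"]
    rows = []
    var_y_ref = None
    for year in years:
        y = (
            genetic
            + qtl.year_effects.get(year, 0.0)
            + rng.normal(0.0, qtl.residual_sd, size=len(genetic))
        )
        if var_y_ref is None:
            var_y_ref = float(np.var(y))
        if qtl.qualitative_thresholds is not None:
            y = 1.0 + np.searchsorted(qtl.qualitative_thresholds, y)
        rows.append(
            pd.DataFrame(
                {"line": truth.lines, "trait": trait, "year": year, "value": y}
            )
        )
    pheno = pd.concat(rows, ignore_index=True)
    pve_rows = []
    for k, (chrom, pos) in enumerate(qtl.loci):
        a = qtl.additive_effects[k]
        v_locus = a * a * float(np.var(doses[:, k]))
        pve_rows.append(
            {
                "trait": trait,
                "chrom": chrom,
                "pos": pos,
                "effect": a,
                "realized_pve": v_locus / var_y_ref if var_y_ref else np.nan,
            }
        )
    pve = pd.DataFrame(pve_rows)
    truth.realized_pve = (
        pve if truth.realized_pve is None
        else pd.concat([truth.realized_pve, pve], ignore_index=True)
    )
    truth.phenotypes = (
        pheno if truth.phenotypes is None
        else pd.concat([truth.phenotypes, pheno], ignore_index=True)
    )
    return pheno


# --------------------------------------------------------------------------- #
# truth helpers for downstream tests
# --------------------------------------------------------------------------- #

def truth_bin_genotypes(truth: TruthSet, bin_size: int = 1_000_000) -> pd.DataFrame:
    """Noise-free bin genotypes straight from the truth blocks.

    Each bin takes the state of its midpoint (bins are far smaller than
    blocks outside breakpoint bins).  Wide DataFrame lines x "chrom:start"
    with codes; used as the idealised genotype matrix in trait-scan tests.
    """
    cols = {}
    for chrom, L in truth.genome.length_map.items():
        starts = np.arange(0, L, bin_size)
        mids = np.minimum(starts + bin_size // 2, L - 1)
        mat = np.empty((len(truth.lines), len(starts)), dtype=np.int8)
        for i, line in enumerate(truth.lines):
            mat[i] = truth.state_at(line, chrom, mids)
        for j, s in enumerate(starts):
            cols[f"{chrom}:{s}"] = mat[:, j]
    return pd.DataFrame(cols, index=pd.Index(truth.lines, name="line"))
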