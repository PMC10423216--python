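# Methods

## Setting

A biparental recombinant inbred line (RIL) population descends from the F1
of two inbred parents by repeated selfing; each line's genome is a mosaic
of the two parental haplotypes separated by crossover junctions, with a
small residue of heterozygosity (≈ (1/2)^(g−1) at filial generation g).
Skim sequencing types each line at a sparse random subset of the parental
variant sites — at 0.03× about 3% of sites, nearly always by a single
read — so every per-site call is error-prone and almost all sites are
missing. The package recovers line genotypes, crossovers, a genetic map
and trait associations from this regime, and ships a simulator that
generates the regime with known truth.

## Parental key

A site enters the key only if both parents are homozygous, non-missing,
have total filtered depth in [6, 100] and at least 3 reads supporting the
called allele, and carry different alleles. The supporting-allele rule is
applied to each parent's *called* allele; stray reads of the other allele
do not rescue an otherwise failing site. The literal alternative — both
allele depths ≥ 3 within one sample — would describe a heterozygote and
contradict the removal of heterozygous calls, so it is not used.
Multi-allelic and indel records are dropped. Every retained site is
informative: one error-free progeny read identifies its parental origin.

## Bin consensus

Non-overlapping 1-Mb windows (0-based half-open starts, final partial bin
kept) collapse the sparse site codes: with nP1 and nP2 parental-coded
sites in a window and p = nP1/(nP1+nP2), the window is P1 if p ≥ 0.7, P2
if 1−p ≥ 0.7, otherwise H. The threshold is interpreted as a *proportion*;
reading it as the raw ratio nP1/nP2 ≥ 0.7 would let both directions hold at
once. Windows with fewer than 5 informative sites are NA (the study's
regime averages ~52 typed sites/Mb/line, so this leaves well under 10% of
bins NA at the shipped presets); a window with more observed H calls than
parental calls is coded H rather than forced to a parent.

## Roaming-score breakpoint detection

Candidates are midpoints between consecutive typed sites of differing
code — sufficient because window contents, hence the score, are piecewise
constant between typed sites. Each side's window (default w = 6.5 Mb)
is classified from its parental-site content: P1 if p ≥ 0.9, P2 if
p ≤ 0.1, H if p ∈ [0.4, 0.6] ("close to a 1:1 ratio"), NA if fewer than
n_min = 10 sites or p in between. The score contrasts the two windows,

    s(x) = |p_L − p_R| · sqrt(n_L·n_R/(n_L+n_R)) / sqrt(n_min),

so a clean switch with both windows at n_min sites scores ~0.7 and the
acceptance floor is s_min = 0.5. The exact scoring function used in the
original pipeline is not public; this contrast statistic implements its
stated property (the greater the difference between the window contents,
the higher the score) and every constant is exposed in `BreakpointConfig`.

Selection is recursive over window scales. At the full width, candidates
are accepted greedily by score (differing, non-NA flanking classes;
score ≥ s_min), suppressing others within one effective window width.
The scan is then repeated with windows clipped at accepted breakpoints
and at successively reduced maximum widths (factor 1.5 per rung, down to
~n_min typed-site spacings), which resolves double crossovers whose
full-width windows contaminate each other. Three boundary refinements:

* windows truncated by a *chromosome end* keep their nominal width but
  have the site minimum scaled by the available fraction (floor 3 sites),
  so terminal crossovers with fewer than n_min distal sites remain
  callable without admitting single-site noise;
* an explicit island rescue evaluates every candidate pair whose inner
  interval is a pure parental run flanked on both sides by the *same*
  opposite parental class; the double anchoring licenses an inner run
  minimum of n_min/2 (floor 3), since a k-site opposite run inside a
  parental block has probability ~ε^k while the coin-flip runs inside
  residual heterozygous blocks are rejected by their H-classified flanks;
* a final pass re-derives each breakpoint's flanking classes with the
  widest windows its accepted neighbours allow, correcting
  intermediate-scale acceptances whose half-contaminated window had
  classified H, and dropping breakpoints whose two refined flanks agree.

Transitions into or out of H regions are reported as state changes but
excluded from crossover counts: in a selfed population an H-block boundary
marks residual heterozygosity, not a meiotic crossover. Each crossover is
delimited by the last left-consistent and first right-consistent typed
sites; the interval between them is its localization uncertainty. The
reverse genetic-map length is 100·B/n cM for B crossovers in n lines,
reported on the observed (uncorrected) RIL scale.

## HMM imputation

A 3-state HMM (P1, P2, H) runs along each line's typed sites per
chromosome. Emissions allow a genotyping error ε̂ (default 0.01 — kept
deliberately distinct from the simulator's true per-read error of 0.002 so
that tests exercise model misspecification): P(P1|P1) = 1−ε̂−ε̂²,
P(P2|P1) = ε̂, P(H|P1) = ε̂²; the H state emits each parental code with
probability (1−p_H)/2 and an observed H with p_H = 0.05 (an observed H
needs ≥ 2 reads, rare at skim coverage). Transitions over an inter-site
gap d use the map-style switch probability t(d) = ½(1 − e^(−2d/D)) with
the recombination distance scale D = 1 Mb; from a parental state the
switch mass splits (1−π_H) to the other parent and π_H = 0.03 (the F6
residual-heterozygosity expectation) into H, and H exits to either parent
with t(d). Viterbi decoding (log domain, ties broken toward the previous
state) gives hard assignments; replacing observed codes that contradict
the decoded state is the resolve-conflicts behaviour and is on by default.
Sites between typed sites take the nearest typed site's decoded state
(equivalently, state changes are placed at gap midpoints); sites outside a
line's typed span stay missing in matrix imputation, while hold-out
scoring extrapolates the terminal states (masking may have removed a
span-edge site, and refusing to impute there would score an artificial
error). A forward pass with 3 states over ~10⁵ sites per line is linear
time; the whole hold-out validation of a 200-line panel takes seconds.

Hold-out validation masks ⌊3%⌋ of each line's non-missing calls per
chromosome (seeded, uniform), re-imputes, and scores the masked positions
against the original observed calls; overall accuracy is the unweighted
mean of per-line accuracies. Note the ceiling is below 1: masked calls
inside residual heterozygous blocks are single-read coin flips that no
imputer can reproduce, and masked calls that were themselves read errors
score as failures. Under the skim regime (19-kb typed spacing analogue)
the measured accuracy is ~96–98%.

## Genetic map

Bin markers are dropped for segregation distortion (1-df χ² of P1:P2 line
counts against 1:1, P < 0.001, H/NA excluded) or missingness > 20%.
Adjacent retained bins give the observed recombination fraction R
(differing non-missing, non-H codes; capped at 0.4999), corrected to the
meiotic fraction by the selfed-RIL relation r = R/(2(1−R)) and converted
with Kosambi d = 25·ln((1+2r)/(1−2r)) cM. Physical (assembly) bin order
is used throughout — the bins are anchored coordinates, so de novo linkage
grouping and marker ordering are out of scope. Totals are reported with
and without the RIL correction. At finite g the observed R has not yet
reached its fixation value (ratio ≈ 1−2^(1−g)), so corrected map totals
from an F6 run ~10–13% below the generating length; tests allow for this.

## Trait scans

Single-marker regression on the 1-Mb bins stands in for composite interval
mapping: at this marker density adjacent-bin recombination is ~1%, so an
interval model adds little, and a biparental RIL panel has no population
structure beyond genome-wide relatedness, which genome-wide permutation
thresholds absorb. Genotypes are coded P1 → +1, P2 → −1 with H excluded
(default) or 0; LOD = (n/2)·log10(RSS₀/RSS₁), capped at 300 when RSS₁ = 0;
PVE = 1 − RSS₁/RSS₀; the genome-wide threshold is the ⌈(1−α)P⌉-th order
statistic of per-permutation maximum LODs (α = 0.05, P = 1000 by default);
PVE > 10% flags a major QTL. Multi-QTL traits make single-marker PVE an
overestimate of any one locus's ICIM-style PVE; this is a documented
limitation, not reconciled. Digenic epistasis is a per-pair F-test of
y ~ g₁ + g₂ + g₁g₂ against the additive model on candidate bins, reporting
the interaction sign. The site-level association scan takes a seeded
uniform subsample (default 10%) of imputed sites, fits the same per-site
regression, and controls FDR by Benjamini–Hochberg at q ≤ 0.05.
Qualitative scored traits (1/2/3) run through the same linear model.
Pooled phenotypes are per-line means over years.

## Simulator

The simulator is first-class code with the study conditions as defaults:

* **Genome presets.** Scaled-down: 7 chromosomes × 100 Mb, key density
  1 site/20 kb, 300 lines — small enough for tests while keeping ≥ 10⁴
  key sites per chromosome. Full-scale (7 × 728.6 Mb at 1 site/307 bp,
  ~16.6 M sites over 5.1 Gb) is available but not used in tests.
* **Meiosis.** Per-chromosome crossover count ~ Poisson(L) with L the map
  length in Morgans (no interference; an obligate-crossover flag exists
  but is off by default since the generating process is not documented).
  Positions avoid a central desert (default 50% of the chromosome centred
  on the centromere) and fall on an arm at a Beta(1.5, 3) relative
  position measured from the telomere — mode ≈ 20% of the arm, matching
  distal crossover localization with vanishing density at the
  pericentric edge. A symmetric per-arm placement was rejected because it
  piles crossovers against the desert boundary, creating sub-resolution
  crossover clusters real data does not show.
* **Selfing.** Explicit, two independent meioses per generation per line,
  default to F6; residual heterozygosity and the selfed-RIL junction
  density (→ 2 junctions per Morgan per chromosome as g grows; verified
  against that closed form within Monte-Carlo error) emerge rather than
  being sampled from their asymptotic distributions.
* **Reads.** Per site per line, reads ~ Poisson(coverage); each read
  reports the true allele with probability 1−ε (default ε = 0.002); a
  site is called only with ≥ 1 read; mixed reads call H; in true H blocks
  each read draws either allele equally. Missingness is e^(−coverage) in
  expectation.
* **Phenotypes.** y = μ + Σaₖxₖ + Σ(aa)ᵢⱼxᵢxⱼ + year + N(0, σ²) with
  x ∈ {−1, +1}, H → 0; qualitative traits threshold the latent value into
  1/2/3 scores; realized per-locus PVE is recorded in the truth set.
* **Determinism.** All randomness flows from one integer seed through
  split seed sequences; identical seeds reproduce byte-identical outputs.

What the simulator does **not** emulate: alignment artifacts and
reference bias (the real data aligns asymmetrically to the two parental
assemblies), locally varying SNP density, segregation distortion,
gene conversion, and crossover interference. Passing tests therefore
demonstrate correctness of the pipeline's statistics under the stated
generative model, not robustness to alignment-level artifacts.

## Problem sizes used in validation

Test and acceptance runs use desk-scale versions of the study regime,
chosen by matching the *information content* the methods see rather than
raw genome size:

* Imputation hold-out: 200 lines × 2 × 100 Mb at 0.03×, key 1/20 kb —
  the study's per-line typed-site spacing regime (~19 kb scaled) with ~2
  crossovers per chromosome.
* Breakpoint intervals: 300 lines × 2 × 300 Mb, key 1/3.5 kb at 0.2× —
  typed informative sites every ~19 kb, as in the study.
* Breakpoint detection properties: the scaled preset at 0.65× coverage.
  The detector's windows see typed sites per window: the study's 19-kb
  spacing gives ~340 sites per 6.5-Mb window, while the scaled key at
  0.03× would give ~10 (every window at the NA floor). 0.65× on the
  1/20-kb key (~150 sites/window) is the closest the preset allows.
* Statistical calibration: 20,000 null bins for the distortion filter;
  100 null scan replicates at 200 permutations each.
* QTL recovery: 20 replicates, 600 lines, additive PVE 0.20, locus drawn
  per replicate from the recombining distal region — localization to
  ±2 Mb is a linkage property and is undefined inside the desert, where
  all bins are perfectly correlated.

## Known limitations

* The roaming score is a reimplementation of an undocumented statistic;
  only its qualitative contract is matched.
* Crossovers with fewer than ~3 typed sites beyond them (extreme
  telomeres) or islands of fewer than ~n_min/2 sites are below the
  detector's information floor and are missed; at the shipped presets
  this is ~2–3% of true junctions.
* The HMM is a functional stand-in for pedigree-aware low-coverage
  imputers, not a bit-exact replacement.
* Hold-out accuracy is bounded away from 1 by design (heterozygous-block
  coin flips, masked read errors).
* Single-marker scans do not provide ICIM-style multi-QTL PVE estimates.
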