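# Methods

## Model

A *composite element* is modeled as a pair of position weight matrices
(PWMs) whose binding sites co-occur at a preferred edge-to-edge distance
and relative orientation. The pipeline reduces a ChIP-Seq experiment to a
set of fixed-width windows anchored on the ChIP'd factor's own motif (the
*primary*), and asks, for every candidate partner motif (the
*secondary*), whether the location of its best site relative to the
anchor is more concentrated than a uniform-placement null allows.

### Scoring

Motifs are column-stochastic position frequency matrices (PFMs) over
A,C,G,T. Scanning uses the log-odds PWM

    pwm[i, b] = log2( p'[i, b] / bg[b] ),
    p'[i, b]  = (pfm[i, b] + c · bg[b]) / (1 + c)

with pseudocount fraction `c = 0.01` (probability-space smoothing toward
the background, so zero PFM entries stay finite) and a 4-vector
background `bg`. A site's score is the column sum over its bases; `N`
bases score their background expectation (zero mean contribution). Both
strands are always scanned; a minus-strand site at start *p* is a
forward hit of the reverse-complement PWM at *p*.

### Window anchoring

Each summit-centered window keeps its single best primary match if that
match scores at least `min_score_frac` (default 0.6) of the motif's
maximum achievable log-odds score; other windows are eliminated. The
0.6 fraction is a conventional relative PWM threshold — strict enough to
reject background yet insensitive to motif width; it is configurable. The
window is then reverse-complemented if the match is on the minus strand
and trimmed symmetrically to the shorter flank, leaving the site exactly
centered (windows are never padded, so off-center matches give shorter
windows; windows whose flanks cannot hold the secondary motif drop out).

### Spacing statistics

For each secondary motif, every centered window contributes exactly one
observation: the best-scoring site over both strands and all start
positions whose span does not overlap the primary site. No score
threshold is applied at this stage — this is deliberate, because the null
model below assumes one placement per window. The observation is a 1-bp
*spacing bin*: a quadrant (upstream/downstream × same/opposite strand)
plus the edge-to-edge gap (gap 0 = abutting). For self-pairing
(secondary = primary, as in tetramer detection) the anchor's own site is
excluded by the same overlap rule.

Under the null of no spacing preference, the best site is equally likely
to land in any of the `B` geometrically available bins, so the count `k`
in a bin out of `n` contributing windows is Binomial(n, 1/B). Occupied
bins receive the exact upper tail `P[X ≥ k]` (direct pmf summation, not a
normal approximation), Bonferroni-adjusted by `B`. The pair's E-value is
its best adjusted p-value times the number of secondary motifs in the
database — a second Bonferroni level that makes E-values comparable
across motifs of different widths (hence different `B`) and across
databases. E-values are not capped above 1 and are floored at 1e-300 so
−log10 transforms stay finite. `B` is computed from the widest retained
flank; with the synthetic generator's default geometry (no jitter) every
window has the same flank and the count is exact.

Pairs passing adjusted p < 0.01 are ranked; redundant secondaries
(paralog PFMs such as the ETS family) are merged by single-linkage
clustering at Pearson ≥ 0.8 between aligned PFMs (best ungapped offset,
both orientations, ≥ 5 aligned columns), each cluster represented by its
most significant member. Many libraries aggregate into a sparse
interaction matrix of E-values; the default report filters at
E < 1e-10 and drops empty rows/columns before rendering.

### Determinism and tie-breaking

All ties are broken deterministically, and deliberately in a way that
commutes with reverse-complementing the input. Reverse-complementing a
centered window maps each quadrant to its mirror image (side and strand
both flip): downstream-same ↔ upstream-opposite and upstream-same ↔
downstream-opposite. Secondary-site ties therefore break by smaller gap,
then mirror class ({downstream-same, upstream-opposite} first), then a
fixed member of the class; primary-match ties break by distance of the
site midpoint from the window center, then a mirror-invariant
offset-sign/strand class, then strand and position. A simpler "leftmost,
plus-strand first" rule would make results depend on which strand the
input FASTA happens to report — with these rules the pipeline's output
(gaps, p-values, E-values) is exactly invariant under
reverse-complementing every input window, and the test suite asserts
this. One visible consequence: for a palindromic anchor such as AP-1's
TGASTCA the orientation is intrinsically ambiguous, and the class rule
resolves it consistently, concentrating a planted signal into a single
quadrant rather than splitting it between the two mirror images.

## De novo discovery

The primary motif can be discovered rather than supplied. The model is
ZOOPS: a window contains no site (probability 1 − γ) or exactly one site
uniform over all positions and strands. Discovery seeds EM with the most
over-represented k-mers (counts merged with reverse complements, ranked
by log2((obs + 0.5)/(exp + 0.5)) against the 0-order background estimated
from the windows). Each seed initializes a PFM at 0.55 match probability
and γ = 0.5; EM then alternates exact posterior site assignment with PFM
and γ re-estimation until the log-likelihood improves by less than `tol`
(default 1e-4) or `max_iter` (default 100) updates. The M-step is maximum
likelihood with a 1e-6 numerical floor, so the observed-data
log-likelihood is non-decreasing (asserted in tests). Candidates from all
seeds (optionally over several widths) are deduplicated at PFM
correlation ≥ 0.9 and ranked by the log-likelihood-ratio score against
the background-only model. Only ZOOPS is implemented (no OOPS/ANR): ChIP
summits are expected to harbor at most one anchor site.

Two honest caveats, both visible in the tests: the top seed's
over-representation ratio is an extreme-value statistic over ~32k
canonical 8-mers, so even on pure noise it sits near 2 bits (a planted
motif clears it by a wide margin); and unpenalized ZOOPS EM on noise will
fit *some* weak pattern, drifting γ upward — the reliable null
discriminator is the likelihood-ratio score per window, which stays near
zero, not the site prior.

## Synthetic data

The generator emulates the structure the pipeline assumes: windows of
background sequence (i.i.d. mononucleotide, uniform by default, with
GC-skew and order-1 Markov options) with a primary site planted at the
center (± optional jitter) on a random strand, and, in `plant_fraction`
of windows, a secondary site at an exact edge-to-edge gap in a chosen
quadrant relative to the primary's orientation. Sites are sampled
column-wise from the PFM by default, so degenerate consensus positions
vary and score thresholds are genuinely exercised; `consensus_only`
plants literal consensus strings for fully deterministic tests. Every
window carries a truth record, and generation is byte-reproducible given
the seed.

Presets encode classic composites: AICE (AP-1 `TGASTCA` + IRF half-site
`TGAAAC`, gap 4 or 0), tandem GAS sites (`TTCNNNGAA`, self-pair, gap 11)
and CTCF/ETS (`CCACNAGGTGGCAG` + `ACAGGAAGT`, gap 8). Defaults: 500-bp
windows, 1000 windows, 60 % plant fraction, no jitter. What the generator
does **not** emulate: real peak-calling noise, summit mislocalization,
sequence composition heterogeneity, repeats, and correlated co-binding of
more than two factors — so passing recovery tests demonstrates the
statistics and bookkeeping are right, not that any particular biological
dataset will yield a given partner.

## Problem sizes and numerical choices

The shipped validation runs use 1000-window datasets for spacing
recovery and 500 null replicates of 500 windows each for calibration —
comfortably enough for the planted effects (hundreds of counts in a
single 1-bp bin against an expectation near 1) while keeping the whole
validation suite to a few minutes on one core. Binomial tails are summed
directly from log-pmf values (exact to floating point; verified against
rational arithmetic to 1e-9 relative error up to n = 5000) and floored
at 1e-300. Degenerate inputs are defined rather than accidental: windows
shorter than the motif yield no match; a window with no legal secondary
placement contributes nothing; a screen retaining zero windows returns an
empty-result flag instead of raising; B = 0 or an empty window set is an
error.

## Known limitations

- The uniform-placement null ignores sequence composition: a GC-rich
  secondary motif in GC-heterogeneous real flanks can deviate from
  uniform placement without any cooperative binding. The Bonferroni ×
  discrete-binomial combination is conservative (measured false-positive
  rate 0/500 at the 0.01 threshold), which trades power for safety.
- With jittered primaries, windows shrink asymmetrically and `B` from the
  widest flank slightly overstates the bin universe for shorter windows,
  adding further conservatism.
- The EM stage ranks by likelihood-ratio score, not a calibrated
  significance; it is a ranking device for choosing the anchor, and a
  user-supplied primary bypasses it entirely.
- Motif-family grouping is by matrix similarity, not curated family
  annotation; an optional user family map can substitute.
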