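"""Spacing analysis of primary/secondary motif pairs.

This is the heart of the pipeline.  For each summit-centered window the
best match to the primary motif (over both strands) is found; windows
without a sufficiently strong match are discarded.  Each retained window
is re-oriented so the primary site reads on the forward strand and trimmed
symmetrically so the site sits exactly at the window center.  The single
best secondary-motif site in the flanks (never overlapping the primary
site) is then recorded as a 1-bp spacing bin: an orientation quadrant
(upstream/downstream x same/opposite strand) plus the edge-to-edge gap in
bp, where gap 0 means the two sites abut.

Under the null hypothesis of no spacing preference the best secondary site
falls uniformly over the B available (quadrant, gap) bins, so the count k
in a bin out of n contributing windows is Binomial(n, 1/B).  Each occupied
bin receives an exact binomial tail p-value P[X >= k], Bonferroni-adjusted
by the number of bins tested; a motif pair's E-value is its best adjusted
p-value times the number of secondary motifs in the database, making
E-values comparable across a database screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .motif_io import ALPHABET, MotifDatabase, MotifModel, reverse_complement
from .peaks_io import SequenceWindow

QUADRANTS = (
    "upstream-same",
    "upstream-opposite",
    "downstream-same",
    "downstream-opposite",
)

# Tie-break order over quadrants.  Reverse-complementing a centered window
# maps each quadrant to its mirror image (side and strand both flip):
# downstream-same <-> upstream-opposite and upstream-same <-> downstream-
# opposite.  Ranking the two mirror classes before the member within each
# class makes every tie-break commute with that mirror map, so pipeline
# results are exactly invariant under reverse-complementing the input.
_QUADRANT_RANK = {
    "downstream-same": 0,
    "upstream-opposite": 1,
    "upstream-same": 2,
    "downstream-opposite": 3,
}

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT_CODE = np.array([3, 2, 1, 0, 4], dtype=np.int8)


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes A=0 C=1 G=2 T=3, other=4 (N)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT_CODE[codes[::-1]]


def revcomp_str(seq: str) -> str:
    table = str.maketrans("ACGTNacgtn", "TGCANtgcan")
    return seq.translate(table)[::-1]


def _scoring_matrix(motif: MotifModel) -> np.ndarray:
    """(width, 5) PWM with an N column scored at its background expectation."""
    n_col = (motif.pwm * motif.background).sum(axis=1, keepdims=True)
    return np.hstack([motif.pwm, n_col])


def sliding_scores(motif: MotifModel, codes: np.ndarray) -> np.ndarray:
    """Log-odds score of the motif at every start position of ``codes``.

    Returns an array of length ``len(codes) - width + 1`` (empty if the
    sequence is shorter than the motif).
    """
    w = motif.width
    L = codes.shape[0]
    if L < w:
        return np.empty(0)
    sm = _scoring_matrix(motif)
    out = np.zeros(L - w + 1)
    for i in range(w):
        out += sm[i, codes[i : i + L - w + 1]]
    return out


@dataclass(frozen=True)
class PrimaryMatch:
    """Best primary-motif site in one window."""

    window_id: str
    position: int  # 0-based start within the window
    strand: str  # '+' or '-'
    score: float


@dataclass(frozen=True)
class CenteredWindow:
    """A window re-oriented and trimmed around its primary-motif site.

    ``seq`` reads the primary site on the forward strand at
    ``primary_span = [p_start, p_end)``, centered so both flanks have equal
    length (the shorter original flank sets the trim, so len(seq) <= W).
    """

    id: str
    seq: str
    primary_span: tuple[int, int]

    @property
    def flank(self) -> int:
        return self.primary_span[0]


@dataclass(frozen=True)
class SpacingBin:
    """One (orientation quadrant, edge-to-edge gap) spacing bin."""

    quadrant: str
    gap: int

    def __post_init__(self) -> None:
        if self.quadrant not in QUADRANTS:
            raise ValueError(f"unknown quadrant {self.quadrant!r}")
        if self.gap < 0:
            raise ValueError("gap must be >= 0")

    @property
    def sort_key(self) -> tuple[int, int]:
        return (self.gap, _QUADRANT_RANK[self.quadrant])


@dataclass
class SpacingHistogram:
    """Counts of best secondary-site placements per spacing bin."""

    counts: dict[SpacingBin, int]
    n: int  # windows contributing a legal secondary site
    B: int  # number of available (quadrant, gap) bins

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n:
            raise ValueError("histogram counts must sum to n")


@dataclass(frozen=True)
class SpacingTestResult:
    bin: SpacingBin
    k: int
    p_raw: float
    p_adj: float


@dataclass
class PairResult:
    """Spacing analysis of one primary x secondary motif pair."""

    primary_name: str
    secondary_name: str
    best: SpacingTestResult | None
    evalue: float | None
    n: int
    histogram: SpacingHistogram | None = None
    tests: list[SpacingTestResult] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return self.best is None


@dataclass(frozen=True)
class SpacingConfig:
    """Knobs for the spacing scan.

    min_score_frac
        Primary-match threshold as a fraction of the motif's maximum
        achievable log-odds score (windows scoring below are eliminated).
    margin
        Restrict the secondary scan to at most this many bp of gap on each
        side of the primary site; None scans the whole retained window.
    pool_quadrants
        Pool the four orientation quadrants into gap-only bins before
        testing.
    """

    min_score_frac: float = 0.6
    margin: int | None = None
    pool_quadrants: bool = False


def find_best_primary(
    window: SequenceWindow, primary: MotifModel, min_score: float | None = None
) -> PrimaryMatch | None:
    """The single best primary-motif site over both strands, or None.

    ``min_score`` is an absolute log-odds threshold; when None it defaults
    to 60% of the motif's maximum achievable score.  Ties between
    equal-scoring sites break toward the site closest to the window
    center, with the remaining keys chosen so that the same physical site
    wins after reverse-complementing the window (results are then exactly
    strand-invariant); the final fallbacks are '+' strand and leftmost
    position.
    """
    if primary.width > window.width:
        return None
    if min_score is None:
        min_score = 0.6 * primary.max_score
    codes = encode_sequence(window.seq)
    fwd = sliding_scores(primary, codes)
    # a '-'-strand site at start p is a forward hit of the reverse-complement
    # motif at the same start
    rev = sliding_scores(reverse_complement(primary), codes)
    best = max(fwd.max(), rev.max())
    if best < min_score:
        return None

    def key(pos: int, strand: str):
        # offset of the site midpoint from the window midpoint; a site at
        # (pos, s) appears at (-c, flipped s) after reverse-complementing,
        # so |c| and the (sign(c) == strand) class are mirror-invariant
        c = pos + primary.width / 2.0 - window.width / 2.0
        if c == 0:
            cls = 0
        else:
            cls = 0 if (c > 0) == (strand == "+") else 1
        return (abs(c), cls, strand != "+", pos)

    candidates = [(int(p), "+") for p in np.flatnonzero(fwd == best)]
    candidates += [(int(p), "-") for p in np.flatnonzero(rev == best)]
    pos, strand = min(candidates, key=lambda t: key(*t))
    return PrimaryMatch(window.id, pos, strand, float(best))


def center_and_orient(
    window: SequenceWindow, match: PrimaryMatch, primary_width: int
) -> CenteredWindow:
    """Re-orient and trim a window around its primary site.

    Minus-strand matches are reverse-complemented first so the site reads
    forward.  The window is then trimmed symmetrically to the shorter flank
    so the site midpoint coincides with the window midpoint; nothing is
    padded, so the result can be shorter than the input.
    """
    seq = window.seq
    pos = match.position
    if match.strand == "-":
        seq = revcomp_str(seq)
        pos = len(seq) - (pos + primary_width)
    left = pos
    right = len(seq) - (pos + primary_width)
    flank = min(left, right)
    trimmed = seq[pos - flank : pos + primary_width + flank]
    return CenteredWindow(id=window.id, seq=trimmed, primary_span=(flank, flank + primary_width))


def scan_secondary_best(
    cw: CenteredWindow,
    secondary: MotifModel,
    margin: int | None = None,
) -> tuple[SpacingBin, float] | None:
    """Best secondary site in the flanks of a centered window.

    Scans both strands at every start whose span does not overlap the
    primary site; no score threshold is applied — the best legal site is
    always taken, mirroring the uniform-placement null.  ``margin`` caps
    the gap.  Ties break toward smaller gap, then by the mirror-symmetric
    quadrant order (downstream-same, upstream-opposite, upstream-same,
    downstream-opposite).  Returns None when no legal placement exists.
    """
    ws = secondary.width
    p_start, p_end = cw.primary_span
    codes = encode_sequence(cw.seq)
    L = len(cw.seq)
    if L < ws:
        return None
    fwd = sliding_scores(secondary, codes)
    rev = sliding_scores(reverse_complement(secondary), codes)
    positions = np.arange(L - ws + 1)
    up_ok = positions + ws <= p_start
    down_ok = positions >= p_end
    gaps = np.where(up_ok, p_start - (positions + ws), positions - p_end)
    legal = up_ok | down_ok
    if margin is not None:
        legal &= gaps <= margin
    if not legal.any():
        return None

    idx = np.flatnonzero(legal)
    # candidate rows: (score, gap, side 0=up/1=down, strand 0=same/1=opp)
    cand_scores = np.concatenate([fwd[idx], rev[idx]])
    cand_gaps = np.concatenate([gaps[idx], gaps[idx]])
    cand_side = np.concatenate([down_ok[idx], down_ok[idx]]).astype(int)
    cand_strand = np.concatenate([np.zeros(idx.size, int), np.ones(idx.size, int)])
    # tie-break rank per quadrant (see _QUADRANT_RANK)
    rank = np.array([[2, 1], [0, 3]])[cand_side, cand_strand]
    order = np.lexsort((rank, cand_gaps, -cand_scores))
    j = order[0]
    quadrant = ("upstream", "downstream")[cand_side[j]] + ("-same", "-opposite")[cand_strand[j]]
    return SpacingBin(quadrant=quadrant, gap=int(cand_gaps[j])), float(cand_scores[j])


def available_bins(
    flank: int, secondary_width: int, margin: int | None = None, pool_quadrants: bool = False
) -> int:
    """Number of legal (quadrant, gap) bins for a centered-window geometry."""
    max_gap = flank - secondary_width
    if margin is not None:
        max_gap = min(max_gap, margin)
    if max_gap < 0:
        return 0
    n_gaps = max_gap + 1
    return n_gaps if pool_quadrants else 4 * n_gaps


def build_histogram(
    placements: Sequence[SpacingBin],
    flank: int,
    secondary_width: int,
    margin: int | None = None,
    pool_quadrants: bool = False,
) -> SpacingHistogram:
    """Tally best-placement bins into a spacing histogram.

    ``flank`` is the widest flank among contributing windows, which fixes
    the bin universe B.
    """
    counts: dict[SpacingBin, int] = {}
    for b in placements:
        counts[b] = counts.get(b, 0) + 1
    B = available_bins(flank, secondary_width, margin, pool_quadrants)
    return SpacingHistogram(counts=counts, n=len(placements), B=B)


def binomial_tail(k: int, n: int, p: float) -> float:
    """Exact upper tail P[X >= k], X ~ Binomial(n, p), by direct summation."""
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    ks = np.arange(k, n + 1)
    return float(np.exp(stats.binom.logpmf(ks, n, p)).sum())


def binomial_spacing_test(hist: SpacingHistogram) -> list[SpacingTestResult]:
    """Per-bin binomial enrichment test with Bonferroni adjustment.

    For every occupied bin, ``p_raw = P[X >= k]`` with
    ``X ~ Binomial(hist.n, 1/hist.B)`` and ``p_adj = min(1, B * p_raw)``.
    Results are ordered by (p_adj, gap, quadrant).
    """
    if hist.B < 1:
        raise ValueError("histogram has no available bins (B = 0)")
    if hist.n < 1:
        raise ValueError("histogram has no observations (n = 0)")
    p = 1.0 / hist.B
    results = []
    for b, k in hist.counts.items():
        p_raw = max(binomial_tail(k, hist.n, p), 1e-300)
        p_adj = min(1.0, hist.B * p_raw)
        results.append(SpacingTestResult(bin=b, k=k, p_raw=p_raw, p_adj=p_adj))
    results.sort(key=lambda r: (r.p_adj, r.bin.sort_key))
    return results


def pair_evalue(best_p_adj: float, n_secondary_motifs: int) -> float:
    """E-value: best adjusted p-value scaled by the database size.

    Not capped at 1 (an E-value may exceed 1); floored at 1e-300.
    """
    if n_secondary_motifs < 1:
        raise ValueError("n_secondary_motifs must be >= 1")
    return max(best_p_adj * n_secondary_motifs, 1e-300)


def center_windows(
    windows: Sequence[SequenceWindow],
    primary: MotifModel,
    min_score: float | None = None,
) -> list[CenteredWindow]:
    """find_best_primary + center_and_orient over a window collection."""
    out = []
    for w in windows:
        m = find_best_primary(w, primary, min_score)
        if m is not None:
            out.append(center_and_orient(w, m, primary.width))
    return out


def _analyze_centered(
    centered: Sequence[CenteredWindow],
    primary: MotifModel,
    secondary: MotifModel,
    n_secondary_motifs: int,
    config: SpacingConfig,
) -> PairResult:
    placements = []
    max_flank = 0
    for cw in centered:
        if cw.flank < secondary.width:
            continue  # both flanks shorter than the secondary motif
        hit = scan_secondary_best(cw, secondary, config.margin)
        if hit is None:
            continue
        b, _score = hit
        if config.pool_quadrants:
            b = SpacingBin(quadrant="downstream-same", gap=b.gap)
        placements.append(b)
        max_flank = max(max_flank, cw.flank)
    if not placements:
        return PairResult(
            primary_name=primary.name,
            secondary_name=secondary.name,
            best=None,
            evalue=None,
            n=0,
        )
    hist = build_histogram(
        placements, max_flank, secondary.width, config.margin, config.pool_quadrants
    )
    tests = binomial_spacing_test(hist)
    best = tests[0]
    return PairResult(
        primary_name=primary.name,
        secondary_name=secondary.name,
        best=best,
        evalue=pair_evalue(best.p_adj, n_secondary_motifs),
        n=hist.n,
        histogram=hist,
        tests=tests,
    )


def analyze_pair(
    windows: Sequence[SequenceWindow],
    primary: MotifModel,
    secondary: MotifModel,
    config: SpacingConfig | None = None,
    n_secondary_motifs: int = 1,
) -> PairResult:
    """End-to-end spacing analysis of one motif pair.

    Composes primary matching, centering, secondary scanning, histogram
    construction and the binomial spacing test.  When no window retains a
    primary match the result carries ``empty = True`` rather than raising.
    For self-pairing (secondary == primary) the primary's own site is
    excluded by the overlap rule, so e.g. tandem-site spacing is measured
    between distinct sites.
    """
    if not windows:
        raise ValueError("windows collection is empty")
    config = config or SpacingConfig()
    min_score = config.min_score_frac * primary.max_score
    centered = center_windows(windows, primary, min_score)
    return _analyze_centered(centered, primary, secondary, n_secondary_motifs, config)


def analyze_library(
    windows: Sequence[SequenceWindow],
    primary: MotifModel,
    db: MotifDatabase,
    alpha: float = 0.01,
    config: SpacingConfig | None = None,
) -> list[PairResult]:
    """Screen every database motif as a secondary against one primary.

    Windows are centered on the primary once; each secondary is then
    scanned against the centered set.  Pairs whose best adjusted p-value
    passes ``alpha`` are returned ranked by ascending p_adj (ties by gap,
    then quadrant, then name).
    """
    if db.size == 0:
        raise ValueError("motif database is empty")
    config = config or SpacingConfig()
    min_score = config.min_score_frac * primary.max_score
    centered = center_windows(windows, primary, min_score)
    results = []
    for secondary in db:
        r = _analyze_centered(centered, primary, secondary, db.size, config)
        if r.best is not None and r.best.p_adj < alpha:
            results.append(r)
    results.sort(key=lambda r: (r.best.p_adj, r.best.bin.sort_key, r.secondary_name))
    return results


def pair_results_to_rows(results: Sequence[PairResult]) -> list[dict]:
    """Flatten PairResults for TSV output."""
    rows = []
    for r in results:
        if r.best is None:
            continue
        rows.append(
            {
                "primary": r.primary_name,
                "secondary": r.secondary_name,
                "quadrant": r.best.bin.quadrant,
                "gap": r.best.bin.gap,
                "k": r.best.k,
                "n": r.n,
                "B": r.histogram.B if r.histogram else 0,
                "p_raw": r.best.p_raw,
                "p_adj": r.best.p_adj,
                "evalue": r.evalue,
            }
        )
    return rows
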