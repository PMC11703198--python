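"""De novo primary-motif discovery by ZOOPS expectation-maximization.

The discovery stage finds the most enriched motif in a set of
summit-centered windows so it can anchor the downstream spacing scan.  It
uses the ZOOPS (zero-or-one occurrence per sequence) likelihood model:
each window either contains no site (probability ``1 - gamma``) or exactly
one site (probability ``gamma``) placed uniformly over all start positions
on either strand, with site columns drawn from the motif PFM and all other
positions from a 0-order background estimated from the windows themselves.

EM alternates a soft assignment of site posteriors over every (position,
strand) candidate plus the no-site state (E-step) with re-estimation of
the PFM and the site prior ``gamma`` (M-step); the observed-data
log-likelihood is non-decreasing across iterations.  Seeding is by
over-represented k-mers, each refined independently; near-duplicate
refined candidates are collapsed by PFM correlation and the survivor with
the largest likelihood-ratio score is the primary motif.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .motif_io import ALPHABET, COMPLEMENT, MotifModel, motif_similarity
from .peaks_io import SequenceWindow
from .spacing_core import encode_sequence, revcomp_str

_EM_PSEUDO = 1e-6  # numerical floor only; keeps the M-step a near-exact MLE


@dataclass(frozen=True)
class DiscoveryConfig:
    """Parameters of the EM motif search."""

    motif_width: int = 8
    n_seeds: int = 10
    max_iter: int = 100
    tol: float = 1e-4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.motif_width < 4:
            raise ValueError("motif_width must be >= 4")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass
class MotifCandidate:
    """A refined motif with its enrichment evidence."""

    motif: MotifModel
    score: float  # log-likelihood ratio vs the background-only model
    n_sites: int  # windows whose posterior site probability exceeds 1/2
    site_prior: float  # fitted ZOOPS gamma
    converged: bool
    loglik_history: list[float] = field(default_factory=list)


def estimate_background(windows: Sequence[SequenceWindow]) -> np.ndarray:
    """0-order background frequencies pooled over all windows (N ignored)."""
    counts = np.zeros(4)
    for w in windows:
        codes = encode_sequence(w.seq)
        counts += np.bincount(codes[codes < 4], minlength=4)
    if counts.sum() == 0:
        raise ValueError("windows contain no unambiguous bases")
    return counts / counts.sum()


def _canonical_kmer(kmer: str) -> str:
    rc = revcomp_str(kmer)
    return min(kmer, rc)


def seed_kmers(
    windows: Sequence[SequenceWindow], k: int, n_seeds: int
) -> list[tuple[str, float]]:
    """Most over-represented k-mers, merged with their reverse complements.

    Each k-mer's count (plus its reverse complement's) is compared with the
    expectation under the 0-order background; seeds are ranked by
    ``log2((obs + 0.5) / (exp + 0.5))``.  Returns up to ``n_seeds``
    ``(kmer, log_ratio)`` pairs; the stored k-mer is the lexicographically
    smaller of the pair.
    """
    if not windows:
        raise ValueError("windows collection is empty")
    if any(k > w.width for w in windows):
        raise ValueError(f"k={k} exceeds a window width")
    bg = estimate_background(windows)
    counts: dict[str, int] = {}
    total_positions = 0
    for w in windows:
        seq = w.seq.upper()
        for j in range(len(seq) - k + 1):
            kmer = seq[j : j + k]
            if "N" in kmer:
                continue
            counts[_canonical_kmer(kmer)] = counts.get(_canonical_kmer(kmer), 0) + 1
            total_positions += 1
    if not counts:
        raise ValueError("no unambiguous k-mers found (all-N sequences?)")
    log_bg = np.log(bg)
    scored: list[tuple[str, float]] = []
    for kmer, obs in counts.items():
        codes = encode_sequence(kmer)
        rc_codes = encode_sequence(revcomp_str(kmer))
        p = np.exp(log_bg[codes].sum()) + np.exp(log_bg[rc_codes].sum())
        if kmer == revcomp_str(kmer):
            p /= 2.0  # palindromes are their own reverse complement
        exp = total_positions * p
        scored.append((kmer, float(np.log2((obs + 0.5) / (exp + 0.5)))))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored[:n_seeds]


def _seed_pfm(seed: str, match_prob: float = 0.55) -> np.ndarray:
    pfm = np.full((len(seed), 4), (1.0 - match_prob) / 3.0)
    for i, b in enumerate(seed):
        pfm[i, ALPHABET.index(b)] = match_prob
    return pfm


def _batch_log_odds_scores(lo: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Sliding log-odds scores for all windows at once.

    ``lo`` is a (w, 4) natural-log odds matrix; ``C`` an (n, L) code matrix
    (code 4 = N scores 0).  Returns (n, L - w + 1).
    """
    w = lo.shape[0]
    lo5 = np.hstack([lo, np.zeros((w, 1))])
    n, L = C.shape
    m = L - w + 1
    S = np.zeros((n, m))
    for i in range(w):
        S += lo5[i, C[:, i : i + m]]
    return S


def em_refine(
    seed: str, windows: Sequence[SequenceWindow], config: DiscoveryConfig
) -> MotifCandidate:
    """Refine a seed k-mer into a PFM by ZOOPS EM.

    Iterates until the log-likelihood improves by less than ``config.tol``
    or ``config.max_iter`` updates have been applied; non-convergence
    returns the best-so-far parameters with ``converged = False``.
    """
    if len(seed) != config.motif_width:
        raise ValueError(
            f"seed length {len(seed)} does not match motif_width {config.motif_width}"
        )
    w = config.motif_width
    usable = [win for win in windows if win.width >= w]
    if not usable:
        raise ValueError("no window is as wide as the motif")
    bg = estimate_background(usable)
    log_bg5 = np.append(np.log(bg), 0.0)

    # group windows by length so each group is one dense code matrix
    by_len: dict[int, list[np.ndarray]] = {}
    for win in usable:
        by_len.setdefault(win.width, []).append(encode_sequence(win.seq))
    groups = [np.stack(rows) for rows in by_len.values()]
    bg_ll = sum(float(log_bg5[C].sum()) for C in groups)  # constant term

    pfm = _seed_pfm(seed)
    gamma = 0.5
    history: list[float] = []
    converged = False

    def strand_scores(pfm_: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = np.log(pfm_ / bg)
        lo_rc = lo[::-1][:, COMPLEMENT]
        return _batch_log_odds_scores(lo, C), _batch_log_odds_scores(lo_rc, C)

    for _ in range(config.max_iter + 1):
        # ---- E-step quantities and current log-likelihood
        ll = bg_ll
        e_stats = []
        q_all = []
        for C in groups:
            Sf, Sr = strand_scores(pfm, C)
            m2 = 2 * Sf.shape[1]
            log_mean_lr = logsumexp(np.hstack([Sf, Sr]), axis=1) - np.log(m2)
            log_denom = np.logaddexp(
                np.log1p(-gamma), np.log(gamma) + log_mean_lr
            )
            ll += float(log_denom.sum())
            log_z_base = np.log(gamma) - np.log(m2) - log_denom
            Zf = np.exp(log_z_base[:, None] + Sf)
            Zr = np.exp(log_z_base[:, None] + Sr)
            e_stats.append((C, Zf, Zr))
            q_all.append(Zf.sum(axis=1) + Zr.sum(axis=1))
        history.append(ll)
        if len(history) > 1 and abs(history[-1] - history[-2]) < config.tol:
            converged = True
            break
        if len(history) == config.max_iter + 1:
            break

        # ---- M-step
        counts = np.full((w, 4), _EM_PSEUDO)
        for C, Zf, Zr in e_stats:
            m = Zf.shape[1]
            for i in range(w):
                cf = np.bincount(
                    C[:, i : i + m].ravel(), weights=Zf.ravel(), minlength=5
                )[:4]
                cr = np.bincount(
                    C[:, w - 1 - i : w - 1 - i + m].ravel(),
                    weights=Zr.ravel(),
                    minlength=5,
                )[:4]
                counts[i] += cf + cr[COMPLEMENT]
        pfm = counts / counts.sum(axis=1, keepdims=True)
        q = np.concatenate(q_all)
        gamma = float(np.clip(q.mean(), 1e-6, 1.0 - 1e-6))

    q = np.concatenate(q_all)
    motif = MotifModel(name=f"denovo_{seed}", pfm=pfm, background=bg)
    return MotifCandidate(
        motif=motif,
        score=history[-1] - bg_ll,
        n_sites=int((q > 0.5).sum()),
        site_prior=gamma,
        converged=converged,
        loglik_history=history,
    )


def discover_primary(
    windows: Sequence[SequenceWindow],
    config: DiscoveryConfig | None = None,
    widths: Sequence[int] | None = None,
) -> list[MotifCandidate]:
    """Full de novo search: seed, refine, deduplicate, rank.

    Runs :func:`em_refine` from each of the top ``n_seeds`` k-mer seeds
    (optionally over several motif widths), collapses candidates whose PFM
    correlation is >= 0.9, and ranks by score.  Element 0 is the primary
    motif.  Deterministic given the configuration.
    """
    if not windows:
        raise ValueError("windows collection is empty")
    config = config or DiscoveryConfig()
    candidates: list[MotifCandidate] = []
    for w in widths or [config.motif_width]:
        cfg = DiscoveryConfig(
            motif_width=w,
            n_seeds=config.n_seeds,
            max_iter=config.max_iter,
            tol=config.tol,
            rng_seed=config.rng_seed,
        )
        for seed, _ratio in seed_kmers(windows, w, cfg.n_seeds):
            candidates.append(em_refine(seed, windows, cfg))
    candidates.sort(key=lambda c: (-c.score, c.motif.name))
    kept: list[MotifCandidate] = []
    for cand in candidates:
        min_w = min(5, cand.motif.width, *[k.motif.width for k in kept] or [cand.motif.width])
        if any(motif_similarity(cand.motif, k.motif, min_overlap=min_w) >= 0.9 for k in kept):
            continue
        kept.append(cand)
    return kept
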