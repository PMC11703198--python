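"""Planted composite-element simulator.

Generates summit-centered-style windows in which a primary motif site is
placed at (or near) the window center on a random strand and, in a chosen
fraction of windows, a secondary site is placed at an exact edge-to-edge
gap in a chosen orientation quadrant relative to the primary.  Every
window comes with a truth record, so planted spacings can be compared with
what the spacing scan recovers.

The background is i.i.d. mononucleotide (uniform by default, GC-skew
configurable) or an order-1 Markov chain.  Sites are sampled column-wise
from the motif PFM by default — so degenerate consensus positions (the
``n`` in TGAnTCA, say) vary across windows and score thresholds are
genuinely exercised — or planted as the literal consensus with
``consensus_only``.

Convenience presets reproduce classic composite elements: AP-1/IRF (AICE),
tandem GAS sites as bound by STAT tetramers, and CTCF/ETS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .motif_io import ALPHABET, MotifModel, motif_from_consensus, reverse_complement
from .peaks_io import SequenceWindow
from .spacing_core import QUADRANTS, revcomp_str

#: preset motif consensi (IUPAC)
AP1_CONSENSUS = "TGASTCA"  # AP-1 (JUN/FOS) TPA-response element
IRF_CONSENSUS = "TGAAAC"  # IRF half-site carrying the GAAA core
GAS_CONSENSUS = "TTCNNNGAA"  # gamma-activated site (STAT dimer palindrome)
CTCF_CONSENSUS = "CCACNAGGTGGCAG"  # CTCF core consensus (zinc-finger module)
ETS_CONSENSUS = "ACAGGAAGT"  # ETS family site with the GGAA core


@dataclass(frozen=True)
class PlantSpec:
    """Full description of one planted-composite simulation.

    ``gap`` is edge-to-edge (0 = abutting) and ``quadrant`` is interpreted
    in the primary site's own frame: "downstream-same" puts the secondary
    3' of the primary on the primary's strand.
    """

    n_windows: int
    primary: MotifModel | str
    secondary: MotifModel | str | None = None
    window_width: int = 500
    background: Sequence[float] | None = None  # mononucleotide freqs
    markov1: np.ndarray | None = None  # optional 4x4 order-1 transition table
    gap: int = 0
    quadrant: str = "downstream-same"
    plant_fraction: float = 1.0
    primary_jitter: int = 0
    consensus_only: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")
        if not 0.0 <= self.plant_fraction <= 1.0:
            raise ValueError("plant_fraction must be in [0, 1]")
        if self.quadrant not in QUADRANTS:
            raise ValueError(f"unknown quadrant {self.quadrant!r}")
        if self.gap < 0:
            raise ValueError("gap must be >= 0")
        if self.primary_jitter < 0:
            raise ValueError("primary_jitter must be >= 0")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated window."""

    window_id: str
    primary_pos: int
    primary_strand: str
    secondary_pos: int | None = None
    secondary_strand: str | None = None
    true_gap: int | None = None


def _as_motif(m: MotifModel | str, name: str) -> MotifModel:
    if isinstance(m, MotifModel):
        return m
    return motif_from_consensus(name, m)


def _sample_site(motif: MotifModel, rng: np.random.Generator, consensus_only: bool) -> str:
    if consensus_only:
        # literal consensus; degenerate columns take their argmax base
        return "".join(ALPHABET[int(np.argmax(col))] for col in motif.pfm)
    idx = [rng.choice(4, p=col / col.sum()) for col in motif.pfm]
    return "".join(ALPHABET[i] for i in idx)


def _draw_background(
    n: int, width: int, bg: np.ndarray, markov1: np.ndarray | None, rng: np.random.Generator
) -> np.ndarray:
    if markov1 is None:
        return rng.choice(4, size=(n, width), p=bg)
    trans = np.asarray(markov1, dtype=float)
    if trans.shape != (4, 4):
        raise ValueError("markov1 transition table must be 4x4")
    trans = trans / trans.sum(axis=1, keepdims=True)
    out = np.empty((n, width), dtype=np.int64)
    out[:, 0] = rng.choice(4, size=n, p=bg)
    # cumulative transition rows let us vectorize over windows
    cum = trans.cumsum(axis=1)
    for j in range(1, width):
        u = rng.random(n)
        out[:, j] = (u[:, None] > cum[out[:, j - 1]]).sum(axis=1)
    return out


def generate(spec: PlantSpec) -> tuple[list[SequenceWindow], list[TruthRecord]]:
    """Simulate windows with planted sites per ``spec``.

    Deterministic given ``spec.rng_seed``.  Raises before emitting anything
    if the window cannot geometrically contain primary + gap + secondary at
    the requested jitter.
    """
    rng = np.random.default_rng(spec.rng_seed)
    primary = _as_motif(spec.primary, "primary")
    secondary = _as_motif(spec.secondary, "secondary") if spec.secondary is not None else None
    W = spec.window_width
    wp = primary.width

    # geometry check (worst case jitter)
    need = wp
    if secondary is not None:
        need = wp + spec.gap + secondary.width
    if need + 2 * spec.primary_jitter > W:
        raise ValueError(
            f"window of width {W} cannot contain the planted element "
            f"(needs {need} bp plus jitter {spec.primary_jitter})"
        )

    bg = np.full(4, 0.25) if spec.background is None else np.asarray(spec.background, float)
    bg = bg / bg.sum()
    codes = _draw_background(spec.n_windows, W, bg, spec.markov1, rng)
    seqs = ["".join(ALPHABET[c] for c in row) for row in codes]

    planted = rng.random(spec.n_windows) < spec.plant_fraction
    windows: list[SequenceWindow] = []
    truths: list[TruthRecord] = []
    for i in range(spec.n_windows):
        seq = seqs[i]
        jitter = int(rng.integers(-spec.primary_jitter, spec.primary_jitter + 1))
        p_pos = W // 2 - wp // 2 + jitter
        site_p = _sample_site(primary, rng, spec.consensus_only)
        seq = seq[:p_pos] + site_p + seq[p_pos + wp :]

        s_pos: int | None = None
        s_strand_frame: str | None = None
        if secondary is not None and planted[i]:
            site_s = _sample_site(secondary, rng, spec.consensus_only)
            side, strand = spec.quadrant.split("-")
            if strand == "opposite":
                site_s = revcomp_str(site_s)
            ws = secondary.width
            if side == "downstream":
                s_pos = p_pos + wp + spec.gap
            else:
                s_pos = p_pos - spec.gap - ws
            if s_pos < 0 or s_pos + ws > W:
                raise ValueError("secondary site falls outside the window; reduce gap or jitter")
            seq = seq[:s_pos] + site_s + seq[s_pos + ws :]
            s_strand_frame = "+" if strand == "same" else "-"

        # random primary strand: flip the whole window with probability 1/2
        p_strand = "+" if rng.random() < 0.5 else "-"
        if p_strand == "-":
            seq = revcomp_str(seq)
            p_pos_out = W - (p_pos + wp)
            if s_pos is not None:
                s_pos = W - (s_pos + secondary.width)
                s_strand_frame = "-" if s_strand_frame == "+" else "+"
        else:
            p_pos_out = p_pos

        wid = f"sim{i}"
        windows.append(SequenceWindow(id=wid, seq=seq, chrom="sim", start=i * W, end=(i + 1) * W))
        truths.append(
            TruthRecord(
                window_id=wid,
                primary_pos=p_pos_out,
                primary_strand=p_strand,
                secondary_pos=s_pos,
                secondary_strand=s_strand_frame,
                true_gap=spec.gap if s_pos is not None else None,
            )
        )
    return windows, truths


def write_truth_tsv(truths: Sequence[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("window_id\tprimary_pos\tprimary_strand\tsecondary_pos\tsecondary_strand\ttrue_gap\n")
        for t in truths:
            fh.write(
                f"{t.window_id}\t{t.primary_pos}\t{t.primary_strand}\t"
                f"{'' if t.secondary_pos is None else t.secondary_pos}\t"
                f"{'' if t.secondary_strand is None else t.secondary_strand}\t"
                f"{'' if t.true_gap is None else t.true_gap}\n"
            )


def generate_aice(
    n: int,
    seed: int,
    gap: int = 4,
    plant_fraction: float = 0.6,
    window_width: int = 500,
) -> tuple[list[SequenceWindow], list[TruthRecord], MotifModel, MotifModel]:
    """AP-1/IRF composite elements: TGASTCA with an IRF GAAA-core site.

    The characteristic AICE spacings are 0 (abutting) and 4 bp; ``gap``
    selects which is planted.
    """
    primary = motif_from_consensus("AP1", AP1_CONSENSUS)
    secondary = motif_from_consensus("IRF", IRF_CONSENSUS)
    spec = PlantSpec(
        n_windows=n,
        primary=primary,
        secondary=secondary,
        window_width=window_width,
        gap=gap,
        quadrant="downstream-same",
        plant_fraction=plant_fraction,
        rng_seed=seed,
    )
    windows, truths = generate(spec)
    return windows, truths, primary, secondary


def generate_gas_tetramer(
    n: int,
    gap: int,
    seed: int,
    plant_fraction: float = 0.6,
    window_width: int = 500,
) -> tuple[list[SequenceWindow], list[TruthRecord], MotifModel]:
    """Two GAS sites at a fixed gap, as bound by STAT tetramers.

    STAT5 tetramers prefer 11-12 bp between the tandem TTCnnnGAA sites;
    self-pair spacing analysis (secondary = primary) should recover
    ``gap``.
    """
    gas = motif_from_consensus("GAS", GAS_CONSENSUS)
    spec = PlantSpec(
        n_windows=n,
        primary=gas,
        secondary=gas,
        window_width=window_width,
        gap=gap,
        quadrant="downstream-same",
        plant_fraction=plant_fraction,
        rng_seed=seed,
    )
    windows, truths = generate(spec)
    return windows, truths, gas


def generate_ctcf_ets(
    n: int,
    seed: int,
    gap: int = 8,
    plant_fraction: float = 0.6,
    window_width: int = 500,
) -> tuple[list[SequenceWindow], list[TruthRecord], MotifModel, MotifModel]:
    """CTCF/ETS composite elements with the reported 8-bp optimal gap."""
    primary = motif_from_consensus("CTCF", CTCF_CONSENSUS)
    secondary = motif_from_consensus("ETS", ETS_CONSENSUS)
    spec = PlantSpec(
        n_windows=n,
        primary=primary,
        secondary=secondary,
        window_width=window_width,
        gap=gap,
        quadrant="downstream-same",
        plant_fraction=plant_fraction,
        rng_seed=seed,
    )
    windows, truths = generate(spec)
    return windows, truths, primary, secondary
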