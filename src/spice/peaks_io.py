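"""Peak file input, peak ranking, window extraction, and co-localization.

Coordinates follow the BED convention throughout: 0-based, half-open
intervals.  narrowPeak files carry the peak significance as column 8
(-log10 p-value) and the summit as column 10 (offset from the interval
start, -1 when absent); plain BED6 files are accepted with the summit
falling back to the interval midpoint.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np


class PeakFormatError(ValueError):
    """Raised when a peak file line cannot be parsed."""


@dataclass(frozen=True)
class PeakRecord:
    """One ChIP-Seq peak in BED half-open coordinates."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."
    signal: float = 0.0
    neglog10p: float = -1.0
    neglog10q: float = -1.0
    summit_offset: int = -1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.chrom}:{self.start}-{self.end}: start must be < end")
        if self.summit_offset >= 0 and not (
            self.start <= self.start + self.summit_offset < self.end
        ):
            raise ValueError(
                f"peak {self.chrom}:{self.start}-{self.end}: summit offset "
                f"{self.summit_offset} falls outside the interval"
            )

    @property
    def summit(self) -> int:
        """Summit position; interval midpoint when no offset is recorded."""
        if self.summit_offset >= 0:
            return self.start + self.summit_offset
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class SequenceWindow:
    """A fixed-width DNA window with genomic provenance."""

    id: str
    seq: str
    chrom: str = "."
    start: int = 0
    end: int = 0

    @property
    def width(self) -> int:
        return len(self.seq)

    @property
    def center_index(self) -> int:
        return len(self.seq) // 2


def read_narrowpeak(path: str | Path) -> list[PeakRecord]:
    """Read an ENCODE narrowPeak (10-column) or BED6 file.

    Comment, ``track`` and ``browser`` lines are skipped.  BED6 records get
    ``summit_offset = -1`` so their summit is the interval midpoint.
    """
    path = Path(path)
    peaks: list[PeakRecord] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) == 1:  # tolerate space-separated input
            fields = line.split()
        if len(fields) < 6:
            raise PeakFormatError(
                f"{path.name}:{lineno}: expected >= 6 columns, found {len(fields)}"
            )
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise PeakFormatError(
                f"{path.name}:{lineno}: non-integer coordinates {fields[1]!r}, {fields[2]!r}"
            ) from None
        try:
            peaks.append(
                PeakRecord(
                    chrom=fields[0],
                    start=start,
                    end=end,
                    name=fields[3],
                    score=float(fields[4]) if fields[4] != "." else 0.0,
                    strand=fields[5],
                    signal=float(fields[6]) if len(fields) > 6 else 0.0,
                    neglog10p=float(fields[7]) if len(fields) > 7 else -1.0,
                    neglog10q=float(fields[8]) if len(fields) > 8 else -1.0,
                    summit_offset=int(fields[9]) if len(fields) > 9 else -1,
                )
            )
        except ValueError as exc:
            raise PeakFormatError(f"{path.name}:{lineno}: {exc}") from None
    return peaks


def select_top_peaks(peaks: Sequence[PeakRecord], n: int) -> list[PeakRecord]:
    """The ``n`` most significant peaks by -log10 p-value.

    Ties are broken by (chrom, start) so the selection is deterministic
    under any permutation of the input.  If fewer than ``n`` peaks exist,
    all are returned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(peaks, key=lambda p: (-p.neglog10p, p.chrom, p.start, p.end))
    return ranked[:n]


def extract_windows(
    peaks: Iterable[PeakRecord],
    genome,
    width: int = 500,
) -> list[SequenceWindow]:
    """Extract summit-centered sequence windows from an indexed genome.

    ``genome`` is a mapping from chromosome name to sequence (e.g. a
    ``pyfaidx.Fasta``, or a plain dict of strings for testing).  Each
    window spans ``[summit - width/2, summit + width/2)``; windows that
    would run past a chromosome end are discarded so every returned window
    has exactly ``width`` bases.  Sequences are upper-cased.
    """
    if width % 2 != 0:
        raise ValueError("width must be even")
    chrom_len: dict[str, int] = {}
    windows: list[SequenceWindow] = []
    for i, peak in enumerate(peaks):
        if peak.chrom not in chrom_len:
            try:
                chrom_len[peak.chrom] = len(genome[peak.chrom])
            except KeyError:
                raise KeyError(f"chromosome {peak.chrom!r} not present in the genome") from None
        half = width // 2
        start = peak.summit - half
        end = peak.summit + half
        if start < 0 or end > chrom_len[peak.chrom]:
            continue
        seq = str(genome[peak.chrom][start:end]).upper()
        windows.append(
            SequenceWindow(
                id=f"peak{i}|{peak.chrom}:{start}-{end}",
                seq=seq,
                chrom=peak.chrom,
                start=start,
                end=end,
            )
        )
    return windows


def write_windows_fasta(windows: Iterable[SequenceWindow], path: str | Path) -> None:
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f">{w.id}\n{w.seq}\n")


def read_windows_fasta(path: str | Path) -> list[SequenceWindow]:
    """Read windows back from FASTA, recovering provenance from the header."""
    windows: list[SequenceWindow] = []
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks).upper()
        chrom, start, end = ".", 0, len(seq)
        if "|" in header:
            _, _, loc = header.partition("|")
            try:
                chrom_part, span = loc.split(":")
                s, e = span.split("-")
                chrom, start, end = chrom_part, int(s), int(e)
            except ValueError:
                pass
        windows.append(SequenceWindow(id=header, seq=seq, chrom=chrom, start=start, end=end))

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].split()[0]
            chunks = []
        else:
            chunks.append(line)
    flush()
    return windows


def peak_overlap(
    a: Sequence[PeakRecord], b: Sequence[PeakRecord]
) -> tuple[int, int, float]:
    """Count peaks in ``a`` that share >= 1 bp with any peak in ``b``.

    Returns ``(total_a, overlapping, fraction)``.  Intervals are half-open,
    so peaks that merely touch do not overlap.
    """
    if not a:
        raise ValueError("peak set `a` is empty: overlap fraction is undefined")
    # merge b's intervals per chromosome, then binary-search each a peak
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in b:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    merged: dict[str, tuple[list[int], list[int]]] = {}
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        starts: list[int] = []
        ends: list[int] = []
        for s, e in ivals:
            if ends and s < ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[chrom] = (starts, ends)

    hits = 0
    for p in a:
        if p.chrom not in merged:
            continue
        starts, ends = merged[p.chrom]
        i = bisect.bisect_right(starts, p.start)
        # candidate merged intervals: the one starting at or before p.start,
        # and any starting inside p
        if i > 0 and ends[i - 1] > p.start:
            hits += 1
            continue
        if i < len(starts) and starts[i] < p.end:
            hits += 1
    return len(a), hits, hits / len(a)
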