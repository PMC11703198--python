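"""Motif models, database parsing, and motif comparison.

Motifs are represented as position frequency matrices (PFMs) over the DNA
alphabet with a fixed column order A, C, G, T.  Scoring uses the log-odds
position weight matrix (PWM) derived from the pseudocount-regularized PFM
against a background mononucleotide model:

    pwm[i, b] = log2( ((pfm[i, b] + c * bg[b]) / (1 + c)) / bg[b] )

where ``c`` is the pseudocount fraction (default 0.01).  The regularization
is a probability-space smoothing toward the background, so every PWM entry
is finite even when a PFM column contains a zero.

Supported database formats: MEME minimal motif format (read and write) and
JASPAR PFM count matrices (read).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

ALPHABET = "ACGT"
#: index permutation sending each base to its Watson-Crick complement
COMPLEMENT = np.array([3, 2, 1, 0])

#: IUPAC nucleotide codes as base subsets (uniform within the subset)
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


class MotifParseError(ValueError):
    """Raised when a motif file cannot be parsed."""


class UnsupportedAlphabetError(MotifParseError):
    """Raised when a motif file declares a non-DNA alphabet."""


def _as_background(background: Sequence[float] | None) -> np.ndarray:
    if background is None:
        return np.full(4, 0.25)
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,):
        raise ValueError("background must have exactly 4 entries (A,C,G,T)")
    if np.any(bg <= 0):
        raise ValueError("background frequencies must all be positive")
    return bg / bg.sum()


@dataclass(frozen=True)
class MotifModel:
    """A named PFM with its derived log-odds scoring matrix.

    Attributes
    ----------
    name : str
        Unique motif identifier.
    pfm : ndarray of shape (width, 4)
        Column-stochastic base probabilities, columns ordered A, C, G, T.
    background : ndarray of shape (4,)
        Background base frequencies used for the log-odds transform.
    pseudocount : float
        Smoothing fraction ``c`` in ``p' = (p + c*bg) / (1 + c)``.
    pwm : ndarray of shape (width, 4)
        log2 odds of the smoothed PFM over the background.
    """

    name: str
    pfm: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.01
    pwm: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        pfm = np.asarray(self.pfm, dtype=float)
        if pfm.ndim != 2 or pfm.shape[1] != 4 or pfm.shape[0] < 1:
            raise ValueError(f"motif {self.name!r}: pfm must be (width, 4) with width >= 1")
        sums = pfm.sum(axis=1)
        if np.any(sums <= 0):
            raise ValueError(f"motif {self.name!r}: pfm has a non-positive column sum")
        pfm = pfm / sums[:, None]
        bg = _as_background(self.background)
        c = float(self.pseudocount)
        if c < 0:
            raise ValueError("pseudocount must be >= 0")
        smoothed = (pfm + c * bg) / (1.0 + c)
        object.__setattr__(self, "pfm", pfm)
        object.__setattr__(self, "background", bg)
        object.__setattr__(self, "pwm", np.log2(smoothed / bg))

    @property
    def width(self) -> int:
        return self.pfm.shape[0]

    @property
    def max_score(self) -> float:
        """Best achievable log-odds score (per-column maxima)."""
        return float(self.pwm.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        """Majority-letter consensus; lowercase where the majority is < 0.5."""
        out = []
        for col in self.pfm:
            b = ALPHABET[int(np.argmax(col))]
            out.append(b if col.max() >= 0.5 else b.lower())
        return "".join(out)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MotifModel):
            return NotImplemented
        return (
            self.name == other.name
            and self.pfm.shape == other.pfm.shape
            and np.allclose(self.pfm, other.pfm)
            and np.allclose(self.background, other.background)
        )

    def __hash__(self) -> int:
        return hash((self.name, self.width))


def reverse_complement(motif: MotifModel) -> MotifModel:
    """Return the motif describing binding on the opposite strand.

    Column ``i`` of the result is the complement permutation of column
    ``width - 1 - i`` of the input; applying the operation twice is the
    identity.
    """
    rc_pfm = motif.pfm[::-1, COMPLEMENT]
    return MotifModel(
        name=motif.name,
        pfm=rc_pfm,
        background=motif.background,
        pseudocount=motif.pseudocount,
    )


def motif_from_consensus(
    name: str,
    consensus: str,
    background: Sequence[float] | None = None,
    pseudocount: float = 0.01,
) -> MotifModel:
    """Build a MotifModel from an IUPAC consensus string.

    Each consensus letter becomes a PFM column that is uniform over the
    bases the IUPAC code denotes (so ``N`` is fully degenerate and ``S``
    splits mass between G and C).
    """
    consensus = consensus.upper()
    pfm = np.zeros((len(consensus), 4))
    for i, letter in enumerate(consensus):
        try:
            bases = IUPAC_CODES[letter]
        except KeyError:
            raise ValueError(f"unknown IUPAC code {letter!r} in consensus {consensus!r}") from None
        for b in bases:
            pfm[i, _BASE_INDEX[b]] = 1.0 / len(bases)
    return MotifModel(name=name, pfm=pfm, background=background, pseudocount=pseudocount)


@dataclass
class MotifDatabase:
    """Ordered, name-unique collection of motifs sharing a background."""

    motifs: list[MotifModel]
    source_background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        names = [m.name for m in self.motifs]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate motif names in database: {sorted(dupes)}")
        self.source_background = _as_background(self.source_background)
        self._by_name = {m.name: m for m in self.motifs}

    @property
    def size(self) -> int:
        return len(self.motifs)

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self) -> Iterator[MotifModel]:
        return iter(self.motifs)

    def __getitem__(self, key: int | str) -> MotifModel:
        if isinstance(key, str):
            return self._by_name[key]
        return self.motifs[key]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name


def read_meme_motifs(path: str | Path, pseudocount: float = 0.01) -> MotifDatabase:
    """Parse a MEME minimal motif file into a :class:`MotifDatabase`.

    The file's background letter frequencies, when present, are used for the
    log-odds transform of every motif; otherwise a uniform background is
    assumed.  Matrix columns are renormalized to sum to one.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    background: np.ndarray | None = None
    motifs: list[MotifModel] = []

    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if line.upper().startswith("ALPHABET"):
            alpha = line.split("=", 1)[-1].strip() if "=" in line else ""
            if alpha and set(alpha.upper()) != set("ACGT"):
                raise UnsupportedAlphabetError(
                    f"{path.name}: alphabet {alpha!r} is not supported (DNA only)"
                )
            i += 1
        elif line.lower().startswith("background letter frequencies"):
            # frequencies may continue on the following line(s)
            i += 1
            tokens: list[str] = []
            while i < n and not lines[i].strip().upper().startswith(("MOTIF", "ALPHABET")):
                stripped = lines[i].strip()
                if stripped:
                    tokens.extend(stripped.split())
                    i += 1
                    if len(tokens) >= 8:
                        break
                else:
                    i += 1
            freq = {tokens[j].upper(): float(tokens[j + 1]) for j in range(0, len(tokens) - 1, 2)}
            if set(freq) - set("ACGT"):
                raise UnsupportedAlphabetError(
                    f"{path.name}: background letters {sorted(freq)} are not ACGT"
                )
            background = _as_background([freq.get(b, 0.25) for b in ALPHABET])
        elif line.upper().startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise MotifParseError(f"{path.name}:{i + 1}: MOTIF line without a name")
            name = parts[1]
            i += 1
            # seek the letter-probability header
            while i < n and not lines[i].strip().lower().startswith("letter-probability matrix"):
                if lines[i].strip().upper().startswith("MOTIF"):
                    raise MotifParseError(
                        f"{path.name}: motif {name!r} has no letter-probability matrix"
                    )
                i += 1
            if i >= n:
                raise MotifParseError(
                    f"{path.name}: motif {name!r} has no letter-probability matrix"
                )
            header = lines[i].strip()
            m_alen = re.search(r"alength=\s*(\d+)", header)
            if m_alen and int(m_alen.group(1)) != 4:
                raise UnsupportedAlphabetError(
                    f"{path.name}: motif {name!r} has alength={m_alen.group(1)}, DNA requires 4"
                )
            m_w = re.search(r"w=\s*(\d+)", header)
            declared_w = int(m_w.group(1)) if m_w else None
            i += 1
            rows: list[list[float]] = []
            while i < n:
                stripped = lines[i].strip()
                if not stripped or stripped.upper().startswith(("MOTIF", "URL")):
                    break
                fields = stripped.split()
                try:
                    values = [float(x) for x in fields]
                except ValueError:
                    break
                if len(values) != 4:
                    raise MotifParseError(
                        f"{path.name}:{i + 1}: motif {name!r} matrix row has "
                        f"{len(values)} columns, expected 4"
                    )
                rows.append(values)
                i += 1
            if declared_w is not None and len(rows) != declared_w:
                raise MotifParseError(
                    f"{path.name}: motif {name!r} declares w={declared_w} "
                    f"but has {len(rows)} matrix rows"
                )
            if not rows:
                raise MotifParseError(f"{path.name}: motif {name!r} has an empty matrix")
            motifs.append(
                MotifModel(
                    name=name,
                    pfm=np.array(rows),
                    background=background if background is not None else None,
                    pseudocount=pseudocount,
                )
            )
        else:
            i += 1

    bg = background if background is not None else np.full(4, 0.25)
    return MotifDatabase(motifs=motifs, source_background=bg)


def write_meme_motifs(db: MotifDatabase, path: str | Path) -> None:
    """Serialize a database in MEME minimal motif format."""
    out = ["MEME version 4", "", "ALPHABET= ACGT", "", "strands: + -", ""]
    bg = db.source_background
    out.append("Background letter frequencies")
    out.append(" ".join(f"{b} {bg[i]:.6f}" for i, b in enumerate(ALPHABET)))
    out.append("")
    for m in db:
        out.append(f"MOTIF {m.name}")
        out.append(f"letter-probability matrix: alength= 4 w= {m.width} nsites= 20 E= 0")
        for col in m.pfm:
            out.append(" ".join(f"{x:.9f}" for x in col))
        out.append("")
    Path(path).write_text("\n".join(out) + "\n")


def read_jaspar_motifs(path: str | Path, pseudocount: float = 0.01) -> MotifDatabase:
    """Parse JASPAR PFM count matrices (``>name`` header, 4 count rows).

    Rows may be bare numbers or the bracketed ``A [ 1 2 3 ]`` style; counts
    are normalized column-wise to probabilities.  Zero-count columns are
    legal before pseudocount smoothing.
    """
    path = Path(path)
    motifs: list[MotifModel] = []
    name: str | None = None
    rows: dict[str, list[float]] = {}

    def flush() -> None:
        nonlocal name, rows
        if name is None:
            return
        if set(rows) != set("ACGT"):
            missing = set("ACGT") - set(rows)
            raise MotifParseError(f"{path.name}: motif {name!r} missing rows for {sorted(missing)}")
        counts = np.array([rows[b] for b in ALPHABET]).T  # (width, 4)
        widths = {len(rows[b]) for b in "ACGT"}
        if len(widths) != 1:
            raise MotifParseError(f"{path.name}: motif {name!r} has ragged count rows")
        motifs.append(MotifModel(name=name, pfm=counts, pseudocount=pseudocount))
        name, rows = None, {}

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].split()[0]
            continue
        m = re.match(r"^([ACGTacgt])\s*[\[\|:]?\s*([\d.\s]+?)\s*\]?\s*$", line)
        if not m:
            raise MotifParseError(f"{path.name}:{lineno}: unrecognized JASPAR row")
        base = m.group(1).upper()
        rows[base] = [float(x) for x in m.group(2).split()]
    flush()
    return MotifDatabase(motifs=motifs)


def motif_similarity(a: MotifModel, b: MotifModel, min_overlap: int = 5) -> float:
    """Best ungapped Pearson correlation between two PFMs.

    The maximum is taken over all relative offsets with at least
    ``min_overlap`` aligned columns and over ``b`` versus its reverse
    complement, correlating the flattened aligned PFM sub-matrices.  The
    score lies in [-1, 1], is symmetric in its arguments, and is invariant
    to reverse-complementing either motif.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if min_overlap > a.width or min_overlap > b.width:
        raise ValueError(
            f"min_overlap={min_overlap} exceeds a motif width "
            f"({a.width} and {b.width})"
        )
    best = -1.0
    for other in (b, reverse_complement(b)):
        # offset = start of `other` relative to start of `a`
        for offset in range(-(other.width - min_overlap), a.width - min_overlap + 1):
            lo = max(0, offset)
            hi = min(a.width, offset + other.width)
            if hi - lo < min_overlap:
                continue
            x = a.pfm[lo:hi].ravel()
            y = other.pfm[lo - offset : hi - offset].ravel()
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            if r > best:
                best = r
    return min(1.0, best)
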