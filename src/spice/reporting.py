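"""Interaction matrices, E-value filtering, and figure rendering.

Many library screens (one per ChIP-Seq library / primary motif) aggregate
into a sparse interaction matrix whose cell (library, secondary motif)
holds the pair E-value.  Cells left empty mean "no significant pair", which
is distinct from an E-value of 1; heat maps render empty cells in the
background color and populated cells by -log10(E-value), with E-values
floored at 1e-300 so the transform stays finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .spacing_core import PairResult, SpacingBin, SpacingHistogram

E_FLOOR = 1e-300


@dataclass
class InteractionMatrix:
    """Sparse library x secondary-motif E-value matrix."""

    rows: list[str]
    cols: list[str]
    values: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (r, c), v in self.values.items():
            if v <= 0:
                raise ValueError(f"cell ({r}, {c}) has non-positive E-value {v}")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.rows), len(self.cols))

    def neglog10(self) -> np.ndarray:
        """Dense -log10(E) view with NaN for empty cells."""
        out = np.full(self.shape, np.nan)
        ri = {r: i for i, r in enumerate(self.rows)}
        ci = {c: j for j, c in enumerate(self.cols)}
        for (r, c), v in self.values.items():
            out[ri[r], ci[c]] = -np.log10(max(v, E_FLOOR))
        return out


def build_matrix(runs: Mapping[str, Sequence[PairResult]]) -> InteractionMatrix:
    """Assemble per-library screen results into one interaction matrix.

    ``runs`` maps a unique library identifier to its ranked PairResults.
    Column order is first-seen order of secondary names.  Absent pairs stay
    empty; no cell is invented.
    """
    rows: list[str] = []
    cols: list[str] = []
    values: dict[tuple[str, str], float] = {}
    for lib, results in runs.items():
        if lib in rows:
            raise ValueError(f"duplicate library identifier {lib!r}")
        rows.append(lib)
        for r in results:
            if r.best is None or r.evalue is None:
                continue
            if r.secondary_name not in cols:
                cols.append(r.secondary_name)
            values[(lib, r.secondary_name)] = max(r.evalue, E_FLOOR)
    return InteractionMatrix(rows=rows, cols=cols, values=values)


def filter_matrix(m: InteractionMatrix, e_threshold: float = 1e-10) -> InteractionMatrix:
    """Keep cells with E-value < threshold; drop empty rows and columns."""
    if e_threshold <= 0:
        raise ValueError("e_threshold must be > 0")
    kept = {(r, c): v for (r, c), v in m.values.items() if v < e_threshold}
    rows = [r for r in m.rows if any(rr == r for rr, _ in kept)]
    cols = [c for c in m.cols if any(cc == c for _, cc in kept)]
    return InteractionMatrix(rows=rows, cols=cols, values=kept)


def matrix_to_tsv(m: InteractionMatrix, path: str | Path) -> None:
    """Long-format TSV (library, motif, evalue); values as repr strings so a
    round trip through text is bit-exact."""
    with open(path, "w") as fh:
        fh.write("library\tmotif\tevalue\n")
        for r in m.rows:
            for c in m.cols:
                if (r, c) in m.values:
                    fh.write(f"{r}\t{c}\t{m.values[(r, c)]!r}\n")


def matrix_from_tsv(path: str | Path) -> InteractionMatrix:
    rows: list[str] = []
    cols: list[str] = []
    values: dict[tuple[str, str], float] = {}
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        r, c, v = line.split("\t")
        if r not in rows:
            rows.append(r)
        if c not in cols:
            cols.append(c)
        values[(r, c)] = float(v)
    return InteractionMatrix(rows=rows, cols=cols, values=values)


def plot_heatmap(m: InteractionMatrix, path: str | Path, cmap: str = "Reds") -> Path:
    """Render the -log10(E) interaction heat map to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not m.rows or not m.cols:
        raise ValueError("interaction matrix is empty; relax the E-value filter")
    data = np.ma.masked_invalid(m.neglog10())
    h = max(2.0, 0.25 * len(m.rows) + 1.5)
    w = max(3.0, 0.25 * len(m.cols) + 1.5)
    fig, ax = plt.subplots(figsize=(w, h))
    mesh = ax.pcolormesh(data, cmap=cmap, edgecolors="0.85", linewidth=0.3)
    mesh.cmap.set_bad("white")
    ax.set_xticks(np.arange(len(m.cols)) + 0.5, m.cols, rotation=90, fontsize=7)
    ax.set_yticks(np.arange(len(m.rows)) + 0.5, m.rows, fontsize=7)
    ax.invert_yaxis()
    fig.colorbar(mesh, ax=ax, label="-log10(E-value)")
    ax.set_xlabel("secondary motif")
    ax.set_ylabel("library / primary motif")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150, metadata=_clean_metadata(path))
    plt.close(fig)
    return path


def plot_spacing_bars(
    hist: SpacingHistogram,
    best_bin: SpacingBin,
    path: str | Path,
    max_gap: int | None = 50,
) -> Path:
    """Bar graph of spacing counts with the preferred bin highlighted red.

    Counts are shown per gap within the best bin's quadrant; other
    quadrants are summarized as a light overlay line.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if hist.n == 0:
        raise ValueError("spacing histogram is empty")
    gaps = sorted({b.gap for b in hist.counts})
    top = max_gap if max_gap is not None else max(gaps)
    xs = np.arange(top + 1)
    quad = best_bin.quadrant
    ys = np.array([hist.counts.get(SpacingBin(quad, g), 0) for g in xs])
    colors = ["red" if g == best_bin.gap else "0.55" for g in xs]
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.bar(xs, ys, color=colors, width=0.9)
    ax.set_xlabel(f"edge-to-edge gap (bp), {quad}")
    ax.set_ylabel("windows")
    ax.set_title(f"preferred spacing: {best_bin.gap} bp ({quad})")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150, metadata=_clean_metadata(path))
    plt.close(fig)
    return path


def _clean_metadata(path: Path) -> dict | None:
    # strip date stamps so identical inputs give byte-identical files
    suffix = path.suffix.lower()
    if suffix == ".svg":
        return {"Date": None}
    if suffix == ".png":
        return {"Software": None}
    return None
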