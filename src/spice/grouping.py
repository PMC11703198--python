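"""Collapse redundant secondary motifs into clusters and re-rank.

Motif databases carry many near-identical matrices for paralogous factors
(ETS1 and ELF1 both match the ETS consensus, say), so a single composite
element shows up once per family member in a library screen.  Results are
grouped by single-linkage clustering on PFM correlation: two secondaries
join when their similarity reaches the threshold, and connected components
form clusters.  Each cluster is represented by its most significant member
and clusters are ranked by that representative's adjusted p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .motif_io import MotifDatabase, motif_similarity
from .spacing_core import PairResult


@dataclass
class MotifCluster:
    """A family of redundant secondary motifs sharing one spacing signal."""

    members: list[PairResult]
    representative: PairResult
    label: str


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_results(
    results: Sequence[PairResult],
    db: MotifDatabase,
    sim_threshold: float = 0.8,
) -> list[MotifCluster]:
    """Single-linkage clustering of screen results by motif similarity.

    Every result appears in exactly one cluster; raising ``sim_threshold``
    only refines the partition (edges can disappear, never appear).
    """
    results = [r for r in results if r.best is not None]
    for r in results:
        if r.secondary_name not in db:
            raise KeyError(f"secondary motif {r.secondary_name!r} not found in the database")
    n = len(results)
    uf = _UnionFind(n)
    for i in range(n):
        mi = db[results[i].secondary_name]
        for j in range(i + 1, n):
            mj = db[results[j].secondary_name]
            min_ov = min(5, mi.width, mj.width)
            if motif_similarity(mi, mj, min_overlap=min_ov) >= sim_threshold:
                uf.union(i, j)
    groups: dict[int, list[PairResult]] = {}
    for i, r in enumerate(results):
        groups.setdefault(uf.find(i), []).append(r)
    clusters = []
    for members in groups.values():
        rep = min(members, key=lambda r: (r.best.p_adj, r.best.bin.sort_key, r.secondary_name))
        clusters.append(MotifCluster(members=members, representative=rep, label=rep.secondary_name))
    clusters.sort(
        key=lambda c: (
            c.representative.best.p_adj,
            c.representative.best.bin.sort_key,
            c.label,
        )
    )
    return clusters


def clusters_to_rows(clusters: Sequence[MotifCluster]) -> list[dict]:
    rows = []
    for i, c in enumerate(clusters):
        rows.append(
            {
                "cluster_id": i,
                "label": c.label,
                "n_members": len(c.members),
                "members": ",".join(sorted(m.secondary_name for m in c.members)),
                "quadrant": c.representative.best.bin.quadrant,
                "gap": c.representative.best.bin.gap,
                "p_adj": c.representative.best.p_adj,
                "evalue": c.representative.evalue,
            }
        )
    return rows
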