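"""GCF assignment by thresholded connected components, and the cutoff sweep.

BGCs of one class form a graph with an edge wherever the pairwise distance is
at or below the cutoff; families are the connected components. The sweep
computes family counts, singleton counts and mean family size across a grid of
cutoffs in a single pass (edges sorted by distance, union-find snapshots), and
a knee heuristic picks the last cutoff before the mean family size explodes.
"""
from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np

from .types import (
    BGCRecord,
    DistanceEdge,
    GCFAssignment,
    SweepResult,
    SweepRow,
    ValidationError,
)

DEFAULT_GRID: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 10))


class UnionFind:
    """Disjoint-set forest with union by size and path compression."""

    def __init__(self, items: Sequence[str]):
        self.parent = {x: x for x in items}
        self.size = {x: 1 for x in items}

    def find(self, x: str) -> str:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]

    def components(self) -> dict[str, list[str]]:
        comps: dict[str, list[str]] = {}
        for x in self.parent:
            comps.setdefault(self.find(x), []).append(x)
        return comps


def _label_components(
    components: dict[str, list[str]], bgc_class: str
) -> tuple[dict[str, str], dict[str, int]]:
    """Number components ascending by their smallest member id."""
    ordered = sorted(components.values(), key=lambda members: min(members))
    membership: dict[str, str] = {}
    sizes: dict[str, int] = {}
    for i, members in enumerate(ordered, start=1):
        gcf_id = f"{bgc_class}_{i}"
        sizes[gcf_id] = len(members)
        for m in members:
            membership[m] = gcf_id
    return membership, sizes


def assign_gcfs(
    edges: Sequence[DistanceEdge],
    bgc_ids: Sequence[str],
    cutoff: float,
    bgc_class: str = "GCF",
) -> GCFAssignment:
    """Assign every BGC of one class to a family at the given cutoff.

    Families are connected components of the graph with an edge where
    ``distance <= cutoff``. Family ids are ``"<class>_<k>"``, numbered
    ascending by each family's smallest member id.
    """
    if not 0 < cutoff < 1:
        raise ValidationError(f"cutoff must lie in (0, 1); got {cutoff}")
    known = set(bgc_ids)
    uf = UnionFind(list(bgc_ids))
    for e in edges:
        if e.bgc_a not in known or e.bgc_b not in known:
            raise ValidationError(f"edge references unknown bgc id: {e.bgc_a}/{e.bgc_b}")
        if e.distance <= cutoff:
            uf.union(e.bgc_a, e.bgc_b)
    membership, sizes = _label_components(uf.components(), bgc_class)
    return GCFAssignment(cutoff=cutoff, membership=membership, sizes=sizes)


def assign_gcfs_all_classes(
    edges_by_class: Mapping[str, Sequence[DistanceEdge]],
    records: Sequence[BGCRecord],
    cutoff: float,
) -> GCFAssignment:
    """Per-class family assignment merged into one membership map."""
    membership: dict[str, str] = {}
    sizes: dict[str, int] = {}
    by_class: dict[str, list[str]] = {}
    for rec in records:
        by_class.setdefault(rec.bgc_class, []).append(rec.bgc_id)
    for cls, ids in sorted(by_class.items()):
        sub = assign_gcfs(edges_by_class.get(cls, ()), ids, cutoff, bgc_class=cls)
        membership.update(sub.membership)
        sizes.update(sub.sizes)
    return GCFAssignment(cutoff=cutoff, membership=membership, sizes=sizes)


def _sweep_one_class(
    edges: Sequence[DistanceEdge],
    bgc_ids: Sequence[str],
    grid: Sequence[float],
    bgc_class: str,
) -> list[SweepRow]:
    n = len(bgc_ids)
    uf = UnionFind(list(bgc_ids))
    ordered = sorted(edges, key=lambda e: e.distance)
    rows = []
    i = 0
    for cutoff in grid:
        while i < len(ordered) and ordered[i].distance <= cutoff:
            uf.union(ordered[i].bgc_a, ordered[i].bgc_b)
            i += 1
        comps = uf.components()
        n_gcfs = len(comps)
        n_singletons = sum(1 for members in comps.values() if len(members) == 1)
        rows.append(
            SweepRow(
                bgc_class=bgc_class,
                cutoff=cutoff,
                n_gcfs=n_gcfs,
                n_singletons=n_singletons,
                mean_gcf_size=n / n_gcfs if n_gcfs else float("nan"),
            )
        )
    return rows


def sweep_cutoffs(
    edges_by_class: Mapping[str, Sequence[DistanceEdge]],
    records: Sequence[BGCRecord],
    grid: Sequence[float] = DEFAULT_GRID,
) -> SweepResult:
    """Clustering metrics per class and pooled ("ALL") across a cutoff grid."""
    grid = list(grid)
    if not grid:
        raise ValidationError("cutoff grid must be non-empty")
    if any(not 0 < c < 1 for c in grid) or any(
        b <= a for a, b in zip(grid, grid[1:])
    ):
        raise ValidationError("grid must be strictly increasing within (0, 1)")
    by_class: dict[str, list[str]] = {}
    for rec in records:
        by_class.setdefault(rec.bgc_class, []).append(rec.bgc_id)

    rows: list[SweepRow] = []
    per_class_rows: dict[str, list[SweepRow]] = {}
    for cls, ids in sorted(by_class.items()):
        cls_rows = _sweep_one_class(edges_by_class.get(cls, ()), ids, grid, cls)
        per_class_rows[cls] = cls_rows
        rows.extend(cls_rows)
    # pooled: classes never share edges, so pooled counts are sums
    n_total = sum(len(ids) for ids in by_class.values())
    for j, cutoff in enumerate(grid):
        n_gcfs = sum(per_class_rows[cls][j].n_gcfs for cls in per_class_rows)
        n_single = sum(per_class_rows[cls][j].n_singletons for cls in per_class_rows)
        rows.append(
            SweepRow(
                bgc_class="ALL",
                cutoff=cutoff,
                n_gcfs=n_gcfs,
                n_singletons=n_single,
                mean_gcf_size=n_total / n_gcfs if n_gcfs else float("nan"),
            )
        )
    return SweepResult(rows=rows)


def select_cutoff(
    sweep: SweepResult,
    policy: str = "knee",
    fixed: float | None = None,
    bgc_class: str = "ALL",
) -> float:
    """Pick a clustering cutoff from a sweep.

    ``fixed`` returns the given value (warning if off-grid). ``knee`` returns
    the grid point whose mean-family-size value lies farthest (perpendicular
    distance, axes min-max normalised) from the chord joining the first and
    last grid points — the last cutoff before family sizes explode. Ties break
    to the smaller cutoff, so a perfectly linear curve yields the grid start.
    """
    rows = sweep.for_class(bgc_class)
    if not rows:
        raise ValidationError(f"sweep holds no rows for class {bgc_class!r}")
    if policy == "fixed":
        if fixed is None:
            raise ValidationError("fixed policy requires a cutoff value")
        if not any(np.isclose(fixed, r.cutoff) for r in rows):
            warnings.warn(f"fixed cutoff {fixed} is not on the sweep grid")
        return fixed
    if policy != "knee":
        raise ValidationError(f"unknown cutoff policy {policy!r}")

    x = np.array([r.cutoff for r in rows], dtype=float)
    y = np.array([r.mean_gcf_size for r in rows], dtype=float)
    if len(x) == 1:
        return float(x[0])
    xn = (x - x[0]) / (x[-1] - x[0])
    yspan = y[-1] - y[0]
    yn = (y - y[0]) / yspan if yspan != 0 else np.zeros_like(y)
    # distance of each point to the chord from (0, yn[0]) to (1, yn[-1])
    p0 = np.array([xn[0], yn[0]])
    p1 = np.array([xn[-1], yn[-1]])
    chord = p1 - p0
    norm = np.hypot(*chord)
    dists = np.abs(chord[0] * (p0[1] - yn) - chord[1] * (p0[0] - xn)) / norm
    best = int(np.argmax(np.round(dists, 12)))  # ties -> smaller cutoff
    return float(x[best])


def gcf_size_table(
    assignment: GCFAssignment,
    records: Sequence[BGCRecord],
    mibig_only: bool = False,
) -> list[int]:
    """Family sizes, optionally restricted to families with a MiBIG-flagged member."""
    if not mibig_only:
        return sorted(assignment.sizes.values(), reverse=True)
    rec_by_id = {r.bgc_id: r for r in records}
    flagged: set[str] = set()
    for bgc_id, gcf_id in assignment.membership.items():
        rec = rec_by_id.get(bgc_id)
        if rec is None:
            raise ValidationError(f"assignment references unknown bgc id {bgc_id!r}")
        if rec.has_mibig_hit:
            flagged.add(gcf_id)
    return sorted((assignment.sizes[g] for g in flagged), reverse=True)


def write_sweep(sweep: SweepResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("bgc_class\tcutoff\tn_gcfs\tn_singletons\tmean_gcf_size\n")
        for r in sweep.rows:
            fh.write(
                f"{r.bgc_class}\t{r.cutoff:.2f}\t{r.n_gcfs}\t{r.n_singletons}"
                f"\t{r.mean_gcf_size:.4f}\n"
            )
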