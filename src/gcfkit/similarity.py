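"""Pairwise BGC distance from domain architecture.

The distance between two BGCs of the same metabolite class combines three
components, each in [0, 1]:

* **Jaccard index** over the sets of domain types present (shared content);
* **adjacency index** — Jaccard over the sets of unordered adjacent
  domain-type pairs (domain order);
* **DSS** (domain sequence similarity) — copies of each shared domain type
  are matched one-to-one to maximise summed copy similarity (1 − normalised
  edit distance of their residue sequences), and the total matched similarity
  is averaged over matched pairs plus all unmatched copies.

``distance = 1 − (w_J·J + w_A·A + w_D·DSS)``. Cross-class pairs are never
formed: each class is clustered independently.
"""
from __future__ import annotations

import itertools
from typing import Sequence

import edlib
import numpy as np
from scipy.optimize import linear_sum_assignment

from .types import BGCRecord, DistanceEdge, DomainCopy, SimilarityWeights, ValidationError


def jaccard_index(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    """|a ∩ b| / |a ∪ b| over domain-type sets. Errors on empty input."""
    if not a or not b:
        raise ValidationError("jaccard_index requires non-empty domain sets")
    return len(a & b) / len(a | b)


def _adjacent_pairs(order: Sequence[str]) -> set[frozenset[str] | tuple[str, str]]:
    # Unordered adjacent pairs; self-pairs (x,x) kept as ordered tuples so a
    # tandem repeat is distinct from nothing.
    pairs: set = set()
    for u, v in zip(order, order[1:]):
        pairs.add(frozenset((u, v)) if u != v else (u, v))
    return pairs


def adjacency_index(a: Sequence[str], b: Sequence[str]) -> float:
    """Jaccard index over unordered adjacent domain-type pairs.

    Lists with fewer than two domains have no pairs: the index is 0 against
    any list that has pairs, and for two single-domain lists it is 1 when the
    types match, else 0.
    """
    if not a or not b:
        raise ValidationError("adjacency_index requires non-empty domain lists")
    if len(a) < 2 and len(b) < 2:
        return 1.0 if a[0] == b[0] else 0.0
    if len(a) < 2 or len(b) < 2:
        return 0.0
    pa, pb = _adjacent_pairs(a), _adjacent_pairs(b)
    return len(pa & pb) / len(pa | pb)


def _copy_similarity(a: DomainCopy, b: DomainCopy) -> float:
    """1 − normalised edit distance of sequences; 1.0 when both lack one."""
    if a.sequence is None and b.sequence is None:
        return 1.0
    sa, sb = a.sequence or "", b.sequence or ""
    denom = max(len(sa), len(sb))
    if denom == 0:
        return 1.0
    dist = edlib.align(sa, sb)["editDistance"]
    return 1.0 - dist / denom


def domain_seq_similarity(a: Sequence[DomainCopy], b: Sequence[DomainCopy]) -> float:
    """Copy-level similarity (DSS) between two domain-copy lists.

    For each domain type shared by both BGCs, copies are matched one-to-one
    by an exact maximum-weight assignment on pairwise copy similarities;
    excess copies of shared types and every copy of a type unique to one BGC
    count as unmatched with similarity 0. The score is

        Σ matched-pair similarity / (n_matched + n_unmatched).
    """
    if not a or not b:
        raise ValidationError("domain_seq_similarity requires non-empty copy lists")
    by_type_a: dict[str, list[DomainCopy]] = {}
    by_type_b: dict[str, list[DomainCopy]] = {}
    for c in a:
        by_type_a.setdefault(c.domain_type, []).append(c)
    for c in b:
        by_type_b.setdefault(c.domain_type, []).append(c)

    shared = set(by_type_a) & set(by_type_b)
    total_sim = 0.0
    n_matched = 0
    n_unmatched = 0
    for dtype in shared:
        ca, cb = by_type_a[dtype], by_type_b[dtype]
        sim = np.array([[_copy_similarity(x, y) for y in cb] for x in ca])
        rows, cols = linear_sum_assignment(-sim)
        total_sim += float(sim[rows, cols].sum())
        n_matched += len(rows)
        n_unmatched += abs(len(ca) - len(cb))
    for dtype in set(by_type_a) - shared:
        n_unmatched += len(by_type_a[dtype])
    for dtype in set(by_type_b) - shared:
        n_unmatched += len(by_type_b[dtype])

    denom = n_matched + n_unmatched
    return total_sim / denom if denom else 0.0


def bgc_distance(
    a: BGCRecord, b: BGCRecord, w: SimilarityWeights | None = None
) -> DistanceEdge:
    """Weighted domain-architecture distance between two same-class BGCs."""
    if a.bgc_class != b.bgc_class:
        raise ValidationError(
            f"cannot compare {a.bgc_id} ({a.bgc_class}) with {b.bgc_id} ({b.bgc_class})"
        )
    w = w or SimilarityWeights()
    first, second = sorted((a, b), key=lambda r: r.bgc_id)
    jac = jaccard_index(a.domain_types, b.domain_types)
    adj = adjacency_index(a.domain_order, b.domain_order)
    dss = domain_seq_similarity(a.domains, b.domains)
    similarity = w.w_jaccard * jac + w.w_adjacency * adj + w.w_dss * dss
    distance = min(1.0, max(0.0, 1.0 - similarity))
    return DistanceEdge(
        bgc_a=first.bgc_id,
        bgc_b=second.bgc_id,
        jaccard=jac,
        adjacency=adj,
        dss=dss,
        distance=distance,
    )


def pairwise_distances(
    records: Sequence[BGCRecord], w: SimilarityWeights | None = None
) -> dict[str, list[DistanceEdge]]:
    """All unordered within-class distance edges, per class.

    Edges are ordered lexicographically by (bgc_a, bgc_b), so the result is
    invariant to the input ordering of records.
    """
    w = w or SimilarityWeights()
    by_class: dict[str, list[BGCRecord]] = {}
    for rec in records:
        by_class.setdefault(rec.bgc_class, []).append(rec)
    edges: dict[str, list[DistanceEdge]] = {}
    for cls, recs in sorted(by_class.items()):
        recs = sorted(recs, key=lambda r: r.bgc_id)
        edges[cls] = [
            bgc_distance(x, y, w) for x, y in itertools.combinations(recs, 2)
        ]
    return edges


def write_edges(edges: Sequence[DistanceEdge], path) -> None:
    """Write an edge-list TSV: bgc_a, bgc_b, jaccard, adjacency, dss, distance."""
    with open(path, "w") as fh:
        fh.write("bgc_a\tbgc_b\tjaccard\tadjacency\tdss\tdistance\n")
        for e in edges:
            fh.write(
                f"{e.bgc_a}\t{e.bgc_b}\t{e.jaccard:.6f}\t{e.adjacency:.6f}"
                f"\t{e.dss:.6f}\t{e.distance:.6f}\n"
            )
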