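"""Core domain types for gene cluster family (GCF) analysis.

A biosynthetic gene cluster (BGC) is represented by its ordered list of
conserved protein-domain copies, its class of predicted metabolite, and the
genome/genus it comes from. Families of similar BGCs (GCFs) are built
downstream from domain-architecture distances.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

#: The seven metabolite classes used to partition every analysis.
BGC_CLASSES: tuple[str, ...] = (
    "NRPS",
    "PKSI",
    "PKSOTHER",
    "PKS-NRP_HYBRIDS",
    "TERPENE",
    "RIPPS",
    "OTHERS",
)


class ValidationError(ValueError):
    """A record or table violates a dataset invariant."""


class FormatError(ValueError):
    """A file does not conform to the expected tabular dialect."""


@dataclass(frozen=True)
class DomainCopy:
    """One copy of a protein domain inside a BGC.

    Parameters
    ----------
    domain_type:
        Domain-family token (e.g. ``"KS"``, ``"AT"``). Non-empty.
    sequence:
        Optional residue string for this copy, used by the copy-level
        similarity component.
    """

    domain_type: str
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.domain_type:
            raise ValidationError("domain_type must be non-empty")


@dataclass
class BGCRecord:
    """One predicted biosynthetic gene cluster."""

    bgc_id: str
    genome_id: str
    genus: str
    species: str
    is_entomopathogen: bool
    bgc_class: str
    domains: list[DomainCopy]
    has_mibig_hit: bool = False
    contig: Optional[str] = None
    start: Optional[int] = None  # 1-based inclusive
    end: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.bgc_id:
            raise ValidationError("bgc_id must be non-empty")
        if self.bgc_class not in BGC_CLASSES:
            raise ValidationError(
                f"record {self.bgc_id!r}: unknown bgc_class {self.bgc_class!r}; "
                f"expected one of {BGC_CLASSES}"
            )
        if not self.domains:
            raise ValidationError(f"record {self.bgc_id!r}: domains must be non-empty")
        if self.start is not None and self.end is not None and self.start > self.end:
            raise ValidationError(f"record {self.bgc_id!r}: start > end")

    @property
    def domain_types(self) -> frozenset[str]:
        return frozenset(d.domain_type for d in self.domains)

    @property
    def domain_order(self) -> tuple[str, ...]:
        return tuple(d.domain_type for d in self.domains)


@dataclass(frozen=True)
class GenomeMeta:
    """Per-genome metadata used for the genome-size association."""

    genome_id: str
    genus: str
    genome_size_mb: float
    n_bgcs: int = 0

    def __post_init__(self) -> None:
        if self.genome_size_mb <= 0:
            raise ValidationError(
                f"genome {self.genome_id!r}: genome_size_mb must be positive"
            )
        if self.n_bgcs < 0:
            raise ValidationError(f"genome {self.genome_id!r}: n_bgcs must be >= 0")


@dataclass
class ClassSummary:
    """BGC counts per metabolite class, per genome and aggregated."""

    counts: dict[str, int]
    per_genome: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cls in BGC_CLASSES:
            self.counts.setdefault(cls, 0)
        bad = [c for c, n in self.counts.items() if n < 0]
        if bad:
            raise ValidationError(f"negative class counts: {bad}")

    @property
    def total(self) -> int:
        return sum(self.counts[c] for c in BGC_CLASSES)

    @property
    def smallest_class(self) -> tuple[str, int]:
        return min(
            ((c, self.counts[c]) for c in BGC_CLASSES), key=lambda kv: (kv[1], kv[0])
        )

    @property
    def largest_class(self) -> tuple[str, int]:
        return max(
            ((c, self.counts[c]) for c in BGC_CLASSES), key=lambda kv: (kv[1], kv[0])
        )


@dataclass(frozen=True)
class AssociationResult:
    """Least-squares fit of BGC count on genome size."""

    pearson_r: float
    slope: float
    intercept: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.pearson_r) > 1 + 1e-12:
            raise ValidationError("|pearson_r| must be <= 1")
        if self.n < 3:
            raise ValidationError("association needs n >= 3")


@dataclass(frozen=True)
class SimilarityWeights:
    """Weights of the three similarity components; must sum to 1.

    The distance between two BGCs of the same class is
    ``1 - (w_jaccard*J + w_adjacency*A + w_dss*DSS)``.
    """

    w_jaccard: float = 0.2
    w_adjacency: float = 0.05
    w_dss: float = 0.75

    def __post_init__(self) -> None:
        if min(self.w_jaccard, self.w_adjacency, self.w_dss) < 0:
            raise ValidationError("similarity weights must be non-negative")
        if abs(self.w_jaccard + self.w_adjacency + self.w_dss - 1.0) > 1e-9:
            raise ValidationError("similarity weights must sum to 1")


@dataclass(frozen=True)
class DistanceEdge:
    """Pairwise distance between two same-class BGCs with its components."""

    bgc_a: str
    bgc_b: str
    jaccard: float
    adjacency: float
    dss: float
    distance: float

    def __post_init__(self) -> None:
        for name in ("jaccard", "adjacency", "dss", "distance"):
            v = getattr(self, name)
            if not (-1e-12 <= v <= 1 + 1e-12):
                raise ValidationError(f"{name}={v} outside [0, 1]")


@dataclass
class GCFAssignment:
    """Family assignment at one distance cutoff.

    ``membership`` maps bgc_id -> gcf_id; gcf_ids look like ``"NRPS_3"``.
    """

    cutoff: float
    membership: dict[str, str]
    sizes: dict[str, int]

    def families(self) -> dict[str, list[str]]:
        fams: dict[str, list[str]] = {}
        for bgc, fam in self.membership.items():
            fams.setdefault(fam, []).append(bgc)
        for members in fams.values():
            members.sort()
        return fams

    @property
    def n_gcfs(self) -> int:
        return len(self.sizes)

    @property
    def n_singletons(self) -> int:
        return sum(1 for s in self.sizes.values() if s == 1)


@dataclass(frozen=True)
class SweepRow:
    """Per-class clustering metrics at one cutoff."""

    bgc_class: str  # "ALL" for pooled
    cutoff: float
    n_gcfs: int
    n_singletons: int
    mean_gcf_size: float


@dataclass
class SweepResult:
    rows: list[SweepRow]

    def for_class(self, bgc_class: str) -> list[SweepRow]:
        return sorted(
            (r for r in self.rows if r.bgc_class == bgc_class), key=lambda r: r.cutoff
        )

    @property
    def cutoffs(self) -> list[float]:
        return sorted({r.cutoff for r in self.rows})


@dataclass
class SpecificityTable:
    """Taxonomic specificity of each GCF and aggregate category counts."""

    per_gcf: dict[str, dict]  # gcf_id -> {size, genera, category}
    category_counts: dict[str, int]

    CATEGORIES = ("singleton", "genus_specific", "multi_genus")


@dataclass(frozen=True)
class ExclusivityHit:
    """A GCF confined to entomopathogenic genera, spanning >= min_genera."""

    gcf_id: str
    genera: frozenset[str]
    member_bgcs: tuple[str, ...]

    @property
    def n_genera(self) -> int:
        return len(self.genera)


def check_unique_ids(records: Sequence[BGCRecord]) -> None:
    """Raise if any bgc_id occurs more than once."""
    seen: set[str] = set()
    for rec in records:
        if rec.bgc_id in seen:
            raise ValidationError(f"duplicate bgc_id {rec.bgc_id!r}")
        seen.add(rec.bgc_id)
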