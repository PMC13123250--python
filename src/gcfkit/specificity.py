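"""Taxonomic specificity of gene cluster families.

Each GCF falls into one of three categories: a *singleton* (one member), a
*genus-specific* family (>= 2 members, all from one genus), or a *multi-genus*
family. A Pearson goodness-of-fit chi-square compares the observed category
counts with a null (uniform by default). Families confined to
insect-pathogenic (entomopathogenic) genera and spanning at least a minimum
number of them are reported as lifestyle-exclusive hits.
"""
from __future__ import annotations

import itertools
from typing import Sequence

from scipy import stats

from .types import (
    BGCRecord,
    ExclusivityHit,
    GCFAssignment,
    SpecificityTable,
    ValidationError,
)

#: Genera treated as entomopathogenic by default (editable configuration).
DEFAULT_ENTOMOPATHOGENIC_GENERA = frozenset(
    {
        "Metarhizium",
        "Beauveria",
        "Cordyceps",
        "Hirsutella",
        "Tolypocladium",
        "Purpureocillium",
        "Akanthomyces",
    }
)


def classify_specificity(
    assignment: GCFAssignment, records: Sequence[BGCRecord]
) -> SpecificityTable:
    """Categorise every GCF as singleton, genus-specific, or multi-genus."""
    rec_by_id = {r.bgc_id: r for r in records}
    per_gcf: dict[str, dict] = {}
    for gcf_id, members in assignment.families().items():
        genera = set()
        for bgc_id in members:
            rec = rec_by_id.get(bgc_id)
            if rec is None:
                raise ValidationError(f"assignment references unknown bgc id {bgc_id!r}")
            genera.add(rec.genus)
        if len(members) == 1:
            category = "singleton"
        elif len(genera) == 1:
            category = "genus_specific"
        else:
            category = "multi_genus"
        per_gcf[gcf_id] = {
            "size": len(members),
            "genera": frozenset(genera),
            "category": category,
        }
    counts = {c: 0 for c in SpecificityTable.CATEGORIES}
    for info in per_gcf.values():
        counts[info["category"]] += 1
    return SpecificityTable(per_gcf=per_gcf, category_counts=counts)


def specificity_chi_square(
    table: SpecificityTable, null: Sequence[float] | None = None
) -> tuple[float, int, float]:
    """Pearson goodness-of-fit chi-square of the three category counts.

    ``null`` gives expected proportions (summing to 1) in the category order
    singleton, genus_specific, multi_genus; the default is uniform. Returns
    (chi2, df, p) with df = number of categories - 1 = 2.
    """
    observed = [table.category_counts[c] for c in SpecificityTable.CATEGORIES]
    total = sum(observed)
    if total < 1:
        raise ValidationError("chi-square needs at least one GCF")
    if null is None:
        null = [1 / 3] * 3
    if abs(sum(null) - 1.0) > 1e-9:
        raise ValidationError("null proportions must sum to 1")
    expected = [total * p for p in null]
    if any(e == 0 for e in expected):
        raise ValidationError("expected count of zero under the null")
    chi2, p = stats.chisquare(observed, f_exp=expected)
    return float(chi2), len(observed) - 1, float(p)


def find_lifestyle_exclusive_gcfs(
    assignment: GCFAssignment,
    records: Sequence[BGCRecord],
    min_genera: int = 3,
    entomopathogenic_genera: frozenset[str] | None = None,
) -> list[ExclusivityHit]:
    """GCFs found only in entomopathogenic genera, spanning >= min_genera.

    A family with even one member from a non-entomopathogenic genus is
    excluded. The genus lifestyle is taken from the records'
    ``is_entomopathogen`` flags unless an explicit genus set is given. Hits
    are sorted by descending genus count, then gcf_id.
    """
    rec_by_id = {r.bgc_id: r for r in records}
    hits = []
    for gcf_id, members in assignment.families().items():
        genera = set()
        contaminated = False
        for bgc_id in members:
            rec = rec_by_id.get(bgc_id)
            if rec is None:
                raise ValidationError(f"assignment references unknown bgc id {bgc_id!r}")
            is_entomo = (
                rec.genus in entomopathogenic_genera
                if entomopathogenic_genera is not None
                else rec.is_entomopathogen
            )
            if not is_entomo:
                contaminated = True
                break
            genera.add(rec.genus)
        if contaminated or len(genera) < min_genera:
            continue
        hits.append(
            ExclusivityHit(
                gcf_id=gcf_id,
                genera=frozenset(genera),
                member_bgcs=tuple(sorted(members)),
            )
        )
    hits.sort(key=lambda h: (-h.n_genera, h.gcf_id))
    return hits


def genus_cooccurrence(hits: Sequence[ExclusivityHit]) -> dict[tuple[str, str], int]:
    """Count, for each unordered genus pair, the exclusive GCFs containing both."""
    table: dict[tuple[str, str], int] = {}
    for hit in hits:
        for a, b in itertools.combinations(sorted(hit.genera), 2):
            table[(a, b)] = table.get((a, b), 0) + 1
    return table


def write_specificity(table: SpecificityTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("gcf_id\tsize\tn_genera\tcategory\n")
        for gcf_id in sorted(table.per_gcf):
            info = table.per_gcf[gcf_id]
            fh.write(
                f"{gcf_id}\t{info['size']}\t{len(info['genera'])}\t{info['category']}\n"
            )


def write_exclusivity(hits: Sequence[ExclusivityHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("gcf_id\tn_genera\tgenera\tmember_bgcs\n")
        for h in hits:
            fh.write(
                f"{h.gcf_id}\t{h.n_genera}\t{','.join(sorted(h.genera))}"
                f"\t{','.join(h.member_bgcs)}\n"
            )
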