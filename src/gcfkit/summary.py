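"""Dataset-level summaries: per-class BGC counts and the genome-size association."""
from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats

from .types import (
    AssociationResult,
    BGCRecord,
    ClassSummary,
    GenomeMeta,
    ValidationError,
)


def summarize_by_class(records: Sequence[BGCRecord]) -> ClassSummary:
    """Count BGCs per metabolite class, overall and per genome.

    The total always equals the number of input records; an empty input
    yields an all-zero summary.
    """
    counts: dict[str, int] = {}
    per_genome: dict[str, dict[str, int]] = {}
    for rec in records:
        counts[rec.bgc_class] = counts.get(rec.bgc_class, 0) + 1
        g = per_genome.setdefault(rec.genome_id, {})
        g[rec.bgc_class] = g.get(rec.bgc_class, 0) + 1
    return ClassSummary(counts=counts, per_genome=per_genome)


def genome_bgc_association(genomes: Sequence[GenomeMeta]) -> AssociationResult:
    """Ordinary least-squares fit of BGC count on genome size (Mb).

    Returns the slope/intercept, Pearson's r and its two-sided p-value.
    Raises if either variable has zero variance (correlation undefined).
    """
    if len(genomes) < 3:
        raise ValidationError("association needs at least 3 genomes")
    x = np.array([g.genome_size_mb for g in genomes], dtype=float)
    y = np.array([g.n_bgcs for g in genomes], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant genome size or BGC count: correlation undefined")
    fit = stats.linregress(x, y)
    return AssociationResult(
        pearson_r=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        n=len(genomes),
    )
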