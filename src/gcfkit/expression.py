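"""Read-count normalisation and BGC induction scoring.

Counts are normalised with median-of-ratios size factors (the standard
RNA-seq library-size estimator), stabilised with a log2(normalised + 1)
transform — a monotone, variance-flattening stand-in for a full
dispersion-trend variance-stabilising transform — and summarised as induction
scores: the mean transformed expression in infection samples minus the mean in
saprophytic controls, per gene and averaged per BGC.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SampleInfo:
    """Metadata for one RNA-seq sample."""

    sample_id: str
    condition: str  # "infection" | "saprophytic_control"
    host: str = "control"  # e.g. "Ac" (pea aphid), "Tc" (flour beetle), "control"
    timepoint: str = "0"


@dataclass
class BGCGeneSet:
    """The ordered genes of one BGC, with its backbone genes flagged."""

    gcf_id: str
    bgc_id: str
    genes: list[str]
    backbone: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"{self.bgc_id}: gene set must be non-empty")
        if not self.backbone <= set(self.genes):
            raise ValidationError(f"{self.bgc_id}: backbone genes must be a subset")


def _check_counts(counts: pd.DataFrame) -> None:
    if (counts.values < 0).any():
        raise ValidationError("counts matrix contains negative entries")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (genes x samples input).

    Genes with a zero in any sample are excluded from the geometric-mean
    reference; the size factor of a sample is the median ratio of its counts
    to the reference. Errors if no gene survives the zero filter.
    """
    _check_counts(counts)
    values = counts.values.astype(float)
    nonzero = (values > 0).all(axis=1)
    if not nonzero.any():
        raise ValidationError("no gene is nonzero in all samples; cannot normalise")
    sub = values[nonzero]
    log_geomean = np.mean(np.log(sub), axis=1)
    ratios = np.log(sub) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def vst_like_transform(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """log2(count / size_factor + 1) — monotone and variance-flattening."""
    _check_counts(counts)
    if factors is None:
        factors = size_factors(counts)
    if (factors <= 0).any():
        raise ValidationError("size factors must be positive")
    normalised = counts.div(factors, axis=1)
    return np.log2(normalised + 1.0)


def _split_samples(
    samples: Sequence[SampleInfo],
) -> tuple[list[SampleInfo], list[SampleInfo]]:
    infection = [s for s in samples if s.condition == "infection"]
    control = [s for s in samples if s.condition == "saprophytic_control"]
    if not infection or not control:
        raise ValidationError("need at least one infection and one control sample")
    return infection, control


def bgc_induction_scores(
    transformed: pd.DataFrame,
    samples: Sequence[SampleInfo],
    gene_set: BGCGeneSet,
) -> dict:
    """Induction scores of one BGC's genes: infection mean - control mean.

    Returns per-gene scores (pooled across hosts and per host), the per-BGC
    mean score, and the list of genes absent from the matrix (skipped with a
    warning, not an error).
    """
    infection, control = _split_samples(samples)
    present = [g for g in gene_set.genes if g in transformed.index]
    missing = [g for g in gene_set.genes if g not in transformed.index]
    if missing:
        logger.warning(
            "%s: %d gene(s) absent from the count matrix: %s",
            gene_set.bgc_id, len(missing), ",".join(missing),
        )
    if not present:
        raise ValidationError(f"{gene_set.bgc_id}: no gene found in the matrix")

    inf_cols = [s.sample_id for s in infection]
    ctl_cols = [s.sample_id for s in control]
    pooled = (
        transformed.loc[present, inf_cols].mean(axis=1)
        - transformed.loc[present, ctl_cols].mean(axis=1)
    )
    per_host: dict[str, pd.Series] = {}
    for host in sorted({s.host for s in infection}):
        host_cols = [s.sample_id for s in infection if s.host == host]
        per_host[host] = (
            transformed.loc[present, host_cols].mean(axis=1)
            - transformed.loc[present, ctl_cols].mean(axis=1)
        )
    return {
        "gcf_id": gene_set.gcf_id,
        "bgc_id": gene_set.bgc_id,
        "per_gene": pooled,
        "per_host": per_host,
        "bgc_score": float(pooled.mean()),
        "backbone": sorted(gene_set.backbone & set(present)),
        "missing_genes": missing,
    }


def heatmap_matrix_export(
    transformed: pd.DataFrame,
    gene_sets: Sequence[BGCGeneSet],
    samples: Sequence[SampleInfo],
    out_dir,
) -> list[Path]:
    """One TSV per BGC: rows = genes (backbone marked '*'), columns ordered
    by (host, timepoint, sample_id); values are transformed expression."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ordered = sorted(samples, key=lambda s: (s.host, s.timepoint, s.sample_id))
    cols = [s.sample_id for s in ordered]
    paths = []
    for gs in gene_sets:
        present = [g for g in gs.genes if g in transformed.index]
        mat = transformed.loc[present, cols].copy()
        mat.index = [f"{g}*" if g in gs.backbone else g for g in present]
        path = out_dir / f"heatmap_{gs.bgc_id}.tsv"
        mat.to_csv(path, sep="\t", index_label="gene")
        paths.append(path)
    return paths


def read_counts_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_counts(df)
    return df


def read_sample_table(path) -> list[SampleInfo]:
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "condition"):
        if col not in df.columns:
            raise ValidationError(f"sample table missing column {col!r}")
    return [
        SampleInfo(
            sample_id=str(row.sample_id),
            condition=str(row.condition),
            host=str(getattr(row, "host", "control")),
            timepoint=str(getattr(row, "timepoint", "0")),
        )
        for row in df.itertuples(index=False)
    ]


def read_gene_sets(path) -> list[BGCGeneSet]:
    """Read a BGC gene-set TSV: gcf_id, bgc_id, gene_id, is_backbone."""
    df = pd.read_csv(path, sep="\t")
    sets: dict[str, BGCGeneSet] = {}
    for row in df.itertuples(index=False):
        key = str(row.bgc_id)
        if key not in sets:
            sets[key] = BGCGeneSet(gcf_id=str(row.gcf_id), bgc_id=key, genes=[str(row.gene_id)])
        else:
            sets[key].genes.append(str(row.gene_id))
        if bool(int(row.is_backbone)):
            sets[key].backbone.add(str(row.gene_id))
    return list(sets.values())
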