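"""Tabular readers and writers.

All formats are plain tab-separated text with a header row:

* BGC inventory — one row per BGC; the ``domains`` column is a semicolon-joined
  ordered token list, each copy optionally carrying a residue sequence after a
  colon (``KS:MAT...;AT;PP``).
* Genome metadata — ``genome_id``, ``genus``, ``genome_size_mb`` (+ optional
  ``n_bgcs``).
* Clustering — the two-column family dialect (BGC name, family label), with
  ``#``-prefixed comment lines tolerated.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence, Union

from .types import (
    BGCRecord,
    DomainCopy,
    FormatError,
    GenomeMeta,
    ValidationError,
    check_unique_ids,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_BGC_REQUIRED = (
    "bgc_id",
    "genome_id",
    "genus",
    "species",
    "is_entomopathogen",
    "bgc_class",
    "domains",
)
_BGC_OPTIONAL = ("has_mibig_hit", "contig", "start", "end")


def _parse_bool(value: str) -> bool:
    v = value.strip().lower()
    if v in ("1", "true", "yes"):
        return True
    if v in ("0", "false", "no"):
        return False
    raise FormatError(f"cannot parse boolean field {value!r}")


def parse_domain_string(text: str, bgc_id: str = "?") -> list[DomainCopy]:
    """Parse ``type[:SEQ];type[:SEQ];...`` into ordered domain copies."""
    if not text.strip():
        raise ValidationError(f"record {bgc_id!r}: empty domain field")
    copies = []
    for token in text.split(";"):
        token = token.strip()
        if not token:
            raise ValidationError(f"record {bgc_id!r}: empty domain token")
        if ":" in token:
            dtype, seq = token.split(":", 1)
            copies.append(DomainCopy(dtype, seq or None))
        else:
            copies.append(DomainCopy(token))
    return copies


def format_domain_string(domains: Sequence[DomainCopy]) -> str:
    return ";".join(
        d.domain_type if d.sequence is None else f"{d.domain_type}:{d.sequence}"
        for d in domains
    )


def read_bgc_table(path: PathLike) -> list[BGCRecord]:
    """Read a BGC inventory TSV into validated records, preserving order."""
    path = Path(path)
    with path.open() as fh:
        header_line = fh.readline()
        if not header_line:
            raise FormatError(f"{path}: empty file")
        header = header_line.rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        for required in _BGC_REQUIRED:
            if required not in col:
                raise FormatError(f"{path}: missing required column {required!r}")
        records: list[BGCRecord] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")

            def get(name: str) -> str:
                idx = col.get(name)
                if idx is None or idx >= len(fields):
                    return ""
                return fields[idx]

            bgc_id = get("bgc_id")
            try:
                rec = BGCRecord(
                    bgc_id=bgc_id,
                    genome_id=get("genome_id"),
                    genus=get("genus"),
                    species=get("species"),
                    is_entomopathogen=_parse_bool(get("is_entomopathogen")),
                    bgc_class=get("bgc_class"),
                    domains=parse_domain_string(get("domains"), bgc_id),
                    has_mibig_hit=_parse_bool(get("has_mibig_hit") or "0"),
                    contig=get("contig") or None,
                    start=int(get("start")) if get("start") else None,
                    end=int(get("end")) if get("end") else None,
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    check_unique_ids(records)
    return records


def write_bgc_table(records: Iterable[BGCRecord], path: PathLike) -> None:
    path = Path(path)
    cols = _BGC_REQUIRED + _BGC_OPTIONAL
    with path.open("w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            row = [
                r.bgc_id,
                r.genome_id,
                r.genus,
                r.species,
                "1" if r.is_entomopathogen else "0",
                r.bgc_class,
                format_domain_string(r.domains),
                "1" if r.has_mibig_hit else "0",
                r.contig or "",
                "" if r.start is None else str(r.start),
                "" if r.end is None else str(r.end),
            ]
            fh.write("\t".join(row) + "\n")


def read_genome_table(path: PathLike) -> list[GenomeMeta]:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        for required in ("genome_id", "genus", "genome_size_mb"):
            if required not in col:
                raise FormatError(f"{path}: missing required column {required!r}")
        genomes = []
        seen: set[str] = set()
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            gid = fields[col["genome_id"]]
            if gid in seen:
                raise ValidationError(f"duplicate genome_id {gid!r}")
            seen.add(gid)
            genomes.append(
                GenomeMeta(
                    genome_id=gid,
                    genus=fields[col["genus"]],
                    genome_size_mb=float(fields[col["genome_size_mb"]]),
                    n_bgcs=int(fields[col["n_bgcs"]]) if "n_bgcs" in col else 0,
                )
            )
    return genomes


def write_genome_table(genomes: Iterable[GenomeMeta], path: PathLike) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("genome_id\tgenus\tgenome_size_mb\tn_bgcs\n")
        for g in genomes:
            fh.write(f"{g.genome_id}\t{g.genus}\t{g.genome_size_mb:.6g}\t{g.n_bgcs}\n")


def read_bigscape_clustering(path: PathLike) -> dict[str, str]:
    """Read the two-column clustering dialect (BGC name, family label).

    Comment lines starting with ``#`` are ignored; rows whose family field is
    not integer-like are skipped with a logged warning and a reported count.
    """
    path = Path(path)
    mapping: dict[str, str] = {}
    skipped = 0
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                skipped += 1
                continue
            name, family = fields[0].strip(), fields[1].strip()
            # Family labels are opaque strings, but must look integer-like at
            # the tail (e.g. "123" or "NRPS_123") to be a clustering row.
            tail = family.rsplit("_", 1)[-1]
            try:
                int(tail)
            except ValueError:
                skipped += 1
                continue
            mapping[name] = family
    if skipped:
        logger.warning("%s: skipped %d malformed clustering rows", path, skipped)
    return mapping


def write_clustering(mapping: dict[str, str], path: PathLike) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#BGC Name\tFamily Number\n")
        for bgc in sorted(mapping):
            fh.write(f"{bgc}\t{mapping[bgc]}\n")
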