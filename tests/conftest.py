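from __future__ import annotations

import numpy as np
import pytest

from gcfkit.types import BGCRecord, DomainCopy


def make_record(
    bgc_id: str,
    domains,
    bgc_class: str = "NRPS",
    genus: str = "Beauveria",
    genome_id: str = "G000",
    is_entomopathogen: bool = True,
    has_mibig_hit: bool = False,
) -> BGCRecord:
    """Build a record from a compact domain spec: "KS" or ("KS", "SEQ")."""
    copies = [
        DomainCopy(d) if isinstance(d, str) else DomainCopy(d[0], d[1])
        for d in domains
    ]
    return BGCRecord(
        bgc_id=bgc_id,
        genome_id=genome_id,
        genus=genus,
        species=f"{genus.lower()}_sp1",
        is_entomopathogen=is_entomopathogen,
        bgc_class=bgc_class,
        domains=copies,
        has_mibig_hit=has_mibig_hit,
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
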