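"""Synthetic datasets with known ground truth.

Two generators back the whole analysis:

* ``simulate_dataset`` builds a BGC inventory the way the clustering assumes
  the real world works: each ancestral gene cluster family has a prototype
  domain architecture (ordered domain tokens, each copy carrying a residue
  sequence); family sizes follow a heavy-tailed law; members are mutated
  copies of the prototype allocated mostly to the family's home genus; every
  genome also receives unrelated orphan BGCs. Prototypes of the same class
  are rejection-sampled to keep a minimum Jaccard separation, so ground-truth
  recovery by distance clustering is well-posed.
* ``simulate_counts_matrix`` builds negative-binomial RNA-seq read counts
  with a planted set of infection-induced genes (mean multiplied by
  ``2**log2fc`` in infection samples).

Everything is deterministic under a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .expression import SampleInfo
from .types import BGCRecord, DomainCopy, GenomeMeta, ValidationError

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Class probabilities matching the observed class composition of a large
#: fungal BGC inventory (NRPS-heavy, RiPP-poor).
DEFAULT_CLASS_PROBS: dict[str, float] = {
    "NRPS": 4950 / 12968,
    "PKSI": 2899 / 12968,
    "TERPENE": 2314 / 12968,
    "OTHERS": 1398 / 12968,
    "PKS-NRP_HYBRIDS": 1156 / 12968,
    "PKSOTHER": 211 / 12968,
    "RIPPS": 40 / 12968,
}

_ENTOMO_POOL = (
    "Metarhizium", "Beauveria", "Cordyceps", "Hirsutella",
    "Tolypocladium", "Purpureocillium", "Akanthomyces",
)
_NON_ENTOMO_POOL = (
    "Fusarium", "Trichoderma", "Claviceps", "Nectria",
    "Geosmithia", "Escovopsis", "Stachybotrys",
)


@dataclass(frozen=True)
class PowerLawSizes:
    """Family sizes ~ discrete power law p(k) ∝ k^(-alpha), k >= 1."""

    alpha: float = 2.5


@dataclass(frozen=True)
class LognormalSizes:
    """Family sizes = round(Lognormal(mu, sigma)), floored at 1."""

    mu: float = 1.4
    sigma: float = 0.8


SizeLaw = Union[PowerLawSizes, LognormalSizes]


@dataclass
class SimConfig:
    """Knobs of the BGC inventory generator.

    Defaults emulate a Hypocreales-like survey scaled to test size: a dozen
    genera (half entomopathogenic), a few genomes per genus, lognormal family
    sizes with mean ~6, NRPS-dominated class mix, low within-family mutation.
    """

    n_genera: int = 12
    entomopathogen_fraction: float = 0.5
    species_per_genus: int = 4
    n_ancestral_gcfs: int = 40
    gcf_size_law: SizeLaw = field(default_factory=LognormalSizes)
    class_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROBS)
    )
    domain_alphabet_size: int = 200
    prototype_length_range: tuple[int, int] = (5, 15)
    sequence_length: int = 30
    mutation_rate: float = 0.02
    indel_rate: float = 0.01
    orphan_rate: float = 1.0
    genus_fidelity: float = 0.85
    prototype_min_separation: float = 0.8  # min Jaccard distance between prototypes
    mibig_rate: float = 0.03
    total_bgc_budget: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.array(list(self.class_probs.values()))
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValidationError("class_probs must sum to 1")
        for name in ("mutation_rate", "indel_rate", "entomopathogen_fraction",
                     "genus_fidelity"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.orphan_rate < 0:
            raise ValidationError("orphan_rate must be >= 0")
        if self.n_ancestral_gcfs == 0 and self.orphan_rate == 0:
            raise ValidationError("no families and no orphans: nothing to simulate")
        lo, hi = self.prototype_length_range
        if not 1 <= lo <= hi:
            raise ValidationError("invalid prototype_length_range")


@dataclass
class GroundTruth:
    """What the generator planted: true family labels and genus sets."""

    true_family: dict[str, str]  # bgc_id -> family label (orphans unique)
    family_genera: dict[str, set[str]]
    induced_genes: set[str] = field(default_factory=set)

    def labels_for(self, bgc_ids: Sequence[str]) -> list[str]:
        return [self.true_family[b] for b in bgc_ids]


def simulate_gcf_sizes(law: SizeLaw, n: int, seed: int | None = None) -> list[int]:
    """Draw n integer family sizes >= 1 from the given law.

    The power law samples the zeta-normalised pmf on k >= 1 by inverse CDF;
    the lognormal is discretised by rounding and floored at 1.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(law, PowerLawSizes):
        if law.alpha <= 1:
            raise ValidationError("power-law alpha must exceed 1 (normalisability)")
        return [int(v) for v in stats.zipf.rvs(law.alpha, size=n, random_state=rng)]
    if isinstance(law, LognormalSizes):
        if law.sigma <= 0:
            raise ValidationError("lognormal sigma must be positive")
        draws = rng.lognormal(mean=law.mu, sigma=law.sigma, size=n)
        return [max(1, int(round(v))) for v in draws]
    raise ValidationError(f"unknown size law {law!r}")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(RESIDUES), size=length))


def _jaccard(a: set, b: set) -> float:
    return len(a & b) / len(a | b)


def _sample_prototype_tokens(
    rng: np.random.Generator,
    length: int,
    alphabet: list[str],
    existing: list[set[str]],
    min_separation: float,
    max_tries: int = 200,
) -> list[str]:
    """Distinct tokens, rejection-sampled to keep Jaccard distance from every
    existing same-class prototype at or above ``min_separation``."""
    for _ in range(max_tries):
        tokens = list(rng.choice(alphabet, size=length, replace=False))
        tset = set(tokens)
        if all(1 - _jaccard(tset, other) >= min_separation for other in existing):
            return tokens
    raise ValidationError(
        "could not sample a sufficiently separated prototype; "
        "increase domain_alphabet_size or lower prototype_min_separation"
    )


def _mutate_copy(
    rng: np.random.Generator, copy: DomainCopy, cfg: SimConfig, alphabet: list[str]
) -> DomainCopy:
    dtype, seq = copy.domain_type, copy.sequence
    if rng.random() < cfg.mutation_rate:  # token identity substitution
        dtype = str(rng.choice(alphabet))
        seq = _random_sequence(rng, cfg.sequence_length)
    elif seq is not None and cfg.mutation_rate > 0:  # point mutations
        chars = list(seq)
        hits = rng.random(len(chars)) < cfg.mutation_rate
        for i in np.flatnonzero(hits):
            chars[i] = str(rng.choice(list(RESIDUES)))
        seq = "".join(chars)
    return DomainCopy(dtype, seq)


def _mutate_architecture(
    rng: np.random.Generator,
    prototype: list[DomainCopy],
    cfg: SimConfig,
    alphabet: list[str],
) -> list[DomainCopy]:
    out: list[DomainCopy] = []
    for copy in prototype:
        if rng.random() < cfg.indel_rate / 2:  # deletion
            continue
        out.append(_mutate_copy(rng, copy, cfg, alphabet))
        if rng.random() < cfg.indel_rate / 2:  # insertion
            out.append(
                DomainCopy(
                    str(rng.choice(alphabet)),
                    _random_sequence(rng, cfg.sequence_length),
                )
            )
    if not out:  # architecture must stay non-empty
        out.append(_mutate_copy(rng, prototype[0], cfg, alphabet))
    return out


def _trim_to_budget(sizes: list[int], budget: int) -> list[int]:
    """Shrink the largest families until the total fits the budget."""
    if budget < len(sizes):
        raise ValidationError("budget smaller than the number of families")
    sizes = list(sizes)
    while sum(sizes) > budget:
        i = int(np.argmax(sizes))
        sizes[i] = max(1, sizes[i] - (sum(sizes) - budget))
    return sizes


def simulate_dataset(
    cfg: SimConfig,
) -> tuple[list[BGCRecord], list[GenomeMeta], GroundTruth]:
    """Generate a BGC inventory with planted family structure.

    Returns the records, per-genome metadata (with a weak positive link
    between genome size and BGC count), and the ground truth.
    """
    rng = np.random.default_rng(cfg.seed)
    classes = list(cfg.class_probs)
    class_p = np.array([cfg.class_probs[c] for c in classes])
    alphabet = [f"D{i:04d}" for i in range(cfg.domain_alphabet_size)]

    # --- taxa ---------------------------------------------------------------
    n_entomo = int(round(cfg.entomopathogen_fraction * cfg.n_genera))
    genera: list[tuple[str, bool]] = []
    for i in range(n_entomo):
        name = _ENTOMO_POOL[i] if i < len(_ENTOMO_POOL) else f"Entomogenus{i:02d}"
        genera.append((name, True))
    for i in range(cfg.n_genera - n_entomo):
        name = (
            _NON_ENTOMO_POOL[i] if i < len(_NON_ENTOMO_POOL) else f"Saprogenus{i:02d}"
        )
        genera.append((name, False))

    genomes_by_genus: dict[str, list[str]] = {}
    genome_genus: dict[str, str] = {}
    genome_entomo: dict[str, bool] = {}
    genome_species: dict[str, str] = {}
    gid = 0
    for genus, entomo in genera:
        for s in range(cfg.species_per_genus):
            genome_id = f"G{gid:03d}"
            gid += 1
            genomes_by_genus.setdefault(genus, []).append(genome_id)
            genome_genus[genome_id] = genus
            genome_entomo[genome_id] = entomo
            genome_species[genome_id] = f"{genus.lower()}_sp{s + 1}"

    all_genomes = sorted(genome_genus)
    genus_names = [g for g, _ in genera]

    # --- ancestral families ---------------------------------------------------
    prototypes: list[list[DomainCopy]] = []
    proto_class: list[str] = []
    tokens_by_class: dict[str, list[set[str]]] = {}
    for _ in range(cfg.n_ancestral_gcfs):
        cls = str(rng.choice(classes, p=class_p))
        length = int(rng.integers(*cfg.prototype_length_range, endpoint=True))
        tokens = _sample_prototype_tokens(
            rng, length, alphabet, tokens_by_class.setdefault(cls, []),
            cfg.prototype_min_separation,
        )
        tokens_by_class[cls].append(set(tokens))
        prototypes.append(
            [DomainCopy(t, _random_sequence(rng, cfg.sequence_length)) for t in tokens]
        )
        proto_class.append(cls)

    sizes: list[int] = []
    if cfg.n_ancestral_gcfs:
        sizes = simulate_gcf_sizes(
            cfg.gcf_size_law, cfg.n_ancestral_gcfs, seed=int(rng.integers(2**31))
        )
        if cfg.total_bgc_budget is not None:
            sizes = _trim_to_budget(sizes, cfg.total_bgc_budget)

    # --- members ----------------------------------------------------------------
    records: list[BGCRecord] = []
    true_family: dict[str, str] = {}
    family_genera: dict[str, set[str]] = {}
    bgc_counter = 0
    for fam_idx, (proto, cls, size) in enumerate(zip(prototypes, proto_class, sizes)):
        label = f"FAM{fam_idx:04d}"
        home_genus = str(rng.choice(genus_names))
        family_genera[label] = set()
        for _ in range(size):
            if rng.random() < cfg.genus_fidelity:
                genus = home_genus
            else:
                others = [g for g in genus_names if g != home_genus]
                genus = str(rng.choice(others)) if others else home_genus
            genome_id = str(rng.choice(genomes_by_genus[genus]))
            bgc_id = f"BGC{bgc_counter:05d}"
            bgc_counter += 1
            records.append(
                BGCRecord(
                    bgc_id=bgc_id,
                    genome_id=genome_id,
                    genus=genus,
                    species=genome_species[genome_id],
                    is_entomopathogen=genome_entomo[genome_id],
                    bgc_class=cls,
                    domains=_mutate_architecture(rng, proto, cfg, alphabet),
                    has_mibig_hit=bool(rng.random() < cfg.mibig_rate),
                )
            )
            true_family[bgc_id] = label
            family_genera[label].add(genus)

    # --- orphans ---------------------------------------------------------------
    orphan_counter = 0
    for genome_id in all_genomes:
        for _ in range(int(rng.poisson(cfg.orphan_rate))):
            cls = str(rng.choice(classes, p=class_p))
            length = int(rng.integers(*cfg.prototype_length_range, endpoint=True))
            try:
                tokens = _sample_prototype_tokens(
                    rng, length, alphabet, tokens_by_class.setdefault(cls, []),
                    cfg.prototype_min_separation,
                )
            except ValidationError:
                continue  # alphabet exhausted: skip rather than break separation
            bgc_id = f"BGC{bgc_counter:05d}"
            bgc_counter += 1
            label = f"ORPHAN{orphan_counter:04d}"
            orphan_counter += 1
            genus = genome_genus[genome_id]
            records.append(
                BGCRecord(
                    bgc_id=bgc_id,
                    genome_id=genome_id,
                    genus=genus,
                    species=genome_species[genome_id],
                    is_entomopathogen=genome_entomo[genome_id],
                    bgc_class=cls,
                    domains=[
                        DomainCopy(t, _random_sequence(rng, cfg.sequence_length))
                        for t in tokens
                    ],
                    has_mibig_hit=bool(rng.random() < cfg.mibig_rate),
                )
            )
            true_family[bgc_id] = label
            family_genera[label] = {genus}

    # --- genome metadata ----------------------------------------------------------
    n_bgcs = {g: 0 for g in all_genomes}
    for rec in records:
        n_bgcs[rec.genome_id] += 1
    genomes = [
        GenomeMeta(
            genome_id=g,
            genus=genome_genus[g],
            genome_size_mb=float(
                max(5.0, 30.0 + 0.15 * n_bgcs[g] + rng.normal(0.0, 3.0))
            ),
            n_bgcs=n_bgcs[g],
        )
        for g in all_genomes
    ]
    return records, genomes, GroundTruth(true_family, family_genera)


# ---------------------------------------------------------------------------
# RNA-seq counts


def make_infection_design(
    n_per_group: int = 3,
    hosts: tuple[str, ...] = ("Ac", "Tc"),
    timepoints: tuple[str, ...] = ("24h", "48h"),
) -> list[SampleInfo]:
    """A balanced infection/control design over hosts and timepoints."""
    samples = []
    for host in hosts:
        for tp in timepoints:
            for r in range(n_per_group):
                samples.append(
                    SampleInfo(f"inf_{host}_{tp}_r{r + 1}", "infection", host, tp)
                )
    for r in range(n_per_group * len(timepoints)):
        samples.append(
            SampleInfo(f"ctl_r{r + 1}", "saprophytic_control", "control", "0")
        )
    return samples


def simulate_counts_matrix(
    n_genes: int,
    samples: Sequence[SampleInfo],
    induced_genes: set[str] | Sequence[str] = (),
    log2fc: float = 2.0,
    dispersion: float = 0.05,
    seed: int | None = None,
    baseline_means: np.ndarray | None = None,
) -> pd.DataFrame:
    """Negative-binomial counts (genes x samples) with planted induction.

    Gene baselines are lognormal unless given; induced genes have their mean
    multiplied by ``2**log2fc`` in infection samples. The NB is parameterised
    mean m and dispersion d with variance m + d m².
    """
    if dispersion <= 0:
        raise ValidationError("dispersion must be positive")
    conditions = {s.condition for s in samples}
    if "infection" not in conditions or "saprophytic_control" not in conditions:
        raise ValidationError("need at least one infection and one control sample")
    rng = np.random.default_rng(seed)
    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    induced = set(induced_genes)
    unknown = induced - set(gene_ids)
    if unknown:
        raise ValidationError(f"induced genes not in the matrix: {sorted(unknown)[:5]}")
    if baseline_means is None:
        baseline_means = rng.lognormal(mean=np.log(200.0), sigma=1.0, size=n_genes)
    baseline_means = np.asarray(baseline_means, dtype=float)
    if baseline_means.shape != (n_genes,):
        raise ValidationError("baseline_means must have one entry per gene")

    induced_mask = np.array([g in induced for g in gene_ids])
    r = 1.0 / dispersion  # NB number of failures
    data = np.zeros((n_genes, len(samples)), dtype=int)
    for j, s in enumerate(samples):
        means = baseline_means.copy()
        if s.condition == "infection":
            means[induced_mask] *= 2.0**log2fc
        pos = means > 0
        p = np.ones_like(means)
        p[pos] = r / (r + means[pos])
        data[:, j] = np.where(pos, rng.negative_binomial(r, p), 0)
    return pd.DataFrame(data, index=gene_ids, columns=[s.sample_id for s in samples])


# ---------------------------------------------------------------------------
# writers


def write_ground_truth(gt: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write("bgc_id\ttrue_family\n")
        for bgc_id in sorted(gt.true_family):
            fh.write(f"{bgc_id}\t{gt.true_family[bgc_id]}\n")


def write_sample_table(samples: Sequence[SampleInfo], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tcondition\thost\ttimepoint\n")
        for s in samples:
            fh.write(f"{s.sample_id}\t{s.condition}\t{s.host}\t{s.timepoint}\n")
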