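"""Synthetic phage families, genomes and contigs for benchmarking.

The generator emulates the structure the classifier exploits in real
phage data:

* a *family* is a pool of protein-coding genes plus a family-specific
  trinucleotide composition (Dirichlet-drawn), standing in for the
  codon-usage / k-mer bias that separates phage families;
* a configurable fraction of each family's genes are mutated copies of
  a *shared pool*, emulating protein homologs shared across families —
  the ambiguity that makes pure alignment-based classification hard;
* a *genome* reverse-translates a random subset of its family's genes
  (with per-genome amino-acid mutations, so each gene founds a protein
  cluster) using family-biased codons, joined by composition-sampled
  intergenic spacers.  All genes sit on the forward strand in a single
  reading frame, and each spacer starts and ends with a stop codon, so
  six-frame translation recovers the planted proteins exactly;
* *contigs* are windows of a genome with uniformly random start and
  length, inheriting the genome's family label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .sequence_io import Contig, ProteinRecord

__all__ = [
    "FamilySpec",
    "ReferenceGenome",
    "generate_families",
    "generate_genome",
    "sample_contigs",
    "genome_masked_split",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# standard-code codons per amino acid (stops excluded by construction)
_CODON_TABLE: dict[str, list[str]] = {}
_BASES = "TCAG"
_AA_BY_CODON = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, _aa in enumerate(_AA_BY_CODON):
    if _aa == "*":
        continue
    _codon = _BASES[_i // 16] + _BASES[(_i // 4) % 4] + _BASES[_i % 4]
    _CODON_TABLE.setdefault(_aa, []).append(_codon)

_TRIMERS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_TRIMER_INDEX = {t: i for i, t in enumerate(_TRIMERS)}
STOP = "TAA"


@dataclass
class FamilySpec:
    """A synthetic phage family: gene pool + nucleotide composition."""

    name: str
    protein_pool: list[str]
    shared_pool_refs: list[int | None]  # per gene: index into shared pool, or None
    composition: np.ndarray  # probability over the 64 trinucleotides
    genome_length: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.protein_pool:
            raise ValueError("protein_pool must be non-empty")
        if not np.isclose(self.composition.sum(), 1.0):
            raise ValueError("composition must sum to 1")


@dataclass
class ReferenceGenome:
    id: str
    family: str
    seq: str
    proteins: list[ProteinRecord]
    gene_coords: list[tuple[int, int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.seq)

    def as_contig(self) -> Contig:
        return Contig(self.id, self.seq)


def _random_protein(rng: np.random.Generator, length_range: tuple[int, int]) -> str:
    length = int(rng.integers(length_range[0], length_range[1] + 1))
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate_protein(rng: np.random.Generator, aa: str, rate: float) -> str:
    out = list(aa)
    hits = np.nonzero(rng.random(len(out)) < rate)[0]
    for i in hits:
        out[i] = AMINO_ACIDS[int(rng.integers(len(AMINO_ACIDS)))]
    return "".join(out)


def generate_families(
    n_families: int = 4,
    genes_per_family: int = 10,
    shared_fraction: float = 0.2,
    seed: int = 0,
    protein_length: tuple[int, int] = (100, 300),
    genome_length: tuple[int, int] = (8000, 12000),
    shared_divergence: float = 0.2,
    dirichlet_alpha: float = 0.5,
) -> list[FamilySpec]:
    """Generate family specs with a controllable shared-protein fraction.

    ``round(shared_fraction * genes_per_family)`` genes of every family
    are point-mutated copies of a common shared pool (each family's copy
    diverges by ``shared_divergence`` substitutions per site, so two
    families' homologs are clearly related but far from identical, as
    cross-family phage homologs are); the rest are independent random
    proteins.  Each family draws its own Dirichlet trinucleotide
    composition.  Deterministic per seed.
    """
    if n_families < 2:
        raise ValueError("need at least 2 families")
    if not (0.0 <= shared_fraction < 1.0):
        raise ValueError("shared_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n_shared = int(round(shared_fraction * genes_per_family))
    shared_pool = [_random_protein(rng, protein_length) for _ in range(n_shared)]

    families = []
    for fi in range(n_families):
        pool: list[str] = []
        refs: list[int | None] = []
        for gi in range(genes_per_family):
            if gi < n_shared:
                pool.append(_mutate_protein(rng, shared_pool[gi], shared_divergence))
                refs.append(gi)
            else:
                pool.append(_random_protein(rng, protein_length))
                refs.append(None)
        composition = rng.dirichlet(np.full(64, dirichlet_alpha))
        families.append(
            FamilySpec(
                name=f"family_{fi}",
                protein_pool=pool,
                shared_pool_refs=refs,
                composition=composition,
                genome_length=genome_length,
            )
        )
    return families


def _reverse_translate(rng: np.random.Generator, aa: str, composition: np.ndarray) -> str:
    codons = []
    for residue in aa:
        options = _CODON_TABLE[residue]
        weights = np.array([composition[_TRIMER_INDEX[c]] for c in options]) + 1e-9
        weights /= weights.sum()
        codons.append(options[int(rng.choice(len(options), p=weights))])
    return "".join(codons)


def _spacer(rng: np.random.Generator, length: int, composition: np.ndarray) -> str:
    """Intergenic DNA of ``length`` nt (a multiple of 3), flanked by
    in-frame stop codons so translation splits between genes."""
    n_trimers = max(length // 3 - 2, 0)
    middle = "".join(
        _TRIMERS[i] for i in rng.choice(64, size=n_trimers, p=composition)
    )
    return STOP + middle + STOP


def generate_genome(
    family: FamilySpec,
    seed: int,
    index: int = 0,
    min_gene_fraction: float = 0.7,
    mutation_rate: float = 0.03,
) -> ReferenceGenome:
    """Assemble one genome of a family.

    A random subset (at least ``min_gene_fraction``) of the family's
    genes, each with fresh per-genome point mutations, reverse-translated
    with family-biased codons and joined by composition-sampled spacers.
    The target length is drawn from the family's range; the realised
    length may differ by up to about one gene.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    genome_id = f"{family.name}_g{index}"
    n_genes = len(family.protein_pool)
    frac = rng.uniform(min_gene_fraction, 1.0)
    n_keep = max(2, int(round(frac * n_genes)))
    chosen = sorted(rng.choice(n_genes, size=min(n_keep, n_genes), replace=False))

    proteins = [
        _mutate_protein(rng, family.protein_pool[g], mutation_rate) for g in chosen
    ]
    gene_dna = [_reverse_translate(rng, p, family.composition) for p in proteins]

    target = int(rng.integers(family.genome_length[0], family.genome_length[1] + 1))
    total_gene_nt = sum(len(g) for g in gene_dna)
    n_spacers = len(gene_dna) + 1
    spare = max(target - total_gene_nt, 9 * n_spacers)
    cuts = rng.dirichlet(np.ones(n_spacers)) * spare
    spacer_lens = [max(9, 3 * int(round(c / 3))) for c in cuts]

    parts = []
    coords = []
    records = []
    pos = 0
    for i, dna in enumerate(gene_dna):
        sp = _spacer(rng, spacer_lens[i], family.composition)
        parts.append(sp)
        pos += len(sp)
        coords.append((pos, pos + len(dna)))
        records.append(
            ProteinRecord(
                id=f"{genome_id}_p{i}",
                parent_id=genome_id,
                frame=0,
                aa_seq=proteins[i],
                source="reference",
            )
        )
        parts.append(dna)
        pos += len(dna)
    parts.append(_spacer(rng, spacer_lens[-1], family.composition))
    return ReferenceGenome(
        id=genome_id,
        family=family.name,
        seq="".join(parts),
        proteins=records,
        gene_coords=coords,
    )


def sample_contigs(
    genome: ReferenceGenome,
    length_range: tuple[int, int],
    count: int,
    seed: int,
    id_prefix: str | None = None,
) -> list[Contig]:
    """Contigs with uniformly random start position and length.

    The drawn length is uniform in ``length_range``; the maximum must
    not exceed the genome length.
    """
    lo, hi = length_range
    if hi > genome.length:
        raise ValueError(
            f"contig length range {length_range} exceeds genome {genome.id} "
            f"({genome.length} nt)"
        )
    if lo > hi or lo < 1:
        raise ValueError(f"invalid length range {length_range}")
    rng = np.random.default_rng(seed)
    prefix = id_prefix or genome.id
    contigs = []
    for i in range(count):
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, genome.length - length + 1))
        contigs.append(Contig(f"{prefix}_c{i}", genome.seq[start : start + length]))
    return contigs


def genome_masked_split(
    genomes: Sequence[ReferenceGenome],
    test_per_family: int = 1,
    seed: int = 0,
) -> tuple[list[ReferenceGenome], list[ReferenceGenome]]:
    """Genome-masked train/test split.

    ``test_per_family`` genomes per family are withheld entirely from
    training, so test contigs represent novel species.  Every family
    must retain at least one training genome.
    """
    rng = np.random.default_rng(seed)
    by_family: dict[str, list[ReferenceGenome]] = {}
    for g in genomes:
        by_family.setdefault(g.family, []).append(g)
    train, test = [], []
    for family in sorted(by_family):
        members = sorted(by_family[family], key=lambda g: g.id)
        if len(members) <= test_per_family:
            raise ValueError(
                f"family {family!r} has only {len(members)} genomes; "
                f"cannot withhold {test_per_family}"
            )
        picks = set(rng.choice(len(members), size=test_per_family, replace=False).tolist())
        for i, g in enumerate(members):
            (test if i in picks else train).append(g)
    return train, test
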