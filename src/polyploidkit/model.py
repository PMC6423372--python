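"""Shared data model.

The coordinate backbone is :class:`GenomeLayout`: chromosomes grouped into
homoeologous quartets (four copies per quartet in a tetraploid) and gene
records with 1-based inclusive coordinates. Rank-based algorithms (synteny
chaining, tandem detection) use ``gene_rank``, the 1-based position of a gene
on its chromosome ordered by start coordinate.

:class:`ExpressionMatrix` holds gene x library integer read counts together
with gene lengths and library metadata (tissue label and a fruit flag), the
inputs for FPKM normalisation and co-expression networks.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "Chromosome",
    "Gene",
    "GenomeLayout",
    "Library",
    "ExpressionMatrix",
    "AlignedPair",
]


@dataclass(frozen=True)
class Chromosome:
    chrom_id: str
    quartet_id: int  # 1..n_quartets
    copy_index: int  # 1..4
    length_bp: int

    def __post_init__(self):
        if not (1 <= self.copy_index <= 4):
            raise ValidationError(
                f"{self.chrom_id}: copy_index must be in 1..4, got {self.copy_index}"
            )
        if self.length_bp < 1:
            raise ValidationError(f"{self.chrom_id}: nonpositive length")


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # '+' or '-'
    family: str
    rank: int  # 1-based position by start on the chromosome


@dataclass
class GenomeLayout:
    """Chromosome quartet structure plus ranked gene records."""

    chromosomes: list[Chromosome]
    genes: list[Gene]
    _by_id: dict[str, Gene] = field(init=False, repr=False)
    _chrom_by_id: dict[str, Chromosome] = field(init=False, repr=False)

    def __post_init__(self):
        self._chrom_by_id = {c.chrom_id: c for c in self.chromosomes}
        if len(self._chrom_by_id) != len(self.chromosomes):
            raise ValidationError("duplicate chromosome id")
        pairs = {(c.quartet_id, c.copy_index) for c in self.chromosomes}
        if len(pairs) != len(self.chromosomes):
            raise ValidationError("duplicate (quartet_id, copy_index) pair")
        self._by_id = {}
        for g in self.genes:
            if g.gene_id in self._by_id:
                raise ValidationError(f"duplicate gene id {g.gene_id!r}")
            chrom = self._chrom_by_id.get(g.chrom_id)
            if chrom is None:
                raise ValidationError(f"{g.gene_id}: unknown chromosome {g.chrom_id!r}")
            if not (1 <= g.start <= g.end <= chrom.length_bp):
                raise ValidationError(
                    f"{g.gene_id}: coordinates [{g.start},{g.end}] outside "
                    f"1..{chrom.length_bp}"
                )
            if g.strand not in "+-":
                raise ValidationError(f"{g.gene_id}: bad strand {g.strand!r}")
            self._by_id[g.gene_id] = g
        # ranks must be consecutive 1..n per chromosome, ordered by start
        for chrom_id, genes in self.genes_by_chromosome().items():
            starts = [g.start for g in genes]
            if starts != sorted(starts):
                raise ValidationError(f"{chrom_id}: ranks not ordered by start")
            if [g.rank for g in genes] != list(range(1, len(genes) + 1)):
                raise ValidationError(f"{chrom_id}: gene ranks not consecutive from 1")

    def gene(self, gene_id: str) -> Gene:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise ValidationError(f"unknown gene id {gene_id!r}") from None

    def chromosome(self, chrom_id: str) -> Chromosome:
        return self._chrom_by_id[chrom_id]

    def genes_by_chromosome(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {c.chrom_id: [] for c in self.chromosomes}
        for g in self.genes:
            out[g.chrom_id].append(g)
        for genes in out.values():
            genes.sort(key=lambda g: g.rank)
        return out

    def quartet_groups(self) -> dict[int, dict[int, Chromosome]]:
        """quartet_id -> copy_index -> Chromosome."""
        out: dict[int, dict[int, Chromosome]] = {}
        for c in self.chromosomes:
            out.setdefault(c.quartet_id, {})[c.copy_index] = c
        return out

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


@dataclass(frozen=True)
class Library:
    library_id: str
    tissue: str = ""
    fruit: bool = False


@dataclass
class ExpressionMatrix:
    """Gene x library integer read counts with gene lengths and library metadata.

    ``counts`` is indexed by gene id with one column per library id;
    ``gene_length_bp`` is indexed identically.
    """

    counts: pd.DataFrame
    gene_length_bp: pd.Series
    libraries: list[Library]

    def __post_init__(self):
        lib_ids = [l.library_id for l in self.libraries]
        if len(set(lib_ids)) != len(lib_ids):
            raise ValidationError("duplicate library id")
        if list(self.counts.columns) != lib_ids:
            raise ValidationError("count columns do not match library metadata")
        if self.counts.index.has_duplicates:
            raise ValidationError("duplicate gene id in counts")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(np.equal(np.mod(vals, 1), 0)):
                raise ValidationError("non-integer read count")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            r, c = np.argwhere(self.counts.to_numpy() < 0)[0]
            raise ValidationError(
                f"negative count for gene {self.counts.index[r]!r} "
                f"in library {self.counts.columns[c]!r}"
            )
        self.gene_length_bp = self.gene_length_bp.reindex(self.counts.index)
        if self.gene_length_bp.isna().any():
            missing = self.gene_length_bp.index[self.gene_length_bp.isna()][0]
            raise ValidationError(f"missing gene length for {missing!r}")
        if (self.gene_length_bp < 1).any():
            raise ValidationError("gene length < 1 bp")
        self.gene_length_bp = self.gene_length_bp.astype(np.int64)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def library_ids(self) -> list[str]:
        return list(self.counts.columns)

    def fruit_library_ids(self) -> list[str]:
        return [l.library_id for l in self.libraries if l.fruit]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            counts=self.counts.loc[list(gene_ids)].copy(),
            gene_length_bp=self.gene_length_bp.loc[list(gene_ids)].copy(),
            libraries=list(self.libraries),
        )


@dataclass(frozen=True)
class AlignedPair:
    """Two equal-length aligned nucleotide sequences over {A,C,G,T,N,-}."""

    seq_a: str
    seq_b: str
    label: str = ""

    def __post_init__(self):
        if len(self.seq_a) != len(self.seq_b):
            raise ValidationError(
                f"aligned pair {self.label!r}: unequal lengths "
                f"{len(self.seq_a)} vs {len(self.seq_b)}"
            )
        alphabet = set("ACGTN-")
        for name, seq in (("seq_a", self.seq_a), ("seq_b", self.seq_b)):
            bad = set(seq.upper()) - alphabet
            if bad:
                raise ValidationError(
                    f"aligned pair {self.label!r}: {name} has invalid symbols {sorted(bad)}"
                )
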