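"""Toy genome container with gene models.

A :class:`ToyGenome` is the substrate for variant-consequence annotation:
named chromosome sequences plus a set of non-overlapping, intron-less genes
whose coding frame is anchored at the gene start.  Coordinates are held
0-based half-open internally (BED convention) and converted to 1-based at
VCF/GFF boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["Gene", "ToyGenome", "read_genome", "write_genome"]


@dataclass(frozen=True)
class Gene:
    """One intron-less protein-coding gene.

    ``start``/``end`` are 0-based half-open on the chromosome; the coding
    frame is anchored at ``start`` (``end`` for minus-strand genes), and the
    coding length ``end - start`` must be divisible by 3.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad gene interval [{self.start}, {self.end})")
        if (self.end - self.start) % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: coding length {self.end - self.start} not divisible by 3"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ToyGenome:
    """Named chromosome sequences plus non-overlapping gene models."""

    chromosomes: dict[str, str]
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes:
            if g.chrom not in self.chromosomes:
                raise ValueError(f"{g.gene_id}: unknown chromosome {g.chrom}")
            if g.end > len(self.chromosomes[g.chrom]):
                raise ValueError(f"{g.gene_id} extends past end of {g.chrom}")
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gs in by_chrom.items():
            gs.sort(key=lambda g: g.start)
            for a, b in zip(gs, gs[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping genes {a.gene_id} and {b.gene_id} on {chrom}"
                    )

    def chrom_length(self, chrom: str) -> int:
        return len(self.chromosomes[chrom])

    def gene_at(self, chrom: str, pos0: int) -> Gene | None:
        """Return the gene covering 0-based position ``pos0``, if any."""
        for g in self.genes:
            if g.chrom == chrom and g.start <= pos0 < g.end:
                return g
        return None

    def coding_sequence(self, gene: Gene) -> str:
        """Coding-strand nucleotide sequence of ``gene``."""
        raw = self.chromosomes[gene.chrom][gene.start : gene.end]
        if gene.strand == "-":
            return str(Seq(raw).reverse_complement())
        return raw


def write_genome(genome: ToyGenome, fasta_path: str | Path, genes_path: str | Path) -> None:
    """Write the genome as FASTA plus a GFF-like gene table (TSV, 1-based)."""
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.chromosomes.items()
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "start": g.start + 1,  # 1-based inclusive on disk
            "end": g.end,
            "strand": g.strand,
        }
        for g in genome.genes
    ]
    pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"]).to_csv(
        genes_path, sep="\t", index=False
    )


def read_genome(fasta_path: str | Path, genes_path: str | Path) -> ToyGenome:
    """Read a genome written by :func:`write_genome`."""
    chromosomes = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    table = pd.read_csv(genes_path, sep="\t")
    genes = [
        Gene(
            gene_id=str(row.gene_id),
            chrom=str(row.chrom),
            start=int(row.start) - 1,
            end=int(row.end),
            strand=str(row.strand),
        )
        for row in table.itertuples()
    ]
    return ToyGenome(chromosomes=chromosomes, genes=genes)
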