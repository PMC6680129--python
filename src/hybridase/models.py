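"""Gene models: transcripts, exon structure, GTF input/output.

Coordinates are 0-based half-open internally; GTF I/O converts to/from the
1-based inclusive convention of the format. Exon lists are kept sorted by
genomic start regardless of strand.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pyranges
from intervaltree import IntervalTree

Interval = tuple[int, int]

BIOTYPES = ("protein_coding", "lncRNA", "pseudogene")


@dataclass
class Transcript:
    id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]  # sorted, non-overlapping, 0-based half-open

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in itertools.pairwise(self.exons):
            if e1 > s2:
                raise ValueError(
                    f"transcript {self.id}: overlapping exons {(s1, e1)} / {(s2, e2)}"
                )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> list[Interval]:
        return [(e1, s2) for (_, e1), (s2, _) in itertools.pairwise(self.exons)]

    def genomic_blocks(self, t_start: int, t_end: int) -> list[Interval]:
        """Map a transcript-coordinate interval to genomic blocks (exon pieces).

        Transcript coordinates run 5'→3' along the *genomic forward strand*
        concatenation of exons (strand-agnostic, as for unstranded RNA-seq).
        """
        if not 0 <= t_start < t_end <= self.length:
            raise ValueError("interval outside transcript")
        blocks: list[Interval] = []
        off = 0
        for s, e in self.exons:
            ln = e - s
            lo, hi = max(t_start - off, 0), min(t_end - off, ln)
            if lo < hi:
                blocks.append((s + lo, s + hi))
            off += ln
        return blocks


@dataclass
class Gene:
    id: str
    chrom: str
    strand: str
    biotype: str
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    @property
    def exon_union(self) -> list[Interval]:
        """Merged union of all transcript exons."""
        ivs = sorted(i for t in self.transcripts for i in t.exons)
        merged: list[Interval] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged

    @property
    def exon_union_length(self) -> int:
        return sum(e - s for s, e in self.exon_union)

    @property
    def tss(self) -> int:
        """Transcription start site (0-based position of the first base)."""
        return self.start if self.strand == "+" else self.end - 1

    def promoter(self, width: int = 2000) -> Interval:
        """Strand-aware window upstream of the TSS (may be clipped at 0)."""
        if self.strand == "+":
            return (max(self.start - width, 0), self.start)
        return (self.end, self.end + width)


class GeneModels:
    """A set of genes keyed by id, with interval lookups over exon unions."""

    def __init__(self, genes: dict[str, Gene], chrom_lengths: dict[str, int] | None = None):
        self.genes = genes
        self.chrom_lengths = chrom_lengths or {}
        self._exon_trees: dict[str, IntervalTree] | None = None

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def __getitem__(self, gene_id: str) -> Gene:
        return self.genes[gene_id]

    def exon_trees(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees of exon-union pieces → gene id."""
        if self._exon_trees is None:
            trees: dict[str, IntervalTree] = {}
            for g in self:
                t = trees.setdefault(g.chrom, IntervalTree())
                for s, e in g.exon_union:
                    t.addi(s, e, g.id)
            self._exon_trees = trees
        return self._exon_trees

    def genes_overlapping(self, chrom: str, blocks: list[Interval]) -> set[str]:
        tree = self.exon_trees().get(chrom)
        if tree is None:
            return set()
        hits: set[str] = set()
        for s, e in blocks:
            for iv in tree.overlap(s, e):
                hits.add(iv.data)
        return hits

    # ----- GTF I/O -------------------------------------------------------

    @classmethod
    def from_gtf(cls, path: str) -> "GeneModels":
        df = pyranges.read_gtf(str(path)).df
        df = df[df.Feature == "exon"]
        genes: dict[str, Gene] = {}
        tx: dict[str, Transcript] = {}
        for row in df.itertuples():
            gid = row.gene_id
            biotype = getattr(row, "gene_biotype", None) or "protein_coding"
            if gid not in genes:
                genes[gid] = Gene(gid, row.Chromosome, row.Strand, biotype)
            tid = row.transcript_id
            if tid not in tx:
                tx[tid] = Transcript(tid, gid, row.Chromosome, row.Strand, [])
                genes[gid].transcripts.append(tx[tid])
            # pyranges stores GTF starts 0-based
            tx[tid].exons.append((int(row.Start), int(row.End)))
        for t in tx.values():
            t.__post_init__()  # re-sort and validate after incremental fill
        return cls(genes)

    def to_gtf(self, path: str, source: str = "hybridase") -> None:
        with open(path, "w") as fh:
            for g in sorted(self.genes.values(), key=lambda g: (g.chrom, g.start)):
                attrs = f'gene_id "{g.id}"; gene_biotype "{g.biotype}";'
                fh.write(
                    f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )
                for t in g.transcripts:
                    ta = f'gene_id "{g.id}"; transcript_id "{t.id}"; gene_biotype "{g.biotype}";'
                    fh.write(
                        f"{g.chrom}\t{source}\ttranscript\t{t.start + 1}\t{t.end}\t.\t{g.strand}\t.\t{ta}\n"
                    )
                    for s, e in t.exons:
                        fh.write(
                            f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{ta}\n"
                        )
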