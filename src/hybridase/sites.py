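"""Fixed divergent sites (FDS): calling, RNA-based refinement, annotation.

An FDS is a position homozygous within each parental species but different
between the species — the informative marker for assigning a hybrid read to
its allele of origin. This module turns raw variant calls into the FDS set
(quality, biallelic-SNV, fixed-homozygosity filters), optionally refines
exonic sites with parental RNA-seq evidence, and labels each site by genomic
region (exonic / promoter / intronic / intergenic).
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .models import GeneModels

_BASES = set("ACGT")

PROMOTER_WIDTH = 2000  # bp upstream of the TSS, strand-aware


@dataclass(frozen=True)
class DivergentSite:
    """One fixed difference between the two parental species.

    ``pos`` is 1-based (VCF convention); ``ref_allele`` is the species-A base
    as found in the reference genome, ``alt_allele`` the species-B base.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    qual: float = 0.0

    def __post_init__(self):
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles identical")
        if self.ref_allele not in _BASES or self.alt_allele not in _BASES:
            raise ValueError("alleles must be single A/C/G/T bases")


@dataclass
class VariantRecord:
    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    qual: float
    genotypes: dict[str, tuple[int | None, int | None]]  # sample -> allele indices


def read_variants(path: str) -> list[VariantRecord]:
    """Read a VCF (plain or bgzipped) into VariantRecords."""
    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            out.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_alleles=tuple(rec.alts or ()),
                    qual=rec.qual if rec.qual is not None else 0.0,
                    genotypes={name: s["GT"] for name, s in rec.samples.items()},
                )
            )
    return out


def write_sites_vcf(path: str, sites: list[DivergentSite], contigs: dict[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hybridase\n")
        for name, ln in contigs.items():
            fh.write(f"##contig=<ID={name},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sorted(sites, key=lambda s: (s.chrom, s.pos)):
            fh.write(f"{s.chrom}\t{s.pos}\t.\t{s.ref_allele}\t{s.alt_allele}\t{s.qual:g}\t.\t.\n")


def read_sites_vcf(path: str) -> list[DivergentSite]:
    """Read a biallelic-SNV VCF as a site list (non-SNV records rejected)."""
    sites = []
    for v in read_variants(path):
        if len(v.alt_alleles) != 1 or len(v.ref_allele) != 1 or len(v.alt_alleles[0]) != 1:
            raise ValueError(f"non-biallelic-SNV record at {v.chrom}:{v.pos}")
        sites.append(DivergentSite(v.chrom, v.pos, v.ref_allele, v.alt_alleles[0], v.qual))
    return sites


class FdsIndex:
    """Fast positional lookup of FDS alleles, per chromosome (0-based arrays)."""

    def __init__(self, sites: list[DivergentSite]):
        self.sites = sorted(sites, key=lambda s: (s.chrom, s.pos))
        self._pos: dict[str, np.ndarray] = {}
        self._ref: dict[str, list[str]] = {}
        self._alt: dict[str, list[str]] = {}
        by_chrom: dict[str, list[DivergentSite]] = {}
        for s in self.sites:
            by_chrom.setdefault(s.chrom, []).append(s)
        for chrom, ss in by_chrom.items():
            self._pos[chrom] = np.array([s.pos - 1 for s in ss], dtype=np.int64)
            self._ref[chrom] = [s.ref_allele for s in ss]
            self._alt[chrom] = [s.alt_allele for s in ss]

    def __len__(self) -> int:
        return len(self.sites)

    def positions_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """0-based FDS positions within [start, end)."""
        pos = self._pos.get(chrom)
        if pos is None:
            return np.empty(0, dtype=np.int64)
        lo, hi = np.searchsorted(pos, [start, end])
        return pos[lo:hi]

    def alleles_at(self, chrom: str, pos0: int) -> tuple[str, str]:
        pos = self._pos[chrom]
        i = int(np.searchsorted(pos, pos0))
        if i >= len(pos) or pos[i] != pos0:
            raise KeyError(f"no FDS at {chrom}:{pos0 + 1}")
        return self._ref[chrom][i], self._alt[chrom][i]


# ---------------------------------------------------------------------------
# FDS calling from variant records


def call_fixed_divergent_sites(
    variants: list[VariantRecord],
    species_of_sample: dict[str, str],
    min_qual: float = 30.0,
) -> tuple[list[DivergentSite], Counter]:
    """Filter raw variant calls down to fixed divergent sites.

    A retained site is a biallelic SNV with QUAL >= min_qual where every
    species-A sample is homozygous for one allele, every species-B sample is
    homozygous for the other, and the two species disagree. Sites are
    normalized so ref_allele is the species-A allele. Returns the site list
    and a per-filter tally whose values sum to the input size.
    """
    species = set(species_of_sample.values())
    if not species_of_sample or species - {"A", "B"} or len(species) < 2:
        raise ValueError("need samples from both species, labelled 'A' and 'B'")
    tally: Counter = Counter()
    sites: list[DivergentSite] = []
    for v in variants:
        if len(v.alt_alleles) != 1:
            tally["multi_allelic"] += 1
            continue
        alleles = (v.ref_allele,) + v.alt_alleles
        if any(len(a) != 1 or a not in _BASES for a in alleles):
            tally["not_snv"] += 1
            continue
        if v.qual < min_qual:
            tally["low_qual"] += 1
            continue
        gts = {s: v.genotypes.get(s) for s in species_of_sample}
        if any(g is None or None in g for g in gts.values()):
            tally["missing_genotype"] += 1
            continue
        if any(g[0] != g[1] for g in gts.values()):
            tally["heterozygous"] += 1
            continue
        per_species: dict[str, set[int]] = {"A": set(), "B": set()}
        for sample, g in gts.items():
            per_species[species_of_sample[sample]].add(g[0])
        if any(len(v_) > 1 for v_ in per_species.values()):
            tally["polymorphic"] += 1
            continue
        a_idx, b_idx = per_species["A"].pop(), per_species["B"].pop()
        if a_idx == b_idx:
            tally["not_divergent"] += 1
            continue
        tally["pass"] += 1
        sites.append(
            DivergentSite(v.chrom, v.pos, alleles[a_idx], alleles[b_idx], v.qual)
        )
    return sites, tally


# ---------------------------------------------------------------------------
# RNA-based refinement


def _allele_counts_at_sites(aln_path: str, index: FdsIndex) -> dict[tuple[str, int], Counter]:
    """Count observed bases at FDS positions from an alignment file."""
    counts: dict[tuple[str, int], Counter] = {}
    with pysam.AlignmentFile(str(aln_path), check_sq=False) as af:
        for rec in af:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            seq = rec.query_sequence
            if seq is None:
                continue
            for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
                # cheap pre-filter: only look up positions that are FDSs
                hits = index.positions_in(rec.reference_name, rpos, rpos + 1)
                if hits.size:
                    counts.setdefault((rec.reference_name, rpos), Counter())[seq[qpos]] += 1
    return counts


def filter_fds_by_parental_rna(
    fds: list[DivergentSite],
    parental_alignments_A: str,
    parental_alignments_B: str,
    min_cov: int = 10,
    min_concordance: float = 0.9,
) -> tuple[list[DivergentSite], list[DivergentSite], Counter]:
    """Drop FDSs contradicted by parental RNA-seq reads.

    An FDS covered by >= min_cov reads in a parent is kept only if at least
    min_concordance of the covering reads carry that parent's expected allele.
    Sites with sub-threshold coverage in both parents pass through unchanged
    (the DNA evidence stands). Returns (kept, dropped, tally).
    """
    index = FdsIndex(fds)
    counts_a = _allele_counts_at_sites(parental_alignments_A, index)
    counts_b = _allele_counts_at_sites(parental_alignments_B, index)
    kept, dropped = [], []
    tally: Counter = Counter()
    for s in fds:
        key = (s.chrom, s.pos - 1)
        bad = False
        for counts, expected in ((counts_a, s.ref_allele), (counts_b, s.alt_allele)):
            c = counts.get(key)
            if c is None:
                continue
            cov = sum(c.values())
            if cov >= min_cov and c.get(expected, 0) / cov < min_concordance:
                bad = True
        if bad:
            dropped.append(s)
            tally["rna_discordant"] += 1
        else:
            kept.append(s)
            tally["kept"] += 1
    return kept, dropped, tally


# ---------------------------------------------------------------------------
# Region annotation


def annotate_fds_regions(
    fds: list[DivergentSite],
    models: GeneModels,
    promoter_width: int = PROMOTER_WIDTH,
) -> pd.DataFrame:
    """Label each FDS exonic / promoter / intronic / intergenic.

    Precedence when windows overlap: exonic > promoter > intronic. The
    promoter is the strand-aware ``promoter_width`` bp window upstream of the
    TSS. Returns a DataFrame (chrom, pos, region, gene_id).
    """
    exon_t: dict[str, IntervalTree] = {}
    prom_t: dict[str, IntervalTree] = {}
    span_t: dict[str, IntervalTree] = {}
    for g in models:
        et = exon_t.setdefault(g.chrom, IntervalTree())
        for s, e in g.exon_union:
            et.addi(s, e, g.id)
        ps, pe = g.promoter(promoter_width)
        if pe > ps:
            prom_t.setdefault(g.chrom, IntervalTree()).addi(ps, pe, g.id)
        span_t.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.id)

    rows = []
    for s in fds:
        p0 = s.pos - 1
        region, gid = "intergenic", ""
        for trees, label in ((exon_t, "exonic"), (prom_t, "promoter"), (span_t, "intronic")):
            tree = trees.get(s.chrom)
            hit = tree.overlap(p0, p0 + 1) if tree is not None else None
            if hit:
                region, gid = label, sorted(iv.data for iv in hit)[0]
                break
        rows.append((s.chrom, s.pos, region, gid))
    return pd.DataFrame(rows, columns=["chrom", "pos", "region", "gene_id"])


def write_fds_bed(path: str, fds: list[DivergentSite]) -> None:
    """0-based half-open BED export for browser use."""
    with open(path, "w") as fh:
        for s in sorted(fds, key=lambda s: (s.chrom, s.pos)):
            fh.write(f"{s.chrom}\t{s.pos - 1}\t{s.pos}\t{s.ref_allele}>{s.alt_allele}\n")
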