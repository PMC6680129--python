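"""Allele-of-origin assignment for uniquely mapped hybrid fragments.

A paired-end fragment is assigned to one parental allele when every FDS it
covers carries that allele's base: fragments showing bases from both alleles
are ambiguous, fragments covering no FDS are uninformative, and both are
excluded downstream. Alignments against the reference and the pseudogenome
(same coordinates) are merged first so neither allele is favoured by mapping
bias; per-gene counts are the average of the two mappings' counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .models import GeneModels
from .sites import FdsIndex

DEFAULT_MAPQ_FLOOR = 30

CALLS = ("alleleA", "alleleB", "ambiguous", "uninformative")


@dataclass
class AlleleCall:
    call: str
    n_sites_A: int = 0
    n_sites_B: int = 0
    n_sites_neither: int = 0


@dataclass
class AlignedFragment:
    """One read pair (or orphan mate) with its evidence at FDS positions."""

    name: str
    chrom: str
    blocks: tuple[tuple[int, int], ...]          # merged key for both mates
    fds_bases: dict[int, str]                    # 0-based ref pos -> observed base
    mapq: int
    uniquely_mapped: bool
    source: str                                  # reference | pseudogenome | both
    records: list = field(default_factory=list, repr=False)
    truth_allele: str | None = None
    truth_gene: str | None = None


def _record_blocks(rec) -> list[tuple[int, int]]:
    blocks = []
    pos = rec.reference_start
    for op, ln in rec.cigartuples or []:
        if op in (0, 7, 8):  # M, =, X
            blocks.append((pos, pos + ln))
            pos += ln
        elif op in (2, 3):  # D, N
            pos += ln
    return blocks


def _fds_bases(rec, index: FdsIndex) -> dict[int, str]:
    """Bases observed at FDS positions, walking aligned blocks directly."""
    out: dict[int, str] = {}
    seq = rec.query_sequence
    if seq is None:
        return out
    qpos = 0
    rpos = rec.reference_start
    chrom = rec.reference_name
    for op, ln in rec.cigartuples or []:
        if op in (0, 7, 8):
            for p0 in index.positions_in(chrom, rpos, rpos + ln):
                out[int(p0)] = seq[qpos + (int(p0) - rpos)]
            qpos += ln
            rpos += ln
        elif op in (1, 4):  # I, S consume query
            qpos += ln
        elif op in (2, 3):
            rpos += ln
    return out


def read_fragments(
    path: str,
    fds_index: FdsIndex,
    source: str,
    mapq_floor: int = DEFAULT_MAPQ_FLOOR,
) -> list[AlignedFragment]:
    """Group alignment records into fragments keyed by read name.

    A fragment is uniquely mapped iff all of its records are primary (no
    secondary/supplementary alignments anywhere for the name) and every mate
    has MAPQ >= mapq_floor.
    """
    by_name: dict[str, list] = {}
    tainted: set[str] = set()
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for rec in af:
            if rec.is_unmapped:
                tainted.add(rec.query_name)
                continue
            if rec.is_secondary or rec.is_supplementary:
                tainted.add(rec.query_name)
                continue
            by_name.setdefault(rec.query_name, []).append(rec)
    frags: list[AlignedFragment] = []
    for name, recs in by_name.items():
        chroms = {r.reference_name for r in recs}
        mapq = min(r.mapping_quality for r in recs)
        unique = (
            name not in tainted
            and len(chroms) == 1
            and mapq >= mapq_floor
        )
        blocks = tuple(sorted(b for r in recs for b in _record_blocks(r)))
        bases: dict[int, str] = {}
        if unique:
            for r in recs:
                for p0, b in _fds_bases(r, fds_index).items():
                    # mate disagreement at one site -> keep a non-allele marker
                    if p0 in bases and bases[p0] != b:
                        bases[p0] = "*"
                    else:
                        bases[p0] = b
        truth = recs[0].get_tag("oA") if recs[0].has_tag("oA") else None
        tgene = recs[0].get_tag("oG") if recs[0].has_tag("oG") else None
        frags.append(
            AlignedFragment(
                name=name,
                chrom=recs[0].reference_name,
                blocks=blocks,
                fds_bases=bases,
                mapq=mapq,
                uniquely_mapped=unique,
                source=source,
                records=recs,
                truth_allele=truth,
                truth_gene=tgene,
            )
        )
    return frags


def classify_fragment(frag: AlignedFragment, fds_index: FdsIndex) -> AlleleCall:
    """Count species-A/species-B bases at covered FDSs and call the allele.

    A base matching neither allele (sequencing error, mate conflict) counts
    toward n_sites_neither and does not influence the call.
    """
    n_a = n_b = n_o = 0
    for p0, base in frag.fds_bases.items():
        ref, alt = fds_index.alleles_at(frag.chrom, p0)
        if base == ref:
            n_a += 1
        elif base == alt:
            n_b += 1
        else:
            n_o += 1
    if n_a and not n_b:
        call = "alleleA"
    elif n_b and not n_a:
        call = "alleleB"
    elif n_a and n_b:
        call = "ambiguous"
    else:
        call = "uninformative"
    return AlleleCall(call, n_a, n_b, n_o)


def merge_alignments(
    ref_frags: list[AlignedFragment],
    pseudo_frags: list[AlignedFragment],
) -> tuple[list[AlignedFragment], Counter]:
    """Merge fragments from the reference and pseudogenome mappings.

    One entry per read name. A fragment unique in exactly one mapping is
    taken from it; unique in both with identical coordinates is kept once
    with source='both'; unique in both at different coordinates is dropped
    and tallied.
    """
    ref_by = {f.name: f for f in ref_frags}
    pseudo_by = {f.name: f for f in pseudo_frags}
    tally: Counter = Counter()
    merged: list[AlignedFragment] = []
    for name in ref_by.keys() | pseudo_by.keys():
        rf, pf = ref_by.get(name), pseudo_by.get(name)
        ru = rf is not None and rf.uniquely_mapped
        pu = pf is not None and pf.uniquely_mapped
        if ru and pu:
            if rf.chrom == pf.chrom and rf.blocks == pf.blocks:
                rf.source = "both"
                merged.append(rf)
                tally["both"] += 1
            else:
                tally["position_conflict_dropped"] += 1
        elif ru:
            merged.append(rf)
            tally["reference_only"] += 1
        elif pu:
            merged.append(pf)
            tally["pseudogenome_only"] += 1
        else:
            tally["non_unique"] += 1
    return merged, tally


def count_gene_alleles(
    fragments: list[AlignedFragment],
    models: GeneModels,
    fds_index: FdsIndex,
    exonic_fds_per_gene: dict[str, int] | None = None,
    sample: str = "sample",
    multi_gene: str = "count_both",
) -> tuple[pd.DataFrame, Counter]:
    """Per-gene per-sample allele counts averaged over the two mappings.

    A fragment contributes to every gene whose exon union its alignment
    overlaps (``multi_gene='drop'`` discards multi-gene fragments instead).
    Counts are means of the per-mapping assigned counts, so values may be
    half-integral.
    """
    per_map: dict[str, np.ndarray] = {}  # gene -> [refA, refB, pseudoA, pseudoB]
    tally: Counter = Counter()
    for frag in fragments:
        call = classify_fragment(frag, fds_index)
        tally[call.call] += 1
        if call.call not in ("alleleA", "alleleB"):
            continue
        gene_hits = models.genes_overlapping(frag.chrom, list(frag.blocks))
        if not gene_hits:
            tally["assigned_no_gene"] += 1
            continue
        if len(gene_hits) > 1:
            tally["multi_gene_fragments"] += 1
            if multi_gene == "drop":
                continue
        col = 0 if call.call == "alleleA" else 1
        for gid in gene_hits:
            arr = per_map.setdefault(gid, np.zeros(4))
            if frag.source in ("reference", "both"):
                arr[col] += 1
            if frag.source in ("pseudogenome", "both"):
                arr[2 + col] += 1
    rows = []
    for gid in models.genes:
        arr = per_map.get(gid, np.zeros(4))
        count_a = (arr[0] + arr[2]) / 2
        count_b = (arr[1] + arr[3]) / 2
        rows.append(
            {"gene": gid, "sample": sample, "countA": count_a, "countB": count_b,
             "n_exonic_fds": (exonic_fds_per_gene or {}).get(gid, 0)}
        )
    return pd.DataFrame(rows), tally


def assignment_summary(calls: Counter | list[AlleleCall]) -> dict[str, float]:
    """Proportions of fragments per call class; they sum to 1."""
    if isinstance(calls, Counter):
        counts = {k: calls.get(k, 0) for k in CALLS}
    else:
        c = Counter(a.call for a in calls)
        counts = {k: c.get(k, 0) for k in CALLS}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no fragments to summarize")
    return {k: v / total for k, v in counts.items()}


def split_by_allele(
    fragments: list[AlignedFragment],
    fds_index: FdsIndex,
    out_a: str,
    out_b: str,
    header: pysam.AlignmentHeader,
) -> tuple[int, int]:
    """Write assigned fragments into per-allele SAM files.

    Ambiguous/uninformative fragments are excluded; returns the fragment
    counts written to each file.
    """
    n_a = n_b = 0
    with pysam.AlignmentFile(str(out_a), "w", header=header) as fa, \
            pysam.AlignmentFile(str(out_b), "w", header=header) as fb:
        for frag in fragments:
            call = classify_fragment(frag, fds_index).call
            if call == "alleleA":
                for rec in frag.records:
                    fa.write(rec)
                n_a += 1
            elif call == "alleleB":
                for rec in frag.records:
                    fb.write(rec)
                n_b += 1
    return n_a, n_b
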