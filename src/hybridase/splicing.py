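"""Allele-specific alternative splicing: events, PSI, likelihood-ratio test.

Events of the five classic types (SE, MXE, A5SS, A3SS, RI) are enumerated
from transcript structure; inclusion/exclusion read support is counted from
allele-split alignments (per mate, exact junction matching); PSI is the
length-normalized inclusion proportion; and per-event allelic differences
are tested with a binomial likelihood-ratio test referred to χ² with one
degree of freedom. Significance additionally requires >= 100 supporting
reads and |Δψ| > 0.10 at FDR <= 1%.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree
from scipy import stats
from scipy.special import xlogy

from .ase import bh_adjust
from .models import GeneModels, Transcript

Interval = tuple[int, int]

MIN_SUPPORT = 100
MIN_DPSI = 0.10
MAX_FDR = 0.01

EVENT_TYPES = ("SE", "MXE", "A5SS", "A3SS", "RI")


@dataclass
class SplicingEvent:
    id: str
    type: str
    gene_id: str
    chrom: str
    strand: str
    inc_junctions: list[Interval]       # introns whose exact match supports inclusion
    exc_junctions: list[Interval]
    inc_segments: list[Interval]        # regions whose exonic overlap supports inclusion
    exc_segments: list[Interval] = field(default_factory=list)
    inc_blocks: list[Interval] = field(default_factory=list)   # local inclusion isoform
    exc_blocks: list[Interval] = field(default_factory=list)   # local exclusion isoform
    l_inc: int = 1
    l_exc: int = 1

    @property
    def span(self) -> Interval:
        coords = [c for ivs in (self.inc_blocks, self.exc_blocks) for iv in ivs for c in iv]
        return (min(coords), max(coords))


def _classify_read(
    event: SplicingEvent,
    blocks: list[Interval],
    junctions: set[Interval],
) -> str | None:
    """'inc', 'exc' or None for one aligned read against one event."""
    inc = any(j in junctions for j in event.inc_junctions) or any(
        bs < seg_e and be > seg_s
        for bs, be in blocks
        for seg_s, seg_e in event.inc_segments
    )
    exc = any(j in junctions for j in event.exc_junctions) or any(
        bs < seg_e and be > seg_s
        for bs, be in blocks
        for seg_s, seg_e in event.exc_segments
    )
    if event.type == "RI":
        # an unspliced read crossing an exon/intron boundary also supports retention
        i_s, i_e = event.exc_junctions[0]
        inc = inc or any(bs < i_e and be > i_s for bs, be in blocks)
    if inc and not exc:
        return "inc"
    if exc and not inc:
        return "exc"
    return None


def effective_lengths(event: SplicingEvent, read_len: int) -> tuple[int, int]:
    """Distinct read start positions supporting each form.

    Slides a read_len window along the event's local inclusion and exclusion
    isoforms and counts windows the read classifier would score for that
    form — the rMATS-style effective length, guaranteed consistent with
    `count_event_reads` because the same classifier decides both.
    """
    out = []
    for blocks, want in ((event.inc_blocks, "inc"), (event.exc_blocks, "exc")):
        t = Transcript("tmp", "tmp", event.chrom, event.strand, list(blocks))
        total = t.length
        n = 0
        for start in range(max(total - read_len + 1, 1)):
            w = t.genomic_blocks(start, min(start + read_len, total))
            juncs = {(e1, s2) for (_, e1), (s2, _) in itertools.pairwise(w)}
            if _classify_read(event, w, juncs) == want:
                n += 1
        out.append(max(n, 1))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# event enumeration


def _pair_events(t1: Transcript, t2: Transcript, gene_id: str, strand: str) -> list[dict]:
    """Candidate events from one ordered transcript pair (t1 vs t2)."""
    chrom = t1.chrom
    e1, e2 = t1.exons, t2.exons
    s1, s2 = set(e1), set(e2)
    j1, j2 = set(t1.introns), set(t2.introns)
    found = []

    # SE: exon of t1 absent in t2, flanks joined directly in t2
    for i in range(1, len(e1) - 1):
        ex = e1[i]
        if ex in s2:
            continue
        up, down = e1[i - 1], e1[i + 1]
        if (up[1], down[0]) in j2 and (up[1], ex[0]) in j1 and (ex[1], down[0]) in j1:
            found.append(dict(
                type="SE", key=("SE", ex, up[1], down[0]),
                inc_junctions=[(up[1], ex[0]), (ex[1], down[0])],
                exc_junctions=[(up[1], down[0])],
                inc_segments=[ex], exc_segments=[],
                inc_blocks=[up, ex, down], exc_blocks=[up, down]))

    # MXE: t1 keeps exA, t2 keeps exB between shared flanks; exA left of exB
    for i in range(1, len(e1) - 1):
        ex_a = e1[i]
        if ex_a in s2:
            continue
        up, down = e1[i - 1], e1[i + 1]
        for k in range(1, len(e2) - 1):
            ex_b = e2[k]
            if ex_b in s1 or not (ex_a[1] <= ex_b[0] or ex_b[1] <= ex_a[0]):
                continue
            if e2[k - 1] != up or e2[k + 1] != down:
                continue
            if (up[1], ex_b[0]) not in j2 or (ex_b[1], down[0]) not in j2:
                continue
            first, second = sorted([ex_a, ex_b])
            found.append(dict(
                type="MXE", key=("MXE", first, second, up[1], down[0]),
                inc_junctions=[(up[1], first[0]), (first[1], down[0])],
                exc_junctions=[(up[1], second[0]), (second[1], down[0])],
                inc_segments=[first], exc_segments=[second],
                inc_blocks=[up, first, down], exc_blocks=[up, second, down]))

    # A5SS / A3SS: exon pair sharing one boundary, alternative end joined to
    # a common partner exon
    for a in e1:
        for b in e2:
            if a == b:
                continue
            if a[0] == b[0] and a[1] != b[1]:
                long_e, short_e = (a, b) if a[1] > b[1] else (b, a)
                # both must splice to the same downstream acceptor
                cands = {d for (don, d) in (j1 | j2) if don == long_e[1]}
                for acc in cands:
                    if (short_e[1], acc) in (j1 | j2):
                        partner = next((x for x in e1 + e2 if x[0] == acc), None)
                        if partner is None:
                            continue
                        ev = "A5SS" if strand == "+" else "A3SS"
                        found.append(dict(
                            type=ev, key=(ev, a[0], short_e[1], long_e[1], acc),
                            inc_junctions=[(long_e[1], acc)],
                            exc_junctions=[(short_e[1], acc)],
                            inc_segments=[(short_e[1], long_e[1])], exc_segments=[],
                            inc_blocks=[long_e, partner],
                            exc_blocks=[short_e, partner]))
            if a[1] == b[1] and a[0] != b[0]:
                long_e, short_e = (a, b) if a[0] < b[0] else (b, a)
                cands = {don for (don, acc) in (j1 | j2) if acc == long_e[0]}
                for don in cands:
                    if (don, short_e[0]) in (j1 | j2):
                        partner = next((x for x in e1 + e2 if x[1] == don), None)
                        if partner is None:
                            continue
                        ev = "A3SS" if strand == "+" else "A5SS"
                        found.append(dict(
                            type=ev, key=(ev, a[1], short_e[0], long_e[0], don),
                            inc_junctions=[(don, long_e[0])],
                            exc_junctions=[(don, short_e[0])],
                            inc_segments=[(long_e[0], short_e[0])], exc_segments=[],
                            inc_blocks=[partner, long_e],
                            exc_blocks=[partner, short_e]))

    # RI: an intron of t2 fully contained in an exon of t1
    for intron in j2:
        i_s, i_e = intron
        for ex in e1:
            if ex[0] < i_s and ex[1] > i_e:
                up = next((x for x in e2 if x[1] == i_s), None)
                down = next((x for x in e2 if x[0] == i_e), None)
                if up is None or down is None:
                    continue
                found.append(dict(
                    type="RI", key=("RI", intron),
                    inc_junctions=[],
                    exc_junctions=[intron],
                    inc_segments=[(i_s, i_e)], exc_segments=[],
                    inc_blocks=[(up[0], down[1])],
                    exc_blocks=[up, down]))
    for f in found:
        f["chrom"], f["strand"], f["gene_id"] = chrom, strand, gene_id
    return found


def enumerate_events(models: GeneModels) -> list[SplicingEvent]:
    """All distinct splicing events across every transcript pair per gene.

    Duplicate events found via several pairs are collapsed; genes with
    malformed transcripts (overlapping exons) are skipped. Output is
    independent of transcript input order.
    """
    events: dict[tuple, SplicingEvent] = {}
    for gene in models:
        try:
            txs = sorted(gene.transcripts, key=lambda t: t.id)
        except ValueError:
            continue
        for t1, t2 in itertools.permutations(txs, 2):
            try:
                cands = _pair_events(t1, t2, gene.id, gene.strand)
            except ValueError:
                break  # malformed transcript: skip gene
            for c in cands:
                key = (gene.id,) + tuple(c.pop("key"))
                if key not in events:
                    ev_id = f"{gene.id}.{c['type']}.{len(events)}"
                    events[key] = SplicingEvent(id=ev_id, **c)
    return sorted(events.values(), key=lambda e: (e.chrom, e.span, e.id))


# ---------------------------------------------------------------------------
# read counting


def _read_blocks_junctions(rec) -> tuple[list[Interval], set[Interval]]:
    blocks: list[Interval] = []
    juncs: set[Interval] = set()
    pos = rec.reference_start
    for op, ln in rec.cigartuples or []:
        if op in (0, 7, 8):
            blocks.append((pos, pos + ln))
            pos += ln
        elif op == 3:
            juncs.add((pos, pos + ln))
            pos += ln
        elif op == 2:
            pos += ln
    return blocks, juncs


def count_event_reads(
    aln_path: str,
    events: list[SplicingEvent],
) -> pd.DataFrame:
    """Inclusion/exclusion read counts per event from one alignment file.

    Each aligned read (mate) is classified independently: it supports the
    inclusion form if it spans an inclusion-defining junction (exact intron
    match) or overlaps an inclusion-specific segment, symmetrically for
    exclusion; reads consistent with both or neither are uncounted.
    """
    trees: dict[str, IntervalTree] = {}
    for i, ev in enumerate(events):
        s, e = ev.span
        trees.setdefault(ev.chrom, IntervalTree()).addi(s, e, i)
    inc = np.zeros(len(events), dtype=np.int64)
    exc = np.zeros(len(events), dtype=np.int64)
    with pysam.AlignmentFile(str(aln_path), check_sq=False) as af:
        for rec in af:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            tree = trees.get(rec.reference_name)
            if tree is None:
                continue
            blocks, juncs = _read_blocks_junctions(rec)
            for iv in tree.overlap(rec.reference_start, rec.reference_end):
                side = _classify_read(events[iv.data], blocks, juncs)
                if side == "inc":
                    inc[iv.data] += 1
                elif side == "exc":
                    exc[iv.data] += 1
    return pd.DataFrame(
        {"event_id": [e.id for e in events], "type": [e.type for e in events],
         "gene": [e.gene_id for e in events], "inc": inc, "exc": exc})


# ---------------------------------------------------------------------------
# PSI and differential test


@dataclass
class PsiEstimate:
    inc: int
    exc: int
    psi: float


def psi(inc: int, exc: int, l_inc: int = 1, l_exc: int = 1) -> PsiEstimate:
    """Length-normalized percent-spliced-in."""
    if inc + exc <= 0:
        raise ValueError("PSI undefined with no supporting reads")
    a, b = inc / l_inc, exc / l_exc
    return PsiEstimate(inc, exc, a / (a + b))


def lrt_differential_psi(
    inc_a: int, exc_a: int, inc_b: int, exc_b: int,
    l_inc: int = 1, l_exc: int = 1,
) -> float:
    """Binomial likelihood-ratio p-value for H0: ψ_A = ψ_B.

    The inclusion-read proportion p = ψ·l_inc/(ψ·l_inc+(1−ψ)·l_exc) is a
    monotone reparameterization of ψ, so the MLEs are the observed count
    fractions and the statistic 2(ℓ1 − ℓ0) is referred to χ²₁. Effective
    lengths affect ψ, not the test.
    """
    n_a, n_b = inc_a + exc_a, inc_b + exc_b
    if n_a <= 0 or n_b <= 0:
        raise ValueError("need reads for both alleles")

    def ll(x: int, n: int, p: float) -> float:
        return float(xlogy(x, p) + xlogy(n - x, 1 - p))

    p_a, p_b = inc_a / n_a, inc_b / n_b
    p_0 = (inc_a + inc_b) / (n_a + n_b)
    stat = 2 * (ll(inc_a, n_a, p_a) + ll(inc_b, n_b, p_b)
                - ll(inc_a, n_a, p_0) - ll(inc_b, n_b, p_0))
    return float(min(max(stats.chi2.sf(max(stat, 0.0), df=1), np.nextafter(0, 1)), 1.0))


def call_ass(
    event_counts: pd.DataFrame,
    min_support: int = MIN_SUPPORT,
    min_dpsi: float = MIN_DPSI,
    max_fdr: float = MAX_FDR,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call significant allele-specific splicing events.

    ``event_counts`` needs columns event_id, type, incA, excA, incB, excB
    and (optionally) l_inc/l_exc. Events with reads in both alleles are
    tested, BH-corrected together, and flagged significant iff support
    (all four counts summed) >= min_support, |Δψ| > min_dpsi and
    FDR <= max_fdr. Returns (results, per-type summary with ASS ratios).
    """
    df = event_counts.copy()
    if "l_inc" not in df:
        df["l_inc"] = 1
    if "l_exc" not in df:
        df["l_exc"] = 1
    psi_a, psi_b, pv = [], [], []
    for r in df.itertuples():
        if r.incA + r.excA > 0 and r.incB + r.excB > 0:
            psi_a.append(psi(r.incA, r.excA, r.l_inc, r.l_exc).psi)
            psi_b.append(psi(r.incB, r.excB, r.l_inc, r.l_exc).psi)
            pv.append(lrt_differential_psi(r.incA, r.excA, r.incB, r.excB,
                                           r.l_inc, r.l_exc))
        else:
            psi_a.append(np.nan)
            psi_b.append(np.nan)
            pv.append(np.nan)
    df["psi_A"], df["psi_B"], df["pvalue"] = psi_a, psi_b, pv
    df["delta_psi"] = df["psi_A"] - df["psi_B"]
    df["support"] = df[["incA", "excA", "incB", "excB"]].sum(axis=1)
    tested = df["pvalue"].notna()
    df["fdr"] = np.nan
    if tested.any():
        df.loc[tested, "fdr"] = bh_adjust(df.loc[tested, "pvalue"])
    df["significant"] = (
        (df["support"] >= min_support)
        & (df["delta_psi"].abs() > min_dpsi)
        & (df["fdr"] <= max_fdr)
    ).fillna(False)

    if "type" in df:
        summary = (
            df.groupby("type")
            .agg(total_events=("event_id", "count"), ass_events=("significant", "sum"))
            .reindex(EVENT_TYPES)
            .dropna(how="all")
        )
        summary["ass_ratio"] = summary["ass_events"] / summary["total_events"]
        summary = summary.reset_index()
    else:
        summary = pd.DataFrame(columns=["type", "total_events", "ass_events", "ass_ratio"])
    return df, summary
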