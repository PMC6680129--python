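"""Synthetic F1-hybrid transcriptomes with known truth.

Generates the full fixture set the analysis consumes: two parental haplotype
genomes that differ only at fixed divergent sites (FDS), multi-exon gene
models of three biotypes, truth-labelled paired-end reads emitted as
truth-aligned SAM (no external aligner needed) plus FASTQ, and truth tables
(per-gene allelic ratio and imprint status, per-event inclusion levels,
per-fragment allele of origin and injected-error positions).

Reciprocal-cross structure: samples exist in both cross directions
(species-A mother × species-B father and the reverse). For an imprinted gene
the expression bias follows the *parental* allele, so the favoured species
allele flips between directions — exactly the signature the reciprocal-cross
design detects.

Two count-level generators (`simulate_gene_counts`, `simulate_event_counts`)
draw the same statistical structure directly at the count level for
calibration studies (type-I error, power, LRT null distribution) where
read-level simulation adds nothing but runtime.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .models import Gene, GeneModels, Transcript
from .sites import DivergentSite, write_sites_vcf
from .pseudogenome import write_fasta

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_OTHER = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}
_COMP = str.maketrans("ACGT", "TGCA")

EVENT_TYPES = ("SE", "RI", "MXE", "A5SS", "A3SS")


@dataclass
class SimulationConfig:
    """Study conditions for the simulated hybrid experiment.

    Defaults emulate the real study design at desk scale: ~1% fixed
    divergence between the parental species (horse/donkey-like), 100 bp
    paired-end reads from ~300 bp fragments, negative-binomial per-gene
    depth, three biological replicates per cross direction, a minority of
    genes with strong cis imbalance, a few imprinted genes, and a subset of
    multi-exon genes carrying an alternative-splicing event with per-allele
    inclusion levels.
    """

    n_genes: int = 100
    exons_per_gene: tuple[int, int] = (3, 8)
    exon_len: tuple[int, int] = (80, 300)
    intron_len: tuple[int, int] = (100, 400)
    intergenic_len: tuple[int, int] = (2500, 4000)
    exonic_fds_rate: float = 0.010
    intronic_fds_rate: float = 0.012
    exonic_rate_multiplier_by_biotype: dict[str, float] = field(default_factory=dict)
    biotype_fractions: dict[str, float] = field(
        default_factory=lambda: {"protein_coding": 0.80, "lncRNA": 0.15, "pseudogene": 0.05}
    )
    ase_fraction: float = 0.10
    ase_fraction_by_biotype: dict[str, float] = field(default_factory=dict)
    ase_ratio: float = 0.8
    imprinted_fraction: float = 0.02
    imprint_ratio: float = 0.9
    allelic_ratio_map: dict[str, float] | None = None
    imprinted_genes: dict[str, str] | None = None  # gene -> paternal|maternal
    splice_fraction: float = 0.25
    ass_fraction: float = 0.3
    dpsi: float = 0.3
    splicing_truth: dict[str, tuple[float, float]] | None = None  # gene -> (psi_A, psi_B)
    read_len: int = 100
    fragment_mean: float = 300.0
    fragment_sd: float = 30.0
    error_rate: float = 0.001
    depth: float = 100.0
    nb_dispersion: float = 0.1
    replicates: int = 3
    tissue: str = "sim"
    chrom: str = "chr1"
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        for rate in (self.exonic_fds_rate, self.intronic_fds_rate):
            if not 0 <= rate <= 0.2:
                raise ValueError(
                    f"fds rate {rate} out of range [0, 0.2]: adjacent sites would collide"
                )
        if abs(sum(self.biotype_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("biotype_fractions must sum to 1")
        for v in (self.ase_ratio, self.imprint_ratio, self.ase_fraction,
                  self.imprinted_fraction, self.splice_fraction, self.ass_fraction):
            if not 0 <= v <= 1:
                raise ValueError("fractions and ratios must lie in [0, 1]")
        if self.allelic_ratio_map:
            if any(not 0 <= r <= 1 for r in self.allelic_ratio_map.values()):
                raise ValueError("allelic ratios must lie in [0, 1]")
        if self.splicing_truth:
            for pa, pb in self.splicing_truth.values():
                if not (0 <= pa <= 1 and 0 <= pb <= 1):
                    raise ValueError("psi values must lie in [0, 1]")
        if self.read_len > self.fragment_mean:
            raise ValueError("read_len exceeds mean fragment length")
        if self.error_rate < 0 or self.error_rate > 0.5:
            raise ValueError("error_rate out of range")


@dataclass
class TruthTable:
    """Simulator ground truth."""

    genes: pd.DataFrame      # gene, biotype, strand, ratio_a, imprint_status, imprint_ratio
    events: pd.DataFrame     # event_id, gene, type, psi_a, psi_b
    fragments: dict[str, pd.DataFrame] = field(default_factory=dict)  # per sample


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    genome_a: dict[str, str]
    genome_b: dict[str, str]
    sites: list[DivergentSite]
    models: GeneModels
    truth: TruthTable
    design: dict[str, tuple[str, str, str]] = field(default_factory=dict)  # sample -> (mother, father, tissue)
    sample_paths: dict[str, dict[str, str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# genome + model construction


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _make_event_transcripts(
    gene_id: str, chrom: str, strand: str, exons: list[tuple[int, int]],
    ev_type: str,
) -> tuple[Transcript, Transcript] | None:
    """Build (inclusion, exclusion) transcripts realizing one event type."""
    k = len(exons)
    if ev_type == "SE" and k >= 3:
        m = k // 2
        inc, exc = exons, exons[:m] + exons[m + 1 :]
    elif ev_type == "RI" and k >= 3:
        m = k // 2 - 1
        merged = (exons[m][0], exons[m + 1][1])
        inc = exons[:m] + [merged] + exons[m + 2 :]
        exc = exons
    elif ev_type == "MXE" and k >= 4:
        m = k // 2 - 1
        inc = exons[: m + 1] + exons[m + 2 :]   # keeps exon m (5'-most alternative)
        exc = exons[:m] + exons[m + 1 :]        # keeps exon m+1
    elif ev_type in ("A5SS", "A3SS") and k >= 3:
        m = k // 2 - 1
        delta = min(40, (exons[m][1] - exons[m][0]) // 2)
        # genomic-left extension difference at the end of exon m ('+' donor)
        want_left_end = (ev_type == "A5SS") == (strand == "+")
        if want_left_end:
            short = (exons[m][0], exons[m][1] - delta)
            inc = exons
            exc = exons[:m] + [short] + exons[m + 1 :]
        else:
            nxt = exons[m + 1]
            short = (nxt[0] + delta, nxt[1])
            inc = exons
            exc = exons[: m + 1] + [short] + exons[m + 2 :]
    else:
        return None
    t_inc = Transcript(f"{gene_id}.t1", gene_id, chrom, strand, inc)
    t_exc = Transcript(f"{gene_id}.t2", gene_id, chrom, strand, exc)
    return t_inc, t_exc


def generate_parental_genomes(
    config: SimulationConfig,
) -> tuple[dict[str, str], dict[str, str], list[DivergentSite], GeneModels, TruthTable]:
    """Lay out gene models on one chromosome and derive the two haplotypes.

    Returns (genomeA, genomeB, sites, models, truth). The two genomes have
    identical length and coordinates and differ exactly at the returned
    sites.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom = config.chrom

    genes: dict[str, Gene] = {}
    gene_rows = []
    event_rows = []
    pos = int(rng.integers(*config.intergenic_len))
    biotypes = list(config.biotype_fractions)
    bio_p = np.array([config.biotype_fractions[b] for b in biotypes])

    for gi in range(config.n_genes):
        gid = f"gene{gi:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = biotypes[rng.choice(len(biotypes), p=bio_p)]
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exons = []
        p = pos
        for ei in range(n_ex):
            ln = int(rng.integers(*config.exon_len))
            exons.append((p, p + ln))
            p += ln
            if ei < n_ex - 1:
                p += int(rng.integers(*config.intron_len))
        gene = Gene(gid, chrom, strand, biotype)

        # splicing designation
        truth_psi = None
        if config.splicing_truth and gid in config.splicing_truth:
            truth_psi = config.splicing_truth[gid]
        elif config.splicing_truth is None and rng.random() < config.splice_fraction and n_ex >= 4:
            base = float(rng.uniform(0.35, 0.65))
            if rng.random() < config.ass_fraction:
                lo = min(max(base - config.dpsi / 2, 0.05), 0.95)
                hi = min(max(base + config.dpsi / 2, 0.05), 0.95)
                truth_psi = (hi, lo) if rng.random() < 0.5 else (lo, hi)
            else:
                truth_psi = (base, base)
        if truth_psi is not None:
            ev_type = EVENT_TYPES[int(rng.choice(5, p=[0.6, 0.1, 0.1, 0.1, 0.1]))]
            made = _make_event_transcripts(gid, chrom, strand, exons, ev_type)
            if made is None:  # too few exons for this type; fall back to SE
                ev_type = "SE"
                made = _make_event_transcripts(gid, chrom, strand, exons, ev_type)
            gene.transcripts.extend(made)
            event_rows.append(
                {"event_id": f"{gid}.{ev_type}", "gene": gid, "type": ev_type,
                 "psi_a": truth_psi[0], "psi_b": truth_psi[1]}
            )
        else:
            gene.transcripts.append(Transcript(f"{gid}.t1", gid, chrom, strand, exons))
        genes[gid] = gene

        # allelic truth
        if config.allelic_ratio_map is not None:
            ratio = config.allelic_ratio_map.get(gid, 0.5)
        else:
            frac = config.ase_fraction_by_biotype.get(biotype, config.ase_fraction)
            if rng.random() < frac:
                ratio = config.ase_ratio if rng.random() < 0.5 else 1 - config.ase_ratio
            else:
                ratio = 0.5
        if config.imprinted_genes is not None:
            imprint = config.imprinted_genes.get(gid, "none")
        else:
            imprint = "none"
            if rng.random() < config.imprinted_fraction:
                imprint = "paternal" if rng.random() < 0.5 else "maternal"
        if imprint != "none":
            ratio = 0.5  # imprinting overrides the species ratio
        gene_rows.append(
            {"gene": gid, "biotype": biotype, "strand": strand, "ratio_a": ratio,
             "imprint_status": imprint, "imprint_ratio": config.imprint_ratio}
        )
        pos = p + int(rng.integers(*config.intergenic_len))

    genome_len = pos
    seq_a = _random_seq(rng, genome_len)

    # FDS placement: per-position Bernoulli, exonic vs non-exonic rates
    rate = np.full(genome_len, config.intronic_fds_rate)
    for g in genes.values():
        mult = config.exonic_rate_multiplier_by_biotype.get(g.biotype, 1.0)
        for s, e in g.exon_union:
            rate[s:e] = config.exonic_fds_rate * mult
    is_fds = rng.random(genome_len) < rate
    fds_pos = np.flatnonzero(is_fds)

    seq_b = seq_a.copy()
    sites: list[DivergentSite] = []
    for p0 in fds_pos:
        ref = seq_a[p0].decode()
        alt = _OTHER[ref][int(rng.integers(0, 3))]
        seq_b[p0] = alt.encode()
        sites.append(DivergentSite(chrom, int(p0) + 1, ref, alt, qual=60.0))

    models = GeneModels(genes, {chrom: genome_len})
    truth = TruthTable(
        genes=pd.DataFrame(gene_rows, columns=["gene", "biotype", "strand", "ratio_a",
                                               "imprint_status", "imprint_ratio"]),
        events=pd.DataFrame(event_rows, columns=["event_id", "gene", "type", "psi_a", "psi_b"]),
    )
    genome_a = {chrom: seq_a.tobytes().decode()}
    genome_b = {chrom: seq_b.tobytes().decode()}
    return genome_a, genome_b, sites, models, truth


# ---------------------------------------------------------------------------
# read simulation


def _sam_header(genome: dict[str, str]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "unsorted"},
         "SQ": [{"SN": name, "LN": len(seq)} for name, seq in genome.items()]}
    )


def _blocks_to_cigar(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    cig = []
    for i, (s, e) in enumerate(blocks):
        if i:
            cig.append((3, s - blocks[i - 1][1]))  # N
        cig.append((0, e - s))  # M
    return cig


def _p_allele_a(row, mother: str, father: str) -> float:
    """Probability a fragment comes from the species-A allele in this sample."""
    if row.imprint_status == "none":
        return row.ratio_a
    favoured = father if row.imprint_status == "paternal" else mother
    return row.imprint_ratio if favoured == "A" else 1.0 - row.imprint_ratio


def _transcript_weights(gene: Gene, psi: float | None) -> list[float]:
    if psi is None or len(gene.transcripts) == 1:
        return [1.0] * len(gene.transcripts)
    return [psi, 1.0 - psi]  # (inclusion t1, exclusion t2), scaled by length later


def simulate_sample_reads(
    config: SimulationConfig,
    genomes: tuple[dict[str, str], dict[str, str]],
    models: GeneModels,
    truth: TruthTable,
    sample_id: str,
    mother: str,
    father: str,
    rng: np.random.Generator,
    out_dir: str | Path,
    allele_override: str | None = None,
) -> pd.DataFrame:
    """Simulate one library and write SAM + paired FASTQ.

    Fragment totals per gene are negative-binomial; the allele of each
    fragment is Bernoulli with the gene's sample-specific species-A
    probability (parent-of-origin aware); the isoform is chosen with
    probability proportional to (molecule fraction × eligible start
    positions) so that length-normalized PSI estimation is unbiased.
    With ``allele_override`` all fragments come from one haplotype
    (parental library).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome_a, genome_b = genomes
    header = _sam_header(genome_a)
    psi_by_gene = {r.gene: (r.psi_a, r.psi_b) for r in truth.events.itertuples()}
    frag_rows = []

    sam_path = out_dir / f"{sample_id}.sam"
    fq1 = out_dir / f"{sample_id}_1.fastq"
    fq2 = out_dir / f"{sample_id}_2.fastq"
    disp = config.nb_dispersion
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as sam, \
            open(fq1, "w") as f1, open(fq2, "w") as f2:
        for row in truth.genes.itertuples():
            gene = models[row.gene]
            p_a = _p_allele_a(row, mother, father)
            if disp > 0:
                n_nb = 1.0 / disp
                total = int(rng.negative_binomial(n_nb, n_nb / (n_nb + config.depth)))
            else:
                total = int(rng.poisson(config.depth))
            for fi in range(total):
                if allele_override is not None:
                    allele = allele_override
                else:
                    allele = "A" if rng.random() < p_a else "B"
                psis = psi_by_gene.get(row.gene)
                psi = None if psis is None else (psis[0] if allele == "A" else psis[1])
                f_len = int(np.clip(rng.normal(config.fragment_mean, config.fragment_sd),
                                    config.read_len, None))
                # isoform choice: molecule fraction x number of start positions
                wts = []
                for w, t in zip(_transcript_weights(gene, psi), gene.transcripts):
                    n_start = max(t.length - f_len + 1, 0)
                    wts.append(w * n_start)
                wsum = sum(wts)
                if wsum == 0:  # fragment longer than every isoform
                    t = max(gene.transcripts, key=lambda t: t.length)
                    f_len = t.length
                else:
                    t = gene.transcripts[int(rng.choice(len(wts), p=np.array(wts) / wsum))]
                start = int(rng.integers(0, max(t.length - f_len + 1, 1)))
                seq_src = genome_a if allele == "A" else genome_b
                name = f"{sample_id}:{row.gene}:{fi}"
                mate_recs = []
                err_positions: list[int] = []
                intervals = (
                    (start, start + config.read_len),
                    (start + f_len - config.read_len, start + f_len),
                )
                mate_seqs = []
                for mi, (ts, te) in enumerate(intervals):
                    blocks = t.genomic_blocks(ts, te)
                    seq = "".join(seq_src[gene.chrom][s:e] for s, e in blocks)
                    if config.error_rate > 0:
                        hits = np.flatnonzero(rng.random(len(seq)) < config.error_rate)
                        if hits.size:
                            sl = list(seq)
                            offsets = np.concatenate(
                                [np.arange(s, e) for s, e in blocks])
                            for h in hits:
                                sl[h] = _OTHER[sl[h]][int(rng.integers(0, 3))]
                                err_positions.append(int(offsets[h]) + 1)
                            seq = "".join(sl)
                    mate_seqs.append(seq)
                    a = pysam.AlignedSegment(header)
                    a.query_name = name
                    a.reference_id = 0
                    a.reference_start = blocks[0][0]
                    a.mapping_quality = 60
                    a.cigartuples = _blocks_to_cigar(blocks)
                    a.query_sequence = seq
                    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
                    a.flag = 99 if mi == 0 else 147
                    mate_recs.append(a)
                mate_recs[0].next_reference_id = 0
                mate_recs[0].next_reference_start = mate_recs[1].reference_start
                mate_recs[1].next_reference_id = 0
                mate_recs[1].next_reference_start = mate_recs[0].reference_start
                span = (mate_recs[1].reference_end - mate_recs[0].reference_start)
                mate_recs[0].template_length = span
                mate_recs[1].template_length = -span
                for a in mate_recs:
                    a.set_tag("oA", allele)
                    a.set_tag("oG", row.gene)
                    if err_positions:
                        a.set_tag("oE", ",".join(map(str, sorted(err_positions))))
                    sam.write(a)
                q = "I" * config.read_len
                f1.write(f"@{name}/1\n{mate_seqs[0]}\n+\n{q}\n")
                rc = mate_seqs[1].translate(_COMP)[::-1]
                f2.write(f"@{name}/2\n{rc}\n+\n{q}\n")
                frag_rows.append(
                    {"read": name, "gene": row.gene, "allele": allele,
                     "transcript": t.id, "start": start, "frag_len": f_len,
                     "n_errors": len(err_positions),
                     "error_positions": ",".join(map(str, sorted(err_positions)))}
                )
    return pd.DataFrame(
        frag_rows, columns=["read", "gene", "allele", "transcript", "start",
                            "frag_len", "n_errors", "error_positions"])


def simulate_hybrid_reads(
    config: SimulationConfig,
    genomes: tuple[dict[str, str], dict[str, str]],
    models: GeneModels,
    truth: TruthTable,
    out_dir: str | Path,
) -> tuple[dict[str, tuple[str, str, str]], dict[str, dict[str, str]]]:
    """Simulate all hybrid samples for both reciprocal-cross directions.

    Returns (design, paths): design maps sample id → (mother, father,
    tissue); paths maps sample id → file locations.
    """
    rng = np.random.default_rng(config.seed + 1)
    design: dict[str, tuple[str, str, str]] = {}
    paths: dict[str, dict[str, str]] = {}
    out_dir = Path(out_dir)
    for mother, father, label in (("A", "B", "AxB"), ("B", "A", "BxA")):
        for r in range(1, config.replicates + 1):
            sid = f"{label}_r{r}"
            frag = simulate_sample_reads(
                config, genomes, models, truth, sid, mother, father, rng, out_dir)
            truth.fragments[sid] = frag
            design[sid] = (mother, father, config.tissue)
            paths[sid] = {
                "sam": str(out_dir / f"{sid}.sam"),
                "fastq1": str(out_dir / f"{sid}_1.fastq"),
                "fastq2": str(out_dir / f"{sid}_2.fastq"),
            }
    return design, paths


def simulate_parental_reads(
    config: SimulationConfig,
    genomes: tuple[dict[str, str], dict[str, str]],
    models: GeneModels,
    truth: TruthTable,
    allele: str,
    out_dir: str | Path,
    sample_id: str | None = None,
) -> pd.DataFrame:
    """Homozygous single-genome library from one parental species."""
    if allele not in ("A", "B"):
        raise ValueError("allele must be 'A' or 'B'")
    rng = np.random.default_rng(config.seed + (2 if allele == "A" else 3))
    sid = sample_id or f"parent{allele}"
    frag = simulate_sample_reads(
        config, genomes, models, truth, sid, allele, allele, rng, out_dir,
        allele_override=allele)
    truth.fragments[sid] = frag
    return frag


def simulate_study(config: SimulationConfig, out_dir: str | Path) -> SimulatedStudy:
    """Generate a complete study: genomes, sites, models, hybrid samples.

    Writes genomeA.fa / genomeB.fa / sites.vcf / models.gtf / truth tables
    under ``out_dir`` along with one SAM + FASTQ pair per sample.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome_a, genome_b, sites, models, truth = generate_parental_genomes(config)
    write_fasta(out_dir / "genomeA.fa", genome_a)
    write_fasta(out_dir / "genomeB.fa", genome_b)
    write_sites_vcf(out_dir / "sites.vcf", sites,
                    {c: len(s) for c, s in genome_a.items()})
    models.to_gtf(out_dir / "models.gtf")
    design, paths = simulate_hybrid_reads(config, (genome_a, genome_b), models, truth, out_dir)
    truth.genes.to_csv(out_dir / "truth_genes.tsv", sep="\t", index=False)
    truth.events.to_csv(out_dir / "truth_events.tsv", sep="\t", index=False)
    with open(out_dir / "design.tsv", "w") as fh:
        fh.write("sample\tmother\tfather\ttissue\n")
        for sid, (m, f, t) in design.items():
            fh.write(f"{sid}\t{m}\t{f}\t{t}\n")
    return SimulatedStudy(config, genome_a, genome_b, sites, models, truth, design, paths)


# ---------------------------------------------------------------------------
# count-level generators for statistical calibration


def simulate_gene_counts(
    ratios: dict[str, float],
    depth: float,
    replicates: int,
    rng: np.random.Generator,
    nb_dispersion: float = 0.1,
    n_exonic_fds: int = 5,
    sample_prefix: str = "rep",
) -> pd.DataFrame:
    """Per-gene assigned allele counts: NB total, binomial species-A split."""
    rows = []
    genes = list(ratios)
    for r in range(1, replicates + 1):
        if nb_dispersion > 0:
            n_nb = 1.0 / nb_dispersion
            totals = rng.negative_binomial(n_nb, n_nb / (n_nb + depth), size=len(genes))
        else:
            totals = rng.poisson(depth, size=len(genes))
        a = rng.binomial(totals, [ratios[g] for g in genes])
        for g, t, x in zip(genes, totals, a):
            rows.append({"gene": g, "sample": f"{sample_prefix}{r}",
                         "countA": float(x), "countB": float(t - x),
                         "n_exonic_fds": n_exonic_fds})
    return pd.DataFrame(rows)


def simulate_reciprocal_counts(
    gene_kinds: dict[str, tuple[str, float]],
    depth: float,
    replicates: int,
    rng: np.random.Generator,
    nb_dispersion: float = 0.1,
    n_exonic_fds: int = 5,
    tissue: str = "sim",
) -> tuple[pd.DataFrame, dict[str, tuple[str, str, str]]]:
    """Counts for both cross directions.

    ``gene_kinds`` maps gene → (kind, ratio) with kind in {balanced, cis,
    paternal, maternal}; ratio is p(species A) for cis genes and
    p(favoured parent) for imprinted genes.
    """
    frames = []
    design: dict[str, tuple[str, str, str]] = {}
    for mother, father, label in (("A", "B", "AxB"), ("B", "A", "BxA")):
        ratios = {}
        for g, (kind, ratio) in gene_kinds.items():
            if kind == "balanced":
                ratios[g] = 0.5
            elif kind == "cis":
                ratios[g] = ratio
            else:
                favoured = father if kind == "paternal" else mother
                ratios[g] = ratio if favoured == "A" else 1 - ratio
        df = simulate_gene_counts(ratios, depth, replicates, rng,
                                  nb_dispersion, n_exonic_fds,
                                  sample_prefix=f"{label}_r")
        frames.append(df)
        for r in range(1, replicates + 1):
            design[f"{label}_r{r}"] = (mother, father, tissue)
    return pd.concat(frames, ignore_index=True), design


def simulate_event_counts(
    psi_pairs: dict[str, tuple[float, float]],
    depth_per_allele: float,
    rng: np.random.Generator,
    l_inc: int = 2,
    l_exc: int = 1,
) -> pd.DataFrame:
    """Inclusion/exclusion read counts per allele for splicing calibration.

    Reads for an event land on the inclusion form with probability
    ψ·l_inc / (ψ·l_inc + (1−ψ)·l_exc), the length-normalized inclusion
    proportion the PSI estimator inverts.
    """
    rows = []
    for ev, (pa, pb) in psi_pairs.items():
        row = {"event_id": ev}
        for allele, psi in (("A", pa), ("B", pb)):
            n = int(rng.poisson(depth_per_allele))
            p = psi * l_inc / (psi * l_inc + (1 - psi) * l_exc)
            inc = int(rng.binomial(n, p)) if n > 0 else 0
            row[f"inc{allele}"] = inc
            row[f"exc{allele}"] = n - inc
        rows.append(row)
    out = pd.DataFrame(rows)
    out["l_inc"] = l_inc
    out["l_exc"] = l_exc
    return out


def config_to_dict(config: SimulationConfig) -> dict:
    return dataclasses.asdict(config)
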