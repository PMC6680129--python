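"""End-to-end orchestration of the hybrid ASE/ASS workflow.

Stages: FDS preparation → pseudogenome → fragment merge and allele
assignment → per-gene counts and FPKM → ASE and imprinting calling →
allele-split alignments → splicing-event quantification and testing →
descriptive statistics. A JSON manifest records the configuration and
per-stage tallies; identical configuration and seed reproduce identical
tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from . import __version__
from .ase import (ALPHA, HI, LO, MIN_EXONIC_FDS, MIN_FPKM, MIN_MEAN_READS,
                  CrossDesign, ase_filter, classify_ase, detect_imprinting)
from .assign import (DEFAULT_MAPQ_FLOOR, classify_fragment, count_gene_alleles,
                     merge_alignments, read_fragments, split_by_allele)
from .features import biotype_ase_proportions, cv_table, fds_density, fpkm_table
from .models import GeneModels
from .pseudogenome import build_pseudogenome, read_fasta, write_fasta
from .sites import (FdsIndex, annotate_fds_regions, filter_fds_by_parental_rna,
                    read_sites_vcf)
from .splicing import (MAX_FDR, MIN_DPSI, MIN_SUPPORT, call_ass,
                       count_event_reads, effective_lengths, enumerate_events)

log = logging.getLogger("hybridase")


@dataclass
class RunConfig:
    reference_fasta: str
    sites_vcf: str
    gtf: str
    design: dict[str, tuple[str, str, str]]     # sample -> (mother, father, tissue)
    sample_sams: dict[str, str]                 # sample -> SAM/BAM vs reference
    pseudo_sams: dict[str, str] | None = None   # sample -> SAM/BAM vs pseudogenome
    parental_rna_a: str | None = None
    parental_rna_b: str | None = None
    out_dir: str = "hybridase_out"
    min_qual: float = 30.0
    min_cov: int = 10
    min_concordance: float = 0.9
    mapq_floor: int = DEFAULT_MAPQ_FLOOR
    min_fds: int = MIN_EXONIC_FDS
    min_mean_reads: float = MIN_MEAN_READS
    min_fpkm: float = MIN_FPKM
    alpha: float = ALPHA
    hi: float = HI
    lo: float = LO
    permissive: bool = False
    min_support: int = MIN_SUPPORT
    min_dpsi: float = MIN_DPSI
    max_fdr: float = MAX_FDR
    read_len: int = 100
    seed: int = 0


@dataclass
class RunResult:
    counts: pd.DataFrame
    ase: dict[str, pd.DataFrame]
    imprinting: dict[str, pd.DataFrame]
    ass: dict[str, pd.DataFrame]
    ass_summary: dict[str, pd.DataFrame]
    fpkm: pd.DataFrame
    fds_annotation: pd.DataFrame
    densities: pd.DataFrame
    assignment: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _load_design(path: str) -> dict[str, tuple[str, str, str]]:
    df = pd.read_csv(path, sep="\t")
    return {r.sample: (r.mother, r.father, r.tissue) for r in df.itertuples()}


def run_end_to_end(config: RunConfig) -> RunResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: v for k, v in dataclasses.asdict(config).items()},
        "stages": {},
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True, default=str).encode()
    ).hexdigest()

    log.info("stage fds: loading sites and annotation")
    reference = read_fasta(config.reference_fasta)
    sites = read_sites_vcf(config.sites_vcf)
    models = GeneModels.from_gtf(config.gtf)
    if config.parental_rna_a and config.parental_rna_b:
        sites, dropped, tally = filter_fds_by_parental_rna(
            sites, config.parental_rna_a, config.parental_rna_b,
            config.min_cov, config.min_concordance)
        manifest["stages"]["fds_rna_filter"] = dict(tally)
    index = FdsIndex(sites)
    annot = annotate_fds_regions(sites, models)
    exonic_per_gene = (
        annot[annot.region == "exonic"].groupby("gene_id").size().to_dict())
    manifest["stages"]["fds"] = {"n_sites": len(sites),
                                 "n_exonic": int((annot.region == "exonic").sum())}

    log.info("stage pseudogenome")
    pseudo = build_pseudogenome(reference, sites)
    write_fasta(out / "pseudogenome.fa", pseudo)

    log.info("stage assign: %d samples", len(config.design))
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "unsorted"},
         "SQ": [{"SN": n, "LN": len(s)} for n, s in reference.items()]})
    all_counts, summary_rows, totals_rows = [], [], []
    split_paths: dict[str, tuple[str, str]] = {}
    for sample, (mother, father, tissue) in config.design.items():
        ref_sam = config.sample_sams[sample]
        pseudo_sam = (config.pseudo_sams or {}).get(sample, ref_sam)
        ref_frags = read_fragments(ref_sam, index, "reference", config.mapq_floor)
        if pseudo_sam == ref_sam:
            for f in ref_frags:
                f.source = "both"
            merged, merge_tally = ref_frags, Counter(both=len(ref_frags))
        else:
            pseudo_frags = read_fragments(pseudo_sam, index, "pseudogenome",
                                          config.mapq_floor)
            merged, merge_tally = merge_alignments(ref_frags, pseudo_frags)
        merged = [f for f in merged if f.uniquely_mapped]
        counts, tally = count_gene_alleles(
            merged, models, index, exonic_per_gene, sample=sample)
        all_counts.append(counts)
        total = sum(tally[k] for k in
                    ("alleleA", "alleleB", "ambiguous", "uninformative")) or 1
        summary_rows.append(
            {"sample": sample, "tissue": tissue,
             **{k: tally.get(k, 0) / total for k in
                ("alleleA", "alleleB", "ambiguous", "uninformative")}})
        for frag in merged:
            for gid in models.genes_overlapping(frag.chrom, list(frag.blocks)):
                totals_rows.append((gid, sample))
        a_path = out / f"{sample}.alleleA.sam"
        b_path = out / f"{sample}.alleleB.sam"
        split_by_allele(merged, index, str(a_path), str(b_path), header)
        split_paths[sample] = (str(a_path), str(b_path))
        manifest["stages"][f"assign:{sample}"] = {
            "merge": dict(merge_tally), "calls": dict(tally)}
    counts = pd.concat(all_counts, ignore_index=True)
    assignment = pd.DataFrame(summary_rows)

    log.info("stage expression")
    totals = (pd.DataFrame(totals_rows, columns=["gene", "sample"])
              .groupby(["gene", "sample"]).size().rename("count").reset_index())
    fpkms = fpkm_table(totals, models)
    biotypes = {g.id: g.biotype for g in models}

    log.info("stage ase/imprinting")
    design = CrossDesign(config.design)
    ase_results: dict[str, pd.DataFrame] = {}
    imprinting: dict[str, pd.DataFrame] = {}
    tissues = sorted({t for _, _, t in config.design.values()})
    for tissue in tissues:
        t_samples = [s for s, (_, _, t) in config.design.items() if t == tissue]
        t_counts = counts[counts["sample"].isin(t_samples)]
        mean_fpkm = fpkms[[s for s in t_samples if s in fpkms.columns]].mean(axis=1)
        eligible, filt_tally = ase_filter(
            t_counts, mean_fpkm, config.min_fds, config.min_mean_reads,
            config.min_fpkm)
        ase_results[tissue] = classify_ase(
            t_counts, eligible, config.alpha, config.hi, config.lo,
            permissive=config.permissive, tissue=tissue)
        manifest["stages"][f"ase:{tissue}"] = dict(filt_tally)
        t_dirs = {(m, f) for s, (m, f, t) in config.design.items() if t == tissue}
        if len(t_dirs) >= 2:
            t_design = CrossDesign({s: design.samples[s] for s in t_samples})
            imprinting[tissue] = detect_imprinting(
                t_counts, t_design, eligible, config.alpha, config.hi, config.lo)

    log.info("stage splice")
    events = enumerate_events(models)
    for ev in events:
        ev.l_inc, ev.l_exc = effective_lengths(ev, config.read_len)
    ass: dict[str, pd.DataFrame] = {}
    ass_summary: dict[str, pd.DataFrame] = {}
    for tissue in tissues:
        t_samples = [s for s, (_, _, t) in config.design.items() if t == tissue]
        agg = None
        for s in t_samples:
            a_df = count_event_reads(split_paths[s][0], events)
            b_df = count_event_reads(split_paths[s][1], events)
            part = a_df.rename(columns={"inc": "incA", "exc": "excA"})
            part["incB"], part["excB"] = b_df["inc"], b_df["exc"]
            cols = ["incA", "excA", "incB", "excB"]
            agg = part if agg is None else agg.assign(
                **{c: agg[c] + part[c] for c in cols})
        if agg is None:
            continue
        agg["l_inc"] = [e.l_inc for e in events]
        agg["l_exc"] = [e.l_exc for e in events]
        ass[tissue], ass_summary[tissue] = call_ass(
            agg, config.min_support, config.min_dpsi, config.max_fdr)
    manifest["stages"]["splice"] = {"n_events": len(events)}

    densities = fds_density(annot, models)

    # persist tables
    counts.to_csv(out / "gene_allele_counts.tsv", sep="\t", index=False)
    assignment.to_csv(out / "assignment_summary.tsv", sep="\t", index=False)
    fpkms.to_csv(out / "fpkm.tsv", sep="\t")
    annot.to_csv(out / "fds_annotation.tsv", sep="\t", index=False)
    densities.to_csv(out / "fds_density.tsv", sep="\t", index=False)
    for tissue in tissues:
        ase_results[tissue].to_csv(out / f"ase.{tissue}.tsv", sep="\t", index=False)
        if tissue in imprinting:
            imprinting[tissue].to_csv(out / f"imprinting.{tissue}.tsv", sep="\t",
                                      index=False)
        if tissue in ass:
            ass[tissue].to_csv(out / f"ass.{tissue}.tsv", sep="\t", index=False)
            ass_summary[tissue].to_csv(out / f"ass_summary.{tissue}.tsv", sep="\t",
                                       index=False)
    cvs = cv_table(fpkms)
    cvs.rename("cv").to_csv(out / "cv.tsv", sep="\t")
    pooled_ase = pd.concat(ase_results.values(), ignore_index=True)
    if not pooled_ase.empty:
        biotype_ase_proportions(pooled_ase, biotypes).to_csv(
            out / "biotype_ase.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)

    return RunResult(counts, ase_results, imprinting, ass, ass_summary, fpkms,
                     annot, densities, assignment, manifest)


def mock_hybrid_experiment(
    parental_sam_a: str,
    parental_sam_b: str,
    sites_vcf: str,
    n_per_parent: int,
    seed: int = 0,
    mapq_floor: int = DEFAULT_MAPQ_FLOOR,
) -> dict:
    """Mix equal numbers of parental fragments and re-assign their origin.

    Validates the assignment machinery: an equal in-silico mixture of the
    two parental libraries should be assigned ~50/50. Returns the assigned
    proportions, the absolute deviation from 0.5, and a two-sided binomial
    test of assigned-A counts against 0.5.
    """
    if n_per_parent <= 0:
        raise ValueError("n_per_parent must be positive")
    from scipy import stats

    index = FdsIndex(read_sites_vcf(sites_vcf))
    rng = np.random.default_rng(seed)
    mixture = []
    for path, source in ((parental_sam_a, "A"), (parental_sam_b, "B")):
        frags = [f for f in read_fragments(path, index, "both", mapq_floor)
                 if f.uniquely_mapped]
        if len(frags) < n_per_parent:
            raise ValueError(
                f"parent {source} has only {len(frags)} unique fragments")
        take = rng.choice(len(frags), size=n_per_parent, replace=False)
        mixture.extend(frags[i] for i in take)
    calls = Counter(classify_fragment(f, index).call for f in mixture)
    n_a, n_b = calls.get("alleleA", 0), calls.get("alleleB", 0)
    assigned = n_a + n_b
    prop_a = n_a / assigned if assigned else np.nan
    pvalue = float(stats.binomtest(n_a, assigned, 0.5).pvalue) if assigned else np.nan
    return {
        "n_fragments": len(mixture),
        "n_assigned": assigned,
        "proportion_A": prop_a,
        "proportion_B": 1 - prop_a if assigned else np.nan,
        "abs_deviation": abs(prop_a - 0.5) if assigned else np.nan,
        "binomial_pvalue": pvalue,
        "calls": dict(calls),
    }
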