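"""Simulation studies that validate the pipeline at its operating conditions.

Each function runs a self-contained experiment against known truth — the
statistical analogue of positive/negative controls: false-positive rate and
power of the ASE caller, imprinting/cis separation across reciprocal
crosses, null calibration and power of the splicing LRT, mock-hybrid
assignment, and exactness of allele assignment without sequencing error.
All randomness flows from the caller's seed.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path

import numpy as np
from scipy import stats

from .ase import CrossDesign, classify_ase, detect_imprinting
from .assign import classify_fragment, read_fragments
from .pipeline import mock_hybrid_experiment
from .simulate import (SimulationConfig, generate_parental_genomes,
                       simulate_event_counts, simulate_gene_counts,
                       simulate_parental_reads, simulate_reciprocal_counts,
                       simulate_study)
from .sites import FdsIndex
from .splicing import call_ass


def ase_error_and_power(
    seed: int,
    n_balanced: int = 500,
    n_imbalanced: int = 50,
    true_ratio: float = 0.8,
    depth: float = 100.0,
    replicates: int = 3,
) -> dict:
    """Type-I error and power of the ASE caller on count-level truth.

    Balanced genes (ratio 0.5) measure the false-call rate; imbalanced genes
    at ``true_ratio`` measure sensitivity and the accuracy of the pooled
    ratio estimate.
    """
    rng = np.random.default_rng(seed)
    ratios = {f"bal{i}": 0.5 for i in range(n_balanced)}
    ratios.update({f"imb{i}": true_ratio for i in range(n_imbalanced)})
    counts = simulate_gene_counts(ratios, depth, replicates, rng)
    res = classify_ase(counts).set_index("gene")
    is_ase = res.classification.str.endswith("_specific")
    balanced = res.index.str.startswith("bal")
    imbalanced = ~balanced
    p1_err = np.abs(res.loc[imbalanced, "p1"] - true_ratio)
    return {
        "false_positive_rate": float(is_ase[balanced].mean()),
        "sensitivity": float(is_ase[imbalanced].mean()),
        "p1_within_tolerance": float((p1_err <= 0.05).mean()),
        "mean_abs_p1_error": float(p1_err.mean()),
        "n_balanced": n_balanced,
        "n_imbalanced": n_imbalanced,
    }


def imprinting_separation(
    seed: int,
    n_imprinted: int = 20,
    n_cis: int = 20,
    n_balanced: int = 60,
    depth: float = 100.0,
    replicates: int = 3,
) -> dict:
    """Recovery and mutual exclusivity of imprinting vs cis-ASE calls."""
    rng = np.random.default_rng(seed)
    kinds: dict[str, tuple[str, float]] = {}
    for i in range(n_imprinted):
        kinds[f"imp{i}"] = ("paternal" if i % 2 else "maternal", 0.9)
    for i in range(n_cis):
        kinds[f"cis{i}"] = ("cis", 0.8 if i % 2 else 0.2)
    for i in range(n_balanced):
        kinds[f"bal{i}"] = ("balanced", 0.5)
    counts, design = simulate_reciprocal_counts(kinds, depth, replicates, rng)
    imp = detect_imprinting(counts, CrossDesign(design))
    imp_called = set(imp.gene)
    direction_ok = all(
        kinds[row.gene][0] == row.direction for row in imp.itertuples()
        if row.gene in kinds and kinds[row.gene][0] in ("paternal", "maternal"))
    ase = classify_ase(counts)
    ase_called = set(ase[ase.classification.str.endswith("_specific")].gene)
    truth_imp = {g for g, (k, _) in kinds.items() if k in ("paternal", "maternal")}
    truth_cis = {g for g, (k, _) in kinds.items() if k == "cis"}
    return {
        "imprinted_recovery": len(imp_called & truth_imp) / n_imprinted,
        "cis_recovery": len(ase_called & truth_cis) / n_cis,
        "n_overlap_calls": len(imp_called & ase_called),
        "directions_correct": bool(direction_ok),
        "n_imprinted": n_imprinted,
        "n_cis": n_cis,
    }


def ass_null_and_power(
    seed: int,
    n_null: int = 500,
    n_planted: int = 10,
    null_psi: float = 0.5,
    dpsi: float = 0.3,
    depth_null: float = 150.0,
    depth_planted: float = 200.0,
) -> dict:
    """Null uniformity of the splicing LRT and power on planted effects.

    Null events share ψ across alleles; planted events differ by ``dpsi``
    and are simulated at ~400 supporting reads — comfortably above the
    300-read floor of the power analysis, so the expected detection rate
    follows the binomial power bound rather than sitting at its margin.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    null_pairs = {f"null{i}": (null_psi, null_psi) for i in range(n_null)}
    planted_pairs = {
        f"ass{i}": (null_psi + dpsi / 2, null_psi - dpsi / 2) for i in range(n_planted)}
    # raw-count psi (l_inc = l_exc): the power analysis is a plain
    # two-binomial comparison, so psi is the inclusion-read proportion
    df = simulate_event_counts(null_pairs, depth_null, rng, l_inc=1, l_exc=1)
    deep = simulate_event_counts(planted_pairs, depth_planted, rng, l_inc=1, l_exc=1)
    df = pd.concat([df, deep], ignore_index=True)
    df["type"] = "SE"
    res, _ = call_ass(df)
    res = res.set_index("event_id")
    null_p = res.loc[res.index.str.startswith("null"), "pvalue"].dropna()
    ks = stats.kstest(null_p, "uniform")
    detected = int(res.loc[res.index.str.startswith("ass"), "significant"].sum())
    return {
        "ks_pvalue": float(ks.pvalue),
        "null_fraction_below_0.05": float((null_p < 0.05).mean()),
        "n_null_tested": int(null_p.size),
        "planted_detected": detected,
        "n_planted": n_planted,
        "false_calls": int(res.loc[res.index.str.startswith("null"), "significant"].sum()),
    }


def assignment_soundness(seed: int, out_dir: str | Path, n_genes: int = 25,
                         depth: float = 60.0) -> dict:
    """Error-free reads must re-derive their truth allele exactly."""
    cfg = SimulationConfig(n_genes=n_genes, depth=depth, error_rate=0.0,
                           seed=seed, replicates=1)
    study = simulate_study(cfg, out_dir)
    index = FdsIndex(study.sites)
    n_frags = n_assigned = n_correct = 0
    calls: Counter = Counter()
    for sid in study.design:
        frags = read_fragments(study.sample_paths[sid]["sam"], index, "both")
        for f in frags:
            call = classify_fragment(f, index)
            calls[call.call] += 1
            n_frags += 1
            if call.call in ("alleleA", "alleleB"):
                n_assigned += 1
                n_correct += call.call[-1] == f.truth_allele
    return {
        "accuracy": n_correct / n_assigned if n_assigned else float("nan"),
        "n_assigned": n_assigned,
        "n_fragments": n_frags,
        "partition_exact": sum(calls.values()) == n_frags,
        "n_ambiguous": calls.get("ambiguous", 0),
    }


def mock_hybrid_calibration(seed: int, out_dir: str | Path, n_genes: int = 60,
                            depth: float = 120.0, n_per_parent: int = 6500) -> dict:
    """Equal parental mixture re-assigned; ≥10⁴ informative fragments."""
    out_dir = Path(out_dir)
    cfg = SimulationConfig(n_genes=n_genes, depth=depth, seed=seed, replicates=1)
    genome_a, genome_b, sites, models, truth = generate_parental_genomes(cfg)
    from .pseudogenome import write_fasta
    from .sites import write_sites_vcf

    out_dir.mkdir(parents=True, exist_ok=True)
    vcf = out_dir / "sites.vcf"
    write_sites_vcf(vcf, sites, {c: len(s) for c, s in genome_a.items()})
    genomes = (genome_a, genome_b)
    simulate_parental_reads(cfg, genomes, models, truth, "A", out_dir)
    simulate_parental_reads(cfg, genomes, models, truth, "B", out_dir)
    return mock_hybrid_experiment(
        str(out_dir / "parentA.sam"), str(out_dir / "parentB.sam"), str(vcf),
        n_per_parent=n_per_parent, seed=seed)


def fds_density_contrast(seed: int, n_genes: int = 150, multiplier: float = 2.0) -> dict:
    """Recovery of a planted exonic FDS-rate contrast between gene classes."""
    from .features import fds_density
    from .sites import annotate_fds_regions

    cfg = SimulationConfig(
        n_genes=n_genes, seed=seed,
        biotype_fractions={"protein_coding": 0.5, "lncRNA": 0.5, "pseudogene": 0.0},
        exonic_rate_multiplier_by_biotype={"lncRNA": multiplier})
    _, _, sites, models, _ = generate_parental_genomes(cfg)
    annot = annotate_fds_regions(sites, models)
    dens = fds_density(annot, models)
    mean_hi = dens[dens.biotype == "lncRNA"].exonic_density.mean()
    mean_lo = dens[dens.biotype == "protein_coding"].exonic_density.mean()
    n_exonic = int((annot.region == "exonic").sum())
    return {
        "observed_ratio": float(mean_hi / mean_lo),
        "expected_ratio": multiplier,
        "n_exonic_sites": n_exonic,
        # Poisson error on a ratio of two ~equal-size site counts
        "three_se_band": float(3 * multiplier * np.sqrt(4 / n_exonic)),
    }
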