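"""Descriptive expression and divergence statistics.

FPKM from exon-union fragment counts, coefficient of variation across
biological replicates, FDS density per genomic region, and biotype-stratified
ASE proportions. Group contrasts use the two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .models import GeneModels


def fpkm(fragment_count: float, gene_length_bp: int, library_size: int) -> float:
    """Fragments per kilobase of exon-union length per million fragments."""
    if gene_length_bp <= 0 or library_size <= 0:
        raise ValueError("gene length and library size must be positive")
    return fragment_count / (gene_length_bp / 1000) / (library_size / 1e6)


def fpkm_table(
    counts: pd.DataFrame, models: GeneModels, library_sizes: dict[str, int] | None = None
) -> pd.DataFrame:
    """Gene × sample FPKM matrix from a long (gene, sample, count) table.

    Library size defaults to the per-sample sum of counted fragments.
    """
    wide = counts.pivot_table(index="gene", columns="sample", values="count",
                              aggfunc="sum", fill_value=0.0)
    lengths = pd.Series({g.id: g.exon_union_length for g in models})
    wide = wide.reindex(lengths.index, fill_value=0.0)
    libs = pd.Series(library_sizes) if library_sizes else wide.sum(axis=0)
    return wide.div(lengths / 1000, axis=0).div(libs / 1e6, axis=1)


def cv(values) -> float:
    """Coefficient of variation: sample (n−1) SD over mean, per gene."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least two replicates")
    m = v.mean()
    if m <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(v.std(ddof=1) / m)


def cv_table(fpkms: pd.DataFrame) -> pd.Series:
    """Per-gene CV across samples; genes with zero mean are NaN."""
    m = fpkms.mean(axis=1)
    sd = fpkms.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sd / m
    out[m <= 0] = np.nan
    return out


def fds_density(
    fds_annotation: pd.DataFrame,
    models: GeneModels,
    promoter_width: int = 2000,
) -> pd.DataFrame:
    """Per-gene FDS densities (sites per kb) in promoter, exon and intron.

    Region lengths: the strand-aware promoter window (possibly clipped at
    the chromosome start), the exon union, and the gene span minus the exon
    union. Zero-length regions yield NaN density.
    """
    per_gene = fds_annotation.groupby(["gene_id", "region"]).size().unstack(fill_value=0)
    rows = []
    for g in models:
        counts = per_gene.loc[g.id] if g.id in per_gene.index else pd.Series(dtype=int)
        ps, pe = g.promoter(promoter_width)
        lengths = {
            "promoter": pe - ps,
            "exonic": g.exon_union_length,
            "intronic": (g.end - g.start) - g.exon_union_length,
        }
        row = {"gene": g.id, "biotype": g.biotype}
        for region, ln in lengths.items():
            n = int(counts.get(region, 0))
            row[f"{region}_density"] = n / ln * 1000 if ln > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def wilcoxon_rank_sum(values_a, values_b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value for two groups."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def biotype_ase_proportions(
    ase_results: pd.DataFrame, biotypes: dict[str, str]
) -> pd.DataFrame:
    """Fraction of eligible genes called ASE per biotype.

    Denominators are the eligible (non-filtered) genes of each biotype;
    biotypes with no eligible genes are absent from the output rather than
    reported as 0/0.
    """
    df = ase_results[ase_results["classification"] != "filtered"].copy()
    df["biotype"] = df["gene"].map(biotypes)
    df["is_ase"] = df["classification"].isin(["alleleA_specific", "alleleB_specific"])
    grouped = df.groupby("biotype").agg(n_genes=("gene", "count"), n_ase=("is_ase", "sum"))
    grouped = grouped[grouped["n_genes"] > 0]
    grouped["proportion"] = grouped["n_ase"] / grouped["n_genes"]
    return grouped.reset_index()
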