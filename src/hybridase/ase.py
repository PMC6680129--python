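"""Allele-specific expression calling and imprinting separation.

The core test is the Storer-Kim exact unconditional test of two binomial
proportions: under H0 (p1 = p2) the pooled estimate p̂ = (x1+x2)/(n1+n2)
parameterizes a product-binomial over all outcome pairs, and the p-value is
the total probability of outcomes whose proportion difference is at least as
extreme as observed. Genes pass a depth/informativeness filter, are tested
on replicate-pooled counts, BH-corrected, and classified allele-specific
only when the imbalance cutoff holds in the pooled estimate and in every
biological replicate. Imprinting is separated from cis (species-allele) ASE
by relabelling counts as paternal/maternal according to each sample's cross
direction and demanding concordance across both reciprocal directions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

TIE_EPS = 1e-12

ALPHA = 0.05
HI, LO = 0.65, 0.35          # strict allelic-imbalance cutoffs
HI_PERMISSIVE, LO_PERMISSIVE = 0.60, 0.40

MIN_EXONIC_FDS = 3
MIN_MEAN_READS = 20
MIN_FPKM = 1.0


# ---------------------------------------------------------------------------
# Storer-Kim exact unconditional test


def storer_kim_test(x1: int, n1: int, x2: int, n2: int) -> float:
    """Two-sided exact unconditional p-value for H0: p1 = p2.

    Sums Bin(y1; n1, p̂)·Bin(y2; n2, p̂) over all outcome pairs with
    |y1/n1 − y2/n2| >= |x1/n1 − x2/n2| − ε, with p̂ the pooled proportion
    and ε a guard against floating-point ties.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("both sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("successes out of range")
    p_hat = (x1 + x2) / (n1 + n2)
    d_obs = abs(x1 / n1 - x2 / n2)
    if d_obs <= TIE_EPS:  # every outcome qualifies
        return 1.0
    y1 = np.arange(n1 + 1)
    y2 = np.arange(n2 + 1)
    pmf1 = stats.binom.pmf(y1, n1, p_hat)
    pmf2 = stats.binom.pmf(y2, n2, p_hat)
    diff = np.abs(y1[:, None] / n1 - y2[None, :] / n2)
    p = float(np.sum(pmf1[:, None] * pmf2[None, :] * (diff >= d_obs - TIE_EPS)))
    return min(max(p, np.nextafter(0, 1)), 1.0)


def storer_kim_grid(n1: int, n2: int) -> np.ndarray:
    """p-values for every (x1, x2) at fixed (n1, n2), vectorized.

    Outcomes sharing s = x1 + x2 share the pooled p̂, so for each s the
    product-binomial surface is computed once, sorted by |difference|, and
    suffix-summed; each observed cell reads off its tail by binary search.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("both sample sizes must be positive")
    y1 = np.arange(n1 + 1)
    y2 = np.arange(n2 + 1)
    diff = np.abs(y1[:, None] / n1 - y2[None, :] / n2)
    flat_diff = diff.ravel()
    order = np.argsort(flat_diff)
    sorted_diff = flat_diff[order]
    s_of_cell = (y1[:, None] + y2[None, :])
    out = np.empty((n1 + 1, n2 + 1))
    for s in range(n1 + n2 + 1):
        p_hat = s / (n1 + n2)
        prob = (stats.binom.pmf(y1, n1, p_hat)[:, None]
                * stats.binom.pmf(y2, n2, p_hat)[None, :]).ravel()[order]
        suffix = np.concatenate([np.cumsum(prob[::-1])[::-1], [0.0]])
        cells = np.flatnonzero((s_of_cell == s).ravel())
        thresholds = flat_diff[cells] - TIE_EPS
        idx = np.searchsorted(sorted_diff, thresholds, side="left")
        out.ravel()[cells] = suffix[idx]
    out[diff <= TIE_EPS] = 1.0  # zero observed difference: whole space qualifies
    return np.clip(out, np.nextafter(0, 1), 1.0)


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(pvalues, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1).

    ``method='storey'`` rescales by Storey's π0 estimate (λ = 0.5) as an
    alternative q-value flavour.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    if method == "storey":
        lam = 0.5
        pi0 = min(np.mean(p > lam) / (1 - lam), 1.0)
        q = np.minimum(q * pi0, 1.0)
    elif method != "bh":
        raise ValueError(f"unknown method {method!r}")
    return q


# ---------------------------------------------------------------------------
# filtering / classification


def _round_half_even(x: float) -> int:
    return int(np.rint(x))


def ase_filter(
    counts: pd.DataFrame,
    fpkm: pd.Series | None = None,
    min_fds: int = MIN_EXONIC_FDS,
    min_mean_reads: float = MIN_MEAN_READS,
    min_fpkm: float = MIN_FPKM,
) -> tuple[set[str], Counter]:
    """Eligibility filter for ASE testing.

    A gene is eligible iff it has >= min_fds exonic FDSs, a mean of
    >= min_mean_reads assigned reads per biological replicate, and (when an
    FPKM table is supplied) mean FPKM >= min_fpkm. Returns the eligible set
    and an exclusion tally whose values sum to the gene count.
    """
    tally: Counter = Counter()
    eligible: set[str] = set()
    grouped = counts.groupby("gene")
    for gene, df in grouped:
        if df["n_exonic_fds"].iloc[0] < min_fds:
            tally["too_few_fds"] += 1
            continue
        if (df["countA"] + df["countB"]).mean() < min_mean_reads:
            tally["low_depth"] += 1
            continue
        if fpkm is not None and gene in fpkm.index and fpkm.loc[gene] < min_fpkm:
            tally["low_fpkm"] += 1
            continue
        tally["eligible"] += 1
        eligible.add(gene)
    return eligible, tally


@dataclass
class SkewStatistic:
    R: float


def skew(count_a: float, count_b: float) -> SkewStatistic:
    """Allelic skew R = (A − B)/(A + B) ∈ [−1, 1]."""
    total = count_a + count_b
    if total <= 0:
        raise ValueError("skew undefined for zero total count")
    return SkewStatistic((count_a - count_b) / total)


def classify_ase(
    counts: pd.DataFrame,
    eligible: set[str] | None = None,
    alpha: float = ALPHA,
    hi: float = HI,
    lo: float = LO,
    permissive: bool = False,
    tissue: str = "",
) -> pd.DataFrame:
    """Call per-gene ASE from replicate counts of one tissue.

    Significance comes from the Storer-Kim test on replicate-pooled counts
    (averaged half-integer counts rounded to nearest, ties to even), BH
    adjusted across all tested genes. A gene is alleleA_specific iff
    q < alpha, pooled p1 > hi, and the per-replicate ratio exceeds hi in
    every replicate; alleleB symmetric with p1 < lo. ``permissive`` swaps
    the cutoffs for 0.6/0.4.
    """
    if permissive:
        hi, lo = HI_PERMISSIVE, LO_PERMISSIVE
    rows = []
    for gene, df in counts.groupby("gene"):
        if eligible is not None and gene not in eligible:
            continue
        x_a = _round_half_even(df["countA"].sum())
        x_b = _round_half_even(df["countB"].sum())
        total = x_a + x_b
        reps = df["countA"] / (df["countA"] + df["countB"])
        rows.append(
            {"gene": gene, "tissue": tissue, "x_a": x_a, "x_b": x_b,
             "p1": x_a / total if total else np.nan,
             "per_replicate_ratios": list(reps),
             "pvalue": storer_kim_test(x_a, total, x_b, total) if total else np.nan}
        )
    res = pd.DataFrame(rows)
    if res.empty:
        return pd.DataFrame(
            columns=["gene", "tissue", "p1", "p2", "pvalue", "qvalue",
                     "per_replicate_ratios", "R", "classification"])
    tested = res["pvalue"].notna()
    res["qvalue"] = np.nan
    res.loc[tested, "qvalue"] = bh_adjust(res.loc[tested, "pvalue"])
    res["p2"] = 1 - res["p1"]

    def _klass(row) -> str:
        if not np.isfinite(row.pvalue):
            return "filtered"
        reps = np.array(row.per_replicate_ratios, dtype=float)
        if row.qvalue < alpha and row.p1 > hi and np.all(reps > hi):
            return "alleleA_specific"
        if row.qvalue < alpha and row.p1 < lo and np.all(reps < lo):
            return "alleleB_specific"
        return "balanced"

    res["classification"] = res.apply(_klass, axis=1)
    res["R"] = np.where(res.x_a + res.x_b > 0,
                        (res.x_a - res.x_b) / (res.x_a + res.x_b), np.nan)
    return res[["gene", "tissue", "p1", "p2", "pvalue", "qvalue",
                "per_replicate_ratios", "R", "classification"]]


# ---------------------------------------------------------------------------
# imprinting via reciprocal crosses


@dataclass
class CrossDesign:
    """sample id → (mother species, father species, tissue)."""

    samples: dict[str, tuple[str, str, str]] = field(default_factory=dict)

    def __post_init__(self):
        species = {m for m, _, _ in self.samples.values()} | {
            f for _, f, _ in self.samples.values()}
        if self.samples and species - {"A", "B"}:
            raise ValueError("species labels must be 'A' and 'B'")

    def directions(self) -> set[tuple[str, str]]:
        return {(m, f) for m, f, _ in self.samples.values()}

    def father_of(self, sample: str) -> str:
        return self.samples[sample][1]


def detect_imprinting(
    counts: pd.DataFrame,
    design: CrossDesign,
    eligible: set[str] | None = None,
    alpha: float = ALPHA,
    hi: float = HI,
    lo: float = LO,
) -> pd.DataFrame:
    """Call parent-of-origin biased genes from reciprocal-cross counts.

    Species counts are relabelled paternal/maternal per the sample's cross
    direction, pooled, and tested (Storer-Kim + BH). A paternal call
    requires q < alpha and a paternal ratio > hi in every sample of both
    directions; maternal symmetric. Genes whose bias follows the species
    allele flip direction under relabelling and cannot satisfy concordance,
    so cis-ASE genes are excluded by construction.
    """
    if len(design.directions()) < 2:
        raise ValueError("imprinting analysis needs both reciprocal cross directions")
    rows = []
    for gene, df in counts.groupby("gene"):
        if eligible is not None and gene not in eligible:
            continue
        pat = np.where([design.father_of(s) == "A" for s in df["sample"]],
                       df["countA"], df["countB"]).astype(float)
        mat = np.where([design.father_of(s) == "A" for s in df["sample"]],
                       df["countB"], df["countA"]).astype(float)
        x_p, x_m = _round_half_even(pat.sum()), _round_half_even(mat.sum())
        total = x_p + x_m
        if total == 0:
            continue
        with np.errstate(invalid="ignore"):
            ratios = pat / (pat + mat)
        rows.append(
            {"gene": gene, "paternal_ratio": x_p / total,
             "per_sample_ratios": list(ratios),
             "pvalue": storer_kim_test(x_p, total, x_m, total)}
        )
    res = pd.DataFrame(rows)
    if res.empty:
        return pd.DataFrame(columns=["gene", "direction", "paternal_ratio",
                                     "per_sample_ratios", "pvalue", "qvalue"])
    res["qvalue"] = bh_adjust(res["pvalue"])

    def _dir(row) -> str:
        r = np.array(row.per_sample_ratios, dtype=float)
        if row.qvalue < alpha and row.paternal_ratio > hi and np.all(r > hi):
            return "paternal"
        if row.qvalue < alpha and row.paternal_ratio < lo and np.all(r < lo):
            return "maternal"
        return "none"

    res["direction"] = res.apply(_dir, axis=1)
    res = res[res["direction"] != "none"]
    return res[["gene", "direction", "paternal_ratio", "per_sample_ratios",
                "pvalue", "qvalue"]].reset_index(drop=True)
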