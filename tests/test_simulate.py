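import hashlib
from pathlib import Path

import numpy as np
import pysam
import pytest

from hybridase.simulate import (SimulationConfig, generate_parental_genomes,
                                simulate_gene_counts, simulate_reciprocal_counts,
                                simulate_study)


def _sha_dir(path: Path) -> dict[str, str]:
    return {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(path.iterdir()) if p.is_file()}


class TestGenomes:
    def test_zero_genes_degenerate(self):
        ga, gb, sites, models, truth = generate_parental_genomes(
            SimulationConfig(n_genes=0, seed=1))
        assert len(models) == 0 and truth.genes.empty
        # haplotypes still differ only at (intergenic) sites
        diff = sum(a != b for a, b in zip(ga["chr1"], gb["chr1"]))
        assert diff == len(sites)

    def test_zero_fds_rate_identical_genomes(self):
        cfg = SimulationConfig(n_genes=3, exonic_fds_rate=0.0,
                               intronic_fds_rate=0.0, seed=2)
        ga, gb, sites, _, _ = generate_parental_genomes(cfg)
        assert ga == gb and not sites

    def test_haplotypes_differ_exactly_at_sites(self):
        ga, gb, sites, _, _ = generate_parental_genomes(SimulationConfig(n_genes=5, seed=3))
        a, b = ga["chr1"], gb["chr1"]
        assert len(a) == len(b)
        diff_pos = {i + 1 for i, (x, y) in enumerate(zip(a, b)) if x != y}
        assert diff_pos == {s.pos for s in sites}
        for s in sites:
            assert a[s.pos - 1] == s.ref_allele and b[s.pos - 1] == s.alt_allele

    def test_every_gene_has_transcripts_and_events_have_two(self):
        cfg = SimulationConfig(n_genes=20, splice_fraction=0.6, seed=4)
        _, _, _, models, truth = generate_parental_genomes(cfg)
        assert all(len(g.transcripts) >= 1 for g in models)
        for ev in truth.events.itertuples():
            assert len(models[ev.gene].transcripts) == 2

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="collide"):
            SimulationConfig(exonic_fds_rate=0.9).validate()
        with pytest.raises(ValueError, match="fragment"):
            SimulationConfig(read_len=400).validate()
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(biotype_fractions={"protein_coding": 0.5}).validate()


def test_seed_determinism_byte_identical(tmp_path):
    cfg = SimulationConfig(n_genes=6, depth=20, seed=9)
    simulate_study(cfg, tmp_path / "run1")
    simulate_study(cfg, tmp_path / "run2")
    assert _sha_dir(tmp_path / "run1") == _sha_dir(tmp_path / "run2")


class TestReadTruth:
    def test_label_soundness_error_free(self, clean_study):
        """At error_rate 0, sequence at overlapped FDSs re-derives the label."""
        pos = {s.pos - 1: (s.ref_allele, s.alt_allele) for s in clean_study.sites}
        sid = next(iter(clean_study.design))
        n_checked = 0
        with pysam.AlignmentFile(clean_study.sample_paths[sid]["sam"], check_sq=False) as af:
            for rec in af:
                votes = set()
                for qp, rp in rec.get_aligned_pairs(matches_only=True):
                    if rp in pos:
                        ref, alt = pos[rp]
                        base = rec.query_sequence[qp]
                        votes.add("A" if base == ref else "B" if base == alt else "?")
                if votes:
                    assert votes == {rec.get_tag("oA")}
                    n_checked += 1
        assert n_checked > 100

    def test_coordinate_soundness(self, clean_study):
        """Each SAM record's bases equal the declared allele's genome slice."""
        sid = next(iter(clean_study.design))
        genomes = {"A": clean_study.genome_a, "B": clean_study.genome_b}
        with pysam.AlignmentFile(clean_study.sample_paths[sid]["sam"], check_sq=False) as af:
            for i, rec in enumerate(af):
                if i >= 500:
                    break
                genome = genomes[rec.get_tag("oA")][rec.reference_name]
                expect = "".join(genome[s:e] for s, e in rec.get_blocks())
                assert rec.query_sequence == expect

    def test_error_positions_recorded(self, noisy_study):
        sid = next(iter(noisy_study.design))
        genomes = {"A": noisy_study.genome_a, "B": noisy_study.genome_b}
        n_err = 0
        with pysam.AlignmentFile(noisy_study.sample_paths[sid]["sam"], check_sq=False) as af:
            for rec in af:
                if not rec.has_tag("oE"):
                    continue
                recorded = {int(x) - 1 for x in rec.get_tag("oE").split(",")}
                genome = genomes[rec.get_tag("oA")][rec.reference_name]
                for qp, rp in rec.get_aligned_pairs(matches_only=True):
                    if rec.query_sequence[qp] != genome[rp]:
                        assert rp in recorded
                        n_err += 1
        assert n_err > 0

    def test_imprinted_gene_flips_between_cross_directions(self, tmp_path):
        """Parent-of-origin bias favours opposite species alleles per direction."""
        cfg = SimulationConfig(
            n_genes=2, depth=400, error_rate=0.0, seed=5, replicates=1,
            splice_fraction=0.0,
            allelic_ratio_map={"gene0000": 0.5, "gene0001": 0.5},
            imprinted_genes={"gene0000": "paternal"},
        )
        study = simulate_study(cfg, tmp_path)
        for sid, (mother, father, _) in study.design.items():
            frac_a = (study.truth.fragments[sid]
                      .query("gene == 'gene0000'").allele.eq("A").mean())
            if father == "A":
                assert frac_a > 0.8
            else:
                assert frac_a < 0.2

    def test_allelic_ratio_binomial_bound(self, tmp_path):
        """Observed allele-A fraction within 3 binomial SDs of the truth."""
        cfg = SimulationConfig(n_genes=1, depth=10_000, error_rate=0.0, seed=6,
                               replicates=1, splice_fraction=0.0,
                               allelic_ratio_map={"gene0000": 0.5})
        study = simulate_study(cfg, tmp_path)
        frag = study.truth.fragments["AxB_r1"]
        n = len(frag)
        frac = frag.allele.eq("A").mean()
        assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / n)


class TestCountSimulators:
    def test_gene_counts_match_ratio(self):
        rng = np.random.default_rng(0)
        df = simulate_gene_counts({"g1": 0.8}, depth=5000, replicates=4, rng=rng)
        frac = df.countA.sum() / (df.countA.sum() + df.countB.sum())
        assert abs(frac - 0.8) < 0.02

    def test_reciprocal_counts_flip_imprinted_only(self):
        rng = np.random.default_rng(1)
        counts, design = simulate_reciprocal_counts(
            {"imp": ("paternal", 0.9), "cis": ("cis", 0.9)},
            depth=3000, replicates=2, rng=rng)
        for gene, should_flip in (("imp", True), ("cis", False)):
            sub = counts[counts.gene == gene].set_index("sample")
            frac = sub.countA / (sub.countA + sub.countB)
            axb = frac[[s for s in frac.index if design[s][1] == "B"]].mean()
            bxa = frac[[s for s in frac.index if design[s][1] == "A"]].mean()
            if should_flip:
                assert (axb < 0.2) != (bxa < 0.2)  # opposite directions
            else:
                assert axb > 0.8 and bxa > 0.8
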