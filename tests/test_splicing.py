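import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import xlogy

from hybridase.models import Gene, GeneModels, Transcript
from hybridase.simulate import SimulationConfig, simulate_study
from hybridase.splicing import (call_ass, count_event_reads, effective_lengths,
                                enumerate_events, lrt_differential_psi, psi)


def _gene(gid, transcripts, strand="+"):
    g = Gene(gid, "chr1", strand, "protein_coding", transcripts)
    return g


def _models(*genes):
    return GeneModels({g.id: g for g in genes})


def _se_gene(gid="g_se", strand="+"):
    inc = Transcript(f"{gid}.t1", gid, "chr1", strand,
                     [(100, 200), (300, 400), (500, 600)])
    exc = Transcript(f"{gid}.t2", gid, "chr1", strand, [(100, 200), (500, 600)])
    return _gene(gid, [inc, exc], strand)


class TestEnumeration:
    def test_canonical_skipped_exon(self):
        events = enumerate_events(_models(_se_gene()))
        assert len(events) == 1
        ev = events[0]
        assert ev.type == "SE"
        assert ev.inc_junctions == [(200, 300), (400, 500)]
        assert ev.exc_junctions == [(200, 500)]

    def test_single_transcript_gene_has_no_events(self):
        t = Transcript("t", "g", "chr1", "+", [(0, 100), (200, 300)])
        assert enumerate_events(_models(_gene("g", [t]))) == []

    def test_one_event_of_each_type(self):
        """Five planted genes yield exactly one SE, MXE, A5SS, A3SS, RI."""
        mxe = _gene("g_mxe", [
            Transcript("m1", "g_mxe", "chr1", "+",
                       [(1000, 1100), (1200, 1300), (1600, 1700)]),
            Transcript("m2", "g_mxe", "chr1", "+",
                       [(1000, 1100), (1400, 1500), (1600, 1700)])])
        a5 = _gene("g_a5", [
            Transcript("a1", "g_a5", "chr1", "+", [(2000, 2150), (2300, 2400)]),
            Transcript("a2", "g_a5", "chr1", "+", [(2000, 2100), (2300, 2400)])])
        a3 = _gene("g_a3", [
            Transcript("b1", "g_a3", "chr1", "+", [(3000, 3100), (3200, 3400)]),
            Transcript("b2", "g_a3", "chr1", "+", [(3000, 3100), (3250, 3400)])])
        ri = _gene("g_ri", [
            Transcript("r1", "g_ri", "chr1", "+", [(4000, 4400)]),
            Transcript("r2", "g_ri", "chr1", "+", [(4000, 4100), (4300, 4400)])])
        events = enumerate_events(_models(_se_gene(), mxe, a5, a3, ri))
        by_type = {e.type: e for e in events}
        assert sorted(e.type for e in events) == ["A3SS", "A5SS", "MXE", "RI", "SE"]
        # A5SS inclusion = long form: extension segment 2100..2150
        assert by_type["A5SS"].inc_segments == [(2100, 2150)]
        assert by_type["A3SS"].inc_segments == [(3200, 3250)]
        assert by_type["RI"].inc_segments == [(4100, 4300)]

    def test_minus_strand_swaps_a5_a3(self):
        a5_plus = _gene("g", [
            Transcript("a1", "g", "chr1", "+", [(2000, 2150), (2300, 2400)]),
            Transcript("a2", "g", "chr1", "+", [(2000, 2100), (2300, 2400)])])
        a3_minus = _gene("g", [
            Transcript("a1", "g", "chr1", "-", [(2000, 2150), (2300, 2400)]),
            Transcript("a2", "g", "chr1", "-", [(2000, 2100), (2300, 2400)])], "-")
        assert enumerate_events(_models(a5_plus))[0].type == "A5SS"
        assert enumerate_events(_models(a3_minus))[0].type == "A3SS"

    def test_order_independent_and_idempotent(self):
        g = _se_gene()
        rev = _gene(g.id, list(reversed(g.transcripts)))
        ids_fwd = [(e.type, e.span) for e in enumerate_events(_models(g))]
        ids_rev = [(e.type, e.span) for e in enumerate_events(_models(rev))]
        assert ids_fwd == ids_rev

    def test_malformed_transcript_skips_gene(self):
        with pytest.raises(ValueError):
            Transcript("bad", "g", "chr1", "+", [(0, 100), (50, 150)])


class TestPsi:
    def test_symmetric_counts(self):
        assert psi(50, 50, 3, 3).psi == pytest.approx(0.5)

    def test_length_normalized_worked_value(self):
        assert psi(30, 10, 2, 1).psi == pytest.approx(0.6)

    def test_boundaries(self):
        assert psi(7, 0).psi == 1.0
        assert psi(0, 7).psi == 0.0

    def test_undefined_with_no_reads(self):
        with pytest.raises(ValueError):
            psi(0, 0)


class TestLrt:
    def test_identical_counts_give_p_one(self):
        assert lrt_differential_psi(40, 60, 40, 60) == 1.0

    def test_opposite_extremes_tiny_p(self):
        assert lrt_differential_psi(90, 10, 10, 90) < 1e-10

    def test_allele_swap_invariance(self):
        a = lrt_differential_psi(33, 17, 12, 48)
        b = lrt_differential_psi(12, 48, 33, 17)
        assert a == pytest.approx(b, rel=1e-12)

    def test_matches_numeric_optimization_oracle(self):
        """Closed-form MLEs agree with numeric profile likelihoods."""
        from scipy import stats

        def oracle(ia, ea, ib, eb):
            def nll_one(p, x, n):
                return -(xlogy(x, p) + xlogy(n - x, 1 - p))

            def best(x, n):
                r = minimize_scalar(nll_one, bounds=(1e-9, 1 - 1e-9),
                                    args=(x, n), method="bounded")
                return -r.fun

            na, nb = ia + ea, ib + eb
            l1 = best(ia, na) + best(ib, nb)
            l0 = minimize_scalar(
                lambda p: nll_one(p, ia, na) + nll_one(p, ib, nb),
                bounds=(1e-9, 1 - 1e-9), method="bounded").fun
            return float(stats.chi2.sf(2 * (l1 + l0), df=1))

        for case in [(30, 10, 10, 30), (55, 45, 40, 60), (5, 95, 9, 91)]:
            assert lrt_differential_psi(*case) == pytest.approx(
                oracle(*case), abs=1e-6)

    def test_boundary_margins_handled(self):
        assert 0 < lrt_differential_psi(10, 0, 0, 10) < 1e-4
        with pytest.raises(ValueError):
            lrt_differential_psi(0, 0, 5, 5)


class TestCallAss:
    def _df(self, **overrides):
        base = dict(event_id="e", type="SE", incA=150, excA=50, incB=60,
                    excB=140, l_inc=1, l_exc=1)
        base.update(overrides)
        return pd.DataFrame([base])

    def test_clear_event_is_significant(self):
        res, summary = call_ass(self._df())
        assert bool(res.significant.iloc[0])
        assert summary.loc[summary.type == "SE", "ass_ratio"].iloc[0] == 1.0

    def test_support_boundary_99_vs_100(self):
        low = self._df(incA=40, excA=10, incB=9, excB=40)   # support 99
        ok = self._df(incA=40, excA=10, incB=10, excB=40)   # support 100
        assert not call_ass(low)[0].significant.iloc[0]
        assert call_ass(ok)[0].significant.iloc[0]

    def test_effect_size_boundary(self):
        """|Δψ| = 0.08 fails the >0.10 clause at any depth."""
        weak = self._df(incA=2700, excA=2300, incB=2300, excB=2700)
        assert weak.pipe(lambda d: call_ass(d)[0]).significant.iloc[0] == False  # noqa: E712
        strong = self._df(incA=2800, excA=2200, incB=2200, excB=2800)
        assert call_ass(strong)[0].significant.iloc[0]

    def test_one_sided_zero_counts_untested(self):
        res, _ = call_ass(self._df(incB=0, excB=0))
        assert not res.significant.iloc[0]
        assert np.isnan(res.pvalue.iloc[0])


class TestEffectiveLengths:
    def test_se_inclusion_has_more_support_positions(self):
        ev = enumerate_events(_models(_se_gene()))[0]
        l_inc, l_exc = effective_lengths(ev, read_len=100)
        # two inclusion junctions + exon body vs one skip junction
        assert l_inc > l_exc
        assert l_exc == 99  # read_len − 1 positions span a single junction


@pytest.fixture(scope="module")
def forced_splice_study(tmp_path_factory):
    cfg = SimulationConfig(
        n_genes=4, depth=300, error_rate=0.0, seed=31, replicates=1,
        splicing_truth={"gene0000": (1.0, 1.0), "gene0001": (0.7, 0.3)},
    )
    return simulate_study(cfg, tmp_path_factory.mktemp("splice_study"))


class TestReadCounting:
    def test_psi_one_yields_zero_exclusion_reads(self, forced_splice_study):
        study = forced_splice_study
        events = enumerate_events(study.models)
        ev = next(e for e in events if e.gene_id == "gene0000")
        sid = next(iter(study.design))
        counts = count_event_reads(study.sample_paths[sid]["sam"], [ev])
        assert counts.exc.iloc[0] == 0
        assert counts.inc.iloc[0] > 0

    def test_planted_psi_recovered_within_three_se(self, forced_splice_study):
        """Pooled ψ per allele lands within 3 binomial SEs of the truth."""
        study = forced_splice_study
        events = enumerate_events(study.models)
        ev = next(e for e in events if e.gene_id == "gene0001")
        ev.l_inc, ev.l_exc = effective_lengths(ev, study.config.read_len)
        # pool alleles across all samples via truth-allele tag on split files
        from hybridase.assign import read_fragments, split_by_allele
        from hybridase.sites import FdsIndex
        import pysam

        index = FdsIndex(study.sites)
        header = pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6"},
             "SQ": [{"SN": c, "LN": len(s)} for c, s in study.genome_a.items()]})
        for allele, truth_psi in (("A", 0.7), ("B", 0.3)):
            inc = exc = 0
            for sid in study.design:
                frags = read_fragments(study.sample_paths[sid]["sam"], index, "both")
                import tempfile, os
                with tempfile.TemporaryDirectory() as td:
                    a_p, b_p = os.path.join(td, "a.sam"), os.path.join(td, "b.sam")
                    split_by_allele(frags, index, a_p, b_p, header)
                    path = a_p if allele == "A" else b_p
                    c = count_event_reads(path, [ev]).iloc[0]
                    inc += c.inc
                    exc += c.exc
            est = psi(inc, exc, ev.l_inc, ev.l_exc).psi
            n = inc + exc
            se = np.sqrt(truth_psi * (1 - truth_psi) / n)
            assert abs(est - truth_psi) <= 3 * se + 0.02
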