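"""Cleavage scoring and m7G site calling."""

import math

import numpy as np
import pytest

from m7gflow.errors import DegenerateInputError, InputError
from m7gflow.reference import Interval, TRNAGene
from m7gflow.simulate import (
    SimulationConfig,
    simulate_trac_libraries,
    simulate_trna_reference,
)
from m7gflow.tracseq import (
    EndCountProfile,
    call_m7g_sites,
    cleavage_score,
    m7g_level_change,
    position_frequency,
)


def profile(counts, library_size, tid="t1"):
    return EndCountProfile(tid, np.array(counts), library_size)


class TestPositionFrequency:
    def test_plain_fraction(self):
        assert position_frequency(profile([200, 0], 1000), 0) == 0.2
        assert position_frequency(profile([200, 0], 1000), 1) == 0.0

    def test_zero_library_degenerate(self):
        with pytest.raises(InputError):
            EndCountProfile("t", np.array([0]), 0)

    def test_pseudocount_formula(self):
        p = profile([50] + [0] * 75, 1000)
        got = position_frequency(p, 0, pseudocount=0.5)
        assert got == pytest.approx((50 + 0.5) / (1000 + 0.5 * 76))


class TestCleavageScore:
    def test_log2_of_frequency_ratio(self):
        t = profile([200, 0], 1000)
        c = profile([50, 0], 1000)
        assert cleavage_score(t, c, 0, pseudocount=0) == pytest.approx(2.0)

    def test_identical_profiles_score_zero(self):
        p = profile([10, 20, 30], 100)
        q = profile([10, 20, 30], 100)
        for i in range(3):
            assert cleavage_score(p, q, i) == 0.0

    def test_zero_control_with_pseudocount(self):
        # independent closed form: shared denominators cancel, so the score
        # is log2((50 + 0.5) / (0 + 0.5)) = log2(101)
        t = profile([50] + [0] * 75, 1000)
        c = profile([0] * 76, 1000)
        got = cleavage_score(t, c, 0, pseudocount=0.5)
        assert got == pytest.approx(math.log2(101.0))
        assert got > 0 and math.isfinite(got)

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(3)
        t = profile(rng.integers(0, 50, size=40), 5000)
        c = profile(rng.integers(0, 50, size=40), 5000)
        for i in range(40):
            assert cleavage_score(t, c, i) == pytest.approx(
                -cleavage_score(c, t, i)
            )

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            cleavage_score(profile([1, 2], 10), profile([1, 2, 3], 10), 0)


def _motif_gene():
    # ABGWY instance "ACGAC" with G at position 51, loop [49, 64)
    seq = list("T" * 76)
    seq[49:54] = list("ACGAC")
    return TRNAGene(id="tRNA-Val-AAC-1-1", amino_acid="Val", anticodon="AAC",
                    sequence="".join(seq), variable_loop=Interval(49, 64))


class TestCallSites:
    def _libs(self, treated_at_52, coverage=100):
        counts_t = np.zeros(76, dtype=int)
        counts_t[52] = treated_at_52  # cleavage read start = G + 1
        counts_c = np.zeros(76, dtype=int)
        counts_c[52] = coverage // 20
        t = {"tRNA-Val-AAC-1-1": EndCountProfile("tRNA-Val-AAC-1-1", counts_t, 10000)}
        c = {"tRNA-Val-AAC-1-1": EndCountProfile("tRNA-Val-AAC-1-1", counts_c, 10000)}
        return t, c

    def test_motif_site_called(self):
        t, c = self._libs(200)
        res = call_m7g_sites(t, c, [_motif_gene()])
        called = res.called_sites()
        assert len(called) == 1
        assert called[0].position == 51
        assert called[0].motif_ok
        assert res.m7g_trna_ids() == {"tRNA-Val-AAC-1-1"}

    def test_high_score_off_motif_not_called(self):
        gene = _motif_gene()
        t, c = self._libs(0)
        # big treated signal at a loop position whose G is not a motif hit
        t["tRNA-Val-AAC-1-1"].counts[60] = 500
        res = call_m7g_sites(t, c, [gene])
        off = [x for x in res.calls if x.position == 59]
        assert off and not off[0].motif_ok and not off[0].called
        assert res.m7g_trna_ids() == set()

    def test_score_below_threshold_not_called(self):
        gene = _motif_gene()
        t, c = self._libs(12, coverage=200)  # score < 1 two-fold gate
        res = call_m7g_sites(t, c, [gene], min_score=1.0)
        site = [x for x in res.calls if x.position == 51]
        assert site and site[0].motif_ok and not site[0].called

    def test_low_coverage_not_called(self):
        t, c = self._libs(5, coverage=20)
        res = call_m7g_sites(t, c, [_motif_gene()], min_coverage=10)
        assert res.called_sites() == []

    def test_gene_without_profile_reported_uncovered(self):
        t, c = self._libs(200)
        extra = TRNAGene(id="tRNA-Gly-GCC-1-1", amino_acid="Gly",
                         anticodon="GCC", sequence="A" * 76,
                         variable_loop=Interval(49, 64))
        res = call_m7g_sites(t, c, [_motif_gene(), extra])
        assert res.uncovered == ["tRNA-Gly-GCC-1-1"]

    def test_profile_without_gene_is_error(self):
        t, c = self._libs(200)
        t["orphan"] = EndCountProfile("orphan", np.zeros(76, dtype=int), 10000)
        with pytest.raises(InputError):
            call_m7g_sites(t, c, [_motif_gene()])

    def test_calls_invariant_to_uniform_scaling(self):
        t, c = self._libs(200)
        res1 = call_m7g_sites(t, c, [_motif_gene()], pseudocount=0.5)
        k = 7
        t2 = {
            tid: EndCountProfile(tid, p.counts * k, p.library_size * k)
            for tid, p in t.items()
        }
        c2 = {
            tid: EndCountProfile(tid, p.counts * k, p.library_size * k)
            for tid, p in c.items()
        }
        res2 = call_m7g_sites(t2, c2, [_motif_gene()], pseudocount=0.5 * k)
        assert [(x.trna_id, x.position, x.called) for x in res1.calls] == [
            (x.trna_id, x.position, x.called) for x in res2.calls
        ]
        for x1, x2 in zip(res1.calls, res2.calls):
            assert x1.score == pytest.approx(x2.score)


class TestSimulatedRecovery:
    def test_all_implanted_sites_called_no_false_positives(self):
        cfg = SimulationConfig(seed=4, n_isotypes=50,
                               n_isodecoders_per_isotype=1)
        ref = simulate_trna_reference(cfg)
        treated, control = simulate_trac_libraries(ref, cfg)
        res = call_m7g_sites(treated, control, ref.genes)
        called = {(c.trna_id, c.position) for c in res.called_sites()}
        assert called == set(ref.sites)
        assert len(ref.sites) == 20


class TestLevelChange:
    def test_identical_conditions_zero_delta(self):
        t, c = TestCallSites()._libs(200)
        res = call_m7g_sites(t, c, [_motif_gene()])
        rep = m7g_level_change(res.calls, res.calls)
        assert (rep.per_site["delta"] == 0).all()

    def test_knockdown_reduces_scores(self, small_config):
        ref = simulate_trna_reference(small_config)
        t, c = simulate_trac_libraries(ref, small_config)
        res_a = call_m7g_sites(t, c, ref.genes)
        t2, c2 = simulate_trac_libraries(
            ref, small_config,
            cleavage_rate=small_config.trac.cleavage_rate / 2,
        )
        res_b = call_m7g_sites(t2, c2, ref.genes)
        rep = m7g_level_change(res_a.calls, res_b.calls)
        assert rep.median_delta < 0

    def test_disjoint_site_sets_error(self):
        t, c = TestCallSites()._libs(200)
        res = call_m7g_sites(t, c, [_motif_gene()])
        shifted = [
            type(x)(x.trna_id, x.position + 1, x.score, x.coverage,
                    x.motif_ok, x.called)
            for x in res.calls
        ]
        with pytest.raises(DegenerateInputError):
            m7g_level_change(res.calls, shifted)
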