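"""Expression normalisation, the Mann-Whitney test, and the class comparison."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import mannwhitneyu

from m7gflow.errors import DegenerateInputError, EmptyInputError, InputError
from m7gflow.expression import (
    CountMatrix,
    aggregate_isotypes,
    compare_m7g_vs_non,
    cpm_normalize,
    lcms_m7g_level,
    log2_relative_to_mean,
    mann_whitney_u,
    normalize_expression,
)
from m7gflow.reference import TRNAGene
from m7gflow.simulate import (
    SimulationConfig,
    simulate_trna_counts,
    simulate_trna_reference,
)


def _gene(gid, aa, ac):
    return TRNAGene(id=gid, amino_acid=aa, anticodon=ac, sequence="ACGT")


class TestAggregate:
    def test_isodecoders_sum_within_isotype(self):
        genes = [_gene("v1", "Val", "AAC"), _gene("v2", "Val", "AAC"),
                 _gene("k1", "Lys", "CTT")]
        m = CountMatrix(
            pd.DataFrame({"s1": [3, 7, 5]}, index=["v1", "v2", "k1"]),
            {"s1": "control"},
        )
        agg = aggregate_isotypes(m, genes)
        assert agg.data.loc["Val-AAC", "s1"] == 10
        assert agg.data.loc["Lys-CTT", "s1"] == 5
        assert agg.data["s1"].sum() == m.data["s1"].sum()

    def test_unmapped_row_named_in_error(self):
        m = CountMatrix(
            pd.DataFrame({"s1": [3]}, index=["tRNA-unknown"]), {"s1": "c"}
        )
        with pytest.raises(InputError, match="tRNA-unknown"):
            aggregate_isotypes(m, [_gene("v1", "Val", "AAC")])


class TestCpm:
    def test_column_scaled_to_million(self):
        m = CountMatrix(pd.DataFrame({"s1": [1, 3]}, index=["a", "b"]),
                        {"s1": "c"})
        out = cpm_normalize(m)
        assert list(out.data["s1"]) == [250000.0, 750000.0]

    def test_idempotent_on_cpm(self):
        m = CountMatrix(
            pd.DataFrame({"s1": [250000.0, 750000.0]}, index=["a", "b"]),
            {"s1": "c"},
        )
        out = cpm_normalize(m)
        assert np.allclose(out.data["s1"], m.data["s1"])

    def test_zero_column_degenerate(self):
        m = CountMatrix(pd.DataFrame({"s1": [0, 0]}, index=["a", "b"]),
                        {"s1": "c"})
        with pytest.raises(DegenerateInputError):
            cpm_normalize(m)


class TestLog2Relative:
    def test_two_point_example(self):
        got = log2_relative_to_mean(np.array([4.0, 1.0]))
        assert got == pytest.approx([np.log2(1.6), np.log2(0.4)])

    def test_constant_vector_all_zero(self):
        assert log2_relative_to_mean([5, 5, 5]) == pytest.approx([0, 0, 0])

    def test_all_zero_degenerate(self):
        with pytest.raises(DegenerateInputError):
            log2_relative_to_mean([0.0, 0.0])

    def test_inverse_recovers_input(self):
        rng = np.random.default_rng(1)
        v = rng.lognormal(0, 1, size=50)
        out = log2_relative_to_mean(v, floor=None)
        back = (2.0**out) * v.mean()
        assert np.max(np.abs(back - v) / v) < 1e-12

    def test_floor_avoids_minus_infinity(self):
        out = log2_relative_to_mean([0.0, 4.0])
        assert np.isfinite(out).all()


def _brute_force_two_sided_p(n, m, u):
    """Enumerate all labelings of ranks 0..n+m-1 and count extreme U values."""
    pooled = np.arange(n + m)
    us = []
    idx = set(range(n + m))
    for combo in combinations(range(n + m), n):
        a = pooled[list(combo)]
        b = pooled[list(idx - set(combo))]
        us.append((a[:, None] > b[None, :]).sum())
    us = np.array(us)
    return min(1.0, 2 * min((us <= u).mean(), (us >= u).mean()))


class TestMannWhitney:
    def test_separated_samples_exact_p(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_multisets_u_symmetry(self):
        a = [1.0, 2.0, 2.0, 5.0]
        u, _ = mann_whitney_u(a, list(a))
        assert u == len(a) * len(a) / 2

    def test_empty_sample_error(self):
        with pytest.raises(InputError):
            mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("n", range(1, 8))
    @pytest.mark.parametrize("m", range(1, 8))
    def test_exact_path_equals_enumeration_oracle(self, n, m):
        """Every achievable U for tie-free samples gives the enumerated p."""
        rng = np.random.default_rng(n * 10 + m)
        for _ in range(3):
            ranks = rng.permutation(n + m)
            a, b = ranks[:n].astype(float), ranks[n:].astype(float)
            u, p = mann_whitney_u(a, b)
            assert p == pytest.approx(_brute_force_two_sided_p(n, m, u))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 30), min_size=9, max_size=25),
        st.lists(st.integers(0, 30), min_size=9, max_size=25),
    )
    def test_approximate_path_matches_reference(self, a, b):
        """Tie-corrected normal approximation agrees with the standard one."""
        u, p = mann_whitney_u(a, b)
        ref = mannwhitneyu(a, b, method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_one_sided_alternatives_are_consistent(self):
        a, b = [1.0, 2.0, 9.0, 11.0], [3.0, 4.0, 5.0, 6.0]
        _, p_less = mann_whitney_u(a, b, alternative="less", exact_max_n=0)
        _, p_greater = mann_whitney_u(a, b, alternative="greater",
                                      exact_max_n=0)
        assert 0 < p_less <= 1 and 0 < p_greater <= 1


class TestClassComparison:
    def _normalized(self, seed, depletion):
        cfg = SimulationConfig(seed=seed)
        cfg.expr.depletion_factor = depletion
        ref = simulate_trna_reference(cfg)
        cm = simulate_trna_counts(ref, cfg)
        norm = normalize_expression(cm, ref.genes)
        membership = {k: (k in ref.m7g_isotypes) for k in norm.data.index}
        return norm, membership

    def test_depletion_detected_with_negative_shift(self):
        norm, membership = self._normalized(seed=2, depletion=0.6)
        rep = compare_m7g_vs_non(norm, membership)
        assert rep.p_value < 0.05
        assert rep.median_delta_m7g < 0
        assert rep.median_delta_m7g < rep.median_delta_non
        assert rep.n_m7g == 20 and rep.n_non == 30

    def test_direction_recovered_across_seeds(self):
        hits = 0
        for seed in range(10):
            norm, membership = self._normalized(seed=seed, depletion=0.6)
            rep = compare_m7g_vs_non(norm, membership)
            hits += (rep.p_value < 0.05 and
                     rep.median_delta_m7g < rep.median_delta_non)
        assert hits >= 9

    def test_per_replicate_option(self):
        norm, membership = self._normalized(seed=3, depletion=0.6)
        rep = compare_m7g_vs_non(norm, membership, average_replicates=False)
        assert rep.p_value < 0.05
        assert rep.median_delta_m7g < rep.median_delta_non

    def test_single_class_is_an_error(self):
        norm, membership = self._normalized(seed=2, depletion=0.6)
        with pytest.raises(InputError):
            compare_m7g_vs_non(norm, {k: True for k in membership})


class TestLcms:
    def test_ratio(self):
        table = {"m7G": 2.0, "A": 50.0, "C": 48.0}
        assert lcms_m7g_level(table) == pytest.approx(0.02)

    def test_absent_m7g_is_zero(self):
        assert lcms_m7g_level({"A": 10.0}) == 0.0

    def test_zero_total_degenerate(self):
        with pytest.raises(DegenerateInputError):
            lcms_m7g_level({"A": 0.0})

    def test_negative_area_error(self):
        with pytest.raises(InputError):
            lcms_m7g_level({"A": -1.0})
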