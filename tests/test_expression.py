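"""Gene-set logic: fold changes, Venn partition, rescue rule, dynamics,
enrichment, anti-correlation, t test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.special import comb

from conftest import make_matrix
from reprotrace.errors import InputError, ParameterError, SelectorError
from reprotrace.expression import (
    ComparisonSpec,
    GeneSet,
    anticorrelated_genes,
    classify_dynamics,
    classify_dynamics_table,
    enrich_terms,
    fold_change,
    t_test,
    transient_met_genes,
    upregulated_set,
    venn_partition,
)


class TestFoldChange:
    def test_identical_groups_give_unit_fold_change(self, tiny_matrix):
        spec = ComparisonSpec(["highKLF4_d8_r1"], ["highKLF4_d8_r2"])
        assert (fold_change(tiny_matrix, spec) == 1.0).all()

    def test_one_log2_unit_is_twofold(self, tiny_matrix):
        spec = ComparisonSpec({"condition": "highKLF4"}, {"condition": "lowKLF4"})
        fc = fold_change(tiny_matrix, spec)
        assert fc["GA"] == pytest.approx(2.0)
        assert fc["GB"] == pytest.approx(1.0)

    def test_matches_bruteforce_ratio_of_geometric_means(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(6, 1, size=(20, 6))
        genes = [f"g{i}" for i in range(20)]
        cols = {
            f"highKLF4_d8_r{i + 1}": list(vals[:, i]) for i in range(3)
        } | {f"lowKLF4_d8_r{i + 1}": list(vals[:, 3 + i]) for i in range(3)}
        m = make_matrix(cols, genes)
        fc = fold_change(m, ComparisonSpec({"condition": "highKLF4"}, {"condition": "lowKLF4"}))
        # oracle: ratio of geometric means of the linearized intensities
        lin = 2.0**vals
        oracle = np.exp(np.log(lin[:, :3]).mean(1)) / np.exp(np.log(lin[:, 3:]).mean(1))
        np.testing.assert_allclose(fc.to_numpy(), oracle, rtol=1e-12)

    def test_empty_or_overlapping_groups_rejected(self, tiny_matrix):
        with pytest.raises(SelectorError):
            fold_change(tiny_matrix, ComparisonSpec({"condition": "mESC"}, {"condition": "MEF"}))
        with pytest.raises(SelectorError):
            fold_change(
                tiny_matrix, ComparisonSpec(["highKLF4_d8_r1"], ["highKLF4_d8_r1"])
            )


class TestUpregulatedSet:
    def test_strict_threshold_excludes_exact_ties(self):
        fc = pd.Series({"a": 1.9, "b": 2.0, "c": 2.1})
        assert upregulated_set(fc).members == frozenset({"c"})
        assert len(upregulated_set(pd.Series({"a": 1.0, "b": 1.0}))) == 0

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ParameterError):
            upregulated_set(pd.Series({"a": 3.0}), threshold=0)

    @given(st.lists(st.floats(0.1, 10), min_size=1, max_size=30), st.floats(1, 5))
    def test_raising_threshold_never_adds_members(self, fcs, thr):
        fc = pd.Series(fcs, index=[f"g{i}" for i in range(len(fcs))])
        low = upregulated_set(fc, thr).members
        high = upregulated_set(fc, thr * 1.5).members
        assert high <= low


def _gs(name, members):
    return GeneSet(name, frozenset(members))


class TestVennPartition:
    def test_identical_sets_fill_only_triple_region(self):
        s = _gs("x", {"a", "b"})
        part = venn_partition(s, s, s)
        assert part.regions["HK_KER_ESC"] == frozenset({"a", "b"})
        assert sum(part.counts.values()) == 2

    def test_disjoint_sets_fill_only_exclusive_regions(self):
        part = venn_partition(_gs("h", {"a"}), _gs("k", {"b"}), _gs("e", {"c"}))
        assert part.counts == {
            "HK_only": 1, "KER_only": 1, "ESC_only": 1,
            "HK_KER": 0, "HK_ESC": 0, "KER_ESC": 0, "HK_KER_ESC": 0,
        }

    @given(st.tuples(
        st.sets(st.integers(0, 200), max_size=100),
        st.sets(st.integers(0, 200), max_size=100),
        st.sets(st.integers(0, 200), max_size=100),
    ))
    def test_matches_membership_bitmask_oracle(self, sets):
        h, k, e = sets
        part = venn_partition(
            _gs("h", map(str, h)), _gs("k", map(str, k)), _gs("e", map(str, e))
        )
        # oracle: classify every gene by its 3-bit membership mask
        expected = {name: set() for name in part.regions}
        names = {
            (1, 0, 0): "HK_only", (0, 1, 0): "KER_only", (0, 0, 1): "ESC_only",
            (1, 1, 0): "HK_KER", (1, 0, 1): "HK_ESC", (0, 1, 1): "KER_ESC",
            (1, 1, 1): "HK_KER_ESC",
        }
        for g in h | k | e:
            expected[names[(int(g in h), int(g in k), int(g in e))]].add(str(g))
        assert {n: set(v) for n, v in part.regions.items()} == expected
        # regions are pairwise disjoint and cover the union
        all_members = [g for v in part.regions.values() for g in v]
        assert len(all_members) == len(set(all_members)) == len(h | k | e)


@pytest.fixture
def rescue_matrix():
    """Three genes in HK∩KER∩ESC: one above mESC at day 8, one below, one at tie."""
    genes = ["above", "below", "tie"]
    day8 = [8.0, 6.0, 7.0]
    esc = [7.0, 7.0, 7.0]
    return make_matrix(
        {
            "highKLF4_d8_r1": day8,
            "highKLF4_d8_r2": day8,
            "lowKLF4_d8_r1": [4.0] * 3,
            "lowKLF4_d8_r2": [4.0] * 3,
            "keratinocyte_r1": [8.0] * 3,
            "MEF_r1": [4.0] * 3,
            "mESC_r1": esc,
        },
        genes,
    )


class TestTransientMetGenes:
    def test_core_region_always_included(self, rescue_matrix):
        part = venn_partition(_gs("h", {"x"}), _gs("k", {"x"}), _gs("e", set()))
        result = transient_met_genes(part, rescue_matrix)
        assert "x" in result  # HK∩KER−ESC needs no rescue check

    def test_rescue_admits_only_day8_exceeding_mesc(self, rescue_matrix):
        triple = {"above", "below", "tie"}
        part = venn_partition(_gs("h", triple), _gs("k", triple), _gs("e", triple))
        result = transient_met_genes(part, rescue_matrix)
        assert result.members == frozenset({"above"})  # strict >, tie excluded

    def test_output_bounded_by_core_and_hk_ker(self, rescue_matrix):
        hk = _gs("h", {"above", "below", "core"})
        ker = _gs("k", {"above", "below", "core"})
        esc = _gs("e", {"above", "below"})
        part = venn_partition(hk, ker, esc)
        result = transient_met_genes(part, rescue_matrix)
        assert part.regions["HK_KER"] <= result.members
        assert result.members <= (hk.members & ker.members)

    def test_missing_samples_raise(self, rescue_matrix):
        triple = {"above"}
        part = venn_partition(_gs("h", triple), _gs("k", triple), _gs("e", triple))
        with pytest.raises(SelectorError):
            transient_met_genes(part, rescue_matrix, esc_condition="iPSC")


class TestClassifyDynamics:
    @pytest.fixture
    def dynamics_matrix(self):
        # flat, transient (peak d8, silenced in iPSC), sustained (stays on)
        genes = ["flat", "transient", "sustained"]
        return make_matrix(
            {
                "highKLF4_d0_r1": [5.0, 5.0, 5.0],
                "highKLF4_d8_r1": [5.0, 7.5, 7.5],
                "highKLF4_d18_r1": [5.0, 7.5, 7.5],
                "MEF_r1": [5.0, 5.0, 5.0],
                "iPSC_r1": [5.0, 5.0, 7.5],
            },
            genes,
        )

    def test_flat_transient_sustained(self, dynamics_matrix):
        assert classify_dynamics(dynamics_matrix, "flat") == "not_induced"
        assert classify_dynamics(dynamics_matrix, "transient") == "transient"
        assert classify_dynamics(dynamics_matrix, "sustained") == "sustained"

    def test_table_and_scalar_agree(self, dynamics_matrix):
        table = classify_dynamics_table(dynamics_matrix)
        for g in dynamics_matrix.genes:
            assert classify_dynamics(dynamics_matrix, g) == table[g]

    def test_missing_gene_or_samples_raise(self, dynamics_matrix):
        with pytest.raises(SelectorError):
            classify_dynamics(dynamics_matrix, "nope")
        with pytest.raises(SelectorError):
            classify_dynamics_table(dynamics_matrix, silenced_condition="mESC")


class TestEnrichTerms:
    def test_term_equals_set_equals_universe_gives_p_one(self):
        genes = [f"g{i}" for i in range(5)]
        df = enrich_terms(genes, genes, {"T": genes})
        assert df.loc[0, "p"] == pytest.approx(1.0)
        assert not df.loc[0, "reported"]

    def test_perfect_overlap_exact_hypergeometric_p(self):
        universe = [f"g{i}" for i in range(20)]
        term = universe[:5]
        df = enrich_terms(term, universe, {"T": term})
        assert df.loc[0, "p"] == pytest.approx(1.0 / comb(20, 5, exact=True))

    def test_empty_set_reports_nothing(self):
        universe = [f"g{i}" for i in range(10)]
        df = enrich_terms([], universe, {"T": universe[:3]})
        assert not df["reported"].any()

    def test_set_outside_universe_rejected(self):
        with pytest.raises(InputError):
            enrich_terms(["x"], ["a", "b"], {"T": ["a"]})


class TestAnticorrelated:
    @pytest.fixture
    def corr_matrix(self):
        days = [0, 2, 4, 8]
        x = np.array([0.0, 1.0, 2.0, 3.0])
        cols = {}
        for d, xi in zip(days, x):
            cols[f"highKLF4_d{d}_r1"] = [
                6 + xi,        # REF
                10 - 2 * xi,   # affine negative transform -> r = -1
                6 + xi,        # copy of reference -> r = +1
                5.0,           # constant -> undefined r
            ]
        return make_matrix(cols, ["REF", "neg", "copy", "const"])

    def test_affine_negative_selected_copy_excluded(self, corr_matrix):
        with pytest.warns(UserWarning, match="zero-variance"):
            res = anticorrelated_genes(corr_matrix, "REF")
        assert res.r["neg"] == pytest.approx(-1.0)
        assert res.r["copy"] == pytest.approx(1.0)
        assert res.selected == frozenset({"neg"})
        assert "const" in res.excluded_zero_variance
        assert "REF" not in res.r.index

    def test_bad_band_or_reference_rejected(self, corr_matrix):
        with pytest.raises(ParameterError):
            anticorrelated_genes(corr_matrix, "REF", band=(-2.0, -0.9))
        with pytest.raises(SelectorError):
            anticorrelated_genes(corr_matrix, "nope")


class TestNormalize:
    def test_quantile_normalization_equalizes_column_distributions(self):
        rng = np.random.default_rng(77)
        raw = pd.DataFrame(rng.gamma(2.0, 100.0, size=(50, 4)) * [1, 2, 5, 0.5])
        from reprotrace.expression import normalize

        out = normalize(raw)
        cols = [np.sort(out[c].to_numpy()) for c in out.columns]
        for c in cols[1:]:
            np.testing.assert_allclose(c, cols[0], rtol=1e-12)
        # rank order within each column is preserved (monotone transform)
        for c in raw.columns:
            assert (np.argsort(raw[c].to_numpy(), kind="stable")
                    == np.argsort(out[c].to_numpy(), kind="stable")).all()

    def test_log2_only_method(self):
        from reprotrace.expression import normalize

        raw = pd.DataFrame({"s1": [1.0, 4.0], "s2": [2.0, 8.0]})
        out = normalize(raw, method="log2")
        np.testing.assert_allclose(out.to_numpy(), [[0, 1], [2, 3]])

    def test_unknown_method_rejected(self):
        from reprotrace.expression import normalize

        with pytest.raises(ParameterError):
            normalize(pd.DataFrame({"s": [1.0]}), method="rankit")


class TestTTest:
    def test_equal_means_give_zero_t_unit_p(self):
        t, p = t_test([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_textbook_pooled_variance(self):
        t, p = t_test([1, 2, 3], [4, 5, 6])
        # hand calculation: sp2 = 1, t = -3 / sqrt(1*(1/3+1/3)) = -3.67423
        assert t == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), rel=1e-12)
        assert 0 < p < 0.05

    def test_approximates_exact_permutation_p(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.0, 1.0, 6)
        b = rng.normal(1.2, 1.0, 6)
        t_obs, p = t_test(a, b)
        # oracle: exact permutation distribution of |t| over all splits
        from itertools import combinations

        pooled = np.concatenate([a, b])
        n = len(a)
        count = total = 0
        for idx in combinations(range(len(pooled)), n):
            mask = np.zeros(len(pooled), bool)
            mask[list(idx)] = True
            t_perm, _ = t_test(pooled[mask], pooled[~mask])
            count += abs(t_perm) >= abs(t_obs) - 1e-12
            total += 1
        p_perm = count / total
        assert p == pytest.approx(p_perm, abs=0.05)

    def test_tiny_groups_rejected(self):
        with pytest.raises(InputError):
            t_test([1.0], [1.0, 2.0])
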