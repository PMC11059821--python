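"""Transformation statistics and the 16-chain grammar."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from xformscan import (
    TransformChain,
    TransformStep,
    apply_chain,
    apply_l2norm,
    apply_log2,
    apply_minmax,
    apply_total,
    apply_zscore,
    enumerate_chains,
)

# moderate magnitudes: the 1e-9 numerical contracts assume vectors that are
# not dominated by float cancellation (near-constant at huge offsets)
positive_matrices = arrays(
    np.float64,
    st.tuples(st.integers(2, 8), st.integers(2, 6)),
    elements=st.floats(0.1, 100.0),
)


class TestTotal:
    def test_proportions_times_target(self):
        out = apply_total(np.array([[1.0, 1.0, 2.0]]), target_sum=20000)
        np.testing.assert_allclose(out, [[5000, 5000, 10000]])

    def test_row_sums_hit_target(self, random_positive_matrix):
        out = apply_total(random_positive_matrix, 20000)
        np.testing.assert_allclose(out.values.sum(axis=1), 20000, rtol=1e-6)

    def test_zero_sum_cell_errors_with_ids(self, tiny_matrix):
        tiny_matrix.values[1] = 0.0
        with pytest.raises(ValueError, match="c1"):
            apply_total(tiny_matrix)

    @given(positive_matrices)
    def test_idempotent(self, V):
        once = apply_total(V, 20000)
        np.testing.assert_allclose(apply_total(once, 20000), once, rtol=1e-9)

    @given(positive_matrices)
    def test_invariant_to_per_cell_scaling(self, V):
        d = np.linspace(0.5, 3.0, V.shape[0])[:, None]
        np.testing.assert_allclose(
            apply_total(d * V, 20000), apply_total(V, 20000), rtol=1e-9, atol=1e-9
        )


class TestLog2:
    def test_powers_of_two(self):
        np.testing.assert_allclose(apply_log2(np.array([[0.0, 1.0, 3.0]])), [[0, 1, 2]])

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            apply_log2(np.array([[-0.5]]))

    def test_all_zero_fixed_point(self):
        np.testing.assert_array_equal(apply_log2(np.zeros((3, 2))), np.zeros((3, 2)))


class TestL2Norm:
    def test_345_triangle(self):
        np.testing.assert_allclose(apply_l2norm(np.array([[3.0, 4.0]])), [[0.6, 0.8]])

    def test_zero_norm_errors(self):
        with pytest.raises(ValueError, match="zero-norm"):
            apply_l2norm(np.array([[0.0, 0.0]]))

    @given(positive_matrices)
    def test_unit_norm_and_idempotent(self, V):
        out = apply_l2norm(V)
        np.testing.assert_allclose(np.linalg.norm(out, axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(apply_l2norm(out), out, atol=1e-9)

    @given(positive_matrices)
    def test_invariant_to_per_cell_scaling(self, V):
        d = np.linspace(0.5, 3.0, V.shape[0])[:, None]
        np.testing.assert_allclose(apply_l2norm(d * V), apply_l2norm(V), atol=1e-9)


class TestMinmax:
    def test_gene_column(self):
        out = apply_minmax(np.array([[2.0], [4.0], [6.0]]), axis="per_gene")
        np.testing.assert_allclose(out, [[0.0], [0.5], [1.0]])

    def test_constant_column_maps_to_zero(self):
        out = apply_minmax(np.array([[5.0], [5.0]]), axis="per_gene")
        np.testing.assert_array_equal(out, [[0.0], [0.0]])

    @given(positive_matrices)
    def test_range_and_idempotence(self, V):
        out = apply_minmax(V, axis="per_gene")
        rng = V.max(axis=0) - V.min(axis=0)
        for j in range(V.shape[1]):
            if rng[j] > 0:
                assert out[:, j].min() == 0.0 and out[:, j].max() == 1.0
            else:
                assert np.all(out[:, j] == 0.0)
        np.testing.assert_allclose(apply_minmax(out, axis="per_gene"), out, atol=1e-12)

    @given(positive_matrices)
    def test_affine_invariance(self, V):
        rng = V.max(axis=0) - V.min(axis=0)
        varying = rng > 1e-6 * (np.abs(V).mean(axis=0) + 1.0)
        out = apply_minmax(2.5 * V + 7.0, axis="per_gene")
        base = apply_minmax(V, axis="per_gene")
        np.testing.assert_allclose(out[:, varying], base[:, varying], atol=1e-9)


class TestZscore:
    def test_column_123(self):
        out = apply_zscore(np.array([[1.0], [2.0], [3.0]]), axis="per_gene")
        # population std of [1,2,3] is sqrt(2/3)
        np.testing.assert_allclose(out, [[-1.224745], [0.0], [1.224745]], atol=1e-6)

    def test_constant_column_maps_to_zero(self):
        np.testing.assert_array_equal(
            apply_zscore(np.full((3, 1), 4.0), axis="per_gene"), np.zeros((3, 1))
        )

    @given(positive_matrices)
    def test_mean_zero_popstd_one(self, V):
        out = apply_zscore(V, axis="per_gene")
        sd = V.std(axis=0)
        varying = sd > 1e-6 * (np.abs(V).mean(axis=0) + 1.0)
        assert np.all(np.abs(out[:, varying].mean(axis=0)) < 1e-9)
        np.testing.assert_allclose(out[:, varying].std(axis=0), 1.0, atol=1e-9)

    @given(positive_matrices)
    def test_affine_invariance_and_idempotence(self, V):
        sd = V.std(axis=0)
        # exclude ill-conditioned columns (spread tiny relative to offset),
        # where float cancellation dominates the comparison
        varying = sd > 1e-2 * (np.abs(V).mean(axis=0) + 1.0)
        base = apply_zscore(V, axis="per_gene")
        shifted = apply_zscore(3.0 * V + 11.0, axis="per_gene")
        np.testing.assert_allclose(shifted[:, varying], base[:, varying], atol=1e-8)
        again = apply_zscore(base, axis="per_gene")
        np.testing.assert_allclose(again[:, varying], base[:, varying], atol=1e-9)


class TestChainGrammar:
    def test_enumerate_returns_16(self):
        chains = enumerate_chains()
        names = [c.name for c in chains]
        assert len(chains) == 16
        assert len(set(names)) == 16
        assert names == sorted(names)
        assert "raw" in names and "total_log2_zscore" in names

    def test_grammar_product_structure(self):
        names = {c.name for c in enumerate_chains()}
        expected = set()
        for t in ("", "total"):
            for lg in ("", "log2"):
                for sc in ("", "l2norm", "minmax", "zscore"):
                    parts = [p for p in (t, lg, sc) if p]
                    expected.add("_".join(parts) if parts else "raw")
        assert names == expected

    @pytest.mark.parametrize(
        "bad",
        [
            ("zscore", "log2"),  # log2 after a signed step
            ("log2", "total"),  # out of grammar order
            ("minmax", "zscore"),  # two scalers
            ("total", "total"),  # repeated kind
        ],
    )
    def test_invalid_orders_rejected(self, bad):
        with pytest.raises(ValueError):
            TransformChain(tuple(TransformStep(k) for k in bad))

    def test_raw_chain_is_identity_copy(self, tiny_matrix):
        out = apply_chain(tiny_matrix, TransformChain(()))
        np.testing.assert_array_equal(out.values, tiny_matrix.values)
        assert out.values is not tiny_matrix.values

    def test_total_then_log2_hand_composed(self):
        chain = TransformChain(
            (TransformStep("total", target_sum=4.0), TransformStep("log2"))
        )
        out = apply_chain(np.array([[1.0, 1.0, 2.0]]), chain)
        np.testing.assert_allclose(out, [[1.0, 1.0, 1.584963]], atol=1e-6)

    def test_step_errors_annotated_with_index(self, tiny_matrix):
        tiny_matrix.values[0] = 0.0
        with pytest.raises(ValueError, match=r"step 0 \(total\)"):
            apply_chain(tiny_matrix, TransformChain.from_name("total_log2"))

    def test_all_16_chains_finite_on_random_positive(self, random_positive_matrix):
        for chain in enumerate_chains():
            out = apply_chain(random_positive_matrix, chain)
            assert np.all(np.isfinite(out.values)), chain.name

    def test_from_name_round_trips(self):
        for chain in enumerate_chains():
            assert TransformChain.from_name(chain.name).name == chain.name
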