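import numpy as np
import pytest

from codivar import (
    Block,
    DegenerateDataError,
    Decomposition,
    ModelSpec,
    columnspace_residual,
    crossover_variance,
    disco_decompose,
    explained_variance,
    jive_decompose,
    o2pls_decompose,
    orthogonality_table,
    rv_modified,
    swiss,
)
from codivar.datamodel import random_orthogonal


def _hand_built(C, D, E, method="jive"):
    """Minimal Decomposition around explicit part matrices (two blocks,
    block 2 mirrors block 1)."""
    I = C.shape[0]
    return Decomposition(
        method=method,
        model=ModelSpec(1, (1, 1)),
        common=[C, C.copy()],
        distinct=[D, D.copy()],
        residual=[E, E.copy()],
        common_scores=np.zeros((I, 1)),
        common_loadings=[np.zeros((C.shape[1], 1))] * 2,
        distinct_scores=[np.zeros((I, 1))] * 2,
        distinct_loadings=[np.zeros((C.shape[1], 1))] * 2,
    )


class TestOrthogonalityTable:
    def test_equal_parts_maximal_magnitude(self, rng):
        # rank-1 C = D: ||C'C||_F then equals ||C||_F^2 exactly
        C = np.outer(rng.standard_normal(6), rng.standard_normal(4))
        dec = _hand_built(C, C.copy(), rng.standard_normal((6, 4)))
        report = orthogonality_table(dec)
        assert abs(report.magnitudes["Ck'Dk"] - 1.0) < 1e-12

    def test_method_flags_follow_pattern_table(self, s2, spec122):
        data, _ = s2
        for fn, method in ((disco_decompose, "disco"), (jive_decompose, "jive"),
                           (o2pls_decompose, "o2pls")):
            report = orthogonality_table(fn(data, spec122))
            assert report.method == method
            assert set(report.magnitudes) == {
                "Ck'Dk", "Ek'Ck", "Ek'Dk", "Ck'Dl", "Dk'Dl", "Ek'Cl", "Ek'Dl"
            }

    def test_jive_expected_zero_entries_pass(self, s2, spec122):
        data, _ = s2
        report = orthogonality_table(jive_decompose(data, spec122))
        assert report.all_passed


class TestExplainedVariance:
    def test_full_rank_noiseless_zero_error(self):
        from codivar import ScenarioConfig, generate_scenario

        data, _ = generate_scenario(ScenarioConfig(
            n_obs=30, n_var=(20, 10), n_common=1, n_distinct=(1, 1),
            common_fractions=([0.5], [0.6]), distinct_fractions=([0.5], [0.4]),
            error_fractions=(0.0, 0.0), loading_style="random", seed=0,
        ))
        var = explained_variance(disco_decompose(data, ModelSpec(1, (1, 1))))
        for b in var.blocks:
            assert b.fraction_error < 1e-12

    def test_disco_fractions_sum_to_one(self, s2, spec122):
        data, _ = s2
        var = explained_variance(disco_decompose(data, spec122))
        for b in var.blocks:
            assert abs(b.additivity_defect) < 1e-10

    def test_type3_error_never_exceeds_raw(self, s2, spec122):
        data, _ = s2
        for fn in (disco_decompose, jive_decompose, o2pls_decompose):
            var = explained_variance(fn(data, spec122), type3=True)
            for b in var.blocks:
                assert b.fraction_error_type3 <= b.fraction_error + 1e-15

    def test_type3_projection_inequality_oracle(self, s1, spec111):
        # oracle: the reattributed energy equals the explicit projection
        # of E onto an orthonormal basis of C's column space
        data, _ = s1
        dec = jive_decompose(data, spec111)
        var = explained_variance(dec, type3=True)
        for k in range(2):
            C, E = dec.common[k], dec.residual[k]
            Q, _ = np.linalg.qr(C)
            rank = np.linalg.matrix_rank(C, tol=1e-10)
            U, s, _ = np.linalg.svd(C, full_matrices=False)
            Q = U[:, :rank]
            E_in = Q @ (Q.T @ E)
            tot = float(np.sum(data.blocks[k].values ** 2))
            expected = float(np.sum((E - E_in) ** 2)) / tot
            assert abs(var.blocks[k].fraction_error_type3 - expected) < 1e-12

    def test_scenario1_residual_projection_small(self, s1, spec111):
        data, _ = s1
        for fn in (jive_decompose, o2pls_decompose):
            dec = fn(data, spec111)
            for k in range(2):
                C, E = dec.common[k], dec.residual[k]
                U, s, _ = np.linalg.svd(C, full_matrices=False)
                Q = U[:, s > 1e-12 * s[0]]
                ratio = np.sum((Q @ (Q.T @ E)) ** 2) / np.sum(E**2)
                assert ratio < 0.01


class TestCrossoverVariance:
    def test_o2pls_zero_by_construction(self, s2, spec122):
        data, _ = s2
        assert crossover_variance(o2pls_decompose(data, spec122), data) == [0.0, 0.0]

    def test_no_foreign_components_zero(self, s1):
        data, _ = s1
        dec = disco_decompose(data, ModelSpec(1, (3, 0)))
        cross = crossover_variance(dec, data)
        assert cross[0] == 0.0  # block 1 has no foreign distinctive scores

    def test_explicit_projector_oracle(self, s2, spec122):
        data, _ = s2
        dec = disco_decompose(data, spec122)
        cross = crossover_variance(dec, data)
        for k in range(2):
            T_f = dec.distinct_scores[1 - k]
            X_k = data.blocks[k].values
            H = T_f @ np.linalg.inv(T_f.T @ T_f) @ T_f.T
            expected = float(np.sum((H @ X_k) ** 2) / np.sum(X_k**2))
            assert abs(cross[k] - expected) < 1e-8


class TestColumnspaceResidual:
    def test_in_space_part_zero(self, rng):
        X = rng.standard_normal((70, 5))
        part = X @ rng.standard_normal((5, 3))
        assert columnspace_residual(part, X) < 1e-10

    def test_full_row_rank_block_zero_for_anything(self, rng):
        X = rng.standard_normal((6, 9))  # J >= I, full row rank
        part = rng.standard_normal((6, 4))
        assert columnspace_residual(part, X) < 1e-10

    def test_planted_orthogonal_direction_qr_oracle(self, rng):
        X = rng.standard_normal((70, 5))
        Q, _ = np.linalg.qr(X)
        v = rng.standard_normal(70)
        v -= Q @ (Q.T @ v)  # orthogonal to X's columns by construction
        part = np.column_stack([X[:, 0], v])
        res = columnspace_residual(part, X)
        assert abs(res - float(v @ v)) < 1e-8 * max(float(v @ v), 1.0)

    def test_accepts_block(self, rng):
        b = Block.from_array(rng.standard_normal((10, 3)))
        assert columnspace_residual(b.values[:, :1], b) < 1e-12


class TestSwiss:
    def test_singleton_subtypes_zero(self):
        scores = np.array([[0.0], [1.0], [4.0]])
        assert swiss(scores, ["a", "b", "c"]) == 0.0

    def test_single_subtype_one(self, rng):
        scores = rng.standard_normal((10, 2))
        assert abs(swiss(scores, ["x"] * 10) - 1.0) < 1e-12

    def test_hand_computed_two_groups(self):
        scores = np.array([[0.0], [2.0], [10.0], [12.0]])
        labels = ["a", "a", "b", "b"]
        # within SS = 2 + 2 = 4; total SS = sum((x - 6)^2) = 104
        assert abs(swiss(scores, labels) - 4.0 / 104.0) < 1e-12

    def test_rotation_and_relabel_invariance(self, rng):
        scores = rng.standard_normal((12, 3))
        labels = np.array(list("aabbccaabbcc"))
        base = swiss(scores, labels)
        R = random_orthogonal(3, rng)
        assert abs(swiss(scores @ R, labels) - base) < 1e-10
        relabeled = np.array([{"a": "z", "b": "y", "c": "x"}[l] for l in labels])
        assert abs(swiss(scores, relabeled) - base) < 1e-12

    def test_single_object_undefined(self):
        with pytest.raises(DegenerateDataError):
            swiss(np.array([[1.0]]), ["a"])


class TestRvModified:
    def test_self_similarity_is_one(self, rng):
        A = rng.standard_normal((15, 4))
        A -= A.mean(axis=0)
        assert abs(rv_modified(A, A) - 1.0) < 1e-12

    def test_orthogonal_configurations_near_zero(self):
        vals = []
        for seed in range(100):
            g = np.random.default_rng(seed)
            Q, _ = np.linalg.qr(g.standard_normal((200, 6)))
            A, B = Q[:, :3], Q[:, 3:]
            vals.append(rv_modified(A, B))
        assert abs(float(np.mean(vals))) < 0.05

    def test_invariance_under_rotation_and_scale(self, rng):
        A = rng.standard_normal((12, 3))
        B = rng.standard_normal((12, 4))
        base = rv_modified(A, B)
        R = random_orthogonal(3, rng)
        assert abs(rv_modified(A @ R * 3.7, B) - base) < 1e-10

    def test_zero_matrix_undefined(self, rng):
        with pytest.raises(DegenerateDataError):
            rv_modified(np.zeros((5, 2)), rng.standard_normal((5, 2)))
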