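import numpy as np
import pytest
from scipy.linalg import subspace_angles

from codivar import (
    InvalidSpecError,
    ModelSpec,
    ScenarioConfig,
    build_target,
    disco_decompose,
    disco_select_model,
    explained_variance,
    find_rotation,
    generate_scenario,
    orthogonality_table,
)
from codivar.datamodel import random_orthogonal
from codivar.disco import _rotation_sweeps, rotation_objective

from .conftest import abs_corr


class TestBuildTarget:
    def test_printed_worked_example(self):
        # J=(2,3), one distinctive per block plus one common component
        t = build_target(2, 3, ModelSpec(1, (1, 1)))
        expected = np.array(
            [[1, 0, 1],
             [1, 0, 1],
             [0, 1, 1],
             [0, 1, 1],
             [0, 1, 1]], dtype=float
        )
        np.testing.assert_array_equal(t.pattern, expected)
        assert t.column_roles == ("distinct-block-1", "distinct-block-2", "common")

    def test_block_diagonal_no_common(self):
        t = build_target(1, 1, ModelSpec(0, (1, 1)))
        np.testing.assert_array_equal(t.pattern, [[1, 0], [0, 1]])

    def test_single_common_column(self):
        t = build_target(2, 2, ModelSpec(1, (0, 0)))
        np.testing.assert_array_equal(t.pattern, np.ones((4, 1)))

    def test_weights_are_complement(self):
        t = build_target(3, 2, ModelSpec(1, (1, 1)))
        np.testing.assert_array_equal(t.weights, 1.0 - t.pattern)

    def test_infeasible_distinct_count(self):
        with pytest.raises(InvalidSpecError):
            build_target(2, 2, ModelSpec(0, (3, 0)))


def _conforming_loadings(rng, J1=6, J2=4, spec=ModelSpec(1, (1, 1))):
    """A loading matrix that exactly matches the zero pattern."""
    target = build_target(J1, J2, spec)
    P = rng.standard_normal(target.pattern.shape) * target.pattern
    return P, target


class TestFindRotation:
    def test_conforming_input_needs_no_rotation(self, rng):
        P, target = _conforming_loadings(rng)
        res = find_rotation(P, target, n_restarts=5, seed=0)
        assert res.objective < 1e-20

    def test_plant_and_recover(self, rng):
        P0, target = _conforming_loadings(rng)
        B0 = random_orthogonal(3, rng)
        res = find_rotation(P0 @ B0, target, n_restarts=10, seed=0)
        assert res.objective < 1e-10
        rotated = (P0 @ B0) @ res.B_opt
        assert np.max(np.abs(rotated * target.weights)) < 1e-6

    def test_returns_orthogonal_matrix(self, rng):
        P = rng.standard_normal((10, 3))
        target = build_target(6, 4, ModelSpec(1, (1, 1)))
        res = find_rotation(P, target, n_restarts=5, seed=0)
        np.testing.assert_allclose(
            res.B_opt.T @ res.B_opt, np.eye(3), atol=1e-10
        )

    def test_two_component_grid_oracle(self, rng):
        # c_t = 2: every orthogonal 2x2 matrix is a rotation or a
        # reflection of angle theta, so exhaustive search is possible
        P = rng.standard_normal((7, 2))
        target = build_target(4, 3, ModelSpec(0, (1, 1)))
        res = find_rotation(P, target, n_restarts=20, seed=0)
        W = target.weights

        def objective_at(theta, reflect):
            c, s = np.cos(theta), np.sin(theta)
            B = np.array([[c, -s], [s, c]])
            if reflect:
                B = B @ np.diag([1.0, -1.0])
            return rotation_objective(P, B, W)

        best = np.inf
        for reflect in (False, True):
            grid = np.arange(0.0, 2 * np.pi, 1e-4)
            vals = [objective_at(t, reflect) for t in grid]
            i = int(np.argmin(vals))
            fine = np.arange(grid[i] - 1e-4, grid[i] + 1e-4, 1e-8)
            best = min(best, min(objective_at(t, reflect) for t in fine))
        assert abs(res.objective - best) < 1e-8

    def test_objective_monotone_within_sweeps(self, rng):
        P = rng.standard_normal((12, 3))
        target = build_target(7, 5, ModelSpec(1, (1, 1)))
        W = target.weights
        B = np.eye(3)
        f_prev = rotation_objective(P, B, W)
        for _ in range(25):
            B, f, _, _ = _rotation_sweeps(P, W, B, tol=-1.0, max_iter=1)
            assert f <= f_prev + 1e-12
            f_prev = f

    def test_shape_mismatch(self, rng):
        target = build_target(3, 2, ModelSpec(1, (1, 1)))
        with pytest.raises(Exception):
            find_rotation(rng.standard_normal((5, 4)), target)


def _noiseless_111(seed=0):
    config = ScenarioConfig(
        n_obs=40, n_var=(30, 20), n_common=1, n_distinct=(1, 1),
        common_fractions=([0.5], [0.6]), distinct_fractions=([0.5], [0.4]),
        error_fractions=(0.0, 0.0), loading_style="random", seed=seed,
    )
    return generate_scenario(config)


class TestDiscoDecompose:
    def test_noiseless_recovery(self):
        data, truth = _noiseless_111()
        dec = disco_decompose(data, ModelSpec(1, (1, 1)))
        for k in range(2):
            assert np.linalg.norm(dec.residual[k]) < 1e-8
        assert max(subspace_angles(dec.common_scores, truth.common_scores)) < 1e-6
        for k in range(2):
            assert max(
                subspace_angles(dec.distinct_scores[k], truth.distinct_scores[k])
            ) < 1e-6

    def test_scenario2_matches_generating_fractions(self, s2, spec122):
        data, _ = s2
        var = explained_variance(disco_decompose(data, spec122))
        b1, b2 = var.blocks
        assert abs(b1.fraction_common - 0.11) < 0.02
        assert abs(b1.fraction_distinct - 0.88) < 0.02
        assert abs(b2.fraction_common - 0.62) < 0.02
        assert abs(b2.fraction_distinct - 0.36) < 0.02

    def test_scenario1_score_recovery(self, s1, spec111):
        data, truth = s1
        dec = disco_decompose(data, spec111)
        assert abs_corr(dec.common_scores[:, 0], truth.common_scores[:, 0]) > 0.995
        for k in range(2):
            assert abs_corr(
                dec.distinct_scores[k][:, 0], truth.distinct_scores[k][:, 0]
            ) > 0.995

    def test_combined_additivity_direct_norm_oracle(self, s2, spec122):
        data, _ = s2
        dec = disco_decompose(data, spec122)
        lhs = float(sum(np.sum(b.values**2) for b in data.blocks))
        rhs = sum(
            float(np.sum(np.hstack(part) ** 2))
            for part in (dec.common, dec.distinct, dec.residual)
        )
        assert abs(lhs - rhs) < 1e-10 * lhs

    def test_reconstruction(self, s2, spec122):
        data, _ = s2
        dec = disco_decompose(data, spec122)
        for k in range(2):
            np.testing.assert_allclose(
                dec.reconstructed(k), data.blocks[k].values, atol=1e-12
            )

    def test_rotation_preserves_fit(self, s1):
        # T_r P_r^t must equal the unrotated SCA fit: the rotated model
        # explains exactly the concatenated rank-c_t approximation
        data, _ = s1
        from codivar.datamodel import truncated_svd

        dec = disco_decompose(data, ModelSpec(1, (1, 1)))
        trip = truncated_svd(data.concatenated(), 3)
        fit_sca = trip.reconstruct()
        fit_rot = np.hstack(
            [data.blocks[k].values - r for k, r in enumerate(dec.extras["sca_residual"])]
        )
        assert np.max(np.abs(fit_rot - fit_sca)) < 1e-12

    def test_residual_splits_into_sca_residual_and_crossover(self, s2, spec122):
        data, _ = s2
        dec = disco_decompose(data, spec122)
        for k in range(2):
            np.testing.assert_allclose(
                dec.residual[k],
                dec.extras["sca_residual"][k] + dec.extras["crossover_parts"][k],
                atol=1e-14,
            )

    def test_shared_common_scores_orthonormal(self, s2, spec122):
        data, _ = s2
        dec = disco_decompose(data, spec122)
        T = np.hstack([dec.common_scores, *dec.distinct_scores])
        np.testing.assert_allclose(T.T @ T, np.eye(5), atol=1e-10)

    def test_table1_same_block_orthogonalities(self, s2, spec122):
        data, _ = s2
        report = orthogonality_table(disco_decompose(data, spec122))
        for name in ("Ck'Dk", "Ck'Dl", "Dk'Dl", "Ek'Ck", "Ek'Cl", "Ek'Dk"):
            assert report.magnitudes[name] < 1e-8, name

    def test_infeasible_spec(self, s1):
        data, _ = s1
        with pytest.raises(InvalidSpecError):
            disco_decompose(data, ModelSpec(0, (0, 0)))


class TestDiscoSelectModel:
    def test_scenario1_selects_true_model(self, s1):
        data, _ = s1
        spec, candidates = disco_select_model(data, seed=0)
        assert (spec.n_common, spec.n_distinct) == (1, (1, 1))
        assert any(c["selected"] for c in candidates)

    def test_scenario2_selects_zero_common(self, s2):
        data, _ = s2
        spec, _ = disco_select_model(data, seed=0)
        assert spec.n_common == 0

    def test_noiseless_exhaustive_partition_oracle(self):
        data, _ = _noiseless_111()
        spec, candidates = disco_select_model(data, seed=0)
        assert (spec.n_common, spec.n_distinct) == (1, (1, 1))
        # oracle: among qualified candidates the selected one has the
        # smallest cross-over, itself numerically zero
        row = next(c for c in candidates if c["selected"])
        assert row["crossover_total"] < 1e-10
        qualified = [c for c in candidates if c["qualified"]]
        assert row["crossover_total"] <= min(c["crossover_total"] for c in qualified) + 1e-12

    def test_candidate_table_covers_all_partitions(self, s1):
        data, _ = s1
        spec, candidates = disco_select_model(data, seed=0)
        c_t = spec.total
        seen = {(c["n_common"], c["n_distinct_1"], c["n_distinct_2"]) for c in candidates}
        expected = {
            (a, b, c_t - a - b)
            for a in range(c_t + 1)
            for b in range(c_t + 1 - a)
        }
        assert seen == expected
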