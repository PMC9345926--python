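"""GLM t-maps, TFCE, permutation FWE, and cluster extraction."""

import itertools
import warnings

import numpy as np
import pytest

from conftest import ols_t_oracle, tfce_oracle
from sbbrep.surface import SurfaceMesh, build_test_mesh
from sbbrep.exploratory import (
    Cluster,
    DesignError,
    DesignMatrix,
    StatMap,
    TFCEParams,
    extract_clusters,
    fit_glm_tmap,
    permutation_fwe,
    tfce_transform,
)


@pytest.fixture(scope="module")
def path4():
    return SurfaceMesh("lh", 4, np.array([[0, 1], [1, 2], [2, 3]]))


class TestDesignMatrix:
    def test_rank_deficient_rejected(self):
        s = np.arange(6, dtype=float)
        with pytest.raises(DesignError):
            DesignMatrix(score=s, confounders=np.column_stack([s, s * 2]))

    def test_columns_are_intercept_score_confounders(self):
        d = DesignMatrix(score=np.array([1.0, 2, 3, 5]), confounders=np.eye(4)[:, :2])
        x = d.matrix()
        assert x.shape == (4, 4)
        assert np.all(x[:, 0] == 1)


class TestFitGlmTmap:
    def test_matches_normal_equations_oracle(self):
        """8 subjects, 2 confounders, random thickness: per-vertex t agrees
        with an independent (X'X)^-1 computation to 1e-10."""
        rng = np.random.default_rng(0)
        score = rng.standard_normal(8)
        conf = rng.standard_normal((8, 2))
        y = rng.standard_normal((8, 25))
        design = DesignMatrix(score=score, confounders=conf)
        t = fit_glm_tmap(y, design)
        t_oracle = ols_t_oracle(y, design.matrix(), coef_index=1)
        assert np.allclose(t, t_oracle, atol=1e-10)

    def test_perfect_fit_gives_inf_sentinel(self):
        s = np.array([1.0, 2, 3, 4, 5, 6])
        y = (2.0 * s)[:, None]
        t = fit_glm_tmap(y, DesignMatrix(score=s))
        assert np.isinf(t[0]) and t[0] > 0

    def test_zero_variance_vertex_gets_zero_with_warning(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal((10, 3))
        y[:, 1] = 2.5
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            t = fit_glm_tmap(y, DesignMatrix(score=rng.standard_normal(10)))
        assert t[1] == 0.0

    def test_null_data_t_centred_at_zero(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal((60, 400))
        t = fit_glm_tmap(y, DesignMatrix(score=rng.standard_normal(60)))
        assert abs(t.mean()) < 0.1

    def test_too_few_subjects_rejected(self):
        with pytest.raises(DesignError):
            fit_glm_tmap(np.ones((3, 2)), DesignMatrix(score=np.array([1.0, 2, 3])))


class TestTfceTransform:
    def test_constant_zero_map_is_zero(self, grid3):
        out = tfce_transform(np.zeros(9), grid3, TFCEParams())
        assert np.all(out == 0)

    def test_isolated_vertex_hand_value(self, path4):
        """Vertex at t=1.0 with zero neighbours: sum_{k=1..10} 1*(0.1k)^2*0.1
        = 0.385."""
        v = np.array([1.0, 0.0, 0.0, 0.0])
        out = tfce_transform(v, path4, TFCEParams(E=1, H=2, dh=0.1), "+")
        assert out[0] == pytest.approx(0.385, abs=1e-12)

    def test_adjacent_pair_hand_value(self, path4):
        """t=(1.0, 0.5) adjacent: 0.2*sum_{h<=0.5}h^2 + 0.1*sum_{h>0.5}h^2
        = 0.11 + 0.33 = 0.44 at the taller vertex."""
        v = np.array([1.0, 0.5, 0.0, 0.0])
        out = tfce_transform(v, path4, TFCEParams(E=1, H=2, dh=0.1), "+")
        assert out[0] == pytest.approx(0.44, abs=1e-12)
        assert out[1] == pytest.approx(0.11, abs=1e-12)

    def test_negative_tail_mirrors_positive(self, grid3):
        rng = np.random.default_rng(3)
        v = rng.standard_normal(9)
        p = TFCEParams(dh=0.1)
        assert np.allclose(
            tfce_transform(v, grid3, p, "-"), tfce_transform(-v, grid3, p, "+")
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_oracle_random_maps(self, ico1, seed):
        rng = np.random.default_rng(seed)
        v = np.abs(rng.standard_normal(ico1.n_vertices))
        n_steps = 37
        out = tfce_transform(v, ico1, TFCEParams(n_steps=n_steps), "+")
        oracle = tfce_oracle(v, ico1, 1.0, 2.0, v.max() / n_steps, n_steps)
        assert np.allclose(out, oracle, atol=1e-9)

    @pytest.mark.parametrize("scale", [1.5, 2.0, 10.0])
    def test_monotone_under_scaling(self, grid3, scale):
        rng = np.random.default_rng(7)
        v = rng.standard_normal(9)
        p = TFCEParams(n_steps=50)
        base = tfce_transform(v, grid3, p, "+")
        scaled = tfce_transform(scale * v, grid3, p, "+")
        assert np.all(scaled >= base - 1e-12)

    def test_depends_only_on_rectified_tail(self, grid3):
        v = np.array([1.0, -5.0, 0.5, 0, 0, 0, -1.0, 0, 2.0])
        w = np.maximum(v, 0.0)
        p = TFCEParams(dh=0.05)
        assert np.allclose(
            tfce_transform(v, grid3, p, "+"), tfce_transform(w, grid3, p, "+")
        )

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            TFCEParams(dh=-0.1)
        with pytest.raises(ValueError):
            TFCEParams(E=-1)


class TestPermutationFwe:
    def test_best_attainable_p_when_effect_dominates(self, path4):
        """An effect far above every permutation max earns p = 1/(n_perm+1)."""
        rng = np.random.default_rng(0)
        n = 40
        score = rng.standard_normal(n)
        y = 0.02 * rng.standard_normal((n, 4))
        y[:, 0] += 5.0 * score
        stat = permutation_fwe(y, DesignMatrix(score=score), path4, n_perm=99, seed=1)
        assert stat.p_fwe["lh"][0] == pytest.approx(1.0 / 100.0)

    def test_p_values_within_bounds_and_deterministic(self, grid3):
        rng = np.random.default_rng(5)
        y = rng.standard_normal((30, 9))
        d = DesignMatrix(score=rng.standard_normal(30))
        s1 = permutation_fwe(y, d, grid3, n_perm=200, seed=77)
        s2 = permutation_fwe(y, d, grid3, n_perm=200, seed=77)
        p = s1.p_fwe["lh"]
        assert np.all((p >= 1 / 201) & (p <= 1.0))
        assert np.array_equal(p, s2.p_fwe["lh"])

    def test_exhaustive_enumeration_matches_independent_oracle(self, path4):
        """n=6 subjects: requesting more permutations than 6! switches to
        full enumeration, which must match an independently coded
        exhaustive Freedman-Lane oracle exactly."""
        rng = np.random.default_rng(9)
        n = 6
        score = rng.standard_normal(n)
        conf = rng.standard_normal((n, 1))
        y = rng.standard_normal((n, 4))
        design = DesignMatrix(score=score, confounders=conf)
        params = TFCEParams(n_steps=20)
        with pytest.warns(RuntimeWarning, match="exhaustively"):
            stat = permutation_fwe(y, design, path4, params, n_perm=720, seed=0)

        # --- oracle: explicit enumeration with lstsq fits and brute TFCE ---
        zz = np.column_stack([np.ones(n), conf])
        proj = zz @ np.linalg.pinv(zz)
        y_res = y - proj @ y
        x_full = design.matrix()

        def tmap(rows):
            with np.errstate(all="ignore"):
                return ols_t_oracle(proj @ y + y_res[rows], x_full, coef_index=1)

        def joint_stat(t):
            gmax = np.abs(t).max()
            if gmax == 0:
                return np.zeros_like(t), 0.0
            dh = gmax / params.n_steps
            per_tail = []
            for tail in (np.maximum(t, 0), np.maximum(-t, 0)):
                k = int(np.floor(tail.max() / dh + 1e-9))
                per_tail.append(
                    tfce_oracle(tail, path4, params.E, params.H, dh, k)
                    if k >= 1
                    else np.zeros_like(t)
                )
            stacked = np.maximum(per_tail[0], per_tail[1])
            return stacked, max(p.max() for p in per_tail)

        obs_stat, _ = joint_stat(tmap(np.arange(n)))
        maxes = []
        for perm in itertools.permutations(range(n)):
            _, m = joint_stat(tmap(np.array(perm)))
            maxes.append(m)
        maxes = np.array(maxes)
        p_oracle = (maxes[:, None] >= obs_stat[None, :] - 1e-12).mean(axis=0)
        assert np.allclose(stat.p_fwe["lh"], p_oracle, atol=1e-12)

    def test_same_permutation_applied_to_both_hemispheres(self, grid3, ico1):
        """Duplicating one hemisphere's data must give identical p-maps for
        the two copies."""
        rng = np.random.default_rng(4)
        y = rng.standard_normal((25, 9))
        meshes = {"lh": grid3, "rh": build_test_mesh("grid", 3, hemisphere="rh")}
        stat = permutation_fwe(
            {"lh": y, "rh": y.copy()},
            DesignMatrix(score=rng.standard_normal(25)),
            meshes,
            n_perm=100,
            seed=3,
        )
        assert np.array_equal(stat.p_fwe["lh"], stat.p_fwe["rh"])

    def test_invalid_n_perm(self, grid3):
        with pytest.raises(ValueError):
            permutation_fwe(
                np.ones((10, 9)),
                DesignMatrix(score=np.arange(10.0)),
                grid3,
                n_perm=0,
            )


class TestExtractClusters:
    def _stat(self, mesh, t, p):
        return StatMap(
            t_values={"lh": np.asarray(t, dtype=float)},
            tfce_pos={"lh": np.zeros(mesh.n_vertices)},
            tfce_neg={"lh": np.zeros(mesh.n_vertices)},
            p_fwe={"lh": np.asarray(p, dtype=float)},
            n_permutations=100,
            seed=0,
        )

    def test_nothing_significant_gives_empty_set(self, grid3):
        stat = self._stat(grid3, np.ones(9), np.full(9, 0.5))
        assert len(extract_clusters(stat, grid3)) == 0

    def test_all_significant_positive_is_one_cluster(self, grid3):
        stat = self._stat(grid3, np.ones(9), np.full(9, 0.01))
        cs = extract_clusters(stat, grid3)
        assert len(cs) == 1
        assert cs.clusters[0].size == 9 and cs.clusters[0].sign == 1

    def test_opposite_sign_corners_become_two_singletons(self, grid3):
        t = np.zeros(9)
        t[0], t[8] = 3.0, -3.0
        p = np.full(9, 0.9)
        p[0] = p[8] = 0.01
        cs = extract_clusters(self._stat(grid3, t, p), grid3)
        assert len(cs) == 2
        signs = sorted(c.sign for c in cs)
        assert signs == [-1, 1]
        assert all(c.size == 1 for c in cs)

    def test_clusters_sorted_by_size_descending(self, grid3):
        t = np.ones(9)
        p = np.array([0.01, 0.01, 0.9, 0.9, 0.9, 0.9, 0.9, 0.01, 0.9])
        cs = extract_clusters(self._stat(grid3, t, p), grid3)
        assert [c.size for c in cs] == [2, 1]

    def test_sign_split_within_one_component(self, path4):
        """Adjacent significant vertices of opposite sign form separate
        clusters."""
        stat = self._stat(path4, [2.0, -2.0, 2.0, 0.0], [0.01, 0.01, 0.01, 0.9])
        cs = extract_clusters(stat, path4)
        assert len(cs) == 3


class TestTfceProperties:
    """Hypothesis-driven TFCE invariants on the 3x3 grid."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    maps_strategy = st.lists(
        st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]), min_size=9, max_size=9
    )

    @given(maps_strategy)
    @settings(derandomize=True, deadline=None, max_examples=100)
    def test_matches_oracle_and_is_nonnegative(self, values):
        from sbbrep.surface import build_test_mesh
        from conftest import tfce_oracle

        mesh = build_test_mesh("grid", 3)
        v = np.array(values)
        got = tfce_transform(v, mesh, TFCEParams(dh=0.25), "+")
        want = tfce_oracle(v, mesh, 1.0, 2.0, 0.25, 4)
        assert np.all(got >= 0)
        assert np.allclose(got, want, atol=1e-12)
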