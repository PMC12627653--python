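"""Factorial design, GLM estimation against independent oracles, and
permutation cluster inference on small enumerable instances."""

import math
from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from fpetdyn.groupglm import (
    build_flexible_factorial,
    cluster_inference_permutation,
    contrast_t,
    extract_clusters,
    fit_glm,
    fit_glm_contrast,
    sign_flip_cluster_inference,
    stack_observations,
    subject_effect_maps,
    two_sample_map_inference,
)
from fpetdyn.imageio import SubjectTable


def _table(n_hc, n_pd):
    return SubjectTable(pd.DataFrame({
        "subject": [f"s{i}" for i in range(n_hc + n_pd)],
        "group": ["HC"] * n_hc + ["PD"] * n_pd,
    }))


class TestDesign:
    def test_block_counting_and_contrast(self):
        rng = np.random.default_rng(0)
        design = build_flexible_factorial(_table(2, 2), n_frames=3,
                                          globals_=rng.normal(size=12))
        assert design.X.shape == (12, 2 + 2 + 3 + 1)
        c = design.group_contrast()
        assert c.sum() == pytest.approx(0.0)
        np.testing.assert_allclose(c[:2], 0.5)
        np.testing.assert_allclose(c[2:4], -0.5)
        assert design.is_estimable(c)

    @pytest.mark.parametrize("S,T", [(4, 3), (5, 6), (3, 2)])
    def test_factor_block_rank(self, S, T):
        """rank [subjects | times] = S + T - 1 (one shared intercept)."""
        table = _table(S // 2, S - S // 2)
        design = build_flexible_factorial(table, n_frames=T)
        assert design.rank == S + T - 1

    def test_missing_frames_detected(self):
        with pytest.raises(ValueError, match="missing frames"):
            build_flexible_factorial(_table(2, 2), n_frames=3,
                                     globals_=np.arange(11.0))

    def test_single_subject_effect_not_estimable(self):
        design = build_flexible_factorial(_table(2, 2), n_frames=3)
        c = np.zeros(design.X.shape[1])
        c[0] = 1.0          # one subject's absolute effect is confounded
        assert not design.is_estimable(c)


class TestEstimation:
    def test_no_effect_noise_free_gives_zero_t(self, rng):
        table = _table(3, 3)
        design = build_flexible_factorial(table, n_frames=4)
        frame_effects = rng.random(4)
        Y = np.tile(frame_effects, 6)[:, None] * np.ones((1, 5))
        Y += rng.random(5)[None, :]     # voxel offsets, same for everyone
        t = fit_glm_contrast(Y, design, design.group_contrast())
        np.testing.assert_allclose(t, 0.0, atol=1e-9)

    def test_reduces_to_classical_two_sample_t(self, rng):
        """One frame per subject, cell-means design: t equals the pooled
        two-sample t computed from its closed form."""
        a = rng.normal(size=6)
        b = rng.normal(loc=0.7, size=5)
        y = np.concatenate([a, b])[:, None]
        X = np.zeros((11, 2))
        X[:6, 0] = 1.0
        X[6:, 1] = 1.0
        import dataclasses

        from fpetdyn.groupglm import DesignMatrix

        design = DesignMatrix(X=X, subjects=[f"s{i}" for i in range(11)],
                              groups=np.array(["A"] * 6 + ["B"] * 5),
                              n_frames=1, subject_cols=np.arange(2),
                              time_cols=np.array([], int), global_col=None,
                              rank=2)
        fit = fit_glm(y, design)
        t = contrast_t(fit, np.array([1.0, -1.0]))[0]
        sp2 = ((6 - 1) * a.var(ddof=1) + (5 - 1) * b.var(ddof=1)) / 9
        t_closed = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / 6 + 1 / 5))
        assert t == pytest.approx(t_closed, abs=1e-12)
        assert fit.df == 9

    def test_matches_normal_equations_oracle_random_instances(self, rng):
        """beta-hat and t agree with an independent normal-equations solve
        to 1e-8 on 100 random full-rank systems."""
        import dataclasses

        from fpetdyn.groupglm import DesignMatrix

        worst = 0.0
        for _ in range(100):
            n, p = 20, 6
            X = rng.normal(size=(n, p))
            Y = rng.normal(size=(n, 3))
            c = rng.normal(size=p)
            design = DesignMatrix(X=X, subjects=[f"s{i}" for i in range(n)],
                                  groups=np.array(["A"] * n), n_frames=1,
                                  subject_cols=np.arange(n) % p,
                                  time_cols=np.array([], int), global_col=None,
                                  rank=int(np.linalg.matrix_rank(X)))
            fit = fit_glm(Y, design)
            # oracle: solve the normal equations directly
            beta_o = np.linalg.solve(X.T @ X, X.T @ Y)
            resid = Y - X @ beta_o
            sigma2_o = np.einsum("ij,ij->j", resid, resid) / (n - p)
            q_o = c @ np.linalg.solve(X.T @ X, c)
            t_o = (c @ beta_o) / np.sqrt(sigma2_o * q_o)
            worst = max(worst, np.abs(fit.beta - beta_o).max(),
                        np.abs(contrast_t(fit, c) - t_o).max())
        assert worst < 1e-8

    def test_factorial_contrast_matches_lstsq_oracle(self, rng):
        """Estimable contrasts of the rank-deficient factorial agree with an
        independent least-squares route (scipy lstsq)."""
        from scipy.linalg import lstsq

        table = _table(3, 4)
        design = build_flexible_factorial(table, n_frames=5,
                                          globals_=rng.normal(size=35))
        Y = rng.normal(size=(35, 4))
        c = design.group_contrast()
        fit = fit_glm(Y, design)
        beta_o, *_ = lstsq(design.X, Y, lapack_driver="gelsd")
        np.testing.assert_allclose(c @ fit.beta, c @ beta_o, atol=1e-9)

    def test_contrast_direction_symmetry(self, windowed, cohort, options):
        mask = cohort["atlas"].brain_mask()
        Y = stack_observations(windowed[:6] + windowed[-6:],
                               mask)[:, :200]
        table = SubjectTable(pd.DataFrame({
            "subject": [f"s{i}" for i in range(12)],
            "group": ["HC"] * 6 + ["PD"] * 6,
        }))
        design = build_flexible_factorial(table, n_frames=30)
        fit = fit_glm(Y, design)
        maps = subject_effect_maps(fit, design)
        small_mask = np.zeros((10, 10, 2), dtype=bool)
        small_mask[:, :, :] = False
        small_mask.flat[:200] = True
        t_ab, _ = two_sample_map_inference(maps, design.groups, small_mask, np.eye(4),
                                           group_a="HC", group_b="PD", n_perm=100)
        t_ba, _ = two_sample_map_inference(maps, design.groups, small_mask, np.eye(4),
                                           group_a="PD", group_b="HC", n_perm=100)
        np.testing.assert_allclose(t_ab.data[small_mask], -t_ba.data[small_mask],
                                   rtol=1e-10)


class TestClusterInference:
    def _mini_maps(self, rng, effect=0.0):
        S = 6
        maps = rng.normal(size=(S, 32))
        maps[:3, :6] += effect
        mask = np.zeros((4, 4, 2), dtype=bool)
        mask.flat[:32] = True
        return maps, mask

    def test_two_sample_exhaustive_matches_bruteforce(self, rng):
        """p-values from the engine equal a from-scratch enumeration of all
        group relabellings."""
        maps, mask = self._mini_maps(rng, effect=3.0)
        groups = np.array(["A"] * 3 + ["B"] * 3)
        tmap, result = two_sample_map_inference(
            maps, groups, mask, np.eye(4), group_a="A", group_b="B",
            cf_threshold_p=0.05, n_perm=100, extent_min=0, alpha=0.05,
        )
        assert result.exhaustive
        threshold = stats.t.isf(0.05, 4)

        def brute_tmap(members):
            a = maps[list(members)]
            b = maps[[i for i in range(6) if i not in members]]
            sp2 = ((a.shape[0] - 1) * a.var(axis=0, ddof=1)
                   + (b.shape[0] - 1) * b.var(axis=0, ddof=1)) / 4
            return (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(sp2 * (2 / 3))

        def brute_max_extent(tv):
            vol = np.zeros(mask.shape)
            vol[mask] = tv
            lab, n = ndimage.label(vol > threshold, structure=np.ones((3, 3, 3)))
            return max((int((lab == i).sum()) for i in range(1, n + 1)), default=0)

        null = [brute_max_extent(brute_tmap(m))
                for m in combinations(range(6), 3) if set(m) != {0, 1, 2}]
        assert len(null) == result.n_perm == math.comb(6, 3) - 1
        for _, row in result.table.iterrows():
            expected_p = (1 + sum(e >= row.extent for e in null)) / (len(null) + 1)
            assert row.p_fwe == pytest.approx(expected_p)

    def test_sign_flip_exhaustive_matches_bruteforce(self, rng):
        maps, mask = self._mini_maps(rng)
        maps[:, :6] += 2.0
        tmap, result = sign_flip_cluster_inference(
            maps, mask, np.eye(4), cf_threshold_p=0.05, n_perm=200, alpha=0.05,
        )
        assert result.exhaustive
        assert result.n_perm == 2**6 - 1
        threshold = stats.t.isf(0.05, 5)

        def brute_max_extent(signs):
            y = maps * np.asarray(signs)[:, None]
            t = y.mean(axis=0) / (y.std(axis=0, ddof=1) / np.sqrt(6))
            vol = np.zeros(mask.shape)
            vol[mask] = t
            lab, n = ndimage.label(vol > threshold, structure=np.ones((3, 3, 3)))
            return max((int((lab == i).sum()) for i in range(1, n + 1)), default=0)

        null = [brute_max_extent(s) for s in product((1, -1), repeat=6)
                if s != (1, 1, 1, 1, 1, 1)]
        for _, row in result.table.iterrows():
            expected_p = (1 + sum(e >= row.extent for e in null)) / (len(null) + 1)
            assert row.p_fwe == pytest.approx(expected_p)

    def test_permutation_p_floor(self, rng):
        """A max extent beating every permutation earns p = 1/(n_perm+1)."""
        S = 20
        maps = rng.normal(size=(S, 64))
        maps[: S // 2, :20] += 8.0          # overwhelming effect
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask.flat[:64] = True
        groups = np.array(["A"] * (S // 2) + ["B"] * (S // 2))
        _, result = two_sample_map_inference(
            maps, groups, mask, np.eye(4), group_a="A", group_b="B",
            n_perm=150, extent_min=0,
        )
        assert not result.exhaustive
        assert result.table.p_fwe.min() == pytest.approx(1 / 151)

    def test_factorial_cluster_inference_runs_end_to_end(self, windowed, cohort, options):
        """Planted SN hypometabolism is recovered on the session cohort."""
        atlas = cohort["atlas"]
        table = cohort["table"]
        mask = atlas.brain_mask()
        Y = stack_observations(windowed, mask)
        globals_ = np.concatenate([img.data[mask].mean(axis=0) for img in windowed])
        design = build_flexible_factorial(table, 30, globals_)
        tmap, result = cluster_inference_permutation(
            Y, design, mask, atlas.affine, group_a="HC", group_b="PD",
            n_perm=200, extent_min=20, seed=0,
        )
        retained = result.retained
        assert len(retained) >= 1
        biggest = int(retained.sort_values("extent").iloc[-1].cluster_id)
        cluster_mask = result.label_map == biggest
        sn = atlas.region_mask("SN_left") | atlas.region_mask("SN_right")
        # the dominant retained cluster covers most of the planted SN
        assert (cluster_mask & sn).sum() > 0.5 * sn.sum()

    def test_extract_clusters_connectivity_26(self):
        vol = np.zeros((3, 3, 3))
        vol[0, 0, 0] = vol[1, 1, 1] = 5.0    # touching only diagonally
        mask = np.ones((3, 3, 3), dtype=bool)
        _, extents = extract_clusters(vol, mask, 1.0)
        assert list(extents) == [2]          # 26-connectivity joins diagonals

    def test_n_perm_minimum_enforced(self, rng):
        maps, mask = self._mini_maps(rng)
        with pytest.raises(ValueError, match="n_perm"):
            two_sample_map_inference(maps, np.array(["A"] * 3 + ["B"] * 3),
                                     mask, np.eye(4), group_a="A", group_b="B",
                                     n_perm=10)
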