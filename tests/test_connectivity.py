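"""Seed regression, t->z mapping, dice, and group-map contracts."""

import numpy as np
import pytest
from scipy import integrate, stats

from fpetdyn.classify import rank_auc
from fpetdyn.connectivity import (
    Z_MAX,
    SeedModel,
    dice_coefficient,
    group_map,
    seed_connectivity_subject,
    t_to_z,
)
from fpetdyn.imageio import LabelImage, StatMap, TimeSeriesImage


class TestTtoZ:
    @pytest.mark.parametrize("df", [1, 5, 28, 1000])
    def test_zero_maps_to_zero(self, df):
        assert t_to_z(0.0, df) == pytest.approx(0.0, abs=1e-12)

    def test_normal_limit_at_large_df(self):
        assert t_to_z(1.96, 10**6) == pytest.approx(1.96, abs=1e-3)

    @pytest.mark.parametrize("t,df", [(2.5, 28), (-1.3, 7), (4.0, 12), (0.7, 3)])
    def test_matches_quadrature_oracle(self, t, df):
        """z from an independent numerical integration of the t density."""
        pdf = lambda x: stats.t.pdf(x, df)  # noqa: E731
        tail, _ = integrate.quad(pdf, abs(t), np.inf)
        z_expected = np.sign(t) * -stats.norm.ppf(tail)
        assert t_to_z(t, df) == pytest.approx(z_expected, abs=1e-6)

    def test_monotone_in_t(self):
        ts = np.linspace(-30, 30, 301)
        zs = t_to_z(ts, 15)
        assert np.all(np.diff(zs) >= 0)

    def test_saturation_bound(self):
        assert t_to_z(1e12, 300) == Z_MAX
        assert t_to_z(-1e12, 300) == -Z_MAX

    def test_df_required(self):
        with pytest.raises(ValueError):
            t_to_z(1.0, 0)


def _toy_image(series_by_voxel, affine=None):
    """Build a 1D-layout image from {voxel index: series} over a 4x1x1 grid."""
    T = len(next(iter(series_by_voxel.values())))
    data = np.zeros((4, 1, 1, T))
    for i, s in series_by_voxel.items():
        data[i, 0, 0] = s
    return TimeSeriesImage(data, affine if affine is not None else np.eye(4), 60.0)


def _toy_atlas():
    labels = np.zeros((4, 1, 1), dtype=np.int32)
    labels[0] = 1             # seed voxel
    labels[1:] = 2            # the rest, labelled so they are in-mask
    return LabelImage(labels, np.eye(4), {1: "seed", 2: "rest"})


class TestSeedRegression:
    def test_affine_function_of_seed_saturates(self, rng):
        seed_series = rng.normal(size=20) + 5
        img = _toy_image({0: seed_series, 1: 2 * seed_series + 1,
                          2: rng.normal(size=20), 3: rng.normal(size=20)})
        tmap, zmap = seed_connectivity_subject(img, _toy_atlas(), SeedModel("seed"))
        assert zmap.data[1, 0, 0] == Z_MAX          # perfect fit capped
        assert zmap.data[0, 0, 0] == Z_MAX          # the seed itself

    def test_orthogonal_voxel_scores_zero(self):
        seed_series = np.array([1.0, 2.0, 1.0, 2.0, 1.0, 2.0])
        orth = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0])   # orthogonal after centering
        orth -= orth.mean()
        assert abs((seed_series - seed_series.mean()) @ orth) < 1e-12
        img = _toy_image({0: seed_series, 1: orth, 2: np.arange(6.0),
                          3: np.ones(6) + np.array([0, 1, 0, 1, 0, 1]) * 0.1})
        tmap, zmap = seed_connectivity_subject(img, _toy_atlas(), SeedModel("seed"))
        assert tmap.data[1, 0, 0] == pytest.approx(0.0, abs=1e-10)
        assert zmap.data[1, 0, 0] == pytest.approx(0.0, abs=1e-10)

    def test_constant_seed_rejected(self):
        img = _toy_image({0: np.ones(8), 1: np.arange(8.0)})
        with pytest.raises(ValueError, match="degenerate seed"):
            seed_connectivity_subject(img, _toy_atlas(), SeedModel("seed"))

    def test_scale_invariance_of_z(self, rng):
        data = {i: rng.normal(size=15) + 3 for i in range(4)}
        img1 = _toy_image(data)
        img2 = _toy_image({i: 7.3 * s for i, s in data.items()})
        _, z1 = seed_connectivity_subject(img1, _toy_atlas(), SeedModel("seed"))
        _, z2 = seed_connectivity_subject(img2, _toy_atlas(), SeedModel("seed"))
        np.testing.assert_allclose(z1.data, z2.data, rtol=1e-9)

    def test_drift_nuisance_removes_trend_driven_association(self, rng):
        trend = np.linspace(0, 4, 30)
        seed_series = trend + 0.3 * rng.normal(size=30) + 5   # trend-dominated seed
        img = _toy_image({0: seed_series, 1: trend + 0.1 * rng.normal(size=30),
                          2: rng.normal(size=30), 3: rng.normal(size=30)})
        _, z_plain = seed_connectivity_subject(img, _toy_atlas(), SeedModel("seed"))
        _, z_drift = seed_connectivity_subject(
            img, _toy_atlas(), SeedModel("seed", nuisance="drift"))
        # voxel 1 tracks the seed only through the shared drift
        assert abs(z_plain.data[1, 0, 0]) > 3.0
        assert abs(z_drift.data[1, 0, 0]) < abs(z_plain.data[1, 0, 0])


class TestRecovery:
    def test_coupled_regions_score_above_control(self, cohort, normalized, options):
        """Mean z in latent-coupled regions exceeds the non-coupled control
        region for every subject of the session cohort."""
        atlas = cohort["atlas"]
        model = SeedModel("SN_left")
        for sid, img in zip(cohort["table"].subjects[:8], normalized[:8]):
            _, zmap = seed_connectivity_subject(img, atlas, model, subject=sid)
            coupled = np.mean([zmap.data[atlas.region_mask(r)].mean()
                               for r in ("putamen_left", "putamen_right",
                                         "thalamus_left", "thalamus_right")])
            control = zmap.data[atlas.region_mask("caudate_left")].mean()
            assert coupled > control

    def test_voxel_recovery_auc(self, cohort, normalized, options):
        """Voxel z-scores discriminate planted coupled voxels from the rest."""
        from fpetdyn.synthio import STRIATO_NIGRO_THALAMIC

        atlas = cohort["atlas"]
        coupled = np.isin(
            atlas.labels,
            [atlas.label_of(r) for r in STRIATO_NIGRO_THALAMIC if r != "SN_left"],
        )
        other = atlas.brain_mask() & ~coupled & (atlas.labels != atlas.label_of("SN_left"))
        model = SeedModel("SN_left")
        for sid, img in zip(cohort["table"].subjects[:8], normalized[:8]):
            _, zmap = seed_connectivity_subject(img, atlas, model, subject=sid)
            scores = np.concatenate([zmap.data[coupled], zmap.data[other]])
            labels = np.concatenate([np.ones(coupled.sum()), np.zeros(other.sum())])
            assert rank_auc(scores, labels) >= 0.9


class TestDice:
    def test_identical_masks(self):
        m = np.zeros((3, 3, 3), bool)
        m[1] = True
        assert dice_coefficient(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((3, 3, 3), bool)
        b = np.zeros((3, 3, 3), bool)
        a[0], b[2] = True, True
        assert dice_coefficient(a, b) == 0.0

    def test_hand_count(self):
        a = np.zeros(10, bool)
        b = np.zeros(10, bool)
        a[:4] = True            # |A| = 4
        b[2:8] = True           # |B| = 6, overlap = 2
        assert dice_coefficient(a, b) == pytest.approx(0.4)

    def test_symmetry(self, rng):
        a = rng.random(50) > 0.5
        b = rng.random(50) > 0.5
        if not (a.any() or b.any()):
            a[0] = True
        assert dice_coefficient(a, b) == dice_coefficient(b, a)

    def test_both_empty_is_an_error(self):
        with pytest.raises(ValueError):
            dice_coefficient(np.zeros(5, bool), np.zeros(5, bool))


class TestGroupMap:
    def _maps(self, rng, n=8, shape=(5, 5, 2), effect=None):
        maps = []
        for _ in range(n):
            data = rng.normal(size=shape)
            if effect is not None:
                data[effect] += 3.0
            maps.append(StatMap(data, np.eye(4), kind="z"))
        return maps

    def test_identical_nonzero_maps_hit_p_floor(self, rng):
        base = np.abs(rng.normal(size=(5, 5, 2))) + 1.0
        maps = [StatMap(base.copy(), np.eye(4), kind="z") for _ in range(10)]
        tmap, clusters = group_map(maps, test="one_sample", n_perm=1100, seed=0)
        assert clusters.exhaustive
        assert clusters.table.p_fwe.min() == pytest.approx(
            1 / (clusters.n_perm + 1))
        # identical maps: guarded maximum at every in-mask voxel
        mask = ~np.isnan(tmap.data)
        assert np.all(tmap.data[mask] > 1e5)

    def test_mask_restricts_suprathreshold_voxels(self, rng):
        mask = np.zeros((5, 5, 2), bool)
        mask[:2] = True
        maps = self._maps(rng, effect=(slice(3, 5),))
        tmap, clusters = group_map(maps, test="one_sample", mask=mask,
                                   n_perm=200, seed=0)
        outside = ~mask
        assert np.all(np.isnan(tmap.data[outside]))
        assert clusters.label_map[outside].max(initial=0) == 0

    def test_two_sample_route(self, rng):
        maps = self._maps(rng, n=12, effect=(slice(0, 2),))
        for m in maps[6:]:
            m.data[0:2] -= 3.0          # remove effect in second group
        groups = np.array(["A"] * 6 + ["B"] * 6)
        tmap, clusters = group_map(maps, test="two_sample", groups=groups,
                                   n_perm=300, seed=0)
        assert tmap.kind == "t" and tmap.df == 10

    def test_needs_three_maps(self, rng):
        with pytest.raises(ValueError):
            group_map(self._maps(rng, n=2), test="one_sample")
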