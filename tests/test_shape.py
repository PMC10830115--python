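"""D2 shape signatures, feature models and PV correlations."""

import numpy as np
import pytest

from navmanifold.shape import (
    bimodality_coefficient,
    d2_distribution,
    dissimilarity,
    make_feature_model,
    pv_correlation,
)
from navmanifold.session import BinnedActivity, BehaviorSeries, TransformLedger
from oracles import brute_l1

import pandas as pd


class TestBimodality:
    def test_uniform_limit(self):
        u = np.random.default_rng(0).uniform(0, 1, 100_000)
        assert bimodality_coefficient(u) == pytest.approx(5 / 9, abs=0.02)

    def test_normal_limit(self):
        g = np.random.default_rng(1).standard_normal(100_000)
        assert bimodality_coefficient(g) == pytest.approx(1 / 3, abs=0.02)

    def test_bimodal_sample_exceeds_uniform_benchmark(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(-3, 0.5, 5000), rng.normal(3, 0.5, 5000)])
        assert bimodality_coefficient(x) > 5 / 9


class TestD2:
    def test_probabilities_normalized(self):
        pts = make_feature_model("sphere", 500, seed=0).points
        sig = d2_distribution(pts, apply_density_filter=False)
        assert sig.probs.sum() == pytest.approx(1.0)
        assert np.all(sig.probs >= 0)

    def test_rigid_motion_and_scale_invariance(self):
        from scipy.stats import ortho_group

        rng = np.random.default_rng(1)
        pts = rng.standard_normal((300, 3))
        q = ortho_group.rvs(3, random_state=2)
        moved = 5.3 * (pts @ q) + np.array([1.0, -2.0, 0.5])
        a = d2_distribution(pts, apply_density_filter=False)
        b = d2_distribution(moved, apply_density_filter=False)
        assert np.allclose(a.probs, b.probs, atol=1e-12)
        assert a.b == pytest.approx(b.b, abs=1e-9)

    def test_degenerate_equal_distances_rejected(self):
        # vertices of a regular simplex: all pairwise distances equal
        pts = np.vstack([np.eye(11)])
        with pytest.raises(ValueError):
            d2_distribution(pts, apply_density_filter=False)


class TestDissimilarity:
    def test_identity_and_symmetry(self):
        s = d2_distribution(make_feature_model("sphere", 800, 0).points,
                            apply_density_filter=False)
        f = d2_distribution(make_feature_model("figure8", 800, 0).points,
                            apply_density_filter=False)
        assert dissimilarity(s, s) == 0.0
        assert dissimilarity(s, f) == pytest.approx(dissimilarity(f, s))

    def test_disjoint_supports_reach_upper_bound(self):
        p = np.zeros(1200)
        q = np.zeros(1200)
        p[:100] = 1 / 100
        q[-100:] = 1 / 100
        assert dissimilarity(p, q) == pytest.approx(2.0)

    def test_matches_independent_l1_oracle(self):
        s = d2_distribution(make_feature_model("sphere", 2000, 0).points,
                            apply_density_filter=False)
        f = d2_distribution(make_feature_model("figure8", 2000, 0).points,
                            apply_density_filter=False)
        assert dissimilarity(s, f) == pytest.approx(brute_l1(s.probs, f.probs), abs=1e-12)

    def test_triangle_inequality(self):
        sigs = [d2_distribution(make_feature_model(k, 600, 0).points,
                                apply_density_filter=False)
                for k in ("sphere", "figure8", "bent_figure8")]
        a, b, c = (dissimilarity(sigs[0], sigs[1]), dissimilarity(sigs[1], sigs[2]),
                   dissimilarity(sigs[0], sigs[2]))
        assert c <= a + b + 1e-12

    def test_bin_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dissimilarity(np.zeros(1200), np.zeros(600))


class TestFeatureModels:
    def test_sphere_radius(self):
        pts = make_feature_model("sphere", 3000, seed=1).points
        r = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
        assert r.mean() == pytest.approx(1.0, rel=0.01)

    def test_figure8_has_two_rings(self):
        from navmanifold.topology import dominant_count, persistence_barcodes

        pts = make_feature_model("figure8", 1500, seed=0).points
        res = persistence_barcodes(pts, maxdim=1, n_landmarks=80, seed=0)
        assert dominant_count(res, 1) == 2

    def test_bent_and_planar_models_differ(self):
        f = d2_distribution(make_feature_model("figure8", 2000, 0).points,
                            apply_density_filter=False)
        b = d2_distribution(make_feature_model("bent_figure8", 2000, 0).points,
                            apply_density_filter=False)
        assert dissimilarity(f, b) > 0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_feature_model("torus_of_doom")

    @pytest.mark.parametrize("ratio", [0.2, 0.4])
    def test_tube_ratio_configurable(self, ratio):
        m = make_feature_model("figure8", 500, seed=0, tube_ratio=ratio)
        assert m.params["tube_ratio"] == ratio


def _behavior_frame(n, u, turn):
    return BehaviorSeries(frame=pd.DataFrame({
        "t_s": np.arange(n) * 0.512, "x_cm": 0.0, "y_cm": 0.0, "speed_cms": 10.0,
        "u": u, "turn": turn, "hd_rad": 0.0, "trial": 0,
        "in_box": False, "in_reward": False,
    }))


class TestPVCorrelation:
    def test_identical_maps_give_unit_correlation(self):
        rng = np.random.default_rng(0)
        n = 400
        u = rng.uniform(0, 1, n)
        turn = np.array(["L", "R"] * (n // 2), dtype=object)
        # rates depend only on u, identically for both turns
        rates = np.stack([np.sin(2 * np.pi * u * (i + 1)) + 2 for i in range(6)], axis=1)
        binned = BinnedActivity(edges=np.arange(n + 1) * 0.512, rates=rates,
                                unit_ids=np.arange(6), ledger=TransformLedger(sqrt=True))
        pv = pv_correlation(binned, _behavior_frame(n, u, turn), n_position_bins=20)
        # small within-bin sampling differences keep r just below 1
        assert np.nanmin(pv["pv_r"]) > 0.85
        assert np.nanmedian(pv["pv_r"]) > 0.97

    def test_independent_maps_give_near_zero(self):
        rng = np.random.default_rng(1)
        n = 2000
        u = rng.uniform(0, 1, n)
        turn = np.where(rng.random(n) < 0.5, "L", "R").astype(object)
        rates = rng.random((n, 40))
        binned = BinnedActivity(edges=np.arange(n + 1) * 0.512, rates=rates,
                                unit_ids=np.arange(40), ledger=TransformLedger(sqrt=True))
        pv = pv_correlation(binned, _behavior_frame(n, u, turn), n_position_bins=10)
        assert abs(np.nanmean(pv["pv_r"])) < 0.15

    def test_sub_more_congruent_than_ca1(self, sub_session, ca1_session):
        r = {}
        for name, data in [("sub", sub_session), ("ca1", ca1_session)]:
            pv = pv_correlation(data["binned"], data["behavior"])
            r[name] = np.nanmean(pv.attrs["arm_r"])
        assert r["sub"] > r["ca1"]
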