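import numpy as np
import pytest

from helpers import rank1_dvh_family
from kbplan.core_grid import StructureMask, VoxelGrid
from kbplan.curve_embedding import fit_embedding
from kbplan.dvh_model import (
    DVHModel,
    FeatureVector,
    TrainConfig,
    build_features,
    default_dth_grid,
    flag_suboptimal,
    predict,
    select_features,
    train,
)
from kbplan.histograms import CumulativeCurve, compute_dth, resample_curve


def make_feature(t, extra_scores=(), t_stage="T2"):
    return FeatureVector(
        oar_volume_cc=10.0,
        target_volume_cc=40.0,
        overlap_fraction=0.0,
        oar_to_body_fraction=0.01,
        dth_scores=np.array([t, *extra_scores]),
        t_stage=t_stage,
        prescription_gy=70.0,
    )


@pytest.fixture
def linear_cohort():
    """Rank-1 DVH family whose single curve score is affine in the lone
    varying feature (dth_score_1)."""
    rng = np.random.default_rng(42)
    ts = rng.uniform(0.0, 1.0, size=80)
    curves = rank1_dvh_family(ts)
    feats = [make_feature(t) for t in ts]
    return list(zip(feats, curves)), ts


class TestBuildFeatures:
    @pytest.fixture
    def geometry(self, rng):
        grid = VoxelGrid(shape=(20, 20, 20), spacing=(2.0, 2.0, 2.0))
        target = np.zeros(grid.shape, bool)
        target[6:13, 6:13, 6:13] = True
        body = StructureMask(grid, np.ones(grid.shape, bool), "body", role="external")
        tm = StructureMask(grid, target, "ptv", role="target")
        # simple embedding fitted on two real DTH curves
        oar1 = np.zeros(grid.shape, bool)
        oar1[14:17, 6:9, 6:9] = True
        oar2 = np.zeros(grid.shape, bool)
        oar2[16:19, 14:17, 14:17] = True
        dgrid = default_dth_grid()
        curves = [
            resample_curve(compute_dth(StructureMask(grid, o, "o"), tm), dgrid)
            for o in (oar1, oar2)
        ]
        emb = fit_embedding(curves)
        return grid, tm, body, emb

    def test_overlap_containment_and_disjoint(self, geometry):
        grid, tm, body, emb = geometry
        inside = np.zeros(grid.shape, bool)
        inside[8:11, 8:11, 8:11] = True
        fv = build_features(StructureMask(grid, inside, "in"), [tm], body, emb)
        assert fv.overlap_fraction == pytest.approx(1.0)
        outside = np.zeros(grid.shape, bool)
        outside[15:18, 15:18, 15:18] = True
        fv2 = build_features(StructureMask(grid, outside, "out"), [tm], body, emb)
        assert fv2.overlap_fraction == pytest.approx(0.0)

    def test_overlap_matches_bruteforce_count(self, geometry, rng):
        grid, tm, body, emb = geometry
        occ = rng.random(grid.shape) < 0.3
        fv = build_features(StructureMask(grid, occ, "r"), [tm], body, emb)
        expect = np.sum(occ & tm.occupancy) / np.sum(occ)
        assert fv.overlap_fraction == pytest.approx(expect)

    def test_empty_oar_raises(self, geometry):
        grid, tm, body, emb = geometry
        with pytest.raises(ValueError, match="empty"):
            build_features(
                StructureMask(grid, np.zeros(grid.shape, bool), "e"), [tm], body, emb
            )


class TestSelectFeatures:
    def _features(self, rng, n):
        return [
            FeatureVector(
                oar_volume_cc=rng.uniform(5, 50),
                target_volume_cc=rng.uniform(20, 200),
                overlap_fraction=rng.uniform(0, 1),
                oar_to_body_fraction=rng.uniform(0, 0.1),
                dth_scores=rng.normal(size=2),
            )
            for _ in range(n)
        ]

    def test_pure_linear_driver_is_selected(self, rng):
        feats = self._features(rng, 120)
        response = np.array([[3.0 * f.overlap_fraction] for f in feats])
        (chosen,) = select_features(feats, response)
        assert "overlap_fraction" in chosen

    def test_single_perfect_feature_forced_selection(self, rng):
        feats = self._features(rng, 40)
        response = np.array([[2.0 * f.dth_scores[0]] for f in feats])
        (chosen,) = select_features(feats, response, alpha=1e-300)
        # alpha so extreme nothing passes; the best feature is still kept
        assert chosen == ["dth_score_1"]

    def test_false_selection_rate_near_alpha(self):
        # response independent of all features: per-feature selection rate
        # of the significance screen should approximate alpha
        rng = np.random.default_rng(123)
        feats = self._features(rng, 200)
        n_feat = len(feats[0].names())
        reps, hits = 2000, 0
        for _ in range(reps):
            response = rng.normal(size=(200, 1))
            (chosen,) = select_features(feats, response, alpha=0.05, force_nonempty=False)
            hits += len(chosen)
        rate = hits / (reps * n_feat)
        assert rate == pytest.approx(0.05, abs=0.03)

    def test_too_few_cases_raise(self, rng):
        feats = self._features(rng, 5)
        with pytest.raises(ValueError, match="10"):
            select_features(feats, np.zeros((5, 1)))


class TestTrainPredict:
    def test_constant_curves_give_constant_prediction_and_zero_band(self):
        curves = rank1_dvh_family([0.5] * 12)
        cases = [(make_feature(t), c) for t, c in zip(np.linspace(0, 1, 12), curves)]
        model = train(cases)
        pred = predict(model, make_feature(0.77))
        target = resample_curve(curves[0], pred.mean.abscissa)
        assert np.allclose(pred.mean.ordinate, target.ordinate, atol=1e-6)
        assert np.allclose(pred.upper95.ordinate, pred.lower95.ordinate, atol=1e-6)

    def test_noiseless_linear_recovery(self, linear_cohort):
        cases, ts = linear_cohort
        model = train(cases[:60])
        emb = model.dvh_embedding
        from kbplan.curve_embedding import project

        errs = []
        for fv, planned in cases[60:]:
            rel = resample_curve(planned, emb.abscissa * fv.prescription_gy)
            true_score = project(
                emb,
                CumulativeCurve(abscissa=emb.abscissa, ordinate=rel.ordinate, kind="dvh"),
            )[0]
            r = model.regressors[0]
            pred_score = r.predict_one(
                np.array([dict(zip(fv.names(), fv.values()))[n] for n in r.feature_names])
            )
            errs.append((true_score - pred_score) / r.y_sd)
        rmse = float(np.sqrt(np.mean(np.square(errs))))
        assert rmse <= model.config.svr_epsilon + 0.01

    def test_training_order_invariance(self, linear_cohort, rng):
        cases, _ = linear_cohort
        cases = cases[:30]
        m1 = train(cases)
        perm = rng.permutation(len(cases))
        m2 = train([cases[i] for i in perm])
        probe = make_feature(0.3)
        p1, p2 = predict(m1, probe), predict(m2, probe)
        assert np.allclose(p1.mean.ordinate, p2.mean.ordinate, atol=1e-9)
        assert np.allclose(p1.upper95.ordinate, p2.upper95.ordinate, atol=1e-9)

    def test_too_few_cases_error_names_minimum(self):
        cases = [(make_feature(t), c) for t, c in zip([0.1, 0.9], rank1_dvh_family([0.1, 0.9]))]
        with pytest.raises(ValueError, match="10"):
            train(cases)

    def test_band_ordering_holds_for_arbitrary_inputs(self, linear_cohort):
        cases, _ = linear_cohort
        model = train(cases[:40])
        for t in (-0.5, 0.0, 0.31, 0.99, 2.0):
            pred = predict(model, make_feature(t))
            assert np.all(pred.lower95.ordinate <= pred.mean.ordinate + 1e-9)
            assert np.all(pred.mean.ordinate <= pred.upper95.ordinate + 1e-9)

    def test_missing_selected_feature_is_named(self, linear_cohort):
        cases, _ = linear_cohort
        model = train(cases[:40])
        lonely = FeatureVector(
            oar_volume_cc=10.0,
            target_volume_cc=40.0,
            overlap_fraction=0.0,
            oar_to_body_fraction=0.01,
            dth_scores=np.array([]),  # no DTH scores at all
        )
        with pytest.raises(ValueError, match="dth_score_1"):
            predict(model, lonely)

    def test_json_round_trip_preserves_predictions(self, linear_cohort):
        cases, _ = linear_cohort
        model = train(cases[:40])
        back = DVHModel.from_json(model.to_json())
        for t in (0.1, 0.5, 0.9):
            a, b = predict(model, make_feature(t)), predict(back, make_feature(t))
            assert np.allclose(a.mean.ordinate, b.mean.ordinate, atol=1e-9)
            assert np.allclose(a.lower95.ordinate, b.lower95.ordinate, atol=1e-9)
            assert np.allclose(a.upper95.ordinate, b.upper95.ordinate, atol=1e-9)

    def test_round_trip_error_within_band_for_most_training_cases(self, linear_cohort):
        cases, _ = linear_cohort
        model = train(cases[:60])
        ok = 0
        for fv, planned in cases[:60]:
            pred = predict(model, fv)
            pl = resample_curve(planned, pred.mean.abscissa)
            half_width = (pred.upper95.ordinate - pred.lower95.ordinate) / 2.0
            if np.mean(np.abs(pl.ordinate - pred.mean.ordinate)) <= max(
                half_width.mean(), 1e-6
            ):
                ok += 1
        assert ok >= 0.9 * 60


class TestFlagSuboptimal:
    def test_plan_at_predicted_mean_is_not_flagged(self, linear_cohort):
        cases, _ = linear_cohort
        model = train(cases[:40])
        fv = make_feature(0.5)
        pred = predict(model, fv)
        assert flag_suboptimal(model, [(fv, pred.mean)]) == []

    def test_plan_far_above_upper_band_is_flagged(self, linear_cohort):
        cases, _ = linear_cohort
        model = train(cases[:40])
        fv = make_feature(0.5)
        pred = predict(model, fv)
        hot = CumulativeCurve(
            abscissa=pred.upper95.abscissa,
            ordinate=np.maximum.accumulate(
                np.clip(pred.upper95.ordinate + 10.0, 0, 100)[::-1]
            )[::-1],
            kind="dvh",
        )
        assert flag_suboptimal(model, [(fv, hot)], case_ids=["hot"]) == ["hot"]
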