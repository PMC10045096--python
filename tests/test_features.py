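"""Feature assembly: phase-summary PCAs, composite-index scores, pipeline
round trips, and leak-free projection of new subjects."""

import numpy as np
import pytest

from gaitdx import (
    GaitdxError,
    FeaturePipelineModel,
    PhaseConvention,
    assemble_features,
    build_characteristic_matrix,
    cohort_pointwise_ttests,
    composite_index_features,
    pca_fit,
    pca_transform,
    phase_mean_features,
    project_cohort,
    project_subject,
    select_characteristic_points,
    split_phases,
)
from gaitdx.errors import GaitdxWarning
from gaitdx.features import PHASE_FEATURE_NAMES
from gaitdx.preprocess import ProcessedWaveforms
from gaitdx.signals import MUSCLES, SIGNALS


def _clone_with_values(pw, values, sid):
    return ProcessedWaveforms(sid, pw.group, pw.leg, values)


class TestPhaseMeanFeatures:
    def test_identical_subjects_give_zero_scores(self, small_cohort):
        base = small_cohort[0]
        cohort = [_clone_with_values(base, base.values, f"s{i}") for i in range(5)]
        cols, _ = phase_mean_features(cohort, PhaseConvention())
        np.testing.assert_allclose(cols, 0.0, atol=1e-10)

    def test_two_archetypes_symmetric_scores(self, small_cohort):
        a, b = small_cohort[0], small_cohort[-1]
        cohort = [
            _clone_with_values(a, a.values, "a1"),
            _clone_with_values(b, b.values, "b1"),
            _clone_with_values(a, a.values, "a2"),
            _clone_with_values(b, b.values, "b2"),
        ]
        cols, _ = phase_mean_features(cohort, PhaseConvention())
        for j in range(3):
            vals = np.unique(np.round(cols[:, j], 10))
            assert len(vals) <= 2
            assert abs(vals.sum()) < 1e-9  # symmetric about 0

    def test_matches_independent_composition_oracle(self, small_cohort):
        conv = PhaseConvention()
        cols, models = phase_mean_features(small_cohort, conv)
        # independent script: build each block by hand, PCA it, take score 1
        stance = np.array([
            [split_phases(pw.signal(m), conv)[0].mean() for m in MUSCLES]
            for pw in small_cohort
        ])
        swing = np.array([
            [split_phases(pw.signal(m), conv)[1].mean() for m in MUSCLES]
            for pw in small_cohort
        ])
        flex = np.array([
            split_phases(pw.signal("knee_flexion"), conv)[1] for pw in small_cohort
        ])
        for j, block in enumerate([stance, swing, flex]):
            oracle = pca_transform(pca_fit(block), block, k=1)[:, 0]
            np.testing.assert_allclose(cols[:, j], oracle, atol=1e-10)

    def test_single_subject_rejected(self, small_cohort):
        with pytest.raises(GaitdxError):
            phase_mean_features(small_cohort[:1], PhaseConvention())


class TestCompositeIndexFeatures:
    def _charmatrix(self, cohort):
        pts = select_characteristic_points(cohort_pointwise_ttests(cohort))
        return build_characteristic_matrix(cohort, pts)

    def test_rank_one_matrix_retains_single_component(self, small_cohort, rng):
        m = self._charmatrix(small_cohort)
        x = rng.normal(size=len(small_cohort))
        m.values = np.outer(x, [1.0, 2.0, -0.5])
        m.points = m.points[:3]
        _, _, k = composite_index_features(m, info_fraction=0.90)
        assert k == 1

    def test_k_zero_gives_empty_block(self, small_cohort):
        scores, model, k = composite_index_features(self._charmatrix(small_cohort), k=0)
        assert scores.shape == (len(small_cohort), 0) and k == 0 and model is None

    def test_matches_pca_oracle(self, small_cohort):
        m = self._charmatrix(small_cohort)
        k = min(3, m.values.shape[1])
        scores, model, k_eff = composite_index_features(m, k=k)
        oracle = pca_transform(pca_fit(m.values), m.values, k=k)
        np.testing.assert_allclose(scores, oracle, atol=1e-10)
        assert k_eff == k

    def test_k_clipped_with_warning(self, small_cohort):
        m = self._charmatrix(small_cohort)
        with pytest.warns(GaitdxWarning):
            _, _, k = composite_index_features(m, k=m.values.shape[1] + 5)
        assert k == m.values.shape[1]


class TestAssembleFeatures:
    @pytest.mark.parametrize(
        "mode, k, expected_cols",
        [("full", 3, 6), ("composite_only", 8, 8), ("full", 0, 3)],
    )
    def test_feature_counts(self, small_cohort, mode, k, expected_cols):
        table, model = assemble_features(small_cohort, k=k, mode=mode)
        n_features = len([c for c in table.columns if c != "group"])
        n_phase = 3 if mode == "full" else 0
        # k clips to the available characteristic points
        assert n_features == n_phase + min(k, len(model.points))
        if len(model.points) >= k:
            assert n_features == expected_cols

    def test_training_columns_centered(self, small_cohort):
        table, _ = assemble_features(small_cohort, k=3)
        feats = table.drop(columns="group")
        np.testing.assert_allclose(feats.mean(axis=0), 0.0, atol=1e-10)

    def test_single_group_rejected(self, small_cohort):
        acld_only = [pw for pw in small_cohort if pw.group == "ACLD"]
        with pytest.raises(GaitdxError):
            assemble_features(acld_only)

    def test_feature_order_matches_published_layout(self, small_cohort):
        table, _ = assemble_features(small_cohort, k=3)
        assert list(table.columns) == [
            "mean_stance_force",
            "mean_swing_force",
            "knee_flexion_swing",
            "CI_1",
            "CI_2",
            "CI_3",
            "group",
        ]


class TestProjectSubject:
    def test_training_round_trip(self, small_cohort):
        table, model = assemble_features(small_cohort, k=3)
        feats = table.drop(columns="group").to_numpy()
        for i, pw in enumerate(small_cohort):
            np.testing.assert_allclose(
                project_subject(model, pw), feats[i], atol=1e-10
            )

    def test_column_mean_subject_maps_to_zero_composite(self, small_cohort):
        _, model = assemble_features(small_cohort, k=3, mode="composite_only")
        base = small_cohort[0]
        values = base.values.copy()
        for j, pt in enumerate(model.points):
            values[SIGNALS.index(pt.signal), pt.percent] = (
                model.composite_model.column_means[j]
            )
        subject = _clone_with_values(base, values, "mean_subject")
        np.testing.assert_allclose(project_subject(model, subject), 0.0, atol=1e-10)

    def test_held_out_subject_matches_matrix_arithmetic_oracle(self, small_cohort):
        train, held_out = small_cohort[:-1], small_cohort[-1]
        _, model = assemble_features(train, k=2)
        got = project_subject(model, held_out)
        # oracle: hand-composed centered-times-loadings arithmetic
        conv = model.convention
        expected = []
        blocks = {
            "mean_stance_force": np.array(
                [split_phases(held_out.signal(m), conv)[0].mean() for m in MUSCLES]
            ),
            "mean_swing_force": np.array(
                [split_phases(held_out.signal(m), conv)[1].mean() for m in MUSCLES]
            ),
            "knee_flexion_swing": split_phases(
                held_out.signal("knee_flexion"), conv
            )[1],
        }
        for name in PHASE_FEATURE_NAMES:
            pm = model.phase_models[name]
            expected.append(
                float((blocks[name] - pm.column_means) @ pm.loadings[:, 0])
            )
        row = np.array(
            [held_out.signal(p.signal)[p.percent] for p in model.points]
        )
        cm = model.composite_model
        expected.extend((row - cm.column_means) @ cm.loadings[:, : model.k_composite])
        np.testing.assert_allclose(got, np.asarray(expected), atol=1e-10)

    def test_pipeline_model_json_round_trip(self, small_cohort):
        table, model = assemble_features(small_cohort, k=2)
        restored = FeaturePipelineModel.from_json(model.to_json())
        restored_table = project_cohort(restored, small_cohort)
        np.testing.assert_allclose(
            restored_table.drop(columns="group").to_numpy(),
            table.drop(columns="group").to_numpy(),
            atol=1e-12,
        )
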