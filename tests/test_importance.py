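import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from msadx.encoding import build_codebook, encode_cohort, fit_normalization
from msadx.importance import (
    DEFAULT_COMPONENT_MAP,
    assign_components,
    feature_importance,
    importance_scores,
    important_features,
    median_weights,
    samplewise_scores,
    top_fraction_mask,
)
from msadx.pwl import PWLConfig, forward, train
from msadx.synthcohort import (
    BinarySpec,
    CategoricalSpec,
    CohortSpec,
    OrdinalSpec,
    default_profiles,
    generate_cohort,
)


class TestSamplewiseScores:
    def test_hand_example(self):
        s = samplewise_scores(np.array([[-3.0, 0.5]]), np.array([[1.0, -2.0]]))
        np.testing.assert_array_equal(s, [[3.0, 1.0]])

    def test_zero_weights_give_zero_row(self):
        s = samplewise_scores(np.zeros((2, 4)), np.ones((2, 4)))
        assert (s == 0).all()

    def test_sign_flips_leave_scores_unchanged(self):
        rng = np.random.default_rng(0)
        w, x = rng.standard_normal((5, 6)), rng.standard_normal((5, 6))
        base = samplewise_scores(w, x)
        np.testing.assert_array_equal(samplewise_scores(-w, x), base)
        np.testing.assert_array_equal(samplewise_scores(w, -x), base)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError, match="shape"):
            samplewise_scores(np.zeros((2, 3)), np.zeros((3, 2)))

    def test_scale_equivariance_of_column_rescaling(self):
        rng = np.random.default_rng(1)
        w, x = rng.standard_normal((8, 5)), rng.standard_normal((8, 5))
        w2, x2 = w.copy(), x.copy()
        x2[:, 2] *= 10.0
        w2[:, 2] /= 10.0
        np.testing.assert_allclose(samplewise_scores(w2, x2),
                                   samplewise_scores(w, x), atol=1e-12)


class TestTopFractionMask:
    @pytest.mark.parametrize("d,m", [(126, 13), (58, 6), (10, 1), (3, 1)])
    def test_ceil_cardinality(self, d, m):
        assert top_fraction_mask(np.arange(d, dtype=float)).sum() == m
        assert m == math.ceil(0.1 * d)

    def test_ties_break_toward_lower_index(self):
        mask = top_fraction_mask(np.ones(10), fraction=0.1)
        assert mask[0] and not mask[1:].any()

    def test_selects_the_largest(self):
        mask = top_fraction_mask(np.array([1.0, 9.0, 3.0, 8.0, 2.0]), 0.4)
        np.testing.assert_array_equal(mask, [False, True, False, True, False])

    def test_empty_row_errors(self):
        with pytest.raises(ValueError):
            top_fraction_mask(np.array([]))

    def test_bad_fraction_errors(self):
        with pytest.raises(ValueError):
            top_fraction_mask(np.ones(5), fraction=0.0)


def _brute_rates(S, fraction):
    n, d = S.shape
    m = math.ceil(fraction * d)
    counts = np.zeros(d)
    for row in S:
        # stable descending sort; ties toward lower index
        order = sorted(range(d), key=lambda k: (-row[k], k))
        for k in order[:m]:
            counts[k] += 1
    return counts / n


class TestImportanceScores:
    def test_always_in_top_set_scores_one(self):
        S = np.zeros((5, 10))
        S[:, 7] = 1.0
        assert importance_scores(S)[7] == 1.0

    def test_never_in_top_set_scores_zero(self):
        S = np.random.default_rng(0).random((20, 10)) + 1.0
        S[:, 4] = 0.0
        assert importance_scores(S, fraction=0.5)[4] == 0.0

    def test_toy_matrix_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        S = rng.choice([0.0, 0.5, 1.0, 2.0], size=(4, 5))
        np.testing.assert_allclose(importance_scores(S, 0.5),
                                   _brute_rates(S, 0.5), atol=1e-15)

    def test_random_matrices_match_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n, d = rng.integers(1, 8), rng.integers(2, 12)
            S = rng.choice([0.0, 0.1, 0.3, 0.3, 0.9], size=(n, d))
            frac = rng.choice([0.1, 0.25, 0.5, 1.0])
            np.testing.assert_allclose(importance_scores(S, frac),
                                       _brute_rates(S, frac), atol=1e-15)

    def test_membership_mass_is_exactly_m_per_sample(self):
        rng = np.random.default_rng(5)
        S = rng.random((30, 17))
        rates = importance_scores(S, 0.1)
        assert rates.sum() * 30 == pytest.approx(math.ceil(1.7) * 30)

    def test_rates_monotone_in_fraction(self):
        rng = np.random.default_rng(6)
        S = rng.random((12, 9))
        prev = np.zeros(9)
        for frac in (0.1, 0.3, 0.6, 1.0):
            r = importance_scores(S, frac)
            assert (r >= prev - 1e-15).all()
            prev = r


class TestMedianWeights:
    def test_constant_column(self):
        assert median_weights(np.full((5, 2), 3.5))[0] == 3.5

    def test_odd_count_median(self):
        assert median_weights(np.array([[-1.0], [0.0], [5.0]]))[0] == 0.0

    def test_even_count_matches_sort_oracle(self):
        rng = np.random.default_rng(7)
        W = rng.standard_normal((6, 3))
        med = median_weights(W)
        for k in range(3):
            srt = np.sort(W[:, k])
            assert med[k] == pytest.approx((srt[2] + srt[3]) / 2, abs=1e-15)


class TestImportantFeatures:
    def _records(self, scores):
        return pd.DataFrame({"feature": [f"f{i}" for i in range(len(scores))],
                             "score": scores,
                             "median_weight": np.zeros(len(scores))})

    def test_all_below_threshold_empty(self):
        assert len(important_features(self._records([0.1, 0.29, 0.0]))) == 0

    def test_inclusive_threshold_and_order(self):
        out = important_features(self._records([0.30, 0.80, 0.299]))
        assert list(out["feature"]) == ["f1", "f0"]
        assert list(out["rank"]) == [1, 2]

    def test_ties_keep_codebook_order(self):
        out = important_features(self._records([0.5, 0.9, 0.5]))
        assert list(out["feature"]) == ["f1", "f0", "f2"]


class TestAssignComponents:
    def test_clinical_component_attribution(self, matrix_b):
        cb = matrix_b.codebook
        recs = pd.DataFrame({
            "feature": ["oth_respiratory_failure", "img_striatal_abnormality",
                        "neuro_finger_to_nose=3", "oth_dementia"],
            "score": [0.8, 0.7, 0.6, 0.5],
            "median_weight": [-0.12, 0.13, 0.06, 0.01],
        })
        out = assign_components(recs, cb)
        comp = dict(zip(out["feature"], out["component"]))
        assert comp["oth_respiratory_failure"] == "A"
        assert comp["img_striatal_abnormality"] == "P"
        assert comp["neuro_finger_to_nose=3"] == "C"
        assert comp["oth_dementia"] == "unassigned"

    def test_sign_labels_follow_encoding_direction(self, matrix_a):
        cb = matrix_a.codebook
        recs = pd.DataFrame({
            # absence-coded binary: negative weight = presence favours class
            "feature": ["oth_respiratory_failure", "auto_syncope",
                        "neuro_finger_to_nose"],
            "score": [0.8, 0.7, 0.9],
            "median_weight": [-0.122, 0.05, 0.06],
        })
        out = assign_components(recs, cb)
        signs = dict(zip(out["feature"], out["sign"]))
        assert signs["oth_respiratory_failure"] == "P"  # strong (negative, B)
        assert signs["auto_syncope"] == "N"             # weak (positive, B)
        assert signs["neuro_finger_to_nose"] == "P"     # strong (positive, O)


PLANTED = {
    "SND": ["oth_dementia", "img_cerebral_atrophy", "auto_syncope"],
    "SDS": ["oth_respiratory_failure", "auto_head_up_tilt",
            "img_white_matter_lesion"],
    "OPCA": ["onset_ataxia", "img_cerebellar_atrophy", "oth_nystagmus"],
}


def _planted_profiles():
    """Flat cohort except three high-contrast binary markers per subtype."""
    profiles = {}
    for lab, prof in default_profiles().items():
        binaries = []
        for s in prof.binary_specs:
            owner = [k for k, v in PLANTED.items() if s.item_id in v]
            p = (0.9 if owner and owner[0] == lab else
                 0.05 if owner else 0.3)
            binaries.append(BinarySpec(s.item_id, p))
        ordinals = tuple(OrdinalSpec(s.item_id, s.lo, s.hi,
                                     (s.lo + s.hi) / 2, 1.0)
                         for s in prof.ordinal_specs)
        cats = tuple(CategoricalSpec(c.item_id, c.levels,
                                     tuple(np.ones(len(c.levels))
                                           / len(c.levels)))
                     for c in prof.categorical_specs)
        profiles[lab] = replace(prof, p_male=0.5, age_mean=65.0, age_sd=9.0,
                                binary_specs=tuple(binaries),
                                ordinal_specs=ordinals,
                                categorical_specs=cats)
    return profiles


class TestPlantedFeatureRecovery:
    def test_planted_markers_rank_in_top_eight(self):
        cohort = generate_cohort(
            CohortSpec(n={"SND": 200, "SDS": 200, "OPCA": 200},
                       missingness_rate=0.0, seed=7),
            _planted_profiles())
        cb = build_codebook("a")
        m = encode_cohort(cohort, cb, fit_normalization(cohort, cb))
        cfg = PWLConfig(n_epochs=40, n_inner_layers=4, layer_size=64,
                        learning_rate=1e-3, seed=3)
        pred = forward(train(m, cfg), m.values)
        for ci, lab in enumerate(("SND", "SDS", "OPCA")):
            imp = feature_importance(pred.weights[:, ci, :], m.values, cb)
            top8 = set(imp.sort_values("score", ascending=False,
                                       kind="stable")["feature"].head(8))
            assert set(PLANTED[lab]) <= top8, lab

    def test_weight_population_options(self, matrix_a, tiny_cfg):
        pred = forward(train(matrix_a, tiny_cfg), matrix_a.values)
        all_pop = feature_importance(pred.weights[:, 0, :], matrix_a.values,
                                     matrix_a.codebook,
                                     weight_population="all")
        topset = feature_importance(pred.weights[:, 0, :], matrix_a.values,
                                    matrix_a.codebook,
                                    weight_population="topset")
        assert (all_pop["score"] == topset["score"]).all()
        assert len(all_pop) == 58
        with pytest.raises(ValueError):
            feature_importance(pred.weights[:, 0, :], matrix_a.values,
                               matrix_a.codebook, weight_population="bogus")
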