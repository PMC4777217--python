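"""Unit tests for normalization, Hill fitting, curve ranking and
reproducibility scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import toxprofiler as tp
from toxprofiler.qhts import (
    DegenerateControlsError,
    fit_titration,
    score_grade,
    summarize_assay_repro,
)


class TestNormalizeActivity:
    def test_control_anchors_agonist(self):
        assert tp.normalize_activity(1000.0, 5000.0, 1000.0, "agonist") == 0.0
        assert tp.normalize_activity(5000.0, 5000.0, 1000.0, "agonist") == 100.0
        assert tp.normalize_activity(3000.0, 5000.0, 1000.0, "agonist") == 50.0

    def test_control_anchors_antagonist(self):
        # DMSO maps to -100%, positive control to 0%
        assert tp.normalize_activity(1000.0, 5000.0, 1000.0, "antagonist") == -100.0
        assert tp.normalize_activity(5000.0, 5000.0, 1000.0, "antagonist") == 0.0

    def test_degenerate_controls_raise(self):
        with pytest.raises(DegenerateControlsError):
            tp.normalize_activity(1.0, 2.0, 2.0)

    @settings(max_examples=50, deadline=None)
    @given(
        raw=st.floats(-1e3, 1e3),
        scale=st.floats(0.01, 100.0),
        shift=st.floats(-1e3, 1e3),
    )
    def test_affine_invariance(self, raw, scale, shift):
        """Rescaling and shifting all raw signals leaves % activity unchanged."""
        base = tp.normalize_activity(raw, 5000.0, 1000.0)
        moved = tp.normalize_activity(
            raw * scale + shift, 5000.0 * scale + shift, 1000.0 * scale + shift
        )
        assert moved == pytest.approx(base, abs=1e-6)


class TestPlateCorrection:
    def test_zero_controls_identity(self, rng):
        plate = rng.normal(size=(4, 4))
        out = tp.correct_plate_pattern(plate, [np.zeros((4, 4))] * 2)
        np.testing.assert_allclose(out, plate)

    def test_plate_equal_to_control_mean_zeroes(self, rng):
        c1, c2 = rng.normal(size=(4, 4)), rng.normal(size=(4, 4))
        out = tp.correct_plate_pattern((c1 + c2) / 2, [c1, c2])
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_hot_column_subtracted(self):
        # hand-computed 4x4: controls carry a +7 artefact in column 2
        control = np.zeros((4, 4))
        control[:, 2] = 7.0
        plate = np.full((4, 4), 10.0)
        out = tp.correct_plate_pattern(plate, [control, control])
        expected = np.full((4, 4), 10.0)
        expected[:, 2] = 3.0
        np.testing.assert_allclose(out, expected)

    def test_no_controls_raises(self):
        with pytest.raises(ValueError):
            tp.correct_plate_pattern(np.zeros((2, 2)), [])


class TestFitHill:
    def test_noise_free_recovery(self, clean_titration):
        fit = fit_titration(clean_titration)
        assert fit.ac50 == pytest.approx(1e-6, rel=0.01)
        assert fit.efficacy == pytest.approx(80.0, rel=0.01)
        assert fit.r2 > 0.999

    def test_constant_responses_unfit(self):
        conc = np.logspace(-9, -4, 8)
        fit = tp.fit_hill(conc, np.full(8, 5.0))
        assert not fit.converged
        assert fit.efficacy == 0.0

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            tp.fit_hill([1e-9, 1e-8, 1e-7], [0, 1, 2])

    def test_noisy_recovery_within_threefold(self):
        """At 5% noise, AC50 within 3-fold of truth in >= 95% of fits."""
        ok = 0
        n = 200
        for s in range(n):
            tit = tp.generate_plate_set(
                1e-6, 80.0, 1.0, noise_sd=5.0, seed=s
            )[0]
            fit = fit_titration(tit)
            if np.isfinite(fit.ac50) and 1 / 3 <= fit.ac50 / 1e-6 <= 3:
                ok += 1
        assert ok / n >= 0.95


class TestClassifyAndRank:
    def _fit(self, ac50=1e-5, eff=90.0, slope=1.0, r2=0.95, baseline=0.0):
        return tp.CurveFit(ac50=ac50, efficacy=eff, hill_slope=slope,
                           baseline=baseline, r2=r2)

    def test_zero_efficacy_inactive(self):
        out = tp.classify_and_rank(self._fit(eff=0.0), np.zeros(8))
        assert out.curve_class == "4"
        assert out.curve_rank == 0

    def test_potent_complete_activator_rank9(self):
        # complete curve, efficacy 90%, AC50 10 nM -> class 1.1, rank +9
        out = tp.classify_and_rank(
            self._fit(ac50=1e-8, eff=90.0), np.linspace(0, 90, 15),
            top_conc=1e-4,
        )
        assert out.curve_class == "1.1"
        assert out.curve_rank == 9

    def test_incomplete_weak_inhibitor_rank_minus3(self):
        # incomplete inhibition, efficacy -40% with threshold 30 -> 2.2, -3
        out = tp.classify_and_rank(
            self._fit(ac50=5e-5, eff=-40.0), np.linspace(0, -27, 15),
            efficacy_threshold=30.0, top_conc=1e-4,
        )
        assert out.curve_class == "2.2"
        assert out.curve_rank == -3

    def test_single_point_activity_class3(self):
        resp = np.zeros(15)
        resp[-1] = 45.0
        out = tp.classify_and_rank(
            tp.CurveFit(ac50=float("nan"), efficacy=0.0, hill_slope=1.0,
                        baseline=0.0, r2=0.0, converged=False),
            resp,
        )
        assert out.curve_class == "3"
        assert out.curve_rank == 1

    def test_rank_zero_iff_class4(self):
        for eff, ac50 in [(0.0, 1e-5), (90.0, 1e-8), (-40.0, 5e-5), (35.0, 1e-5)]:
            out = tp.classify_and_rank(
                self._fit(eff=eff, ac50=ac50), np.linspace(0, eff or 1, 15),
                top_conc=1e-4,
            )
            assert (out.curve_rank == 0) == (out.curve_class == "4")

    def test_rank_magnitude_monotone_in_efficacy(self):
        """Raising |efficacy| (other things fixed) never lowers |rank|."""
        prev = 0
        for eff in [10.0, 35.0, 65.0, 95.0]:
            out = tp.classify_and_rank(
                self._fit(eff=eff), np.linspace(0, eff, 15), top_conc=1e-4
            )
            assert abs(out.curve_rank) >= prev
            prev = abs(out.curve_rank)


class TestReproCalls:
    @pytest.mark.parametrize(
        "ranks,expected",
        [
            ((5, 6, 5), "active_match"),
            ((0, 0, 0), "inactive_match"),
            ((7, 0, -6), "mismatch"),
            ((3, 3, 0), "mismatch"),          # active together with inactive
            ((5, -5, 4), "mismatch"),         # conflicting signs
            ((1, 2, 1), "inconclusive"),      # all marginal
            ((4, 4, 1), "active_match"),      # 2 active + 1 marginal
            ((0, 0, 2), "inconclusive"),      # 2 inactive + 1 marginal
        ],
    )
    def test_call_rule_table(self, ranks, expected):
        assert tp.call_reproducibility(ranks).call == expected

    def test_wrong_replicate_count(self):
        with pytest.raises(ValueError):
            tp.call_reproducibility([1, 2])

    def test_triplicate_pipeline_active_match(self):
        """Potent compound at low noise reproduces as an active match."""
        tits = tp.generate_plate_set(
            1e-7, 85.0, 1.0, noise_sd=2.0, n_replicates=3, seed=5
        )
        ranks = [fit_titration(t).curve_rank for t in tits]
        assert tp.call_reproducibility(ranks).call == "active_match"


class TestAssayScore:
    @pytest.mark.parametrize(
        "rates,expected",
        [
            ((11.10, 84.86, 4.04, 0.00), 103.02),
            ((23.92, 59.47, 16.50, 0.10), 90.61),
            ((0.0, 100.0, 0.0, 0.0), 100.0),
        ],
    )
    def test_score_formula(self, rates, expected):
        assert tp.assay_repro_score(*rates) == pytest.approx(expected, abs=1e-9)

    def test_grades(self):
        assert score_grade(95.0) == "A"
        assert score_grade(85.0) == "B"
        assert score_grade(75.0) == "C"

    def test_summarize_counts(self):
        calls = [tp.call_reproducibility(r) for r in
                 [(5, 5, 5), (0, 0, 0), (0, 0, 0), (7, 0, -6)]]
        s = summarize_assay_repro(calls)
        assert s.pct_active_match == 25.0
        assert s.pct_inactive_match == 50.0
        assert s.pct_mismatch == 25.0
        assert s.score == pytest.approx(2 * 25 + 50 - 0 - 2 * 25)


class TestAc50FoldChange:
    def test_identical_values_fold_one(self):
        assert tp.ac50_fold_change([2e-6] * 4) == pytest.approx(1.0)

    def test_tenfold_pair_closed_form(self):
        # sample SD of {-6, -5} is 1/sqrt(2); 10**0.7071 ~ 5.09
        assert tp.ac50_fold_change([1e-6, 1e-5]) == pytest.approx(
            10 ** (1 / np.sqrt(2)), rel=1e-9
        )

    def test_scale_invariance(self):
        vals = [1e-7, 4e-7, 9e-7]
        assert tp.ac50_fold_change(vals) == pytest.approx(
            tp.ac50_fold_change([v * 37.5 for v in vals]), rel=1e-12
        )

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError):
            tp.ac50_fold_change([1e-6, 0.0])
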