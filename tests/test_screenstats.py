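"""Plate statistics: summaries, control fits, z-scores, hits, classification."""

import numpy as np
import pandas as pd
import pytest

from mitoscreen import screenstats as ss
from mitoscreen.errors import ControlFitError, DegenerateControlsError
from mitoscreen.synth import (
    EffectSpec,
    SceneParams,
    screen_platemap,
    simulate_screen_records,
    simulate_well_records,
)

from .oracles import sorted_median


def _records(norm_values):
    n = len(norm_values)
    return pd.DataFrame(
        {
            "cytoplasm_area_px": np.full(n, 400),
            "integrated_mito_AU": np.asarray(norm_values) * 400.0,
            "normalized_mito_AU_per_px": norm_values,
        }
    )


class TestSummaries:
    def test_median_of_three(self):
        s = ss.summarize_well(_records([1.0, 2.0, 9.0]))
        assert s.median_normalized_mito_AU_per_px == 2.0
        assert s.cell_count == 3

    def test_single_cell_medians_equal_that_cell(self):
        s = ss.summarize_well(_records([7.5]))
        assert s.median_normalized_mito_AU_per_px == 7.5
        assert s.median_integrated_mito_AU == 7.5 * 400

    def test_empty_well_has_zero_count_and_missing_medians(self):
        s = ss.summarize_well(_records([]))
        assert s.cell_count == 0
        assert np.isnan(s.median_normalized_mito_AU_per_px)

    def test_medians_match_sort_based_oracle(self):
        recs = simulate_well_records(SceneParams(), EffectSpec.null(), 3)
        assert len(recs) == 130
        s = ss.summarize_well(recs)
        for col, out in (
            ("cytoplasm_area_px", s.median_cyto_area_px),
            ("integrated_mito_AU", s.median_integrated_mito_AU),
            ("normalized_mito_AU_per_px", s.median_normalized_mito_AU_per_px),
        ):
            assert out == pytest.approx(sorted_median(recs[col]))


def _well_table(control_vals, day=1):
    rows = []
    for i, v in enumerate(control_vals):
        rows.append(
            dict(plate="P", well=f"W{i}", day=day, role="control", compound_id="DMSO",
                 cell_count=100, median_cyto_area_px=v, median_integrated_mito_AU=v,
                 median_normalized_mito_AU_per_px=v)
        )
    return pd.DataFrame(rows)


class TestControlFits:
    def test_degenerate_controls_rejected(self):
        with pytest.raises(DegenerateControlsError):
            ss.fit_controls(_well_table([10.0, 10.0, 10.0, 10.0]))

    def test_moment_estimator_arithmetic(self):
        fits = ss.fit_controls(_well_table([90.0, 100.0, 110.0]), estimator="moment")
        d = fits[(1, "normalized_mito")]
        assert d.location == pytest.approx(100.0)
        assert d.scale == pytest.approx(10.0)

    def test_robust_estimator_resists_outlier(self):
        fits = ss.fit_controls(_well_table([1.0, 2.0, 3.0, 4.0, 100.0]))
        d = fits[(1, "normalized_mito")]
        assert d.location == 3.0
        assert d.scale == pytest.approx(1.4826)

    def test_too_few_controls_names_day(self):
        with pytest.raises(ControlFitError, match="day 1"):
            ss.fit_controls(_well_table([5.0, 6.0]))


class TestZScores:
    def test_centering_and_arithmetic(self):
        d = ss.ControlDistribution(1, "normalized_mito", 100.0, 10.0, "moment", 5)
        assert ss.well_z(100.0, d) == 0.0
        assert ss.well_z(120.0, d) == pytest.approx(2.0)
        assert np.isnan(ss.well_z(float("nan"), d))

    def test_scale_equivariance(self):
        d1 = ss.ControlDistribution(1, "m", 50.0, 5.0, "moment", 5)
        k = 7.3
        dk = ss.ControlDistribution(1, "m", 50.0 * k, 5.0 * k, "moment", 5)
        assert ss.well_z(60.0, d1) == pytest.approx(ss.well_z(60.0 * k, dk))

    def test_composite_single_replicate_is_identity(self):
        assert ss.composite_z([2.5]) == 2.5

    def test_composite_stouffer_arithmetic(self):
        assert ss.composite_z([2.0, 3.0]) == pytest.approx(5.0 / np.sqrt(2))

    def test_composite_empty_or_all_nan_is_missing(self):
        assert np.isnan(ss.composite_z([]))
        assert np.isnan(ss.composite_z([float("nan")]))

    def test_composite_null_calibration_monte_carlo(self, rng):
        """Stouffer pairs of standard normals keep unit variance (1e4 draws)."""
        z = rng.standard_normal((10000, 2))
        comp = z.sum(axis=1) / np.sqrt(2)
        assert comp.var() == pytest.approx(1.0, abs=0.05)


class TestToxicityAndHits:
    def test_threshold_is_strict_at_40(self):
        assert not ss.toxicity_filter(39)
        assert ss.toxicity_filter(40)
        assert not ss.toxicity_filter(0)

    def test_hit_threshold_is_strict(self):
        scores = pd.DataFrame(
            dict(compound_id=["a", "b"], passed_toxicity=[True, True],
                 z_normalized_mito=[1.99, 1.98])
        )
        hits = ss.call_hits(scores)
        assert hits.compound_id.tolist() == ["a"]

    def test_empty_input_empty_output(self):
        assert len(ss.call_hits(pd.DataFrame())) == 0

    def test_toxicity_gates_hits(self):
        scores = pd.DataFrame(
            dict(compound_id=["a"], passed_toxicity=[False], z_normalized_mito=[5.0])
        )
        assert len(ss.call_hits(scores)) == 0

    def test_null_hit_fraction_matches_normal_tail(self, rng):
        """3840 null compounds in duplicate: hit fraction sits in the 95%
        binomial interval around the one-sided N(0,1) tail at 1.98 (0.0239)."""
        n = 3840
        comp = rng.standard_normal((n, 2)).sum(axis=1) / np.sqrt(2)
        frac = (comp > 1.98).mean()
        p = 0.0239
        half = 1.96 * np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < half


class TestFoldChangesAndClassification:
    def _summaries(self):
        wells = _well_table([100.0, 98.0, 102.0])
        treat = pd.DataFrame(
            [dict(plate="P", well="T1", day=1, role="treatment", compound_id="X",
                  cell_count=100, median_cyto_area_px=100.0,
                  median_integrated_mito_AU=150.0,
                  median_normalized_mito_AU_per_px=1.5)]
        )
        return pd.concat([wells, treat], ignore_index=True)

    def test_identical_to_controls_gives_unit_folds(self):
        wells = _well_table([100.0, 98.0, 102.0])
        fm, fa = ss.fold_changes(wells, wells[wells.well == "W0"])
        assert fm == pytest.approx(1.0)
        assert fa == pytest.approx(1.0)

    def test_fold_arithmetic(self):
        df = self._summaries()
        fm, fa = ss.fold_changes(df, df[df.compound_id == "X"])
        assert fm == pytest.approx(1.5)
        assert fa == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "z_raw,z_area,z_norm,expected",
        [
            (5.0, 5.0, 0.2, "proportional"),
            (4.0, 0.3, 4.0, "dissociated_up"),
            (-1.0, 0.0, -4.0, "dissociated_down"),
            (0.0, 0.0, 0.0, "none"),
            (5.0, 0.5, 1.5, "none"),  # raw hit but area flat, norm sub-threshold
        ],
    )
    def test_effect_classification_rule(self, z_raw, z_area, z_norm, expected):
        assert ss.classify_effect(z_raw, z_area, z_norm) == expected


@pytest.fixture(scope="module")
def planted_scores():
    effects = {
        "MITO1": EffectSpec.mito_only(1.5),
        "TOX1": EffectSpec.toxic(0.2),
        "NULL1": EffectSpec.null(),
    }
    pm = screen_platemap(sorted(effects), days=(1, 2), controls_per_plate=16,
                         control_plates_per_day=0)
    cells = simulate_screen_records(pm, effects, SceneParams(), master_seed=4)
    wells = ss.summarize_wells(cells, pm)
    return ss.score_compounds(wells)


class TestScreenLevel:
    def test_hits_imply_toxicity_pass(self, planted_scores):
        assert (planted_scores[planted_scores.is_hit].passed_toxicity).all()

    def test_toxic_compound_fails_filter_and_mito_only_hits(self, planted_scores):
        s = planted_scores.set_index("compound_id")
        assert not s.loc["TOX1"].passed_toxicity
        assert s.loc["MITO1"].is_hit
        assert s.loc["MITO1"].effect_class == "dissociated_up"
        assert np.isnan(s.loc["TOX1"].z_normalized_mito)

    def test_monotonicity_of_z_norm_in_content_multiplier(self):
        """Raising the planted content multiplier never lowers the mean
        composite z of the normalized metric."""
        means = []
        for m in (1.0, 1.2, 1.5, 2.0):
            effect = EffectSpec.mito_only(m) if m > 1 else EffectSpec.null()
            effects = {f"C{i}": effect for i in range(12)}
            pm = screen_platemap(sorted(effects), days=(1, 2), controls_per_plate=16,
                                 control_plates_per_day=0)
            cells = simulate_screen_records(pm, effects, SceneParams(), master_seed=9)
            scores = ss.score_compounds(ss.summarize_wells(cells, pm))
            means.append(scores.z_normalized_mito.mean())
        assert all(b >= a for a, b in zip(means, means[1:]))
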