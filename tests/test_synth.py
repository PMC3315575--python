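"""The synthetic-plate generator: geometry, coupling law, planted effects,
rendering and determinism."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoscreen.errors import MissingEffectError, PackingError, PlateMapError
from mitoscreen.synth import (
    EffectSpec,
    SceneParams,
    generate_plate,
    generate_scene,
    make_platemap,
    render_channels,
    screen_platemap,
    simulate_well_records,
    validate_platemap,
    well_name,
)

ZERO_NOISE = dict(
    noise_gaussian_sd=0.0, poisson_scaling=0.0, blur_sigma_px=0.0,
    illumination_gradient_amplitude=0.0, well_gain_cv=0.0,
)


class TestScene:
    def test_empty_scene(self):
        p = SceneParams(target_cell_count=0, nuclear_background=0.0,
                        boundary_background=0.0, mito_background=0.0)
        truth, rasters = generate_scene(p, EffectSpec.null(), 0)
        assert truth.n_cells == 0
        for raster in rasters.values():
            assert not raster.any()

    def test_single_cell_content_law_is_exact(self):
        """gamma=1, a=5, multipliers 1, no scatter: content = 5 * cell area."""
        p = SceneParams(
            image_height_px=64, image_width_px=64, target_cell_count=1,
            cell_radius_mean_px=8.0, cell_radius_cv=0.0, content_scale=5.0,
            content_area_exponent=1.0, content_cv=0.0,
        )
        truth, _ = generate_scene(p, EffectSpec.null(), 3)
        assert truth.n_cells == 1
        row = truth.cells.iloc[0]
        assert row.true_content_AU == pytest.approx(5.0 * row.cell_area_px)

    def test_one_truth_row_per_rendered_cell(self, null_scene):
        truth, _ = null_scene
        mask_labels = set(np.unique(truth.cell_labels)) - {0}
        assert mask_labels == set(truth.cells.cell_id)
        assert truth.cells.cell_id.is_unique

    def test_nucleus_strictly_inside_cell(self, null_scene):
        truth, _ = null_scene
        assert (truth.cells.nucleus_area_px > 0).all()
        assert (truth.cells.nucleus_area_px < truth.cells.cell_area_px).all()
        inside = truth.cell_labels[truth.nucleus_labels > 0]
        assert np.array_equal(inside, truth.nucleus_labels[truth.nucleus_labels > 0])

    def test_mito_raster_integrates_to_content_over_cytoplasm(self):
        p = SceneParams(mito_background=0.0, nuclear_bleed_fraction=0.0)
        truth, rasters = generate_scene(p, EffectSpec.null(), 11)
        cyto = np.where(truth.nucleus_labels > 0, 0, truth.cell_labels)
        sums = np.bincount(cyto.ravel(), weights=rasters["mito"].ravel(),
                           minlength=truth.n_cells + 1)[1:]
        assert np.allclose(sums, truth.cells.true_content_AU, rtol=1e-8)

    def test_impossible_packing_reports_achieved_count(self):
        p = SceneParams(image_height_px=64, image_width_px=64,
                        target_cell_count=400, cell_radius_mean_px=12.0)
        with pytest.raises(PackingError) as exc:
            generate_scene(p, EffectSpec.null(), 0)
        assert exc.value.achieved < exc.value.requested == 400

    def test_determinism(self):
        p = SceneParams()
        t1, r1 = generate_scene(p, EffectSpec.null(), 9)
        t2, r2 = generate_scene(p, EffectSpec.null(), 9)
        pd.testing.assert_frame_equal(t1.cells, t2.cells)
        for ch in r1:
            assert np.array_equal(r1[ch], r2[ch])

    def test_coupling_law_slope_recovered(self):
        """log(content) on log(area) over null cells recovers gamma +- 0.1."""
        for gamma in (1.0, 1.3):
            areas, contents = [], []
            p = SceneParams(content_area_exponent=gamma)
            for seed in range(2):
                truth, _ = generate_scene(p, EffectSpec.null(), 21 + seed)
                areas.append(truth.cells.cell_area_px.to_numpy(float))
                contents.append(truth.cells.true_content_AU.to_numpy(float))
            a = np.concatenate(areas)
            c = np.concatenate(contents)
            assert a.size >= 200
            slope = np.polyfit(np.log(a), np.log(c), 1)[0]
            assert slope == pytest.approx(gamma, abs=0.1)

    def test_proportional_effect_preserves_content_area_ratio(self):
        """Monte-Carlo oracle: mean content/area ratio matches null wells."""
        p = SceneParams()
        ratios = {"null": [], "prop": []}
        for seed in range(3):
            t_null, _ = generate_scene(p, EffectSpec.null(), 40 + seed)
            t_prop, _ = generate_scene(p, EffectSpec.proportional(1.5), 80 + seed)
            ratios["null"].append(
                t_null.cells.true_content_AU / t_null.cells.cell_area_px
            )
            ratios["prop"].append(
                t_prop.cells.true_content_AU / t_prop.cells.cell_area_px
            )
        null_r = np.concatenate([r.to_numpy() for r in ratios["null"]])
        prop_r = np.concatenate([r.to_numpy() for r in ratios["prop"]])
        assert null_r.size >= 100 and prop_r.size >= 100
        se = np.hypot(null_r.std() / np.sqrt(null_r.size),
                      prop_r.std() / np.sqrt(prop_r.size))
        assert abs(prop_r.mean() - null_r.mean()) < 4 * se

    def test_mito_only_effect_plants_content_ratio(self):
        """Treated/null mean content within the multiplier +- 3 SE."""
        m = 1.5
        p = SceneParams()
        null_c, treat_c = [], []
        for seed in range(3):
            t0, _ = generate_scene(p, EffectSpec.null(), 200 + seed)
            t1, _ = generate_scene(p, EffectSpec.mito_only(m), 300 + seed)
            null_c.append(t0.cells.true_content_AU.to_numpy(float))
            treat_c.append(t1.cells.true_content_AU.to_numpy(float))
        x0, x1 = np.concatenate(null_c), np.concatenate(treat_c)
        ratio = x1.mean() / x0.mean()
        se = ratio * np.hypot(x0.std() / x0.mean() / np.sqrt(x0.size),
                              x1.std() / x1.mean() / np.sqrt(x1.size))
        assert abs(ratio - m) < 3 * se

    def test_toxic_effect_thins_cell_count(self):
        p = SceneParams()
        counts = [
            generate_scene(p, EffectSpec.toxic(0.2), s)[0].n_cells for s in range(10)
        ]
        assert 10 < np.mean(counts) < 40  # expectation 26


class TestRender:
    def test_identity_when_all_degradations_off(self):
        p = SceneParams(**ZERO_NOISE)
        raster = np.arange(256 * 256, dtype=float).reshape(256, 256)
        out = render_channels({"mito": raster}, p, 0)
        assert np.array_equal(out["mito"], raster)

    def test_gradient_max_min_ratio(self):
        p = SceneParams(**{**ZERO_NOISE, "illumination_gradient_amplitude": 0.5})
        out = render_channels({"mito": np.full(p.shape, 100.0)}, p, 0)
        assert out["mito"].max() / out["mito"].min() == pytest.approx(1.5, rel=1e-6)

    def test_seed_determinism_bit_identical(self):
        p = SceneParams()
        raster = {"mito": np.full(p.shape, 500.0)}
        a = render_channels(raster, p, 123)
        b = render_channels(raster, p, 123)
        assert np.array_equal(a["mito"], b["mito"])

    def test_output_clipped_to_bit_depth(self):
        p = SceneParams(**ZERO_NOISE)
        out = render_channels({"mito": np.full((64, 64), 1e6)}, p, 0)
        assert out["mito"].max() <= 65535


class TestPlate:
    def _small_map(self):
        rows = [
            dict(plate="P1", well=well_name(i), day=1,
                 role="control" if i < 2 else "treatment",
                 compound_id="DMSO" if i < 2 else "CPD1", dose_uM=0.0 if i < 2 else 10.0)
            for i in range(4)
        ]
        return make_platemap(rows)

    def test_three_images_per_well(self, tmp_path):
        p = SceneParams(image_height_px=64, image_width_px=64, target_cell_count=8,
                        cell_radius_mean_px=7.0)
        data = generate_plate(self._small_map(), {"CPD1": EffectSpec.null()}, p,
                              master_seed=1, outdir=tmp_path)
        assert len(data.images) == 12  # 3 channels x 4 wells
        assert len(list(tmp_path.glob("*.tif"))) == 12
        truth = pd.read_csv(tmp_path / "truth_cells.csv")
        assert len(truth) == len(data.truth_cells) > 0

    def test_missing_effect_names_compound(self):
        with pytest.raises(MissingEffectError, match="CPD1"):
            generate_plate(self._small_map(), {}, SceneParams(), 0)

    def test_plate_determinism_byte_identical(self, tmp_path):
        p = SceneParams(image_height_px=64, image_width_px=64, target_cell_count=8,
                        cell_radius_mean_px=7.0)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        for d in (d1, d2):
            generate_plate(self._small_map(), {"CPD1": EffectSpec.null()}, p, 7, outdir=d)
        for f1 in sorted(d1.iterdir()):
            assert f1.read_bytes() == (d2 / f1.name).read_bytes()

    def test_platemap_validation(self):
        rows = [
            dict(plate="P1", well="A01", day=1, role="control", compound_id="DMSO",
                 dose_uM=0.0),
            dict(plate="P1", well="A01", day=1, role="treatment", compound_id="X",
                 dose_uM=1.0),
        ]
        with pytest.raises(PlateMapError, match="duplicate"):
            make_platemap(rows)
        rows = [dict(plate="P1", well="A01", day=1, role="treatment", compound_id="X",
                     dose_uM=1.0)]
        with pytest.raises(PlateMapError, match="no control"):
            make_platemap(rows)

    def test_screen_platemap_layout(self):
        pm = screen_platemap([f"C{i}" for i in range(10)], days=(1, 2),
                             controls_per_plate=4, control_plates_per_day=1)
        validate_platemap(pm)
        day1 = pm[pm.day == 1]
        assert (day1.role == "control").sum() == 4 + 384
        assert (day1.role == "treatment").sum() == 10


class TestTabular:
    def test_control_well_count_matches_target(self):
        recs = simulate_well_records(SceneParams(), EffectSpec.null(), 0)
        assert len(recs) == 130

    def test_area_multiplier_divides_count_and_scales_area(self):
        p = SceneParams()
        null = simulate_well_records(p, EffectSpec.null(), 1)
        prop = simulate_well_records(p, EffectSpec.proportional(1.5), 2)
        assert len(prop) == round(130 / 1.5)
        assert prop.cell_area_px.mean() / null.cell_area_px.mean() == pytest.approx(
            1.5, rel=0.15
        )

    def test_normalized_metric_unchanged_by_proportional_effect(self):
        p = SceneParams(well_gain_cv=0.0)
        rng = np.random.default_rng(5)
        null = pd.concat([simulate_well_records(p, EffectSpec.null(), rng)
                          for _ in range(5)])
        prop = pd.concat([simulate_well_records(p, EffectSpec.proportional(1.5), rng)
                          for _ in range(5)])
        assert prop.normalized_mito_AU_per_px.mean() == pytest.approx(
            null.normalized_mito_AU_per_px.mean(), rel=0.03
        )


@settings(derandomize=True, max_examples=40, deadline=None)
@given(m=st.floats(min_value=1.05, max_value=3.0),
       gamma=st.floats(min_value=0.5, max_value=2.0))
def test_proportional_effect_invariant(m, gamma):
    """area_multiplier = content_multiplier**(1/gamma) for proportional effects."""
    e = EffectSpec.proportional(m, gamma)
    assert e.area_multiplier == pytest.approx(m ** (1.0 / gamma))
    assert e.effect_class == "proportional"


def test_effect_spec_invariants_enforced():
    with pytest.raises(ValueError):
        EffectSpec(effect_class="null", content_multiplier=2.0)
    with pytest.raises(ValueError):
        EffectSpec(effect_class="mito_only", area_multiplier=1.2)
    with pytest.raises(ValueError):
        EffectSpec(effect_class="toxic", survival_fraction=1.0)
    with pytest.raises(ValueError):
        EffectSpec(effect_class="mito_down", content_multiplier=1.5)
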