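import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from colonyscreen import (
    CalibrationFit,
    ColonyProfile,
    NoiseModel,
    compute_fitness,
    extract_intensities,
    fit_titration,
    make_plate_layout,
    make_truth_table,
    measure_colony_size,
    predict_ratio,
    quantify_plate,
    ratio_to_fraction,
    render_plate_images,
    segment_plate,
)
from colonyscreen.quantify import FractionEstimate

SCALE = 10.0


class TestSegmentPlate:
    def test_one_region_per_position(self, zero_noise_plate):
        layout, _, gfp, _ = zero_noise_plate
        regions = segment_plate(gfp, layout, SCALE)
        assert len(regions) == 96

    def test_regions_tile_without_overlap_and_contain_truth_centers(
        self, zero_noise_plate
    ):
        layout, _, gfp, _ = zero_noise_plate
        regions = segment_plate(gfp, layout, SCALE)
        covered = np.zeros(gfp.shape, dtype=int)
        for reg in regions:
            covered[reg.slices] += 1
        assert covered.max() == 1  # no overlap
        by_rc = {(p.row, p.col): p for p in layout.positions}
        for reg in regions:
            p = by_rc[(reg.row, reg.col)]
            cy, cx = p.center_y * SCALE, p.center_x * SCALE
            assert reg.y0 <= cy < reg.y1 and reg.x0 <= cx < reg.x1

    def test_layout_beyond_image_bounds_names_position(self):
        layout = make_plate_layout(8, 12, 9.0)
        tiny = np.zeros((100, 100), dtype=np.uint16)
        with pytest.raises(ValueError, match=r"\(0,2\)|\(0,1\)"):
            segment_plate(tiny, layout, SCALE)

    def test_blank_image_segments_and_flags_downstream(self):
        layout = make_plate_layout(8, 12, 9.0)
        blank = np.full((720, 1080), 100, dtype=np.uint16)
        regions = segment_plate(blank, layout, SCALE)
        measured = extract_intensities(blank, blank, regions)
        assert len(measured) == 96
        assert all("low_rfp" in m.flags for m in measured)


class TestExtractIntensities:
    def test_recovers_known_integrated_signal_within_2pct(
        self, zero_noise_plate
    ):
        layout, truth, gfp, rfp = zero_noise_plate
        regions = segment_plate(gfp, layout, SCALE)
        measured = {m.position: m for m in extract_intensities(gfp, rfp, regions)}
        for rec in truth.table.itertuples(index=False):
            m = measured[(rec.row, rec.col)]
            assert m.rfp_intensity == pytest.approx(rec.rfp_signal, rel=0.02)
            if rec.gfp_signal > 1e4:  # quantization dominates tiny signals
                assert m.gfp_intensity == pytest.approx(rec.gfp_signal, rel=0.02)

    def test_background_only_region_flagged_with_near_zero_sums(self):
        img = np.full((90, 90), 100, dtype=np.uint16)
        from colonyscreen.quantify import Region

        reg = Region(0, 0, 0, 90, 0, 90)
        (m,) = extract_intensities(img, img, [reg])
        assert m.gfp_intensity == 0.0 and m.rfp_intensity == 0.0
        assert "low_rfp" in m.flags and "background_only" in m.flags
        assert m.ratio is None

    def test_ratio_is_gfp_over_rfp(self):
        from colonyscreen.quantify import Region

        gfp = np.zeros((50, 50))
        rfp = np.zeros((50, 50))
        gfp[20:30, 20:30] = 5.0  # sums: 500 vs 1000 over flat zero background
        rfp[20:30, 20:30] = 10.0
        (m,) = extract_intensities(gfp, rfp, [Region(0, 0, 0, 50, 0, 50)])
        assert m.ratio == pytest.approx(0.5)

    def test_mismatched_shapes_rejected(self):
        from colonyscreen.quantify import Region

        with pytest.raises(ValueError, match="shapes"):
            extract_intensities(
                np.zeros((10, 10)), np.zeros((12, 10)), [Region(0, 0, 0, 10, 0, 10)]
            )


class TestFitTitration:
    def test_exact_recovery_of_alpha_beta(self):
        G = np.arange(0, 1.01, 0.1)
        fit = fit_titration(G, predict_ratio(G, 2.0, 0.5))
        assert fit.alpha == pytest.approx(2.0, abs=1e-6)
        assert fit.beta == pytest.approx(0.5, abs=1e-6)

    def test_linear_limit(self):
        G = np.arange(0, 1.01, 0.1)
        fit = fit_titration(G, 1.5 * G)
        assert fit.alpha == pytest.approx(1.5, abs=1e-8)
        assert fit.beta == pytest.approx(0.0, abs=1e-8)

    def test_noisy_fit_matches_grid_search_oracle(self):
        rng = np.random.default_rng(42)
        G = np.arange(0, 1.01, 0.1)
        I = np.clip(predict_ratio(G, 2.0, 0.5) + rng.normal(0, 0.05, G.shape), 0, None)
        fit = fit_titration(G, I)
        # dense brute-force grid over (alpha, beta)
        alphas = np.linspace(1.0, 3.0, 801)
        betas = np.linspace(0.0, 0.9, 721)
        A, B = np.meshgrid(alphas, betas, indexing="ij")
        pred = A[:, :, None] * G[None, None, :] / (1 - B[:, :, None] * G[None, None, :])
        sse = ((pred - I) ** 2).sum(axis=2)
        i, j = np.unravel_index(sse.argmin(), sse.shape)
        assert fit.alpha == pytest.approx(alphas[i], abs=alphas[1] - alphas[0])
        assert fit.beta == pytest.approx(betas[j], abs=betas[1] - betas[0])

    def test_fitted_curve_nondecreasing_on_unit_interval(self):
        rng = np.random.default_rng(1)
        G = np.arange(0, 1.01, 0.1)
        I = np.clip(predict_ratio(G, 1.2, 0.7) + rng.normal(0, 0.1, G.shape), 0, None)
        fit = fit_titration(G, I)
        dense = fit.predict(np.linspace(0, 1, 200))
        assert np.all(np.diff(dense) >= -1e-12)

    def test_degenerate_fractions_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_titration([0.5, 0.5, 0.5], [1.0, 1.1, 0.9])
        with pytest.raises(ValueError, match="span"):
            fit_titration([0.4, 0.5, 0.6], [0.8, 1.0, 1.2])


class TestRatioToFraction:
    def test_zero_ratio_maps_to_zero(self, default_cal):
        assert ratio_to_fraction(0.0, default_cal).G == 0.0

    def test_saturating_ratio_maps_to_one(self, default_cal):
        I = default_cal.alpha / (1 - default_cal.beta)
        est = ratio_to_fraction(I, default_cal)
        assert est.G == pytest.approx(1.0, abs=1e-12)
        assert not est.clipped

    @settings(deadline=None, max_examples=200)
    @given(
        G=st.floats(0.0, 1.0),
        alpha=st.floats(0.05, 50.0),
        beta=st.floats(-2.0, 0.99),
    )
    def test_round_trip_is_identity(self, G, alpha, beta):
        cal = CalibrationFit(alpha=alpha, beta=beta)
        I = float(predict_ratio(G, alpha, beta))
        if I < 0:  # beta < 0 keeps I >= 0 for G in [0,1]; guard anyway
            return
        assert ratio_to_fraction(I, cal).G == pytest.approx(G, abs=1e-9)

    def test_values_beyond_one_are_clipped_and_flagged(self, default_cal):
        I = 2.0 * default_cal.alpha / (1 - default_cal.beta)
        est = ratio_to_fraction(I, default_cal)
        assert est.G == 1.0 and est.clipped and "clipped" in est.flags

    def test_invalid_calibration_for_ratio_rejected(self):
        cal = CalibrationFit(alpha=1.0, beta=-2.0)
        with pytest.raises(ValueError, match="invalid calibration"):
            ratio_to_fraction(1.0, cal)  # alpha + beta*I = -1


class TestComputeFitness:
    @staticmethod
    def _est(pos, G):
        return FractionEstimate(position=pos, G=G)

    def test_control_at_half_gives_unit_fitness(self):
        ests = [self._est((0, 0), 0.5), self._est((1, 0), 0.5)]
        recs = compute_fitness(ests, [(0, 0)])
        assert {r.position: r.fitness for r in recs} == {(0, 0): 1.0, (1, 0): 1.0}

    def test_outcompeted_sample_has_zero_fitness(self):
        recs = compute_fitness(
            [self._est((0, 0), 0.5), self._est((1, 0), 0.0)], [(0, 0)]
        )
        assert recs[1].fitness == 0.0

    def test_normalization_by_control_mean(self):
        ests = [
            self._est((0, 0), 0.4),
            self._est((0, 1), 0.6),
            self._est((1, 0), 0.25),
        ]
        recs = compute_fitness(ests, [(0, 0), (0, 1)])
        assert recs[2].fitness == pytest.approx(0.5)

    def test_control_mean_is_exactly_one_after_normalization(self):
        rng = np.random.default_rng(0)
        controls = [(0, c) for c in range(5)]
        ests = [self._est(p, rng.uniform(0.3, 0.7)) for p in controls]
        ests += [self._est((1, c), rng.uniform(0, 1)) for c in range(5)]
        recs = compute_fitness(ests, controls)
        ctrl_fit = [r.fitness for r in recs if r.position in set(controls)]
        assert np.mean(ctrl_fit) == pytest.approx(1.0, abs=1e-12)

    def test_no_valid_controls_rejected(self):
        with pytest.raises(ValueError, match="control"):
            compute_fitness([self._est((0, 0), 0.5)], [(5, 5)])

    def test_zero_control_mean_rejected(self):
        with pytest.raises(ValueError, match="cannot normalize"):
            compute_fitness(
                [self._est((0, 0), 0.0), self._est((1, 0), 0.5)], [(0, 0)]
            )


class TestMeasureColonySize:
    @staticmethod
    def _render_single(radius_mm, pitch=18.0):
        lay = make_plate_layout(1, 1, pitch, titration_spec=None,
                                control_positions=[(0, 0)])
        truth = make_truth_table(lay, seed=0)
        profile = ColonyProfile(radius_mm=radius_mm, edge_sigma_mm=0.02)
        noise = NoiseModel(background_sd=0.0, multiplicative_cv=0.0)
        _, rfp, _ = render_plate_images(
            lay, truth, CalibrationFit(2.0, 0.5), noise, profile, SCALE
        )
        reg = segment_plate(rfp, lay, SCALE)[0]
        return rfp, reg

    def test_flat_top_radius_recovered(self):
        rfp, reg = self._render_single(1.5)
        assert measure_colony_size(rfp, reg, SCALE) == pytest.approx(3.0, abs=0.1)

    def test_background_only_region_measures_zero(self):
        img = np.full((90, 90), 100, dtype=np.uint16)
        from colonyscreen.quantify import Region

        assert measure_colony_size(img, Region(0, 0, 0, 90, 0, 90), SCALE) == 0.0

    def test_doubling_radius_doubles_diameter(self):
        _, reg1 = self._render_single(1.5)
        rfp1, reg1 = self._render_single(1.5)
        rfp2, reg2 = self._render_single(3.0)
        d1 = measure_colony_size(rfp1, reg1, SCALE)
        d2 = measure_colony_size(rfp2, reg2, SCALE)
        assert d2 == pytest.approx(2 * d1, rel=0.02)


class TestEndToEnd:
    def test_zero_noise_fractions_within_0p02(self, zero_noise_plate):
        layout, truth, gfp, rfp = zero_noise_plate
        df, cal = quantify_plate(gfp, rfp, layout, SCALE)
        merged = df.merge(truth.table, on=["row", "col"])
        err = (merged["fraction"] - merged["true_fraction"]).abs()
        assert err.max() < 0.02
        assert cal.alpha == pytest.approx(2.0, rel=0.01)
        assert cal.beta == pytest.approx(0.5, abs=0.01)

    def test_titration_row_round_trips_through_its_own_fit(self, zero_noise_plate):
        layout, _, gfp, rfp = zero_noise_plate
        df, _ = quantify_plate(gfp, rfp, layout, SCALE)
        tit = df[df.role == "titration"]
        err = (tit["fraction"] - tit["known_fraction"]).abs()
        assert err.max() < 0.02

    def test_plate_controls_average_exactly_one(self, zero_noise_plate):
        layout, _, gfp, rfp = zero_noise_plate
        df, _ = quantify_plate(gfp, rfp, layout, SCALE)
        ctrl = df[df.role == "control_1to1"]
        assert ctrl["fitness"].mean() == pytest.approx(1.0, abs=1e-9)
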