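"""Tortuosity, fractal dimension, density, zones, calibers, disc metrics."""

import numpy as np
import pytest
from skimage import draw

from retimorph.morphometry import (
    ZONE_B,
    ZONE_C,
    SegmentExcluded,
    avr,
    caliber_hubbard,
    caliber_knudtson,
    disc_cup_metrics,
    distance_tortuosity,
    fractal_dimension,
    measure_image,
    select_six_widest,
    squared_curvature_tortuosity,
    tortuosity_density,
    vessel_density,
    zone_mask,
)
from retimorph.seg_io import AV_ARTERY, AV_VEIN, DiscGeometry, SegmentationBundle
from retimorph.vessel_graph import VesselSegment

from conftest import chain_from_polyline, semicircle_chain, sine_chain


class TestDistanceTortuosity:
    def test_straight_is_one(self, straight_segment):
        assert distance_tortuosity(straight_segment) == pytest.approx(1.0, abs=1e-6)

    def test_diagonal_staircase_is_one(self):
        # worst digital-length orientation (22.5 deg): staircase must not inflate
        t = np.arange(200.0)
        seg = VesselSegment(
            points=chain_from_polyline(np.column_stack([t * np.tan(np.pi / 8), t]))
        )
        assert distance_tortuosity(seg) == pytest.approx(1.0, abs=0.01)

    def test_semicircle_matches_pi_over_2(self, semicircle_segment):
        assert distance_tortuosity(semicircle_segment) == pytest.approx(
            np.pi / 2, rel=0.02
        )

    def test_closed_loop_excluded(self):
        rr, cc = draw.circle_perimeter(50, 50, 30, method="bresenham")
        mask = np.zeros((100, 100), dtype=bool)
        mask[rr, cc] = True
        from retimorph.vessel_graph import decompose_segments

        ring = decompose_segments(mask)[0]
        with pytest.raises(SegmentExcluded):
            distance_tortuosity(ring)

    @pytest.mark.parametrize("scale", [0.5, 2.0])
    def test_similarity_invariance(self, scale):
        base = semicircle_chain(50)
        scaled = VesselSegment(points=semicircle_chain(int(50 * scale)))
        ref = VesselSegment(points=base)
        assert distance_tortuosity(scaled) == pytest.approx(
            distance_tortuosity(ref), rel=0.02
        )


class TestSquaredCurvatureTortuosity:
    def test_straight_is_zero(self, straight_segment):
        assert squared_curvature_tortuosity(straight_segment) == pytest.approx(
            0.0, abs=1e-6
        )

    def test_semicircle_integral(self, semicircle_segment):
        # constant curvature 1/r over arc pi*r integrates to pi/r
        assert squared_curvature_tortuosity(semicircle_segment) == pytest.approx(
            np.pi / 50, rel=0.10
        )

    def test_doubling_radius_halves_value(self):
        v50 = squared_curvature_tortuosity(VesselSegment(points=semicircle_chain(50)))
        v100 = squared_curvature_tortuosity(VesselSegment(points=semicircle_chain(100)))
        assert v50 / v100 == pytest.approx(2.0, rel=0.10)

    def test_too_short_excluded(self):
        seg = VesselSegment(points=np.array([[0, 0], [0, 1], [0, 2]]))
        with pytest.raises(SegmentExcluded):
            squared_curvature_tortuosity(seg)


class TestTortuosityDensity:
    def test_straight_is_zero(self, straight_segment):
        assert tortuosity_density(straight_segment) == 0.0

    def test_single_arc_is_zero(self, semicircle_segment):
        # one constant-sign subsegment: the (n-1)/n factor kills it
        assert tortuosity_density(semicircle_segment) == pytest.approx(0.0, abs=1e-4)

    def test_sine_matches_brute_force_oracle(self):
        """Partition-at-inflections arithmetic against an independent
        finite-difference implementation (Gaussian-smoothed coordinates)."""
        from scipy.ndimage import gaussian_filter1d

        def oracle(points, sigma=4.0, eps=1e-3):
            p = points.astype(float)
            r = gaussian_filter1d(p[:, 0], sigma, mode="nearest")
            c = gaussian_filter1d(p[:, 1], sigma, mode="nearest")
            q = np.column_stack([r, c])
            d = np.linalg.norm(np.diff(q, axis=0), axis=1)
            s = np.concatenate([[0], np.cumsum(d)])
            dr, dc = np.gradient(r, s), np.gradient(c, s)
            d2r, d2c = np.gradient(dr, s), np.gradient(dc, s)
            kap = (dc * d2r - dr * d2c) / (dr**2 + dc**2) ** 1.5
            signs = np.where(np.abs(kap) < eps, 0, np.sign(kap))
            bounds, cur = [0], 0
            for i, sg in enumerate(signs):
                if sg == 0:
                    continue
                if cur == 0:
                    cur = sg
                elif sg != cur:
                    bounds.append(i)
                    cur = sg
            bounds.append(len(q) - 1)
            n = len(bounds) - 1
            if n <= 1:
                return 0.0
            ex = 0.0
            for a, b in zip(bounds[:-1], bounds[1:]):
                sub = q[a : b + 1]
                arc = np.linalg.norm(np.diff(sub, axis=0), axis=1).sum()
                ch = np.linalg.norm(sub[-1] - sub[0])
                if ch > 0:
                    ex += arc / ch - 1
            return (n - 1) / n / s[-1] * ex

        # peaks at the ends, 3 interior inflections
        pts = sine_chain(25, 12, np.pi / 2, np.pi / 2 + 3 * np.pi)
        value = tortuosity_density(VesselSegment(points=pts))
        assert value == pytest.approx(oracle(pts), rel=0.25)
        # and against the analytic truth of the continuous curve
        assert value == pytest.approx(0.00583, rel=0.15)

    def test_similarity_invariance(self):
        small = sine_chain(15, 10, np.pi / 2, np.pi / 2 + 3 * np.pi)
        large = sine_chain(30, 20, np.pi / 2, np.pi / 2 + 3 * np.pi)
        v_small = tortuosity_density(VesselSegment(points=small))
        v_large = tortuosity_density(VesselSegment(points=large))
        # value scales as 1/length; invariant form multiplies back
        assert 2 * v_large == pytest.approx(v_small, rel=0.10)


class TestFractalDimension:
    def test_line_near_one(self):
        mask = np.zeros((512, 512), dtype=bool)
        mask[256, :] = True
        assert fractal_dimension(mask) == pytest.approx(1.0, abs=0.1)

    def test_filled_square_is_two(self):
        assert fractal_dimension(np.ones((512, 512), dtype=bool)) == pytest.approx(
            2.0, abs=0.05
        )

    def test_single_pixel_is_zero(self):
        mask = np.zeros((512, 512), dtype=bool)
        mask[100, 100] = True
        assert fractal_dimension(mask) == pytest.approx(0.0, abs=0.05)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            fractal_dimension(np.zeros((64, 64), dtype=bool))

    def test_bounded_for_arbitrary_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            mask = rng.random((128, 128)) > rng.uniform(0.2, 0.95)
            if mask.any():
                assert 0.0 <= fractal_dimension(mask) <= 2.0

    def test_r2_diagnostic(self):
        fd, r2 = fractal_dimension(np.ones((256, 256), dtype=bool), return_r2=True)
        assert r2 == pytest.approx(1.0, abs=1e-9)


class TestVesselDensity:
    def test_full_cover(self):
        region = np.ones((10, 10), dtype=bool)
        assert vessel_density(region, region) == 1.0

    def test_exact_quarter(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[:10, :10] = True
        assert vessel_density(mask) == 0.25

    def test_empty_mask_zero(self):
        assert vessel_density(np.zeros((8, 8), dtype=bool)) == 0.0

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            vessel_density(np.ones((8, 8), dtype=bool), np.zeros((8, 8), dtype=bool))


class TestZoneMask:
    disc = DiscGeometry(center=(300.0, 300.0), height=100, width=100)

    def test_zone_b_radii_and_area(self):
        annulus = zone_mask(self.disc, ZONE_B, (600, 600))
        rr, cc = np.nonzero(annulus)
        dist = np.hypot(rr - 300, cc - 300)
        assert dist.min() >= 100 - 1 and dist.max() <= 150 + 1
        assert annulus.sum() == pytest.approx(np.pi * (150**2 - 100**2), rel=0.01)

    def test_zone_c_radii_and_area(self):
        annulus = zone_mask(self.disc, ZONE_C, (600, 600))
        rr, cc = np.nonzero(annulus)
        dist = np.hypot(rr - 300, cc - 300)
        assert dist.min() >= 100 - 1 and dist.max() <= 250 + 1
        assert annulus.sum() == pytest.approx(np.pi * (250**2 - 100**2), rel=0.01)

    def test_zone_b_subset_of_zone_c(self):
        b = zone_mask(self.disc, ZONE_B, (600, 600))
        c = zone_mask(self.disc, ZONE_C, (600, 600))
        assert (c | ~b).all()

    def test_corner_disc_clipped(self):
        corner = DiscGeometry(center=(0.0, 0.0), height=100, width=100)
        annulus = zone_mask(corner, ZONE_B, (600, 600))
        # quarter of the full annulus survives
        assert annulus.sum() == pytest.approx(np.pi * (150**2 - 100**2) / 4, rel=0.05)


class TestSelectSixWidest:
    def _segments(self, widths, label="artery"):
        out = []
        for i, w in enumerate(widths):
            pts = np.column_stack([np.full(20, 5 + i), np.arange(20)])
            out.append(
                VesselSegment(points=pts, widths=np.full(20, float(w)), label=label, segment_id=i)
            )
        return out

    def test_exactly_six_all_returned(self):
        sel = select_six_widest(self._segments([5, 6, 7, 8, 9, 10]), "artery")
        assert sorted(sel.widths) == [5, 6, 7, 8, 9, 10]
        assert sel.complete

    def test_top_six_of_ten(self):
        sel = select_six_widest(self._segments(range(1, 11)), "artery")
        assert sorted(sel.widths) == [5, 6, 7, 8, 9, 10]

    def test_fewer_than_six_flagged(self):
        sel = select_six_widest(self._segments([3, 4, 5, 6]), "artery")
        assert len(sel.widths) == 4 and not sel.complete

    def test_label_filtering(self):
        segs = self._segments([5, 6], "artery") + self._segments([7, 8], "vein")
        sel = select_six_widest(segs, "vein")
        assert sorted(sel.widths) == [7, 8]


class TestCaliberKnudtson:
    def test_single_width_identity(self):
        assert caliber_knudtson([17.3], "artery") == 17.3

    def test_six_equal_twenties_artery(self):
        # hand-iterated: 3x 24.890 -> {30.976, 24.890} -> 34.969
        assert caliber_knudtson([20] * 6, "artery") == pytest.approx(34.969, abs=0.01)

    def test_equal_sets_avr_closed_form(self):
        # 8 equal widths -> three carry-free pairing rounds, so the branching
        # coefficients factor out exactly: AVR = (0.88/0.95)^3
        crae = caliber_knudtson([20] * 8, "artery")
        crve = caliber_knudtson([20] * 8, "vein")
        assert avr(crae, crve) == pytest.approx((0.88 / 0.95) ** 3, abs=1e-12)

    def test_six_equal_sets_avr_with_carry(self):
        # with six widths the round-2 carry escapes one coefficient, so the
        # ratio sits above the pure-cube value
        crae = caliber_knudtson([20] * 6, "artery")
        crve = caliber_knudtson([20] * 6, "vein")
        assert avr(crae, crve) == pytest.approx(0.81798, abs=1e-4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            caliber_knudtson([], "artery")

    def test_matches_independent_pairing_oracle(self):
        """Random sextets against a separately coded pairing reduction."""

        def oracle(widths, k):
            w = sorted(widths)
            while len(w) > 1:
                combined = [
                    k * np.sqrt(w[i] ** 2 + w[len(w) - 1 - i] ** 2)
                    for i in range(len(w) // 2)
                ]
                if len(w) % 2:
                    combined.append(w[len(w) // 2])
                w = sorted(combined)
            return w[0]

        rng = np.random.default_rng(42)
        for _ in range(200):
            widths = rng.uniform(3, 40, size=rng.integers(1, 7))
            for vt, k in (("artery", 0.88), ("vein", 0.95)):
                assert caliber_knudtson(widths, vt) == pytest.approx(
                    oracle(widths, k), abs=1e-9
                )

    def test_permutation_invariant_and_monotone(self):
        rng = np.random.default_rng(5)
        widths = rng.uniform(5, 30, size=6)
        base = caliber_knudtson(widths, "vein")
        assert caliber_knudtson(widths[::-1], "vein") == pytest.approx(base)
        widths[2] += 3.0
        assert caliber_knudtson(widths, "vein") > base


class TestCaliberHubbard:
    def test_vein_zero_pair_is_additive_constant(self):
        assert caliber_hubbard([0.0, 0.0], "vein") == pytest.approx(
            np.sqrt(450.05), abs=1e-9
        )

    def test_artery_equal_pair_direct_substitution(self):
        # sqrt(0.87*400 + 1.01*400 - 0.22*400 - 10.76) = sqrt(653.24)
        assert caliber_hubbard([20, 20], "artery") == pytest.approx(
            np.sqrt(653.24), abs=1e-9
        )

    def test_negative_radicand_diagnostic(self):
        with pytest.raises(ValueError, match="radicand"):
            caliber_hubbard([1.0, 1.0], "artery")

    def test_six_equal_matches_pairing_oracle(self):
        def combine_a(a, b):
            wa, wb = max(a, b), min(a, b)
            return np.sqrt(0.87 * wa**2 + 1.01 * wb**2 - 0.22 * wa * wb - 10.76)

        def oracle(widths):
            w = sorted(widths)
            while len(w) > 1:
                nxt = [combine_a(w[i], w[len(w) - 1 - i]) for i in range(len(w) // 2)]
                if len(w) % 2:
                    nxt.append(w[len(w) // 2])
                w = sorted(nxt)
            return w[0]

        for width in (15.0, 20.0, 30.0):
            assert caliber_hubbard([width] * 6, "artery") == pytest.approx(
                oracle([width] * 6), abs=1e-9
            )


class TestAvr:
    def test_equal_calibers(self):
        assert avr(25.0, 25.0) == 1.0

    def test_division(self):
        assert avr(34.97, 41.80) == pytest.approx(0.8366, abs=1e-4)

    def test_zero_crve_rejected(self):
        with pytest.raises(ValueError):
            avr(20.0, 0.0)


class TestDiscCupMetrics:
    @staticmethod
    def _ellipse_mask(frame, center, r_row, r_col):
        mask = np.zeros(frame, dtype=bool)
        rr, cc = draw.ellipse(*center, r_row, r_col, shape=frame)
        mask[rr, cc] = True
        return mask

    def test_half_size_cup(self):
        disc = self._ellipse_mask((300, 300), (150, 150), 50, 60)
        cup = self._ellipse_mask((300, 300), (150, 150), 25, 30)
        m = disc_cup_metrics(disc, cup)
        assert m["vertical_CDR"] == pytest.approx(0.5, abs=0.02)
        assert m["horizontal_CDR"] == pytest.approx(0.5, abs=0.02)

    def test_cup_equals_disc(self):
        disc = self._ellipse_mask((200, 200), (100, 100), 40, 40)
        m = disc_cup_metrics(disc, disc)
        assert m["vertical_CDR"] == 1.0 and m["horizontal_CDR"] == 1.0

    def test_empty_cup_reports_missing(self):
        disc = self._ellipse_mask((200, 200), (100, 100), 40, 40)
        m = disc_cup_metrics(disc, np.zeros((200, 200), dtype=bool))
        assert m["vertical_CDR"] is None
        assert m["disc_height"] == pytest.approx(80, abs=1)

    def test_empty_disc_rejected(self):
        with pytest.raises(ValueError):
            disc_cup_metrics(np.zeros((50, 50), dtype=bool))


class TestMeasureImage:
    def test_synthetic_scene_closure(self, default_scene):
        bundle, ledger = default_scene
        record = measure_image(bundle)
        total = np.prod(ledger.frame)
        assert record.values["vessel_density_whole"] == ledger.vessel_area / total
        ledger_dt = np.average(
            [t.distance_tortuosity for t in ledger.segments],
            weights=[t.arc_length for t in ledger.segments],
        )
        assert record.values["distance_tortuosity_whole"] == pytest.approx(
            ledger_dt, rel=0.02
        )
        mean_truth_width = np.mean([t.width for t in ledger.segments])
        assert record.values["average_width_whole"] == pytest.approx(
            mean_truth_width, abs=1.0
        )

    def test_no_disc_drops_zones_keeps_whole(self, default_scene):
        bundle, _ = default_scene
        stripped = SegmentationBundle(
            vessel_mask=bundle.vessel_mask, av_labels=bundle.av_labels, source_id="x"
        )
        record = measure_image(stripped)
        assert record.values["vessel_density_whole"] is not None
        assert record.values.get("vessel_density_zoneB") is None
        assert "no_disc" in record.flags

    def test_empty_bundle_gives_missing_record(self):
        empty = SegmentationBundle(vessel_mask=np.zeros((64, 64), dtype=bool))
        record = measure_image(empty)
        assert "empty_vessel_mask" in record.flags
        assert all(v is None for v in record.values.values())

    def test_uncertain_pixels_excluded_from_caliber(self):
        # two ribbons: one artery, one uncertain -> no vein caliber, artery only
        from retimorph.seg_io import AV_UNCERTAIN

        vessel = np.zeros((400, 400), dtype=bool)
        av = np.zeros((400, 400), dtype=np.uint8)
        vessel[100:105, 50:350] = True  # ~100 px above the disc center
        av[100:105, 50:350] = AV_ARTERY
        vessel[300:305, 50:350] = True
        av[300:305, 50:350] = AV_UNCERTAIN
        # disc diameter ~80: Zone B annulus spans radii 80..120, so both
        # ribbons cross it
        disc = np.zeros((400, 400), dtype=bool)
        rr, cc = draw.disk((200, 200), 40)
        disc[rr, cc] = True
        bundle = SegmentationBundle(
            vessel_mask=vessel, av_labels=av, disc_mask=disc, source_id="u"
        )
        record = measure_image(bundle)
        assert record.values["CRAE_knudtson_zoneB"] is not None
        assert record.values["CRVE_knudtson_zoneB"] is None
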