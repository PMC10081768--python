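"""Spyderleg geometry, flow filtering/projection, and slippage records."""

import numpy as np
import pytest

from myoslip.coupling import (
    CouplingConfig,
    Spyderleg,
    build_spyderlegs,
    centripetal_samples,
    membrane_velocity,
    myosin_velocity,
)
from myoslip.flow import FlowField


CFG = CouplingConfig()  # pixel 0.1 µm, interval 5.7 s, stride 6, θ=1.5, 2 µm window


def _disk(shape, cx, cy, r):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return np.hypot(xx - cx, yy - cy) <= r


def _flow_field(shape, fn):
    """FlowField whose (dx, dy) at each pixel is fn(x, y) in µm/min."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    vx, vy = fn(xx.astype(float), yy.astype(float))
    k = CFG.um_per_min_factor
    return FlowField(flow=np.stack([vx / k, vy / k], axis=-1),
                     pixel_size=CFG.pixel_size, myosin_interval=CFG.myosin_interval)


class TestBuildSpyderlegs:
    def test_circular_mask_uniform_anchors_pointing_at_center(self):
        mask = _disk((128, 128), 64, 64, 40)
        legs = build_spyderlegs(mask, (64.0, 64.0), CFG)
        assert len(legs) == CFG.legs_per_cell
        for k, leg in enumerate(legs):
            phi = 2 * np.pi * k / CFG.legs_per_cell
            r = np.linalg.norm(leg.anchor - leg.center)
            assert r == pytest.approx(40.0, abs=0.75)
            # direction is exactly the unit vector anchor -> center
            expect = -np.array([np.cos(phi), np.sin(phi)])
            np.testing.assert_allclose(leg.direction, expect, atol=1e-9)
            assert np.linalg.norm(leg.direction) == pytest.approx(1.0)

    def test_window_pixels_within_depth_brute_force(self):
        mask = _disk((128, 128), 64, 64, 40)
        legs = build_spyderlegs(mask, (64.0, 64.0), CFG)
        depth_px = CFG.window_depth / CFG.pixel_size
        for leg in legs:
            ys, xs = leg.window_pixels
            assert len(ys) > 0
            for y, x in zip(ys, xs):
                s = np.dot([x, y] - leg.anchor, leg.direction)
                assert -1e-9 <= s <= depth_px + 1e-9
                assert mask[y, x]

    def test_window_extends_20px_at_default_units(self):
        # 2 µm at 0.1 µm/px = 20 px inward from the boundary
        mask = _disk((128, 128), 64, 64, 45)
        legs = build_spyderlegs(mask, (64.0, 64.0), CFG)
        leg = legs[0]  # along +x
        ys, xs = leg.window_pixels
        s = (xs - leg.anchor[0]) * leg.direction[0] + (ys - leg.anchor[1]) * leg.direction[1]
        assert s.max() == pytest.approx(20.0, abs=1.0)

    def test_window_is_subset_of_label_and_annulus(self):
        mask = _disk((96, 96), 48, 48, 30)
        legs = build_spyderlegs(mask, (48.0, 48.0), CFG)
        depth_px = CFG.window_depth / CFG.pixel_size
        for leg in legs:
            ys, xs = leg.window_pixels
            assert mask[ys, xs].all()
            rho = np.hypot(xs - 48.0, ys - 48.0)
            assert (rho >= 30 - depth_px - 1.5).all()

    def test_center_outside_label_raises(self):
        mask = _disk((64, 64), 20, 20, 10)
        with pytest.raises(ValueError, match="center"):
            build_spyderlegs(mask, (50.0, 50.0), CFG)

    def test_open_contour_leg_skipped_with_warning(self, caplog):
        mask = np.zeros((64, 64), dtype=bool)
        mask[20:44, 20:64] = True  # touches the right image edge
        with caplog.at_level("WARNING", logger="myoslip.coupling"):
            legs = build_spyderlegs(mask, (40.0, 32.0), CFG)
        assert len(legs) < CFG.legs_per_cell
        assert any("did not cross" in r.message for r in caplog.records)


def _leg_along_x(anchor_x=80.0, cy=48.0):
    """Hand-built leg pointing in -x (toward a center on the left)."""
    ys = np.full(10, int(cy))
    xs = np.arange(70, 80)
    return Spyderleg(cell=1, pair_index=0, leg_id=0,
                     center=np.array([48.0, cy]), anchor=np.array([anchor_x, cy]),
                     direction=np.array([-1.0, 0.0]), window_depth=2.0,
                     window_pixels=(ys, xs))


class TestCentripetalSamples:
    def test_aligned_vector_retained_as_its_speed(self):
        leg = _leg_along_x()
        f = _flow_field((96, 96), lambda x, y: (np.full_like(x, -2.0), np.zeros_like(y)))
        samples = centripetal_samples(f, leg, CFG)
        np.testing.assert_allclose(samples, 2.0)

    def test_perpendicular_vector_discarded(self):
        leg = _leg_along_x()
        f = _flow_field((96, 96), lambda x, y: (np.zeros_like(x), np.full_like(y, 2.0)))
        assert len(centripetal_samples(f, leg, CFG)) == 0

    def test_outward_vector_discarded(self):
        leg = _leg_along_x()
        f = _flow_field((96, 96), lambda x, y: (np.full_like(x, 2.0), np.zeros_like(y)))
        assert len(centripetal_samples(f, leg, CFG)) == 0

    def test_threshold_enumeration_brute_force(self):
        # magnitudes {1.0, 1.4, 1.6, 2.0} along the leg -> retain {1.6, 2.0}
        leg = _leg_along_x()
        ys, xs = leg.window_pixels
        mags = [1.0, 1.4, 1.6, 2.0]
        flow = np.zeros((96, 96, 2))
        k = CFG.um_per_min_factor
        for (y, x), m in zip(zip(ys[:4], xs[:4]), mags):
            flow[y, x, 0] = -m / k
        leg4 = Spyderleg(**{**leg.__dict__, "window_pixels": (ys[:4], xs[:4])})
        f = FlowField(flow=flow, pixel_size=CFG.pixel_size, myosin_interval=CFG.myosin_interval)
        samples = centripetal_samples(f, leg4, CFG)
        brute = [m for m in mags if m >= 1.5]
        np.testing.assert_allclose(sorted(samples), brute, atol=1e-12)
        assert samples.mean() == pytest.approx(1.8)

    def test_filter_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        leg = _leg_along_x()
        f = _flow_field((96, 96),
                        lambda x, y: (rng.normal(-1.5, 1.0, x.shape), rng.normal(0, 1, y.shape)))
        prev = None
        for theta in (0.0, 0.5, 1.0, 1.5, 2.0, 3.0):
            cfg = CouplingConfig(speed_threshold=theta)
            got = set(np.round(centripetal_samples(f, leg, cfg), 9))
            if prev is not None:
                assert got <= prev
            prev = got

    def test_centripetal_threshold_variant(self):
        leg = _leg_along_x()
        # speed 2.0 at 40° to the leg: magnitude passes θ, component 1.53 passes
        # as magnitude-threshold sample but fails a centripetal threshold of 1.6
        vx = -2.0 * np.cos(np.deg2rad(40))
        vy = 2.0 * np.sin(np.deg2rad(40))
        f = _flow_field((96, 96), lambda x, y: (np.full_like(x, vx), np.full_like(y, vy)))
        mag_cfg = CouplingConfig(speed_threshold=1.6, threshold_on="magnitude")
        cen_cfg = CouplingConfig(speed_threshold=1.6, threshold_on="centripetal")
        assert len(centripetal_samples(f, leg, mag_cfg)) == 10
        assert len(centripetal_samples(f, leg, cen_cfg)) == 0


class TestMyosinVelocity:
    def test_constant_samples_give_their_value(self):
        leg = _leg_along_x()
        f = _flow_field((96, 96), lambda x, y: (np.full_like(x, -1.8), np.zeros_like(y)))
        v, n = myosin_velocity(leg, [f] * 6, CFG)
        assert v == pytest.approx(1.8)
        assert n == 60

    def test_stationary_myosin_flagged_no_flow(self):
        leg = _leg_along_x()
        f = _flow_field((96, 96), lambda x, y: (np.zeros_like(x), np.zeros_like(y)))
        v, n = myosin_velocity(leg, [f] * 6, CFG)
        assert n == 0 and np.isnan(v)

    def test_pooled_vs_per_pair_averaging(self):
        leg = _leg_along_x()
        f1 = _flow_field((96, 96), lambda x, y: (np.full_like(x, -2.0), np.zeros_like(y)))
        # second pair: half the window below threshold
        def fn(x, y):
            vx = np.where(x < 75, -3.0, -0.5)
            return vx, np.zeros_like(y)
        f2 = _flow_field((96, 96), fn)
        v_pool, n = myosin_velocity(leg, [f1, f2], CFG)
        # pooled: 10 samples of 2.0 and 5 of 3.0
        assert n == 15
        assert v_pool == pytest.approx((10 * 2.0 + 5 * 3.0) / 15)
        cfg = CouplingConfig(pool_samples=False)
        v_pair, _ = myosin_velocity(leg, [f1, f2], cfg)
        assert v_pair == pytest.approx((2.0 + 3.0) / 2)


class TestMembraneVelocity:
    def test_inward_step_closed_form(self):
        # 0.2 µm inward over one membrane interval (34.2 s) ≈ 0.351 µm/min
        mask0 = _disk((128, 128), 64, 64, 40)
        mask1 = _disk((128, 128), 64, 64, 38)  # 2 px = 0.2 µm
        legs = build_spyderlegs(mask0, (64.0, 64.0), CFG)
        dt = CFG.membrane_dt_min
        expected = 0.2 / dt
        for leg in legs[:8]:
            v = membrane_velocity(mask0, mask1, leg, CFG)
            assert v == pytest.approx(expected, abs=0.12 * expected)

    def test_static_mask_zero(self):
        mask = _disk((96, 96), 48, 48, 30)
        legs = build_spyderlegs(mask, (48.0, 48.0), CFG)
        for leg in legs[:6]:
            assert membrane_velocity(mask, mask, leg, CFG) == pytest.approx(0.0, abs=1e-9)

    def test_outward_motion_negative(self):
        mask0 = _disk((128, 128), 64, 64, 36)
        mask1 = _disk((128, 128), 64, 64, 40)
        legs = build_spyderlegs(mask0, (64.0, 64.0), CFG)
        assert membrane_velocity(mask0, mask1, legs[0], CFG) < 0

    def test_no_crossing_returns_none(self):
        mask0 = _disk((64, 64), 32, 32, 20)
        legs = build_spyderlegs(mask0, (32.0, 32.0), CFG)
        mask1 = np.ones((64, 64), dtype=bool)  # boundary beyond the image
        assert membrane_velocity(mask0, mask1, legs[0], CFG) is None


class TestSlippageRecords:
    def test_slippage_is_exact_difference(self, small_pipeline):
        _, df = small_pipeline
        ok = df[df["flag"] == ""]
        np.testing.assert_allclose(ok["slippage"], ok["v_myo"] - ok["v_mem"], atol=1e-12)

    def test_one_record_per_cell_leg_pair(self, small_pipeline, small_movie):
        result, df = small_pipeline
        movie, _ = small_movie
        n_pairs = len(movie.membrane_frames) - 1
        n_cells = len(result.track.centers)
        assert len(df) == n_cells * CFG.legs_per_cell * n_pairs

    def test_flagged_records_have_nan_slippage(self, small_pipeline):
        _, df = small_pipeline
        bad = df[df["flag"] != ""]
        assert bad["slippage"].isna().all()


class TestHandBuiltOracle:
    """8-leg fixture with hand-assigned flow vectors vs brute-force pooling."""

    def test_pooled_means_match_exhaustive_computation(self):
        cfg = CouplingConfig(legs_per_cell=8)
        mask = _disk((128, 128), 64, 64, 40)
        legs = build_spyderlegs(mask, (64.0, 64.0), cfg)
        assert len(legs) == 8
        rng = np.random.default_rng(4)
        k = cfg.um_per_min_factor
        flow = np.zeros((128, 128, 2))
        assigned = {}  # (y, x) -> (vx, vy) µm/min
        for leg in legs:
            ys, xs = leg.window_pixels
            for y, x in zip(ys, xs):
                v = rng.normal(0, 1.5, 2)
                assigned[(y, x)] = v
                flow[y, x] = v / k
        f = FlowField(flow=flow, pixel_size=cfg.pixel_size,
                      myosin_interval=cfg.myosin_interval)
        for leg in legs:
            got = centripetal_samples(f, leg, cfg)
            brute = []
            for y, x in zip(*leg.window_pixels):
                vx, vy = assigned[(y, x)]
                cent = vx * leg.direction[0] + vy * leg.direction[1]
                if np.hypot(vx, vy) >= cfg.speed_threshold and cent > 0:
                    brute.append(cent)
            np.testing.assert_allclose(np.sort(got), np.sort(brute), atol=1e-9)
            if brute:
                v, n = myosin_velocity(leg, [f], cfg)
                assert n == len(brute)
                assert v == pytest.approx(np.mean(brute))
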