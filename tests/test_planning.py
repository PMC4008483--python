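import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pcplan.centerline import Centerline, DerivativeProfile, LabeledProfile
from pcplan.phantom import PhantomSpec, generate_phantom, generate_profile_population
from pcplan.planning import (
    PlanningError,
    Template,
    angles_to_normal,
    build_template,
    cross_correlate,
    detect_turning_points,
    plan_all,
    plan_ica_plane,
    plan_va_plane,
    rough_region,
)


def brute_force_turns(segment, lmin=2):
    """Exhaustive three-segment variance minimizer (the independent oracle)."""
    x = np.asarray(segment, dtype=float)
    n = len(x)
    best = None
    for k1 in range(lmin, n - 2 * lmin + 1):
        for k2 in range(k1 + lmin, n - lmin + 1):
            v = sum(
                float(np.sum((seg - seg.mean()) ** 2))
                for seg in (x[:k1], x[k1:k2], x[k2:])
            )
            if best is None or v < best[0]:
                best = (v, k1, k2)
    return best[1], best[2], best[0]


def _profile(values, dz=1.5, z0=0.0, axis="AP"):
    return DerivativeProfile(values=np.asarray(values, dtype=float), dz=dz, z0=z0, axis=axis)


class TestDetectTurningPoints:
    def test_piecewise_constant_is_exact(self):
        turns = detect_turning_points([0, 0, 0, 5, 5, 5, 0, 0, 0])
        assert (turns.k1, turns.k2) == (3, 6)
        assert turns.v_total == pytest.approx(0.0)

    def test_constant_segment_tie_rule(self):
        turns = detect_turning_points(np.ones(12), lmin=2)
        assert (turns.k1, turns.k2) == (2, 4)
        assert turns.v_total == pytest.approx(0.0)

    def test_offset_maps_back_to_profile_coordinates(self):
        turns = detect_turning_points([0, 0, 0, 5, 5, 5, 0, 0, 0], offset=10)
        assert (turns.k1, turns.k2) == (13, 16)

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError):
            detect_turning_points([1.0, 2.0, 3.0], lmin=2)

    def test_matches_exhaustive_search_on_random_segments(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(12, 60))
            x = rng.normal(size=n) + np.repeat(
                rng.normal(scale=3, size=3), [n // 3, n // 3, n - 2 * (n // 3)]
            )
            turns = detect_turning_points(x)
            bk1, bk2, bv = brute_force_turns(x)
            assert (turns.k1, turns.k2) == (bk1, bk2)
            assert turns.v_total == pytest.approx(bv, rel=1e-9, abs=1e-9)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=12, max_size=48))
    def test_dp_equals_oracle_property(self, values):
        turns = detect_turning_points(values)
        bk1, bk2, _ = brute_force_turns(values)
        assert (turns.k1, turns.k2) == (bk1, bk2)


class TestCrossCorrelate:
    def _template(self, values, **kw):
        defaults = dict(dz=1.5, turn_lower=3, turn_upper=8, pad=10)
        defaults.update(kw)
        return Template(values=np.asarray(values, dtype=float), **defaults)

    def test_self_correlation_at_zero(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=30)
        m, r = cross_correlate(_profile(v), self._template(v))
        assert m == 0
        assert r == pytest.approx(1.0)

    def test_shift_recovery(self):
        rng = np.random.default_rng(1)
        g = rng.normal(size=20)
        f = np.concatenate([np.zeros(7), g, np.zeros(5)])
        m, _ = cross_correlate(_profile(f), self._template(g))
        assert m == 7

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        g = rng.normal(size=20)
        f = np.concatenate([np.zeros(7), g, np.zeros(5)])
        m0, r0 = cross_correlate(_profile(f), self._template(g))
        m1, r1 = cross_correlate(_profile(0.5 * f + 3.0), self._template(g))
        assert (m0, round(r0, 9)) == (m1, round(r1, 9))

    def test_degenerate_profile_rejected(self):
        with pytest.raises(ValueError, match="profile shorter"):
            cross_correlate(
                _profile(np.zeros(10)), self._template(np.arange(30.0), turn_upper=20)
            )


class TestRoughRegion:
    def test_padding_arithmetic(self):
        t = Template(values=np.zeros(60), dz=1.5, turn_lower=20, turn_upper=35, pad=10)
        assert rough_region(_profile(np.zeros(60)), t, m=0) == (10, 45)

    def test_clipping_at_zero(self):
        t = Template(values=np.zeros(60), dz=1.5, turn_lower=20, turn_upper=35, pad=10)
        lo, hi = rough_region(_profile(np.zeros(60)), t, m=-15)
        assert lo == 0

    def test_region_too_short_is_failure(self):
        t = Template(values=np.zeros(60), dz=1.5, turn_lower=20, turn_upper=35, pad=2)
        with pytest.raises(PlanningError, match="outside profile"):
            rough_region(_profile(np.zeros(30)), t, m=25)


class TestBuildTemplate:
    def test_identical_profiles_average_to_themselves(self, default_spec):
        pop = generate_profile_population(
            10, default_spec, turn_height_jitter=0, shift_jitter=0, profile_noise_sd=0, seed=3
        )
        t = build_template(pop)
        ref = pop[0]
        assert len(t) == len(ref.profile)
        np.testing.assert_allclose(t.values, ref.profile.values, atol=1e-12)
        assert (t.turn_lower, t.turn_upper) == (ref.turn_lower, ref.turn_upper)

    def test_offset_pair_aligns_on_turn_midpoints(self):
        base = np.concatenate([np.zeros(15), np.full(10, 2.0), np.zeros(15)])
        a = LabeledProfile(_profile(base), 15, 25)
        b = LabeledProfile(_profile(np.roll(base, 4)), 19, 29)
        t = build_template([a, b])
        seg = t.values[t.turn_lower : t.turn_upper]
        np.testing.assert_allclose(seg, 2.0, atol=1e-12)

    def test_mismatched_dz_rejected(self):
        a = LabeledProfile(_profile(np.zeros(20), dz=1.5), 5, 10)
        b = LabeledProfile(_profile(np.zeros(20), dz=1.0), 5, 10)
        with pytest.raises(ValueError, match="dz"):
            build_template([a, b])

    def test_rough_region_contains_true_turns_on_held_out(self, default_spec, templates):
        held = generate_profile_population(10, default_spec, seed=55)
        hits = 0
        for lp in held:
            m, _ = cross_correlate(lp.profile, templates["L"])
            lo, hi = rough_region(lp.profile, templates["L"], m)
            hits += lo <= lp.turn_lower and lp.turn_upper <= hi
        assert hits == 10


class TestPlanes:
    def _vertical(self, n=20, x=10.0, y=20.0, dz=1.5):
        z = np.arange(n) * dz
        return Centerline("VA", np.column_stack([np.full_like(z, x), np.full_like(z, y), z]))

    def test_vertical_tube_plane(self):
        cl = self._vertical()
        prof = _profile(np.zeros(20))
        turns = detect_turning_points([0, 0, 0, 1, 1, 1, 0, 0, 0])
        turns.k1, turns.k2 = 3, 9
        plane = plan_va_plane(cl, prof, turns)
        np.testing.assert_allclose(plane.normal, [0, 0, 1], atol=1e-9)
        np.testing.assert_allclose(plane.angulation, (0, 0, 0), atol=1e-9)
        assert plane.center[2] == pytest.approx(prof.z_of(6))

    def test_oblique_tube_angulation(self):
        dz = 1.5
        z = np.arange(20) * dz
        cl = Centerline("VA", np.column_stack([np.full_like(z, 5.0), 20 + 0.5 * z, z]))
        prof = _profile(np.full(20, 0.5))
        turns = detect_turning_points(np.r_[np.zeros(5), np.ones(5), np.zeros(5)])
        turns.k1, turns.k2 = 5, 12
        plane = plan_va_plane(cl, prof, turns)
        expect = np.array([0, 0.5, 1.0]) / np.linalg.norm([0, 0.5, 1.0])
        np.testing.assert_allclose(plane.normal, expect, atol=1e-9)
        assert plane.angulation[0] == pytest.approx(np.degrees(np.arctan(0.5)), abs=1e-6)
        assert plane.angulation[1] == pytest.approx(0.0, abs=1e-9)

    def test_angulation_round_trips_to_normal(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            v = rng.normal(size=3)
            v[2] = abs(v[2]) + 0.5
            v /= np.linalg.norm(v)
            z = np.arange(20) * 1.0
            cl = Centerline("VA", np.outer(z / v[2], v) + [10, 20, 0])
            plane = plan_va_plane(cl, _profile(np.zeros(20), dz=1.0), _turns(5, 12))
            back = angles_to_normal(plane.angulation[0], plane.angulation[1])
            np.testing.assert_allclose(back, plane.normal, atol=1e-9)

    def test_normal_invariant_to_point_order(self):
        cl = self._vertical()
        rev = Centerline("VA", cl.points[::-1])
        p1 = plan_ica_plane(cl, (0, 0, 15.0))
        p2 = plan_ica_plane(rev, (0, 0, 15.0))
        np.testing.assert_allclose(p1.normal, p2.normal, atol=1e-9)

    def test_ica_plane_at_turn_height(self):
        cl = self._vertical(x=12.0, y=24.0)
        plane = plan_ica_plane(cl, np.array([50.0, 60.0, 16.5]))
        np.testing.assert_allclose(plane.center, [12.0, 24.0, 16.5], atol=1e-9)
        np.testing.assert_allclose(plane.normal, [0, 0, 1], atol=1e-9)


def _turns(k1, k2):
    from pcplan.planning import TurningPointPair

    return TurningPointPair(k1=k1, k2=k2, v_total=0.0)


class TestPlanAll:
    def test_default_phantom_four_planes(self, phantom_default, templates):
        volume, _ = phantom_default
        res = plan_all(volume, templates["L"], templates["R"])
        assert res.overall == "ok"
        assert res.n_planes == 4
        for art in res.arteries.values():
            assert abs(np.linalg.norm(art.plane.normal) - 1) < 1e-9

    def test_both_vas_dropped_aborts(self, templates):
        volume, _ = generate_phantom(PhantomSpec(seed=21, drop_arteries=("LVA", "RVA")))
        res = plan_all(volume, templates["L"], templates["R"])
        assert res.overall == "aborted"
        assert "three arteries" in res.reason or "vertebral" in res.reason

    def test_one_va_dropped_three_planes(self, templates):
        volume, _ = generate_phantom(PhantomSpec(seed=21, drop_arteries=("RVA",)))
        res = plan_all(volume, templates["L"], templates["R"])
        assert res.overall == "ok"
        assert res.n_planes == 3
        # cross-side fallback: the RICA plane comes from the left VA's turn
        assert res.arteries["RICA"].status == "ok"
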