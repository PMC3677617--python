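"""Worm-like-chain mechanics, fitting, calibration and contour accounting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rejmech as rm
from rejmech.config import kbt
from rejmech.constructs import ConstructSpec, Segment
from rejmech.wlc import FitError, fit_wlc_segment

PARAMS = rm.WLCParams(persistence_length_p=0.4, contour_length_Lc=100.0,
                      temperature_T=298.0)


class TestWlcForce:
    def test_zero_extension_gives_zero_force(self):
        assert rm.wlc_force(0.0, PARAMS) == 0.0

    def test_half_contour_closed_form(self):
        # at x = Lc/2 the Marko-Siggia bracket evaluates to exactly 1.25
        expected = kbt(298.0) / 0.4 * 1.25
        assert rm.wlc_force(50.0, PARAMS) == pytest.approx(expected, rel=1e-12)
        assert rm.wlc_force(50.0, PARAMS) == pytest.approx(12.8573, abs=1e-3)

    def test_monotone_increasing(self):
        assert rm.wlc_force(0.9 * 100, PARAMS) > rm.wlc_force(0.5 * 100, PARAMS)
        xs = np.linspace(0, 99.0, 200)
        forces = rm.wlc_force(xs, PARAMS)
        assert np.all(np.diff(forces) > 0)

    def test_divergence_near_contour_length(self):
        assert rm.wlc_force(0.999 * 100, PARAMS) > 1e4

    @pytest.mark.parametrize("x", [-1.0, 100.0, 150.0])
    def test_domain_errors_name_offending_value(self, x):
        with pytest.raises(ValueError, match=f"{x:g}"):
            rm.wlc_force(x, PARAMS)

    @given(st.floats(min_value=0.05, max_value=2.0),
           st.floats(min_value=10.0, max_value=500.0),
           st.floats(min_value=0.01, max_value=0.99))
    @settings(max_examples=50, derandomize=True)
    def test_force_nonnegative_and_finite(self, p, lc, frac):
        params = rm.WLCParams(p, lc, 298.0)
        f = rm.wlc_force(frac * lc, params)
        assert np.isfinite(f) and f >= 0


class TestInvertWlc:
    def test_zero_force_maps_to_zero(self):
        assert rm.invert_wlc(0.0, PARAMS) == 0.0

    def test_known_value_round_trip(self):
        assert rm.invert_wlc(12.857303125, PARAMS) == pytest.approx(50.0, abs=1e-6)

    @pytest.mark.parametrize("x", [1.0, 25.0, 80.0])
    def test_round_trip_identity(self, x):
        assert abs(rm.invert_wlc(rm.wlc_force(x, PARAMS), PARAMS) - x) < 1e-6

    def test_round_trip_on_grid(self):
        for x in np.linspace(0.5, 99.0, 50):
            assert abs(rm.invert_wlc(rm.wlc_force(x, PARAMS), PARAMS) - x) < 1e-6

    def test_negative_force_rejected(self):
        with pytest.raises(ValueError):
            rm.invert_wlc(-1.0, PARAMS)


class TestFitWlcSegment:
    def _sample(self, lc=120.0, p=0.4, n=60, fmax=250.0):
        gen = rm.WLCParams(p, lc, 298.0)
        x_hi = rm.invert_wlc(fmax, gen)
        xs = np.linspace(2.0, x_hi, n)
        return np.column_stack([xs, rm.wlc_force(xs, gen)])

    def test_noiseless_recovery_exact(self):
        fit = fit_wlc_segment(self._sample(), p_fixed=0.4)
        assert fit.params.contour_length_Lc == pytest.approx(120.0, abs=0.01)
        # generating Lc recovered to < 0.1%
        assert abs(fit.params.contour_length_Lc - 120.0) / 120.0 < 1e-3

    def test_noisy_recovery_coverage(self):
        # 100 replicates with 5 pN force noise: >= 95% land within 2 nm
        pts = self._sample()
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = pts + np.column_stack(
                [np.zeros(len(pts)), rng.normal(0, 5.0, len(pts))]
            )
            fit = fit_wlc_segment(noisy, p_fixed=0.4)
            hits += abs(fit.params.contour_length_Lc - 120.0) < 2.0
        assert hits >= 95

    def test_deterministic(self):
        pts = self._sample()
        a = fit_wlc_segment(pts, p_fixed=0.4)
        b = fit_wlc_segment(pts, p_fixed=0.4)
        assert a.params.contour_length_Lc == b.params.contour_length_Lc

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            fit_wlc_segment(self._sample(n=3))

    def test_degenerate_flat_segment_signalled(self):
        pts = np.column_stack([np.linspace(0, 10, 20), np.zeros(20)])
        with pytest.raises(FitError):
            fit_wlc_segment(pts)

    def test_free_persistence_length(self):
        fit = fit_wlc_segment(self._sample(), p_fixed=None)
        assert fit.p_was_free
        assert fit.params.persistence_length_p == pytest.approx(0.4, rel=0.05)


class TestEquipartition:
    def test_reference_cantilever(self):
        k = rm.spring_constant_equipartition(0.08229, 298.0)
        assert k == pytest.approx(50.0, abs=0.01)

    def test_inverse_proportionality(self):
        k1 = rm.spring_constant_equipartition(0.05)
        k2 = rm.spring_constant_equipartition(0.10)
        assert k1 == pytest.approx(2 * k2, rel=1e-12)

    @pytest.mark.parametrize("var", [0.0, -1.0])
    def test_nonpositive_variance_rejected(self, var):
        with pytest.raises(ValueError):
            rm.spring_constant_equipartition(var)


class TestChainContourLength:
    def test_single_i27_unfolded_and_delta(self):
        c = ConstructSpec("one-I27", (Segment("I27-1", "I27", 89, True, "I27"),))
        unfolded = rm.chain_contour_length(c, state=[False])
        folded = rm.chain_contour_length(c, state=[True])
        assert unfolded == pytest.approx(32.485, abs=0.01)
        # released increment consistent with the ~29 +/- 8 nm I27 fingerprint
        assert unfolded - folded == pytest.approx(28.085, abs=0.01)

    def test_rejd4_coil_length(self):
        c = ConstructSpec("coil", (Segment("REJd4", "coil", 108, False),))
        assert rm.chain_contour_length(c) == pytest.approx(39.42, abs=0.01)

    def test_unfolding_strictly_increases(self, i27_construct):
        folded = [s.folded for s in i27_construct.segments]
        base = rm.chain_contour_length(i27_construct, state=folded)
        for i, seg in enumerate(i27_construct.segments):
            if not seg.folded:
                continue
            state = list(folded)
            state[i] = False
            assert rm.chain_contour_length(i27_construct, state=state) > base

    def test_additive_and_order_independent(self):
        segs = (Segment("a", "I27", 89, True, "I27"),
                Segment("b", "coil", 50, False),
                Segment("c", "FNIII", 89, True, "x"))
        total = rm.chain_contour_length(ConstructSpec("abc", segs),
                                        state=[True, False, True])
        parts = sum(
            rm.chain_contour_length(ConstructSpec(s.name, (s,)), state=[s.folded])
            for s in segs
        )
        assert total == pytest.approx(parts, abs=1e-12)

    def test_unknown_domain_class_rejected(self):
        c = ConstructSpec("bad", (Segment("z", "mystery", 10, True, "z"),))
        with pytest.raises(KeyError, match="mystery"):
            rm.chain_contour_length(c, state=[True])

    def test_state_length_mismatch_rejected(self, i27_construct):
        with pytest.raises(ValueError):
            rm.chain_contour_length(i27_construct, state=[True])
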