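"""Finite-difference partials, M, grids and isopleths."""

import math

import numpy as np
import pytest

from heatsens.indices import IndexValue, swbgt, utci, wbt
from heatsens.psychro import AirState
from heatsens.variational import (
    FDScheme,
    MASK_INDEX_UNDEFINED,
    MASK_M_INFINITE,
    MASK_OUTSIDE_ENVELOPE,
    REGIMES,
    default_axes,
    delta_m,
    evaluate_along,
    m_grid,
    marginal_m,
    partial_h,
    partial_t,
    regime_summary,
    trace_isopleth,
)


def linear_index(a: float, b: float, c: float = 0.0):
    """Synthetic index U = a*T + b*h + c with known exact partials."""

    def ev(state: AirState) -> IndexValue:
        return IndexValue(a * state.t_c + b * state.rh_pct + c)

    return ev


class TestPartials:
    @pytest.mark.parametrize("mode", ["forward", "central"])
    def test_exact_on_linear_fields(self, mode):
        scheme = FDScheme(mode=mode)
        s = AirState(25.0, 50.0)
        assert partial_t(linear_index(1.0, 0.0), s, scheme).value == pytest.approx(1.0)
        assert partial_t(linear_index(2.0, 1.0), s, scheme).value == pytest.approx(2.0)
        assert partial_h(linear_index(0.0, 1.0), s, scheme).value == pytest.approx(1.0)
        assert partial_h(linear_index(1.0, 0.0), s, scheme).value == pytest.approx(0.0)

    def test_forward_central_agree_on_wbt(self):
        s = AirState(30.0, 50.0)
        f = partial_t(wbt, s, FDScheme(0.1, 0.1, "forward")).value
        c = partial_t(wbt, s, FDScheme(0.01, 0.01, "central")).value
        assert f == pytest.approx(c, abs=0.01)

    def test_saturation_boundary_backward_step_flagged(self):
        r = partial_h(swbgt, AirState(30.0, 100.0))
        assert r.defined and r.boundary
        # one-sided value still approximates the true slope
        inner = partial_h(swbgt, AirState(30.0, 99.0))
        assert r.value == pytest.approx(inner.value, rel=0.05)

    def test_undefined_stencil_propagates_reason(self):
        # e crosses 5 kPa within the stencil at this state
        r = partial_t(utci, AirState(50.0, 16.0))
        assert not r.defined and r.reason == "T_LIMIT"


class TestMarginalM:
    def test_ratio_on_linear_index(self):
        m = marginal_m(linear_index(1.0, 0.1), AirState(25.0, 50.0))
        assert m.value == pytest.approx(10.0)

    def test_infinite_sentinel_for_humidity_flat_index(self):
        m = marginal_m(linear_index(1.0, 0.0), AirState(25.0, 50.0))
        assert m.defined and m.infinite and math.isinf(m.value)
        assert m.reason == "M_INFINITE"

    def test_utci_low_temperature_dominance(self):
        m = marginal_m(utci, AirState(20.0, 50.0))
        assert m.finite and m.value >= 15.0

    @pytest.mark.parametrize(
        "transform",
        [lambda v: 2.0 * v, lambda v: v ** 3 + v, lambda v: math.exp(v / 20.0)],
        ids=["2U", "U^3+U", "exp(U/20)"],
    )
    @pytest.mark.parametrize("base", [swbgt, wbt], ids=["SWBGT", "WBT"])
    def test_invariant_under_monotone_rescaling(self, base, transform):
        """M is a ratio of partials, so any increasing rescale cancels."""

        def rescaled(state: AirState) -> IndexValue:
            v = base(state)
            return IndexValue(transform(v.value)) if v.defined else v

        for t, h in [(25.0, 40.0), (33.0, 70.0)]:
            m0 = marginal_m(base, AirState(t, h)).value
            m1 = marginal_m(rescaled, AirState(t, h)).value
            assert m1 == pytest.approx(m0, rel=0.02)

    def test_forward_central_gap_halves_with_step(self):
        s = AirState(30.0, 50.0)
        gaps = []
        for d in (0.4, 0.2, 0.1):
            mf = marginal_m(swbgt, s, FDScheme(d, d, "forward")).value
            mc = marginal_m(swbgt, s, FDScheme(d, d, "central")).value
            gaps.append(abs(mf - mc))
        assert gaps[1] / gaps[0] == pytest.approx(0.5, abs=0.15)
        assert gaps[2] / gaps[1] == pytest.approx(0.5, abs=0.15)


class TestDeltaM:
    def test_identity_and_antisymmetry(self):
        s = AirState(30.0, 50.0)
        assert delta_m(utci, utci, s).value == 0.0
        ab = delta_m(utci, wbt, s).value
        ba = delta_m(wbt, utci, s).value
        assert ab == -ba  # exact to floating round-off

    def test_undefined_when_either_m_infinite(self):
        s = AirState(25.0, 50.0)
        r = delta_m(linear_index(1.0, 0.0), wbt, s)
        assert not r.defined and "M_INFINITE" in r.reason


class TestMGrid:
    def test_constant_field_for_linear_index(self):
        field = m_grid(
            linear_index(1.0, 0.2),
            np.arange(10.0, 30.1, 5.0),
            np.arange(20.0, 80.1, 20.0),
            index_name="LIN",
        )
        assert np.allclose(field.values, 5.0)
        assert (field.mask == 0).all()

    def test_wbt_m_varies_less_than_utci(self):
        """WBT's humidity weighting is nearly condition-independent."""
        t_axis = np.arange(5.0, 45.1, 4.0)
        h_axis = np.arange(10.0, 95.1, 10.0)
        f_wbt = m_grid(wbt, t_axis, h_axis, index_name="WBT")
        f_utci = m_grid(utci, t_axis, h_axis, index_name="UTCI")
        rng_wbt = np.nanmax(f_wbt.values) - np.nanmin(f_wbt.values)
        rng_utci = np.nanmax(f_utci.values) - np.nanmin(f_utci.values)
        assert rng_wbt < rng_utci

    def test_envelope_masking_matches_contains(self):
        from heatsens.envelope import synthetic_envelope

        env = synthetic_envelope(bin_width=5.0)
        t_axis = np.arange(20.0, 55.1, 5.0)
        h_axis = np.arange(10.0, 100.1, 15.0)
        field = m_grid(wbt, t_axis, h_axis, envelope=env, index_name="WBT")
        for i, t in enumerate(t_axis):
            for j, h in enumerate(h_axis):
                inside = env.contains(AirState(float(t), float(h)))
                assert (field.mask[i, j] == MASK_OUTSIDE_ENVELOPE) == (not inside)

    def test_mask_codes_distinct(self):
        # UTCI undefined in the hot-humid corner; humidity-flat synthetic
        # index infinite everywhere
        field = m_grid(utci, np.array([48.0]), np.array([80.0]), index_name="UTCI")
        assert field.mask[0, 0] == MASK_INDEX_UNDEFINED
        flat = m_grid(
            linear_index(1.0, 0.0), np.array([20.0]), np.array([50.0]), index_name="F"
        )
        assert flat.mask[0, 0] == MASK_M_INFINITE

    def test_empty_axes_rejected(self):
        with pytest.raises(ValueError):
            m_grid(wbt, np.array([]), np.array([50.0]))

    def test_long_format_round_trip(self):
        field = m_grid(
            swbgt, np.array([20.0, 25.0]), np.array([40.0, 60.0]), index_name="SWBGT"
        )
        df = field.to_frame()
        assert list(df.columns) == [
            "t_c", "rh_pct", "index", "m_pct_per_degc", "mask_code"
        ]
        assert len(df) == 4 and (df["index"] == "SWBGT").all()


class TestIsopleths:
    def test_vertical_line_for_temperature_field(self):
        iso = trace_isopleth(
            linear_index(1.0, 0.0), 30.0,
            np.arange(20.0, 40.1, 1.0), np.arange(0.0, 100.1, 10.0),
        )
        assert not iso.empty
        assert np.allclose(iso.points[:, 0], 30.0, atol=1e-9)
        assert iso.points[:, 1].min() == 0.0 and iso.points[:, 1].max() == 100.0

    def test_horizontal_line_for_humidity_field(self):
        iso = trace_isopleth(
            linear_index(0.0, 1.0), 50.0,
            np.arange(20.0, 40.1, 5.0), np.arange(0.0, 100.1, 5.0),
        )
        assert not iso.empty
        assert np.allclose(iso.points[:, 1], 50.0, atol=1e-9)

    def test_points_reevaluate_to_level(self):
        t_axis = np.arange(18.0, 50.01, 0.5)
        h_axis = np.arange(1.0, 100.01, 1.0)
        iso = trace_isopleth(wbt, 20.0, t_axis, h_axis, index_name="WBT")
        assert not iso.empty
        for t, h in iso.points[::10]:
            assert wbt(AirState(float(t), float(h))).value == pytest.approx(
                20.0, abs=0.05
            )

    def test_passes_saturation_anchor_and_ordered_humidity(self):
        iso = trace_isopleth(
            wbt, 20.0, np.arange(18.0, 50.01, 0.5), np.arange(1.0, 100.01, 1.0)
        )
        pts = iso.points
        # monotone humidity ordering within each branch
        for branch in iso.branches:
            assert branch[0, 1] <= branch[-1, 1]
        # saturation anchor: WBT = T at rh = 100
        top = pts[np.argmax(pts[:, 1])]
        assert top[1] == pytest.approx(100.0, abs=1.0)
        assert top[0] == pytest.approx(20.0, abs=0.1)
        # extends into hot-dry territory
        assert pts[:, 0].max() > 45.0 and pts[:, 1].min() < 10.0

    def test_unbracketed_level_empty_flagged(self):
        iso = trace_isopleth(
            wbt, 99.0, np.arange(20.0, 30.1, 2.0), np.arange(10.0, 90.1, 20.0)
        )
        assert iso.empty and iso.points.shape == (0, 2)

    def test_evaluate_along_self_is_constant(self):
        t_axis = np.arange(20.0, 45.01, 1.0)
        h_axis = np.arange(5.0, 100.01, 5.0)
        iso = trace_isopleth(swbgt, 25.0, t_axis, h_axis, index_name="SWBGT")
        df = evaluate_along(iso, swbgt)
        assert df["defined"].all()
        assert np.allclose(df["value"], 25.0, atol=0.05)


class TestRegimeSummary:
    def test_hot_humid_regime_all_indices_agree(self):
        """In hot-humid conditions every index is humidity-sensitive:
        finite M of at most 10 % RH per degC across the whole registry."""
        from heatsens.indices import REGISTRY

        df = regime_summary(dict(REGISTRY))
        humid = df[df["regime"] == "hot_humid"]
        assert len(humid) == 8
        assert humid["defined"].all() and not humid["infinite"].any()
        assert (humid["m_pct_per_degc"] <= 10.0).all()

    def test_canonical_points_and_orderings(self):
        df = regime_summary({"WBT": wbt, "UTCI": utci})
        assert set(df["regime"]) == set(REGIMES)
        pivot = df.pivot(index="index", columns="regime", values="m_pct_per_degc")
        # temperature dominates UTCI at low temperature, not WBT
        assert pivot.loc["UTCI", "low_temperature"] > pivot.loc["WBT", "low_temperature"]
        # hot-dry: UTCI exceeds WBT as well
        assert pivot.loc["UTCI", "hot_dry"] > pivot.loc["WBT", "hot_dry"]

    def test_units_invariance_of_cross_index_ordering(self):
        """Which index weights humidity most is the same question whether
        humidity is measured as relative or specific humidity: at a fixed
        state the representation change rescales every index's M by the
        same positive factor."""
        from heatsens.psychro import rh_from_specific_humidity, specific_humidity

        def m_in_q(ev, t, h, dq=1e-5, dt=0.1):
            q0 = specific_humidity(t, h)
            u0 = ev(AirState(t, h)).value
            ut = ev(AirState(t + dt, h)).value
            hq = rh_from_specific_humidity(q0 + dq, t)
            uq = ev(AirState(t, hq)).value
            return ((ut - u0) / dt) / ((uq - u0) / dq)

        evaluators = {"WBT": wbt, "UTCI": utci, "SWBGT": swbgt}
        for regime, (t, h) in REGIMES.items():
            m_h = {n: marginal_m(ev, AirState(t, h)).value for n, ev in evaluators.items()}
            m_q = {n: m_in_q(ev, t, h) for n, ev in evaluators.items()}
            assert sorted(m_h, key=m_h.get) == sorted(m_q, key=m_q.get), regime


def test_default_axes_match_figure_domain():
    t_axis, h_axis = default_axes()
    assert t_axis[0] == 0.0 and t_axis[-1] == 50.0
    assert h_axis[0] == 1.0 and h_axis[-1] == 100.0
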