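"""Core polymer statistics: geometry limits, identities, turn length, volumes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helixchrom.polymer import (
    PolymerDomainError,
    PolymerModel,
    SingularSeparationError,
    crosslink_frequency,
    fiber_reference_density,
    helix_turn_kb,
    helix_turn_length,
    helix_turn_length_approx,
    helix_volumetric_density,
    kuhn_segments,
    kuhn_segments_from_distance,
    mean_spatial_distance,
    predict_spatial_distance_curve,
    volume_report,
    volumetric_density,
)

LINEAR = PolymerModel(family="linear", S=2.709, L=9.6)
CIRCULAR = PolymerModel(family="circular", S=2.515, c=110.515, L=9.6)


def helix(D=292.03, P=162.13, S=2.709, L=9.6, k=1.0):
    return PolymerModel(family="helix", S=S, D=D, P=P, L=L, k=k)


# ---------------------------------------------------------------------------
# spatial distance geometry
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("model", [LINEAR, CIRCULAR, helix()])
def test_coincident_sites_have_zero_distance(model):
    assert mean_spatial_distance(model, 0.0) == 0.0
    assert kuhn_segments(model, 0.0) == 0.0


def test_closed_circle_limit_is_periodic():
    """P = 0 reduces the helix to a circle of size D: period pi D / L kb."""
    m = helix(D=300.0, P=0.0)
    period = math.pi * 300.0 / 9.6
    s = np.linspace(0.1, period * 0.99, 64)
    r = mean_spatial_distance(m, s)
    r_shift = mean_spatial_distance(m, s + period)
    np.testing.assert_allclose(r, r_shift, rtol=1e-9, atol=1e-9)
    assert mean_spatial_distance(m, period) == pytest.approx(0.0, abs=1e-9)
    # chord of a circle with diameter D: maximal at the half turn
    assert mean_spatial_distance(m, period / 2) == pytest.approx(300.0, rel=1e-12)


def test_full_turn_distance_equals_step(fig_helix):
    """At one full geometric turn the chord vanishes and <R> = P."""
    s_turn = helix_turn_kb(fig_helix)
    assert mean_spatial_distance(fig_helix, s_turn) == pytest.approx(
        fig_helix.P, rel=1e-12
    )


def test_circular_arc_symmetry():
    s = np.linspace(0.0, CIRCULAR.c, 41)
    np.testing.assert_allclose(
        kuhn_segments(CIRCULAR, s), kuhn_segments(CIRCULAR, CIRCULAR.c - s), rtol=1e-12
    )


def test_one_kuhn_segment_per_segment_length():
    assert kuhn_segments(LINEAR, LINEAR.S) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# substitution identities: each family's beta equals (<R>/(S L))^2
# ---------------------------------------------------------------------------

@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    family=st.sampled_from(["linear", "circular", "helix"]),
    S=st.floats(0.5, 10.0),
    L=st.sampled_from([9.6, 11.1]),
    c=st.floats(50.0, 500.0),
    D=st.floats(10.0, 800.0),
    P=st.floats(0.0, 600.0),
    frac=st.floats(1e-3, 1.0),
)
def test_beta_matches_distance_substitution(family, S, L, c, D, P, frac):
    model = PolymerModel(family=family, S=S, L=L, c=c, D=D, P=P)
    s = frac * (c if family == "circular" else 340.0)
    direct = kuhn_segments(model, s)
    via_distance = kuhn_segments_from_distance(model, mean_spatial_distance(model, s))
    assert abs(direct - via_distance) < 1e-9 * max(1.0, direct)


# ---------------------------------------------------------------------------
# crosslinking frequency
# ---------------------------------------------------------------------------

def test_frequency_is_linear_in_k(fig_helix):
    s = np.array([10.0, 60.0, 94.0, 200.0])
    doubled = fig_helix.with_params(k=2.0)
    np.testing.assert_allclose(
        crosslink_frequency(doubled, s), 2.0 * crosslink_frequency(fig_helix, s),
        rtol=1e-12,
    )


def test_frequency_singular_at_zero(fig_helix):
    with pytest.raises(SingularSeparationError):
        crosslink_frequency(fig_helix, 0.0)


def test_linear_decay_is_monotone_past_mode():
    """Beyond the small-s mode (~1.2 S) the linear-chain X(s) only decreases."""
    s = np.linspace(1.3 * LINEAR.S, 500.0, 5000)
    x = crosslink_frequency(LINEAR, s)
    assert np.all(np.diff(x) < 0)


def test_modulation_direction_at_best_fit(fig_helix):
    """Collisions around 100 kb beat those around 60 kb for the fitted helix."""
    assert crosslink_frequency(fig_helix, 100.0) > crosslink_frequency(fig_helix, 60.0)


def test_negative_separation_rejected(fig_helix):
    with pytest.raises(PolymerDomainError):
        mean_spatial_distance(fig_helix, -1.0)
    with pytest.raises(PolymerDomainError):
        mean_spatial_distance(CIRCULAR, CIRCULAR.c + 1.0)


def test_outputs_finite_over_parameter_neighborhood():
    """All quantities stay finite for s in (0, 1e4] with params +/-50% of best fit."""
    s = np.geomspace(0.01, 1e4, 200)
    for scale_D in (0.5, 1.0, 1.5):
        for scale_P in (0.5, 1.0, 1.5):
            m = helix(D=292.03 * scale_D, P=162.13 * scale_P, S=2.709, k=1.0)
            assert np.isfinite(mean_spatial_distance(m, s)).all()
            assert np.isfinite(crosslink_frequency(m, s)).all()


# ---------------------------------------------------------------------------
# turn length (second derivative method)
# ---------------------------------------------------------------------------

def test_turn_length_matches_reference(fig_helix):
    """First X(s) maximum past the initial decay: 94.090 kb at the best fit."""
    sh = helix_turn_length(fig_helix)
    assert sh == pytest.approx(94.090, abs=1.6)


def test_turn_length_agrees_with_grid_oracle():
    m = helix(D=290.0, P=160.0, S=2.709)
    sh = helix_turn_length(m)
    sh_grid = helix_turn_length(m, grid_step=0.001)
    assert abs(sh - sh_grid) < 0.01
    assert abs(sh - helix_turn_length_approx(m)) < 0.5


def test_turn_length_requires_helix():
    with pytest.raises(PolymerDomainError):
        helix_turn_length(LINEAR)


# ---------------------------------------------------------------------------
# volumetrics
# ---------------------------------------------------------------------------

def test_fiber_reference_density_value():
    """Cylinder of a 30-nm fiber advancing 9.6 nm per kb: ~6.8e3 nm^3/kb."""
    assert fiber_reference_density() == pytest.approx(6.8e3, rel=0.01)


def test_density_scaling_homogeneity():
    """V = pi (D/2)^2 R / s is quadratic in D and linear in R."""
    base = volumetric_density(30.0, 9.6, 1.0)
    assert volumetric_density(60.0, 9.6, 1.0) == pytest.approx(4 * base)
    assert volumetric_density(30.0, 19.2, 1.0) == pytest.approx(2 * base)
    assert volumetric_density(30.0, 9.6, 2.0) == pytest.approx(base / 2)


def test_density_rejects_degenerate_inputs():
    with pytest.raises(PolymerDomainError):
        volumetric_density(30.0, 9.6, 0.0)


def test_volume_report(fig_helix):
    rep = volume_report(fig_helix, diploid_genome_kb=6.0e6, nucleus_diameter_um=10.0)
    assert rep.Vs == pytest.approx(1.02e5, rel=0.05)
    assert rep.fold == pytest.approx(rep.Vs / rep.V_fiber, rel=1e-12)
    assert rep.fold == pytest.approx(15.00, abs=0.73)
    assert rep.genome_volume == pytest.approx(610.0, rel=0.03)
    assert rep.nucleus_volume == pytest.approx((4 / 3) * math.pi * 125.0, rel=1e-12)
    # a diploid genome folded as the helix overfills a 10-um nucleus
    assert rep.genome_volume > rep.nucleus_volume


def test_helix_density_requires_positive_geometry():
    with pytest.raises(PolymerDomainError):
        helix_volumetric_density(helix(P=0.0))


# ---------------------------------------------------------------------------
# spatial distance prediction curves
# ---------------------------------------------------------------------------

def test_distance_curve_trivial_grid():
    out = predict_spatial_distance_curve(LINEAR, [0.0])
    assert out["R_nm"].tolist() == [0.0]


def test_helix_curve_oscillates_then_grows(fig_helix):
    grid = np.linspace(1.0, 2000.0, 4000)
    curve = predict_spatial_distance_curve(fig_helix, grid)["R_nm"].to_numpy()
    short = curve[grid <= 200.0]
    assert np.any(np.diff(short) < 0)  # non-monotonic below ~200 kb
    # asymptotic slope = axial rise per kb = P / turn
    slope = (curve[-1] - curve[2000]) / (grid[-1] - grid[2000])
    assert slope == pytest.approx(fig_helix.P / helix_turn_kb(fig_helix), rel=0.05)


def test_helix_and_linear_curves_cross_below_1mb(fig_helix):
    grid = np.linspace(1.0, 1000.0, 5000)
    diff = (
        predict_spatial_distance_curve(fig_helix, grid)["R_nm"].to_numpy()
        - predict_spatial_distance_curve(LINEAR, grid)["R_nm"].to_numpy()
    )
    assert np.any(np.sign(diff[:-1]) != np.sign(diff[1:]))


def test_distance_curve_envelope_widens_with_se(fig_helix):
    grid = np.linspace(10.0, 300.0, 30)
    curve = predict_spatial_distance_curve(fig_helix, grid, se={"D": 4.80, "P": 8.75})
    width = curve["R_hi_nm"] - curve["R_lo_nm"]
    assert (width > 0).all()


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

def test_model_serialization_round_trip(fig_helix):
    assert PolymerModel.from_json(fig_helix.to_json()) == fig_helix


def test_model_validation():
    with pytest.raises(ValueError):
        PolymerModel(family="helix", S=2.7)  # D, P missing
    with pytest.raises(ValueError):
        PolymerModel(family="circular", S=2.7)  # c missing
    with pytest.raises(ValueError):
        PolymerModel(family="linear", S=-1.0)
    with pytest.raises(ValueError):
        PolymerModel.from_dict({"family": "linear", "S": 1.0, "bogus": 1})
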