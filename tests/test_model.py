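"""Core cascade: examples frozen from an extended-precision oracle, plus
property tests for the model's structural invariants.

Expected values marked 'oracle' were computed once with 40-digit mpmath
arithmetic directly from the closed-form definitions and frozen here.
"""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoseed import (
    ConversionParams,
    ExtrapolationWarning,
    FractionSurfaceParams,
    FruitSetQuadParams,
    LinearLinkParams,
    ModelParams,
    ParameterError,
    PollenBetaParams,
    derive_beta_shape,
    duration_interpolation,
    fraction_surface,
    fruit_mass,
    germinated_pollen,
    pollen_count_to_number,
    pollen_number,
    predict_fruit_mass,
    predict_table,
    seed_number,
    truss_yield,
    viable_pollen,
)

# extended-precision oracle values (40-digit arithmetic on the closed forms)
ALPHA_ORACLE = 0.2770145197464938
BETA_ORACLE = 1.662087118478963
POLLEN_14 = 52110.32595813555
POLLEN_30 = 39691.44293556308
VIABLE_CTRL = 62134.0          # 0.94 * 6.61e4
GERM_CTRL = 19261.54           # 0.31 * 0.94 * 6.61e4
SEEDS_CTRL = 33.048464         # 1.6e-3 * GERM_CTRL + 2.23
MASS_CTRL = 4.637780192        # 7.8e-2 * SEEDS_CTRL + 2.06
MASS_COLLAPSED = 2.23394       # 7.8e-2 * 2.23 + 2.06 (no germinated pollen)


def beta_params_strategy():
    """Valid pollen beta parameterisations over a broad physical range.

    mu is kept below ln(N_star) so the derived exponents stay positive and
    the stationary point at T_opt is a maximum (the physical regime).
    """
    return st.builds(
        PollenBetaParams,
        mu=st.floats(0.0, 9.0),
        T_b=st.floats(0.0, 15.0),
        T_c=st.floats(35.0, 60.0),
        T_opt=st.floats(16.0, 30.0),
        T_0=st.just(1.0),
        N_star=st.floats(1e4, 1e6),
    )


class TestBetaShape:
    def test_published_shape_values(self, params):
        alpha, beta = derive_beta_shape(params.pollen_beta)
        assert alpha == pytest.approx(ALPHA_ORACLE, rel=1e-12)
        assert beta == pytest.approx(BETA_ORACLE, rel=1e-12)
        assert round(beta, 2) == 1.66
        assert round(alpha, 2) == 0.28

    def test_flat_exponent_limit(self):
        # mu = ln(N_star) makes the numerator vanish: a flat exponent pair
        p = PollenBetaParams(mu=math.log(6.61e4))
        alpha, beta = derive_beta_shape(p)
        assert alpha == 0.0 and beta == 0.0

    def test_degenerate_denominator_raises(self):
        # delta1 = delta2 = 1 makes delta3*ln(delta1) + ln(delta2) == 0
        p = PollenBetaParams(mu=1.0, T_b=17.0, T_c=19.0, T_opt=18.0, N_star=10.0)
        with pytest.raises(ParameterError, match="degenerate"):
            derive_beta_shape(p)


class TestPollenNumber:
    def test_peak_equals_n_star(self, params):
        assert pollen_number(18.0, params.pollen_beta) == pytest.approx(
            6.61e4, rel=1e-9
        )

    @pytest.mark.parametrize("T", [13.0, 48.0, 5.0, 60.0])
    def test_zero_at_and_beyond_boundaries(self, params, T):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ExtrapolationWarning)
            assert pollen_number(T, params.pollen_beta) == 0.0

    @pytest.mark.parametrize(
        "T, expected", [(14.0, POLLEN_14), (30.0, POLLEN_30)]
    )
    def test_oracle_values(self, params, T, expected):
        assert pollen_number(T, params.pollen_beta) == pytest.approx(
            expected, rel=1e-9
        )

    def test_cold_side_steeper(self, params):
        # equal offsets below/above the optimum: the cold side falls faster
        assert pollen_number(14.0, params.pollen_beta) < pollen_number(
            22.0, params.pollen_beta
        )

    def test_vectorised_matches_scalar(self, params):
        T = np.array([14.0, 18.0, 30.0, 34.0])
        vec = pollen_number(T, params.pollen_beta)
        assert vec == pytest.approx([pollen_number(t, params.pollen_beta) for t in T])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(p=beta_params_strategy())
    def test_peak_identity_property(self, p):
        """The constrained shape makes the curve peak at T_opt with value N_star."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ExtrapolationWarning)
            assert pollen_number(p.T_opt, p) == pytest.approx(p.N_star, rel=1e-9)
            # and it is a maximum: neighbours are not higher
            eps = 0.01
            assert pollen_number(p.T_opt - eps, p) <= p.N_star * (1 + 1e-9)
            assert pollen_number(p.T_opt + eps, p) <= p.N_star * (1 + 1e-9)


class TestDurationInterpolation:
    @pytest.mark.parametrize(
        "D, t1, t2, expected",
        [
            (0.0, 0.78, -0.11, 0.78),
            (4.0, 0.78, -0.11, -0.98),
            (4.0, 0.34, -0.06, -0.62),
        ],
    )
    def test_latent_level(self, D, t1, t2, expected):
        assert duration_interpolation(D, t1, t2) == pytest.approx(expected)


class TestFractionSurface:
    @pytest.mark.parametrize("D", [0.0, 1.0, 3.0, 4.0, 6.0, 8.0])
    def test_vertex_identity_viability(self, params, D):
        assert fraction_surface(18.0, D, params.viability) == pytest.approx(
            0.94, abs=1e-12
        )

    @pytest.mark.parametrize("D", [0.0, 1.0, 3.0, 4.0, 6.0, 8.0])
    def test_vertex_identity_germination(self, params, D):
        assert fraction_surface(18.0, D, params.germination) == pytest.approx(
            0.31, abs=1e-12
        )

    def test_oracle_value_off_vertex(self, params):
        assert fraction_surface(30.0, 4.0, params.viability) == pytest.approx(
            0.08666666666666667, abs=1e-12
        )

    def test_clamped_to_zero(self, params):
        assert fraction_surface(34.0, 6.0, params.germination) == 0.0

    def test_clamped_to_one(self):
        # a latent level above 1 cannot push the fraction above 1
        p = FractionSurfaceParams(alpha_max=0.5, theta1=2.0, theta2=0.0, T_opt=18.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ExtrapolationWarning)
            assert fraction_surface(1.0, 0.0, p) == 1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        alpha=st.floats(0.05, 1.0),
        t1=st.floats(-1.0, 1.0),
        t2=st.floats(-0.5, 0.0),
        D=st.floats(0.0, 8.0),
    )
    def test_vertex_identity_property(self, alpha, t1, t2, D):
        p = FractionSurfaceParams(alpha_max=alpha, theta1=t1, theta2=t2, T_opt=18.0)
        assert fraction_surface(18.0, D, p) == pytest.approx(alpha, abs=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        T=st.floats(14.0, 34.0),
        d_pair=st.tuples(st.floats(0.0, 8.0), st.floats(0.0, 8.0)),
    )
    def test_duration_monotone_for_negative_theta2(self, params, T, d_pair):
        """Away from the optimum, longer stress never raises the fraction."""
        d_lo, d_hi = sorted(d_pair)
        f_lo = fraction_surface(T, d_lo, params.viability)
        f_hi = fraction_surface(T, d_hi, params.viability)
        assert f_hi <= f_lo + 1e-12


class TestCascade:
    def test_viable_pollen_control(self, params):
        assert viable_pollen(
            18.0, 0.0, params.pollen_beta, params.viability
        ) == pytest.approx(VIABLE_CTRL, rel=1e-9)

    def test_viable_zero_below_base(self, params):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ExtrapolationWarning)
            assert viable_pollen(13.0, 4.0, params.pollen_beta, params.viability) == 0.0

    def test_germinated_control(self, params):
        assert germinated_pollen(
            18.0, 0.0, params.pollen_beta, params.viability, params.germination
        ) == pytest.approx(GERM_CTRL, rel=1e-9)

    def test_ordering_single_regime(self, params):
        n_p = pollen_number(14.0, params.pollen_beta)
        n_v = viable_pollen(14.0, 4.0, params.pollen_beta, params.viability)
        n_g = germinated_pollen(
            14.0, 4.0, params.pollen_beta, params.viability, params.germination
        )
        assert 0 < n_g < n_v < n_p

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(T=st.floats(0.0, 50.0), D=st.floats(0.0, 10.0))
    def test_ordering_property(self, params, T, D):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ExtrapolationWarning)
            n_p = pollen_number(T, params.pollen_beta)
            n_v = viable_pollen(T, D, params.pollen_beta, params.viability)
            n_g = germinated_pollen(
                T, D, params.pollen_beta, params.viability, params.germination
            )
        assert 0.0 <= n_g <= n_v + 1e-9 and n_v <= n_p + 1e-9


class TestLinearLinks:
    def test_seed_intercept(self, params):
        assert seed_number(0.0, params.seed_link, params.conversion) == 2.23

    def test_mass_intercept(self, params):
        assert fruit_mass(0.0, params.mass_link) == 2.06

    def test_seed_arithmetic(self, params):
        assert seed_number(10_000.0, params.seed_link, params.conversion) == (
            pytest.approx(18.23)
        )

    def test_mass_arithmetic(self, params):
        assert fruit_mass(20.0, params.mass_link) == pytest.approx(3.62)

    def test_control_chain(self, params):
        seeds = seed_number(GERM_CTRL, params.seed_link, params.conversion)
        assert seeds == pytest.approx(SEEDS_CTRL, rel=1e-9)
        assert fruit_mass(seeds, params.mass_link) == pytest.approx(
            MASS_CTRL, rel=1e-9
        )

    def test_flower_to_fruit_factor_scales_slope_term(self, params):
        conv2 = ConversionParams(c_flower_to_fruit=2.0)
        s1 = seed_number(1000.0, params.seed_link, params.conversion)
        s2 = seed_number(1000.0, params.seed_link, conv2)
        assert s2 - params.seed_link.intercept == pytest.approx(
            2.0 * (s1 - params.seed_link.intercept)
        )


class TestPredictFruitMass:
    def test_control_value(self, params):
        assert predict_fruit_mass(18.0, 0.0, params) == pytest.approx(
            MASS_CTRL, rel=1e-9
        )

    def test_collapsed_cascade_value(self, params):
        """Where germination clamps to 0 the mass falls to m2*b1 + b2.

        At 30 degC for 4 days the germination surface is already clamped at
        zero under the published parameters, so the predicted mass is the
        no-germinated-pollen baseline 2.234 g — noticeably below the ~2.9 g
        scenario value quoted from the unrounded original calibration.  The
        rounded published parameters do not regenerate that scenario.
        """
        assert predict_fruit_mass(30.0, 4.0, params) == pytest.approx(
            MASS_COLLAPSED, rel=1e-12
        )
        assert predict_fruit_mass(34.0, 6.0, params) == pytest.approx(
            MASS_COLLAPSED, rel=1e-12
        )

    def test_composition_identity_bitwise(self, params):
        """The single entry point equals the explicit stage-by-stage chain."""
        for T in np.linspace(5.0, 50.0, 12):
            for D in (0.0, 2.0, 5.0, 8.0):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ExtrapolationWarning)
                    n_g = germinated_pollen(
                        T, D, params.pollen_beta, params.viability, params.germination
                    )
                    chained = fruit_mass(
                        seed_number(n_g, params.seed_link, params.conversion),
                        params.mass_link,
                    )
                    assert predict_fruit_mass(T, D, params) == chained

    def test_output_floor(self, params):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ExtrapolationWarning)
            tt, dd = np.meshgrid(np.linspace(0, 50, 50), np.linspace(0, 10, 20))
            m = predict_fruit_mass(tt, dd, params)
        assert np.all(m >= params.mass_link.intercept)


class TestTrussYield:
    def test_passthrough_when_set_is_one(self, params):
        quad = FruitSetQuadParams(1.0, 0.0, 0.0)
        y = truss_yield(18.0, 0.0, params, n_flowers=9.0, fruit_set=quad)
        assert y == pytest.approx(9.0 * predict_fruit_mass(18.0, 0.0, params))

    def test_zero_when_set_is_zero(self, params):
        quad = FruitSetQuadParams(0.0, 0.0, 0.0)
        assert truss_yield(18.0, 0.0, params, fruit_set=quad) == 0.0

    def test_missing_coefficients_raise(self, params):
        with pytest.raises(ParameterError, match="fruit-set coefficients required"):
            truss_yield(18.0, 0.0, params)

    def test_negative_flowers_raise(self, params):
        quad = FruitSetQuadParams(1.0, 0.0, 0.0)
        with pytest.raises(ParameterError):
            truss_yield(18.0, 0.0, params, n_flowers=-1.0, fruit_set=quad)


class TestPollenCountConversion:
    @pytest.mark.parametrize(
        "count, expected", [(0.0, 0.0), (13.0, 13_000.0), (66.1, 6.61e4)]
    )
    def test_conversion(self, count, expected):
        assert pollen_count_to_number(count) == pytest.approx(expected)

    def test_negative_count_raises(self):
        with pytest.raises(ParameterError):
            pollen_count_to_number(-1.0)


class TestPredictTable:
    def test_columns_and_values(self, params):
        df = predict_table([(18.0, 0.0), (30.0, 4.0)], params)
        assert list(df.columns) == [
            "temperature_C", "duration_d", "n_pollen", "f_viable", "n_viable",
            "f_germ", "n_germ", "n_seeds", "fruit_mass_g",
        ]
        assert df["fruit_mass_g"].to_numpy() == pytest.approx(
            [MASS_CTRL, MASS_COLLAPSED]
        )
        assert df["n_pollen"].iloc[0] == pytest.approx(6.61e4, rel=1e-9)


class TestExtrapolationWarning:
    def test_warns_outside_calibrated_range(self, params):
        with pytest.warns(ExtrapolationWarning):
            pollen_number(40.0, params.pollen_beta)
        with pytest.warns(ExtrapolationWarning):
            fraction_surface(20.0, 9.5, params.viability)

    def test_silent_inside_range(self, params):
        with warnings.catch_warnings():
            warnings.simplefilter("error", ExtrapolationWarning)
            pollen_number(18.0, params.pollen_beta)
            fraction_surface(30.0, 4.0, params.viability)
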