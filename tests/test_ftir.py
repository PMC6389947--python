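"""Polarized ATR-FTIR: band decomposition round trips, structure
fractions, and the dichroic-ratio/order-parameter/strand-tilt chain."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from amypore.ftir import (
    ATRGeometry,
    BandComponent,
    BandComponentSet,
    BandFitter,
    BandModel,
    FittedBand,
    PolarizedSpectrumPair,
    R_from_order_parameter,
    baseline_correct,
    dichroic_ratio,
    fit_bands,
    gaussian_band,
    lipid_order,
    order_parameter_from_R,
    solvable_gamma_limit,
    solve_strand_tilt_at,
    strand_tilt,
    structure_fractions,
)
from amypore.synth import SpectrumScenario, gen_polarized_pair

GEOM = ATRGeometry()  # germanium, 45 deg incidence, thick film


def bands(*specs):
    return BandComponentSet(
        bands=tuple(FittedBand(label, 1650.0, 15.0, 0.0, par, perp)
                    for label, par, perp in specs),
        rss=0.0,
        redchi=0.0,
    )


class TestBandFitting:
    def test_single_gaussian_area_recovered_exactly(self):
        nu = np.arange(1550.0, 1750.0, 1.0)
        spec = gaussian_band(nu, 1628.0, 20.0, 1.0)
        pair = PolarizedSpectrumPair(nu, spec, spec)
        model = BandModel(
            components=(BandComponent("sheet", (1620.0, 1636.0)),)
        )
        comps = fit_bands(pair, model, region=(1580.0, 1680.0), baseline="none")
        assert comps.area("sheet", "par") == pytest.approx(1.0, abs=1e-6)
        assert comps.area("sheet", "perp") == pytest.approx(1.0, abs=1e-6)
        assert comps.band("sheet").center == pytest.approx(1628.0, abs=1e-6)

    def test_five_component_noise_free_round_trip(self):
        pair = gen_polarized_pair(SpectrumScenario.amide_i())
        comps = fit_bands(pair, baseline="none")
        for label, truth in pair.meta["ground_truth"].items():
            assert comps.area(label, "par") == pytest.approx(
                truth["area_par"], rel=0.01
            )
            assert comps.area(label, "perp") == pytest.approx(
                truth["area_perp"], rel=0.01
            )

    def test_five_component_noisy_recovery_within_five_percent(self):
        pair = gen_polarized_pair(SpectrumScenario.amide_i(noise_frac=0.005, seed=7))
        comps = fit_bands(pair, baseline="none")
        for label, truth in pair.meta["ground_truth"].items():
            assert comps.area(label, "par") == pytest.approx(truth["area_par"], rel=0.05)
            assert comps.area(label, "perp") == pytest.approx(
                truth["area_perp"], rel=0.05
            )

    def test_empty_region_raises(self):
        pair = gen_polarized_pair(SpectrumScenario.amide_i())
        with pytest.raises(ValueError, match="region"):
            fit_bands(pair, region=(900.0, 1000.0))

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            PolarizedSpectrumPair(
                np.arange(10.0), np.zeros(10), np.zeros(9)
            )

    def test_baseline_linear_removes_tilted_offset(self):
        nu = np.arange(1550.0, 1750.0, 1.0)
        signal = gaussian_band(nu, 1650.0, 20.0, 1.0)
        tilted = signal + 0.01 * (nu - nu[0]) + 0.3
        corrected = baseline_correct(nu, tilted, "linear")
        # the band sits mid-region, so endpoint anchoring recovers it
        assert np.allclose(corrected, signal, atol=1e-6)

    def test_rubberband_baseline_is_nonnegative_for_peaks(self):
        nu = np.arange(0.0, 100.0)
        y = np.exp(-0.5 * ((nu - 50.0) / 5.0) ** 2) + 0.001 * nu
        corrected = baseline_correct(nu, y, "rubberband")
        assert corrected.min() >= -1e-9
        assert corrected.max() == pytest.approx(1.0, abs=0.01)


class TestStructureFractions:
    def test_equal_areas_give_quarter_each(self):
        comps = bands(("turn", 1, 1), ("helix", 1, 1), ("irregular", 1, 1),
                      ("sheet", 1, 1))
        fr = structure_fractions(comps)
        assert fr.as_dict() == pytest.approx(
            {"alpha": 0.25, "beta": 0.25, "turn": 0.25, "irregular": 0.25}
        )

    def test_dominant_sheet_fraction(self):
        comps = bands(("sheet", 4, 4), ("turn", 2, 2), ("helix", 2, 2),
                      ("irregular", 2, 2))
        assert structure_fractions(comps).beta == pytest.approx(0.4)

    def test_single_nonzero_component(self):
        comps = bands(("sheet", 1, 1), ("turn", 0, 0), ("helix", 0, 0),
                      ("irregular", 0, 0))
        assert structure_fractions(comps).beta == pytest.approx(1.0)

    def test_side_chain_bands_excluded_from_denominator(self):
        comps = bands(("sheet", 1, 1), ("turn", 1, 1), ("helix", 1, 1),
                      ("irregular", 1, 1), ("side", 10, 10))
        fr = structure_fractions(comps)
        assert sum(fr.as_dict().values()) == pytest.approx(1.0)
        assert fr.beta == pytest.approx(0.25)

    def test_component_order_is_irrelevant(self):
        a = bands(("sheet", 4, 3), ("turn", 2, 1), ("helix", 1, 2), ("irregular", 1, 1))
        b = bands(("irregular", 1, 1), ("helix", 1, 2), ("turn", 2, 1), ("sheet", 4, 3))
        assert structure_fractions(a).as_dict() == pytest.approx(
            structure_fractions(b).as_dict()
        )

    def test_fractions_always_sum_to_one(self):
        comps = bands(("sheet", 0.31, 0.27), ("turn", 0.11, 0.21),
                      ("helix", 0.05, 0.07), ("irregular", 0.02, 0.09))
        for combo in ("par_plus_2perp", "par", "perp"):
            fr = structure_fractions(comps, combination=combo)
            assert sum(fr.as_dict().values()) == pytest.approx(1.0, abs=1e-9)

    def test_zero_total_area_raises(self):
        comps = bands(("sheet", 0, 0), ("turn", 0, 0))
        with pytest.raises(ValueError, match="zero"):
            structure_fractions(comps)


class TestDichroicRatio:
    def test_equal_areas_unity(self):
        assert dichroic_ratio(1.0, 1.0) == 1.0

    def test_paper_scale_value(self):
        assert dichroic_ratio(0.89, 1.0) == pytest.approx(0.89)

    def test_simple_ratio(self):
        assert dichroic_ratio(2.0, 4.0) == 0.5

    def test_zero_perpendicular_area_raises(self):
        with pytest.raises(ZeroDivisionError):
            dichroic_ratio(1.0, 0.0)


class TestOrderParameter:
    def test_isotropic_dichroic_ratio_closed_form(self):
        # S_d = 0 means C = 1/3 and R = (E_x^2 + E_z^2) / E_y^2
        expected = (1.398**2 + 0.629**2) / 1.516**2
        assert GEOM.isotropic_ratio == pytest.approx(expected)
        assert expected == pytest.approx(1.022, abs=1e-3)
        res = order_parameter_from_R(expected, GEOM, alpha_deg=90.0)
        assert res.S == pytest.approx(0.0, abs=1e-12)
        assert res.S_dipole == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("s", [-0.4, 0.0, 0.7])
    def test_inversion_round_trip(self, s):
        r = R_from_order_parameter(s, GEOM, alpha_deg=90.0)
        back = order_parameter_from_R(r, GEOM, alpha_deg=90.0)
        assert back.S == pytest.approx(s, abs=1e-9)
        assert back.in_physical_range

    @given(s=st.floats(min_value=-0.5, max_value=1.0))
    def test_inversion_identity_on_full_physical_range(self, s):
        r = R_from_order_parameter(s, GEOM, alpha_deg=90.0)
        assert order_parameter_from_R(r, GEOM, alpha_deg=90.0).S == pytest.approx(
            s, abs=1e-9
        )

    @given(
        r1=st.floats(min_value=0.95, max_value=4.0),
        dr=st.floats(min_value=1e-3, max_value=1.0),
    )
    def test_monotone_in_r_direction_set_by_alpha(self, r1, dr):
        # with the dipole perpendicular to the axis (alpha = 90),
        # 3cos^2(alpha) - 1 < 0, so S decreases as R grows
        s1 = order_parameter_from_R(r1, GEOM, alpha_deg=90.0).S
        s2 = order_parameter_from_R(r1 + dr, GEOM, alpha_deg=90.0).S
        assert s2 < s1
        # along the axis (alpha = 0) the direction flips
        s1a = order_parameter_from_R(r1, GEOM, alpha_deg=0.0).S
        s2a = order_parameter_from_R(r1 + dr, GEOM, alpha_deg=0.0).S
        assert s2a > s1a

    def test_magic_angle_is_rejected(self):
        with pytest.raises(ValueError, match="magic"):
            order_parameter_from_R(1.0, GEOM, alpha_deg=math.degrees(
                math.acos(math.sqrt(1.0 / 3.0))
            ))

    def test_unattainable_ratio_flagged_not_clipped(self):
        # R below E_x^2/E_y^2 cannot come from any uniaxial distribution
        r_min = GEOM.e_x**2 / GEOM.e_y**2
        res = order_parameter_from_R(0.9 * r_min, GEOM, alpha_deg=90.0)
        assert not res.attainable
        assert math.isnan(res.S)


class TestLipidOrder:
    @pytest.mark.parametrize("s_true", [0.5, 0.6, 0.7])
    def test_round_trip_recovers_order_parameter(self, s_true):
        pair = gen_polarized_pair(SpectrumScenario.ch2_stretch(s_lipid=s_true))
        res = lipid_order(pair, baseline="none")
        assert res.S == pytest.approx(s_true, abs=0.01)
        # well-ordered membranes sit in the 0.5-0.7 band
        assert 0.45 <= res.S <= 0.75
        assert res.antisym_peak == pytest.approx(2922.0, abs=0.5)

    def test_isotropic_ratio_gives_zero_order(self):
        pair = gen_polarized_pair(SpectrumScenario.ch2_stretch(s_lipid=0.0))
        assert lipid_order(pair, baseline="none").S == pytest.approx(0.0, abs=0.01)

    def test_missing_ch2_region_raises(self):
        pair = gen_polarized_pair(SpectrumScenario.amide_i())
        with pytest.raises(ValueError, match="CH2"):
            lipid_order(pair)


class TestStrandTilt:
    def test_isotropic_ratio_puts_strands_at_magic_angle(self):
        beta = solve_strand_tilt_at(GEOM.isotropic_ratio, 0.0, GEOM)
        assert beta == pytest.approx(math.degrees(math.acos(math.sqrt(1 / 3))), abs=1e-6)

    def test_paper_scale_ratios_give_20_to_27_degree_tilt_upright_barrel(self):
        # measured beta-sheet dichroic ratios around 0.87-0.89 map to
        # strand tilts in the 20-27 degree band for an upright barrel
        for r_beta in (0.872, 0.88, 0.89):
            beta = solve_strand_tilt_at(r_beta, 0.0, GEOM)
            assert 20.0 <= beta <= 27.1

    def test_tilt_table_monotone_decreasing_in_barrel_tilt(self):
        res = strand_tilt(0.89, GEOM, gamma_grid_deg=range(0, 21))
        table = res.beta_of_gamma
        assert table["solvable"].all()
        betas = table["beta_deg"].to_numpy()
        assert np.all(np.diff(betas) < 0)

    def test_no_solution_beyond_analytic_gamma_limit(self):
        """For R_beta = 0.89 the nested order relation admits a strand
        tilt only up to a sharp barrel-tilt limit; with the default
        (thick-film germanium) field amplitudes that limit is ~27 deg
        (see docs/methods.md for the convention dependence).  Beyond it
        the solver must flag no solution rather than extrapolate."""
        limit = solvable_gamma_limit(0.89, GEOM)
        assert limit == pytest.approx(27.0, abs=0.1)
        assert not math.isnan(solve_strand_tilt_at(0.89, limit - 0.5, GEOM))
        assert math.isnan(solve_strand_tilt_at(0.89, limit + 0.5, GEOM))

    def test_stronger_dichroism_shrinks_the_solvable_range(self):
        assert solvable_gamma_limit(0.86, GEOM) < solvable_gamma_limit(0.89, GEOM)

    def test_empty_or_out_of_range_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            strand_tilt(0.89, GEOM, gamma_grid_deg=[])
        with pytest.raises(ValueError, match="20"):
            strand_tilt(0.89, GEOM, gamma_grid_deg=[0.0, 25.0])
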