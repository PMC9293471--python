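"""One-dimensional anatomical gm model: components, composition, genotype contrast."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mesocond import anatomy as an
from mesocond.constants import DiffusionConstants

CONST = DiffusionConstants()


class TestSurfaceMeasures:
    @pytest.mark.parametrize("l, w, expected", [(100, 100, 1.42), (200, 100, 2.84)])
    def test_surface_per_area(self, l, w, expected):
        assert an.surface_per_area(l, w) == pytest.approx(expected)

    def test_surface_matches_reference_mesophyll_value(self):
        # inverse computation: l/W = 17.5/1.42 = 12.32 reproduces the wild-type Sm
        assert an.surface_per_area(1232.0, 100.0) == pytest.approx(17.49, abs=0.01)

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError):
            an.surface_per_area(100.0, 0.0)

    @pytest.mark.parametrize("sias, smes, expected", [(0, 50, 0.0), (30, 30, 0.5), (30, 70, 0.3)])
    def test_ias_fraction(self, sias, smes, expected):
        assert an.ias_fraction(sias, smes) == pytest.approx(expected)

    def test_ias_fraction_both_zero_rejected(self):
        with pytest.raises(ValueError):
            an.ias_fraction(0.0, 0.0)


class TestComponents:
    def test_gas_phase_worked_value(self):
        g, g_mol = an.gas_phase_conductance(CONST, 0.3, 68.5)
        assert g == pytest.approx(1.51e-4 * 0.3 / (0.5 * 68.5e-6 * 1.57), rel=1e-12)
        assert g == pytest.approx(0.8425, abs=5e-4)
        assert g_mol == pytest.approx(g * CONST.molar_density, rel=1e-12)

    def test_gas_phase_linear_in_fias(self):
        g1, _ = an.gas_phase_conductance(CONST, 0.2, 68.5)
        g2, _ = an.gas_phase_conductance(CONST, 0.4, 68.5)
        assert g2 == pytest.approx(2 * g1, rel=1e-12)

    def test_wall_and_stroma_worked_values(self):
        g_cw = an.liquid_component_conductance(1.79e-9, 1.0, 0.3, 0.128e-6)
        assert g_cw == pytest.approx(4.195e-3, abs=2e-6)
        g_st = an.liquid_component_conductance(1.79e-9, 0.3, 1.0, 0.5 * 2.6e-6)
        assert g_st == pytest.approx(4.131e-4, abs=2e-7)

    def test_inverse_proportional_to_path_length(self):
        g1 = an.liquid_component_conductance(1.79e-9, 0.3, 1.0, 1e-6)
        g2 = an.liquid_component_conductance(1.79e-9, 0.3, 1.0, 0.5e-6)
        assert g2 == pytest.approx(2 * g1, rel=1e-12)


def random_anatomy(rng):
    return an.AnatomyMeasurements(
        Tleaf=rng.uniform(40, 120),
        Sm=(sm := rng.uniform(8, 30)),
        Sc=sm * rng.uniform(0.5, 1.0),
        Tcw=rng.uniform(0.05, 0.4),
        Tcyt=rng.uniform(0.01, 0.3),
        Tchl=rng.uniform(0.5, 4.0),
        f_ias=rng.uniform(0.1, 0.5),
    )


def oracle_gm(anat, const):
    """Independent resistor-chain evaluation, coded step by step."""
    r = 0.0
    r += (anat.Tcw * 1e-6) / (const.Dw * const.rf_cw * const.p_cw) / anat.Sm
    r += (1.0 / const.g_pl) / anat.Sm
    r += (anat.Tcyt * 1e-6) / (const.Dw * const.rf_cyt * const.p_cyt) / anat.Sc
    r += (1.0 / const.g_env) / anat.Sc
    r += (0.5 * anat.Tchl * 1e-6) / (const.Dw * const.rf_st * const.p_st) / anat.Sc
    g_liq = 1.0 / r
    g_ias = const.Da * anat.f_ias / (0.5 * anat.Tleaf * 1e-6 * const.tau)
    gm_ms = 1.0 / (1.0 / g_ias + (const.R * const.Tk / const.H) / g_liq)
    return gm_ms * const.pressure / (const.R * const.Tk)


class TestComposeGm:
    def test_matches_resistor_chain_oracle_on_1000_random_anatomies(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            anat = random_anatomy(rng)
            res = an.compose_gm(anat, CONST)
            assert res.gm_model == pytest.approx(oracle_gm(anat, CONST), rel=1e-12)

    def test_component_shares_sum_to_one(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            shares = an.resistance_shares(an.compose_gm(random_anatomy(rng), CONST))
            assert sum(shares.values()) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("trait, direction", [
        ("Tcw", -1), ("Tcyt", -1), ("Tchl", -1),
        ("Sm", +1), ("Sc", +1), ("f_ias", +1),
    ])
    def test_gm_monotone_in_each_trait(self, trait, direction):
        rng = np.random.default_rng(11)
        for _ in range(20):
            anat = random_anatomy(rng)
            new = {trait: getattr(anat, trait) * 1.05}
            if trait == "Sc" and new["Sc"] > anat.Sm:
                # keep Sc <= Sm by enlarging Sm in both, so only Sc differs
                anat = dataclasses.replace(anat, Sm=new["Sc"])
            lo = an.compose_gm(anat, CONST).gm_model
            hi = an.compose_gm(dataclasses.replace(anat, **new), CONST).gm_model
            assert (hi - lo) * direction > 0

    def test_gm_below_both_phase_limits(self):
        res = an.compose_gm(an.RICE_T65_WT, CONST)
        g_liq_mol = res.g_liq / CONST.henry_factor * CONST.molar_density
        assert res.gm_model < res.g_ias_mol
        assert res.gm_model < g_liq_mol

    def test_vanishing_liquid_path_approaches_gas_limit(self):
        anat = dataclasses.replace(an.RICE_T65_WT, Tcw=1e-7, Tcyt=1e-7, Tchl=1e-7)
        const = dataclasses.replace(CONST, g_pl=1e6, g_env=1e6)
        res = an.compose_gm(anat, const)
        assert res.gm_model_ms == pytest.approx(res.g_ias, rel=1e-3)

    def test_sc_above_sm_rejected(self):
        with pytest.raises(ValueError):
            dataclasses.replace(an.RICE_T65_WT, Sc=25.0)


class TestCompareGenotypes:
    def test_identical_inputs_give_zero(self):
        res = an.compose_gm(an.RICE_T65_WT, CONST)
        cmp = an.compare_genotypes(res, res)
        assert cmp["liquid_total_per_leaf_area"] == pytest.approx(0.0, abs=1e-12)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in cmp["per_surface"].values())

    def test_reference_genotype_means_reproduce_printed_reductions(self):
        wt = an.compose_gm(an.RICE_T65_WT, CONST)
        d1 = an.compose_gm(an.RICE_T65_D1, CONST)
        cmp = an.compare_genotypes(wt, d1)
        assert cmp["liquid_total_per_leaf_area"] == pytest.approx(53.0, abs=2.0)
        assert cmp["per_surface"]["cw"] == pytest.approx(18.0, abs=2.0)
        assert cmp["per_surface"]["st"] == pytest.approx(44.0, abs=2.0)

    def test_doubling_sc_halves_intracellular_leaf_resistances_only(self):
        a = an.RICE_T65_WT
        b = dataclasses.replace(a, Sc=2 * a.Sc, Sm=max(a.Sm, 2 * a.Sc))
        ra, rb = an.compose_gm(a, CONST), an.compose_gm(b, CONST)
        cmp = an.compare_genotypes(ra, rb)
        for comp in ("cyt", "env", "st"):
            assert rb.r_components_leaf[comp] == pytest.approx(
                ra.r_components_leaf[comp] / 2, rel=1e-12)
            assert cmp["per_surface"][comp] == pytest.approx(0.0, abs=1e-12)


@given(scale=st.floats(0.5, 2.0))
def test_per_surface_wall_reduction_tracks_thickness_ratio(scale):
    """Per-surface wall resistance scales exactly with Tcw, so the percent
    reduction equals 1 - Tcw_B/Tcw_A regardless of the other traits."""
    a = an.RICE_T65_WT
    b = dataclasses.replace(an.RICE_T65_D1, Tcw=a.Tcw * scale)
    cmp = an.compare_genotypes(an.compose_gm(a, CONST), an.compose_gm(b, CONST))
    assert cmp["per_surface"]["cw"] == pytest.approx(100 * (1 - scale), abs=1e-9)
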