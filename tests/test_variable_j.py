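"""Variable-J gm estimation: cuticular correction, Harley Cc, Fick gm, regressions."""

import numpy as np
import pytest

from mesocond import variable_j as vj
from mesocond.fluorescence import CalibrationResult
from mesocond.simulate import TruthParams, simulate_co2_response
from tests.test_io import make_record


class TestCorrectCi:
    def test_off_mode_is_identity(self):
        rec = make_record()
        assert vj.correct_ci(rec, mode="off") == rec.Ci_raw

    def test_no_flux_no_drawdown(self):
        rec = make_record(An=0.0, El=0.003, Wi=0.03, Wa=0.01)
        assert vj.correct_ci(rec) == pytest.approx(rec.Ca)

    def test_worked_example(self):
        rec = make_record(An=20.0, Ca=400.0, El=0.003, Wi=0.03, Wa=0.01)
        # g_tw = 0.003/0.02 = 0.15; g' = 0.14; Ci = 400 - 1.6*20/0.14
        assert vj.correct_ci(rec, Ec=0.005) == pytest.approx(400 - 32 / 0.14, rel=1e-9)
        assert vj.correct_ci(rec, Ec=0.005) == pytest.approx(171.43, abs=0.01)

    def test_infeasible_correction_raises(self):
        rec = make_record(El=0.0001, Wi=0.03, Wa=0.01)  # g_tw = 0.005 < 2*Ec
        with pytest.raises(vj.CorrectionInfeasibleError):
            vj.correct_ci(rec, Ec=0.005)


class TestChloroplasticCc:
    def test_zero_gross_assimilation_returns_gamma_star(self):
        assert vj.chloroplastic_cc(-1.0, 1.0, 150.0, 40.0) == pytest.approx(40.0)

    def test_worked_example(self):
        # 40 * (150 + 168) / (150 - 84) = 40*318/66
        assert vj.chloroplastic_cc(20.0, 1.0, 150.0, 40.0) == pytest.approx(40 * 318 / 66)

    def test_limit_large_j_approaches_gamma_star_from_above(self):
        vals = [vj.chloroplastic_cc(20.0, 1.0, j, 40.0) for j in (1e3, 1e6, 1e9)]
        assert vals[0] > vals[1] > vals[2] > 40.0
        assert vals[2] == pytest.approx(40.0, rel=1e-6)

    def test_nonphysical_denominator_raises(self):
        with pytest.raises(vj.NonPhysicalRegimeError):
            vj.chloroplastic_cc(20.0, 1.0, 80.0, 40.0)

    def test_cc_decreases_with_j_matching_finite_differences(self):
        """Sign check: Cc strictly decreases in J on the admissible side, so the
        inferred gm = An/(Ci - Cc) decreases as J grows (verified against the
        analytic sensitivity)."""
        an, rd, gs = 20.0, 1.0, 40.0
        js = np.linspace(100, 300, 21)
        ccs = np.array([vj.chloroplastic_cc(an, rd, j, gs) for j in js])
        assert np.all(np.diff(ccs) < 0)
        # finite difference vs d(Cc)/dJ = -12*(An+Rd)*Gamma*/(J-4(An+Rd))^2
        j0 = 150.0
        fd = (vj.chloroplastic_cc(an, rd, j0 + 1e-4, gs)
              - vj.chloroplastic_cc(an, rd, j0 - 1e-4, gs)) / 2e-4
        analytic = -12 * (an + rd) * gs / (j0 - 4 * (an + rd)) ** 2
        assert fd == pytest.approx(analytic, rel=1e-5)


class TestGmVariableJ:
    def rec(self, **over):
        # El chosen so the Boyer correction returns the stomatal-only Ci
        base = dict(An=20.0, Ca=400.0, gsw=0.3, El=(0.3 + 0.01) * 0.02,
                    Wi=0.03, Wa=0.01)
        base.update(over)
        return make_record(**base)

    def test_worked_example_and_round_trip(self):
        est = vj.gm_variable_j(self.rec(), Rd=1.0, J=150.0, gamma_star=40.0)
        cc = 40 * 318 / 66
        assert est.Cc == pytest.approx(cc)
        assert est.Ci_corr == pytest.approx(400 - 1.6 * 20 / 0.3)
        assert est.gm == pytest.approx(20.0 / (est.Ci_corr - cc))
        # Fick round trip is exact
        assert est.Ci_corr - 20.0 / est.gm == pytest.approx(cc, abs=1e-12)
        assert est.gsc == pytest.approx(0.3 / 1.6)
        assert est.wue_i == pytest.approx(20.0 / 0.3)
        assert est.drawdown_surface == pytest.approx(400 - est.Ci_corr)
        assert est.drawdown_mesophyll == pytest.approx(est.Ci_corr - cc)

    def test_spec_magnitude_example(self):
        # An=20, Ci=280, Cc=192.73 -> gm ~ 0.2292
        gm = 20.0 / (280.0 - 40 * 318 / 66)
        assert gm == pytest.approx(0.2292, abs=2e-4)

    def test_singular_point_flagged_not_dropped(self):
        # J chosen so Cc lands exactly on Ci_corr: solve backwards
        rec = self.rec()
        ci = vj.correct_ci(rec)
        gross = rec.An + 1.0
        j_sing = 4.0 * gross * (ci + 2 * 40.0) / (ci - 40.0)
        est = vj.gm_variable_j(rec, Rd=1.0, J=j_sing, gamma_star=40.0)
        assert est.gm is None
        assert not est.reliable

    def test_nonphysical_regime_flagged(self):
        est = vj.gm_variable_j(self.rec(), Rd=1.0, J=50.0, gamma_star=40.0)
        assert est.gm is None and not est.reliable

    def test_sensitivity_window_flags_high_ci_points(self):
        # J barely above the singularity -> dCc/dAn explodes -> unreliable
        est = vj.gm_variable_j(self.rec(), Rd=1.0, J=90.0, gamma_star=40.0)
        assert est.sensitivity > 50
        assert not est.reliable


class TestGmVsGscRegression:
    def test_exact_line(self):
        import pandas as pd

        gsc = np.linspace(0.05, 0.3, 10)
        df = pd.DataFrame({"genotype": "WT", "gsc": gsc, "gm": 0.1 + 0.5 * gsc})
        out = vj.gm_vs_gsc_regression(df)
        assert out.loc[0, "slope"] == pytest.approx(0.5, rel=1e-9)
        assert out.loc[0, "intercept"] == pytest.approx(0.1, rel=1e-9)

    def test_small_group_skipped(self):
        import pandas as pd

        df = pd.DataFrame({"genotype": ["WT", "WT"], "gsc": [0.1, 0.2], "gm": [0.2, 0.3]})
        assert vj.gm_vs_gsc_regression(df).empty

    def test_two_genotype_slopes_within_2_se(self, rng):
        import pandas as pd

        frames = []
        true = {"WT": 0.9, "d1": 0.4}
        for geno, slope in true.items():
            gsc = np.linspace(0.05, 0.30, 20)
            gm = 0.05 + slope * gsc + 0.02 * rng.standard_normal(20)
            frames.append(pd.DataFrame({"genotype": geno, "gsc": gsc, "gm": gm}))
        out = vj.gm_vs_gsc_regression(pd.concat(frames, ignore_index=True))
        for _, row in out.iterrows():
            assert abs(row["slope"] - true[row["genotype"]]) < 2 * row["slope_se"]


def test_noise_free_round_trip_recovers_true_gm(truth, established_constants):
    """Forward-simulated noise-free curve: variable-J recovers gm within 1%."""
    curve = simulate_co2_response(truth)
    est = vj.estimate_curve(curve, established_constants["calibration"],
                            established_constants["laisk"].Rd,
                            established_constants["resolved"].gamma_star)
    reliable = [e for e in est if e.reliable]
    assert len(reliable) >= 5
    for e in reliable:
        assert e.gm == pytest.approx(truth.gm_true, rel=0.01)
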