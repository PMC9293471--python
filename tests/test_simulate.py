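"""Forward simulator: physical limits, seed contract, estimator consistency."""

import dataclasses

import numpy as np
import pytest

from mesocond import fluorescence as fl, fvcb, laisk as lk, variable_j as vj
from mesocond.simulate import (
    STUDY_CA_SEQUENCE,
    StudyDesign,
    TruthParams,
    j_light,
    laisk_curves_from_records,
    simulate_calibration_curve,
    simulate_co2_response,
    simulate_laisk_curves,
    simulate_point,
    simulate_study,
    write_study,
)


class TestSimulatePoint:
    def test_no_drawdown_limit(self, truth):
        p = dataclasses.replace(truth, gm_true=1e9, gsw_true=1e9)
        rec = simulate_point(400.0, 1500.0, 0.21, p)
        assert rec.Ci_raw == pytest.approx(400.0, abs=1e-3)

    def test_supply_chain_consistency(self, truth):
        """The solved point satisfies both Fick steps and the FvCB demand."""
        rec = simulate_point(400.0, 1500.0, 0.21, truth)
        ci = 400.0 - rec.An / truth.gsc_true
        cc = ci - rec.An / truth.gm_true
        kt = fvcb.kinetics_at(25.0)
        an_demand = fvcb.fvcb_assimilation(cc, truth.Vcmax_true, j_light(1500, truth),
                                           truth.Rd_true, truth.gamma_star_true, kt["Km"])
        assert rec.An == pytest.approx(an_demand, abs=1e-8)

    def test_fluorescence_consistent_with_electron_budget(self, truth):
        rec = simulate_point(400.0, 1500.0, 0.21, truth)
        phi = fl.phi_psii(rec.Ft, rec.Fm_prime)
        j = phi * rec.PPFD * truth.alpha_beta_true
        ci = 400.0 - rec.An / truth.gsc_true
        cc = ci - rec.An / truth.gm_true
        gross = rec.An + truth.Rd_true
        assert j == pytest.approx(gross * (4 * cc + 8 * truth.gamma_star_true)
                                  / (cc - truth.gamma_star_true), rel=1e-9)

    def test_low_o2_has_pure_co2_sink(self, truth):
        rec = simulate_point(400.0, 1500.0, 0.01, truth)
        phi = fl.phi_psii(rec.Ft, rec.Fm_prime)
        assert phi * rec.PPFD * truth.alpha_beta_true == pytest.approx(
            4 * (rec.An + truth.Rd_true), rel=1e-9)

    def test_cuticular_correction_round_trips(self, truth):
        rec = simulate_point(400.0, 1500.0, 0.21, truth)
        assert vj.correct_ci(rec) == pytest.approx(rec.Ci_raw, rel=1e-12)


class TestSeedContract:
    def test_identical_seeds_identical_records(self, truth):
        p = dataclasses.replace(truth, sigma_A=0.3, sigma_phi=0.005, seed=77)
        c1 = simulate_co2_response(p)
        c2 = simulate_co2_response(p)
        assert [(r.An, r.Ft) for r in c1] == [(r.An, r.Ft) for r in c2]

    def test_study_bytes_identical(self, tmp_path):
        params = {"WT": TruthParams(sigma_A=0.1)}
        design = StudyDesign(n_plants=2, n_days=4)
        p1 = write_study(simulate_study(params, design, seed=3), tmp_path / "a")
        p2 = write_study(simulate_study(params, design, seed=3), tmp_path / "b")
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes()


class TestEstimatorConsistency:
    def test_noise_free_full_parameter_recovery(self, truth, established_constants):
        """Every targeted truth entry is recovered within 2% (0.1 umol/mol for
        Ci*) from noise-free synthetic protocols."""
        cal = established_constants["calibration"]
        laisk_res = established_constants["laisk"]
        resolved = established_constants["resolved"]
        assert cal.alpha_beta == pytest.approx(truth.alpha_beta_true, rel=0.02)
        assert laisk_res.Ci_star == pytest.approx(truth.ci_star_true, abs=0.1)
        assert laisk_res.Rd == pytest.approx(truth.Rd_true, rel=0.02)
        assert resolved.gamma_star == pytest.approx(truth.gamma_star_true, rel=0.02)

        curve = simulate_co2_response(truth)
        estimates = vj.estimate_curve(curve, cal, laisk_res.Rd, resolved.gamma_star)
        gm_curve = vj.curve_gm(estimates, curve)
        assert gm_curve == pytest.approx(truth.gm_true, rel=0.02)

        # A-Cc conversion with the curve gm, then the FvCB fit
        an = np.array([r.An for r in curve])
        ci = np.array([vj.correct_ci(r) for r in curve])
        cc = fvcb.aci_to_acc(an, ci, gm_curve)
        fit = fvcb.fit_fvcb(cc, an, Rd=laisk_res.Rd)
        assert fit.Vcmax == pytest.approx(truth.Vcmax_true, rel=0.02)
        # the fitted J is the electron transport at the measurement irradiance;
        # invert the light response to compare against Jmax_true
        assert fit.Jmax == pytest.approx(j_light(1500.0, truth), rel=0.02)

    def test_rmse_grows_with_noise(self, established_constants):
        """Estimator RMSE is monotone in sigma_A (common random numbers)."""
        cal = established_constants["calibration"]
        laisk_res = established_constants["laisk"]
        gamma = established_constants["resolved"].gamma_star
        rmses = []
        for sigma in (0.0, 0.15, 0.3, 0.6):
            errs = []
            for rep in range(120):
                rng = np.random.default_rng(500 + rep)
                p = TruthParams(sigma_A=sigma)
                curve = simulate_co2_response(p, rng=rng)
                est = vj.estimate_curve(curve, cal, laisk_res.Rd, gamma)
                errs.append(vj.robust_curve_gm(est) - p.gm_true)
            rmses.append(float(np.sqrt(np.mean(np.square(errs)))))
        assert all(a < b for a, b in zip(rmses, rmses[1:]))


def test_laisk_fixture_lines_intersect_at_truth(truth):
    """Low-Ci pencils at three irradiances pass exactly through (Ci*, -Rd)."""
    curves = laisk_curves_from_records(simulate_laisk_curves(truth))
    assert len(curves) == 3
    ppfds = [c[0] for c in curves]
    assert ppfds == sorted(ppfds)
    for ppfd, ci, an_arr in curves:
        slope, intercept = np.polyfit(ci, an_arr, 1)
        at_star = intercept + slope * truth.ci_star_true
        assert at_star == pytest.approx(-truth.Rd_true, abs=1e-9)


def test_study_sequence_is_the_instrument_protocol():
    assert STUDY_CA_SEQUENCE[0] == 400 and STUDY_CA_SEQUENCE.count(400) == 2
    assert len(STUDY_CA_SEQUENCE) == 12
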