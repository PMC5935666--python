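"""4PL fitting, ROUT outliers, Ki, occupancy, and structure-function correlation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fluorens as fl
from fluorens.pharmacology import (
    CompetitionAssay,
    ki_from_ic50_exact,
    rout_outliers,
    trfret_at_free_ligand,
)
from fluorens.synthetic import serial_dilution


class TestFourPL:
    def test_noise_free_round_trip(self):
        concs = serial_dilution(5e-5, 12)
        curve = fl.simulate_dose_response(0.3, 0.9, 1e-6, 1.0, concs)
        fit = fl.fit_4pl(curve)
        assert fit.bottom == pytest.approx(0.3, rel=1e-6)
        assert fit.top == pytest.approx(0.9, rel=1e-6)
        assert fit.ec50 == pytest.approx(1e-6, rel=1e-6)
        assert fit.hill == pytest.approx(1.0, rel=1e-6)

    def test_logec50_stable_under_noise(self):
        concs = np.repeat(serial_dilution(5e-5, 12), 2)
        errs = []
        for seed in range(100):
            curve = fl.simulate_dose_response(0.3, 0.9, 1e-6, 1.0, concs,
                                              noise_sd=0.01, seed=seed)
            errs.append(fl.fit_4pl(curve).logec50 - np.log10(1e-6))
        assert np.max(np.abs(errs)) <= 0.15

    def test_flat_data_rejected(self):
        curve = fl.DoseResponseCurve(serial_dilution(5e-5, 12), np.full(12, 0.4))
        with pytest.raises(ValueError, match="no dose dependence"):
            fl.fit_4pl(curve)

    def test_too_few_concentrations_rejected(self):
        curve = fl.DoseResponseCurve(serial_dilution(1e-5, 4),
                                     np.array([0.1, 0.2, 0.5, 0.8]))
        with pytest.raises(ValueError, match="at least 5"):
            fl.fit_4pl(curve)

    def test_mask_reproduces_truncated_fit(self):
        """A concentration mask drops the top points of a biphasic curve."""
        concs = serial_dilution(5e-5, 12)
        curve = fl.simulate_dose_response(0.2, 0.8, 1e-6, 1.0, concs)
        # corrupt the two highest concentrations (second transition)
        curve.response[:2] += np.array([0.5, 0.3])
        mask = np.ones(12, dtype=bool)
        mask[:2] = False
        fit = fl.fit_4pl(curve, mask=mask)
        assert fit.ec50 == pytest.approx(1e-6, rel=1e-4)


class TestRout:
    def test_q_zero_never_flags(self):
        concs = serial_dilution(5e-5, 12)
        curve = fl.simulate_dose_response(0.2, 0.9, 1e-6, 1.0, concs,
                                          noise_sd=0.02, n_outliers=1, seed=3)
        res = rout_outliers(curve, q=0.0)
        assert res.outlier_flags.sum() == 0

    def test_injected_outlier_flagged(self):
        concs = serial_dilution(5e-5, 12)
        curve = fl.simulate_dose_response(0.2, 0.9, 1e-6, 1.0, concs,
                                          noise_sd=0.02, n_outliers=1, seed=11)
        res = rout_outliers(curve, q=1.0)
        assert res.outlier_flags[curve.outlier_truth].all()

    def test_flags_reported_not_dropped(self):
        concs = serial_dilution(5e-5, 12)
        curve = fl.simulate_dose_response(0.2, 0.9, 1e-6, 1.0, concs,
                                          noise_sd=0.02, n_outliers=1, seed=11)
        res = rout_outliers(curve, q=1.0)
        assert res.outlier_flags.size == curve.response.size  # table intact
        assert res.cleaned_fit.n == int((~res.outlier_flags).sum())

    def test_too_few_points_rejected(self):
        curve = fl.DoseResponseCurve(serial_dilution(1e-5, 6),
                                     np.linspace(0.9, 0.1, 6))
        with pytest.raises(ValueError, match="at least 8"):
            rout_outliers(curve)


class TestBoundTracer:
    def test_assay_constants_worked_example(self):
        # Ro 8 nM, Lo 5 nM, Kd 7.9 nM
        lb = fl.bound_tracer(5e-9, 8e-9, 7.9e-9)
        assert lb == pytest.approx(2.131e-9, abs=2e-12)

    def test_fixed_point_iteration_cross_check(self):
        """Independent route: iterate free-species mass action to convergence."""
        lo, ro, kd = 5e-9, 8e-9, 7.9e-9
        lb = 0.0
        for _ in range(200):
            rf = ro - lb
            lb = lo * rf / (kd + rf)
        assert fl.bound_tracer(lo, ro, kd) == pytest.approx(lb, rel=1e-9)

    def test_tight_binding_stoichiometric_limit(self):
        assert fl.bound_tracer(5e-9, 8e-9, 1e-15) == pytest.approx(5e-9, rel=1e-4)

    def test_no_tracer_no_binding(self):
        assert fl.bound_tracer(0.0, 8e-9, 7.9e-9) == 0.0

    def test_equilibrium_relation_holds(self):
        lo, ro, kd = 5e-9, 8e-9, 7.9e-9
        lb = fl.bound_tracer(lo, ro, kd)
        assert (ro - lb) * (lo - lb) / lb == pytest.approx(kd, rel=1e-10)


class TestKi:
    def test_printed_equation_worked_example(self):
        assay = CompetitionAssay(lo=5e-9, ro=8e-9, kd=7.9e-9, ic50=100e-9)
        assert assay.lb == pytest.approx(2.131e-9, abs=2e-12)
        assert fl.ki_from_ic50(assay) == pytest.approx(49.4e-9, abs=0.1e-9)

    def test_linearity_in_ic50(self):
        a = CompetitionAssay(lo=5e-9, ro=8e-9, kd=7.9e-9, ic50=100e-9)
        b = CompetitionAssay(lo=5e-9, ro=8e-9, kd=7.9e-9, ic50=200e-9)
        assert fl.ki_from_ic50(b) == pytest.approx(2 * fl.ki_from_ic50(a), rel=1e-12)

    def test_exact_inversion_recovers_truth_across_grid(self):
        """The exact-equilibrium inversion round-trips Ki to numerical
        precision over the assay constant grid."""
        for kd in (5e-9, 7.9e-9, 50e-9):
            for ki in (1e-9, 1e-8, 1e-7, 1e-6):
                ic50 = fl.competition_ic50(5e-9, 8e-9, kd, ki)
                back = ki_from_ic50_exact(
                    CompetitionAssay(lo=5e-9, ro=8e-9, kd=kd, ic50=ic50))
                assert back == pytest.approx(ki, rel=1e-8)

    def test_invalid_denominator_rejected(self):
        # with a *measured* Lb override inconsistent with a large Kd the
        # closed form's denominator turns negative
        assay = CompetitionAssay(lo=5e-9, ro=8e-9, kd=1e-7, ic50=1e-7, lb=4e-9)
        with pytest.raises(ValueError, match="validity"):
            fl.ki_from_ic50(assay)

    def test_quadratic_lb_denominator_reduces_to_2_lb_ro(self):
        """With Lb from the two-species quadratic, the closed form's
        denominator collapses algebraically to 2*Lb*Ro."""
        for kd in (5e-9, 7.9e-9, 50e-9):
            assay = CompetitionAssay(lo=5e-9, ro=8e-9, kd=kd, ic50=1e-7)
            denom = (assay.lo * assay.ro
                     + assay.lb * (assay.ro - assay.lo + assay.lb - assay.kd))
            assert denom == pytest.approx(2 * assay.lb * assay.ro, rel=1e-9)


class TestOccupancy:
    def test_nmr_sample_conditions_near_full_occupancy(self):
        # 150 uM protein, 187.5 uM ligand, 4 nM affinity
        occ = fl.predict_occupancy(150e-6, 187.5e-6, 4e-9)
        assert occ.occupancy > 0.99

    def test_no_ligand_no_occupancy(self):
        assert fl.predict_occupancy(150e-6, 0.0, 4e-9).occupancy == 0.0

    def test_weak_binder_low_occupancy(self):
        occ = fl.predict_occupancy(150e-6, 187.5e-6, 1.0)
        assert occ.occupancy < 0.001

    def test_monotone_in_ligand_and_affinity(self):
        occs_l = [fl.predict_occupancy(150e-6, lt, 1e-6).occupancy
                  for lt in (50e-6, 150e-6, 300e-6)]
        assert occs_l == sorted(occs_l)
        occs_k = [fl.predict_occupancy(150e-6, 187.5e-6, k).occupancy
                  for k in (1e-9, 1e-6, 1e-3)]
        assert occs_k == sorted(occs_k, reverse=True)

    def test_weak_binders_below_93_percent(self):
        """Poorly binding ligands fall under the occupancy threshold used to
        qualify NMR samples."""
        occ = fl.predict_occupancy(150e-6, 300e-6, 40e-6)
        assert occ.occupancy < 0.93


class TestTrfretEndpoint:
    def _fit(self):
        concs = serial_dilution(5e-5, 12)
        return fl.fit_4pl(fl.simulate_dose_response(0.2, 0.8, 1e-6, 1.0, concs))

    def test_midpoint_at_ec50(self):
        fit = self._fit()
        val, sub = trfret_at_free_ligand(fit, fit.ec50)
        assert val == pytest.approx(0.5, abs=1e-6)
        assert not sub

    def test_saturating_ligand_approaches_top(self):
        fit = self._fit()
        val, _ = trfret_at_free_ligand(fit, 1.0)
        assert val == pytest.approx(0.8, abs=1e-4)

    def test_failed_fit_substitutes_nearest_measurement(self):
        concs = serial_dilution(5e-5, 12)
        curve = fl.simulate_dose_response(0.2, 0.8, 1e-6, 1.0, concs)
        val, sub = trfret_at_free_ligand(None, 9e-7, curve=curve)
        i = int(np.argmin(np.abs(np.log10(concs) - np.log10(9e-7))))
        assert sub and val == curve.response[i]


class TestCorrelation:
    def test_perfect_line_r2_one(self):
        x = np.linspace(-84.3, -83.2, 8)
        res = fl.correlate_shift_function(x, 2 * x + 1)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)

    def test_independent_y_low_r2(self):
        """Median R^2 over permutations of an unrelated y stays near zero."""
        rng = np.random.default_rng(0)
        x = np.linspace(-84.3, -83.2, 17)
        y = rng.normal(size=17)
        r2s = [fl.correlate_shift_function(x, rng.permutation(y)).r_squared
               for _ in range(500)]
        assert np.median(r2s) < 0.1

    def test_affine_invariance_of_r2(self):
        rng = np.random.default_rng(1)
        x = np.linspace(-84.3, -83.2, 10)
        y = 0.5 * x + rng.normal(0, 0.05, 10)
        a = fl.correlate_shift_function(x, y).r_squared
        b = fl.correlate_shift_function(3 * x - 7, -2 * y + 1).r_squared
        assert a == pytest.approx(b, rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            fl.correlate_shift_function(np.full(5, -84.0), np.arange(5.0))


@settings(derandomize=True, max_examples=40, deadline=None)
@given(lo=st.floats(1e-10, 1e-7), ro=st.floats(1e-10, 1e-7),
       kd=st.floats(1e-10, 1e-6))
def test_bound_tracer_physical_bounds(lo, ro, kd):
    """Lb never exceeds either total and is non-negative."""
    lb = fl.bound_tracer(lo, ro, kd)
    assert 0.0 <= lb <= min(lo, ro) + 1e-18
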