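import numpy as np
import pytest

from saxsemble.saxscalc import (GuinierFitError, GuinierResult, SaxsProfile,
                                chi_goodness, debye_profile, guinier_fit,
                                kratky_dimensionless, pr_from_coordinates,
                                pr_transform, sphere_pr, sphere_profile, vc_mw)
from saxsemble.structmodel import radius_of_gyration
from saxsemble.synthetic import (default_q_grid, make_toy_complex,
                                 simulate_saxs, true_average_profile)

from conftest import bead_conformer, uniform_sphere_cloud

Q = np.linspace(0.006, 0.5, 200)


def guinier_curve(q, rg=20.0, i0=100.0, sigma_rel=None):
    I = i0 * np.exp(-q ** 2 * rg ** 2 / 3.0)
    sigma = sigma_rel * I if sigma_rel else None
    return SaxsProfile(q, I, sigma=sigma)


class TestProfileIO:
    def test_three_column_round_trip(self, tmp_path):
        prof = guinier_curve(Q, sigma_rel=0.01)
        path = tmp_path / "curve.dat"
        prof.to_file(path)
        back = SaxsProfile.from_file(path)
        np.testing.assert_allclose(back.q, prof.q)
        np.testing.assert_allclose(back.I, prof.I)
        np.testing.assert_allclose(back.sigma, prof.sigma)

    def test_validation_rejects_bad_grids(self):
        with pytest.raises(ValueError):
            SaxsProfile(np.array([0.0, 0.1]), np.array([1.0, 1.0])).validate()
        with pytest.raises(ValueError):
            SaxsProfile(np.array([0.1, 0.2]), np.array([1.0, 1.0]),
                        sigma=np.array([0.1, -0.1])).validate()


class TestDebye:
    def test_single_bead_flat_curve(self):
        prof = debye_profile(bead_conformer([[0, 0, 0]]), Q)
        np.testing.assert_allclose(prof.I, 1.0)

    def test_two_bead_closed_form(self):
        d = 25.0
        prof = debye_profile(bead_conformer([[0, 0, 0], [d, 0, 0]]), Q,
                             method="exact")
        expected = 2.0 * (1.0 + np.sin(Q * d) / (Q * d))
        np.testing.assert_allclose(prof.I, expected, rtol=1e-12)

    def test_forward_intensity_at_zero_angle(self):
        conf = uniform_sphere_cloud(60, 12.0, seed=1)
        q = np.concatenate([[1e-6], Q])
        prof = debye_profile(conf, q, method="exact")
        assert prof.I[0] == pytest.approx(60 ** 2, rel=1e-6)

    def test_histogram_matches_exact_within_tenth_percent(self):
        rng = np.random.default_rng(0)
        conf = bead_conformer(rng.normal(scale=10, size=(50, 3)))
        exact = debye_profile(conf, Q, method="exact")
        hist = debye_profile(conf, Q, method="histogram", bin_width=0.25)
        assert np.max(np.abs(hist.I / exact.I - 1.0)) < 1e-3

    def test_histogram_converges_as_bins_shrink(self):
        rng = np.random.default_rng(1)
        conf = bead_conformer(rng.normal(scale=10, size=(80, 3)))
        exact = debye_profile(conf, Q, method="exact")
        errs = [np.max(np.abs(
            debye_profile(conf, Q, method="histogram", bin_width=b).I
            / exact.I - 1.0)) for b in (1.0, 0.5, 0.25)]
        assert errs[0] > errs[1] > errs[2]


class TestGuinier:
    def test_exact_guinier_curve_recovered_to_4sf(self):
        g = guinier_fit(guinier_curve(np.linspace(1e-3, 0.3, 500)))
        assert g.Rg == pytest.approx(20.0, rel=1e-4)
        assert g.I0 == pytest.approx(100.0, rel=1e-4)

    def test_flat_profile_is_a_fit_failure(self):
        with pytest.raises(GuinierFitError):
            guinier_fit(SaxsProfile(Q, np.ones_like(Q)))

    def test_window_respects_qrg_limit(self):
        g = guinier_fit(guinier_curve(Q), qrg_limit=1.3)
        assert g.q_range_used[1] * g.Rg <= 1.3 + 1e-9

    def test_debye_rg_matches_coordinate_rg_for_globule(self):
        conf = uniform_sphere_cloud(300, 15.0, seed=3)
        prof = debye_profile(conf, np.linspace(0.004, 0.2, 150), method="exact")
        g = guinier_fit(prof)
        assert g.Rg == pytest.approx(radius_of_gyration(conf), rel=0.03)


class TestPofR:
    def test_sphere_profile_inverts_to_sphere_distance_distribution(self):
        R = 15.0
        prof = sphere_profile(Q, R, i0=1000.0)
        prof = SaxsProfile(prof.q, prof.I, sigma=0.01 * np.abs(prof.I) + 1e-7)
        pr = pr_transform(prof, dmax=2 * R * 1.1)
        pr.validate()
        L1 = np.trapezoid(np.abs(pr.p - sphere_pr(pr.r, R)), pr.r)
        assert L1 < 0.05

    def test_round_trip_chi_near_one_on_noisy_data(self, two_state_truth):
        noisy = simulate_saxs(two_state_truth, seed=17)
        dmax = max(float(np.ptp(m.coords, axis=0).max()) * 1.6
                   for m in two_state_truth.members)
        pr = pr_transform(noisy, dmax=dmax)
        assert 0.5 < pr.chi < 1.5

    def test_second_moment_rg_agrees_with_guinier(self):
        conf = uniform_sphere_cloud(300, 15.0, seed=4)
        prof = debye_profile(conf, Q, method="exact")
        prof = SaxsProfile(prof.q, prof.I, sigma=0.01 * prof.I)
        g = guinier_fit(prof)
        pr = pr_transform(prof, dmax=33.0)
        assert pr.rg() == pytest.approx(g.Rg, rel=0.05)

    def test_coordinate_histogram_basics(self):
        two = bead_conformer([[0, 0, 0], [40.0, 0, 0]])
        pr = pr_from_coordinates(two, bin_width=0.5)
        assert pr.dmax == pytest.approx(40.0)
        assert pr.r[np.argmax(pr.p)] == pytest.approx(40.0, abs=0.5)
        # scaling coordinates x2 doubles Dmax and rescales the shape
        four = bead_conformer([[0, 0, 0], [80.0, 0, 0]])
        assert pr_from_coordinates(four).dmax == pytest.approx(80.0)

    def test_uniform_cloud_matches_sphere_closed_form(self):
        with pytest.warns(UserWarning):
            pr = pr_from_coordinates(uniform_sphere_cloud(3000, 10.0, seed=6),
                                     bin_width=0.5)
        L1 = np.trapezoid(np.abs(pr.p - sphere_pr(pr.r, 10.0)), pr.r)
        assert L1 < 0.05


class TestKratky:
    def test_globular_reference_peak(self):
        prof = guinier_curve(np.linspace(1e-3, 0.35, 3000))
        peak = kratky_dimensionless(prof, 20.0, 100.0).peak()
        assert peak[0] == pytest.approx(np.sqrt(3.0), abs=1e-3)
        assert peak[1] == pytest.approx(3.0 / np.e, abs=1e-3)

    def test_flexible_limit_has_no_interior_peak(self):
        prof = SaxsProfile(Q, 100.0 / Q ** 2)
        curve = kratky_dimensionless(prof, 20.0, 100.0)
        assert np.all(np.diff(curve.y) >= -1e-9)
        assert curve.peak() is None

    def test_intensity_scale_invariance(self):
        prof = guinier_curve(Q)
        a = kratky_dimensionless(prof, 20.0, 100.0)
        scaled = SaxsProfile(prof.q, 7.3 * prof.I)
        b = kratky_dimensionless(scaled, 20.0, 730.0)
        np.testing.assert_allclose(a.y, b.y)


class TestVcMw:
    def test_guinier_model_closed_form(self):
        q = np.linspace(1e-4, 2.0, 20000)
        prof = guinier_curve(q)
        g = GuinierResult(20.0, 100.0, (0, 0), 0.0)
        vc, _ = vc_mw(prof, g, q_limit=np.inf)
        assert vc == pytest.approx(2.0 * 20.0 ** 2 / 3.0, rel=1e-4)

    def test_intensity_scale_invariance(self):
        q = np.linspace(1e-4, 0.3, 3000)
        prof = guinier_curve(q)
        g = GuinierResult(20.0, 100.0, (0, 0), 0.0)
        scaled = SaxsProfile(q, 5.0 * prof.I)
        g2 = GuinierResult(20.0, 500.0, (0, 0), 0.0)
        assert vc_mw(prof, g)[0] == pytest.approx(vc_mw(scaled, g2)[0])

    def test_mw_within_15_percent_of_sequence_mass(self):
        topology, sources = make_toy_complex(n_domains=1, seed=7)
        dom = sources["D1"]
        prof = debye_profile(dom, default_q_grid(200), method="exact")
        with pytest.warns(UserWarning):
            vc, mw = vc_mw(prof, guinier_fit(prof))
        seq_mass_kda = dom.n_atoms * 0.110
        assert mw == pytest.approx(seq_mass_kda, rel=0.15)


class TestChi:
    def test_identical_curves_give_zero(self):
        prof = guinier_curve(Q, sigma_rel=0.01)
        assert chi_goodness(prof, prof) == 0.0

    def test_noise_at_stated_sigma_gives_chi_near_one(self, two_state_truth):
        chis = []
        for s in range(5):
            noisy = simulate_saxs(two_state_truth, seed=40 + s)
            clean = true_average_profile(two_state_truth, noisy.q)
            chis.append(chi_goodness(clean, noisy))
        n = len(Q)
        assert np.mean(chis) == pytest.approx(1.0, abs=3.0 / np.sqrt(n))

    def test_model_scale_invariance(self):
        exp = guinier_curve(Q, sigma_rel=0.02)
        model = SaxsProfile(Q, exp.I * np.exp(Q))
        scaled = SaxsProfile(Q, 123.0 * model.I)
        assert chi_goodness(model, exp) == pytest.approx(
            chi_goodness(scaled, exp))

    def test_disjoint_grids_raise(self):
        a = guinier_curve(np.linspace(0.01, 0.1, 50))
        b = guinier_curve(np.linspace(0.2, 0.4, 50))
        with pytest.raises(ValueError):
            chi_goodness(a, b)
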