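"""Half-bleach boundary model: roots, series solution, normalization, fitting."""

import numpy as np
import pytest
from numpy.polynomial.legendre import leggauss

from globule import synthetic_data as sd
from globule.boundary_model import (
    BoundaryGeometry,
    HalfBleachModel,
    RecoveryPair,
    boundary_roots,
    fit_halfbleach,
    halfbleach_curves,
    halfbleach_modes,
    halfbleach_profile,
    n0_closed_form_weights,
    normalize_recovery_pair,
)
from globule.validation import fd_halfbleach_curves, fd_halfbleach_profile


class TestBoundaryRoots:
    @pytest.mark.parametrize(
        "n,p,expected,tol",
        [
            (1, 0.0, 1.8412, 5e-4),  # first extremum of J1
            (0, 0.0, 3.8317, 5e-4),  # first zero of J1 = first extremum of J0
            (0, 1e6, 2.4048, 1e-3),  # large-p limit: first zero of J0
        ],
    )
    def test_known_roots(self, n, p, expected, tol):
        roots = boundary_roots(n, p, 1)
        assert roots[0] == pytest.approx(expected, abs=tol)

    def test_roots_sorted_and_counted(self):
        for n, p in [(0, 2.0), (3, 0.7), (7, 15.0)]:
            roots = boundary_roots(n, p, 8)
            assert roots.size == 8
            assert np.all(np.diff(roots) > 0)
            assert np.all(roots > 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            boundary_roots(0, -1.0, 3)
        with pytest.raises(ValueError):
            boundary_roots(0, 1.0, 0)


class TestSeriesSolution:
    def test_n0_term_matches_closed_form(self):
        """Quadrature-projected rim-exchange weights equal 2p^2/(a^2(a^2+p^2))."""
        p = 5.0
        series = halfbleach_modes(p, 0.05)
        n0 = [m for m in series.modes if m.n == 0]
        alphas = np.array([m.alpha for m in n0])
        weights = np.array([m.w_B for m in n0])
        assert np.allclose(weights, n0_closed_form_weights(p, alphas), rtol=1e-10)

    def test_initial_step_profile(self):
        """t=0 reproduces the half-disk bleach up to bounded Gibbs ringing."""
        model = HalfBleachModel(BoundaryGeometry(1.0, 2.0))
        r = np.array([0.25, 0.5, 0.75])
        prof = halfbleach_profile(model, 0.0, np.array([0.5 * np.pi, 1.5 * np.pi]), r)
        assert np.allclose(prof[0], 0.0, atol=0.02)  # non-bleached half
        assert np.allclose(prof[1], 1.0, atol=0.02)  # bleached half

    def test_closed_disk_equilibrates_to_half(self):
        model = HalfBleachModel(BoundaryGeometry(1.0, 0.0))
        prof = halfbleach_profile(
            model, 10.0, np.array([0.3, 2.0, 4.0]), np.array([0.1, 0.6, 0.95])
        )
        assert np.allclose(prof, 0.5, atol=1e-4)

    def test_curves_initial_condition(self):
        cB, cNB = halfbleach_curves(3.0, np.array([0.0]))
        assert cB[0] == 1.0 and cNB[0] == 0.0

    def test_conservation_without_boundary_exchange(self):
        """p=0: bleached material never leaves the disk."""
        t = np.geomspace(0.01, 20, 30)
        cB, cNB = halfbleach_curves(0.0, t)
        assert np.abs(cB + cNB - 1.0).max() < 1e-6
        assert cB[-1] == pytest.approx(0.5, abs=1e-6)
        assert cNB[-1] == pytest.approx(0.5, abs=1e-6)

    def test_semicircle_curves_match_profile_quadrature(self):
        """c_B/c_NB equal Gauss-Legendre integrals of the profile (p=5)."""
        p = 5.0
        model = HalfBleachModel(BoundaryGeometry(1.0, p))
        xg, wg = leggauss(80)
        r = 0.5 * (xg + 1.0)
        wr = 0.5 * wg
        series = halfbleach_modes(p, 0.05)
        for t in [0.05, 0.1, 0.2, 0.5, 1.0, 2.0]:
            cB_s, cNB_s = halfbleach_curves(p, np.array([t]), series=series)
            vals = {}
            for lohi, key in (((np.pi, 2 * np.pi), "B"), ((0.0, np.pi), "NB")):
                phi = 0.5 * (lohi[1] - lohi[0]) * (xg + 1.0) + lohi[0]
                wphi = 0.5 * (lohi[1] - lohi[0]) * wg
                prof = halfbleach_profile(model, t, phi, r, series=series)
                # profile is (pi/2)*concentration; mass = int c r dr dphi
                mass = (2.0 / np.pi) * np.einsum("i,j,ij->", wphi, wr * r, prof)
                vals[key] = mass
            assert vals["B"] == pytest.approx(cB_s[0], abs=1e-4)
            assert vals["NB"] == pytest.approx(cNB_s[0], abs=1e-4)

    def test_profile_matches_finite_difference_oracle(self):
        """Series profile vs Crank-Nicolson at p=1, t/tauD=0.5, bleached side."""
        p, t = 1.0, 0.5
        model = HalfBleachModel(BoundaryGeometry(1.0, p))
        r_fd, phi_fd, c_fd = fd_halfbleach_profile(p, t)
        prof = halfbleach_profile(model, t, phi_fd, r_fd)
        sel = np.abs(r_fd - 0.5).argmin()
        bleached = phi_fd > np.pi
        dev = np.abs(prof[bleached, sel] - c_fd[bleached, sel])
        assert dev.max() < 0.01

    def test_nonbleached_dip_deepens_with_permeability_loss(self):
        """The transient darkening of the non-bleached half is the boundary
        signature: its depth grows monotonically as p decreases."""
        t = np.geomspace(0.01, 5.0, 60)
        minima = []
        for p in [0.0, 0.5, 1.0, 2.0, 5.0, 20.0]:
            _, cNB = halfbleach_curves(p, t)
            minima.append((1.0 - cNB).min())
        assert np.all(np.diff(minima) > 0)  # increasing with p = decreasing as p drops

    def test_time_rescaling_invariance(self):
        """Curves depend on t only through t/tauD."""
        t_over = np.geomspace(0.02, 3.0, 12)
        for tauD in [1.0, 7.0, 50.0]:
            model = HalfBleachModel(BoundaryGeometry(1.0, 2.0), tauD=tauD)
            cB, cNB = halfbleach_curves(model, t_over)
            cB_ref, cNB_ref = halfbleach_curves(2.0, t_over)
            assert np.allclose(cB, cB_ref, atol=1e-9)
            assert np.allclose(cNB, cNB_ref, atol=1e-9)

    def test_curve_shapes(self):
        """c_B decays monotonically; c_NB rises then decays for 0 < p < inf."""
        t = np.geomspace(5e-3, 10.0, 80)
        cB, cNB = halfbleach_curves(2.0, t)
        assert np.all(np.diff(cB) < 1e-9)
        peak = np.argmax(cNB)
        assert 0 < peak < t.size - 1
        assert np.all(np.diff(cNB[: peak + 1]) > -1e-9)
        assert np.all(np.diff(cNB[peak:]) < 1e-9)


class TestNormalization:
    def test_forward_construct_then_invert(self):
        """Raw pair built from known curves normalizes back to 1-c_B, 1-c_NB."""
        model = HalfBleachModel(BoundaryGeometry(1.0, 3.0), tauD=12.0)
        pair, _ = sd.gen_halfbleach_pair(model, 50, 1.0)
        norm = normalize_recovery_pair(pair)
        t_post = norm.times[norm.t_bleach :] - norm.times[norm.t_bleach]
        cB, cNB = halfbleach_curves(model, t_post / model.tauD)
        assert np.allclose(norm.signal_B[norm.t_bleach :], 1.0 - cB, atol=1e-10)
        assert np.allclose(norm.signal_NB[norm.t_bleach :], 1.0 - cNB, atol=1e-10)
        assert norm.signal_B[: norm.t_bleach].mean() == pytest.approx(1.0)
        assert norm.signal_NB[: norm.t_bleach].mean() == pytest.approx(1.0)

    def test_bleach_frame_is_exactly_zero(self):
        model = HalfBleachModel(BoundaryGeometry(1.0, 1.0), tauD=5.0)
        pair, _ = sd.gen_halfbleach_pair(model, 30, 0.5, noise=0.05, rng=3)
        norm = normalize_recovery_pair(pair)
        assert norm.signal_B[norm.t_bleach] == 0.0

    def test_zero_bleach_depth_raises(self):
        n = 20
        const = np.full(n, 500.0)
        pair = RecoveryPair(
            times=np.arange(n, dtype=float),
            signal_B=const,
            signal_NB=const,
            N_B=10,
            N_NB=10,
            t_bleach=5,
            raw_means={"I_B": const, "I_NB": const,
                       "I_Nucleus": np.full(n, 1000.0), "I_BG": np.full(n, 100.0)},
        )
        with pytest.raises(ValueError, match="bleach depth"):
            normalize_recovery_pair(pair)

    def test_nonpositive_denominator_raises(self):
        n = 10
        pair = RecoveryPair(
            times=np.arange(n, dtype=float),
            signal_B=np.linspace(1000, 500, n),
            signal_NB=np.full(n, 900.0),
            N_B=10,
            N_NB=10,
            t_bleach=2,
            raw_means={
                "I_B": np.linspace(1000, 500, n),
                "I_NB": np.full(n, 900.0),
                "I_Nucleus": np.full(n, 100.0),
                "I_BG": np.full(n, 100.0),
            },
        )
        with pytest.raises(ValueError, match="I_Nucleus"):
            normalize_recovery_pair(pair)


class TestFitting:
    def test_noise_free_round_trip(self):
        model = HalfBleachModel(BoundaryGeometry(1.0, 2.0), tauD=10.0)
        pair, _ = sd.gen_halfbleach_pair(model, 65, 1.0)
        fit = fit_halfbleach(normalize_recovery_pair(pair), fit_immobile=False)
        assert fit.model.p == pytest.approx(2.0, rel=0.01)
        assert fit.model.tauD == pytest.approx(10.0, rel=0.01)
        assert all(np.isfinite(v) for v in fit.stderr.values())

    def test_impermeable_pair_fits_to_zero_permeability(self):
        model = HalfBleachModel(BoundaryGeometry(1.0, 0.0), tauD=10.0)
        pair, _ = sd.gen_halfbleach_pair(model, 65, 1.0)
        fit = fit_halfbleach(normalize_recovery_pair(pair), fit_immobile=False)
        assert fit.model.p <= 0.05

    def test_replicate_averaged_noisy_recovery(self):
        """35 replicates at 2% noise: p and tauD recovered within 10%."""
        model = HalfBleachModel(BoundaryGeometry(1.0, 2.0), tauD=10.0)
        sig_B, sig_NB = [], []
        for rng in sd.child_rngs(42, 35):
            pair, _ = sd.gen_halfbleach_pair(model, 65, 1.0, noise=0.02, rng=rng)
            norm = normalize_recovery_pair(pair)
            sig_B.append(norm.signal_B)
            sig_NB.append(norm.signal_NB)
        avg = RecoveryPair(
            times=norm.times,
            signal_B=np.mean(sig_B, axis=0),
            signal_NB=np.mean(sig_NB, axis=0),
            N_B=norm.N_B, N_NB=norm.N_NB, t_bleach=norm.t_bleach,
            state="normalized",
        )
        fit = fit_halfbleach(avg, fit_immobile=False)
        assert fit.model.p == pytest.approx(2.0, rel=0.10)
        assert fit.model.tauD == pytest.approx(10.0, rel=0.10)

    def test_unnormalized_pair_rejected(self):
        model = HalfBleachModel(BoundaryGeometry(1.0, 1.0), tauD=5.0)
        pair, _ = sd.gen_halfbleach_pair(model, 30, 1.0)
        with pytest.raises(ValueError, match="normalized"):
            fit_halfbleach(pair)


def test_series_vs_finite_difference_small_grid():
    """One fast oracle spot check (the full p-grid sweep runs in acceptance)."""
    t = np.geomspace(0.02, 3.0, 10)
    cB_fd, cNB_fd = fd_halfbleach_curves(2.0, t, nr=40, nphi=80)
    cB, cNB = halfbleach_curves(2.0, t)
    assert np.abs(cB - cB_fd).max() < 0.01
    assert np.abs(cNB - cNB_fd).max() < 0.01
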