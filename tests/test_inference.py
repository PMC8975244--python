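"""Fits: diffusivities, mobility inversion, membrane parameters, cell case."""

import numpy as np
import pytest

from memprobe.estimators import LagStatistic, compute_angle_covariance, compute_msd, log_lag_grid
from memprobe.inference import (
    chi2_sensitivity,
    detect_msd_crossover,
    fit_cell_covariance,
    fit_membrane_params,
    fit_rotational_diffusivity,
    fit_translational_diffusivity,
    invert_mobility,
    propagate_qmax_uncertainty,
    sd_rod_drag,
)
from memprobe.model import (
    KBT_ROOM,
    MembraneParams,
    WavenumberBand,
    sphere_msd_model,
    theta_msad_asymptote,
)
from memprobe.synthetic import SimConfig, make_noisy_msad_dataset, simulate_cell_walk


def _line_stat(lags, slope, rel_err=1e-3, kind="msd"):
    lags = np.asarray(lags, float)
    vals = slope * lags
    return LagStatistic(
        lags=lags, values=vals, stderr=rel_err * vals,
        n_pairs=np.full(lags.size, 1000), kind=kind,
    )


class TestDiffusivityFits:
    def test_exact_line_recovers_slope(self):
        D0 = 0.4e-12
        stat = _line_stat(np.geomspace(1e-4, 1e-2, 10), 4 * D0)
        fit = fit_translational_diffusivity(stat, R=7e-6)
        assert fit.D_t == pytest.approx(D0, rel=1e-9)

    def test_bounded_curve_without_range_selection_underestimates(self):
        # fitting the full bounded-sphere curve including long lags biases
        # D down; the self-consistent range selection avoids it
        Dt, R = 0.52e-12, 7e-6
        lags = np.geomspace(1e-4, 100.0, 40)
        vals = sphere_msd_model(lags, Dt, R)
        stat = LagStatistic(lags=lags, values=vals,
                            stderr=np.full(40, 1e-3 * vals.max()),
                            n_pairs=np.full(40, 100), kind="msd")
        good = fit_translational_diffusivity(stat, R=R)
        naive = fit_translational_diffusivity(stat, R=None)
        assert good.D_t == pytest.approx(Dt, rel=0.02)
        assert naive.D_t < 0.8 * Dt

    def test_no_valid_lag_raises(self):
        stat = _line_stat([10.0, 20.0], 4e-12)
        with pytest.raises(ValueError):
            fit_translational_diffusivity(stat, R=1e-6)

    def test_rotational_exact_line(self):
        stat = _line_stat(np.geomspace(2e-4, 2e-3, 8), 4 * 27.7,
                          kind="msad_physical")
        fit = fit_rotational_diffusivity(stat)
        assert fit.D_r == pytest.approx(27.7, rel=1e-9)
        assert "subdiffusive_flag" not in fit.fit_range

    def test_subdiffusive_input_flagged(self):
        lags = np.geomspace(2e-4, 2e-1, 20)
        vals = 0.5 * lags**0.5
        stat = LagStatistic(lags=lags, values=vals, stderr=1e-3 * vals,
                            n_pairs=np.full(20, 100), kind="msad_physical")
        fit = fit_rotational_diffusivity(stat)
        assert fit.fit_range.get("subdiffusive_flag")


class TestMobilityInversion:
    def test_roundtrip_identity(self, rng):
        # draws inside the Saffman-Delbrueck validity region (l_m >> l_eff)
        for _ in range(10):
            eta_m = 10 ** rng.uniform(-9, -8)
            l_eff = 10 ** rng.uniform(-7.3, -6.7)
            gt, gr = sd_rod_drag(eta_m, l_eff, eta=1e-3)
            res = invert_mobility(KBT_ROOM / gt, KBT_ROOM / gr)
            assert res.eta_m == pytest.approx(eta_m, rel=1e-6)
            assert res.l_eff == pytest.approx(l_eff, rel=1e-6)

    def test_saffman_delbrueck_length_order_one_micron(self):
        # printed tense no-cholesterol diffusivities
        res = invert_mobility(0.52e-12, 27.7, eta=1e-3)
        assert res.l_m == pytest.approx(res.eta_m / 1e-3, rel=1e-12)
        assert 0.5e-6 < res.l_m < 2e-6  # ~1 um at order-of-magnitude rounding

    def test_forward_model_monotone_in_membrane_viscosity(self):
        # within the SD regime larger membrane viscosity means larger drag
        l_eff = 2e-7
        etas = np.geomspace(1e-9, 1e-8, 8)
        gts, grs = zip(*[sd_rod_drag(em, l_eff, 1e-3) for em in etas])
        assert np.all(np.diff(gts) > 0) and np.all(np.diff(grs) > 0)

    def test_nonpositive_diffusivity_rejected(self):
        with pytest.raises(ValueError):
            invert_mobility(-1.0, 27.7)


class TestMembraneFit:
    def test_noiseless_self_consistency(self, nochol_params, band):
        lags = np.geomspace(1e-4, 1.0, 30)
        offset = 6e-4
        stats, variances = make_noisy_msad_dataset(
            nochol_params, band, lags, 0.0, 1, seed=1, static_offset=offset
        )
        fit = fit_membrane_params(stats[0], variances[0], band, seed=0)
        assert fit.kappa_c == pytest.approx(nochol_params.kappa_c, rel=1e-3)
        assert fit.sigma == pytest.approx(nochol_params.sigma, rel=1e-2)
        assert fit.b == pytest.approx(nochol_params.b, rel=1e-2)
        assert fit.static_offset == pytest.approx(offset, rel=1e-2)

    def test_cholesterol_set_self_consistency(self, chol_params, band):
        lags = np.geomspace(1e-4, 1.0, 30)
        stats, variances = make_noisy_msad_dataset(
            chol_params, band, lags, 0.0, 1, seed=2, static_offset=6e-4
        )
        fit = fit_membrane_params(stats[0], variances[0], band, seed=0,
                                  fixed={"eta_m": chol_params.eta_m})
        assert fit.kappa_c == pytest.approx(19.2 * KBT_ROOM, rel=1e-2)
        assert fit.b == pytest.approx(1.2e9, rel=0.05)

    def test_scale_equivariance_in_kbt(self, nochol_params, band):
        # doubling kBT with all data fixed must double kappa_c in J while
        # keeping kappa_c/kBT the dimensionless estimate
        lags = np.geomspace(1e-4, 1.0, 20)
        stats, variances = make_noisy_msad_dataset(
            nochol_params, band, lags, 0.0, 1, seed=3, static_offset=6e-4
        )
        fit = fit_membrane_params(stats[0], variances[0], band, seed=0)
        assert fit.kappa_c / fit.kBT == pytest.approx(7.3, rel=1e-3)


class TestChi2Sensitivity:
    @pytest.fixture(scope="class")
    def fitted(self, nochol_params, band):
        lags = np.geomspace(1e-4, 1.0, 25)
        stats, variances = make_noisy_msad_dataset(
            nochol_params, band, lags, 0.02, 1, seed=4, static_offset=6e-4
        )
        fit = fit_membrane_params(stats[0], variances[0], band, seed=0)
        chi2_sensitivity(fit, stats[0], variances[0], band)
        return fit

    def test_profiles_minimized_at_fit(self, fitted):
        for name, (grid, prof) in fitted.profiles.items():
            assert prof.min() >= fitted.chi2 - 1e-6
            i_min = np.argmin(prof)
            assert prof[i_min] <= fitted.chi2 + 1.0

    def test_intervals_bracket_estimates(self, fitted):
        for name in ("kappa_c", "sigma", "b"):
            lo, hi = fitted.intervals[name]
            val = getattr(fitted, name)
            assert lo <= val <= hi

    def test_floppy_tension_profile_one_sided(self, band):
        floppy = MembraneParams(kappa_c=19.2 * KBT_ROOM, sigma=1e-9, b=1.2e9)
        lags = np.geomspace(1e-4, 1.0, 25)
        stats, variances = make_noisy_msad_dataset(
            floppy, band, lags, 0.03, 1, seed=5, static_offset=6e-4
        )
        fit = fit_membrane_params(stats[0], variances[0], band, seed=0)
        chi2_sensitivity(fit, stats[0], variances[0], band)
        assert fit.flags["sigma_lower_open"]


class TestQmaxPropagation:
    def test_zero_uncertainty_zero_shift(self, nochol_params):
        lags = np.geomspace(1e-4, 1.0, 20)
        band = WavenumberBand.from_geometry(7e-6, 140e-9)
        stats, variances = make_noisy_msad_dataset(
            nochol_params, band, lags, 0.0, 1, seed=6, static_offset=6e-4
        )
        out = propagate_qmax_uncertainty(
            stats[0], variances[0], R=7e-6, l=140e-9, dl=0.0, seed=0
        )
        assert out["kappa_c"]["shift_plus"] == pytest.approx(0.0, abs=1e-25)

    def test_rod_length_uncertainty_shifts_rigidity(self, nochol_params):
        lags = np.geomspace(1e-4, 1.0, 20)
        band = WavenumberBand.from_geometry(7e-6, 140e-9)
        stats, variances = make_noisy_msad_dataset(
            nochol_params, band, lags, 0.0, 1, seed=7, static_offset=6e-4
        )
        out = propagate_qmax_uncertainty(
            stats[0], variances[0], R=7e-6, l=140e-9, dl=20e-9, seed=0
        )
        assert abs(out["kappa_c"]["shift_plus"]) > 0
        # shifts roughly antisymmetric to first order
        assert np.sign(out["kappa_c"]["shift_plus"]) != np.sign(
            out["kappa_c"]["shift_minus"]
        )


class TestCellCovarianceFit:
    def test_ou_rate_recovery(self):
        cfg = SimConfig(seed=15, n_steps=100_000)
        _, th = simulate_cell_walk(cfg)
        lags = np.arange(1, 26) * cfg.dt
        cov = compute_angle_covariance(th, lags, cfg.dt)
        fit = fit_cell_covariance(cov)
        assert abs(fit.omega - cfg.theta_rate) < 3 * fit.omega_stderr + 0.05 * cfg.theta_rate

    def test_band_fraction_linearity(self):
        # amplitude anchored so kappa(dq/q=0.2) = 2 kBT implies exactly
        # kappa(0.9) = 9 kBT
        a0 = KBT_ROOM * 0.2 / (2 * np.pi * 2 * KBT_ROOM)
        lags = np.geomspace(2e-4, 5e-3, 12)
        cov = LagStatistic(
            lags=lags, values=a0 * np.exp(-610 * lags),
            stderr=np.full(12, 1e-5), n_pairs=np.full(12, 1000),
            kind="covariance", meta={"variance": a0},
        )
        fit = fit_cell_covariance(cov)
        lo, hi = fit.kappa_range
        assert lo == pytest.approx(2.0, rel=1e-3)
        assert hi == pytest.approx(9.0, rel=1e-3)
        assert hi / lo == pytest.approx(4.5, rel=1e-9)

    def test_amplitude_doubling_halves_rigidity(self):
        lags = np.geomspace(2e-4, 5e-3, 12)

        def fit_a0(a0):
            cov = LagStatistic(
                lags=lags, values=a0 * np.exp(-610 * lags),
                stderr=np.full(12, 1e-6), n_pairs=np.full(12, 1000),
                kind="covariance", meta={"variance": a0},
            )
            return fit_cell_covariance(cov).kappa_range[0]

        assert fit_a0(0.02) / fit_a0(0.04) == pytest.approx(2.0, rel=1e-6)

    def test_nonpositive_covariance_rejected(self):
        lags = np.geomspace(2e-4, 5e-3, 6)
        cov = LagStatistic(
            lags=lags, values=np.array([1e-3, 1e-3, -1e-4, 1e-4, 1e-4, 1e-4]),
            stderr=np.full(6, 1e-5), n_pairs=np.full(6, 100), kind="covariance",
        )
        with pytest.raises(ValueError):
            fit_cell_covariance(cov)


class TestMsdCrossover:
    def test_pure_diffusion_crossover_at_first_lag(self):
        cfg = SimConfig(seed=16, n_steps=200_000, corral_sigma=1e-5,
                        hop_rate=0.0, Dt_free=0.06e-12)
        pos, _ = simulate_cell_walk(cfg)
        msd = compute_msd(pos, log_lag_grid(cfg.dt, pos.t[-1], per_decade=12))
        out = detect_msd_crossover(msd)
        assert out["found"]
        assert out["crossover_lag"] == pytest.approx(msd.lags[0])
        assert out["D_t_long"] == pytest.approx(0.06e-12, rel=0.1)

    def test_pure_confinement_flagged(self):
        cfg = SimConfig(seed=17, n_steps=200_000, hop_rate=0.0)
        pos, _ = simulate_cell_walk(cfg)
        msd = compute_msd(pos, log_lag_grid(cfg.dt, pos.t[-1], per_decade=12))
        out = detect_msd_crossover(msd)
        assert not out["found"]
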