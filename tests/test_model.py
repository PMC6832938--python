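"""Characterisation and quantification: recovery, pooling, reports, plots."""

import matplotlib
import numpy as np
import pytest

import isebayes as ib
from conftest import FAST

matplotlib.use("Agg")

CTX = ib.ModelContext(z=2, temperature_c=21.0)


def characterize(ds, **kwargs):
    kwargs.setdefault("config", FAST)
    return ib.characterize_array(ds, CTX, **kwargs)


class TestCharacterize:
    def test_recovers_known_sensor_within_posterior_uncertainty(self):
        true = ib.SensorParams(a=100.0, b=29.18, c=1e-6, sigma=0.2)
        cal = ib.simulate_calibration({1: true}, seed=3)
        ds = ib.build_dataset(cal, [], ib.Mode.CALIBRATION_ONLY)
        res = characterize(ds, config=ib.MCMCConfig(2, 3000, 1500, seed=2))
        for name, truth in [("a", true.a), ("b", true.b), ("sigma", true.sigma)]:
            s = res.summaries[f"{name}[1]"]
            sd = (s.upper95 - s.lower95) / 3.92
            assert abs(s.median - truth) < 2.5 * sd, name
        c = res.summaries["c[1]"]
        assert c.lower95 < true.c < c.upper95

    def test_three_sensor_dataset_gives_three_blocks(self):
        ds, _, _ = ib.lead_like_example(seed=5, mode=ib.Mode.CALIBRATION_ONLY)
        res = characterize(ds)
        assert res.n_ise == 3
        for i in (1, 2, 3):
            assert f"logLOD[{i}]" in res.draws
            lod = res.lod(i)
            assert lod.lower95 <= lod.median <= lod.upper95

    def test_detection_defaults_are_five_percent(self):
        ds, _, _ = ib.lead_like_example(seed=6, mode=ib.Mode.CALIBRATION_ONLY)
        res = characterize(ds)
        assert res.detection == ib.DetectionSpec(alpha=0.05, beta=0.05)
        assert "alpha=0.05, beta=0.05" in res.summary()

    def test_sensors_are_independent_blocks(self):
        """A two-sensor joint fit must match per-sensor fits within MC error."""
        p1 = ib.SensorParams(100.0, 29.2, 1e-6, 0.5)
        p2 = ib.SensorParams(150.0, 28.5, 3e-6, 1.0)
        cfg = ib.MCMCConfig(2, 3000, 1500, seed=8)
        both = ib.build_dataset(
            ib.simulate_calibration({1: p1, 2: p2}, seed=9), [], ib.Mode.CALIBRATION_ONLY
        )
        res_both = characterize(both, config=cfg)
        cal1 = [r for r in both.calibration if r.ise_id == 1]
        res_one = characterize(
            ib.build_dataset(cal1, [], ib.Mode.CALIBRATION_ONLY), config=cfg
        )
        for name in ("a[1]", "b[1]"):
            s_b, s_o = res_both.summaries[name], res_one.summaries[name]
            sd = (s_o.upper95 - s_o.lower95) / 3.92
            assert abs(s_b.median - s_o.median) < 0.5 * sd, name

    def test_posterior_lod_consistent_with_plugin_at_large_n(self):
        """With lots of calibration data the posterior median log LOD and the
        plug-in value at the posterior medians must agree closely."""
        true = ib.SensorParams(a=120.0, b=29.18, c=2e-6, sigma=0.5)
        design = [lx + d for lx in ib.DEFAULT_DESIGN for d in (0.0, 0.33, 0.67)] * 3
        cal = ib.simulate_calibration({1: true}, design, seed=12)
        ds = ib.build_dataset(cal, [], ib.Mode.CALIBRATION_ONLY)
        res = characterize(ds, config=ib.MCMCConfig(2, 3000, 1500, seed=3))
        plugin = np.log10(ib.lod_plugin(res.params(1), res.detection))
        assert res.lod(1).median == pytest.approx(plugin, abs=0.05)

    def test_report_layout_matches_convention(self):
        ds, _, _ = ib.lead_like_example(seed=7, mode=ib.Mode.CALIBRATION_ONLY)
        res = characterize(ds)
        text = res.summary()
        assert "y = a + b log(x + c)" in text
        assert "ISE #2:" in text
        assert "Estimated log LOD{alpha=0.05, beta=0.05} (95% CI):" in text
        # estimates printed as 3-sig-fig scientific notation
        assert any(
            tok.count("e+") or tok.count("e-") for tok in text.split()
        )

    def test_plot_writes_file(self, tmp_path):
        ds, _, _ = ib.lead_like_example(seed=7, mode=ib.Mode.CALIBRATION_ONLY)
        res = characterize(ds)
        out = tmp_path / "posteriors.png"
        res.plot(out)
        assert out.stat().st_size > 0


class TestQuantifyBasic:
    def test_noise_free_single_sensor_recovers_activity(self, single_sensor):
        cal = ib.simulate_calibration({1: single_sensor}, seed=2)
        emf = ib.emf_expected(single_sensor, 1e-5)
        exact = [
            ib.CalibrationRecord(r.ise_id, r.log10x,
                                 ib.emf_expected(single_sensor, 10.0 ** r.log10x))
            for r in cal
        ]
        ds = ib.build_dataset(exact, [ib.BasicSampleRecord(1, 1, emf)], ib.Mode.BASIC)
        res = ib.quantify_samples(ds, CTX, config=ib.MCMCConfig(2, 2000, 1500, seed=3))
        assert res.activity(1).median == pytest.approx(-5.0, abs=0.05)

    def test_calibration_only_mode_is_a_usage_error(self, calibration_only_dataset):
        with pytest.raises(ValueError, match="CalibrationModel"):
            ib.ActivityModel(calibration_only_dataset, CTX)

    def test_linear_limit_matches_prediction_interval_inversion(self):
        """One sensor, all-Nernstian data, c pinned near zero: Bayesian
        activity intervals must track classical inverse prediction
        intervals from linear regression within 10%."""
        import statsmodels.api as sm

        rng = np.random.default_rng(31)
        true = ib.SensorParams(a=150.0, b=29.0, c=1e-30, sigma=0.5)
        # enough points that the residual-variance prior (half-normal vs the
        # implicit 1/sigma of the t machinery) no longer moves the interval
        lx = np.linspace(-5.0, -3.0, 12)
        y_cal = true.a + true.b * lx + rng.normal(0, true.sigma, lx.size)
        cal = [ib.CalibrationRecord(1, float(l), float(v)) for l, v in zip(lx, y_cal)]
        y0 = true.a + true.b * (-4.0)
        ds = ib.build_dataset(cal, [ib.BasicSampleRecord(1, 1, float(y0))], ib.Mode.BASIC)

        priors = ib.PriorSpec(
            a_mean=float(np.median(y_cal)), a_sd=1000.0,
            b_mean=29.18, b_sd=14.59,
            log10c_low=-32.0, log10c_high=-28.0,  # pins c ~ 0: pure line
            sigma_high=25.0, log10x_low=-8.0, log10x_high=-1.0,
        )
        res = ib.quantify_samples(
            ds, CTX, config=ib.MCMCConfig(2, 8000, 2000, seed=5), priors=priors
        )
        s = res.activity(1)
        bayes_width = s.upper95 - s.lower95

        # classical: invert the 95% prediction interval of the OLS line
        ols = sm.OLS(y_cal, sm.add_constant(lx)).fit()
        grid = np.linspace(-6.0, -2.0, 4001)
        pred = ols.get_prediction(sm.add_constant(grid)).summary_frame(alpha=0.05)
        inside = (y0 >= pred.obs_ci_lower.to_numpy()) & (y0 <= pred.obs_ci_upper.to_numpy())
        classical = grid[inside]
        classical_width = classical.max() - classical.min()
        assert bayes_width == pytest.approx(classical_width, rel=0.10)
        assert s.median == pytest.approx(-4.0, abs=0.05)

    def test_slope_interval_tightens_as_points_double(self):
        """Doubling the calibration density shrinks the slope interval."""
        true = ib.SensorParams(a=100.0, b=29.18, c=1e-6, sigma=0.5)
        widths = {}
        for label, reps in [("n7", 1), ("n14", 2)]:
            per_rep = []
            for seed in range(5):
                cal = ib.simulate_calibration(
                    {1: true}, list(ib.DEFAULT_DESIGN) * reps, seed=20 + seed
                )
                ds = ib.build_dataset(cal, [], ib.Mode.CALIBRATION_ONLY)
                res = characterize(ds, config=ib.MCMCConfig(2, 1500, 1000, seed=seed))
                s = res.summaries["b[1]"]
                per_rep.append(s.upper95 - s.lower95)
            widths[label] = float(np.median(per_rep))
        assert widths["n14"] < widths["n7"]


class TestDownWeighting:
    def test_very_noisy_extra_sensor_barely_moves_estimates(self):
        """Adding a fourth sensor with 20x the noise shifts each sample's
        posterior median by well under half a posterior SD (median over 20
        replicates): its likelihood terms carry 1/sigma^2 weight."""
        base = {
            1: ib.SensorParams(100.0, 29.2, 1e-6, 0.8),
            2: ib.SensorParams(120.0, 29.0, 1.5e-6, 0.8),
            3: ib.SensorParams(140.0, 28.9, 2e-6, 0.8),
        }
        noisy = dict(base)
        noisy[4] = ib.SensorParams(160.0, 29.1, 1.5e-6, 16.0)
        cfg = dict(n_chains=2, n_iter=1500, n_burn=1000)
        shifts = []
        for rep in range(20):
            acts = {1: 1e-4}
            cal4 = ib.simulate_calibration(noisy, seed=3000 + rep)
            exp4 = ib.simulate_basic(noisy, acts, seed=3000 + rep)
            ds4 = ib.build_dataset(cal4, exp4, ib.Mode.BASIC)
            res4 = ib.quantify_samples(
                ds4, CTX, config=ib.MCMCConfig(**cfg, seed=rep + 1)
            )
            cal3 = [r for r in cal4 if r.ise_id <= 3]
            exp3 = [r for r in exp4 if r.ise_id <= 3]
            ds3 = ib.build_dataset(cal3, exp3, ib.Mode.BASIC)
            res3 = ib.quantify_samples(
                ds3, CTX, config=ib.MCMCConfig(**cfg, seed=rep + 1)
            )
            sd = float(res3.draws["log10x[1]"].std())
            shift = abs(res4.activity(1).median - res3.activity(1).median)
            shifts.append(shift / sd)
        assert float(np.median(shifts)) < 0.5


class TestQuantifyStandardAddition:
    def test_seventeen_sample_array_structure(self):
        ds, _, acts = ib.lead_like_example(seed=1)
        res = ib.quantify_samples(ds, CTX, config=FAST)
        table = res.activities()
        assert len(table) == 17
        assert res.mode is ib.Mode.STANDARD_ADDITION
        assert (table.lower95 <= table["median"]).all()
        assert (table["median"] <= table.upper95).all()
        assert (table.lower95 <= table.lower50).all()
        assert (table.upper50 <= table.upper95).all()
        assert "Standard Addition" in res.summary()

    def test_plot_honours_range_and_colour(self, tmp_path):
        from matplotlib.colors import to_rgba

        ds, _, _ = ib.lead_like_example(seed=1)
        res = ib.quantify_samples(ds, CTX, config=FAST)
        fig, ax = res.plot(tmp_path / "f.png", ylab="log a", ylim=(-7, -3), color="tomato")
        assert ax.get_ylim() == (-7.0, -3.0)
        assert ax.get_ylabel() == "log a"
        assert tuple(ax.collections[0].get_color()[0]) == to_rgba("tomato")
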