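"""Generator tests: fGn exactness, breath-process structure, rendering, cohorts."""

import numpy as np
import pytest
from dataclasses import replace

import breathcomplex as bc
from breathcomplex.metrics import cross_sample_entropy, sample_entropy
from breathcomplex.synthetic import _CYCLE, fgn_autocovariance


class TestFgn:
    def test_white_noise_has_no_lag1_correlation(self):
        x = bc.generate_fgn(bc.FgnSpec(n=4096, hurst=0.5, seed=11))
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r1) < 0.05

    def test_requested_mean_and_sd_scale_the_output(self):
        x = bc.generate_fgn(bc.FgnSpec(n=8192, hurst=0.7, mean=5.0, sd=2.0, seed=1))
        assert np.mean(x) == pytest.approx(5.0, abs=0.5)
        assert np.std(x) == pytest.approx(2.0, rel=0.15)

    def test_deterministic_given_seed(self):
        spec = bc.FgnSpec(n=256, hurst=0.8, seed=42)
        assert np.array_equal(bc.generate_fgn(spec), bc.generate_fgn(spec))

    @pytest.mark.parametrize("hurst", [0.3, 0.5, 0.8])
    def test_autocovariance_matches_closed_form(self, hurst):
        """Empirical autocovariance at lags 0..5 within 3 SE of the fGn form."""
        n, n_seeds = 2048, 50
        lags = np.arange(6)
        acv = np.zeros((n_seeds, lags.size))
        for s in range(n_seeds):
            x = bc.generate_fgn(bc.FgnSpec(n=n, hurst=hurst, seed=1000 + s))
            for k in lags:
                acv[s, k] = np.mean(x[: n - k] * x[k:])
        target = fgn_autocovariance(hurst, lags)
        se = acv.std(axis=0, ddof=1) / np.sqrt(n_seeds)
        assert np.all(np.abs(acv.mean(axis=0) - target) <= 3 * se + 1e-12)

    @pytest.mark.parametrize(
        "kwargs", [{"hurst": 1.2}, {"hurst": 0.0}, {"n": 8}, {"sd": 0.0}]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        params = {"n": 64, "hurst": 0.5, "sd": 1.0, **kwargs}
        with pytest.raises(bc.ParameterError):
            bc.FgnSpec(**params)

    @pytest.mark.parametrize("hurst", [0.5, 0.7, 0.9])
    def test_dfa_recovers_hurst(self, hurst):
        alphas = [
            bc.dfa(bc.generate_fgn(bc.FgnSpec(n=8192, hurst=hurst, seed=s)))[0]
            for s in range(20)
        ]
        assert abs(np.mean(alphas) - hurst) <= 0.05


class TestBreathProcess:
    def test_strictly_periodic_limit_has_zero_entropy(self):
        """regularity=1 gives a strictly periodic IBI series: SampEn -> 0 while
        the CV stays at its configured value (the blend preserves variance)."""
        spec = bc.control_like_template(n_breaths=300, regularity=1.0, sigh_rate=0.0, seed=5)
        series = bc.generate_breath_series(spec)
        assert sample_entropy(series.ibi) == 0.0
        cv = np.std(series.ibi, ddof=1) / series.ibi.mean()
        assert cv == pytest.approx(spec.ibi_cv, rel=0.05)

    def test_cv_invariant_in_regularity(self):
        cvs = []
        for reg in [0.0, 0.4, 0.8]:
            spec = bc.control_like_template(
                n_breaths=2000, regularity=reg, sigh_rate=0.0, seed=9
            )
            ibi = bc.generate_breath_series(spec).ibi
            cvs.append(np.std(ibi, ddof=1) / ibi.mean())
        assert np.ptp(cvs) < 0.02

    def test_full_coupling_makes_channels_identical(self):
        """coupling_rho=1 with equal Hurst: the z-innovations coincide, so
        cross-SampEn equals SampEn of the common z-series with self-matches."""
        spec = bc.control_like_template(
            n_breaths=300, coupling_rho=1.0, regularity=0.0, sigh_rate=0.0,
            ibi_hurst=0.6, rv_hurst=0.6, seed=21,
        )
        series = bc.generate_breath_series(spec)
        zx = (series.ibi - series.ibi.mean()) / np.std(series.ibi, ddof=1)
        zy = (series.rv[:-1] - series.rv[:-1].mean()) / np.std(series.rv[:-1], ddof=1)
        assert np.allclose(zx, zy, atol=1e-10)

    def test_cross_entropy_decreases_with_coupling(self):
        """Paired-seed Monte Carlo: mean cross-SampEn non-increasing in rho."""
        means = []
        for rho in [0.0, 0.3, 0.6, 0.9]:
            vals = []
            for s in range(20):
                spec = bc.control_like_template(
                    n_breaths=400, coupling_rho=rho, regularity=0.0,
                    sigh_rate=0.0, seed=s,
                )
                ser = bc.generate_breath_series(spec)
                vals.append(cross_sample_entropy(ser.ibi, ser.rv[:-1]))
            means.append(np.mean(vals))
        assert all(a >= b - 1e-9 for a, b in zip(means, means[1:]))
        assert means[0] > means[-1]

    def test_entropy_decreases_with_strong_regularity(self):
        """Mean SampEn_IBI decreases over regularity {0.3, 0.6, 0.9} and the
        0 -> 0.9 drop is large (a weak periodic admixture can raise SampEn
        slightly, so monotonicity is asserted where determinism dominates)."""
        means = {}
        for reg in [0.0, 0.3, 0.6, 0.9]:
            vals = []
            for s in range(20):
                spec = bc.control_like_template(
                    n_breaths=400, regularity=reg, sigh_rate=0.0, seed=s
                )
                vals.append(sample_entropy(bc.generate_breath_series(spec).ibi))
            means[reg] = np.mean(vals)
        assert means[0.3] > means[0.6] > means[0.9]
        assert means[0.0] - means[0.9] > 0.5

    def test_sighs_scale_amplitude(self):
        spec = bc.control_like_template(n_breaths=500, sigh_rate=0.05, seed=2)
        with_sighs = bc.generate_breath_series(spec)
        without = bc.generate_breath_series(replace(spec, sigh_rate=0.0))
        n_sighs = with_sighs.metadata["n_sighs"]
        assert n_sighs > 0
        ratio = with_sighs.rv / without.rv
        assert np.sum(np.isclose(ratio, spec.sigh_amplitude_factor)) == n_sighs

    def test_invalid_parameters_rejected(self):
        with pytest.raises(bc.ParameterError):
            bc.control_like_template(regularity=1.5)
        with pytest.raises(bc.ParameterError):
            bc.control_like_template(sigh_rate=0.25)
        with pytest.raises(bc.ParameterError):
            bc.control_like_template(coupling_rho=-1.2)


class TestRender:
    def test_noiseless_maxima_match_ground_truth(self, noiseless_render):
        signal, truth = noiseless_render
        fs = signal.fs
        for t_k, a_k in zip(truth.peak_times, truth.rv):
            k = int(round(t_k * fs))
            lo, hi = max(0, k - 5), k + 6
            local_argmax = lo + np.argmax(signal.samples[lo:hi])
            assert abs(local_argmax - t_k * fs) <= 1.0
            # peak times fall between samples; the sampled maximum sits below
            # the continuous-time amplitude by up to (pi*dt/2h)^2 relative
            assert signal.samples[local_argmax] == pytest.approx(a_k, rel=5e-4)

    def test_signal_length_matches_breath_count(self):
        spec = bc.control_like_template(n_breaths=100, ibi_mean=0.5, ibi_cv=0.0,
                                        regularity=0.0, sigh_rate=0.0, seed=1)
        signal, truth = bc.render_signal(bc.generate_breath_series(spec),
                                         bc.RenderSpec(fs=1000.0))
        expected = truth.peak_times[-1] * 1000
        assert abs(signal.n_samples - expected) < 600  # within one pulse width

    def test_artifact_epoch_scores_worst(self):
        spec = bc.control_like_template(n_breaths=220, seed=13)
        series = bc.generate_breath_series(spec)
        render = bc.RenderSpec(fs=200.0, noise_sd=0.02,
                               artifact_epochs=((60.0, 20.0, 5.0),))
        signal, _ = bc.render_signal(series, render, seed=0)
        window = bc.select_analysis_window(signal, duration=30.0, hop=10.0)
        # chosen window avoids the artifact epoch entirely
        start_s = window.start_index / signal.fs
        assert start_s + 30.0 <= 60.0 or start_s >= 80.0

    def test_duration_overflow_rejected(self):
        spec = bc.control_like_template(n_breaths=200, seed=1)
        series = bc.generate_breath_series(spec)
        with pytest.raises(bc.ConfigurationError):
            bc.render_signal(series, bc.RenderSpec(fs=100.0), duration=30.0)

    def test_overlapping_artifacts_rejected(self):
        with pytest.raises(bc.ConfigurationError):
            bc.RenderSpec(artifact_epochs=((0.0, 10.0, 2.0), (5.0, 10.0, 2.0)))


class TestCohort:
    def test_cohort_is_reproducible(self):
        cfg = bc.SynthCohortConfig(
            groups={"a": bc.control_like_template(), "b": bc.asthma_like_template()},
            n_per_group=2, record_duration=60.0,
            render=bc.RenderSpec(fs=100.0, noise_sd=0.05), master_seed=99,
        )
        c1, c2 = bc.generate_cohort(cfg), bc.generate_cohort(cfg)
        for r1, r2 in zip(c1, c2):
            assert r1.subject_id == r2.subject_id
            assert np.array_equal(r1.signal.samples, r2.signal.samples)
            assert np.array_equal(r1.truth.ibi, r2.truth.ibi)

    def test_recordings_within_group_differ(self):
        cfg = bc.SynthCohortConfig(
            groups={"a": bc.control_like_template()}, n_per_group=2,
            record_duration=60.0, render=bc.RenderSpec(fs=100.0), master_seed=1,
        )
        recs = bc.generate_cohort(cfg)
        assert not np.array_equal(recs[0].truth.ibi[:20], recs[1].truth.ibi[:20])

    def test_single_recording_group_generates_but_model_rejects(self):
        import pandas as pd

        cfg = bc.SynthCohortConfig(
            groups={"a": bc.control_like_template(), "b": bc.control_like_template()},
            n_per_group=1, record_duration=60.0,
            render=bc.RenderSpec(fs=100.0), master_seed=1,
        )
        recs = bc.generate_cohort(cfg)
        assert len(recs) == 2
        table = pd.DataFrame(
            {"subject_id": ["a-0", "b-0"], "group": ["a", "b"], "sampen_ibi": [1.0, 2.0]}
        )
        with pytest.raises(bc.InsufficientDataError):
            bc.CohortComplexity(table)

    def test_period3_cycle_is_standardized(self):
        assert np.mean(_CYCLE) == pytest.approx(0.0, abs=1e-12)
        assert np.mean(_CYCLE**2) == pytest.approx(1.0, rel=1e-12)
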