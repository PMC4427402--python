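"""Simulator tests: Bessel-ratio calibration against an independent series
oracle, track statistics recovery, rendering closure, cohort structure."""

import numpy as np
import pytest

from neutrotax import (
    AssayConfig,
    Attractant,
    ChannelGeometry,
    ConditionSpec,
    MotilityParams,
    ShapeParams,
    calibrate_kappa,
    expected_ci,
    generate_cohort,
    measure_condition,
    render_frames,
    render_shape_field,
    simulate_track,
    simulate_tracks,
    summarize_condition,
    two_sample_ttest,
)
from neutrotax.simulate import place_cells, render_field


# ---------------------------------------------------------------------------
# independent oracle: truncated power series for the modified Bessel ratio
# ---------------------------------------------------------------------------

def bessel_ratio_series(kappa: float, tol: float = 1e-18) -> float:
    """I1(kappa)/I0(kappa) from the defining power series
    I_m(x) = sum_k (x/2)^(2k+m) / (k! (k+m)!), truncated when terms vanish."""
    half = kappa / 2.0

    def i_m(m: int) -> float:
        term = half**m
        for j in range(1, m + 1):
            term /= j
        total, k = term, 0
        while term > tol * total:
            k += 1
            term *= half * half / (k * (k + m))
            total += term
        return total

    return i_m(1) / i_m(0)


def bisect_kappa(target: float, lo: float = 0.0, hi: float = 50.0, iters: int = 60) -> float:
    """Brute-force bisection inversion of the series oracle."""
    for _ in range(iters):
        mid = (lo + hi) / 2.0
        if bessel_ratio_series(mid) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


class TestExpectedCI:
    def test_isotropic_walk_has_zero_ci(self):
        assert expected_ci(0.0) == 0.0

    def test_strong_bias_approaches_one(self):
        assert expected_ci(1e6) == pytest.approx(1.0, abs=1e-5)

    @pytest.mark.parametrize("kappa", [0.25, 0.5, 1.0, 2.0, 5.0, 10.0])
    def test_matches_series_oracle(self, kappa):
        assert expected_ci(kappa) == pytest.approx(bessel_ratio_series(kappa), abs=1e-6)

    def test_strictly_increasing(self):
        ks = np.linspace(0.0, 20.0, 50)
        vals = [expected_ci(k) for k in ks]
        assert np.all(np.diff(vals) > 0)

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError):
            expected_ci(-0.1)


class TestCalibrateKappa:
    def test_zero_target(self):
        assert calibrate_kappa(0.0) == 0.0

    @pytest.mark.parametrize("target", np.round(np.arange(0.1, 0.95, 0.1), 2).tolist())
    def test_round_trip(self, target):
        assert expected_ci(calibrate_kappa(target)) == pytest.approx(target, abs=1e-6)

    def test_first_copd_patient_ci(self):
        """Calibration at C.I. 0.533 matches brute-force series inversion."""
        assert calibrate_kappa(0.533) == pytest.approx(bisect_kappa(0.533), abs=1e-6)

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            calibrate_kappa(bad)


class TestSimulateTrack:
    def test_determinism(self, config):
        mot = MotilityParams(kappa=1.0)
        a = simulate_track(mot, config, (500.0, 200.0), seed=42)
        b = simulate_track(mot, config, (500.0, 200.0), seed=42)
        assert np.array_equal(a.xy, b.xy) and np.array_equal(a.t, b.t)

    def test_strong_bias_constant_speed_is_straight(self, wide_config):
        """Near-deterministic limit: straight run up-gradient, C.I. ~ 1."""
        from neutrotax import chemotactic_index

        mot = MotilityParams(kappa=1e8, mean_step_speed=0.15, speed_shape=1e8)
        tr = simulate_track(mot, wide_config, (2500.0, 4000.0), seed=0)
        assert chemotactic_index(tr, wide_config.gradient_axis) > 0.9999
        steps = np.diff(tr.xy, axis=0)
        assert np.allclose(np.linalg.norm(steps, axis=1), 1.5, rtol=1e-3)

    def test_start_outside_channel_rejected(self, config):
        with pytest.raises(ValueError):
            simulate_track(MotilityParams(), config, (-1.0, 50.0), seed=0)

    @pytest.mark.parametrize("kappa", [0.0, 2.0])
    def test_tracks_confined_to_channel(self, kappa):
        cfg = AssayConfig(geometry=ChannelGeometry(width=20.0), field_length=50.0,
                          n_frames=300)
        mot = MotilityParams(kappa=kappa, mean_step_speed=0.5)
        tr = simulate_track(mot, cfg, (25.0, 10.0), seed=3)
        assert np.all(tr.xy[:, 0] >= 0) and np.all(tr.xy[:, 0] <= 50.0)
        assert np.all(tr.xy[:, 1] >= 0) and np.all(tr.xy[:, 1] <= 20.0)

    def test_persistence_accepts_and_stays_bounded(self, config):
        mot = MotilityParams(kappa=1.0, persistence=0.5)
        tr = simulate_track(mot, config, (500.0, 200.0), seed=7)
        assert len(tr) == config.n_frames
        assert np.all((tr.xy[:, 1] >= 0) & (tr.xy[:, 1] <= config.geometry.width))


class TestEstimatorRecovery:
    def test_mean_ci_recovers_calibration_target(self, config):
        """500 tracks at kappa calibrated for C.I. 0.5 average to 0.5 ± 0.02."""
        mot = MotilityParams(kappa=calibrate_kappa(0.5), mean_step_speed=0.129)
        tracks = simulate_tracks(500, mot, config, seed=11)
        s = summarize_condition(tracks, config.gradient_axis)
        assert s.mean_ci == pytest.approx(0.5, abs=0.02)

    def test_mean_ci_within_three_sems(self, config):
        for target, seed in [(0.3, 5), (0.7, 6)]:
            mot = MotilityParams(kappa=calibrate_kappa(target))
            s = summarize_condition(
                simulate_tracks(300, mot, config, seed=seed), config.gradient_axis
            )
            # finite-track ratio bias is well under this band
            assert abs(s.mean_ci - target) < 3 * s.sem_ci + 0.01

    def test_speed_recovery_wide_channel(self, wide_config):
        mot = MotilityParams(kappa=1.0, mean_step_speed=0.2)
        tracks = simulate_tracks(
            200, mot, wide_config, seed=12,
            start_region=((2000.0, 3000.0), (2000.0, 3000.0)),
        )
        s = summarize_condition(tracks, wide_config.gradient_axis)
        assert s.mean_speed == pytest.approx(0.2, rel=0.02)


class TestConditionSpec:
    fmlp = Attractant("fMLP", family="terminal", potency=1.0)
    fmlp_hi = Attractant("fMLP-100nM", family="terminal", potency=2.0)
    il8 = Attractant("IL-8", family="intermediate", potency=1.5)
    sputum = Attractant("COPD-sputum", family="intermediate", potency=1.2)

    def test_single_gradient_full_potency(self):
        c = ConditionSpec("il8", top_attractant=self.il8)
        assert c.bias_sign == 1 and c.effective_kappa == 1.5

    def test_terminal_dominates_intermediate(self):
        """fMLP wins the competing gradient even at lower potency."""
        c = ConditionSpec("compete", top_attractant=self.il8, bottom_attractant=self.fmlp)
        assert c.bias_sign == -1
        assert c.effective_kappa == pytest.approx(1.0 - 0.5 * 1.5)

    def test_dominance_is_dose_dependent(self):
        lo = ConditionSpec("lo", top_attractant=self.fmlp, bottom_attractant=self.il8)
        hi = ConditionSpec("hi", top_attractant=self.fmlp_hi, bottom_attractant=self.il8)
        assert hi.effective_kappa > lo.effective_kappa > 0

    def test_higher_potency_wins_within_family(self):
        c = ConditionSpec("sputa", top_attractant=self.il8, bottom_attractant=self.sputum)
        assert c.bias_sign == 1

    def test_uniform_field_unbiased(self):
        c = ConditionSpec("uniform", top_attractant=self.il8, bottom_attractant=self.il8)
        assert c.bias_sign == 0 and c.effective_kappa == 0.0
        assert ConditionSpec("medium").effective_kappa == 0.0


class TestRendering:
    def test_circular_cells_measure_ar_one(self):
        shape = ShapeParams(area=150.0, aspect_ratio_true=1.0, orientation_mode="isotropic")
        labels, _ = render_shape_field(25, shape, pixel_size=0.5, seed=1)
        mean_ar, _, ms = measure_condition(labels, pixel_size=0.5)
        assert len(ms) == 25
        assert mean_ar == pytest.approx(1.0, abs=0.02)

    def test_single_static_cell_ar2_recovered(self):
        """AR 2, 200 µm², no noise: morphology recovers within 5% at 0.5 µm/px."""
        shape = ShapeParams(area=200.0, aspect_ratio_true=2.0)
        labels, _ = render_shape_field(1, shape, pixel_size=0.5, seed=4, noise_sd=0.0)
        mean_ar, _, ms = measure_condition(labels, pixel_size=0.5)
        assert mean_ar == pytest.approx(2.0, rel=0.05)
        assert ms[0].area == pytest.approx(200.0, rel=0.05)

    def test_label_stack_unique_ownership(self, rng):
        cfg = AssayConfig(geometry=ChannelGeometry(width=200.0), field_length=300.0,
                          n_frames=5)
        mot = MotilityParams(kappa=1.0, mean_step_speed=0.2)
        starts = place_cells(6, (300.0, 200.0), 40.0, rng, margin=20.0)
        tracks = [
            simulate_track(mot, cfg, tuple(s), seed=i, track_id=i)
            for i, s in enumerate(starts)
        ]
        labels, gray = render_frames(tracks, ShapeParams(aspect_ratio_true=1.5), cfg, seed=2)
        assert labels.shape == gray.shape and labels.shape[0] == 5
        present = set(np.unique(labels)) - {0}
        assert present == set(range(1, 7))  # one label per track, all drawn

    def test_cell_too_large_rejected(self, rng):
        big = ShapeParams(area=1e6, aspect_ratio_true=1.0)
        with pytest.raises(ValueError, match="too large"):
            render_field(np.array([[50.0, 50.0]]), np.array([0.0]), [big],
                         (100.0, 100.0), 1.0, rng)

    def test_place_cells_separation_guarantee(self, rng):
        centers = place_cells(30, (500.0, 500.0), 50.0, rng, margin=10.0)
        d = np.linalg.norm(centers[:, None] - centers[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 50.0

    def test_place_cells_capacity_error(self, rng):
        with pytest.raises(ValueError, match="holds at most"):
            place_cells(100, (100.0, 100.0), 50.0, rng)


class TestCohort:
    def test_same_seed_identical_export(self, tmp_path):
        from neutrotax.io import write_cohort_manifest, write_tracks_csv

        paths = []
        for run in ("a", "b"):
            cohort = generate_cohort(n_copd=3, n_control=3, tracks_per_subject=5, seed=99)
            mpath = tmp_path / f"manifest_{run}.csv"
            write_cohort_manifest(cohort, mpath)
            tpath = tmp_path / f"tracks_{run}.csv"
            write_tracks_csv(cohort.subjects[0].tracks, tpath)
            paths.append((mpath, tpath))
        assert paths[0][0].read_bytes() == paths[1][0].read_bytes()
        assert paths[0][1].read_bytes() == paths[1][1].read_bytes()

    def test_structure_and_potency_ordering(self):
        cohort = generate_cohort(n_copd=5, n_control=5, tracks_per_subject=3, seed=7)
        assert len(cohort.copd) == 5 and len(cohort.control) == 5
        copd_potency = np.mean([s.potency for s in cohort.copd])
        ctrl_potency = np.mean([s.potency for s in cohort.control])
        assert copd_potency > ctrl_potency
        for s in cohort.copd:
            assert s.fev1_fvc_pct is not None and 0 < s.fev1_l <= s.fvc_l
        for s in cohort.control:
            assert s.fev1_fvc_pct is None

    def test_noiseless_map_yields_tight_correlation(self):
        """With zero map noise, measured C.I. vs FEV1/FVC is nearly collinear."""
        from neutrotax import chemotactic_index
        from scipy.stats import linregress

        cohort = generate_cohort(
            n_copd=6, n_control=2, correlation_noise_sd=0.0,
            tracks_per_subject=100, seed=21,
        )
        fev, ci = [], []
        for s in cohort.copd:
            cis = [chemotactic_index(t, cohort.config.gradient_axis) for t in s.tracks]
            fev.append(s.fev1_fvc_pct)
            ci.append(np.mean(cis))
        r = linregress(fev, ci)
        assert r.slope < 0
        assert r.rvalue**2 > 0.9

    def test_group_difference_power(self):
        """Default cohorts separate COPD from control in most replicates.

        Monte-Carlo oracle power at the default effect (C.I. 0.39 vs 0.22,
        sd 0.10/0.06, n = 5+5) is ~0.77; assert comfortably above chance and
        within that expectation over 200 replicates.
        """
        rej = 0
        n_rep = 200
        for rep in range(n_rep):
            cohort = generate_cohort(tracks_per_subject=12, seed=10_000 + rep)
            group_means = {}
            for grp, subjects in (("COPD", cohort.copd), ("control", cohort.control)):
                means = []
                for s in subjects:
                    summ = summarize_condition(s.tracks, cohort.config.gradient_axis)
                    means.append(summ.mean_ci)
                group_means[grp] = means
            res = two_sample_ttest(group_means["COPD"], group_means["control"])
            rej += res.significant
        assert 0.65 <= rej / n_rep <= 0.9

    @pytest.mark.parametrize("kwargs", [
        dict(ci_copd_mean=1.0), dict(ci_control_mean=-0.1), dict(n_copd=1),
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_cohort(tracks_per_subject=2, **kwargs)
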