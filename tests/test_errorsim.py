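"""Error-mechanism primitives and the five synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest

from mistime.errorsim import (
    EquationErrorSpec,
    ErrorSpec,
    SequentialDelaySpec,
    TimecourseDataset,
    draw_berkson_truth,
    draw_classical_observations,
    generate_glut4_dataset,
    generate_linear_dataset,
    generate_oscillation_dataset,
    generate_parasite_dataset,
    generate_tumour_dataset,
    sequential_timing_errors,
)
from mistime.models import ParasiteParams, evaluate_model


class TestErrorDraws:
    def test_zero_variance_is_identity(self, rng):
        x = np.linspace(-2, 2, 11)
        spec = ErrorSpec("classical", "normal", var_u=0.0)
        assert np.array_equal(draw_classical_observations(x, spec, rng), x)
        bspec = ErrorSpec("berkson", "uniform", delta=0.0)
        assert np.array_equal(draw_berkson_truth(x, bspec, rng), x)

    def test_kind_mismatch_is_misuse(self, rng):
        with pytest.raises(ValueError):
            draw_classical_observations([0.0], ErrorSpec("berkson", "normal", var_u=1.0), rng)
        with pytest.raises(ValueError):
            draw_berkson_truth([0.0], ErrorSpec("classical", "normal", var_u=1.0), rng)

    def test_classical_moments_match_spec(self, rng):
        # the linear-design timing error: zero-mean normal with VARIANCE 0.25
        n = 10**6
        x = np.zeros(n)
        w = draw_classical_observations(x, ErrorSpec("classical", "normal", var_u=0.25), rng)
        u = w - x
        se_mean = 0.5 / np.sqrt(n)
        assert abs(u.mean()) < 3 * se_mean
        assert u.var() == pytest.approx(0.25, rel=0.01)

    def test_berkson_uniform_support_and_bias(self, rng):
        w = np.zeros(10**5)
        spec = ErrorSpec("berkson", "uniform", delta=0.7, biased=True)
        x = draw_berkson_truth(w, spec, rng)
        assert np.all((x - w >= 0) & (x - w <= 0.7))
        assert spec.bias == pytest.approx(0.35)
        centred = ErrorSpec("berkson", "uniform", delta=0.7, biased=False)
        assert centred.bias == 0.0

    def test_berkson_normal_variance(self, rng):
        w = np.zeros(10**6)
        x = draw_berkson_truth(w, ErrorSpec("berkson", "normal", var_u=0.0625), rng)
        assert (x - w).var() == pytest.approx(0.0625, rel=0.01)


class TestSequentialDelays:
    def test_degenerate_durations_are_cumulative_exact(self, rng):
        spec = SequentialDelaySpec(mean_duration=1.0 / 6.0, sd_duration=0.0)
        U = sequential_timing_errors(6, 31, spec, rng)
        expect = np.tile((np.arange(1, 7) / 6.0)[:, None], (1, 31))
        assert np.allclose(U, expect)
        assert U[5, 0] == pytest.approx(1.0)  # sixth subject delayed a full day

    def test_fixed_order_strictly_increasing(self, rng):
        U = sequential_timing_errors(6, 10, SequentialDelaySpec(ordering="fixed"), rng)
        assert np.all(np.diff(U, axis=0) > 0)

    def test_mean_first_delay(self):
        # mean of the first measured subject's delay is the mean duration
        rng = np.random.default_rng(7)
        spec = SequentialDelaySpec(1.0 / 6.0, 0.1, "fixed")
        draws = np.array(
            [sequential_timing_errors(1, 1, spec, rng)[0, 0] for _ in range(10**5)]
        )
        se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - 1.0 / 6.0) < 3 * se

    def test_random_order_shuffles(self):
        rng = np.random.default_rng(3)
        spec = SequentialDelaySpec(1.0 / 6.0, 0.1, "random_per_day")
        U = sequential_timing_errors(6, 40, spec, rng)
        # with shuffling, the first subject is not the least-delayed every day
        assert not np.all(np.diff(U, axis=0) > 0)


class TestLinearGenerator:
    def test_zero_error_recovers_line_exactly(self, rng):
        ds = generate_linear_dataset(
            "controlled_berkson",
            error_spec=ErrorSpec("berkson", "normal", var_u=0.0),
            eq_error=EquationErrorSpec("none", 0.0),
            rng=rng,
        )
        slope, intercept = np.polyfit(ds.w, ds.y, 1)
        assert slope == pytest.approx(1.0, abs=1e-12)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_controlled_berkson_structure(self, rng):
        ds = generate_linear_dataset("controlled_berkson", n=50, rng=rng)
        assert sorted(set(ds.w)) == [-2.0, -1.0, 0.0, 1.0, 2.0]
        assert all(np.sum(ds.w == v) == 10 for v in (-2, -1, 0, 1, 2))
        assert len(set(ds.x)) == 50  # every replicate has its own hidden truth

    def test_replicate_structure_enforced(self, rng):
        with pytest.raises(ValueError):
            generate_linear_dataset("controlled_berkson", n=48, rng=rng)

    def test_berkson_response_depends_only_on_truth(self, rng):
        ds = generate_linear_dataset(
            "noncontrolled_berkson", eq_error=EquationErrorSpec("none", 0.0), rng=rng
        )
        assert np.array_equal(ds.y, ds.x)  # y = 0 + 1*x exactly


class TestOscillationGenerator:
    def test_case2_zero_errors_hits_amplitude(self, rng):
        ds = generate_oscillation_dataset(
            "controlled_case2",
            error_spec=ErrorSpec("berkson", "normal", var_u=0.0),
            eq_error=EquationErrorSpec("none", 0.0),
            rng=rng,
        )
        # protocol points are turning points of cos(4x): responses alternate +/-3
        assert set(np.round(ds.y, 9)) == {-3.0, 3.0}

    def test_noncontrolled_range(self, rng):
        ds = generate_oscillation_dataset("noncontrolled_classical", rng=rng)
        assert len(ds) == 50
        assert np.all((ds.x >= -2) & (ds.x <= 2))


class TestParasiteGenerator:
    def test_noise_free_matches_curve(self, rng, parasite_truth):
        ds = generate_parasite_dataset(parasite_truth, sigma_U=0.0, sigma_eps=0.0, rng=rng)
        assert np.array_equal(ds.w, np.arange(0, 26, 2.0))
        assert np.allclose(ds.y, evaluate_model("parasite", parasite_truth, ds.w))

    def test_protocol_days_recorded_regardless_of_timing_error(self, rng):
        ds = generate_parasite_dataset(sigma_U=0.4, sigma_eps=0.0, rng=rng)
        assert np.array_equal(ds.w, np.arange(0, 26, 2.0))
        assert not np.array_equal(ds.x, ds.w)

    def test_multiplicative_error_scale(self, parasite_truth):
        rel = []
        for seed in range(400):
            ds = generate_parasite_dataset(
                parasite_truth, sigma_U=0.0, sigma_eps=0.1, rng=np.random.default_rng(seed)
            )
            rel.extend(ds.y / evaluate_model("parasite", parasite_truth, ds.w) - 1.0)
        assert np.std(rel) == pytest.approx(0.1, rel=0.05)


class TestTumourGenerator:
    def test_perfect_scenario_times_equal_protocol(self, rng):
        ds = generate_tumour_dataset("perfect", rng=rng)
        assert np.array_equal(ds.x, ds.w)
        assert len(ds) == 6 * 31

    def test_ordered_delays_increase_with_tumour_index(self, rng):
        ds = generate_tumour_dataset("ordered", rng=rng)
        delays = (ds.x - ds.w).reshape(6, 31, order="C")
        frame = ds.frame
        for day in np.arange(0, 62, 2.0):
            day_delays = frame[frame.protocol_time == day]
            ordered = day_delays.sort_values("subject_id")["true_time"].to_numpy() - day
            assert np.all(np.diff(ordered) > 0)

    def test_response_is_exact_gompertz_of_true_time(self, rng):
        ds = generate_tumour_dataset("random_order", rng=rng)
        for sid, p in ds.true_params.items():
            sub = ds.subset(sid)
            assert np.allclose(sub.y, evaluate_model("gompertz", p, sub.x))


class TestGlut4Generator:
    def test_exact_curve_when_error_free(self, rng):
        ds = generate_glut4_dataset(Delta=0.0, sigma_Y=0.0, n_rep=2, rng=rng)
        from conftest import GLUT4_REF

        assert len(ds) == 24
        assert np.allclose(ds.y, evaluate_model("glut4", GLUT4_REF, ds.w))

    def test_row_count(self, rng):
        ds = generate_glut4_dataset(Delta=0.2, sigma_Y=0.05, n_rep=1000, rng=rng)
        assert len(ds) == 12000

    def test_lognormal_mean_matches_model(self, rng):
        from conftest import GLUT4_REF

        ds = generate_glut4_dataset(Delta=0.0, sigma_Y=0.05, n_rep=4000, rng=rng)
        frame = ds.frame
        for t in (0.0, 10.0, 60.0):
            sample = frame[frame.protocol_time == t]["response"]
            expect = evaluate_model("glut4", GLUT4_REF, t)
            assert sample.mean() == pytest.approx(expect, abs=4 * 0.05 / np.sqrt(len(sample)))


class TestDatasetContainer:
    def test_determinism_same_seed(self):
        a = generate_tumour_dataset("ordered", rng=np.random.default_rng(42))
        b = generate_tumour_dataset("ordered", rng=np.random.default_rng(42))
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_csv_round_trip(self, tmp_path, rng):
        ds = generate_parasite_dataset(rng=rng)
        path = tmp_path / "parasite.csv"
        ds.to_csv(path)
        back = TimecourseDataset.read_csv(path)
        pd.testing.assert_frame_equal(ds.frame, back.frame)
        assert back.metadata["design"] == ds.metadata["design"]

    def test_external_data_without_truth(self):
        frame = pd.DataFrame(
            {"subject_id": [0, 0], "protocol_time": [0.0, 1.0], "response": [1.0, 2.0]}
        )
        ds = TimecourseDataset(frame)
        assert not ds.has_truth
        with pytest.raises(ValueError):
            _ = ds.x
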