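"""Network architecture contracts, optimization sanity, and persistence."""

import numpy as np
import pytest

from meginverse import (
    NetworkConfig,
    TrainConfig,
    build_network,
    count_parameters,
    load_model,
    predict_window,
    reconstruct_timeseries,
    save_model,
    train_model,
)
from meginverse.errors import InvalidConfigError, InputContractError
from meginverse.network import _Flatten, default_kernel_schedule
from meginverse.signals import SensorRecording


def tiny_config(**overrides):
    """Small architecture for fast optimization tests."""
    defaults = dict(
        n_sensors=8,
        n_sources=12,
        window_length=9,
        conv_feature_schedule=(8, 16),
        fc_layers=2,
        fc_width=32,
    )
    return NetworkConfig(**{**defaults, **overrides})


class TestArchitecture:
    def test_default_kernel_schedule_consumes_window(self):
        for w in (9, 13, 21, 31):
            ks = default_kernel_schedule(w, 4)
            extent = w
            for k in ks:
                extent = extent - k + 1
            assert extent == 1

    def test_default_21_sample_schedule(self):
        assert default_kernel_schedule(21, 4) == (5, 5, 3, 11)

    def test_bad_kernel_schedule_reports_achievable_extents(self):
        with pytest.raises(InvalidConfigError, match="extents"):
            NetworkConfig(
                n_sensors=8, n_sources=4, window_length=21,
                conv_feature_schedule=(8, 16),
                conv_kernel_schedule=(5, 5),
            )

    def test_even_window_rejected(self):
        with pytest.raises(InvalidConfigError):
            NetworkConfig(n_sensors=8, n_sources=4, window_length=20)

    def test_output_is_source_count_vector(self, rng):
        cfg = tiny_config()
        net = build_network(cfg, seed=0)
        out = net.forward(rng.normal(size=(1, 8, 9)).astype(np.float32))
        assert out.shape == (1, 12)

    def test_preflatten_map_has_sensor_rows_and_final_features(self, rng):
        """The conv block ends with S rows of conv_feature_schedule[-1]
        features at temporal extent 1."""
        cfg = NetworkConfig(n_sensors=32, n_sources=60, window_length=21)
        net = build_network(cfg, seed=0)
        x = rng.normal(size=(2, 32, 21)).astype(np.float32)[:, :, None, :]
        for layer in net.layers:
            if isinstance(layer, _Flatten):
                break
            x = layer.forward(x, training=False)
        assert x.shape == (2, 32, 128, 1)

    def test_parameter_count_matches_hand_tally(self):
        """Layer-by-layer arithmetic oracle for the default S=32, D=60 net."""
        cfg = NetworkConfig(n_sensors=32, n_sources=60, window_length=21)
        net = build_network(cfg, seed=0)
        features = [1, 16, 32, 64, 128]
        kernels = [5, 5, 3, 11]
        conv = sum(
            k * cin * cout + cout
            for k, cin, cout in zip(kernels, features[:-1], features[1:])
        )
        bn = sum(2 * c for c in features[1:-1])  # between consecutive convs
        fc_sizes = [32 * 128, 500, 500, 500, 500, 500, 500]
        fc = sum(a * b + b for a, b in zip(fc_sizes[:-1], fc_sizes[1:]))
        out = 500 * 60 + 60
        assert count_parameters(net) == conv + bn + fc + out


class TestTraining:
    def test_overfits_single_batch(self, rng):
        """One 64-example batch, >=500 epochs: loss collapses below 1% of
        the first-epoch loss."""
        cfg = tiny_config()
        net = build_network(cfg, seed=1)
        w = rng.normal(size=(64, 8, 9))
        t = rng.normal(size=(64, 12)) * 0.5
        tc = TrainConfig(
            learning_rate=1e-3, batch_size=64, epochs=500, seed=1,
            validation_fraction=0.0,
        )
        model = train_model(net, w, t, tc)
        losses = model.history["train_loss"]
        assert losses[-1] < 0.01 * losses[0]
        # and predictions match targets to matching tolerance
        pred = predict_window(model, w)
        assert np.mean((pred - t) ** 2) < 0.05 * np.mean(t**2)

    def test_identical_seed_gives_identical_weights(self, rng):
        w = rng.normal(size=(40, 8, 9))
        t = rng.normal(size=(40, 12))
        tc = TrainConfig(epochs=3, seed=9)
        m1 = train_model(build_network(tiny_config(), seed=9), w, t, tc)
        m2 = train_model(build_network(tiny_config(), seed=9), w, t, tc)
        for k, a in m1.net.state_arrays().items():
            np.testing.assert_array_equal(a, m2.net.state_arrays()[k])

    def test_default_optimizer_hyperparameters(self):
        tc = TrainConfig()
        assert tc.learning_rate == 1e-4
        assert tc.batch_size == 64

    def test_loss_recorded_per_epoch_with_validation(self, rng):
        w = rng.normal(size=(50, 8, 9))
        t = rng.normal(size=(50, 12))
        model = train_model(
            build_network(tiny_config(), seed=0), w, t,
            TrainConfig(epochs=4, seed=0, validation_fraction=0.2),
        )
        assert len(model.history["train_loss"]) == 4
        assert np.all(np.isfinite(model.history["val_loss"]))


class TestPrediction:
    @pytest.fixture(scope="class")
    def overfit_model(self):
        rng = np.random.default_rng(5)
        net = build_network(tiny_config(), seed=5)
        w = rng.normal(size=(64, 8, 9))
        t = rng.normal(size=(64, 12)) * 0.3
        model = train_model(
            net, w, t,
            TrainConfig(learning_rate=1e-3, batch_size=64, epochs=800, seed=5,
                        validation_fraction=0.0),
        )
        return model, w, t

    def test_zeroed_output_layer_predicts_zero(self, rng):
        net = build_network(tiny_config(), seed=0)
        final = net.layers[-1]
        final.w[:] = 0.0
        final.b[:] = 0.0
        w = rng.normal(size=(10, 8, 9))
        from meginverse.network import TrainedModel

        model = TrainedModel(
            net=net, config=net.config, train_config=TrainConfig(),
            input_mean=np.zeros(8), input_std=np.ones(8),
            target_scale=3.0, history={},
        )
        out = predict_window(model, w[0])
        np.testing.assert_array_equal(out, np.zeros(12))

    def test_shape_mismatch_rejected(self, overfit_model, rng):
        model, _, _ = overfit_model
        with pytest.raises(InputContractError):
            predict_window(model, rng.normal(size=(8, 11)))

    def test_overfit_predictions_match_targets(self, overfit_model):
        model, w, t = overfit_model
        pred = predict_window(model, w)
        assert np.mean((pred - t) ** 2) < 0.05 * np.mean(t**2)

    def test_batched_equals_individual_predictions(self, overfit_model):
        """BN runs in inference mode, so batching cannot change outputs."""
        model, w, _ = overfit_model
        batch = predict_window(model, w[:8])
        singles = np.stack([predict_window(model, x) for x in w[:8]])
        # float32 GEMM vs GEMV accumulation order differs at the last bits
        np.testing.assert_allclose(batch, singles, rtol=1e-3, atol=1e-6)


class TestReconstruction:
    def _recording(self, model, t_len, rng):
        s = model.config.n_sensors
        return SensorRecording(samples=rng.normal(size=(s, t_len)), snr_db=np.inf)

    @pytest.fixture(scope="class")
    def any_model(self):
        net = build_network(tiny_config(), seed=2)
        rng = np.random.default_rng(2)
        return train_model(
            net, rng.normal(size=(30, 8, 9)), rng.normal(size=(30, 12)),
            TrainConfig(epochs=1, seed=2, validation_fraction=0.0),
        )

    def test_window_length_recording_gives_one_column(self, any_model, rng):
        rec = self._recording(any_model, 9, rng)
        r = reconstruct_timeseries(any_model, rec)
        assert r.valid_stop - r.valid_start == 1
        assert r.activity.amplitudes.shape == (12, 9)
        edges = np.delete(np.arange(9), 4)
        assert not r.activity.amplitudes[:, edges].any()
        np.testing.assert_array_equal(r.edge_columns, edges)

    def test_valid_region_length(self, any_model, rng):
        rec = self._recording(any_model, 50, rng)
        r = reconstruct_timeseries(any_model, rec)
        assert r.valid_stop - r.valid_start == 50 - 9 + 1

    def test_too_short_recording_rejected(self, any_model, rng):
        with pytest.raises(InputContractError):
            reconstruct_timeseries(any_model, self._recording(any_model, 5, rng))

    def test_columns_match_per_window_predictions(self, any_model, rng):
        rec = self._recording(any_model, 20, rng)
        r = reconstruct_timeseries(any_model, rec)
        for c in (4, 10, 15):
            window = rec.samples[:, c - 4 : c + 5]
            np.testing.assert_allclose(
                r.activity.amplitudes[:, c],
                predict_window(any_model, window),
                rtol=2e-5, atol=1e-8,
            )


def test_end_to_end_overfit_recovers_source_traces():
    """Train on windows of one noiseless trial; the reconstructed active
    dipole trace correlates > 0.95 with the ground truth."""
    import meginverse as mi

    sensors = mi.build_sensor_helmet(8, radius=0.12)
    grid = mi.build_source_grid(radius=0.07, spacing=0.035, orientation_seed=0)
    lf = mi.assemble_leadfield(sensors, grid)
    rng = np.random.default_rng(3)
    sc = mi.make_scenario("single_focal", 1, grid, rng, duration=0.4)
    act = mi.render_source_activity(sc)
    rec = mi.simulate_recording(act, lf, np.inf)

    w = 9
    half = w // 2
    centers = np.arange(half, 400 - half)
    windows = np.stack([rec.samples[:, c - half : c + half + 1] for c in centers])
    targets = act.amplitudes[:, centers].T

    cfg = tiny_config(n_sensors=8, n_sources=grid.count, window_length=w)
    net = build_network(cfg, seed=3)
    model = train_model(
        net, windows, targets,
        TrainConfig(learning_rate=1e-3, batch_size=64, epochs=150, seed=3,
                    validation_fraction=0.0),
    )
    r = reconstruct_timeseries(model, rec)
    idx = sc.active_indices[0]
    est = r.activity.amplitudes[idx, r.valid]
    true = act.amplitudes[idx, r.valid]
    corr = np.corrcoef(est, true)[0, 1]
    assert corr > 0.95


def test_model_round_trip_is_bit_exact(tmp_path, rng):
    net = build_network(tiny_config(), seed=4)
    w = rng.normal(size=(30, 8, 9))
    t = rng.normal(size=(30, 12))
    model = train_model(net, w, t, TrainConfig(epochs=2, seed=4))
    save_model(tmp_path / "model", model)
    back = load_model(tmp_path / "model")
    np.testing.assert_array_equal(
        predict_window(model, w), predict_window(back, w)
    )
    assert back.train_config == model.train_config
    assert back.target_scale == model.target_scale
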