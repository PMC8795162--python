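"""Split-protocol round mechanics, training loop, and the centralized oracle."""

import numpy as np
import pytest

from splitsite.models import builtin_spec
from splitsite.nn import Adam, ParameterSet, ShapeError
from splitsite.partition import parse_ratio, stratified_partition
from splitsite.protocol import (
    AuditingBus,
    EndSystemState,
    FeatureMap,
    GradientSlice,
    ServerState,
    TrainConfig,
    TrainingAborted,
    _init_split_params,
    client_backward,
    client_forward,
    concatenate_feature_maps,
    local_batch_sizes,
    server_step,
    sync_client_weights,
    train,
)
from splitsite.synthetic import make_image_set

from conftest import tiny_split_model


def make_client(model, client_id=1, seed=0, indices=None):
    cp, _ = _init_split_params(model, seed)
    return EndSystemState(
        client_id=client_id,
        stack=model.client_stack,
        params=cp,
        optimizer=Adam(),
        local_indices=np.arange(10) if indices is None else indices,
        rng=np.random.default_rng(seed),
    )


def make_server(model, seed=0):
    _, sp = _init_split_params(model, seed)
    return ServerState(model.server_stack, sp, Adam(), model.spec.loss_name)


class TestLocalBatchSizes:
    def test_proportional_apportionment(self):
        part = stratified_partition(None, 1000, parse_ratio("8:1:1"), seed=0)
        assert local_batch_sizes(64, part) == [51, 7, 6]

    def test_equal_sizes_divide_evenly(self):
        part = stratified_partition(None, 400, parse_ratio("1:1:1:1"), seed=0)
        assert local_batch_sizes(64, part) == [16, 16, 16, 16]

    def test_minimum_one_sample_protected(self):
        part = stratified_partition(None, 1001, parse_ratio("1000:1"), seed=0)
        assert local_batch_sizes(5, part) == [4, 1]

    def test_batch_smaller_than_client_count_rejected(self):
        part = stratified_partition(None, 30, parse_ratio("1:1:1"), seed=0)
        with pytest.raises(ValueError):
            local_batch_sizes(2, part)


class TestClientForward:
    def test_zero_weights_give_zero_activations(self, tiny_model):
        client = make_client(tiny_model)
        for name in client.params.names():
            client.params.arrays[name][:] = 0.0
        fm = client_forward(client, np.random.default_rng(0).normal(size=(4, 8, 8, 1)), np.zeros(4))
        assert np.all(fm.activations == 0.0)

    def test_activation_shape_and_no_raw_samples_in_message(self, tiny_model):
        client = make_client(tiny_model)
        x = np.random.default_rng(1).normal(0.4, 0.2, (16, 8, 8, 1))
        fm = client_forward(client, x, np.ones(16))
        assert fm.activations.shape == (16, 4, 4, 2)
        assert not hasattr(fm, "samples")
        assert fm.labels.shape == (16,)

    def test_identical_parameters_give_identical_activations(self, tiny_model):
        a, b = make_client(tiny_model, 1, seed=5), make_client(tiny_model, 2, seed=5)
        x = np.random.default_rng(2).normal(size=(3, 8, 8, 1))
        fa = client_forward(a, x, np.zeros(3))
        fb = client_forward(b, x, np.zeros(3))
        assert np.array_equal(fa.activations, fb.activations)

    def test_non_finite_activations_abort(self, tiny_model):
        client = make_client(tiny_model)
        client.params.arrays["00_conv2d/kernel"][:] = np.inf
        with pytest.raises(FloatingPointError):
            client_forward(client, np.ones((2, 8, 8, 1)), np.zeros(2))


class TestConcatenation:
    def _maps(self, sizes, shape=(4, 4, 2)):
        rng = np.random.default_rng(0)
        return [
            FeatureMap(i + 1, rng.normal(size=(s, *shape)), rng.integers(0, 2, s), 0)
            for i, s in enumerate(sizes)
        ]

    def test_joined_batch_is_sum_of_local_batches(self):
        joined, labels, bounds = concatenate_feature_maps(self._maps([51, 7, 6]))
        assert joined.shape[0] == 64 and labels.shape[0] == 64
        assert [b[0] for b in bounds] == [1, 2, 3]

    def test_single_map_is_identity(self):
        (fm,) = self._maps([5])
        joined, labels, bounds = concatenate_feature_maps([fm])
        assert np.array_equal(joined, fm.activations)
        assert bounds == [(1, 0, 5)]

    def test_slicing_at_boundaries_inverts_concatenation(self):
        maps = self._maps([3, 4, 2])
        joined, _, bounds = concatenate_feature_maps(maps)
        for fm, (cid, start, stop) in zip(maps, bounds):
            assert cid == fm.client_id
            assert np.array_equal(joined[start:stop], fm.activations)

    def test_shape_mismatch_names_offending_client(self):
        maps = self._maps([3, 4])
        maps[1] = FeatureMap(2, np.zeros((4, 3, 3, 2)), np.zeros(4), 0)
        with pytest.raises(ShapeError, match="client 2"):
            concatenate_feature_maps(maps)

    def test_duplicate_client_ids_rejected(self):
        maps = self._maps([3, 4])
        maps[1].client_id = 1
        with pytest.raises(ValueError, match="duplicate"):
            concatenate_feature_maps(maps)


class TestServerStep:
    def test_bce_of_half_probability_is_ln_two(self, tiny_model):
        server = make_server(tiny_model)
        for name in server.params.names():  # zero weights -> sigmoid(0) = 0.5
            server.params.arrays[name][:] = 0.0
        acts = np.random.default_rng(0).normal(size=(4, 4, 4, 2))
        loss, _ = server_step(server, acts, np.ones(4), [(1, 0, 4)], apply_update=False)
        assert loss == pytest.approx(np.log(2), rel=1e-12)

    def test_perfect_mse_prediction_gives_zero_loss_and_gradient(self):
        from splitsite.nn import LayerDef, Stack

        stack = Stack([LayerDef("dense", units=1), LayerDef("activation", activation="linear")])
        params = ParameterSet({"00_dense/weight": np.array([[1.0]]), "00_dense/bias": np.zeros(1)})
        server = ServerState(stack, params, Adam(), "mse")
        acts = np.array([[2.0], [3.0]])
        loss, slices = server_step(server, acts, np.array([2.0, 3.0]), [(1, 0, 2)])
        assert loss == 0.0
        assert np.all(slices[0].grad == 0.0)

    def test_gradient_slices_partition_the_joined_gradient(self, tiny_model):
        server = make_server(tiny_model)
        acts = np.random.default_rng(3).normal(size=(10, 4, 4, 2))
        bounds = [(1, 0, 5), (2, 5, 8), (3, 8, 10)]
        _, slices = server_step(server, acts, np.ones(10), bounds, apply_update=False)
        assert sum(s.grad.shape[0] for s in slices) == 10
        assert [s.client_id for s in slices] == [1, 2, 3]


class TestClientBackward:
    def test_zero_gradient_slice_leaves_parameters_unchanged(self, tiny_model):
        client = make_client(tiny_model)
        x = np.random.default_rng(0).normal(size=(4, 8, 8, 1))
        fm = client_forward(client, x, np.zeros(4), batch_index=3)
        before = client.params.copy()
        client_backward(client, GradientSlice(1, np.zeros_like(fm.activations), 3))
        assert client.params.allclose(before)

    def test_stale_batch_cache_rejected(self, tiny_model):
        client = make_client(tiny_model)
        x = np.random.default_rng(0).normal(size=(4, 8, 8, 1))
        fm = client_forward(client, x, np.zeros(4), batch_index=3)
        with pytest.raises(ValueError, match="stale"):
            client_backward(client, GradientSlice(1, np.zeros_like(fm.activations), 4))

    def test_shape_mismatch_rejected(self, tiny_model):
        client = make_client(tiny_model)
        client_forward(client, np.zeros((4, 8, 8, 1)), np.zeros(4), batch_index=0)
        with pytest.raises(ShapeError):
            client_backward(client, GradientSlice(1, np.zeros((4, 3, 3, 2)), 0))


class TestSyncClientWeights:
    def test_mean_of_opposite_weights_is_zero(self, tiny_model):
        a, b = make_client(tiny_model, 1), make_client(tiny_model, 2)
        for name in a.params.names():
            b.params.arrays[name] = -a.params[name]
        sync_client_weights([a, b], mode="mean")
        assert all(np.all(a.params[n] == 0) for n in a.params.names())

    def test_idempotent_on_identical_clients(self, tiny_model):
        a, b = make_client(tiny_model, 1, seed=4), make_client(tiny_model, 2, seed=4)
        before = a.params.copy()
        sync_client_weights([a, b], mode="mean")
        assert a.params.allclose(before) and b.params.allclose(before)

    def test_broadcast_copies_client_one(self, tiny_model):
        a, b = make_client(tiny_model, 1, seed=1), make_client(tiny_model, 2, seed=2)
        sync_client_weights([a, b], mode="broadcast")
        assert b.params.allclose(a.params)

    def test_template_mismatch_rejected(self, tiny_model):
        a = make_client(tiny_model, 1)
        b = make_client(tiny_model, 2)
        b.params = ParameterSet({"other": np.zeros(3)})
        with pytest.raises(ValueError, match="template"):
            sync_client_weights([a, b])


def _train_setup(n=120, side=8, ratio="1:1:1", seed=3, **config_kw):
    model = tiny_split_model(side)
    imgs = make_image_set(n, side, lesion_contrast=0.5, noise_sd=0.05, seed=seed)
    part = stratified_partition(imgs.labels, n, parse_ratio(ratio), seed=seed)
    config = TrainConfig(spec=model.spec, partition=part, seed=seed, **config_kw)
    return model, imgs, config


class TestTrain:
    def test_loss_decreases_on_separable_data(self):
        model, imgs, config = _train_setup(n=240, epochs=20)
        history, _ = train(config, imgs.images, imgs.labels, model=model)
        assert history.rows[-1]["train_loss"] < history.rows[0]["train_loss"]

    def test_zero_epochs_returns_empty_history_and_initial_parameters(self):
        model, imgs, config = _train_setup(epochs=0)
        history, state = train(config, imgs.images, imgs.labels, model=model)
        assert history.rows == []
        cp0, sp0 = _init_split_params(model, config.seed)
        assert state["clients"][0].allclose(cp0)
        assert state["server"].allclose(sp0)

    def test_deterministic_given_seed(self):
        model, imgs, config = _train_setup(epochs=3)
        h1, _ = train(config, imgs.images, imgs.labels, model=model, record_steps=True)
        h2, _ = train(config, imgs.images, imgs.labels, model=model, record_steps=True)
        assert h1.step_losses == h2.step_losses

    def test_concatenation_conserves_batch_sizes_every_round(self):
        model, imgs, config = _train_setup(n=120, epochs=2)
        history, _ = train(config, imgs.images, imgs.labels, model=model, record_steps=True)
        for batch in history.step_batches:
            assert batch.size >= config.partition.n_clients

    def test_sync_mode_matches_centralized_training(self):
        """A 3-client sync-mode run equals monolithic training on the pooled
        batches, step for step (the equivalence oracle)."""
        model, imgs, config = _train_setup(n=240, epochs=5, sync_mode=True, seed=7)
        history, _ = train(config, imgs.images, imgs.labels, model=model, record_steps=True)

        # independent centralized oracle: same layers, pooled data, same batches
        cstack, sstack = model.client_stack, model.server_stack
        cp, sp = _init_split_params(model, config.seed)
        copt, sopt = Adam(), Adam()
        central_losses = []
        for batch in history.step_batches:
            xb, yb = imgs.images[batch], imgs.labels[batch].astype(float)
            fm, ccache = cstack.forward(xb, cp)
            out, scache = sstack.forward(fm, sp)
            loss, dcut, sgrads = sstack.loss_backward(yb, out, scache, sp, "binary_crossentropy")
            _, cgrads = cstack.backward(dcut, ccache, cp)
            sopt.step(sp, sgrads)
            copt.step(cp, cgrads)
            central_losses.append(loss)
        split_losses = np.asarray(history.step_losses)
        central_losses = np.asarray(central_losses)
        rel = np.abs(split_losses - central_losses) / np.maximum(np.abs(central_losses), 1e-12)
        assert rel.max() < 1e-5

    def test_server_only_receives_transmitted_feature_maps(self):
        """Message hygiene: every payload the server consumed was sent across
        the bus, and no raw input batch ever crossed it."""
        import hashlib

        model, imgs, config = _train_setup(n=60, epochs=2)
        bus = AuditingBus()
        train(config, imgs.images, imgs.labels, model=model, bus=bus)
        assert bus.received_feature_hashes <= bus.sent_feature_hashes
        raw_hashes = {
            hashlib.sha256(np.ascontiguousarray(imgs.images[i : i + 1]).tobytes()).hexdigest()
            for i in range(imgs.images.shape[0])
        }
        assert raw_hashes.isdisjoint(bus.received_feature_hashes)
        assert bus.gradient_hashes  # gradients flowed back

    def test_partition_size_mismatch_rejected(self):
        model, imgs, config = _train_setup(n=120)
        with pytest.raises(ValueError, match="partition"):
            train(config, imgs.images[:100], imgs.labels[:100], model=model)

    def test_non_finite_loss_aborts_with_context(self, tiny_model):
        model, imgs, config = _train_setup(epochs=1)
        imgs.images[0, 0, 0, 0] = np.nan
        with pytest.raises((TrainingAborted, FloatingPointError)):
            train(config, imgs.images, imgs.labels, model=model)
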