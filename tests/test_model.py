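"""Network layers, losses, training mechanics."""

import numpy as np
import pytest

import valvenet as vn
from valvenet.model import (ClosureSurrogate, Standardizer, SurrogateConfig,
                            _batch_loss_and_grad, augment_translate,
                            bc_weighted_loss, bc_weighted_loss_grad,
                            bc_weights, encode_input, total_loss, train)
from valvenet.nn import Adam, Conv2D, Dense, ReLU

TINY = SurrogateConfig(conv_channels=(4,), embedding_size=8, code_size=16,
                       head_hidden=6, epochs=0, seed=3)


# -- BC-weighted loss ---------------------------------------------------------

def test_bc_loss_zero_for_perfect_prediction(rng):
    u = rng.normal(size=(3, 8, 8, 3))
    assert bc_weighted_loss(u, u) == 0.0


def test_bc_loss_suppresses_fixed_node_error():
    # weights (0, 1): the error at the zero-target entry costs nothing
    assert bc_weighted_loss(np.array([1.0, 2.0]), np.array([0.0, 2.0])) == 0.0


def test_bc_loss_hand_computed_case():
    # weights (0.5, 1): loss = (0.5*1 + 1*4)/2 = 2.25
    loss = bc_weighted_loss(np.array([0.0, 0.0]), np.array([1.0, 2.0]))
    np.testing.assert_allclose(loss, 2.25)


def test_bc_loss_all_zero_target_falls_back_to_mse():
    loss = bc_weighted_loss(np.array([1.0, 1.0]), np.zeros(2))
    np.testing.assert_allclose(loss, 1.0)


def test_bc_loss_rejects_nan():
    with pytest.raises(FloatingPointError):
        bc_weighted_loss(np.array([np.nan]), np.array([1.0]))
    with pytest.raises(ValueError):
        bc_weighted_loss(np.zeros(3), np.zeros(4))


def test_bc_nodal_weights_share_across_components():
    u = np.zeros((2, 2, 3))
    u[1, 1] = (3.0, 4.0, 0.0)  # magnitude 5
    w = bc_weights(u, vector_axis=-1)
    assert w[1, 1, 2] == 1.0  # zero z-component still fully weighted
    assert np.all(w[0, 0] == 0.0)


def test_bc_loss_gradient_matches_finite_differences(rng):
    u_true = rng.normal(size=(4, 5)) * np.array([0, 1, 1, 1, 1.0])
    u_pred = rng.normal(size=(4, 5))
    grad = bc_weighted_loss_grad(u_pred, u_true)
    h = 1e-6
    for _ in range(20):
        i, j = rng.integers(4), rng.integers(5)
        up, um = u_pred.copy(), u_pred.copy()
        up[i, j] += h
        um[i, j] -= h
        fd = (bc_weighted_loss(up, u_true) - bc_weighted_loss(um, u_true)) / (2 * h)
        assert abs(grad[i, j] - fd) / max(1e-8, abs(fd) + abs(grad[i, j])) < 1e-5


def test_total_loss_additivity(rng):
    u_true = rng.normal(size=(3, 4, 4, 3))
    u_pred = u_true + 0.1 * rng.normal(size=u_true.shape)
    def_term = sum(bc_weighted_loss(u_pred[k], u_true[k]) for k in range(3))
    area_term = (0.3 - 0.2) ** 2
    combined = total_loss(u_pred, u_true, 0.3, 0.2, lambda_c=1.0)
    np.testing.assert_allclose(combined, def_term + area_term)
    np.testing.assert_allclose(total_loss(u_pred, u_true, 0.3, 0.2, lambda_c=0.0),
                               def_term)
    assert total_loss(u_true, u_true, 0.5, 0.5) == 0.0


# -- input encoding and augmentation ------------------------------------------

def test_encode_input_pressure_vector(rng):
    ds = vn.generate_dataset(3, seed=5)
    std = Standardizer.fit(ds.material, ds.pressure, ds.coaptation)
    tex, mat, press = encode_input(ds[0], std, SurrogateConfig())
    assert press.shape == (10,)
    assert np.all(press == press[0])  # one repeated scalar
    np.testing.assert_allclose(std.pressure_inverse(press), ds.pressure[0])
    np.testing.assert_array_equal(tex, ds.reference[0])
    np.testing.assert_allclose(std.material_inverse(mat), ds.material[0],
                               rtol=1e-10)


def test_encode_input_grid_mismatch_raises():
    ds = vn.generate_dataset(1, seed=5)
    with pytest.raises(ValueError):
        encode_input(ds[0], Standardizer(), SurrogateConfig(grid=(6, 6)))


def test_augment_translate_shifts_inputs_only(rng):
    ds = vn.generate_dataset(2, seed=5)
    sample = ds[0]
    aug = augment_translate(sample, np.random.default_rng(4), translation_range=0.5)
    shift = aug.reference[0, 0, 0] - sample.reference[0, 0, 0]
    np.testing.assert_allclose(aug.reference, sample.reference + shift)
    assert np.array_equal(aug.displacement, sample.displacement)
    assert aug.coaptation_area == sample.coaptation_area
    same = augment_translate(sample, np.random.default_rng(4), translation_range=0.5)
    np.testing.assert_array_equal(same.reference, aug.reference)
    null = augment_translate(sample, np.random.default_rng(4), translation_range=0.0)
    np.testing.assert_array_equal(null.reference, sample.reference)


# -- forward pass -------------------------------------------------------------

def test_forward_contract_and_determinism(rng):
    model = ClosureSurrogate(TINY)
    tex = rng.normal(size=(4, 3, 8, 8, 3))
    mat = rng.normal(size=(4, 4))
    press = rng.normal(size=(4, 10))
    out1 = model.forward(tex, mat, press)
    out2 = model.forward(tex, mat, press)
    assert out1.displacement.shape == (4, 3, 8, 8, 3)
    assert out1.code.shape == (4, TINY.code_size)
    np.testing.assert_array_equal(out1.displacement, out2.displacement)
    np.testing.assert_array_equal(out1.coaptation_area, out2.coaptation_area)


def test_coaptation_prediction_nonnegative_for_random_inputs(rng):
    model = ClosureSurrogate(TINY)
    for _ in range(10):
        tex = 5.0 * rng.standard_normal((1000, 3, 8, 8, 3))
        mat = 3.0 * rng.standard_normal((1000, 4))
        press = 3.0 * rng.standard_normal((1000, 10))
        area = model.forward(tex, mat, press).coaptation_area
        assert np.all(area >= 0.0)


def test_extract_code_deterministic(rng):
    model = ClosureSurrogate(TINY)
    tex = rng.normal(size=(2, 3, 8, 8, 3))
    mat = rng.normal(size=(2, 4))
    press = rng.normal(size=(2, 10))
    c1 = model.extract_code(tex, mat, press)
    c2 = model.extract_code(tex, mat, press)
    assert c1.shape == (2, TINY.code_size)
    np.testing.assert_array_equal(c1, c2)


def test_unshared_encoders_build_and_run(rng):
    cfg = SurrogateConfig(conv_channels=(4,), embedding_size=8, code_size=16,
                          share_encoder=False, epochs=0)
    model = ClosureSurrogate(cfg)
    out = model.forward(rng.normal(size=(2, 3, 8, 8, 3)),
                        rng.normal(size=(2, 4)), rng.normal(size=(2, 10)))
    assert out.displacement.shape == (2, 3, 8, 8, 3)


# -- gradients through the network --------------------------------------------

@pytest.mark.parametrize("layer_factory, x_shape", [
    (lambda rng: Dense(6, 4, rng), (5, 6)),
    (lambda rng: Conv2D(2, 3, 3, rng), (2, 5, 5, 2)),
])
def test_layer_gradients_match_finite_differences(rng, layer_factory, x_shape):
    layer = layer_factory(rng)
    x = rng.normal(size=x_shape)
    y = layer.forward(x)
    dy = rng.normal(size=y.shape)
    loss = lambda: float(np.sum(layer.forward(x) * dy))
    dx = layer.backward(dy)
    h = 1e-6
    # input gradient
    for _ in range(5):
        idx = tuple(rng.integers(s) for s in x.shape)
        xp, xm = x.copy(), x.copy()
        xp[idx] += h
        xm[idx] -= h
        fd = (np.sum(layer.forward(xp) * dy) - np.sum(layer.forward(xm) * dy)) / (2 * h)
        assert abs(dx[idx] - fd) < 1e-6 * max(1.0, abs(fd))
    # parameter gradients
    layer.forward(x)
    layer.backward(dy)
    for p, g in zip(layer.params(), layer.grads()):
        flat = p.ravel()
        for _ in range(3):
            j = rng.integers(flat.size)
            old = flat[j]
            flat[j] = old + h
            lp = loss()
            flat[j] = old - h
            lm = loss()
            flat[j] = old
            fd = (lp - lm) / (2 * h)
            assert abs(g.ravel()[j] - fd) < 1e-6 * max(1.0, abs(fd))


def test_full_model_gradient_check(rng):
    model = ClosureSurrogate(TINY, Standardizer())
    tex = rng.normal(size=(3, 3, 8, 8, 3))
    mat = rng.normal(size=(3, 4))
    press = rng.normal(size=(3, 10))
    u_true = 0.1 * rng.normal(size=(3, 3, 8, 8, 3))
    a_true = rng.uniform(0.1, 0.3, 3)

    def loss_fn():
        b = model.forward(tex, mat, press)
        return _batch_loss_and_grad(model, b.displacement, u_true,
                                    b.coaptation_area, a_true)

    _, d_u, d_area = loss_fn()
    model.backward(d_u, d_area)
    grads = [g.copy() for g in model.grads()]
    h = 1e-6
    worst = 0.0
    for p, g in zip(model.params(), grads):
        flat = p.ravel()
        for _ in range(2):
            j = rng.integers(flat.size)
            old = flat[j]
            flat[j] = old + h
            lp = loss_fn()[0]
            flat[j] = old - h
            lm = loss_fn()[0]
            flat[j] = old
            fd = (lp - lm) / (2 * h)
            an = g.ravel()[j]
            worst = max(worst, abs(fd - an) / max(1e-7, abs(fd) + abs(an)))
    assert worst < 1e-5


# -- training -----------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_dataset():
    return vn.generate_dataset(10, seed=9)


def test_zero_epochs_returns_initialization(tiny_dataset):
    cfg = SurrogateConfig(conv_channels=(4,), embedding_size=8, code_size=16,
                          epochs=0, seed=7)
    model, history = train(tiny_dataset, np.arange(8), np.arange(8, 10), cfg)
    fresh = ClosureSurrogate(cfg, model.standardizer)
    for a, b in zip(model.params(), fresh.params()):
        np.testing.assert_array_equal(a, b)
    assert history.train_loss == []


def test_single_step_decreases_batch_loss(tiny_dataset):
    ds = tiny_dataset
    std = Standardizer.fit(ds.material, ds.pressure, ds.coaptation)
    cfg = SurrogateConfig(conv_channels=(4,), embedding_size=8, code_size=16,
                          epochs=0, seed=1)
    model = ClosureSurrogate(cfg, std)
    sel = np.arange(4)
    tex = ds.reference[sel]
    mat = std.material(ds.material[sel])
    press = std.pressure_vector(ds.pressure[sel])

    def batch_loss():
        b = model.forward(tex, mat, press)
        return _batch_loss_and_grad(model, b.displacement, ds.displacement[sel],
                                    b.coaptation_area, ds.coaptation[sel])

    loss0, d_u, d_area = batch_loss()
    model.backward(d_u, d_area)
    Adam(model.params(), lr=1e-4).step(model.grads())
    assert batch_loss()[0] < loss0


@pytest.fixture(scope="module")
def overfit_model(tiny_dataset):
    cfg = SurrogateConfig(conv_channels=(8,), embedding_size=16, code_size=32,
                          head_hidden=8, epochs=500, batch_size=10,
                          augment=False, seed=2)
    model, history = train(tiny_dataset, np.arange(10), np.arange(10), cfg)
    return model, history


def test_overfit_small_corpus(overfit_model):
    _, history = overfit_model
    assert history.train_loss[-1] < 0.01 * history.train_loss[0]


def test_trained_code_separates_belly_parameter(overfit_model):
    from valvenet.design import ValveDesignParams, build_valve
    model, _ = overfit_model
    std = model.standardizer
    mat = std.material(np.array([[400.0, 200.0, 1.0, 0.05]]))
    press = std.pressure_vector(np.array([80.0]))
    codes = []
    for belly in (0.2, 0.8):
        valve = build_valve(ValveDesignParams(belly=belly))
        codes.append(model.extract_code(valve.textures()[None], mat, press)[0])
    assert np.linalg.norm(codes[0] - codes[1]) > 0.0


def test_training_divergence_aborts(tiny_dataset):
    cfg = SurrogateConfig(conv_channels=(4,), embedding_size=8, code_size=16,
                          epochs=50, learning_rate=1e150, augment=False, seed=0)
    with pytest.raises(RuntimeError, match="diverged"):
        train(tiny_dataset, np.arange(8), np.arange(8, 10), cfg)


def test_train_requires_nonempty_splits(tiny_dataset):
    with pytest.raises(ValueError):
        train(tiny_dataset, np.arange(0), np.arange(8, 10), TINY)


def test_model_save_load_round_trip(tiny_dataset, tmp_path, rng):
    cfg = SurrogateConfig(conv_channels=(4,), embedding_size=8, code_size=16,
                          epochs=1, seed=5)
    model, _ = train(tiny_dataset, np.arange(8), np.arange(8, 10), cfg)
    model.save(tmp_path / "model.pkl")
    back = ClosureSurrogate.load(tmp_path / "model.pkl")
    tex = rng.normal(size=(2, 3, 8, 8, 3))
    mat = rng.normal(size=(2, 4))
    press = rng.normal(size=(2, 10))
    np.testing.assert_array_equal(back.forward(tex, mat, press).displacement,
                                  model.forward(tex, mat, press).displacement)
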