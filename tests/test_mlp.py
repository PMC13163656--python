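"""The three-layer sigmoid network and its online training loop."""

import numpy as np
import pytest

import geneimage as g
from geneimage.mlp import _sigmoid


def toy_model(n=5, k=2, nh=4, seed=3, **kw):
    cfg = g.MLPConfig(n_inputs=n, n_outputs=k, n_hidden=nh, seed=seed, **kw)
    return g.init_mlp(cfg, [f"org{i}" for i in range(k)])


@pytest.mark.parametrize("n,k,expected", [
    (100, 4, 20),       # sqrt(400)
    (4465, 31, 372),    # sqrt(138415) ~ 372.04
    (1900, 31, 243),    # sqrt(58900) ~ 242.69
    (1, 1, 1),
])
def test_geometric_pyramid_rule(n, k, expected):
    assert g.hidden_size(n, k) == expected


def test_hidden_size_rejects_nonpositive():
    with pytest.raises(ValueError):
        g.hidden_size(0, 3)


def test_init_is_seed_deterministic_and_bounded():
    a, b = toy_model(seed=7), toy_model(seed=7)
    c = toy_model(seed=8)
    assert np.array_equal(a.hidden_weights, b.hidden_weights)
    assert np.array_equal(a.output_weights, b.output_weights)
    assert not np.array_equal(a.hidden_weights, c.hidden_weights)
    assert np.abs(a.hidden_weights).max() <= 0.5


def test_forward_zero_weights_gives_half():
    model = toy_model()
    model.hidden_weights[:] = 0.0
    model.output_weights[:] = 0.0
    out = g.forward(model, np.zeros(5))
    assert np.allclose(out, 0.5)


def test_forward_outputs_strictly_inside_unit_interval():
    model = toy_model(seed=12)
    rng = np.random.default_rng(0)
    for _ in range(10):
        out = g.forward(model, rng.integers(0, 2, 5).astype(float))
        assert np.all(out > 0) and np.all(out < 1)


def test_forward_rejects_dimension_mismatch():
    with pytest.raises(ValueError, match="n_inputs"):
        g.forward(toy_model(), np.zeros(6))


def test_hidden_unit_permutation_leaves_outputs_unchanged():
    model = toy_model(n=6, k=3, nh=5, seed=9)
    perm = np.array([3, 0, 4, 1, 2])
    permuted = g.MLPModel(
        config=model.config,
        hidden_weights=model.hidden_weights[perm],
        output_weights=np.hstack(
            [model.output_weights[:, :-1][:, perm], model.output_weights[:, -1:]]
        ),
        label_order=list(model.label_order),
    )
    x = np.array([1, 0, 1, 1, 0, 1], dtype=float)
    assert np.allclose(g.forward(model, x), g.forward(permuted, x))


def test_rmse_hand_computed_case():
    model = toy_model(n=2, k=2, nh=2)
    x = np.zeros(2)
    y = g.forward(model, x)
    # targets equal to outputs -> 0
    assert g.rmse(model, [x], [y]) == pytest.approx(0.0)
    # 2 samples x 2 outputs with per-unit errors e: sqrt(mean(e^2))
    t1 = y + np.array([0.1, -0.3])
    t2 = y + np.array([0.2, 0.0])
    expected = np.sqrt((0.01 + 0.09 + 0.04 + 0.0) / 4)
    assert g.rmse(model, [x, x], [t1, t2]) == pytest.approx(expected)
    with pytest.raises(ValueError):
        g.rmse(model, [], [])


def test_training_converges_and_classifies_training_set():
    rng = np.random.default_rng(4)
    xs = [rng.integers(0, 2, 50).astype(float) for _ in range(3)]
    ts = [np.eye(3)[i] for i in range(3)]
    model = toy_model(n=50, k=3, nh=12, seed=5)
    trained, log = g.train_online(model, xs, ts)
    assert log[-1] <= 0.01
    assert g.rmse(trained, xs, ts) <= 0.01
    for x, t in zip(xs, ts):
        assert np.argmax(g.forward(trained, x)) == np.argmax(t)
    # non-increasing tail: training error must have improved overall
    assert log[-1] < log[0]


def test_training_is_seed_deterministic():
    rng = np.random.default_rng(4)
    xs = [rng.integers(0, 2, 30).astype(float) for _ in range(2)]
    ts = [np.eye(2)[i] for i in range(2)]
    runs = []
    for _ in range(2):
        trained, log = g.train_online(toy_model(n=30, k=2, nh=8, seed=21), xs, ts)
        runs.append((trained.hidden_weights.copy(), trained.output_weights.copy(), log))
    assert np.array_equal(runs[0][0], runs[1][0])
    assert np.array_equal(runs[0][1], runs[1][1])
    assert runs[0][2] == runs[1][2]


def test_zero_learning_rate_leaves_error_constant():
    xs = [np.ones(5), np.zeros(5)]
    ts = [np.eye(2)[0], np.eye(2)[1]]
    model = toy_model(learning_rate=0.0, momentum=0.0, max_epochs=30)
    with pytest.raises(g.NonConvergenceError) as exc:
        g.train_online(model, xs, ts)
    log = exc.value.log
    assert len(log) == 30
    assert all(v == pytest.approx(log[0]) for v in log)


def test_duplicate_one_hot_targets_rejected():
    xs = [np.ones(5), np.zeros(5)]
    ts = [np.eye(2)[0], np.eye(2)[0]]
    with pytest.raises(ValueError, match="one-hot"):
        g.train_online(toy_model(), xs, ts)


def test_backprop_gradient_matches_finite_differences():
    """One momentum-free update equals lr * (-dE/dw) for E = 0.5*sum((y-t)^2)."""
    lr = 1e-2
    cfg = g.MLPConfig(n_inputs=4, n_outputs=3, n_hidden=5, seed=13,
                      learning_rate=lr, momentum=0.0, max_epochs=1,
                      shuffle_each_epoch=False)
    model = g.init_mlp(cfg, ["a", "b", "c"])
    x = np.array([1.0, 0.0, 1.0, 1.0])
    t = np.array([1.0, 0.0, 0.0])

    def loss(hw, ow):
        h = _sigmoid(hw[:, :-1] @ x + hw[:, -1])
        y = _sigmoid(ow[:, :-1] @ h + ow[:, -1])
        return 0.5 * np.sum((y - t) ** 2)

    hw0, ow0 = model.hidden_weights.copy(), model.output_weights.copy()
    # the backprop deltas exactly as the training loop computes them
    h = _sigmoid(hw0[:, :-1] @ x + hw0[:, -1])
    y = _sigmoid(ow0[:, :-1] @ h + ow0[:, -1])
    delta_o = (t - y) * y * (1 - y)
    delta_h = (ow0[:, :-1].T @ delta_o) * h * (1 - h)
    analytic_hw = np.hstack([np.outer(delta_h, x), delta_h[:, None]])
    analytic_ow = np.hstack([np.outer(delta_o, h), delta_o[:, None]])

    eps = 1e-6
    for mat, analytic in ((hw0, analytic_hw), (ow0, analytic_ow)):
        it = np.nditer(mat, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            hw_p, ow_p = hw0.copy(), ow0.copy()
            hw_m, ow_m = hw0.copy(), ow0.copy()
            if mat is hw0:
                hw_p[idx] += eps
                hw_m[idx] -= eps
            else:
                ow_p[idx] += eps
                ow_m[idx] -= eps
            fd = (loss(hw_p, ow_p) - loss(hw_m, ow_m)) / (2 * eps)
            grad = -analytic[idx]  # backprop computes the descent direction
            assert abs(fd - grad) <= 1e-6 * max(1.0, abs(fd)), idx


def test_model_round_trip(tmp_path):
    model = toy_model(n=7, k=2, nh=3, seed=2)
    path = tmp_path / "model.json"
    g.save_model(model, path)
    loaded = g.load_model(path)
    assert loaded.config == model.config
    assert loaded.label_order == model.label_order
    assert np.array_equal(loaded.hidden_weights, model.hidden_weights)
    assert np.array_equal(loaded.output_weights, model.output_weights)
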