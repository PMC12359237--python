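"""Network forward/backward, constraint losses, refinement, strategies."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from minnflux import (
    MechanisticContext,
    MinnConfig,
    SchedulerConfig,
    apply_bound_strategy,
    data_loss,
    ema_balance,
    fba_gradient,
    fba_loss,
    mechanistic_refine,
    nn_forward,
    predict,
    scheduler_weights,
    solve_fba,
    total_loss,
    train_minn,
)
from minnflux.minn_core import (
    LossState,
    TrainedMinn,
    init_weights,
    refine_backward,
    stable_step_size,
)
from minnflux.synthetic_fixtures import GLC_UPTAKE, O2_UPTAKE, SyntheticSpec, simulate_dataset


def _random_ctx(rng, m=None, n=None, nin=2):
    m = m or int(rng.integers(2, 6))
    n = n or int(rng.integers(max(3, nin + 1), 9))
    S = rng.normal(size=(m, n))
    Pin = np.zeros((nin, n))
    cols = rng.choice(n, nin, replace=False)
    for i, j in enumerate(cols):
        Pin[i, j] = 1.0
    return MechanisticContext(
        S, Pin, np.eye(n),
        [f"r{i}" for i in range(n)], [f"m{i}" for i in range(m)],
        [f"r{j}" for j in cols], [f"r{i}" for i in range(n)],
    )


PAIR_CTX = MechanisticContext(
    S=np.array([[1.0, -1.0]]), Pin=np.zeros((0, 2)), Pref=np.eye(2),
    reaction_ids=["R1", "R2"], metabolite_ids=["A"],
    input_reaction_ids=[], target_ids=["R1", "R2"],
)


# --------------------------------------------------------------- nn_forward

def test_forward_zero_weights_zero_output():
    w = {"Wh": np.zeros((3, 4)), "bh": np.zeros(4),
         "Wout": np.zeros((4, 2)), "bout": np.zeros(2)}
    V0, _ = nn_forward(np.ones((5, 3)), w)
    assert np.all(V0 == 0.0)


def test_forward_hand_evaluated_relu():
    w = {"Wh": np.array([[1.0]]), "bh": np.zeros(1),
         "Wout": np.array([[2.0]]), "bout": np.array([1.0])}
    V0, _ = nn_forward(np.array([[3.0]]), w)
    assert V0[0, 0] == pytest.approx(7.0)
    V0, _ = nn_forward(np.array([[-3.0]]), w)
    assert V0[0, 0] == pytest.approx(1.0)  # relu kills the negative input


def test_forward_deterministic_without_dropout(rng):
    w = init_weights(4, 8, 3, rng)
    X = np.tile(rng.normal(size=(1, 4)), (2, 1))
    V0, _ = nn_forward(X, w, training=False)
    assert np.array_equal(V0[0], V0[1])


def test_forward_shape_mismatch_errors(rng):
    w = init_weights(4, 8, 3, rng)
    with pytest.raises(ValueError, match="expected"):
        nn_forward(np.zeros((2, 5)), w)


# ----------------------------------------------------------------- fba_loss

def test_fba_loss_zero_on_fba_solution(split_model, toy_ctx):
    sol = solve_fba(split_model)
    v = sol.fluxes.reindex(toy_ctx.reaction_ids).to_numpy()
    vin = v @ toy_ctx.Pin.T
    l2, l3, l4 = fba_loss(v, toy_ctx, vin)
    assert l2 + l3 + l4 == pytest.approx(0.0, abs=1e-12)


def test_fba_loss_hand_arithmetic_steady_state():
    l2, l3, l4 = fba_loss(np.array([[2.0, 1.0]]), PAIR_CTX, None)
    assert l2 == pytest.approx(1.0)
    assert l4 == pytest.approx(0.0)


def test_fba_loss_hand_arithmetic_negativity():
    l2, l3, l4 = fba_loss(np.array([[0.0, -0.3]]), PAIR_CTX, None)
    assert l4 == pytest.approx(0.045)  # 0.3^2 / n with n = 2


def test_fba_loss_upper_bound_term(rng):
    ctx = _random_ctx(rng, m=2, n=4, nin=1)
    j = int(np.argmax(ctx.Pin[0]))
    V = np.zeros((1, 4))
    V[0, j] = 3.0
    _, l3, _ = fba_loss(V, ctx, np.array([[1.0]]))
    assert l3 == pytest.approx(4.0)  # relu(3-1)^2 / nin


def test_fba_gradient_matches_finite_differences(rng):
    for _ in range(20):
        ctx = _random_ctx(rng)
        V = rng.normal(size=(1, ctx.n))
        Vin = rng.normal(size=(1, ctx.nin))
        g = fba_gradient(V, ctx, Vin)
        eps = 1e-6
        for j in range(ctx.n):
            Vp, Vm = V.copy(), V.copy()
            Vp[0, j] += eps
            Vm[0, j] -= eps
            fd = (sum(fba_loss(Vp, ctx, Vin)) - sum(fba_loss(Vm, ctx, Vin))) / (2 * eps)
            if abs(fd) > 1e-8:
                assert abs(g[0, j] - fd) / max(abs(fd), 1e-10) < 1e-5


# ------------------------------------------------------- mechanistic_refine

def test_refine_fixed_point_on_feasible_input():
    V0 = np.array([[1.5, 1.5]])
    V, _ = mechanistic_refine(V0, PAIR_CTX, None, lr_mech=0.1, k_iter=5)
    assert np.allclose(V, V0)


def test_refine_hand_computed_single_step():
    V, _ = mechanistic_refine(
        np.array([[2.0, 1.0]]), PAIR_CTX, None, lr_mech=0.1, k_iter=1
    )
    assert np.allclose(V, [[1.8, 1.2]])
    l2, _, _ = fba_loss(V, PAIR_CTX, None)
    assert l2 == pytest.approx(0.36)


def test_refine_monotone_decrease_below_stability_bound(rng):
    for _ in range(10):
        ctx = _random_ctx(rng)
        lr = stable_step_size(ctx)
        V = rng.normal(size=(2, ctx.n)) * 3
        Vin = np.abs(rng.normal(size=(2, ctx.nin)))
        losses = [sum(fba_loss(V, ctx, Vin))]
        for _ in range(15):
            V, _ = mechanistic_refine(V, ctx, Vin, lr, 1)
            losses.append(sum(fba_loss(V, ctx, Vin)))
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))


def test_refine_backward_matches_finite_differences(rng):
    ctx = _random_ctx(rng, m=3, n=6)
    V0 = rng.normal(size=(2, ctx.n))
    Vin = np.abs(rng.normal(size=(2, ctx.nin)))
    lr, k = 0.05, 6

    def scalar(V0_):
        V, _ = mechanistic_refine(V0_, ctx, Vin, lr, k)
        return float(np.sum(np.sin(V)))  # arbitrary smooth downstream loss

    V, cache = mechanistic_refine(V0, ctx, Vin, lr, k, need_cache=True)
    gV0, _ = refine_backward(np.cos(V), cache, ctx, Vin, lr)
    eps = 1e-6
    for i in range(2):
        for j in range(ctx.n):
            Vp, Vm = V0.copy(), V0.copy()
            Vp[i, j] += eps
            Vm[i, j] -= eps
            fd = (scalar(Vp) - scalar(Vm)) / (2 * eps)
            assert gV0[i, j] == pytest.approx(fd, rel=1e-4, abs=1e-8)


# ---------------------------------------------------------------- data_loss

def test_ne_hand_value():
    l1, _ = data_loss(np.array([[1.0, 2.0]]), np.array([[2.0, 2.0]]))
    assert l1 == pytest.approx(1.0 / np.sqrt(8.0))  # 0.35355...


def test_ne_perfect_prediction_and_zero_reference():
    l1, g = data_loss(np.array([[2.0, 2.0]]), np.array([[2.0, 2.0]]))
    assert l1 == 0.0 and np.all(g == 0.0)
    with pytest.raises(ValueError, match="all-zero"):
        data_loss(np.array([[1.0, 1.0]]), np.array([[0.0, 0.0]]))


@settings(deadline=None, max_examples=30)
@given(scale=st.floats(min_value=1e-3, max_value=1e3))
def test_ne_is_scale_invariant(scale):
    pred = np.array([[1.0, 3.0, -1.0]])
    ref = np.array([[2.0, 2.5, 0.5]])
    l1, _ = data_loss(pred, ref)
    l1s, _ = data_loss(pred * scale, ref * scale)
    assert l1s == pytest.approx(l1, rel=1e-9)


def test_mse_mode_hand_value():
    l1, g = data_loss(np.array([[1.0, 2.0]]), np.array([[2.0, 2.0]]), mode="mse")
    assert l1 == pytest.approx(0.5)
    assert np.allclose(g, [[-1.0, 0.0]])


# -------------------------------------------------------------- strategies

def test_total_loss_arithmetic():
    comps = (0.2, 0.01, 0.0, 0.0)
    cfg = MinnConfig(strategy="c_balanced", c=10.0)
    total, _ = total_loss(comps, cfg, epoch=0, state=LossState())
    assert total == pytest.approx(2.01)
    total, _ = total_loss(comps, MinnConfig(strategy="divided"), 0, LossState())
    assert total == pytest.approx(0.2)


def test_c_equal_one_reduces_to_unbalanced():
    comps = (0.3, 0.05, 0.02, 0.01)
    a, _ = total_loss(comps, MinnConfig(strategy="c_balanced", c=1.0), 0, LossState())
    b, _ = total_loss(comps, MinnConfig(strategy="unbalanced"), 0, LossState())
    assert a == pytest.approx(b)


def test_bound_strategy_values_and_continuity():
    assert apply_bound_strategy(0.05, 0.1, 10.0) == pytest.approx(0.05)
    assert apply_bound_strategy(0.2, 0.1, 10.0) == pytest.approx(1.1)
    eps = 1e-12
    below = apply_bound_strategy(0.1 - eps, 0.1, 10.0)
    above = apply_bound_strategy(0.1 + eps, 0.1, 10.0)
    assert above - below == pytest.approx(0.0, abs=1e-10)


def test_bound_with_huge_threshold_is_identity():
    assert apply_bound_strategy(123.4, 1e12, 10.0) == 123.4


def test_ema_balance_semantics():
    total, state = ema_balance(0.7, 0.02, LossState(), decay=0.9)
    assert total == pytest.approx(2.0)  # first step: normalized by itself
    total, _ = ema_balance(4.0, 0.01, LossState(ema_data=2.0, ema_mech=0.02), 0.9)
    assert total == pytest.approx(2.5)
    # constant losses: total stays 2 at the fixed point
    state = LossState()
    for _ in range(50):
        total, state = ema_balance(0.3, 0.001, state, 0.9)
    assert total == pytest.approx(2.0, rel=1e-6)


def test_scheduler_weight_phases():
    sched = SchedulerConfig(final_data_weight=0.95)
    assert scheduler_weights(0, sched) == (0.1, 0.9)
    assert scheduler_weights(80, sched) == (0.95, pytest.approx(0.05))
    sched = SchedulerConfig(final_data_weight=0.9)
    w_data, w_mech = scheduler_weights(50, sched)
    assert w_data == pytest.approx(0.5) and w_mech == pytest.approx(0.5)


@settings(deadline=None, max_examples=50)
@given(epoch=st.integers(min_value=0, max_value=200),
       fdw=st.floats(min_value=0.8, max_value=1.0))
def test_scheduler_weights_always_sum_to_one(epoch, fdw):
    w_data, w_mech = scheduler_weights(epoch, SchedulerConfig(final_data_weight=fdw))
    assert w_data + w_mech == pytest.approx(1.0)
    assert 0.0 <= w_data <= 1.0


def test_scheduler_final_weight_one_matches_divided():
    comps = (0.4, 0.1, 0.05, 0.01)
    cfg = MinnConfig(strategy="scheduler",
                     schedule=SchedulerConfig(final_data_weight=1.0))
    total, _ = total_loss(comps, cfg, epoch=100, state=LossState())
    div, _ = total_loss(comps, MinnConfig(strategy="divided"), 100, LossState())
    assert total == pytest.approx(div)


def test_unknown_strategy_rejected():
    with pytest.raises(ValueError, match="strategy"):
        MinnConfig(strategy="nope")


def test_config_yaml_round_trip():
    cfg = MinnConfig(dh=96, strategy="scheduler",
                     schedule=SchedulerConfig(final_data_weight=0.85), seed=5)
    assert MinnConfig.from_yaml(cfg.to_yaml()) == cfg


# ----------------------------------------------------------------- training

@pytest.fixture(scope="module")
def trained_setup():
    import minnflux as mf

    model = mf.split_reversible(mf.make_toy_gem())
    ctx = MechanisticContext.from_model(model, [GLC_UPTAKE, O2_UPTAKE])
    spec = SyntheticSpec(n_samples=40, omics_noise_sd=0.0, target_noise_sd=0.0,
                         seed=3)
    dataset = simulate_dataset(model, spec)
    cfg = MinnConfig(dh=48, lr_nn=3e-3, epochs=400, strategy="c_balanced",
                     c=10.0, seed=0)
    return model, ctx, dataset, cfg


def test_training_drives_constraint_loss_down(trained_setup):
    _, ctx, dataset, cfg = trained_setup
    trained = train_minn(dataset, ctx, cfg)
    log = trained.training_log
    lfba0 = log[["L2", "L3", "L4"]].iloc[0].sum()
    lfba1 = log[["L2", "L3", "L4"]].iloc[-1].sum()
    assert lfba1 < lfba0 / 10.0


def test_training_is_deterministic_given_seed(trained_setup):
    _, ctx, dataset, cfg = trained_setup
    a = train_minn(dataset, ctx, cfg)
    b = train_minn(dataset, ctx, cfg)
    for key in a.weights:
        assert np.array_equal(a.weights[key], b.weights[key])
    assert a.training_log.equals(b.training_log)


def test_predict_on_training_data_after_convergence(trained_setup):
    _, ctx, dataset, cfg = trained_setup
    trained = train_minn(dataset, ctx, cfg)
    V, proj = predict(trained, dataset.features)
    ne, _ = data_loss(proj, dataset.reference_fluxes.to_numpy())
    assert ne < 0.05
    # near-feasible targets: the negative part of the refined output is
    # below 2% of the flux scale
    assert V.min() > -0.02 * V.max()


def test_predict_identical_rows_for_identical_inputs(trained_setup):
    _, ctx, dataset, cfg = trained_setup
    trained = train_minn(dataset, ctx, cfg)
    X = dataset.features.iloc[[0, 0]]
    V, _ = predict(trained, X)
    assert np.array_equal(V[0], V[1])


def test_predict_missing_feature_errors(trained_setup):
    _, ctx, dataset, cfg = trained_setup
    trained = train_minn(dataset, ctx, cfg)
    with pytest.raises(ValueError, match="missing feature columns"):
        predict(trained, dataset.features.drop(columns=["tx_000"]))


def test_divided_ends_with_larger_violation_than_balanced(trained_setup):
    """With a partial reference panel the data-only loss leaves the
    unobserved fluxes unconstrained, so the steady-state violation stays
    high; the composite loss represses it."""
    model, ctx, _, cfg = trained_setup
    from dataclasses import replace

    ref = ["R1", "R2a", "RESP", "ACPROD", "EX_co2", "EX_ac", "BIOMASS"]
    spec = SyntheticSpec(n_samples=30, omics_noise_sd=0.0, target_noise_sd=0.0,
                         reference_ids=ref, seed=3)
    dataset = simulate_dataset(model, spec)
    pctx = MechanisticContext.from_model(model, [GLC_UPTAKE, O2_UPTAKE],
                                         reference_ids=ref)
    bal = train_minn(dataset, pctx, replace(cfg, epochs=200))
    div = train_minn(dataset, pctx, replace(cfg, epochs=200, strategy="divided"))
    assert div.training_log["L2"].iloc[-1] > bal.training_log["L2"].iloc[-1]


def test_trained_model_save_load_round_trip(trained_setup, tmp_path):
    _, ctx, dataset, cfg = trained_setup
    trained = train_minn(dataset, ctx, cfg)
    path = tmp_path / "model.npz"
    trained.save(str(path))
    loaded = TrainedMinn.load(str(path))
    V1, _ = predict(trained, dataset.features)
    V2, _ = predict(loaded, dataset.features)
    assert np.allclose(V1, V2)
    assert loaded.config == trained.config
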