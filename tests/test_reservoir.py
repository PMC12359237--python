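"""Reservoir pipeline: FBA surrogate pretraining and the pFBA coupling."""

import numpy as np
import pandas as pd
import pytest

from minnflux import (
    MechanisticContext,
    MinnConfig,
    ReservoirDataset,
    SyntheticSpec,
    fba_loss,
    pretrain_block,
    reservoir_constrain_pfba,
    sample_fba_dataset,
    simulate_dataset,
    solve_fba,
    solve_pfba,
    train_reservoir_minn,
)
from minnflux.reservoir import _block_forward
from minnflux.synthetic_fixtures import GLC_UPTAKE, O2_UPTAKE

VIN_IDS = ["EX_glc_rev", "EX_o2_rev", "EX_co2", "EX_etoh", "EX_ac"]
RANGES = {
    "EX_glc_rev": (6.0, 10.0),
    "EX_o2_rev": (1.0, 4.0),
    "EX_co2": (2.0, 6.0),
    "EX_etoh": (0.0, 2.0),
    "EX_ac": (0.0, 2.0),
}


@pytest.fixture(scope="module")
def full_ctx(split_model):
    return MechanisticContext.from_model(split_model, VIN_IDS, reference_ids=None)


@pytest.fixture(scope="module")
def reservoir_data(split_model):
    return sample_fba_dataset(split_model, VIN_IDS, RANGES, n=250, seed=5)


@pytest.fixture(scope="module")
def block(reservoir_data, full_ctx):
    cfg = MinnConfig(dh=64, lr_nn=3e-3, epochs=350, strategy="c_balanced",
                     c=10.0, seed=0)
    return pretrain_block(reservoir_data, full_ctx, cfg)


# ------------------------------------------------------- dataset sampling

def test_collapsed_range_reproduces_single_solve(split_model):
    feasible = {"EX_glc_rev": 8.0, "EX_o2_rev": 3.0, "EX_co2": 4.0,
                "EX_etoh": 1.0, "EX_ac": 1.0}
    point = {rid: (v, v) for rid, v in feasible.items()}
    rds = sample_fba_dataset(split_model, VIN_IDS, point, n=1, seed=0)
    from minnflux.reservoir import _fix_directional

    overrides = {}
    for rid, (lo, _) in point.items():
        overrides.update(_fix_directional(split_model, rid, lo))
    direct = solve_pfba(split_model, overrides)
    assert np.allclose(
        rds.fluxes.iloc[0].reindex(direct.fluxes.index), direct.fluxes, atol=1e-9
    )


def test_records_satisfy_constraint_loss(reservoir_data, full_ctx):
    V = reservoir_data.fluxes.to_numpy()
    Vin = reservoir_data.vin.to_numpy()
    for i in range(len(V)):
        assert sum(fba_loss(V[i], full_ctx, Vin[i])) < 1e-9


def test_records_attain_fba_objective(split_model, reservoir_data):
    from minnflux.reservoir import _fix_directional

    for i in range(0, len(reservoir_data), 50):
        draw = reservoir_data.vin.iloc[i]
        overrides = {}
        for rid, value in draw.items():
            overrides.update(_fix_directional(split_model, rid, float(value)))
        ref = solve_fba(split_model, overrides)
        assert reservoir_data.fluxes.iloc[i]["BIOMASS"] == pytest.approx(
            ref.objective_value, abs=1e-6
        )


def test_sampling_is_seeded(split_model):
    a = sample_fba_dataset(split_model, VIN_IDS, RANGES, n=20, seed=9)
    b = sample_fba_dataset(split_model, VIN_IDS, RANGES, n=20, seed=9)
    assert a.vin.equals(b.vin) and a.fluxes.equals(b.fluxes)


def test_hopeless_ranges_abort(split_model):
    bad = dict(RANGES)
    bad["EX_co2"] = (50.0, 60.0)  # carbon balance can never reach this
    from minnflux.gem_toolkit import InfeasibleModelError

    with pytest.raises(InfeasibleModelError, match="feasibility rate"):
        sample_fba_dataset(split_model, VIN_IDS, bad, n=5, seed=0,
                           max_draw_factor=20)


def test_dataset_csv_round_trip(tmp_path, reservoir_data):
    reservoir_data.to_csv(tmp_path)
    back = ReservoirDataset.read_csv(tmp_path)
    pd.testing.assert_frame_equal(back.vin, reservoir_data.vin)
    pd.testing.assert_frame_equal(back.fluxes, reservoir_data.fluxes)


# ------------------------------------------------------------ pretraining

def test_block_generalizes_to_heldout_fba_solutions(block):
    assert block.holdout_ne < 0.1


def test_block_reproduces_training_records(block, reservoir_data):
    from minnflux.minn_core import data_loss

    vin = reservoir_data.vin.to_numpy()[:50]
    V, _, _ = _block_forward(block, vin)
    ne, _ = data_loss(V, reservoir_data.fluxes.to_numpy()[:50])
    assert ne < 0.05


def test_frozen_block_weights_unchanged_by_front_training(
    split_model, block, full_ctx
):
    before = {k: v.copy() for k, v in block.trained.weights.items()}
    spec = SyntheticSpec(n_samples=12, omics_noise_sd=0.02, reference_ids=None,
                         seed=8)
    ds = simulate_dataset(split_model, spec)
    cfg = MinnConfig(dh=32, lr_nn=3e-3, epochs=50, strategy="divided", seed=1)
    train_reservoir_minn(ds, block, cfg)
    for k in before:
        assert np.array_equal(before[k], block.trained.weights[k])


@pytest.fixture(scope="module")
def linear_front_setup(reservoir_data, block):
    """Omics features as linear mixes of the reservoir's feasible exchange
    draws — the generating exchange map is then identifiable by inversion."""
    from minnflux.synthetic_fixtures import OmicsDataset

    rng = np.random.default_rng(3)
    vin = reservoir_data.vin.to_numpy()
    A = rng.normal(size=(5, 8))
    feats = vin @ A + rng.normal(0.0, 0.01, size=(len(vin), 8))
    fdf = pd.DataFrame(feats, index=reservoir_data.vin.index,
                       columns=[f"tx_{i:03d}" for i in range(8)])
    fdf["uptake[EX_glc_rev]"] = vin[:, 0]
    fdf["uptake[EX_o2_rev]"] = vin[:, 1]
    ds = OmicsDataset(
        features=fdf, reference_fluxes=reservoir_data.fluxes.copy(),
        input_cols=["uptake[EX_glc_rev]", "uptake[EX_o2_rev]"],
        input_reaction_ids=["EX_glc_rev", "EX_o2_rev"],
    )
    cfg = MinnConfig(dh=64, lr_nn=3e-3, epochs=1000, strategy="divided", seed=1)
    return ds, train_reservoir_minn(ds, block, cfg), vin


def test_front_recovers_generating_exchanges(linear_front_setup):
    ds, res, vin_true = linear_front_setup
    pred = res.predict_vin(ds.features).to_numpy()
    rel = np.abs(pred - vin_true).mean(0) / (np.abs(vin_true).mean(0) + 1e-9)
    assert np.all(rel < 0.1)


def test_composed_model_keeps_constraint_violation_bounded(
    linear_front_setup, reservoir_data, block, full_ctx
):
    """The frozen block bounds the mechanistic violation of the composition."""
    ds, res, _ = linear_front_setup
    V, _ = res.predict_fluxes(ds.features)
    vin_pred = res.predict_vin(ds.features).to_numpy()
    composed = sum(fba_loss(V, full_ctx, vin_pred))
    block_V, _, _ = _block_forward(block, reservoir_data.vin.to_numpy())
    block_level = sum(fba_loss(block_V, full_ctx, reservoir_data.vin.to_numpy()))
    assert composed < 10 * block_level


# -------------------------------------------------------- constrained pFBA

def test_true_exchange_values_reproduce_plain_pfba(split_model):
    from minnflux.reservoir import _fix_directional

    meas = {"EX_glc_rev": 8.0, "EX_o2_rev": 3.0}
    overrides = {}
    for rid, v in meas.items():
        overrides.update(_fix_directional(split_model, rid, v))
    plain = solve_pfba(split_model, overrides)
    true_ex = {rid: float(plain.fluxes[rid]) for rid in ("EX_co2", "EX_etoh", "EX_ac")}
    sol, relax = reservoir_constrain_pfba(split_model, true_ex, meas)
    assert relax == 0.0
    assert np.allclose(sol.fluxes.reindex(plain.fluxes.index), plain.fluxes,
                       atol=1e-5)


def test_imposed_exchanges_are_honored(split_model):
    meas = {"EX_glc_rev": 8.0, "EX_o2_rev": 3.0}
    target = {"EX_co2": 3.2, "EX_etoh": 0.4, "EX_ac": 4.0}
    sol, relax = reservoir_constrain_pfba(split_model, target, meas, width=1e-7)
    assert relax == 0.0
    for rid, value in target.items():
        assert sol.fluxes[rid] == pytest.approx(value, abs=1e-6)


def test_unreachable_prediction_falls_back_to_upper_bounds(split_model):
    meas = {"EX_glc_rev": 4.0, "EX_o2_rev": 2.0}
    # more carbon out than in: only the one-sided fallback can satisfy this
    target = {"EX_co2": 30.0, "EX_etoh": 30.0, "EX_ac": 30.0}
    sol, relax = reservoir_constrain_pfba(split_model, target, meas)
    assert relax == 1.0
    for rid, value in target.items():
        assert sol.fluxes[rid] <= value * 1.1 + 1e-6


def test_conflicting_measurements_fail_explicitly(split_model):
    # fixed oxygen uptake exceeds what the fixed glucose feed can consume
    meas = {"EX_glc_rev": 4.0, "EX_o2_rev": 10.0}
    target = {"EX_co2": 4.0, "EX_etoh": 0.0, "EX_ac": 0.0}
    from minnflux.gem_toolkit import InfeasibleModelError

    with pytest.raises(InfeasibleModelError, match="conflicting"):
        reservoir_constrain_pfba(split_model, target, meas)


def test_negative_prediction_clipped_to_zero(split_model):
    meas = {"EX_glc_rev": 8.0, "EX_o2_rev": 3.0}
    sol, _ = reservoir_constrain_pfba(
        split_model, {"EX_co2": 3.0, "EX_etoh": -0.2, "EX_ac": 5.0}, meas
    )
    assert sol.fluxes["EX_etoh"] == pytest.approx(0.0, abs=1e-5)
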