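"""The MINN-reservoir: a frozen neural FBA surrogate feeding pFBA.

Two-step training. First, a MINN with *no* omics input is trained purely on
simulated FBA solutions — exchange fluxes drawn at random within observed
ranges, full flux distribution from the LP solver — so it becomes a frozen
approximator of an FBA solver (the *pretrained block*). Second, a fresh
front network learns to map omics profiles to the block's exchange-flux
input ``Vin``; the frozen block turns that into a full flux distribution,
and only the front network's weights are updated. At prediction time the
block's inferred exchange fluxes are handed to parsimonious FBA as extra
constraints, so the final output is a genuine LP solution.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import cobra

from .gem_toolkit import FWD_SUFFIX, REV_SUFFIX, InfeasibleModelError
from .cbm_solvers import FluxVector, solve_fba, solve_pfba
from .minn_core import (
    FeatureScaler,
    LossState,
    MechanisticContext,
    MinnConfig,
    TrainedMinn,
    _Adam,
    _check_finite,
    _strategy_coefficients,
    data_loss,
    fba_gradient,
    fba_loss,
    init_weights,
    mechanistic_refine,
    nn_backward,
    nn_forward,
    refine_backward,
    train_minn,
)
from .synthetic_fixtures import OmicsDataset

logger = logging.getLogger("minnflux")

__all__ = [
    "ReservoirDataset",
    "PretrainedBlock",
    "ReservoirMinn",
    "sample_fba_dataset",
    "pretrain_block",
    "train_reservoir_minn",
    "reservoir_constrain_pfba",
]


def _opposite(rid: str) -> str | None:
    if rid.endswith(REV_SUFFIX):
        return rid[: -len(REV_SUFFIX)] + FWD_SUFFIX
    if rid.endswith(FWD_SUFFIX):
        return rid[: -len(FWD_SUFFIX)] + REV_SUFFIX
    return None


def _fix_directional(model: cobra.Model, rid: str, value: float, width: float = 0.0):
    """Overrides pinning a directional exchange at ``value`` (+- width),
    zeroing its opposite-direction partner if the model has one."""
    ov = {rid: (max(value - width, 0.0), value + width)}
    opp = _opposite(rid)
    if opp and opp in model.reactions:
        ov[opp] = (0.0, 0.0)
    return ov


@dataclass
class ReservoirDataset:
    """Simulated FBA solutions: sampled exchange inputs and full fluxes."""

    vin: pd.DataFrame        # samples x exchange ids (directional magnitudes)
    fluxes: pd.DataFrame     # samples x split reactions
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.vin.index.equals(self.fluxes.index):
            raise ValueError("vin and flux tables disagree on records")

    def __len__(self) -> int:
        return len(self.vin)

    def to_csv(self, outdir: str) -> dict:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        table = self.vin.add_prefix("vin:").join(self.fluxes)
        table.to_csv(out / "reservoir_dataset.csv")
        (out / "reservoir_dataset.json").write_text(json.dumps(self.meta, indent=2))
        return {
            "table": str(out / "reservoir_dataset.csv"),
            "meta": str(out / "reservoir_dataset.json"),
        }

    @classmethod
    def read_csv(cls, outdir: str) -> "ReservoirDataset":
        out = Path(outdir)
        table = pd.read_csv(out / "reservoir_dataset.csv", index_col=0)
        vin_cols = [c for c in table.columns if c.startswith("vin:")]
        meta = json.loads((out / "reservoir_dataset.json").read_text())
        return cls(
            vin=table[vin_cols].rename(columns=lambda c: c[4:]),
            fluxes=table.drop(columns=vin_cols),
            meta=meta,
        )


def sample_fba_dataset(
    model: cobra.Model,
    vin_ids: list[str],
    ranges: dict[str, tuple[float, float]],
    n: int,
    seed: int,
    max_draw_factor: int = 100,
    parsimonious: bool = True,
) -> ReservoirDataset:
    """Simulate ``n`` FBA solutions under randomly drawn exchange fluxes.

    Each record draws one value per exchange uniformly from its range (all
    ranges are over the non-negative directional flux magnitudes), pins the
    exchanges there, and solves FBA. By default the parsimonious solution is
    recorded: FBA optima are usually degenerate, and an arbitrary vertex per
    record would teach the surrogate an arbitrary (and inconsistent) choice
    among alternative pathways; pFBA keeps the objective value and picks the
    canonical minimal-flux representative. Infeasible draws are redrawn and
    counted; a feasibility rate below 1% aborts. Deterministic given
    ``seed``.
    """
    missing = [rid for rid in vin_ids if rid not in model.reactions]
    if missing:
        raise KeyError(f"exchange reactions not in model: {missing}")
    for rid in vin_ids:
        lo, hi = ranges[rid]
        if hi < lo or lo < 0:
            raise ValueError(f"range for {rid} must satisfy 0 <= lo <= hi")
    rng = np.random.default_rng(seed)
    records, flux_rows = [], []
    attempts = 0
    max_attempts = max_draw_factor * n
    while len(records) < n:
        if attempts >= max_attempts:
            raise InfeasibleModelError(
                f"feasibility rate below {n / max_attempts:.1%}: "
                f"{len(records)} feasible in {attempts} draws"
            )
        attempts += 1
        draw = {rid: rng.uniform(*ranges[rid]) for rid in vin_ids}
        overrides = {}
        for rid, value in draw.items():
            overrides.update(_fix_directional(model, rid, value))
        sol = (solve_pfba if parsimonious else solve_fba)(model, overrides)
        if sol.status != "optimal":
            continue
        records.append(draw)
        flux_rows.append(sol.fluxes)
    index = [f"sim_{i:04d}" for i in range(n)]
    vin = pd.DataFrame(records, index=index)[list(vin_ids)]
    fluxes = pd.DataFrame(flux_rows)
    fluxes.index = index
    meta = {
        "model_id": model.id,
        "seed": seed,
        "n": n,
        "attempts": attempts,
        "ranges": {k: list(v) for k, v in ranges.items()},
    }
    logger.info("sample_fba_dataset: %d records in %d draws", n, attempts)
    return ReservoirDataset(vin=vin, fluxes=fluxes, meta=meta)


@dataclass
class PretrainedBlock:
    """A frozen MINN approximating the FBA solver on its exchange inputs."""

    trained: TrainedMinn
    holdout_ne: float
    frozen: bool = True

    @property
    def vin_ids(self) -> list[str]:
        return list(self.trained.ctx.input_reaction_ids)


def _block_dataset(rdataset: ReservoirDataset) -> OmicsDataset:
    vin_ids = list(rdataset.vin.columns)
    feats = rdataset.vin.copy()
    feats.columns = [f"vin[{rid}]" for rid in vin_ids]
    return OmicsDataset(
        features=feats,
        reference_fluxes=rdataset.fluxes.copy(),
        input_cols=list(feats.columns),
        input_reaction_ids=vin_ids,
    )


def pretrain_block(
    rdataset: ReservoirDataset,
    ctx: MechanisticContext,
    config: MinnConfig,
    holdout_frac: float = 0.2,
) -> PretrainedBlock:
    """Train a MINN from exchange inputs alone to reproduce FBA solutions.

    The context must reference every split reaction (identity reference
    projection) and take the sampled exchanges as its inputs. A held-out
    fraction of records reports the block's generalization NE; weights are
    frozen afterwards.
    """
    if list(ctx.target_ids) != list(rdataset.fluxes.columns):
        raise ValueError("block context must target the full flux distribution")
    dataset = _block_dataset(rdataset)
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(dataset.n_samples)
    n_hold = max(1, int(round(holdout_frac * dataset.n_samples)))
    hold_ids = [dataset.sample_ids[i] for i in order[:n_hold]]
    train_ids = [dataset.sample_ids[i] for i in order[n_hold:]]
    trained = train_minn(dataset.subset(train_ids), ctx, config)
    from .minn_core import predict  # late import keeps module surface tidy

    hold = dataset.subset(hold_ids)
    _, proj = predict(trained, hold.features)
    ne, _ = data_loss(proj, hold.reference_fluxes.to_numpy(dtype=float))
    trained.frozen = True
    return PretrainedBlock(trained=trained, holdout_ne=float(ne))


@dataclass
class ReservoirMinn:
    """Front network (omics -> exchange fluxes) plus the frozen block."""

    front_weights: dict
    front_scaler: FeatureScaler
    block: PretrainedBlock
    config: MinnConfig
    training_log: pd.DataFrame
    input_cols: list[str]

    def predict_vin(self, X: pd.DataFrame) -> pd.DataFrame:
        Xs = self.front_scaler.transform(X)
        vin, _ = nn_forward(Xs, self.front_weights, training=False)
        return pd.DataFrame(vin, index=X.index, columns=self.block.vin_ids)

    def predict_fluxes(self, X: pd.DataFrame):
        """Flux distribution and reference projection via the frozen block."""
        vin = self.predict_vin(X).to_numpy(dtype=float)
        return _block_forward(self.block, vin)[:2]


def _block_forward(block: PretrainedBlock, vin: np.ndarray, need_cache: bool = False):
    t = block.trained
    xb = (vin - t.scaler.mean) / t.scaler.std
    V0, cache_nn = nn_forward(xb, t.weights, training=False)
    V, cache_ref = mechanistic_refine(
        V0, t.ctx, vin, t.lr_mech, t.config.k_iter, need_cache=need_cache
    )
    proj = V @ t.ctx.Pref.T
    return V, proj, (xb, cache_nn, cache_ref)


def train_reservoir_minn(
    dataset: OmicsDataset,
    block: PretrainedBlock,
    config: MinnConfig,
) -> ReservoirMinn:
    """Fit the front network against reference fluxes through the frozen block.

    The front network maps the dataset's features (omics plus measured
    medium exchanges) to the block's exchange-flux input; gradients flow
    through the block's network and refinement loop but update only the
    front weights. Deterministic given ``config.seed``.
    """
    if not block.frozen:
        raise ValueError("the pretrained block must be frozen")
    t = block.trained
    ctx = t.ctx
    rng = np.random.default_rng(config.seed)
    scaler = FeatureScaler.fit(dataset.features)
    X = scaler.transform(dataset.features)
    Vref = dataset.reference_fluxes.to_numpy(dtype=float)
    if Vref.shape[1] != ctx.Pref.shape[0]:
        raise ValueError("dataset references do not match the block's projection")
    N = len(X)
    nvin = len(block.vin_ids)

    weights = init_weights(X.shape[1], config.dh, nvin, rng)
    # start the predicted exchanges at the block's training mean: the block
    # is only a faithful FBA surrogate near the region it was trained on
    weights["bout"] = t.scaler.mean.copy()
    block_snapshot = {k: v.copy() for k, v in t.weights.items()}
    opt = _Adam(weights, config.lr_nn, config.weight_decay)
    state = LossState()
    batch = N if config.batch_size is None else min(config.batch_size, N)
    log_rows = []
    for epoch in range(config.epochs):
        order = rng.permutation(N) if batch < N else np.arange(N)
        ep = {"L1": 0.0, "L2": 0.0, "L3": 0.0, "L4": 0.0, "total": 0.0}
        n_batches = 0
        for start in range(0, N, batch):
            idx = order[start : start + batch]
            Xb, Rb = X[idx], Vref[idx]
            vin_pred, cache_front = nn_forward(
                Xb, weights, training=True, dropout=config.dropout, rng=rng
            )
            V, _, (xb, cache_nn, cache_ref) = _block_forward(
                block, vin_pred, need_cache=True
            )
            Vproj = V @ ctx.Pref.T
            l1, g_data_proj = data_loss(Vproj, Rb, config.ne_mode)
            l2, l3, l4 = fba_loss(V, ctx, vin_pred)
            l_mech = l2 + l3 + l4
            for nm, val in (("L1", l1), ("L2", l2), ("L3", l3), ("L4", l4)):
                _check_finite(nm, val)
            c_data, c_mech, total, state = _strategy_coefficients(
                l1, l_mech, config, epoch, state
            )
            gV = c_data * (g_data_proj @ ctx.Pref)
            g_vin_direct = np.zeros_like(vin_pred)
            if c_mech:
                gV = gV + c_mech * fba_gradient(V, ctx, vin_pred) / len(idx)
                excess = np.maximum(V @ ctx.Pin.T - vin_pred, 0.0)
                g_vin_direct -= c_mech * (2.0 / ctx.nin) * excess / len(idx)
            gV0, g_vin_ref = refine_backward(gV, cache_ref, ctx, vin_pred, t.lr_mech)
            _, g_xb = nn_backward(gV0, cache_nn, t.weights)
            g_vin = g_xb / t.scaler.std + g_vin_ref + g_vin_direct
            grads, _ = nn_backward(g_vin, cache_front, weights)
            opt.step(weights, grads)
            n_batches += 1
            for nm, val in (("L1", l1), ("L2", l2), ("L3", l3), ("L4", l4), ("total", total)):
                ep[nm] += val
        row = {k: v / n_batches for k, v in ep.items()}
        row["epoch"] = epoch
        log_rows.append(row)

    for k in block_snapshot:  # frozen contract: block weights bit-identical
        assert np.array_equal(block_snapshot[k], t.weights[k])
    log = pd.DataFrame(log_rows).set_index("epoch")
    return ReservoirMinn(
        front_weights=weights, front_scaler=scaler, block=block, config=config,
        training_log=log, input_cols=list(dataset.input_cols),
    )


RELAXATION_LADDER = (0.0, 0.01, 0.05, 0.10)


def reservoir_constrain_pfba(
    model: cobra.Model,
    predicted: dict[str, float],
    measured: dict[str, float],
    width: float = 1e-6,
    cap_ids: tuple = (),
    relax_floor: float = 1.0,
) -> tuple[FluxVector, float]:
    """Run pFBA with predicted exchange fluxes imposed as extra constraints.

    ``measured`` (glucose and oxygen uptakes) are fixed exactly — except ids
    listed in ``cap_ids``, which are imposed as capacities ``(0, value)``,
    the usual treatment of a measured maximal uptake rate. Each entry of
    ``predicted`` is imposed as a tight bound pair ``value +- width`` on its
    directional reaction. If the combined problem is infeasible the
    predicted bounds are relaxed in steps (+-1%, +-5%, +-10%, applied to
    ``max(|value|, relax_floor)`` so that near-zero predictions — e.g. a
    small spurious secretion through a knocked-out route — also gain
    absolute slack), each relaxation logged. As a last resort the lower
    bounds are dropped to zero (the constraint weakens to "at most the
    predicted value plus pad", reported as relaxation level 1.0): if the
    model cannot produce the predicted secretion, it is not forced to.
    Returns the solution and the relaxation level used. Negative
    predictions are clipped to zero.
    """
    overrides = {}
    for rid, value in measured.items():
        if rid in cap_ids:
            overrides[rid] = (0.0, float(value))
            opp = _opposite(rid)
            if opp and opp in model.reactions:
                overrides[opp] = (0.0, 0.0)
        else:
            overrides.update(_fix_directional(model, rid, float(value)))
    clipped = {rid: max(float(v), 0.0) for rid, v in predicted.items()}
    for rid, v in predicted.items():
        if v < 0:
            logger.warning("negative predicted exchange %s=%.3g clipped to 0", rid, v)
    for relax in (*RELAXATION_LADDER, 1.0):
        one_sided = relax >= 1.0
        ov = dict(overrides)
        for rid, value in clipped.items():
            pad = max(abs(value), relax_floor) * min(relax, 0.10) + width
            lb = 0.0 if one_sided else max(value - pad, 0.0)
            ov[rid] = (lb, value + pad)
            opp = _opposite(rid)
            if opp and opp in model.reactions:
                ov[opp] = (0.0, 0.0)
        sol = solve_pfba(model, ov)
        if sol.status == "optimal":
            if one_sided:
                logger.warning(
                    "constrained pFBA fell back to one-sided (upper-bound) "
                    "constraints"
                )
            elif relax > 0:
                logger.warning(
                    "constrained pFBA required +-%.0f%% relaxation", 100 * relax
                )
            return sol, relax
    raise InfeasibleModelError(
        "constrained pFBA infeasible even after relaxation; conflicting "
        f"constraints: measured={measured}, predicted={clipped}"
    )
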