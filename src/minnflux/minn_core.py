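"""The metabolic-informed neural network (MINN).

A one-hidden-layer feed-forward network maps a sample's multi-omics profile
(transcript levels, protein abundances, measured input exchange fluxes) to an
initial estimate ``V0`` of the full flux distribution of a split metabolic
model. A *mechanistic layer* — an unrolled gradient-descent loop on the
FBA-constraint loss

    L_FBA(V) = (1/m) ||S V||^2                      steady state
             + (1/n_in) ||relu(Pin V - Vin)||^2     measured upper bounds
             + (1/n) ||relu(-V)||^2                 non-negativity

— then refines ``V0`` toward the FBA solution space. The training loss
combines a scale-free data term (normalized error against measured reference
fluxes) with the same constraint terms, under one of several balancing
strategies (fixed multiplier, excess-penalty bound, exponential-average
normalization, phase scheduler, or data-only).

Everything here is plain numpy. Gradients are propagated by hand-written
reverse-mode rules, including through the unrolled refinement loop (whose
per-step Jacobian is ``I - lr * H`` with ``H`` the generalized Hessian of
``L_FBA``); they are checked against central finite differences in the test
suite.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
import cobra

from .gem_toolkit import (
    build_projection,
    input_projection,
    net_flux_targets,
    stoichiometric_matrix,
)

__all__ = [
    "MechanisticContext",
    "MinnConfig",
    "SchedulerConfig",
    "LossState",
    "TrainedMinn",
    "init_weights",
    "nn_forward",
    "nn_backward",
    "fba_loss",
    "fba_gradient",
    "mechanistic_refine",
    "refine_backward",
    "data_loss",
    "total_loss",
    "apply_bound_strategy",
    "ema_balance",
    "scheduler_weights",
    "train_minn",
    "predict",
]

STRATEGIES = (
    "mse_base",
    "unbalanced",
    "c_balanced",
    "bound",
    "ema",
    "scheduler",
    "scheduler_bound",
    "divided",
)


# ---------------------------------------------------------------------------
# mechanistic context
# ---------------------------------------------------------------------------

@dataclass
class MechanisticContext:
    """Stoichiometry and projections tying network outputs to a split model.

    ``S`` is m x n over the split (possibly reduced) model, ``Pin`` selects
    the ``n_in`` measured input fluxes (unit rows), ``Pref`` maps the flux
    vector to the measured reference fluxes (signed net-flux rows).
    """

    S: np.ndarray
    Pin: np.ndarray
    Pref: np.ndarray
    reaction_ids: list[str]
    metabolite_ids: list[str]
    input_reaction_ids: list[str]
    target_ids: list[str]
    model_id: str = ""

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.Pin = np.asarray(self.Pin, dtype=float)
        self.Pref = np.asarray(self.Pref, dtype=float)
        n = len(self.reaction_ids)
        if self.S.shape[1] != n or self.Pin.shape[1] != n or self.Pref.shape[1] != n:
            raise ValueError("context matrices disagree on the reaction dimension")
        if self.S.shape[0] < 1 or n < 1:
            raise ValueError("context needs at least one metabolite and reaction")

    @property
    def m(self) -> int:
        return self.S.shape[0]

    @property
    def n(self) -> int:
        return self.S.shape[1]

    @property
    def nin(self) -> int:
        return self.Pin.shape[0]

    @classmethod
    def from_model(
        cls,
        model: cobra.Model,
        input_ids: list[str],
        reference_ids: list[str] | None = None,
    ) -> "MechanisticContext":
        """Build the context from a split cobra model.

        ``input_ids`` are directional reaction ids carrying the measured
        input fluxes (for uptake through a split exchange, the ``_rev``
        member). ``reference_ids`` are base reaction ids measured as net
        fluxes; ``None`` means every reaction is a reference target.
        """
        if any(r.lower_bound < 0 for r in model.reactions):
            raise ValueError("context requires a split model (all bounds >= 0)")
        pin = input_projection(model, input_ids)
        if reference_ids is None:
            rids = [r.id for r in model.reactions]
            pref = build_projection(model, [(rid, {rid: 1.0}) for rid in rids])
        else:
            pref = build_projection(model, net_flux_targets(model, reference_ids))
        return cls(
            S=stoichiometric_matrix(model),
            Pin=pin.matrix,
            Pref=pref.matrix,
            reaction_ids=[r.id for r in model.reactions],
            metabolite_ids=[m.id for m in model.metabolites],
            input_reaction_ids=list(pin.target_ids),
            target_ids=list(pref.target_ids),
            model_id=model.id or "",
        )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SchedulerConfig:
    """Three-phase loss-weight schedule (epochs; weights are data-side).

    Phase 1 holds the balance at ``phase1_data_weight`` (mechanistic-
    dominated); a linear transition over ``transition_len`` epochs then moves
    it to ``final_data_weight``, which holds for the rest of training.
    """

    phase1_end: int = 30
    transition_len: int = 40
    final_len: int = 80
    phase1_data_weight: float = 0.1
    final_data_weight: float = 0.9

    @property
    def transition_end(self) -> int:
        return self.phase1_end + self.transition_len

    @property
    def total_epochs(self) -> int:
        return self.transition_end + self.final_len


@dataclass
class MinnConfig:
    """Hyperparameters and strategy selection; fully determines a run."""

    dh: int = 64
    lr_nn: float = 1e-3
    lr_mech: float | None = None  # None -> 0.9 / (Lipschitz bound of grad L_FBA)
    k_iter: int = 10
    dropout: float = 0.0
    weight_decay: float = 0.0
    c: float = 1.0
    epochs: int = 300
    batch_size: int | None = None  # None -> full batch
    strategy: str = "c_balanced"
    ne_mode: str = "norm_ratio"  # or "elementwise"; mse_base forces "mse"
    bound_threshold: float = 0.01
    bound_factor: float = 10.0
    ema_decay: float = 0.9
    schedule: SchedulerConfig = field(default_factory=SchedulerConfig)
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        for name in ("dh", "lr_nn", "k_iter", "epochs", "c", "ema_decay"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.lr_mech is not None and self.lr_mech <= 0:
            raise ValueError("lr_mech must be > 0")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.ema_decay >= 1:
            raise ValueError("ema_decay must be in (0, 1)")
        if not 0.0 <= self.schedule.final_data_weight <= 1.0:
            raise ValueError("final_data_weight must be in [0, 1]")
        if self.strategy in ("bound", "scheduler_bound"):
            if self.bound_threshold <= 0 or self.bound_factor <= 1:
                raise ValueError("bound strategy needs threshold > 0, factor > 1")

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "MinnConfig":
        d = yaml.safe_load(text)
        sched = d.pop("schedule", None)
        cfg = cls(**d) if sched is None else cls(schedule=SchedulerConfig(**sched), **d)
        return cfg


@dataclass
class LossState:
    """Mutable balancing state carried across training steps."""

    ema_data: float | None = None
    ema_mech: float | None = None


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

def init_weights(din: int, dh: int, dout: int, rng: np.random.Generator) -> dict:
    """Fan-in-scaled Gaussian initialization; output bias starts at zero."""
    return {
        "Wh": rng.normal(0.0, np.sqrt(2.0 / din), size=(din, dh)),
        "bh": np.zeros(dh),
        "Wout": rng.normal(0.0, np.sqrt(1.0 / dh), size=(dh, dout)),
        "bout": np.zeros(dout),
    }


def nn_forward(
    X: np.ndarray,
    weights: dict,
    training: bool = False,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """V0 = relu(X Wh + bh) Wout + bout, with inverted dropout on the hidden
    activation during training. Returns ``(V0, cache)``."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != weights["Wh"].shape[0]:
        raise ValueError(
            f"input batch has shape {X.shape}, expected (N, {weights['Wh'].shape[0]})"
        )
    Z = X @ weights["Wh"] + weights["bh"]
    A = np.maximum(Z, 0.0)
    if training and dropout > 0.0:
        if rng is None:
            raise ValueError("dropout during training requires an rng")
        mask = (rng.random(A.shape) >= dropout) / (1.0 - dropout)
    else:
        mask = np.ones_like(A)
    Ad = A * mask
    V0 = Ad @ weights["Wout"] + weights["bout"]
    return V0, {"X": X, "Z": Z, "Ad": Ad, "mask": mask}


def nn_backward(grad_V0: np.ndarray, cache: dict, weights: dict):
    """Reverse-mode through :func:`nn_forward`.

    Returns ``(grads, grad_X)`` with ``grads`` keyed like ``weights``.
    """
    gWout = cache["Ad"].T @ grad_V0
    gbout = grad_V0.sum(axis=0)
    gAd = grad_V0 @ weights["Wout"].T
    gZ = gAd * cache["mask"] * (cache["Z"] > 0)
    gWh = cache["X"].T @ gZ
    gbh = gZ.sum(axis=0)
    gX = gZ @ weights["Wh"].T
    return {"Wh": gWh, "bh": gbh, "Wout": gWout, "bout": gbout}, gX


# ---------------------------------------------------------------------------
# FBA-constraint loss and the mechanistic layer
# ---------------------------------------------------------------------------

def _as_batch(V: np.ndarray) -> np.ndarray:
    V = np.asarray(V, dtype=float)
    return V[None, :] if V.ndim == 1 else V


def fba_loss(V: np.ndarray, ctx: MechanisticContext, Vin: np.ndarray | None):
    """Batch-mean constraint terms ``(L2, L3, L4)`` of the FBA loss."""
    V = _as_batch(V)
    L2 = float(np.mean(np.sum((V @ ctx.S.T) ** 2, axis=1))) / ctx.m
    if ctx.nin and Vin is not None:
        excess = np.maximum(V @ ctx.Pin.T - _as_batch(Vin), 0.0)
        L3 = float(np.mean(np.sum(excess**2, axis=1))) / ctx.nin
    else:
        L3 = 0.0
    L4 = float(np.mean(np.sum(np.maximum(-V, 0.0) ** 2, axis=1))) / ctx.n
    return L2, L3, L4


def fba_gradient(
    V: np.ndarray, ctx: MechanisticContext, Vin: np.ndarray | None
) -> np.ndarray:
    """Per-sample gradient of L_FBA with respect to V (shape like V)."""
    V = _as_batch(V)
    G = (2.0 / ctx.m) * (V @ ctx.S.T) @ ctx.S
    if ctx.nin and Vin is not None:
        excess = np.maximum(V @ ctx.Pin.T - _as_batch(Vin), 0.0)
        G = G + (2.0 / ctx.nin) * excess @ ctx.Pin
    G = G - (2.0 / ctx.n) * np.maximum(-V, 0.0)
    return G


def _fba_hvp(
    u: np.ndarray, V: np.ndarray, ctx: MechanisticContext, Vin: np.ndarray | None
) -> np.ndarray:
    """Generalized-Hessian-vector product of the per-sample L_FBA at V."""
    Hu = (2.0 / ctx.m) * (u @ ctx.S.T) @ ctx.S
    if ctx.nin and Vin is not None:
        mask = (V @ ctx.Pin.T - _as_batch(Vin)) > 0
        Hu = Hu + (2.0 / ctx.nin) * (mask * (u @ ctx.Pin.T)) @ ctx.Pin
    Hu = Hu + (2.0 / ctx.n) * (V < 0) * u
    return Hu


def stable_step_size(ctx: MechanisticContext, safety: float = 0.9) -> float:
    """A step size below ``1 / L`` with ``L`` a Lipschitz bound on grad L_FBA.

    ``L <= 2 lam_max(S^T S)/m + 2 lam_max(Pin^T Pin)/n_in + 2/n``; gradient
    descent on L_FBA with any step below ``1/L`` cannot increase the loss.
    """
    lam = 2.0 * float(np.linalg.eigvalsh(ctx.S.T @ ctx.S)[-1]) / ctx.m
    if ctx.nin:
        lam += 2.0 * float(np.linalg.eigvalsh(ctx.Pin.T @ ctx.Pin)[-1]) / ctx.nin
    lam += 2.0 / ctx.n
    return safety / lam


def mechanistic_refine(
    V0: np.ndarray,
    ctx: MechanisticContext,
    Vin: np.ndarray | None,
    lr_mech: float,
    k_iter: int,
    need_cache: bool = False,
):
    """Refine V0 by ``k_iter`` gradient-descent steps on L_FBA.

    Returns ``(V, cache)``; the cache (iterates visited) supports the
    reverse-mode pass so training gradients flow through the loop.
    """
    if lr_mech <= 0 or k_iter < 1:
        raise ValueError("need lr_mech > 0 and k_iter >= 1")
    V = _as_batch(V0).copy()
    cache = []
    for _ in range(k_iter):
        if need_cache:
            cache.append(V.copy())
        V = V - lr_mech * fba_gradient(V, ctx, Vin)
    return V, cache


def refine_backward(
    grad_out: np.ndarray,
    cache: list[np.ndarray],
    ctx: MechanisticContext,
    Vin: np.ndarray | None,
    lr_mech: float,
):
    """Reverse-mode through :func:`mechanistic_refine`.

    Propagates ``grad_out`` (gradient at the refined output) back to the
    initial estimate ``V0`` and to the bound vector ``Vin`` (the latter is
    needed when the bounds are themselves predicted, as in the reservoir).
    Each forward step has Jacobian ``I - lr * H(V_t)`` in V and
    ``lr * (2/n_in) Pin^T diag(mask_t)`` in Vin.
    """
    g = np.asarray(grad_out, dtype=float).copy()
    g_vin = np.zeros((g.shape[0], ctx.nin)) if ctx.nin else None
    for V_t in reversed(cache):
        if ctx.nin and Vin is not None:
            mask = (V_t @ ctx.Pin.T - _as_batch(Vin)) > 0
            g_vin += lr_mech * (2.0 / ctx.nin) * mask * (g @ ctx.Pin.T)
        g = g - lr_mech * _fba_hvp(g, V_t, ctx, Vin)
    return g, g_vin


# ---------------------------------------------------------------------------
# data loss
# ---------------------------------------------------------------------------

def data_loss(
    Vproj: np.ndarray, Vref: np.ndarray, mode: str = "norm_ratio"
) -> tuple[float, np.ndarray]:
    """Data term and its gradient with respect to the projected fluxes.

    ``norm_ratio`` (default) is the normalized error: per sample the ratio of
    the residual norm to the reference norm, averaged over the batch —
    scale-invariant, so large fluxes do not dominate small ones.
    ``elementwise`` averages per-entry relative errors; ``mse`` is the plain
    mean squared error. The returned gradient already carries the batch-mean
    factor.
    """
    P = _as_batch(Vproj)
    R = _as_batch(Vref)
    if P.shape != R.shape:
        raise ValueError(f"prediction {P.shape} vs reference {R.shape} shape mismatch")
    N, k = P.shape
    res = P - R
    if mode == "norm_ratio":
        ref_norm = np.linalg.norm(R, axis=1)
        if np.any(ref_norm == 0):
            raise ValueError("normalized error undefined: a reference row is all-zero")
        res_norm = np.linalg.norm(res, axis=1)
        L1 = float(np.mean(res_norm / ref_norm))
        safe = np.where(res_norm > 0, res_norm, 1.0)
        grad = res / (safe * ref_norm)[:, None] / N
        grad[res_norm == 0] = 0.0
        return L1, grad
    if mode == "elementwise":
        if np.any(R == 0):
            raise ValueError("elementwise relative error undefined: zero reference")
        L1 = float(np.mean(np.abs(res) / np.abs(R)))
        grad = np.sign(res) / np.abs(R) / (N * k)
        return L1, grad
    if mode == "mse":
        L1 = float(np.mean(res**2))
        return L1, 2.0 * res / (N * k)
    raise ValueError(f"unknown data-loss mode {mode!r}")


# ---------------------------------------------------------------------------
# balancing strategies
# ---------------------------------------------------------------------------

def apply_bound_strategy(l_mech: float, threshold: float, factor: float) -> float:
    """Excess-penalty bound: below the threshold the mechanistic loss passes
    through unchanged; the excess above it is multiplied by ``factor``.
    Continuous at the threshold."""
    if threshold <= 0 or factor <= 1:
        raise ValueError("need threshold > 0 and factor > 1")
    if l_mech <= threshold:
        return l_mech
    return threshold + factor * (l_mech - threshold)


def ema_balance(
    l_data: float, l_mech: float, state: LossState, decay: float
) -> tuple[float, LossState]:
    """Normalize each loss by the exponential average of its history.

    Each contribution is the current loss divided by its running average
    (initialized to the current value, so the first total is exactly 2); the
    averages then absorb the current values with weight ``1 - decay``. The
    divisors are treated as constants by the gradient.
    """
    if not 0 < decay < 1:
        raise ValueError("decay must be in (0, 1)")
    ema_d = l_data if state.ema_data is None else state.ema_data
    ema_m = l_mech if state.ema_mech is None else state.ema_mech
    total = l_data / ema_d + l_mech / ema_m
    new = LossState(
        ema_data=decay * ema_d + (1.0 - decay) * l_data,
        ema_mech=decay * ema_m + (1.0 - decay) * l_mech,
    )
    return total, new


def scheduler_weights(epoch: int, schedule: SchedulerConfig) -> tuple[float, float]:
    """(data weight, mechanistic weight) at ``epoch``; they always sum to 1."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    w0, w1 = schedule.phase1_data_weight, schedule.final_data_weight
    if epoch < schedule.phase1_end:
        w = w0
    elif epoch < schedule.transition_end:
        frac = (epoch - schedule.phase1_end) / schedule.transition_len
        w = w0 + (w1 - w0) * frac
    else:
        w = w1
    return w, 1.0 - w


def _strategy_coefficients(
    l1: float, l_mech: float, config: MinnConfig, epoch: int, state: LossState
):
    """Scalar weights (c_data, c_mech), the logged total, and new state.

    Every strategy reduces to an affine combination ``c_data * L1 + c_mech *
    L_mech`` for the purposes of backpropagation (the bound's multiplicative
    factor and the EMA divisors enter as gradient-constant coefficients).
    """
    s = config.strategy
    if s in ("unbalanced", "mse_base"):
        return 1.0, 1.0, l1 + l_mech, state
    if s == "c_balanced":
        return config.c, 1.0, config.c * l1 + l_mech, state
    if s == "divided":
        return 1.0, 0.0, l1, state
    if s == "bound":
        bounded = apply_bound_strategy(l_mech, config.bound_threshold, config.bound_factor)
        c_mech = 1.0 if l_mech <= config.bound_threshold else config.bound_factor
        return 1.0, c_mech, l1 + bounded, state
    if s == "ema":
        total, new_state = ema_balance(l1, l_mech, state, config.ema_decay)
        ema_d = l1 if state.ema_data is None else state.ema_data
        ema_m = l_mech if state.ema_mech is None else state.ema_mech
        return 1.0 / ema_d, 1.0 / ema_m, total, new_state
    if s == "scheduler":
        w_data, w_mech = scheduler_weights(epoch, config.schedule)
        return w_data, w_mech, w_data * l1 + w_mech * l_mech, state
    if s == "scheduler_bound":
        w_data, w_mech = scheduler_weights(epoch, config.schedule)
        bounded = apply_bound_strategy(l_mech, config.bound_threshold, config.bound_factor)
        factor = 1.0 if l_mech <= config.bound_threshold else config.bound_factor
        return w_data, w_mech * factor, w_data * l1 + w_mech * bounded, state
    raise ValueError(f"unknown strategy {s!r}")


def total_loss(
    components: tuple[float, float, float, float],
    config: MinnConfig,
    epoch: int,
    state: LossState,
) -> tuple[float, LossState]:
    """Scalar training loss for (L1, L2, L3, L4) under the active strategy."""
    l1, l2, l3, l4 = components
    _, _, total, new_state = _strategy_coefficients(l1, l2 + l3 + l4, config, epoch, state)
    return total, new_state


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class FeatureScaler:
    """Per-feature standardization fitted on training samples only."""

    columns: list[str]
    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, X: pd.DataFrame) -> "FeatureScaler":
        mean = X.to_numpy(dtype=float).mean(axis=0)
        std = X.to_numpy(dtype=float).std(axis=0)
        std = np.where(std > 0, std, 1.0)
        return cls(list(X.columns), mean, std)

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.columns if c not in X.columns]
        if missing:
            raise ValueError(f"input is missing feature columns: {missing}")
        return (X[self.columns].to_numpy(dtype=float) - self.mean) / self.std


@dataclass
class TrainedMinn:
    """A fitted MINN: weights, scaler, config and the context it was built on."""

    weights: dict
    config: MinnConfig
    scaler: FeatureScaler
    ctx: MechanisticContext
    lr_mech: float
    training_log: pd.DataFrame
    input_cols: list[str]
    frozen: bool = False

    def save(self, path: str) -> None:
        arrays = {f"w_{k}": v for k, v in self.weights.items()}
        arrays["scaler_mean"] = self.scaler.mean
        arrays["scaler_std"] = self.scaler.std
        meta = {
            "config": yaml.safe_load(self.config.to_yaml()),
            "scaler_columns": self.scaler.columns,
            "input_cols": self.input_cols,
            "lr_mech": self.lr_mech,
            "frozen": self.frozen,
            "ctx": {
                "reaction_ids": self.ctx.reaction_ids,
                "metabolite_ids": self.ctx.metabolite_ids,
                "input_reaction_ids": self.ctx.input_reaction_ids,
                "target_ids": self.ctx.target_ids,
                "model_id": self.ctx.model_id,
            },
        }
        arrays["ctx_S"] = self.ctx.S
        arrays["ctx_Pin"] = self.ctx.Pin
        arrays["ctx_Pref"] = self.ctx.Pref
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str) -> "TrainedMinn":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        cfg = MinnConfig.from_yaml(yaml.safe_dump(meta["config"]))
        ctx = MechanisticContext(
            S=data["ctx_S"], Pin=data["ctx_Pin"], Pref=data["ctx_Pref"],
            **meta["ctx"],
        )
        scaler = FeatureScaler(
            meta["scaler_columns"], data["scaler_mean"], data["scaler_std"]
        )
        weights = {k[2:]: data[k] for k in data.files if k.startswith("w_")}
        return cls(
            weights=weights, config=cfg, scaler=scaler, ctx=ctx,
            lr_mech=float(meta["lr_mech"]), training_log=pd.DataFrame(),
            input_cols=meta["input_cols"], frozen=bool(meta["frozen"]),
        )


class _Adam:
    """Adam with decoupled weight decay applied to weight matrices only."""

    def __init__(self, params: dict, lr: float, weight_decay: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.wd and k in ("Wh", "Wout"):
                params[k] -= self.lr * self.wd * params[k]


def _check_finite(name: str, value) -> None:
    if not np.all(np.isfinite(value)):
        raise RuntimeError(f"non-finite value in {name}; aborting training")


def _dataset_arrays(dataset, ctx: MechanisticContext):
    """Align an omics dataset to a context; returns (X df, Vref, Vin)."""
    if list(dataset.reference_fluxes.columns) != list(ctx.target_ids):
        raise ValueError(
            "dataset reference-flux labels do not match the context targets"
        )
    if list(dataset.input_reaction_ids) != list(ctx.input_reaction_ids):
        raise ValueError("dataset input exchanges do not match the context")
    Vref = dataset.reference_fluxes.to_numpy(dtype=float)
    Vin = dataset.features[dataset.input_cols].to_numpy(dtype=float)
    return dataset.features, Vref, Vin


def train_minn(dataset, ctx: MechanisticContext, config: MinnConfig) -> TrainedMinn:
    """Fit the MINN on an omics dataset by mini-batch gradient descent.

    The forward pass is ``nn_forward`` followed by ``mechanistic_refine``;
    the backward pass flows through both. The strategy in ``config`` decides
    how the data and constraint losses combine. Deterministic given
    ``config.seed``.
    """
    X_df, Vref, Vin = _dataset_arrays(dataset, ctx)
    rng = np.random.default_rng(config.seed)
    scaler = FeatureScaler.fit(X_df)
    X = scaler.transform(X_df)
    N, din = X.shape
    mode = "mse" if config.strategy == "mse_base" else config.ne_mode
    lr_mech = config.lr_mech if config.lr_mech is not None else stable_step_size(ctx)

    weights = init_weights(din, config.dh, ctx.n, rng)
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
            Xb, Rb, Ib = X[idx], Vref[idx], Vin[idx]
            V0, cache_nn = nn_forward(
                Xb, weights, training=True, dropout=config.dropout, rng=rng
            )
            V, cache_ref = mechanistic_refine(
                V0, ctx, Ib, lr_mech, config.k_iter, need_cache=True
            )
            Vproj = V @ ctx.Pref.T
            l1, g_data_proj = data_loss(Vproj, Rb, mode)
            l2, l3, l4 = fba_loss(V, ctx, Ib)
            l_mech = l2 + l3 + l4
            for nm, val in (("L1", l1), ("L2", l2), ("L3", l3), ("L4", l4)):
                _check_finite(nm, val)
            c_data, c_mech, total, state = _strategy_coefficients(
                l1, l_mech, config, epoch, state
            )
            gV = c_data * (g_data_proj @ ctx.Pref)
            if c_mech:
                gV = gV + c_mech * fba_gradient(V, ctx, Ib) / len(idx)
            gV0, _ = refine_backward(gV, cache_ref, ctx, Ib, lr_mech)
            grads, _ = nn_backward(gV0, cache_nn, weights)
            _check_finite("gradients", np.concatenate([g.ravel() for g in grads.values()]))
            opt.step(weights, grads)
            n_batches += 1
            for nm, val in (("L1", l1), ("L2", l2), ("L3", l3), ("L4", l4), ("total", total)):
                ep[nm] += val
        row = {k: v / n_batches for k, v in ep.items()}
        row["epoch"] = epoch
        row["c_data"], row["c_mech"] = c_data, c_mech
        log_rows.append(row)

    log = pd.DataFrame(log_rows).set_index("epoch")
    return TrainedMinn(
        weights=weights, config=config, scaler=scaler, ctx=ctx, lr_mech=lr_mech,
        training_log=log, input_cols=list(dataset.input_cols),
    )


def predict(model: TrainedMinn, X: pd.DataFrame):
    """Predicted flux distribution ``Vout`` and its reference projection.

    Applies the stored scaler, the feed-forward pass (no dropout) and the
    mechanistic refinement with each sample's measured input bounds.
    """
    Xs = model.scaler.transform(X)
    Vin = X[model.input_cols].to_numpy(dtype=float)
    V0, _ = nn_forward(Xs, model.weights, training=False)
    V, _ = mechanistic_refine(
        V0, model.ctx, Vin, model.lr_mech, model.config.k_iter
    )
    return V, V @ model.ctx.Pref.T
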