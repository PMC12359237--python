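"""Metrics and the nested cross-validation protocol for flux prediction.

Small multi-omics panels (tens of samples) cannot afford a fixed test set,
so evaluation follows a dual loop: an outer leave-one-out over samples, and
for each outer split an inner 5-fold cross-validation over the remaining
samples that selects hyperparameters before the final model is retrained on
all of them and scored on the single held-out sample. Metrics follow the
flux-prediction literature: R^2, MAE, RMSE and the normalized error across
the reference fluxes of the held-out sample, plus the steady-state violation
of the full predicted distribution as a feasibility proxy.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import cobra

from .cbm_solvers import solve_pfba
from .minn_core import MechanisticContext, MinnConfig, data_loss, predict, train_minn
from .synthetic_fixtures import OmicsDataset

logger = logging.getLogger("minnflux")

__all__ = [
    "MetricSet",
    "EvaluationReport",
    "metric_suite",
    "steady_state_violation",
    "nested_loo_cv",
    "pfba_baseline",
    "DEFAULT_SEARCH_SPACE",
    "SCHEDULER_SEARCH_SPACE",
]

METRIC_COLS = ("r2", "mae", "rmse", "ne", "l2_violation")


@dataclass
class MetricSet:
    """Per-sample prediction metrics; ``r2`` is None for constant references."""

    r2: float | None
    mae: float
    rmse: float
    ne: float
    l2_violation: float | None = None

    def as_dict(self) -> dict:
        return {
            "r2": np.nan if self.r2 is None else self.r2,
            "mae": self.mae,
            "rmse": self.rmse,
            "ne": self.ne,
            "l2_violation": np.nan if self.l2_violation is None else self.l2_violation,
        }


def metric_suite(v_pred, v_ref, ne_mode: str = "norm_ratio") -> MetricSet:
    """R^2, MAE, RMSE and NE of one prediction across its reference fluxes."""
    p = np.asarray(v_pred, dtype=float)
    r = np.asarray(v_ref, dtype=float)
    if p.shape != r.shape or p.ndim != 1 or len(p) < 2:
        raise ValueError("metric_suite expects two aligned vectors of length >= 2")
    res = p - r
    ss_res = float(res @ res)
    ss_tot = float(((r - r.mean()) ** 2).sum())
    r2 = None if ss_tot == 0 else 1.0 - ss_res / ss_tot
    ne, _ = data_loss(p[None, :], r[None, :], mode=ne_mode)
    return MetricSet(
        r2=r2,
        mae=float(np.mean(np.abs(res))),
        rmse=float(np.sqrt(np.mean(res**2))),
        ne=float(ne),
    )


def steady_state_violation(V, S) -> float:
    """(1/m) ||S V||_2^2 — the steady-state loss of a flux vector (batch mean)."""
    S = np.asarray(S, dtype=float)
    V = np.asarray(V, dtype=float)
    if V.ndim == 1:
        V = V[None, :]
    return float(np.mean(np.sum((V @ S.T) ** 2, axis=1))) / S.shape[0]


# ---------------------------------------------------------------------------
# hyperparameter search
# ---------------------------------------------------------------------------

DEFAULT_SEARCH_SPACE = {
    "dh": ("choice", [64, 128, 256, 512, 1024]),
    "lr_nn": ("log_uniform", 1e-4, 1e-2),
    "dropout": ("uniform", 0.0, 0.5),
    "weight_decay": ("log_uniform", 1e-6, 1e-2),
    "c": ("log_uniform", 1.0, 1e4),
}

#: the scheduler strategy tunes only the final-phase data weight
SCHEDULER_SEARCH_SPACE = {"final_data_weight": ("uniform", 0.8, 1.0)}


def _sample_space(space: dict, rng: np.random.Generator) -> dict:
    draw = {}
    for name, spec in space.items():
        kind = spec[0]
        if kind == "choice":
            draw[name] = rng.choice(spec[1]).item()
        elif kind == "uniform":
            draw[name] = float(rng.uniform(spec[1], spec[2]))
        elif kind == "log_uniform":
            draw[name] = float(np.exp(rng.uniform(np.log(spec[1]), np.log(spec[2]))))
        else:
            raise ValueError(f"unknown search distribution {kind!r}")
    return draw


def _with_overrides(config: MinnConfig, overrides: dict) -> MinnConfig:
    overrides = dict(overrides)
    fdw = overrides.pop("final_data_weight", None)
    cfg = replace(config, **overrides)
    if fdw is not None:
        cfg = replace(cfg, schedule=replace(cfg.schedule, final_data_weight=fdw))
    return cfg


def _fingerprint(sample_ids, scaler_mean: np.ndarray) -> dict:
    h = hashlib.sha256()
    h.update("|".join(sample_ids).encode())
    h.update(np.asarray(scaler_mean, dtype=float).tobytes())
    return {"train_ids": list(sample_ids), "hash": h.hexdigest()}


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-split metrics with recomputable aggregates and a run manifest."""

    per_split: pd.DataFrame
    strategy: str
    seed: int
    chosen_configs: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)
    fingerprints: dict = field(default_factory=dict)

    def aggregate(self) -> pd.DataFrame:
        """Mean and standard deviation per metric over successful splits."""
        cols = [c for c in METRIC_COLS if c in self.per_split.columns]
        stats = self.per_split[cols].agg(["mean", "std"])
        return stats

    def to_files(self, prefix: str) -> None:
        self.per_split.to_csv(f"{prefix}_per_split.csv")
        payload = {
            "strategy": self.strategy,
            "seed": self.seed,
            "aggregate": json.loads(self.aggregate().to_json()),
            "chosen_configs": self.chosen_configs,
            "manifest": self.manifest,
        }
        with open(f"{prefix}_aggregate.json", "w") as fh:
            json.dump(payload, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

def _kfold_indices(ids: list[str], k: int, rng: np.random.Generator):
    order = list(rng.permutation(len(ids)))
    folds = [order[i::k] for i in range(k)]
    for i in range(k):
        val = [ids[j] for j in folds[i]]
        train = [ids[j] for f in folds[:i] + folds[i + 1 :] for j in f]
        yield train, val


def nested_loo_cv(
    dataset: OmicsDataset,
    ctx: MechanisticContext,
    base_config: MinnConfig,
    search_space: dict | None = None,
    seed: int = 0,
    n_candidates: int = 3,
    inner_k: int = 5,
) -> EvaluationReport:
    """Leave-one-out outer loop with an inner k-fold hyperparameter search.

    For each held-out sample, ``n_candidates`` random configurations are
    drawn from ``search_space`` (strategy-appropriate default if None) and
    scored by mean validation NE over the inner folds; the winner is
    retrained on all training samples and scored on the held-out sample.
    Scalers and hyperparameters are fitted strictly within each split's
    training samples (fingerprints of every fit are recorded so leakage is
    checkable). Deterministic given ``seed``.
    """
    if dataset.n_samples < inner_k + 1:
        raise ValueError(
            f"nested CV needs at least {inner_k + 1} samples, got {dataset.n_samples}"
        )
    if search_space is None:
        search_space = (
            SCHEDULER_SEARCH_SPACE
            if base_config.strategy in ("scheduler", "scheduler_bound")
            else DEFAULT_SEARCH_SPACE
        )
    ss = np.random.SeedSequence(seed)
    outer_seeds = ss.spawn(dataset.n_samples)
    rows, chosen, fingerprints = {}, {}, {}
    for i, held_id in enumerate(dataset.sample_ids):
        train_ids = [s for s in dataset.sample_ids if s != held_id]
        rng = np.random.default_rng(outer_seeds[i])
        fit_seed = int(rng.integers(2**31 - 1))
        candidates = [_sample_space(search_space, rng) for _ in range(n_candidates)]
        split_prints = []
        try:
            scores = []
            for overrides in candidates:
                cfg = _with_overrides(base_config, overrides)
                cfg = replace(cfg, seed=fit_seed)
                fold_ne = []
                for fold_train, fold_val in _kfold_indices(train_ids, inner_k, rng):
                    trained = train_minn(dataset.subset(fold_train), ctx, cfg)
                    split_prints.append(
                        _fingerprint(fold_train, trained.scaler.mean)
                    )
                    val = dataset.subset(fold_val)
                    _, proj = predict(trained, val.features)
                    ne, _ = data_loss(
                        proj, val.reference_fluxes.to_numpy(dtype=float),
                        base_config.ne_mode,
                    )
                    fold_ne.append(ne)
                scores.append(float(np.mean(fold_ne)))
            best = candidates[int(np.argmin(scores))]
            cfg = replace(_with_overrides(base_config, best), seed=fit_seed)
            final = train_minn(dataset.subset(train_ids), ctx, cfg)
            split_prints.append(_fingerprint(train_ids, final.scaler.mean))
            held = dataset.subset([held_id])
            V, proj = predict(final, held.features)
            ms = metric_suite(
                proj[0], held.reference_fluxes.to_numpy(dtype=float)[0],
                base_config.ne_mode,
            )
            ms.l2_violation = steady_state_violation(V[0], ctx.S)
            rows[held_id] = ms.as_dict() | {"inner_ne": min(scores)}
            chosen[held_id] = best
        except Exception as exc:  # a failed split is recorded, not fatal
            logger.warning("split %s failed: %s", held_id, exc)
            rows[held_id] = {c: np.nan for c in METRIC_COLS}
        fingerprints[held_id] = split_prints
    per_split = pd.DataFrame.from_dict(rows, orient="index")
    manifest = {
        "n_samples": dataset.n_samples,
        "n_candidates": n_candidates,
        "inner_k": inner_k,
        "base_config": dataclasses.asdict(base_config),
        "model_id": ctx.model_id,
        "dataset_hash": hashlib.sha256(
            pd.util.hash_pandas_object(dataset.features).to_numpy().tobytes()
        ).hexdigest(),
    }
    return EvaluationReport(
        per_split=per_split, strategy=base_config.strategy, seed=seed,
        chosen_configs=chosen, manifest=manifest, fingerprints=fingerprints,
    )


def pfba_baseline(
    dataset: OmicsDataset,
    model: cobra.Model,
    ctx: MechanisticContext,
    ko_column: str = "ko_gene",
    cap_ids: tuple = (),
) -> EvaluationReport:
    """Parsimonious FBA scored sample-by-sample against the reference fluxes.

    Per sample, the measured uptakes (the dataset's input exchanges) are
    fixed — ids in ``cap_ids`` are imposed as capacities ``(0, value)``
    instead — the sample's knockout (a gene id, or a reaction id for
    synthetic metadata) is applied, and the pFBA solution is projected onto
    the reference panel. Infeasible samples are recorded as failures.
    """
    from .reservoir import _fix_directional, _opposite

    rows = {}
    pref = ctx.Pref
    rid_order = ctx.reaction_ids
    for sample in dataset.sample_ids:
        vin = dataset.features.loc[sample, dataset.input_cols].to_numpy(dtype=float)
        overrides = {}
        for rid, value in zip(dataset.input_reaction_ids, vin):
            if rid in cap_ids:
                overrides[rid] = (0.0, float(value))
                opp = _opposite(rid)
                if opp and opp in model.reactions:
                    overrides[opp] = (0.0, 0.0)
            else:
                overrides.update(_fix_directional(model, rid, float(value)))
        ko = ""
        if len(dataset.metadata) and ko_column in dataset.metadata.columns:
            ko = str(dataset.metadata.loc[sample, ko_column] or "")
        with model:
            if ko and ko in model.genes:
                model.genes.get_by_id(ko).knock_out()
            elif ko and ko in model.reactions:
                model.reactions.get_by_id(ko).bounds = (0.0, 0.0)
            sol = solve_pfba(model, overrides)
        if sol.status != "optimal":
            logger.warning("pFBA baseline infeasible for sample %s", sample)
            rows[sample] = {c: np.nan for c in METRIC_COLS}
            continue
        v = sol.fluxes.reindex(rid_order).to_numpy(dtype=float)
        ms = metric_suite(
            pref @ v, dataset.reference_fluxes.loc[sample].to_numpy(dtype=float)
        )
        ms.l2_violation = steady_state_violation(v, ctx.S)
        rows[sample] = ms.as_dict()
    per_split = pd.DataFrame.from_dict(rows, orient="index")
    return EvaluationReport(
        per_split=per_split, strategy="pfba_baseline", seed=0,
        manifest={"model_id": model.id},
    )
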