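"""End-to-end optimization: stratified splits, mini-batch training of the full
architecture under the combined loss, checkpointing, and risk prediction.

All randomness flows from a single seed through named sub-generators (split /
parameter init / batch shuffling), so a fixed seed and single-threaded numpy
reproduce the run exactly.  The best-validation-loss parameter set is kept and
restored at the end (early stopping on patience).

The classification label for the BCE head is y_i = 1 iff the event occurred
within the grid (d_i = 1 and t_i <= s_J); subjects censored before s_J get
y_i = 0, a known optimistic-label simplification documented in the methods
note.  Follow-up beyond the grid end is truncated to (s_J, censored) for the
hazard likelihood.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import objectives
from .autodiff import Adam, SGD, Tensor
from .cohort import Cohort, CohortError, FeatureSchema, TimeGrid
from .layers import ArchitectureConfig, SurvivalNet
from .objectives import LossWeights

logger = logging.getLogger(__name__)

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; architecture sizes live in ``arch``."""

    seed: int = 0
    split: tuple[float, float, float] = (0.70, 0.15, 0.15)
    batch_size: int = 128
    epochs: int = 60
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    weights: LossWeights = field(default_factory=LossWeights)
    triplet_margin: float = 1.0
    pch_mode: str = "interval"
    loss_weight_mode: str = "fixed"
    bce_observable_only: bool = False
    patience: int = 10
    arch: ArchitectureConfig = field(default_factory=ArchitectureConfig)
    grid: TimeGrid = field(default_factory=TimeGrid)

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9 or any(s <= 0 for s in self.split):
            raise CohortError(f"split ratios must be positive and sum to 1: {self.split}")
        if self.batch_size < 2 or self.epochs < 1 or self.learning_rate <= 0:
            raise CohortError("batch size >= 2, epochs >= 1, learning rate > 0 required")
        if self.optimizer not in ("adam", "sgd"):
            raise CohortError(f"unknown optimizer {self.optimizer!r}")
        if self.loss_weight_mode not in ("fixed", "uncertainty"):
            raise CohortError(f"unknown loss weight mode {self.loss_weight_mode!r}")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "split": list(self.split),
            "batch_size": self.batch_size,
            "epochs": self.epochs,
            "learning_rate": self.learning_rate,
            "optimizer": self.optimizer,
            "weights": {"a": self.weights.a, "b": self.weights.b,
                        "c": self.weights.c, "triplet": self.weights.triplet},
            "triplet_margin": self.triplet_margin,
            "pch_mode": self.pch_mode,
            "loss_weight_mode": self.loss_weight_mode,
            "bce_observable_only": self.bce_observable_only,
            "patience": self.patience,
            "arch": {
                "embed_dim": self.arch.embed_dim,
                "bottleneck_dim": self.arch.bottleneck_dim,
                "ae_hidden": self.arch.ae_hidden,
                "heads": self.arch.attention.heads,
                "layers": self.arch.attention.layers,
                "ff_width": self.arch.attention.ff_width,
                "init_scale": self.arch.init_scale,
            },
            "grid": self.grid.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        from .layers import AttentionConfig

        arch_d = d.get("arch", {})
        arch = ArchitectureConfig(
            embed_dim=int(arch_d.get("embed_dim", 32)),
            bottleneck_dim=int(arch_d.get("bottleneck_dim", 16)),
            ae_hidden=int(arch_d.get("ae_hidden", 24)),
            attention=AttentionConfig(
                heads=int(arch_d.get("heads", 4)),
                layers=int(arch_d.get("layers", 2)),
                ff_width=int(arch_d.get("ff_width", 64)),
            ),
            init_scale=float(arch_d.get("init_scale", 0.05)),
        )
        w = d.get("weights", {})
        return cls(
            seed=int(d.get("seed", 0)),
            split=tuple(d.get("split", (0.70, 0.15, 0.15))),
            batch_size=int(d.get("batch_size", 128)),
            epochs=int(d.get("epochs", 60)),
            learning_rate=float(d.get("learning_rate", 1e-3)),
            optimizer=str(d.get("optimizer", "adam")),
            weights=LossWeights(
                a=float(w.get("a", 0.3)), b=float(w.get("b", 0.14)),
                c=float(w.get("c", 0.95)), triplet=float(w.get("triplet", 1.0)),
            ),
            triplet_margin=float(d.get("triplet_margin", 1.0)),
            pch_mode=str(d.get("pch_mode", "interval")),
            loss_weight_mode=str(d.get("loss_weight_mode", "fixed")),
            bce_observable_only=bool(d.get("bce_observable_only", False)),
            patience=int(d.get("patience", 10)),
            arch=arch,
            grid=TimeGrid.from_dict(d["grid"]) if "grid" in d else TimeGrid(),
        )


@dataclass
class FittedModel:
    """Trained network plus the config/schema that produced it and the
    per-epoch loss history."""

    net: SurvivalNet
    config: TrainConfig
    schema: FeatureSchema
    history: list[dict]

    def predict_hazards(self, cohort: Cohort, batch_size: int = 1024) -> np.ndarray:
        """Per-interval per-day hazard rates, shape (n, J)."""
        if cohort.schema.feature_names != self.schema.feature_names:
            raise CohortError("cohort schema does not match the model's schema")
        cat_idx, num_z = cohort.encode()
        out = []
        for lo in range(0, len(cohort), batch_size):
            sl = slice(lo, lo + batch_size)
            *_, lam = self.net.forward(cat_idx[sl], num_z[sl])
            out.append(lam.data)
        return np.concatenate(out, axis=0)

    def predict_risk(self, cohort: Cohort, horizons: Sequence[float]) -> np.ndarray:
        """Cumulative event risk at each horizon; shape (n, len(horizons)),
        each row nondecreasing across increasing horizons."""
        lam = self.predict_hazards(cohort)
        grid = self.config.grid
        cols = [objectives.cumulative_risk(lam, grid, float(h)) for h in horizons]
        return np.stack(cols, axis=1)

    def predict_event_probability(self, cohort: Cohort, batch_size: int = 1024) -> np.ndarray:
        """Classification-head probability of an event within the grid."""
        cat_idx, num_z = cohort.encode()
        out = []
        for lo in range(0, len(cohort), batch_size):
            sl = slice(lo, lo + batch_size)
            _, _, _, p, _ = self.net.forward(cat_idx[sl], num_z[sl])
            out.append(p.data)
        return np.concatenate(out, axis=0)

    def save(self, path) -> None:
        """Single-file checkpoint: versioned JSON with parameter arrays."""
        payload = {
            "version": CHECKPOINT_VERSION,
            "config": self.config.to_dict(),
            "schema": self.schema.to_dict(),
            "history": self.history,
            "parameters": [a.tolist() for a in self.net.state_arrays()],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "FittedModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("version") != CHECKPOINT_VERSION:
            raise CohortError(f"unsupported checkpoint version {payload.get('version')}")
        config = TrainConfig.from_dict(payload["config"])
        schema = FeatureSchema.from_dict(payload["schema"])
        net = SurvivalNet(schema, config.grid.n_intervals, config.arch,
                          np.random.default_rng(config.seed))
        net.load_state_arrays([np.asarray(a) for a in payload["parameters"]])
        return cls(net=net, config=config, schema=schema, history=payload["history"])


def split_cohort(cohort: Cohort, cfg: TrainConfig) -> tuple[Cohort, Cohort, Cohort]:
    """Disjoint, exhaustive train/validation/test split, stratified by the
    event indicator, reproducible from the seed."""
    rng = np.random.default_rng([cfg.seed, 101])  # named sub-stream: split
    ids = np.asarray(cohort.patient_ids)
    events = cohort.events
    parts: list[list[str]] = [[], [], []]
    for stratum in (0, 1):
        sub = ids[events == stratum]
        if len(sub) == 0:
            continue
        perm = rng.permutation(len(sub))
        n_train = int(round(cfg.split[0] * len(sub)))
        n_val = int(round(cfg.split[1] * len(sub)))
        cutpoints = [n_train, n_train + n_val]
        for part, chunk in zip(parts, np.split(sub[perm], cutpoints)):
            part.extend(chunk.tolist())
    if any(len(p) == 0 for p in parts):
        raise CohortError(
            f"split produced an empty partition from {len(cohort)} records: "
            f"{[len(p) for p in parts]}"
        )
    return tuple(cohort.subset(p) for p in parts)


def _training_arrays(cohort: Cohort, grid: TimeGrid):
    """Encode a cohort for the loss: features, grid-clipped (t, d), the BCE
    label, and the observable mask (event within the grid, or followed to
    its end)."""
    cat_idx, num_z = cohort.encode()
    t = cohort.times.copy()
    d = cohort.events.astype(float)
    beyond = t > grid.end
    d[beyond] = 0.0
    t[beyond] = grid.end
    y = ((cohort.events == 1) & (cohort.times <= grid.end)).astype(float)
    observable = (y == 1) | (cohort.times >= grid.end)
    return cat_idx, num_z, t, d, y, observable


def _batch_loss(net: SurvivalNet, cfg: TrainConfig, cat_idx, num_z, t, d, y,
                observable, log_sigmas: Tensor | None = None):
    h_rec, h, fx, p, lam = net.forward(cat_idx, num_z)
    l_mse = objectives.reconstruction_loss(h, h_rec)
    if cfg.bce_observable_only and observable.any() and not observable.all():
        obs = np.flatnonzero(observable)
        l_bce = objectives.bce_loss(p.gather_rows(obs), y[obs])
    else:
        l_bce = objectives.bce_loss(p, y)
    l_pc = objectives.pch_loss(lam, t, d, cfg.grid, mode=cfg.pch_mode)
    l_tri = objectives.triplet_loss(fx, y.astype(int), margin=cfg.triplet_margin)
    # triplet is a sum over anchors; normalize by batch size so the weight
    # means the same thing at any batch size
    l_tri = l_tri * (1.0 / len(t))
    if log_sigmas is None:
        total = objectives.total_loss(l_mse, l_bce, l_pc, l_tri, cfg.weights)
    else:
        # homoscedastic-uncertainty weighting: sum_k e^{-s_k} L_k + s_k
        total = Tensor(0.0)
        for k, loss_k in enumerate((l_mse, l_bce, l_pc, l_tri)):
            s_k = log_sigmas.gather_rows(np.array([k])).reshape(())
            total = total + (-s_k).exp() * loss_k + s_k
    components = {
        "mse": l_mse.item(), "bce": l_bce.item(),
        "pch": l_pc.item(), "triplet": l_tri.item(), "total": total.item(),
    }
    return total, components


def train_model(train: Cohort, validation: Cohort, cfg: TrainConfig) -> FittedModel:
    """Mini-batch gradient descent on the combined loss with early stopping on
    the validation total loss; returns the best-validation checkpoint."""
    schema = train.schema
    init_rng = np.random.default_rng([cfg.seed, 202])   # named sub-stream: init
    batch_rng = np.random.default_rng([cfg.seed, 303])  # named sub-stream: batching
    net = SurvivalNet(schema, cfg.grid.n_intervals, cfg.arch, init_rng)
    log_sigmas = (Tensor(np.zeros(4), requires_grad=True)
                  if cfg.loss_weight_mode == "uncertainty" else None)
    opt_cls = Adam if cfg.optimizer == "adam" else SGD
    params = net.parameters() + ([log_sigmas] if log_sigmas is not None else [])
    opt = opt_cls(params, lr=cfg.learning_rate)

    tr = _training_arrays(train, cfg.grid)
    va = _training_arrays(validation, cfg.grid)
    n = len(train)
    history: list[dict] = []
    best_val = np.inf
    best_state = net.state_arrays()
    stale = 0
    for epoch in range(cfg.epochs):
        perm = batch_rng.permutation(n)
        epoch_total = 0.0
        comps_sum = {"mse": 0.0, "bce": 0.0, "pch": 0.0, "triplet": 0.0}
        n_batches = 0
        for lo in range(0, n, cfg.batch_size):
            idx = perm[lo:lo + cfg.batch_size]
            if len(idx) < 2:
                continue  # a 1-record tail cannot form contrastive pairs
            total, comps = _batch_loss(
                net, cfg, tr[0][idx], tr[1][idx], tr[2][idx], tr[3][idx],
                tr[4][idx], tr[5][idx], log_sigmas
            )
            if not np.isfinite(total.item()):
                raise CohortError(
                    f"training diverged at epoch {epoch}: total loss {total.item()}"
                )
            opt.zero_grad()
            total.backward()
            opt.step()
            epoch_total += comps["total"]
            for k in comps_sum:
                comps_sum[k] += comps[k]
            n_batches += 1
        with np.errstate(all="ignore"):
            _, val_comps = _batch_loss(net, cfg, *va, log_sigmas)
        row = {
            "epoch": epoch,
            "train_total": epoch_total / max(n_batches, 1),
            **{f"train_{k}": v / max(n_batches, 1) for k, v in comps_sum.items()},
            "val_total": val_comps["total"],
        }
        history.append(row)
        logger.info("epoch %d: train %.4f  val %.4f", epoch,
                    row["train_total"], row["val_total"])
        if val_comps["total"] < best_val - 1e-9:
            best_val = val_comps["total"]
            best_state = net.state_arrays()
            stale = 0
        else:
            stale += 1
            if stale > cfg.patience:
                logger.info("early stop at epoch %d (patience %d)", epoch, cfg.patience)
                break
    net.load_state_arrays(best_state)
    return FittedModel(net=net, config=cfg, schema=schema, history=history)


def predict_risk(model: FittedModel, cohort: Cohort,
                 horizons: Sequence[float]) -> np.ndarray:
    """Module-level alias for :meth:`FittedModel.predict_risk`."""
    return model.predict_risk(cohort, horizons)
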