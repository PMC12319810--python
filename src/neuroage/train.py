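"""Training loop with dual-validation model selection and ensembling.

The protocol: squared-error loss, small batches, an internal validation
set stratified by 5-year age bins (5% of the training subjects by
default), an external validation set from a held-out site, and selection
of the epoch minimizing the *average* of the two validation losses — so
the kept checkpoint balances in-distribution and cross-site performance.
The ensemble trains ``n_ensemble`` members that share configuration and
data splits but differ in weight initialization (seeds seed+0..n-1); each
member gets its own regression-to-the-mean bias correction fitted on the
union of the two validation sets.

Validation losses are computed on raw (pre-correction) outputs, since the
bias correction is fitted only after model selection.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import _nn
from .augment import AugmentConfig, apply_plan, sample_plan
from .errors import ConfigError
from .model import BrainAgeModel, ModelConfig, build_model
from .predict import BiasCorrection, fit_bias_correction

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "stratified_internal_split",
    "split_external_site",
    "train_model",
    "train_ensemble",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    batch_size: int = 4
    lr: float = 1e-2
    weight_decay: float = 1e-4
    seed: int = 0
    n_ensemble: int = 5
    internal_val_fraction: float = 0.05
    stratify_bin_years: float = 5.0
    external_site: str | None = None
    augment: AugmentConfig | None = None
    lr_schedule: str = "cosine"  # cosine | constant

    def __post_init__(self):
        if self.epochs < 0:
            raise ConfigError("epochs must be >= 0")
        if not 0.0 < self.internal_val_fraction < 1.0:
            raise ConfigError("internal_val_fraction must be in (0, 1)")
        if self.batch_size < 1 or self.n_ensemble < 1:
            raise ConfigError("batch_size and n_ensemble must be >= 1")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    internal_val_loss: list[float] = field(default_factory=list)
    external_val_loss: list[float] = field(default_factory=list)
    selected_epoch: int | None = None

    @property
    def selection_criterion(self) -> list[float]:
        return [
            (i + e) / 2.0
            for i, e in zip(self.internal_val_loss, self.external_val_loss)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(len(self.train_loss)),
                "train_loss": self.train_loss,
                "internal_val_loss": self.internal_val_loss,
                "external_val_loss": self.external_val_loss,
            }
        )


def stratified_internal_split(
    cohort: pd.DataFrame,
    fraction: float = 0.05,
    bin_years: float = 5.0,
    seed: int = 0,
    min_per_bin: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subject-level validation split balanced over age bins.

    Subjects (not scans) are assigned to bins of ``bin_years`` by their
    first-visit age; within each occupied bin,
    ``max(min_per_bin, round(fraction * bin size))`` subjects go to
    validation, so every sufficiently occupied bin is represented across
    the lifespan. ``min_per_bin=0`` disables the at-least-one rule (used
    only to realize the degenerate fraction -> 0 limit).
    """
    if not 0.0 < fraction < 1.0:
        raise ConfigError("fraction must be in (0, 1)")
    if len(cohort) == 0:
        raise ConfigError("cohort is empty")
    rng = np.random.default_rng(seed)
    subjects = cohort.groupby("subject_id", sort=True)["age"].min()
    bins = np.floor(subjects.values / bin_years).astype(int)
    val_subjects: list[str] = []
    for bin_id in np.unique(bins):
        members = subjects.index.values[bins == bin_id]
        n_val = max(min_per_bin, int(round(fraction * members.size)))
        n_val = min(n_val, members.size)
        if n_val > 0:
            val_subjects.extend(
                rng.choice(members, size=n_val, replace=False).tolist()
            )
    in_val = cohort["subject_id"].isin(val_subjects)
    return cohort[~in_val].copy(), cohort[in_val].copy()


def split_external_site(
    cohort: pd.DataFrame, external_site: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hold out every scan from one site as the external validation set."""
    mask = cohort["site"] == external_site
    return cohort[~mask].copy(), cohort[mask].copy()


def _materialize(rows: pd.DataFrame, loader: Callable):
    volumes, ages = [], []
    for row in rows.itertuples():
        vol, age = loader(row)
        volumes.append(np.ascontiguousarray(vol, dtype=np.float32))
        ages.append(float(age))
    return volumes, np.array(ages, dtype=np.float32)


def _eval_mse(model: BrainAgeModel, volumes, ages, batch_size=8) -> float:
    if len(volumes) == 0:
        return math.nan
    preds = []
    for start in range(0, len(volumes), batch_size):
        batch = np.stack(volumes[start : start + batch_size])
        preds.append(model.forward(batch, train=False))
    preds = np.concatenate(preds)
    return float(np.mean((preds - ages) ** 2))


def _epoch_lr(config: TrainConfig, epoch: int) -> float:
    if config.lr_schedule == "constant" or config.epochs <= 1:
        return config.lr
    return config.lr * 0.5 * (1.0 + math.cos(math.pi * epoch / config.epochs))


def train_model(
    train_rows: pd.DataFrame,
    internal_val: pd.DataFrame,
    external_val: pd.DataFrame,
    model_config: ModelConfig,
    train_config: TrainConfig,
    loader: Callable,
) -> tuple[BrainAgeModel, TrainHistory]:
    """Train one model and return the best-epoch checkpoint.

    ``loader`` maps a cohort row to ``(preprocessed volume, age)``. The
    returned model carries the weights of the epoch with the lowest
    average of internal and external validation losses, not the final
    epoch. With ``epochs=0`` the freshly initialized model is returned
    unchanged.
    """
    if len(train_rows) == 0:
        raise ConfigError("empty training set")
    model = build_model(model_config, seed=train_config.seed)
    history = TrainHistory()
    if train_config.epochs == 0:
        return model, history

    x_train, y_train = _materialize(train_rows, loader)
    x_ival, y_ival = _materialize(internal_val, loader)
    x_eval, y_eval = _materialize(external_val, loader)

    optimizer = _nn.AdamW(
        model.params(), lr=train_config.lr,
        weight_decay=train_config.weight_decay,
    )
    rng = np.random.default_rng([train_config.seed & 0x7FFFFFFF, 0xA5])
    best_state = None
    best_criterion = math.inf
    n = len(x_train)
    for epoch in range(train_config.epochs):
        order = rng.permutation(n)
        lr = _epoch_lr(train_config, epoch)
        epoch_losses = []
        for start in range(0, n, train_config.batch_size):
            idx = order[start : start + train_config.batch_size]
            volumes = []
            for i in idx:
                vol = x_train[i]
                if train_config.augment is not None:
                    plan = sample_plan(train_config.augment, rng)
                    vol = apply_plan(vol, plan).astype(np.float32)
                volumes.append(vol)
            batch = np.stack(volumes)
            targets = y_train[idx]
            optimizer.zero_grad()
            preds = model.forward(batch, train=True, rng=rng)
            err = preds - targets
            epoch_losses.append(float(np.mean(err**2)))
            model.backward(2.0 * err / err.size)
            optimizer.step(lr=lr)
        ival = _eval_mse(model, x_ival, y_ival)
        eval_ = _eval_mse(model, x_eval, y_eval)
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.internal_val_loss.append(ival)
        history.external_val_loss.append(eval_)
        criterion = np.nanmean([ival, eval_])
        if math.isnan(criterion):
            criterion = history.train_loss[-1]
        if criterion < best_criterion:
            best_criterion = criterion
            best_state = model.get_state()
            history.selected_epoch = epoch
    if best_state is not None:
        model.set_state(best_state)
    return model, history


def train_ensemble(
    train_rows: pd.DataFrame,
    internal_val: pd.DataFrame,
    external_val: pd.DataFrame,
    model_config: ModelConfig,
    train_config: TrainConfig,
    loader: Callable,
) -> list[tuple[BrainAgeModel, BiasCorrection]]:
    """Train ``n_ensemble`` members differing only in initialization.

    All members see identical data splits; member ``i`` uses seed
    ``seed + i``. Each member's bias correction is fitted on its own raw
    predictions over the union of the internal and external validation
    sets.
    """
    fit_rows = pd.concat([internal_val, external_val], ignore_index=True)
    x_fit, y_fit = _materialize(fit_rows, loader)
    members: list[tuple[BrainAgeModel, BiasCorrection]] = []
    for member in range(train_config.n_ensemble):
        member_config = dataclasses.replace(
            train_config, seed=train_config.seed + member
        )
        model, _ = train_model(
            train_rows, internal_val, external_val,
            model_config, member_config, loader,
        )
        raw = np.array([model.predict(v) for v in x_fit])
        correction = fit_bias_correction(
            raw, y_fit, fit_set_id="internal+external validation"
        )
        members.append((model, correction))
    return members
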