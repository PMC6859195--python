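"""Training of the reconstruction network on streamed synthetic FIDs.

Each run draws a fresh set of random FIDs from the generator, normalises
them by their first point, holds out 10% for cross-validation, and
minimises the mean-squared deviation between the network output and the
fully sampled FID with the ADAM optimiser (learning rate 0.00012,
moment decays 0.9/0.999).  Runs of a fixed number of epochs repeat until
the cross-validation MSE and MAE both drop below the stopping thresholds
— at 12.5% sampling (5e-4, 0.013) and at 18.75% sampling
(1.5e-4, 0.008) — or until the run budget is exhausted.

One model is trained per sampling schedule; the saved model records its
schedule and refuses mismatched inference.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import fid_model, network
from .fid_model import AxisMeta
from .network import NetworkParams
from .schedules import SamplingSchedule

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "loss_mse",
    "loss_mae",
    "train",
    "evaluate_validation",
    "stopping_thresholds",
]

#: stopping thresholds (mse, mae) keyed by sampling fraction
_THRESHOLDS = {0.125: (5e-4, 0.013), 0.1875: (1.5e-4, 0.008)}


def stopping_thresholds(fraction: float) -> tuple[float, float]:
    """Validation (MSE, MAE) stopping thresholds for a sampling fraction.

    Only the two studied fractions have stated thresholds; any other
    fraction requires explicit user values.
    """
    for frac, thr in _THRESHOLDS.items():
        if abs(fraction - frac) < 1e-9:
            return thr
    raise KeyError(
        f"no default stopping thresholds for sampling fraction {fraction}; "
        "pass mse_stop/mae_stop explicitly"
    )


def loss_mse(predicted: np.ndarray, target: np.ndarray) -> float:
    """Mean squared deviation over all 2*np real values (batch-averaged)."""
    predicted = np.asarray(predicted)
    target = np.asarray(target)
    if predicted.shape != target.shape:
        raise ValueError(f"shape mismatch {predicted.shape} vs {target.shape}")
    return float(np.mean((predicted - target) ** 2))


def loss_mae(predicted: np.ndarray, target: np.ndarray) -> float:
    """Mean absolute deviation over all 2*np real values (batch-averaged)."""
    predicted = np.asarray(predicted)
    target = np.asarray(target)
    if predicted.shape != target.shape:
        raise ValueError(f"shape mismatch {predicted.shape} vs {target.shape}")
    return float(np.mean(np.abs(predicted - target)))


@dataclasses.dataclass
class TrainConfig:
    """All knobs of one training job.

    Desk-scale defaults (5e4 FIDs per run) keep a run in minutes on one
    CPU; the procedure is unchanged at larger ``n_fids``/``max_runs``.
    """

    schedule: SamplingSchedule
    axis: AxisMeta
    n_cells: int = 3
    n_fids: int = 50_000
    learning_rate: float = 0.00012
    epochs_per_run: int = 20
    max_runs: int = 50
    mse_stop: float | None = None  # default: stopping_thresholds(fraction)
    mae_stop: float | None = None
    batch_size: int = 256
    validation_fraction: float = 0.10
    seed: int = 0
    tied: bool = True

    def __post_init__(self) -> None:
        if self.schedule.n_points != self.axis.n_points:
            raise ValueError("schedule grid size must match axis n_points")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation fraction must be in (0, 1)")
        if self.mse_stop is None or self.mae_stop is None:
            mse, mae = stopping_thresholds(self.schedule.fraction)
            if self.mse_stop is None:
                self.mse_stop = mse
            if self.mae_stop is None:
                self.mae_stop = mae

    @property
    def sp(self) -> int:
        return self.schedule.sp

    @property
    def n_points(self) -> int:
        return self.axis.n_points


@dataclasses.dataclass
class TrainHistory:
    """Per-epoch metrics of a whole training job."""

    train_mse: list = dataclasses.field(default_factory=list)
    val_mse: list = dataclasses.field(default_factory=list)
    val_mae: list = dataclasses.field(default_factory=list)
    run_index: list = dataclasses.field(default_factory=list)
    stop_reason: str = ""

    def append(self, run: int, tmse: float, vmse: float, vmae: float) -> None:
        self.run_index.append(run)
        self.train_mse.append(tmse)
        self.val_mse.append(vmse)
        self.val_mae.append(vmae)


class _Adam:
    """ADAM with conventional moment parameters (0.9 / 0.999, eps 1e-8)."""

    def __init__(self, params: NetworkParams, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {name: {"kernel": np.zeros_like(l.kernel),
                         "bias": np.zeros_like(l.bias)}
                  for name, l in params.layers()}
        self.v = {name: {"kernel": np.zeros_like(l.kernel),
                         "bias": np.zeros_like(l.bias)}
                  for name, l in params.layers()}

    def step(self, params: NetworkParams, grads: dict) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for name, layer in params.layers():
            for slot, arr in (("kernel", layer.kernel), ("bias", layer.bias)):
                g = grads[name][slot]
                m = self.m[name][slot]
                v = self.v[name][slot]
                m *= self.beta1
                m += (1.0 - self.beta1) * g
                v *= self.beta2
                v += (1.0 - self.beta2) * g * g
                arr -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


def _make_dataset(config: TrainConfig, rng: np.random.Generator):
    """Generate one run's worth of normalised FIDs and split 90/10.

    Returns (X_train, Y_train, X_val, Y_val): X is flattened sparse input
    (n, 2sp); Y the full FID target (n, 2, np).  float32 storage halves
    the memory of large runs; the optimiser itself works in float64.
    """
    idx = config.schedule.indices
    n_pts = config.n_points
    X = np.empty((config.n_fids, 2 * config.sp), dtype=np.float32)
    Y = np.empty((config.n_fids, 2, n_pts), dtype=np.float32)
    done = 0
    for batch in fid_model.stream_batches(config.n_fids, 8192, config.sp,
                                          config.axis, rng):
        b = batch.shape[0]
        sl = slice(done, done + b)
        sub = batch[:, idx]
        X[sl, :config.sp] = sub.real
        X[sl, config.sp:] = sub.imag
        Y[sl, 0] = batch.real
        Y[sl, 1] = batch.imag
        done += b
    n_val = max(1, int(round(config.validation_fraction * config.n_fids)))
    return X[:-n_val], Y[:-n_val], X[-n_val:], Y[-n_val:]


def evaluate_validation(params: NetworkParams, fids: np.ndarray,
                        schedule: SamplingSchedule) -> tuple[float, float]:
    """(MSE, MAE) of the network against fully sampled normalised FIDs.

    ``fids`` is a complex (n, np) array of first-point-normalised FIDs;
    the sparse network inputs are extracted under ``schedule``.
    """
    sub = fids[:, schedule.indices]
    X = np.concatenate([sub.real, sub.imag], axis=1)
    Y = np.stack([fids.real, fids.imag], axis=1)
    mask = network.schedule_mask_vector(schedule)
    pred = network.forward_batch(np.asarray(X, dtype=np.float64), mask, params)
    return loss_mse(pred, Y), loss_mae(pred, Y)


def _metrics_batched(params, X, Y, mask, batch: int = 4096):
    """Validation metrics without materialising one huge forward pass."""
    n = X.shape[0]
    se = ae = 0.0
    for lo in range(0, n, batch):
        pred = network.forward_batch(X[lo:lo + batch], mask, params)
        diff = pred - Y[lo:lo + batch]
        se += float(np.sum(diff ** 2))
        ae += float(np.sum(np.abs(diff)))
    total = n * Y.shape[1] * Y.shape[2]
    return se / total, ae / total


def train(config: TrainConfig,
          init: NetworkParams | None = None) -> tuple[NetworkParams, TrainHistory]:
    """Run the full optimisation loop.

    Reproducible bit-for-bit for a fixed (seed, config) on one thread.
    Raises on a non-finite loss (diverged optimisation).
    """
    rng = np.random.default_rng(config.seed)
    params = init if init is not None else network.init_params(
        config.sp, config.n_points, config.n_cells,
        seed=rng.integers(2 ** 31), tied=config.tied)
    mask = network.schedule_mask_vector(config.schedule)
    opt = _Adam(params, config.learning_rate)
    history = TrainHistory()

    for run in range(config.max_runs):
        Xtr, Ytr, Xval, Yval = _make_dataset(config, rng)
        n_tr = Xtr.shape[0]
        for epoch in range(config.epochs_per_run):
            order = rng.permutation(n_tr)
            epoch_mse = 0.0
            for lo in range(0, n_tr, config.batch_size):
                sel = order[lo:lo + config.batch_size]
                xb = Xtr[sel]  # float32 minibatches keep the step cheap
                yb = Ytr[sel]
                pred, cache = network.forward_batch(xb, mask, params,
                                                    with_cache=True)
                diff = pred - yb
                batch_mse = float(np.mean(diff ** 2))
                if not np.isfinite(batch_mse):
                    raise FloatingPointError(
                        f"non-finite training loss at run {run}, epoch "
                        f"{epoch}: {batch_mse}")
                epoch_mse += batch_mse * sel.size
                dY = (2.0 / diff.size) * diff
                grads = network.backward_batch(dY, cache, params)
                opt.step(params, grads)
            vmse, vmae = _metrics_batched(params, Xval, Yval, mask)
            history.append(run, epoch_mse / n_tr, vmse, vmae)
        if history.val_mse[-1] < config.mse_stop and \
                history.val_mae[-1] < config.mae_stop:
            history.stop_reason = "thresholds-met"
            return params, history
    history.stop_reason = "max-runs"
    return params, history
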