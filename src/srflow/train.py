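"""Training-pipeline orchestration.

Thin functional layer over :class:`srflow.models.SRFlowRegressor`: it
assembles low-/high-resolution volume arrays from flow series via the
k-space degradation model, runs the patch-based training loop, selects
the checkpoint by validation PVNR, and benchmarks the learned model
against the cubic-spline baseline.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .degrade import DegradationConfig, degrade_series
from .losses import LossConfig
from .metrics import evaluate
from .models import CubicSplineUpsampler, SRFlowRegressor
from .volume import FlowSeries, VelocityField

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "make_splits",
    "series_to_arrays",
    "train",
    "select_best",
    "benchmark",
]


@dataclass
class TrainConfig:
    """Optimization hyperparameters of the training loop."""

    epochs: int = 200
    batch_size: int = 4
    lr: float = 1e-3
    lr_decay: float = 0.9
    decay_every: int = 10
    patches_per_epoch: int = 500
    loss_name: str = "opt"
    seed: int = 0
    scale: int = 2

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size, self.decay_every,
               self.patches_per_epoch) < 1:
            raise ValueError("epoch/batch sizes must be positive")
        if not (0.0 < self.lr_decay <= 1.0):
            raise ValueError("lr_decay must lie in (0, 1]")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class TrainHistory:
    """Per-epoch training loss and validation PVNR."""

    loss: List[float] = field(default_factory=list)
    val_pvnr: List[float] = field(default_factory=list)
    best_epoch: int = 0

    def __post_init__(self) -> None:
        if self.val_pvnr and len(self.val_pvnr) != len(self.loss):
            raise ValueError("loss and val_pvnr must have equal length")


def make_splits(
    subject_ids: Sequence, n_folds: int, seed: int = 0
) -> List[Tuple[list, list]]:
    """Disjoint validation folds covering every subject once.

    Returns ``n_folds`` (train_ids, val_ids) pairs; the shuffle is
    deterministic per seed so one split can be reused across model and
    loss variants.
    """
    ids = list(subject_ids)
    if n_folds > len(ids) or n_folds < 1:
        raise ValueError(
            f"cannot make {n_folds} folds out of {len(ids)} subjects"
        )
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    folds = [list(order[i::n_folds]) for i in range(n_folds)]
    return [
        ([x for x in ids if x not in fold], fold) for fold in folds
    ]


def series_to_arrays(
    series_list: Sequence[FlowSeries], degr_cfg: DegradationConfig
) -> Tuple[np.ndarray, np.ndarray]:
    """Degrade each frame of each series; stack into (n, ..., 3) arrays."""
    lrs, hrs = [], []
    for k, series in enumerate(series_list):
        sub_cfg = DegradationConfig(
            scale=degr_cfg.scale, v_max=degr_cfg.v_max,
            noise_sd=degr_cfg.noise_sd, seed=degr_cfg.seed + 7919 * k,
            magnitude_source=degr_cfg.magnitude_source,
        )
        lo = degrade_series(series, sub_cfg)
        for lf, hf in zip(lo, series):
            lrs.append(lf.data)
            hrs.append(hf.data)
    return np.stack(lrs), np.stack(hrs)


def train(
    model_cfg: dict,
    train_series: Sequence[FlowSeries],
    degr_cfg: DegradationConfig,
    loss_cfg_or_name,
    cfg: TrainConfig,
    val_series: Optional[Sequence[FlowSeries]] = None,
    init_from: Optional[SRFlowRegressor] = None,
) -> Tuple[SRFlowRegressor, TrainHistory]:
    """Run the full pipeline: degrade, fit, select by validation PVNR.

    ``model_cfg`` holds SRFlowRegressor architecture keyword arguments;
    ``loss_cfg_or_name`` is a preset name ('l1', 'mp_l1', 'opt', ...).
    ``init_from`` warm-starts from a fitted estimator's weights with a
    fresh optimizer state (fine-tuning mode).
    """
    loss_name = (
        loss_cfg_or_name if isinstance(loss_cfg_or_name, str) else "opt"
    )
    est = SRFlowRegressor(
        scale=cfg.scale,
        loss=loss_name,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        learning_rate=cfg.lr,
        lr_decay=cfg.lr_decay,
        decay_every=cfg.decay_every,
        patches_per_epoch=cfg.patches_per_epoch,
        random_state=cfg.seed,
        **model_cfg,
    )
    X, y = series_to_arrays(train_series, degr_cfg)
    Xv = yv = None
    if val_series is not None:
        Xv, yv = series_to_arrays(val_series, degr_cfg)
    if init_from is not None:
        # fine-tuning: reuse the source weights with fresh optimizer state
        est._warm_start_params = [
            p.data.copy() for p in init_from.net_.parameters()
        ]
    est.fit(X, y, Xv, yv)
    history = TrainHistory(
        loss=est.history_["loss"],
        val_pvnr=est.history_["val_pvnr"],
        best_epoch=est.best_epoch_,
    )
    return est, history


def select_best(history: TrainHistory) -> int:
    """Epoch (1-based) with the highest validation PVNR; earliest on ties."""
    if not history.val_pvnr:
        raise ValueError("history has no validation record")
    arr = np.asarray(history.val_pvnr)
    return int(np.argmax(arr)) + 1


def benchmark(
    est: SRFlowRegressor,
    val_series: Sequence[FlowSeries],
    degr_cfg: DegradationConfig,
    mask: Optional[np.ndarray] = None,
) -> Dict[str, dict]:
    """Per-volume metrics for the network and the spline baseline.

    Returns, per method, the list of per-volume metric reports, their
    mean/SD aggregation, and wall-clock inference time (reported only).
    """
    X, y = series_to_arrays(val_series, degr_cfg)
    spline = CubicSplineUpsampler(scale=degr_cfg.scale).fit()

    out: Dict[str, dict] = {}
    for name, predictor in (("srflow", est.predict), ("cubic_spline", spline.predict)):
        t0 = time.perf_counter()
        preds = predictor(X)
        elapsed = time.perf_counter() - t0
        reports = [
            evaluate(p, r, mask).as_dict() for p, r in zip(preds, y)
        ]
        agg = {
            k: {
                "mean": float(np.mean([r[k] for r in reports])),
                "sd": float(np.std([r[k] for r in reports])),
            }
            for k in ("pvnr", "rms_speed", "edir", "rms_div")
        }
        out[name] = {
            "per_volume": reports,
            "aggregate": agg,
            "wall_clock_s": elapsed,
        }
    return out
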