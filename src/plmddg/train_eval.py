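"""Training loop, early stopping, k-fold cross-validation, evaluation.

Metrics follow their standard definitions: Pearson correlation (PCC)
for trend agreement, MAE/RMSE/MSE (kcal/mol) for absolute accuracy.
Cross-validation reports both the per-fold mean +/- std and the *pooled*
metrics over the concatenated out-of-fold predictions, since the two
conventions differ slightly and both are in common use.  An
outlier-subset analysis evaluates the top fraction of records with the
most extreme |ddG| (both highly positive and highly negative).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .dataset import MutationRecord, split_folds
from .errors import ConfigurationError, LeakageError, ShapeError
from .model import DdgRegressor, LossConfig, ModelConfig
from .nn import Adam


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; epochs/patience/validation-fraction mirror the
    reference protocol (150 epochs, patience 40, 10% validation)."""

    max_epochs: int = 150
    early_stop_patience: int = 40
    validation_fraction: float = 0.10
    batch_size: int = 32
    learning_rate: float = 1e-4
    optimizer_name: str = "adam"
    seed: int = 0
    monitor: str = "val_loss"  # or "val_pcc"
    delta: float = 1.0  # pseudo-Huber transition scale

    def __post_init__(self) -> None:
        if not 0.0 < self.validation_fraction < 1.0:
            raise ConfigurationError("validation_fraction must be in (0, 1)")
        if self.early_stop_patience >= self.max_epochs:
            raise ConfigurationError("patience must be smaller than max_epochs")
        if self.monitor not in ("val_loss", "val_pcc"):
            raise ConfigurationError(f"unknown monitor {self.monitor!r}")


@dataclass
class EvalReport:
    """Cross-validation report: per-fold, aggregate, pooled and outlier metrics."""

    per_fold: list[dict]
    mean: dict
    std: dict
    pooled: dict
    outlier: dict
    antisymmetry_pcc: float | None
    n_records: int
    seed: int
    train_config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def clean(o):
            if isinstance(o, dict):
                return {k: clean(v) for k, v in o.items()}
            if isinstance(o, list):
                return [clean(v) for v in o]
            if isinstance(o, float) and not math.isfinite(o):
                return None
            return o

        return json.dumps(clean(asdict(self)), indent=2)


# ---------------------------------------------------------------------------
# metrics


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """PCC / MAE / RMSE / MSE; PCC is NaN (flagged) for constant vectors."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ShapeError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size == 0:
        raise ShapeError("empty prediction set")
    err = y_true - y_pred
    mse = float(np.mean(err**2))
    out = {
        "mae": float(np.mean(np.abs(err))),
        "rmse": float(np.sqrt(mse)),
        "mse": mse,
    }
    if y_true.size < 2 or np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
        out["pcc"] = float("nan")
        out["pcc_defined"] = False
    elif np.array_equal(y_true, y_pred):
        out["pcc"] = 1.0  # avoid float rounding on the exact-identity case
        out["pcc_defined"] = True
    else:
        out["pcc"] = float(stats.pearsonr(y_true, y_pred)[0])
        out["pcc_defined"] = True
    return out


# ---------------------------------------------------------------------------
# training with early stopping


@dataclass
class TrainHistory:
    train_loss: list[float]
    val_metric: list[float]
    best_epoch: int  # 1-based
    stopped_epoch: int  # 1-based


def _pair_aware_val_split(
    records: Sequence[MutationRecord], fraction: float, seed: int
) -> np.ndarray:
    """Boolean mask: True = validation.  A forward record and its reverse
    never straddle the split."""
    groups: dict = {}
    for r in records:
        groups.setdefault(r.site_key, []).append(True)
    keys = list(groups)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(keys))
    n_val = max(1, int(round(fraction * len(keys))))
    if n_val >= len(keys):
        raise ConfigurationError("validation split would consume all records")
    val_keys = {keys[i] for i in order[:n_val]}
    return np.array([r.site_key in val_keys for r in records])


def train(
    model: DdgRegressor,
    train_records: Sequence[MutationRecord],
    channel_arrays: list[np.ndarray],
    config: TrainConfig = TrainConfig(),
) -> tuple[dict, TrainHistory]:
    """Train with early stopping; returns (best state_dict, history).

    ``channel_arrays[i]`` has shape (N, L, D_i), aligned with
    ``train_records``.  The monitored metric (validation loss by default,
    negated validation PCC optionally) must improve within
    ``early_stop_patience`` epochs or training stops; the returned weights
    are those of the best epoch.
    """
    if not len(train_records):
        raise ConfigurationError("empty training set")
    y = np.array([r.ddg for r in train_records])
    val_mask = _pair_aware_val_split(
        train_records, config.validation_fraction, config.seed
    )
    if not val_mask.any() or val_mask.all():
        raise ConfigurationError("degenerate validation split")
    tr_idx = np.flatnonzero(~val_mask)
    va_idx = np.flatnonzero(val_mask)
    Xtr = [c[tr_idx] for c in channel_arrays]
    Xva = [c[va_idx] for c in channel_arrays]
    ytr, yva = y[tr_idx], y[va_idx]

    opt = Adam(model.parameters(), lr=config.learning_rate)
    loss_cfg = LossConfig(config.delta)
    rng = np.random.default_rng(config.seed + 1)

    best_metric = np.inf
    best_state = model.state_dict()
    best_epoch = 0
    since_improve = 0
    hist_loss: list[float] = []
    hist_val: list[float] = []
    epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(ytr))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = [c[idx] for c in Xtr]
            loss = model.loss(batch, ytr[idx], loss_cfg, train_rng=rng)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        hist_loss.append(float(np.mean(losses)))

        val_pred = model.predict(Xva)
        if config.monitor == "val_loss":
            metric = float(
                _pseudo_huber_value(yva, val_pred, loss_cfg.delta)
            )
        else:
            m = compute_metrics(yva, val_pred)
            metric = -m["pcc"] if m["pcc_defined"] else np.inf
        hist_val.append(metric)

        if metric < best_metric:
            best_metric = metric
            best_state = model.state_dict()
            best_epoch = epoch
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= config.early_stop_patience:
                break

    model.load_state_dict(best_state)
    history = TrainHistory(hist_loss, hist_val, best_epoch, epoch)
    return best_state, history


def _pseudo_huber_value(y_true, y_pred, delta: float) -> float:
    a = (np.asarray(y_true, float) - np.asarray(y_pred, float)) / delta
    return float(np.mean(delta * delta * (np.sqrt(1 + a * a) - 1)))


# ---------------------------------------------------------------------------
# cross-validation


def kfold_cv(
    records: Sequence[MutationRecord],
    channel_arrays: list[np.ndarray],
    model_config: ModelConfig,
    train_config: TrainConfig = TrainConfig(),
    k: int = 10,
    fold_seed: int = 0,
    pairing: str = "pairwise",
    outlier_fraction: float = 0.10,
) -> tuple[EvalReport, np.ndarray]:
    """k-fold cross-validation; returns (report, out-of-fold predictions).

    Every record is predicted exactly once, by the model trained on the
    other k-1 folds.  Per-fold metrics are aggregated as mean +/- std;
    pooled metrics are computed over all concatenated predictions.
    """
    records = list(records)
    folds = split_folds(records, k, fold_seed, pairing)
    y = np.array([r.ddg for r in records])
    oof = np.full(len(records), np.nan)
    per_fold = []
    for fold in range(k):
        test_idx = np.flatnonzero(folds == fold)
        train_idx = np.flatnonzero(folds != fold)
        model = DdgRegressor(model_config)
        sub_cfg = TrainConfig(**{**asdict(train_config),
                                 "seed": train_config.seed + fold})
        train(
            model,
            [records[i] for i in train_idx],
            [c[train_idx] for c in channel_arrays],
            sub_cfg,
        )
        preds = model.predict([c[test_idx] for c in channel_arrays])
        oof[test_idx] = preds
        per_fold.append(compute_metrics(y[test_idx], preds))

    assert not np.isnan(oof).any(), "out-of-fold coverage is incomplete"
    names = ("pcc", "mae", "rmse", "mse")
    mean = {n: float(np.nanmean([f[n] for f in per_fold])) for n in names}
    std = {n: float(np.nanstd([f[n] for f in per_fold])) for n in names}
    pooled = compute_metrics(y, oof)

    out_idx, outlier_metrics = outlier_subset(y, oof, outlier_fraction)

    anti = _antisymmetry_pcc(records, oof)
    report = EvalReport(
        per_fold=per_fold,
        mean=mean,
        std=std,
        pooled=pooled,
        outlier=outlier_metrics,
        antisymmetry_pcc=anti,
        n_records=len(records),
        seed=fold_seed,
        train_config=asdict(train_config),
    )
    return report, oof


def _antisymmetry_pcc(
    records: Sequence[MutationRecord], preds: np.ndarray
) -> float | None:
    """Diagnostic: correlation between forward predictions and negated
    reverse predictions over forward/reverse pairs (None if unpaired)."""
    fwd = {}
    rev = {}
    for r, p in zip(records, preds):
        (rev if r.is_reverse else fwd)[r.site_key] = p
    common = sorted(set(fwd) & set(rev))
    if len(common) < 2:
        return None
    a = np.array([fwd[k] for k in common])
    b = np.array([-rev[k] for k in common])
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return None
    return float(stats.pearsonr(a, b)[0])


# ---------------------------------------------------------------------------
# independent evaluation


def evaluate_independent(
    model: DdgRegressor,
    test_records: Sequence[MutationRecord],
    channel_arrays: list[np.ndarray],
    train_complexes: set[str] | None = None,
    allow_overlap: bool = False,
) -> tuple[dict, list[dict]]:
    """Blind-test evaluation; returns (metrics, per-record prediction rows).

    If the training complexes are supplied, any overlap with the test set
    raises a leakage error unless explicitly allowed.
    """
    if train_complexes is not None and not allow_overlap:
        overlap = train_complexes & {r.complex_id for r in test_records}
        if overlap:
            raise LeakageError(
                f"complex(es) {sorted(overlap)} appear in both train and test; "
                f"pass allow_overlap=True to override"
            )
    preds = model.predict(channel_arrays)
    y = np.array([r.ddg for r in test_records])
    rows = [
        {
            "complex_id": r.complex_id,
            "chain": r.chain,
            "mutation": r.mutation_name,
            "is_reverse": r.is_reverse,
            "y_true": float(t),
            "y_pred": float(p),
        }
        for r, t, p in zip(test_records, y, preds)
    ]
    return compute_metrics(y, preds), rows


# ---------------------------------------------------------------------------
# outlier analysis


def outlier_subset(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    fraction: float = 0.10,
) -> tuple[np.ndarray, dict]:
    """Indices and metrics of the top ``fraction`` most extreme |ddG| records.

    Records are ranked by |y_true| descending; ceil(fraction * n) are taken,
    with ties at the cutoff broken by stable input order.
    """
    if not 0.0 < fraction < 1.0:
        raise ConfigurationError(f"fraction must be in (0, 1), got {fraction}")
    y_true = np.asarray(y_true, float)
    n = y_true.size
    if n == 0:
        return np.array([], dtype=int), {}
    m = math.ceil(fraction * n)
    order = np.argsort(-np.abs(y_true), kind="stable")
    idx = np.sort(order[:m])
    metrics = compute_metrics(y_true[idx], np.asarray(y_pred, float)[idx])
    metrics["n"] = int(m)
    return idx, metrics
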