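"""Training and evaluation pipeline.

Protocol: AdamW (β1=0.9, β2=0.999, ε=1e-8, weight decay 1e-4), constant
initial learning rate 0.001, batch size 12, augmentation probability 0.5,
hybrid CE+Dice main loss (λ1=0.4, λ2=0.6) plus the dynamically weighted
auxiliary disentanglement loss.  All randomness (split, shuffling,
augmentation) derives from one integer seed, so a run is bit-reproducible.
The checkpoint with the best validation foreground Dice is kept.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import autograd as ag
from .augment import augment, compute_stats, preprocess
from .dfm import dfm_loss
from .losses import LossWeights, combined_loss
from .metrics import MetricsReport, evaluate_cases
from .model import DCANet, ModelConfig, image_to_batch
from .nn import AdamW
from .phantoms import LabeledImage, load_dataset


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    epochs: int = 150
    batch_size: int = 12
    lr: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    weight_decay: float = 1e-4
    aug_prob: float = 0.5
    seed: int = 0
    lambda1: float = 0.4
    lambda2: float = 0.6
    dfm_weight: float = 1.0
    val_fraction: float = 0.1
    input_size: tuple | None = None   # None: native phantom size

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if not 0 <= self.aug_prob <= 1:
            raise ValueError("aug_prob must lie in [0, 1]")


@dataclasses.dataclass
class RunRecord:
    train_losses: list          # per-epoch mean total training loss
    main_losses: list           # per-epoch mean segmentation (CE+Dice) loss
    val_dice: list              # per-epoch validation foreground mean Dice
    best_epoch: int
    best_val_dice: float
    best_checkpoint: str | None
    config: dict
    seed: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def save_checkpoint(path, model: DCANet, epoch: int, seed: int,
                    stats=None) -> None:
    meta = json.dumps({"config": model.config.to_dict(), "epoch": epoch,
                       "seed": seed,
                       "stats": list(stats) if stats is not None else None})
    state = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.array(meta), **state)


def load_checkpoint(path) -> tuple:
    """Returns (model, meta) with weights restored and eval mode set."""
    archive = np.load(path, allow_pickle=False)
    meta = json.loads(str(archive["__meta__"]))
    model = DCANet(ModelConfig.from_dict(meta["config"]), seed=meta["seed"])
    model.load_state_dict({k[len("param/"):]: archive[k]
                           for k in archive.files if k.startswith("param/")})
    model.eval()
    return model, meta


def _make_batch(samples, stats, size, input_channels):
    imgs, labels = [], []
    for s in samples:
        img, lbl = preprocess(s, size, stats)
        imgs.append(image_to_batch(img, input_channels)[0])
        labels.append(lbl)
    return np.stack(imgs), np.stack(labels).astype(np.intp)


def foreground_mean_dice(model: DCANet, samples, stats, size) -> float:
    """Mean over foreground classes of the per-class mean Dice."""
    in_ch = model.config.encoder.input_channels
    model.eval()

    def predict(image):
        img, _ = preprocess(LabeledImage(image, np.zeros(image.shape[:2],
                                                         dtype=np.uint8),
                                         np.array([1.0])), size, stats)
        batch = image_to_batch(img, in_ch)
        return np.argmax(model(batch).logits.data, axis=1)[0]

    report = evaluate_cases(predict, samples, model.config.num_classes)
    return report.mean_dice


def split_dataset(samples, val_fraction: float, seed: int):
    """Deterministic train/val split: shuffle manifest order under the seed."""
    idx = np.random.default_rng(seed).permutation(len(samples))
    n_val = max(1, int(round(val_fraction * len(samples))))
    val_idx = set(idx[:n_val].tolist())
    train = [s for i, s in enumerate(samples) if i not in val_idx]
    val = [s for i, s in enumerate(samples) if i in val_idx]
    return train, val


def train(model_cfg: ModelConfig, train_cfg: TrainConfig, data_dir,
          out_dir=None, samples=None) -> RunRecord:
    """Train on a phantom dataset directory (or pre-loaded ``samples``)."""
    if samples is None:
        samples, _ = load_dataset(data_dir)
    train_samples, val_samples = split_dataset(samples, train_cfg.val_fraction,
                                               train_cfg.seed)
    size = train_cfg.input_size or train_samples[0].image.shape[:2]
    stats = compute_stats(train_samples)
    in_ch = model_cfg.encoder.input_channels

    model = DCANet(model_cfg, seed=train_cfg.seed)
    opt = AdamW(model.parameters(), lr=train_cfg.lr, beta1=train_cfg.beta1,
                beta2=train_cfg.beta2, eps=train_cfg.eps,
                weight_decay=train_cfg.weight_decay)
    weights = LossWeights(train_cfg.lambda1, train_cfg.lambda2)
    rng = np.random.default_rng(train_cfg.seed)

    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    train_losses, main_losses, val_dices = [], [], []
    best_epoch, best_dice, best_path = -1, -np.inf, None
    n = len(train_samples)
    for epoch in range(train_cfg.epochs):
        model.train()
        order = rng.permutation(n)
        epoch_losses, epoch_main = [], []
        for start in range(0, n, train_cfg.batch_size):
            chunk = [train_samples[i] for i in order[start:start + train_cfg.batch_size]]
            if train_cfg.aug_prob > 0:
                chunk = [augment(s, train_cfg.aug_prob, rng) for s in chunk]
            images, labels = _make_batch(chunk, stats, size, in_ch)
            out = model(images)
            main = combined_loss(out.logits, labels, weights).total
            loss = main
            if model_cfg.use_dfm and train_cfg.dfm_weight > 0:
                aux = dfm_loss(out.priors, labels, alpha=model_cfg.dfm_alpha,
                               lambda_bg=model_cfg.dfm_lambda_bg)
                loss = loss + train_cfg.dfm_weight * aux.total
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {start // train_cfg.batch_size}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
            epoch_main.append(main.item())
        train_losses.append(float(np.mean(epoch_losses)))
        main_losses.append(float(np.mean(epoch_main)))

        dice = foreground_mean_dice(model, val_samples, stats, size)
        val_dices.append(dice)
        if dice > best_dice:
            best_epoch, best_dice = epoch, dice
            if out_dir is not None:
                best_path = str(out_dir / "best_checkpoint.npz")
                save_checkpoint(best_path, model, epoch, train_cfg.seed,
                                stats=stats)

    record = RunRecord(
        train_losses=train_losses, main_losses=main_losses,
        val_dice=val_dices, best_epoch=best_epoch,
        best_val_dice=float(best_dice), best_checkpoint=best_path,
        config={"model": model_cfg.to_dict(),
                "train": dataclasses.asdict(train_cfg)},
        seed=train_cfg.seed,
    )
    if out_dir is not None:
        with open(out_dir / "run_record.json", "w") as fh:
            json.dump(record.to_dict(), fh, indent=1, default=_json_default)
    record.model = model          # convenience handle for in-process use
    record.stats = stats
    record.val_samples = val_samples
    return record


def _json_default(obj):
    if isinstance(obj, tuple):
        return list(obj)
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def evaluate_checkpoint(checkpoint_path, data_dir, stats=None) -> MetricsReport:
    """Deterministic evaluation of a saved model over a dataset directory."""
    model, meta = load_checkpoint(checkpoint_path)
    samples, manifest = load_dataset(data_dir)
    if manifest["num_fg_classes"] != model.config.num_classes:
        raise ValueError(
            f"checkpoint expects K={model.config.num_classes} classes, dataset "
            f"has K={manifest['num_fg_classes']}"
        )
    if stats is None:
        stats = meta.get("stats") or compute_stats(samples)
    size = samples[0].image.shape[:2]
    in_ch = model.config.encoder.input_channels

    def predict(image):
        img = (np.asarray(image, dtype=np.float64) - stats[0]) / stats[1]
        batch = image_to_batch(img, in_ch)
        return np.argmax(model(batch).logits.data, axis=1)[0]

    return evaluate_cases(predict, samples, model.config.num_classes)


def run_ablation(base_model_cfg: ModelConfig, base_train_cfg: TrainConfig,
                 data_dir, grid: list, samples=None):
    """Train/evaluate a list of variants on the same seeded data.

    ``grid`` entries are dicts with any of: ``flags`` (module toggles),
    ``alpha``, ``loss_weights`` (λ1, λ2 pair) and ``seed``.  Returns a
    pandas DataFrame with one row per variant (errors recorded per row).
    """
    import pandas as pd

    if not grid:
        raise ValueError("ablation grid is empty")
    if samples is None:
        samples, _ = load_dataset(data_dir)
    rows = []
    for entry in grid:
        row = {"flags": json.dumps(entry.get("flags", {})),
               "alpha": entry.get("alpha", base_model_cfg.dfm_alpha),
               "lambda1": entry.get("loss_weights",
                                    (base_train_cfg.lambda1,
                                     base_train_cfg.lambda2))[0],
               "lambda2": entry.get("loss_weights",
                                    (base_train_cfg.lambda1,
                                     base_train_cfg.lambda2))[1],
               "seed": entry.get("seed", base_train_cfg.seed)}
        try:
            flags = entry.get("flags", {})
            mcfg = dataclasses.replace(
                base_model_cfg,
                use_fcu=flags.get("use_fcu", base_model_cfg.use_fcu),
                use_dfm=flags.get("use_dfm", base_model_cfg.use_dfm),
                use_caia=flags.get("use_caia", base_model_cfg.use_caia),
                dfm_alpha=row["alpha"],
            )
            tcfg = dataclasses.replace(base_train_cfg, seed=row["seed"],
                                       lambda1=row["lambda1"],
                                       lambda2=row["lambda2"])
            record = train(mcfg, tcfg, data_dir, samples=samples)
            model, stats = record.model, record.stats
            size = base_train_cfg.input_size or samples[0].image.shape[:2]
            in_ch = mcfg.encoder.input_channels
            model.eval()

            def predict(image, _m=model, _s=stats, _c=in_ch):
                img = (np.asarray(image, dtype=np.float64) - _s[0]) / _s[1]
                return np.argmax(_m(image_to_batch(img, _c)).logits.data, axis=1)[0]

            report = evaluate_cases(predict, record.val_samples,
                                    mcfg.num_classes)
            row["params"] = model.num_parameters()
            row["mean_dice"] = report.mean_dice
            row["mean_iou"] = report.mean_iou
            row["mean_hd95"] = report.mean_hd95
            for c in range(1, mcfg.num_classes + 1):
                row[f"dice_{c}"] = float(report.per_class_dice[c - 1])
            row["error"] = ""
        except (ValueError, FloatingPointError) as err:
            row["error"] = str(err)
        rows.append(row)
    return pd.DataFrame(rows)
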