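"""Training and inference orchestration.

The end-to-end flow mirrors how the method is used on real smear data:
enhance the images once offline (AHE-Retinex), split image/mask pairs
9:1 into train and test, train the CBAM U-net with the combined
focal+Dice loss in two phases — the VGG16-style encoder frozen first,
then everything fine-tuned together — and evaluate the confusion-matrix
metric suite on the held-out split.

Defaults follow the study conditions: 9:1 split, batch size 2, Adam with
initial learning rate 1e-4, 50 frozen + 50 unfrozen epochs.  CPU-scale
experiments shrink the epochs and the model width, not the procedure.

Checkpoints are .npz weight archives with a JSON sidecar holding the
model configuration, so a checkpoint is self-describing.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import yaml
from skimage.transform import resize

from . import io, losses, metrics, nn, synthdata
from .attention_unet import CBAMUNet, ModelConfig, build_model, predict_mask
from .enhancement import RetinexConfig, ahe_retinex
from .losses import LossConfig, combined_loss_t

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "split_dataset",
    "train",
    "evaluate",
    "save_checkpoint",
    "load_checkpoint",
    "segment",
    "run_experiment",
]


@dataclass
class TrainConfig:
    split_ratio: float = 0.9          # train fraction
    batch_size: int = 2
    learning_rate: float = 1e-4
    frozen_epochs: int = 50
    unfrozen_epochs: int = 50
    seed: int = 0
    input_size: tuple = (512, 512)
    optimizer: str = "adam"
    enhancement_enabled: bool = True

    def __post_init__(self):
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must be a fraction in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer != "adam":
            raise ValueError(f"unknown optimizer '{self.optimizer}'")


@dataclass
class TrainHistory:
    """Per-epoch records: phase, mean training loss, validation metrics."""

    epochs: list = field(default_factory=list)

    def append(self, phase: str, train_loss: float, val_loss=None, val_miou=None):
        self.epochs.append({"phase": phase, "train_loss": train_loss,
                            "val_loss": val_loss, "val_miou": val_miou})

    def __len__(self):
        return len(self.epochs)


def split_dataset(items, ratio: float = 0.9, seed: int = 0):
    """Deterministic shuffled split into ceil(ratio*n) train / rest test."""
    items = list(items)
    if len(items) < 2:
        raise ValueError("need at least 2 items to split")
    order = np.random.default_rng(seed).permutation(len(items))
    n_train = int(math.ceil(ratio * len(items)))
    train_set = [items[i] for i in order[:n_train]]
    test_set = [items[i] for i in order[n_train:]]
    return train_set, test_set


def _prepare(pairs, input_size):
    """Resize to the network size and scale images to [0, 1], NCHW."""
    xs, ys = [], []
    for img, mask in pairs:
        img = np.asarray(img, dtype=np.float64)
        mask = np.asarray(mask)
        if img.shape[:2] != tuple(input_size):
            img = resize(img, (*input_size, 3), order=1, preserve_range=True,
                         anti_aliasing=True)
            mask = resize(mask, input_size, order=0, preserve_range=True,
                          anti_aliasing=False).astype(np.int64)
        xs.append(img.transpose(2, 0, 1) / 255.0)
        ys.append(mask.astype(np.int64))
    return np.stack(xs), np.stack(ys)


def evaluate(net: CBAMUNet, pairs, num_classes: int) -> dict:
    """Confusion-matrix metrics of a model over image/mask pairs."""
    cm = np.zeros((num_classes, num_classes), dtype=np.int64)
    for img, mask in pairs:
        pred = predict_mask(net, np.asarray(img, dtype=np.uint8))
        cm += metrics.confusion_matrix(pred, np.asarray(mask), num_classes)
    return {"confusion_matrix": cm, "miou": metrics.miou(cm),
            "accuracy": metrics.accuracy(cm)}


def train(cfg: TrainConfig, model_cfg: ModelConfig, loss_cfg: LossConfig,
          train_pairs, val_pairs=None, net: CBAMUNet | None = None):
    """Two-phase training; returns (net, TrainHistory).

    Phase 1 updates everything except the encoder (``frozen_epochs``);
    phase 2 fine-tunes all parameters (``unfrozen_epochs``).  Optimizer
    moment estimates persist across the phase boundary.  A NaN loss
    aborts with a diagnostic rather than training on.
    """
    if len(train_pairs) == 0:
        raise ValueError("training set is empty")
    for _, mask in train_pairs:
        m = np.asarray(mask)
        if m.min() < 0 or m.max() >= model_cfg.num_classes:
            raise ValueError(
                f"mask labels must lie in [0, {model_cfg.num_classes})")
    rng = np.random.default_rng(cfg.seed)
    if net is None:
        net = build_model(model_cfg, seed=cfg.seed)
    xs, ys = _prepare(train_pairs, cfg.input_size)

    enc_ids = {id(p) for p in net.encoder_parameters()}
    all_params = net.parameters()
    head_params = [p for p in all_params if id(p) not in enc_ids]
    opt = nn.Adam(head_params, lr=cfg.learning_rate)

    history = TrainHistory()
    n = len(train_pairs)
    steps = max(1, math.ceil(n / cfg.batch_size))
    for epoch in range(cfg.frozen_epochs + cfg.unfrozen_epochs):
        frozen = epoch < cfg.frozen_epochs
        opt.set_params(head_params if frozen else all_params)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for s in range(steps):
            idx = order[s * cfg.batch_size:(s + 1) * cfg.batch_size]
            if len(idx) == 0:
                continue
            probs = net(xs[idx])
            loss = combined_loss_t(probs, ys[idx], loss_cfg)
            val = loss.item()
            if not np.isfinite(val):
                raise RuntimeError(
                    f"non-finite loss {val} at epoch {epoch}, step {s}; "
                    "lower the learning rate or check the input masks")
            net.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += val
        val_loss = val_miou = None
        if val_pairs:
            ev = evaluate(net, val_pairs, model_cfg.num_classes)
            val_miou = ev["miou"]
        history.append("frozen" if frozen else "unfrozen", epoch_loss / steps,
                       val_loss, val_miou)
    return net, history


def save_checkpoint(path, net: CBAMUNet) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **net.state_dict())
    meta = asdict(net.cfg)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path) -> CBAMUNet:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    meta["input_size"] = tuple(meta["input_size"])
    if meta.get("decoder_channels") is not None:
        meta["decoder_channels"] = tuple(meta["decoder_channels"])
    cfg = ModelConfig(**meta)
    net = build_model(cfg, seed=0)
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as arc:
        net.load_state_dict({k: arc[k] for k in arc.files})
    return net


def segment(weights_path, img_path, out_path, palette=synthdata.DEFAULT_PALETTE,
            overlay_path=None) -> np.ndarray:
    """Segment one image file with a checkpoint; writes the indexed mask
    and (optionally) a blended overlay.  Returns the label mask."""
    net = load_checkpoint(weights_path)
    img = io.read_image(img_path)
    h, w = net.cfg.input_size
    net_in = img
    if img.shape[:2] != (h, w):
        net_in = np.clip(np.rint(resize(img.astype(float), (h, w, 3), order=1,
                                        preserve_range=True, anti_aliasing=True)),
                         0, 255).astype(np.uint8)
    mask = predict_mask(net, net_in)
    if mask.shape != img.shape[:2]:
        mask = resize(mask, img.shape[:2], order=0, preserve_range=True,
                      anti_aliasing=False).astype(np.int64)
    io.write_mask(out_path, mask, palette)
    if overlay_path is not None:
        colors = np.asarray(palette, dtype=np.float64)[mask]
        overlay = np.clip(0.55 * img + 0.45 * colors, 0, 255).astype(np.uint8)
        io.write_image(overlay_path, overlay)
    return mask


# -- experiment runner -----------------------------------------------------

_SCHEMA = {
    "seed": int,
    "out_dir": str,
    "data": dict,
    "enhancement": dict,
    "model": dict,
    "train": dict,
    "loss": dict,
}
_DATA_KEYS = {"n_images", "canvas_size", "n_cells", "noise_sigma", "rbc_density",
              "class_mix", "easy_task", "size"}
_LOSS_KEYS = {"type", "gamma", "dice_smooth", "combine_weights"}


def _check_keys(section: str, given: dict, allowed) -> None:
    unknown = set(given) - set(allowed)
    if unknown:
        raise ValueError(f"unknown config key(s) in '{section}': {sorted(unknown)}")


def run_experiment(config_file) -> dict:
    """Run enhance -> split -> train -> evaluate from a YAML/JSON config.

    Writes metrics.json, history.json, checkpoints and a log under the
    run directory and returns the metrics dict.
    """
    t0 = time.time()
    cfg_raw = yaml.safe_load(Path(config_file).read_text())
    _check_keys("top level", cfg_raw, _SCHEMA)
    seed = int(cfg_raw.get("seed", 0))
    out_dir = Path(cfg_raw.get("out_dir", "runs/run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines = []

    def log(msg):
        log_lines.append(msg)

    data_cfg = dict(cfg_raw.get("data", {}))
    _check_keys("data", data_cfg, _DATA_KEYS)
    enh_cfg = dict(cfg_raw.get("enhancement", {}))
    enh_keys = {"enabled"} | {f.name for f in
                              RetinexConfig.__dataclass_fields__.values()}
    _check_keys("enhancement", enh_cfg, enh_keys)
    model_kw = dict(cfg_raw.get("model", {}))
    _check_keys("model", model_kw, ModelConfig.__dataclass_fields__)
    train_kw = dict(cfg_raw.get("train", {}))
    _check_keys("train", train_kw, TrainConfig.__dataclass_fields__)
    loss_kw = dict(cfg_raw.get("loss", {}))
    _check_keys("loss", loss_kw, _LOSS_KEYS)
    loss_kw.pop("type", None)

    # -- data --------------------------------------------------------------
    if data_cfg.get("easy_task"):
        size = int(data_cfg.get("size", 64))
        pairs = synthdata.make_easy_task(int(data_cfg.get("n_images", 16)),
                                         size=size, seed=seed)
        num_classes_data = 4
    else:
        size = None
        n_images = int(data_cfg.get("n_images", 16))
        pairs = []
        for i in range(n_images):
            spec = synthdata.SyntheticSmearSpec(
                canvas_size=tuple(data_cfg.get("canvas_size", (128, 128))),
                n_cells=int(data_cfg.get("n_cells", 2)),
                noise_sigma=float(data_cfg.get("noise_sigma", 5.0)),
                rbc_density=float(data_cfg.get("rbc_density", 2.0e-4)),
                seed=seed * 100_003 + i,
            )
            pairs.append(synthdata.generate_smear(spec))
        num_classes_data = 6
    log(f"generated {len(pairs)} synthetic image/mask pairs")

    # -- enhancement (offline, before training) ----------------------------
    if enh_cfg.pop("enabled", True):
        rcfg_kw = {k: v for k, v in enh_cfg.items()}
        rcfg = RetinexConfig(**rcfg_kw) if rcfg_kw else RetinexConfig()
        pairs = [(ahe_retinex(img, rcfg), mask) for img, mask in pairs]
        log("applied AHE-Retinex enhancement")

    if "input_size" in train_kw:
        train_kw["input_size"] = tuple(train_kw["input_size"])
    tcfg = TrainConfig(seed=seed, **train_kw)
    model_kw.setdefault("num_classes", num_classes_data)
    model_kw.setdefault("input_size", tuple(tcfg.input_size))
    if "decoder_channels" in model_kw and model_kw["decoder_channels"] is not None:
        model_kw["decoder_channels"] = tuple(model_kw["decoder_channels"])
    model_kw["input_size"] = tuple(model_kw["input_size"])
    mcfg = ModelConfig(**model_kw)
    lcfg = LossConfig(**loss_kw)

    train_set, test_set = split_dataset(pairs, tcfg.split_ratio, seed)
    log(f"split: {len(train_set)} train / {len(test_set)} test")
    net, history = train(tcfg, mcfg, lcfg, train_set, val_pairs=test_set)

    best_epoch = max(range(len(history)),
                     key=lambda i: history.epochs[i]["val_miou"] or 0.0)
    save_checkpoint(out_dir / "last.npz", net)
    result = evaluate(net, test_set, mcfg.num_classes)
    report = metrics.report(result["confusion_matrix"],
                            class_names=None if mcfg.num_classes != 6
                            else list(synthdata.CLASS_NAMES))
    out = {
        "test_miou_pct": report.miou,
        "test_accuracy_pct": report.accuracy,
        "per_class": report.per_class,
        "best_epoch": best_epoch,
        "runtime_s": round(time.time() - t0, 2),
    }
    (out_dir / "metrics.json").write_text(json.dumps(out, indent=2))
    (out_dir / "history.json").write_text(json.dumps(history.epochs, indent=2))
    (out_dir / "log.txt").write_text("\n".join(log_lines) + "\n")
    return out
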