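"""Deterministic, resumable training: L1 loss + Adam (lr 1e-4, 0.9/0.999/1e-8).

The learning rate is constant (only the initial rate is part of the recipe);
checkpoints capture weights, optimizer moments and the sampler RNG state so a
resumed run reproduces the uninterrupted run bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .data import ImageGray, PatchPair, bicubic_resize
from .errors import ConfigError, IOPathError, ShapeError
from .metrics import EvalConvention, evaluate_pair
from .model import Model, ModelConfig, build_model, forward_tensor, mcrn_forward
from .nn import Tensor

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "Adam",
    "l1_loss",
    "train_model",
    "evaluate_model",
    "save_train_checkpoint",
    "load_train_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    batch_size: int = 16
    max_steps: int = 1000
    seed: int = 0
    loss: str = "L1"
    checkpoint_every: int = 0  # 0 disables periodic checkpoints
    val_fraction: float = 0.0

    def __post_init__(self):
        if self.lr < 0:
            raise ConfigError("lr must be >= 0")
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ConfigError("beta1/beta2 must lie in [0, 1)")
        if self.eps <= 0:
            raise ConfigError("eps must be > 0")
        if self.batch_size < 1 or self.max_steps < 0:
            raise ConfigError("batch_size must be >= 1 and max_steps >= 0")
        if self.loss != "L1":
            raise ConfigError(f"only the L1 loss is supported, got {self.loss!r}")
        if not (0 <= self.val_fraction < 1):
            raise ConfigError("val_fraction must lie in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainHistory:
    steps: list[int] = field(default_factory=list)
    losses: list[float] = field(default_factory=list)
    val_steps: list[int] = field(default_factory=list)
    val_reports: list[dict] = field(default_factory=list)

    def append(self, step: int, loss: float) -> None:
        if self.steps and step <= self.steps[-1]:
            raise ConfigError("history steps must be strictly increasing")
        self.steps.append(step)
        self.losses.append(loss)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("step,loss\n")
            for s, l in zip(self.steps, self.losses):
                fh.write(f"{s},{l:.10g}\n")


def l1_loss(pred, target) -> float:
    """Mean absolute difference between two equally-shaped batches."""
    a = pred.data if isinstance(pred, Tensor) else np.asarray(pred, dtype=np.float64)
    b = target.data if isinstance(target, Tensor) else np.asarray(target, dtype=np.float64)
    if a.shape != b.shape:
        raise ShapeError(f"l1_loss shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean(np.abs(a - b)))


class Adam:
    """Standard Adam with bias correction over a named parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            m = self.m[k]
            v = self.v[k]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for k in self.params:
            out[f"adam_m/{k}"] = self.m[k]
            out[f"adam_v/{k}"] = self.v[k]
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray], t: int) -> None:
        self.t = t
        for k in self.params:
            self.m[k] = np.array(arrays[f"adam_m/{k}"])
            self.v[k] = np.array(arrays[f"adam_v/{k}"])


class _PairSampler:
    """Epoch-shuffled batch sampler whose full state is serializable."""

    def __init__(self, n: int, batch: int, seed: int):
        self.n = n
        self.batch = batch
        self.rng = np.random.default_rng(seed)
        self.queue: list[int] = []

    def next_batch(self) -> list[int]:
        while len(self.queue) < self.batch:
            self.queue.extend(self.rng.permutation(self.n).tolist())
        out, self.queue = self.queue[: self.batch], self.queue[self.batch :]
        return out

    def state(self) -> dict:
        return {"rng": self.rng.bit_generator.state, "queue": list(self.queue)}

    def load_state(self, st: dict) -> None:
        self.rng.bit_generator.state = st["rng"]
        self.queue = [int(i) for i in st["queue"]]


def _stack_pairs(pairs: Sequence[PatchPair], idx: Sequence[int], dtype=np.float64):
    lr = np.stack([pairs[i].lr.pixels for i in idx])[:, None, :, :]
    hr = np.stack([pairs[i].hr.pixels for i in idx])[:, None, :, :]
    return Tensor(lr.astype(dtype)), Tensor(hr.astype(dtype))


def save_train_checkpoint(
    path: str | Path, model: Model, opt: Adam, sampler: _PairSampler,
    cfg: TrainConfig, step: int,
) -> None:
    arrays = {f"param/{k}": t.data for k, t in model.parameters().items()}
    arrays.update(opt.state_arrays())
    meta = {
        "config": model.config.to_dict(),
        "train_config": cfg.to_dict(),
        "step": step,
        "sampler": sampler.state(),
    }
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode("utf-8"), dtype=np.uint8)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_train_checkpoint(path: str | Path):
    """Return (model, meta, raw_arrays) for resuming."""
    path = Path(path)
    if not path.exists():
        raise IOPathError(f"no such checkpoint: {path}")
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode("utf-8"))
        model = build_model(ModelConfig.from_dict(meta["config"]), seed=0)
        params = model.parameters()
        for k, t in params.items():
            t.data = z[f"param/{k}"].copy()
        arrays = {k: z[k].copy() for k in z.files if k.startswith(("adam_m/", "adam_v/"))}
    return model, meta, arrays


def train_model(
    model: Model,
    pairs: Sequence[PatchPair],
    cfg: TrainConfig,
    out_dir: str | Path | None = None,
    resume_from: str | Path | None = None,
    log_fn=None,
) -> tuple[Model, TrainHistory]:
    """Optimize the model on LR/HR patch pairs.

    Deterministic given ``cfg.seed``; resuming from a checkpoint written by
    this function reproduces the uninterrupted run exactly.
    """
    if not pairs:
        raise ConfigError("train_model needs at least one patch pair")
    scales = {p.scale for p in pairs}
    if scales != {model.config.scale}:
        raise ConfigError(
            f"pair scales {sorted(scales)} do not match model scale {model.config.scale}"
        )
    sizes = {(p.lr.height, p.lr.width) for p in pairs}
    if len(sizes) != 1:
        raise ConfigError(f"all patch pairs must share one LR size, got {sizes}")

    val_pairs: list[PatchPair] = []
    if cfg.val_fraction > 0:
        split_rng = np.random.default_rng([cfg.seed, 17])
        order = split_rng.permutation(len(pairs))
        n_val = max(1, int(round(cfg.val_fraction * len(pairs))))
        if n_val >= len(pairs):
            raise ConfigError("val_fraction leaves no training pairs")
        val_idx = set(order[:n_val].tolist())
        val_pairs = [pairs[i] for i in sorted(val_idx)]
        pairs = [p for i, p in enumerate(pairs) if i not in val_idx]

    params = model.parameters()
    opt = Adam(params, cfg.lr, cfg.beta1, cfg.beta2, cfg.eps)
    sampler = _PairSampler(len(pairs), cfg.batch_size, cfg.seed)
    start_step = 0
    if resume_from is not None:
        resumed_model, meta, arrays = load_train_checkpoint(resume_from)
        if resumed_model.config != model.config:
            raise ConfigError("checkpoint model config does not match")
        for k, t in params.items():
            t.data = resumed_model.parameters()[k].data
        start_step = int(meta["step"])
        opt.load_state_arrays(arrays, t=start_step)
        sampler.load_state(meta["sampler"])

    history = TrainHistory()
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    for step in range(start_step + 1, cfg.max_steps + 1):
        idx = sampler.next_batch()
        x, y = _stack_pairs(pairs, idx, dtype=model.dtype)
        model.zero_grad()
        pred = forward_tensor(x, model)
        loss = nn.l1_mean(pred, y)
        loss.backward()
        opt.step()
        history.append(step, float(loss.data))
        if log_fn is not None:
            log_fn(step, float(loss.data))
        if cfg.checkpoint_every and step % cfg.checkpoint_every == 0:
            if val_pairs:
                vx, vy = _stack_pairs(val_pairs, range(len(val_pairs)), model.dtype)
                vloss = l1_loss(forward_tensor(vx, model), vy)
                history.val_steps.append(step)
                history.val_reports.append({"l1": vloss})
            if out_dir is not None:
                save_train_checkpoint(
                    out_dir / f"step{step:06d}.npz", model, opt, sampler, cfg, step
                )
    if out_dir is not None:
        save_train_checkpoint(out_dir / "last.npz", model, opt, sampler, cfg,
                              max(cfg.max_steps, start_step))
        history.to_csv(out_dir / "history.csv")
    return model, history


def evaluate_model(
    model: Model,
    hr_images: Sequence[ImageGray],
    conv: EvalConvention | None = None,
) -> dict:
    """Degrade each HR image, super-resolve, and score against the original.

    The bicubic-upsampled baseline is scored side by side.  Returns per-image
    reports and corpus means for both routes.
    """
    gamma = model.config.scale
    if conv is None:
        conv = EvalConvention(border_shave=gamma)
    per_image = []
    for img in hr_images:
        h = (img.height // gamma) * gamma
        w = (img.width // gamma) * gamma
        if h < 8 * gamma or w < 8 * gamma:
            raise ShapeError(f"image {img.height}x{img.width} too small for scale {gamma}")
        hr = ImageGray(img.pixels[:h, :w], img.source_depth)
        lr = bicubic_resize(hr, 1.0 / gamma)
        sr = mcrn_forward(lr, model)
        baseline = bicubic_resize(lr, float(gamma))
        per_image.append(
            {
                "model": evaluate_pair(hr, sr, conv).to_dict(),
                "bicubic": evaluate_pair(hr, baseline, conv).to_dict(),
            }
        )
    corpus = {}
    for route in ("model", "bicubic"):
        corpus[route] = {
            key: float(np.mean([r[route][key] for r in per_image]))
            for key in ("psnr_db", "ssim", "entropy_bits", "avg_gradient")
        }
    return {"corpus": corpus, "per_image": per_image}
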