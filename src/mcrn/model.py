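"""Multichannel residual attention super-resolution network.

Assembly: initial 3x3 feature extraction -> multichannel dilated residual
block -> n alternating up/down back-projection stages with dense cascading
and error feedback -> residual attention module (3 blocks + long skip) on the
reduced LR-grid cascade -> subpixel reconstruction to the target scale.

The back-projection stages keep two feature histories: ``L`` maps on the
input (LR) grid and ``H`` maps on the ``s``-times finer grid.  Reconstruction
consumes the reduced concatenation of the down-block outputs (LR grid) and
performs the single upsampling of the network via pixel shuffle, matching the
layer geometry table of the reference architecture.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .data import ImageGray
from .errors import ConfigError, IOPathError, ShapeError
from .nn import Tensor

__all__ = [
    "ScaleSpec",
    "ModelConfig",
    "StageCache",
    "BlockWeights",
    "RabWeights",
    "ReconstructionWeights",
    "Model",
    "build_model",
    "init_features",
    "dilated_multichannel_block",
    "channel_attention",
    "residual_attention_block",
    "residual_attention_module",
    "up_block",
    "down_block",
    "reconstruct",
    "forward_tensor",
    "mcrn_forward",
    "save_checkpoint",
    "load_checkpoint",
]

# deconv/conv geometry per scale factor: kernel, stride, pad with
# (kernel - 2*pad) == stride so the pair is an exact x s up/down map
_SCALE_GEOMETRY = {2: (4, 2, 1), 3: (7, 3, 2), 4: (8, 4, 2)}


@dataclass(frozen=True)
class ScaleSpec:
    """Up/down-sampling geometry for one integer scale factor."""

    s: int
    kernel: int
    stride: int
    pad: int

    def __post_init__(self):
        if self.s not in (2, 3, 4):
            raise ConfigError(f"scale factor must be one of 2, 3, 4; got {self.s}")
        if self.kernel - 2 * self.pad != self.stride or self.stride != self.s:
            raise ConfigError(
                f"inconsistent scale geometry k={self.kernel} s={self.stride} "
                f"p={self.pad}: need kernel - 2*pad == stride == scale"
            )

    @classmethod
    def for_scale(cls, s: int) -> "ScaleSpec":
        if s not in _SCALE_GEOMETRY:
            raise ConfigError(f"scale factor must be one of 2, 3, 4; got {s}")
        k, st, p = _SCALE_GEOMETRY[s]
        return cls(s=s, kernel=k, stride=st, pad=p)


@dataclass(frozen=True)
class ModelConfig:
    """All architecture hyperparameters."""

    base_channels: int = 64
    n_ud_stages: int = 3
    n_rab: int = 3
    dilation_rates: tuple[int, ...] = (1, 3, 5)
    scale: int = 2

    def __post_init__(self):
        if self.scale not in (2, 3, 4):
            raise ConfigError(f"scale factor must be one of 2, 3, 4; got {self.scale}")
        if self.n_ud_stages < 1:
            raise ConfigError("n_ud_stages must be >= 1")
        if self.n_rab < 1:
            raise ConfigError("n_rab must be >= 1")
        rates = tuple(self.dilation_rates)
        if any(b <= a for a, b in zip(rates, rates[1:])):
            raise ConfigError(f"dilation_rates must be strictly increasing: {rates}")
        if self.base_channels < 1:
            raise ConfigError("base_channels must be >= 1")
        object.__setattr__(self, "dilation_rates", rates)

    @property
    def attention_channels(self) -> int:
        """Squeeze bottleneck width: base_channels / 16 (floored at 1)."""
        return max(self.base_channels // 16, 1)

    @property
    def scale_spec(self) -> ScaleSpec:
        return ScaleSpec.for_scale(self.scale)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dilation_rates"] = list(self.dilation_rates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "dilation_rates" in d:
            d["dilation_rates"] = tuple(d["dilation_rates"])
        return cls(**d)


@dataclass
class StageCache:
    """Feature histories and per-stage intermediates of the back-projection loop.

    ``L_history[0]`` is the seed feature map from the dilated block; entries
    ``1..n`` are down-block outputs.  ``H_history`` holds the n up-block
    outputs on the fine grid.
    """

    L_history: list[Tensor] = field(default_factory=list)
    H_history: list[Tensor] = field(default_factory=list)
    intermediates: list[dict] = field(default_factory=list)

    @property
    def n_stages(self) -> int:
        return len(self.H_history)


@dataclass
class ConvWeights:
    w: Tensor
    b: Tensor
    alpha: Tensor | None = None  # PReLU slope; None => linear layer


@dataclass
class BlockWeights:
    """Weights of one up/down back-projection stage.

    ``p`` (deconv) and ``g`` (conv) are shared between the up-block and the
    down-block of the stage; ``reduce_1x1`` fuses the L-history for the
    up-block and ``k`` fuses the H-history for the down-block.
    """

    reduce_1x1: ConvWeights
    p: ConvWeights
    g: ConvWeights
    q: ConvWeights
    k: ConvWeights


@dataclass
class RabWeights:
    conv: ConvWeights
    att_down: ConvWeights  # 1x1, C -> C/16
    att_up: ConvWeights    # 1x1, C/16 -> C


@dataclass
class ReconstructionWeights:
    pre: ConvWeights   # 3x3, C -> gamma^2 * C, activated
    post: ConvWeights  # 3x3, C -> 1, linear


@dataclass
class Model:
    config: ModelConfig
    init: ConvWeights
    dil_branches: list[ConvWeights]
    dil_fuse: ConvWeights
    stages: list[BlockWeights]
    cascade_reduce: ConvWeights
    rabs: list[RabWeights]
    ra_tail: ConvWeights
    recon: ReconstructionWeights

    def parameters(self) -> dict[str, Tensor]:
        """Every learnable tensor, keyed by a stable dotted name."""
        params: dict[str, Tensor] = {}

        def put(prefix: str, cw: ConvWeights):
            params[f"{prefix}.w"] = cw.w
            params[f"{prefix}.b"] = cw.b
            if cw.alpha is not None:
                params[f"{prefix}.alpha"] = cw.alpha

        put("init", self.init)
        for rate, cw in zip(self.config.dilation_rates, self.dil_branches):
            put(f"dil.branch{rate}", cw)
        put("dil.fuse", self.dil_fuse)
        for n, st in enumerate(self.stages, start=1):
            put(f"stage{n}.reduce", st.reduce_1x1)
            put(f"stage{n}.p", st.p)
            put(f"stage{n}.g", st.g)
            put(f"stage{n}.q", st.q)
            put(f"stage{n}.k", st.k)
        put("cascade", self.cascade_reduce)
        for i, rab in enumerate(self.rabs, start=1):
            put(f"rab{i}.conv", rab.conv)
            put(f"rab{i}.att_down", rab.att_down)
            put(f"rab{i}.att_up", rab.att_up)
        put("ra_tail", self.ra_tail)
        put("recon.pre", self.recon.pre)
        put("recon.post", self.recon.post)
        return params

    def zero_grad(self) -> None:
        for t in self.parameters().values():
            t.zero_grad()

    def astype(self, dtype) -> "Model":
        """Cast all weights in place (float32 for speed, float64 for accuracy)."""
        for t in self.parameters().values():
            t.data = t.data.astype(dtype)
        return self

    @property
    def dtype(self):
        return self.init.w.data.dtype


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def _he_conv(rng, out_ch, in_ch, k, activated=True) -> ConvWeights:
    fan_in = in_ch * k * k
    w = rng.standard_normal((out_ch, in_ch, k, k)) * np.sqrt(2.0 / fan_in)
    cw = ConvWeights(
        w=Tensor(w, requires_grad=True),
        b=Tensor(np.zeros(out_ch), requires_grad=True),
        alpha=Tensor(np.full(out_ch, 0.25), requires_grad=True) if activated else None,
    )
    return cw


def _he_deconv(rng, in_ch, out_ch, k, activated=True) -> ConvWeights:
    # transposed-conv weight layout is (C_in, C_out, k, k)
    fan_in = in_ch * k * k
    w = rng.standard_normal((in_ch, out_ch, k, k)) * np.sqrt(2.0 / fan_in)
    return ConvWeights(
        w=Tensor(w, requires_grad=True),
        b=Tensor(np.zeros(out_ch), requires_grad=True),
        alpha=Tensor(np.full(out_ch, 0.25), requires_grad=True) if activated else None,
    )


def build_model(config: ModelConfig, seed: int = 0) -> Model:
    """Allocate all weights with seeded variance-scaling init (biases zero)."""
    rng = np.random.default_rng(seed)
    c = config.base_channels
    ca = config.attention_channels
    k = config.scale_spec.kernel

    init = _he_conv(rng, c, 1, 3)
    dil_branches = [_he_conv(rng, c, c, 3, activated=False) for _ in config.dilation_rates]
    dil_fuse = _he_conv(rng, c, c * len(config.dilation_rates), 1)

    stages = []
    for n in range(1, config.n_ud_stages + 1):
        stages.append(
            BlockWeights(
                reduce_1x1=_he_conv(rng, c, n * c, 1),
                p=_he_deconv(rng, c, c, k),
                g=_he_conv(rng, c, c, k),
                q=_he_deconv(rng, c, c, k),
                k=_he_conv(rng, c, n * c, 1),
            )
        )
    cascade_reduce = _he_conv(rng, c, config.n_ud_stages * c, 1)
    rabs = [
        RabWeights(
            conv=_he_conv(rng, c, c, 3),
            att_down=_he_conv(rng, ca, c, 1, activated=False),
            att_up=_he_conv(rng, c, ca, 1, activated=False),
        )
        for _ in range(config.n_rab)
    ]
    ra_tail = _he_conv(rng, c, c, 3, activated=False)
    gamma = config.scale
    recon = ReconstructionWeights(
        pre=_he_conv(rng, gamma * gamma * c, c, 3),
        post=_he_conv(rng, 1, c, 3, activated=False),
    )
    return Model(
        config=config,
        init=init,
        dil_branches=dil_branches,
        dil_fuse=dil_fuse,
        stages=stages,
        cascade_reduce=cascade_reduce,
        rabs=rabs,
        ra_tail=ra_tail,
        recon=recon,
    )


# ---------------------------------------------------------------------------
# block operations
# ---------------------------------------------------------------------------

def _conv(x: Tensor, cw: ConvWeights, stride=1, pad=0, dilation=1) -> Tensor:
    y = nn.conv2d(x, cw.w, cw.b, stride=stride, pad=pad, dilation=dilation)
    if cw.alpha is not None:
        y = nn.prelu(y, cw.alpha)
    return y


def _deconv(x: Tensor, cw: ConvWeights, stride, pad) -> Tensor:
    y = nn.conv_transpose2d(x, cw.w, cw.b, stride=stride, pad=pad)
    if cw.alpha is not None:
        y = nn.prelu(y, cw.alpha)
    return y


def init_features(x: Tensor, cw: ConvWeights) -> Tensor:
    """Initial 3x3 feature extraction, 1 -> base channels, spatial dims kept."""
    if x.data.ndim != 4 or x.data.shape[1] != 1:
        raise ShapeError(f"init_features expects (N,1,H,W), got {x.data.shape}")
    return _conv(x, cw, pad=1)


def dilated_multichannel_block(
    x: Tensor, branches: list[ConvWeights], fuse: ConvWeights,
    rates: tuple[int, ...] = (1, 3, 5),
) -> Tensor:
    """Parallel dilated 3x3 branches, concat, 1x1 fuse + activation, residual add."""
    outs = [
        _conv(x, cw, pad=rate, dilation=rate) for cw, rate in zip(branches, rates)
    ]
    fused = _conv(nn.concat(outs, axis=1), fuse)
    return nn.add(fused, x)


def channel_attention(x: Tensor, down: ConvWeights, up: ConvWeights) -> Tensor:
    """Squeeze-excite gate: GAP -> 1x1 reduce -> ReLU -> 1x1 expand -> sigmoid -> scale."""
    z = nn.global_avg_pool(x)
    z = nn.relu(nn.conv2d(z, down.w, down.b))
    gate = nn.sigmoid(nn.conv2d(z, up.w, up.b))
    return nn.mul(x, gate)


def residual_attention_block(x: Tensor, w: RabWeights) -> Tensor:
    """3x3 conv + activation -> channel attention -> short skip."""
    y = _conv(x, w.conv, pad=1)
    y = channel_attention(y, w.att_down, w.att_up)
    return nn.add(y, x)


def residual_attention_module(
    x: Tensor, rabs: list[RabWeights], tail: ConvWeights
) -> Tensor:
    """Chain of residual attention blocks, a linear 3x3 tail conv, long skip.

    The tail conv makes the whole module an exact identity when its weights
    are zero (nested residual identity) and matches the table's middle layer.
    """
    y = x
    for w in rabs:
        y = residual_attention_block(y, w)
    y = _conv(y, tail, pad=1)
    return nn.add(y, x)


def _check_history(history: list[Tensor], what: str) -> None:
    if not history:
        raise ShapeError(f"{what} history is empty")
    dims = {t.data.shape[2:] for t in history}
    if len(dims) != 1:
        raise ShapeError(f"{what} history has mismatched spatial dims: {dims}")


def up_block(cache: StageCache, w: BlockWeights, spec: ScaleSpec) -> Tensor:
    """One up-projection with error feedback; appends H^n to the cache.

    concat(L history) -> 1x1 reduce -> L'; H0 = deconv_p(L'); L0 = conv_g(H0);
    e_l = L0 - L'; H1 = deconv_q(e_l); H = H0 + H1.
    """
    _check_history(cache.L_history, "L")
    lcat = nn.concat(cache.L_history, axis=1)
    l_prev = _conv(lcat, w.reduce_1x1)
    h0 = _deconv(l_prev, w.p, spec.stride, spec.pad)
    l0 = _conv(h0, w.g, stride=spec.stride, pad=spec.pad)
    e_l = nn.sub(l0, l_prev)
    h1 = _deconv(e_l, w.q, spec.stride, spec.pad)
    h = nn.add(h0, h1)
    cache.H_history.append(h)
    cache.intermediates.append(
        {"L_prev": l_prev, "H0": h0, "L0": l0, "e_l": e_l, "H1": h1}
    )
    return h


def down_block(cache: StageCache, w: BlockWeights, spec: ScaleSpec) -> Tensor:
    """One down-projection with error feedback; appends L^n to the cache.

    concat(H history) -> 1x1 fuse (k) -> H'; L1 = conv_g(H'); H3 = deconv_p(L1);
    e_h = H3 - H'; L2 = conv_g(e_h); L = L1 + L2.
    """
    _check_history(cache.H_history, "H")
    hcat = nn.concat(cache.H_history, axis=1)
    h2 = _conv(hcat, w.k)
    l1 = _conv(h2, w.g, stride=spec.stride, pad=spec.pad)
    h3 = _deconv(l1, w.p, spec.stride, spec.pad)
    e_h = nn.sub(h3, h2)
    l2 = _conv(e_h, w.g, stride=spec.stride, pad=spec.pad)
    l_out = nn.add(l1, l2)
    cache.L_history.append(l_out)
    if not cache.intermediates:
        cache.intermediates.append({})
    cache.intermediates[-1].update(
        {"H2": h2, "L1": l1, "H3": h3, "e_h": e_h, "L2": l2}
    )
    return l_out


def reconstruct(t: Tensor, w: ReconstructionWeights, gamma: int) -> Tensor:
    """3x3 conv -> pixel shuffle by gamma -> linear 3x3 conv to one channel."""
    y = _conv(t, w.pre, pad=1)
    if y.data.shape[1] % (gamma * gamma):
        raise ShapeError(
            f"reconstruct: {y.data.shape[1]} channels not divisible by gamma^2"
        )
    y = nn.pixel_shuffle(y, gamma)
    return _conv(y, w.post, pad=1)


# ---------------------------------------------------------------------------
# full forward pass
# ---------------------------------------------------------------------------

def forward_tensor(x: Tensor, model: Model, cache_out: StageCache | None = None) -> Tensor:
    """Run the network on a batch (N,1,H,W); output is (N,1,sH,sW), unclipped."""
    cfg = model.config
    spec = cfg.scale_spec
    f = init_features(x, model.init)
    f = dilated_multichannel_block(
        f, model.dil_branches, model.dil_fuse, cfg.dilation_rates
    )
    cache = cache_out if cache_out is not None else StageCache()
    cache.L_history.append(f)
    for w in model.stages:
        up_block(cache, w, spec)
        down_block(cache, w, spec)
    # dense cascade of the down-block outputs (LR grid), reduced to base width
    t = _conv(nn.concat(cache.L_history[1:], axis=1), model.cascade_reduce)
    t = residual_attention_module(t, model.rabs, model.ra_tail)
    return reconstruct(t, model.recon, cfg.scale)


def mcrn_forward(lr: ImageGray, model: Model) -> ImageGray:
    """Super-resolve one LR image; output clipped to [0,1] at export."""
    if lr.height < 8 or lr.width < 8:
        raise ShapeError(f"input must be at least 8x8, got {lr.height}x{lr.width}")
    x = Tensor(lr.pixels[None, None, :, :])
    y = forward_tensor(x, model)
    return ImageGray(np.clip(y.data[0, 0], 0.0, 1.0), source_depth=lr.source_depth)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: Model, path: str | Path, extra: dict | None = None) -> None:
    """Write a single .npz archive holding the config JSON and all weights."""
    arrays = {f"param/{k}": t.data for k, t in model.parameters().items()}
    meta = {"config": model.config.to_dict(), "extra": extra or {}}
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(
    path: str | Path, expect_config: ModelConfig | None = None
) -> tuple[Model, dict]:
    """Rebuild a model from a checkpoint; mismatched configs are an error."""
    path = Path(path)
    if not path.exists():
        raise IOPathError(f"no such checkpoint: {path}")
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode("utf-8"))
        config = ModelConfig.from_dict(meta["config"])
        if expect_config is not None and expect_config != config:
            raise ConfigError(
                f"checkpoint config {config} does not match expected {expect_config}"
            )
        model = build_model(config, seed=0)
        params = model.parameters()
        stored = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
        if set(stored) != set(params):
            missing = set(params) ^ set(stored)
            raise ConfigError(f"checkpoint parameter names mismatch: {sorted(missing)}")
        for k, t in params.items():
            if t.data.shape != stored[k].shape:
                raise ConfigError(
                    f"checkpoint shape mismatch for {k}: "
                    f"{stored[k].shape} vs {t.data.shape}"
                )
            t.data = stored[k].astype(np.float64)
    return model, meta.get("extra", {})
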