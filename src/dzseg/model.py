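"""The segmentation network: ViT encoder, LoRA-adapted attention, All-MLP decoder.

Architecture, in the order a frame flows through it:

1. The prompted RGB frame is split into non-overlapping p x p patches, each
   linearly embedded to a D-dimensional token; a learned class token is
   prepended and learned positional embeddings are added (standard ViT).
2. M pre-norm transformer blocks.  Attention queries and values carry
   low-rank adapters: Q = W_q x + s * B_q A_q x (same for V), with the base
   projections frozen and only the rank-r A/B matrices trainable.  B starts
   at zero, so the adapted network is functionally identical to the frozen
   base at step 0.
3. At each selected block ("stage") the class token is broadcast to every
   spatial position and channel-concatenated with the patch-token grid
   (sqrt(N) x sqrt(N) x 2D), then bilinearly upsampled x4.
4. The decoder is an All-MLP head: a per-position linear layer aligns each
   stage to a common width C, the stages are channel-concatenated, a second
   linear layer fuses n*C -> C (with a GELU), and a third maps C to the
   per-class logits, which are bilinearly resized to the output resolution.

All bilinear resampling uses the align-corners-false convention, fixed
project-wide.  Per-head attention scaling is 1/sqrt(D/num_heads).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._autodiff import Parameter, Tensor
from .errors import ConfigError, ShapeError

__all__ = [
    "EncoderConfig", "LoRAConfig", "DecoderConfig", "TokenSequence",
    "SegmentationModel", "build_model", "count_trainable_parameters",
    "save_checkpoint", "load_checkpoint",
    "bilinear_matrix", "resize_bilinear", "resize_nearest",
    "IMAGENET_MEAN", "IMAGENET_STD", "normalize_image",
]

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_STD = np.array([0.229, 0.224, 0.225])


# ---------------------------------------------------------------------------
# configs


@dataclass
class EncoderConfig:
    """ViT encoder hyperparameters.

    The full-scale preset mirrors ViT-Base/14 at 532 px input with stages
    collected after blocks 3, 6, 9 and 12 (1-based).
    """

    patch_size: int = 14
    embed_dim: int = 768
    num_blocks: int = 12
    num_heads: int = 12
    selected_stages: tuple[int, ...] = (3, 6, 9, 12)
    input_size: int = 532

    def validate(self) -> None:
        if self.input_size % self.patch_size != 0:
            raise ConfigError(
                f"input_size {self.input_size} is not divisible by patch_size {self.patch_size}")
        if self.embed_dim % self.num_heads != 0:
            raise ConfigError(
                f"embed_dim {self.embed_dim} is not divisible by num_heads {self.num_heads}")
        if not self.selected_stages:
            raise ConfigError("selected_stages must be non-empty")
        for m in self.selected_stages:
            if not 1 <= m <= self.num_blocks:
                raise ConfigError(
                    f"selected stage {m} outside [1, {self.num_blocks}]")

    @property
    def grid_side(self) -> int:
        return self.input_size // self.patch_size

    @property
    def num_patches(self) -> int:
        return self.grid_side ** 2


@dataclass
class LoRAConfig:
    """Low-rank adaptation knobs; rank 0 disables adaptation entirely."""

    rank: int = 4
    targets: tuple[str, ...] = ("query", "value")
    a_init_scale: float = 0.02
    scaling_factor: float = 1.0

    def validate(self) -> None:
        if self.rank < 0:
            raise ConfigError(f"rank must be >= 0, got {self.rank}")
        if self.rank > 0 and not self.targets:
            raise ConfigError("targets must be non-empty when rank > 0")
        bad = set(self.targets) - {"query", "value"}
        if bad:
            raise ConfigError(f"unsupported LoRA targets {sorted(bad)}")


@dataclass
class DecoderConfig:
    """All-MLP decoder knobs."""

    common_dim: int = 256
    num_stages: int = 4
    num_classes: int = 2

    def validate(self) -> None:
        if self.num_classes < 2:
            raise ConfigError(f"num_classes must be >= 2, got {self.num_classes}")
        if self.num_stages < 1:
            raise ConfigError("num_stages must be >= 1")


TINY_PRESET = dict(
    enc=dict(patch_size=8, embed_dim=32, num_blocks=2, num_heads=4,
             selected_stages=(1, 2), input_size=64),
    dec=dict(common_dim=32, num_stages=2, num_classes=2),
)


# ---------------------------------------------------------------------------
# resampling helpers (align-corners-false bilinear, expressed as matrices)


def bilinear_matrix(n_out: int, n_in: int) -> np.ndarray:
    """(n_out, n_in) row-stochastic matrix for 1-D bilinear resampling."""
    w = np.zeros((n_out, n_in))
    if n_in == 1:
        w[:, 0] = 1.0
        return w
    scale = n_in / n_out
    src = (np.arange(n_out) + 0.5) * scale - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    w[np.arange(n_out), lo] += 1.0 - frac
    w[np.arange(n_out), hi] += frac
    return w


def resize_bilinear(image: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Bilinear resize of an (H, W[, C]) array; returns float64."""
    wr = bilinear_matrix(size[0], image.shape[0])
    wc = bilinear_matrix(size[1], image.shape[1])
    x = np.asarray(image, dtype=np.float64)
    if x.ndim == 2:
        return wr @ x @ wc.T
    return np.einsum("ih,jw,hwc->ijc", wr, wc, x, optimize=True)


def resize_nearest(mask: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resize; preserves the label set exactly."""
    rows = np.minimum((np.arange(size[0]) + 0.5) * mask.shape[0] / size[0],
                      mask.shape[0] - 1).astype(int)
    cols = np.minimum((np.arange(size[1]) + 0.5) * mask.shape[1] / size[1],
                      mask.shape[1] - 1).astype(int)
    return mask[np.ix_(rows, cols)]


def normalize_image(image: np.ndarray) -> np.ndarray:
    """8-bit RGB -> float64, scaled to [0,1] then channel-standardized."""
    x = np.asarray(image, dtype=np.float64) / 255.0
    return (x - IMAGENET_MEAN) / IMAGENET_STD


# ---------------------------------------------------------------------------
# network modules


@dataclass
class TokenSequence:
    """Class token + N patch tokens as one (B, N+1, D) tensor."""

    tokens: Tensor

    @property
    def class_token(self) -> Tensor:
        return self.tokens[:, 0:1, :]

    @property
    def patch_tokens(self) -> Tensor:
        return self.tokens[:, 1:, :]

    @property
    def num_patches(self) -> int:
        return self.tokens.shape[1] - 1


class _Linear:
    """y = x @ W + b with an optional LoRA adapter on top."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 trainable: bool, lora_rank: int = 0,
                 lora_scale: float = 1.0, lora_a_scale: float = 0.02,
                 lora_rng: np.random.Generator | None = None):
        self.weight = Parameter(rng.normal(0.0, 0.02, (d_in, d_out)),
                                requires_grad=trainable)
        self.bias = Parameter(np.zeros(d_out), requires_grad=trainable)
        self.lora_scale = lora_scale
        if lora_rank > 0:
            # adapters draw from their own stream so the base initialization
            # is bit-identical whether or not adaptation is enabled
            a_rng = lora_rng if lora_rng is not None else rng
            self.lora_a = Parameter(a_rng.normal(0.0, lora_a_scale, (d_in, lora_rank)))
            self.lora_b = Parameter(np.zeros((lora_rank, d_out)))
        else:
            self.lora_a = self.lora_b = None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight + self.bias
        if self.lora_a is not None:
            y = y + ((x @ self.lora_a) @ self.lora_b) * self.lora_scale
        return y

    def params(self, prefix: str) -> dict[str, Parameter]:
        out = {f"{prefix}.weight": self.weight, f"{prefix}.bias": self.bias}
        if self.lora_a is not None:
            out[f"{prefix}.lora_a"] = self.lora_a
            out[f"{prefix}.lora_b"] = self.lora_b
        return out


class _LayerNorm:
    def __init__(self, dim: int, trainable: bool):
        self.gamma = Parameter(np.ones(dim), requires_grad=trainable)
        self.beta = Parameter(np.zeros(dim), requires_grad=trainable)

    def __call__(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.gamma, self.beta)

    def params(self, prefix: str) -> dict[str, Parameter]:
        return {f"{prefix}.gamma": self.gamma, f"{prefix}.beta": self.beta}


class Attention:
    """Multi-head self-attention with optional LoRA on Q and V projections."""

    def __init__(self, dim: int, num_heads: int, lora: LoRAConfig,
                 rng: np.random.Generator,
                 lora_rng: np.random.Generator | None = None):
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        rq = lora.rank if "query" in lora.targets else 0
        rv = lora.rank if "value" in lora.targets else 0
        kw = dict(rng=rng, trainable=False, lora_scale=lora.scaling_factor,
                  lora_a_scale=lora.a_init_scale, lora_rng=lora_rng)
        self.q = _Linear(dim, dim, lora_rank=rq, **kw)
        self.k = _Linear(dim, dim, lora_rank=0, **kw)
        self.v = _Linear(dim, dim, lora_rank=rv, **kw)
        self.proj = _Linear(dim, dim, lora_rank=0, **kw)

    def _split(self, x: Tensor) -> Tensor:
        b, t, d = x.shape
        return x.reshape(b, t, self.num_heads, self.head_dim).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor) -> Tensor:
        b, t, d = x.shape
        q = self._split(self.q(x))
        k = self._split(self.k(x))
        v = self._split(self.v(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.head_dim))
        attn = scores.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, t, d)
        return self.proj(out)

    def attention_weights(self, x: Tensor) -> Tensor:
        """Softmax attention maps (B, heads, T, T); rows sum to 1."""
        q, k = self._split(self.q(x)), self._split(self.k(x))
        return ((q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.head_dim))
                ).softmax(axis=-1)

    def params(self, prefix: str) -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        for name, lin in (("q", self.q), ("k", self.k), ("v", self.v),
                          ("proj", self.proj)):
            out.update(lin.params(f"{prefix}.{name}"))
        return out


class Block:
    """Pre-norm transformer block: MHSA + 4x MLP, both with residuals."""

    def __init__(self, dim: int, num_heads: int, lora: LoRAConfig,
                 rng: np.random.Generator,
                 lora_rng: np.random.Generator | None = None):
        self.norm1 = _LayerNorm(dim, trainable=False)
        self.attn = Attention(dim, num_heads, lora, rng, lora_rng)
        self.norm2 = _LayerNorm(dim, trainable=False)
        self.fc1 = _Linear(dim, 4 * dim, rng, trainable=False)
        self.fc2 = _Linear(4 * dim, dim, rng, trainable=False)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.fc2(self.fc1(self.norm2(x)).gelu())

    def params(self, prefix: str) -> dict[str, Parameter]:
        out = self.norm1.params(f"{prefix}.norm1")
        out.update(self.attn.params(f"{prefix}.attn"))
        out.update(self.norm2.params(f"{prefix}.norm2"))
        out.update(self.fc1.params(f"{prefix}.fc1"))
        out.update(self.fc2.params(f"{prefix}.fc2"))
        return out


class Encoder:
    """Patch embedding + class token + M blocks, collecting stage outputs."""

    def __init__(self, cfg: EncoderConfig, lora: LoRAConfig,
                 rng: np.random.Generator,
                 lora_rng: np.random.Generator | None = None):
        cfg.validate()
        lora.validate()
        self.cfg = cfg
        d, p = cfg.embed_dim, cfg.patch_size
        self.patch_proj = _Linear(p * p * 3, d, rng, trainable=False)
        self.cls_token = Parameter(rng.normal(0.0, 0.02, (1, 1, d)),
                                   requires_grad=False)
        self.pos_embed = Parameter(rng.normal(0.0, 0.02, (1, cfg.num_patches + 1, d)),
                                   requires_grad=False)
        self.blocks = [Block(d, cfg.num_heads, lora, rng, lora_rng)
                       for _ in range(cfg.num_blocks)]

    def embed_patches(self, images: np.ndarray) -> TokenSequence:
        """Normalized (B, H, W, 3) frames -> class + patch tokens.

        Positional embeddings are interpolated when the spatial grid differs
        from the configured one (standard ViT practice), so the encoder also
        accepts other p-divisible sizes.
        """
        b, h, w = images.shape[:3]
        p = self.cfg.patch_size
        if h % p != 0 or w % p != 0:
            raise ShapeError(
                f"input size {h}x{w} is not divisible by patch size {p}")
        gh, gw = h // p, w // p
        patches = (images.reshape(b, gh, p, gw, p, 3)
                   .transpose(0, 1, 3, 2, 4, 5)
                   .reshape(b, gh * gw, p * p * 3))
        tok = self.patch_proj(Tensor(patches))
        pos = self._positional(gh, gw)
        cls = Tensor(np.broadcast_to(self.cls_token.data, (b, 1, tok.shape[2])).copy())
        tokens = Tensor.concat([cls, tok], axis=1) + Tensor(pos)
        return TokenSequence(tokens)

    def _positional(self, gh: int, gw: int) -> np.ndarray:
        g = self.cfg.grid_side
        pe = self.pos_embed.data
        if (gh, gw) == (g, g):
            return pe
        grid = pe[:, 1:, :].reshape(g, g, -1)
        wr, wc = bilinear_matrix(gh, g), bilinear_matrix(gw, g)
        interp = np.einsum("ih,jw,hwd->ijd", wr, wc, grid, optimize=True)
        return np.concatenate([pe[:, :1, :],
                               interp.reshape(1, gh * gw, -1)], axis=1)

    def collect_stages(self, seq: TokenSequence) -> list[Tensor]:
        """Run all blocks; return the fused grid of every selected stage.

        Each stage grid is (B, 4*sqrt(N), 4*sqrt(N), 2D): patch tokens
        reshaped spatially, class token broadcast and channel-concatenated,
        then bilinearly upsampled x4.
        """
        selected = set(self.cfg.selected_stages)
        x = seq.tokens
        stages = []
        for i, block in enumerate(self.blocks, start=1):
            x = block(x)
            if i in selected:
                stages.append(self._stage_map(TokenSequence(x)))
        return stages

    def _stage_map(self, seq: TokenSequence) -> Tensor:
        b, t, d = seq.tokens.shape
        n = t - 1
        g = int(round(np.sqrt(n)))
        if g * g != n:
            raise ShapeError(f"patch token count {n} is not a perfect square")
        grid = seq.patch_tokens.reshape(b, g, g, d)
        cls = seq.class_token.reshape(b, 1, 1, d)
        cls_grid = Tensor(np.zeros((b, g, g, d))) + cls  # broadcast to the grid
        fused = Tensor.concat([grid, cls_grid], axis=-1)
        w = bilinear_matrix(4 * g, g)
        return fused.interp2d(w, w)

    def params(self) -> dict[str, Parameter]:
        out = self.patch_proj.params("encoder.patch_proj")
        out["encoder.cls_token"] = self.cls_token
        out["encoder.pos_embed"] = self.pos_embed
        for i, blk in enumerate(self.blocks):
            out.update(blk.params(f"encoder.block{i}"))
        return out


class Decoder:
    """All-MLP head: align stages to C, concat, fuse to C, classify."""

    def __init__(self, cfg: DecoderConfig, stage_channels: int,
                 rng: np.random.Generator):
        cfg.validate()
        self.cfg = cfg
        self.align = [_Linear(stage_channels, cfg.common_dim, rng, trainable=True)
                      for _ in range(cfg.num_stages)]
        self.fuse = _Linear(cfg.num_stages * cfg.common_dim, cfg.common_dim,
                            rng, trainable=True)
        self.classify = _Linear(cfg.common_dim, cfg.num_classes, rng, trainable=True)

    def __call__(self, features: list[Tensor], output_size: int) -> Tensor:
        if len(features) != self.cfg.num_stages:
            raise ShapeError(
                f"decoder expects {self.cfg.num_stages} stages, got {len(features)}")
        sizes = {f.shape[1:3] for f in features}
        if len(sizes) != 1:
            raise ShapeError(f"stage spatial sizes differ: {sorted(sizes)}")
        aligned = [lin(f) for lin, f in zip(self.align, features)]
        fused = self.fuse(Tensor.concat(aligned, axis=-1)).gelu()
        logits = self.classify(fused)
        side = logits.shape[1]
        if side != output_size:
            w = bilinear_matrix(output_size, side)
            logits = logits.interp2d(w, w)
        return logits

    def params(self) -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        for i, lin in enumerate(self.align):
            out.update(lin.params(f"decoder.align{i}"))
        out.update(self.fuse.params("decoder.fuse"))
        out.update(self.classify.params("decoder.classify"))
        return out


class SegmentationModel:
    """Encoder + decoder; prompted frames in, per-pixel class logits out."""

    def __init__(self, enc: EncoderConfig, lora: LoRAConfig, dec: DecoderConfig,
                 seed: int = 0):
        if dec.num_stages != len(enc.selected_stages):
            raise ConfigError(
                f"decoder num_stages {dec.num_stages} != "
                f"{len(enc.selected_stages)} selected encoder stages")
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
        lora_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
        self.enc_cfg, self.lora_cfg, self.dec_cfg = enc, lora, dec
        self.encoder = Encoder(enc, lora, rng, lora_rng)
        self.decoder = Decoder(dec, 2 * enc.embed_dim, rng)

    def forward(self, images: np.ndarray, output_size: int | None = None) -> Tensor:
        """Normalized (B, H, W, 3) frames -> (B, S, S, N_cls) logits."""
        if output_size is None:
            output_size = images.shape[1]
        seq = self.encoder.embed_patches(images)
        stages = self.encoder.collect_stages(seq)
        return self.decoder(stages, output_size)

    def predict_labels(self, images: np.ndarray,
                       output_size: int | None = None) -> np.ndarray:
        logits = self.forward(images, output_size)
        return np.argmax(logits.data, axis=-1).astype(np.uint8)

    def named_parameters(self) -> dict[str, Parameter]:
        out = self.encoder.params()
        out.update(self.decoder.params())
        return out

    def trainable_parameters(self) -> list[Parameter]:
        return [p for p in self.named_parameters().values() if p.requires_grad]


def build_model(enc: EncoderConfig, lora: LoRAConfig, dec: DecoderConfig,
                pretrained_checkpoint: str | Path | None = None,
                seed: int = 0) -> SegmentationModel:
    """Assemble the network; optionally load encoder weights from a checkpoint.

    Without a checkpoint the encoder is seeded-randomly initialized.  The
    decoder is always randomly initialized, and LoRA B matrices start at
    zero, so at step 0 the adapted model is functionally identical to the
    un-adapted base.
    """
    enc.validate(); lora.validate(); dec.validate()
    model = SegmentationModel(enc, lora, dec, seed=seed)
    if pretrained_checkpoint is not None:
        _load_encoder_weights(model, Path(pretrained_checkpoint))
    return model


def count_trainable_parameters(model: SegmentationModel) -> dict[str, int]:
    """Partition the parameter count into LoRA / decoder / frozen."""
    counts = {"lora_params": 0, "decoder_params": 0, "frozen_params": 0}
    for name, p in model.named_parameters().items():
        if ".lora_" in name:
            counts["lora_params"] += p.data.size
        elif name.startswith("decoder."):
            counts["decoder_params"] += p.data.size
        else:
            counts["frozen_params"] += p.data.size
    return counts


def frozen_hash(model: SegmentationModel) -> str:
    """SHA-256 over all frozen parameters, in name order.

    Training must leave this unchanged: only LoRA adapters and the decoder
    are allowed to move.
    """
    import hashlib
    h = hashlib.sha256()
    for name, p in sorted(model.named_parameters().items()):
        if not p.requires_grad:
            h.update(name.encode())
            h.update(np.ascontiguousarray(p.data).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# checkpoints: .npz weights + JSON config sidecar


def save_checkpoint(model: SegmentationModel, path: str | Path) -> None:
    path = Path(path)
    np.savez(path, **{k: v.data for k, v in model.named_parameters().items()})
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "encoder": asdict(model.enc_cfg),
        "lora": asdict(model.lora_cfg),
        "decoder": asdict(model.dec_cfg),
    }, indent=2))


def load_checkpoint(path: str | Path, seed: int = 0) -> SegmentationModel:
    """Rebuild a model from its sidecar configs and stored weights."""
    path = Path(path)
    cfg = json.loads(path.with_suffix(".json").read_text())
    for key in ("encoder", "lora", "decoder"):
        for k, v in cfg[key].items():
            if isinstance(v, list):
                cfg[key][k] = tuple(v)
    model = SegmentationModel(EncoderConfig(**cfg["encoder"]),
                              LoRAConfig(**cfg["lora"]),
                              DecoderConfig(**cfg["decoder"]), seed=seed)
    _load_all_weights(model, path)
    return model


def _assign(params: dict[str, Parameter], stored: dict, names) -> None:
    mismatched = [
        f"{n}: expected {params[n].data.shape}, found {stored[n].shape}"
        for n in names if stored[n].shape != params[n].data.shape]
    if mismatched:
        raise ShapeError("checkpoint shape mismatch: " + "; ".join(mismatched))
    for n in names:
        params[n].data = np.asarray(stored[n], dtype=np.float64)


def _load_all_weights(model: SegmentationModel, path: Path) -> None:
    with np.load(path if path.suffix else path.with_suffix(".npz")) as stored:
        params = model.named_parameters()
        missing = sorted(set(params) - set(stored.files))
        if missing:
            raise ShapeError(f"checkpoint missing parameters: {missing}")
        _assign(params, dict(stored.items()), list(params))


def _load_encoder_weights(model: SegmentationModel, path: Path) -> None:
    with np.load(path) as stored:
        params = {k: v for k, v in model.named_parameters().items()
                  if k.startswith("encoder.") and ".lora_" not in k}
        missing = sorted(set(params) - set(stored.files))
        if missing:
            raise ShapeError(f"checkpoint missing encoder parameters: {missing}")
        _assign(params, dict(stored.items()), list(params))
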