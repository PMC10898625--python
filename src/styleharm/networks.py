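"""The five network roles of the harmonization model.

A shared content encoder maps a 2.5D slice to a spatial content code; a
style encoder with one output head per site maps a slice to a low-dimensional
style vector; a shared generator decodes a (content, style) pair back to an
image, injecting style through adaptive instance normalization (AdaIN); a
style generator (mapping network) with per-site heads turns a standard-normal
latent code into a style vector; and a discriminator with per-site heads
scores images as real or fake.

Architectural layout follows the multi-domain image-to-image translation
lineage (strided-conv encoders, AdaIN residual decoder, conv trunk with
per-site heads); all widths are configurable through :class:`ModelConfig`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .errors import ConfigError, InvalidArgumentError, ShapeError, ModelError

__all__ = [
    "ModelConfig", "ModelBundle", "ContentCode", "StyleCode", "LatentCode",
    "build_models", "encode_content", "encode_style", "generate_style",
    "decode", "discriminate", "save_bundle", "load_bundle",
]


@dataclass(frozen=True)
class ModelConfig:
    """Dimensions of the model.

    ``canvas`` is the square working size of a padded 2.5D slice,
    ``downsampling`` the total spatial reduction of the content encoder
    (a power of two), ``d_s``/``d_z`` the style/latent dimensionalities and
    ``base_width`` the channel count after the first convolution.
    """

    n_sites: int
    canvas: int = 64
    in_channels: int = 3
    base_width: int = 16
    downsampling: int = 2
    d_s: int = 8
    d_z: int = 16
    n_res_content: int = 1
    n_res_generator: int = 2
    style_trunk_width: int = 64
    leaky_slope: float = 0.2
    # AdaIN style projections start near zero so early training behaves like
    # a style-agnostic autoencoder; style modulation grows in via the
    # adversarial and style-consistency gradients.
    style_proj_init: float = 0.1
    # channels of the content code; redundancy here lets the decoder average
    # out the unit-variance training perturbation of the content features
    # (None: base_width * downsampling)
    content_width: int | None = None
    # optional: tanh output scaled then clipped back to [-1, 1] (scale > 1
    # reaches the normalization extremes without saturating); 1.0 disables
    output_scale: float = 1.0
    # decoder upsampling: nearest-neighbour + conv, or sub-pixel
    # (depth-to-space) convolution
    upsample_mode: str = "subpixel"

    def __post_init__(self):
        if self.n_sites < 2:
            raise ConfigError("harmonization needs at least 2 sites")
        ds = self.downsampling
        if ds < 1 or ds & (ds - 1):
            raise ConfigError("downsampling must be a power of two >= 1")
        if self.canvas % ds:
            raise ConfigError(
                f"canvas {self.canvas} not divisible by downsampling {ds}")

    @property
    def n_down(self) -> int:
        return int(np.log2(self.downsampling))

    @property
    def content_channels(self) -> int:
        if self.content_width is not None:
            return self.content_width
        return self.base_width * self.downsampling

    @property
    def content_size(self) -> int:
        return self.canvas // self.downsampling


# Thin semantic wrappers around arrays; the networks accept/return Tensors and
# these types document the contracts at module boundaries.
@dataclass
class ContentCode:
    features: np.ndarray  # (B, C_c, H_c, W_c)


@dataclass
class StyleCode:
    vector: np.ndarray  # (B, d_s) or (d_s,)


@dataclass
class LatentCode:
    vector: np.ndarray  # (B, d_z) or (d_z,)


@dataclass
class ModelBundle:
    """All trainable parameters plus the configuration.

    Parameters live in one flat name->Tensor dict; role prefixes are
    ``cenc`` (content encoder), ``senc`` (style encoder), ``gen`` (generator),
    ``sgen`` (style generator) and ``disc`` (discriminator).
    """

    config: ModelConfig
    params: dict[str, Tensor] = field(default_factory=dict)

    def group(self, *prefixes: str) -> dict[str, Tensor]:
        return {k: v for k, v in self.params.items()
                if k.split(".", 1)[0] in prefixes}

    def generator_side(self) -> dict[str, Tensor]:
        return self.group("cenc", "senc", "gen", "sgen")

    def discriminator_side(self) -> dict[str, Tensor]:
        return self.group("disc")

    def summary(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for k, v in self.params.items():
            role = k.split(".", 1)[0]
            counts[role] = counts.get(role, 0) + v.size
        counts["total"] = sum(v.size for v in self.params.values())
        return counts

    def check_finite(self) -> None:
        for k, v in self.params.items():
            if not np.all(np.isfinite(v.data)):
                raise ModelError(f"non-finite parameters in {k}")


# -- construction -------------------------------------------------------------

def _conv_init(rng, f, c, k):
    w = rng.standard_normal((f, c, k, k)) * np.sqrt(2.0 / (c * k * k))
    return w.astype(ad.DTYPE), np.zeros(f, dtype=ad.DTYPE)

def _fc_init(rng, din, dout):
    w = rng.standard_normal((din, dout)) * np.sqrt(2.0 / din)
    return w.astype(ad.DTYPE), np.zeros(dout, dtype=ad.DTYPE)


def build_models(config: ModelConfig, seed: int) -> ModelBundle:
    """Deterministically initialize all five network roles."""
    rng = np.random.default_rng(seed)
    P: dict[str, Tensor] = {}

    def addp(name, w, b):
        P[name + ".w"] = Tensor(w, requires_grad=True)
        P[name + ".b"] = Tensor(b, requires_grad=True)

    cfg = config
    w0 = cfg.base_width

    # content encoder: conv3 stem, n_down strided conv4 (or a stride-1
    # projection when downsampling is 1), residual blocks
    addp("cenc.stem", *_conv_init(rng, w0, cfg.in_channels, 3))
    ch = w0
    for d in range(cfg.n_down):
        out_ch = cfg.content_channels if d == cfg.n_down - 1 else ch * 2
        addp(f"cenc.down{d}", *_conv_init(rng, out_ch, ch, 4))
        ch = out_ch
    if ch != cfg.content_channels:
        addp("cenc.proj", *_conv_init(rng, cfg.content_channels, ch, 3))
        ch = cfg.content_channels
    for r in range(cfg.n_res_content):
        addp(f"cenc.res{r}.conv1", *_conv_init(rng, ch, ch, 3))
        addp(f"cenc.res{r}.conv2", *_conv_init(rng, ch, ch, 3))

    def style_proj_init(din, dout):
        w, bias = _fc_init(rng, din, dout)
        return w * ad.DTYPE(cfg.style_proj_init), bias

    # generator: AdaIN residual blocks, upsampling convs, output conv
    for r in range(cfg.n_res_generator):
        addp(f"gen.res{r}.conv1", *_conv_init(rng, ch, ch, 3))
        addp(f"gen.res{r}.style1", *style_proj_init(cfg.d_s, 2 * ch))
        addp(f"gen.res{r}.conv2", *_conv_init(rng, ch, ch, 3))
        addp(f"gen.res{r}.style2", *style_proj_init(cfg.d_s, 2 * ch))
    for d in range(cfg.n_down):
        if cfg.upsample_mode == "subpixel":
            # ICNR: the four sub-pixel phases share one filter at init, so
            # the layer starts exactly as nearest-neighbour upsampling and
            # learns sharper kernels from there (no checkerboard artifacts)
            base, _ = _conv_init(rng, ch // 2, ch, 3)
            w4 = np.repeat(base, 4, axis=0)
            addp(f"gen.up{d}", w4, np.zeros((ch // 2) * 4, dtype=ad.DTYPE))
        else:
            addp(f"gen.up{d}", *_conv_init(rng, ch // 2, ch, 3))
        addp(f"gen.up{d}.style", *style_proj_init(cfg.d_s, 2 * (ch // 2)))
        ch //= 2
    addp("gen.out", *_conv_init(rng, cfg.in_channels, ch, 3))

    # style encoder / discriminator trunks: 4 strided convs + fc + heads
    for role in ("senc", "disc"):
        ch = cfg.in_channels
        widths = [w0, 2 * w0, 4 * w0, 4 * w0]
        for d, f in enumerate(widths):
            addp(f"{role}.conv{d}", *_conv_init(rng, f, ch, 4))
            ch = f
        addp(f"{role}.fc", *_fc_init(rng, ch, ch))
        out_dim = cfg.d_s if role == "senc" else 1
        for s in range(cfg.n_sites):
            addp(f"{role}.head{s}", *_fc_init(rng, ch, out_dim))

    # style generator (mapping network): MLP trunk + per-site heads
    tw = cfg.style_trunk_width
    addp("sgen.fc0", *_fc_init(rng, cfg.d_z, tw))
    addp("sgen.fc1", *_fc_init(rng, tw, tw))
    for s in range(cfg.n_sites):
        addp(f"sgen.head{s}", *_fc_init(rng, tw, cfg.d_s))

    return ModelBundle(config=cfg, params=P)


# -- forward passes -----------------------------------------------------------

def _check_image(cfg: ModelConfig, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=ad.DTYPE)
    if x.ndim == 3:
        x = x[None]
    if x.ndim != 4 or x.shape[1] != cfg.in_channels or \
            x.shape[2] != cfg.canvas or x.shape[3] != cfg.canvas:
        raise ShapeError(
            f"expected (B, {cfg.in_channels}, {cfg.canvas}, {cfg.canvas}) "
            f"input, got {x.shape}")
    return x


def _check_site(cfg: ModelConfig, site: int) -> int:
    site = int(site)
    if not 0 <= site < cfg.n_sites:
        raise InvalidArgumentError(
            f"site {site} out of range [0, {cfg.n_sites})")
    return site


def _conv(P, name, x, stride=1, pad=1):
    return ad.conv2d(x, P[name + ".w"], P[name + ".b"], stride=stride, pad=pad)


def _fc(P, name, x):
    return ad.linear(x, P[name + ".w"], P[name + ".b"])


def encode_content(bundle: ModelBundle, x, train_mode: bool = False,
                   rng: np.random.Generator | None = None) -> Tensor:
    """Content code of a slice batch; adds the N(0, I) perturbation in training.

    The perturbation regularizes the content space (it realizes the sampling
    of the unit-covariance Gaussian whose mean the alignment loss pulls to
    zero) and is never applied at inference.
    """
    cfg = bundle.config
    P = bundle.params
    xt = x if isinstance(x, Tensor) else ad.as_tensor(_check_image(cfg, x))
    h = ad.relu(ad.instance_norm(_conv(P, "cenc.stem", xt)))
    for d in range(cfg.n_down):
        h = ad.relu(ad.instance_norm(_conv(P, f"cenc.down{d}", h, stride=2)))
    if "cenc.proj.w" in P:
        h = ad.relu(ad.instance_norm(_conv(P, "cenc.proj", h)))
    for r in range(cfg.n_res_content):
        y = ad.relu(ad.instance_norm(_conv(P, f"cenc.res{r}.conv1", h)))
        y = ad.instance_norm(_conv(P, f"cenc.res{r}.conv2", y))
        h = ad.add(h, y)
    if train_mode:
        if rng is None:
            raise InvalidArgumentError("train_mode content encoding needs rng")
        eta = rng.standard_normal(h.shape).astype(ad.DTYPE)
        h = ad.add(h, Tensor(eta))
    return h


def _trunk(P, cfg, role, x):
    h = x
    for d in range(4):
        h = ad.leaky_relu(_conv(P, f"{role}.conv{d}", h, stride=2),
                          cfg.leaky_slope)
    h = ad.mean(h, axis=(2, 3))  # global average pool -> (B, C)
    return ad.leaky_relu(_fc(P, f"{role}.fc", h), cfg.leaky_slope)


def encode_style(bundle: ModelBundle, x, site: int) -> Tensor:
    """Style vector of a slice batch through the given site's head."""
    cfg = bundle.config
    site = _check_site(cfg, site)
    xt = x if isinstance(x, Tensor) else ad.as_tensor(_check_image(cfg, x))
    h = _trunk(bundle.params, cfg, "senc", xt)
    return _fc(bundle.params, f"senc.head{site}", h)


def encode_style_multi(bundle: ModelBundle, xs, sites) -> list[Tensor]:
    """Style vectors for several equal-size batches in one trunk pass."""
    cfg = bundle.config
    sites = [_check_site(cfg, s) for s in sites]
    ts = [x if isinstance(x, Tensor) else ad.as_tensor(_check_image(cfg, x))
          for x in xs]
    B = ts[0].shape[0]
    h = _trunk(bundle.params, cfg, "senc", ad.concatenate(ts, axis=0))
    return [_fc(bundle.params, f"senc.head{s}", h[k * B:(k + 1) * B])
            for k, s in enumerate(sites)]


def generate_style(bundle: ModelBundle, z, site: int) -> Tensor:
    """Map a standard-normal latent code to a site-specific style vector."""
    cfg = bundle.config
    site = _check_site(cfg, site)
    zv = z.vector if isinstance(z, LatentCode) else z
    zt = zv if isinstance(zv, Tensor) else ad.as_tensor(
        np.atleast_2d(np.asarray(zv, dtype=ad.DTYPE)))
    if zt.shape[-1] != cfg.d_z:
        raise ShapeError(f"latent code length {zt.shape[-1]} != d_z {cfg.d_z}")
    P = bundle.params
    h = ad.relu(_fc(P, "sgen.fc0", zt))
    h = ad.relu(_fc(P, "sgen.fc1", h))
    return _fc(P, f"sgen.head{site}", h)


def _adain(h: Tensor, s: Tensor, P, name: str) -> Tensor:
    """Adaptive instance normalization: style -> per-channel scale and shift."""
    gb = _fc(P, name, s)  # (B, 2C)
    C = h.shape[1]
    gamma = ad.reshape(gb[:, :C], (-1, C, 1, 1))
    beta = ad.reshape(gb[:, C:], (-1, C, 1, 1))
    return ad.add(ad.mul(ad.instance_norm(h), ad.add(gamma, 1.0)), beta)


def decode(bundle: ModelBundle, c, s) -> Tensor:
    """Generate an image from a content code and a style vector; output in [-1, 1]."""
    cfg = bundle.config
    P = bundle.params
    ct = c if isinstance(c, Tensor) else ad.as_tensor(
        np.asarray(c.features if isinstance(c, ContentCode) else c,
                   dtype=ad.DTYPE))
    sv = s.vector if isinstance(s, StyleCode) else s
    st = sv if isinstance(sv, Tensor) else ad.as_tensor(
        np.atleast_2d(np.asarray(sv, dtype=ad.DTYPE)))
    if ct.ndim != 4 or ct.shape[1] != cfg.content_channels or \
            ct.shape[2] != cfg.content_size or ct.shape[3] != cfg.content_size:
        raise ShapeError(f"content code shape {ct.shape} does not match config")
    if st.shape[-1] != cfg.d_s:
        raise ShapeError(f"style length {st.shape[-1]} != d_s {cfg.d_s}")
    if st.shape[0] == 1 and ct.shape[0] > 1:
        st = ad.concatenate([st] * ct.shape[0], axis=0)
    if st.shape[0] != ct.shape[0]:
        raise ShapeError("content/style batch sizes differ")
    h = ct
    for r in range(cfg.n_res_generator):
        y = _conv(P, f"gen.res{r}.conv1", h)
        y = ad.relu(_adain(y, st, P, f"gen.res{r}.style1"))
        y = _conv(P, f"gen.res{r}.conv2", y)
        y = _adain(y, st, P, f"gen.res{r}.style2")
        h = ad.add(h, y)
    for d in range(cfg.n_down):
        if cfg.upsample_mode == "subpixel":
            h = ad.depth_to_space2(_conv(P, f"gen.up{d}", h))
        else:
            h = _conv(P, f"gen.up{d}", ad.upsample_nearest2(h))
        h = ad.relu(_adain(h, st, P, f"gen.up{d}.style"))
    y = ad.tanh(_conv(P, "gen.out", h))
    if cfg.output_scale != 1.0:
        y = ad.clamp(ad.mul(y, float(cfg.output_scale)), -1.0, 1.0)
    return y


def discriminate_multi(bundle: ModelBundle, xs, sites) -> list[Tensor]:
    """Real-probabilities for several equal-size batches in one trunk pass."""
    cfg = bundle.config
    sites = [_check_site(cfg, s) for s in sites]
    ts = [x if isinstance(x, Tensor) else ad.as_tensor(_check_image(cfg, x))
          for x in xs]
    B = ts[0].shape[0]
    h = _trunk(bundle.params, cfg, "disc", ad.concatenate(ts, axis=0))
    return [ad.sigmoid(ad.reshape(
        _fc(bundle.params, f"disc.head{s}", h[k * B:(k + 1) * B]), (-1,)))
        for k, s in enumerate(sites)]


def discriminate(bundle: ModelBundle, x, site: int) -> Tensor:
    """Probability-of-real score per image through the given site's head."""
    cfg = bundle.config
    site = _check_site(cfg, site)
    xt = x if isinstance(x, Tensor) else ad.as_tensor(_check_image(cfg, x))
    h = _trunk(bundle.params, cfg, "disc", xt)
    logit = _fc(bundle.params, f"disc.head{site}", h)
    return ad.sigmoid(ad.reshape(logit, (-1,)))


# -- checkpoint I/O -----------------------------------------------------------

def save_bundle(bundle: ModelBundle, path, extra_arrays=None,
                meta: dict | None = None) -> None:
    """Write parameters (+ optional optimizer arrays and JSON metadata) to .npz."""
    arrays = {f"param.{k}": v.data for k, v in bundle.params.items()}
    if extra_arrays:
        arrays.update(extra_arrays)
    meta = dict(meta or {})
    meta["config"] = dataclasses.asdict(bundle.config)
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_bundle(path) -> tuple[ModelBundle, dict, dict]:
    """Restore a bundle; returns (bundle, non-parameter arrays, metadata)."""
    with np.load(path) as npz:
        arrays = {k: npz[k] for k in npz.files}
    meta = json.loads(bytes(arrays.pop("meta_json")).decode())
    config = ModelConfig(**meta.pop("config"))
    params = {}
    extras = {}
    for k, v in arrays.items():
        if k.startswith("param."):
            params[k[len("param."):]] = Tensor(v, requires_grad=True)
        else:
            extras[k] = v
    bundle = ModelBundle(config=config, params=params)
    return bundle, extras, meta
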