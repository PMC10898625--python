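"""The seven loss terms of content-style disentangled cycle translation.

Sign and reduction conventions
------------------------------
* Every L1-based term is the **mean** absolute difference over elements (not a
  sum), so loss weights are comparable across canvas sizes.
* The adversarial value is the two-term log-likelihood
  ``E[log D_i(x_i)] + E[log(1 - D_j(x_j~))]``; the discriminator ascends it.
  The generator, in training, minimizes the non-saturating surrogate
  ``-E[log D_j(x_j~)]`` instead of descending the saturating minimax form.
* The style diversity term measures ``mean |G(c, s) - G(c, s')|`` for two
  styles from distinct latent codes.  Minimizing it would collapse intra-site
  diversity, so by default it enters the total with a **negative** sign (the
  generator maximizes diversity); ``diversity_sign=+1`` restores the literal
  minimized form.
* Style consistency compares by default the style used for generation with the
  style re-extracted from the generated image (``s_j`` vs ``s_j~``); the
  training loop can instead compare the *source* style ``s_i`` against
  ``s_j~`` (``literal_style_consistency``), though that contradicts
  disentanglement and is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .errors import ShapeError, TrainingDivergenceError

__all__ = [
    "LossWeights", "LossReport", "EPS",
    "adversarial_loss", "content_consistency", "style_consistency",
    "content_alignment", "style_diversity", "cycle_loss", "identity_loss",
    "image_gradient", "total_loss",
]

EPS = 1e-7  # log clamp; prevents log(0) at saturated discriminator scores


@dataclass(frozen=True)
class LossWeights:
    """Weights of the total objective."""

    lambda_adv: float = 1.0
    lambda_cont: float = 10.0
    lambda_ca: float = 0.01
    lambda_sd: float = 1.0
    lambda_sty: float = 10.0
    lambda_cyc: float = 10.0
    lambda_g: float = 0.1
    lambda_id: float = 10.0

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be nonnegative")


@dataclass
class LossReport:
    """Scalar value of each term plus the weighted total."""

    adv: float
    cont: float
    ca: float
    sd: float
    sty: float
    cyc: float
    id: float
    total: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _pair(a, b, name: str) -> tuple[Tensor, Tensor]:
    at, bt = ad.as_tensor(a), ad.as_tensor(b)
    if at.shape != bt.shape:
        raise ShapeError(f"{name}: shape mismatch {at.shape} vs {bt.shape}")
    return at, bt


def adversarial_loss(score_real, score_fake) -> Tensor:
    """``mean log(score_real) + mean log(1 - score_fake)`` with scores clamped
    to [EPS, 1-EPS].  The discriminator maximizes this value."""
    r = ad.clamp(ad.as_tensor(score_real), EPS, 1.0 - EPS)
    f = ad.clamp(ad.as_tensor(score_fake), EPS, 1.0 - EPS)
    return ad.add(ad.mean(ad.log(r)),
                  ad.mean(ad.log(ad.add(ad.mul(f, -1.0), 1.0))))


def nonsaturating_generator_loss(score_fake) -> Tensor:
    """``-mean log(score_fake)``: the stable generator-side adversarial term."""
    f = ad.clamp(ad.as_tensor(score_fake), EPS, 1.0 - EPS)
    return ad.mul(ad.mean(ad.log(f)), -1.0)


def content_consistency(c_i, c_tilde_j) -> Tensor:
    """Mean absolute difference between source and re-extracted content codes."""
    a, b = _pair(c_i, c_tilde_j, "content_consistency")
    return ad.l1_mean(a, b)


def style_consistency(s_target, s_tilde) -> Tensor:
    """Mean absolute difference between the generation style and the style
    re-extracted from the generated image."""
    a, b = _pair(s_target, s_tilde, "style_consistency")
    return ad.l1_mean(a, b)



def content_alignment(c) -> Tensor:
    """KL(N(c, I) || N(0, I)) for unit-covariance Gaussians, reduced to the
    closed form 0.5 * mean(c**2)."""
    ct = ad.as_tensor(c)
    return ad.mul(ad.mean(ad.mul(ct, ct)), 0.5)


def style_diversity(x_tilde, x_tilde_prime, ceiling: float | None = None) -> Tensor:
    """Mean absolute difference between two images generated from the same
    content with styles from distinct latent codes; optionally clipped at
    ``ceiling`` (used when the generator maximizes the term)."""
    a, b = _pair(x_tilde, x_tilde_prime, "style_diversity")
    d = ad.l1_mean(a, b)
    if ceiling is not None:
        d = ad.clamp(d, None, float(ceiling))
    return d


def image_gradient(x) -> Tensor:
    """Forward finite differences along both spatial axes, concatenated on a
    new leading channel pair; the replicated edge contributes a zero diff.

    Accepts any array whose last two axes are spatial.
    """
    xt = ad.as_tensor(x)
    if xt.ndim < 2:
        raise ShapeError("image_gradient needs at least 2 spatial axes")
    h_ax, w_ax = xt.ndim - 2, xt.ndim - 1
    sl = [slice(None)] * xt.ndim

    def fdiff(axis):
        lo = list(sl)
        hi = list(sl)
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        d = ad.add(xt[tuple(hi)], ad.mul(xt[tuple(lo)], -1.0))
        zshape = list(xt.shape)
        zshape[axis] = 1
        return ad.concatenate([d, Tensor(np.zeros(zshape, dtype=ad.DTYPE))],
                              axis=axis)

    gx = fdiff(h_ax)
    gy = fdiff(w_ax)
    return ad.concatenate([gx, gy], axis=0)


def cycle_loss(x, x_hat, lambda_g: float = 0.1) -> Tensor:
    """Pixel-wise plus gradient-wise cycle reconstruction error:
    ``mean|x - x^| + lambda_g * mean|g(x) - g(x^)|``."""
    a, b = _pair(x, x_hat, "cycle_loss")
    pix = ad.l1_mean(a, b)
    grad = ad.l1_mean(image_gradient(a), image_gradient(b))
    return ad.add(pix, ad.mul(grad, float(lambda_g)))


def identity_loss(x, x_bar) -> Tensor:
    """Mean absolute difference between an image and its self-translation."""
    a, b = _pair(x, x_bar, "identity_loss")
    return ad.l1_mean(a, b)


def total_loss(terms: dict[str, float], weights: LossWeights,
               diversity_sign: int = -1) -> LossReport:
    """Weighted total of the seven terms.

    ``terms`` maps {adv, cont, ca, sd, sty, cyc, id} to scalar values; the
    diversity term enters with ``diversity_sign`` (default -1: maximized by
    the generator).  Raises on non-finite terms, naming the offender.
    """
    vals = {k: float(terms[k]) for k in ("adv", "cont", "ca", "sd", "sty",
                                         "cyc", "id")}
    for k, v in vals.items():
        if not np.isfinite(v):
            raise TrainingDivergenceError(f"loss term '{k}' is non-finite")
    w = weights
    total = (w.lambda_adv * vals["adv"]
             + w.lambda_cont * vals["cont"]
             + w.lambda_ca * vals["ca"]
             + diversity_sign * w.lambda_sd * vals["sd"]
             + w.lambda_sty * vals["sty"]
             + w.lambda_cyc * vals["cyc"]
             + w.lambda_id * vals["id"])
    return LossReport(total=total, **vals)
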