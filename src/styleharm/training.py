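"""Adversarial training by content-style disentangled cycle translation.

Each step draws an ordered pair of distinct sites (i, j), translates a batch
of site-i slices forward into site j's style (style taken either from the
per-site style generator on a latent draw, or from a reference batch of real
site-j images), translates backward to reconstruct the source, and produces
the self-translation.  The per-site discriminator is updated first on
(real x_i at branch i, generated x_j~ at branch j); the generator-side
modules (content encoder, style encoders, generator, style generators) are
then updated on the weighted total with the discriminator frozen.  All
randomness flows through one seeded generator in :class:`TrainState`, so a
run is a pure function of (data, config, seed) and can be checkpointed and
resumed bitwise.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _autodiff as ad
from . import losses as L
from . import networks as nets
from ._autodiff import Adam, Tensor, no_grad
from .errors import InvalidArgumentError, TrainingDivergenceError
from .losses import LossReport, LossWeights
from .networks import ModelBundle, ModelConfig

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig", "TrainState", "sample_site_pair", "cs_dct_step", "fit",
    "save_checkpoint", "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (ADAM, learning rate 1e-4 by default)."""

    total_steps: int
    seed: int = 0
    learning_rate: float = 1e-4
    batch_size: int = 4
    weights: LossWeights = field(default_factory=LossWeights)
    style_source_mix: float = 0.5   # fraction of steps on the reference path
    checkpoint_interval: int = 500
    sd_ceiling: float = 0.5         # clip on the maximized diversity term
    content_noise_scale: float = 1.0  # scale of the N(0, I) content perturbation
    literal_diversity_sign: bool = False
    literal_style_consistency: bool = False

    def __post_init__(self):
        if self.learning_rate < 0:
            raise InvalidArgumentError("learning_rate must be >= 0")
        if self.batch_size < 1:
            raise InvalidArgumentError("batch_size must be >= 1")
        if not 0.0 <= self.style_source_mix <= 1.0:
            raise InvalidArgumentError("style_source_mix must be in [0, 1]")


class TrainState:
    """Mutable training state: step, optimizers, rng, loss history."""

    def __init__(self, bundle: ModelBundle, config: TrainConfig):
        self.step = 0
        self.rng = np.random.default_rng(config.seed)
        self.opt_g = Adam(bundle.generator_side(), lr=config.learning_rate)
        self.opt_d = Adam(bundle.discriminator_side(), lr=config.learning_rate)
        self.history: list[dict[str, float]] = []


def sample_site_pair(n_sites: int, rng: np.random.Generator) -> tuple[int, int]:
    """Uniform draw over all N(N-1) ordered pairs with i != j."""
    if n_sites < 2:
        raise InvalidArgumentError("need at least 2 sites")
    k = int(rng.integers(n_sites * (n_sites - 1)))
    i, r = divmod(k, n_sites - 1)
    j = r if r < i else r + 1
    return i, j


def _as_batch(x) -> np.ndarray:
    x = np.asarray(x, dtype=ad.DTYPE)
    if x.ndim == 3:
        x = x[None]
    return x


def cs_dct_step(bundle: ModelBundle, batch_i, batch_j,
                config: TrainConfig, state: TrainState,
                path: str | None = None) -> LossReport:
    """One alternating discriminator/generator update on a site pair.

    ``batch_i``/``batch_j`` are ``(pixels, site)`` with pixels (B, 3, H, W) in
    [-1, 1].  ``path`` forces 'latent' or 'reference' style sourcing;
    ``None`` draws it from the configured mix.
    """
    x_i, i = batch_i
    x_j, j = batch_j
    i, j = int(i), int(j)
    if i == j:
        raise InvalidArgumentError(
            "translation pair needs distinct sites (identity is covered by "
            "the identity loss)")
    x_i = _as_batch(x_i)
    x_j = _as_batch(x_j)
    cfg = bundle.config
    rng = state.rng
    B = x_i.shape[0]

    if path is None:
        path = "reference" if rng.random() < config.style_source_mix else "latent"
    if path not in ("latent", "reference"):
        raise InvalidArgumentError(f"unknown style path {path!r}")

    # draw all stochastic inputs once so both phases see the same sample
    eta = (config.content_noise_scale * rng.standard_normal(
        (B, cfg.content_channels, cfg.content_size, cfg.content_size)
    )).astype(ad.DTYPE)
    z = rng.standard_normal((B, cfg.d_z)).astype(ad.DTYPE)
    z2 = rng.standard_normal((B, cfg.d_z)).astype(ad.DTYPE)

    def style_j():
        if path == "latent":
            return nets.generate_style(bundle, z, j)
        return nets.encode_style(bundle, x_j, j)

    # -- discriminator update -------------------------------------------------
    with no_grad():
        c_pert = ad.add(nets.encode_content(bundle, x_i), Tensor(eta))
        x_fake = nets.decode(bundle, c_pert, style_j()).data
    score_real, score_fake = nets.discriminate_multi(
        bundle, [x_i, x_fake], [i, j])
    adv_value = L.adversarial_loss(score_real, score_fake)
    d_loss = ad.mul(adv_value, -1.0)  # D ascends the printed objective
    state.opt_d.zero_grad()
    d_loss.backward()
    if config.learning_rate > 0:
        state.opt_d.step()

    # -- generator-side update (discriminator frozen) -------------------------
    for p in bundle.discriminator_side().values():
        p.requires_grad = False
    try:
        c_clean = nets.encode_content(bundle, x_i)
        c_i = ad.add(c_clean, Tensor(eta))
        s_j = style_j()
        s_i = nets.encode_style(bundle, x_i, i)
        # one batched decode for the forward, diversity and identity images
        # (per-sample instance norms keep the samples independent)
        if path == "latent":
            s_j2 = nets.generate_style(bundle, z2, j)
            styles = ad.concatenate([s_j, s_j2, s_i], axis=0)
            c_rep = ad.concatenate([c_i, c_i, c_i], axis=0)
        else:
            styles = ad.concatenate([s_j, s_i], axis=0)
            c_rep = ad.concatenate([c_i, c_i], axis=0)
        decoded = nets.decode(bundle, c_rep, styles)
        x_t = decoded[:B]
        x_bar = decoded[-B:]
        g_adv = L.nonsaturating_generator_loss(
            nets.discriminate(bundle, x_t, j))
        c_t = nets.encode_content(bundle, x_t)
        cont = L.content_consistency(c_clean, c_t)
        s_t = nets.encode_style(bundle, x_t, j)
        sty = L.style_consistency(s_i if config.literal_style_consistency
                                  else s_j, s_t)
        ca = L.content_alignment(c_clean)
        x_hat = nets.decode(bundle, c_t, s_i)
        cyc = L.cycle_loss(x_i, x_hat, config.weights.lambda_g)
        ident = L.identity_loss(x_i, x_bar)
        if path == "latent":
            sd = L.style_diversity(x_t, decoded[B:2 * B],
                                   ceiling=config.sd_ceiling)
        else:
            sd = Tensor(0.0)
        w = config.weights
        sd_sign = 1.0 if config.literal_diversity_sign else -1.0
        g_total = ad.add(
            ad.add(ad.mul(g_adv, w.lambda_adv), ad.mul(cont, w.lambda_cont)),
            ad.add(
                ad.add(ad.mul(ca, w.lambda_ca), ad.mul(sd, sd_sign * w.lambda_sd)),
                ad.add(ad.mul(sty, w.lambda_sty),
                       ad.add(ad.mul(cyc, w.lambda_cyc),
                              ad.mul(ident, w.lambda_id)))))
        if not np.isfinite(g_total.data):
            raise TrainingDivergenceError("generator total loss is non-finite")
        state.opt_g.zero_grad()
        g_total.backward()
        if config.learning_rate > 0:
            state.opt_g.step()
    finally:
        for p in bundle.discriminator_side().values():
            p.requires_grad = True

    report = L.total_loss(
        {"adv": float(g_adv), "cont": float(cont), "ca": float(ca),
         "sd": float(sd), "sty": float(sty), "cyc": float(cyc),
         "id": float(ident)},
        config.weights,
        diversity_sign=1 if config.literal_diversity_sign else -1)
    state.step += 1
    row = report.as_dict()
    row.update(step=state.step, d_loss=float(d_loss),
               d_real=float(np.mean(score_real.data)),
               d_fake=float(np.mean(score_fake.data)),
               path=0.0 if path == "latent" else 1.0)
    state.history.append(row)
    return report


def fit(datasets: dict[int, np.ndarray], config: TrainConfig,
        model_config: ModelConfig | None = None,
        bundle: ModelBundle | None = None,
        state: TrainState | None = None,
        checkpoint_dir=None) -> tuple[ModelBundle, list[dict[str, float]]]:
    """Train for ``config.total_steps`` over uniformly sampled site pairs.

    ``datasets`` maps site id -> (N, 3, canvas, canvas) arrays in [-1, 1].
    Pass ``bundle``/``state`` to continue from a checkpoint.  On divergence
    the last finite checkpoint on disk is retained and the error re-raised.
    """
    sites = sorted(datasets.keys())
    if len(sites) < 2:
        raise InvalidArgumentError("need datasets for at least 2 sites")
    for s in sites:
        if len(datasets[s]) < 1:
            raise InvalidArgumentError(f"site {s} has no samples")
    if bundle is None:
        if model_config is None:
            model_config = ModelConfig(n_sites=len(sites))
        bundle = nets.build_models(model_config, seed=config.seed)
    if state is None:
        state = TrainState(bundle, config)
    data = {s: _as_batch(datasets[s]) for s in sites}
    site_index = {k: s for k, s in enumerate(sites)}

    ckpt_dir = Path(checkpoint_dir) if checkpoint_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)

    while state.step < config.total_steps:
        ia, ja = sample_site_pair(len(sites), state.rng)
        si, sj = site_index[ia], site_index[ja]
        bi = data[si][state.rng.integers(len(data[si]), size=config.batch_size)]
        bj = data[sj][state.rng.integers(len(data[sj]), size=config.batch_size)]
        report = cs_dct_step(bundle, (bi, si), (bj, sj), config, state)
        if state.step % 100 == 0 or state.step == config.total_steps:
            logger.info("step %d/%d total=%.4f cyc=%.4f id=%.4f",
                        state.step, config.total_steps, report.total,
                        report.cyc, report.id)
        if ckpt_dir and (state.step % config.checkpoint_interval == 0
                         or state.step == config.total_steps):
            save_checkpoint(bundle, state, config,
                            ckpt_dir / f"step{state.step:07d}.npz")
    return bundle, state.history


# -- checkpointing ------------------------------------------------------------

def save_checkpoint(bundle: ModelBundle, state: TrainState,
                    config: TrainConfig, path) -> None:
    """Checkpoint parameters, optimizer moments, rng state and history."""
    extra = {}
    extra.update(state.opt_g.state_arrays("adam_g"))
    extra.update(state.opt_d.state_arrays("adam_d"))
    cfg_dict = dataclasses.asdict(config)
    cfg_dict["weights"] = dataclasses.asdict(config.weights)
    meta = {
        "step": state.step,
        "t_g": state.opt_g.t,
        "t_d": state.opt_d.t,
        "rng_state": _jsonable_rng(state.rng.bit_generator.state),
        "train_config": cfg_dict,
        "history": state.history,
    }
    nets.save_bundle(bundle, path, extra_arrays=extra, meta=meta)


def load_checkpoint(path) -> tuple[ModelBundle, TrainState, TrainConfig]:
    """Restore a checkpoint to bit-identical continuation."""
    bundle, extras, meta = nets.load_bundle(path)
    cfg_dict = dict(meta["train_config"])
    cfg_dict["weights"] = LossWeights(**cfg_dict["weights"])
    config = TrainConfig(**cfg_dict)
    state = TrainState(bundle, config)
    state.step = int(meta["step"])
    state.opt_g.t = int(meta["t_g"])
    state.opt_d.t = int(meta["t_d"])
    state.opt_g.load_state_arrays("adam_g", extras)
    state.opt_d.load_state_arrays("adam_d", extras)
    state.rng.bit_generator.state = _unjsonable_rng(meta["rng_state"])
    state.history = [dict(r) for r in meta["history"]]
    return bundle, state, config


def _jsonable_rng(s):
    if isinstance(s, dict):
        return {k: _jsonable_rng(v) for k, v in s.items()}
    if isinstance(s, np.integer):
        return int(s)
    return s


def _unjsonable_rng(s):
    return s
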