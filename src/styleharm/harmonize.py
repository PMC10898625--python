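"""Inference: apply a trained model to harmonize images.

Four modes are supported.  *Site* mode draws one or more style codes from the
target site's style generator (one latent draw shared across all slices of a
volume, so the output has a single coherent appearance).  *Reference* mode
extracts the style once from a reference image through that site's style
encoder head.  *Identity* mode re-generates each slice from its own content
and own-site style, which should return the input unchanged when
disentanglement is complete.  *Interpolation* mode decodes the shared content
with convex combinations ``(1-beta)*s_A + beta*s_B`` of two site styles,
producing a continuum of intermediate appearances.

The content-code perturbation used during training is always disabled here.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from . import networks as nets
from . import volume_io as vio
from ._autodiff import no_grad
from .errors import InvalidArgumentError, ModelError
from .networks import ModelBundle
from .volume_io import Slice25D, Volume

__all__ = [
    "HarmonizationRequest", "harmonize_to_site", "harmonize_to_reference",
    "identity_translate", "interpolate_styles", "continuous_harmonize",
    "harmonize_slices",
]


@dataclass
class HarmonizationRequest:
    """What to harmonize and how."""

    source: Volume | list[Slice25D]
    mode: str = "site"            # site | reference | identity | interpolation
    target_site: int | None = None
    reference: np.ndarray | Volume | None = None
    n_styles: int = 1
    betas: list[float] = field(default_factory=list)
    seed: int = 0
    n_central: int | None = None  # default: full axial extent

    def __post_init__(self):
        if self.mode not in ("site", "reference", "identity", "interpolation"):
            raise InvalidArgumentError(f"unknown mode {self.mode!r}")
        if any(not 0.0 <= b <= 1.0 for b in self.betas):
            raise InvalidArgumentError("betas must lie in [0, 1]")
        if self.n_styles < 1:
            raise InvalidArgumentError("n_styles must be >= 1")


def _model_slices(bundle: ModelBundle, req: HarmonizationRequest
                  ) -> list[Slice25D]:
    if isinstance(req.source, Volume):
        n_central = req.n_central or req.source.voxels.shape[2]
        return vio.volume_to_model_inputs(req.source, n_central,
                                          bundle.config.canvas)
    return list(req.source)


def _slice_stack(slices: list[Slice25D]) -> np.ndarray:
    return np.stack([np.moveaxis(s.pixels, -1, 0) for s in slices]).astype(
        ad.DTYPE)


def harmonize_slices(bundle: ModelBundle, slices: list[Slice25D],
                     style: np.ndarray) -> list[Slice25D]:
    """Decode every slice's content with one shared style vector.

    Returns new slices carrying the source bookkeeping records, so they can
    be reassembled (and denormalized on the source intensity scale).
    """
    bundle.check_finite()
    x = _slice_stack(slices)
    with no_grad():
        c = nets.encode_content(bundle, x)
        y = nets.decode(bundle, c, np.atleast_2d(style)).data
    out = []
    for sl, yi in zip(slices, y):
        out.append(dataclasses.replace(sl, pixels=np.moveaxis(yi, 0, -1)))
    return out


def _to_volume(slices: list[Slice25D], template: Volume) -> Volume:
    return vio.reassemble_volume(slices, template)


def _output(bundle, req, slices, style) -> Volume | list[Slice25D]:
    harm = harmonize_slices(bundle, slices, style)
    if isinstance(req.source, Volume):
        return _to_volume(harm, req.source)
    return harm


def harmonize_to_site(bundle: ModelBundle, request: HarmonizationRequest
                      ) -> list[Volume | list[Slice25D]]:
    """Harmonize to a target site with ``n_styles`` seeded latent style draws."""
    if request.target_site is None:
        raise InvalidArgumentError("site mode needs target_site")
    slices = _model_slices(bundle, request)
    rng = np.random.default_rng(request.seed)
    outputs = []
    for _ in range(request.n_styles):
        z = rng.standard_normal((1, bundle.config.d_z)).astype(ad.DTYPE)
        with no_grad():
            s = nets.generate_style(bundle, z, request.target_site).data
        outputs.append(_output(bundle, request, slices, s))
    return outputs


def extract_reference_style(bundle: ModelBundle,
                            reference: np.ndarray | Volume,
                            site: int) -> np.ndarray:
    """Style of a reference image: its central 2.5D slice, one extraction."""
    if reference is None:
        raise InvalidArgumentError("reference mode needs a reference image")
    if isinstance(reference, Volume):
        sls = vio.volume_to_model_inputs(reference, 1, bundle.config.canvas)
        x = _slice_stack(sls)
    else:
        ref = np.asarray(reference, dtype=ad.DTYPE)
        if ref.ndim == 3 and ref.shape[-1] == bundle.config.in_channels:
            ref = np.moveaxis(ref, -1, 0)
        if ref.ndim == 2:
            ref = np.repeat(ref[None], bundle.config.in_channels, axis=0)
        x = ref[None]
    with no_grad():
        return nets.encode_style(bundle, x, site).data


def harmonize_to_reference(bundle: ModelBundle,
                           request: HarmonizationRequest
                           ) -> Volume | list[Slice25D]:
    """Harmonize all source slices to the style of one reference image."""
    if request.target_site is None:
        raise InvalidArgumentError(
            "reference mode needs target_site (the reference's site branch)")
    s = extract_reference_style(bundle, request.reference, request.target_site)
    slices = _model_slices(bundle, request)
    return _output(bundle, request, slices, s)


def identity_translate(bundle: ModelBundle, source: Volume | list[Slice25D],
                       own_site: int) -> Volume | list[Slice25D]:
    """Self-translation: each slice decoded from its own content and style."""
    req = HarmonizationRequest(source=source, mode="identity",
                               target_site=own_site)
    slices = _model_slices(bundle, req)
    bundle.check_finite()
    x = _slice_stack(slices)
    with no_grad():
        c = nets.encode_content(bundle, x)
        s = nets.encode_style(bundle, x, own_site)  # per-slice own style
        y = nets.decode(bundle, c, s).data
    harm = [dataclasses.replace(sl, pixels=np.moveaxis(yi, 0, -1))
            for sl, yi in zip(slices, y)]
    if isinstance(source, Volume):
        return _to_volume(harm, source)
    return harm


def interpolate_styles(s_a: np.ndarray, s_b: np.ndarray,
                       beta: float) -> np.ndarray:
    """Convex combination (1-beta)*s_A + beta*s_B of two style codes."""
    if not 0.0 <= beta <= 1.0:
        raise InvalidArgumentError(f"beta {beta} outside [0, 1]")
    s_a = np.asarray(s_a, dtype=ad.DTYPE)
    s_b = np.asarray(s_b, dtype=ad.DTYPE)
    if s_a.shape != s_b.shape:
        raise InvalidArgumentError("style codes must have equal length")
    if beta == 0.0:
        return s_a.copy()
    if beta == 1.0:
        return s_b.copy()
    return ((1.0 - ad.DTYPE(beta)) * s_a + ad.DTYPE(beta) * s_b).astype(
        ad.DTYPE)


def continuous_harmonize(bundle: ModelBundle, source: Volume | list[Slice25D],
                         site_a: int, site_b: int, betas: list[float],
                         seed: int = 0,
                         styles: tuple[np.ndarray, np.ndarray] | None = None,
                         ) -> list[Volume | list[Slice25D]]:
    """One output per beta along the style path from site A to site B.

    Endpoint styles come from seeded latent draws of the two sites' style
    generators unless explicit ``styles=(s_A, s_B)`` are given.  All outputs
    share the source's content codes; beta=0 and beta=1 reproduce the
    endpoint harmonizations exactly.
    """
    if not betas:
        raise InvalidArgumentError("betas must be non-empty")
    req = HarmonizationRequest(source=source, mode="interpolation",
                               target_site=site_a, betas=list(betas),
                               seed=seed)
    if styles is None:
        rng = np.random.default_rng(seed)
        z_a = rng.standard_normal((1, bundle.config.d_z)).astype(ad.DTYPE)
        z_b = rng.standard_normal((1, bundle.config.d_z)).astype(ad.DTYPE)
        with no_grad():
            s_a = nets.generate_style(bundle, z_a, site_a).data
            s_b = nets.generate_style(bundle, z_b, site_b).data
    else:
        s_a, s_b = (np.atleast_2d(np.asarray(s, dtype=ad.DTYPE))
                    for s in styles)
    slices = _model_slices(bundle, req)
    outputs = []
    for beta in betas:
        s = interpolate_styles(s_a, s_b, float(beta))
        outputs.append(_output(bundle, req, slices, s))
    return outputs
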