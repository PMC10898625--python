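"""Multi-site synthetic MR-like phantom data with known content and style.

Real multi-site brain MRI is access-restricted, so this module generates the
structure such data is assumed to have: a shared anatomy (site-invariant
content) rendered under site-specific appearance styles (site-dependent
intensity levels, contrast exponent, multiplicative bias field, blur and
noise), with intra-site style jitter.  Because content and style are known
exactly, it can also produce what real studies rarely have: *paired*
renderings of the same anatomy under every site's style (synthetic traveling
phantoms) together with ground-truth tissue masks.

The anatomy is a nested-ellipse head phantom -- an outer CSF-like ring, a
GM-like shell, a WM-like core and a small CSF-like central ventricle --
warped by a smooth random deformation.  Tissue classes are labelled
0=background, 1=CSF-like, 2=GM-like, 3=WM-like, with per-class mean
intensities strictly increasing (a T1-like ordering).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import resize

from .errors import InvalidArgumentError

__all__ = [
    "SiteStyleSpec", "PhantomSample", "SyntheticDataset",
    "make_site_specs", "sample_anatomy", "render", "make_dataset",
    "degrade_resolution", "write_dataset",
]

N_TISSUE_CLASSES = 3
FWHM_TO_SIGMA = 1.0 / 2.3548200450309493  # sigma = FWHM / (2 sqrt(2 ln 2))

# Per-class base intensity ranges sites are drawn from (background is 0).
# Ranges are disjoint so class means are strictly ordered for every site.
_CLASS_RANGES = ((0.20, 0.40), (0.45, 0.65), (0.70, 0.95))
_MIN_SITE_SEPARATION = 0.12  # max-norm distance between site class-mean vectors


@dataclass(frozen=True)
class SiteStyleSpec:
    """The appearance style of one imaging site.

    ``class_means`` holds the background plus the three tissue-class mean
    intensities on a [0, 1] scale; the rendered value of class k is
    ``class_means[k] ** gamma``.  Dispersion parameters describe the
    site's bias field, blur, noise and intra-site jitter.
    """

    site_id: int
    class_means: tuple[float, ...]
    gamma: float
    bias_amplitude: float
    bias_scale: float
    noise_sd: float
    blur_fwhm: float
    jitter_sd: float

    def __post_init__(self):
        if len(self.class_means) != N_TISSUE_CLASSES + 1:
            raise InvalidArgumentError("class_means must have 4 entries")
        if list(self.class_means) != sorted(self.class_means) or \
                len(set(self.class_means)) != len(self.class_means):
            raise InvalidArgumentError("class_means must be strictly increasing")
        if self.gamma <= 0:
            raise InvalidArgumentError("gamma must be positive")
        for name in ("bias_amplitude", "noise_sd", "blur_fwhm", "jitter_sd"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be nonnegative")


@dataclass
class PhantomSample:
    """A rendered phantom with its ground truth."""

    image: np.ndarray
    mask: np.ndarray
    anatomy_seed: int
    site_id: int
    style_draw: dict[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise InvalidArgumentError("image and mask shapes differ")
        if not np.all(np.isfinite(self.image)):
            raise InvalidArgumentError("image must be finite")


def make_site_specs(n_sites: int, seed: int, jitter_sd: float = 0.02,
                    ) -> list[SiteStyleSpec]:
    """Draw ``n_sites`` pairwise-distinct site styles, deterministically.

    Class-mean vectors are rejection-sampled to stay at least
    ``_MIN_SITE_SEPARATION`` apart in max-norm so sites remain separable by
    appearance alone despite intra-site jitter.
    """
    if n_sites < 2:
        raise InvalidArgumentError("harmonization needs at least 2 sites")
    rng = np.random.default_rng(seed)
    specs: list[SiteStyleSpec] = []
    mean_vecs: list[np.ndarray] = []
    for site in range(n_sites):
        for _ in range(10_000):
            means = np.array([rng.uniform(lo, hi) for lo, hi in _CLASS_RANGES])
            if all(np.max(np.abs(means - m)) >= _MIN_SITE_SEPARATION
                   for m in mean_vecs):
                break
        else:  # pragma: no cover - only hit with very many sites
            raise InvalidArgumentError(
                f"cannot place {n_sites} separable sites")
        mean_vecs.append(means)
        specs.append(SiteStyleSpec(
            site_id=site,
            class_means=(0.0, *np.round(means, 6)),
            gamma=float(rng.uniform(0.75, 1.3)),
            bias_amplitude=float(rng.uniform(0.02, 0.08)),
            bias_scale=float(rng.uniform(12.0, 24.0)),
            noise_sd=float(rng.uniform(0.01, 0.03)),
            blur_fwhm=float(rng.uniform(1.0, 2.5)),
            jitter_sd=float(jitter_sd),
        ))
    return specs


# -- anatomy ------------------------------------------------------------------

def _template_labels(xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
    """Analytic nested-ellipse labels at (possibly warped) unit coordinates.

    ``xx, yy`` are coordinates in [-1, 1] across the canvas.
    """
    r_head = np.sqrt((xx / 0.84) ** 2 + (yy / 0.72) ** 2)
    r_vent = np.sqrt(((xx - 0.05) / 0.20) ** 2 + (yy / 0.12) ** 2)
    labels = np.zeros(xx.shape, dtype=np.uint8)
    labels[r_head <= 1.0] = 1               # CSF-like outer ring
    labels[r_head <= 0.82] = 2              # GM-like shell
    labels[r_head <= 0.58] = 3              # WM-like core
    labels[(r_vent <= 1.0) & (labels == 3)] = 1   # CSF-like ventricle
    return labels


def sample_anatomy(anatomy_seed: int, shape: tuple[int, int] = (64, 64),
                   deform_amplitude: float | None = None) -> np.ndarray:
    """Deterministic warped nested-ellipse tissue mask with labels {0,1,2,3}.

    ``deform_amplitude`` is the RMS displacement in pixels (default 4% of the
    smaller canvas side); 0 yields the exact analytic template.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 2 or min(shape) < 32:
        raise InvalidArgumentError(
            f"shape {shape} too small for nested structures (min 32 px)")
    if deform_amplitude is None:
        deform_amplitude = 0.04 * min(shape)
    rng = np.random.default_rng(anatomy_seed)
    ys = np.linspace(-1.0, 1.0, shape[0])
    xs = np.linspace(-1.0, 1.0, shape[1])
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    if deform_amplitude > 0:
        sigma = min(shape) / 8.0
        disp = []
        for _ in range(2):
            d = gaussian_filter(rng.standard_normal(shape), sigma)
            rms = np.sqrt(np.mean(d ** 2))
            disp.append(d / rms * deform_amplitude)
        # displacements are in pixels; convert to unit coordinates
        yy = yy + disp[0] * (2.0 / (shape[0] - 1))
        xx = xx + disp[1] * (2.0 / (shape[1] - 1))
    labels = _template_labels(xx, yy)
    if len(np.unique(labels)) != N_TISSUE_CLASSES + 1:  # pragma: no cover
        raise InvalidArgumentError(
            "deformation destroyed a tissue class; lower deform_amplitude")
    return labels


# -- rendering ----------------------------------------------------------------

def render(mask: np.ndarray, spec: SiteStyleSpec,
           sample_rng: np.random.Generator) -> PhantomSample:
    """Render a tissue mask under a site style.

    Pipeline: jitter the class means and gamma, map classes to intensities,
    multiply by a smooth bias field, blur, add Gaussian noise.  With all
    dispersion parameters zero the image is the deterministic piecewise
    constant ``class_means[k] ** gamma``.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2 or not np.isin(mask, range(N_TISSUE_CLASSES + 1)).all():
        raise InvalidArgumentError("mask must be 2-D with labels in {0,1,2,3}")
    means = np.array(spec.class_means, dtype=np.float64)
    gamma = spec.gamma
    if spec.jitter_sd > 0:
        jit = sample_rng.standard_normal(N_TISSUE_CLASSES + 1)
        means = means * (1.0 + spec.jitter_sd * jit)
        gamma = gamma * (1.0 + spec.jitter_sd * sample_rng.standard_normal())
        means = np.clip(means, 0.0, None)
    values = means ** gamma
    img = values[mask]
    if spec.bias_amplitude > 0:
        fld = gaussian_filter(sample_rng.standard_normal(mask.shape),
                              spec.bias_scale)
        fld /= np.max(np.abs(fld))
        img = img * (1.0 + spec.bias_amplitude * fld)
    if spec.blur_fwhm > 0:
        img = gaussian_filter(img, spec.blur_fwhm * FWHM_TO_SIGMA)
    if spec.noise_sd > 0:
        img = img + spec.noise_sd * sample_rng.standard_normal(mask.shape)
    return PhantomSample(
        image=img.astype(np.float32),
        mask=mask.astype(np.uint8),
        anatomy_seed=-1,
        site_id=spec.site_id,
        style_draw={"class_means": means.tolist(), "gamma": float(gamma)},
    )


# -- datasets -----------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Unpaired per-site training sets plus a paired traveling-phantom test set.

    ``train[site]`` is a list of samples with site-disjoint anatomies;
    ``paired_test[a][site]`` renders test anatomy ``a`` under every site.
    """

    specs: list[SiteStyleSpec]
    train: dict[int, list[PhantomSample]]
    paired_test: list[dict[int, PhantomSample]]
    seed: int
    shape: tuple[int, int]

    @property
    def n_sites(self) -> int:
        return len(self.specs)


def make_dataset(specs: list[SiteStyleSpec], n_train_per_site: int,
                 n_paired_test: int, seed: int,
                 shape: tuple[int, int] = (64, 64)) -> SyntheticDataset:
    """Generate the full synthetic study.

    Training anatomies are disjoint across sites (unpaired, as in real
    multi-site data) and disjoint from the test anatomies; each test anatomy
    is rendered under *all* site styles with its mask retained.
    """
    if n_train_per_site < 1 or n_paired_test < 1:
        raise InvalidArgumentError("need at least one sample per split")
    n_sites = len(specs)
    rng = np.random.default_rng(seed)
    n_anat = n_sites * n_train_per_site + n_paired_test
    # unique anatomy seeds; offset keeps them clear of typical user seeds
    anat_seeds = [int(s) for s in
                  rng.choice(2 ** 31 - 1, size=n_anat, replace=False)]
    train: dict[int, list[PhantomSample]] = {}
    k = 0
    for spec in specs:
        samples = []
        for _ in range(n_train_per_site):
            aseed = anat_seeds[k]
            k += 1
            mask = sample_anatomy(aseed, shape)
            s = render(mask, spec, rng)
            s.anatomy_seed = aseed
            samples.append(s)
        train[spec.site_id] = samples
    paired: list[dict[int, PhantomSample]] = []
    for _ in range(n_paired_test):
        aseed = anat_seeds[k]
        k += 1
        mask = sample_anatomy(aseed, shape)
        group = {}
        for spec in specs:
            s = render(mask, spec, rng)
            s.anatomy_seed = aseed
            group[spec.site_id] = s
        paired.append(group)
    return SyntheticDataset(specs=list(specs), train=train,
                            paired_test=paired, seed=seed, shape=shape)


def degrade_resolution(image: np.ndarray, factor: float) -> np.ndarray:
    """Simulate a coarser acquisition at the same grid size.

    The image is anti-alias blurred, resampled to ``1/factor`` of its size and
    resampled back, emulating e.g. a 1 mm image re-acquired at 1.25 mm
    (factor 1.25).
    """
    if factor <= 1:
        raise InvalidArgumentError("factor must be > 1")
    image = np.asarray(image, dtype=np.float64)
    small = tuple(max(1, int(round(s / factor))) for s in image.shape)
    down = resize(image, small, order=3, anti_aliasing=True, mode="edge")
    up = resize(down, image.shape, order=3, anti_aliasing=False, mode="edge")
    return up.astype(np.float32)


def to_model_slice(sample: PhantomSample):
    """Bridge a 2-D phantom into the model's 2.5D input contract.

    The single slice is replicated into the three channels (the through-plane
    analog of a 2-D phantom), normalized to [-1, 1] and tagged with the
    sample's site.  Phantoms are rendered at canvas size, so no padding is
    needed.
    """
    from .volume_io import Slice25D, normalize_channels

    px = np.repeat(sample.image[..., None], 3, axis=-1).astype(np.float32)
    sl = Slice25D(pixels=px, site_id=sample.site_id,
                  volume_id=f"anat{sample.anatomy_seed}", center_index=0)
    return normalize_channels(sl)


def stack_for_training(samples: list[PhantomSample]) -> np.ndarray:
    """(N, 3, H, W) float32 training array in [-1, 1] from phantom samples."""
    return np.stack([np.moveaxis(to_model_slice(s).pixels, -1, 0)
                     for s in samples])


# -- on-disk form -------------------------------------------------------------

def write_dataset(ds: SyntheticDataset, out_dir) -> dict:
    """Write every sample as NIfTI (image + mask) plus a JSON manifest."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []

    def save(sample: PhantomSample, name: str, split: str, group: int | None):
        img_path = out_dir / f"{name}.nii.gz"
        msk_path = out_dir / f"{name}_mask.nii.gz"
        affine = np.eye(4)
        nib.save(nib.Nifti1Image(sample.image[..., None].astype(np.float32),
                                 affine), img_path)
        nib.save(nib.Nifti1Image(sample.mask[..., None].astype(np.uint8),
                                 affine), msk_path)
        entries.append({
            "file": img_path.name, "mask": msk_path.name,
            "site_id": sample.site_id, "anatomy_seed": sample.anatomy_seed,
            "split": split, "paired_group": group,
            "sha256": hashlib.sha256(
                sample.image.tobytes()).hexdigest()[:16],
        })

    for site, samples in ds.train.items():
        for i, s in enumerate(samples):
            save(s, f"train_s{site}_{i:04d}", "train", None)
    for g, group in enumerate(ds.paired_test):
        for site, s in group.items():
            save(s, f"test_g{g:03d}_s{site}", "paired_test", g)
    manifest = {
        "seed": ds.seed, "shape": list(ds.shape),
        "specs": [asdict(sp) for sp in ds.specs],
        "samples": entries,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
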