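"""Volume I/O and the 2.5D slice pipeline.

A 3-D volume is turned into model inputs by (1) selecting the centermost
axial slices, (2) forming a three-channel 2.5D window around each retained
center (adjacent slices in the channels, edges replicated), (3) linearly
normalizing each channel into [-1, 1] and (4) zero-padding to the square
training canvas.  Every step records exactly what it did (per-channel
(min, max); original size and pad offsets) so the pipeline inverts bit- or
float-exactly, and harmonized model outputs can be placed back into a copy of
the source volume.

Conventions: the axial axis is the third array axis, all indices are 0-based,
odd padding differences put the extra pixel on the bottom/right, and
denormalization of a harmonized slice reuses the *source* slice's intensity
record (generated images have no native scale of their own).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import (AssemblyError, DataError, DimensionError,
                     InvalidArgumentError, VolumeIOError)

__all__ = [
    "Volume", "Slice25D", "load_volume", "save_volume", "extract_slices_25d",
    "normalize_channels", "denormalize_channels", "pad_to_canvas", "crop_back",
    "reassemble_volume", "volume_to_model_inputs",
]


@dataclass
class Volume:
    """A 3-D intensity array with voxel spacing and optional site label."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    site_id: int | None = None
    volume_id: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise DimensionError(
                f"volume must have 3 axes, got {self.voxels.ndim}")
        if any(s <= 0 for s in self.spacing):
            raise InvalidArgumentError("spacing must be positive")
        if not np.all(np.isfinite(self.voxels)):
            raise DataError("volume contains non-finite values")


@dataclass
class Slice25D:
    """One three-channel 2.5D window plus its inversion bookkeeping.

    ``pixels`` is (H, W, 3).  ``norm_record`` is a list of three
    (min, max, degenerate) tuples once normalized; ``pad_record`` is
    (orig_h, orig_w, top, left, canvas) once padded; both are ``None``
    before the corresponding step.
    """

    pixels: np.ndarray
    site_id: int | None
    volume_id: str
    center_index: int
    norm_record: list[tuple[float, float, bool]] | None = None
    pad_record: tuple[int, int, int, int, int] | None = None


# -- NIfTI --------------------------------------------------------------------

def load_volume(path, site_id: int | None = None,
                volume_id: str | None = None) -> Volume:
    """Read a 3-D NIfTI volume (spacing from the header zooms)."""
    import nibabel as nib

    path = Path(path)
    try:
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # noqa: BLE001 - re-raise with path context
        raise VolumeIOError(f"cannot read volume {path}: {exc}") from exc
    if data.ndim != 3:
        raise DimensionError(
            f"{path}: expected a 3-D image, got {data.ndim} axes")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(voxels=data.astype(np.float32), spacing=spacing,
                  site_id=site_id,
                  volume_id=volume_id or path.name.split(".")[0])


def save_volume(volume: Volume, path) -> None:
    """Write a volume as NIfTI with a diagonal affine from its spacing."""
    import nibabel as nib

    affine = np.diag([*volume.spacing, 1.0])
    try:
        nib.save(nib.Nifti1Image(volume.voxels.astype(np.float32), affine),
                 str(path))
    except Exception as exc:  # noqa: BLE001
        raise VolumeIOError(f"cannot write volume {path}: {exc}") from exc


# -- 2.5D windows -------------------------------------------------------------

def extract_slices_25d(volume: Volume, n_central: int,
                       stride: int = 1) -> list[Slice25D]:
    """Windows of three adjacent axial slices around each retained center.

    The ``n_central`` centermost axial indices are retained; window centers
    are taken at the given stride within that band, and edge slices are
    replicated so every retained index can be a center.
    """
    vox = volume.voxels
    nz = vox.shape[2]
    if nz < 3:
        raise InvalidArgumentError("volume must have at least 3 axial slices")
    if not 1 <= n_central <= nz:
        raise InvalidArgumentError(
            f"n_central {n_central} outside [1, {nz}]")
    if stride < 1:
        raise InvalidArgumentError("stride must be >= 1")
    start = (nz - n_central) // 2
    centers = range(start, start + n_central)[::stride]
    out = []
    for c in centers:
        chans = [vox[:, :, min(max(c + d, 0), nz - 1)] for d in (-1, 0, 1)]
        out.append(Slice25D(
            pixels=np.stack(chans, axis=-1).astype(np.float32),
            site_id=volume.site_id, volume_id=volume.volume_id,
            center_index=int(c)))
    return out


def normalize_channels(sl: Slice25D,
                       bounds: tuple[float, float] | None = None) -> Slice25D:
    """Map each channel linearly so min -> -1 and max -> +1.

    By default the (min, max) come from each channel itself (per-slice
    normalization); pass explicit ``bounds`` — e.g. the whole volume's range
    — for per-volume normalization.  A constant channel maps to all zeros
    and is flagged degenerate in the record (its level is still recorded so
    inversion restores it).
    """
    px = np.asarray(sl.pixels, dtype=np.float32)
    if not np.all(np.isfinite(px)):
        raise DataError("slice contains NaN/Inf")
    record = []
    out = np.empty_like(px)
    for ch in range(px.shape[-1]):
        c = px[..., ch]
        if bounds is not None:
            lo, hi = float(bounds[0]), float(bounds[1])
        else:
            lo, hi = float(c.min()), float(c.max())
        if hi - lo <= 0:
            out[..., ch] = 0.0
            record.append((lo, hi, True))
        else:
            out[..., ch] = (c - lo) / (hi - lo) * 2.0 - 1.0
            record.append((lo, hi, False))
    return dataclasses.replace(sl, pixels=out, norm_record=record)


def denormalize_channels(sl: Slice25D) -> Slice25D:
    """Invert :func:`normalize_channels` using the slice's record."""
    if sl.norm_record is None:
        raise InvalidArgumentError("slice has no normalization record")
    px = np.asarray(sl.pixels, dtype=np.float32)
    out = np.empty_like(px)
    for ch, (lo, hi, degenerate) in enumerate(sl.norm_record):
        if degenerate:
            out[..., ch] = lo
        else:
            out[..., ch] = (px[..., ch] + 1.0) / 2.0 * (hi - lo) + lo
    return dataclasses.replace(sl, pixels=out, norm_record=None)


def pad_to_canvas(sl: Slice25D, canvas: int) -> Slice25D:
    """Center the slice in a zero square canvas (extra pixel bottom/right)."""
    h, w = sl.pixels.shape[:2]
    if h > canvas or w > canvas:
        raise InvalidArgumentError(
            f"slice {h}x{w} larger than canvas {canvas}; refusing to crop")
    top = (canvas - h) // 2
    left = (canvas - w) // 2
    out = np.zeros((canvas, canvas, sl.pixels.shape[2]), dtype=np.float32)
    out[top:top + h, left:left + w] = sl.pixels
    return dataclasses.replace(sl, pixels=out,
                               pad_record=(h, w, top, left, canvas))


def crop_back(sl: Slice25D) -> Slice25D:
    """Invert :func:`pad_to_canvas` bit-exactly using the pad record."""
    if sl.pad_record is None:
        raise InvalidArgumentError("slice has no pad record")
    h, w, top, left, _ = sl.pad_record
    return dataclasses.replace(sl, pixels=sl.pixels[top:top + h, left:left + w],
                               pad_record=None)


def volume_to_model_inputs(volume: Volume, n_central: int, canvas: int,
                           stride: int = 1,
                           normalization: str = "slice") -> list[Slice25D]:
    """extract -> normalize -> pad, ready for the networks.

    ``normalization`` is 'slice' (each channel by its own range, the
    default) or 'volume' (every channel by the volume's global range).
    """
    if normalization not in ("slice", "volume"):
        raise InvalidArgumentError(
            f"unknown normalization {normalization!r}")
    bounds = None
    if normalization == "volume":
        bounds = (float(volume.voxels.min()), float(volume.voxels.max()))
    return [pad_to_canvas(normalize_channels(s, bounds=bounds), canvas)
            for s in extract_slices_25d(volume, n_central, stride)]


def reassemble_volume(slices: list[Slice25D], template: Volume) -> Volume:
    """Place each slice's center channel back into a copy of the template.

    Inverts padding and normalization from the recorded metadata; axial
    positions outside the retained band keep the template's voxels.
    """
    if not slices:
        raise AssemblyError("no slices to assemble")
    centers = [s.center_index for s in slices]
    if len(set(centers)) != len(centers):
        raise AssemblyError("duplicate center_index in slice set")
    order = sorted(centers)
    gaps = set(np.diff(order)) if len(order) > 1 else set()
    if len(gaps) > 1:
        raise AssemblyError(f"inconsistent center_index stride: gaps {gaps}")
    vol_ids = {s.volume_id for s in slices}
    if len(vol_ids) != 1:
        raise AssemblyError(f"slices from multiple volumes: {vol_ids}")
    out = template.voxels.copy()
    nz = out.shape[2]
    for sl in slices:
        if not 0 <= sl.center_index < nz:
            raise AssemblyError(
                f"center_index {sl.center_index} outside template")
        s = sl
        if s.pad_record is not None:
            s = crop_back(s)
        if s.norm_record is not None:
            s = denormalize_channels(s)
        out[:, :, sl.center_index] = s.pixels[..., 1]
    return Volume(voxels=out, spacing=template.spacing,
                  site_id=template.site_id, volume_id=template.volume_id)
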