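"""Volume I/O and the 2.5D slice pipeline: exact-inversion bookkeeping."""

import numpy as np
import pytest

from styleharm import volume_io as vio
from styleharm.errors import (AssemblyError, DataError, DimensionError,
                              InvalidArgumentError, VolumeIOError)


def _random_volume(shape=(16, 16, 16), seed=0, spacing=(1.0, 1.0, 2.5)):
    rng = np.random.default_rng(seed)
    return vio.Volume(voxels=rng.uniform(0, 100, shape).astype(np.float32),
                      spacing=spacing, site_id=1, volume_id="v0")


def test_nifti_round_trip(tmp_path):
    vol = _random_volume()
    path = tmp_path / "v.nii.gz"
    vio.save_volume(vol, path)
    back = vio.load_volume(path, site_id=1)
    np.testing.assert_allclose(back.voxels, vol.voxels, atol=1e-6)
    assert back.spacing == vol.spacing


def test_load_rejects_4d_and_missing(tmp_path):
    import nibabel as nib

    p = tmp_path / "v4.nii.gz"
    nib.save(nib.Nifti1Image(np.zeros((4, 4, 4, 2), dtype=np.float32),
                             np.eye(4)), p)
    with pytest.raises(DimensionError):
        vio.load_volume(p)
    with pytest.raises(VolumeIOError):
        vio.load_volume(tmp_path / "missing.nii.gz")


def test_volume_invariants():
    with pytest.raises(DimensionError):
        vio.Volume(voxels=np.zeros((4, 4)))
    with pytest.raises(DataError):
        vio.Volume(voxels=np.full((4, 4, 4), np.nan))
    with pytest.raises(InvalidArgumentError):
        vio.Volume(voxels=np.zeros((4, 4, 4)), spacing=(1, 0, 1))


@pytest.mark.parametrize("nz,n_central,stride,expected", [
    (64, 60, 1, 60),   # stride 1 with edge replication: one window per center
    (64, 60, 3, 20),   # stride 3: 60/3
    (8, 8, 1, 8),      # whole volume retained; edges replicated
])
def test_window_counts(nz, n_central, stride, expected):
    vol = _random_volume((8, 8, nz))
    slices = vio.extract_slices_25d(vol, n_central, stride)
    assert len(slices) == expected
    centers = [s.center_index for s in slices]
    assert len(set(centers)) == len(centers)


def test_window_channels_are_adjacent_slices():
    vol = _random_volume((6, 6, 10))
    slices = vio.extract_slices_25d(vol, 10, 1)
    mid = slices[5]
    assert mid.center_index == 5
    np.testing.assert_array_equal(mid.pixels[..., 0], vol.voxels[:, :, 4])
    np.testing.assert_array_equal(mid.pixels[..., 1], vol.voxels[:, :, 5])
    np.testing.assert_array_equal(mid.pixels[..., 2], vol.voxels[:, :, 6])
    # edge replication at the volume boundary
    first = slices[0]
    np.testing.assert_array_equal(first.pixels[..., 0], vol.voxels[:, :, 0])


def test_thin_volume_rejected():
    vol = _random_volume((6, 6, 2))
    with pytest.raises(InvalidArgumentError):
        vio.extract_slices_25d(vol, 2)


def test_normalize_endpoints_and_round_trip():
    px = np.zeros((4, 4, 3), dtype=np.float32)
    px[..., 0] = np.linspace(0, 100, 16).reshape(4, 4)
    px[0, 0, 0], px[-1, -1, 0] = 0.0, 100.0
    px[2, 2, 0] = 50.0
    px[..., 1] = np.linspace(-5, 3, 16).reshape(4, 4)
    px[..., 2] = 7.0  # constant channel
    sl = vio.Slice25D(pixels=px, site_id=0, volume_id="v", center_index=0)
    ns = vio.normalize_channels(sl)
    assert ns.pixels.min() >= -1.0 and ns.pixels.max() <= 1.0
    assert ns.pixels[0, 0, 0] == pytest.approx(-1.0)
    assert ns.pixels[-1, -1, 0] == pytest.approx(1.0)
    assert ns.pixels[2, 2, 0] == pytest.approx(0.0)
    assert np.all(ns.pixels[..., 2] == 0.0)
    assert ns.norm_record[2][2] is True  # degenerate flag
    back = vio.denormalize_channels(ns)
    np.testing.assert_allclose(back.pixels, px, atol=1e-5)


def test_per_volume_normalization_shares_bounds():
    vol = _random_volume((8, 8, 6), seed=5)
    slices = vio.volume_to_model_inputs(vol, 4, 16, normalization="volume")
    lo, hi = float(vol.voxels.min()), float(vol.voxels.max())
    for s in slices:
        for rec in s.norm_record:
            assert rec[:2] == (lo, hi)
    with pytest.raises(InvalidArgumentError):
        vio.volume_to_model_inputs(vol, 4, 16, normalization="bogus")


def test_normalize_rejects_nan():
    px = np.full((4, 4, 3), np.nan, dtype=np.float32)
    sl = vio.Slice25D(pixels=px, site_id=0, volume_id="v", center_index=0)
    with pytest.raises(DataError):
        vio.normalize_channels(sl)


def test_pad_offsets_and_round_trip():
    px = np.random.default_rng(0).uniform(-1, 1, (200, 200, 3)).astype(
        np.float32)
    sl = vio.Slice25D(pixels=px, site_id=0, volume_id="v", center_index=0)
    padded = vio.pad_to_canvas(sl, 256)
    assert padded.pad_record[:4] == (200, 200, 28, 28)  # (256-200)/2
    cropped = vio.crop_back(padded)
    assert np.array_equal(cropped.pixels, px)  # bit-exact
    # odd difference: extra pixel bottom/right
    sl2 = vio.Slice25D(pixels=px[:199, :199], site_id=0, volume_id="v",
                       center_index=0)
    p2 = vio.pad_to_canvas(sl2, 256)
    assert p2.pad_record[:4] == (199, 199, 28, 28)
    with pytest.raises(InvalidArgumentError):
        vio.pad_to_canvas(
            vio.Slice25D(pixels=np.zeros((300, 300, 3), dtype=np.float32),
                         site_id=0, volume_id="v", center_index=0), 256)


def test_full_pipeline_round_trip_identity():
    """extract -> normalize -> pad -> crop -> denormalize -> reassemble is the
    identity on the central band."""
    vol = _random_volume((40, 44, 20), seed=3)
    slices = vio.volume_to_model_inputs(vol, n_central=12, canvas=64)
    assert all(s.pixels.min() >= -1.0 and s.pixels.max() <= 1.0
               for s in slices)
    out = vio.reassemble_volume(slices, vol)
    start = (20 - 12) // 2
    band = slice(start, start + 12)
    np.testing.assert_allclose(out.voxels[:, :, band],
                               vol.voxels[:, :, band], atol=1e-5)
    # outside the band: template copied bit-exactly
    assert np.array_equal(out.voxels[:, :, :start], vol.voxels[:, :, :start])
    assert out.spacing == vol.spacing


def test_reassemble_rejects_duplicates_and_mixed_volumes():
    vol = _random_volume((8, 8, 8))
    slices = vio.volume_to_model_inputs(vol, 4, 16)
    dup = slices + [slices[0]]
    with pytest.raises(AssemblyError):
        vio.reassemble_volume(dup, vol)
    import dataclasses
    other = [dataclasses.replace(slices[0], volume_id="other")] + slices[1:]
    with pytest.raises(AssemblyError):
        vio.reassemble_volume(other, vol)
    with pytest.raises(AssemblyError):
        vio.reassemble_volume([], vol)
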