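"""Synthetic multi-site phantom generator: determinism, content/style
factorization, dataset structure, resolution degradation."""

import numpy as np
import pytest

from styleharm import synthetic_sites as syn
from styleharm.errors import InvalidArgumentError


def test_site_specs_deterministic_and_distinct():
    a = syn.make_site_specs(3, seed=7)
    b = syn.make_site_specs(3, seed=7)
    assert a == b
    c = syn.make_site_specs(3, seed=8)
    assert any(sa != sc for sa, sc in zip(a, c))
    # pairwise distinct styles within one draw
    for i in range(3):
        for j in range(i + 1, 3):
            assert a[i].class_means != a[j].class_means


def test_site_specs_require_two_sites():
    with pytest.raises(InvalidArgumentError):
        syn.make_site_specs(1, seed=0)


def test_spec_invariants_enforced():
    with pytest.raises(InvalidArgumentError):
        syn.SiteStyleSpec(site_id=0, class_means=(0.0, 0.5, 0.4, 0.9),
                          gamma=1.0, bias_amplitude=0.0, bias_scale=10,
                          noise_sd=0.0, blur_fwhm=0.0, jitter_sd=0.0)
    with pytest.raises(InvalidArgumentError):
        syn.SiteStyleSpec(site_id=0, class_means=(0.0, 0.3, 0.5, 0.9),
                          gamma=-1.0, bias_amplitude=0.0, bias_scale=10,
                          noise_sd=0.0, blur_fwhm=0.0, jitter_sd=0.0)


def test_anatomy_deterministic_with_all_classes():
    m1 = syn.sample_anatomy(11, (64, 64))
    m2 = syn.sample_anatomy(11, (64, 64))
    assert np.array_equal(m1, m2)
    counts = np.bincount(m1.ravel(), minlength=4)
    assert np.all(counts[:4] > 0)
    assert set(np.unique(m1)) == {0, 1, 2, 3}


def test_anatomy_zero_deformation_is_analytic_template():
    m = syn.sample_anatomy(5, (64, 64), deform_amplitude=0.0)
    m2 = syn.sample_anatomy(99, (64, 64), deform_amplitude=0.0)
    assert np.array_equal(m, m2)  # seed only enters through the deformation


def test_anatomy_too_small_rejected():
    with pytest.raises(InvalidArgumentError):
        syn.sample_anatomy(0, (16, 16))


def _clean_spec(site_id=0, gamma=1.3):
    return syn.SiteStyleSpec(site_id=site_id,
                             class_means=(0.0, 0.3, 0.55, 0.9),
                             gamma=gamma, bias_amplitude=0.0, bias_scale=10,
                             noise_sd=0.0, blur_fwhm=0.0, jitter_sd=0.0)


def test_render_noiseless_closed_form():
    """With all dispersion off, class k renders exactly class_means[k]^gamma."""
    mask = syn.sample_anatomy(3, (64, 64))
    s = syn.render(mask, _clean_spec(), np.random.default_rng(0))
    for k, m in enumerate((0.0, 0.3, 0.55, 0.9)):
        vals = s.image[mask == k]
        assert np.allclose(vals, m ** 1.3, atol=1e-6)


def test_render_content_invariance_across_sites():
    mask = syn.sample_anatomy(4, (64, 64))
    specs = syn.make_site_specs(2, seed=0)
    rng = np.random.default_rng(1)
    a = syn.render(mask, specs[0], rng)
    b = syn.render(mask, specs[1], rng)
    assert np.array_equal(a.mask, b.mask)
    assert not np.allclose(a.image, b.image)


def test_render_deterministic_given_rng_seed():
    mask = syn.sample_anatomy(4, (64, 64))
    spec = syn.make_site_specs(2, seed=0)[0]
    a = syn.render(mask, spec, np.random.default_rng(42))
    b = syn.render(mask, spec, np.random.default_rng(42))
    assert np.array_equal(a.image, b.image)


def test_dataset_counts_and_disjoint_anatomies():
    specs = syn.make_site_specs(3, seed=0)
    ds = syn.make_dataset(specs, n_train_per_site=5, n_paired_test=4, seed=0)
    assert sum(len(v) for v in ds.train.values()) == 15
    assert len(ds.paired_test) == 4
    assert all(len(g) == 3 for g in ds.paired_test)
    train_seeds = {s.anatomy_seed for v in ds.train.values() for s in v}
    test_seeds = {g[0].anatomy_seed for g in ds.paired_test}
    assert len(train_seeds) == 15  # disjoint across sites too
    assert not train_seeds & test_seeds
    for g in ds.paired_test:  # paired: same anatomy -> identical masks
        masks = [g[k].mask for k in sorted(g)]
        assert all(np.array_equal(masks[0], m) for m in masks[1:])


def test_dataset_generation_is_deterministic():
    specs = syn.make_site_specs(2, seed=3)
    a = syn.make_dataset(specs, 3, 2, seed=5)
    b = syn.make_dataset(specs, 3, 2, seed=5)
    for site in a.train:
        for x, y in zip(a.train[site], b.train[site]):
            assert np.array_equal(x.image, y.image)


def test_style_separability_by_class_means():
    """Sites are identifiable from appearance alone: nearest clean-template
    classification of per-class mean intensities is perfect over 100
    samples per site."""
    specs = syn.make_site_specs(3, seed=0)
    mask = syn.sample_anatomy(1, (64, 64))
    templates = []
    for spec in specs:
        import dataclasses
        clean = dataclasses.replace(spec, jitter_sd=0.0, noise_sd=0.0,
                                    bias_amplitude=0.0)
        img = syn.render(mask, clean, np.random.default_rng(0)).image
        templates.append([img[mask == k].mean() for k in (1, 2, 3)])
    templates = np.array(templates)
    rng = np.random.default_rng(9)
    correct = total = 0
    for spec in specs:
        for _ in range(100):
            img = syn.render(mask, spec, rng).image
            feats = np.array([img[mask == k].mean() for k in (1, 2, 3)])
            pred = np.argmin(np.linalg.norm(templates - feats, axis=1))
            correct += pred == spec.site_id
            total += 1
    assert correct == total


def test_degrade_resolution_contract_and_edge_width():
    edge = np.zeros((64, 64), dtype=np.float32)
    edge[:, 32:] = 1.0
    deg = syn.degrade_resolution(edge, 1.25)
    assert deg.shape == edge.shape
    from styleharm.evaluation import edge_transition_width
    assert edge_transition_width(deg) > edge_transition_width(edge)
    with pytest.raises(InvalidArgumentError):
        syn.degrade_resolution(edge, 1.0)


def test_degrade_resolution_removes_high_frequency_energy():
    rng = np.random.default_rng(0)
    img = rng.standard_normal((64, 64)).astype(np.float32)

    def high_energy(x):
        f = np.abs(np.fft.fftshift(np.fft.fft2(x))) ** 2
        r = np.hypot(*np.meshgrid(np.arange(64) - 32, np.arange(64) - 32))
        return f[r > 16].sum()

    once = syn.degrade_resolution(img, 1.5)
    twice = syn.degrade_resolution(once, 1.5)
    assert high_energy(once) < high_energy(img)
    assert high_energy(twice) < high_energy(once)


def test_to_model_slice_contract():
    specs = syn.make_site_specs(2, seed=0)
    mask = syn.sample_anatomy(2, (64, 64))
    sample = syn.render(mask, specs[1], np.random.default_rng(0))
    sl = syn.to_model_slice(sample)
    assert sl.pixels.shape == (64, 64, 3)
    assert sl.pixels.min() >= -1.0 and sl.pixels.max() <= 1.0
    assert sl.site_id == 1
    # channels replicated from the 2-D phantom
    assert np.array_equal(sl.pixels[..., 0], sl.pixels[..., 1])


def test_write_dataset_manifest(tmp_path):
    specs = syn.make_site_specs(2, seed=0)
    ds = syn.make_dataset(specs, 2, 1, seed=0, shape=(32, 32))
    manifest = syn.write_dataset(ds, tmp_path)
    assert len(manifest["samples"]) == 2 * 2 + 1 * 2 + 0  # train + paired
    splits = {e["split"] for e in manifest["samples"]}
    assert splits == {"train", "paired_test"}
    assert (tmp_path / "manifest.json").exists()
    for e in manifest["samples"]:
        assert (tmp_path / e["file"]).exists()
        assert (tmp_path / e["mask"]).exists()
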