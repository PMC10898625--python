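"""Network-role contracts: shapes, determinism, per-site branching,
perturbation statistics and gradient flow."""

import numpy as np
import pytest

import styleharm as sh
from styleharm import _autodiff as ad
from styleharm import networks as nets
from styleharm.errors import ConfigError, InvalidArgumentError, ShapeError

CFG = sh.ModelConfig(n_sites=3, canvas=32, base_width=4, d_s=4, d_z=6)


@pytest.fixture(scope="module")
def bundle():
    return nets.build_models(CFG, seed=1)


def _x(b=2, seed=0, cfg=CFG):
    rng = np.random.default_rng(seed)
    return rng.uniform(-1, 1, (b, 3, cfg.canvas, cfg.canvas)).astype(
        np.float32)


def test_build_deterministic_and_branch_counts():
    a = nets.build_models(CFG, seed=7)
    b = nets.build_models(CFG, seed=7)
    assert set(a.params) == set(b.params)
    for k in a.params:
        assert np.array_equal(a.params[k].data, b.params[k].data)
    for role in ("senc", "disc", "sgen"):
        heads = [k for k in a.params if k.startswith(f"{role}.head")]
        assert len(heads) == 2 * CFG.n_sites  # weight + bias per site
    summary = a.summary()
    assert summary["total"] == sum(v for k, v in summary.items()
                                   if k != "total")


def test_invalid_config_rejected():
    with pytest.raises(ConfigError):
        sh.ModelConfig(n_sites=3, canvas=100, downsampling=8)
    with pytest.raises(ConfigError):
        sh.ModelConfig(n_sites=1)


def test_content_encoding_deterministic_and_shaped(bundle):
    x = _x()
    a = nets.encode_content(bundle, x)
    b = nets.encode_content(bundle, x)
    assert np.array_equal(a.data, b.data)
    assert a.shape == (2, CFG.content_channels, CFG.content_size,
                       CFG.content_size)
    with pytest.raises(ShapeError):
        nets.encode_content(bundle, np.zeros((2, 3, 16, 16),
                                             dtype=np.float32))


def test_content_perturbation_moments(bundle):
    """In training mode the code is E(x) + eta with eta ~ N(0, I): the
    difference from the clean code has mean ~0 and variance ~1."""
    cfg = sh.ModelConfig(n_sites=2, canvas=64, base_width=4, d_s=4, d_z=6)
    big = nets.build_models(cfg, seed=0)
    x = _x(b=4, cfg=cfg)
    clean = nets.encode_content(big, x)
    rng = np.random.default_rng(5)
    noisy = nets.encode_content(big, x, train_mode=True, rng=rng)
    diff = (noisy.data - clean.data).ravel()
    n = diff.size
    assert n >= 10_000
    assert abs(diff.mean()) < 3 * np.sqrt(1.0 / n)
    assert abs(diff.var() - 1.0) < 3 * np.sqrt(2.0 / n)


def test_style_encoder_site_branches(bundle):
    x = _x()
    s0 = nets.encode_style(bundle, x, 0)
    s0b = nets.encode_style(bundle, x, 0)
    s1 = nets.encode_style(bundle, x, 1)
    assert np.array_equal(s0.data, s0b.data)
    assert not np.allclose(s0.data, s1.data)
    assert s0.shape == (2, CFG.d_s)
    with pytest.raises(InvalidArgumentError):
        nets.encode_style(bundle, x, CFG.n_sites)


def test_style_generator_contract(bundle):
    rng = np.random.default_rng(0)
    z1 = rng.standard_normal((2, CFG.d_z)).astype(np.float32)
    z2 = rng.standard_normal((2, CFG.d_z)).astype(np.float32)
    s1 = nets.generate_style(bundle, z1, 1)
    s1b = nets.generate_style(bundle, z1, 1)
    s2 = nets.generate_style(bundle, z2, 1)
    assert np.array_equal(s1.data, s1b.data)
    assert not np.allclose(s1.data, s2.data)
    assert s1.shape == (2, CFG.d_s)
    with pytest.raises(InvalidArgumentError):
        nets.generate_style(bundle, z1, -1)


def test_decode_bounded_deterministic_style_sensitive(bundle):
    rng = np.random.default_rng(2)
    c = rng.standard_normal((2, CFG.content_channels, CFG.content_size,
                             CFG.content_size)).astype(np.float32)
    s_a = rng.standard_normal((2, CFG.d_s)).astype(np.float32)
    s_b = rng.standard_normal((2, CFG.d_s)).astype(np.float32)
    y1 = nets.decode(bundle, c, s_a)
    y2 = nets.decode(bundle, c, s_a)
    y3 = nets.decode(bundle, c, s_b)
    assert np.array_equal(y1.data, y2.data)
    assert not np.allclose(y1.data, y3.data)
    assert y1.data.min() >= -1.0 and y1.data.max() <= 1.0
    assert y1.shape == (2, 3, CFG.canvas, CFG.canvas)
    with pytest.raises(ShapeError):
        nets.decode(bundle, c[:, :2], s_a)


def test_discriminator_branches_and_batching(bundle):
    x = _x(b=3)
    d0 = nets.discriminate(bundle, x, 0)
    d1 = nets.discriminate(bundle, x, 1)
    assert d0.shape == (3,)
    assert np.all(np.isfinite(d0.data))
    assert np.all((d0.data > 0) & (d0.data < 1))
    assert not np.allclose(d0.data, d1.data)
    with pytest.raises(InvalidArgumentError):
        nets.discriminate(bundle, x, 5)


def test_gradient_flow_through_every_parameter_group():
    """Every network role receives a nonzero gradient from a combined
    translation loss (no dead branches)."""
    b = nets.build_models(CFG, seed=3)
    rng = np.random.default_rng(0)
    x_i = ad.Tensor(_x(2, 1))
    x_j = ad.Tensor(_x(2, 2))
    z = ad.Tensor(rng.standard_normal((2, CFG.d_z)).astype(np.float32))
    c = nets.encode_content(b, x_i)
    s_j = nets.generate_style(b, z, 1)
    s_ref = nets.encode_style(b, x_j, 1)
    x_t = nets.decode(b, c, ad.add(s_j, s_ref))
    d = nets.discriminate(b, x_t, 1)
    loss = ad.add(ad.mean(ad.abs_(ad.add(x_t, ad.mul(x_i, -1.0)))),
                  ad.mean(d))
    loss.backward()
    for role in ("cenc", "senc", "gen", "sgen", "disc"):
        grads = [p.grad for k, p in b.params.items()
                 if k.startswith(role) and ("head" not in k or
                                            ".head1." in k)]
        assert grads, role
        assert any(g is not None and np.any(g != 0) for g in grads), role


def test_checkpoint_round_trip_bit_identical(tmp_path, bundle):
    path = tmp_path / "ckpt.npz"
    nets.save_bundle(bundle, path, meta={"step": 3})
    restored, _, meta = nets.load_bundle(path)
    assert meta["step"] == 3
    assert restored.config == bundle.config
    x = _x()
    np.testing.assert_array_equal(
        nets.encode_content(bundle, x).data,
        nets.encode_content(restored, x).data)
    for k in bundle.params:
        assert np.array_equal(bundle.params[k].data,
                              restored.params[k].data)
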