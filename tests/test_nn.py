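import numpy as np
import pytest

from resdist.nn import autograd as ag
from resdist.nn.autograd import Tensor
from resdist.nn.layers import (RCIN, Conv2d, Maxout, SEBlock, col_norm,
                               instance_norm, row_norm)
from resdist.nn.networks import (DEFAULT_BLOCKS, BuildError, NetworkSpec,
                                 _ResBlockCOV, build_network, load_checkpoint,
                                 save_checkpoint)


def _gradcheck(build_loss, params, rng, n_probe=4, eps=1e-6, tol=1e-4):
    """Compare autograd gradients against central finite differences."""
    loss = build_loss()
    loss.backward()
    grads = [p.grad.copy() for p in params]
    for p, g in zip(params, grads):
        flat = p.data.ravel()
        for i in rng.choice(flat.size, size=min(n_probe, flat.size),
                            replace=False):
            orig = flat[i]
            flat[i] = orig + eps
            lp = build_loss().item()
            flat[i] = orig - eps
            lm = build_loss().item()
            flat[i] = orig
            fd = (lp - lm) / (2 * eps)
            assert g.ravel()[i] == pytest.approx(fd, rel=tol, abs=tol)


# ---------------------------------------------------------------------------
# autograd primitives

def test_gradcheck_conv2d():
    rng = np.random.default_rng(0)
    x = Tensor(rng.normal(size=(3, 6, 6)), requires_grad=True)
    conv = Conv2d(3, 2, 3, rng=rng)
    _gradcheck(lambda: (conv(x) * conv(x)).sum(),
               [x, conv.weight, conv.bias], rng)


def test_gradcheck_asymmetric_kernels():
    rng = np.random.default_rng(1)
    x = Tensor(rng.normal(size=(2, 5, 5)), requires_grad=True)
    c1 = Conv2d(2, 2, 7, 1, rng=rng)
    c2 = Conv2d(2, 2, 1, 7, rng=rng)
    _gradcheck(lambda: (c2(c1(x)) ** 2).sum(), [x, c1.weight, c2.weight], rng)


def test_gradcheck_rcin_se_maxout():
    rng = np.random.default_rng(2)
    x = Tensor(rng.normal(size=(4, 5, 5)), requires_grad=True)
    rcin = RCIN(4, rng=rng)
    se = SEBlock(4, reduction=2, rng=rng)
    mo = Maxout(4, 2, groups=2, rng=rng)

    def loss():
        return (mo(se(rcin(x))) ** 2).sum()

    _gradcheck(loss, [x, rcin.fuse.weight, se.w1, se.w2, mo.expand.weight],
               rng)


def test_gradcheck_log_softmax():
    rng = np.random.default_rng(3)
    x = Tensor(rng.normal(size=(5, 3, 3)), requires_grad=True)
    w = Tensor(rng.normal(size=(5, 3, 3)))
    _gradcheck(lambda: (ag.log_softmax(x, axis=0) * w).sum(), [x], rng,
               n_probe=8)


def test_no_grad_blocks_graph():
    x = Tensor(np.ones((2, 2)), requires_grad=True)
    with ag.no_grad():
        y = (x * 3.0).sum()
    assert y._backward is None


# ---------------------------------------------------------------------------
# normalization blocks

def test_instance_norm_constant_input_zero():
    x = Tensor(np.full((3, 4, 4), 7.0))
    out = instance_norm(x)
    np.testing.assert_allclose(out.data, 0.0, atol=1e-9)


def test_row_norm_statistics():
    rng = np.random.default_rng(4)
    x = Tensor(rng.normal(size=(3, 8, 8)))
    out = row_norm(x).data
    np.testing.assert_allclose(out.mean(axis=2), 0.0, atol=1e-5)
    np.testing.assert_allclose(out.std(axis=2), 1.0, atol=1e-5)


def test_col_norm_statistics():
    rng = np.random.default_rng(5)
    x = Tensor(rng.normal(size=(2, 9, 9)))
    out = col_norm(x).data
    np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-5)
    np.testing.assert_allclose(out.std(axis=1), 1.0, atol=1e-5)


def test_rcin_output_nonnegative():
    rng = np.random.default_rng(6)
    x = Tensor(rng.normal(size=(4, 6, 6)))
    out = RCIN(4, rng=rng)(x)
    assert np.all(out.data >= 0)


def test_rcin_degenerate_length_one():
    x = Tensor(np.ones((2, 1, 1)))
    out = RCIN(2, rng=np.random.default_rng(0))(x)
    assert np.all(np.isfinite(out.data))


# ---------------------------------------------------------------------------
# Maxout / SE

def test_channel_group_max_values():
    x = Tensor(np.stack([np.full((2, 2), 3.0), np.full((2, 2), 5.0)]))
    out = ag.channel_group_max(x, groups=2)
    np.testing.assert_allclose(out.data, 5.0)


def test_maxout_idempotent_on_duplicates():
    x = np.random.default_rng(7).normal(size=(1, 3, 3))
    dup = Tensor(np.concatenate([x, x], axis=0))
    out = ag.channel_group_max(dup, groups=2)
    np.testing.assert_allclose(out.data, x)


def test_maxout_reduces_cov_width():
    mo = Maxout(483, 64, groups=2, rng=np.random.default_rng(8))
    out = mo(Tensor(np.random.default_rng(9).normal(size=(483, 4, 4))))
    assert out.shape == (64, 4, 4)


def test_se_zero_bottleneck_halves_input():
    rng = np.random.default_rng(10)
    se = SEBlock(4, reduction=2, rng=rng)
    se.w2.data[:] = 0.0
    se.b2.data[:] = 0.0
    x = Tensor(rng.normal(size=(4, 5, 5)))
    np.testing.assert_allclose(se(x).data, x.data / 2.0, atol=1e-12)


def test_se_ratio_constant_per_channel():
    rng = np.random.default_rng(11)
    se = SEBlock(6, reduction=3, rng=rng)
    x = rng.normal(size=(6, 4, 4)) + 5.0
    out = se(Tensor(x)).data
    ratios = out / x
    for c in range(6):
        np.testing.assert_allclose(ratios[c], ratios[c].flat[0], atol=1e-12)
        assert 0.0 < ratios[c].flat[0] < 1.0


@pytest.mark.parametrize("L", [8, 17])
def test_se_shape_preserved(L):
    rng = np.random.default_rng(12)
    se = SEBlock(4, reduction=2, rng=rng)
    x = Tensor(rng.normal(size=(4, L, L)))
    assert se(x).shape == (4, L, L)


# ---------------------------------------------------------------------------
# networks

def test_default_block_counts():
    for branch, cin in [("COV", 483), ("PLM", 482), ("PRE", 484),
                        ("OTHER", 53)]:
        net = build_network(NetworkSpec(branch=branch, input_channels=cin,
                                        trunk_width=4, seed=0))
        assert net.summary()["residual_blocks"] == DEFAULT_BLOCKS[branch]


def test_forward_shapes_and_heads():
    spec = NetworkSpec(branch="COV", input_channels=6, trunk_width=4,
                       residual_blocks=2, se_reduction=2, seed=1)
    net = build_network(spec)
    x = np.random.default_rng(13).normal(size=(12, 12, 6))
    pred = net.predict(x)
    assert pred.real_distance.shape == (12, 12)
    assert pred.distogram.shape == (12, 12, 25)
    np.testing.assert_allclose(pred.distogram.sum(axis=2), 1.0, atol=1e-5)
    assert np.all(pred.real_distance >= 0)
    np.testing.assert_allclose(pred.real_distance, pred.real_distance.T)


def test_length_agnostic_forward():
    spec = NetworkSpec(branch="PRE", input_channels=5, trunk_width=4,
                       residual_blocks=1, se_reduction=2, seed=2)
    net = build_network(spec)
    rng = np.random.default_rng(14)
    for L in (10, 50):
        pred = net.predict(rng.normal(size=(L, L, 5)))
        assert pred.real_distance.shape == (L, L)


def test_zeroed_residual_block_is_identity():
    rng = np.random.default_rng(15)
    block = _ResBlockCOV(3, se_reduction=3, rng=rng)
    for p in block.parameters():
        p.data[:] = 0.0
    x = np.abs(rng.normal(size=(3, 6, 6)))  # nonneg so ReLU passes it
    out = block(Tensor(x))
    np.testing.assert_allclose(out.data, x, atol=1e-12)


def test_invalid_spec_rejected():
    with pytest.raises(BuildError):
        NetworkSpec(branch="NOPE", input_channels=4)
    with pytest.raises(BuildError):
        NetworkSpec(branch="COV", input_channels=0)


def test_checkpoint_round_trip(tmp_path):
    spec = NetworkSpec(branch="PLM", input_channels=7, trunk_width=4,
                       residual_blocks=1, se_reduction=2, seed=3)
    net = build_network(spec)
    x = np.random.default_rng(16).normal(size=(9, 9, 7))
    before = net.predict(x)
    save_checkpoint(net, tmp_path / "plm.checkpoint")
    back = load_checkpoint(tmp_path / "plm.checkpoint")
    after = back.predict(x)
    np.testing.assert_array_equal(before.real_distance, after.real_distance)
    np.testing.assert_array_equal(before.distogram, after.distogram)
    assert back.spec.branch == "PLM"


def test_checkpoint_mismatch_rejected(tmp_path):
    spec = NetworkSpec(branch="PLM", input_channels=7, trunk_width=4,
                       residual_blocks=1, se_reduction=2, seed=3)
    save_checkpoint(build_network(spec), tmp_path / "a.checkpoint")
    import json
    sp = tmp_path / "a.checkpoint.spec.json"
    data = json.loads(sp.read_text())
    data["trunk_width"] = 8
    sp.write_text(json.dumps(data))
    with pytest.raises(BuildError):
        load_checkpoint(tmp_path / "a.checkpoint")


def test_summary_text_contains_counts():
    net = build_network(NetworkSpec(branch="OTHER", input_channels=5,
                                    trunk_width=4, residual_blocks=3,
                                    se_reduction=2))
    text = net.summary_text()
    assert "residual_blocks: 3" in text
    assert "classification_head_channels: 25" in text
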