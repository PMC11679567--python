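"""Network structure: TMSC, SSA, budgets, shape and determinism contracts."""

import numpy as np
import pytest

from mffnet.nn import Conv1d, Tensor
from mffnet.srrn import (BudgetError, MFFNet, SRRNBranch, SRRNConfig,
                         SSABlock, SSAConfig, TMSCBlock, TMSCConfig,
                         count_flops, count_params)


@pytest.fixture(scope="module")
def net():
    return MFFNet(seed=0)


def test_default_budgets(net):
    assert count_params(net) <= 11_000
    assert count_flops(net) <= 1.3e8


def test_budget_violation_fails_construction():
    with pytest.raises(BudgetError):
        MFFNet(SRRNConfig(encoder_width_per_kernel=16), seed=0)


def test_param_count_hand_oracle():
    conv = Conv1d(2, 4, 3, rng=np.random.default_rng(0))
    assert sum(p.data.size for p in conv.parameters()) == 3 * 2 * 4 + 4


def test_tmsc_concatenation_and_length(rng):
    cfg = TMSCConfig(in_channels=5, out_channels_per_kernel=2)
    block = TMSCBlock(cfg, np.random.default_rng(0))
    out = block(Tensor(rng.standard_normal((2, 5, 40))))
    assert out.shape == (2, 3 * 2, 40)       # 3 kernels x 2 channels, same L
    # zero weights -> zero output (linearity, before any activation)
    for conv in block.convs:
        conv.weight.data[:] = 0.0
        conv.bias.data[:] = 0.0
    out = block(Tensor(rng.standard_normal((2, 5, 40))))
    assert np.all(out.data == 0.0)


def test_tmsc_short_input_rejected(rng):
    block = TMSCBlock(TMSCConfig(in_channels=2), np.random.default_rng(0))
    with pytest.raises(ValueError, match="kernel"):
        block(Tensor(rng.standard_normal((1, 2, 5))))


def test_ssa_uniform_weights_for_identical_segments():
    ssa = SSABlock(SSAConfig(segment_len=10, channels=2),
                   np.random.default_rng(0))
    seg = np.random.default_rng(1).standard_normal((2, 10))
    x = Tensor(np.tile(seg, (1, 1, 4)))      # 4 identical segments
    w = ssa.segment_weights(x).data
    np.testing.assert_allclose(w, 0.25, atol=1e-9)
    assert abs(w.sum() - 1.0) < 1e-6


def test_ssa_noisy_segment_gets_lowest_weight():
    rng = np.random.default_rng(2)
    ssa = SSABlock(SSAConfig(segment_len=15, channels=3),
                   np.random.default_rng(0))
    t = np.arange(90) / 30.0
    x = np.tile(np.sin(2 * np.pi * 2.0 * t), (1, 3, 1))
    x[0, :, 30:45] = 8.0 * rng.standard_normal((3, 15))  # corrupt segment 2
    w = ssa.segment_weights(Tensor(x)).data[0]
    assert np.argmin(w) == 2
    assert abs(w.sum() - 1.0) < 1e-6


def test_ssa_weights_sum_to_one(rng):
    ssa = SSABlock(SSAConfig(segment_len=8, channels=4),
                   np.random.default_rng(3))
    w = ssa.segment_weights(Tensor(rng.standard_normal((5, 4, 40)))).data
    np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-6)


def test_ssa_preserves_shape_with_padding(rng):
    ssa = SSABlock(SSAConfig(segment_len=8, channels=3),
                   np.random.default_rng(0))
    x = Tensor(rng.standard_normal((2, 3, 21)))   # 21 not divisible by 8
    assert ssa(x).shape == (2, 3, 21)


def test_refine_latent_length_and_reconstruct_roundtrip(rng):
    cfg = SRRNConfig()
    branch = SRRNBranch(cfg, np.random.default_rng(0))
    x = Tensor(rng.standard_normal((2, 12, 450)))
    latent = branch.refine(x)
    assert latent.shape[-1] == int(np.ceil(450 / 2 ** cfg.encoder_depth))
    out = branch.reconstruct(latent)
    assert out.shape == (2, cfg.branch_channels, 450)


def test_branches_have_independent_parameters(net, rng):
    x = Tensor(rng.standard_normal((1, 12, 450)))
    outs = [branch(x).data for branch in net.branches]
    assert not np.allclose(outs[0], outs[1])
    p0 = net.branches[0].enc_tmsc[0].convs[0].weight.data
    p1 = net.branches[1].enc_tmsc[0].convs[0].weight.data
    assert not np.allclose(p0, p1)


def test_forward_deterministic_and_shape_contract(net, rng):
    x = rng.standard_normal((3, 3, 12, 450))
    net.eval()
    out1 = net(x).data
    out2 = net(x).data
    np.testing.assert_array_equal(out1, out2)
    assert out1.shape == (3, 450)


def test_compose_bvp_rejects_inconsistent_shapes(net, rng):
    a = Tensor(rng.standard_normal((1, 9, 450)))
    b = Tensor(rng.standard_normal((1, 9, 449)))
    with pytest.raises(ValueError, match="shape"):
        net.compose_bvp([a, b, a])


def test_fusion_permutation_symmetry(rng):
    """Permuting bands together with fusion weights leaves output fixed."""
    net = MFFNet(seed=1)
    net.eval()
    x = rng.standard_normal((2, 3, 12, 450))
    out = net(x).data
    C = net.cfg.branch_channels
    perm = [2, 0, 1]
    net.branches = [net.branches[k] for k in perm]
    w = net.fusion.weight.data.reshape(1, 3, C, 1)
    net.fusion.weight.data = w[:, perm].reshape(1, 3 * C, 1)
    out_perm = net(x[:, perm]).data
    np.testing.assert_allclose(out, out_perm, atol=1e-9)


def test_gradient_reaches_every_parameter(net, rng):
    net.train()
    out = net(rng.standard_normal((2, 3, 12, 450)))
    (out ** 2).mean().backward()
    missing = [p for p in net.parameters() if p.grad is None]
    assert not missing
    assert all(np.any(p.grad != 0) for p in net.parameters())
    net.zero_grad()


def test_single_band_config_is_a_projection_of_one_branch(rng):
    net1 = MFFNet(SRRNConfig(num_bands=1), seed=0)
    net1.eval()
    out = net1(rng.standard_normal((1, 1, 12, 450)))
    assert out.shape == (1, 450)


def test_flop_count_matches_hand_count_for_single_conv():
    conv = Conv1d(2, 4, 3, padding=1, rng=np.random.default_rng(0))
    L = 10
    # 2 * K*Cin*Cout*L MACs-as-FLOPs + bias adds
    assert conv.flops(L) == 2 * 3 * 2 * 4 * 10 + 4 * 10
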