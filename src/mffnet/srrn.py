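"""Signal refinement & reconstruction network (SRRN).

One encoder/decoder branch per frequency band, with independent weights per
branch, fused by a 1x1 convolution into a single recovered blood-volume-pulse
trace.  The encoder stacks temporal multiscale convolution (TMSC) stages —
parallel kernels of sizes 3/5/7 whose outputs are concatenated — each
followed by batch-norm, ELU and stride-2 average pooling.  The decoder
mirrors it with spectrum self-attention (SSA), a stride-2 transposed
convolution, batch-norm and ELU per stage, restoring the temporal length
exactly.

The SSA module scores time segments by the similarity of their DCT spectra
to the mean spectrum of the window: a segment whose spectrum deviates from
the rest (transient noise, motion) receives a low weight.  The weighted
signal is then passed through a squeeze-excitation-style channel gate.

The architecture is governed by hard budgets rather than fixed widths: the
default configuration must stay within ``param_budget`` trainable scalars
and ``flop_budget`` FLOPs per forward pass (1 multiply-accumulate = 2 FLOPs;
normalization, activations and pooling counted once per element).
Construction fails if a configuration violates either budget.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.fft import dct as _scipy_dct

from .nn import (AvgPool1d, BatchNorm1d, Conv1d, ConvTranspose1d, Module,
                 Tensor, concat)
from .decompose import MultiBandStack

__all__ = [
    "TMSCConfig", "SSAConfig", "SRRNConfig", "TMSCBlock", "SSABlock",
    "SRRNBranch", "MFFNet", "BVPSignal", "count_params", "count_flops",
    "stack_to_tensor", "BudgetError",
]


class BudgetError(ValueError):
    """Raised when a configuration exceeds the parameter or FLOP budget."""


@dataclass(frozen=True)
class TMSCConfig:
    in_channels: int = 12
    out_channels_per_kernel: int = 3
    kernel_sizes: tuple[int, ...] = (3, 5, 7)

    def __post_init__(self):
        if any(k % 2 == 0 for k in self.kernel_sizes):
            raise ValueError("TMSC kernel sizes must be odd")
        if self.in_channels < 1 or self.out_channels_per_kernel < 1:
            raise ValueError("channel counts must be >= 1")

    @property
    def out_channels(self) -> int:
        return self.out_channels_per_kernel * len(self.kernel_sizes)


@dataclass(frozen=True)
class SSAConfig:
    segment_len: int = 15
    channels: int = 9
    se_hidden: int = 4
    softmax_temp: float = 4.0

    def __post_init__(self):
        if self.segment_len < 8:
            raise ValueError("segment_len must be >= 8")


@dataclass(frozen=True)
class SRRNConfig:
    """Hyper-parameters of the full multi-band network."""

    num_bands: int = 3
    input_len: int = 450
    input_channels: int = 12          # 4 regions x 3 YUV channels
    encoder_depth: int = 3
    encoder_width_per_kernel: int = 3  # -> 9 channels after concatenation
    kernel_sizes: tuple[int, ...] = (3, 5, 7)
    decoder_depth: int = 3
    ssa_segment_len: int = 15
    param_budget: int = 11_000
    flop_budget: float = 1.3e8

    @property
    def branch_channels(self) -> int:
        return self.encoder_width_per_kernel * len(self.kernel_sizes)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "SRRNConfig":
        d = json.loads(s)
        for key in ("kernel_sizes",):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


class TMSCBlock(Module):
    """Parallel temporal convolutions (same-padding), channel-concatenated."""

    def __init__(self, cfg: TMSCConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.convs = [
            Conv1d(cfg.in_channels, cfg.out_channels_per_kernel, k,
                   padding=k // 2, rng=rng)
            for k in cfg.kernel_sizes
        ]

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] < max(self.cfg.kernel_sizes):
            raise ValueError(
                f"input length {x.shape[-1]} shorter than largest kernel "
                f"{max(self.cfg.kernel_sizes)}")
        return concat([conv(x) for conv in self.convs], axis=1)

    def flops(self, L: int) -> int:
        return sum(c.flops(L) for c in self.convs)


def _dct_matrix(n: int) -> np.ndarray:
    """Orthonormal DCT-II matrix (rows = basis functions)."""
    return _scipy_dct(np.eye(n), type=2, norm="ortho", axis=0)


class SSABlock(Module):
    """Spectrum self-attention: down-weight spectrally anomalous segments.

    (a) the C x L feature map is cut into S segments of ``segment_len``
    samples and each segment is DCT-transformed; (b) a 1x1 convolution
    collapses the channel axis to one spectral descriptor per segment, and
    the cosine similarity of each descriptor to the mean descriptor, passed
    through a softmax over segments, gives weights summing to 1; (c) the
    weights (rescaled by S so a uniform attention is the identity) multiply
    their segments, followed by a squeeze-excitation channel gate.
    """

    def __init__(self, cfg: SSAConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        C, H = cfg.channels, cfg.se_hidden
        self.chan_weight = Tensor(rng.normal(0, 1 / np.sqrt(C), C),
                                  requires_grad=True)
        self.chan_bias = Tensor(np.zeros(1), requires_grad=True)
        self.se_w1 = Tensor(rng.normal(0, np.sqrt(2.0 / C), (C, H)),
                            requires_grad=True)
        self.se_b1 = Tensor(np.zeros(H), requires_grad=True)
        self.se_w2 = Tensor(rng.normal(0, np.sqrt(2.0 / H), (H, C)),
                            requires_grad=True)
        self.se_b2 = Tensor(np.ones(C), requires_grad=True)  # gate starts open
        self._dct_cache: dict[int, np.ndarray] = {}

    def _segments(self, x: Tensor) -> tuple[Tensor, int, int]:
        B, C, L = x.shape
        seg = self.cfg.segment_len
        if seg > L:
            raise ValueError(f"segment_len {seg} exceeds feature length {L}")
        pad = (-L) % seg
        if pad:
            x = x.pad_last(0, pad)
        S = (L + pad) // seg
        return x.reshape(B, C, S, seg), S, pad

    def segment_weights(self, x: Tensor) -> Tensor:
        """Per-segment attention weights, normalized to sum to 1."""
        xs, S, _ = self._segments(x)
        B, C = xs.shape[0], xs.shape[1]
        seg = self.cfg.segment_len
        if seg not in self._dct_cache:
            self._dct_cache[seg] = _dct_matrix(seg)
        D = Tensor(self._dct_cache[seg].T)          # right-multiply form
        spectra = xs @ D                            # [B, C, S, seg]
        desc = ((spectra * self.chan_weight.reshape(1, C, 1, 1)).sum(axis=1)
                + self.chan_bias)                   # [B, S, seg]
        eps = 1e-12
        # unit-normalize per segment so one high-power segment cannot
        # dominate the consensus spectrum
        unit = desc / (((desc ** 2).sum(axis=-1, keepdims=True) + eps) ** 0.5)
        m = unit.mean(axis=1, keepdims=True)        # [B, 1, seg]
        sim = (unit * m).sum(axis=-1)               # mean pairwise cosine
        return (sim * self.cfg.softmax_temp).softmax(axis=-1)

    def forward(self, x: Tensor) -> Tensor:
        B, C, L = x.shape
        xs, S, pad = self._segments(x)
        wts = self.segment_weights(x)               # [B, S]
        xw = xs * (wts.reshape(B, 1, S, 1) * float(S))
        xw = xw.reshape(B, C, L + pad)
        if pad:
            xw = xw[..., :L]
        z = xw.mean(axis=-1)                        # [B, C]
        gate = ((z @ self.se_w1 + self.se_b1).elu()
                @ self.se_w2 + self.se_b2).sigmoid()
        return xw * gate.reshape(B, C, 1)

    def flops(self, L: int) -> int:
        C = self.cfg.channels
        seg = self.cfg.segment_len
        S = -(-L // seg)
        dct_f = 2 * C * S * seg * seg               # matmul per segment
        collapse = 2 * C * S * seg                  # 1x1 channel collapse
        attn = 8 * S * seg + 5 * S                  # mean/cosine/softmax
        weighting = C * L
        se = C * L + 2 * C * self.cfg.se_hidden * 2 + 2 * C + C * L
        return dct_f + collapse + attn + weighting + se

    def out_len(self, L: int) -> int:
        return L


class SRRNBranch(Module):
    """One band's refine (encoder) / reconstruct (decoder) pair."""

    def __init__(self, cfg: SRRNConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        C = cfg.branch_channels
        self.enc_tmsc: list[TMSCBlock] = []
        self.enc_bn: list[BatchNorm1d] = []
        in_ch = cfg.input_channels
        for _ in range(cfg.encoder_depth):
            tcfg = TMSCConfig(in_channels=in_ch,
                              out_channels_per_kernel=cfg.encoder_width_per_kernel,
                              kernel_sizes=cfg.kernel_sizes)
            self.enc_tmsc.append(TMSCBlock(tcfg, rng))
            self.enc_bn.append(BatchNorm1d(C))
            in_ch = C
        self.pool = AvgPool1d()
        self.dec_ssa: list[SSABlock] = []
        self.dec_deconv: list[ConvTranspose1d] = []
        self.dec_bn: list[BatchNorm1d] = []
        for _ in range(cfg.decoder_depth):
            self.dec_ssa.append(SSABlock(
                SSAConfig(segment_len=cfg.ssa_segment_len, channels=C), rng))
            self.dec_deconv.append(ConvTranspose1d(C, C, rng=rng))
            self.dec_bn.append(BatchNorm1d(C))
        # temporal lengths after each encoder pool, used to crop the decoder
        self.enc_lens = [cfg.input_len]
        for _ in range(cfg.encoder_depth):
            self.enc_lens.append(-(-self.enc_lens[-1] // 2))

    def refine(self, x: Tensor) -> Tensor:
        """Encoder: [B, C_in, T] -> latent [B, C, ceil(T / 2^depth)]."""
        for tmsc, bn in zip(self.enc_tmsc, self.enc_bn):
            x = self.pool(bn(tmsc(x)).elu())
        return x

    def reconstruct(self, latent: Tensor) -> Tensor:
        """Decoder: latent -> [B, C, T], exact temporal length restored."""
        x = latent
        targets = self.enc_lens[-2::-1]  # lengths to restore, innermost first
        for ssa, deconv, bn, target in zip(self.dec_ssa, self.dec_deconv,
                                           self.dec_bn, targets):
            x = deconv(ssa(x))
            if x.shape[-1] != target:
                x = x[..., :target]
            x = bn(x).elu()
        return x

    def forward(self, x: Tensor) -> Tensor:
        return self.reconstruct(self.refine(x))

    def flops(self) -> int:
        total = 0
        C = self.cfg.branch_channels
        L = self.cfg.input_len
        for tmsc, bn in zip(self.enc_tmsc, self.enc_bn):
            total += tmsc.flops(L)
            total += bn.flops(L) + C * L        # BN + ELU per element
            L = self.pool.out_len(L)
            total += C * L                       # pooling
        targets = self.enc_lens[-2::-1]
        for ssa, deconv, bn, target in zip(self.dec_ssa, self.dec_deconv,
                                           self.dec_bn, targets):
            total += ssa.flops(L)
            total += deconv.flops(L)
            L = target
            total += bn.flops(L) + C * L
        return total


@dataclass
class BVPSignal:
    """A recovered blood-volume-pulse trace."""

    values: np.ndarray
    fps: float = 30.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("BVP signal contains non-finite values")


class MFFNet(Module):
    """Multi-band branches + 1x1 fusion into one BVP trace.

    Input: ``[B, K, C_in, T]`` float array (band-decomposed, channel-
    flattened spatio-temporal maps).  Output: ``[B, T]``.
    """

    def __init__(self, cfg: SRRNConfig | None = None, seed: int = 0):
        super().__init__()
        self.cfg = cfg or SRRNConfig()
        rng = np.random.default_rng(seed)
        self.branches = [SRRNBranch(self.cfg, rng)
                         for _ in range(self.cfg.num_bands)]
        C = self.cfg.branch_channels
        self.fusion = Conv1d(self.cfg.num_bands * C, 1, 1, rng=rng)
        n_params, n_flops = count_params(self), count_flops(self)
        if n_params > self.cfg.param_budget:
            raise BudgetError(
                f"{n_params} trainable parameters exceed the budget of "
                f"{self.cfg.param_budget}")
        if n_flops > self.cfg.flop_budget:
            raise BudgetError(
                f"{n_flops:.3g} FLOPs exceed the budget of "
                f"{self.cfg.flop_budget:.3g}")

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float64))
        if x.ndim != 4 or x.shape[1] != self.cfg.num_bands:
            raise ValueError(
                f"expected input [B, {self.cfg.num_bands}, "
                f"{self.cfg.input_channels}, T], got {x.shape}")
        outs = [branch(x[:, k]) for k, branch in enumerate(self.branches)]
        return self.compose_bvp(outs)

    def compose_bvp(self, per_band: list[Tensor]) -> Tensor:
        shapes = {t.shape for t in per_band}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent per-band shapes: {shapes}")
        fused = self.fusion(concat(per_band, axis=1))    # [B, 1, T]
        return fused.reshape(fused.shape[0], fused.shape[2])

    def predict(self, x, fps: float = 30.0) -> list[BVPSignal]:
        """Inference helper: eval-mode forward to BVPSignal objects."""
        was_training = self.training
        self.eval()
        out = self.forward(x).data
        if was_training:
            self.train()
        return [BVPSignal(values=row, fps=fps) for row in out]


def count_params(net: Module) -> int:
    """Number of trainable scalars."""
    return net.num_params()


def count_flops(net: MFFNet, input_len: int | None = None) -> int:
    """FLOPs of one forward pass (1 MAC = 2 FLOPs; BN/activation/pool
    counted once per element)."""
    total = sum(branch.flops() for branch in net.branches)
    L = input_len or net.cfg.input_len
    total += net.fusion.flops(L)
    return int(total)


def stack_to_tensor(stack: MultiBandStack) -> np.ndarray:
    """[K, T, I, C] multi-band stack -> [K, I*C, T] network input."""
    K, T, I, C = stack.values.shape
    return stack.values.transpose(0, 2, 3, 1).reshape(K, I * C, T)
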