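"""Training: negative-Pearson loss and the over-sampling scheme (OSS).

Heart-rate distributions in rPPG corpora are heavily imbalanced (resting
rates dominate), so a network trained on plain shuffled batches overfits the
common HR range.  The over-sampling scheme counters this in two phases:
phase 1 trains on all samples with a large learning rate; phase 2 fine-tunes
with a small learning rate on batches whose composition is stratified by HR
group — every group contributes the same number of slots per batch, with
replacement inside under-represented groups.

The loss is 1 - r, the negative sample Pearson correlation between the
predicted and reference pulse waveforms; it is invariant to the scale and
offset of both arguments, which matches how BVP is measured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, Tensor
from .decompose import BandSpec, decompose_multiband
from .srrn import MFFNet, stack_to_tensor
from .stmap import (PreprocessConfig, RGBRegionSeries, SpatioTemporalMap,
                    inject_white_noise, preprocess)

logger = logging.getLogger(__name__)

__all__ = [
    "SampleRecord", "HRGrouping", "TrainPlan", "pearson_loss",
    "pearson_loss_np", "stratified_batches", "prepare_input", "train",
]


@dataclass
class SampleRecord:
    """One training pair: normalized map + reference BVP + scalar HR."""

    stmap: SpatioTemporalMap
    gt_bvp: np.ndarray
    gt_hr: float

    def __post_init__(self):
        self.gt_bvp = np.asarray(self.gt_bvp, dtype=np.float64)
        if not np.all(np.isfinite(self.gt_bvp)):
            raise ValueError("ground-truth BVP contains non-finite values")
        if not 36.0 <= self.gt_hr <= 240.0:
            raise ValueError(f"gt_hr {self.gt_hr} outside [36, 240] bpm")


@dataclass(frozen=True)
class HRGrouping:
    """HR bins used to stratify batches; default 10-bpm bins over 40-180."""

    bin_edges: tuple[float, ...] = tuple(float(b) for b in range(40, 190, 10))

    def group_of(self, hr_bpm: float) -> int:
        idx = int(np.searchsorted(self.bin_edges, hr_bpm, side="right")) - 1
        return int(np.clip(idx, 0, len(self.bin_edges) - 2))

    @property
    def n_groups(self) -> int:
        return len(self.bin_edges) - 1


@dataclass
class TrainPlan:
    phase1_lr: float = 3e-3
    phase2_lr: float = 3e-4
    phase1_epochs: int = 10
    phase2_epochs: int = 5
    batch_size: int = 32
    rng_seed: int = 0
    noise_snr_db: float = 10.0   # training-time white-noise augmentation

    def __post_init__(self):
        if not self.phase1_lr > self.phase2_lr > 0:
            raise ValueError("require phase1_lr > phase2_lr > 0")


def pearson_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Differentiable 1 - Pearson(pred, target), averaged over the batch.

    ``pred``: Tensor [B, N]; ``target``: array [B, N].  Range [0, 2].
    """
    t = np.asarray(target, dtype=np.float64)
    if pred.ndim == 1:
        pred = pred.reshape(1, -1)
        t = t.reshape(1, -1)
    tc = t - t.mean(axis=1, keepdims=True)
    t_norm = np.sqrt((tc ** 2).sum(axis=1))
    if np.any(t_norm == 0):
        raise ValueError("constant target trace: Pearson undefined")
    pc = pred - pred.mean(axis=1, keepdims=True)
    denom = (((pc ** 2).sum(axis=1) + 1e-24) ** 0.5) * t_norm
    r = (pc * tc).sum(axis=1) / denom
    return (1.0 - r).mean()


def pearson_loss_np(pred: np.ndarray, target: np.ndarray) -> float:
    """Scalar 1 - r for plain arrays; constant pred reports r = 0 (loss 1)."""
    pred = np.asarray(pred, dtype=np.float64).ravel()
    target = np.asarray(target, dtype=np.float64).ravel()
    if len(pred) != len(target) or len(pred) < 2:
        raise ValueError("need equal-length arrays of length >= 2")
    if np.std(target) == 0:
        raise ValueError("constant target trace: Pearson undefined")
    if np.std(pred) == 0:
        logger.warning("pearson_loss: constant prediction, reporting r = 0")
        return 1.0
    r = np.corrcoef(pred, target)[0, 1]
    return float(1.0 - r)


def stratified_batches(records: list[SampleRecord], grouping: HRGrouping,
                       batch_size: int, seed: int, n_batches: int,
                       strict: bool = False):
    """Yield index batches with equal per-group representation.

    Each batch holds ``batch_size // G`` samples from every non-empty HR
    group, the remainder distributed round-robin; groups smaller than their
    quota are sampled with replacement (over-sampling).  Deterministic under
    ``seed``.  With ``strict=True`` an HR bin that received no samples is an
    error (named in the message) instead of being dropped.
    """
    by_group: dict[int, list[int]] = {}
    for idx, rec in enumerate(records):
        by_group.setdefault(grouping.group_of(rec.gt_hr), []).append(idx)
    if strict:
        empty = [g for g in range(grouping.n_groups) if g not in by_group]
        if empty:
            bins = [f"[{grouping.bin_edges[g]}, {grouping.bin_edges[g+1]}) bpm"
                    for g in empty]
            raise ValueError("empty HR group(s): " + ", ".join(bins))
    groups = sorted(by_group)
    G = len(groups)
    if G == 0:
        raise ValueError("no samples")
    if batch_size < G:
        raise ValueError(f"batch_size {batch_size} < {G} non-empty groups")
    rng = np.random.default_rng(seed)
    base, rem = divmod(batch_size, G)
    for b in range(n_batches):
        batch: list[int] = []
        for j, g in enumerate(groups):
            quota = base + (1 if (j + b) % G < rem else 0)
            pool = by_group[g]
            if quota <= len(pool):
                batch.extend(rng.choice(pool, size=quota, replace=False))
            else:
                batch.extend(rng.choice(pool, size=quota, replace=True))
        rng.shuffle(batch)
        yield [int(i) for i in batch]


def prepare_input(stmap: SpatioTemporalMap, bands: BandSpec,
                  noise_snr_db: float = np.inf,
                  rng_seed: int = 0) -> np.ndarray:
    """Normalized map -> [K, C, T] network input (optional noise augment)."""
    if not np.isinf(noise_snr_db):
        stmap = inject_white_noise(
            stmap, PreprocessConfig(noise_snr_db=noise_snr_db,
                                    rng_seed=rng_seed))
    return stack_to_tensor(decompose_multiband(stmap, bands))


def _epoch(model: MFFNet, inputs: np.ndarray, targets: np.ndarray,
           batches, opt: Adam) -> float:
    losses = []
    for idx in batches:
        opt.zero_grad()
        out = model(inputs[idx])
        loss = pearson_loss(out, targets[idx])
        if not np.isfinite(loss.data):
            raise RuntimeError(
                f"training diverged: loss = {float(loss.data)}")
        loss.backward()
        opt.step()
        losses.append(float(loss.data))
    return float(np.mean(losses))


def train(model: MFFNet, records: list[SampleRecord], plan: TrainPlan,
          grouping: HRGrouping | None = None,
          bands: BandSpec | None = None,
          oversample: bool = True) -> list[dict]:
    """Two-phase training; returns per-epoch history rows.

    Phase 1: plain shuffled batches at ``phase1_lr``.  Phase 2: HR-stratified
    batches at ``phase2_lr`` (or plain batches when ``oversample=False``,
    which is the ablation baseline).  Targets are z-scored reference BVP
    traces; the loss is the negative Pearson correlation.
    """
    grouping = grouping or HRGrouping()
    bands = bands or BandSpec(fps=records[0].stmap.fps)
    rng = np.random.default_rng(plan.rng_seed)
    n = len(records)
    inputs = np.stack([
        prepare_input(rec.stmap, bands, plan.noise_snr_db,
                      rng_seed=int(rng.integers(2**31)))
        for rec in records
    ])
    targets = np.stack([
        (rec.gt_bvp - rec.gt_bvp.mean()) / rec.gt_bvp.std()
        for rec in records
    ])
    history: list[dict] = []
    steps_per_epoch = max(1, n // plan.batch_size)

    model.train()
    opt = Adam(model.parameters(), lr=plan.phase1_lr)
    for epoch in range(plan.phase1_epochs):
        order = rng.permutation(n)
        batches = [order[i * plan.batch_size:(i + 1) * plan.batch_size]
                   for i in range(steps_per_epoch)]
        mean_loss = _epoch(model, inputs, targets, batches, opt)
        history.append({"phase": 1, "epoch": epoch, "loss": mean_loss})
        logger.info("phase 1 epoch %d: loss %.4f", epoch, mean_loss)

    opt = Adam(model.parameters(), lr=plan.phase2_lr)
    for epoch in range(plan.phase2_epochs):
        if oversample:
            batches = stratified_batches(
                records, grouping, plan.batch_size,
                seed=int(rng.integers(2**31)), n_batches=steps_per_epoch)
        else:
            order = rng.permutation(n)
            batches = [order[i * plan.batch_size:(i + 1) * plan.batch_size]
                       for i in range(steps_per_epoch)]
        mean_loss = _epoch(model, inputs, targets, batches, opt)
        history.append({"phase": 2, "epoch": epoch, "loss": mean_loss})
        logger.info("phase 2 epoch %d: loss %.4f", epoch, mean_loss)
    model.eval()
    return history
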