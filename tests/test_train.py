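"""Loss closed forms, stratified sampler counting, small training runs."""

import numpy as np
import pytest

from mffnet.nn import Tensor
from mffnet.srrn import MFFNet, SRRNConfig
from mffnet.stmap import SpatioTemporalMap
from mffnet.train import (HRGrouping, SampleRecord, TrainPlan, pearson_loss,
                          pearson_loss_np, prepare_input, stratified_batches,
                          train)


@pytest.mark.parametrize("pred,target,expected", [
    ([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0], 0.0),
    ([1.0, 2.0, 3.0, 4.0], [-1.0, -2.0, -3.0, -4.0], 2.0),
    ([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 5.0], 0.0173),
])
def test_pearson_loss_closed_forms(pred, target, expected):
    loss = pearson_loss_np(np.array(pred), np.array(target))
    assert loss == pytest.approx(expected, abs=1e-3)
    diff = pearson_loss(Tensor(np.array([pred], dtype=float)),
                        np.array([target], dtype=float))
    assert float(diff.data) == pytest.approx(expected, abs=1e-3)


def test_pearson_loss_affine_invariance(rng):
    pred = rng.standard_normal(100)
    target = rng.standard_normal(100)
    base = pearson_loss_np(pred, target)
    shifted = pearson_loss_np(3.2 * pred + 7.0, 0.5 * target - 2.0)
    assert abs(base - shifted) < 1e-9


def test_pearson_loss_constant_pred_warns(caplog, rng):
    loss = pearson_loss_np(np.full(10, 2.0), rng.standard_normal(10))
    assert loss == 1.0
    with pytest.raises(ValueError):
        pearson_loss_np(rng.standard_normal(10), np.full(10, 2.0))


def _records_with_hrs(hrs, rng):
    recs = []
    for hr in hrs:
        stmap = SpatioTemporalMap(rng.standard_normal((450, 4, 3)),
                                  fps=30.0, normalized=True)
        recs.append(SampleRecord(stmap=stmap,
                                 gt_bvp=rng.standard_normal(450),
                                 gt_hr=float(hr)))
    return recs


def test_grouping_assigns_each_sample_once():
    g = HRGrouping()
    assert g.n_groups == 14
    for hr in (40.0, 45.0, 99.9, 179.9, 180.0):
        assert 0 <= g.group_of(hr) < g.n_groups
    assert g.group_of(65.0) == 2


def test_stratified_batches_equal_quota(rng):
    hrs = ([65] * 10 + [75] * 10 + [85] * 10 + [95] * 10)
    recs = _records_with_hrs(hrs, rng)
    batches = list(stratified_batches(recs, HRGrouping(), batch_size=16,
                                      seed=0, n_batches=5))
    g = HRGrouping()
    for batch in batches:
        assert len(batch) == 16
        counts = np.bincount([g.group_of(recs[i].gt_hr) for i in batch],
                             minlength=g.n_groups)
        assert all(c in (0, 4) for c in counts)
        assert (counts > 0).sum() == 4


def test_oversampling_counts(rng):
    """Size-(100,5,5,5) groups each supply ~25% of slots over many batches."""
    hrs = [65] * 100 + [95] * 5 + [125] * 5 + [155] * 5
    recs = _records_with_hrs(hrs, rng)
    g = HRGrouping()
    tally = np.zeros(g.n_groups)
    for batch in stratified_batches(recs, g, batch_size=16, seed=1,
                                    n_batches=100):
        for i in batch:
            tally[g.group_of(recs[i].gt_hr)] += 1
    occupied = tally[tally > 0]
    assert len(occupied) == 4
    np.testing.assert_allclose(occupied, 400, atol=1)  # 1600 slots / 4


def test_stratified_batches_deterministic(rng):
    recs = _records_with_hrs([65] * 8 + [95] * 8, rng)
    a = list(stratified_batches(recs, HRGrouping(), 8, seed=9, n_batches=4))
    b = list(stratified_batches(recs, HRGrouping(), 8, seed=9, n_batches=4))
    assert a == b


def test_strict_mode_names_empty_bins(rng):
    recs = _records_with_hrs([65] * 4, rng)
    with pytest.raises(ValueError, match=r"\[50.0, 60.0\)"):
        list(stratified_batches(recs, HRGrouping(), 14, seed=0, n_batches=1,
                                strict=True))


def test_batch_size_smaller_than_groups_rejected(rng):
    recs = _records_with_hrs([65, 95, 125, 155], rng)
    with pytest.raises(ValueError, match="batch_size"):
        list(stratified_batches(recs, HRGrouping(), 2, seed=0, n_batches=1))


def test_trainplan_requires_decreasing_lr():
    with pytest.raises(ValueError):
        TrainPlan(phase1_lr=1e-4, phase2_lr=1e-3)


def test_single_sample_overfit():
    """Capacity sanity: the network memorizes one window quickly."""
    from mffnet.synth import SynthConfig, gen_sample
    from mffnet.stmap import preprocess
    from mffnet.decompose import BandSpec
    from mffnet.nn import Adam

    s = gen_sample(SynthConfig(snr_db=np.inf, drift_amp=0.0,
                               artifact_rate=0.0, seed=1), 0)
    x = prepare_input(preprocess(s.stmap), BandSpec(fps=30.0))[None]
    target = ((s.gt_bvp - s.gt_bvp.mean()) / s.gt_bvp.std())[None]
    model = MFFNet(seed=0)
    model.train()
    opt = Adam(model.parameters(), lr=3e-3)
    final = None
    for step in range(500):
        opt.zero_grad()
        loss = pearson_loss(model(x), target)
        loss.backward()
        opt.step()
        final = float(loss.data)
        if final < 0.01:
            break
    assert final < 0.01


def test_training_is_seeded_and_records_history(rng):
    recs = _records_with_hrs([65] * 6 + [95] * 6, rng)
    for r in recs:
        # give the targets structure so Pearson loss is well-defined
        t = np.arange(450) / 30.0
        r.gt_bvp = np.cos(2 * np.pi * r.gt_hr / 60.0 * t)
    plan = TrainPlan(phase1_epochs=2, phase2_epochs=1, batch_size=4,
                     rng_seed=5, noise_snr_db=np.inf)

    def run():
        model = MFFNet(seed=5)
        return train(model, recs, plan), model

    (h1, m1), (h2, m2) = run(), run()
    assert [row["loss"] for row in h1] == [row["loss"] for row in h2]
    assert {row["phase"] for row in h1} == {1, 2}
    assert len(h1) == 3
    from mffnet.decompose import BandSpec
    x = np.stack([prepare_input(r.stmap, BandSpec(fps=30.0))
                  for r in recs[:2]])
    np.testing.assert_array_equal(m1(x).data, m2(x).data)
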