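"""Training mechanics: freezing, determinism, schedule arithmetic, checkpoints."""

import numpy as np
import pytest

import macgan.training as tr
from macgan import (PhantomConfig, TrainConfig, cases_from_phantoms, fit,
                    load_checkpoint, target_mask, validate)
from macgan.nn import AdamW
from macgan.training import (build_networks, discriminator_step,
                             generator_step, predict_volume)


def tiny_cases(n=2, seed=0):
    cfg = PhantomConfig(shape=(16, 16, 16), liver_axes=(5.0, 5.0, 5.0),
                        n_tumors=1, tumor_radius_range=(1.0, 2.0), seed=seed)
    return cases_from_phantoms(n, cfg)


def tiny_config(**kw):
    base = dict(target="liver", base_channels=2, crop_depth=16, seed=0,
                max_epochs=2, plateau_patience=30, stop_patience=60)
    base.update(kw)
    return TrainConfig(**base)


def checksum(net):
    return [p.data.copy() for p in net.parameters()]


def unchanged(before, net):
    return all(np.array_equal(b, p.data)
               for b, p in zip(before, net.parameters()))


def make_batch(cases, target="liver"):
    x = np.stack([c["image"] for c in cases])[:, None]
    y = np.stack([target_mask(c["label"], target) for c in cases])[:, None]
    return x, y


def test_generator_step_freezes_discriminator():
    cfg = tiny_config()
    gen, disc = build_networks(cfg)
    og = AdamW(gen.parameters(), lr=cfg.lr)
    batch = make_batch(tiny_cases())
    d_before, g_before = checksum(disc), checksum(gen)
    log = generator_step(batch, gen, disc, cfg, og)
    assert unchanged(d_before, disc)
    assert not unchanged(g_before, gen)
    assert np.isfinite(log["g_loss"])


def test_discriminator_step_freezes_generator():
    cfg = tiny_config()
    gen, disc = build_networks(cfg)
    od = AdamW(disc.parameters(), lr=cfg.lr)
    batch = make_batch(tiny_cases())
    g_before, d_before = checksum(gen), checksum(disc)
    log = discriminator_step(batch, gen, disc, cfg, od)
    assert unchanged(g_before, gen)
    assert not unchanged(d_before, disc)
    assert np.isfinite(log["d_loss"])
    assert 0 < log["d_real"] < 1 and 0 < log["d_fake"] < 1


def test_steps_are_seed_deterministic():
    cfg = tiny_config()
    batch = make_batch(tiny_cases())
    outs = []
    for _ in range(2):
        gen, disc = build_networks(cfg)
        og = AdamW(gen.parameters(), lr=cfg.lr)
        generator_step(batch, gen, disc, cfg, og)
        outs.append(checksum(gen))
    assert all(np.array_equal(a, b) for a, b in zip(*outs))


def test_validate_with_stub_predictions(monkeypatch):
    cases = tiny_cases()
    gen, _ = build_networks(tiny_config())
    monkeypatch.setattr(tr, "predict_volume",
                        lambda g, img: np.ones_like(img))
    # all-foreground stub vs liver mask: dice < 1 but > 0
    mid = validate({"liver": gen}, cases)
    assert 0.0 < mid < 1.0
    # perfect stub: return the reference mask itself
    monkeypatch.setattr(
        tr, "predict_volume",
        lambda g, img, _c=iter(cases + cases): target_mask(next(_c)["label"], "liver"))
    assert validate({"liver": gen}, cases) == pytest.approx(1.0)
    # all-background stub with nonempty references
    monkeypatch.setattr(tr, "predict_volume",
                        lambda g, img: np.zeros_like(img))
    assert validate({"liver": gen}, cases) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        validate({"liver": gen}, [])


def test_plateau_halving_and_early_stop(monkeypatch):
    """A flat validation metric halves the lr after `plateau_patience`
    epochs and stops the run `stop_patience` epochs after the best."""
    monkeypatch.setattr(tr, "validate", lambda gens, vs: 0.5)
    cfg = tiny_config(max_epochs=50, plateau_patience=2, stop_patience=3)
    cases = tiny_cases()
    _, _, state = fit(cfg, cases, cases)
    # best at epoch 1; stale epochs 2,3,4 → stop after epoch 4
    assert state.epoch == 4
    assert state.epochs_since_improvement == 3
    # halving triggered once stale count reached 2 (end of epoch 3)
    assert state.current_lr == pytest.approx(cfg.lr / 2)
    assert state.best_val_dice == pytest.approx(0.5)


def test_trainconfig_invariants():
    with pytest.raises(ValueError):
        TrainConfig(stop_patience=10, plateau_patience=30)
    with pytest.raises(ValueError):
        TrainConfig(crop_depth=24)
    with pytest.raises(ValueError):
        TrainConfig(target="spleen")


def test_fit_epoch_has_equal_update_counts(tmp_path):
    cfg = tiny_config(max_epochs=2)
    cases = tiny_cases()
    _, _, state = fit(cfg, cases, cases, workdir=tmp_path)
    trace = (tmp_path / "trace.jsonl").read_text().strip().splitlines()
    assert len(trace) == state.step
    import json
    for line in trace:
        rec = json.loads(line)
        assert "g_loss" in rec and "d_loss" in rec  # one G and one D update


def test_checkpoint_reload_reproduces_validation_exactly(tmp_path):
    cfg = tiny_config(max_epochs=3)
    cases = tiny_cases()
    gen, _, state = fit(cfg, cases, cases, workdir=tmp_path)
    gen2, _, cfg2, meta = load_checkpoint(tmp_path / "final.npz")
    assert cfg2 == cfg
    val = validate({cfg.target: gen2}, cases)
    assert val == state.final_val_dice
    # reloaded parameters are bit-identical
    for (n1, p1), (n2, p2) in zip(gen.named_parameters(), gen2.named_parameters()):
        assert n1 == n2 and np.array_equal(p1.data, p2.data)


def test_full_runs_with_same_seed_produce_identical_traces():
    cfg = tiny_config(max_epochs=2, seed=9)
    cases = tiny_cases()
    h1 = fit(cfg, cases, cases)[2].history
    h2 = fit(cfg, cases, cases)[2].history
    assert h1 == h2


def test_predict_volume_unpads_to_native_depth():
    cfg = tiny_config()
    gen, _ = build_networks(cfg)
    img = np.random.default_rng(0).random((20, 16, 16)).astype(np.float32)
    prob = predict_volume(gen, img)
    assert prob.shape == img.shape
    assert np.isfinite(prob).all()
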