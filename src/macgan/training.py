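"""Alternating adversarial training with plateau scheduling and early stop.

Each batch takes one generator step (discriminator frozen) followed by one
discriminator step (fake labels detached), per the 1:1 alternation of
conditional-GAN training.  The optimizer is AdamW at lr 2e-4; the mean
validation Dice drives the schedule: halve the learning rate after 30
epochs without improvement, stop after 60 stale epochs or 300 epochs.
Training samples are random depth crops (a multiple of 16 slices) so
variable-depth volumes fit a batch; validation and inference run on whole,
reflect-padded volumes.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from .losses import (TverskyParams, discriminator_loss, generator_loss,
                     tversky_loss)
from .metrics import dice as dice_metric
from .networks import (Discriminator, DiscriminatorConfig, Generator,
                       GeneratorConfig)
from .nn import AdamW, Tensor, no_grad
from .phantom import PhantomConfig, make_phantom
from .preprocess import WindowSpec, apply_window, normalize01
from .volume import Volume

__all__ = ["TrainConfig", "TrainState", "target_mask", "cases_from_phantoms",
           "random_depth_crop", "generator_step", "discriminator_step",
           "predict_volume", "validate", "fit", "save_checkpoint",
           "load_checkpoint", "recalibrate_batchnorm", "build_networks"]


@dataclass
class TrainConfig:
    """Hyperparameters of one training run (one binary target class)."""

    target: str = "liver"            # "liver" (labels 1+2) or "tumor" (label 2)
    lr: float = 2e-4
    weight_decay: float = 1e-2
    batch_size: int = 2
    max_epochs: int = 300
    plateau_patience: int = 30       # epochs without improvement → halve lr
    stop_patience: int = 60          # epochs without improvement → stop
    crop_depth: int = 32             # training-time depth crop, multiple of 16
    seed: int = 0
    loss_mode: str = "nolog"
    tversky_alpha: float = 0.7
    tversky_beta: float = 0.3
    lambda_seg: float = 1.0
    base_channels: int = 16
    use_ma: bool = True
    improvement_tol: float = 1e-5    # strict improvement margin for patience
    stop_train_dice: float | None = None  # early exit for overfit runs
    validate_every: int = 1          # epochs between validation passes

    def __post_init__(self):
        if self.target not in ("liver", "tumor"):
            raise ValueError(f"target must be 'liver' or 'tumor', got {self.target!r}")
        if self.stop_patience < self.plateau_patience:
            raise ValueError("stop_patience must be >= plateau_patience")
        if self.crop_depth % 16:
            raise ValueError(f"crop_depth must be divisible by 16, got {self.crop_depth}")

    @property
    def tversky(self) -> TverskyParams:
        return TverskyParams(self.tversky_alpha, self.tversky_beta)


@dataclass
class TrainState:
    epoch: int = 0
    step: int = 0
    best_val_dice: float = -np.inf
    epochs_since_improvement: int = 0
    epochs_since_lr_drop: int = 0
    current_lr: float = 2e-4
    final_val_dice: float = float("nan")
    history: list = field(default_factory=list)


def target_mask(labels: np.ndarray, target: str) -> np.ndarray:
    """Binary foreground for one class: liver = labels {1,2}, tumor = {2}."""
    labels = np.asarray(labels)
    if target == "liver":
        return (labels >= 1).astype(np.float32)
    if target == "tumor":
        return (labels == 2).astype(np.float32)
    raise ValueError(f"unknown target {target!r}")


def cases_from_phantoms(n: int, config: PhantomConfig,
                        window: WindowSpec = WindowSpec()):
    """Preprocessed (image in [0,1], integer label) case list for training."""
    cases = []
    for i in range(n):
        cfg = PhantomConfig(**{**config.__dict__, "seed": config.seed + i})
        img, lab = make_phantom(cfg)
        img = normalize01(apply_window(img, window), window)
        cases.append({"image": img.data.astype(np.float32),
                      "label": lab.data.astype(np.int16)})
    return cases


def random_depth_crop(image, label, crop_depth, rng):
    d = image.shape[0]
    if d < crop_depth:
        pad = crop_depth - d
        image = np.pad(image, ((0, pad), (0, 0), (0, 0)), mode="reflect")
        label = np.pad(label, ((0, pad), (0, 0), (0, 0)), mode="reflect")
        return image, label
    if d == crop_depth:
        return image, label
    start = int(rng.integers(0, d - crop_depth + 1))
    return image[start:start + crop_depth], label[start:start + crop_depth]


def _batch_arrays(cases, target):
    x = np.stack([c["image"] for c in cases])[:, None]          # [N,1,D,H,W]
    y = np.stack([target_mask(c["label"], target) for c in cases])[:, None]
    return x, y


def generator_step(batch, gen: Generator, disc: Discriminator,
                   config: TrainConfig, opt_g: AdamW) -> dict:
    """One generator update; the discriminator's parameters stay untouched."""
    x, y = batch
    xt, yt = Tensor(x), Tensor(y)
    disc.freeze(True)
    try:
        g = gen(xt)
        d_fake = disc(xt, g)
        t_loss = tversky_loss(yt, g, config.tversky)
        loss = generator_loss(d_fake, yt, g, config.tversky,
                              mode=config.loss_mode, lam=config.lambda_seg)
        if not np.isfinite(loss.item()):
            raise FloatingPointError(
                f"non-finite generator loss {loss.item()} "
                f"(d_fake mean {float(d_fake.data.mean()):.4g})")
        gen.zero_grad()
        disc.zero_grad()
        loss.backward()
        opt_g.step()
    finally:
        disc.freeze(False)
    train_dice = dice_metric(g.data >= 0.5, y >= 0.5)
    return {"g_loss": loss.item(), "tversky_loss": t_loss.item(),
            "d_fake": float(d_fake.data.mean()), "train_dice": train_dice,
            "_fake": g.detach()}


def discriminator_step(batch, gen: Generator, disc: Discriminator,
                       config: TrainConfig, opt_d: AdamW,
                       fake: Tensor | None = None) -> dict:
    """One discriminator update; fake labels are detached from the generator.

    ``fake`` may carry the generator output already computed for this batch
    (detached); otherwise the frozen generator is run once to produce it.
    """
    x, y = batch
    xt, yt = Tensor(x), Tensor(y)
    if fake is None:
        was_training = gen.training
        gen.eval()
        try:
            with no_grad():
                fake = gen(xt).detach()
        finally:
            gen.train(was_training)
    else:
        fake = fake.detach()
    d_real = disc(xt, yt)
    d_fake = disc(xt, fake)
    loss = discriminator_loss(d_real, d_fake, mode=config.loss_mode)
    if not np.isfinite(loss.item()):
        raise FloatingPointError(f"non-finite discriminator loss {loss.item()}")
    disc.zero_grad()
    loss.backward()
    opt_d.step()
    return {"d_loss": loss.item(), "d_real": float(d_real.data.mean()),
            "d_fake": float(d_fake.data.mean())}


def recalibrate_batchnorm(gen: Generator, train_set, config: TrainConfig):
    """Re-estimate batch-norm running statistics over the training set.

    With batch size 2 the running averages lag the batch statistics the
    generator was actually trained with; one full pass with the exact
    per-batch statistics (averaged across batches) makes eval-mode
    predictions consistent with training behavior.
    """
    from .nn.layers import BatchNorm3d
    bns = [m for m in gen.modules() if isinstance(m, BatchNorm3d)]
    if not bns:
        return
    saved = [(b.momentum, b.running_mean.copy(), b.running_var.copy())
             for b in bns]
    sums = [(np.zeros_like(b.running_mean), np.zeros_like(b.running_var))
            for b in bns]
    was_training = gen.training
    gen.train(True)
    n_batches = 0
    try:
        for b in bns:
            b.momentum = 1.0
        for i in range(0, len(train_set), config.batch_size):
            chunk = train_set[i:i + config.batch_size]
            depths = {c["image"].shape[0] for c in chunk}
            if len(depths) != 1:  # mixed depths: process singly
                for c in chunk:
                    xi = np.asarray(c["image"], dtype=np.float32)
                    pad = (-xi.shape[0]) % 16
                    if pad:
                        xi = np.pad(xi, ((0, pad), (0, 0), (0, 0)),
                                        mode="reflect")
                    with no_grad():
                        gen(Tensor(xi[None, None]))
                    for (ms, vs), b in zip(sums, bns):
                        ms += b.running_mean
                        vs += b.running_var
                    n_batches += 1
                continue
            x = np.stack([c["image"] for c in chunk])[:, None].astype(np.float32)
            pad = (-x.shape[2]) % 16
            if pad:
                x = np.pad(x, ((0, 0), (0, 0), (0, pad), (0, 0), (0, 0)),
                           mode="reflect")
            with no_grad():
                gen(Tensor(x))
            for (ms, vs), b in zip(sums, bns):
                ms += b.running_mean
                vs += b.running_var
            n_batches += 1
    finally:
        gen.train(was_training)
        for b, (mom, rm, rv) in zip(bns, saved):
            b.momentum = mom
    for (ms, vs), b in zip(sums, bns):
        b.running_mean[...] = ms / n_batches
        b.running_var[...] = vs / n_batches


def predict_volume(gen: Generator, image: np.ndarray) -> np.ndarray:
    """Whole-volume probability map; depth reflect-padded to ×16, un-padded."""
    vol = Volume(np.asarray(image, dtype=np.float32))
    from .preprocess import pad_depth_to_multiple, unpad_depth
    padded, pad = pad_depth_to_multiple(vol, 16)
    was_training = gen.training
    gen.eval()
    try:
        with no_grad():
            prob = gen(Tensor(padded.data[None, None]))
    finally:
        gen.train(was_training)
    return unpad_depth(prob.data[0, 0], pad)


def validate(generators: dict, val_set) -> float:
    """Mean over cases of the mean Dice across the supplied class models.

    ``generators`` maps target name ("liver"/"tumor") to a Generator; with
    both present this is the mean of liver and tumor Dice.  Predictions are
    binarized at 0.5 and compared un-postprocessed.
    """
    if not val_set:
        raise ValueError("validation set is empty")
    if not generators:
        raise ValueError("no generator supplied")
    per_case = []
    for case in val_set:
        scores = []
        for target, gen in generators.items():
            prob = predict_volume(gen, case["image"])
            ref = target_mask(case["label"], target)
            scores.append(dice_metric(prob >= 0.5, ref >= 0.5))
        per_case.append(float(np.mean(scores)))
    return float(np.mean(per_case))


def save_checkpoint(path, gen, disc, config: TrainConfig, state: TrainState):
    payload = {f"gen:{k}": v for k, v in gen.state_dict().items()}
    payload.update({f"disc:{k}": v for k, v in disc.state_dict().items()})
    meta = {"config": asdict(config),
            "epoch": state.epoch,
            "best_val_dice": state.best_val_dice,
            "current_lr": state.current_lr}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **payload)


def build_networks(config: TrainConfig):
    gen = Generator(GeneratorConfig(base_channels=config.base_channels,
                                    use_ma=config.use_ma, seed=config.seed))
    disc = Discriminator(DiscriminatorConfig(seed=config.seed + 1))
    return gen, disc


def load_checkpoint(path):
    """Rebuild (generator, discriminator, config, meta) from a checkpoint."""
    with np.load(path) as arc:
        meta = json.loads(bytes(arc["__meta__"]).decode())
        config = TrainConfig(**meta["config"])
        gen, disc = build_networks(config)
        gen.load_state_dict({k[4:]: arc[k] for k in arc.files if k.startswith("gen:")})
        disc.load_state_dict({k[5:]: arc[k] for k in arc.files if k.startswith("disc:")})
    return gen, disc, config, meta


def fit(config: TrainConfig, train_set, val_set, workdir=None,
        gen: Generator | None = None, disc: Discriminator | None = None,
        start_epoch: int = 1):
    """Run the full alternating schedule; returns (gen, disc, TrainState).

    The best-validation checkpoint and a per-step JSONL trace are written to
    ``workdir`` when given.  Pass the networks of a loaded checkpoint plus
    ``start_epoch`` to resume a run.  Divergence (non-finite losses in 3
    consecutive epochs) aborts.
    """
    if not train_set:
        raise ValueError("training set is empty")
    if not val_set:
        raise ValueError("validation set is empty")
    rng = np.random.default_rng(config.seed)
    if gen is None or disc is None:
        gen, disc = build_networks(config)
    opt_g = AdamW(gen.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    opt_d = AdamW(disc.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    state = TrainState(current_lr=config.lr)
    trace_fh = None
    if workdir:
        os.makedirs(workdir, exist_ok=True)
        with open(os.path.join(workdir, "config.json"), "w") as fh:
            json.dump(asdict(config), fh, indent=2)
        trace_fh = open(os.path.join(workdir, "trace.jsonl"), "w")
    bad_epochs = 0
    try:
        for epoch in range(start_epoch, config.max_epochs + 1):
            state.epoch = epoch
            order = rng.permutation(len(train_set))
            epoch_logs = []
            epoch_ok = True
            for i in range(0, len(order), config.batch_size):
                idx = order[i:i + config.batch_size]
                crops = []
                for j in idx:
                    img, lab = random_depth_crop(train_set[j]["image"],
                                                 train_set[j]["label"],
                                                 config.crop_depth, rng)
                    crops.append({"image": img, "label": lab})
                batch = _batch_arrays(crops, config.target)
                try:
                    g_log = generator_step(batch, gen, disc, config, opt_g)
                    d_log = discriminator_step(batch, gen, disc, config, opt_d,
                                               fake=g_log.pop("_fake"))
                except FloatingPointError:
                    epoch_ok = False
                    break
                state.step += 1
                rec = {"epoch": epoch, "step": state.step, **g_log, **d_log}
                epoch_logs.append(rec)
                if trace_fh:
                    trace_fh.write(json.dumps(rec) + "\n")
            if not epoch_ok:
                bad_epochs += 1
                if bad_epochs >= 3:
                    raise RuntimeError("training diverged: non-finite losses "
                                       "in 3 consecutive epochs")
                continue
            bad_epochs = 0

            mean_train_dice = float(np.mean([r["train_dice"] for r in epoch_logs]))
            rec = {"epoch": epoch, "train_dice": mean_train_dice,
                   "lr": state.current_lr,
                   "tversky_loss": float(np.mean(
                       [r["tversky_loss"] for r in epoch_logs]))}
            if epoch % config.validate_every == 0:
                val = validate({config.target: gen}, val_set)
                rec["val_dice"] = val
                if val > state.best_val_dice + config.improvement_tol:
                    state.best_val_dice = val
                    state.epochs_since_improvement = 0
                    state.epochs_since_lr_drop = 0
                    if workdir:
                        save_checkpoint(os.path.join(workdir, "best.npz"),
                                        gen, disc, config, state)
                else:
                    state.epochs_since_improvement += config.validate_every
                    state.epochs_since_lr_drop += config.validate_every
            state.history.append(rec)
            if state.epochs_since_lr_drop >= config.plateau_patience:
                state.current_lr /= 2.0
                opt_g.lr = opt_d.lr = state.current_lr
                state.epochs_since_lr_drop = 0
            if (config.stop_train_dice is not None
                    and mean_train_dice >= config.stop_train_dice):
                break
            if state.epochs_since_improvement >= config.stop_patience:
                break
    finally:
        if trace_fh:
            trace_fh.close()
    recalibrate_batchnorm(gen, train_set, config)
    state.final_val_dice = validate({config.target: gen}, val_set)
    if workdir:
        save_checkpoint(os.path.join(workdir, "final.npz"), gen, disc,
                        config, state)
        if not os.path.exists(os.path.join(workdir, "best.npz")):
            save_checkpoint(os.path.join(workdir, "best.npz"), gen, disc,
                            config, state)
    return gen, disc, state
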