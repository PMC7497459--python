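"""Adversarial training loop and single-image virtual staining.

Training alternates one discriminator update and one generator update
per image pair (batch size 1): the discriminator ascends
E[log D(x,y)] + E[log(1 - D(x,G(x,z)))]; the generator descends its
adversarial term plus lambda * L1(y, G(x,z)) with lambda = 100.  Adam
(beta1 = 0.5, beta2 = 0.999) with a constant learning rate of 0.001 for
the generator and 0.0002 for the discriminator; 200 epochs by default,
where an epoch is one seeded-shuffle pass over the training pairs.

Everything is seeded; a run aborts (keeping the last finite checkpoint)
if any loss becomes non-finite.  Inference maps a [0, 1] RGB image
through the generator ([-1, 1] internally) and back; dropout — the
model's only stochasticity — stays active by default and is switched
off by ``deterministic=True``.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .cgan import (DiscriminatorConfig, GeneratorConfig, PatchDiscriminator,
                   UNetGenerator, adversarial_loss, adversarial_loss_grads,
                   l1_loss, l1_loss_grad)
from .dataset import TrainingDataset

__all__ = [
    "TrainConfig",
    "TrainingHistory",
    "train",
    "virtual_stain",
    "save_checkpoint",
    "load_checkpoint",
    "to_network_range",
    "from_network_range",
]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (defaults are the reference settings)."""

    epochs: int = 200
    lr_generator: float = 0.001
    lr_discriminator: float = 0.0002
    beta1: float = 0.5
    beta2: float = 0.999
    batch_size: int = 1
    lambda_l1: float = 100.0
    d_g_iteration_ratio: tuple[int, int] = (1, 1)
    seed: int = 0
    checkpoint_every: int = 0        # epochs; 0 disables
    checkpoint_dir: str | None = None

    def __post_init__(self):
        for name in ("lr_generator", "lr_discriminator"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.d_g_iteration_ratio != (1, 1):
            raise ValueError("exactly one discriminator step per generator step")
        if self.batch_size != 1:
            raise ValueError("the training loop is defined for batch size 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass
class TrainingHistory:
    """Per-epoch records: generator adversarial loss, discriminator loss,
    train L1, held-out L1, and wall-clock seconds."""

    epochs: list[int] = field(default_factory=list)
    g_adv: list[float] = field(default_factory=list)
    d_loss: list[float] = field(default_factory=list)
    l1_train: list[float] = field(default_factory=list)
    l1_test: list[float] = field(default_factory=list)
    seconds: list[float] = field(default_factory=list)
    d_steps: int = 0
    g_steps: int = 0
    aborted: bool = False

    def append(self, epoch, g_adv, d_loss, l1_train, l1_test, seconds):
        if self.epochs and epoch <= self.epochs[-1]:
            raise ValueError("epoch indices must be strictly increasing")
        self.epochs.append(epoch)
        self.g_adv.append(g_adv)
        self.d_loss.append(d_loss)
        self.l1_train.append(l1_train)
        self.l1_test.append(l1_test)
        self.seconds.append(seconds)

    def to_jsonl(self) -> str:
        lines = []
        for i, e in enumerate(self.epochs):
            lines.append(json.dumps({
                "epoch": e, "g_adv": self.g_adv[i], "d_loss": self.d_loss[i],
                "l1_train": self.l1_train[i], "l1_test": self.l1_test[i],
                "seconds": self.seconds[i]}))
        return "\n".join(lines)


def to_network_range(img: np.ndarray) -> np.ndarray:
    """(H, W, 3) float [0, 1]  ->  (1, 3, H, W) float32 in [-1, 1]."""
    x = np.asarray(img, dtype=np.float32)
    if x.ndim != 3 or x.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {img.shape}")
    return (x * 2.0 - 1.0).transpose(2, 0, 1)[None]


def from_network_range(x: np.ndarray) -> np.ndarray:
    """(1, 3, H, W) in [-1, 1]  ->  (H, W, 3) float in [0, 1]."""
    return np.clip((x[0].transpose(1, 2, 0) + 1.0) / 2.0, 0.0, 1.0)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: Path | str, generator: UNetGenerator,
                    discriminator: PatchDiscriminator | None = None,
                    extra: dict | None = None) -> None:
    """Serialise weights as .npz plus a JSON architecture manifest."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"G/{k}": v for k, v in generator.state_dict().items()}
    if discriminator is not None:
        arrays.update({f"D/{k}": v for k, v in discriminator.state_dict().items()})
    np.savez(path, **arrays)
    manifest = {
        "generator": {**generator.config.__dict__,
                      "in_channels": generator.in_channels,
                      "out_channels": generator.out_channels,
                      "channels": generator.config.channel_schedule()},
        "discriminator": (None if discriminator is None else
                          {**discriminator.config.__dict__,
                           "in_channels": discriminator.in_channels,
                           "channels": discriminator.config.channel_schedule()}),
        "extra": extra or {},
    }
    Path(str(path) + ".json").write_text(json.dumps(manifest, indent=2, default=str))


def load_checkpoint(path: Path | str, *, seed: int = 0
                    ) -> tuple[UNetGenerator, PatchDiscriminator | None, dict]:
    path = Path(path)
    manifest = json.loads(Path(str(path) + ".json").read_text())
    gman = dict(manifest["generator"])
    in_ch = gman.pop("in_channels")
    out_ch = gman.pop("out_channels")
    gman.pop("channels")
    gcfg = GeneratorConfig(**gman)
    rng = np.random.default_rng(seed)
    gen = UNetGenerator(gcfg, in_channels=in_ch, out_channels=out_ch, rng=rng)
    data = np.load(path)
    gen.load_state_dict({k[2:]: data[k] for k in data.files if k.startswith("G/")})
    disc = None
    if manifest["discriminator"] is not None:
        dman = dict(manifest["discriminator"])
        din = dman.pop("in_channels")
        dman.pop("channels")
        disc = PatchDiscriminator(DiscriminatorConfig(**dman), in_channels=din, rng=rng)
        disc.load_state_dict({k[2:]: data[k] for k in data.files if k.startswith("D/")})
    return gen, disc, manifest.get("extra", {})


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _evaluate_l1(gen: UNetGenerator, pairs) -> float:
    """Held-out mean L1 in network range, dropout off."""
    if not pairs:
        return float("nan")
    vals = []
    for p in pairs:
        x = to_network_range(p.x)
        y = to_network_range(p.y)
        y_hat = gen.forward(x, train=False, dropout=False)
        vals.append(l1_loss(y, y_hat))
    return float(np.mean(vals))


def train(dataset: TrainingDataset,
          gen_cfg: GeneratorConfig | None = None,
          disc_cfg: DiscriminatorConfig | None = None,
          train_cfg: TrainConfig | None = None,
          *, test_pairs=None,
          generator: UNetGenerator | None = None,
          discriminator: PatchDiscriminator | None = None,
          optimizers: tuple[nn.Adam, nn.Adam] | None = None,
          start_epoch: int = 0,
          progress: bool = False) -> tuple[UNetGenerator, TrainingHistory]:
    """Train the cGAN on a paired dataset; returns (generator, history).

    Pass ``generator``/``discriminator``/``optimizers``/``start_epoch``
    to continue from a checkpointed state; otherwise fresh seeded
    networks are built from the configs.
    """
    cfg = train_cfg or TrainConfig()
    gen_cfg = gen_cfg or GeneratorConfig()
    disc_cfg = disc_cfg or DiscriminatorConfig()
    if len(dataset) == 0:
        raise ValueError("training dataset is empty")

    rng = np.random.default_rng(cfg.seed)
    init_rng = np.random.default_rng(rng.integers(0, 2 ** 31))
    if generator is None:
        generator = UNetGenerator(gen_cfg, rng=init_rng)
    if discriminator is None:
        discriminator = PatchDiscriminator(disc_cfg, rng=init_rng)
    if optimizers is None:
        opt_g = nn.Adam(generator.parameters(), cfg.lr_generator, (cfg.beta1, cfg.beta2))
        opt_d = nn.Adam(discriminator.parameters(), cfg.lr_discriminator,
                        (cfg.beta1, cfg.beta2))
    else:
        opt_g, opt_d = optimizers

    history = TrainingHistory()
    pairs = dataset.pairs
    shuffle_rng = np.random.default_rng(rng.integers(0, 2 ** 31))
    # burn shuffles already consumed by a previous (checkpointed) segment
    for _ in range(start_epoch):
        shuffle_rng.permutation(len(pairs))

    ckpt_dir = Path(cfg.checkpoint_dir) if cfg.checkpoint_dir else None

    for epoch in range(start_epoch, cfg.epochs):
        t0 = time.perf_counter()
        order = shuffle_rng.permutation(len(pairs))
        e_gadv, e_dloss, e_l1 = [], [], []
        for idx in order:
            p = pairs[idx]
            x = to_network_range(p.x)
            y = to_network_range(p.y)

            # ---- discriminator step (first, then generator) ----
            y_fake = generator.forward(x, train=False, dropout=True)  # detached
            d_real = discriminator.forward(x, y, train=True)
            g_real, _ = adversarial_loss_grads(d_real, d_real)
            discriminator.backward(-g_real)           # ascend -> descend negative
            d_fake = discriminator.forward(x, y_fake, train=True)
            _, g_fake = adversarial_loss_grads(d_fake, d_fake)
            discriminator.backward(-g_fake)
            loss_d = -adversarial_loss(d_real, d_fake)
            opt_d.step()
            discriminator.zero_grads()
            history.d_steps += 1

            # ---- generator step ----
            y_hat = generator.forward(x, train=True, dropout=True)
            d_gen = discriminator.forward(x, y_hat, train=True)
            _, g_fake = adversarial_loss_grads(d_gen, d_gen)
            # generator *minimises* E[log(1 - D)]: gradient is +g_fake
            gin = discriminator.backward(g_fake)
            g_yhat = gin[:, 3:6] + cfg.lambda_l1 * l1_loss_grad(y, y_hat)
            generator.backward(g_yhat)
            opt_g.step()
            generator.zero_grads()
            discriminator.zero_grads()
            history.g_steps += 1

            adv_g = float(np.mean(np.log1p(-np.clip(d_gen, 1e-7, 1 - 1e-7))))
            l1 = l1_loss(y, y_hat)
            e_gadv.append(adv_g)
            e_dloss.append(loss_d)
            e_l1.append(l1)
            if not (np.isfinite(loss_d) and np.isfinite(l1)):
                history.aborted = True
                break

        assert history.d_steps == history.g_steps, "D/G update counters diverged"
        l1_test = _evaluate_l1(generator, test_pairs) if test_pairs is not None else float("nan")
        history.append(epoch, float(np.mean(e_gadv)), float(np.mean(e_dloss)),
                       float(np.mean(e_l1)), l1_test, time.perf_counter() - t0)
        if progress:
            print(f"epoch {epoch}: d={history.d_loss[-1]:.4f} "
                  f"g_adv={history.g_adv[-1]:.4f} l1={history.l1_train[-1]:.4f} "
                  f"l1_test={l1_test:.4f} ({history.seconds[-1]:.1f}s)")
        if history.aborted:
            break
        if ckpt_dir and cfg.checkpoint_every and (epoch + 1) % cfg.checkpoint_every == 0:
            save_checkpoint(ckpt_dir / f"epoch_{epoch + 1:04d}.npz",
                            generator, discriminator,
                            extra={"epoch": epoch + 1, "seed": cfg.seed})
    if ckpt_dir:
        save_checkpoint(ckpt_dir / "final.npz", generator, discriminator,
                        extra={"epoch": cfg.epochs, "seed": cfg.seed,
                               "aborted": history.aborted})
    return generator, history


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def virtual_stain(generator: UNetGenerator | Path | str, image: np.ndarray,
                  deterministic: bool = False, seed: int | None = None) -> np.ndarray:
    """Virtually stain one unstained RGB image.

    ``generator`` is a trained network or a checkpoint path.  Returns an
    RGB float image in [0, 1] with the input's spatial size.  Dropout is
    active by default (stochastic staining); ``deterministic=True``
    disables it, making repeated calls bit-identical.
    """
    if not isinstance(generator, UNetGenerator):
        generator, _, _ = load_checkpoint(generator)
    img = np.asarray(image)
    if img.dtype == np.uint8:
        img = img / 255.0
    img = img.astype(np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {image.shape}")
    h, w = img.shape[:2]
    m = generator.min_input_size
    if min(h, w) < m:
        raise ValueError(f"image {h}x{w} below the minimum size {m} for "
                         f"{generator.config.n_levels} stride-2 levels")
    if not deterministic and seed is not None:
        generator.dropout_rng = np.random.default_rng(seed)
    x = to_network_range(img)
    y = generator.forward(x, train=False, dropout=not deterministic)
    return from_network_range(y)
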