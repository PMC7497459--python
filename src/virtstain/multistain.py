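"""Single-generator multi-domain stain translation.

One generator produces H&E, PSR, or orcein renderings from the same
unstained image, conditioned on the target stain: the three-element
one-hot domain label is broadcast as three extra input channels.  The
discriminator sees the image alone and carries two heads on a shared
five-block trunk: an adversarial sigmoid patch map and an auxiliary
domain classifier (1x1 convolution, global average pooling, softmax).

Loss structure (log-loss adversarial term, consistent with the paired
model):

    D:  maximise E[log D_adv(y)] + E[log(1 - D_adv(G(x, d)))]
        minus lambda_cls * CE(D_cls(y), d)           (on real images)
    G:  minimise E[log(1 - D_adv(G(x, d)))]
        + lambda_cls * CE(D_cls(G(x, d)), d)
        + lambda_rec * L1(G(G(x, d), 0), x)

The reconstruction pass translates the generated stained image back to
the unstained source; since "unstained" is not one of the stain
domains, the back-translation is conditioned on the all-zero label
vector.  Defaults: lambda_cls = 1, lambda_rec = 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import nn
from .cgan import (DiscriminatorConfig, GeneratorConfig, UNetGenerator,
                   adversarial_loss, adversarial_loss_grads, l1_loss, l1_loss_grad)
from .dataset import TrainingDataset
from .phantom import StainDomain
from .training import from_network_range, to_network_range

__all__ = [
    "MultiStainConfig",
    "MultiStainDiscriminator",
    "MultiStainHistory",
    "build_multistain_generator",
    "stain_as",
    "train_multistain",
]

N_DOMAINS = len(StainDomain)


@dataclass(frozen=True)
class MultiStainConfig:
    n_domains: int = N_DOMAINS
    lambda_cls: float = 1.0
    lambda_rec: float = 10.0
    gen: GeneratorConfig = field(default_factory=GeneratorConfig)
    disc: DiscriminatorConfig = field(default_factory=DiscriminatorConfig)
    epochs: int = 200
    lr_generator: float = 0.001
    lr_discriminator: float = 0.0002
    beta1: float = 0.5
    beta2: float = 0.999
    seed: int = 0

    def __post_init__(self):
        if self.n_domains != N_DOMAINS:
            raise ValueError(f"n_domains must equal the number of stain domains "
                             f"({N_DOMAINS})")
        if self.lambda_cls < 0 or self.lambda_rec < 0:
            raise ValueError("loss weights must be >= 0")


@dataclass
class MultiStainHistory:
    epochs: list[int] = field(default_factory=list)
    g_adv: list[float] = field(default_factory=list)
    g_cls: list[float] = field(default_factory=list)
    g_rec: list[float] = field(default_factory=list)
    g_total: list[float] = field(default_factory=list)
    d_loss: list[float] = field(default_factory=list)
    cls_accuracy_fake: list[float] = field(default_factory=list)


def _domain_planes(label: StainDomain | None, h: int, w: int) -> np.ndarray:
    planes = np.zeros((1, N_DOMAINS, h, w), dtype=np.float32)
    if label is not None:
        planes[0, list(StainDomain).index(label)] = 1.0
    return planes


def _multistain_gen_config(gcfg: GeneratorConfig | None) -> GeneratorConfig:
    """Conditioning adjustments for the multi-domain generator: the
    broadcast one-hot label is a constant channel, so first-block
    normalisation (which would subtract it away) is disabled, and the
    label is additionally fed to every decoder block so the target
    domain has a direct path to the output colours."""
    import dataclasses
    gcfg = gcfg or GeneratorConfig()
    return dataclasses.replace(gcfg, first_layer_norm=False,
                               decoder_label_channels=N_DOMAINS)


def build_multistain_generator(cfg: MultiStainConfig | GeneratorConfig | None = None,
                               *, seed: int = 0) -> UNetGenerator:
    """U-Net generator over RGB + one-hot domain planes (6 input channels)."""
    gcfg = cfg.gen if isinstance(cfg, MultiStainConfig) else cfg
    rng = np.random.default_rng(seed)
    return UNetGenerator(_multistain_gen_config(gcfg), in_channels=3 + N_DOMAINS, rng=rng)


class MultiStainDiscriminator:
    """Adversarial PatchGAN trunk plus an auxiliary domain classifier.

    The adversarial head follows the paired discriminator's layout (five
    stride-2 down blocks to a sigmoid patch map) but sees the image
    alone.  The domain classifier is a private shallow branch off the
    input image (two norm-free stride-2 convolutions, global average
    pooling to K logits): the trunk's per-image normalisation removes
    exactly the global colour statistics that identify a stain, so the
    classifier cannot share it.
    """

    def __init__(self, config: DiscriminatorConfig | None = None, *,
                 n_domains: int = N_DOMAINS,
                 rng: np.random.Generator | None = None):
        self.config = config or DiscriminatorConfig()
        cfg = self.config
        rng = rng if rng is not None else np.random.default_rng(0)
        self.n_domains = n_domains
        ch = cfg.channel_schedule()
        self.blocks = []
        prev = 3
        for i, c in enumerate(ch):
            conv = nn.Conv2d(prev, c, rng=rng, init=cfg.init, name=f"md{i}.conv")
            bn = nn.BatchNorm2d(c, name=f"md{i}.bn") if i > 0 else None
            self.blocks.append((conv, bn, nn.LeakyReLU(cfg.leaky_slope)))
            prev = c
        self.adv_head = nn.Conv2d(prev, 1, k=4, stride=1, pad=((1, 2), (1, 2)),
                                  rng=rng, init=cfg.init, name="md_adv.conv")
        self.adv_sigmoid = nn.Sigmoid()
        cls_ch = min(16, cfg.base_channels)
        self.cls_conv1 = nn.Conv2d(3, cls_ch, rng=rng, init="gaussian",
                                   name="md_cls1.conv")
        self.cls_act = nn.LeakyReLU(cfg.leaky_slope)
        self.cls_conv2 = nn.Conv2d(cls_ch, n_domains, rng=rng, init="gaussian",
                                   name="md_cls2.conv")
        self._pad_layer = nn.ReflectPad2d(((0, 0), (0, 0)))
        self._trunk_out_shape = None
        self._cls_map_shape = None
        self._img_shape = None

    def parameters(self):
        out = []
        for conv, bn, _ in self.blocks:
            out.extend(conv.parameters())
            if bn is not None:
                out.extend(bn.parameters())
        out.extend(self.adv_head.parameters())
        out.extend(self.cls_conv1.parameters())
        out.extend(self.cls_conv2.parameters())
        return out

    def zero_grads(self):
        for _, _, g in self.parameters():
            g[...] = 0.0

    def state_dict(self):
        return {name: value for name, value, _ in self.parameters()}

    def load_state_dict(self, state):
        for name, value, _ in self.parameters():
            value[...] = state[name]

    def forward(self, img: np.ndarray, train: bool = True
                ) -> tuple[np.ndarray, np.ndarray]:
        """Returns (adversarial probability map, domain logits (N, K))."""
        n, _, h, w = img.shape
        m = 2 ** self.config.n_down_blocks
        rem_h, rem_w = (-h) % m, (-w) % m
        self._pad_layer.pad = ((rem_h // 2, rem_h - rem_h // 2),
                               (rem_w // 2, rem_w - rem_w // 2))
        cur = self._pad_layer.forward(img.astype(np.float32, copy=False), train)
        for conv, bn, act in self.blocks:
            cur = conv.forward(cur, train)
            if bn is not None:
                cur = bn.forward(cur, train)
            cur = act.forward(cur, train)
        self._trunk_out_shape = cur.shape
        adv = np.clip(self.adv_sigmoid.forward(self.adv_head.forward(cur, train), train),
                      1e-7, 1.0 - 1e-7)
        imgf = img.astype(np.float32, copy=False)
        self._img_shape = imgf.shape
        cls_map = self.cls_conv2.forward(
            self.cls_act.forward(self.cls_conv1.forward(imgf, train), train), train)
        self._cls_map_shape = cls_map.shape
        logits = cls_map.mean(axis=(2, 3))
        return adv, logits

    def backward(self, g_adv: np.ndarray | None,
                 g_logits: np.ndarray | None) -> np.ndarray:
        g_in = None
        if g_adv is not None:
            g_trunk = self.adv_head.backward(self.adv_sigmoid.backward(g_adv))
            g = g_trunk
            for conv, bn, act in reversed(self.blocks):
                g = act.backward(g)
                if bn is not None:
                    g = bn.backward(g)
                g = conv.backward(g)
            g_in = self._pad_layer.backward(g)
        if g_logits is not None:
            _, _, mh, mw = self._cls_map_shape
            g_map = np.broadcast_to(
                (g_logits / (mh * mw))[:, :, None, None],
                (g_logits.shape[0], self.n_domains, mh, mw)).astype(np.float32)
            g = self.cls_conv2.backward(g_map)
            g = self.cls_act.backward(g)
            g_cls = self.cls_conv1.backward(g)
            g_in = g_cls if g_in is None else g_in + g_cls
        if g_in is None:
            raise ValueError("backward needs at least one head gradient")
        return g_in


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _cross_entropy(logits: np.ndarray, domain: StainDomain
                   ) -> tuple[float, np.ndarray]:
    """Mean CE and gradient w.r.t. logits for a single target domain."""
    p = _softmax(logits.astype(np.float64))
    k = list(StainDomain).index(domain)
    ce = float(-np.log(np.clip(p[:, k], 1e-12, None)).mean())
    grad = p.copy()
    grad[:, k] -= 1.0
    return ce, (grad / logits.shape[0]).astype(np.float32)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def stain_as(generator: UNetGenerator, image: np.ndarray,
             target: StainDomain | str, *, deterministic: bool = True) -> np.ndarray:
    """Translate an unstained RGB image into the target stain domain."""
    target = StainDomain.from_label(target)
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {image.shape}")
    h, w = img.shape[:2]
    if min(h, w) < generator.min_input_size:
        raise ValueError(f"image {h}x{w} below minimum size {generator.min_input_size}")
    x = np.concatenate([to_network_range(img), _domain_planes(target, h, w)], axis=1)
    y = generator.forward(x, train=False, dropout=not deterministic,
                          label=target.one_hot)
    return from_network_range(y)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_multistain(datasets: Mapping[StainDomain, TrainingDataset],
                     cfg: MultiStainConfig | None = None, *,
                     progress: bool = False
                     ) -> tuple[UNetGenerator, MultiStainDiscriminator, MultiStainHistory]:
    """Train the multi-domain generator on paired datasets for all stains."""
    cfg = cfg or MultiStainConfig()
    missing = [d for d in StainDomain if d not in datasets or len(datasets[d]) == 0]
    if missing:
        raise ValueError(f"missing training data for domains: "
                         f"{[d.value for d in missing]}")

    rng = np.random.default_rng(cfg.seed)
    init_rng = np.random.default_rng(rng.integers(0, 2 ** 31))
    gen = UNetGenerator(_multistain_gen_config(cfg.gen), in_channels=3 + N_DOMAINS,
                        rng=init_rng)
    gen_cycle = gen.spawn()
    disc = MultiStainDiscriminator(cfg.disc, rng=init_rng)
    opt_g = nn.Adam(gen.parameters(), cfg.lr_generator, (cfg.beta1, cfg.beta2))
    opt_d = nn.Adam(disc.parameters(), cfg.lr_discriminator, (cfg.beta1, cfg.beta2))

    items = [(d, p) for d in StainDomain for p in datasets[d].pairs]
    shuffle_rng = np.random.default_rng(rng.integers(0, 2 ** 31))
    history = MultiStainHistory()

    for epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(len(items))
        e = {"g_adv": [], "g_cls": [], "g_rec": [], "g_total": [],
             "d_loss": [], "acc": []}
        for idx in order:
            domain, pair = items[idx]
            h, w = pair.x.shape[:2]
            x_img = to_network_range(pair.x)
            y_img = to_network_range(pair.y)
            x_in = np.concatenate([x_img, _domain_planes(domain, h, w)], axis=1)

            onehot = domain.one_hot
            zeros = np.zeros(N_DOMAINS, dtype=np.float32)

            # ---- discriminator ----
            y_fake = gen.forward(x_in, train=False, dropout=True, label=onehot)
            adv_r, logits_r = disc.forward(y_img, train=True)
            ce_r, g_logits_r = _cross_entropy(logits_r, domain)
            g_real, _ = adversarial_loss_grads(adv_r, adv_r)
            disc.backward(-g_real, cfg.lambda_cls * g_logits_r)
            adv_f, _ = disc.forward(y_fake, train=True)
            _, g_fake = adversarial_loss_grads(adv_f, adv_f)
            disc.backward(-g_fake, None)
            opt_d.step()
            disc.zero_grads()
            e["d_loss"].append(-adversarial_loss(adv_r, adv_f) + cfg.lambda_cls * ce_r)

            # ---- generator ----
            y_hat = gen.forward(x_in, train=True, dropout=True, label=onehot)
            adv_g, logits_g = disc.forward(y_hat, train=True)
            ce_g, g_logits_g = _cross_entropy(logits_g, domain)
            # non-saturating generator loss: minimise -E[log D(G(x, d))]
            # (without a paired L1 term the minimax form's gradient dies
            # through the saturated sigmoid and nothing drives colour)
            p = np.clip(adv_g, 1e-7, 1 - 1e-7)
            g_ns = (-1.0 / p / p.size).astype(np.float32)
            gin = disc.backward(g_ns, cfg.lambda_cls * g_logits_g)
            g_yhat = gin.copy()

            rec_in = np.concatenate([y_hat, _domain_planes(None, h, w)], axis=1)
            x_rec = gen_cycle.forward(rec_in, train=True, dropout=True, label=zeros)
            rec = l1_loss(x_img, x_rec)
            g_rec_in = gen_cycle.backward(cfg.lambda_rec * l1_loss_grad(x_img, x_rec))
            g_yhat += g_rec_in[:, :3]

            gen.backward(g_yhat)
            opt_g.step()
            gen.zero_grads()
            disc.zero_grads()

            adv_val = float(-np.mean(np.log(p)))
            total = adv_val + cfg.lambda_cls * ce_g + cfg.lambda_rec * rec
            e["g_adv"].append(adv_val)
            e["g_cls"].append(ce_g)
            e["g_rec"].append(rec)
            e["g_total"].append(total)
            k = int(np.argmax(logits_g, axis=1)[0])
            e["acc"].append(float(k == list(StainDomain).index(domain)))

        history.epochs.append(epoch)
        for key, dest in (("g_adv", history.g_adv), ("g_cls", history.g_cls),
                          ("g_rec", history.g_rec), ("g_total", history.g_total),
                          ("d_loss", history.d_loss)):
            dest.append(float(np.mean(e[key])))
        history.cls_accuracy_fake.append(float(np.mean(e["acc"])))
        if progress:
            print(f"epoch {epoch}: d={history.d_loss[-1]:.3f} "
                  f"adv={history.g_adv[-1]:.3f} cls={history.g_cls[-1]:.3f} "
                  f"rec={history.g_rec[-1]:.3f} acc={history.cls_accuracy_fake[-1]:.2f}")
    return gen, disc, history


def classify_domain(disc: MultiStainDiscriminator, image: np.ndarray) -> StainDomain:
    """Domain the auxiliary classifier assigns to an RGB [0, 1] image."""
    _, logits = disc.forward(to_network_range(image), train=False)
    return list(StainDomain)[int(np.argmax(logits, axis=1)[0])]
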