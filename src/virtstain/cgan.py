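"""Conditional GAN for paired unstained -> stained image translation.

The generator is a U-Net: eight stride-2 4x4 encoder convolutions, each
followed by batch normalisation and a leaky rectifier, mirrored by
stride-2 transposed convolutions with skip connections between levels of
equal resolution, and a tanh output mapping to [-1, 1].  Dropout (rate
0.5) in the three innermost decoder blocks supplies the noise z of the
conditional model.  The discriminator is a PatchGAN: it sees the
condition image concatenated channel-wise with the real or generated
candidate, applies five stride-2 down blocks growing the channel count
to 512, reduces to one channel and emits a sigmoid probability map.

Loss layer (natural logarithms throughout):

    L_cGAN(G, D) = E[log D(x, y)] + E[log(1 - D(x, G(x, z)))]
    L_L1(G)      = E[ |y - G(x, z)|_1 ]  (mean over pixels and channels)
    G* = arg min_G max_D  L_cGAN(G, D) + lambda * L_L1(G),   lambda = 100

Inputs whose side is not a multiple of 2**n_levels are reflect-padded up
to the next multiple before the encoder and centre-cropped back after
the decoder (500 x 500 -> 512 x 512 -> 500 x 500), which preserves the
stated eight-level architecture for the 500-pixel patches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

__all__ = [
    "GeneratorConfig",
    "DiscriminatorConfig",
    "LossTerms",
    "UNetGenerator",
    "PatchDiscriminator",
    "build_generator",
    "build_discriminator",
    "adversarial_loss",
    "adversarial_loss_grads",
    "l1_loss",
    "l1_loss_grad",
    "total_objective",
    "PROB_EPS",
]

PROB_EPS = 1e-7  # probabilities clamped away from {0, 1} before log


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorConfig:
    """U-Net generator hyperparameters.

    Defaults follow the reference architecture: 8 stride-2 levels with
    4x4 kernels, batch norm after each encoder convolution, dropout 0.5,
    skips, tanh output.  ``n_levels`` may be lowered for small inputs
    (an HxW input supports at most log2(min(H, W)) levels).
    """

    n_levels: int = 8
    base_channels: int = 64
    max_channels: int = 512
    kernel: int = 4
    stride: int = 2
    dropout_rate: float = 0.5
    n_dropout_blocks: int = 3          # innermost decoder blocks carrying z
    init: str = "uniform"              # nonnegative uniform, or "gaussian"
    leaky_slope: float = 0.2
    first_layer_norm: bool = True      # False keeps constant input channels
                                       # (broadcast domain labels) alive past
                                       # the first block's normalisation
    decoder_label_channels: int = 0    # >0: a label vector of this length is
                                       # broadcast as constant channels into
                                       # every decoder block (direct
                                       # conditioning path for multi-domain
                                       # translation)

    def __post_init__(self):
        if self.kernel != 4 or self.stride != 2:
            raise ValueError("the architecture is defined for 4x4 kernels of stride 2")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")

    def channel_schedule(self) -> list[int]:
        return [min(self.base_channels * 2 ** i, self.max_channels)
                for i in range(self.n_levels)]


@dataclass(frozen=True)
class DiscriminatorConfig:
    """PatchGAN discriminator: five stride-2 down blocks to 512 channels,
    then a 4x4 size-preserving convolution to one channel and a sigmoid."""

    n_down_blocks: int = 5
    base_channels: int = 64
    max_channels: int = 512
    final_channels: int = 1
    kernel: int = 4
    init: str = "uniform"
    leaky_slope: float = 0.2

    def __post_init__(self):
        if self.kernel != 4:
            raise ValueError("the architecture is defined for 4x4 kernels")
        if self.final_channels != 1:
            raise ValueError("the discriminator reduces to a single channel")

    def channel_schedule(self) -> list[int]:
        return [min(self.base_channels * 2 ** i, self.max_channels)
                for i in range(self.n_down_blocks)]


@dataclass(frozen=True)
class LossTerms:
    l_cgan: float          # nats, batch expectation of the adversarial log terms
    l_l1: float            # mean absolute intensity difference
    lambda_l1: float
    total: float = field(init=False)

    def __post_init__(self):
        if self.l_l1 < 0:
            raise ValueError("l_l1 is a mean absolute difference and must be >= 0")
        object.__setattr__(self, "total", self.l_cgan + self.lambda_l1 * self.l_l1)


# ---------------------------------------------------------------------------
# size/padding rule
# ---------------------------------------------------------------------------

def _pad_amounts(size: int, multiple: int) -> tuple[int, int]:
    rem = (-size) % multiple
    return rem // 2, rem - rem // 2


def padded_size(size: int, n_levels: int) -> int:
    m = 2 ** n_levels
    return size + ((-size) % m)


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

class UNetGenerator:
    """U-Net generator; see module docstring for the layer walk."""

    def __init__(self, config: GeneratorConfig | None = None, *,
                 in_channels: int = 3, out_channels: int = 3,
                 rng: np.random.Generator | None = None,
                 dropout_rng: np.random.Generator | None = None):
        self.config = config or GeneratorConfig()
        cfg = self.config
        rng = rng if rng is not None else np.random.default_rng(0)
        self.dropout_rng = dropout_rng if dropout_rng is not None else np.random.default_rng(
            rng.integers(0, 2 ** 31))
        self.in_channels = in_channels
        self.out_channels = out_channels
        ch = cfg.channel_schedule()
        L = cfg.n_levels

        self.enc_convs: list[nn.Conv2d] = []
        self.enc_bns: list[nn.BatchNorm2d] = []
        self.enc_acts: list[nn.LeakyReLU] = []
        prev = in_channels
        for i, c in enumerate(ch):
            self.enc_convs.append(nn.Conv2d(prev, c, rng=rng, init=cfg.init,
                                            name=f"enc{i}.conv"))
            self.enc_bns.append(nn.BatchNorm2d(c, name=f"enc{i}.bn")
                                if (i > 0 or cfg.first_layer_norm) else None)
            self.enc_acts.append(nn.LeakyReLU(cfg.leaky_slope))
            prev = c

        # decoder blocks j = 0 .. L-1; block j upsamples level L-1-j -> L-2-j
        self.dec_convs: list[nn.ConvTranspose2d] = []
        self.dec_bns: list[nn.BatchNorm2d | None] = []
        self.dec_drops: list[nn.Dropout | None] = []
        self.dec_acts: list[nn.Layer] = []
        K = cfg.decoder_label_channels
        for j in range(L):
            cin = (ch[L - 1] if j == 0 else 2 * ch[L - 1 - j]) + K
            cout = out_channels if j == L - 1 else ch[L - 2 - j]
            self.dec_convs.append(nn.ConvTranspose2d(cin, cout, rng=rng, init=cfg.init,
                                                     name=f"dec{j}.deconv"))
            if j == L - 1:
                self.dec_bns.append(None)
                self.dec_drops.append(None)
                self.dec_acts.append(nn.Tanh())
            else:
                self.dec_bns.append(nn.BatchNorm2d(cout, name=f"dec{j}.bn"))
                drop = (nn.Dropout(cfg.dropout_rate, self.dropout_rng)
                        if j < cfg.n_dropout_blocks and cfg.dropout_rate > 0 else None)
                self.dec_drops.append(drop)
                self.dec_acts.append(nn.ReLU())
        self._pad_layer = nn.ReflectPad2d(((0, 0), (0, 0)))
        self._crop = None
        self.last_encoder_shapes: list[tuple[int, int]] = []

    # -- bookkeeping ---------------------------------------------------

    @property
    def n_levels(self) -> int:
        return self.config.n_levels

    @property
    def min_input_size(self) -> int:
        return 2 ** self.config.n_levels

    def _all_layers(self):
        for lst in (self.enc_convs, self.dec_convs):
            yield from lst
        for lst in (self.enc_bns, self.dec_bns):
            yield from (l for l in lst if l is not None)

    def parameters(self):
        out = []
        for layer in self._all_layers():
            out.extend(layer.parameters())
        return out

    def zero_grads(self):
        for _, _, g in self.parameters():
            g[...] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: value for name, value, _ in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, value, _ in self.parameters():
            value[...] = state[name]

    def spawn(self) -> "UNetGenerator":
        """A second forward context sharing all parameters and gradient
        buffers (used for the cycle pass of the multi-domain model)."""
        import copy as _copy
        new = _copy.copy(self)
        new.enc_convs = [l.spawn() for l in self.enc_convs]
        new.enc_bns = [l.spawn() if l is not None else None for l in self.enc_bns]
        new.enc_acts = [nn.LeakyReLU(self.config.leaky_slope) for _ in self.enc_acts]
        new.dec_convs = [l.spawn() for l in self.dec_convs]
        new.dec_bns = [l.spawn() if l is not None else None for l in self.dec_bns]
        new.dec_drops = [l.spawn() if l is not None else None for l in self.dec_drops]
        new.dec_acts = [type(l)() for l in self.dec_acts]
        new._pad_layer = nn.ReflectPad2d(((0, 0), (0, 0)))
        return new

    # -- forward / backward --------------------------------------------

    def _check_size(self, h: int, w: int):
        m = self.min_input_size
        if min(h, w) < m:
            raise ValueError(
                f"input {h}x{w} too small for {self.config.n_levels} stride-2 levels; "
                f"minimum side is {m} (after padding the side must be a multiple of {m})")
        if h % 2 or w % 2:
            raise ValueError(f"input sides must be even, got {h}x{w}")

    def forward(self, x: np.ndarray, train: bool = True,
                dropout: bool | None = None,
                label: np.ndarray | None = None) -> np.ndarray:
        """Map an (N, C, H, W) tensor in [-1, 1] to (N, out_c, H, W).

        ``dropout`` overrides whether the z-noise dropout is active;
        when None it follows ``train``.  ``label`` (length
        ``decoder_label_channels``) is broadcast as constant channels
        into every decoder block when the config enables it.
        """
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(f"expected (N,{self.in_channels},H,W), got {x.shape}")
        K = self.config.decoder_label_channels
        if (label is None) != (K == 0):
            raise ValueError("label must be given iff decoder_label_channels > 0")
        n, _, h, w = x.shape
        self._check_size(h, w)
        m = self.min_input_size
        self._pad_layer.pad = (_pad_amounts(h, m), _pad_amounts(w, m))
        xp = self._pad_layer.forward(x.astype(np.float32, copy=False), train)
        self._crop = (h, w, self._pad_layer.pad)

        skips = []
        self.last_encoder_shapes = []
        cur = xp
        for conv, bn, act in zip(self.enc_convs, self.enc_bns, self.enc_acts):
            cur = conv.forward(cur, train)
            if bn is not None:
                cur = bn.forward(cur, train)
            cur = act.forward(cur, train)
            skips.append(cur)
            self.last_encoder_shapes.append(cur.shape[2:])

        L = self.config.n_levels
        for j in range(L):
            if j == 0:
                inp = skips[L - 1]
            else:
                inp = np.concatenate([cur, skips[L - 1 - j]], axis=1)
            if K:
                nb, _, hh, ww = inp.shape
                planes = np.broadcast_to(
                    np.asarray(label, dtype=np.float32)[None, :, None, None],
                    (nb, K, hh, ww))
                inp = np.concatenate([inp, planes], axis=1)
            cur = self.dec_convs[j].forward(inp, train)
            if self.dec_bns[j] is not None:
                cur = self.dec_bns[j].forward(cur, train)
            if self.dec_drops[j] is not None:
                cur = self.dec_drops[j].forward(cur, train, active=dropout)
            cur = self.dec_acts[j].forward(cur, train)

        (pt, _), (pl, _) = self._crop[2]
        out = cur[:, :, pt:pt + h, pl:pl + w]
        return np.ascontiguousarray(out)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        """Accumulate parameter gradients; returns the input gradient."""
        h, w, pad = self._crop
        (pt, pb), (pl, pr) = pad
        if pt or pb or pl or pr:
            n, c = gy.shape[:2]
            g = np.zeros((n, c, h + pt + pb, w + pl + pr), dtype=np.float32)
            g[:, :, pt:pt + h, pl:pl + w] = gy
        else:
            g = gy.astype(np.float32, copy=False)

        L = self.config.n_levels
        K = self.config.decoder_label_channels
        skip_grads: dict[int, np.ndarray] = {}
        for j in range(L - 1, -1, -1):
            g = self.dec_acts[j].backward(g)
            if self.dec_drops[j] is not None:
                g = self.dec_drops[j].backward(g)
            if self.dec_bns[j] is not None:
                g = self.dec_bns[j].backward(g)
            g = self.dec_convs[j].backward(g)
            if K:
                g = g[:, :-K]           # label planes are inputs, not activations
            if j == 0:
                skip_grads[L - 1] = skip_grads.get(L - 1, 0) + g
                g = None
            else:
                level = L - 1 - j
                # first channels flow up the decoder, the rest to the skip
                c_split = g.shape[1] - self.enc_convs[level].cout
                skip_grads[level] = skip_grads.get(level, 0) + g[:, c_split:]
                g = g[:, :c_split]

        gin = None
        for i in range(L - 1, -1, -1):
            gcur = skip_grads.get(i, None)
            if gin is not None:
                gcur = gin if gcur is None else gcur + gin
            gcur = self.enc_acts[i].backward(gcur)
            if self.enc_bns[i] is not None:
                gcur = self.enc_bns[i].backward(gcur)
            gin = self.enc_convs[i].backward(gcur)

        return self._pad_layer.backward(gin)


def build_generator(config: GeneratorConfig | None = None, *,
                    in_channels: int = 3, seed: int = 0) -> UNetGenerator:
    """Construct a seeded U-Net generator from its configuration."""
    rng = np.random.default_rng(seed)
    return UNetGenerator(config, in_channels=in_channels, rng=rng)


# ---------------------------------------------------------------------------
# discriminator
# ---------------------------------------------------------------------------

class PatchDiscriminator:
    """Conditional PatchGAN.  Input is the channel concatenation of the
    condition image x and the candidate (y or G(x, z)); output is a
    per-patch probability map in (0, 1) which the losses average.

    The final 4x4 convolution uses asymmetric (1, 2) padding so that it
    preserves the spatial size of the last down block: a 512 x 512 input
    yields a 16 x 16 map after the five stride-2 blocks.
    """

    def __init__(self, config: DiscriminatorConfig | None = None, *,
                 in_channels: int = 6,
                 rng: np.random.Generator | None = None):
        self.config = config or DiscriminatorConfig()
        cfg = self.config
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_channels = in_channels
        ch = cfg.channel_schedule()

        self.blocks: list[tuple[nn.Conv2d, nn.BatchNorm2d | None, nn.LeakyReLU]] = []
        prev = in_channels
        for i, c in enumerate(ch):
            conv = nn.Conv2d(prev, c, rng=rng, init=cfg.init, name=f"d{i}.conv")
            bn = nn.BatchNorm2d(c, name=f"d{i}.bn") if i > 0 else None
            self.blocks.append((conv, bn, nn.LeakyReLU(cfg.leaky_slope)))
            prev = c
        self.final = nn.Conv2d(prev, cfg.final_channels, k=4, stride=1,
                               pad=((1, 2), (1, 2)), rng=rng, init=cfg.init,
                               name="d_final.conv")
        self.sigmoid = nn.Sigmoid()
        self._pad_layer = nn.ReflectPad2d(((0, 0), (0, 0)))

    def trunk_layers(self):
        for conv, bn, _ in self.blocks:
            yield conv
            if bn is not None:
                yield bn

    def parameters(self):
        out = []
        for layer in self.trunk_layers():
            out.extend(layer.parameters())
        out.extend(self.final.parameters())
        return out

    def zero_grads(self):
        for _, _, g in self.parameters():
            g[...] = 0.0

    def state_dict(self):
        return {name: value for name, value, _ in self.parameters()}

    def load_state_dict(self, state):
        for name, value, _ in self.parameters():
            value[...] = state[name]

    def forward(self, x: np.ndarray, candidate: np.ndarray | None = None,
                train: bool = True) -> np.ndarray:
        """Probability map for (condition, candidate).  The two images may
        be passed separately or pre-concatenated along channels."""
        if candidate is not None:
            if candidate.shape != x.shape:
                raise ValueError(
                    f"condition and candidate shapes differ: {x.shape} vs {candidate.shape}")
            x = np.concatenate([x, candidate], axis=1)
        if x.shape[1] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {x.shape[1]}")
        n, _, h, w = x.shape
        m = 2 ** self.config.n_down_blocks
        self._pad_layer.pad = (_pad_amounts(h, m), _pad_amounts(w, m))
        cur = self._pad_layer.forward(x.astype(np.float32, copy=False), train)
        for conv, bn, act in self.blocks:
            cur = conv.forward(cur, train)
            if bn is not None:
                cur = bn.forward(cur, train)
            cur = act.forward(cur, train)
        cur = self.final.forward(cur, train)
        # float32 sigmoid rounds to exactly 0/1 when saturated; keep the
        # map in the open interval, matching the loss layer's clamping
        return np.clip(self.sigmoid.forward(cur, train), PROB_EPS, 1.0 - PROB_EPS)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        """Input gradient w.r.t. the concatenated (x, candidate) tensor."""
        g = self.sigmoid.backward(gy)
        g = self.final.backward(g)
        for conv, bn, act in reversed(self.blocks):
            g = act.backward(g)
            if bn is not None:
                g = bn.backward(g)
            g = conv.backward(g)
        return self._pad_layer.backward(g)


def build_discriminator(config: DiscriminatorConfig | None = None, *,
                        in_channels: int = 6, seed: int = 0) -> PatchDiscriminator:
    rng = np.random.default_rng(seed)
    return PatchDiscriminator(config, in_channels=in_channels, rng=rng)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _clamp_probs(p: np.ndarray) -> np.ndarray:
    return np.clip(p, PROB_EPS, 1.0 - PROB_EPS)


def adversarial_loss(d_real: np.ndarray, d_fake: np.ndarray) -> float:
    """E[log D(x, y)] + E[log(1 - D(x, G(x, z)))], in nats.

    Expectations are batch means over the probability maps.  The
    discriminator maximises this; the generator minimises its second
    term.  Probabilities at exactly 0 or 1 are clamped at 1e-7.
    """
    d_real = _clamp_probs(np.asarray(d_real, dtype=np.float64))
    d_fake = _clamp_probs(np.asarray(d_fake, dtype=np.float64))
    return float(np.mean(np.log(d_real)) + np.mean(np.log1p(-d_fake)))


def adversarial_loss_grads(d_real: np.ndarray, d_fake: np.ndarray
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of the adversarial value w.r.t. the two probability maps."""
    r = _clamp_probs(np.asarray(d_real, dtype=np.float64))
    f = _clamp_probs(np.asarray(d_fake, dtype=np.float64))
    g_real = (1.0 / r) / r.size
    g_fake = (-1.0 / (1.0 - f)) / f.size
    return g_real.astype(np.float32), g_fake.astype(np.float32)


def l1_loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean absolute difference over all pixels and channels."""
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {y_hat.shape}")
    return float(np.mean(np.abs(np.asarray(y, dtype=np.float64)
                                - np.asarray(y_hat, dtype=np.float64))))


def l1_loss_grad(y: np.ndarray, y_hat: np.ndarray) -> np.ndarray:
    """Gradient of l1_loss w.r.t. y_hat."""
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {y_hat.shape}")
    return (np.sign(y_hat - y) / y.size).astype(np.float32)


def total_objective(l_cgan: float, l_l1: float, lambda_l1: float = 100.0) -> LossTerms:
    """Global objective: adversarial value plus lambda-weighted L1 term."""
    if lambda_l1 < 0:
        raise ValueError("lambda_l1 must be >= 0")
    return LossTerms(l_cgan=float(l_cgan), l_l1=float(l_l1), lambda_l1=float(lambda_l1))
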