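"""ECG→PPG translation: a 1-D U-Net generator trained adversarially.

The generator is a fully-convolutional encoder–decoder with skip connections
joining mirrored levels: the encoder compresses the ECG through strided
convolutions, the decoder reconstructs a synchronized PPG at the input
resolution, and skips restore the positional detail (beat locations) lost in
the bottleneck. The output activation is tanh, matching the [-1, 1] amplitude
normalization of the segments.

The adversary is a Markovian (patch) discriminator: a strided convolutional
stack over the channel-wise concatenation of the ECG and a (real or
generated) PPG, emitting one logit per receptive-field patch rather than a
single scalar, so realism is judged locally along the waveform.

Training follows the conditional image-translation recipe: the discriminator
minimizes binary cross-entropy (or least-squares when configured) on
real/fake patch logits while the generator minimizes the adversarial term
plus ``lambda_rec`` times the mean-absolute reconstruction error against the
reference PPG.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from . import _nn as nn
from .preprocess import SegmentStore

__all__ = [
    "GeneratorSpec", "DiscriminatorSpec", "TrainConfig", "TranslatorModel",
    "UNetGenerator", "PatchDiscriminator",
    "build_generator", "build_discriminator", "gan_train", "generate_ppg",
    "save_model", "load_model",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """U-Net shape: ``depth`` encoder levels, ``base_filters`` at the top level
    (doubling per level, capped at 8x), kernel width, and skip toggles.
    ``input_len`` must be divisible by ``2**depth``."""

    depth: int = 4
    base_filters: int = 8
    kernel: int = 9
    skip: bool = True
    input_len: int = 3072
    max_filter_mult: int = 8

    def __post_init__(self) -> None:
        if self.input_len % (2**self.depth) != 0:
            raise ValueError(
                f"input_len {self.input_len} not divisible by 2^depth = {2**self.depth}"
            )

    def level_channels(self, i: int) -> int:
        return min(self.base_filters * 2**i, self.base_filters * self.max_filter_mult)


@dataclass(frozen=True)
class DiscriminatorSpec:
    n_layers: int = 4
    base_filters: int = 8
    kernel: int = 9
    patch_output: bool = True
    max_filter_mult: int = 8


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 10
    batch_size: int = 8
    lr_g: float = 2e-4
    lr_d: float = 2e-4
    beta1: float = 0.5
    adv_loss: str = "bce"        # "bce" | "lsgan"
    lambda_rec: float = 100.0
    crop_len: int | None = None  # random training crops (fully-conv nets)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_rec < 0:
            raise ValueError("lambda_rec must be >= 0")
        if self.lr_g <= 0 or self.lr_d <= 0:
            raise ValueError("learning rates must be > 0")
        if self.adv_loss not in ("bce", "lsgan"):
            raise ValueError("adv_loss must be 'bce' or 'lsgan'")


class UNetGenerator:
    """Fully-convolutional U-Net; accepts any length divisible by 2^depth."""

    def __init__(self, spec: GeneratorSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        ch = [spec.level_channels(i) for i in range(spec.depth)]
        self.enc = []
        in_ch = 1
        for i in range(spec.depth):
            self.enc.append([nn.Conv1d(in_ch, ch[i], spec.kernel, stride=2, rng=rng),
                             nn.LeakyReLU(0.2)])
            in_ch = ch[i]
        self.dec = []
        cur = ch[-1]
        for i in range(spec.depth - 2, -1, -1):
            cin = cur + (ch[i] if spec.skip else 0)
            self.dec.append([nn.Upsample1d(2), nn.Conv1d(cin, ch[i], spec.kernel, rng=rng),
                             nn.LeakyReLU(0.2)])
            cur = ch[i]
        self.final_up = nn.Upsample1d(2)
        self.final_conv = nn.Conv1d(cur, 1, spec.kernel, rng=rng)
        self.out_act = nn.Tanh()
        self._skips: list | None = None

    def params(self):
        out = []
        for conv, act in self.enc:
            out += conv.params()
        for up, conv, act in self.dec:
            out += conv.params()
        out += self.final_conv.params()
        return out

    @property
    def n_skip_connections(self) -> int:
        return (self.spec.depth - 1) if self.spec.skip else 0

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[2] % (2**self.spec.depth) != 0:
            raise ValueError(
                f"length {x.shape[2]} not divisible by 2^depth = {2**self.spec.depth}"
            )
        skips = []
        h = x
        for conv, act in self.enc:
            h = act.forward(conv.forward(h))
            skips.append(h)
        self._skips = skips
        for level, (up, conv, act) in enumerate(self.dec):
            h = up.forward(h)
            if self.spec.skip:
                enc_idx = self.spec.depth - 2 - level
                h = np.concatenate([h, skips[enc_idx]], axis=1)
            h = act.forward(conv.forward(h))
        h = self.final_up.forward(h)
        return self.out_act.forward(self.final_conv.forward(h))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.out_act.backward(dy)
        dy = self.final_conv.backward(dy)
        dy = self.final_up.backward(dy)
        skip_grads = [None] * self.spec.depth
        for level in range(len(self.dec) - 1, -1, -1):
            up, conv, act = self.dec[level]
            dy = conv.backward(act.backward(dy))
            if self.spec.skip:
                enc_idx = self.spec.depth - 2 - level
                split = dy.shape[1] - self._skips[enc_idx].shape[1]
                skip_grads[enc_idx] = dy[:, split:, :]
                dy = dy[:, :split, :]
            dy = up.backward(dy)
        for i in range(self.spec.depth - 1, -1, -1):
            conv, act = self.enc[i]
            if skip_grads[i] is not None:
                dy = dy + skip_grads[i]
            dy = conv.backward(act.backward(dy))
        return dy


class PatchDiscriminator:
    """Markovian critic on (ECG, PPG) channel pairs → per-patch logits."""

    def __init__(self, spec: DiscriminatorSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        layers: list = []
        in_ch = 2
        for i in range(spec.n_layers):
            out_ch = min(spec.base_filters * 2**i, spec.base_filters * spec.max_filter_mult)
            layers += [nn.Conv1d(in_ch, out_ch, spec.kernel, stride=2, rng=rng),
                       nn.LeakyReLU(0.2)]
            in_ch = out_ch
        layers.append(nn.Conv1d(in_ch, 1, spec.kernel, stride=1, rng=rng))
        self.net = nn.Sequential(layers)

    def params(self):
        return self.net.params()

    def receptive_field(self) -> int:
        """Input samples seen by one patch logit (always < typical input)."""
        rf = 1
        for _ in range(self.spec.n_layers + 1):
            rf = rf * 2 + (self.spec.kernel - 1)
        return rf

    def forward(self, ecg: np.ndarray, ppg: np.ndarray) -> np.ndarray:
        if ecg.shape != ppg.shape:
            raise ValueError("ecg and ppg channel shapes must match")
        x = np.concatenate([ecg, ppg], axis=1)
        out = self.net.forward(x)
        self._last_len = out.shape[2]
        if self.spec.patch_output:
            return out  # (N, 1, patches)
        return out.mean(axis=2, keepdims=True)

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if not self.spec.patch_output:
            dy = np.repeat(dy, self._last_len, axis=2) / self._last_len
        dx = self.net.backward(dy)
        return dx[:, 0:1, :], dx[:, 1:2, :]


@dataclass
class TranslatorModel:
    generator: UNetGenerator
    discriminator: PatchDiscriminator
    config: TrainConfig
    history: dict = field(default_factory=lambda: {"g_loss": [], "d_loss": [], "rec_mae": []})


def build_generator(spec: GeneratorSpec, seed: int = 0) -> UNetGenerator:
    return UNetGenerator(spec, seed=seed)


def build_discriminator(spec: DiscriminatorSpec, seed: int = 0) -> PatchDiscriminator:
    return PatchDiscriminator(spec, seed=seed)


def _pad_to_multiple(x: np.ndarray, mult: int) -> tuple[np.ndarray, int]:
    """Reflect-pad the last axis up to a multiple of ``mult``."""
    length = x.shape[-1]
    target = -(-length // mult) * mult
    pad = target - length
    if pad == 0:
        return x, 0
    return np.pad(x, [(0, 0)] * (x.ndim - 1) + [(0, pad)], mode="reflect"), pad


def _adv_losses(cfg: TrainConfig):
    if cfg.adv_loss == "bce":
        return nn.bce_with_logits
    return nn.mse_loss  # least-squares GAN on raw logits


def gan_train(pairs: SegmentStore, cfg: TrainConfig,
              gen_spec: GeneratorSpec | None = None,
              disc_spec: DiscriminatorSpec | None = None,
              verbose: bool = False) -> TranslatorModel:
    """Adversarial training on paired (ECG, PPG) segments.

    Alternates one discriminator step and one generator step per batch. The
    generator objective is the adversarial term plus ``lambda_rec`` times the
    L1 reconstruction error against the reference PPG. Per-epoch mean losses
    are recorded in the model history; a non-finite loss aborts with a
    diagnostic.
    """
    if len(pairs) == 0:
        raise ValueError("training store is empty")
    if pairs.n_channels != 2:
        raise ValueError("pairs must carry both ECG and PPG channels")
    gen_spec = gen_spec or GeneratorSpec()
    disc_spec = disc_spec or DiscriminatorSpec()
    rng = np.random.default_rng(cfg.seed)
    gen = UNetGenerator(gen_spec, seed=cfg.seed)
    disc = PatchDiscriminator(disc_spec, seed=cfg.seed + 1)
    opt_g = nn.Adam(gen.params(), lr=cfg.lr_g, beta1=cfg.beta1)
    opt_d = nn.Adam(disc.params(), lr=cfg.lr_d, beta1=cfg.beta1)
    adv = _adv_losses(cfg)
    model = TranslatorModel(gen, disc, cfg)

    data = pairs.segments  # (n, 2, L)
    n = data.shape[0]
    mult = 2**gen_spec.depth
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        g_losses, d_losses, maes = [], [], []
        for start in range(0, n, cfg.batch_size):
            batch = data[order[start : start + cfg.batch_size]]
            if cfg.crop_len is not None and cfg.crop_len < batch.shape[-1]:
                off = rng.integers(0, batch.shape[-1] - cfg.crop_len + 1)
                batch = batch[..., off : off + cfg.crop_len]
            batch, _ = _pad_to_multiple(batch, mult)
            ecg = batch[:, 0:1, :]
            ppg = batch[:, 1:2, :]

            fake = gen.forward(ecg)

            # --- discriminator step (generator output detached) ---
            opt_d.zero_grad()
            logits_real = disc.forward(ecg, ppg)
            loss_real, d_real = adv(logits_real, 1.0)
            disc.backward(d_real)
            logits_fake = disc.forward(ecg, fake)
            loss_fake, d_fake = adv(logits_fake, 0.0)
            disc.backward(d_fake)
            opt_d.step()
            d_loss = 0.5 * (loss_real + loss_fake)

            # --- generator step ---
            opt_g.zero_grad()
            fake = gen.forward(ecg)
            logits = disc.forward(ecg, fake)
            loss_adv, d_logits = adv(logits, 1.0)
            for p in disc.params():
                p.grad[...] = 0.0  # discriminator frozen during G update
            _, d_fake_from_disc = disc.backward(d_logits)
            loss_rec, d_rec = nn.l1_loss(fake, ppg)
            gen.backward(d_fake_from_disc + cfg.lambda_rec * d_rec)
            opt_g.step()
            g_loss = loss_adv + cfg.lambda_rec * loss_rec

            if not (np.isfinite(g_loss) and np.isfinite(d_loss)):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}, batch {start // cfg.batch_size}"
                )
            g_losses.append(g_loss)
            d_losses.append(d_loss)
            maes.append(loss_rec)
        model.history["g_loss"].append(float(np.mean(g_losses)))
        model.history["d_loss"].append(float(np.mean(d_losses)))
        model.history["rec_mae"].append(float(np.mean(maes)))
        if verbose:
            print(f"epoch {epoch + 1}/{cfg.epochs}: "
                  f"G {model.history['g_loss'][-1]:.4f} "
                  f"D {model.history['d_loss'][-1]:.4f} "
                  f"MAE {model.history['rec_mae'][-1]:.4f}")
    return model


def generate_ppg(model: TranslatorModel, ecg: np.ndarray) -> np.ndarray:
    """Translate one ECG array (or a batch) into a synchronized PPG.

    Input is reflect-padded up to the U-Net's divisibility requirement and
    the output cropped back, so any segment length is accepted. Values are
    bounded in [-1, 1] by the tanh output.
    """
    ecg = np.asarray(ecg, dtype=float)
    if not np.all(np.isfinite(ecg)):
        raise ValueError("ECG input contains non-finite values")
    single = ecg.ndim == 1
    x = ecg[None, None, :] if single else ecg.reshape(ecg.shape[0], 1, ecg.shape[-1])
    length = x.shape[-1]
    x, _ = _pad_to_multiple(x, 2**model.generator.spec.depth)
    y = model.generator.forward(x)[..., :length]
    return y[0, 0] if single else y[:, 0, :]


def save_model(model: TranslatorModel, path: str | Path) -> None:
    """Single-archive checkpoint: parameters + config snapshot."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"g_{i}": p.value for i, p in enumerate(model.generator.params())}
    arrays |= {f"d_{i}": p.value for i, p in enumerate(model.discriminator.params())}
    meta = {
        "gen_spec": asdict(model.generator.spec),
        "disc_spec": asdict(model.discriminator.spec),
        "config": asdict(model.config),
        "history": model.history,
    }
    np.savez(path, _meta=np.array(json.dumps(meta)), **arrays)


def load_model(path: str | Path) -> TranslatorModel:
    with np.load(f"{path}" if str(path).endswith(".npz") else f"{path}.npz",
                 allow_pickle=False) as npz:
        meta = json.loads(str(npz["_meta"]))
        gen = UNetGenerator(GeneratorSpec(**meta["gen_spec"]))
        disc = PatchDiscriminator(DiscriminatorSpec(**meta["disc_spec"]))
        for i, p in enumerate(gen.params()):
            p.value[...] = npz[f"g_{i}"]
        for i, p in enumerate(disc.params()):
            p.value[...] = npz[f"d_{i}"]
    model = TranslatorModel(gen, disc, TrainConfig(**meta["config"]))
    model.history = meta["history"]
    return model
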