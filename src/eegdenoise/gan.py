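"""Adversarial LSTM denoiser: generator/discriminator pair and training.

The generator maps one normalized 5-s window (window_len, 1) onto a
cleaned window of the same shape: four 64-unit LSTM layers (full-sequence
outputs), each followed by a PReLU, then a per-timestep dense map to one
tanh output.  The discriminator stacks LSTM layers of 1024/512/256/128
units with LeakyReLU(0.2) between them, flattens (window_len x 128 wide)
and scores real-vs-generated with a single sigmoid unit.

Training alternates per batch: the discriminator sees wavelet-cleaned
references labeled real and generator outputs labeled fake (binary
cross-entropy); the generator, with the discriminator frozen, minimizes

    w_mse * MSE(S', S) + w_adv * BCE(D(S'), real)

with weights (1.0, 5e-4), Adam (lr 1e-3, betas 0.9/0.999, eps 1e-8),
batch 128, 500 epochs in the full-scale "paper" preset.  A reduced
"desk" preset keeps the same objective at a size a single CPU can train
in minutes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .types import Segment

__all__ = ["GeneratorSpec", "DiscriminatorSpec", "TrainConfig",
           "TrainedDenoiser", "build_generator", "build_discriminator",
           "train", "denoise", "save_model", "load_model",
           "paper_generator", "paper_discriminator", "desk_generator",
           "desk_discriminator", "desk_train_config", "paper_train_config"]


@dataclass
class GeneratorSpec:
    window_len: int = 640
    lstm_units: tuple[int, ...] = (64, 64, 64, 64)

    def __post_init__(self) -> None:
        if self.window_len < 1 or not self.lstm_units:
            raise ValueError("window_len >= 1 and at least one LSTM layer required")


@dataclass
class DiscriminatorSpec:
    window_len: int = 640
    lstm_units: tuple[int, ...] = (1024, 512, 256, 128)
    leaky_slope: float = 0.2

    def __post_init__(self) -> None:
        if self.window_len < 1 or not self.lstm_units:
            raise ValueError("window_len >= 1 and at least one LSTM layer required")

    @property
    def flatten_width(self) -> int:
        return self.window_len * self.lstm_units[-1]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    batch_size: int = 128
    epochs: int = 500
    w_mse: float = 1.0
    w_adv: float = 5e-4
    seed: int = 0
    per_epoch_discriminator: bool = False  # update D once per epoch instead
    generator: GeneratorSpec = field(default_factory=GeneratorSpec)
    discriminator: DiscriminatorSpec = field(default_factory=DiscriminatorSpec)

    def __post_init__(self) -> None:
        for v in (self.learning_rate, self.beta1, self.beta2, self.epsilon,
                  self.batch_size, self.epochs, self.w_mse):
            if not v > 0:
                raise ValueError("training hyperparameters must be positive")
        if self.w_adv < 0:
            raise ValueError("adversarial weight must be non-negative")


def paper_generator(window_len: int = 640) -> GeneratorSpec:
    return GeneratorSpec(window_len=window_len, lstm_units=(64, 64, 64, 64))


def paper_discriminator(window_len: int = 640) -> DiscriminatorSpec:
    return DiscriminatorSpec(window_len=window_len,
                             lstm_units=(1024, 512, 256, 128))


def desk_generator(window_len: int = 640) -> GeneratorSpec:
    """Reduced generator for single-CPU runs: 2 x 16-unit LSTM layers."""
    return GeneratorSpec(window_len=window_len, lstm_units=(16, 16))


def desk_discriminator(window_len: int = 640) -> DiscriminatorSpec:
    """Reduced discriminator for single-CPU runs."""
    return DiscriminatorSpec(window_len=window_len, lstm_units=(32, 16))


def paper_train_config(seed: int = 0) -> TrainConfig:
    return TrainConfig(seed=seed)


def desk_train_config(seed: int = 0, window_len: int = 640,
                      epochs: int = 30, batch_size: int = 8) -> TrainConfig:
    """Single-CPU preset: small batch (more updates per epoch) and a
    higher learning rate, which the reduced model tolerates; the
    objective and update scheme are identical to the full preset."""
    return TrainConfig(
        epochs=epochs, batch_size=batch_size, seed=seed,
        learning_rate=3e-3,
        generator=desk_generator(window_len),
        discriminator=desk_discriminator(window_len),
    )


def build_generator(spec: GeneratorSpec, seed: int = 0) -> nn.Sequential:
    """(B, window_len, 1) -> (B, window_len, 1), outputs in (-1, 1)."""
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    d = 1
    for units in spec.lstm_units:
        layers.append(nn.LSTM(d, units, rng))
        layers.append(nn.PReLU(units))
        d = units
    layers.append(nn.TimeDistributedDense(d, 1, rng, activation="tanh"))
    return nn.Sequential(layers)


def build_discriminator(spec: DiscriminatorSpec, seed: int = 0) -> nn.Sequential:
    """(B, window_len, 1) -> (B, 1) probability in (0, 1)."""
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    d = 1
    for units in spec.lstm_units:
        layers.append(nn.LSTM(d, units, rng))
        layers.append(nn.LeakyReLU(spec.leaky_slope))
        d = units
    layers.append(nn.FlattenDense(spec.flatten_width, rng))
    return nn.Sequential(layers)


@dataclass
class TrainedDenoiser:
    """Trained generator (+discriminator) with per-epoch loss history."""

    generator: nn.Sequential
    discriminator: nn.Sequential
    history: dict[str, list[float]]
    config: TrainConfig

    @property
    def window_len(self) -> int:
        return self.config.generator.window_len


def _segments_to_batch(segments: list[Segment], window_len: int) -> np.ndarray:
    mat = np.stack([s.x for s in segments])
    if mat.shape[1] != window_len:
        raise ValueError(
            f"segments of length {mat.shape[1]} do not match model window "
            f"length {window_len}")
    return mat[:, :, None]


def train(noisy: list[Segment], clean_ref: list[Segment],
          cfg: TrainConfig) -> TrainedDenoiser:
    """Adversarial training on index-aligned (noisy, reference) pairs.

    ``clean_ref`` are the wavelet-cleaned versions of the same segments;
    ground-truth clean signals (when simulating) are never used here.
    Deterministic for a fixed ``cfg.seed`` on one platform.
    """
    if len(noisy) != len(clean_ref) or not noisy:
        raise ValueError("noisy and clean_ref must be non-empty aligned lists")
    wl = cfg.generator.window_len
    X = _segments_to_batch(noisy, wl)
    S = _segments_to_batch(clean_ref, wl)

    ss = np.random.SeedSequence(cfg.seed)
    g_seed, d_seed, shuffle_seed = (int(s) for s in ss.generate_state(3))
    G = build_generator(cfg.generator, seed=g_seed)
    D = build_discriminator(cfg.discriminator, seed=d_seed)
    opt_g = nn.Adam(G, lr=cfg.learning_rate, beta1=cfg.beta1,
                    beta2=cfg.beta2, eps=cfg.epsilon)
    opt_d = nn.Adam(D, lr=cfg.learning_rate, beta1=cfg.beta1,
                    beta2=cfg.beta2, eps=cfg.epsilon)
    rng = np.random.default_rng(shuffle_seed)

    n = X.shape[0]
    history: dict[str, list[float]] = {
        "generator_loss": [], "discriminator_loss": [], "generator_mse": []}
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        g_losses, d_losses, mses = [], [], []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, sb = X[idx], S[idx]
            fake = G.forward(xb)

            # --- discriminator step: real references vs generated fakes.
            if not cfg.per_epoch_discriminator or start == 0:
                D.zero_grads()
                batch = np.concatenate([sb, fake], axis=0)
                labels = np.concatenate(
                    [np.ones((sb.shape[0], 1)), np.zeros((fake.shape[0], 1))])
                prob = D.forward(batch)
                d_loss, dlogit = nn.bce_loss(prob, labels)
                D.backward(dlogit)
                opt_d.step()
                d_losses.append(d_loss)

            # --- generator step, discriminator frozen.
            G.zero_grads()
            fake = G.forward(xb)
            mse, dmse = nn.mse_loss(fake, sb)
            prob = D.forward(fake)
            adv, dlogit = nn.bce_loss(prob, np.ones((fake.shape[0], 1)))
            D.zero_grads()
            dfake_adv = D.backward(dlogit)  # gradient through frozen D
            D.zero_grads()                  # discard D's own gradients
            g_loss = cfg.w_mse * mse + cfg.w_adv * adv
            G.backward(cfg.w_mse * dmse + cfg.w_adv * dfake_adv)
            opt_g.step()
            g_losses.append(g_loss)
            mses.append(mse)
            if not np.isfinite(g_loss) or (d_losses and not np.isfinite(d_losses[-1])):
                raise FloatingPointError(
                    f"training diverged (NaN/inf loss) at epoch {epoch}")
        history["generator_loss"].append(float(np.mean(g_losses)))
        history["discriminator_loss"].append(float(np.mean(d_losses)))
        history["generator_mse"].append(float(np.mean(mses)))
    return TrainedDenoiser(generator=G, discriminator=D, history=history,
                           config=cfg)


def denoise(model: TrainedDenoiser, segments: list[Segment],
            batch_size: int = 64) -> list[Segment]:
    """Run the trained generator over segments; metadata is preserved."""
    if not segments:
        return []
    X = _segments_to_batch(segments, model.window_len)
    outs = []
    for start in range(0, X.shape[0], batch_size):
        outs.append(model.generator.forward(X[start : start + batch_size]))
    Y = np.concatenate(outs, axis=0)[:, :, 0]
    return [seg.with_data(y) for seg, y in zip(segments, Y)]


# ---------------------------------------------------------------------------
# Serialization: npz weights + JSON architecture sidecar

_FORMAT_VERSION = 1


def save_model(model: TrainedDenoiser, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for i, w in enumerate(model.generator.get_weights()):
        arrays[f"g_{i}"] = w
    for i, w in enumerate(model.discriminator.get_weights()):
        arrays[f"d_{i}"] = w
    with open(path, "wb") as fh:  # keep the exact path (no .npz appended)
        np.savez(fh, **arrays)
    cfg = asdict(model.config)
    meta = {"format_version": _FORMAT_VERSION, "config": cfg,
            "history": model.history}
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def load_model(path: str | Path) -> TrainedDenoiser:
    path = Path(path)
    meta_path = Path(str(path) + ".json")
    if not path.exists() or not meta_path.exists():
        raise FileNotFoundError(f"model container {path} (+ .json) not found")
    try:
        meta = json.loads(meta_path.read_text())
        arrays = np.load(path)
    except Exception as exc:  # corrupted container
        raise ValueError(f"cannot load model from {path}: {exc}") from exc
    if meta.get("format_version") != _FORMAT_VERSION:
        raise ValueError(
            f"model format version {meta.get('format_version')} not supported")
    cfg_d = meta["config"]
    cfg_d["generator"] = GeneratorSpec(
        window_len=cfg_d["generator"]["window_len"],
        lstm_units=tuple(cfg_d["generator"]["lstm_units"]))
    cfg_d["discriminator"] = DiscriminatorSpec(
        window_len=cfg_d["discriminator"]["window_len"],
        lstm_units=tuple(cfg_d["discriminator"]["lstm_units"]),
        leaky_slope=cfg_d["discriminator"]["leaky_slope"])
    cfg = TrainConfig(**cfg_d)
    G = build_generator(cfg.generator, seed=0)
    D = build_discriminator(cfg.discriminator, seed=0)
    G.set_weights([arrays[f"g_{i}"] for i in range(len(G.params))])
    D.set_weights([arrays[f"d_{i}"] for i in range(len(D.params))])
    return TrainedDenoiser(generator=G, discriminator=D,
                           history=meta["history"], config=cfg)
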