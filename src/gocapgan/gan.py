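"""Wasserstein GAN over protein sequences with a capsule-network critic.

The generator maps a latent noise vector through a linear projection and six
residual 1-D convolution blocks to per-position residue logits, discretised
with a Gumbel-softmax so its output stays on the probability simplex while
remaining differentiable.  The critic (discriminator) runs an initial 1-D
convolution, six residual blocks, then a capsule stage — convolution,
reshape into primary capsules, squash, three rounds of dynamic routing, a
length layer — and a final linear map to one unbounded realness score per
sequence.

Training minimises the Wasserstein objective: the critic maximises
E[D(x_real)] - E[D(x_fake)] under a soft 1-Lipschitz constraint (gradient
penalty with weight lambda on interpolated inputs; optional weight clipping),
the generator minimises -E[D(x_fake)].  Optimiser is RMSprop
(lr 1e-4, alpha 0.99, eps 1e-8) for both networks.
"""

from __future__ import annotations

import gc
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import tensor as T
from .tensor import Tensor
from .capsule import route_t, squash_t, lengths_t
from .seqio import EncodedBatch, Vocabulary, decode_batch

__all__ = [
    "GanConfig",
    "Generator",
    "Discriminator",
    "TrainState",
    "GanTrainingError",
    "build_generator",
    "build_discriminator",
    "generator_param_count",
    "discriminator_param_count",
    "critic_loss",
    "generator_loss",
    "gradient_penalty",
    "train_gan",
    "generate_sequences",
    "save_checkpoint",
    "load_checkpoint",
]


class GanTrainingError(RuntimeError):
    pass


@dataclass
class GanConfig:
    """Hyperparameters for the sequence GAN.

    Defaults follow the published training setup (batch size 32, sequence
    length 160, 12 epochs, lambda 10, 128-dimensional noise, RMSprop with
    learning rate 1e-4, alpha 0.99, eps 1e-8, Wasserstein loss); quantities
    the setup leaves open (critic steps per generator step, kernel size,
    Gumbel temperature, capsule geometry, model width) carry standard
    defaults and are freely configurable.
    """

    batch_size: int = 32
    seq_len: int = 160
    noise_dim: int = 128
    epochs: int = 12
    gp_lambda: float = 10.0
    learning_rate: float = 1e-4
    rmsprop_alpha: float = 0.99
    rmsprop_eps: float = 1e-8
    n_res_blocks: int = 6
    channels: int = 64
    kernel_size: int = 5
    n_critic: int = 5
    gumbel_tau: float = 1.0
    leaky_slope: float = 0.2
    residual_scale: float = 0.3
    vocab_size: int = 21
    capsule_conv_channels: int | None = None  # default: same as channels
    primary_capsule_dim: int = 8
    out_capsules: int = 10
    out_capsule_dim: int = 16
    routing_iterations: int = 3
    bias_mode: str = "per_pair"
    lipschitz: str = "gp"  # "gp" | "clip"
    clip_value: float = 0.01
    seed: int = 0

    def __post_init__(self):
        for name in ("batch_size", "seq_len", "noise_dim", "n_res_blocks", "channels",
                     "kernel_size", "n_critic", "primary_capsule_dim", "out_capsules",
                     "out_capsule_dim", "routing_iterations", "vocab_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.gp_lambda < 0:
            raise ValueError("gp_lambda must be >= 0")
        if self.gumbel_tau <= 0 or self.learning_rate <= 0:
            raise ValueError("gumbel_tau and learning_rate must be > 0")
        if self.lipschitz not in ("gp", "clip"):
            raise ValueError("lipschitz must be 'gp' or 'clip'")
        if self.bias_mode not in ("per_pair", "per_output"):
            raise ValueError("bias_mode must be 'per_pair' or 'per_output'")
        if self.capsule_conv_channels is None:
            self.capsule_conv_channels = self.channels

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GanConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @property
    def n_primary_capsules(self) -> int:
        total = self.seq_len * self.capsule_conv_channels
        if total % self.primary_capsule_dim != 0:
            raise ValueError(
                f"capsule reshape does not tile: seq_len*capsule_conv_channels = "
                f"{self.seq_len}*{self.capsule_conv_channels} = {total} is not a "
                f"multiple of primary_capsule_dim = {self.primary_capsule_dim}"
            )
        return total // self.primary_capsule_dim


# -- layers -------------------------------------------------------------------


def _conv_indices(L: int, k: int):
    """im2col gather indices and validity mask for same-padded 1-D conv."""
    pad = (k - 1) // 2
    t = np.arange(L)[:, None]
    u = np.arange(k)[None, :]
    p = (t + u - pad).ravel()
    valid = ((p >= 0) & (p < L)).astype(np.float64)
    return np.clip(p, 0, L - 1), valid[None, :, None]


def conv1d(x: Tensor, W: Tensor, b: Tensor, idx, mask) -> Tensor:
    """Same-padded 1-D convolution; x is (B, L, C_in), W is (k*C_in, C_out)."""
    B, L, C = x.data.shape
    k = idx.shape[0] // L
    patches = T.mul(T.take(x, idx, axis=1), T.constant(mask))
    patches = T.reshape(patches, (B, L, k * C))
    return T.add(T.matmul(patches, W), b)


class _Module:
    """Parameter container with flat name->Tensor access."""

    def __init__(self):
        self.params: dict[str, Tensor] = {}

    def add_param(self, name: str, array: np.ndarray) -> Tensor:
        t = T.parameter(array)
        self.params[name] = t
        return t

    def param_count(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    def state_arrays(self) -> dict:
        return {k: v.data for k, v in self.params.items()}

    def load_state(self, arrays: dict) -> None:
        for k, v in self.params.items():
            if k not in arrays:
                raise ValueError(f"checkpoint missing parameter {k!r} "
                                 f"(expected shape {v.data.shape})")
            if arrays[k].shape != v.data.shape:
                raise ValueError(
                    f"checkpoint/config mismatch at layer {k!r}: checkpoint shape "
                    f"{arrays[k].shape}, configured shape {v.data.shape}"
                )
            v.data = np.asarray(arrays[k], dtype=np.float64)


def _he(rng, fan_in, shape):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Generator(_Module):
    """Noise -> linear -> six residual conv blocks -> logits -> Gumbel-softmax."""

    def __init__(self, config: GanConfig):
        super().__init__()
        self.config = config
        c = config
        rng = np.random.default_rng(c.seed)
        d, L, k, V = c.channels, c.seq_len, c.kernel_size, c.vocab_size
        self.add_param("input.W", _he(rng, c.noise_dim, (c.noise_dim, L * d)))
        self.add_param("input.b", np.zeros(L * d))
        for i in range(c.n_res_blocks):
            for j in (1, 2):
                self.add_param(f"res{i}.conv{j}.W", _he(rng, k * d, (k * d, d)))
                self.add_param(f"res{i}.conv{j}.b", np.zeros(d))
        self.add_param("out.W", _he(rng, d, (d, V)))
        self.add_param("out.b", np.zeros(V))
        self._idx, self._mask = _conv_indices(L, k)

    def forward(self, z: Tensor, gumbel_noise: np.ndarray | None = None) -> Tensor:
        c = self.config
        B = z.data.shape[0]
        h = T.add(T.matmul(z, self.params["input.W"]), self.params["input.b"])
        h = T.reshape(h, (B, c.seq_len, c.channels))
        for i in range(c.n_res_blocks):
            r = conv1d(h, self.params[f"res{i}.conv1.W"], self.params[f"res{i}.conv1.b"],
                       self._idx, self._mask)
            r = T.leaky_relu(r, c.leaky_slope)
            r = conv1d(r, self.params[f"res{i}.conv2.W"], self.params[f"res{i}.conv2.b"],
                       self._idx, self._mask)
            r = T.leaky_relu(r, c.leaky_slope)
            h = T.add(h, T.mul(r, c.residual_scale))
        logits = T.add(T.matmul(h, self.params["out.W"]), self.params["out.b"])
        if gumbel_noise is not None:
            logits = T.add(logits, T.constant(gumbel_noise))
        return T.softmax(T.mul(logits, 1.0 / c.gumbel_tau), axis=-1)

    def sample(self, n: int, rng: np.random.Generator) -> Tensor:
        c = self.config
        z = T.constant(rng.normal(size=(n, c.noise_dim)))
        u = rng.uniform(1e-12, 1.0, size=(n, c.seq_len, c.vocab_size))
        gumbel = -np.log(-np.log(u))
        return self.forward(z, gumbel_noise=gumbel)


class Discriminator(_Module):
    """Conv -> six residual blocks -> capsule stage -> length layer -> linear score."""

    def __init__(self, config: GanConfig):
        super().__init__()
        self.config = config
        c = config
        J = c.n_primary_capsules  # validates the capsule tiling
        rng = np.random.default_rng(c.seed + 1)
        d, L, k, V = c.channels, c.seq_len, c.kernel_size, c.vocab_size
        dc, pd = c.capsule_conv_channels, c.primary_capsule_dim
        K, do = c.out_capsules, c.out_capsule_dim
        self.add_param("in_conv.W", _he(rng, k * V, (k * V, d)))
        self.add_param("in_conv.b", np.zeros(d))
        for i in range(c.n_res_blocks):
            for j in (1, 2):
                self.add_param(f"res{i}.conv{j}.W", _he(rng, k * d, (k * d, d)))
                self.add_param(f"res{i}.conv{j}.b", np.zeros(d))
        self.add_param("cap_conv.W", _he(rng, k * d, (k * d, dc)))
        self.add_param("cap_conv.b", np.zeros(dc))
        self.add_param("caps.W", rng.normal(0.0, 0.1, size=(J, pd, K * do)))
        if c.bias_mode == "per_pair":
            self.add_param("caps.B", np.zeros((J, K, do)))
        else:
            self.add_param("caps.B", np.zeros((K, do)))
        self.add_param("head.W", _he(rng, K, (K, 1)))
        self.add_param("head.b", np.zeros(1))
        self._idx, self._mask = _conv_indices(L, k)

    def forward(self, x: Tensor, return_parts: bool = False):
        c = self.config
        B = x.data.shape[0]
        J, K, do, pd = (c.n_primary_capsules, c.out_capsules,
                        c.out_capsule_dim, c.primary_capsule_dim)
        h = T.leaky_relu(
            conv1d(x, self.params["in_conv.W"], self.params["in_conv.b"],
                   self._idx, self._mask), c.leaky_slope)
        for i in range(c.n_res_blocks):
            r = conv1d(h, self.params[f"res{i}.conv1.W"], self.params[f"res{i}.conv1.b"],
                       self._idx, self._mask)
            r = T.leaky_relu(r, c.leaky_slope)
            r = conv1d(r, self.params[f"res{i}.conv2.W"], self.params[f"res{i}.conv2.b"],
                       self._idx, self._mask)
            r = T.leaky_relu(r, c.leaky_slope)
            h = T.add(h, T.mul(r, c.residual_scale))
        residual_out = h
        hc = T.leaky_relu(
            conv1d(h, self.params["cap_conv.W"], self.params["cap_conv.b"],
                   self._idx, self._mask), c.leaky_slope)
        u = squash_t(T.reshape(hc, (B, J, pd)), axis=-1)  # primary capsules
        u_t = T.transpose(u, (1, 0, 2))  # (J, B, pd): stacked matmul over capsules
        votes = T.matmul(u_t, self.params["caps.W"])  # (J, B, K*do)
        votes = T.transpose(T.reshape(votes, (J, B, K, do)), (1, 0, 2, 3))
        if c.bias_mode == "per_pair":
            votes = T.add(votes, self.params["caps.B"])
        else:
            bias = T.reshape(self.params["caps.B"], (1, 1, K, do))
            votes = T.add(votes, bias)
        coupling, _, v, _ = route_t(votes, iterations=c.routing_iterations)
        lengths = lengths_t(v, axis=-1)  # (B, K)
        score = T.add(T.matmul(lengths, self.params["head.W"]), self.params["head.b"])
        score = T.reshape(score, (B,))
        if return_parts:
            return score, {"lengths": lengths, "coupling": coupling,
                           "residual_out": residual_out, "capsule_v": v}
        return score


def build_generator(config: GanConfig) -> Generator:
    return Generator(config)


def build_discriminator(config: GanConfig) -> Discriminator:
    return Discriminator(config)


def generator_param_count(config: GanConfig) -> int:
    """Closed-form trainable parameter total for the generator topology."""
    c = config
    d, L, k, V = c.channels, c.seq_len, c.kernel_size, c.vocab_size
    total = c.noise_dim * L * d + L * d          # input linear
    total += c.n_res_blocks * 2 * (k * d * d + d)  # residual convs
    total += d * V + V                            # output projection
    return total


def discriminator_param_count(config: GanConfig) -> int:
    """Closed-form trainable parameter total for the critic topology."""
    c = config
    d, k, V = c.channels, c.kernel_size, c.vocab_size
    dc, pd = c.capsule_conv_channels, c.primary_capsule_dim
    J, K, do = c.n_primary_capsules, c.out_capsules, c.out_capsule_dim
    total = k * V * d + d
    total += c.n_res_blocks * 2 * (k * d * d + d)
    total += k * d * dc + dc
    total += J * K * do * pd
    total += (J * K * do) if c.bias_mode == "per_pair" else (K * do)
    total += K + 1
    return total


# -- losses -------------------------------------------------------------------


def _mean(x):
    if isinstance(x, Tensor):
        if x.data.size == 0:
            raise ValueError("empty score vector")
        return x.mean()
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty score vector")
    return float(x.mean())


def critic_loss(scores_real, scores_fake):
    """Wasserstein critic loss: mean(fake) - mean(real) (minimised)."""
    if isinstance(scores_real, Tensor) or isinstance(scores_fake, Tensor):
        return T.add(_mean(scores_fake), T.mul(_mean(scores_real), -1.0))
    return _mean(scores_fake) - _mean(scores_real)


def generator_loss(scores_fake):
    """Wasserstein generator loss: -mean(fake scores)."""
    if isinstance(scores_fake, Tensor):
        return T.mul(_mean(scores_fake), -1.0)
    return -_mean(scores_fake)


def gradient_penalty(disc: Discriminator, real, fake, gp_lambda: float,
                     rng: np.random.Generator):
    """Two-sided gradient penalty at random interpolates of real and fake.

    Draws one epsilon ~ U(0,1) per example, forms x~ = eps*real + (1-eps)*fake,
    and returns lambda * mean((||grad_x D(x~)||_2 - 1)^2) as a Tensor whose
    graph reaches the critic parameters (double backprop).
    """
    if gp_lambda < 0:
        raise ValueError("gp_lambda must be >= 0")
    real_a = real.tensor if isinstance(real, EncodedBatch) else np.asarray(real, dtype=np.float64)
    fake_a = fake.data if isinstance(fake, Tensor) else np.asarray(fake, dtype=np.float64)
    if real_a.shape != fake_a.shape:
        raise ValueError(f"real/fake shape mismatch: {real_a.shape} vs {fake_a.shape}")
    if gp_lambda == 0:
        return T.constant(0.0)
    eps = rng.uniform(size=(real_a.shape[0], 1, 1))
    interp = T.parameter(eps * real_a + (1.0 - eps) * fake_a)
    scores = disc.forward(interp)
    (g,) = T.grad(scores.sum(), [interp])
    sq = T.tsum(T.power(g, 2.0), axis=(1, 2))
    norm = T.sqrt(sq + 1e-24)
    return T.mul(T.power(norm - 1.0, 2.0).mean(), gp_lambda)


# -- optimiser ----------------------------------------------------------------


class RMSprop:
    """RMSprop with running squared-gradient average (alpha) and epsilon."""

    def __init__(self, params: dict, lr: float, alpha: float = 0.99, eps: float = 1e-8):
        self.params = params
        self.lr, self.alpha, self.eps = lr, alpha, eps
        self.sq = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self, grads: dict) -> None:
        for k, p in self.params.items():
            g = grads[k]
            self.sq[k] = self.alpha * self.sq[k] + (1.0 - self.alpha) * g * g
            p.data = p.data - self.lr * g / (np.sqrt(self.sq[k]) + self.eps)


# -- checkpoints --------------------------------------------------------------


def save_checkpoint(path, gen: Generator, disc: Discriminator, config: GanConfig,
                    step: int, extra: dict | None = None) -> Path:
    """Write parameters (.npz) plus a JSON manifest next to it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"gen.{k}": v for k, v in gen.state_arrays().items()}
    arrays.update({f"disc.{k}": v for k, v in disc.state_arrays().items()})
    np.savez(path, **arrays)
    manifest = {
        "step": step,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    if extra:
        manifest.update(extra)
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))
    return path


def load_checkpoint(path, config: GanConfig | None = None):
    """Rebuild generator and critic from a checkpoint; returns (gen, disc, manifest)."""
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    cfg = config or GanConfig.from_dict(manifest["config"])
    gen, disc = Generator(cfg), Discriminator(cfg)
    with np.load(path) as data:
        gen.load_state({k[4:]: data[k] for k in data.files if k.startswith("gen.")})
        disc.load_state({k[5:]: data[k] for k in data.files if k.startswith("disc.")})
    return gen, disc, manifest


# -- training -----------------------------------------------------------------


@dataclass
class TrainState:
    """Append-only training bookkeeping."""

    step: int = 0
    critic_losses: list = field(default_factory=list)
    gen_losses: list = field(default_factory=list)
    gp_values: list = field(default_factory=list)
    checkpoints: list = field(default_factory=list)
    seed: int = 0


def _check_finite(value: float, what: str, state: TrainState):
    if not np.isfinite(value):
        last = state.checkpoints[-1] if state.checkpoints else "<none>"
        raise GanTrainingError(
            f"{what} became non-finite at step {state.step}; "
            f"last good checkpoint: {last}"
        )


def train_gan(gen: Generator, disc: Discriminator, data: EncodedBatch,
              config: GanConfig, out_dir=None, progress=None) -> TrainState:
    """Alternating WGAN training: n_critic critic updates then one generator
    update per data batch; one epoch is floor(N/batch_size) full batches
    (drop-last).  Checkpoints are written per epoch when out_dir is given.
    Fully reproducible from config.seed.
    """
    c = config
    N = data.n
    n_batches = N // c.batch_size
    if n_batches < 1:
        raise ValueError(f"need at least one full batch: N={N} < batch_size={c.batch_size}")
    rng = np.random.default_rng(c.seed)
    state = TrainState(seed=c.seed)
    opt_d = RMSprop(disc.params, c.learning_rate, c.rmsprop_alpha, c.rmsprop_eps)
    opt_g = RMSprop(gen.params, c.learning_rate, c.rmsprop_alpha, c.rmsprop_eps)
    if out_dir is not None:
        out_dir = Path(out_dir)
        ck = save_checkpoint(out_dir / "checkpoint_init.npz", gen, disc, c, 0)
        state.checkpoints.append(str(ck))

    d_names = list(disc.params)
    g_names = list(gen.params)
    for epoch in range(c.epochs):
        perm = rng.permutation(N)
        for bi in range(n_batches):
            idx = perm[bi * c.batch_size : (bi + 1) * c.batch_size]
            real = data.tensor[idx]
            real_t = T.constant(real)
            for _ in range(c.n_critic):
                with T.no_grad():
                    fake = gen.sample(c.batch_size, rng).detach()
                loss_w = critic_loss(disc.forward(real_t), disc.forward(fake))
                if c.lipschitz == "gp" and c.gp_lambda > 0:
                    gp = gradient_penalty(disc, real, fake, c.gp_lambda, rng)
                    total = T.add(loss_w, gp)
                    gp_val = float(gp.data)
                else:
                    total, gp_val = loss_w, 0.0
                grads = T.grad(total, [disc.params[k] for k in d_names])
                opt_d.step({k: g.data for k, g in zip(d_names, grads)})
                if c.lipschitz == "clip":
                    for p in disc.params.values():
                        np.clip(p.data, -c.clip_value, c.clip_value, out=p.data)
                state.step += 1
                state.critic_losses.append(float(loss_w.data))
                state.gp_values.append(gp_val)
                _check_finite(state.critic_losses[-1], "critic loss", state)
            fake = gen.sample(c.batch_size, rng)
            loss_g = generator_loss(disc.forward(fake))
            grads = T.grad(loss_g, [gen.params[k] for k in g_names])
            opt_g.step({k: g.data for k, g in zip(g_names, grads)})
            state.step += 1
            state.gen_losses.append(float(loss_g.data))
            _check_finite(state.gen_losses[-1], "generator loss", state)
            gc.collect()  # large per-step graphs; don't wait for generational GC
            if progress is not None:
                progress(epoch, bi, state)
        if out_dir is not None:
            ck = save_checkpoint(out_dir / f"checkpoint_epoch{epoch + 1}.npz",
                                 gen, disc, c, state.step,
                                 extra={"epoch": epoch + 1})
            state.checkpoints.append(str(ck))
    return state


def generate_sequences(gen: Generator, n: int, seed: int,
                       vocab: Vocabulary | None = None) -> list:
    """Sample n decoded sequences from the generator; deterministic given seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    vocab = vocab or Vocabulary()
    rng = np.random.default_rng(seed)
    out = []
    chunk = 64
    for start in range(0, n, chunk):
        m = min(chunk, n - start)
        batch = gen.sample(m, rng)
        out.extend(decode_batch(EncodedBatch(tensor=batch.data), vocab))
    return out
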