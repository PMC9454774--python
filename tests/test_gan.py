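"""GAN construction, Wasserstein losses, gradient penalty, training loop."""

import dataclasses

import numpy as np
import pytest

from gocapgan import tensor as T
from gocapgan.gan import (GanConfig, RMSprop, build_discriminator,
                          build_generator, critic_loss,
                          discriminator_param_count, generate_sequences,
                          generator_loss, generator_param_count,
                          gradient_penalty, load_checkpoint, save_checkpoint,
                          train_gan)
from gocapgan.seqio import AMINO_ACIDS, EncodedBatch, encode_batch, ProteinRecord


# -- builders -----------------------------------------------------------------


def test_parameter_counts_match_analytic_sums(tiny_gan_config):
    gen = build_generator(tiny_gan_config)
    disc = build_discriminator(tiny_gan_config)
    assert gen.param_count() == generator_param_count(tiny_gan_config)
    assert disc.param_count() == discriminator_param_count(tiny_gan_config)


def test_same_seed_builds_identical_weights(tiny_gan_config):
    g1, g2 = build_generator(tiny_gan_config), build_generator(tiny_gan_config)
    for k in g1.params:
        assert np.array_equal(g1.params[k].data, g2.params[k].data)


def test_generator_output_is_on_the_simplex(tiny_gan_config, rng):
    gen = build_generator(tiny_gan_config)
    out = gen.sample(4, rng)
    c = tiny_gan_config
    assert out.data.shape == (4, c.seq_len, c.vocab_size)
    assert np.allclose(out.data.sum(axis=-1), 1.0, atol=1e-9)
    assert out.data.min() >= 0.0


def test_discriminator_scores_and_coupling_rows(tiny_gan_config, rng):
    disc = build_discriminator(tiny_gan_config)
    x = np.zeros((4, tiny_gan_config.seq_len, tiny_gan_config.vocab_size))
    x[..., 0] = 1.0
    score, parts = disc.forward(T.constant(x), return_parts=True)
    assert score.data.shape == (4,)
    assert np.all(np.isfinite(score.data))
    assert np.allclose(parts["coupling"].data.sum(axis=-1), 1.0, atol=1e-9)
    assert np.all(parts["lengths"].data < 1.0)


def test_untileable_capsule_reshape_raises():
    with pytest.raises(ValueError, match="tile"):
        GanConfig(seq_len=15, channels=7, capsule_conv_channels=7,
                  primary_capsule_dim=8).n_primary_capsules


# -- losses -------------------------------------------------------------------


def test_critic_loss_examples_and_antisymmetry(rng):
    assert critic_loss(np.array([1.0, 1.0]), np.array([0.0, 0.0])) == -1.0
    s = rng.normal(size=10)
    assert critic_loss(s, s) == pytest.approx(0.0)
    a, b = rng.normal(size=6), rng.normal(size=6)
    assert critic_loss(a, b) == pytest.approx(float(b.mean() - a.mean()))
    assert critic_loss(a, b) == pytest.approx(-critic_loss(b, a))
    with pytest.raises(ValueError):
        critic_loss(np.array([]), np.array([]))


def test_generator_loss_examples(rng):
    assert generator_loss(np.array([0.0, 0.0])) == 0.0
    assert generator_loss(np.array([2.0, 4.0])) == -3.0
    s = rng.normal(size=8)
    assert generator_loss(s) == pytest.approx(float(-s.mean()))
    with pytest.raises(ValueError):
        generator_loss(np.array([]))


# -- gradient penalty ---------------------------------------------------------


class _LinearCritic:
    """D(x) = w . flatten(x) with configurable weight norm."""

    def __init__(self, shape, norm, seed=0):
        rng = np.random.default_rng(seed)
        w = rng.normal(size=(int(np.prod(shape)), 1))
        self.w = T.parameter(w / np.linalg.norm(w) * norm)
        self.shape = shape

    def forward(self, x):
        B = x.data.shape[0]
        flat = T.reshape(x, (B, int(np.prod(self.shape))))
        return T.reshape(T.matmul(flat, self.w), (B,))


class _ConstantCritic:
    def forward(self, x):
        return T.constant(np.full(x.data.shape[0], 3.7))


def test_gradient_penalty_is_zero_when_lambda_is_zero(tiny_gan_config, rng):
    disc = build_discriminator(tiny_gan_config)
    shape = (4, tiny_gan_config.seq_len, tiny_gan_config.vocab_size)
    real, fake = rng.uniform(size=shape), rng.uniform(size=shape)
    assert float(gradient_penalty(disc, real, fake, 0.0, rng).data) == 0.0
    with pytest.raises(ValueError):
        gradient_penalty(disc, real, fake, -1.0, rng)


def test_gradient_penalty_unit_norm_linear_critic_is_zero(rng):
    shape = (6, 5, 3)
    critic = _LinearCritic(shape[1:], norm=1.0)
    real, fake = rng.uniform(size=shape), rng.uniform(size=shape)
    gp = gradient_penalty(critic, real, fake, 10.0, rng)
    assert abs(float(gp.data)) < 1e-9


def test_gradient_penalty_constant_critic_equals_lambda(rng):
    shape = (6, 5, 3)
    real, fake = rng.uniform(size=shape), rng.uniform(size=shape)
    gp = gradient_penalty(_ConstantCritic(), real, fake, 10.0, rng)
    assert float(gp.data) == pytest.approx(10.0, abs=1e-9)


def test_gradient_penalty_nonnegative_on_real_critic(tiny_gan_config, rng):
    disc = build_discriminator(tiny_gan_config)
    shape = (4, tiny_gan_config.seq_len, tiny_gan_config.vocab_size)
    for _ in range(3):
        real, fake = rng.uniform(size=shape), rng.uniform(size=shape)
        assert float(gradient_penalty(disc, real, fake, 10.0, rng).data) >= 0.0


def test_critic_loss_decreases_on_separable_point_masses(tiny_gan_config, rng):
    """With no Lipschitz constraint an unconstrained critic drives the
    Wasserstein loss down over the first critic-only updates."""
    c = tiny_gan_config
    disc = build_discriminator(c)
    real = np.zeros((8, c.seq_len, c.vocab_size)); real[..., 0] = 1.0
    fake = np.zeros((8, c.seq_len, c.vocab_size)); fake[..., 1] = 1.0
    opt = RMSprop(disc.params, lr=1e-3)
    losses = []
    names = list(disc.params)
    for _ in range(10):
        loss = critic_loss(disc.forward(T.constant(real)),
                           disc.forward(T.constant(fake)))
        grads = T.grad(loss, [disc.params[k] for k in names])
        opt.step({k: g.data for k, g in zip(names, grads)})
        losses.append(float(loss.data))
    assert losses[-1] < losses[0]


# -- training loop ------------------------------------------------------------


def _small_data(config, n=40, seed=5):
    rng = np.random.default_rng(seed)
    recs = [ProteinRecord(f"P{i}", "".join(rng.choice(list(AMINO_ACIDS),
                                                      size=int(rng.integers(8, config.seq_len + 1)))))
            for i in range(n)]
    return encode_batch(recs, seq_len=config.seq_len)


def test_zero_epochs_yields_empty_histories_and_init_checkpoint(
        tiny_gan_config, tmp_path):
    cfg = dataclasses.replace(tiny_gan_config, epochs=0)
    gen, disc = build_generator(cfg), build_discriminator(cfg)
    state = train_gan(gen, disc, _small_data(cfg), cfg, out_dir=tmp_path)
    assert state.critic_losses == [] and state.gen_losses == []
    assert state.step == 0
    assert (tmp_path / "checkpoint_init.npz").exists()


def test_history_lengths_follow_step_count_arithmetic(tiny_gan_config):
    cfg = dataclasses.replace(tiny_gan_config, epochs=2, batch_size=8, n_critic=2)
    gen, disc = build_generator(cfg), build_discriminator(cfg)
    data = _small_data(cfg, n=20)  # floor(20/8) = 2 batches per epoch
    state = train_gan(gen, disc, data, cfg)
    cycles = cfg.epochs * (data.n // cfg.batch_size)
    assert len(state.critic_losses) == cycles * cfg.n_critic
    assert len(state.gen_losses) == cycles
    assert state.step == cycles * (cfg.n_critic + 1)
    assert len(state.gp_values) == len(state.critic_losses)
    assert all(v >= 0 for v in state.gp_values)


def test_training_is_bitwise_reproducible(tiny_gan_config):
    cfg = dataclasses.replace(tiny_gan_config, epochs=1, batch_size=8, n_critic=1)
    data = _small_data(cfg, n=16)
    runs = []
    for _ in range(2):
        gen, disc = build_generator(cfg), build_discriminator(cfg)
        runs.append(train_gan(gen, disc, data, cfg))
    assert runs[0].critic_losses == runs[1].critic_losses
    assert runs[0].gen_losses == runs[1].gen_losses


def test_checkpoint_round_trip_and_mismatch_error(tiny_gan_config, tmp_path):
    gen, disc = build_generator(tiny_gan_config), build_discriminator(tiny_gan_config)
    path = save_checkpoint(tmp_path / "ck.npz", gen, disc, tiny_gan_config, step=0)
    gen2, disc2, manifest = load_checkpoint(path)
    for k in disc.params:
        assert np.array_equal(disc.params[k].data, disc2.params[k].data)
    assert manifest["config_hash"] == tiny_gan_config.config_hash()
    wrong = dataclasses.replace(tiny_gan_config, out_capsules=4)
    with pytest.raises(ValueError, match="shape"):
        load_checkpoint(path, config=wrong)


def test_generate_sequences_deterministic_and_in_alphabet(tiny_gan_config):
    gen = build_generator(tiny_gan_config)
    s1 = generate_sequences(gen, 1, seed=42)
    s2 = generate_sequences(gen, 1, seed=42)
    assert s1 == s2
    seqs = generate_sequences(gen, 32, seed=7)
    assert len(seqs) == 32
    alphabet = set(AMINO_ACIDS)
    for s in seqs:
        assert len(s) <= tiny_gan_config.seq_len
        assert set(s) <= alphabet
    with pytest.raises(ValueError):
        generate_sequences(gen, 0, seed=1)
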