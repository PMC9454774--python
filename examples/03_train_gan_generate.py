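"""Train a tiny Wasserstein GAN on synthetic proteins and sample sequences.

The critic ends in a capsule stage (squash -> 3 routing rounds -> length
layer -> linear score); training alternates 5 critic updates (Wasserstein
loss + gradient penalty, RMSprop lr 1e-4) with one generator update.
Scaled down here to run in about a minute.
"""

from gocapgan import (GanConfig, SyntheticDesign, build_discriminator,
                      build_generator, encode_batch, generate_corpus,
                      generate_sequences, train_gan)

design = SyntheticDesign(n_classes=4, n_proteins=64, min_len=24, max_len=40,
                         seed=1)
records, _, _ = generate_corpus(design)

config = GanConfig(batch_size=16, seq_len=40, noise_dim=32, epochs=2,
                   channels=8, capsule_conv_channels=8, primary_capsule_dim=8,
                   out_capsules=4, out_capsule_dim=4, n_critic=5, seed=1)
gen = build_generator(config)
disc = build_discriminator(config)
print(f"generator parameters: {gen.param_count():,}")
print(f"critic parameters:    {disc.param_count():,}")

data = encode_batch(records, seq_len=config.seq_len)
state = train_gan(gen, disc, data, config)
print(f"updates: {state.step}   critic loss {state.critic_losses[0]:+.3f} -> "
      f"{state.critic_losses[-1]:+.3f}   gradient penalty "
      f"{state.gp_values[0]:.2f} -> {state.gp_values[-1]:.2f}")
# critic loss moving negative = the critic separates real from generated;
# the penalty decaying toward 0 = the 1-Lipschitz constraint is satisfied

for i, seq in enumerate(generate_sequences(gen, 3, seed=7)):
    print(f"gen_{i}: {seq}")
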