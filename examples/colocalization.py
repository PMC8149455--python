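"""Mander's colocalization coefficients on paired punctate channels.

Simulates two-channel images at low and high true overlap (as when a
protein is compared against an ER marker it colocalizes with versus a
mitochondrial marker it does not), and reports per-group mean +/- SD.
"""

from conskit import ColocSimSpec, ChannelPair, batch_coloc, simulate_coloc_pair

pairs = []
for g, (group, overlap) in enumerate((("ER_marker", 0.9), ("mito_marker", 0.1))):
    for rep in range(2):  # two biologically independent samples per group
        sim = simulate_coloc_pair(ColocSimSpec(overlap_fraction=overlap,
                                               seed=100 * g + rep))
        pairs.append(ChannelPair(channel_a=sim.channel_a, channel_b=sim.channel_b,
                                 pair_id=f"{group}_rep{rep + 1}", group=group))

per_pair, per_group = batch_coloc(pairs)
print(per_pair.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(per_group.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

# M1 is the fraction of channel-a signal on pixels where channel b is above
# threshold ("colocalized signal over total signal"); high M1/M2 for the ER
# group and low for the mitochondrial group reproduces the expected contrast.
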