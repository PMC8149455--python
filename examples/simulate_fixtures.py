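"""Write inspectable synthetic fixtures for every pipeline stage.

Generates an ortholog alignment with a planted consensus substitution, a
replicated decay table, and one pair of intensity matrices, in the same
text formats the analysis functions read.
"""

from pathlib import Path

from conskit import (
    ColocSimSpec,
    DecaySimSpec,
    MsaSimSpec,
    simulate_coloc_pair,
    simulate_decay,
    simulate_ortholog_msa,
    write_alignment,
    write_channel_tsv,
    write_decay_tsv,
)

out = Path("fixtures")
out.mkdir(exist_ok=True)

msa = simulate_ortholog_msa(MsaSimSpec(
    query="MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ", n_homologs=25,
    conservation=0.9, planted=((17, "C", 0.85),), gap_rate=0.05,
    n_insert_columns=2, seed=1))
write_alignment(msa, out / "orthologs.fasta")

decay = simulate_decay(DecaySimSpec(t_half_true=20.0, cv=0.10,
                                    n_replicates=4, seed=2))
write_decay_tsv(decay, out / "decay.tsv")

pair = simulate_coloc_pair(ColocSimSpec(overlap_fraction=0.5, seed=3))
write_channel_tsv(pair.channel_a, out / "channel_a.tsv")
write_channel_tsv(pair.channel_b, out / "channel_b.tsv")

for f in sorted(out.iterdir()):
    print(f"{f}  ({f.stat().st_size} bytes)")

# Same seed, same spec -> byte-identical files: every generator is a pure
# function of its specification, so fixtures are reproducible anywhere.
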