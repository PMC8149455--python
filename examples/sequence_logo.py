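"""Per-column information content and letter heights for a sequence logo.

Computes the Schneider-Stephens logo metrics (bits) on the packaged toy
alignment and prints the three most and least conserved positions.
"""

from importlib import resources

from conskit import alignment_logo, read_alignment, slice_to_query

with resources.as_file(
    resources.files("conskit.data").joinpath("toy_msa.fasta")
) as path:
    alignment = read_alignment(path, query_id="query")

sliced, _ = slice_to_query(alignment)
columns = sorted(alignment_logo(sliced), key=lambda c: -c.information)

print("pos  information(bits)  top letters")
for col in columns[:3] + columns[-3:]:
    letters = sorted(col.heights.items(), key=lambda kv: -kv[1])[:3]
    desc = " ".join(f"{aa}:{h:.2f}" for aa, h in letters)
    print(f"{col.position:<4d} {col.information:<18.3f} {desc}")

# Information runs from 0 bits (column uniform over the 20 amino acids) to
# log2(20) = 4.32 bits (perfectly conserved); letter height is frequency
# times column information, i.e. the stack heights a logo plotter draws.
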