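"""Rank candidate consensus substitutions from an ortholog alignment.

Loads the small packaged alignment (a query plus ten simulated orthologs),
slices it to query coordinates, scores every position by the difference in
relative entropy between the homolog-consensus residue and the wild-type
residue, and prints the ranked candidates.
"""

from importlib import resources

from conskit import rank_variants, read_alignment, slice_to_query

with resources.as_file(
    resources.files("conskit.data").joinpath("toy_msa.fasta")
) as path:
    alignment = read_alignment(path, query_id="query")

sliced, column_map = slice_to_query(alignment)
print(f"{alignment.n_rows - 1} homologs, {sliced.length} query positions")

scores = rank_variants(sliced)
print(f"{len(scores)} candidate substitution(s):")
print("variant  f_consensus  f_wt   coverage  score(bits)")
for s in scores:
    print(f"{s.label:<8} {s.f_consensus:<12.3f} {s.f_wt:<6.3f} {s.coverage:<9d} {s.score:.3f}")

# A large positive score means the homolog consensus residue is strongly
# preferred over the wild-type at that position -- the substitutions a
# consensus-design campaign would synthesize and test.
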