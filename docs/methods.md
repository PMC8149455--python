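# Methods

## Consensus scoring model

At each position `i` of the sliced alignment, the frequency `f_ik` of amino
acid `k` is the raw proportion among counted residues: homolog rows only (the
query is excluded by default, since the frequencies are meant to describe the
ortholog set; `ScoringOptions.include_query_in_counts` flips this for
sensitivity analysis), with gaps and the ambiguity codes X/B/Z/* excluded from
both numerator and denominator. No pseudocounts are applied; the convention
`0·log 0 = 0` covers residues absent from a column. The per-residue relative
entropy is `D_ik = f_ik·log(f_ik/q_k)` and the mutation score is
`S_i = D_ic − D_iw`, where `c` is the column consensus and `w` the wild-type
residue. Individual `D_ik` terms can be negative (residue rarer in the column
than in the proteome); only the complete 20-term sum is guaranteed
nonnegative (Gibbs' inequality), which the test suite asserts as a property.

**Log base.** Scores are reported in bits (base 2, matching sequence-logo
conventions) and the base is configurable. Because changing base multiplies
every score by the same positive constant, the candidate ranking is base
invariant; this is both tested per-module and checked at acceptance scale.

**Background composition `q_k`.** The model compares column frequencies to
proteome-wide residue frequencies. A single background vector is applied to
all sequences; the packaged default is the Swiss-Prot release-statistics
average composition (`conskit/data/background_swissprot.tsv`), renormalized
on load, and any two-column table can be substituted. Per-species
backgrounds would be a refinement but are not implemented: one vector keeps
the statistic well-defined for a mixed ortholog set.

**Consensus ties.** When two residues tie for the column maximum, the one
with the lower background probability wins (it is the more surprising residue
and maximizes `D_ic`), then ties break alphabetically. This makes ranking
deterministic.

**Candidate filtering.** Positions enter the ranked list when (a) coverage —
non-gap, non-ambiguous counted residues — reaches `min_coverage_fraction`
(default 0.5) of the counted rows, (b) the consensus differs from the
wild-type (equal-consensus positions carry no substitution proposal and have
`S_i = 0` by construction), and (c) the consensus frequency reaches
`min_consensus_frequency` (default 0). Positions whose wild-type residue is
an ambiguity code are flagged and skipped. The list is sorted by descending
score, ties by ascending position, and truncated to `top_n` (default 20,
the size of a typical synthesis campaign). Whether a real campaign applies
further manual filters on top of the truncation is unknowable from the
score alone; pure truncation is the assumed rule.

## Slicing

Scores must be reported in the query protein's own numbering. `slice_to_query`
removes every alignment column where the query row is gapped and returns a
`ColumnMap` from 1-based query positions to the original 0-based columns, so
the operation is reversible and auditable. Slicing is idempotent, and
applying the map to the original alignment reproduces the slice exactly —
both are asserted as properties.

## Logo metrics

Column information follows the Schneider–Stephens convention WebLogo uses by
default for proteins: `information = log₂(20) − H` bits with
`H = −Σ f_ik log₂ f_ik`, and letter height `f_ik × information`. No
small-sample correction is applied (column coverages here are ~100, where the
correction is negligible and would complicate the exact endpoint invariants
`information ∈ [0, log₂ 20]`). Units are bits, recorded in the TSV header;
gap fraction is a separate output column, never folded into heights.

## Terminal-phase half-life

`fit_terminal_halflife` implements the standard "best-fit" terminal-window
rule used by non-compartmental PK software: every contiguous terminal window
of ≥ `min_points` (default 3) positive-valued points starting at or after the
observed maximum is fitted by ordinary least squares of `ln(value)` on time;
the window with the highest adjusted R² wins, with ties (within 1e-9, which
absorbs float rounding on noiseless data) resolved toward the longer window.
Then `λz = −slope` and `t½ = ln 2 / λz`. Nonpositive values are excluded —
their logarithm is undefined — never imputed. A nonnegative best slope raises
a no-decay error rather than returning a meaningless negative rate. Exposure
metrics (AUC, clearance) and compartmental models are deliberately out of
scope.

Replicated designs can be handled two ways, both exposed: fit each replicate
and summarize (`summarize_fits` reports median and IQR of `t½`), or average
replicates sharing a time grid (`mean_series`, arithmetic mean — the usual
lab practice) and fit once. The recovery checks use the replicate mean.

## Mander's colocalization

For channels `a`, `b` with thresholds `t_a`, `t_b`:
`M1 = Σ aᵢ·[bᵢ > t_b] / Σ aᵢ·[aᵢ > t_a]` and symmetrically for `M2`. With
zero thresholds (the default) these are the classic overlap fractions.
Automated threshold selection (Costes-style) is intentionally not
implemented: thresholding policy belongs to the caller, and results are
functions of the supplied thresholds. Z-stacks are handled by passing each
optical section as one pair and aggregating with `batch_coloc`, which reports
mean ± sample SD per group label.

## Synthetic data: what it emulates and what it does not

`simulate_ortholog_msa` draws homolog columns i.i.d.: at unplanted positions
a homolog matches the wild-type with probability `conservation` (default
0.95) and otherwise draws from the background composition excluding the
wild-type; at a planted position the planted residue appears with its stated
frequency, the remainder split the same way. Gaps strike each homolog residue
independently (`gap_rate`, default 0.05), which leaves the conditional
residue frequencies among non-gap rows unchanged. `n_insert_columns`
(default 0) interleaves columns gapped in the query row — occupied by a
background draw in 30% of homologs — so slicing is exercised non-trivially.
Defaults mirror the motivating study's retrieval design (100 homologs, the
query being one named sequence among them). Because the scoring statistic is
purely columnwise, columnwise simulation is sufficient to validate it; the
generator deliberately has **no phylogeny**, so green tests establish correct
computation of the statistic, not robustness to tree-structured correlation
among orthologs (real BLAST sets are not i.i.d. draws).

`simulate_decay` produces `c0·exp(−ln 2·t/t½)·ε` with `ε` lognormal,
calibrated to multiplicative mean 1 at coefficient of variation `cv`
(default 0.10, a typical bioanalytical CV; default design: 4 replicates at
6, 24, 72, 168, 336 h — the 6 h/1 d/3 d/7 d/14 d sacrifice schedule of the
emulated experiment). It is single-phase by construction: it validates the
terminal fit, not the window-selection behavior on multi-phasic profiles.

`simulate_coloc_pair` places Gaussian puncta (amplitude 100, σ = 1.5 px,
truncated at 3σ so background pixels are exactly zero) on a 64×64 grid;
a controlled fraction of channel-a spots is duplicated into channel b, the
rest placed independently. Additive half-normal noise is off by default:
with classic zero-threshold Mander's, any nonzero background makes every
pixel "positive" and drives both coefficients to 1, so the default emulates
background-subtracted images; users adding noise should supply thresholds.
Chance overlap of independently placed spots means the expected coefficients
at `overlap_fraction = 0` are small but not exactly zero.

All generators are pure functions of their spec including its seed: same
spec, byte-identical output.

## Numerical and formatting choices

- Frequencies, scores and logo metrics are computed in double precision;
  scoring agrees with a direct formula evaluation to 1e-12.
- Output tables render floats with 9 significant digits (`%.9g`) and `\n`
  line endings, making repeated runs byte-identical and round-trips faithful
  beyond the documented 6-significant-digit table contract.
- Background compositions are renormalized on load when they sum to within
  a factor of anything but 1 (percent tables load unchanged in meaning);
  zero or negative entries are rejected rather than smoothed.
- Degenerate inputs fail loudly with typed exceptions (`conskit.errors`):
  all-gap query rows, zero-coverage columns, all-constant decay series,
  zero-signal channels, shape mismatches.

## Known limitations

- One background vector for all species; no per-species compositions.
- No structure- or topology-aware filtering of candidates, and no scoring of
  multi-site combinations; the score proposes single substitutions only.
- The half-life module assumes a monotone terminal phase; it does not model
  absorption or distribution phases beyond excluding pre-peak points.
- Colocalization offers no segmentation or automated thresholding; inputs
  are plain intensity matrices or grayscale images.
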