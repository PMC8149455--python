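"""Relative-entropy scoring: frequencies, KL terms, consensus calls, ranking."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from conskit import (
    AMINO_ACIDS,
    BackgroundComposition,
    ScoringOptions,
    column_profile,
    consensus_residue,
    default_background,
    load_background,
    rank_variants,
    relative_entropy_term,
    score_position,
    slice_to_query,
)
from conskit.consensus import PositionProfile
from conskit.errors import (
    AmbiguousResidueError,
    CompositionError,
    ConskitError,
    NoDataError,
)
from conftest import make_alignment


class TestBackground:
    def test_uniform_file(self, tmp_path):
        p = tmp_path / "bg.tsv"
        p.write_text("".join(f"{aa}\t0.05\n" for aa in AMINO_ACIDS))
        bg = load_background(p)
        assert all(bg[aa] == pytest.approx(0.05) for aa in AMINO_ACIDS)

    def test_renormalization(self, tmp_path):
        p = tmp_path / "bg.tsv"
        p.write_text("# percent-style table\n" + "".join(f"{aa}\t0.10\n" for aa in AMINO_ACIDS))
        bg = load_background(p)
        assert sum(bg[aa] for aa in AMINO_ACIDS) == pytest.approx(1.0, abs=1e-12)
        assert bg["W"] == pytest.approx(0.05)

    def test_missing_amino_acid_rejected(self, tmp_path):
        p = tmp_path / "bg.tsv"
        p.write_text("".join(f"{aa}\t0.05\n" for aa in AMINO_ACIDS if aa != "W"))
        with pytest.raises(CompositionError, match="W"):
            load_background(p)

    def test_nonpositive_probability_rejected(self):
        q = {aa: 0.05 for aa in AMINO_ACIDS}
        q["A"] = 0.0
        with pytest.raises(CompositionError):
            BackgroundComposition(q=q)

    def test_packaged_default_is_normalized(self):
        bg = default_background()
        assert sum(bg[aa] for aa in AMINO_ACIDS) == pytest.approx(1.0, abs=1e-9)
        # leucine is the most common residue in proteomes, tryptophan the rarest
        assert bg["L"] > bg["W"]


class TestColumnProfile:
    def test_single_homolog_column(self):
        aln = make_alignment({"q": "S", "h1": "M"})
        prof = column_profile(aln, 1)
        assert prof.frequency("M") == 1.0 and prof.coverage == 1
        assert prof.wt_aa == "S"

    def test_hand_counted_frequencies(self):
        aln = make_alignment({"q": "S", "h1": "A", "h2": "A", "h3": "A", "h4": "S"})
        prof = column_profile(aln, 1)
        assert prof.frequency("A") == pytest.approx(0.75)
        assert prof.frequency("S") == pytest.approx(0.25)
        assert prof.coverage == 4

    def test_gaps_and_ambiguity_excluded(self):
        aln = make_alignment({"q": "S", "h1": "C", "h2": "C", "h3": "-", "h4": "X"})
        prof = column_profile(aln, 1)
        assert prof.coverage == 2 and prof.frequency("C") == 1.0
        assert prof.gap_fraction == pytest.approx(0.5)

    def test_query_included_when_requested(self):
        aln = make_alignment({"q": "S", "h1": "C"})
        prof = column_profile(aln, 1, ScoringOptions(include_query_in_counts=True))
        assert prof.coverage == 2 and prof.frequency("S") == 0.5

    def test_position_out_of_range(self):
        aln = make_alignment({"q": "SS", "h1": "CC"})
        with pytest.raises(ConskitError):
            column_profile(aln, 3)


class TestRelativeEntropyTerm:
    @pytest.mark.parametrize(
        "f,q,base,expected",
        [
            (0.05, 0.05, 2, 0.0),          # f == q: log ratio vanishes
            (0.0, 0.3, 2, 0.0),            # 0 log 0 convention
            (1.0, 0.0625, 2, 4.0),         # log2(16)
            (0.5, 0.5, 10, 0.0),
        ],
    )
    def test_hand_values(self, f, q, base, expected):
        assert relative_entropy_term(f, q, base) == pytest.approx(expected, abs=1e-12)

    def test_negative_when_rarer_than_background(self):
        assert relative_entropy_term(0.01, 0.1, 2) < 0

    def test_invalid_background_rejected(self):
        with pytest.raises(ConskitError):
            relative_entropy_term(0.5, 0.0, 2)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 10**6), st.floats(1e-6, 1 - 1e-6))
    def test_full_column_kl_sum_nonnegative(self, seed, conc):
        """Gibbs' inequality: the complete 20-term KL sum is >= 0."""
        import numpy as np

        rng = np.random.default_rng(seed)
        f = rng.dirichlet(np.full(20, conc * 5))
        q = rng.dirichlet(np.full(20, 5.0))
        total = sum(
            relative_entropy_term(fi, qi, 2) for fi, qi in zip(f, q) if qi > 0
        )
        assert total >= -1e-9

    @settings(derandomize=True, max_examples=50)
    @given(
        st.floats(0.05, 0.45), st.floats(0.01, 0.04), st.floats(1e-4, 0.5)
    )
    def test_monotone_in_f_above_background(self, f, q, df):
        """With f > q fixed-background, the term strictly increases in f."""
        f2 = min(f + df, 1.0)
        assert relative_entropy_term(f2, q, 2) > relative_entropy_term(f, q, 2)


class TestConsensusResidue:
    def test_unique_maximum(self, uniform_bg):
        prof = PositionProfile(1, "S", {"C": 8, "S": 2}, 10, 10)
        assert consensus_residue(prof, uniform_bg) == ("C", 0.8)

    def test_tie_broken_by_lower_background(self):
        q = {aa: 0.05 for aa in AMINO_ACIDS}
        q["A"], q["V"] = 0.08, 0.02
        bg = BackgroundComposition(q=q)
        prof = PositionProfile(1, "S", {"A": 5, "V": 5}, 10, 10)
        assert consensus_residue(prof, bg)[0] == "V"

    def test_tie_broken_alphabetically_when_background_equal(self, uniform_bg):
        prof = PositionProfile(1, "S", {"V": 5, "A": 5}, 10, 10)
        assert consensus_residue(prof, uniform_bg)[0] == "A"

    def test_zero_coverage_errors(self, uniform_bg):
        prof = PositionProfile(1, "S", {}, 0, 10)
        with pytest.raises(NoDataError):
            consensus_residue(prof, uniform_bg)


class TestScorePosition:
    def test_hand_worked_example(self, uniform_bg):
        # f = {C: .8, S: .2}, wt S, uniform background, bits:
        # D_ic = .8*log2(16) = 3.2 ; D_iw = .2*log2(4) = 0.4 ; S = 2.8
        prof = PositionProfile(5, "S", {"C": 8, "S": 2}, 10, 10)
        vs = score_position(prof, uniform_bg)
        assert vs.d_consensus == pytest.approx(3.2, abs=1e-12)
        assert vs.d_wt == pytest.approx(0.4, abs=1e-12)
        assert vs.score == pytest.approx(2.8, abs=1e-12)
        assert vs.label == "S5C"

    def test_consensus_equal_wildtype_scores_zero(self, uniform_bg):
        prof = PositionProfile(1, "S", {"S": 10}, 10, 10)
        vs = score_position(prof, uniform_bg)
        assert vs.consensus_aa == "S" and vs.score == 0.0
        assert vs.d_consensus == vs.d_wt

    def test_ambiguous_wildtype_flagged(self, uniform_bg):
        prof = PositionProfile(1, "X", {"C": 10}, 10, 10)
        with pytest.raises(AmbiguousResidueError):
            score_position(prof, uniform_bg)

    def test_score_equals_term_difference(self, uniform_bg):
        prof = PositionProfile(1, "S", {"C": 7, "S": 2, "A": 1}, 10, 10)
        vs = score_position(prof, uniform_bg)
        direct = relative_entropy_term(0.7, 0.05, 2) - relative_entropy_term(0.2, 0.05, 2)
        assert vs.score == pytest.approx(direct, abs=1e-12)


class TestRankVariants:
    def _planted_alignment(self):
        # 10 homologs; position 2 (wt S) has consensus C in 9/10;
        # other positions conserved at wild-type.
        rows = {"q": "MSK"}
        for i in range(9):
            rows[f"h{i}"] = "MCK"
        rows["h9"] = "MSK"
        return make_alignment(rows)

    def test_all_identical_homologs_give_empty_list(self, uniform_bg):
        rows = {"q": "MSK"} | {f"h{i}": "MSK" for i in range(5)}
        assert rank_variants(make_alignment(rows), uniform_bg) == []

    def test_planted_position_ranks_first(self, uniform_bg):
        scores = rank_variants(self._planted_alignment(), uniform_bg)
        assert scores and scores[0].label == "S2C"

    def test_matches_bruteforce_over_positions(self, uniform_bg):
        """Independent oracle: score all positions directly and compare."""
        aln = self._planted_alignment()
        opts = ScoringOptions(top_n=0)
        got = rank_variants(aln, uniform_bg, opts)
        expected = []
        for pos in range(1, aln.length + 1):
            prof = column_profile(aln, pos, opts)
            c, f_c = consensus_residue(prof, uniform_bg)
            if c == prof.wt_aa:
                continue
            f_w = prof.frequency(prof.wt_aa)
            s = relative_entropy_term(f_c, 0.05, 2) - relative_entropy_term(f_w, 0.05, 2)
            expected.append((pos, c, s))
        expected.sort(key=lambda t: (-t[2], t[0]))
        assert [(v.position, v.consensus_aa) for v in got] == [
            (p, c) for p, c, _ in expected
        ]
        for v, (_, _, s) in zip(got, expected):
            assert v.score == pytest.approx(s, abs=1e-12)

    def test_top_n_truncates_to_largest(self, uniform_bg):
        rows = {"q": "SS"}
        for i in range(8):
            rows[f"h{i}"] = "CC" if i < 7 else "CS"  # pos1: 8xC, pos2: 7xC+1xS
        aln = make_alignment(rows)
        full = rank_variants(aln, uniform_bg, ScoringOptions(top_n=0))
        top1 = rank_variants(aln, uniform_bg, ScoringOptions(top_n=1))
        assert len(full) == 2 and len(top1) == 1
        assert top1[0].score == max(v.score for v in full)

    def test_coverage_gate_skips_sparse_columns(self, uniform_bg):
        # position 2 has 2/10 coverage, below the default 50% gate
        rows = {"q": "MS"}
        for i in range(8):
            rows[f"h{i}"] = "M-"
        rows["h8"], rows["h9"] = "MC", "MC"
        scores = rank_variants(make_alignment(rows), uniform_bg)
        assert scores == []

    def test_min_consensus_frequency_gate(self, uniform_bg):
        aln = self._planted_alignment()  # consensus frequency 0.9
        assert rank_variants(aln, uniform_bg, ScoringOptions(min_consensus_frequency=0.95)) == []
        assert rank_variants(aln, uniform_bg, ScoringOptions(min_consensus_frequency=0.85))

    def test_no_homologs_errors(self, uniform_bg):
        aln = make_alignment({"q": "MSK"})
        with pytest.raises(NoDataError):
            rank_variants(aln, uniform_bg)

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(st.integers(0, 10**6))
    def test_ranking_is_base_invariant(self, seed):
        """Property: order of candidates never depends on the log base."""
        from conskit import MsaSimSpec, simulate_ortholog_msa

        uniform_bg = BackgroundComposition(q={aa: 0.05 for aa in AMINO_ACIDS})

        spec = MsaSimSpec(
            query="MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ", n_homologs=30,
            conservation=0.7, gap_rate=0.05, seed=seed,
        )
        sliced, _ = slice_to_query(simulate_ortholog_msa(spec))
        orders = []
        for base in (2.0, math.e, 10.0):
            opts = ScoringOptions(log_base=base, top_n=0)
            orders.append([v.label for v in rank_variants(sliced, uniform_bg, opts)])
        assert orders[0] == orders[1] == orders[2]
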