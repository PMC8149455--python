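"""Relative-entropy consensus scoring of an ortholog alignment.

The engineering idea: at each position ``i`` of the query protein, compare the
residue the homologs most often use (the *consensus*, ``c``) with the
wild-type residue ``w``. Conservation of residue ``k`` at position ``i`` is
measured by the per-residue Kullback-Leibler (relative-entropy) term

    D_ik = f_ik * log(f_ik / q_k)

where ``f_ik`` is the observed column frequency of ``k`` among homologs and
``q_k`` the proteome-wide background probability of ``k``. The mutation score

    S_i = D_ic - D_iw

is large and positive exactly where the homolog consensus is strongly
preferred over the wild-type residue — the positions a consensus-design
campaign proposes to substitute. Ranking positions by ``S_i`` is invariant to
the logarithm base (all scores scale by the same positive constant); scores
are reported in bits (base 2) by default.

Frequencies are raw column proportions (no pseudocounts); the convention
``0 * log(0) = 0`` handles residues absent from a column. Gaps and the
ambiguity codes X/B/Z/* are excluded from both counts and coverage: the
statistic is defined over the 20 amino acids only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

from .alignment import AMINO_ACIDS, AMBIGUOUS, GAP, Alignment
from .errors import (
    AmbiguousResidueError,
    CompositionError,
    ConskitError,
    NoDataError,
)

_AA_SET = frozenset(AMINO_ACIDS)


@dataclass(frozen=True)
class BackgroundComposition:
    """Background probability ``q_k`` for each of the 20 amino acids.

    Probabilities are strictly positive and renormalized to sum to 1.
    """

    q: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = _AA_SET - set(self.q)
        if missing:
            raise CompositionError(
                f"background composition missing amino acids: {sorted(missing)}"
            )
        extra = set(self.q) - _AA_SET
        if extra:
            raise CompositionError(f"unknown amino acids in composition: {sorted(extra)}")
        for aa, p in self.q.items():
            if not (p > 0):
                raise CompositionError(f"background probability for {aa} must be > 0, got {p}")
        total = sum(self.q.values())
        if abs(total - 1.0) > 1e-6:
            object.__setattr__(
                self, "q", {aa: p / total for aa, p in self.q.items()}
            )

    def __getitem__(self, aa: str) -> float:
        return self.q[aa]


@dataclass(frozen=True)
class ScoringOptions:
    """Tunable knobs of the scoring pipeline.

    log_base
        Base of the logarithm in the relative-entropy terms; 2 gives bits.
        Ranking is invariant to this choice.
    include_query_in_counts
        Whether the query row contributes to column frequencies. Off by
        default: frequencies describe the homolog set.
    min_coverage_fraction
        Positions whose non-gap, non-ambiguous coverage falls below this
        fraction of the counted rows are skipped (sparse columns carry
        unreliable frequencies).
    min_consensus_frequency
        Minimum consensus frequency for a position to be proposed.
    top_n
        Truncate the ranked candidate list to this many entries; 0 or
        negative keeps every eligible position.
    """

    log_base: float = 2.0
    include_query_in_counts: bool = False
    min_coverage_fraction: float = 0.5
    min_consensus_frequency: float = 0.0
    top_n: int = 20

    def __post_init__(self) -> None:
        if not self.log_base > 1:
            raise ConskitError(f"log_base must be > 1, got {self.log_base}")
        if not 0 <= self.min_coverage_fraction <= 1:
            raise ConskitError(
                f"min_coverage_fraction must lie in [0, 1], got {self.min_coverage_fraction}"
            )


@dataclass(frozen=True)
class PositionProfile:
    """Amino-acid counts and frequencies of one sliced-alignment column."""

    position: int                      # 1-based query position
    wt_aa: str                         # query residue at the position
    counts: Mapping[str, int]          # amino acid -> count (20 keys max)
    coverage: int                      # non-gap, non-ambiguous residues counted
    n_considered: int                  # rows the count ran over (incl. gaps/ambig)
    f: Mapping[str, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.f is None:
            freq = (
                {aa: n / self.coverage for aa, n in self.counts.items()}
                if self.coverage > 0
                else {}
            )
            object.__setattr__(self, "f", freq)

    def frequency(self, aa: str) -> float:
        """Observed frequency ``f_ik`` of amino acid ``aa``; 0 if absent."""
        return self.f.get(aa, 0.0)

    @property
    def gap_fraction(self) -> float:
        """Fraction of considered rows that were gaps or ambiguity codes."""
        if self.n_considered == 0:
            return 0.0
        return 1.0 - self.coverage / self.n_considered


@dataclass(frozen=True)
class VariantScore:
    """One candidate substitution with its supporting quantities."""

    position: int
    wt_aa: str
    consensus_aa: str
    f_wt: float
    f_consensus: float
    coverage: int
    d_wt: float
    d_consensus: float
    score: float

    @property
    def label(self) -> str:
        """Protein-variant nomenclature, e.g. ``'S298C'``."""
        return f"{self.wt_aa}{self.position}{self.consensus_aa}"


def default_background() -> BackgroundComposition:
    """The packaged Swiss-Prot-average composition."""
    ref = resources.files("conskit.data").joinpath("background_swissprot.tsv")
    with resources.as_file(ref) as path:
        return load_background(path)


def load_background(path: str | Path) -> BackgroundComposition:
    """Load a two-column (amino acid, probability) delimited file.

    ``#`` comment lines are ignored; tab or whitespace delimits the columns;
    probabilities are renormalized to sum to 1 (so percent tables load fine).
    """
    q: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace("\t", " ").split()
            if len(parts) != 2:
                raise CompositionError(f"malformed composition line: {raw!r}")
            aa, value = parts[0].upper(), float(parts[1])
            if aa in q:
                raise CompositionError(f"duplicate amino acid {aa!r} in {path}")
            q[aa] = value
    return BackgroundComposition(q=q)


def column_profile(
    sliced: Alignment, position: int, options: ScoringOptions | None = None
) -> PositionProfile:
    """Count amino acids in one column of a sliced alignment.

    ``position`` is 1-based in query coordinates. The query row is excluded
    from the counts unless ``options.include_query_in_counts``; gaps and
    ambiguity codes never count and do not enter coverage.
    """
    options = options or ScoringOptions()
    if not 1 <= position <= sliced.length:
        raise ConskitError(
            f"position {position} out of range 1..{sliced.length}"
        )
    col = position - 1
    qi = sliced.query_index
    counts: dict[str, int] = {}
    n_considered = 0
    for row_index, row in enumerate(sliced.rows):
        if row_index == qi and not options.include_query_in_counts:
            continue
        n_considered += 1
        ch = row[col]
        if ch == GAP or ch in AMBIGUOUS:
            continue
        counts[ch] = counts.get(ch, 0) + 1
    return PositionProfile(
        position=position,
        wt_aa=sliced.query_row[col],
        counts=counts,
        coverage=sum(counts.values()),
        n_considered=n_considered,
    )


def relative_entropy_term(f: float, q: float, log_base: float = 2.0) -> float:
    """Per-residue relative-entropy term ``f * log_base(f / q)``.

    ``0 * log 0`` is taken as 0. The term may be negative when ``f < q``
    (the residue is rarer in the column than in the proteome); only the full
    sum over the 20 amino acids is guaranteed nonnegative.
    """
    if not 0 <= f <= 1:
        raise ConskitError(f"frequency must lie in [0, 1], got {f}")
    if not 0 < q < 1:
        raise ConskitError(f"background probability must lie in (0, 1), got {q}")
    if f == 0:
        return 0.0
    return f * math.log(f / q) / math.log(log_base)


def consensus_residue(
    profile: PositionProfile, background: BackgroundComposition | None = None
) -> tuple[str, float]:
    """The most frequent amino acid in a column and its frequency.

    Frequency ties are broken toward the residue with the *lower* background
    probability (the more surprising residue, which maximizes its
    relative-entropy term), then alphabetically.
    """
    if profile.coverage == 0:
        raise NoDataError(f"position {profile.position}: no counted residues")
    background = background or default_background()
    best = min(profile.f.items(), key=lambda kv: (-kv[1], background[kv[0]], kv[0]))
    return best


def score_position(
    profile: PositionProfile,
    background: BackgroundComposition | None = None,
    options: ScoringOptions | None = None,
) -> VariantScore:
    """Score one position: ``S_i = D_ic - D_iw``.

    Raises :class:`AmbiguousResidueError` when the wild-type residue is an
    ambiguity code (the position is flagged, not scored).
    """
    background = background or default_background()
    options = options or ScoringOptions()
    wt = profile.wt_aa
    if wt not in _AA_SET:
        raise AmbiguousResidueError(
            f"position {profile.position}: wild-type residue {wt!r} is not a "
            "standard amino acid; position flagged"
        )
    c, f_c = consensus_residue(profile, background)
    f_w = profile.frequency(wt)
    d_c = relative_entropy_term(f_c, background[c], options.log_base)
    d_w = relative_entropy_term(f_w, background[wt], options.log_base)
    return VariantScore(
        position=profile.position,
        wt_aa=wt,
        consensus_aa=c,
        f_wt=f_w,
        f_consensus=f_c,
        coverage=profile.coverage,
        d_wt=d_w,
        d_consensus=d_c,
        score=0.0 if c == wt else d_c - d_w,
    )


def rank_variants(
    sliced: Alignment,
    background: BackgroundComposition | None = None,
    options: ScoringOptions | None = None,
) -> list[VariantScore]:
    """Rank candidate consensus substitutions across a sliced alignment.

    Every position is profiled; positions are kept when their coverage
    reaches ``min_coverage_fraction`` of the counted rows, the consensus
    differs from wild-type, and the consensus frequency reaches
    ``min_consensus_frequency``. Ambiguous wild-type positions are skipped.
    The result is sorted by descending score (ties by ascending position) and
    truncated to ``top_n`` entries when ``top_n > 0``.
    """
    background = background or default_background()
    options = options or ScoringOptions()
    n_counted = sliced.n_rows if options.include_query_in_counts else sliced.n_rows - 1
    if n_counted < 1:
        raise NoDataError("alignment has no homolog rows to count")
    scored: list[VariantScore] = []
    for position in range(1, sliced.length + 1):
        profile = column_profile(sliced, position, options)
        if profile.coverage == 0:
            continue
        if profile.coverage < options.min_coverage_fraction * n_counted:
            continue
        try:
            vs = score_position(profile, background, options)
        except AmbiguousResidueError:
            continue
        if vs.consensus_aa == vs.wt_aa:
            continue
        if vs.f_consensus < options.min_consensus_frequency:
            continue
        scored.append(vs)
    scored.sort(key=lambda v: (-v.score, v.position))
    if options.top_n > 0:
        scored = scored[: options.top_n]
    return scored


def score_alignment_file(
    msa_path: str | Path,
    query_id: str,
    out_path: str | Path,
    background: BackgroundComposition | str | Path | None = None,
    options: ScoringOptions | None = None,
) -> list[VariantScore]:
    """End-to-end scoring pipeline: read, slice, rank, write the TSV table.

    Returns the ranked scores; the written table is byte-identical across
    repeated runs on the same inputs.
    """
    from .alignment import read_alignment, slice_to_query, write_variant_table

    if background is None:
        background = default_background()
    elif not isinstance(background, BackgroundComposition):
        background = load_background(background)
    alignment = read_alignment(msa_path, query_id)
    sliced, _ = slice_to_query(alignment)
    scores = rank_variants(sliced, background, options)
    write_variant_table(scores, out_path)
    return scores
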