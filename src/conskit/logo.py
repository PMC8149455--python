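"""Sequence-logo metrics: per-column information content and letter heights.

Uses the Schneider-Stephens information-content convention that WebLogo
applies by default to protein logos: column information is
``log2(20) - H`` bits, where ``H`` is the Shannon entropy of the observed
residue frequencies, and each letter's height is its frequency times the
column information. No small-sample correction is applied. Gap fraction is
reported as its own column rather than folded into heights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .alignment import AMINO_ACIDS, Alignment
from .consensus import PositionProfile, ScoringOptions, column_profile
from .errors import NoDataError

MAX_INFORMATION = math.log2(20)


@dataclass(frozen=True)
class LogoColumn:
    """Information content (bits) and letter heights of one column."""

    position: int
    entropy: float
    information: float
    heights: Mapping[str, float]
    gap_fraction: float


def column_logo(profile: PositionProfile) -> LogoColumn:
    """Compute entropy, information and letter heights for one column.

    ``H = -sum_k f_ik log2 f_ik`` over observed residues;
    ``information = log2(20) - H``; ``height_k = f_ik * information``.
    """
    if profile.coverage == 0:
        raise NoDataError(f"position {profile.position}: no counted residues")
    entropy = -sum(f * math.log2(f) for f in profile.f.values() if f > 0)
    information = MAX_INFORMATION - entropy
    heights = {aa: f * information for aa, f in profile.f.items()}
    return LogoColumn(
        position=profile.position,
        entropy=entropy,
        information=information,
        heights=heights,
        gap_fraction=profile.gap_fraction,
    )


def alignment_logo(
    sliced: Alignment, options: ScoringOptions | None = None
) -> list[LogoColumn]:
    """Logo metrics for every position of a sliced alignment.

    Zero-coverage columns yield a zero-information column with no heights
    rather than an error, so whole-alignment export never aborts midway.
    """
    options = options or ScoringOptions()
    columns: list[LogoColumn] = []
    for position in range(1, sliced.length + 1):
        profile = column_profile(sliced, position, options)
        if profile.coverage == 0:
            columns.append(
                LogoColumn(
                    position=position,
                    entropy=0.0,
                    information=0.0,
                    heights={},
                    gap_fraction=profile.gap_fraction,
                )
            )
        else:
            columns.append(column_logo(profile))
    return columns


def export_logo(
    sliced: Alignment, path: str | Path, options: ScoringOptions | None = None
) -> None:
    """Write per-position logo metrics as TSV.

    Columns: position, information (bits), gap_fraction, then one height
    column (bits) per amino acid in alphabetical order. Any logo plotter can
    consume the result.
    """
    columns = alignment_logo(sliced, options)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# units: bits\n")
        fh.write(
            "\t".join(("position", "information", "gap_fraction", *AMINO_ACIDS)) + "\n"
        )
        for col in columns:
            heights = (format(col.heights.get(aa, 0.0), ".9g") for aa in AMINO_ACIDS)
            fh.write(
                "\t".join(
                    (
                        str(col.position),
                        format(col.information, ".9g"),
                        format(col.gap_fraction, ".9g"),
                        *heights,
                    )
                )
                + "\n"
            )
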