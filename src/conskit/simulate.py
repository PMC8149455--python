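"""Synthetic inputs for every pipeline stage.

Three generators emulate the statistical structure the analyses assume,
so the whole pipeline can be validated without downloads:

* :func:`simulate_ortholog_msa` — an ortholog alignment around a query, with
  i.i.d. per-column conservation, optional planted consensus substitutions,
  gaps, and optional insertion columns (gaps in the query row). Columnwise
  simulation suffices because the scoring statistic is columnwise; no
  phylogeny is modeled.
* :func:`simulate_decay` — replicated single-exponential decay series with
  multiplicative lognormal noise (measurements are positive).
* :func:`simulate_coloc_pair` — paired punctate channels in which a
  controlled fraction of Gaussian spots is shared between channels.

All generators are pure functions of their spec (seed included): the same
spec yields byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .alignment import AMINO_ACIDS, GAP, Alignment
from .coloc import ChannelPair
from .consensus import BackgroundComposition, default_background
from .errors import SimSpecError
from .kinetics import TimeSeries

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Sampling design used in the decay experiments this generator emulates:
#: 6 h, then 1, 3, 7 and 14 days post-dose.
DEFAULT_DECAY_TIMES: tuple[float, ...] = (6.0, 24.0, 72.0, 168.0, 336.0)


@dataclass(frozen=True)
class MsaSimSpec:
    """Specification of a simulated ortholog alignment.

    At each unplanted query position, a homolog carries the wild-type residue
    with probability ``conservation`` and otherwise a background draw
    (excluding the wild-type). At a planted position ``(pos, aa, freq)`` the
    planted residue appears with probability ``freq``; the remainder is split
    between wild-type (probability ``conservation``) and background draws.
    Each homolog residue is independently replaced by a gap with probability
    ``gap_rate``. ``n_insert_columns`` extra columns, gapped in the query
    row, are interleaved so that slicing is exercised non-trivially.
    """

    query: str
    n_homologs: int = 100
    conservation: float = 0.95
    planted: tuple[tuple[int, str, float], ...] = ()
    gap_rate: float = 0.05
    n_insert_columns: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "query", self.query.upper())
        object.__setattr__(self, "planted", tuple(self.planted))
        if not self.query or any(ch not in _AA_INDEX for ch in self.query):
            raise SimSpecError("query must be a nonempty standard-amino-acid sequence")
        if self.n_homologs < 1:
            raise SimSpecError("n_homologs must be >= 1")
        for p in (self.conservation, self.gap_rate):
            if not 0 <= p <= 1:
                raise SimSpecError(f"probabilities must lie in [0, 1], got {p}")
        seen: set[int] = set()
        for pos, aa, freq in self.planted:
            if not 1 <= pos <= len(self.query):
                raise SimSpecError(f"planted position {pos} outside query length")
            if pos in seen:
                raise SimSpecError(f"duplicate planted position {pos}")
            seen.add(pos)
            if aa not in _AA_INDEX:
                raise SimSpecError(f"planted residue {aa!r} is not a standard amino acid")
            if aa == self.query[pos - 1]:
                raise SimSpecError(
                    f"planted residue at position {pos} equals the wild-type {aa!r}"
                )
            if not 0 <= freq <= 1:
                raise SimSpecError(f"planted frequency must lie in [0, 1], got {freq}")
        if self.n_insert_columns < 0:
            raise SimSpecError("n_insert_columns must be >= 0")


@dataclass(frozen=True)
class DecaySimSpec:
    """Specification of replicated single-exponential decay measurements."""

    c0: float = 100.0
    t_half_true: float = 79.0
    times: tuple[float, ...] = DEFAULT_DECAY_TIMES
    cv: float = 0.10
    n_replicates: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        if not self.times:
            raise SimSpecError("times must be nonempty")
        if self.c0 <= 0 or self.t_half_true <= 0:
            raise SimSpecError("c0 and t_half_true must be > 0")
        if self.cv < 0:
            raise SimSpecError("cv must be >= 0")
        if self.n_replicates < 1:
            raise SimSpecError("n_replicates must be >= 1")


@dataclass(frozen=True)
class ColocSimSpec:
    """Specification of a paired punctate two-channel image.

    ``n_puncta`` Gaussian spots are placed in channel a; a fraction
    ``overlap_fraction`` of them is duplicated at the same location in
    channel b, the rest of b's spots are placed independently. Spots are
    truncated at 3 standard deviations so background pixels are exactly
    zero unless ``noise_sd > 0`` (half-normal additive noise).
    """

    shape: tuple[int, int] = (64, 64)
    n_puncta: int = 20
    overlap_fraction: float = 0.5
    amplitude: float = 100.0
    spot_sigma: float = 1.5
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        if len(self.shape) != 2 or min(self.shape) < 1:
            raise SimSpecError(f"shape must be 2-D and positive, got {self.shape}")
        if not 0 <= self.overlap_fraction <= 1:
            raise SimSpecError("overlap_fraction must lie in [0, 1]")
        if self.n_puncta < 0:
            raise SimSpecError("n_puncta must be >= 0")
        if self.amplitude <= 0 or self.spot_sigma <= 0:
            raise SimSpecError("amplitude and spot_sigma must be > 0")
        if self.noise_sd < 0:
            raise SimSpecError("noise_sd must be >= 0")
        radius = int(math.ceil(3 * self.spot_sigma))
        if min(self.shape) < 2 * radius + 1:
            raise SimSpecError(
                f"shape {self.shape} smaller than the spot footprint "
                f"({2 * radius + 1} px)"
            )


def _background_draw(
    rng: np.random.Generator,
    n: int,
    q: np.ndarray,
    exclude_index: int | None,
) -> np.ndarray:
    probs = q.copy()
    if exclude_index is not None:
        probs[exclude_index] = 0.0
    probs /= probs.sum()
    return rng.choice(len(AMINO_ACIDS), size=n, p=probs)


def simulate_ortholog_msa(
    spec: MsaSimSpec, background: BackgroundComposition | None = None
) -> Alignment:
    """Generate an alignment of ``n_homologs`` homologs plus the query row.

    Background draws use the same composition as scoring (the packaged
    default unless overridden), keeping the null model calibrated.
    """
    background = background or default_background()
    q = np.array([background[aa] for aa in AMINO_ACIDS])
    rng = np.random.default_rng(spec.seed)
    L, n = len(spec.query), spec.n_homologs
    planted_by_pos = {pos: (aa, freq) for pos, aa, freq in spec.planted}

    residues = np.empty((n, L), dtype=np.int64)
    for j in range(L):
        wt_idx = _AA_INDEX[spec.query[j]]
        column = np.empty(n, dtype=np.int64)
        plant = planted_by_pos.get(j + 1)
        if plant is not None:
            aa, freq = plant
            take_plant = rng.random(n) < freq
            column[take_plant] = _AA_INDEX[aa]
            rest = ~take_plant
        else:
            rest = np.ones(n, dtype=bool)
        n_rest = int(rest.sum())
        conserve = rng.random(n_rest) < spec.conservation
        draws = _background_draw(rng, n_rest, q, exclude_index=wt_idx)
        rest_col = np.where(conserve, wt_idx, draws)
        column[rest] = rest_col
        residues[:, j] = column

    gap_mask = rng.random((n, L)) < spec.gap_rate

    aa_arr = np.array(list(AMINO_ACIDS))
    homolog_cols = np.where(gap_mask, GAP, aa_arr[residues])  # (n, L) of 1-char strings
    query_cols = np.array(list(spec.query))

    if spec.n_insert_columns:
        # Insertion columns carry a gap in the query; each homolog is occupied
        # by a background draw with probability 0.3, else gapped.
        slots = np.sort(rng.integers(0, L + 1, size=spec.n_insert_columns))
        occupied = rng.random((n, spec.n_insert_columns)) < 0.3
        ins_draws = _background_draw(
            rng, n * spec.n_insert_columns, q, exclude_index=None
        ).reshape(n, spec.n_insert_columns)
        ins_cols = np.where(occupied, aa_arr[ins_draws], GAP)
        homolog_parts: list[np.ndarray] = []
        query_parts: list[np.ndarray] = []
        prev = 0
        for k, slot in enumerate(slots):
            homolog_parts.append(homolog_cols[:, prev:slot])
            homolog_parts.append(ins_cols[:, k : k + 1])
            query_parts.append(query_cols[prev:slot])
            query_parts.append(np.array([GAP]))
            prev = slot
        homolog_parts.append(homolog_cols[:, prev:])
        query_parts.append(query_cols[prev:])
        homolog_cols = np.concatenate(homolog_parts, axis=1)
        query_cols = np.concatenate(query_parts)

    ids = ("query",) + tuple(f"homolog_{i + 1:03d}" for i in range(n))
    rows = ("".join(query_cols),) + tuple("".join(r) for r in homolog_cols)
    return Alignment(ids=ids, rows=rows, query_id="query")


def simulate_decay(spec: DecaySimSpec) -> list[TimeSeries]:
    """Generate one noisy exponential-decay series per replicate.

    Values are ``c0 * exp(-ln2 * t / t_half_true) * eps`` with ``eps``
    lognormal with mean 1 and coefficient of variation ``cv``.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.times)
    clean = spec.c0 * np.exp(-math.log(2) * t / spec.t_half_true)
    if spec.cv > 0:
        sigma2 = math.log(1 + spec.cv**2)
        mu = -sigma2 / 2  # mean-1 lognormal
        eps = rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=(spec.n_replicates, t.size))
    else:
        eps = np.ones((spec.n_replicates, t.size))
    return [
        TimeSeries(times=spec.times, values=tuple(clean * eps[r]), series_id=f"rep{r + 1}")
        for r in range(spec.n_replicates)
    ]


def _add_spots(
    img: np.ndarray, centers: np.ndarray, amplitude: float, sigma: float
) -> None:
    radius = int(math.ceil(3 * sigma))
    span = np.arange(-radius, radius + 1)
    yy, xx = np.meshgrid(span, span, indexing="ij")
    kernel = amplitude * np.exp(-(yy**2 + xx**2) / (2 * sigma**2))
    kernel[yy**2 + xx**2 > radius**2] = 0.0  # hard cutoff: zero background
    for cy, cx in centers:
        img[cy - radius : cy + radius + 1, cx - radius : cx + radius + 1] += kernel


def simulate_coloc_pair(spec: ColocSimSpec) -> ChannelPair:
    """Generate one paired-channel punctate image with controlled overlap."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    radius = int(math.ceil(3 * spec.spot_sigma))

    def draw_centers(k: int) -> np.ndarray:
        ys = rng.integers(radius, h - radius, size=k)
        xs = rng.integers(radius, w - radius, size=k)
        return np.column_stack([ys, xs])

    n_shared = int(round(spec.overlap_fraction * spec.n_puncta))
    centers_a = draw_centers(spec.n_puncta)
    centers_b = np.concatenate(
        [centers_a[:n_shared], draw_centers(spec.n_puncta - n_shared)], axis=0
    )

    a = np.zeros(spec.shape)
    b = np.zeros(spec.shape)
    _add_spots(a, centers_a, spec.amplitude, spec.spot_sigma)
    _add_spots(b, centers_b, spec.amplitude, spec.spot_sigma)
    if spec.noise_sd > 0:
        a += np.abs(rng.normal(0.0, spec.noise_sd, size=spec.shape))
        b += np.abs(rng.normal(0.0, spec.noise_sd, size=spec.shape))
    return ChannelPair(channel_a=a, channel_b=b)


def write_decay_tsv(series: Sequence[TimeSeries], path) -> None:
    """Write series to the TSV layout read_decay_table consumes."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("series_id\ttime_h\tvalue\n")
        for s in series:
            sid = s.series_id or "series1"
            for t, v in zip(s.times, s.values):
                fh.write(f"{sid}\t{format(t, '.9g')}\t{format(v, '.9g')}\n")


def write_channel_tsv(channel: np.ndarray, path) -> None:
    """Write one intensity matrix as whitespace-free TSV."""
    np.savetxt(path, np.asarray(channel, dtype=float), fmt="%.9g", delimiter="\t")
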