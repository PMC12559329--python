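"""Synthetic GLOE-seq-style read generation from planted nick profiles.

A *nick* at index ``p`` on strand ``s`` is a broken backbone between the
nucleotide at ``p`` and its 3' neighbour on that strand; the nucleotide at
``p`` carries the free 3'-OH that the capture chemistry marks.

Read-geometry contract (shared with :mod:`nickloop.nickmap`):

    The emitted read is a substring of the strand *complementary* to the
    nicked strand, starting at the base paired with the 3'-OH nucleotide and
    extending in the complementary strand's own 5'->3' direction.

Consequently a read that maps to the top strand reports a cut on the bottom
strand and vice versa, and the read's 5'-most mapped reference base sits
directly across the nick's 3'-OH nucleotide.  The exact +-1 phasing of the
wet protocol's adapter chemistry is not recoverable from published material;
correctness here is defined as simulator/caller round-trip identity under
this single documented convention.

For a 3'-OH inside the extrahelical loop the partner base is undefined; the
read then starts across the first paired base 3' of the loop, so loop-internal
nicks are collapsed onto the first post-loop position by any caller.  The
bundled presets never plant loop-internal nicks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, NamedTuple, Union

import numpy as np
import pandas as pd

from nickloop.errors import ConfigError
from nickloop.substrates import TOP, BOTTOM, HeteroduplexSubstrate

_OTHER_BASES = {
    "A": np.array(["C", "G", "T"]),
    "C": np.array(["A", "G", "T"]),
    "G": np.array(["A", "C", "T"]),
    "T": np.array(["A", "C", "G"]),
}


class FastqRead(NamedTuple):
    id: str
    sequence: str
    qualities: str


class TruncatedGeometric:
    """Geometric read-length distribution truncated to [min_len, max_len].

    Mimics sonication-driven fragment-length spread; ``mean_len`` sets the
    untruncated mean above ``min_len``.
    """

    def __init__(self, mean_len: float = 75.0, min_len: int = 30, max_len: int = 150):
        if not min_len <= mean_len <= max_len:
            raise ConfigError("need min_len <= mean_len <= max_len")
        self.mean_len = float(mean_len)
        self.min_len = int(min_len)
        self.max_len = int(max_len)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        p = 1.0 / max(self.mean_len - self.min_len + 1.0, 1.0)
        draws = self.min_len + rng.geometric(p, size=size) - 1
        return np.minimum(draws, self.max_len)


@dataclass
class NickProfile:
    """Planted per-position, per-strand nick intensities (simulation truth).

    Intensity vectors are indexed in each strand's native 5'->3' frame; the
    loop-carrying strand's vector has length N+L, the other's length N.
    """

    substrate: HeteroduplexSubstrate
    intensity_top: np.ndarray
    intensity_bottom: np.ndarray

    def __post_init__(self):
        self.intensity_top = np.asarray(self.intensity_top, dtype=float)
        self.intensity_bottom = np.asarray(self.intensity_bottom, dtype=float)
        for name, vec in ((TOP, self.intensity_top), (BOTTOM, self.intensity_bottom)):
            want = self.substrate.strand_len(name)
            if vec.shape != (want,):
                raise ConfigError(f"intensity_{name} must have length {want}, got {vec.shape}")
            if np.any(vec < 0) or not np.all(np.isfinite(vec)):
                raise ConfigError(f"intensity_{name} must be finite and non-negative")

    def intensity(self, strand: str) -> np.ndarray:
        return self.intensity_top if strand == TOP else self.intensity_bottom

    @property
    def total_mass(self) -> float:
        return float(self.intensity_top.sum() + self.intensity_bottom.sum())

    def swap_strands(self) -> "NickProfile":
        """Profile with the two intensity vectors exchanged (loop-free
        substrates only, where the strands have equal length)."""
        return NickProfile(self.substrate, self.intensity_bottom.copy(), self.intensity_top.copy())


@dataclass
class SimulatedReadSet:
    """FASTQ records plus the per-read ground-truth nick table."""

    reads: List[FastqRead]
    truth: pd.DataFrame = field(repr=False)

    def write_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.qualities}\n")

    def write_truth(self, path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def multi_peak_profile(substrate: HeteroduplexSubstrate, peaks) -> NickProfile:
    """Build a profile from explicit ``(strand, native_position, weight)`` peaks."""
    top = np.zeros(substrate.strand_len(TOP))
    bottom = np.zeros(substrate.strand_len(BOTTOM))
    for strand, pos, weight in peaks:
        vec = top if strand == TOP else bottom
        vec[pos % len(vec)] += weight
    return NickProfile(substrate, top, bottom)


def preset_profile(scenario: str, substrate: HeteroduplexSubstrate, params: dict | None = None) -> NickProfile:
    """Nick-intensity presets for the two incision scenarios observed on
    looped substrates, plus a uniform control.

    ``mutl_opposite_5prime``
        MutSbeta-MutLgamma incision pattern: a decaying series of discrete
        peaks on the strand opposite the loop, all 5' of the loop on that
        strand (so that 3'-OH-primed displacement synthesis runs toward the
        loop).  Params: ``n_peaks`` (10), ``spacing`` (25 nt), ``first_offset``
        (10 nt 5' of the loop), ``decay_length`` (120 nt), ``background``
        (0.05 uniform fraction on the same strand).
    ``fan1_loop3prime``
        FAN1 (with RFC-PCNA) incision: one dominant peak on the looped strand
        exactly one nucleotide 3' of the loop (looped-strand coordinate
        ``loop3_boundary + 1``), plus a low uniform background on the looped
        strand.  Params: ``background`` (0.05).
    ``uniform``
        Equal intensity at every position of ``params['strand']`` ('top').
    """
    params = dict(params or {})
    top = np.zeros(substrate.strand_len(TOP))
    bottom = np.zeros(substrate.strand_len(BOTTOM))
    vec = {TOP: top, BOTTOM: bottom}

    if scenario == "mutl_opposite_5prime":
        n_peaks = int(params.pop("n_peaks", 10))
        spacing = int(params.pop("spacing", 25))
        first_offset = int(params.pop("first_offset", 10))
        decay_length = float(params.pop("decay_length", 120.0))
        background = float(params.pop("background", 0.05))
        opp = substrate.opposite_strand
        v = vec[opp]
        n, i = substrate.N, substrate.loop.insertion_point
        gap5 = n - i - 1  # last opposite-strand base 5' of the loop gap
        weights = np.exp(-(first_offset + spacing * np.arange(n_peaks)) / decay_length)
        weights *= (1.0 - background) / weights.sum()
        for k in range(n_peaks):
            v[(gap5 - first_offset - spacing * k) % len(v)] += weights[k]
        v += background / len(v)
    elif scenario == "fan1_loop3prime":
        background = float(params.pop("background", 0.05))
        v = vec[substrate.looped_strand]
        peak = (substrate.loop3_boundary + 1) % len(v)
        v += background / len(v)
        v[peak] += 1.0 - background
    elif scenario == "uniform":
        strand = params.pop("strand", TOP)
        if strand not in (TOP, BOTTOM):
            raise ConfigError(f"uniform profile strand must be 'top' or 'bottom', got {strand!r}")
        vec[strand] += 1.0 / len(vec[strand])
    else:
        raise ConfigError(f"unknown nick-profile scenario {scenario!r}")
    if params:
        raise ConfigError(f"unknown parameters for scenario {scenario!r}: {sorted(params)}")
    return NickProfile(substrate, top, bottom)


def _circular_substring(seq: str, start: int, length: int) -> str:
    reps = length // len(seq) + 2
    tiled = seq * reps
    start %= len(seq)
    return tiled[start:start + length]


def _read_start(substrate: HeteroduplexSubstrate, strand: str, pos: int):
    """(template_strand, start) of the read emitted for a nick at
    ``strand[pos]`` under the geometry contract."""
    partner = substrate.pair_position(strand, pos)
    if partner is None:
        # unpaired 3'-OH inside the loop: start across the first paired base
        # 3' of the loop (carrier duplex coordinate == insertion_point)
        d = substrate.loop.insertion_point
        n = substrate.N
        opp = substrate.opposite_strand
        return (opp, (n - 1 - d) % n)
    return partner


def simulate_reads(profile: NickProfile, n_reads: int,
                   read_length: Union[int, TruncatedGeometric] = 75,
                   error_rate: float = 0.0, seed: int = 0) -> SimulatedReadSet:
    """Draw nicks from a profile and emit single-end GLOE-seq-style reads.

    Nick positions are sampled from the normalized intensity profile; each
    read is a (circular) substring of the strand complementary to the nicked
    strand per the module-level geometry contract.  Substitution errors are
    injected per base at ``error_rate``; qualities are constant ('I').
    Deterministic for a fixed ``seed``.
    """
    if n_reads < 0:
        raise ConfigError("n_reads must be >= 0")
    if not 0.0 <= error_rate < 1.0:
        raise ConfigError("error_rate must lie in [0,1)")
    substrate = profile.substrate
    empty_truth = pd.DataFrame(columns=["read_id", "strand", "nick_position", "read_length"])
    if n_reads == 0:
        return SimulatedReadSet(reads=[], truth=empty_truth)
    if profile.total_mass <= 0:
        raise ConfigError("cannot simulate reads from an all-zero nick profile")
    if substrate.loop_occurrences_elsewhere() > 0:
        warnings.warn(
            "loop sequence occurs elsewhere in the plasmid; loop-spanning "
            "reads may multi-map", stacklevel=2)

    rng = np.random.default_rng(seed)
    top = profile.intensity_top
    combined = np.concatenate([top, profile.intensity_bottom])
    cdf = np.cumsum(combined)
    idx = np.searchsorted(cdf, rng.random(n_reads) * cdf[-1], side="right")

    if isinstance(read_length, (int, np.integer)):
        if read_length < 1:
            raise ConfigError("read_length must be >= 1")
        lengths = np.full(n_reads, int(read_length))
    else:
        lengths = read_length.sample(rng, n_reads)

    seqs = {s: substrate.strand_seq(s) for s in (TOP, BOTTOM)}
    reads: List[FastqRead] = []
    rows = []
    n_top = len(top)
    for serial, (j, length) in enumerate(zip(idx, lengths)):
        if j < n_top:
            strand, pos = TOP, int(j)
        else:
            strand, pos = BOTTOM, int(j - n_top)
        template_strand, start = _read_start(substrate, strand, pos)
        seq = _circular_substring(seqs[template_strand], start, int(length))
        if error_rate > 0.0:
            hits = np.nonzero(rng.random(int(length)) < error_rate)[0]
            if hits.size:
                chars = list(seq)
                for h in hits:
                    chars[h] = rng.choice(_OTHER_BASES[chars[h]])
                seq = "".join(chars)
        read_id = f"r{serial:06d}"
        reads.append(FastqRead(read_id, seq, "I" * int(length)))
        rows.append((read_id, strand, pos, int(length)))
    truth = pd.DataFrame(rows, columns=["read_id", "strand", "nick_position", "read_length"])
    return SimulatedReadSet(reads=reads, truth=truth)


def truth_to_counts(truth: pd.DataFrame, substrate: HeteroduplexSubstrate):
    """Bin a simulation truth table into cut-profile arrays.

    Returns ``(counts_top, counts_bottom, loop_local)`` in plasmid / loop-local
    coordinates, directly comparable to a :class:`nickloop.nickmap.CutProfile`.
    """
    n, L = substrate.N, substrate.L
    counts_top = np.zeros(n, dtype=int)
    counts_bottom = np.zeros(n, dtype=int)
    loop_local = np.zeros(L, dtype=int)
    for strand, pos in zip(truth["strand"], truth["nick_position"]):
        kind, j = substrate.profile_bin(strand, int(pos))
        if kind == TOP:
            counts_top[j] += 1
        elif kind == BOTTOM:
            counts_bottom[j] += 1
        else:
            loop_local[j] += 1
    return counts_top, counts_bottom, loop_local


def profile_to_bin_distribution(profile: NickProfile):
    """Normalized expected cut-profile distribution implied by a nick profile.

    Used to compare an inferred :class:`CutProfile` against the planted truth
    via total-variation distance.  Loop-internal intensity (none in the
    bundled presets) is binned loop-locally.
    """
    substrate = profile.substrate
    n, L = substrate.N, substrate.L
    top = np.zeros(n)
    bottom = np.zeros(n)
    loop_local = np.zeros(L)
    for strand in (TOP, BOTTOM):
        vec = profile.intensity(strand)
        for pos in np.nonzero(vec)[0]:
            kind, j = substrate.profile_bin(strand, int(pos))
            if kind == TOP:
                top[j] += vec[pos]
            elif kind == BOTTOM:
                bottom[j] += vec[pos]
            else:
                loop_local[j] += vec[pos]
    total = top.sum() + bottom.sum() + loop_local.sum()
    return top / total, bottom / total, loop_local / total
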