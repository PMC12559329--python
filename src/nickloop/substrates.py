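"""Circular heteroduplex plasmid substrates with extrahelical loops.

Coordinate conventions used throughout the package
--------------------------------------------------

* The *top* strand is the plasmid FASTA sequence read 5'->3'; the *bottom*
  strand is its reverse complement, also indexed 5'->3' in its own ("native")
  frame.  Base ``bottom[b]`` pairs with ``top[N-1-b]``.
* All coordinates are 0-based and interpreted modulo the strand length
  (circular molecules).
* The *duplex frame* of the loop-carrying strand is the coordinate system of
  that strand before loop insertion (for a top-strand loop this is simply the
  plasmid coordinate).  The loop of length L sits between duplex positions
  ``insertion_point - 1`` and ``insertion_point`` of the carrier strand.
* In the *looped-strand frame* (length N+L) the loop occupies positions
  ``insertion_point .. insertion_point + L - 1``.

Cut/nick positions reported by the mapping pipeline use plasmid (top-strand)
coordinates with a strand flag; :meth:`HeteroduplexSubstrate.profile_bin`
is the single place where native strand coordinates are projected onto that
frame, so the simulator and the cut caller cannot drift apart.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from nickloop.errors import ConfigError, FormatError

_BASES = np.array(["A", "C", "G", "T"])
_VALID = frozenset("ACGT")

TOP = "top"
BOTTOM = "bottom"


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return str(Seq(seq).reverse_complement())


class InLoop(NamedTuple):
    """Sentinel for a looped-strand position that falls inside the loop.

    ``offset`` is the loop-local offset (0 .. L-1 from the 5' end of the
    loop).  Such positions have no duplex-frame image.
    """

    offset: int


class StrandPair(NamedTuple):
    """Both strands of a (possibly modified) circular duplex, native 5'->3'."""

    top: str
    bottom: str


@dataclass(frozen=True)
class CircularPlasmid:
    """A circular double-stranded plasmid, stored as its top strand."""

    name: str
    sequence: str

    def __post_init__(self):
        if len(self.sequence) == 0:
            raise ConfigError("plasmid sequence must be non-empty")
        bad = set(self.sequence) - _VALID
        if bad:
            raise FormatError(f"non-ACGT characters in plasmid sequence: {sorted(bad)}")

    @property
    def length_nt(self) -> int:
        return len(self.sequence)

    def rotate(self, k: int) -> "CircularPlasmid":
        """Return the same circular molecule with its origin moved to ``k``."""
        n = self.length_nt
        k %= n
        return CircularPlasmid(self.name, self.sequence[k:] + self.sequence[:k])


@dataclass(frozen=True)
class LoopSpec:
    """An extrahelical loop on one strand of a circular duplex.

    ``insertion_point`` is a duplex coordinate of the carrier strand in that
    strand's own 5'->3' sense: the loop sits between duplex positions
    ``insertion_point - 1`` and ``insertion_point``.
    """

    carrier_strand: str
    insertion_point: int
    loop_sequence: str

    def __post_init__(self):
        if self.carrier_strand not in (TOP, BOTTOM):
            raise ConfigError(f"carrier_strand must be 'top' or 'bottom', got {self.carrier_strand!r}")
        bad = set(self.loop_sequence) - _VALID
        if bad:
            raise FormatError(f"non-ACGT characters in loop sequence: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.loop_sequence)


@dataclass(frozen=True)
class HeteroduplexSubstrate:
    """Circular duplex plasmid with an extrahelical loop on one strand."""

    plasmid: CircularPlasmid
    loop: LoopSpec
    looped_strand_seq: str = field(repr=False)
    opposite_strand_seq: str = field(repr=False)
    loop5_boundary: int
    loop3_boundary: int

    # -- basic geometry -------------------------------------------------
    @property
    def N(self) -> int:
        """Duplex (plasmid) length."""
        return self.plasmid.length_nt

    @property
    def L(self) -> int:
        """Loop length."""
        return self.loop.length

    @property
    def looped_strand(self) -> str:
        """Name of the strand carrying the loop."""
        return self.loop.carrier_strand

    @property
    def opposite_strand(self) -> str:
        """Name of the loop-free strand."""
        return BOTTOM if self.loop.carrier_strand == TOP else TOP

    def strand_seq(self, strand: str) -> str:
        """Native 5'->3' sequence of ``strand`` ('top' or 'bottom')."""
        if strand == self.looped_strand:
            return self.looped_strand_seq
        if strand == self.opposite_strand:
            return self.opposite_strand_seq
        raise ConfigError(f"unknown strand {strand!r}")

    def strand_len(self, strand: str) -> int:
        return len(self.strand_seq(strand))

    # -- coordinate projections ----------------------------------------
    def looped_to_duplex(self, pos: int) -> Union[int, InLoop]:
        """Project a looped-strand coordinate onto the carrier duplex frame."""
        nl = self.N + self.L
        if not 0 <= pos < nl:
            raise ConfigError(f"looped-strand position {pos} out of range [0,{nl})")
        i, L = self.loop.insertion_point, self.L
        if pos < i:
            return pos
        if pos < i + L:
            return InLoop(pos - i)
        return pos - L

    def duplex_to_looped(self, pos: int) -> int:
        """Project a carrier duplex coordinate into the looped-strand frame."""
        if not 0 <= pos < self.N:
            raise ConfigError(f"duplex position {pos} out of range [0,{self.N})")
        if pos < self.loop.insertion_point:
            return pos
        return pos + self.L

    def pair_position(self, strand: str, pos: int) -> Union[tuple, None]:
        """Return ``(other_strand, other_pos)`` of the base paired with
        ``strand[pos]``, or ``None`` for an unpaired (loop-internal) base."""
        n = self.N
        if strand == self.looped_strand:
            d = self.looped_to_duplex(pos)
            if isinstance(d, InLoop):
                return None
            return (self.opposite_strand, n - 1 - d)
        seqlen = self.strand_len(strand)
        if not 0 <= pos < seqlen:
            raise ConfigError(f"{strand} position {pos} out of range [0,{seqlen})")
        d = n - 1 - pos  # carrier duplex coordinate of the partner
        return (self.looped_strand, self.duplex_to_looped(d))

    def profile_bin(self, strand: str, pos: int) -> tuple:
        """Project a native strand coordinate onto the cut-profile frame.

        Returns ``("top", j)`` or ``("bottom", j)`` with ``j`` a plasmid
        (top-strand) coordinate, or ``("loop", offset)`` for loop-internal
        positions of the looped strand.
        """
        n = self.N
        if strand == self.looped_strand:
            d = self.looped_to_duplex(pos)
            if isinstance(d, InLoop):
                return ("loop", d.offset)
            plasmid_j = d if strand == TOP else n - 1 - d
            return (strand, plasmid_j)
        seqlen = self.strand_len(strand)
        if not 0 <= pos < seqlen:
            raise ConfigError(f"{strand} position {pos} out of range [0,{seqlen})")
        plasmid_j = pos if strand == TOP else n - 1 - pos
        return (strand, plasmid_j)

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "plasmid": {"name": self.plasmid.name, "sequence": self.plasmid.sequence},
            "loop": {
                "carrier_strand": self.loop.carrier_strand,
                "insertion_point": self.loop.insertion_point,
                "loop_sequence": self.loop.loop_sequence,
            },
            "loop5_boundary": self.loop5_boundary,
            "loop3_boundary": self.loop3_boundary,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @staticmethod
    def from_dict(d: dict) -> "HeteroduplexSubstrate":
        plasmid = CircularPlasmid(d["plasmid"]["name"], d["plasmid"]["sequence"].upper())
        loop = LoopSpec(
            d["loop"]["carrier_strand"],
            int(d["loop"]["insertion_point"]),
            d["loop"]["loop_sequence"].upper(),
        )
        return make_heteroduplex(plasmid, loop)

    @staticmethod
    def from_json(path) -> "HeteroduplexSubstrate":
        try:
            d = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"invalid substrate JSON: {exc}") from exc
        return HeteroduplexSubstrate.from_dict(d)

    def loop_occurrences_elsewhere(self) -> int:
        """Occurrences of the loop sequence in the loop-free circular duplex.

        Repetitive loop context (e.g. a CAG tract flanking a (CAG)4 loop)
        makes loop-spanning reads multi-map; the read simulator warns when
        this count is nonzero.
        """
        if self.L == 0:
            return 0
        doubled = self.plasmid.sequence * 2
        count = start = 0
        while True:
            idx = doubled.find(self.loop.loop_sequence, start)
            if idx == -1 or idx >= self.N:
                return count
            count += 1
            start = idx + 1


def generate_plasmid(length_nt: int, gc_fraction: float = 0.5, seed: int = 0,
                     name: str = "synthetic_plasmid") -> CircularPlasmid:
    """Generate a random circular plasmid with a target GC content.

    Bases are drawn i.i.d. with P(G) = P(C) = ``gc_fraction``/2; the realized
    GC fraction therefore fluctuates binomially around the target.  A fixed
    ``seed`` gives a reproducible sequence.
    """
    if length_nt < 100:
        raise ConfigError(f"length_nt must be >= 100, got {length_nt}")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ConfigError(f"gc_fraction must lie in [0,1], got {gc_fraction}")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    seq = "".join(rng.choice(_BASES, size=length_nt, p=[at, gc, gc, at]))
    return CircularPlasmid(name, seq)


def load_plasmid(fasta_source) -> CircularPlasmid:
    """Load a single-record FASTA as a circular plasmid (uppercased)."""
    records = list(SeqIO.parse(fasta_source, "fasta"))
    if len(records) != 1:
        raise FormatError(f"expected exactly one FASTA record, found {len(records)}")
    rec = records[0]
    seq = str(rec.seq).upper()
    if not seq:
        raise FormatError("empty FASTA record")
    bad = set(seq) - _VALID
    if bad:
        raise FormatError(f"non-ACGT characters in FASTA: {sorted(bad)}")
    return CircularPlasmid(rec.id or "plasmid", seq)


def write_plasmid(plasmid: CircularPlasmid, path) -> None:
    """Write the plasmid top strand as FASTA, flagged circular in the header."""
    rec = SeqRecord(Seq(plasmid.sequence), id=plasmid.name, description="circular=true")
    SeqIO.write([rec], str(path), "fasta")


def make_heteroduplex(plasmid: CircularPlasmid, loop: LoopSpec) -> HeteroduplexSubstrate:
    """Assemble a heteroduplex substrate from a duplex plasmid and a loop.

    The carrier strand receives ``loop.loop_sequence`` between duplex
    positions ``insertion_point - 1`` and ``insertion_point``; the opposite
    strand is unchanged.  For an empty loop the substrate degenerates to the
    plain duplex (``loop3_boundary = loop5_boundary - 1``).
    """
    n = plasmid.length_nt
    i = loop.insertion_point
    if not 0 <= i < n:
        raise ConfigError(f"insertion_point {i} out of range [0,{n})")
    top = plasmid.sequence
    bottom = revcomp(top)
    carrier = top if loop.carrier_strand == TOP else bottom
    looped = carrier[:i] + loop.loop_sequence + carrier[i:]
    opposite = bottom if loop.carrier_strand == TOP else top
    return HeteroduplexSubstrate(
        plasmid=plasmid,
        loop=loop,
        looped_strand_seq=looped,
        opposite_strand_seq=opposite,
        loop5_boundary=i,
        loop3_boundary=i + loop.length - 1,
    )


def expansion_product(substrate: HeteroduplexSubstrate) -> StrandPair:
    """Sequences of both strands after repeat expansion.

    Expansion fills in the strand opposite the loop: displacement synthesis
    copies the loop, so the opposite strand gains the reverse complement of
    the loop sequence across the loop site.  The looped strand is unchanged;
    both strands end up N+L nucleotides long.  For a (CAG)4 top-strand loop
    the bottom strand gains (CTG)4.
    """
    i, n = substrate.loop.insertion_point, substrate.N
    insert = revcomp(substrate.loop.loop_sequence)
    opp = substrate.opposite_strand_seq
    # the loop gap between carrier duplex i-1 and i sits between opposite
    # native positions n-i-1 and n-i
    expanded_opp = opp[: n - i] + insert + opp[n - i:]
    if substrate.looped_strand == TOP:
        return StrandPair(top=substrate.looped_strand_seq, bottom=expanded_opp)
    return StrandPair(top=expanded_opp, bottom=substrate.looped_strand_seq)


def contraction_product(substrate: HeteroduplexSubstrate) -> StrandPair:
    """Sequences of both strands after repeat contraction.

    Contraction excises the loop from the carrier strand: both strands of
    the product equal the loop-free duplex of length N.
    """
    top = substrate.plasmid.sequence
    return StrandPair(top=top, bottom=revcomp(top))


def coord_map(substrate: HeteroduplexSubstrate, position: int,
              from_frame: str, to_frame: str) -> Union[int, InLoop]:
    """Map a position between the looped-strand and carrier-duplex frames.

    Loop-internal looped-strand positions map to an :class:`InLoop` sentinel
    carrying the loop-local offset; every other mapping is bijective.
    """
    frames = ("looped_strand", "duplex")
    if from_frame not in frames or to_frame not in frames:
        raise ConfigError(f"frames must be one of {frames}")
    if from_frame == to_frame:
        limit = substrate.N + substrate.L if from_frame == "looped_strand" else substrate.N
        if not 0 <= position < limit:
            raise ConfigError(f"position {position} out of range [0,{limit})")
        return position
    if from_frame == "looped_strand":
        return substrate.looped_to_duplex(position)
    return substrate.duplex_to_looped(position)
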