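"""Strand-specific cut calling on circular looped substrates.

Pipeline stages:

1. :func:`build_reference` — triple-concatenate the circular reference
   (both the loop-free duplex top strand and the looped strand) so that
   every read of length < N has at least one non-wrapping alignment.
2. :func:`align_reads` — exact k-mer seed + ungapped extension against both
   orientations of the duplex reference; ties at distinct circular loci are
   ambiguous, alignments over the mismatch budget unmapped.  A SAM import
   path (:func:`read_sam_alignments`) accepts external-aligner output
   against the exported 3x reference.
3. :func:`call_cuts` — keep unique alignments starting in the middle copy
   window [N, 2N), shift to plasmid coordinates and assign each read's cut
   to the strand opposite its mapping strand: a read aligned to the top
   strand at plasmid start ``s`` reports a bottom-strand nick across ``s``;
   a read aligned to the bottom strand (reverse-orientation hit over
   ``[s, s+len)``) reports a top-strand nick at ``s+len-1``.  Both rules are
   the inverse of the read geometry documented in :mod:`nickloop.gloesim`.
4. :func:`rescue_loop_reads` — reads the primary pass could not place
   (typically loop-spanning reads) are re-aligned against the looped-strand
   reference; cuts landing inside the loop are kept in loop-local
   coordinates rather than projected onto the duplex.
5. :func:`finalize_profile` / :func:`export_profile` — merge, reconcile
   read-count conservation, normalize (CPM) and export TSV/BED/polar plot.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from nickloop.errors import ConfigError, ConsistencyError, FormatError
from nickloop.gloesim import FastqRead
from nickloop.substrates import TOP, BOTTOM, HeteroduplexSubstrate, revcomp

N_COPIES = 3

PASS_PRIMARY = "primary"
PASS_RESCUE = "loop_rescue"

STATUS_UNIQUE = "unique"
STATUS_AMBIGUOUS = "ambiguous"
STATUS_UNMAPPED = "unmapped"
STATUS_OUT_OF_WINDOW = "out_of_window"


@dataclass(frozen=True)
class ReferenceBundle:
    """Triple-concatenated circular references for the two mapping passes."""

    duplex_ref: str = field(repr=False)
    loop_ref: str = field(repr=False)
    substrate: HeteroduplexSubstrate
    exclude_loop_from_rescue: bool = False

    @property
    def duplex_unit(self) -> int:
        return len(self.duplex_ref) // N_COPIES

    @property
    def loop_unit(self) -> int:
        return len(self.loop_ref) // N_COPIES


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    pass_name: str
    ref_strand: Optional[str]  # strand the READ aligned to; None unless unique
    start: Optional[int]  # 0-based leftmost coordinate on the 3x reference
    mapped_length: Optional[int]
    status: str
    mismatches: Optional[int] = None


@dataclass
class CutCalls:
    """Per-read cut assignments from one mapping pass.

    ``calls`` holds ``(read_id, kind, index)`` with ``kind`` in
    {'top','bottom','loop'}; indices are plasmid coordinates ('top'/'bottom')
    or loop-local offsets ('loop').  ``statuses`` records the fate of every
    read that entered the pass.
    """

    substrate: HeteroduplexSubstrate
    pass_name: str
    calls: List[Tuple[str, str, int]]
    statuses: Dict[str, str]

    @property
    def leftover_ids(self) -> List[str]:
        return [rid for rid, st in self.statuses.items() if st != STATUS_UNIQUE]


@dataclass
class CutProfile:
    """Inferred per-position, per-strand cut counts on the plasmid.

    ``counts_top[j]`` / ``counts_bottom[j]`` count nicks whose 3'-OH
    nucleotide sits at plasmid coordinate ``j`` on the respective strand
    (bottom-strand nicks are indexed by their paired top-strand coordinate);
    ``loop_local_counts`` holds rescue-pass cuts falling inside the
    extrahelical loop, in loop-local coordinates.
    """

    substrate: HeteroduplexSubstrate
    counts_top: np.ndarray
    counts_bottom: np.ndarray
    loop_local_counts: np.ndarray
    totals: Dict[str, int]
    read_calls: Dict[str, Tuple[str, int]] = field(default_factory=dict, repr=False)

    @property
    def n_mapped(self) -> int:
        return self.totals["n_unique_primary"] + self.totals["n_rescued"]

    def _cpm(self, counts: np.ndarray) -> np.ndarray:
        m = self.n_mapped
        if m == 0:
            return np.zeros_like(counts, dtype=float)
        return counts * (1e6 / m)

    @property
    def cpm_top(self) -> np.ndarray:
        return self._cpm(self.counts_top)

    @property
    def cpm_bottom(self) -> np.ndarray:
        return self._cpm(self.counts_bottom)

    @property
    def cpm_loop(self) -> np.ndarray:
        return self._cpm(self.loop_local_counts)

    def strand_counts(self, strand: str) -> np.ndarray:
        return self.counts_top if strand == TOP else self.counts_bottom

    def modal_cut(self, strand: str) -> int:
        """Plasmid coordinate of the most frequent cut on ``strand``."""
        return int(np.argmax(self.strand_counts(strand)))


def build_reference(substrate: HeteroduplexSubstrate,
                    exclude_loop_from_rescue: bool = False) -> ReferenceBundle:
    """Triple-concatenated references for primary and loop-rescue mapping.

    ``exclude_loop_from_rescue`` switches the second-pass reference from the
    full looped strand (default; loop-internal hits are reported loop-locally)
    to the carrier strand with the loop deleted.
    """
    duplex_ref = substrate.plasmid.sequence * N_COPIES
    if exclude_loop_from_rescue:
        carrier = substrate.plasmid.sequence if substrate.looped_strand == TOP \
            else revcomp(substrate.plasmid.sequence)
        loop_ref = carrier * N_COPIES
    else:
        loop_ref = substrate.looped_strand_seq * N_COPIES
    return ReferenceBundle(duplex_ref=duplex_ref, loop_ref=loop_ref,
                           substrate=substrate,
                           exclude_loop_from_rescue=exclude_loop_from_rescue)


def export_reference(bundle: ReferenceBundle, path) -> None:
    """Write the 3x duplex reference as FASTA (for external aligners)."""
    name = bundle.substrate.plasmid.name
    with open(path, "w") as fh:
        fh.write(f">{name}_x{N_COPIES} concatenated={N_COPIES} circular_unit={bundle.duplex_unit}\n")
        seq = bundle.duplex_ref
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")


# ---------------------------------------------------------------------------
# internal aligner: exact k-mer seed + ungapped extension
# ---------------------------------------------------------------------------

class KmerAligner:
    """Ungapped seed-and-extend aligner for a small 3x circular reference.

    Non-overlapping k-mer seeds are taken from the read (and its reverse
    complement); with ``max_mismatches`` < number of disjoint seeds, every
    alignment within the mismatch budget is guaranteed to be found.  Hits are
    deduplicated modulo the circular unit length; equal-score hits at
    distinct circular loci make a read ambiguous.  Unique hits are
    canonicalized to a start in the middle copy ``[unit, 2*unit)``.
    """

    def __init__(self, ref: str, k: int = 20, max_mismatches: int = 2):
        if k < 1:
            raise ConfigError("seed size k must be >= 1")
        if max_mismatches < 0:
            raise ConfigError("max_mismatches must be >= 0")
        self.k = k
        self.max_mismatches = max_mismatches
        self.ref = ref
        self.unit = len(ref) // N_COPIES
        self.ref_arr = np.frombuffer(ref.encode(), dtype=np.uint8)
        self.index: Dict[str, List[int]] = {}
        for i in range(len(ref) - k + 1):
            self.index.setdefault(ref[i:i + k], []).append(i)

    def _seed_offsets(self, read_len: int) -> List[int]:
        k = self.k
        offsets = list(range(0, read_len - k + 1, k))
        last = read_len - k
        if last >= 0 and last not in offsets:
            offsets.append(last)
        return offsets

    def _candidates(self, seq: str) -> List[int]:
        starts = set()
        for off in self._seed_offsets(len(seq)):
            for pos in self.index.get(seq[off:off + self.k], ()):
                start = pos - off
                if 0 <= start <= len(self.ref) - len(seq):
                    starts.add(start)
        return sorted(starts)

    def align(self, seq: str):
        """Best ungapped placement of ``seq`` on either reference orientation.

        Returns ``(orientation, canonical_start, mismatches)`` for a unique
        hit, the string ``'ambiguous'`` or ``'unmapped'`` otherwise.
        Orientation '+' means the read matches the reference sequence
        forward; '-' means its reverse complement does.
        """
        if len(seq) < self.k or len(seq) > self.unit:
            return STATUS_UNMAPPED
        best: Dict[Tuple[str, int], int] = {}  # (orientation, start mod unit) -> mismatches
        best_repr: Dict[Tuple[str, int], int] = {}
        for orientation, query in (("+", seq), ("-", revcomp(seq))):
            q_arr = np.frombuffer(query.encode(), dtype=np.uint8)
            for start in self._candidates(query):
                mm = int(np.count_nonzero(self.ref_arr[start:start + len(query)] != q_arr))
                key = (orientation, start % self.unit)
                if key not in best or mm < best[key]:
                    best[key] = mm
                    best_repr[key] = start
        if not best:
            return STATUS_UNMAPPED
        min_mm = min(best.values())
        if min_mm > self.max_mismatches:
            return STATUS_UNMAPPED
        winners = [key for key, mm in best.items() if mm == min_mm]
        if len(winners) > 1:
            return STATUS_AMBIGUOUS
        orientation, locus = winners[0]
        start = self.unit + locus  # middle-copy representative
        if start + len(seq) > len(self.ref):  # read longer than unit cannot happen here
            start = best_repr[winners[0]]
        return (orientation, start, min_mm)


def _coerce_reads(reads) -> List[FastqRead]:
    """Accept a list of FastqRead or a FASTQ path/handle."""
    if isinstance(reads, (str, Path)):
        try:
            records = list(SeqIO.parse(str(reads), "fastq"))
        except ValueError as exc:
            raise FormatError(f"malformed FASTQ: {exc}") from exc
        return [FastqRead(r.id, str(r.seq).upper(),
                          "".join(chr(q + 33) for q in r.letter_annotations["phred_quality"]))
                for r in records]
    return list(reads)


def _align_pass(reads: Sequence[FastqRead], ref: str, ref_strand_plus: str,
                pass_name: str, seed_k: int, max_mismatches: int) -> List[AlignmentRecord]:
    aligner = KmerAligner(ref, k=seed_k, max_mismatches=max_mismatches)
    other = BOTTOM if ref_strand_plus == TOP else TOP
    records = []
    for read in reads:
        res = aligner.align(read.sequence)
        if res == STATUS_UNMAPPED or res == STATUS_AMBIGUOUS:
            records.append(AlignmentRecord(read.id, pass_name, None, None, None, res))
            continue
        orientation, start, mm = res
        strand = ref_strand_plus if orientation == "+" else other
        records.append(AlignmentRecord(read.id, pass_name, strand, start,
                                       len(read.sequence), STATUS_UNIQUE, mm))
    return records


def align_reads(reads, bundle: ReferenceBundle, params: Optional[dict] = None) -> List[AlignmentRecord]:
    """Primary-pass alignment of reads against the 3x duplex reference.

    ``params``: ``seed_k`` (20) and ``max_mismatches`` (2).  ``reads`` may be
    a FASTQ path or a sequence of :class:`FastqRead`.
    """
    params = dict(params or {})
    seed_k = int(params.pop("seed_k", 20))
    max_mm = int(params.pop("max_mismatches", 2))
    if params:
        raise ConfigError(f"unknown alignment parameters: {sorted(params)}")
    read_list = _coerce_reads(reads)
    for r in read_list:
        if not r.sequence:
            raise FormatError(f"empty read sequence for {r.id!r}")
    return _align_pass(read_list, bundle.duplex_ref, TOP, PASS_PRIMARY, seed_k, max_mm)


# ---------------------------------------------------------------------------
# cut calling
# ---------------------------------------------------------------------------

def _middle_window_plasmid_start(record: AlignmentRecord, unit: int, copies: str):
    """Plasmid-frame start of an alignment, or None if outside the selected
    copy window."""
    if copies == "middle":
        if not unit <= record.start < 2 * unit:
            return None
        return record.start - unit
    if copies == "all":
        return record.start % unit
    raise ConfigError(f"copies mode must be 'middle' or 'all', got {copies!r}")


def call_cuts(alignments: Iterable[AlignmentRecord], substrate: HeteroduplexSubstrate,
              copies: str = "middle") -> CutCalls:
    """Convert unique primary-pass alignments into strand-specific cut calls.

    Reads aligned to the top strand report cuts on the bottom strand and
    vice versa (see module docstring for the exact coordinate rules).
    Ambiguous, unmapped and out-of-window reads are recorded for the rescue
    pass, never silently dropped.
    """
    n = substrate.N
    calls: List[Tuple[str, str, int]] = []
    statuses: Dict[str, str] = {}
    for rec in alignments:
        if rec.status != STATUS_UNIQUE:
            statuses[rec.read_id] = rec.status
            continue
        s = _middle_window_plasmid_start(rec, n, copies)
        if s is None:
            statuses[rec.read_id] = STATUS_OUT_OF_WINDOW
            continue
        if rec.ref_strand == TOP:
            calls.append((rec.read_id, BOTTOM, s % n))
        else:
            calls.append((rec.read_id, TOP, (s + rec.mapped_length - 1) % n))
        statuses[rec.read_id] = STATUS_UNIQUE
    return CutCalls(substrate, PASS_PRIMARY, calls, statuses)


def rescue_loop_reads(unmapped_reads, substrate: HeteroduplexSubstrate,
                      bundle: Optional[ReferenceBundle] = None,
                      params: Optional[dict] = None,
                      copies: str = "middle") -> CutCalls:
    """Second-pass mapping of leftover reads against the looped strand.

    Loop-spanning reads fail the duplex-only primary pass; aligning them to
    the looped-strand reference recovers their cuts.  Cuts whose coordinate
    falls inside the loop are reported loop-locally (they cannot be placed
    on the duplex).
    """
    params = dict(params or {})
    seed_k = int(params.pop("seed_k", 20))
    max_mm = int(params.pop("max_mismatches", 2))
    if params:
        raise ConfigError(f"unknown alignment parameters: {sorted(params)}")
    if bundle is None:
        bundle = build_reference(substrate)
    read_list = _coerce_reads(unmapped_reads)
    looped = substrate.looped_strand
    records = _align_pass(read_list, bundle.loop_ref, looped, PASS_RESCUE, seed_k, max_mm)

    unit = bundle.loop_unit
    i0 = substrate.loop.insertion_point
    calls: List[Tuple[str, str, int]] = []
    statuses: Dict[str, str] = {}
    loop_in_ref = not bundle.exclude_loop_from_rescue
    for rec in records:
        if rec.status != STATUS_UNIQUE:
            statuses[rec.read_id] = rec.status
            continue
        if copies == "middle":
            if not unit <= rec.start < 2 * unit:
                statuses[rec.read_id] = STATUS_OUT_OF_WINDOW
                continue
            q0 = rec.start - unit
        else:
            q0 = rec.start % unit
        if rec.ref_strand == looped:
            # read drawn from the looped strand: cut on the opposite strand,
            # across the read's 5'-most base
            if loop_in_ref:
                partner = substrate.pair_position(looped, q0)
                if partner is None:
                    calls.append((rec.read_id, "loop", q0 - i0))
                else:
                    strand, pos = partner
                    kind, j = substrate.profile_bin(strand, pos)
                    calls.append((rec.read_id, kind, j))
            else:
                # loop-deleted reference: coordinates are carrier duplex frame
                opp_duplex = (substrate.N - 1 - q0) % substrate.N
                opp = substrate.opposite_strand
                j = opp_duplex if opp == TOP else substrate.N - 1 - opp_duplex
                calls.append((rec.read_id, opp, j))
        else:
            # read drawn from the opposite strand: cut on the looped strand,
            # at the reference base under the read's 5'-most base
            q1 = (q0 + rec.mapped_length - 1) % unit
            if loop_in_ref:
                kind, j = substrate.profile_bin(looped, q1)
                calls.append((rec.read_id, kind, j))
            else:
                j = q1 if looped == TOP else substrate.N - 1 - q1
                calls.append((rec.read_id, looped, j))
        statuses[rec.read_id] = STATUS_UNIQUE
    return CutCalls(substrate, PASS_RESCUE, calls, statuses)


def finalize_profile(primary: CutCalls, rescue: Optional[CutCalls] = None) -> CutProfile:
    """Merge primary and rescue cut calls into a finalized profile.

    Enforces read-count conservation: every read that entered the primary
    pass ends up counted exactly once as uniquely called, rescued, ambiguous
    or unmapped.  A read left ambiguous by either pass (and not rescued) is
    reported ambiguous.
    """
    substrate = primary.substrate
    n, L = substrate.N, substrate.L
    counts_top = np.zeros(n, dtype=int)
    counts_bottom = np.zeros(n, dtype=int)
    loop_local = np.zeros(L, dtype=int)
    read_calls: Dict[str, Tuple[str, int]] = {}

    def _accumulate(calls):
        for rid, kind, idx in calls:
            if kind == TOP:
                counts_top[idx] += 1
            elif kind == BOTTOM:
                counts_bottom[idx] += 1
            elif kind == "loop":
                loop_local[idx] += 1
            else:
                raise ConsistencyError(f"unknown call kind {kind!r}")
            read_calls[rid] = (kind, idx)

    _accumulate(primary.calls)
    rescue_statuses = rescue.statuses if rescue is not None else {}
    if rescue is not None:
        if rescue.substrate is not primary.substrate and \
                rescue.substrate.to_dict() != primary.substrate.to_dict():
            raise ConsistencyError("primary and rescue calls come from different substrates")
        _accumulate(rescue.calls)

    n_input = len(primary.statuses)
    n_unique_primary = sum(1 for st in primary.statuses.values() if st == STATUS_UNIQUE)
    n_rescued = sum(1 for st in rescue_statuses.values() if st == STATUS_UNIQUE)
    n_ambiguous = 0
    n_unmapped = 0
    for rid, st in primary.statuses.items():
        if st == STATUS_UNIQUE:
            continue
        final = rescue_statuses.get(rid)
        if final == STATUS_UNIQUE:
            continue
        if st == STATUS_AMBIGUOUS or final == STATUS_AMBIGUOUS:
            n_ambiguous += 1
        else:
            n_unmapped += 1
    # rescued reads that never went through the primary pass (direct calls)
    extra_rescued = sum(1 for rid in rescue_statuses if rid not in primary.statuses)
    totals = {
        "n_input": n_input + extra_rescued,
        "n_unique_primary": n_unique_primary,
        "n_rescued": n_rescued,
        "n_ambiguous": n_ambiguous + sum(
            1 for rid, st in rescue_statuses.items()
            if rid not in primary.statuses and st == STATUS_AMBIGUOUS),
        "n_unmapped_final": n_unmapped + sum(
            1 for rid, st in rescue_statuses.items()
            if rid not in primary.statuses and st not in (STATUS_UNIQUE, STATUS_AMBIGUOUS)),
    }
    if totals["n_input"] != (totals["n_unique_primary"] + totals["n_rescued"]
                             + totals["n_ambiguous"] + totals["n_unmapped_final"]):
        raise ConsistencyError(f"read-count conservation violated: {totals}")
    n_called = int(counts_top.sum() + counts_bottom.sum() + loop_local.sum())
    if n_called != totals["n_unique_primary"] + totals["n_rescued"]:
        raise ConsistencyError(
            f"call count {n_called} does not match mapped total "
            f"{totals['n_unique_primary'] + totals['n_rescued']}")
    return CutProfile(substrate, counts_top, counts_bottom, loop_local, totals, read_calls)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_nickmap(substrate: HeteroduplexSubstrate, reads,
                seed_k: int = 20, max_mismatches: int = 2,
                copies: str = "middle",
                exclude_loop_from_rescue: bool = False,
                sam_path=None) -> CutProfile:
    """Full cut-calling pipeline: primary alignment, cut calls, loop rescue.

    With ``sam_path`` given, the primary pass uses external-aligner records
    (coordinates against the exported 3x reference) instead of the internal
    aligner; the rescue pass still runs internally.
    """
    bundle = build_reference(substrate, exclude_loop_from_rescue=exclude_loop_from_rescue)
    read_list = _coerce_reads(reads)
    params = {"seed_k": seed_k, "max_mismatches": max_mismatches}
    if sam_path is not None:
        records = read_sam_alignments(sam_path, bundle)
        seen = {r.read_id for r in records}
        records += [AlignmentRecord(r.id, PASS_PRIMARY, None, None, None, STATUS_UNMAPPED)
                    for r in read_list if r.id not in seen]
    else:
        records = align_reads(read_list, bundle, params)
    primary = call_cuts(records, substrate, copies=copies)
    leftover_ids = set(primary.leftover_ids)
    leftover_reads = [r for r in read_list if r.id in leftover_ids]
    rescue = rescue_loop_reads(leftover_reads, substrate, bundle, params, copies=copies)
    return finalize_profile(primary, rescue)


def read_sam_alignments(sam_path, bundle: ReferenceBundle) -> List[AlignmentRecord]:
    """Import primary-pass alignments from a SAM file (external aligner).

    Coordinates must refer to the exported 3x duplex reference
    (:func:`export_reference`).  Flag 16 (reverse) means the read aligned to
    the bottom strand; MAPQ 0 records are treated as ambiguous.
    """
    import pysam

    records = []
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_secondary or aln.is_supplementary:
                continue
            if aln.is_unmapped:
                records.append(AlignmentRecord(aln.query_name, PASS_PRIMARY,
                                               None, None, None, STATUS_UNMAPPED))
                continue
            if aln.mapping_quality == 0:
                records.append(AlignmentRecord(aln.query_name, PASS_PRIMARY,
                                               None, None, None, STATUS_AMBIGUOUS))
                continue
            strand = BOTTOM if aln.is_reverse else TOP
            records.append(AlignmentRecord(
                aln.query_name, PASS_PRIMARY, strand,
                int(aln.reference_start), int(aln.reference_length),
                STATUS_UNIQUE))
    return records


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def profile_to_frame(profile: CutProfile) -> pd.DataFrame:
    """Long-format per-position table (position, strand, count, cpm)."""
    n, L = profile.substrate.N, profile.substrate.L
    frames = [
        pd.DataFrame({"position": np.arange(n), "strand": TOP,
                      "count": profile.counts_top, "cpm": profile.cpm_top}),
        pd.DataFrame({"position": np.arange(n), "strand": BOTTOM,
                      "count": profile.counts_bottom, "cpm": profile.cpm_bottom}),
    ]
    if L:
        frames.append(pd.DataFrame({"position": np.arange(L), "strand": "loop",
                                    "count": profile.loop_local_counts,
                                    "cpm": profile.cpm_loop}))
    return pd.concat(frames, ignore_index=True)


def read_profile_tsv(path):
    """Re-import an exported profile TSV as (counts_top, counts_bottom, loop_local)."""
    df = pd.read_csv(path, sep="\t")
    def _vec(strand):
        sub = df[df["strand"] == strand].sort_values("position")
        return sub["count"].to_numpy(dtype=int)
    return _vec(TOP), _vec(BOTTOM), _vec("loop")


def export_profile(profile: CutProfile, out_prefix) -> Dict[str, str]:
    """Write TSV/BED/polar-plot/summary artifacts for a finalized profile.

    Returns a dict of artifact paths.  The polar plot draws the looped
    strand in red and the opposite strand in black, with the loop position
    marked, mirroring the strand-colour convention of the assay's readout.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {}

    tsv = out_prefix.with_suffix(".profile.tsv")
    profile_to_frame(profile).to_csv(tsv, sep="\t", index=False)
    paths["tsv"] = str(tsv)

    bed = out_prefix.with_suffix(".cuts.bed")
    name = profile.substrate.plasmid.name
    with open(bed, "w") as fh:
        for strand, counts, flag in ((TOP, profile.counts_top, "+"),
                                     (BOTTOM, profile.counts_bottom, "-")):
            for pos in np.nonzero(counts)[0]:
                fh.write(f"{name}\t{pos}\t{pos + 1}\tcut_{strand}\t{counts[pos]}\t{flag}\n")
    paths["bed"] = str(bed)

    svg = out_prefix.with_suffix(".polar.svg")
    _polar_plot(profile, svg)
    paths["polar"] = str(svg)

    summary = out_prefix.with_suffix(".summary.json")
    with open(summary, "w") as fh:
        json.dump({
            "totals": profile.totals,
            "plasmid": name,
            "plasmid_length": profile.substrate.N,
            "loop_length": profile.substrate.L,
            "looped_strand": profile.substrate.looped_strand,
            "modal_cut_top": profile.modal_cut(TOP),
            "modal_cut_bottom": profile.modal_cut(BOTTOM),
        }, fh, indent=1)
        fh.write("\n")
    paths["summary"] = str(summary)
    return paths


def _polar_plot(profile: CutProfile, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    substrate = profile.substrate
    n = substrate.N
    theta = 2.0 * math.pi * np.arange(n) / n
    looped = substrate.looped_strand
    series = [
        (looped, "red", "looped strand"),
        (substrate.opposite_strand, "black", "opposite strand"),
    ]
    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(projection="polar")
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    for strand, color, label in series:
        counts = profile.strand_counts(strand)
        ax.plot(theta, counts, color=color, lw=0.8, label=label)
    loop_theta = 2.0 * math.pi * (substrate.loop.insertion_point % n) / n
    top = max(1, int(max(profile.counts_top.max(), profile.counts_bottom.max())))
    ax.plot([loop_theta, loop_theta], [0, top], color="tab:blue", ls="--", lw=1.0,
            label="loop position")
    ax.set_title(f"{substrate.plasmid.name}: strand-specific cuts")
    ax.legend(loc="lower left", bbox_to_anchor=(0.85, 0.9), fontsize=8)
    fig.savefig(path)
    plt.close(fig)
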