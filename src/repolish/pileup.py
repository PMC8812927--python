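"""Pileup construction with homopolymer-aware alignment trimming.

Each alignment is converted into per-position *pieces*: the read content
attributed to one assembly position.  A piece is empty (the read says
this assembly base is deleted), a single base (confirmation or
substitution), or a base followed by inserted bases (insertion relative
to the assembly).

Before contributing pieces, every alignment is trimmed at its end: the
terminal run of identical read bases, plus one more base, is removed
(two bases minimum).  An alignment that ends inside a homopolymer
cannot attest the run's full length — the read may have been cut mid-run
— so those bases are unreliable witnesses for homopolymer-length
errors, which are exactly the errors long-read assemblies are worst at.

Depth is *fractional*: a read segment with ``k`` reported alignments
adds ``1/k`` depth to each position it covers, which approximates the
depth a conventional best-hit alignment would produce.  Piece counts,
by contrast, stay raw integers — inside a collapsed or multi-copy
repeat the full strength of every alignment is wanted as evidence, and
this count/depth asymmetry is what lets errors in repeats be fixed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .io import AlignmentRecord, Assembly, ReadAlignmentGroup

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"

# byte -> base code, 255 for anything outside ACGT
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _b, _i in _BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i


def encode_bases(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0 C=1 G=2 T=3, other=255)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class PileupColumn:
    """Evidence at one assembly position.

    ``piece_counts`` maps piece strings (``""`` for deletion) to raw
    integer counts; ``depth`` is the reciprocal-weighted fractional
    depth.  In repeats the count total may legitimately exceed depth.
    """

    contig: str
    position: int
    ref_base: str
    piece_counts: dict[str, int] = field(default_factory=dict)
    depth: float = 0.0


def terminal_trim_length(aligned_seq: str) -> int:
    """Number of bases to trim from the end of an aligned sequence.

    Returns ``r + 1`` where ``r`` is the length of the terminal run of
    identical bases, so at least two bases are always trimmed; the
    result is capped at the sequence length (a single-letter sequence
    contributes nothing).
    """
    if not aligned_seq:
        raise ValueError("cannot trim an empty aligned sequence")
    last = aligned_seq[-1]
    r = 1
    while r < len(aligned_seq) and aligned_seq[-1 - r] == last:
        r += 1
    return min(r + 1, len(aligned_seq))


def leading_trim_length(aligned_seq: str) -> int:
    """Mirror of :func:`terminal_trim_length` for the alignment start."""
    if not aligned_seq:
        raise ValueError("cannot trim an empty aligned sequence")
    first = aligned_seq[0]
    r = 1
    while r < len(aligned_seq) and aligned_seq[r] == first:
        r += 1
    return min(r + 1, len(aligned_seq))


def walk_cigar(
    record: AlignmentRecord, assembly: Assembly
) -> list[tuple[int, str]]:
    """Convert one resolved alignment into ``(position, piece)`` pairs.

    M/=/X ops yield one single-base piece per reference position; an I
    op appends its bases to the piece of the preceding reference
    position (an insertion before the first reference-consuming op has
    no anchor and is discarded); a D op yields empty pieces at each
    deleted position; S/H contribute nothing.  Positions are strictly
    increasing with exactly one piece per covered position.
    """
    if record.stored_seq is None:
        raise ValueError(f"read {record.query_name!r}: no sequence to walk")
    record.validate(assembly)
    seq = record.stored_seq
    pieces: list[list] = []  # [position, piece-string]
    read_i = 0
    ref_i = record.ref_start
    for op, n in record.cigar:
        if op in "M=X":
            for j in range(n):
                pieces.append([ref_i + j, seq[read_i + j]])
            read_i += n
            ref_i += n
        elif op == "I":
            if pieces:
                pieces[-1][1] += seq[read_i : read_i + n]
            read_i += n
        elif op == "D":
            for j in range(n):
                pieces.append([ref_i + j, ""])
            ref_i += n
        elif op == "S":
            read_i += n
        elif op == "H":
            pass
        else:  # pragma: no cover - validate() rejects these
            raise ValueError(f"unsupported CIGAR op {op!r}")
    return [(p, v) for p, v in pieces]


def trim_pieces(
    pieces: list[tuple[int, str]],
    trim_len: int,
    mode: str = "end_only",
) -> list[tuple[int, str]]:
    """Drop pieces built from the trimmed ends of the aligned sequence.

    The trimmed read suffix is the last *trim_len* read bases consumed
    by the alignment; the first covered position whose piece uses any of
    those bases — and every later position, including trailing deletion
    pieces — is dropped.  In ``both_ends`` mode the mirrored rule is
    applied at the alignment start using the leading run of identical
    bases (the leading trim length is derived from the pieces
    themselves, whose concatenation is the aligned sequence).
    """
    if mode not in ("end_only", "both_ends"):
        raise ValueError(f"unknown trim mode {mode!r}")
    if not pieces:
        return []
    lens = [len(v) for _, v in pieces]
    total = sum(lens)
    threshold = total - trim_len
    if threshold <= 0:
        return []
    kept = []
    consumed = 0
    for (pos, v), n in zip(pieces, lens):
        if n and consumed + n > threshold:
            break
        kept.append((pos, v))
        consumed += n
    if mode == "both_ends" and kept:
        joined = "".join(v for _, v in pieces)
        lead = leading_trim_length(joined)
        consumed = 0
        last_affected = -1
        for i, (_, v) in enumerate(kept):
            if v and consumed < lead:
                last_affected = i
            consumed += len(v)
        kept = kept[last_affected + 1 :]
    return kept


class Pileup:
    """Per-contig pileup: base-count matrices plus a sparse overlay.

    Single-base A/C/G/T pieces live in an ``(L, 4)`` integer matrix;
    empty (deletion) and multi-base (insertion) pieces live in a sparse
    per-position :class:`collections.Counter` overlay, since they are
    rare.  Fractional depth is a float array per contig.
    """

    def __init__(self, assembly: Assembly):
        self.assembly = assembly
        self.base_counts: dict[str, np.ndarray] = {
            name: np.zeros((len(seq), 4), dtype=np.int64)
            for name, seq in assembly.contigs.items()
        }
        self.extra_counts: dict[str, dict[int, Counter]] = {
            name: {} for name in assembly.contigs
        }
        self.depth: dict[str, np.ndarray] = {
            name: np.zeros(len(seq), dtype=np.float64)
            for name, seq in assembly.contigs.items()
        }

    def piece_counts(self, contig: str, position: int) -> dict[str, int]:
        counts: dict[str, int] = {}
        row = self.base_counts[contig][position]
        for i in range(4):
            if row[i]:
                counts[_BASES[i]] = int(row[i])
        overlay = self.extra_counts[contig].get(position)
        if overlay:
            for piece, n in overlay.items():
                counts[piece] = counts.get(piece, 0) + n
        return counts

    def column(self, contig: str, position: int) -> PileupColumn:
        return PileupColumn(
            contig=contig,
            position=position,
            ref_base=self.assembly.contigs[contig][position],
            piece_counts=self.piece_counts(contig, position),
            depth=float(self.depth[contig][position]),
        )

    def columns(self, contig: str) -> list[PileupColumn]:
        return [
            self.column(contig, pos)
            for pos in range(self.assembly.length(contig))
        ]

    def total_depth(self) -> float:
        return float(sum(d.sum() for d in self.depth.values()))


def _add_record_fast(
    pileup: Pileup, record: AlignmentRecord, k: int, trim_mode: str
) -> bool:
    """Vectorised accumulation for indel-free ACGT alignments.

    Returns False when the record needs the generic piece walk.
    """
    # canonical clip–match–clip shape only; anything else walks generically
    lead_clip = 0
    phase = 0  # 0 leading clips, 1 match run, 2 trailing clips
    for op, n in record.cigar:
        if op in "M=X":
            if phase == 2:
                return False
            phase = 1
        elif op in "SH":
            if phase == 0 and op == "S":
                lead_clip += n
            elif phase == 1:
                phase = 2
        else:
            return False
    if phase == 0:
        return True  # no aligned bases at all
    aligned_len = record.ref_consumed()
    seq = record.stored_seq[lead_clip : lead_clip + aligned_len]
    codes = encode_bases(seq)
    if (codes == 255).any():
        return False
    trim = terminal_trim_length(seq)
    lo = leading_trim_length(seq) if trim_mode == "both_ends" else 0
    hi = aligned_len - trim
    if hi <= lo:
        return True
    start = record.ref_start
    rows = np.arange(start + lo, start + hi)
    bc = pileup.base_counts[record.contig]
    bc[rows, codes[lo:hi]] += 1
    pileup.depth[record.contig][start + lo : start + hi] += 1.0 / k
    return True


def _add_record_generic(
    pileup: Pileup, record: AlignmentRecord, k: int, trim_mode: str
) -> None:
    pieces = walk_cigar(record, pileup.assembly)
    if not pieces:
        return
    aligned_seq = "".join(v for _, v in pieces)
    if not aligned_seq:
        return
    trim = terminal_trim_length(aligned_seq)
    kept = trim_pieces(pieces, trim, mode=trim_mode)
    bc = pileup.base_counts[record.contig]
    extra = pileup.extra_counts[record.contig]
    depth = pileup.depth[record.contig]
    frac = 1.0 / k
    for pos, v in kept:
        if len(v) == 1 and v in _BASE_INDEX:
            bc[pos, _BASE_INDEX[v]] += 1
        else:
            extra.setdefault(pos, Counter())[v] += 1
        depth[pos] += frac


def build_pileup(
    assembly: Assembly,
    groups: list[ReadAlignmentGroup],
    trim_mode: str = "end_only",
) -> Pileup:
    """Accumulate all alignment groups into a :class:`Pileup`.

    Each alignment contributes +1 to the piece count and ``+1/k`` depth
    at every retained (post-trim) position, ``k`` being its group's
    alignment count — so counts and depth always describe the same
    evidence set.
    """
    pileup = Pileup(assembly)
    for group in groups:
        k = group.k
        for record in group.records:
            if record.contig not in assembly.contigs:
                raise ValueError(
                    f"read {record.query_name!r}: alignment references "
                    f"unknown contig {record.contig!r}"
                )
            if not _add_record_fast(pileup, record, k, trim_mode):
                _add_record_generic(pileup, record, k, trim_mode)
    return pileup
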