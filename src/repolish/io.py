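"""FASTA and SAM input/output for assembly polishing.

The polisher consumes alignments produced in *all-alignments-per-read*
mode, where an aligner reports every location a read maps to rather than
a single best hit.  Alignments are therefore modelled read-segment-wise:
all alignments of one read segment (R1, R2 or an unpaired read) form a
:class:`ReadAlignmentGroup` whose size ``k`` is that segment's alignment
count.  ``k`` is what turns raw alignments into fractional read depth
downstream.

SAM dialect quirks handled here:

* secondary alignments commonly carry ``*`` in the SEQ column; the
  sequence is recovered from a same-read record that has one,
  reverse-complemented when the strand flags differ;
* supplementary (chimeric) alignments are excluded by default — split
  alignments are rare for short reads against a bacterial assembly and
  complicate per-position evidence extraction.

Coordinates are 0-based half-open throughout; SAM's 1-based POS is
converted at the parsing boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

DNA_BASES = "ACGT"
#: IUPAC ambiguity codes that are replaced by random unambiguous bases on load.
AMBIGUITY_CODES = frozenset("RYSWKMBDHVN")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: CIGAR operations that consume read bases / reference positions.
READ_CONSUMING_OPS = frozenset("M=XIS")
REF_CONSUMING_OPS = frozenset("M=XD")

_PYSAM_OP_CHARS = "MIDNSHP=X"


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved per base)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Assembly:
    """An ordered collection of named uppercase DNA contigs.

    Contig sequences are restricted to A/C/G/T after loading; ambiguity
    codes are replaced at load time (seeded) so that downstream pileup
    arithmetic never meets a non-nucleotide character.
    """

    contigs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.contigs:
            if not name:
                raise ValueError("contig names must be non-empty")

    @property
    def names(self) -> list[str]:
        return list(self.contigs)

    def length(self, name: str) -> int:
        return len(self.contigs[name])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Assembly) and self.contigs == other.contigs


def load_assembly(path: str | Path, seed: int = 0) -> Assembly:
    """Read a FASTA file into an :class:`Assembly`.

    Sequences are uppercased and any IUPAC ambiguity code (e.g. ``N``)
    is replaced by a random unambiguous base drawn from a generator
    seeded with *seed*, so repeated loads are reproducible.  Characters
    outside the nucleotide alphabet are fatal.
    """
    rng = np.random.default_rng(seed)
    contigs: dict[str, str] = {}
    n_replaced = 0
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if not name:
            raise ValueError(f"{path}: FASTA record with empty name")
        if name in contigs:
            raise ValueError(f"{path}: duplicate contig name {name!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - set(DNA_BASES)
        if bad - AMBIGUITY_CODES:
            raise ValueError(
                f"{path}: contig {name!r} contains non-nucleotide "
                f"characters {sorted(bad - AMBIGUITY_CODES)!r}"
            )
        if bad:
            chars = list(seq)
            for i, c in enumerate(chars):
                if c not in DNA_BASES:
                    chars[i] = DNA_BASES[rng.integers(4)]
                    n_replaced += 1
            seq = "".join(chars)
        contigs[name] = seq
    if not contigs:
        raise ValueError(f"{path}: no FASTA records found")
    if n_replaced:
        logger.warning("replaced %d ambiguous bases with random bases", n_replaced)
    return Assembly(contigs)


def write_fasta(assembly: Assembly, path: str | Path, width: int = 70) -> None:
    """Write contigs to *path* in input order, wrapped at *width* columns."""
    with open(path, "w") as fh:
        for name, seq in assembly.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass
class AlignmentRecord:
    """One SAM alignment line.

    ``stored_seq`` is the SEQ column — the read in reference-forward
    orientation — or ``None`` when the record carried ``*``.
    ``segment_index`` distinguishes R1/R2/unpaired so that mates are
    never pooled into one alignment count.
    """

    query_name: str
    segment_index: str  # "1", "2" or "u"
    contig: str | None
    ref_start: int  # 0-based
    cigar: list[tuple[str, int]]
    stored_seq: str | None
    is_reverse: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False
    is_unmapped: bool = False
    nm: int | None = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.query_name, self.segment_index)

    def read_consumed(self) -> int:
        return sum(n for op, n in self.cigar if op in READ_CONSUMING_OPS)

    def ref_consumed(self) -> int:
        return sum(n for op, n in self.cigar if op in REF_CONSUMING_OPS)

    @property
    def ref_end(self) -> int:
        """0-based exclusive end on the reference."""
        return self.ref_start + self.ref_consumed()

    def validate(self, assembly: Assembly | None = None) -> None:
        if self.is_unmapped:
            return
        for op, n in self.cigar:
            if op not in "M=XIDSH":
                raise ValueError(
                    f"read {self.query_name!r}: unsupported CIGAR op {op!r}"
                )
            if n < 1:
                raise ValueError(f"read {self.query_name!r}: CIGAR length < 1")
        if self.stored_seq is not None:
            if self.read_consumed() != len(self.stored_seq):
                raise ValueError(
                    f"read {self.query_name!r}: CIGAR consumes "
                    f"{self.read_consumed()} read bases but SEQ has "
                    f"{len(self.stored_seq)}"
                )
        if assembly is not None:
            if self.contig not in assembly.contigs:
                raise ValueError(
                    f"read {self.query_name!r}: unknown contig {self.contig!r}"
                )
            if self.ref_end > assembly.length(self.contig):
                raise ValueError(
                    f"read {self.query_name!r}: alignment overruns contig "
                    f"{self.contig!r} ({self.ref_end} > "
                    f"{assembly.length(self.contig)})"
                )


@dataclass
class ReadAlignmentGroup:
    """All usable alignments of one read segment; ``k`` is its alignment count."""

    key: tuple[str, str]
    records: list[AlignmentRecord]

    @property
    def k(self) -> int:
        return len(self.records)


def _segment_index(aln: pysam.AlignedSegment) -> str:
    if aln.is_paired:
        return "1" if aln.is_read1 else "2"
    return "u"


def parse_sam(path: str | Path, assembly: Assembly | None = None) -> list[AlignmentRecord]:
    """Parse a SAM text file into :class:`AlignmentRecord` objects.

    When *assembly* is given, ``@SQ`` names/lengths and per-record
    coordinates are validated against it.  Optional tags are ignored
    apart from ``NM``, kept for the optional mismatch filter.
    """
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        if assembly is not None:
            for name, length in zip(sam.references, sam.lengths):
                if name not in assembly.contigs:
                    raise ValueError(f"{path}: @SQ contig {name!r} not in assembly")
                if length != assembly.length(name):
                    raise ValueError(
                        f"{path}: @SQ length for {name!r} is {length}, "
                        f"assembly has {assembly.length(name)}"
                    )
        iterator = enumerate(sam)
        while True:
            try:
                i, aln = next(iterator)
            except StopIteration:
                break
            except (OSError, ValueError) as exc:
                # htslib reports the offending SAM line on stderr
                raise ValueError(f"{path}: malformed SAM: {exc}") from exc
            try:
                if aln.is_unmapped:
                    rec = AlignmentRecord(
                        query_name=aln.query_name,
                        segment_index=_segment_index(aln),
                        contig=None,
                        ref_start=-1,
                        cigar=[],
                        stored_seq=aln.query_sequence,
                        is_unmapped=True,
                    )
                else:
                    cigar = [
                        (_PYSAM_OP_CHARS[op], n) for op, n in aln.cigartuples
                    ]
                    rec = AlignmentRecord(
                        query_name=aln.query_name,
                        segment_index=_segment_index(aln),
                        contig=aln.reference_name,
                        ref_start=aln.reference_start,
                        cigar=cigar,
                        stored_seq=aln.query_sequence,
                        is_reverse=aln.is_reverse,
                        is_secondary=aln.is_secondary,
                        is_supplementary=aln.is_supplementary,
                        nm=aln.get_tag("NM") if aln.has_tag("NM") else None,
                    )
                    rec.validate(assembly)
            except ValueError as exc:
                raise ValueError(f"{path}: alignment record {i + 1}: {exc}") from exc
            records.append(rec)
    return records


def group_and_resolve(
    records: list[AlignmentRecord],
    include_supplementary: bool = False,
) -> list[ReadAlignmentGroup]:
    """Group alignments per read segment and repair missing sequences.

    Unmapped records (and, by default, supplementary ones) are dropped.
    Within a group, a record whose SEQ was ``*`` receives the sequence
    of a same-group record that has one, reverse-complemented when the
    two records map to opposite strands.  Groups in which no record
    carries a sequence cannot contribute evidence and are dropped with a
    warning tally — never fatally, since some aligners emit such
    orphans.
    """
    grouped: dict[tuple[str, str], list[AlignmentRecord]] = {}
    for rec in records:
        if rec.is_unmapped:
            continue
        if rec.is_supplementary and not include_supplementary:
            continue
        grouped.setdefault(rec.key, []).append(rec)

    groups: list[ReadAlignmentGroup] = []
    n_dropped_groups = 0
    n_dropped_records = 0
    for key, recs in grouped.items():
        donor = next((r for r in recs if r.stored_seq is not None), None)
        if donor is None:
            n_dropped_groups += 1
            continue
        resolved: list[AlignmentRecord] = []
        for rec in recs:
            if rec.stored_seq is None:
                seq = donor.stored_seq
                if rec.is_reverse != donor.is_reverse:
                    seq = reverse_complement(seq)
                rec = replace(rec, stored_seq=seq)
            if rec.read_consumed() != len(rec.stored_seq):
                # e.g. a hard-clipped record whose donor is full length
                n_dropped_records += 1
                continue
            resolved.append(rec)
        if resolved:
            groups.append(ReadAlignmentGroup(key=key, records=resolved))
        else:
            n_dropped_groups += 1
    if n_dropped_groups:
        logger.warning(
            "dropped %d read group(s) with no resolvable sequence", n_dropped_groups
        )
    if n_dropped_records:
        logger.warning(
            "dropped %d record(s) whose CIGAR did not match the resolved "
            "sequence length",
            n_dropped_records,
        )
    return groups
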