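"""Reference-based assembly assessment.

Accuracy is measured by a unit-cost global (Needleman–Wunsch) alignment
of the assembly to its reference, computed with edlib: the error count
is the number of non-matching alignment columns, identity is matching
columns over alignment length, and the Phred-scaled quality is
``Q = -10 * log10(1 - identity)``.

Errors are typed (substitution / insertion / deletion) and attributed
to repeat or non-repeat regions.  Repeat regions are defined
operationally, the way a short-read aligner sees them: simulate deep
error-free reads from the reference, align them in all-per-read mode,
and mark every position covered by a read that aligned to more than one
place.

A polisher's effect is summarised per reference position as a confusion
matrix: an error it fixed (TP), a correct base it left alone (TN), an
error it missed (FN), or an error it introduced (FP).  Both the
unpolished and polished sequences are projected onto reference
coordinates through pairwise global alignments; insertion columns are
attributed to their left-anchoring reference position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import edlib

from .io import Assembly
from .sim import exhaustive_align, simulate_reads
from .sim import _parse_edlib_cigar  # shared cigar tokenizer

#: numeric stand-in for a perfect (infinite) Q-score in tables
DEFAULT_QSCORE_CAP = 90.0


@dataclass
class AssessmentReport:
    error_count: int
    identity: float
    qscore: float
    alignment_length: int
    errors_by_type: dict[str, int] = field(default_factory=dict)
    errors_in_repeat: int | None = None
    errors_outside_repeat: int | None = None


@dataclass
class RepeatAnnotation:
    """Per-contig sorted, merged 0-based half-open intervals."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for contig, ivs in self.intervals.items():
            self.intervals[contig] = merge_intervals(ivs)

    def contains(self, contig: str, position: int) -> bool:
        return any(
            s <= position < e for s, e in self.intervals.get(contig, [])
        )

    def total_length(self) -> int:
        return sum(e - s for ivs in self.intervals.values() for s, e in ivs)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for contig, ivs in self.intervals.items():
                for s, e in ivs:
                    fh.write(f"{contig}\t{s}\t{e}\n")

    @classmethod
    def from_bed(cls, path: str | Path) -> "RepeatAnnotation":
        intervals: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                contig, s, e = line.split()[:3]
                intervals.setdefault(contig, []).append((int(s), int(e)))
        return cls(intervals)


@dataclass
class ConfusionMatrix:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def merge_intervals(
    intervals: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


_OP_LABEL = {"=": "match", "X": "sub", "I": "ins", "D": "del"}


def global_align(
    seq_a: str, seq_b: str
) -> tuple[int, list[tuple[str, int | None, int | None]]]:
    """Unit-cost global alignment of *seq_a* against *seq_b*.

    Returns the edit distance and the aligned columns as
    ``(label, a_pos, b_pos)`` tuples with labels match/sub/ins/del;
    ``ins`` is a base of *seq_a* absent from *seq_b*, ``del`` the
    converse.  The distance equals the number of non-match columns.
    """
    if not seq_a or not seq_b:
        raise ValueError("global alignment needs two non-empty sequences")
    res = edlib.align(seq_a, seq_b, mode="NW", task="path")
    columns: list[tuple[str, int | None, int | None]] = []
    a_i = b_i = 0
    for op, n in _parse_edlib_cigar(res["cigar"]):
        label = _OP_LABEL[op]
        for _ in range(n):
            if op in "=X":
                columns.append((label, a_i, b_i))
                a_i += 1
                b_i += 1
            elif op == "I":
                columns.append((label, a_i, None))
                a_i += 1
            else:
                columns.append((label, None, b_i))
                b_i += 1
    return res["editDistance"], columns


def _pair_contigs(a: Assembly, b: Assembly) -> list[tuple[str, str]]:
    if set(a.contigs) == set(b.contigs):
        return [(n, n) for n in a.names]
    if len(a.contigs) == 1 and len(b.contigs) == 1:
        return [(a.names[0], b.names[0])]
    raise ValueError(
        "cannot pair contigs: names differ and the assemblies are not "
        "single-contig"
    )


def qscore_from_identity(
    identity: float, cap: float = DEFAULT_QSCORE_CAP
) -> float:
    if identity >= 1.0:
        return cap
    return min(cap, -10.0 * math.log10(1.0 - identity))


def assess(
    polished: Assembly,
    reference: Assembly,
    repeats: RepeatAnnotation | None = None,
    qscore_cap: float = DEFAULT_QSCORE_CAP,
) -> AssessmentReport:
    """Globally align each contig to its reference and count errors.

    When a repeat annotation is supplied, each error column is mapped to
    a reference coordinate (insertions to their left anchor, deletions
    to the deleted reference position) and tested for membership.
    """
    total_cols = 0
    matches = 0
    by_type = {"substitution": 0, "insertion": 0, "deletion": 0}
    in_repeat = 0
    for a_name, r_name in _pair_contigs(polished, reference):
        _, columns = global_align(
            polished.contigs[a_name], reference.contigs[r_name]
        )
        total_cols += len(columns)
        last_ref = 0
        for label, _a_pos, b_pos in columns:
            if b_pos is not None:
                last_ref = b_pos
            if label == "match":
                matches += 1
                continue
            kind = {"sub": "substitution", "ins": "insertion", "del": "deletion"}[
                label
            ]
            by_type[kind] += 1
            if repeats is not None:
                anchor = b_pos if b_pos is not None else last_ref
                if repeats.contains(r_name, anchor):
                    in_repeat += 1
    error_count = total_cols - matches
    identity = matches / total_cols if total_cols else 1.0
    return AssessmentReport(
        error_count=error_count,
        identity=identity,
        qscore=qscore_from_identity(identity, qscore_cap),
        alignment_length=total_cols,
        errors_by_type=by_type,
        errors_in_repeat=in_repeat if repeats is not None else None,
        errors_outside_repeat=(
            error_count - in_repeat if repeats is not None else None
        ),
    )


def find_repeats(
    reference: Assembly,
    read_length: int = 150,
    depth: float = 300.0,
    seed: int = 0,
    max_edits: int = 2,
) -> RepeatAnnotation:
    """Detect repeats as regions where simulated reads multi-map.

    Deep error-free unpaired reads are simulated from the reference and
    aligned in all-per-read mode; every reference position covered by a
    read with two or more alignments is flagged, and flagged runs are
    merged into intervals.  This marks exactly the regions in which
    best-hit alignment is ambiguous at the chosen read length.
    """
    reads = simulate_reads(
        reference, read_length=read_length, depth=depth, seed=seed
    )
    read_hits = exhaustive_align(
        reads, reference, max_edits=max_edits, mode="all", seed=seed
    )
    flagged = {
        name: bytearray(reference.length(name)) for name in reference.names
    }
    for rh in read_hits:
        if len(rh.hits) < 2:
            continue
        for hit in rh.hits:
            flags = flagged[hit.contig]
            for i in range(hit.start, hit.end):
                flags[i] = 1
    intervals: dict[str, list[tuple[int, int]]] = {}
    for name, flags in flagged.items():
        ivs: list[tuple[int, int]] = []
        start = None
        for i, f in enumerate(flags):
            if f and start is None:
                start = i
            elif not f and start is not None:
                ivs.append((start, i))
                start = None
        if start is not None:
            ivs.append((start, len(flags)))
        if ivs:
            intervals[name] = ivs
    return RepeatAnnotation(intervals)


def _reference_alleles(assembly_seq: str, reference_seq: str) -> list[str]:
    """Project an assembly onto reference coordinates.

    Each reference position receives the assembly content aligned over
    it: its base (match or substitution) plus any insertion anchored to
    it, or the empty string where the assembly deleted it.  A leading
    insertion, which has no left anchor, is folded into position 0.
    """
    _, columns = global_align(assembly_seq, reference_seq)
    alleles = [""] * len(reference_seq)
    last_ref: int | None = None
    prefix = ""
    for label, a_pos, b_pos in columns:
        if label in ("match", "sub"):
            alleles[b_pos] = assembly_seq[a_pos]
            last_ref = b_pos
        elif label == "del":
            alleles[b_pos] = ""
            last_ref = b_pos
        else:  # ins
            if last_ref is None:
                prefix += assembly_seq[a_pos]
            else:
                alleles[last_ref] += assembly_seq[a_pos]
    if prefix:
        alleles[0] = prefix + alleles[0]
    return alleles


def confusion(
    reference: Assembly,
    unpolished: Assembly,
    polished: Assembly,
) -> ConfusionMatrix:
    """Classify the polisher's effect at every reference position.

    TP: an unpolished error the polisher fixed; TN: a correct base left
    alone; FN: an error that persists; FP: an error the polisher
    introduced.  The four counts sum to the reference length.
    """
    cm = ConfusionMatrix()
    pairs_u = dict(
        (r, a) for a, r in _pair_contigs(unpolished, reference)
    )
    pairs_p = dict(
        (r, a) for a, r in _pair_contigs(polished, reference)
    )
    for r_name in reference.names:
        ref_seq = reference.contigs[r_name]
        alleles_u = _reference_alleles(
            unpolished.contigs[pairs_u[r_name]], ref_seq
        )
        alleles_p = _reference_alleles(
            polished.contigs[pairs_p[r_name]], ref_seq
        )
        for p, ref_base in enumerate(ref_seq):
            ok_u = alleles_u[p] == ref_base
            ok_p = alleles_p[p] == ref_base
            if ok_u and ok_p:
                cm.tn += 1
            elif ok_u:
                cm.fp += 1
            elif ok_p:
                cm.tp += 1
            else:
                cm.fn += 1
    return cm


def write_report_tsv(report: AssessmentReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "error_count\tidentity\tqscore\talignment_length\t"
            "substitutions\tinsertions\tdeletions\t"
            "errors_in_repeat\terrors_outside_repeat\n"
        )
        fh.write(
            f"{report.error_count}\t{report.identity:.6f}\t"
            f"{report.qscore:.2f}\t{report.alignment_length}\t"
            f"{report.errors_by_type.get('substitution', 0)}\t"
            f"{report.errors_by_type.get('insertion', 0)}\t"
            f"{report.errors_by_type.get('deletion', 0)}\t"
            f"{'' if report.errors_in_repeat is None else report.errors_in_repeat}\t"
            f"{'' if report.errors_outside_repeat is None else report.errors_outside_repeat}\n"
        )


def write_confusion_tsv(cm: ConfusionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tp\ttn\tfp\tfn\n")
        fh.write(f"{cm.tp}\t{cm.tn}\t{cm.fp}\t{cm.fn}\n")
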