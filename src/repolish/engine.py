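"""The conservative threshold-based polishing rule.

At each assembly position two count thresholds are derived from the
fractional read depth ``d``:

* valid threshold  ``T_v = max(min_depth, fraction_valid * d)``
* invalid threshold ``T_i = fraction_invalid * d``

A piece is *valid* when its count is strictly greater than ``T_v`` and
*invalid* when strictly less than ``T_i``; counts between the two
thresholds fall in a dead zone.  The assembly base is changed only when
there is exactly one valid piece, it differs from the current base, and
every other observed piece is invalid.  Any ambiguity — no valid piece,
several valid pieces, or anything in the dead zone — leaves the base
untouched, which is what makes the polisher safe to run on an already
correct assembly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    AlignmentRecord,
    Assembly,
    group_and_resolve,
    load_assembly,
    parse_sam,
    write_fasta,
)
from .pileup import Pileup, PileupColumn, build_pileup, encode_bases

logger = logging.getLogger(__name__)


@dataclass
class PolishParams:
    """Tunable parameters of one polishing round.

    Defaults follow the rule "more than half the depth, and at least
    five reads, must agree on the one alternative"; ``fraction_invalid``
    caps how much competing evidence is tolerated.
    """

    fraction_valid: float = 0.5
    fraction_invalid: float = 0.2
    min_depth: int = 5
    trim_mode: str = "end_only"
    max_errors: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fraction_invalid <= self.fraction_valid <= 1):
            raise ValueError(
                "need 0 < fraction_invalid <= fraction_valid <= 1, got "
                f"{self.fraction_invalid} / {self.fraction_valid}"
            )
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        if self.trim_mode not in ("end_only", "both_ends"):
            raise ValueError(f"unknown trim mode {self.trim_mode!r}")


@dataclass
class ChangeRecord:
    """One applied edit, in pre-polish coordinates."""

    contig: str
    position: int
    old_base: str
    new_piece: str
    depth: float
    count: int
    classification: str  # substitution / insertion / deletion

    def __post_init__(self) -> None:
        expected = (
            "deletion"
            if not self.new_piece
            else "substitution"
            if len(self.new_piece) == 1
            else "insertion"
        )
        if self.classification != expected:
            raise ValueError(
                f"classification {self.classification!r} inconsistent with "
                f"piece {self.new_piece!r}"
            )


def thresholds(depth: float, params: PolishParams) -> tuple[float, float]:
    """(valid, invalid) count thresholds at a position of given depth."""
    return (
        max(float(params.min_depth), params.fraction_valid * depth),
        params.fraction_invalid * depth,
    )


def classify_column(
    column: PileupColumn, params: PolishParams
) -> tuple[list[str], list[str], list[str]]:
    """Split a column's observed pieces into (valid, invalid, neither).

    Both comparisons are strict, so a count sitting exactly on a
    threshold lands in the dead zone.  Pieces within each class are
    ordered by descending count, then lexically, for determinism.
    """
    t_valid, t_invalid = thresholds(column.depth, params)
    valid, invalid, neither = [], [], []
    items = sorted(column.piece_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    for piece, count in items:
        if count > t_valid:
            valid.append(piece)
        elif count < t_invalid:
            invalid.append(piece)
        else:
            neither.append(piece)
    return valid, invalid, neither


def decide_change(
    column: PileupColumn, params: PolishParams
) -> ChangeRecord | None:
    """Apply the single-unambiguous-alternative rule to one column."""
    valid, _invalid, neither = classify_column(column, params)
    if len(valid) != 1 or neither:
        return None
    piece = valid[0]
    if piece == column.ref_base:
        return None
    classification = (
        "deletion" if not piece else "substitution" if len(piece) == 1 else "insertion"
    )
    return ChangeRecord(
        contig=column.contig,
        position=column.position,
        old_base=column.ref_base,
        new_piece=piece,
        depth=column.depth,
        count=column.piece_counts[piece],
        classification=classification,
    )


def _candidate_positions(pileup: Pileup, contig: str) -> np.ndarray:
    """Positions where a change is even conceivable: any non-reference vote.

    A change needs a valid piece differing from the reference base, so
    positions whose only counted piece is the reference base itself can
    be skipped wholesale.
    """
    bc = pileup.base_counts[contig]
    ref_codes = encode_bases(pileup.assembly.contigs[contig])
    total = bc.sum(axis=1)
    ref_count = np.where(
        ref_codes < 4, bc[np.arange(len(ref_codes)), np.minimum(ref_codes, 3)], 0
    )
    candidates = set(np.nonzero(total - ref_count)[0].tolist())
    candidates.update(pileup.extra_counts[contig].keys())
    return np.array(sorted(candidates), dtype=np.int64)


def count_dead_zone_positions(pileup: Pileup, params: PolishParams) -> int:
    """Number of positions holding at least one piece in the dead zone."""
    n = 0
    for contig in pileup.assembly.names:
        bc = pileup.base_counts[contig]
        d = pileup.depth[contig]
        t_valid = np.maximum(float(params.min_depth), params.fraction_valid * d)
        t_invalid = params.fraction_invalid * d
        present = bc > 0
        dead = present & ~(bc > t_valid[:, None]) & ~(bc < t_invalid[:, None])
        flags = dead.any(axis=1)
        for pos, overlay in pileup.extra_counts[contig].items():
            if flags[pos]:
                continue
            tv, ti = t_valid[pos], t_invalid[pos]
            if any(not (c > tv or c < ti) for c in overlay.values()):
                flags[pos] = True
        n += int(flags.sum())
    return n


def apply_changes(
    assembly: Assembly,
    pileup: Pileup,
    params: PolishParams,
) -> tuple[Assembly, list[ChangeRecord]]:
    """Evaluate every column and rebuild the polished contigs.

    Zero-depth positions always keep the assembly base.  The change list
    is ordered by contig (input order) then position; the polished
    contig is the concatenation of new pieces where changed and
    reference bases elsewhere.
    """
    changes: list[ChangeRecord] = []
    polished: dict[str, str] = {}
    for contig, seq in assembly.contigs.items():
        contig_changes: list[ChangeRecord] = []
        for pos in _candidate_positions(pileup, contig):
            change = decide_change(pileup.column(contig, int(pos)), params)
            if change is not None:
                contig_changes.append(change)
        parts = list(seq)
        for change in contig_changes:
            parts[change.position] = change.new_piece
        polished[contig] = "".join(parts)
        changes.extend(contig_changes)
    return Assembly(polished), changes


def filter_alignments(
    records: list[AlignmentRecord], max_errors: int | None
) -> list[AlignmentRecord]:
    """Optionally drop alignments whose NM edit distance exceeds *max_errors*.

    Disabled (``None``) is the identity; the polisher's threshold rule
    already tolerates noisy alignments, so this is purely an optional
    guard for pathological inputs.
    """
    if max_errors is None:
        return records
    kept = []
    for rec in records:
        if rec.is_unmapped:
            kept.append(rec)
            continue
        if rec.nm is None:
            raise ValueError(
                f"read {rec.query_name!r} has no NM tag; re-align with an "
                "aligner that reports NM or disable the max-errors filter"
            )
        if rec.nm <= max_errors:
            kept.append(rec)
    return kept


def write_changes_tsv(changes: list[ChangeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tpos\told\tnew\tdepth\tcount\tclass\n")
        for c in changes:
            new = c.new_piece if c.new_piece else "-"
            fh.write(
                f"{c.contig}\t{c.position}\t{c.old_base}\t{new}\t"
                f"{c.depth:.6f}\t{c.count}\t{c.classification}\n"
            )


def write_debug_tsv(
    pileup: Pileup,
    changes: list[ChangeRecord],
    path: str | Path,
) -> None:
    """Per-position dump: depth, piece counts and the polishing outcome."""
    changed = {(c.contig, c.position): c for c in changes}
    with open(path, "w") as fh:
        fh.write("contig\tpos\tref\tdepth\tpieces\tstatus\n")
        for contig in pileup.assembly.names:
            seq = pileup.assembly.contigs[contig]
            depth = pileup.depth[contig]
            for pos in range(len(seq)):
                counts = pileup.piece_counts(contig, pos)
                pieces = ";".join(
                    f"{p if p else '-'}:{n}"
                    for p, n in sorted(
                        counts.items(), key=lambda kv: (-kv[1], kv[0])
                    )
                )
                change = changed.get((contig, pos))
                status = f"changed:{change.classification}" if change else "kept"
                fh.write(
                    f"{contig}\t{pos}\t{seq[pos]}\t{depth[pos]:.6f}\t"
                    f"{pieces or '-'}\t{status}\n"
                )


def polish_round(
    assembly_path: str | Path,
    sam_paths: list[str | Path],
    params: PolishParams | None = None,
    out_fasta: str | Path | None = None,
    changes_tsv: str | Path | None = None,
    debug_tsv: str | Path | None = None,
) -> dict:
    """Run one full polishing round from files on disk.

    Multiple SAM inputs (e.g. R1 and R2 aligned separately, each in
    all-alignments mode) are concatenated before grouping.  Further
    rounds require re-aligning reads against the polished output.
    Returns a summary with per-contig change counts by class and the
    number of dead-zone positions.
    """
    params = params or PolishParams()
    assembly = load_assembly(assembly_path, seed=params.seed)
    records: list[AlignmentRecord] = []
    for path in sam_paths:
        records.extend(parse_sam(path, assembly=assembly))
    records = filter_alignments(records, params.max_errors)
    groups = group_and_resolve(records)
    if not groups:
        logger.warning("no usable alignments; assembly left unchanged")
    pileup = build_pileup(assembly, groups, trim_mode=params.trim_mode)
    polished, changes = apply_changes(assembly, pileup, params)

    per_contig: dict[str, dict[str, int]] = {}
    for contig in assembly.names:
        per_contig[contig] = {"substitution": 0, "insertion": 0, "deletion": 0}
    for c in changes:
        per_contig[c.contig][c.classification] += 1
    summary = {
        "contigs": len(assembly.contigs),
        "alignments": sum(g.k for g in groups),
        "read_segments": len(groups),
        "changes": len(changes),
        "per_contig": per_contig,
        "dead_zone_positions": count_dead_zone_positions(pileup, params),
    }
    for contig, counts in per_contig.items():
        logger.info(
            "%s: %d substitution(s), %d insertion(s), %d deletion(s)",
            contig,
            counts["substitution"],
            counts["insertion"],
            counts["deletion"],
        )

    if out_fasta is not None:
        write_fasta(polished, out_fasta)
    if changes_tsv is not None:
        write_changes_tsv(changes, changes_tsv)
    if debug_tsv is not None:
        write_debug_tsv(pileup, changes, debug_tsv)
    summary["polished"] = polished
    summary["change_records"] = changes
    return summary
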