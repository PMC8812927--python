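"""Shared fixture builders for the test suite."""

from __future__ import annotations

import re

import numpy as np
import pytest

from repolish import (
    Assembly,
    AlignmentRecord,
    PolishParams,
    ReadAlignmentGroup,
    write_fasta,
    write_sam,
)
from repolish.engine import polish_round
from repolish.sim import plant_benchmark_errors as plant_targeted_errors

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    return [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]


def make_record(
    seq: str | None,
    cigar: str,
    ref_start: int = 0,
    contig: str = "c1",
    name: str = "r1",
    segment: str = "u",
    **flags,
) -> AlignmentRecord:
    return AlignmentRecord(
        query_name=name,
        segment_index=segment,
        contig=contig,
        ref_start=ref_start,
        cigar=parse_cigar(cigar),
        stored_seq=seq,
        **flags,
    )


def single_groups(records: list[AlignmentRecord]) -> list[ReadAlignmentGroup]:
    """One group of k=1 per record, for hand-built pileup fixtures."""
    return [
        ReadAlignmentGroup(key=(f"{r.query_name}#{i}", r.segment_index), records=[r])
        for i, r in enumerate(records)
    ]


def hits_to_groups(read_hits) -> list[ReadAlignmentGroup]:
    """Convert aligner output straight to groups, skipping the SAM files."""
    from repolish import reverse_complement

    groups = []
    for rh in read_hits:
        recs = []
        for h in rh.hits:
            q = reverse_complement(rh.read.seq) if h.is_reverse else rh.read.seq
            recs.append(
                AlignmentRecord(
                    query_name=rh.read.name,
                    segment_index=rh.read.segment,
                    contig=h.contig,
                    ref_start=h.start,
                    cigar=h.cigar,
                    stored_seq=q,
                    is_reverse=h.is_reverse,
                )
            )
        if recs:
            groups.append(
                ReadAlignmentGroup(key=(rh.read.name, rh.read.segment), records=recs)
            )
    return groups




def polish_via_files(
    assembly: Assembly,
    read_hits,
    tmp_path,
    params: PolishParams | None = None,
    tag: str = "x",
) -> dict:
    """Round-trip through FASTA/SAM files and run one polishing round."""
    asm_path = tmp_path / f"{tag}_assembly.fasta"
    sam_path = tmp_path / f"{tag}_alignments.sam"
    out_path = tmp_path / f"{tag}_polished.fasta"
    write_fasta(assembly, asm_path)
    write_sam(read_hits, assembly, sam_path)
    return polish_round(
        asm_path,
        [sam_path],
        params or PolishParams(),
        out_fasta=out_path,
        changes_tsv=tmp_path / f"{tag}_changes.tsv",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
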