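"""Self-contained synthetic fixtures for polishing experiments.

The module builds everything a polishing run needs without touching the
network or an external aligner:

* bacterial-like random genomes with exact repeats planted at recorded
  locations (repeats are where best-hit alignment starves errors of
  coverage, so fixtures must contain them);
* error-injected copies of a genome with a ground-truth error list —
  substitutions, homopolymer indels (which extend or contract an
  existing run of identical bases) and non-homopolymer indels, each
  class at its own per-base rate;
* error-free short reads tiling the genome to a target mean depth;
* an exhaustive edit-distance aligner which reports, for each read and
  strand, every locally optimal location within a maximum edit
  distance.  In ``all`` mode one primary alignment plus secondary
  records (with ``*`` sequences, as real aligners emit) are produced;
  in ``best_only`` mode just the primary — the two modes reproduce the
  all-per-read versus best-hit alignment behaviours whose contrast the
  polisher exploits.

The aligner is seed-and-verify: exact k-mer seeds locate candidate loci
(pigeonhole over ``max_edits + 2`` seeds guarantees a hit for any read
within the edit budget) and each candidate window is verified with an
edit-distance alignment, so the reported distances are exact.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np
import pysam

from .io import Assembly, reverse_complement

DNA_BASES = "ACGT"

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass
class ErrorProfile:
    """Per-base error-injection rates, one per error class.

    The default 1e-4 per class mirrors typical residual error levels in
    a long-read assembly after long-read polishing (~0.01% per class).
    """

    rate_substitution: float = 1e-4
    rate_homopolymer_insertion: float = 1e-4
    rate_homopolymer_deletion: float = 1e-4
    rate_other_indel: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "rate_substitution",
            "rate_homopolymer_insertion",
            "rate_homopolymer_deletion",
            "rate_other_indel",
        ):
            rate = getattr(self, name)
            if not (0 <= rate <= 0.01):
                raise ValueError(f"{name}={rate} outside [0, 0.01]")


@dataclass
class PlantedError:
    """One injected error, in clean-reference coordinates.

    For insertions ``ref_allele`` is empty and ``alt_allele`` is the
    base inserted immediately after ``position``; for deletions
    ``alt_allele`` is empty.
    """

    contig: str
    position: int
    type: str  # sub / hp_ins / hp_del / other_ins / other_del
    ref_allele: str
    alt_allele: str
    in_repeat: bool = False


def random_sequence(length: int, rng: np.random.Generator) -> str:
    codes = rng.integers(0, 4, size=length)
    return "".join(DNA_BASES[c] for c in codes)


def make_genome(
    length: int,
    repeat_length: int = 0,
    repeat_copies: int = 0,
    seed: int = 0,
    name: str = "chromosome",
) -> tuple[Assembly, list[tuple[int, int]]]:
    """Random genome with ``repeat_copies`` exact copies of one segment.

    Copies are planted at non-overlapping random positions; the
    0-based half-open intervals are returned alongside the assembly.
    """
    rng = np.random.default_rng(seed)
    if repeat_copies and repeat_copies * repeat_length >= length:
        raise ValueError(
            f"cannot fit {repeat_copies} x {repeat_length} bp repeats "
            f"in a {length} bp genome"
        )
    seq = list(random_sequence(length, rng))
    intervals: list[tuple[int, int]] = []
    if repeat_copies:
        repeat = random_sequence(repeat_length, rng)
        for _ in range(10000):
            starts = sorted(
                int(rng.integers(0, length - repeat_length + 1))
                for _ in range(repeat_copies)
            )
            if all(
                b - a >= repeat_length for a, b in zip(starts, starts[1:])
            ):
                break
        else:
            raise ValueError("could not place non-overlapping repeat copies")
        for s in starts:
            seq[s : s + repeat_length] = repeat
            intervals.append((s, s + repeat_length))
    return Assembly({name: "".join(seq)}), intervals


def _homopolymer_mask(seq: str) -> np.ndarray:
    """True at positions belonging to a run of >= 2 identical bases."""
    a = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    mask = np.zeros(len(a), dtype=bool)
    if len(a) > 1:
        same = a[1:] == a[:-1]
        mask[1:] |= same
        mask[:-1] |= same
    return mask


def _in_intervals(pos: int, intervals: list[tuple[int, int]]) -> bool:
    return any(s <= pos < e for s, e in intervals)


def plant_errors(assembly: Assembly, errors: list[PlantedError]) -> Assembly:
    """Apply a list of errors (clean-reference coordinates) to contigs.

    Errors are applied from the highest position downward so that each
    stated position stays valid while editing.
    """
    mutated = dict(assembly.contigs)
    for err in sorted(errors, key=lambda e: (e.contig, -e.position)):
        chars = list(mutated[err.contig])
        p = err.position
        if err.type == "sub":
            if chars[p] != err.ref_allele:
                raise ValueError(f"ref allele mismatch at {err.contig}:{p}")
            chars[p] = err.alt_allele
        elif err.type.endswith("_ins"):
            chars[p] = chars[p] + err.alt_allele
        elif err.type.endswith("_del"):
            if chars[p] != err.ref_allele:
                raise ValueError(f"ref allele mismatch at {err.contig}:{p}")
            del chars[p]
        else:
            raise ValueError(f"unknown error type {err.type!r}")
        mutated[err.contig] = "".join(chars)
    return Assembly(mutated)


def inject_errors(
    assembly: Assembly,
    profile: ErrorProfile,
    repeat_intervals: list[tuple[int, int]] | None = None,
) -> tuple[Assembly, list[PlantedError]]:
    """Inject random errors of all four classes into a copy of *assembly*.

    The number of events per class is binomial in the contig length at
    the class rate; event sites are then drawn uniformly from the
    positions eligible for that class (homopolymer indels need a run of
    at least two identical bases, non-homopolymer indels must avoid
    such runs).  The ground-truth list comes back sorted by position in
    clean-reference coordinates, with ``in_repeat`` set from the planted
    repeat intervals.
    """
    rng = np.random.default_rng(profile.seed)
    repeat_intervals = repeat_intervals or []
    all_errors: list[PlantedError] = []
    for contig, seq in assembly.contigs.items():
        length = len(seq)
        hp = _homopolymer_mask(seq)
        hp_positions = np.nonzero(hp)[0]
        other_positions = np.nonzero(~hp)[0]
        all_positions = np.arange(length)
        used: set[int] = set()
        classes = [
            ("sub", profile.rate_substitution, all_positions),
            ("hp_ins", profile.rate_homopolymer_insertion, hp_positions),
            ("hp_del", profile.rate_homopolymer_deletion, hp_positions),
            ("other", profile.rate_other_indel, other_positions),
        ]
        for kind, rate, eligible in classes:
            n_events = int(rng.binomial(length, rate))
            n_events = min(n_events, len(eligible))
            if n_events == 0:
                continue
            sites = rng.choice(eligible, size=n_events, replace=False)
            for p in sorted(int(s) for s in sites):
                if p in used:
                    continue
                used.add(p)
                base = seq[p]
                if kind == "sub":
                    alt = DNA_BASES[
                        (DNA_BASES.index(base) + 1 + int(rng.integers(3))) % 4
                    ]
                    err_type, ref_a, alt_a = "sub", base, alt
                elif kind == "hp_ins":
                    err_type, ref_a, alt_a = "hp_ins", "", base
                elif kind == "hp_del":
                    err_type, ref_a, alt_a = "hp_del", base, ""
                else:  # non-homopolymer indel: insertion or deletion, 50/50
                    if rng.integers(2):
                        choices = [
                            b
                            for b in DNA_BASES
                            if b != base
                            and (p + 1 >= length or b != seq[p + 1])
                        ]
                        alt = choices[int(rng.integers(len(choices)))]
                        err_type, ref_a, alt_a = "other_ins", "", alt
                    else:
                        err_type, ref_a, alt_a = "other_del", base, ""
                all_errors.append(
                    PlantedError(
                        contig=contig,
                        position=p,
                        type=err_type,
                        ref_allele=ref_a,
                        alt_allele=alt_a,
                        in_repeat=_in_intervals(p, repeat_intervals),
                    )
                )
    all_errors.sort(key=lambda e: (e.contig, e.position))
    return plant_errors(assembly, all_errors), all_errors


def find_homopolymer(seq: str, start: int, stop: int) -> int:
    """First position of a run of >= 2 identical bases in [start, stop)."""
    for p in range(start, min(stop, len(seq) - 1)):
        if seq[p] == seq[p + 1]:
            return p
    raise ValueError("no homopolymer in window")


def find_non_homopolymer(seq: str, start: int, stop: int) -> int:
    """First position in [start, stop) not belonging to a run of >= 2."""
    for p in range(start, stop):
        left = p > 0 and seq[p] == seq[p - 1]
        right = p + 1 < len(seq) and seq[p] == seq[p + 1]
        if not left and not right:
            return p
    raise ValueError("no non-homopolymer position in window")


def _other_base(base: str, avoid: str = "") -> str:
    for b in DNA_BASES:
        if b != base and b not in avoid:
            return b
    raise AssertionError("no base available")


def plant_benchmark_errors(
    genome: Assembly,
    repeat_intervals: list[tuple[int, int]],
    seed: int = 0,
    n_unique: int = 10,
    margin: int = 300,
) -> tuple[Assembly, list[PlantedError]]:
    """The repeat-repair benchmark fixture: one substitution and one
    homopolymer deletion deep inside the first repeat copy, plus
    assorted errors in unique sequence.

    Repeat-interior errors sit more than *margin* bases (choose margin
    above the read length) from the copy edges, so under best-hit
    alignment no unique-anchored read can cover them and reads wholly
    inside the repeat prefer the error-free copy — the coverage
    starvation this polisher exists to beat.  Unique errors are spaced
    widely and kept away from repeats and contig ends so each has
    unambiguous evidence.
    """
    rng = np.random.default_rng(seed)
    name = genome.names[0]
    seq = genome.contigs[name]
    length = len(seq)
    s, e = repeat_intervals[0]
    if e - s <= 2 * margin + 60:
        raise ValueError("repeat too short for the requested interior margin")
    hp = find_homopolymer(seq, s + margin + 40, e - margin)
    sub_pos = s + margin if abs(s + margin - hp) > 30 else s + margin + 35
    errors = [
        PlantedError(name, sub_pos, "sub", seq[sub_pos], _other_base(seq[sub_pos])),
        PlantedError(name, hp, "hp_del", seq[hp], ""),
    ]

    def in_forbidden(p: int) -> bool:
        if p < 200 or p > length - 200:
            return True
        return any(rs - 250 <= p < re_ + 250 for rs, re_ in repeat_intervals)

    kinds = ["sub", "sub", "sub", "sub", "hp_ins", "hp_ins", "hp_del",
             "hp_del", "other_ins", "other_del"][:n_unique]
    taken = [sub_pos, hp]
    for kind in kinds:
        for _ in range(1000):
            p = int(rng.integers(200, length - 200))
            if in_forbidden(p) or any(abs(p - t) < 300 for t in taken):
                continue
            try:
                if kind in ("hp_ins", "hp_del"):
                    p = find_homopolymer(seq, p, p + 100)
                elif kind in ("other_ins", "other_del"):
                    p = find_non_homopolymer(seq, p, p + 100)
            except ValueError:
                continue
            if in_forbidden(p) or any(abs(p - t) < 300 for t in taken):
                continue
            break
        else:
            raise RuntimeError("could not place benchmark errors")
        taken.append(p)
        base = seq[p]
        if kind == "sub":
            errors.append(PlantedError(name, p, "sub", base, _other_base(base)))
        elif kind == "hp_ins":
            errors.append(PlantedError(name, p, "hp_ins", "", base))
        elif kind == "hp_del":
            errors.append(PlantedError(name, p, "hp_del", base, ""))
        elif kind == "other_ins":
            avoid = base + (seq[p + 1] if p + 1 < length else "")
            errors.append(
                PlantedError(name, p, "other_ins", "", _other_base(base, avoid))
            )
        else:
            errors.append(PlantedError(name, p, "other_del", base, ""))
    errors.sort(key=lambda err: err.position)
    return plant_errors(genome, errors), errors


def write_errors_tsv(errors: list[PlantedError], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tposition\ttype\tref\talt\tin_repeat\n")
        for e in errors:
            fh.write(
                f"{e.contig}\t{e.position}\t{e.type}\t{e.ref_allele or '-'}\t"
                f"{e.alt_allele or '-'}\t{int(e.in_repeat)}\n"
            )


@dataclass
class SimRead:
    """A simulated read with its true origin encoded in the name."""

    name: str
    seq: str
    contig: str
    start: int
    is_reverse: bool
    segment: str = "u"  # "u", "1" or "2"


def simulate_reads(
    assembly: Assembly,
    read_length: int = 150,
    depth: float = 300.0,
    seed: int = 0,
    paired: bool = False,
    fragment_length: int = 400,
    sub_rate: float = 0.0,
) -> list[SimRead]:
    """Error-free reads at uniform random positions and strands.

    Enough reads are drawn for the target mean depth (coverage identity
    ``n = depth * G / read_length``).  ``sub_rate`` optionally adds
    uniform substitution noise for robustness experiments; the default
    reads are error-free.  Paired mode emits R1/R2 from the two ends of
    fixed-length fragments.
    """
    rng = np.random.default_rng(seed)
    names = list(assembly.contigs)
    lengths = np.array([assembly.length(n) for n in names], dtype=float)
    if read_length > lengths.min():
        raise ValueError("read_length exceeds the shortest contig")
    reads: list[SimRead] = []

    def finalize(seq: str) -> str:
        if sub_rate > 0:
            chars = list(seq)
            for i in np.nonzero(rng.random(len(chars)) < sub_rate)[0]:
                old = chars[i]
                chars[i] = DNA_BASES[
                    (DNA_BASES.index(old) + 1 + int(rng.integers(3))) % 4
                ]
            seq = "".join(chars)
        return seq

    total = float(lengths.sum())
    if not paired:
        n_reads = math.ceil(depth * total / read_length)
        for i in range(n_reads):
            ci = int(rng.choice(len(names), p=lengths / total))
            contig = names[ci]
            start = int(rng.integers(0, assembly.length(contig) - read_length + 1))
            fragment = assembly.contigs[contig][start : start + read_length]
            rev = bool(rng.integers(2))
            seq = reverse_complement(fragment) if rev else fragment
            strand = "-" if rev else "+"
            reads.append(
                SimRead(
                    name=f"r{i:07d}|{contig}|{start}|{strand}",
                    seq=finalize(seq),
                    contig=contig,
                    start=start,
                    is_reverse=rev,
                )
            )
    else:
        frag = max(fragment_length, read_length)
        n_frags = math.ceil(depth * total / (2 * read_length))
        for i in range(n_frags):
            ci = int(rng.choice(len(names), p=lengths / total))
            contig = names[ci]
            contig_len = assembly.length(contig)
            f = min(frag, contig_len)
            start = int(rng.integers(0, contig_len - f + 1))
            left = assembly.contigs[contig][start : start + read_length]
            right = assembly.contigs[contig][start + f - read_length : start + f]
            reads.append(
                SimRead(
                    name=f"r{i:07d}|{contig}|{start}|+",
                    seq=finalize(left),
                    contig=contig,
                    start=start,
                    is_reverse=False,
                    segment="1",
                )
            )
            reads.append(
                SimRead(
                    name=f"r{i:07d}|{contig}|{start}|+",
                    seq=finalize(reverse_complement(right)),
                    contig=contig,
                    start=start + f - read_length,
                    is_reverse=True,
                    segment="2",
                )
            )
    return reads


def write_fastq(reads: list[SimRead], path: str | Path) -> None:
    """FASTQ with constant quality; read names encode the true origin."""
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.name}\n{read.seq}\n+\n{'I' * len(read.seq)}\n")


@dataclass
class Hit:
    """One alignment location: 0-based half-open reference interval."""

    contig: str
    start: int
    end: int
    edit_distance: int
    cigar: list[tuple[str, int]]
    is_reverse: bool


@dataclass
class ReadHits:
    read: SimRead
    hits: list[Hit] = field(default_factory=list)
    primary_index: int | None = None


def _parse_edlib_cigar(cigar: str) -> list[tuple[str, int]]:
    return [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]


def _collapse_to_m(cigar: list[tuple[str, int]]) -> list[tuple[str, int]]:
    """Merge =/X runs into M ops, the dialect most tools emit."""
    out: list[tuple[str, int]] = []
    for op, n in cigar:
        op = "M" if op in "=X" else op
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return out


class _KmerIndex:
    def __init__(self, assembly: Assembly, k: int):
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in assembly.contigs.items():
            for pos in range(len(seq) - k + 1):
                self.index.setdefault(seq[pos : pos + k], []).append((name, pos))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self.index.get(kmer, [])


def _seed_offsets(read_len: int, k: int, n_seeds: int) -> list[int]:
    if read_len < k:
        return []
    last = read_len - k
    if n_seeds <= 1:
        return [0]
    return sorted({round(i * last / (n_seeds - 1)) for i in range(n_seeds)})


def exhaustive_align(
    reads: list[SimRead],
    assembly: Assembly,
    max_edits: int = 3,
    mode: str = "all",
    seed: int = 0,
    seed_k: int = 21,
) -> list[ReadHits]:
    """Find every locally optimal alignment within *max_edits* per read.

    For each read and strand, exact k-mer seeds nominate candidate loci;
    overlapping candidates collapse into one locus which is verified by
    edit-distance alignment over a padded window, so each reported hit
    is the best alignment of its locus.  The primary is the hit with
    the lowest edit distance (ties broken by a seeded RNG); ``all``
    mode keeps the remaining hits as secondaries, ``best_only`` drops
    them.  Reads with no hit within the budget are reported unmapped.
    """
    if mode not in ("all", "best_only"):
        raise ValueError(f"unknown alignment mode {mode!r}")
    rng = np.random.default_rng(seed)
    index = _KmerIndex(assembly, seed_k)
    n_seeds = max_edits + 2
    results: list[ReadHits] = []
    for read in reads:
        hits: list[Hit] = []
        for is_reverse in (False, True):
            q = reverse_complement(read.seq) if is_reverse else read.seq
            offsets = _seed_offsets(len(q), seed_k, n_seeds)
            candidates: dict[str, set[int]] = {}
            for off in offsets:
                for contig, pos in index.lookup(q[off : off + seed_k]):
                    candidates.setdefault(contig, set()).add(pos - off)
            for contig, starts in candidates.items():
                contig_seq = assembly.contigs[contig]
                clusters: list[list[int]] = []
                for s in sorted(starts):
                    if clusters and s - clusters[-1][-1] <= len(q) // 2:
                        clusters[-1].append(s)
                    else:
                        clusters.append([s])
                for cluster in clusters:
                    w_start = max(0, cluster[0] - max_edits)
                    w_end = min(
                        len(contig_seq), cluster[-1] + len(q) + max_edits
                    )
                    window = contig_seq[w_start:w_end]
                    res = edlib.align(
                        q, window, mode="HW", task="path", k=max_edits
                    )
                    if res["editDistance"] < 0:
                        continue
                    loc = res["locations"][0]
                    hits.append(
                        Hit(
                            contig=contig,
                            start=w_start + loc[0],
                            end=w_start + loc[1] + 1,
                            edit_distance=res["editDistance"],
                            cigar=_collapse_to_m(
                                _parse_edlib_cigar(res["cigar"])
                            ),
                            is_reverse=is_reverse,
                        )
                    )
        # collapse overlapping hits at one locus, keeping the best
        hits.sort(key=lambda h: (h.contig, h.start, h.edit_distance))
        merged: list[Hit] = []
        for h in hits:
            if (
                merged
                and merged[-1].contig == h.contig
                and h.start < merged[-1].end
            ):
                if h.edit_distance < merged[-1].edit_distance:
                    merged[-1] = h
            else:
                merged.append(h)
        best = min((h.edit_distance for h in merged), default=None)
        primary = None
        if merged:
            tied = [i for i, h in enumerate(merged) if h.edit_distance == best]
            primary = tied[int(rng.integers(len(tied)))]
        if mode == "best_only" and merged:
            merged = [merged[primary]]
            primary = 0
        results.append(ReadHits(read=read, hits=merged, primary_index=primary))
    return results


def write_sam(
    read_hits: list[ReadHits], assembly: Assembly, path: str | Path
) -> None:
    """Write alignments as SAM text.

    The primary record carries the read sequence in reference-forward
    orientation; secondary records (FLAG 0x100) carry ``*``, as real
    all-per-read aligner output does, which exercises downstream
    sequence recovery.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": name, "LN": assembly.length(name)}
            for name in assembly.names
        ],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        tid = {name: i for i, name in enumerate(assembly.names)}
        for rh in read_hits:
            pair_flag = {"u": 0, "1": 0x1 | 0x40, "2": 0x1 | 0x80}[rh.read.segment]
            if not rh.hits:
                a = pysam.AlignedSegment(out.header)
                a.query_name = rh.read.name
                a.flag = 0x4 | pair_flag
                a.query_sequence = rh.read.seq
                a.query_qualities = pysam.qualitystring_to_array(
                    "I" * len(rh.read.seq)
                )
                out.write(a)
                continue
            order = [rh.primary_index] + [
                i for i in range(len(rh.hits)) if i != rh.primary_index
            ]
            for rank, i in enumerate(order):
                hit = rh.hits[i]
                a = pysam.AlignedSegment(out.header)
                a.query_name = rh.read.name
                flag = pair_flag
                if hit.is_reverse:
                    flag |= 0x10
                if rank > 0:
                    flag |= 0x100
                a.flag = flag
                a.reference_id = tid[hit.contig]
                a.reference_start = hit.start
                a.mapping_quality = 60 if len(rh.hits) == 1 else 0
                a.cigarstring = "".join(f"{n}{op}" for op, n in hit.cigar)
                if rank == 0:
                    seq = (
                        reverse_complement(rh.read.seq)
                        if hit.is_reverse
                        else rh.read.seq
                    )
                    a.query_sequence = seq
                    a.query_qualities = pysam.qualitystring_to_array(
                        "I" * len(seq)
                    )
                a.set_tag("NM", hit.edit_distance)
                out.write(a)


def cigar_edit_distance(
    hit: Hit, query: str, assembly: Assembly
) -> int:
    """Re-walk a hit's CIGAR against the assembly and count differences.

    Independent of the aligner's reported distance: M runs are compared
    base by base; I/D lengths count in full.
    """
    seq = assembly.contigs[hit.contig]
    dist = 0
    qi, ri = 0, hit.start
    for op, n in hit.cigar:
        if op in "M=X":
            dist += sum(
                1 for j in range(n) if query[qi + j] != seq[ri + j]
            )
            qi += n
            ri += n
        elif op == "I":
            dist += n
            qi += n
        elif op == "D":
            dist += n
            ri += n
        else:
            raise ValueError(f"unexpected op {op!r} in simulated alignment")
    return dist
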