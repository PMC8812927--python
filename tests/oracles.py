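"""Independent brute-force oracles used by the test suite.

Everything here re-derives results from first principles, by a different
mechanism than the implementation under test: pileups via an explicit
read-base/reference-position correspondence table with exact rational
depth, alignments via full dynamic-programming matrices.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from fractions import Fraction

import numpy as np


def _alignment_events(record):
    """Explicit (kind, ref_pos, read_idx) event per aligned base."""
    events = []
    ri = record.ref_start
    qi = 0
    for op, n in record.cigar:
        if op in "M=X":
            for _ in range(n):
                events.append(("aligned", ri, qi))
                ri += 1
                qi += 1
        elif op == "I":
            for _ in range(n):
                events.append(("ins", ri, qi))
                qi += 1
        elif op == "D":
            for _ in range(n):
                events.append(("del", ri, None))
                ri += 1
        elif op == "S":
            qi += n
        elif op == "H":
            pass
        else:
            raise ValueError(op)
    return events


def _run_plus_one(seq: str, from_end: bool) -> int:
    if not seq:
        return 0
    s = seq[::-1] if from_end else seq
    r = 1
    while r < len(s) and s[r] == s[0]:
        r += 1
    return min(r + 1, len(s))


def oracle_pieces(record, trim_mode: str = "end_only"):
    """Trimmed (position, piece) list derived from the event table."""
    events = _alignment_events(record)
    seq = record.stored_seq
    order: list[int] = []
    piece_str: dict[int, str] = {}
    piece_reads: dict[int, set] = {}
    last_pos = None
    for kind, rpos, qidx in events:
        if kind == "aligned":
            order.append(rpos)
            piece_str[rpos] = seq[qidx]
            piece_reads[rpos] = {qidx}
            last_pos = rpos
        elif kind == "del":
            order.append(rpos)
            piece_str[rpos] = ""
            piece_reads[rpos] = set()
            last_pos = rpos
        else:  # insertion: attach to the previous reference position
            if last_pos is None:
                continue  # no anchor: discarded
            piece_str[last_pos] += seq[qidx]
            piece_reads[last_pos].add(qidx)
    used = sorted(i for pos in order for i in piece_reads[pos])
    aligned_seq = "".join(seq[i] for i in used)
    if not aligned_seq:
        return []
    trim = _run_plus_one(aligned_seq, from_end=True)
    if trim >= len(used):
        return []  # nothing attested: the whole alignment is trimmed
    trimmed = set(used[len(used) - trim :])
    kept = []
    for pos in order:
        if piece_reads[pos] & trimmed:
            break
        kept.append(pos)
    if trim_mode == "both_ends":
        lead = _run_plus_one(aligned_seq, from_end=False)
        lead_idx = set(used[:lead])
        last_affected = -1
        for i, pos in enumerate(kept):
            if piece_reads[pos] & lead_idx:
                last_affected = i
        kept = kept[last_affected + 1 :]
    return [(pos, piece_str[pos]) for pos in kept]


def oracle_pileup(assembly, groups, trim_mode: str = "end_only"):
    """Piece counts and exact rational depth per (contig, position)."""
    counts: dict[tuple[str, int], Counter] = defaultdict(Counter)
    depth: dict[tuple[str, int], Fraction] = defaultdict(Fraction)
    for group in groups:
        for record in group.records:
            for pos, piece in oracle_pieces(record, trim_mode):
                counts[(record.contig, pos)][piece] += 1
                depth[(record.contig, pos)] += Fraction(1, group.k)
    return counts, depth


def nw_distance(a: str, b: str) -> int:
    """Textbook unit-cost global alignment distance."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (a[i - 1] != b[j - 1]),
            )
        prev = cur
    return prev[n]


def nw_ref_alleles(asm: str, ref: str) -> list[str]:
    """Reference-coordinate projection via an explicit NW traceback.

    Tie preference in traceback: match/sub > deletion (ref base skipped
    in assembly) > insertion.  Insertions attach to the left-anchoring
    reference position; a leading insertion folds into position 0.
    """
    m, n = len(asm), len(ref)
    dp = np.zeros((m + 1, n + 1), dtype=int)
    dp[:, 0] = np.arange(m + 1)
    dp[0, :] = np.arange(n + 1)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            dp[i, j] = min(
                dp[i - 1, j - 1] + (asm[i - 1] != ref[j - 1]),
                dp[i - 1, j] + 1,
                dp[i, j - 1] + 1,
            )
    ops = []  # walked back-to-front
    i, j = m, n
    while i > 0 or j > 0:
        if (
            i > 0
            and j > 0
            and dp[i, j] == dp[i - 1, j - 1] + (asm[i - 1] != ref[j - 1])
        ):
            ops.append(("aligned", i - 1, j - 1))
            i -= 1
            j -= 1
        elif j > 0 and dp[i, j] == dp[i, j - 1] + 1:
            ops.append(("del", None, j - 1))
            j -= 1
        else:
            ops.append(("ins", i - 1, None))
            i -= 1
    ops.reverse()
    alleles = [""] * n
    last_ref = None
    prefix = ""
    for kind, a_pos, r_pos in ops:
        if kind == "aligned":
            alleles[r_pos] = asm[a_pos]
            last_ref = r_pos
        elif kind == "del":
            alleles[r_pos] = ""
            last_ref = r_pos
        else:
            if last_ref is None:
                prefix += asm[a_pos]
            else:
                alleles[last_ref] += asm[a_pos]
    if prefix:
        alleles[0] = prefix + alleles[0]
    return alleles


def semiglobal_end_distances(query: str, ref: str) -> np.ndarray:
    """Full-DP infix alignment: best distance of *query* ending at each
    reference position (inclusive end), with a free start."""
    m = len(query)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    prev = np.arange(m + 1)
    ends = np.empty(len(ref), dtype=int)
    idx = np.arange(m)
    for j, c in enumerate(ref.encode()):
        diag = prev[:-1] + (q != c)
        up = prev[1:] + 1
        d = np.minimum(diag, up)
        # serial left-dependency (cur[i-1] + 1) resolved as a sloped
        # prefix minimum; the free-start row contributes cur[i] <= i
        cur_tail = np.minimum(np.minimum.accumulate(d - idx) + idx, idx + 1)
        prev = np.concatenate(([0], cur_tail))
        ends[j] = prev[-1]
    return ends


def semiglobal_optima(query: str, ref: str, max_edits: int):
    """Locally optimal hit distances: cluster end positions with
    distance <= max_edits that lie within a read length of each other,
    and report each cluster's minimum."""
    ends = semiglobal_end_distances(query, ref)
    good = np.nonzero(ends <= max_edits)[0]
    clusters = []
    for e in good:
        if clusters and e - clusters[-1][-1] <= len(query) // 2:
            clusters[-1].append(e)
        else:
            clusters.append([e])
    return [int(ends[np.array(c)].min()) for c in clusters]
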