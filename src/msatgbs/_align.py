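"""Star alignment of a read stack against a reference sequence.

Every read is globally aligned to the reference with edlib; the per-column
state counts (base / gap) and per-junction insertion counts that fall out of
this are the shared substrate for consensus building (genotype module) and
flank-variant screening (homoplasy module).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

import edlib

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

_BASE_ORDER = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4, "N": 5}


def cigar_events(cigar: str):
    """Yield (op, length) pairs from an edlib extended CIGAR."""
    for m in _CIGAR_RE.finditer(cigar):
        yield m.group(2), int(m.group(1))


@dataclass
class StackAlignment:
    reference: str
    n: int
    columns: list[Counter]  # per reference column: base or '-' counts
    insertions: list[Counter]  # per junction (len(ref)+1): inserted string counts
    # per read: list of (op, ref_pos, length); op in {I, D}
    indel_events: list[list[tuple[str, int, int]]]
    # per read: full walk as returned by align_pair (kept on request)
    walks: list[list[tuple[str, int, int, str]]] | None = None


def _left_normalize(op: str, rpos: int, piece: str, length: int, ref: str):
    """Shift an indel to its leftmost equivalent placement.

    Within any repetitive context (homopolymers included) an indel has many
    cost-equal placements and the aligner's choice is arbitrary; without a
    canonical placement, identical indels from different reads land on
    different junctions and column votes never aggregate.
    """
    if op == "D":
        while rpos > 0 and ref[rpos - 1] == ref[rpos - 1 + length]:
            rpos -= 1
        return rpos, piece
    while rpos > 0 and piece and ref[rpos - 1] == piece[-1]:
        piece = ref[rpos - 1] + piece[:-1]
        rpos -= 1
    return rpos, piece


def align_pair(query: str, reference: str) -> tuple[int, list[tuple[str, int, int, str]]]:
    """Global alignment; returns (distance, walk) where walk items are
    (op, ref_pos, length, query_piece) with op in {=, X, I, D}.  Indels are
    reported left-normalized."""
    res = edlib.align(query, reference, mode="NW", task="path")
    walk = []
    qpos = rpos = 0
    for op, length in cigar_events(res["cigar"]):
        if op in ("=", "X", "M"):
            walk.append((op, rpos, length, query[qpos : qpos + length]))
            qpos += length
            rpos += length
        elif op == "I":  # present in read, absent from reference
            piece = query[qpos : qpos + length]
            npos, piece = _left_normalize("I", rpos, piece, length, reference)
            walk.append(("I", npos, length, piece))
            qpos += length
        else:  # deletion from the read
            npos, _ = _left_normalize("D", rpos, "", length, reference)
            walk.append(("D", npos, length, ""))
            rpos += length
    return res["editDistance"], walk


def stack_align(
    reference: str, reads: list[str], keep_walks: bool = False
) -> StackAlignment:
    L = len(reference)
    columns = [Counter() for _ in range(L)]
    insertions = [Counter() for _ in range(L + 1)]
    indel_events: list[list[tuple[str, int, int]]] = []
    walks: list[list[tuple[str, int, int, str]]] = []
    for read in reads:
        _, walk = align_pair(read, reference)
        events: list[tuple[str, int, int]] = []
        for op, rpos, length, piece in walk:
            if op in ("=", "X", "M"):
                for i, ch in enumerate(piece):
                    columns[rpos + i][ch] += 1
            elif op == "I":
                insertions[rpos][piece] += 1
                events.append(("I", rpos, length))
            else:
                for i in range(length):
                    columns[rpos + i]["-"] += 1
                events.append(("D", rpos, length))
        indel_events.append(events)
        if keep_walks:
            walks.append(walk)
    return StackAlignment(
        reference, len(reads), columns, insertions, indel_events,
        walks if keep_walks else None,
    )


def _majority_state(col: Counter) -> str:
    """Plurality state of a column; base ties resolved in A<C<G<T order and
    a base preferred over a gap on exact ties."""
    best = max(col.items(), key=lambda kv: (kv[1], -_BASE_ORDER.get(kv[0], 9)))
    return best[0]


#: Read fraction required before an indel is edited into the consensus
#: (strict majority).  Real reference-read defects are backed by most reads
#: even when other errors fragment their placements; independent errors at
#: one flank junction stay far below one half.  Repeat tracts, where
#: canonical placement concentrates unrelated errors, must be excluded via
#: ``protect`` instead.
INDEL_EDIT_THRESHOLD = 0.5


def consensus_from_stack(
    stack: StackAlignment,
    indel_threshold: float = INDEL_EDIT_THRESHOLD,
    protect: tuple[int, int] | None = None,
) -> tuple[str, list[int | None]]:
    """Column-wise consensus against the reference read.

    Substitutions follow the column plurality; insertions are spliced in
    and columns dropped as gaps only above ``indel_threshold`` support.
    Within the optional ``protect`` reference interval no indel edits are
    applied at all: inside a repeat tract the aligner concentrates
    unrelated per-read indel errors on one canonical junction, so even a
    large majority there is not evidence of a real edit.  Returns the
    consensus string and a map from reference column -> consensus
    coordinate (None for dropped columns).
    """
    ps, pe = protect if protect is not None else (0, -1)
    out: list[str] = []
    ref_to_cons: list[int | None] = [None] * len(stack.reference)
    for j in range(len(stack.reference) + 1):
        protected = ps < j <= pe if protect is not None else False
        ins = stack.insertions[j]
        if not protected and ins and sum(ins.values()) > indel_threshold * stack.n:
            piece = max(ins.items(), key=lambda kv: (kv[1], -len(kv[0]), kv[0]))[0]
            out.append(piece)
        if j < len(stack.reference):
            col = stack.columns[j]
            in_protect = ps <= j < pe if protect is not None else False
            if (
                not in_protect
                and col
                and col.get("-", 0) > indel_threshold * stack.n
            ):
                continue
            bases = {s: c for s, c in col.items() if s != "-"}
            state = _majority_state(bases) if bases else stack.reference[j]
            ref_to_cons[j] = sum(len(p) for p in out)
            out.append(state)
    return "".join(out), ref_to_cons


def net_indel(events: list[tuple[str, int, int]], lo: int, hi: int) -> int:
    """Net length change (insertions - deletions) of one read relative to the
    reference, restricted to the reference window [lo, hi).  Insertions at
    junction j count when lo < j <= hi; deletions count by their overlap
    with the window."""
    net = 0
    for op, pos, length in events:
        if op == "I":
            if lo < pos <= hi:
                net += length
        else:
            overlap = min(pos + length, hi) - max(pos, lo)
            if overlap > 0:
                net -= overlap
    return net
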