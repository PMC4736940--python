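"""Tolerance-bounded demultiplexing of combinatorially barcoded amplicon reads.

Each read (or its reverse complement) is expected to carry, in order:

    fwd barcode . fwd tail . fwd locus primer . insert
        . rev locus primer' . rev tail' . rev barcode'

A read is assigned to an (individual, locus) bin only when both barcodes and
both locus-specific primers match uniquely within their Levenshtein-distance
tolerances (defaults: 2 errors per barcode, 3 per primer, accommodating a
~6% per-base combined sequencing + PCR error rate) and the two primers name
the same locus.  Anything else is rejected with a reason code; rejection is
a value, never an exception.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path

import edlib
import numpy as np
from Bio import SeqIO

from ._seq import reverse_complement
from .panel import PanelConfig

logger = logging.getLogger(__name__)

#: Positional slack (bp) added around each element's expected window.
WINDOW_SLACK = 5

#: A barcode match must beat the runner-up barcode by this many errors;
#: combinatorial identity is undefined for a read sitting between two codes.
BARCODE_MARGIN = 2

REJECT_REASONS = (
    "no_fwd_barcode",
    "no_fwd_primer",
    "no_rev_primer",
    "no_rev_barcode",
    "ambiguous",
    "locus_conflict",
    "both_orientations",
)


@dataclass(frozen=True)
class DemuxTolerances:
    """Maximum edit distance allowed per identifying element."""

    barcode_max_errors: int = 2
    primer_max_errors: int = 3

    def __post_init__(self) -> None:
        if self.barcode_max_errors < 0 or self.primer_max_errors < 0:
            raise ValueError("tolerances must be non-negative")


@dataclass(frozen=True)
class MatchResult:
    """Best fuzzy match of one element class within a read window."""

    candidate_id: str | None
    distance: int | None
    interval: tuple[int, int] | None  # 0-based half-open, window-local
    status: str  # unique | ambiguous | none
    tied_ids: tuple[str, ...] = ()


@dataclass
class AssignedRead:
    read_id: str
    sequence: str  # oriented to + strand (forward barcode first)
    individual: str | None = None
    locus: str | None = None
    orientation: str | None = None  # "+" | "-"
    fwd_barcode: MatchResult | None = None
    fwd_primer: MatchResult | None = None
    rev_primer: MatchResult | None = None
    rev_barcode: MatchResult | None = None
    reject_reason: str | None = None

    @property
    def assigned(self) -> bool:
        return self.individual is not None and self.locus is not None


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (unit-cost substitutions, insertions, deletions)."""
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def find_element(
    read: str,
    candidates: dict[str, str],
    max_errors: int,
    window: tuple[int, int] | None = None,
    min_margin: int = 0,
) -> MatchResult:
    """Semi-global search for the best-matching candidate inside a window.

    Every candidate is aligned end-gap-free on the read side ("infix" mode)
    within ``window`` (0-based half-open; default: whole read).  The candidate
    with the smallest edit distance wins if that distance is within
    ``max_errors``; a tie between two distinct candidates is reported as
    ambiguous rather than guessed, as is a runner-up candidate closer than
    ``min_margin`` extra errors (a margin makes combinatorial identity robust
    even for reads whose own barcode is damaged beyond tolerance and happens
    to resemble another code in context).  Among equally good placements of
    one candidate the leftmost interval is reported; exact ties between
    candidate ids are listed in lexicographic order.
    """
    if not candidates:
        raise ValueError("find_element: empty candidate list")
    if window is None:
        window = (0, len(read))
    start = max(0, window[0])
    end = min(len(read), window[1])
    segment = read[start:end]
    best: list[tuple[str, int, tuple[int, int]]] = []
    best_d: int | None = None
    second_d: int | None = None
    for cid in sorted(candidates):
        seq = candidates[cid]
        if not segment:
            continue
        res = edlib.align(
            seq, segment, mode="HW", task="locations", k=max_errors + min_margin
        )
        d = res["editDistance"]
        if d < 0:  # no placement within k
            continue
        if d > max_errors:
            if second_d is None or d < second_d:
                second_d = d
            continue
        loc = min(res["locations"], key=lambda se: (se[0] if se[0] is not None else 0))
        s = loc[0] if loc[0] is not None else 0
        interval = (start + s, start + loc[1] + 1)  # edlib end is inclusive
        if best_d is None or d < best_d:
            if best_d is not None and (second_d is None or best_d < second_d):
                second_d = best_d
            best_d = d
            best = [(cid, d, interval)]
        elif d == best_d:
            best.append((cid, d, interval))
        elif second_d is None or d < second_d:
            second_d = d
    if best_d is None:
        return MatchResult(None, None, None, "none")
    if len(best) > 1:
        return MatchResult(
            None, best_d, None, "ambiguous", tied_ids=tuple(cid for cid, _, _ in best)
        )
    if min_margin and second_d is not None and second_d - best_d < min_margin:
        return MatchResult(None, best_d, None, "ambiguous", tied_ids=(best[0][0],))
    cid, d, interval = best[0]
    return MatchResult(cid, d, interval, "unique")


def _attempt(read: str, panel: PanelConfig, tol: DemuxTolerances) -> AssignedRead:
    """Try to parse one orientation of a read.  Windows are chained 5'->3'
    for the forward elements and mirrored from the 3' end for the reverse
    ones; each window is the element's expected position +/- tolerance and a
    small positional slack."""
    out = AssignedRead(read_id="", sequence=read)
    n = len(read)

    fwd_bcs = {b.id: b.sequence for b in panel.forward_barcodes}
    bc_len = max(len(s) for s in fwd_bcs.values())
    out.fwd_barcode = find_element(
        read, fwd_bcs, tol.barcode_max_errors,
        (0, bc_len + tol.barcode_max_errors + WINDOW_SLACK),
        min_margin=BARCODE_MARGIN,
    )
    if out.fwd_barcode.status != "unique":
        out.reject_reason = (
            "ambiguous" if out.fwd_barcode.status == "ambiguous" else "no_fwd_barcode"
        )
        return out

    tail_len = len(panel.forward_tail.sequence)
    fwd_primers = {loc.name: loc.fwd_primer for loc in panel.loci}
    p_len = max(len(s) for s in fwd_primers.values())
    anchor = out.fwd_barcode.interval[1] + tail_len
    out.fwd_primer = find_element(
        read, fwd_primers, tol.primer_max_errors,
        (anchor - WINDOW_SLACK, anchor + p_len + tol.primer_max_errors + WINDOW_SLACK),
    )
    if out.fwd_primer.status != "unique":
        out.reject_reason = (
            "ambiguous" if out.fwd_primer.status == "ambiguous" else "no_fwd_primer"
        )
        return out

    # Reverse-end elements: search the reverse complement of the read's tail
    # with the same forward-style windows, then map intervals back.
    rc = reverse_complement(read)
    rev_bcs = {b.id: b.sequence for b in panel.reverse_barcodes}
    rbc_len = max(len(s) for s in rev_bcs.values())
    m = find_element(
        rc, rev_bcs, tol.barcode_max_errors,
        (0, rbc_len + tol.barcode_max_errors + WINDOW_SLACK),
        min_margin=BARCODE_MARGIN,
    )
    out.rev_barcode = _flip(m, n)
    if m.status != "unique":
        out.reject_reason = "ambiguous" if m.status == "ambiguous" else "no_rev_barcode"
        return out

    rtail_len = len(panel.reverse_tail.sequence)
    rev_primers = {loc.name: loc.rev_primer for loc in panel.loci}
    rp_len = max(len(s) for s in rev_primers.values())
    anchor = m.interval[1] + rtail_len
    mp = find_element(
        rc, rev_primers, tol.primer_max_errors,
        (anchor - WINDOW_SLACK, anchor + rp_len + tol.primer_max_errors + WINDOW_SLACK),
    )
    out.rev_primer = _flip(mp, n)
    if mp.status != "unique":
        out.reject_reason = "ambiguous" if mp.status == "ambiguous" else "no_rev_primer"
        return out

    if out.fwd_primer.candidate_id != out.rev_primer.candidate_id:
        out.reject_reason = "locus_conflict"
        return out

    individual = panel.sample_sheet.individual_for(
        out.fwd_barcode.candidate_id, out.rev_barcode.candidate_id
    )
    if individual is None:
        # Barcode pair not on the sample sheet: combinatorial identity unknown.
        out.reject_reason = "no_fwd_barcode"
        return out
    out.individual = individual
    out.locus = out.fwd_primer.candidate_id
    return out


def _flip(m: MatchResult, read_len: int) -> MatchResult:
    """Map a match interval found on the reverse complement back onto
    forward-read coordinates (still 0-based half-open)."""
    if m.interval is None:
        return m
    s, e = m.interval
    return MatchResult(m.candidate_id, m.distance, (read_len - e, read_len - s), m.status, m.tied_ids)


def _n_matched(a: AssignedRead) -> int:
    return sum(
        1
        for m in (a.fwd_barcode, a.fwd_primer, a.rev_primer, a.rev_barcode)
        if m is not None and m.status == "unique"
    )


def assign_read(
    read_id: str, sequence: str, panel: PanelConfig, tol: DemuxTolerances | None = None
) -> AssignedRead:
    """Assign a read to an (individual, locus) bin, trying both strands.

    The returned read's ``sequence`` is oriented to the + strand (forward
    barcode first); ``orientation`` records the strand the raw read was on.
    If both strands parse completely the read is rejected as pathological.
    """
    tol = tol or DemuxTolerances()
    fwd = _attempt(sequence, panel, tol)
    rev = _attempt(reverse_complement(sequence), panel, tol)
    if fwd.assigned and rev.assigned:
        bad = AssignedRead(read_id=read_id, sequence=sequence)
        bad.reject_reason = "both_orientations"
        return bad
    if fwd.assigned:
        chosen, orient = fwd, "+"
    elif rev.assigned:
        chosen, orient = rev, "-"
    else:
        # Report the orientation that parsed further (ties -> forward).
        chosen = fwd if _n_matched(fwd) >= _n_matched(rev) else rev
        orient = "+" if chosen is fwd else "-"
    chosen.read_id = read_id
    chosen.orientation = orient
    return chosen


@dataclass
class DemuxResult:
    bins: dict[tuple[str, str], list[AssignedRead]]
    n_input: int
    n_assigned: int
    reject_counts: Counter
    n_malformed: int = 0

    def yield_report(self) -> dict:
        per_individual: Counter = Counter()
        per_locus: Counter = Counter()
        per_bin = {k: len(v) for k, v in self.bins.items()}
        for (ind, loc), n in per_bin.items():
            per_individual[ind] += n
            per_locus[loc] += n

        def stats(counts: dict) -> dict:
            vals = np.array(sorted(counts.values())) if counts else np.array([0])
            return {
                "min": int(vals.min()),
                "median": float(np.median(vals)),
                "max": int(vals.max()),
            }

        return {
            "n_input": self.n_input,
            "n_assigned": self.n_assigned,
            "n_rejected": self.n_input - self.n_assigned,
            "reject_counts": dict(self.reject_counts),
            "per_individual": dict(per_individual),
            "per_locus": dict(per_locus),
            "per_bin": {f"{i}__{l}": n for (i, l), n in per_bin.items()},
            "per_individual_stats": stats(per_individual),
            "per_locus_stats": stats(per_locus),
            "per_bin_stats": stats(per_bin),
        }


def _iter_reads(path) -> "list[tuple[str, str]]":
    path = Path(path)
    fmt = "fasta" if path.suffix.lower() in (".fa", ".fasta", ".fna") else "fastq"
    out = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            out.append((rec.id, str(rec.seq).upper()))
    return out


def demultiplex(
    reads,
    panel: PanelConfig,
    tol: DemuxTolerances | None = None,
    min_reads_per_bin: int = 1,
    out_dir=None,
) -> DemuxResult:
    """Group reads into (individual, locus) bins.

    ``reads`` is a FASTQ/FASTA path or an iterable of (read id, sequence)
    pairs.  When ``out_dir`` is given, each bin with at least
    ``min_reads_per_bin`` reads is written as ``<individual>__<locus>.fasta``
    (reads oriented to + strand) next to a tab-separated yield report and a
    rejection log.
    """
    tol = tol or DemuxTolerances()
    if isinstance(reads, (str, Path)):
        reads = _iter_reads(reads)
    bins: dict[tuple[str, str], list[AssignedRead]] = defaultdict(list)
    rejects: Counter = Counter()
    rejected_reads: list[tuple[str, str]] = []
    n_input = n_assigned = n_malformed = 0
    for read_id, seq in reads:
        n_input += 1
        if not seq or set(seq) - set("ACGTN"):
            n_malformed += 1
            logger.warning("skipping malformed read %s", read_id)
            continue
        a = assign_read(read_id, seq, panel, tol)
        if a.assigned:
            n_assigned += 1
            bins[(a.individual, a.locus)].append(a)
        else:
            rejects[a.reject_reason] += 1
            rejected_reads.append((read_id, a.reject_reason))
    # deterministic bin ordering irrespective of input order
    ordered = {
        k: sorted(bins[k], key=lambda a: a.read_id) for k in sorted(bins)
    }
    result = DemuxResult(ordered, n_input, n_assigned, rejects, n_malformed)
    if out_dir is not None:
        _write_outputs(result, rejected_reads, Path(out_dir), min_reads_per_bin)
    return result


def _write_outputs(
    result: DemuxResult, rejected: list[tuple[str, str]], out_dir: Path, min_reads: int
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for (ind, loc), group in result.bins.items():
        if len(group) < min_reads:
            continue
        with open(out_dir / f"{ind}__{loc}.fasta", "w") as fh:
            for a in group:
                fh.write(f">{a.read_id} orientation={a.orientation}\n{a.sequence}\n")
    rep = result.yield_report()
    with open(out_dir / "yield_report.tsv", "w") as fh:
        fh.write("section\tkey\tvalue\n")
        for section in ("per_individual", "per_locus", "per_bin"):
            for k, v in sorted(rep[section].items()):
                fh.write(f"{section}\t{k}\t{v}\n")
        for section in ("per_individual_stats", "per_locus_stats", "per_bin_stats"):
            for k, v in rep[section].items():
                fh.write(f"{section}\t{k}\t{v}\n")
        fh.write(f"totals\tn_input\t{rep['n_input']}\n")
        fh.write(f"totals\tn_assigned\t{rep['n_assigned']}\n")
        fh.write(f"totals\tn_rejected\t{rep['n_rejected']}\n")
    with open(out_dir / "rejections.tsv", "w") as fh:
        fh.write("read_id\treason\n")
        for rid, reason in rejected:
            fh.write(f"{rid}\t{reason}\n")
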