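"""Microsatellite genotype calling from per-bin read-length histograms.

The manual procedure this automates is: view all reads of one individual at
one locus as a read-length histogram, pick one or two allele peaks, and
verify them by read alignment.  Indel-rich amplicon errors (at a 6% combined
per-base rate a 300 bp read carries several insertions and deletions) smear
raw read lengths far beyond the one-repeat-unit spacing of real alleles, so
the histogram handed to the peak caller is alignment-corrected:

* one reference per locus is built from reads pooled across individuals
  (every individual shares the locus flanks), with the repeat zone shielded
  from alignment-degenerate column votes and its content taken from the
  read segment that best fits a margins-plus-pure-repeat model;
* each read's repeat-unit count is voted by realigning its anchored tract
  window against the reference window with whole motif units edited in or
  out -- flank errors add the same cost to every candidate and cancel;
* genuinely ambiguous reads (a single indel in a short motif ties adjacent
  counts) abstain, and symmetric multi-way ties resolve to their middle;
* the absolute length scale is pinned by the modal whole-insert residual of
  the largest vote cluster, after subtracting indels private to each read.

The corrected histogram then goes through the classical peak logic: top
peak, second peak at a minimum fraction of the top, stutter absorption one
repeat unit below.  Raw measured lengths are recorded alongside for
diagnostics, and a genotype is attempted only at five or more reads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._align import align_pair, consensus_from_stack, stack_align
from .demux import AssignedRead
from .panel import LocusDef, PanelConfig


@dataclass(frozen=True)
class CallerParams:
    min_depth: int = 5  # reads required to attempt a genotype
    stutter_ratio: float = 0.5  # peak one motif below a larger peak is absorbed below this
    het_ratio: float = 0.3  # second peak accepted at >= this fraction of the top peak
    min_allele_reads: int = 2

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        for r in (self.stutter_ratio, self.het_ratio):
            if not 0 < r <= 1:
                raise ValueError("ratios must be in (0, 1]")


@dataclass
class LengthHistogram:
    key: tuple[str, str]  # (individual, locus)
    counts: dict[int, int] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class Allele:
    length: int  # full amplicon bp
    support: int
    consensus: str | None = None  # insert consensus (between the primers)


@dataclass
class GenotypeCall:
    individual: str
    locus: str
    status: str  # called | insufficient_depth | uncalled
    alleles: list[Allele] = field(default_factory=list)
    total_depth: int = 0
    raw_histogram: LengthHistogram | None = None
    corrected_histogram: LengthHistogram | None = None
    # (insert sequences, corrected lengths) kept for the homoplasy screen so
    # it can regroup reads exactly as the caller did; not serialized
    read_data: tuple[list[str], list[int | None]] | None = None
    # (left, right) flank lengths outside the repeat window on the locus
    # reference; locus-level constants the screen uses to bound the tract
    tract_flanks: tuple[int, int] | None = None
    # per allele length: locus reference with the tract edited to that
    # allele's unit count — a clean alignment reference for the screen
    allele_refs: dict[int, str] | None = None

    @property
    def genotype(self) -> tuple[int, int] | None:
        """Diploid allele-length pair (homozygotes duplicated), or None."""
        if self.status != "called" or not self.alleles:
            return None
        lens = sorted(a.length for a in self.alleles)
        if len(lens) == 1:
            lens = [lens[0], lens[0]]
        return (lens[0], lens[1])


def measure_length(read: AssignedRead) -> tuple[int, int] | None:
    """(full amplicon bp, insert bp) for an assigned read, on the oriented
    read's own coordinates; None when a reverse anchor is missing."""
    if not (read.fwd_barcode and read.rev_barcode and read.fwd_primer and read.rev_primer):
        return None
    if None in (
        read.fwd_barcode.interval,
        read.rev_barcode.interval,
        read.fwd_primer.interval,
        read.rev_primer.interval,
    ):
        return None
    amplicon = read.rev_barcode.interval[1] - read.fwd_barcode.interval[0]
    insert = read.rev_primer.interval[0] - read.fwd_primer.interval[1]
    return amplicon, insert


def build_histogram(key: tuple[str, str], lengths: list[int]) -> LengthHistogram:
    return LengthHistogram(key, dict(sorted(Counter(lengths).items())))


def _rank_key(locus: LocusDef):
    """Sort key for peaks: higher count first, ties toward the length closer
    to the locus size-band midpoint, then toward the longer allele."""

    def key(item: tuple[int, int]):
        length, count = item
        return (-count, abs(length - locus.midpoint), -length)

    return key


def call_genotype(
    hist: LengthHistogram, locus: LocusDef, params: CallerParams | None = None
) -> GenotypeCall:
    """Pick one or two allele peaks from a length histogram.

    The top peak is allele 1.  A second peak qualifies when it carries at
    least ``het_ratio`` of the top peak's reads, is not a stutter artifact
    (exactly one motif length below a larger accepted peak with fewer than
    ``stutter_ratio`` of its reads), and has ``min_allele_reads`` support.
    """
    params = params or CallerParams()
    ind, loc_name = hist.key
    call = GenotypeCall(ind, loc_name, "uncalled", total_depth=hist.depth)
    if hist.depth < params.min_depth:
        call.status = "insufficient_depth"
        return call
    if not hist.counts:
        return call
    items = sorted(hist.counts.items(), key=_rank_key(locus))
    top_len, top_count = items[0]
    if top_count < params.min_allele_reads:
        return call
    motif_len = len(locus.motif)
    second = None
    for length, count in items[1:]:
        if count < params.min_allele_reads or count < params.het_ratio * top_count:
            continue
        is_stutter = (
            length == top_len - motif_len and count < params.stutter_ratio * top_count
        )
        if is_stutter:
            continue
        second = (length, count)
        break
    call.status = "called"
    alleles = [Allele(top_len, top_count)]
    if second is not None:
        alleles.append(Allele(second[0], second[1]))
    call.alleles = sorted(alleles, key=lambda a: a.length)
    return call


def consensus(inserts: list[str], motif: str | None = None) -> str:
    """Majority consensus of the reads supporting one allele, star-aligned
    to a modal-length medoid seed; ties at a column go A<C<G<T and columns
    are dropped or spliced only above the indel-edit threshold.  When the
    repeat ``motif`` is given, the seed's repeat zone is protected from
    indel edits (within a tract, unrelated errors pile up on canonical
    junctions and fake majority support)."""
    from .homoplasy import locate_repeat

    if not inserts:
        raise ValueError("consensus of zero reads")
    seed = _pick_seed(inserts)
    stack = stack_align(seed, inserts)
    protect = None
    if motif:
        zone = locate_repeat(seed, motif, max_interrupt=6)
        if zone is not None:
            zs, ze = _extend_zone(seed, zone.start, zone.end, len(motif))
            protect = (max(0, zs - 2), min(len(seed), ze + 2))
    cons, _ = consensus_from_stack(stack, protect=protect)
    return cons


#: Reads sampled when picking the medoid alignment seed of a bin.
_SEED_SAMPLE = 25


def _pick_seed(inserts: list[str]) -> str:
    """Medoid read of the bin: the read minimizing total edit distance to a
    deterministic sample of the others.  A seed whose repeat tract carries
    an indel error would scatter every other read's compensating insertion
    across degenerate junctions of the repeat, corrupting the consensus
    length; the medoid is tract-length-correct by majority."""
    import edlib

    if len(inserts) == 1:
        return inserts[0]
    # candidates come from the modal length class: in a pool of several
    # alleles the *median* length falls between allele classes, where every
    # read is an error read
    lengths = Counter(len(s) for s in inserts)
    modal = max(lengths.items(), key=lambda kv: (kv[1], -kv[0]))[0]
    ordered = sorted(inserts, key=lambda s: (abs(len(s) - modal), len(s), s))
    candidates = ordered[:_SEED_SAMPLE]
    sample = ordered[:_SEED_SAMPLE]
    best = None
    for cand in candidates:
        total = sum(
            edlib.align(cand, other, mode="NW", task="distance")["editDistance"]
            for other in sample
            if other is not cand
        )
        if best is None or total < best[0]:
            best = (total, cand)
    return best[1]


#: Flank margin (bp) kept on each side of the repeat zone when a read's
#: tract window is extracted.  Indels belonging to the tract park at the run
#: boundary and can spill a couple of bases into motif-compatible flank, so
#: the window edges must sit in unique sequence.
TRACT_MARGIN = 6

#: Hard cap on repeat-unit offsets tried on each side of the consensus
#: copy number (the locus size band sets the actual span).
REPEAT_SEARCH_SPAN = 25

#: A per-read indel within the window is treated as that read's own
#: sequencing error (and subtracted from its residual) when fewer than this
#: fraction of reads show an indel of the same kind at the same place.
_PRIVATE_INDEL_SUPPORT = 0.25


#: Unique flank sequence (bp) used to anchor a read's tract window.
_ANCHOR_LEN = 14


def _anchored_segment(
    read: str,
    left_anchor: str,
    right_anchor: str,
    expect_left: int | None = None,
    expect_right: int | None = None,
) -> str | None:
    """Read bases between two unique flank anchors, located by fuzzy infix
    search.  Unlike the global alignment walk, this never mis-attributes a
    long tract extension: aligning 40 extra repeat bases against flank as
    mismatches can be cheaper than one long insertion, which would silently
    push the extension out of any walk-derived window.  Among equally good
    anchor placements the one closest to its expected position (from the
    construct geometry) wins."""
    import edlib

    if len(left_anchor) < 8 or len(right_anchor) < 8:
        return None
    k = max(2, len(left_anchor) // 4)
    res_l = edlib.align(left_anchor, read, mode="HW", task="locations", k=k)
    res_r = edlib.align(right_anchor, read, mode="HW", task="locations", k=k)
    if res_l["editDistance"] < 0 or res_r["editDistance"] < 0:
        return None
    if expect_left is None:
        start = min(loc[1] for loc in res_l["locations"]) + 1
    else:
        start = min(res_l["locations"], key=lambda lc: abs((lc[0] or 0) - expect_left))[1] + 1
    if expect_right is None:
        end = max(loc[0] for loc in res_r["locations"])
    else:
        end = min(res_r["locations"], key=lambda lc: abs((lc[0] or 0) - expect_right))[0]
    if end < start:
        return None
    return read[start:end]


def _segment_for(ins: str, ref: dict) -> str:
    """Tract window of one read against a built reference: anchored
    extraction with geometric expectations, walk-based fallback."""
    a, b, cons = ref["a"], ref["b"], ref["cons"]
    seg = _anchored_segment(
        ins,
        ref["left_anchor"],
        ref["right_anchor"],
        expect_left=a - len(ref["left_anchor"]),
        expect_right=len(ins) - (len(cons) - b),
    )
    if seg is None:
        _, walk = align_pair(ins, cons)
        seg = _window_segment(walk, a, b)
    return seg


def _window_segment(walk, lo: int, hi: int) -> str:
    """Read bases aligned to reference window [lo, hi), insertions at the
    right edge included."""
    parts: list[str] = []
    for op, rpos, length, piece in walk:
        if op in ("=", "X", "M"):
            s, e = max(lo, rpos), min(hi, rpos + length)
            if e > s:
                parts.append(piece[s - rpos : e - rpos])
        elif op == "I" and lo < rpos <= hi:
            parts.append(piece)
    return "".join(parts)


def _extend_zone(cons: str, zs: int, ze: int, m: int) -> tuple[int, int]:
    """Widen a repeat zone while the flanking base continues the period;
    alignment degeneracy extends exactly as far as the pattern does."""
    while zs > 0 and zs - 1 + m < len(cons) and cons[zs - 1] == cons[zs - 1 + m]:
        zs -= 1
    while ze < len(cons) and ze - m >= 0 and cons[ze] == cons[ze - m]:
        ze += 1
    return zs, ze


def _vote_unit_offset(
    seg: str, window_ref: str, cut: int, unit: str, span: tuple[int, int]
) -> int:
    """Repeat-unit offset of one read relative to the reference window.

    The window is aligned against the reference with ``d`` whole units
    inserted at (or removed before) the repeat-run end ``cut``; the offset
    with the smallest edit distance wins.  A single indel error in a short
    motif genuinely ties two adjacent offsets (an "AC" tract one base short
    is one deletion from d and one insertion from d-1); tied reads abstain
    (None) — splitting them either way would plant spurious one-unit peaks,
    and biasing them toward the majority would starve heterozygote minority
    alleles.
    """
    import edlib

    m = len(unit)
    best_d = None
    best: list[int] = []
    for d in range(span[0], span[1] + 1):
        if d >= 0:
            cand = window_ref[:cut] + unit * d + window_ref[cut:]
        else:
            if cut + d * m < 0:
                continue
            cand = window_ref[: cut + d * m] + window_ref[cut:]
        dist = edlib.align(seg, cand, mode="NW", task="distance")["editDistance"]
        if best_d is None or dist < best_d:
            best_d, best = dist, [d]
        elif dist == best_d:
            best.append(d)
    return best, best_d


def build_reference(
    inserts: list[str], locus: LocusDef, overhead: int
) -> dict | None:
    """Build the alignment reference and length calibration for a read set.

    Within a repeat tract, unit-cost alignments are degenerate: the aligner
    concentrates unrelated per-read indel errors on the same canonical
    junctions, so no column vote — and therefore no consensus — can be
    trusted for the tract's *length*.  The caller instead works with two
    quantities that are placement-free:

    * each read's repeat-unit offset ``d_i`` from the consensus, found by
      realigning the read's tract window against the window with whole
      motif units added or removed (``_vote_unit_offset``); and
    * each read's residual ``r_i`` = window length - reference window
      length - ``d_i x motif``, after subtracting indels private to the
      read (low column support, i.e. its own sequencing errors).

    True allele lengths are ``base + d x motif`` where base =
    ``len(consensus) + anchor`` and the anchor — the modal residual of the
    consensus's own vote cluster — absorbs any net indel error the
    consensus inherited from its seed read inside the tract.  Flank errors
    never contribute: private ones are subtracted, shared ones cancel
    between ``len(consensus)`` and the residuals.  Returns None when no
    repeat tract is recognizable.

    Because every allele at a locus shares its flanks, a reference built
    from reads pooled across individuals applies to every individual at
    that locus (see ``call_all_bins``).
    """
    from .homoplasy import locate_repeat  # deferred: homoplasy imports this module

    m = len(locus.motif)
    seed = _pick_seed(inserts)
    # Iterated protected consensus.  A seed defect that couples a
    # substitution with an indel splits the reads between two equal-cost
    # alignment explanations, so neither reaches majority on the first
    # pass; once the substitution half is fixed by column plurality, the
    # indel support concentrates and the next pass completes the repair.
    cons = seed
    for _ in range(3):
        stack = stack_align(cons, inserts)
        # generous interrupt merging: the reference's own errors split its
        # repeat runs, and any part of the tract left outside the
        # protected interval is open to indel-edit corruption
        zone_c = locate_repeat(cons, locus.motif, max_interrupt=6)
        protect = None
        if zone_c is not None:
            pzs, pze = _extend_zone(cons, zone_c.start, zone_c.end, m)
            protect = (max(0, pzs - 2), min(len(cons), pze + 2))
        new, _ = consensus_from_stack(stack, protect=protect)
        if new == cons:
            break
        cons = new
    zone = locate_repeat(cons, locus.motif, max_interrupt=3)
    run = locate_repeat(cons, locus.motif, max_interrupt=0)
    if zone is None or run is None:
        return None
    zs, ze = _extend_zone(cons, zone.start, zone.end, m)
    a = max(0, zs - TRACT_MARGIN)
    b = min(len(cons), ze + TRACT_MARGIN)
    # anchors must be unique sequence: if the located zone missed part of
    # the tract, a boundary can sit mid-repeat and its "anchor" would match
    # anywhere in the tract, truncating read segments arbitrarily
    while a > 0:
        la = cons[max(0, a - _ANCHOR_LEN) : a]
        if len(la) < 8 or locate_repeat(la, locus.motif, max_interrupt=1, min_copies=2) is None:
            break
        a = max(0, a - m)
    while b < len(cons):
        ra = cons[b : b + _ANCHOR_LEN]
        if len(ra) < 8 or locate_repeat(ra, locus.motif, max_interrupt=1, min_copies=2) is None:
            break
        b = min(len(cons), b + m)
    left_anchor = cons[max(0, a - _ANCHOR_LEN) : a]
    right_anchor = cons[b : b + _ANCHOR_LEN]

    # The consensus window content inherits its seed read's tract errors
    # (shielded from column votes by the protected zone), which blur the
    # unit-vote geometry.  Candidate replacements are the read segments
    # that best fit the idealized haplotype model — consensus margins
    # around a pure repeat: with enough reads some segment is an error-free
    # observation of a real allele's window, and any clean allele serves,
    # because votes are relative and the anchor sets the absolute length.
    # Each candidate (and the consensus window itself) is validated by its
    # vote abstention rate on a read subsample; the sharpest wins.
    segs = []
    for ins in inserts:
        seg = _anchored_segment(
            ins, left_anchor, right_anchor,
            expect_left=a - len(left_anchor),
            expect_right=len(ins) - (len(cons) - b),
        )
        if seg:
            segs.append(seg)
    candidates = [cons[a:b]]
    if len(segs) >= 3:
        left_m, right_m = cons[a:zs], cons[ze:b]
        unit0 = cons[run.start : run.start + m]
        ranked = sorted(
            set(segs),
            key=lambda s: (_model_misfit(s, left_m, right_m, unit0), len(s), s),
        )
        # graft each donor's repeat zone into the consensus margins: the
        # margins are column-corrected over the whole read set, while a
        # donor read's own margin errors would poison the reference
        grafted = []
        for donor in ranked[:3]:
            dz = locate_repeat(donor, locus.motif, max_interrupt=3)
            if dz is None:
                continue
            ds, de = _extend_zone(donor, dz.start, dz.end, m)
            grafted.append(left_m + donor[ds:de] + right_m)
        candidates = grafted + ranked[:3] + candidates
    best_ref = None
    best_score = None
    probe = inserts[:: max(1, len(inserts) // 60)]
    seen_windows = set()
    for window in candidates:
        if window in seen_windows:
            continue
        seen_windows.add(window)
        trial = _window_ref(cons, a, b, window, locus, m, left_anchor, right_anchor, overhead)
        if trial is None:
            continue
        voted = 0
        dists = []
        for ins in probe:
            best, dist = _vote_unit_offset(
                _segment_for(ins, trial), trial["window_ref"], trial["cut"],
                trial["unit"], trial["span"],
            )
            voted += len(best) == 1
            dists.append(dist if dist is not None else len(window))
        rate = voted / max(1, len(probe))
        dists.sort()
        med = dists[len(dists) // 2] if dists else 0
        # cleaner content first: constant window defects (graft seams,
        # donor margin errors) raise every read's distance
        score = (round(rate, 3), -med)
        if best_score is None or score > best_score:
            best_ref, best_score = trial, score
    if best_ref is None:
        return None
    ref = best_ref

    # Calibration anchor: the net offset between the consensus window
    # content and the true zone model, measured on the largest vote cluster
    # (one shared allele).  Each member's residual is its window length
    # against the model after subtracting indels private to the read — own
    # sequencing errors, identified by low support *within the cluster*.
    # A non-zero anchor means the window content itself is off the repeat
    # lattice — in which case clean reads tie between adjacent unit counts
    # and abstain en masse — so the window is repaired by the anchor and
    # the votes repeated until it lands on the lattice.
    anchor: int | None = None
    for attempt in range(4):
        anchor = _measure_anchor(inserts, ref)
        if anchor is None:
            return None
        if anchor % m == 0 or attempt == 3:
            # a whole-unit offset does not break vote geometry; the base
            # absorbs it directly
            break
        repair = anchor % m  # smallest positive edit restoring the lattice
        if 2 * repair > m:
            repair -= m
        cut_abs = ref["a"] + ref["cut"]
        cons = ref["cons"]
        if repair > 0:
            patch = (ref["unit"] * 2)[:repair]
            cons = cons[:cut_abs] + patch + cons[cut_abs:]
        else:
            if cut_abs + repair < ref["a"]:
                break
            cons = cons[: cut_abs + repair] + cons[cut_abs:]
        b_new = ref["b"] + repair
        ref["cons"] = cons
        ref["b"] = b_new
        ref["window_ref"] = cons[ref["a"] : b_new]
        ref["right_anchor"] = cons[b_new : b_new + _ANCHOR_LEN]
    ref["base"] = overhead + len(ref["cons"]) + anchor
    return ref


def _measure_anchor(inserts: list[str], ref: dict) -> int | None:
    """Modal lattice offset of the reference window against the largest
    vote cluster (see ``build_reference``)."""
    cons, a, b, m = ref["cons"], ref["a"], ref["b"], ref["m"]
    seg_d: list[tuple[str, int]] = []
    for ins in inserts:
        seg = _segment_for(ins, ref)
        best, _dist = _vote_unit_offset(seg, ref["window_ref"], ref["cut"], ref["unit"], ref["span"])
        if len(best) == 1:
            seg_d.append((ins, best[0]))
    if not seg_d:
        return None
    votes = Counter(d for _, d in seg_d)
    top_d = max(votes.items(), key=lambda kv: (kv[1], -abs(kv[0]), kv[0]))[0]
    cluster = [ins for ins, d in seg_d if d == top_d]
    # align the cluster against a reference of its *own* length: relative to
    # the unedited consensus, the cluster's unit difference would scatter
    # across junctions and be mistaken for private errors
    cut_abs = a + ref["cut"]
    if top_d >= 0:
        cons_top = cons[:cut_abs] + ref["unit"] * top_d + cons[cut_abs:]
    else:
        cons_top = cons[: cut_abs + top_d * m] + cons[cut_abs:]
    stack_c = stack_align(cons_top, cluster, keep_walks=True)
    nc = len(cluster)
    L_top = len(cons_top)
    residuals: list[int] = []
    for walk, ins in zip(stack_c.walks, cluster):
        # whole-insert residual: reference defects anywhere (window, flank
        # or anchor region) appear as shared indels, while each read's own
        # errors are private (low support within the cluster) and cancel
        resid = len(ins) - L_top
        for op, rpos, length, _piece in walk:
            if op == "I":
                if sum(stack_c.insertions[rpos].values()) < _PRIVATE_INDEL_SUPPORT * nc:
                    resid -= length
            elif op == "D":
                for j in range(rpos, min(rpos + length, L_top)):
                    if stack_c.columns[j].get("-", 0) < _PRIVATE_INDEL_SUPPORT * nc:
                        resid += 1
        residuals.append(resid)
    counts = Counter(residuals)
    return max(counts.items(), key=lambda kv: (kv[1], -abs(kv[0]), kv[0]))[0]


def lengths_against(ref: dict, inserts: list[str]) -> list[int | None]:
    """Corrected full-amplicon length per read against a built reference;
    None for reads whose unit count is ambiguous (vote abstention)."""
    out: list = []
    for ins in inserts:
        seg = _segment_for(ins, ref)
        best, _dist = _vote_unit_offset(seg, ref["window_ref"], ref["cut"], ref["unit"], ref["span"])
        if len(best) == 1:
            out.append(ref["base"] + best[0] * ref["m"])
        elif len(best) % 2 == 1:
            # errors tie candidates symmetrically around the true count, so
            # an odd tie set resolves to its middle member
            out.append(ref["base"] + best[len(best) // 2] * ref["m"])
        else:
            out.append(tuple(ref["base"] + d * ref["m"] for d in best))
    return out


def corrected_lengths(
    inserts: list[str], locus: LocusDef, overhead: int
) -> tuple[list[int | None], str]:
    ref = build_reference(inserts, locus, overhead)
    if ref is None:
        return [overhead + len(s) for s in inserts], ""
    return lengths_against(ref, inserts), ref["cons"]


def _prepare_bin(
    reads: list[AssignedRead],
    locus: LocusDef,
    panel: PanelConfig,
    params: CallerParams,
):
    """Measure, correct and stage one bin.  Returns (key, call|None, data):
    a finished insufficient-depth call, or staged data for finalization."""
    ind = reads[0].individual if reads else "NA"
    key = (ind or "NA", locus.name)
    measured = []
    inserts = []
    for r in reads:
        ml = measure_length(r)
        if ml is None:
            continue
        measured.append(ml)
        inserts.append(r.sequence[r.fwd_primer.interval[1] : r.rev_primer.interval[0]])
    raw_hist = build_histogram(key, [a for a, _ in measured])
    if raw_hist.depth < params.min_depth:
        call = GenotypeCall(key[0], key[1], "insufficient_depth", total_depth=raw_hist.depth)
        call.raw_histogram = raw_hist
        return key, call, None
    return key, None, {"inserts": inserts, "raw_hist": raw_hist}


def _finalize_bin(
    key: tuple[str, str], locus: LocusDef, params: CallerParams, data: dict
) -> GenotypeCall:
    # ties between adjacent unit counts abstain: every resolution scheme
    # tried plants spurious one-unit peaks
    corr = [v if isinstance(v, int) else None for v in data["corr"]]
    voted = [v for v in corr if v is not None]
    corr_hist = build_histogram(key, voted)
    call = call_genotype(corr_hist, locus, params)
    # the depth gate counts all measured reads, including vote abstentions
    call.total_depth = data["raw_hist"].depth
    call.raw_histogram = data["raw_hist"]
    call.corrected_histogram = corr_hist
    call.read_data = (data["inserts"], corr)
    call.tract_flanks = data.get("flanks")
    ref = data.get("ref")
    if call.status == "called" and ref is not None:
        call.allele_refs = {
            a.length: allele_reference(ref, a.length)
            for a in call.alleles
            if allele_reference(ref, a.length) is not None
        }
    if call.status == "called":
        refined = []
        for allele in call.alleles:
            if len(call.alleles) == 1:
                # a single called allele is supported by every read,
                # including vote abstainers
                group = list(data["inserts"])
            else:
                group = [s for s, L in zip(data["inserts"], corr) if L == allele.length]
            cons = consensus(group, locus.motif) if group else None
            refined.append(Allele(allele.length, allele.support, cons))
        call.alleles = refined
    return call


def allele_reference(ref: dict, allele_length: int) -> str | None:
    """Locus reference insert with the tract edited to one allele's unit
    count: a clean alignment reference for screening that allele's reads."""
    m = ref["m"]
    delta = allele_length - ref["base"]
    if delta % m != 0:
        return None
    d = delta // m
    cut_abs = ref["a"] + ref["cut"]
    cons = ref["cons"]
    if d >= 0:
        return cons[:cut_abs] + ref["unit"] * d + cons[cut_abs:]
    if cut_abs + d * m < ref["a"]:
        return None
    return cons[: cut_abs + d * m] + cons[cut_abs:]


def _window_ref(
    cons: str, a: int, b: int, window: str, locus: LocusDef, m: int,
    left_anchor: str, right_anchor: str, overhead: int = 0,
) -> dict | None:
    """Assemble a candidate reference around one window content."""
    from .homoplasy import locate_repeat

    run_c = locate_repeat(window, locus.motif, max_interrupt=0)
    zone_c = locate_repeat(window, locus.motif, max_interrupt=3)
    if run_c is None or zone_c is None:
        return None
    new_cons = cons[:a] + window + cons[b:]
    # candidate offsets must reach every allele the locus size band allows
    L0 = overhead + len(new_cons)
    lo, hi = locus.expected_range
    span_up = min(REPEAT_SEARCH_SPAN, max(3, (hi - L0) // m + 2))
    span_down = min(
        REPEAT_SEARCH_SPAN,
        (run_c.end - zone_c.start) // m,
        max(3, (L0 - lo) // m + 2),
    )
    return {
        "cons": new_cons,
        "m": m,
        "a": a,
        "b": a + len(window),
        "zone": (a + zone_c.start, a + zone_c.end),
        "window_ref": window,
        "cut": run_c.end,
        "unit": window[run_c.start : run_c.start + m],
        "span": (-span_down, span_up),
        "left_anchor": left_anchor,
        "right_anchor": right_anchor,
    }


def _model_misfit(seg: str, left: str, right: str, unit: str) -> int:
    """Edit distance of a window segment to the nearest idealized haplotype
    (margins around a whole number of motif copies)."""
    import edlib

    m = len(unit)
    k_est = round((len(seg) - len(left) - len(right)) / m)
    best = None
    for k in range(max(1, k_est - 1), k_est + 2):
        cand = left + unit * k + right
        d = edlib.align(seg, cand, mode="NW", task="distance")["editDistance"]
        if best is None or d < best:
            best = d
    return best if best is not None else len(seg)


#: Reads pooled per locus when building a shared reference.
_LOCUS_POOL_CAP = 240


def call_bin(
    reads: list[AssignedRead],
    locus: LocusDef,
    panel: PanelConfig,
    params: CallerParams | None = None,
) -> GenotypeCall:
    """Full calling pipeline for one isolated (individual, locus) bin."""
    params = params or CallerParams()
    key, call, data = _prepare_bin(reads, locus, panel, params)
    if call is not None:
        return call
    overhead = panel.fixed_overhead(locus)
    ref = build_reference(data["inserts"], locus, overhead)
    if ref is None:
        data["corr"] = [overhead + len(s) for s in data["inserts"]]
    else:
        data["corr"] = lengths_against(ref, data["inserts"])
        zl, zr = ref["zone"]
        data["flanks"] = (zl, len(ref["cons"]) - zr)
        data["ref"] = ref
    return _finalize_bin(key, locus, params, data)


def call_all_bins(
    bins: dict[tuple[str, str], list[AssignedRead]],
    panel: PanelConfig,
    params: CallerParams | None = None,
    include_missing: bool = True,
    share_locus_reference: bool = True,
) -> list[GenotypeCall]:
    """Call every bin, sharing one alignment reference per locus.

    All individuals share a locus's flanking sequence, so a reference built
    from reads pooled across individuals has essentially error-free flanks
    and one common length calibration; every bin's alleles then lie on the
    same lattice — the within-run equivalent of binning alleles across
    capillary lanes — and low-depth bins no longer have to estimate their
    own anchor.  Optionally emits zero-depth calls for absent individual x
    locus combinations so genotyping rates have a denominator.
    """
    params = params or CallerParams()
    calls: list[GenotypeCall] = []
    staged: dict[tuple[str, str], dict] = {}
    seen = set()
    for (ind, loc_name), reads in sorted(bins.items()):
        key, call, data = _prepare_bin(reads, panel.locus(loc_name), panel, params)
        seen.add(key)
        if call is not None:
            calls.append(call)
        else:
            staged[key] = data
    by_locus: dict[str, list[tuple[str, str]]] = {}
    for key in staged:
        by_locus.setdefault(key[1], []).append(key)
    for loc_name, keys in sorted(by_locus.items()):
        locus = panel.locus(loc_name)
        overhead = panel.fixed_overhead(locus)
        ref = None
        if share_locus_reference:
            pooled: list[str] = []
            for key in sorted(keys):
                pooled.extend(staged[key]["inserts"])
            if len(pooled) > _LOCUS_POOL_CAP:
                stride = -(-len(pooled) // _LOCUS_POOL_CAP)
                pooled = pooled[::stride]
            ref = build_reference(pooled, locus, overhead)
        for key in sorted(keys):
            data = staged[key]
            bin_ref = ref
            if bin_ref is None:
                bin_ref = build_reference(data["inserts"], locus, overhead)
            if bin_ref is None:
                data["corr"] = [overhead + len(s) for s in data["inserts"]]
            else:
                data["corr"] = lengths_against(bin_ref, data["inserts"])
                zl, zr = bin_ref["zone"]
                data["flanks"] = (zl, len(bin_ref["cons"]) - zr)
                data["ref"] = bin_ref
            calls.append(_finalize_bin(key, locus, params, data))
    if include_missing:
        for ind in panel.individuals:
            for locus in panel.loci:
                if (ind, locus.name) not in seen:
                    calls.append(GenotypeCall(ind, locus.name, "insufficient_depth"))
    calls.sort(key=lambda c: (c.individual, c.locus))
    return calls


# ----------------------------------------------------------------------
# serialization


def calls_to_dataframe(calls: list[GenotypeCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        g = c.genotype
        rows.append(
            {
                "individual": c.individual,
                "locus": c.locus,
                "status": c.status,
                "allele1": g[0] if g else None,
                "allele2": g[1] if g else None,
                "support1": c.alleles[0].support if c.alleles else None,
                "support2": (c.alleles[-1].support if len(c.alleles) > 1 else
                             (c.alleles[0].support if c.alleles else None)),
                "depth": c.total_depth,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["individual", "locus", "status", "allele1", "allele2",
                 "support1", "support2", "depth"],
    )


def write_genotypes(calls: list[GenotypeCall], path, fmt: str = "csv") -> None:
    path = Path(path)
    if fmt == "csv":
        calls_to_dataframe(calls).to_csv(path, index=False)
    elif fmt == "genepop":
        _write_genepop(calls, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_genotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("allele1", "allele2"):
        df[col] = df[col].astype("Int64")
    return df


def _write_genepop(calls: list[GenotypeCall], path: Path) -> None:
    """GenePop layout: alleles as 3-digit codes from bp lengths; lengths
    beyond 999 bp fall back to a per-locus length-rank encoding written as a
    trailing comment table."""
    loci = sorted({c.locus for c in calls})
    individuals = sorted({c.individual for c in calls})
    by_key = {(c.individual, c.locus): c for c in calls}
    all_lengths = [a for c in calls if c.genotype for a in c.genotype]
    rank_mode = any(L > 999 for L in all_lengths)
    mapping: dict[int, int] = {}
    if rank_mode:
        mapping = {L: i + 1 for i, L in enumerate(sorted(set(all_lengths)))}

    def code(L: int | None) -> str:
        if L is None:
            return "000"
        return f"{mapping.get(L, L) if rank_mode else L:03d}"

    with open(path, "w") as fh:
        fh.write("Microsatellite GBS genotypes\n")
        for loc in loci:
            fh.write(f"{loc}\n")
        fh.write("Pop\n")
        for ind in individuals:
            fields = []
            for loc in loci:
                c = by_key.get((ind, loc))
                g = c.genotype if c else None
                fields.append(code(g[0]) + code(g[1]) if g else "000000")
            fh.write(f"{ind} , " + " ".join(fields) + "\n")
        if rank_mode:
            fh.write("\n")
            for L, r in sorted(mapping.items()):
                fh.write(f"; code {r:03d} = {L} bp\n")
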