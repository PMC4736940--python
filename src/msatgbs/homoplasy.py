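"""Size-homoplasy screening: sequence variation hidden at equal allele length.

Alleles identical in length but different in sequence are invisible to
fragment sizing.  Because reads supporting one called allele length are a
stack of (possibly two) same-length haplotypes, a real flank variant shows
up as an alignment column where a substantial fraction of reads disagree
with the consensus.  The screen reports SNP and indel states outside the
microsatellite repeat tract that are carried by at least 20% of the reads,
in genotypes with 10 or more reads; unclustered sequencing errors rarely
reach both the fraction and the concordant-read thresholds.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from ._align import stack_align
from .genotype import GenotypeCall, corrected_lengths, measure_length
from .panel import LocusDef, PanelConfig


@dataclass(frozen=True)
class ScreenParams:
    min_reads: int = 10  # genotype depth required to screen at all
    fraction_threshold: float = 0.2  # minimum read fraction per variant state
    min_variant_reads: int = 4  # concordant reads per state (error guard)

    def __post_init__(self) -> None:
        if not 0 < self.fraction_threshold <= 1:
            raise ValueError("fraction_threshold must be in (0,1]")


@dataclass(frozen=True)
class RepeatInterval:
    """Location of the repeat tract on a consensus, 0-based half-open."""

    start: int
    end: int
    motif: str
    copies: int


@dataclass(frozen=True)
class HomoplasyRecord:
    individual: str
    locus: str
    allele_length: int
    kind: str  # "SNP" | "indel"
    position: int  # consensus coordinate
    alt: str  # alternative base, '-' for a gap, or inserted string
    fraction: float
    support: int


def _rotations(motif: str) -> list[str]:
    return sorted({motif[i:] + motif[:i] for i in range(len(motif))})


def _homopolymer_run(seq: str, j: int) -> int:
    """Length of the homopolymer run through position j (clamped)."""
    if not 0 <= j < len(seq):
        return 0
    base = seq[j]
    lo = j
    while lo > 0 and seq[lo - 1] == base:
        lo -= 1
    hi = j
    while hi + 1 < len(seq) and seq[hi + 1] == base:
        hi += 1
    return hi - lo + 1



def _repeat_context(ref: str, j: int, motif: str) -> bool:
    """True when the neighbourhood of column j reads as repeat sequence."""
    m = len(motif)
    lo = max(0, j - 2 * m)
    window = ref[lo : j + 2 * m + 1]
    hits = 0
    rots = _rotations(motif)
    for p in range(len(window) - m + 1):
        if window[p : p + m] in rots:
            hits += 1
    return hits >= m + 1


def locate_repeat(
    consensus: str, motif: str, max_interrupt: int = 1, min_copies: int = 3
) -> RepeatInterval | None:
    """Longest run of exact tandem motif copies on the consensus.

    All rotations of the motif are tried; two runs separated by at most
    ``max_interrupt`` bases are merged (an interrupted tract).  Ties go to
    the leftmost run.  Returns None when fewer than ``min_copies`` copies
    are found anywhere.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    m = len(motif)
    best: tuple[int, int, int] | None = None  # (copies, -start) ordering via compare
    for rot in _rotations(motif):
        runs = []
        i = 0
        n = len(consensus)
        while i + m <= n:
            if consensus[i : i + m] == rot:
                j = i
                while j + m <= n and consensus[j : j + m] == rot:
                    j += m
                runs.append((i, j, (j - i) // m))
                i = j
            else:
                i += 1
        merged = []
        for run in runs:
            if merged and run[0] - merged[-1][1] <= max_interrupt:
                s, _, c = merged[-1]
                merged[-1] = (s, run[1], c + run[2])
            else:
                merged.append(run)
        for s, e, c in merged:
            if best is None or c > best[2] or (c == best[2] and s < best[0]):
                best = (s, e, c)
    if best is None or best[2] < min_copies:
        return None
    return RepeatInterval(best[0], best[1], motif, best[2])


def screen_genotype(
    reads,
    call: GenotypeCall,
    locus: LocusDef,
    panel: PanelConfig,
    params: ScreenParams | None = None,
) -> list[HomoplasyRecord] | None:
    """Screen one called genotype for flank variation.

    Returns None when the genotype is skipped (depth below ``min_reads`` or
    no recognizable repeat tract); otherwise the (possibly empty) record
    list.  Variant positions are consensus coordinates; states inside the
    repeat tract, or within one motif length of it, are ignored as repeat
    slippage.
    """
    params = params or ScreenParams()
    if call.status != "called":
        raise ValueError("screen_genotype requires a called genotype")
    if call.total_depth < params.min_reads:
        return None
    # regroup reads by allele exactly as the caller did
    if call.read_data is not None:
        inserts, corr = call.read_data
    else:
        inserts = []
        for r in reads:
            if measure_length(r) is None:
                continue
            inserts.append(r.sequence[r.fwd_primer.interval[1] : r.rev_primer.interval[0]])
        corr, _ = corrected_lengths(inserts, locus, panel.fixed_overhead(locus))
    records: list[HomoplasyRecord] = []
    screened_any = False
    for allele in call.alleles:
        if len(call.alleles) == 1:
            group = list(inserts)  # every read supports the single allele
        else:
            group = [s for s, L in zip(inserts, corr) if L == allele.length]
        # prefer the locus-level allele reference: its flanks are averaged
        # over every individual at the locus, so a small group's own
        # consensus artifacts cannot masquerade as variants
        ref = None
        if call.allele_refs is not None:
            ref = call.allele_refs.get(allele.length)
        if ref is None:
            ref = allele.consensus
        if ref is None or len(group) < 2:
            continue
        # exact run for the core tract: interrupt merging would swallow
        # nearby flank bases and hide variants sitting just off the repeat
        tract = locate_repeat(ref, locus.motif, max_interrupt=0)
        if tract is None:
            tract = locate_repeat(ref, locus.motif)
        if tract is None:
            continue
        screened_any = True
        # substitutions are excluded inside the core tract only; indel
        # states also within the wider flank-union band (the locus
        # reference knows the flank lengths outside the repeat window, so
        # a tract fragmented by consensus errors can never expose repeat
        # columns as "flank"), plus one motif of spill margin
        ts, te = tract.start, tract.end
        ws, we = ts, te
        if call.tract_flanks is not None:
            fl, fr = call.tract_flanks
            ws = min(ws, fl)
            we = max(we, len(ref) - fr)
        margin = len(locus.motif)
        lo, hi = ws - margin, we + margin
        stack = stack_align(ref, group)
        n = stack.n
        # the insert boundaries come from fuzzy primer matches and wobble
        # by a couple of bases per read; the outermost columns are not
        # interpretable as variants
        edge = 3  # indel states: primer-boundary wobble zone
        snp_edge = 2  # substitutions are immune to pure length wobble
        for j, col in enumerate(stack.columns):
            if ts <= j < te:
                continue
            if j < snp_edge or j >= len(ref) - snp_edge:
                continue
            in_margin = lo <= j < hi
            repeatish = in_margin and _repeat_context(ref, j, locus.motif)
            for state, count in sorted(col.items()):
                if state == ref[j]:
                    continue
                if state == "-" and (in_margin or j < edge or j >= len(ref) - edge):
                    continue
                if state != "-" and repeatish:
                    # a fragmented core tract can leave repeat columns in
                    # the "flank": substitution states there are slippage
                    # re-registration, not variants
                    continue
                frac = count / n
                if frac < params.fraction_threshold or count < params.min_variant_reads:
                    continue
                if state == "-" and _homopolymer_run(ref, j) >= 2:
                    # indel errors left-normalize onto the first column of a
                    # base run, so independent errors pile up there; demand
                    # twice the evidence at any run
                    if frac < 2 * params.fraction_threshold:
                        continue
                kind = "indel" if state == "-" else "SNP"
                records.append(
                    HomoplasyRecord(
                        call.individual, call.locus, allele.length,
                        kind, j, state, frac, count,
                    )
                )
        for j in range(len(ref) + 1):
            if lo < j <= hi:
                continue
            if j < edge or j > len(ref) - edge:
                continue
            ins = stack.insertions[j]
            count = sum(ins.values())
            if count == 0:
                continue
            frac = count / n
            if frac < params.fraction_threshold or count < params.min_variant_reads:
                continue
            if (
                max(_homopolymer_run(ref, j - 1), _homopolymer_run(ref, j)) >= 2
                and frac < 2 * params.fraction_threshold
            ):
                continue
            piece = max(ins.items(), key=lambda kv: (kv[1], -len(kv[0]), kv[0]))[0]
            records.append(
                HomoplasyRecord(
                    call.individual, call.locus, allele.length,
                    "indel", j, f"+{piece}", frac, count,
                )
            )
    if not screened_any:
        return None
    return records


def screen_all(
    bins,
    calls: list[GenotypeCall],
    panel: PanelConfig,
    params: ScreenParams | None = None,
) -> tuple[list[HomoplasyRecord], int, int]:
    """Screen every called genotype; returns (records, n screened, n skipped).

    A variant state recurring in most screened individuals at one locus is
    discarded: the alignment reference is built from these same reads, so
    locus-fixed variation cannot exist and such recurrence marks a
    reference artifact, not segregating homoplasy.
    """
    params = params or ScreenParams()
    records: list[HomoplasyRecord] = []
    n_screened = n_skipped = 0
    screened_per_locus: Counter = Counter()
    for call in calls:
        if call.status != "called":
            continue
        reads = bins.get((call.individual, call.locus), [])
        res = screen_genotype(reads, call, panel.locus(call.locus), panel, params)
        if res is None:
            n_skipped += 1
        else:
            n_screened += 1
            screened_per_locus[call.locus] += 1
            records.extend(res)
    # positions are counted from both insert ends: a right-flank artifact
    # keeps a fixed distance from the insert's 3' end while its left-based
    # coordinate drifts with allele length
    left_key: Counter = Counter()
    right_key: Counter = Counter()
    overheads = {loc.name: panel.fixed_overhead(loc) for loc in panel.loci}

    def keys(r: HomoplasyRecord):
        pos_r = (r.allele_length - overheads[r.locus]) - r.position
        return (r.locus, r.kind, r.alt, r.position), (r.locus, r.kind, r.alt, pos_r)

    # artifact families run at high read fraction in nearly every
    # individual; a genuine two-haplotype variant sits near one half, so
    # only high-fraction records define and join a family
    high = 0.7
    seen_genotype = set()
    for r in records:
        if r.fraction < high:
            continue
        kl, kr = keys(r)
        gid = (r.individual, r.locus)
        if (kl, gid) not in seen_genotype:
            left_key[kl] += 1
            seen_genotype.add((kl, gid))
        if (kr, gid) not in seen_genotype:
            right_key[kr] += 1
            seen_genotype.add((kr, gid))
    kept = []
    for r in records:
        n_loc = screened_per_locus[r.locus]
        kl, kr = keys(r)
        if (
            r.fraction >= high
            and n_loc >= 3
            and (left_key[kl] > 0.6 * n_loc or right_key[kr] > 0.6 * n_loc)
        ):
            continue
        kept.append(r)
    return kept, n_screened, n_skipped


def summarize_homoplasy(
    records: list[HomoplasyRecord], n_screened: int
) -> dict:
    """Prevalence summary: % of screened genotypes with at least one record,
    number of distinct affected loci, and the SNP vs indel split."""
    if n_screened == 0:
        return {
            "n_screened": 0,
            "zero_denominator": True,
            "pct_genotypes_with_homoplasy": None,
            "n_loci_affected": 0,
            "snp_fraction": None,
            "indel_fraction": None,
            "n_records": 0,
        }
    affected = {(r.individual, r.locus) for r in records}
    n_snp = sum(1 for r in records if r.kind == "SNP")
    n_ind = len(records) - n_snp
    total = len(records)
    return {
        "n_screened": n_screened,
        "zero_denominator": False,
        "pct_genotypes_with_homoplasy": 100.0 * len(affected) / n_screened,
        "n_loci_affected": len({r.locus for r in records}),
        "snp_fraction": n_snp / total if total else None,
        "indel_fraction": n_ind / total if total else None,
        "n_records": total,
    }


def records_to_dataframe(records: list[HomoplasyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "individual": r.individual,
                "locus": r.locus,
                "allele_length": r.allele_length,
                "type": r.kind,
                "position": r.position,
                "alt": r.alt,
                "fraction": r.fraction,
                "support": r.support,
            }
            for r in records
        ],
        columns=["individual", "locus", "allele_length", "type", "position",
                 "alt", "fraction", "support"],
    )
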