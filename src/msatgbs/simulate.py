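"""Synthetic barcoded-amplicon read sets with known truth.

The generator emulates single-end 454-style amplicon sequencing of a
combinatorially barcoded microsatellite panel: every individual x locus
genotype (one or two alleles whose lengths differ by whole repeat units)
is expanded into full amplicons, reads are drawn in both orientations with
negative-binomial coverage weighted 1:1:8 across the three amplicon size
classes, and per-base errors are applied at a combined sequencing + PCR
rate of 6% (indel-rich, as on the 454 platform).  A manifest records the
true origin of every read so each downstream stage can be scored exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import reverse_complement
from .panel import (
    SIZE_CLASS_RANGES,
    Barcode,
    LocusDef,
    PanelConfig,
    UniversalTail,
    build_combinatorial_table,
    expected_amplicon,
    validate_barcode_set,
)

logger = logging.getLogger(__name__)

_BASES = "ACGT"


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class ErrorModel:
    """Per-base error process.  The total rate is split into substitutions,
    insertions and deletions; 454 amplicon data are indel-dominated, so the
    default split is 40/30/30.  ``homopolymer_multiplier`` > 1 raises the
    indel rate at bases repeating their predecessor."""

    rate: float = 0.06
    substitution_fraction: float = 0.4
    insertion_fraction: float = 0.3
    deletion_fraction: float = 0.3
    homopolymer_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise SimulationError("error rate must be in [0,1]")
        total = self.substitution_fraction + self.insertion_fraction + self.deletion_fraction
        if abs(total - 1.0) > 1e-9:
            raise SimulationError("error-type fractions must sum to 1")


@dataclass(frozen=True)
class CoverageModel:
    """Negative-binomial reads per genotype, scaled by size-class weight so
    expected read counts per class follow the pooling ratio (default 1:1:8)."""

    mean: float = 30.0
    dispersion: float = 6.0
    weights: dict = field(default_factory=lambda: {"I": 1.0, "II": 1.0, "III": 8.0})
    truncation_prob: float = 0.0
    truncation_mean: float = 50.0

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.dispersion <= 0:
            raise SimulationError("coverage mean and dispersion must be positive")
        if any(w <= 0 for w in self.weights.values()):
            raise SimulationError("size-class weights must be positive")

    def class_mean(self, size_class: str) -> float:
        w = self.weights[size_class]
        scale = len(self.weights) * w / sum(self.weights.values())
        return self.mean * scale


@dataclass(frozen=True)
class PlantedVariant:
    """A length-preserving sequence difference planted on one allele's flank
    (the signature of size homoplasy)."""

    kind: str  # "snp" | "indel"
    allele_index: int
    position: int  # insert coordinate of the primary edit
    alt: str  # substituted base (snp) or inserted base (indel)
    position2: int | None = None  # compensating insertion site (indel)


@dataclass(frozen=True)
class TruthGenotype:
    individual: str
    locus: str
    allele_lengths: tuple[int, ...]  # full amplicon bp, sorted
    allele_inserts: tuple[str, ...]
    tract_intervals: tuple[tuple[int, int], ...]  # insert coords, half-open
    variants: tuple[PlantedVariant, ...] = ()

    @property
    def is_het_by_length(self) -> bool:
        return len(set(self.allele_lengths)) > 1


@dataclass(frozen=True)
class LocusTemplate:
    """Fixed flanking sequence for one simulated locus; alleles differ only
    in the number of motif copies between the flanks."""

    locus: LocusDef
    flank_left: str
    flank_right: str

    def insert_for_repeats(self, k: int) -> tuple[str, tuple[int, int]]:
        if k < 1:
            raise SimulationError("repeat count must be >= 1")
        tract = self.locus.motif * k
        s = len(self.flank_left)
        return self.flank_left + tract + self.flank_right, (s, s + len(tract))


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def random_barcode_set(
    rng: np.random.Generator, n: int, side: str, length: int = 10, min_distance: int = 7
) -> list[Barcode]:
    """Greedily sample barcodes whose pairwise Levenshtein distance is at
    least ``min_distance``.  The SAFE criterion only needs > 2 x the demux
    tolerance (i.e. 5); the default of 7 adds margin so that even a barcode
    carrying three or four errors — beyond tolerance, hence rejected — is
    never within tolerance of a *different* barcode."""
    from .demux import edit_distance

    out: list[str] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 300000:
            raise SimulationError("could not build a safe barcode set; relax constraints")
        cand = _random_dna(rng, length)
        if all(edit_distance(cand, s) >= min_distance for s in out):
            out.append(cand)
    prefix = "F" if side == "forward" else "R"
    return [Barcode(f"{prefix}{i+1:02d}", s, side) for i, s in enumerate(out)]


def _random_primer_set(rng: np.random.Generator, n: int, length: int = 20, min_distance: int = 8) -> list[str]:
    from .demux import edit_distance

    out: list[str] = []
    while len(out) < n:
        cand = _random_dna(rng, length)
        if all(edit_distance(cand, s) >= min_distance for s in out):
            out.append(cand)
    return out


#: Motifs cycled across simulated loci (di-, tri-, tetranucleotide).
DEFAULT_MOTIFS = ("AC", "AGC", "ACGT")

_REF_REPEATS = 15  # repeat copies at the reference (mid-range) allele
_REPEAT_SPAN = 5  # alleles drawn at +/- this many copies around the reference


def make_panel(
    rng: np.random.Generator,
    n_individuals: int = 16,
    n_loci: int = 12,
    n_fwd_barcodes: int = 12,
    n_rev_barcodes: int = 8,
    barcode_length: int = 10,
    scheme: str = "3-PCR",
    motifs: tuple[str, ...] = DEFAULT_MOTIFS,
) -> tuple[PanelConfig, dict[str, LocusTemplate]]:
    """Build a self-consistent synthetic panel plus per-locus templates.

    Loci are spread round-robin over the three amplicon size classes and the
    given motifs; flank lengths are set so the reference allele (15 repeat
    copies) sits at the centre of its size-class band.
    """
    fwd = random_barcode_set(rng, n_fwd_barcodes, "forward", barcode_length)
    rev = random_barcode_set(rng, n_rev_barcodes, "reverse", barcode_length)
    fwd_tail = UniversalTail("tailF", _random_dna(rng, 18), "forward")
    rev_tail = UniversalTail("tailR", _random_dna(rng, 18), "reverse")
    fwd_primers = _random_primer_set(rng, n_loci)
    rev_primers = _random_primer_set(rng, n_loci)

    overhead = (
        2 * barcode_length + len(fwd_tail.sequence) + len(rev_tail.sequence) + 2 * 20
    )
    loci: list[LocusDef] = []
    templates: dict[str, LocusTemplate] = {}
    classes = ("I", "II", "III")
    for i in range(n_loci):
        size_class = classes[i % 3]
        motif = motifs[i % len(motifs)]
        lo, hi = SIZE_CLASS_RANGES[size_class]
        center = (lo + hi) // 2
        tract_ref = _REF_REPEATS * len(motif)
        flank_total = center - overhead - tract_ref
        if flank_total < 16:
            raise SimulationError(
                f"size class {size_class} cannot host {motif} x {_REF_REPEATS} "
                "with this construct; shorten tails/primers"
            )
        locus = LocusDef(
            name=f"Loc{i+1:02d}",
            fwd_primer=fwd_primers[i],
            rev_primer=rev_primers[i],
            motif=motif,
            size_class=size_class,
            expected_range=(lo, hi),
            multiplex_id=f"mp{i % 3 + 1}",
        )
        loci.append(locus)
        left = flank_total // 2
        templates[locus.name] = LocusTemplate(
            locus, _random_dna(rng, left), _random_dna(rng, flank_total - left)
        )

    individuals = [f"ind{i+1:03d}" for i in range(n_individuals)]
    sheet = build_combinatorial_table(fwd, rev, individuals)
    panel = PanelConfig(
        forward_barcodes=fwd,
        reverse_barcodes=rev,
        forward_tail=fwd_tail,
        reverse_tail=rev_tail,
        loci=loci,
        sample_sheet=sheet,
        scheme=scheme,
    )
    for pool in (fwd, rev):
        rep = validate_barcode_set(pool, tolerance=2)
        assert rep["safe"], "generated barcode set is not SAFE"
    return panel, templates


def synthesize_insert(
    panel: PanelConfig, template: LocusTemplate, target_amplicon_length: int
) -> tuple[str, tuple[int, int]]:
    """Insert whose amplicon has exactly ``target_amplicon_length`` bp.

    The repeat count is rounded down to a whole number of motif copies and
    the right flank absorbs the remainder (logged); at least one full copy
    is required.
    """
    m = len(template.locus.motif)
    overhead = panel.fixed_overhead(template.locus)
    fixed = overhead + len(template.flank_left) + len(template.flank_right)
    tract_len = target_amplicon_length - fixed
    if tract_len < m:
        raise SimulationError(
            f"{template.locus.name}: target {target_amplicon_length} bp leaves no room "
            "for a repeat tract"
        )
    k, rem = divmod(tract_len, m)
    flank_right = template.flank_right
    if rem:
        logger.info(
            "%s: target %d bp off-lattice; extending right flank by %d",
            template.locus.name, target_amplicon_length, rem,
        )
        flank_right = template.flank_right + template.flank_right[:rem]
    insert, _ = LocusTemplate(template.locus, template.flank_left, flank_right).insert_for_repeats(k)
    s = len(template.flank_left)
    return insert, (s, s + k * m)


def _apply_variant(insert: str, tract: tuple[int, int], v: PlantedVariant) -> str:
    if v.kind == "snp":
        return insert[: v.position] + v.alt + insert[v.position + 1 :]
    # compensated indel: delete at position, insert `alt` at position2 (> position)
    assert v.position2 is not None and v.position2 > v.position
    out = insert[: v.position] + insert[v.position + 1 :]
    q = v.position2 - 1  # account for the deletion upstream
    return out[:q] + v.alt + out[q:]


def simulate_genotypes(
    panel: PanelConfig,
    templates: dict[str, LocusTemplate],
    rng: np.random.Generator,
    het_prob: float = 0.5,
    homoplasy_prevalence: float = 0.0,
    homoplasy_snp_share: float = 0.8,
) -> list[TruthGenotype]:
    """Draw one genotype per individual x locus.

    With probability ``het_prob`` a genotype is heterozygous for two repeat
    counts (allele lengths differing by whole motif units); with probability
    ``homoplasy_prevalence`` it is instead a same-length sequence
    heterozygote - two alleles of identical length where one flank carries a
    SNP (share ``homoplasy_snp_share``) or a compensated indel, i.e. planted
    size homoplasy.
    """
    truths: list[TruthGenotype] = []
    for ind in panel.individuals:
        for locus in panel.loci:
            tpl = templates[locus.name]
            m = len(locus.motif)
            ks = rng.integers(_REF_REPEATS - _REPEAT_SPAN, _REF_REPEATS + _REPEAT_SPAN + 1, size=2)
            u = rng.random()
            if u < homoplasy_prevalence:
                k = int(ks[0])
                insert, tract = tpl.insert_for_repeats(k)
                variant = _plant_variant(insert, tract, rng, homoplasy_snp_share)
                alt_insert = _apply_variant(insert, tract, variant)
                length = panel.fixed_overhead(locus) + len(insert)
                truths.append(
                    TruthGenotype(ind, locus.name, (length, length), (insert, alt_insert),
                                  (tract, tract), (variant,))
                )
                continue
            het = u < homoplasy_prevalence + het_prob * (1 - homoplasy_prevalence)
            if het and ks[0] != ks[1]:
                pair = sorted(int(k) for k in ks)
            else:
                pair = [int(ks[0]), int(ks[0])]
            inserts, tracts, lengths = [], [], []
            for k in pair:
                ins, tract = tpl.insert_for_repeats(k)
                inserts.append(ins)
                tracts.append(tract)
                lengths.append(panel.fixed_overhead(locus) + len(ins))
            truths.append(
                TruthGenotype(ind, locus.name, tuple(lengths), tuple(inserts), tuple(tracts))
            )
    return truths


def _plant_variant(
    insert: str, tract: tuple[int, int], rng: np.random.Generator, snp_share: float
) -> PlantedVariant:
    s, e = tract
    # pick flank positions away from the tract and the insert ends
    left = list(range(2, max(2, s - 2)))
    right = list(range(min(len(insert) - 2, e + 2), len(insert) - 2))
    flank = left + right
    pos = int(rng.choice(flank))
    if rng.random() < snp_share:
        ref = insert[pos]
        alt = _BASES[(_BASES.index(ref) + 1 + int(rng.integers(0, 3))) % 4]
        return PlantedVariant("snp", 1, pos, alt)
    # compensated indel: delete in the left flank, re-insert in the right flank
    if not left or not right:
        ref = insert[pos]
        alt = _BASES[(_BASES.index(ref) + 1) % 4]
        return PlantedVariant("snp", 1, pos, alt)
    p = int(rng.choice(left))
    q = int(rng.choice(right))
    return PlantedVariant("indel", 1, p, _BASES[int(rng.integers(0, 4))], q)


def apply_errors(
    seq: str, rng: np.random.Generator, model: ErrorModel
) -> tuple[str, np.ndarray]:
    """Mutate one read; returns (sequence, error positions in input coords)."""
    n = len(seq)
    if model.rate == 0.0 or n == 0:
        return seq, np.empty(0, dtype=int)
    rates = np.full(n, model.rate)
    if model.homopolymer_multiplier != 1.0:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        hp = np.concatenate(([False], arr[1:] == arr[:-1]))
        rates[hp] = np.minimum(1.0, rates[hp] * model.homopolymer_multiplier)
    hits = np.nonzero(rng.random(n) < rates)[0]
    if hits.size == 0:
        return seq, hits
    kinds = rng.random(hits.size)
    extra = rng.integers(0, 4, size=hits.size)
    parts: list[str] = []
    prev = 0
    s_frac = model.substitution_fraction
    si_frac = s_frac + model.insertion_fraction
    for pos, kv, xb in zip(hits, kinds, extra):
        parts.append(seq[prev:pos])
        if kv < s_frac:  # substitution to a different base
            parts.append(_BASES[(_BASES.index(seq[pos]) + 1 + xb % 3) % 4])
        elif kv < si_frac:  # insertion after the base
            parts.append(seq[pos])
            parts.append(_BASES[xb])
        # else deletion: emit nothing
        prev = pos + 1
    parts.append(seq[prev:])
    return "".join(parts), hits


def generate_reads(
    truths: list[TruthGenotype],
    panel: PanelConfig,
    error_model: ErrorModel | None = None,
    coverage_model: CoverageModel | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Expand truth genotypes into reads plus a per-read manifest.

    Reads are the full amplicon or its reverse complement (probability 0.5
    each) with per-base errors applied.  The manifest records, per read, the
    true origin, orientation, and the number of planted errors falling in
    each identifying element of the construct (both barcodes, both primers),
    so demultiplexing can be scored against tolerance exactly.
    """
    error_model = error_model or ErrorModel()
    coverage_model = coverage_model or CoverageModel()
    rng = rng or np.random.default_rng(0)
    reads: list[tuple[str, str]] = []
    rows: list[dict] = []
    counter = 0
    for t in truths:
        locus = panel.locus(t.locus)
        f_id, r_id = panel.sample_sheet.barcode_pair(t.individual)
        fb = panel.barcode(f_id, "forward").sequence
        rb = panel.barcode(r_id, "reverse").sequence
        amplicons = [expected_amplicon(panel, locus, t.individual, ins) for ins in t.allele_inserts]
        mu = coverage_model.class_mean(locus.size_class)
        k = coverage_model.dispersion
        n_reads = int(rng.negative_binomial(k, k / (k + mu)))
        for _ in range(n_reads):
            allele = int(rng.integers(0, len(amplicons)))
            amp = amplicons[allele]
            # element intervals on the error-free amplicon
            b1 = (0, len(fb))
            p1s = len(fb) + len(panel.forward_tail.sequence)
            p1 = (p1s, p1s + len(locus.fwd_primer))
            p2e = len(amp) - len(rb) - len(panel.reverse_tail.sequence)
            p2 = (p2e - len(locus.rev_primer), p2e)
            b2 = (len(amp) - len(rb), len(amp))
            mutated, hits = apply_errors(amp, rng, error_model)
            if coverage_model.truncation_prob > 0 and rng.random() < coverage_model.truncation_prob:
                cut = int(rng.geometric(1.0 / coverage_model.truncation_mean))
                mutated = mutated[: max(30, len(mutated) - cut)]
            orientation = "+" if rng.random() < 0.5 else "-"
            seq = mutated if orientation == "+" else reverse_complement(mutated)
            rid = f"read{counter:07d}"
            counter += 1
            reads.append((rid, seq))
            rows.append(
                {
                    "read_id": rid,
                    "individual": t.individual,
                    "locus": t.locus,
                    "allele_index": allele,
                    "allele_length": t.allele_lengths[allele],
                    "orientation": orientation,
                    "n_errors": int(hits.size),
                    "err_fwd_barcode": int(((hits >= b1[0]) & (hits < b1[1])).sum()),
                    "err_fwd_primer": int(((hits >= p1[0]) & (hits < p1[1])).sum()),
                    "err_rev_primer": int(((hits >= p2[0]) & (hits < p2[1])).sum()),
                    "err_rev_barcode": int(((hits >= b2[0]) & (hits < b2[1])).sum()),
                }
            )
    manifest = pd.DataFrame(
        rows,
        columns=[
            "read_id", "individual", "locus", "allele_index", "allele_length",
            "orientation", "n_errors", "err_fwd_barcode", "err_fwd_primer",
            "err_rev_primer", "err_rev_barcode",
        ],
    )
    return reads, manifest


def write_fastq(reads: list[tuple[str, str]], path, quality_char: str = "D") -> None:
    """Write reads as Sanger FASTQ with a constant placeholder quality
    (Q35; qualities are not used downstream)."""
    with open(Path(path), "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


def write_fasta(reads: list[tuple[str, str]], path) -> None:
    with open(Path(path), "w") as fh:
        for rid, seq in reads:
            fh.write(f">{rid}\n{seq}\n")
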