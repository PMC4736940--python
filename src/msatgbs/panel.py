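"""Amplicon panel definitions for combinatorially barcoded microsatellite GBS.

A panel describes the four-primer PCR construct used to tag every amplicon
with an individual-specific pair of DNA barcodes:

    fwdBarcode - fwdTail - fwdPrimer - insert - revPrimer' - revTail' - revBarcode'

(primed parts are reverse-complemented on the top strand).  An individual is
identified by the *pair* (forward barcode, reverse barcode), so F x R
individuals are distinguishable with only F + R oligos.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import yaml

from ._seq import reverse_complement, validate_dna

SIZE_CLASSES = ("I", "II", "III")

#: Default full-amplicon length band per size class (bp).
SIZE_CLASS_RANGES = {"I": (115, 213), "II": (203, 320), "III": (265, 416)}

SCHEMES = ("3-PCR", "6-PCR", "18-PCR")


class PanelError(ValueError):
    """Invalid panel configuration."""


@dataclass(frozen=True)
class Barcode:
    """A sample-identifying oligo, nominally 10 bp, on one side of the construct."""

    id: str
    sequence: str
    side: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        validate_dna(self.sequence, what=f"barcode {self.id}")
        if self.side not in ("forward", "reverse"):
            raise PanelError(f"barcode side must be forward/reverse, got {self.side!r}")


@dataclass(frozen=True)
class UniversalTail:
    """Universal primer sequence appended 5' of a locus-specific primer."""

    id: str
    sequence: str
    side: str

    def __post_init__(self) -> None:
        validate_dna(self.sequence, what=f"tail {self.id}")


@dataclass(frozen=True)
class LocusDef:
    """One microsatellite locus: primers (tails excluded), motif and size band."""

    name: str
    fwd_primer: str
    rev_primer: str
    motif: str
    size_class: str
    expected_range: tuple[int, int]
    multiplex_id: str = ""

    def __post_init__(self) -> None:
        if not self.fwd_primer or not self.rev_primer:
            raise PanelError(f"locus {self.name}: primers must be non-empty")
        validate_dna(self.fwd_primer, what=f"{self.name} fwd primer")
        validate_dna(self.rev_primer, what=f"{self.name} rev primer")
        validate_dna(self.motif, what=f"{self.name} motif")
        if self.size_class not in SIZE_CLASSES:
            raise PanelError(f"locus {self.name}: unknown size class {self.size_class!r}")
        lo, hi = self.expected_range
        if lo <= 0 or hi < lo:
            raise PanelError(f"locus {self.name}: bad expected range {self.expected_range}")

    @property
    def midpoint(self) -> float:
        lo, hi = self.expected_range
        return (lo + hi) / 2.0


@dataclass
class SampleSheet:
    """Rows of (individual, forward barcode id, reverse barcode id)."""

    rows: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        pairs = [(f, r) for _, f, r in self.rows]
        if len(set(pairs)) != len(pairs):
            raise PanelError("sample sheet: a (forward, reverse) barcode pair is reused")
        inds = [i for i, _, _ in self.rows]
        if len(set(inds)) != len(inds):
            raise PanelError("sample sheet: duplicate individual id")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def barcode_pair(self, individual: str) -> tuple[str, str]:
        for ind, f, r in self.rows:
            if ind == individual:
                return f, r
        raise KeyError(individual)

    def individual_for(self, fwd_id: str, rev_id: str) -> str | None:
        for ind, f, r in self.rows:
            if f == fwd_id and r == rev_id:
                return ind
        return None


@dataclass
class PanelConfig:
    forward_barcodes: list[Barcode]
    reverse_barcodes: list[Barcode]
    forward_tail: UniversalTail
    reverse_tail: UniversalTail
    loci: list[LocusDef]
    sample_sheet: SampleSheet
    scheme: str = "3-PCR"
    size_class_weights: dict[str, float] = field(
        default_factory=lambda: {"I": 1.0, "II": 1.0, "III": 8.0}
    )

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise PanelError(f"unknown PCR scheme {self.scheme!r}")
        if any(w <= 0 for w in self.size_class_weights.values()):
            raise PanelError("size-class weights must be positive")
        fwd_ids = {b.id for b in self.forward_barcodes}
        rev_ids = {b.id for b in self.reverse_barcodes}
        for _, f, r in self.sample_sheet:
            if f not in fwd_ids or r not in rev_ids:
                raise PanelError(f"sample sheet references unknown barcode {f!r}/{r!r}")
        names = [loc.name for loc in self.loci]
        if len(set(names)) != len(names):
            raise PanelError("duplicate locus name")

    # -- lookups -------------------------------------------------------
    def barcode(self, bc_id: str, side: str) -> Barcode:
        pool = self.forward_barcodes if side == "forward" else self.reverse_barcodes
        for b in pool:
            if b.id == bc_id:
                return b
        raise PanelError(f"unknown {side} barcode id {bc_id!r}")

    def locus(self, name: str) -> LocusDef:
        for loc in self.loci:
            if loc.name == name:
                return loc
        raise PanelError(f"unknown locus {name!r}")

    @property
    def individuals(self) -> list[str]:
        return [ind for ind, _, _ in self.sample_sheet]

    def fixed_overhead(self, locus: LocusDef) -> int:
        """Length contributed by everything except the insert (bp)."""
        row = next(r for r in self.sample_sheet.rows)
        fb = self.barcode(row[1], "forward")
        rb = self.barcode(row[2], "reverse")
        return (
            len(fb.sequence)
            + len(self.forward_tail.sequence)
            + len(locus.fwd_primer)
            + len(locus.rev_primer)
            + len(self.reverse_tail.sequence)
            + len(rb.sequence)
        )

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "size_class_weights": dict(self.size_class_weights),
            "forward_tail": {"id": self.forward_tail.id, "sequence": self.forward_tail.sequence},
            "reverse_tail": {"id": self.reverse_tail.id, "sequence": self.reverse_tail.sequence},
            "forward_barcodes": [{"id": b.id, "sequence": b.sequence} for b in self.forward_barcodes],
            "reverse_barcodes": [{"id": b.id, "sequence": b.sequence} for b in self.reverse_barcodes],
            "loci": [
                {
                    "name": l.name,
                    "fwd_primer": l.fwd_primer,
                    "rev_primer": l.rev_primer,
                    "motif": l.motif,
                    "size_class": l.size_class,
                    "min_len": l.expected_range[0],
                    "max_len": l.expected_range[1],
                    "multiplex": l.multiplex_id,
                }
                for l in self.loci
            ],
            "sample_sheet": [
                {"individual": i, "fwd_barcode": f, "rev_barcode": r}
                for i, f, r in self.sample_sheet
            ],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "PanelConfig":
        return cls(
            forward_barcodes=[Barcode(b["id"], b["sequence"], "forward") for b in d["forward_barcodes"]],
            reverse_barcodes=[Barcode(b["id"], b["sequence"], "reverse") for b in d["reverse_barcodes"]],
            forward_tail=UniversalTail(d["forward_tail"]["id"], d["forward_tail"]["sequence"], "forward"),
            reverse_tail=UniversalTail(d["reverse_tail"]["id"], d["reverse_tail"]["sequence"], "reverse"),
            loci=[
                LocusDef(
                    name=l["name"],
                    fwd_primer=l["fwd_primer"],
                    rev_primer=l["rev_primer"],
                    motif=l["motif"],
                    size_class=l["size_class"],
                    expected_range=(int(l["min_len"]), int(l["max_len"])),
                    multiplex_id=str(l.get("multiplex", "")),
                )
                for l in d["loci"]
            ],
            sample_sheet=SampleSheet(
                [(r["individual"], r["fwd_barcode"], r["rev_barcode"]) for r in d["sample_sheet"]]
            ),
            scheme=d.get("scheme", "3-PCR"),
            size_class_weights={k: float(v) for k, v in d.get(
                "size_class_weights", {"I": 1.0, "II": 1.0, "III": 8.0}
            ).items()},
        )

    @classmethod
    def load(cls, path) -> "PanelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def build_combinatorial_table(
    fwd: list[Barcode], rev: list[Barcode], individuals: list[str]
) -> SampleSheet:
    """Assign each individual a distinct (forward, reverse) barcode pair.

    Pairs are taken in row-major order with the forward barcode varying
    slowest, so the assignment is reproducible for a given barcode ordering.
    With 12 forward and 8 reverse barcodes, up to 96 individuals can be
    tagged.
    """
    for pool, side in ((fwd, "forward"), (rev, "reverse")):
        ids = [b.id for b in pool]
        if len(set(ids)) != len(ids):
            raise PanelError(f"duplicate {side} barcode id")
    capacity = len(fwd) * len(rev)
    if len(individuals) > capacity:
        raise PanelError(
            f"{len(individuals)} individuals exceed the combinatorial capacity "
            f"{len(fwd)} x {len(rev)} = {capacity}"
        )
    pairs = itertools.product(fwd, rev)
    return SampleSheet(
        [(ind, f.id, r.id) for ind, (f, r) in zip(individuals, pairs)]
    )


def validate_barcode_set(barcodes: list[Barcode], tolerance: int) -> dict:
    """Check a one-sided barcode set against a demultiplexing tolerance.

    A set is SAFE when the minimum pairwise Levenshtein distance exceeds
    2 x tolerance: any read within `tolerance` errors of one barcode is then
    strictly closer to it than to every other barcode, so fuzzy assignment
    cannot be ambiguous.  This is a sufficient (conservative) condition.
    """
    from .demux import edit_distance  # local import to avoid a cycle

    if tolerance < 0:
        raise PanelError("tolerance must be non-negative")
    seqs = [b.sequence for b in barcodes]
    problems: list[str] = []
    if len(set(seqs)) != len(seqs):
        problems.append("duplicate sequence")
    min_dist = None
    for a, b in itertools.combinations(seqs, 2):
        d = edit_distance(a, b)
        min_dist = d if min_dist is None else min(min_dist, d)
    safe = not problems and (min_dist is None or min_dist > 2 * tolerance)
    return {
        "n": len(barcodes),
        "min_pairwise_distance": min_dist,
        "tolerance": tolerance,
        "safe": safe,
        "problems": problems,
    }


def expected_amplicon(
    panel: PanelConfig, locus: LocusDef, individual: str, insert: str
) -> str:
    """Error-free amplicon for one individual/locus/insert (top strand)."""
    if not insert:
        raise PanelError("insert must be non-empty")
    f_id, r_id = panel.sample_sheet.barcode_pair(individual)
    fb = panel.barcode(f_id, "forward")
    rb = panel.barcode(r_id, "reverse")
    return (
        fb.sequence
        + panel.forward_tail.sequence
        + locus.fwd_primer
        + insert
        + reverse_complement(locus.rev_primer)
        + reverse_complement(panel.reverse_tail.sequence)
        + reverse_complement(rb.sequence)
    )
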