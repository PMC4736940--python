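"""Panel construction: barcode combinatorics, safety validation, amplicon
assembly and config round-trips."""

import itertools

import numpy as np
import pytest

from msatgbs._seq import reverse_complement
from msatgbs.panel import (
    Barcode,
    LocusDef,
    PanelConfig,
    PanelError,
    build_combinatorial_table,
    expected_amplicon,
    validate_barcode_set,
)
from msatgbs.simulate import make_panel, simulate_genotypes


def _codes(n, side, length=10, seed=0):
    rng = np.random.default_rng(seed)
    return [
        Barcode(f"{side[0]}{i}", "".join("ACGT"[b] for b in rng.integers(0, 4, length)), side)
        for i in range(n)
    ]


def _dp_levenshtein(a: str, b: str) -> int:
    """Independent full-table dynamic-programming oracle."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


class TestCombinatorialTable:
    @pytest.mark.parametrize(
        "n_fwd,n_rev,n_ind",
        [(12, 8, 96), (1, 1, 1), (3, 2, 6)],
    )
    def test_distinct_pairs(self, n_fwd, n_rev, n_ind):
        sheet = build_combinatorial_table(
            _codes(n_fwd, "forward"), _codes(n_rev, "reverse", seed=1),
            [f"ind{i}" for i in range(n_ind)],
        )
        pairs = [(f, r) for _, f, r in sheet]
        assert len(sheet) == n_ind
        assert len(set(pairs)) == n_ind

    def test_exhaustive_enumeration_3x2(self):
        fwd, rev = _codes(3, "forward"), _codes(2, "reverse", seed=1)
        sheet = build_combinatorial_table(fwd, rev, [f"i{k}" for k in range(6)])
        expected = list(itertools.product([b.id for b in fwd], [b.id for b in rev]))
        assert [(f, r) for _, f, r in sheet] == expected  # row-major, fwd slowest

    def test_capacity_error(self):
        with pytest.raises(PanelError, match="capacity"):
            build_combinatorial_table(
                _codes(2, "forward"), _codes(2, "reverse", seed=1),
                [f"i{k}" for k in range(5)],
            )


class TestValidateBarcodeSet:
    def test_safe_pair(self):
        bcs = [Barcode("a", "AAAAAAAAAA", "forward"), Barcode("b", "TTTTTTTTTT", "forward")]
        rep = validate_barcode_set(bcs, tolerance=2)
        assert rep["min_pairwise_distance"] == 10
        assert rep["safe"]

    def test_unsafe_pair(self):
        bcs = [Barcode("a", "AAAAAAAAAA", "forward"), Barcode("b", "AAAAAAAATT", "forward")]
        rep = validate_barcode_set(bcs, tolerance=2)
        assert rep["min_pairwise_distance"] == 2
        assert not rep["safe"]

    def test_duplicate_sequence_fails(self):
        bcs = [Barcode("a", "ACGTACGTAC", "forward"), Barcode("b", "ACGTACGTAC", "forward")]
        assert not validate_barcode_set(bcs, tolerance=0)["safe"]

    def test_min_distance_matches_dp_oracle(self):
        bcs = _codes(12, "forward", seed=5)
        rep = validate_barcode_set(bcs, tolerance=2)
        oracle = min(
            _dp_levenshtein(a.sequence, b.sequence)
            for a, b in itertools.combinations(bcs, 2)
        )
        assert rep["min_pairwise_distance"] == oracle


class TestExpectedAmplicon:
    def test_concatenation_oracle(self, small_panel):
        panel, templates = small_panel
        locus = panel.loci[0]
        ind = panel.individuals[0]
        insert = "ACGTACGTTT"
        f_id, r_id = panel.sample_sheet.barcode_pair(ind)
        manual = (
            panel.barcode(f_id, "forward").sequence
            + panel.forward_tail.sequence
            + locus.fwd_primer
            + insert
            + reverse_complement(locus.rev_primer)
            + reverse_complement(panel.reverse_tail.sequence)
            + reverse_complement(panel.barcode(r_id, "reverse").sequence)
        )
        assert expected_amplicon(panel, locus, ind, insert) == manual

    def test_length_conservation_many_random_inserts(self, small_panel):
        panel, _ = small_panel
        rng = np.random.default_rng(3)
        locus = panel.loci[1]
        ind = panel.individuals[2]
        overhead = panel.fixed_overhead(locus)
        for _ in range(200):
            n = int(rng.integers(1, 120))
            insert = "".join("ACGT"[b] for b in rng.integers(0, 4, n))
            assert len(expected_amplicon(panel, locus, ind, insert)) == overhead + n

    def test_empty_insert_rejected(self, small_panel):
        panel, _ = small_panel
        with pytest.raises(PanelError):
            expected_amplicon(panel, panel.loci[0], panel.individuals[0], "")


class TestPanelConfig:
    def test_yaml_round_trip(self, small_panel, tmp_path):
        panel, _ = small_panel
        path = tmp_path / "panel.yaml"
        panel.save(path)
        loaded = PanelConfig.load(path)
        assert loaded.to_dict() == panel.to_dict()

    def test_unknown_scheme_rejected(self, small_panel):
        panel, _ = small_panel
        d = panel.to_dict()
        d["scheme"] = "9-PCR"
        with pytest.raises(PanelError):
            PanelConfig.from_dict(d)

    def test_bad_motif_rejected(self):
        with pytest.raises(ValueError):
            LocusDef("L", "ACGT", "ACGT", "AXC", "I", (115, 213))

    def test_sample_sheet_pairs_injective(self, small_panel):
        panel, _ = small_panel
        pairs = [(f, r) for _, f, r in panel.sample_sheet]
        assert len(set(pairs)) == len(pairs)


def test_generated_panels_are_safe_and_alleles_on_lattice():
    """Simulator panels are SAFE and drawn alleles differ by whole motifs."""
    rng = np.random.default_rng(11)
    panel, templates = make_panel(rng, n_individuals=4, n_loci=3)
    for pool in (panel.forward_barcodes, panel.reverse_barcodes):
        assert validate_barcode_set(pool, tolerance=2)["safe"]
    truths = simulate_genotypes(panel, templates, rng, het_prob=0.7)
    for t in truths:
        m = len(panel.locus(t.locus).motif)
        lo, hi = panel.locus(t.locus).expected_range
        a, b = sorted(t.allele_lengths)
        assert (b - a) % m == 0
        assert lo <= a <= b <= hi
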