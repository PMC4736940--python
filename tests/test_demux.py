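"""Fuzzy demultiplexing: edit distance, element search, read assignment and
binning, scored against an independent DP oracle and the simulator manifest."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msatgbs import simulate as sim
from msatgbs._seq import reverse_complement
from msatgbs.demux import (
    DemuxTolerances,
    assign_read,
    demultiplex,
    edit_distance,
    find_element,
)

DNA = st.text(alphabet="ACGT", min_size=0, max_size=25)


def _dp_levenshtein(a, b):
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


class TestEditDistance:
    @pytest.mark.parametrize(
        "a,b,d", [("ACGT", "ACGT", 0), ("AAAA", "AAA", 1), ("", "ACG", 3), ("AC", "", 2)]
    )
    def test_examples(self, a, b, d):
        assert edit_distance(a, b) == d

    def test_500_random_pairs_match_dp_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            a = "".join("ACGT"[x] for x in rng.integers(0, 4, rng.integers(0, 30)))
            b = "".join("ACGT"[x] for x in rng.integers(0, 4, rng.integers(0, 30)))
            assert edit_distance(a, b) == _dp_levenshtein(a, b)

    @settings(deadline=None, max_examples=120, derandomize=True)
    @given(DNA, DNA, DNA)
    def test_metric_properties(self, a, b, c):
        assert edit_distance(a, b) == edit_distance(b, a)
        assert (edit_distance(a, b) == 0) == (a == b)
        assert edit_distance(a, c) <= edit_distance(a, b) + edit_distance(b, c)


class TestFindElement:
    BCS = {"b1": "AAAAACCCCC", "b2": "GGGGGTTTTT"}

    def test_exact_prefix_match(self):
        m = find_element("AAAAACCCCC" + "ACGT" * 10, self.BCS, 2, (0, 12))
        assert (m.candidate_id, m.distance, m.status) == ("b1", 0, "unique")
        assert m.interval == (0, 10)

    def test_two_substitutions_within_tolerance(self):
        read = "ATAAACCCCG" + "ACGT" * 10  # two substitutions in b1
        m = find_element(read, self.BCS, 2, (0, 12))
        assert (m.candidate_id, m.distance) == ("b1", 2)

    def test_three_substitutions_rejected(self):
        read = "ATAACCCCGG" + "ACGT" * 10
        m = find_element(read, self.BCS, 2, (0, 12))
        assert m.status == "none"

    def test_tie_is_ambiguous_not_guessed(self):
        cands = {"x": "AAAA", "y": "AAAT"}
        m = find_element("AAAC" + "G" * 10, cands, 2, (0, 6))
        assert m.status == "ambiguous"
        assert m.tied_ids == ("x", "y")

    def test_empty_candidates_error(self):
        with pytest.raises(ValueError):
            find_element("ACGT", {}, 2)


class TestAssignRead:
    def test_error_free_read_and_its_reverse_complement(self, simulated_run):
        panel, templates, truths, _, _ = simulated_run
        t = truths[0]
        locus = panel.locus(t.locus)
        amp = sim.expected_amplicon(panel, locus, t.individual, t.allele_inserts[0])
        fwd = assign_read("r+", amp, panel)
        rev = assign_read("r-", reverse_complement(amp), panel)
        assert (fwd.individual, fwd.locus, fwd.orientation) == (t.individual, t.locus, "+")
        assert (rev.individual, rev.locus, rev.orientation) == (t.individual, t.locus, "-")
        assert rev.sequence == amp  # oriented back to + strand

    def test_rejection_is_a_value_with_reason(self, small_panel):
        panel, _ = small_panel
        junk = "ACGT" * 60
        a = assign_read("junk", junk, panel)
        assert not a.assigned
        assert a.reject_reason in {
            "no_fwd_barcode", "no_fwd_primer", "no_rev_primer",
            "no_rev_barcode", "ambiguous", "locus_conflict", "both_orientations",
        }


class TestDemultiplex:
    def test_empty_input(self, small_panel):
        panel, _ = small_panel
        result = demultiplex([], panel)
        assert result.n_input == 0 and result.bins == {}

    def test_conservation_and_order_independence(self, simulated_run):
        panel, _, _, reads, _ = simulated_run
        sub = reads[:600]
        res = demultiplex(sub, panel)
        assert res.n_input == res.n_assigned + sum(res.reject_counts.values()) + res.n_malformed
        shuffled = list(reversed(sub))
        res2 = demultiplex(shuffled, panel)
        assert {k: [a.read_id for a in v] for k, v in res.bins.items()} == {
            k: [a.read_id for a in v] for k, v in res2.bins.items()
        }

    def test_no_misassignment_and_counts_match_manifest(self, simulated_run):
        """Assigned reads never contradict the simulator manifest; reads with
        all four elements within tolerance are assigned correctly."""
        panel, _, _, reads, manifest = simulated_run
        res = demultiplex(reads, panel)
        truth = manifest.set_index("read_id")
        n_in_tol = n_in_tol_assigned = 0
        assigned_ids = {}
        for key, group in res.bins.items():
            for a in group:
                assigned_ids[a.read_id] = key
        for rid, row in truth.iterrows():
            if rid in assigned_ids:
                assert assigned_ids[rid] == (row["individual"], row["locus"])
            within = (
                row["err_fwd_barcode"] <= 2 and row["err_rev_barcode"] <= 2
                and row["err_fwd_primer"] <= 3 and row["err_rev_primer"] <= 3
            )
            if within:
                n_in_tol += 1
                n_in_tol_assigned += rid in assigned_ids
        # most within-tolerance reads are recovered; the barcode identity
        # margin deliberately sacrifices reads whose window also resembles
        # a second code, trading yield for zero misassignment
        assert n_in_tol_assigned / n_in_tol > 0.75

    def test_yield_report_medians_on_toy_bins(self, small_panel):
        panel, templates = small_panel
        rng = np.random.default_rng(1)
        truths = sim.simulate_genotypes(panel, templates, rng, het_prob=0.0)
        em = sim.ErrorModel(rate=0.0)
        cov = sim.CoverageModel(mean=8, weights={"I": 1.0, "II": 1.0, "III": 1.0})
        reads, manifest = sim.generate_reads(truths, panel, em, cov, rng)
        res = demultiplex(reads, panel)
        rep = res.yield_report()
        counts = sorted(rep["per_bin"].values())
        assert rep["per_bin_stats"]["min"] == counts[0]
        assert rep["per_bin_stats"]["max"] == counts[-1]
        assert rep["per_bin_stats"]["median"] == float(np.median(counts))

    def test_error_free_reads_fully_recovered(self, small_panel):
        panel, templates = small_panel
        rng = np.random.default_rng(5)
        truths = sim.simulate_genotypes(panel, templates, rng)
        reads, manifest = sim.generate_reads(
            truths, panel, sim.ErrorModel(rate=0.0),
            sim.CoverageModel(mean=10, weights={"I": 1, "II": 1, "III": 1}), rng,
        )
        res = demultiplex(reads, panel)
        assert res.n_assigned == len(reads)
        per_bin_manifest = manifest.groupby(["individual", "locus"]).size()
        for key, group in res.bins.items():
            assert len(group) == per_bin_manifest[key]
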