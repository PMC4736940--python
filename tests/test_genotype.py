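"""Allele calling: the peak caller's decision rules, the alignment-based
length correction, and serialization."""

import numpy as np
import pytest

from msatgbs import demux as dx
from msatgbs import simulate as sim
from msatgbs.genotype import (
    CallerParams,
    build_histogram,
    call_all_bins,
    call_genotype,
    calls_to_dataframe,
    consensus,
    measure_length,
    read_genotypes,
    write_genotypes,
)
from msatgbs.panel import LocusDef

LOC = LocusDef("L", "ACGTACGTACGTACGTACGT", "TGCATGCATGCATGCATGCA", "AC", "I", (115, 213))


def _hist(counts):
    return build_histogram(("ind", "L"), sum(([k] * v for k, v in counts.items()), []))


class TestCallGenotype:
    def test_depth_below_minimum_is_insufficient(self):
        call = call_genotype(_hist({180: 4}), LOC)
        assert call.status == "insufficient_depth"

    def test_single_peak_is_homozygote(self):
        call = call_genotype(_hist({180: 20}), LOC)
        assert call.status == "called"
        assert call.genotype == (180, 180)

    def test_clear_heterozygote(self):
        call = call_genotype(_hist({180: 12, 184: 9}), LOC)
        assert call.genotype == (180, 184)

    def test_stutter_peak_absorbed(self):
        # one motif (2 bp) below the top peak at under half its height
        call = call_genotype(_hist({180: 20, 178: 8}), LOC)
        assert call.genotype == (180, 180)

    def test_stutter_sized_peak_kept_when_strong(self):
        call = call_genotype(_hist({180: 20, 178: 12}), LOC)
        assert call.genotype == (178, 180)

    def test_second_peak_below_het_ratio_ignored(self):
        call = call_genotype(_hist({180: 20, 188: 4}), LOC)  # 4 < 0.3*20
        assert call.genotype == (180, 180)

    def test_min_allele_reads_guard(self):
        call = call_genotype(_hist({180: 20, 184: 1}), LOC)
        assert call.genotype == (180, 180)

    def test_monotone_depth_gate(self):
        """Raising min_depth never increases the genotyped fraction."""
        hists = [_hist({180: d}) for d in range(1, 15)]
        called = [
            sum(call_genotype(h, LOC, CallerParams(min_depth=md)).status == "called" for h in hists)
            for md in (1, 5, 8, 12)
        ]
        assert called == sorted(called, reverse=True)


class TestConsensus:
    def test_identical_reads(self):
        assert consensus(["ACGTACGT"] * 5) == "ACGTACGT"

    def test_lone_substitution_outvoted(self):
        reads = ["ACGTACGT", "ACGTACGT", "ACCTACGT"]
        assert consensus(reads) == "ACGTACGT"


class TestEndToEnd:
    def test_error_free_reads_give_exact_truth(self, small_panel):
        panel, templates = small_panel
        rng = np.random.default_rng(31)
        truths = sim.simulate_genotypes(panel, templates, rng, het_prob=0.5)
        reads, _ = sim.generate_reads(
            truths, panel, sim.ErrorModel(rate=0.0),
            sim.CoverageModel(mean=14, weights={"I": 1, "II": 1, "III": 1}), rng,
        )
        res = dx.demultiplex(reads, panel)
        calls = call_all_bins(res.bins, panel, include_missing=False)
        truth_by = {(t.individual, t.locus): t for t in truths}
        for c in calls:
            if c.status != "called":
                continue
            assert c.genotype == tuple(sorted(truth_by[(c.individual, c.locus)].allele_lengths))

    def test_measured_and_corrected_lengths(self, small_panel):
        """Error-free reads measure the exact truth length; with 6% errors
        the corrected histogram's mode recovers it."""
        panel, templates = small_panel
        rng = np.random.default_rng(8)
        truths = sim.simulate_genotypes(panel, templates, rng, het_prob=0.0)
        t = truths[0]
        locus = panel.locus(t.locus)
        clean, _ = sim.generate_reads(
            [t], panel, sim.ErrorModel(rate=0.0), sim.CoverageModel(mean=10), rng
        )
        res = dx.demultiplex(clean, panel)
        for a in next(iter(res.bins.values())):
            assert measure_length(a)[0] == t.allele_lengths[0]
        noisy, _ = sim.generate_reads(
            [t], panel, sim.ErrorModel(), sim.CoverageModel(mean=50), rng
        )
        res = dx.demultiplex(noisy, panel)
        calls = call_all_bins(res.bins, panel, include_missing=False)
        c = calls[0]
        corr_mode = max(c.corrected_histogram.counts.items(), key=lambda kv: kv[1])[0]
        assert corr_mode == t.allele_lengths[0]
        # raw lengths carry several indel errors per read and only centre
        # loosely on the truth
        raw_mode = max(c.raw_histogram.counts.items(), key=lambda kv: kv[1])[0]
        assert abs(raw_mode - t.allele_lengths[0]) <= 5

    def test_caller_deterministic_under_read_order(self, simulated_run):
        panel, _, _, reads, _ = simulated_run
        res = dx.demultiplex(reads, panel)
        calls1 = call_all_bins(res.bins, panel)
        shuffled = {k: list(reversed(v)) for k, v in res.bins.items()}
        calls2 = call_all_bins(shuffled, panel)
        g1 = {(c.individual, c.locus): (c.status, c.genotype) for c in calls1}
        g2 = {(c.individual, c.locus): (c.status, c.genotype) for c in calls2}
        assert g1 == g2


class TestSerialization:
    def _calls(self, simulated_run):
        panel, _, _, reads, _ = simulated_run
        res = dx.demultiplex(reads, panel)
        return call_all_bins(res.bins, panel), panel

    def test_csv_round_trip(self, simulated_run, tmp_path):
        calls, _ = self._calls(simulated_run)
        path = tmp_path / "genotypes.csv"
        write_genotypes(calls, path, "csv")
        df = read_genotypes(path)
        orig = calls_to_dataframe(calls)
        for col in ("individual", "locus", "status", "depth"):
            assert list(df[col]) == list(orig[col])
        called = orig["status"] == "called"
        assert list(df.loc[called, "allele1"]) == list(orig.loc[called, "allele1"])

    def test_genepop_layout(self, simulated_run, tmp_path):
        calls, panel = self._calls(simulated_run)
        path = tmp_path / "genotypes.gen"
        write_genotypes(calls, path, "genepop")
        lines = path.read_text().splitlines()
        loci = sorted({c.locus for c in calls})
        assert lines[1 : 1 + len(loci)] == loci
        assert lines[1 + len(loci)] == "Pop"
        body = [l for l in lines[2 + len(loci) :] if " , " in l]
        assert len(body) == len({c.individual for c in calls})
        for line in body:
            fields = line.split(" , ")[1].split()
            assert all(len(f) == 6 and f.isdigit() for f in fields)
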