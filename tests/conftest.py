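"""Shared fixtures: all test data is simulated at run time."""

from __future__ import annotations

import numpy as np
import pytest

from msatgbs import demux as dx
from msatgbs import genotype as gt
from msatgbs import simulate as sim
from msatgbs._seq import reverse_complement
from msatgbs.panel import expected_amplicon


@pytest.fixture(scope="session")
def small_panel():
    """4 individuals x 3 loci (one per size class / motif)."""
    rng = np.random.default_rng(42)
    panel, templates = sim.make_panel(rng, n_individuals=4, n_loci=3)
    return panel, templates


@pytest.fixture(scope="session")
def simulated_run(small_panel):
    """Full simulated read set with truth and manifest (equal class weights
    so every bin is reasonably covered)."""
    panel, templates = small_panel
    rng = np.random.default_rng(7)
    truths = sim.simulate_genotypes(panel, templates, rng, het_prob=0.5)
    coverage = sim.CoverageModel(mean=30.0, weights={"I": 1.0, "II": 1.0, "III": 1.0})
    reads, manifest = sim.generate_reads(truths, panel, sim.ErrorModel(), coverage, rng)
    return panel, templates, truths, reads, manifest


def make_screen_bins(
    seed: int,
    fraction: float,
    n_genotypes: int = 60,
    n_individuals: int = 8,
    n_loci: int = 6,
):
    """Bins of same-length two-haplotype genotypes with a planted flank
    variant carried by an exact fraction of the reads; used by the
    homoplasy-screen tests.  Returns (panel, bins, truths)."""
    rng = np.random.default_rng(seed)
    panel, templates = sim.make_panel(rng, n_individuals=n_individuals, n_loci=n_loci)
    truths = sim.simulate_genotypes(
        panel, templates, rng, het_prob=0.0, homoplasy_prevalence=1.0
    )
    error_model = sim.ErrorModel()
    bins: dict = {}
    kept = []
    for t in truths[:n_genotypes]:
        locus = panel.locus(t.locus)
        depth = 0
        while depth < 10:
            k, mu = 6.0, 30.0
            depth = int(rng.negative_binomial(k, k / (k + mu)))
        carriers = round(fraction * depth)
        amps = [expected_amplicon(panel, locus, t.individual, ins) for ins in t.allele_inserts]
        for i in range(depth):
            amp = amps[1] if i < carriers else amps[0]
            mutated, _ = sim.apply_errors(amp, rng, error_model)
            if rng.random() < 0.5:
                mutated = reverse_complement(mutated)
            a = dx.assign_read(f"r{t.individual}_{t.locus}_{i}", mutated, panel)
            if a.assigned:
                bins.setdefault((a.individual, a.locus), []).append(a)
        kept.append(t)
    return panel, bins, kept


def genotype_accuracy(seed: int, n_individuals: int = 16, n_loci: int = 12,
                      het_prob: float = 0.5, min_depth: int = 10):
    """End-to-end accuracy of called genotypes vs truth at depth >= min_depth."""
    rng = np.random.default_rng(seed)
    panel, templates = sim.make_panel(rng, n_individuals=n_individuals, n_loci=n_loci)
    truths = sim.simulate_genotypes(panel, templates, rng, het_prob=het_prob)
    coverage = sim.CoverageModel(mean=30.0, weights=dict(panel.size_class_weights))
    reads, manifest = sim.generate_reads(truths, panel, sim.ErrorModel(), coverage, rng)
    result = dx.demultiplex(reads, panel)
    calls = gt.call_all_bins(result.bins, panel)
    truth_by_key = {(t.individual, t.locus): t for t in truths}
    n = n_ok = 0
    for c in calls:
        if c.status != "called" or c.total_depth < min_depth:
            continue
        t = truth_by_key[(c.individual, c.locus)]
        n += 1
        n_ok += c.genotype == tuple(sorted(t.allele_lengths))
    return n_ok, n
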