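"""End-to-end simulated run: panel -> reads -> demux -> calls -> screen -> stats.

Used by the command-line ``msatgbs run`` and by the acceptance checks; every
random choice flows from one integer seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import demux as dx
from . import genotype as gt
from . import homoplasy as hp
from . import simulate as sim
from . import stats as st


def run_pipeline(
    seed: int,
    out_dir=None,
    n_individuals: int = 16,
    n_loci: int = 12,
    coverage_mean: float = 30.0,
    error_rate: float = 0.06,
    het_prob: float = 0.5,
    homoplasy_prevalence: float = 0.3,
    reference_offset: int = 2,
) -> dict:
    """Simulate a barcoded amplicon experiment and analyse it start to finish.

    ``reference_offset`` shifts the emulated capillary reference sizes by a
    constant per locus, exercising the per-locus size calibration of the
    correspondence analysis.  Returns a report dict; when ``out_dir`` is
    given, genotypes, homoplasy records, model-selection tables and the
    report are written there.
    """
    rng = np.random.default_rng(seed)
    panel, templates = sim.make_panel(rng, n_individuals=n_individuals, n_loci=n_loci)
    truths = sim.simulate_genotypes(
        panel, templates, rng, het_prob=het_prob,
        homoplasy_prevalence=homoplasy_prevalence,
    )
    error_model = sim.ErrorModel(rate=error_rate)
    coverage = sim.CoverageModel(mean=coverage_mean, weights=dict(panel.size_class_weights))
    reads, manifest = sim.generate_reads(truths, panel, error_model, coverage, rng)

    result = dx.demultiplex(reads, panel)
    truth_by_read = manifest.set_index("read_id")
    n_wrong = 0
    for (ind, loc), group in result.bins.items():
        for a in group:
            row = truth_by_read.loc[a.read_id]
            if row["individual"] != ind or row["locus"] != loc:
                n_wrong += 1

    calls = gt.call_all_bins(result.bins, panel)
    truth_by_key = {(t.individual, t.locus): t for t in truths}
    n_called = n_correct = 0
    for c in calls:
        if c.status != "called":
            continue
        n_called += 1
        t = truth_by_key[(c.individual, c.locus)]
        if c.genotype == tuple(sorted(t.allele_lengths)):
            n_correct += 1

    records, n_screened, n_skipped = hp.screen_all(result.bins, calls, panel)
    summary = hp.summarize_homoplasy(records, n_screened)
    detected = {(r.individual, r.locus) for r in records}
    planted_screened = planted_found = 0
    screened_keys = set()
    for c in calls:
        if c.status == "called":
            reads_bin = result.bins.get((c.individual, c.locus), [])
            if c.total_depth >= 10 and reads_bin:
                screened_keys.add((c.individual, c.locus))
    for t in truths:
        if t.variants and (t.individual, t.locus) in screened_keys:
            planted_screened += 1
            if (t.individual, t.locus) in detected:
                planted_found += 1

    calls_df = gt.calls_to_dataframe(calls)
    reference = pd.DataFrame(
        [
            {
                "individual": t.individual,
                "locus": t.locus,
                "allele1": sorted(t.allele_lengths)[0] + reference_offset,
                "allele2": sorted(t.allele_lengths)[-1] + reference_offset,
            }
            for t in truths
        ]
    )
    corr = st.build_correspondence(calls_df, reference, panel)
    models = [
        st.ModelSpec("no_effects"),
        st.ModelSpec("reads2", ("depth_bin2",)),
        st.ModelSpec("reads3", ("depth_bin3",)),
        st.ModelSpec("mst", ("mst",)),
        st.ModelSpec("reads3_x_mst", ("depth_bin3", "mst")),
    ]
    corr_fits = st.fit_correspondence_models(corr, models)
    curve = st.correspondence_curve(corr)

    yield_df = (
        manifest.groupby(["individual", "locus"]).size().rename("read_count").reset_index()
    )
    yield_models = [
        st.ModelSpec("no_effects"),
        st.ModelSpec("individual", ("individual",)),
        st.ModelSpec("locus", ("locus",)),
    ]
    yield_fits = st.fit_yield_models(yield_df, yield_models)

    report = {
        "seed": seed,
        "n_individuals": n_individuals,
        "n_loci": n_loci,
        "n_reads": len(reads),
        "n_assigned": result.n_assigned,
        "assignment_rate": result.n_assigned / max(1, len(reads)),
        "n_misassigned": n_wrong,
        "n_genotypes_possible": n_individuals * n_loci,
        "n_called": n_called,
        "genotyping_rate": n_called / (n_individuals * n_loci),
        "genotype_accuracy": n_correct / max(1, n_called),
        "correspondence_pct": 100.0 * corr["match"].mean() if len(corr) else None,
        "n_correspondence_records": len(corr),
        "homoplasy": summary,
        "planted_homoplasy_screened": planted_screened,
        "planted_homoplasy_detected": planted_found,
        "best_correspondence_model": corr_fits[0].name,
        "best_yield_model": yield_fits[0].name,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        panel.save(out / "panel.yaml")
        gt.write_genotypes(calls, out / "genotypes.csv", "csv")
        gt.write_genotypes(calls, out / "genotypes.gen", "genepop")
        hp.records_to_dataframe(records).to_csv(out / "homoplasy_records.csv", index=False)
        st.fits_to_dataframe(corr_fits).to_csv(out / "model_selection.tsv", sep="\t", index=False)
        st.fits_to_dataframe(yield_fits).to_csv(out / "yield_model_selection.tsv", sep="\t", index=False)
        curve.to_csv(out / "correspondence_curve.tsv", sep="\t", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
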