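"""Concordance and read-yield statistics for microsatellite GBS.

Agreement between sequencing-based genotypes and reference (capillary)
genotypes is modelled as grouped Bernoulli data: candidate models partition
the genotype comparisons into cells by read-depth bin, repeat-motif type
(MST) and/or PCR size-class-combination, each cell getting its own
maximum-likelihood match proportion.  Read yield is modelled the same way
with a plug-in multinomial likelihood over category cells.  Models are
ranked by the finite-sample Akaike information criterion

    AICc = -2 logL + 2K + 2K(K+1)/(n - K - 1)

with Akaike weights exp(-dAICc/2) normalized over the compared set.  Group
contrasts use Bonferroni-corrected two-proportion z-tests and Mann-Whitney
tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

MST_LABELS = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}

#: Read-depth thresholds of the correspondence curve.
DEFAULT_CURVE_THRESHOLDS = (5, 10, 50, 100, 150, 200, 250, 300, 400, 500)


def depth_bin2(depth: int) -> str:
    return "0-5" if depth < 5 else "5+"


def depth_bin3(depth: int) -> str:
    if depth < 5:
        return "0-5"
    if depth < 10:
        return "5-10"
    return "10+"


@dataclass(frozen=True)
class ModelSpec:
    """A grouping model: the listed record columns jointly partition the
    data into cells; an empty factor list is the single-cell null model."""

    name: str
    factors: tuple[str, ...] = ()


@dataclass
class ModelFit:
    name: str
    K: int
    logL: float
    aicc: float
    daicc: float = float("nan")
    weight: float = float("nan")


# ----------------------------------------------------------------------
# correspondence with a reference genotype table


def build_correspondence(
    calls_df: pd.DataFrame,
    reference_df: pd.DataFrame,
    panel=None,
    calibrate: bool = True,
) -> pd.DataFrame:
    """Score each called genotype against the reference table.

    Capillary size calls are estimates on an instrument-specific scale, so
    per locus a single integer offset (the mode of reference minus GBS over
    all shared allele calls) is estimated first; a genotype matches when
    both offset-adjusted alleles agree.  Output rows carry depth, depth
    bins, motif-type (MST) label and PCR scheme for downstream modelling.
    """
    ref = reference_df.set_index(["individual", "locus"])
    rows = []
    called = calls_df[calls_df["status"] == "called"]
    offsets: dict[str, int] = {}
    if calibrate:
        for locus, grp in called.groupby("locus"):
            diffs: list[int] = []
            for _, r in grp.iterrows():
                key = (r["individual"], locus)
                if key not in ref.index:
                    continue
                rr = ref.loc[key]
                ga = sorted((int(r["allele1"]), int(r["allele2"])))
                ra = sorted((int(rr["allele1"]), int(rr["allele2"])))
                diffs.extend([ra[0] - ga[0], ra[1] - ga[1]])
            if diffs:
                vals, counts = np.unique(diffs, return_counts=True)
                order = sorted(zip(vals, counts), key=lambda vc: (-vc[1], abs(vc[0]), vc[0]))
                offsets[locus] = int(order[0][0])
    mst_by_locus = {}
    scheme = None
    if panel is not None:
        mst_by_locus = {l.name: MST_LABELS[len(l.motif)] for l in panel.loci}
        scheme = panel.scheme
    ref_loci = set(reference_df["locus"])
    for _, r in called.iterrows():
        locus = r["locus"]
        if locus not in ref_loci:
            continue
        key = (r["individual"], locus)
        if key not in ref.index:
            continue
        rr = ref.loc[key]
        off = offsets.get(locus, 0)
        ga = sorted((int(r["allele1"]) + off, int(r["allele2"]) + off))
        ra = sorted((int(rr["allele1"]), int(rr["allele2"])))
        depth = int(r["depth"])
        rows.append(
            {
                "individual": r["individual"],
                "locus": locus,
                "match": int(ga == ra),
                "depth": depth,
                "depth_bin2": depth_bin2(depth),
                "depth_bin3": depth_bin3(depth),
                "mst": mst_by_locus.get(locus, "unknown"),
                "scheme": scheme or "NA",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["individual", "locus", "match", "depth", "depth_bin2",
                 "depth_bin3", "mst", "scheme"],
    )


# ----------------------------------------------------------------------
# likelihoods, AICc, model ranking


def binomial_loglik(records: pd.DataFrame, model: ModelSpec) -> tuple[float, int]:
    """Grouped-Bernoulli log-likelihood at the ML cell proportions.

    logL = sum over cells [k ln(p) + (n-k) ln(1-p)] with p = k/n; the
    combinatorial constant is omitted (identical across models on the same
    records, so rankings are unaffected).  K is the number of cells.
    """
    if model.factors:
        groups = records.groupby(list(model.factors), observed=True)["match"]
        cells = [(g.sum(), g.size) for _, g in groups]
    else:
        cells = [(records["match"].sum(), len(records))]
    logL = 0.0
    for k, n in cells:
        if n == 0:
            raise ValueError(f"model {model.name}: empty cell")
        p = k / n
        if 0 < p:
            logL += k * math.log(p)
        if p < 1:
            logL += (n - k) * math.log(1 - p)
    return logL, len(cells)


def multinomial_loglik(yield_df: pd.DataFrame, model: ModelSpec,
                       count_col: str = "read_count") -> tuple[float, int]:
    """Plug-in multinomial log-likelihood over category cells.

    logL = sum_i n_i ln(n_i / N); empty cells contribute 0 to the sum but
    still count toward K (K is the number of category levels, e.g. 3 for a
    three-scheme factor).
    """
    N = yield_df[count_col].sum()
    if N <= 0:
        raise ValueError("total reads must be positive")
    if model.factors:
        counts = yield_df.groupby(list(model.factors), observed=True)[count_col].sum()
        K = 1
        for f in model.factors:
            K *= yield_df[f].nunique()
    else:
        counts = pd.Series([N])
        K = 1
    logL = 0.0
    for n_i in counts:
        if n_i > 0:
            logL += n_i * math.log(n_i / N)
    return float(logL), int(K)


def aicc(logL: float, K: int, n: int) -> float:
    """Finite-sample Akaike information criterion."""
    if n <= K + 1:
        raise ValueError(f"AICc undefined for n={n} <= K+1={K + 1}")
    return -2.0 * logL + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def rank_models(fits: list[ModelFit]) -> list[ModelFit]:
    """Fill in dAICc and Akaike weights; return fits sorted by AICc."""
    if not fits:
        raise ValueError("no model fits to rank")
    best = min(f.aicc for f in fits)
    rel = [math.exp(-(f.aicc - best) / 2.0) for f in fits]
    total = sum(rel)
    out = []
    for f, r in sorted(zip(fits, rel), key=lambda fr: fr[0].aicc):
        out.append(ModelFit(f.name, f.K, f.logL, f.aicc, f.aicc - best, r / total))
    return out


def fit_correspondence_models(
    records: pd.DataFrame, models: list[ModelSpec]
) -> list[ModelFit]:
    n = len(records)
    fits = []
    for m in models:
        logL, K = binomial_loglik(records, m)
        fits.append(ModelFit(m.name, K, logL, aicc(logL, K, n)))
    return rank_models(fits)


def fit_yield_models(
    yield_df: pd.DataFrame, models: list[ModelSpec], count_col: str = "read_count"
) -> list[ModelFit]:
    n = int(yield_df[count_col].sum())
    fits = []
    for m in models:
        logL, K = multinomial_loglik(yield_df, m, count_col)
        fits.append(ModelFit(m.name, K, logL, aicc(logL, K, n)))
    return rank_models(fits)


def fits_to_dataframe(fits: list[ModelFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"model": f.name, "K": f.K, "logL": f.logL, "AICc": f.aicc,
          "dAICc": f.daicc, "weight": f.weight} for f in fits]
    )


# ----------------------------------------------------------------------
# group contrasts


def proportion_ztests(
    groups: dict[str, tuple[int, int]], pairs: list[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Pooled-variance two-proportion z-tests, Bonferroni-corrected.

    ``groups`` maps a label to (successes, trials).  Degenerate pairs with
    zero pooled variance are reported with z = 0, p = 1 and a flag.
    """
    names = sorted(groups)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    m = len(pairs)
    rows = []
    for a, b in pairs:
        k1, n1 = groups[a]
        k2, n2 = groups[b]
        if min(n1, n2) <= 0:
            raise ValueError("group sizes must be positive")
        p1, p2 = k1 / n1, k2 / n2
        pp = (k1 + k2) / (n1 + n2)
        var = pp * (1 - pp) * (1 / n1 + 1 / n2)
        degenerate = var == 0
        z = 0.0 if degenerate else (p1 - p2) / math.sqrt(var)
        p = 1.0 if degenerate else 2.0 * sps.norm.sf(abs(z))
        rows.append(
            {
                "group1": a, "group2": b, "p1": p1, "p2": p2, "z": z,
                "p_value": p, "p_bonferroni": min(1.0, p * m),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def mannwhitney_tests(
    samples: dict[str, "np.ndarray | list"],
    pairs: list[tuple[str, str]] | None = None,
    method: str = "auto",
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per pair, Bonferroni-corrected across pairs.

    Small tie-free samples use the exact null distribution; all-tied pairs
    are reported with p = 1 and a flag.
    """
    names = sorted(samples)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    m = len(pairs)
    rows = []
    for a, b in pairs:
        x = np.asarray(samples[a], dtype=float)
        y = np.asarray(samples[b], dtype=float)
        if x.size == 0 or y.size == 0:
            raise ValueError("each group needs at least one observation")
        all_tied = np.unique(np.concatenate([x, y])).size == 1
        if all_tied:
            u, p = x.size * y.size / 2.0, 1.0
        else:
            u, p = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        rows.append(
            {
                "group1": a, "group2": b, "U": float(u), "p_value": float(p),
                "p_bonferroni": min(1.0, float(p) * m), "all_tied": all_tied,
            }
        )
    return pd.DataFrame(rows)


def per_individual_read_stats(yield_df: pd.DataFrame,
                              count_col: str = "read_count") -> pd.DataFrame:
    """Total / median / max reads per individual (rows) for group tests."""
    g = yield_df.groupby("individual")[count_col]
    return pd.DataFrame(
        {"total": g.sum(), "median": g.median(), "max": g.max()}
    ).reset_index()


# ----------------------------------------------------------------------
# correspondence vs depth threshold


def correspondence_curve(
    records: pd.DataFrame, thresholds=DEFAULT_CURVE_THRESHOLDS
) -> pd.DataFrame:
    """Match percentage among genotypes at or above each depth threshold."""
    rows = []
    for t in thresholds:
        sub = records[records["depth"] >= t]
        n = len(sub)
        rows.append(
            {
                "threshold": t,
                "n_genotypes": n,
                "pct_corresponding": (100.0 * sub["match"].mean()) if n else None,
            }
        )
    return pd.DataFrame(rows)
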