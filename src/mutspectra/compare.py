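"""Binomial enrichment of mutation types between genomic compartments.

One compartment is designated *test* and the other *reference*.  The null
model for type i is

    S_i^T ~ Binomial(O_i^T, p_i),   p_i = d_i^R * D^T / D^R,

i.e. the count of type i in the test compartment follows the reference
compartment's per-opportunity diversity for that type, rescaled by the
ratio of overall diversities so that an even shift in diversity across all
types is not flagged.  The expected count is E_i = O_i^T p_i, and the
enrichment ratio

    e_i = (d_i^T / D^T) / (d_i^R / D^R) = S_i^T / E_i

is the test compartment's relative diversity over the reference's.
P-values are exact two-tailed binomial probabilities (minimum-likelihood
convention); significance is declared below a Bonferroni-corrected level
alpha / m with m the number of testable types.

The reference spectrum is treated as fixed: sampling error in d_i^R is
ignored.  This is a good approximation when the reference holds far more
variants than the test compartment (a chromosome against the rest of the
genome, a window against all other windows); with comparably sized
compartments the test is anticonservative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import PolarizationMode
from .intervals import CompartmentSet, bin_by_score, weighted_quantiles, window_means
from .io import Genome
from .opportunities import count_contexts
from .spectrum import NO_FILTER, FrequencyFilter, SpectrumTable, tabulate

logger = logging.getLogger(__name__)

MINLIKE = "minlike"
DOUBLED = "doubled"


def binomial_pvalue(k: int, n: int, p: float, tail: str = MINLIKE) -> float:
    """Exact two-tailed binomial p-value.

    ``minlike`` sums the probability of every outcome no more likely than
    the observed one; ``doubled`` doubles the smaller one-sided tail
    (capped at 1).
    """
    if tail == MINLIKE:
        return float(stats.binomtest(k, n, p).pvalue)
    if tail == DOUBLED:
        lo = stats.binom.cdf(k, n, p)
        hi = stats.binom.sf(k - 1, n, p)
        return float(min(1.0, 2.0 * min(lo, hi)))
    raise ValueError(f"unknown tail convention {tail!r}")


def binomial_ci(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) two-sided CI on a binomial proportion."""
    res = stats.binomtest(successes, trials, 0.5).proportion_ci(
        confidence_level=level, method="exact"
    )
    return float(res.low), float(res.high)


def enrichment_test(
    test: SpectrumTable,
    ref: SpectrumTable,
    alpha: float = 0.05,
    tail: str = MINLIKE,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Per-type enrichment of ``test`` relative to ``ref``.

    Returns a frame indexed like the input tables with columns S, O, p_null,
    expected, enrichment, ci_lo, ci_hi, pvalue, significant, testable.
    Types without reference information (zero reference opportunities or
    counts) are reported but flagged untestable and excluded from the
    Bonferroni denominator.
    """
    if test.labels != ref.labels:
        raise ValueError("test and reference tables cover different type sets")
    if ref.S_tot == 0 or not np.isfinite(ref.D) or ref.D == 0:
        raise ValueError("degenerate reference compartment (no diversity)")

    f = test.D / ref.D
    n = len(test.labels)
    p_null = np.full(n, np.nan)
    expected = np.full(n, np.nan)
    enr = np.full(n, np.nan)
    pval = np.full(n, np.nan)
    ci_lo = np.full(n, np.nan)
    ci_hi = np.full(n, np.nan)
    testable = (test.O > 0) & (ref.O > 0) & (ref.S > 0)
    clamped = np.zeros(n, dtype=bool)

    for i in np.flatnonzero(testable):
        p = ref.d[i] * f
        if p > 1.0:
            clamped[i] = True
            p = 1.0
        p_null[i] = p
        O_t = int(test.O[i])
        S_t = int(test.S[i])
        expected[i] = O_t * p
        enr[i] = S_t / expected[i] if expected[i] > 0 else np.nan
        pval[i] = binomial_pvalue(S_t, O_t, p, tail=tail)
        lo, hi = binomial_ci(S_t, O_t, level=ci_level)
        if p > 0:
            ci_lo[i], ci_hi[i] = lo / p, hi / p
    if clamped.any():
        logger.warning(
            "null probability clamped to 1 for %d types", int(clamped.sum())
        )

    m = int(testable.sum())
    significant = np.zeros(n, dtype=bool)
    if m:
        significant[testable] = pval[testable] < alpha / m
    return pd.DataFrame(
        {
            "S": test.S,
            "O": test.O,
            "p_null": p_null,
            "expected": expected,
            "enrichment": enr,
            "ci_lo": ci_lo,
            "ci_hi": ci_hi,
            "pvalue": pval,
            "significant": significant,
            "testable": testable,
            "clamped": clamped,
        },
        index=test.labels,
    )


def pooled_class_enrichment(
    test: SpectrumTable, ref: SpectrumTable, alpha: float = 0.05, tail: str = MINLIKE
) -> pd.DataFrame:
    """Enrichment test on the six-class collapse of two 96-type tables."""
    return enrichment_test(
        test.collapse_to_classes(), ref.collapse_to_classes(), alpha=alpha, tail=tail
    )


def scored_bin_enrichment(
    variants: pd.DataFrame,
    genome: Genome,
    scored: CompartmentSet,
    bins: Sequence[CompartmentSet],
    reference: CompartmentSet,
    exclusions: Optional[CompartmentSet] = None,
    pol: PolarizationMode = PolarizationMode(),
    filt: FrequencyFilter = NO_FILTER,
    alpha: float = 0.05,
    classes: bool = True,
    exclude_cpg: bool = False,
) -> pd.DataFrame:
    """Enrichment within score bins against one fixed external reference.

    ``bins`` are compartments from :func:`bin_by_score` (e.g. hotspot
    intensity tiers); ``reference`` is an external compartment (e.g. the
    genome outside all hotspots) from which ``exclusions`` are subtracted on
    both sides.  Returns one row per (bin, type-or-class); empty bins are
    flagged with ``empty=True`` rather than failing.
    """
    if exclusions is not None:
        reference = reference.subtract(exclusions)
        bins = [b.drop_scores().subtract(exclusions, name=b.name) for b in bins]
    else:
        bins = [b.drop_scores() if b.scored else b for b in bins]

    ref_tab = tabulate(variants, reference, genome, pol=pol, filt=filt)
    if exclude_cpg:
        ref_tab = ref_tab.exclude_types("cpg")
    if classes:
        ref_tab = ref_tab.collapse_to_classes()
    out = []
    for comp in bins:
        opp = count_contexts(genome, comp)
        if opp.total == 0:
            res = pd.DataFrame(index=ref_tab.labels)
            res["empty"] = True
            res["bin"] = comp.name
            out.append(res)
            continue
        tab = tabulate(variants, comp, genome, pol=pol, filt=filt, opp=opp)
        if exclude_cpg:
            tab = tab.exclude_types("cpg")
        if classes:
            tab = tab.collapse_to_classes()
        res = enrichment_test(tab, ref_tab, alpha=alpha)
        res["empty"] = False
        res["bin"] = comp.name
        out.append(res)
    result = pd.concat(out)
    result.index.name = "type"
    return result.reset_index().set_index(["bin", "type"])


@dataclass
class MatchingDiagnostics:
    """How well the subsampled reference matches the test covariate."""

    test_mean: float
    matched_ref_mean: float
    unmatched_ref_mean: float
    n_test_windows: int
    n_matched_windows: int
    matched_reference: CompartmentSet


def match_reference_windows(
    test_windows: CompartmentSet,
    ref_windows: CompartmentSet,
    n_bins: int,
    seed: int,
) -> tuple[CompartmentSet, MatchingDiagnostics]:
    """Subsample reference windows to match the test covariate distribution.

    The covariate is binned into ``n_bins`` quantile bins computed on the
    test windows; reference windows are first restricted to the test's
    observed covariate range (common support) and then subsampled (seeded)
    so the reference bin proportions equal the test's.  Raises if a bin
    occupied by test windows has no reference window to draw from.
    """
    x_test = test_windows.scores()
    x_ref_all = ref_windows.scores()
    support = (x_ref_all >= x_test.min()) & (x_ref_all <= x_test.max())
    ref_rows = np.flatnonzero(support)
    x_ref = x_ref_all[support]
    edges = weighted_quantiles(
        x_test, np.ones_like(x_test), np.arange(1, n_bins) / n_bins
    )
    bins_t = np.searchsorted(edges, x_test, side="right")
    bins_r = np.searchsorted(edges, x_ref, side="right")
    t_counts = np.bincount(bins_t, minlength=n_bins)
    r_counts = np.bincount(bins_r, minlength=n_bins)
    occupied = t_counts > 0
    missing = occupied & (r_counts == 0)
    if missing.any():
        b = int(np.flatnonzero(missing)[0])
        raise ValueError(
            f"no reference windows available in covariate bin {b} "
            f"(test holds {t_counts[b]} windows there)"
        )
    scale = (r_counts[occupied] / t_counts[occupied]).min()
    rng = np.random.default_rng(seed)
    keep_rows: list[np.ndarray] = []
    for b in np.flatnonzero(occupied):
        want = max(1, int(round(scale * t_counts[b])))
        pool = np.flatnonzero(bins_r == b)
        keep_rows.append(rng.choice(pool, size=min(want, len(pool)), replace=False))
    rows = ref_rows[np.sort(np.concatenate(keep_rows))]
    matched = CompartmentSet(
        f"{ref_windows.name}_matched", ref_windows.df.iloc[rows].reset_index(drop=True)
    )
    diag = MatchingDiagnostics(
        test_mean=float(x_test.mean()),
        matched_ref_mean=float(x_ref_all[rows].mean()),
        unmatched_ref_mean=float(x_ref_all.mean()),
        n_test_windows=len(test_windows),
        n_matched_windows=len(rows),
        matched_reference=matched.drop_scores(f"{ref_windows.name}_matched"),
    )
    return diag.matched_reference, diag


def matched_comparison(
    variants: pd.DataFrame,
    genome: Genome,
    test: CompartmentSet,
    ref_pool: CompartmentSet,
    covariate: CompartmentSet,
    n_bins: int = 10,
    seed: int = 0,
    pol: PolarizationMode = PolarizationMode(),
    filt: FrequencyFilter = NO_FILTER,
    alpha: float = 0.05,
    exclude_cpg: bool = False,
    windows: Optional[CompartmentSet] = None,
    window_width: int = 1_000_000,
) -> tuple[pd.DataFrame, MatchingDiagnostics]:
    """Enrichment of ``test`` against a covariate-matched reference.

    The covariate (e.g. replication timing) is averaged over windows tiling
    the genome; reference windows are subsampled so their covariate
    distribution matches the test compartment's, and the enrichment test is
    run against the pooled matched reference.  Removes covariate-driven
    differences so that residual enrichment reflects other influences.
    """
    from .intervals import tile_windows

    if windows is None:
        windows = tile_windows(genome.extent, window_width)
    means = window_means(covariate, windows)
    wdf = windows.df.assign(score=means).dropna(subset=["score"])

    def _windows_in(comp: CompartmentSet, name: str) -> CompartmentSet:
        centre = (wdf["start"] + wdf["end"]) // 2
        inside = comp.contains(wdf["contig"].to_numpy(), centre.to_numpy())
        return CompartmentSet(name, wdf[inside].reset_index(drop=True))

    wt = _windows_in(test, f"{test.name}_windows")
    wr = _windows_in(ref_pool, f"{ref_pool.name}_windows")
    matched_ref, diag = match_reference_windows(wt, wr, n_bins=n_bins, seed=seed)

    test_region = wt.drop_scores(test.name).intersect(test, name=test.name)
    ref_region = matched_ref.intersect(ref_pool, name=matched_ref.name)
    test_tab = tabulate(variants, test_region, genome, pol=pol, filt=filt)
    ref_tab = tabulate(variants, ref_region, genome, pol=pol, filt=filt)
    if exclude_cpg:
        test_tab = test_tab.exclude_types("cpg")
        ref_tab = ref_tab.exclude_types("cpg")
    return enrichment_test(test_tab, ref_tab, alpha=alpha), diag
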