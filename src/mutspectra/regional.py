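"""Regional enrichment and its regression on a covariate.

Each window (or chromosome) is compared against the *rest* of the scope —
all other windows combined, leaving the focal one out — so that pooling the
per-window counts always reproduces the scope-wide spectrum exactly.  The
per-class enrichment of window w,

    e_{w,c} = (d_c^w / D^w) / (d_c^{rest} / D^{rest}),

is then regressed (ordinary least squares) on the window's mean covariate,
e.g. replication timing; the fraction of variance explained (R^2) and the
slope quantify how strongly the covariate shapes that mutation class along
the genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .catalog import CLASSES, CLASS_OF_TYPE, N_TYPES, PolarizationMode
from .intervals import CompartmentSet, window_means
from .io import Genome
from .opportunities import genome_context_indices, N_CONTEXTS
from .catalog import CONTEXT_OF_TYPE
from .spectrum import NO_FILTER, FrequencyFilter, classify


class InsufficientWindowsError(ValueError):
    """Fewer usable units than the trend fit requires."""


@dataclass
class TrendFit:
    """OLS fit of per-unit enrichment on the unit's mean covariate."""

    mutation_class: str
    slope: float
    intercept: float
    r_squared: float
    pvalue: float
    n: int


def _per_window_counts(
    variants: pd.DataFrame,
    genome: Genome,
    windows: CompartmentSet,
    pol: PolarizationMode,
    filt: FrequencyFilter,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window type counts S (n_windows, 96) and opportunities O."""
    nw = len(windows)
    cache = genome_context_indices(genome)
    O_ctx = np.zeros((nw, N_CONTEXTS), dtype=np.int64)
    for row in windows.df.itertuples():
        ctx = cache[row.contig][row.start : row.end]
        ctx = ctx[ctx >= 0]
        if len(ctx):
            O_ctx[row.Index] += np.bincount(ctx, minlength=N_CONTEXTS)
    O = O_ctx[:, CONTEXT_OF_TYPE]

    cls = classify(variants, genome, pol)
    ok = (cls["type_index"].to_numpy() >= 0) & filt.mask(
        cls["dac"].to_numpy(dtype=np.int64), cls["an"].to_numpy(dtype=np.int64)
    )
    cls = cls[ok]
    widx = windows.interval_index(
        cls["contig"].to_numpy(), cls["pos"].to_numpy(dtype=np.int64) - 1
    )
    keep = widx >= 0
    flat = widx[keep] * N_TYPES + cls["type_index"].to_numpy()[keep]
    S = np.bincount(flat, minlength=nw * N_TYPES).reshape(nw, N_TYPES)
    return S.astype(np.int64), O


def window_enrichment(
    variants: pd.DataFrame,
    genome: Genome,
    windows: CompartmentSet,
    covariate: Optional[CompartmentSet] = None,
    pol: PolarizationMode = PolarizationMode(),
    filt: FrequencyFilter = NO_FILTER,
) -> pd.DataFrame:
    """Class-level leave-one-out enrichment of every window.

    Returns one row per window with the window coordinates, its mean
    covariate (NaN when no track is given), per-class counts ``S_<class>``
    and enrichments ``e_<class>``, and a ``degenerate`` flag for windows
    with no variants or no opportunities (excluded from trend fits).
    The scope is the union of the windows themselves: each window's
    reference is all other windows combined.
    """
    S96, O96 = _per_window_counts(variants, genome, windows, pol, filt)
    S = np.stack(
        [S96[:, CLASS_OF_TYPE == c].sum(axis=1) for c in range(6)], axis=1
    )
    O = np.stack(
        [O96[:, CLASS_OF_TYPE == c].sum(axis=1) for c in range(6)], axis=1
    )
    S_tot = S.sum(axis=1)
    O_tot = O.sum(axis=1)
    S_rest = S.sum(axis=0)[None, :] - S
    O_rest = O.sum(axis=0)[None, :] - O
    S_rest_tot = S_tot.sum() - S_tot
    O_rest_tot = O_tot.sum() - O_tot

    with np.errstate(divide="ignore", invalid="ignore"):
        rel_w = (S / O) / (S_tot / O_tot)[:, None]
        rel_rest = (S_rest / O_rest) / (S_rest_tot / O_rest_tot)[:, None]
        e = rel_w / rel_rest
    degenerate = (S_tot == 0) | (O_tot == 0) | (S_rest_tot == 0)

    out = windows.df[["contig", "start", "end"]].copy()
    if covariate is not None:
        out["mean_covariate"] = window_means(covariate, windows)
    elif windows.scored:
        out["mean_covariate"] = windows.scores()
    else:
        out["mean_covariate"] = np.nan
    for c, cls_name in enumerate(CLASSES):
        out[f"S_{cls_name}"] = S[:, c]
    for c, cls_name in enumerate(CLASSES):
        out[f"e_{cls_name}"] = e[:, c]
    out["S_tot"] = S_tot
    out["degenerate"] = degenerate
    return out


def fit_trend(
    enrichments: pd.DataFrame,
    mutation_class: str,
    covariate_col: str = "mean_covariate",
    log_scale: bool = False,
) -> TrendFit:
    """OLS of per-window class enrichment on the window covariate.

    R^2 is the squared correlation between enrichment and covariate; with a
    constant covariate it is reported as NaN (undefined), not zero.
    Windows flagged degenerate or with missing values are dropped.
    """
    if mutation_class not in CLASSES:
        raise ValueError(f"unknown mutation class {mutation_class!r}")
    col = f"e_{mutation_class}"
    df = enrichments
    if "degenerate" in df:
        df = df[~df["degenerate"]]
    y = df[col].to_numpy(dtype=float)
    x = df[covariate_col].to_numpy(dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    if len(y) < 3:
        raise InsufficientWindowsError(
            f"need >= 3 usable windows, have {len(y)}"
        )
    if log_scale:
        if (y <= 0).any():
            raise ValueError("log-scale fit requires positive enrichments")
        y = np.log(y)
    if np.ptp(x) == 0:
        return TrendFit(mutation_class, np.nan, np.nan, np.nan, np.nan, len(y))
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return TrendFit(
        mutation_class=mutation_class,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        pvalue=float(model.pvalues[1]),
        n=len(y),
    )


def fit_all_trends(
    enrichments: pd.DataFrame,
    covariate_col: str = "mean_covariate",
    log_scale: bool = False,
) -> pd.DataFrame:
    rows = []
    for cls_name in CLASSES:
        fit = fit_trend(enrichments, cls_name, covariate_col, log_scale)
        rows.append(
            {
                "mutation_class": fit.mutation_class,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "pvalue": fit.pvalue,
                "n": fit.n,
            }
        )
    return pd.DataFrame(rows).set_index("mutation_class")


def chromosome_enrichment(
    variants: pd.DataFrame,
    genome: Genome,
    contigs: Optional[Sequence[str]] = None,
    covariate: Optional[CompartmentSet] = None,
    pol: PolarizationMode = PolarizationMode(),
    filt: FrequencyFilter = NO_FILTER,
) -> pd.DataFrame:
    """Leave-one-out class enrichment with whole contigs as the units.

    Identical statistic to :func:`window_enrichment` but computed per
    chromosome against all other chromosomes combined; feeding the result to
    :func:`fit_trend` gives the chromosome-level covariate trend.
    """
    extent = genome.extent
    if contigs is None:
        contigs = list(extent)
    units = CompartmentSet(
        "chromosomes", [(c, 0, extent[c]) for c in contigs], merge=False
    )
    return window_enrichment(
        variants, genome, units, covariate=covariate, pol=pol, filt=filt
    )
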