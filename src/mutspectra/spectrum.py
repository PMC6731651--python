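"""Per-compartment mutation spectra.

The central quantities, per mutation type i within a compartment:

    S_i   segregating sites of type i (one count per derived allele)
    O_i   mutational opportunities for type i
    d_i = S_i / O_i                    diversity of type i
    D   = S_tot / O_tot                total diversity
    r_i = d_i / D                      relative diversity

Relative diversity is the quantity compared across compartments: dividing by
the compartment's total diversity cancels population-genetic forces that
scale diversity evenly over all types.  The opportunity-weighted relative
diversities satisfy sum_i r_i * (O_i / O_tot) = 1 whenever S_tot > 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .catalog import (
    CATALOG,
    CLASSES,
    CPG_TYPE_MASK,
    MAJOR_ALLELE,
    N_CODE,
    N_TYPES,
    TYPE_LABELS,
    TYPE_LUT,
    CLASS_OF_TYPE,
    MutationType,
    PolarizationMode,
    SKIP_BAD_ANCESTRAL,
    SKIP_N_FLANK,
    SKIP_NO_FLANK,
    SKIP_NON_SNP,
    SKIP_REF_MISMATCH,
    SKIP_TIE,
)

SKIP_REF_ABSENT = "reference-absent"
from .intervals import CompartmentSet
from .io import Genome
from .opportunities import OpportunityTable


@dataclass(frozen=True)
class FrequencyFilter:
    """Bounds on the derived allele count/frequency of retained variants.

    The default keeps everything; a ``max_daf`` of 0.01 reproduces the
    sensitivity analysis that drops variants at 1% frequency or greater.
    """

    max_daf: Optional[float] = None
    min_dac: Optional[int] = None
    max_dac: Optional[int] = None

    def __post_init__(self) -> None:
        if self.max_daf is not None and not 0 < self.max_daf <= 1:
            raise ValueError("max_daf must be in (0, 1]")
        if (
            self.min_dac is not None
            and self.max_dac is not None
            and self.min_dac > self.max_dac
        ):
            raise ValueError("min_dac must be <= max_dac")

    def mask(self, dac: np.ndarray, an: np.ndarray) -> np.ndarray:
        keep = np.ones(len(dac), dtype=bool)
        if self.max_daf is not None:
            keep &= dac / an < self.max_daf
        if self.min_dac is not None:
            keep &= dac >= self.min_dac
        if self.max_dac is not None:
            keep &= dac <= self.max_dac
        return keep


NO_FILTER = FrequencyFilter()


# ---------------------------------------------------------------------------
# Polarization and classification of observation frames
# ---------------------------------------------------------------------------


def polarize(obs: pd.DataFrame, pol: PolarizationMode, genome: Optional[Genome] = None) -> pd.DataFrame:
    """Resolve ancestral/derived alleles for every observation row.

    Returns a frame with columns (contig, pos, anc, der, dac, an, skip);
    rows that cannot be polarized carry a skip reason and NaN-free dummy
    allele codes.  Under the major-allele rule the most frequent allele at a
    site (reference included) is ancestral; every other observed allele is
    derived and counted separately, so a site where an alternate allele is
    major yields a derived observation of the reference allele.  Exact
    50/50 sites are ambiguous and skipped.
    """
    df = obs.sort_values(["contig", "pos"], kind="mergesort").reset_index(drop=True)
    n = len(df)
    anc = np.zeros(n, dtype=np.int16)
    der = np.zeros(n, dtype=np.int16)
    dac = np.zeros(n, dtype=np.int64)
    skip = np.full(n, "", dtype=object)
    if n == 0:
        return df.assign(anc=anc, der=der, dac=dac, skip=skip)

    ref = df["ref"].to_numpy(dtype=np.int16)
    alt = df["alt"].to_numpy(dtype=np.int16)
    ac = df["ac"].to_numpy(dtype=np.int64)
    an = df["an"].to_numpy(dtype=np.int64)
    bad = (ref >= 4) | (alt >= 4)
    skip[bad] = SKIP_NON_SNP

    site = (
        (df["contig"] != df["contig"].shift()) | (df["pos"] != df["pos"].shift())
    ).to_numpy().cumsum() - 1
    n_sites = site[-1] + 1
    site_ac_sum = np.bincount(site, weights=ac, minlength=n_sites).astype(np.int64)
    ref_count = an - site_ac_sum[site]  # per-row; AN constant within a site

    if pol.mode == MAJOR_ALLELE:
        site_max_ac = np.full(n_sites, -1, dtype=np.int64)
        np.maximum.at(site_max_ac, site, ac)
        row_max = site_max_ac[site]
        # how many alleles (alts + possibly ref) attain the maximum count
        is_max = (ac == row_max).astype(np.int64)
        n_max_alt = np.bincount(site, weights=is_max, minlength=n_sites)[site]
        ref_major = ref_count > row_max
        tie = (ref_count == row_max) | ((ref_count < row_max) & (n_max_alt > 1))
        # index of the major alt per site (valid where not ref_major/tie)
        major_alt = np.zeros(n_sites, dtype=np.int16)
        sel = ac == row_max
        major_alt[site[sel]] = alt[sel]
        row_major_alt = major_alt[site]

        simple = ref_major & ~bad
        anc[simple], der[simple], dac[simple] = ref[simple], alt[simple], ac[simple]

        flipped = ~ref_major & ~tie & ~bad
        own = flipped & (ac == row_max)  # the major alt's own row -> derived ref
        other = flipped & (ac != row_max)
        anc[own], der[own], dac[own] = alt[own], ref[own], ref_count[own]
        anc[other], der[other] = row_major_alt[other], alt[other]
        dac[other] = ac[other]
        # a major alt with the reference absent from the sample leaves no
        # derived reference allele to count
        gone = own & (ref_count == 0)
        skip[gone] = SKIP_REF_ABSENT
        skip[tie & ~bad] = SKIP_TIE
    else:
        if genome is None and pol.ancestral_sequence is None:
            raise ValueError("ancestral polarization requires a sequence")
        aseq = pol.ancestral_sequence
        pos0 = df["pos"].to_numpy(dtype=np.int64) - 1
        anc_base = np.full(n, N_CODE, dtype=np.int16)
        for contig, sub in df.groupby("contig", sort=False):
            arr = aseq[contig]
            p = pos0[sub.index.to_numpy()]
            ok = (p >= 0) & (p < len(arr))
            vals = np.full(len(p), N_CODE, dtype=np.int16)
            vals[ok] = arr[p[ok]]
            anc_base[sub.index.to_numpy()] = vals
        anc_is_ref = anc_base == ref
        anc_is_alt = anc_base == alt
        ok = (anc_is_ref | anc_is_alt) & ~bad
        anc[ok] = anc_base[ok]
        der[ok] = np.where(anc_is_ref[ok], alt[ok], ref[ok])
        dac[ok] = np.where(anc_is_ref[ok], ac[ok], ref_count[ok])
        gone = ok & (dac == 0)
        skip[gone] = SKIP_REF_ABSENT
        skip[~ok & ~bad] = SKIP_BAD_ANCESTRAL

    skip[(skip == "") & (dac <= 0)] = SKIP_REF_ABSENT
    return df.assign(anc=anc, der=der, dac=dac, skip=skip)


def classify(
    obs: pd.DataFrame,
    genome: Genome,
    pol: PolarizationMode = PolarizationMode(),
) -> pd.DataFrame:
    """Polarize and classify observations onto the 96-type catalog.

    Adds columns ``type_index`` (0..95, or -1) and ``skip`` (reason, empty
    when classified).  Flanking bases come from the reference genome; only
    the central base is replaced by the ancestral allele.
    """
    out = polarize(obs, pol, genome)
    n = len(out)
    type_index = np.full(n, -1, dtype=np.int16)
    if n == 0:
        return out.assign(type_index=type_index)
    skip = out["skip"].to_numpy()
    pos0 = out["pos"].to_numpy(dtype=np.int64) - 1
    left = np.full(n, N_CODE, dtype=np.int16)
    right = np.full(n, N_CODE, dtype=np.int16)
    centre = np.full(n, N_CODE, dtype=np.int16)
    edge = np.zeros(n, dtype=bool)
    for contig, sub in out.groupby("contig", sort=False):
        if contig not in genome:
            raise KeyError(f"contig {contig!r} not in genome")
        seq = genome[contig]
        idx = sub.index.to_numpy()
        p = pos0[idx]
        if (p < 0).any() or (p >= len(seq)).any():
            raise IndexError(f"position out of range on {contig}")
        inner = (p >= 1) & (p <= len(seq) - 2)
        edge[idx[~inner]] = True
        ii = idx[inner]
        pi = p[inner]
        left[ii] = seq[pi - 1]
        right[ii] = seq[pi + 1]
        centre[ii] = seq[pi]

    skip = skip.copy()
    free = skip == ""
    skip[free & edge] = SKIP_NO_FLANK
    free = skip == ""
    nflank = (left == N_CODE) | (right == N_CODE)
    skip[free & nflank] = SKIP_N_FLANK
    free = skip == ""
    mismatch = centre != out["ref"].to_numpy(dtype=np.int16)
    skip[free & mismatch] = SKIP_REF_MISMATCH
    free = skip == ""
    if free.any():
        anc = out["anc"].to_numpy(dtype=np.int16)
        der = out["der"].to_numpy(dtype=np.int16)
        codes = (left[free] << 4) | (anc[free] << 2) | right[free]
        type_index[free] = TYPE_LUT[codes, der[free]]
    return out.assign(type_index=type_index, skip=skip)


# ---------------------------------------------------------------------------
# Spectrum tables
# ---------------------------------------------------------------------------


class SpectrumTable:
    """Counts, opportunities and (relative) diversity per mutation type."""

    def __init__(
        self,
        compartment: str,
        S: np.ndarray,
        O: np.ndarray,
        labels: Optional[Sequence[str]] = None,
        skip_log: Optional[pd.DataFrame] = None,
    ):
        S = np.asarray(S, dtype=np.int64)
        O = np.asarray(O, dtype=np.int64)
        if S.shape != O.shape:
            raise ValueError("S and O must have the same shape")
        if (S < 0).any() or (O < 0).any():
            raise ValueError("counts must be nonnegative")
        if (S > O).any():
            raise ValueError("segregating sites cannot exceed opportunities")
        if labels is None:
            if len(S) != N_TYPES:
                raise ValueError("labels required for non-96-type tables")
            labels = list(TYPE_LABELS)
        self.compartment = compartment
        self.skip_log = skip_log

        self.S_tot = int(S.sum())
        self.O_tot = int(O.sum())
        self.D = self.S_tot / self.O_tot if self.O_tot else float("nan")
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(O > 0, S / np.where(O > 0, O, 1), np.nan)
            r = d / self.D if self.D and self.D > 0 else np.full(len(S), np.nan)
        frame = pd.DataFrame({"S": S, "O": O, "d": d, "r": r}, index=list(labels))
        if len(S) == N_TYPES and list(labels) == list(TYPE_LABELS):
            frame.insert(0, "mutation_class", [t.mutation_class for t in CATALOG])
            frame.insert(1, "context", [t.context for t in CATALOG])
            frame.insert(2, "alt", [t.alt for t in CATALOG])
        self.frame = frame

    # -- accessors ------------------------------------------------------------

    @property
    def labels(self) -> list[str]:
        return list(self.frame.index)

    @property
    def S(self) -> np.ndarray:
        return self.frame["S"].to_numpy()

    @property
    def O(self) -> np.ndarray:
        return self.frame["O"].to_numpy()

    @property
    def d(self) -> np.ndarray:
        return self.frame["d"].to_numpy()

    @property
    def r(self) -> np.ndarray:
        return self.frame["r"].to_numpy()

    def normalization_residual(self) -> float:
        """|sum_i r_i O_i / O_tot - 1|; zero up to rounding when S_tot > 0."""
        if self.S_tot == 0 or self.O_tot == 0:
            return float("nan")
        terms = np.nan_to_num(self.r * self.O / self.O_tot)
        return abs(float(terms.sum()) - 1.0)

    # -- transforms -----------------------------------------------------------

    def collapse_to_classes(self) -> "SpectrumTable":
        """Aggregate type rows into the six mutation classes.

        Works on the full 96-type table and on subsets (e.g. after CpG
        exclusion); the class of a row is read off its type label.
        """
        try:
            cls_idx = np.array(
                [CLASSES.index(f"{l[1]}>{l[5]}") for l in self.labels]
            )
        except (ValueError, IndexError) as err:
            raise ValueError(
                "collapse requires catalog-labelled type rows"
            ) from err
        S = np.bincount(cls_idx, weights=self.S, minlength=6).astype(np.int64)
        O = np.bincount(cls_idx, weights=self.O, minlength=6).astype(np.int64)
        return SpectrumTable(self.compartment, S, O, labels=list(CLASSES))

    def exclude_types(
        self, drop: Union[str, Iterable[Union[str, MutationType, int]]]
    ) -> "SpectrumTable":
        """Drop types from the table and from the totals behind D and r.

        ``drop`` may be the string ``"cpg"`` (the 12 CpG types) or any
        iterable of catalog members, labels, or indices.  Passing an empty
        iterable returns an identical table.
        """
        if isinstance(drop, str):
            if drop.lower() != "cpg":
                raise ValueError("string shorthand must be 'cpg'")
            mask = CPG_TYPE_MASK.copy()
        else:
            mask = np.zeros(len(self.frame), dtype=bool)
            for item in drop:
                if isinstance(item, MutationType):
                    mask[item.index] = True
                elif isinstance(item, str):
                    mask[self.labels.index(item)] = True
                else:
                    mask[int(item)] = True
        keep = ~mask
        return SpectrumTable(
            self.compartment,
            self.S[keep],
            self.O[keep],
            labels=[l for l, k in zip(self.labels, keep) if k],
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SpectrumTable({self.compartment!r}, {len(self.frame)} types, "
            f"S_tot={self.S_tot}, D={self.D:.4g})"
        )


def tabulate(
    variants: pd.DataFrame,
    comp: CompartmentSet,
    genome: Genome,
    pol: PolarizationMode = PolarizationMode(),
    filt: FrequencyFilter = NO_FILTER,
    opp: Optional[OpportunityTable] = None,
) -> SpectrumTable:
    """Build the 96-type spectrum of a compartment from an observation frame.

    A variant belongs to the compartment if its focal position does; flanks
    may lie outside.  Observations that fail classification are recorded in
    the table's ``skip_log`` but their positions still count as
    opportunities, since opportunities are a property of the sequence alone.
    """
    from .opportunities import count_contexts

    if opp is None:
        opp = count_contexts(genome, comp)
    elif opp.compartment != comp.name:
        raise ValueError(
            f"opportunity table for {opp.compartment!r} does not match "
            f"compartment {comp.name!r}"
        )
    inside = comp.contains(
        variants["contig"].to_numpy(), variants["pos"].to_numpy(dtype=np.int64) - 1
    )
    sub = variants[inside]
    cls = classify(sub, genome, pol)
    ok = cls["type_index"].to_numpy() >= 0
    keep = ok & filt.mask(
        cls["dac"].to_numpy(dtype=np.int64), cls["an"].to_numpy(dtype=np.int64)
    )
    S = np.bincount(
        cls.loc[keep, "type_index"].to_numpy(), minlength=N_TYPES
    ).astype(np.int64)
    skip_log = cls.loc[~ok, ["contig", "pos", "skip"]].rename(
        columns={"skip": "reason"}
    )
    return SpectrumTable(comp.name, S, opp.type_counts, skip_log=skip_log)


def sfs(
    variants: pd.DataFrame, filt: FrequencyFilter = NO_FILTER
) -> pd.Series:
    """Site-frequency spectrum: derived allele count -> number of variants.

    Uses the callset's derived (alternate) allele counts directly; singleton
    and doubleton fractions are the mass at counts 1 and 2.
    """
    if "ac" not in variants or "an" not in variants:
        raise ValueError("observation frame lacks allele-count fields")
    ac = variants["ac"].to_numpy(dtype=np.int64)
    an = variants["an"].to_numpy(dtype=np.int64)
    keep = filt.mask(ac, an)
    counts = pd.Series(ac[keep]).value_counts().sort_index()
    counts.index.name = "derived_count"
    counts.name = "n_variants"
    return counts
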