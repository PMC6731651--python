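"""Mutational-opportunity counting.

An opportunity for mutation type i is a genomic site where a single base
change could have produced a mutation of that type: any site whose
trinucleotide context canonicalizes to the context of type i.  Opportunity
counts depend only on sequence composition, never on observed variants, and
are the denominators that turn segregating-site counts into per-type
diversity.  Each canonical context count serves all three alternate alleles,
so the 96-vector of type opportunities sums to three times the 32-vector of
context counts.

Sites whose trinucleotide window is incomplete (contig ends) or contains an
ambiguous base contribute nothing; variants at such sites are likewise
skipped during tabulation, keeping numerator and denominator consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import (
    CONTEXT_LABELS,
    CONTEXT_LUT,
    CONTEXT_OF_TYPE,
    N_CONTEXTS,
    TYPE_LABELS,
)
from .intervals import CompartmentSet
from .io import Genome


def context_index_array(seq: np.ndarray) -> np.ndarray:
    """Canonical context index (0..31) of every position of a contig.

    Positions lacking a full N-free trinucleotide (the two end positions, and
    any position whose window touches a non-ACGT base) are -1.
    """
    seq = np.asarray(seq, dtype=np.uint8)
    out = np.full(len(seq), -1, dtype=np.int16)
    if len(seq) < 3:
        return out
    left = seq[:-2].astype(np.int16)
    mid = seq[1:-1].astype(np.int16)
    right = seq[2:].astype(np.int16)
    valid = (left < 4) & (mid < 4) & (right < 4)
    codes = (left << 4) | (mid << 2) | right
    inner = np.where(valid, CONTEXT_LUT[np.where(valid, codes, 0)], -1)
    out[1:-1] = inner
    return out


class _ContextCache(dict):
    """Per-Genome cache of context index arrays, keyed by contig."""

    def __init__(self, genome: Genome):
        super().__init__()
        self.genome = genome

    def __missing__(self, contig: str) -> np.ndarray:
        arr = context_index_array(self.genome[contig])
        self[contig] = arr
        return arr


_caches: "dict[int, _ContextCache]" = {}


def genome_context_indices(genome: Genome) -> _ContextCache:
    """Context index arrays for a genome, cached per Genome object."""
    key = id(genome)
    cache = _caches.get(key)
    if cache is None or cache.genome is not genome:
        cache = _ContextCache(genome)
        _caches[key] = cache
    return cache


@dataclass
class OpportunityTable:
    """Opportunity counts for one compartment.

    ``context_counts`` is the 32-vector of canonical context site counts;
    ``type_counts`` expands it to the 96 types (each context serving its
    three alternate alleles).
    """

    compartment: str
    context_counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.context_counts, dtype=np.int64)
        if arr.shape != (N_CONTEXTS,):
            raise ValueError("context_counts must have shape (32,)")
        if (arr < 0).any():
            raise ValueError("opportunity counts must be nonnegative")
        self.context_counts = arr

    @property
    def type_counts(self) -> np.ndarray:
        return self.context_counts[CONTEXT_OF_TYPE]

    @property
    def total(self) -> int:
        """Sum over the 96 types (three times the context total)."""
        return int(self.type_counts.sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.context_counts, index=list(CONTEXT_LABELS), name="O")

    def type_series(self) -> pd.Series:
        return pd.Series(self.type_counts, index=list(TYPE_LABELS), name="O")

    def __add__(self, other: "OpportunityTable") -> "OpportunityTable":
        return OpportunityTable(
            f"{self.compartment}+{other.compartment}",
            self.context_counts + other.context_counts,
        )


def count_contexts(genome: Genome, comp: CompartmentSet) -> OpportunityTable:
    """Count mutational opportunities per canonical context inside ``comp``."""
    counts = np.zeros(N_CONTEXTS, dtype=np.int64)
    cache = genome_context_indices(genome)
    extent = genome.extent
    for row in comp.df.itertuples():
        if row.contig not in extent:
            raise KeyError(f"contig {row.contig!r} not in genome")
        if row.end > extent[row.contig]:
            raise ValueError(
                f"interval {row.contig}:{row.start}-{row.end} exceeds contig"
            )
        ctx = cache[row.contig][row.start : row.end]
        ctx = ctx[ctx >= 0]
        if len(ctx):
            counts += np.bincount(ctx, minlength=N_CONTEXTS)
    return OpportunityTable(comp.name, counts)
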