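"""The 96-type trinucleotide mutation catalog.

A single-base substitution observed in its trinucleotide context defines a
raw type ``(context, alt)`` with 64 × 3 = 192 possibilities.  Because a
mutation on one strand is the reverse-complement mutation on the other, raw
types are collapsed onto a canonical catalog whose central (mutated) base is
a pyrimidine: for example ``CGT>CAT`` is recorded as ``ACG>ATG``.  This
leaves 32 canonical contexts × 3 alternate alleles = 96 mutation types,
grouped into six classes (C>A, C>G, C>T, T>A, T>C, T>G).

Catalog order is fixed and class-major: the six classes in the order above,
and within each class the 16 contexts lexicographically (ACA, ACC, ACG, …).
All tables in the package index their rows in this order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

BASES = "ACGT"
A, C, G, T = range(4)
N_CODE = 4  # any non-ACGT symbol

CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
N_TYPES = 96
N_CONTEXTS = 32

_ENCODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_CLASS_INDEX = {(C, A): 0, (C, G): 1, (C, T): 2, (T, A): 3, (T, C): 4, (T, G): 5}


class AmbiguousBaseError(ValueError):
    """A context or allele contains a symbol outside {A, C, G, T}."""


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in np.asarray(codes))


def complement_code(code: int) -> int:
    # A<->T and C<->G is 3 - code under the A,C,G,T = 0..3 encoding
    return 3 - code


def revcomp(seq: str) -> str:
    codes = encode(seq)
    if (codes == N_CODE).any():
        raise AmbiguousBaseError(f"non-ACGT base in {seq!r}")
    return decode(3 - codes[::-1])


def _context_code(left: int, mid: int, right: int) -> int:
    return (left << 4) | (mid << 2) | right


def _decode_context(code: int) -> tuple[int, int, int]:
    return (code >> 4) & 3, (code >> 2) & 3, code & 3


# ---------------------------------------------------------------------------
# Lookup tables, built once at import.
#
# TYPE_LUT[context_code, alt_code] -> canonical type index in 0..95, or -1
#     when alt equals the central base (not a substitution).
# CONTEXT_LUT[context_code] -> canonical context index in 0..31
#     (central-C contexts occupy 0..15, central-T contexts 16..31).
# ---------------------------------------------------------------------------

TYPE_LUT = np.full((64, 4), -1, dtype=np.int16)
CONTEXT_LUT = np.full(64, -1, dtype=np.int16)

for _code in range(64):
    _l, _m, _r = _decode_context(_code)
    if _m in (C, T):
        _cl, _cm, _cr = _l, _m, _r
        _flip = False
    else:
        _cl, _cm, _cr = 3 - _r, 3 - _m, 3 - _l
        _flip = True
    _ctx_idx = (0 if _cm == C else 16) + 4 * _cl + _cr
    CONTEXT_LUT[_code] = _ctx_idx
    for _alt in range(4):
        if _alt == _m:
            continue
        _calt = 3 - _alt if _flip else _alt
        TYPE_LUT[_code, _alt] = 16 * _CLASS_INDEX[(_cm, _calt)] + 4 * _cl + _cr

# canonical context index (0..31) used by each of the 96 types
CONTEXT_OF_TYPE = np.array(
    [(0 if i < 48 else 16) + i % 16 for i in range(N_TYPES)], dtype=np.int16
)

# CpG types: central C immediately followed by G (contexts ACG, CCG, GCG, TCG)
CPG_TYPE_MASK = np.array([i < 48 and i % 4 == G for i in range(N_TYPES)], dtype=bool)


@dataclass(frozen=True, order=True)
class MutationType:
    """One canonical strand-collapsed trinucleotide substitution."""

    sort_index: int = field(init=False, repr=False, compare=True)
    context: str = field(compare=False)
    alt: str = field(compare=False)

    def __post_init__(self) -> None:
        codes = encode(self.context)
        alt = encode(self.alt)
        if len(codes) != 3 or (codes == N_CODE).any() or alt[0] == N_CODE:
            raise AmbiguousBaseError(f"bad type {self.context}>{self.alt}")
        if codes[1] not in (C, T):
            raise ValueError("canonical context must have a pyrimidine center")
        idx = int(TYPE_LUT[_context_code(*codes), alt[0]])
        if idx < 0:
            raise ValueError("alt equals the central base")
        object.__setattr__(self, "sort_index", idx)

    @property
    def index(self) -> int:
        """Position in the fixed class-major catalog order."""
        return self.sort_index

    @property
    def ref(self) -> str:
        return self.context[1]

    @property
    def mutation_class(self) -> str:
        return f"{self.ref}>{self.alt}"

    @property
    def label(self) -> str:
        return f"{self.context}>{self.context[0]}{self.alt}{self.context[2]}"

    def __str__(self) -> str:  # pragma: no cover
        return self.label


def _build() -> tuple[MutationType, ...]:
    out: list[Optional[MutationType]] = [None] * N_TYPES
    for ci, cls in enumerate(CLASSES):
        ref, alt = cls[0], cls[2]
        for li, left in enumerate(BASES):
            for ri, right in enumerate(BASES):
                t = MutationType(context=f"{left}{ref}{right}", alt=alt)
                assert t.index == 16 * ci + 4 * li + ri
                out[t.index] = t
    return tuple(out)  # type: ignore[arg-type]


CATALOG: tuple[MutationType, ...] = _build()
TYPE_LABELS: tuple[str, ...] = tuple(t.label for t in CATALOG)
CLASS_OF_TYPE = np.repeat(np.arange(6), 16)

# canonical 32 contexts, ordered consistently with CONTEXT_LUT indices
CONTEXT_LABELS: tuple[str, ...] = tuple(
    f"{l}{m}{r}" for m in "CT" for l in BASES for r in BASES
)


def build_catalog() -> list[MutationType]:
    """Return the 96 canonical mutation types in fixed class-major order."""
    return list(CATALOG)


def canonicalize(context: str, alt: str) -> MutationType:
    """Map any raw ``(context, alt)`` observation onto its canonical type.

    Contexts with a purine center are replaced by their reverse complement,
    with the alternate allele complemented accordingly, so that a raw type
    and its reverse-complement partner return the same catalog member.
    """
    codes = encode(context)
    if len(codes) != 3:
        raise ValueError("context must be a 3-mer")
    alt_codes = encode(alt)
    if (codes == N_CODE).any() or len(alt_codes) != 1 or alt_codes[0] == N_CODE:
        raise AmbiguousBaseError(f"non-ACGT symbol in {context!r}>{alt!r}")
    idx = int(TYPE_LUT[_context_code(*codes), alt_codes[0]])
    if idx < 0:
        raise ValueError("alt equals the central base")
    return CATALOG[idx]


def is_cpg_type(t: Union[MutationType, int, str]) -> bool:
    """True iff the type mutates a C that is immediately 5' of a G.

    These are the four CpG contexts ACG, CCG, GCG and TCG (any alternate
    allele), the hypermutable targets of methyl-cytosine deamination; several
    compartment comparisons exclude them.
    """
    if isinstance(t, MutationType):
        return bool(CPG_TYPE_MASK[t.index])
    if isinstance(t, str):
        return bool(CPG_TYPE_MASK[TYPE_LABELS.index(t)])
    return bool(CPG_TYPE_MASK[int(t)])


# ---------------------------------------------------------------------------
# Variant observations and polarization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantObservation:
    """One derived allele at one site of a cohort callset.

    Multiallelic sites yield several observations sharing contig/position,
    each derived allele counted as if it were a separate biallelic site.
    Positions are 1-based (VCF convention).
    """

    contig: str
    position: int
    ref_base: str
    alt_base: str
    derived_count: int
    sample_chromosomes: int

    def __post_init__(self) -> None:
        if not 1 <= self.derived_count < self.sample_chromosomes:
            raise ValueError(
                "derived_count must satisfy 1 <= count < sample_chromosomes"
            )


MAJOR_ALLELE = "major-allele"
ANCESTRAL_GENOME = "ancestral-genome"


@dataclass(frozen=True)
class PolarizationMode:
    """How the ancestral allele at a site is decided.

    ``major-allele`` treats the most frequent allele in the sample as
    ancestral; ``ancestral-genome`` reads the ancestral base from a supplied
    reconstructed sequence.
    """

    mode: str = MAJOR_ALLELE
    ancestral_sequence: Optional[object] = None  # Genome-like mapping

    def __post_init__(self) -> None:
        if self.mode not in (MAJOR_ALLELE, ANCESTRAL_GENOME):
            raise ValueError(f"unknown polarization mode {self.mode!r}")
        if (self.mode == ANCESTRAL_GENOME) != (self.ancestral_sequence is not None):
            raise ValueError(
                "ancestral_sequence is required iff mode is 'ancestral-genome'"
            )


@dataclass(frozen=True)
class Skip:
    """Marker for a variant excluded from classification, with the reason."""

    reason: str


SKIP_N_FLANK = "n-flank"
SKIP_NO_FLANK = "no-flank"
SKIP_TIE = "ambiguous-polarization"
SKIP_NON_SNP = "non-snp"
SKIP_REF_MISMATCH = "ref-mismatch"
SKIP_BAD_ANCESTRAL = "ancestral-not-observed"


def classify_variant(
    v: VariantObservation, genome, pol: PolarizationMode
) -> Union[MutationType, Skip]:
    """Classify one observation onto the catalog, or return a skip marker.

    The flanking bases always come from the reference ``genome``; only the
    central base is replaced by the ancestral allele when polarization says
    the reference is derived.  Sites where the derived frequency is exactly
    one half cannot be polarized by the major-allele rule and are skipped.
    """
    if v.contig not in genome:
        raise KeyError(f"contig {v.contig!r} not in genome")
    seq = genome[v.contig]
    pos0 = v.position - 1
    if not 0 <= pos0 < len(seq):
        raise IndexError(f"position {v.position} out of range for {v.contig}")
    if pos0 == 0 or pos0 == len(seq) - 1:
        return Skip(SKIP_NO_FLANK)
    ref = encode(v.ref_base)
    alt = encode(v.alt_base)
    if len(v.ref_base) != 1 or len(v.alt_base) != 1:
        return Skip(SKIP_NON_SNP)
    if ref[0] == N_CODE or alt[0] == N_CODE:
        return Skip(SKIP_NON_SNP)
    left, mid, right = int(seq[pos0 - 1]), int(seq[pos0]), int(seq[pos0 + 1])
    if left == N_CODE or right == N_CODE:
        return Skip(SKIP_N_FLANK)
    if mid != ref[0]:
        return Skip(SKIP_REF_MISMATCH)

    if pol.mode == MAJOR_ALLELE:
        doubled = 2 * v.derived_count
        if doubled == v.sample_chromosomes:
            return Skip(SKIP_TIE)
        if doubled < v.sample_chromosomes:
            anc, der = int(ref[0]), int(alt[0])
        else:
            anc, der = int(alt[0]), int(ref[0])
    else:
        aseq = pol.ancestral_sequence[v.contig]  # type: ignore[index]
        anc = int(aseq[pos0])
        if anc == int(ref[0]):
            der = int(alt[0])
        elif anc == int(alt[0]):
            der = int(ref[0])
        else:
            return Skip(SKIP_BAD_ANCESTRAL)

    idx = int(TYPE_LUT[_context_code(left, anc, right), der])
    if idx < 0:  # pragma: no cover - anc == der cannot happen above
        return Skip(SKIP_NON_SNP)
    return CATALOG[idx]
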