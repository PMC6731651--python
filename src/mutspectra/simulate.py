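"""Synthetic genomes, compartments and rare-variant callsets with known truth.

The generator emulates the statistical structure of a large diploid cohort's
site-level callset — not its demography or linkage:

* per-type segregating-site counts are Poisson with mean
  ``opportunities x base_rate x multiplier``, the low-rate limit of
  independent per-site mutation;
* derived allele counts follow a truncated power law ``P(j) ~ j^-alpha`` on
  ``1..n-1`` chromosomes, a singleton-heavy frequency spectrum;
* a configurable fraction of observations sit at multiallelic sites, built
  by co-locating two independent derived alleles of the same context;
* compartment- or window-specific rate multipliers plant enrichments and
  covariate effects against which pipeline recovery is judged.

Defaults model the cohort the analyses are designed around: 6,930 diploid
individuals (13,860 chromosomes), alpha = 1.8 (a ~53% singleton fraction at
that sample size), ~6% multiallelic observations, and a base spectrum with
transition-dominated class weights and elevated CpG C>T rates.

Everything is driven by one ``numpy`` Generator so that identical
configuration and seed give byte-identical FASTA/VCF/BED outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .catalog import CLASSES, CLASS_OF_TYPE, CONTEXT_OF_TYPE, N_TYPES, C, T
from .intervals import CompartmentSet
from .io import Genome, OBS_COLUMNS
from .opportunities import OpportunityTable, genome_context_indices

# Stylized germline class weights (fraction of a transition-dominated
# spectrum) and the fold-elevation of C>T rates in CpG contexts.
DEFAULT_CLASS_WEIGHTS = {
    "C>A": 0.10,
    "C>G": 0.09,
    "C>T": 0.42,
    "T>A": 0.06,
    "T>C": 0.24,
    "T>G": 0.09,
}
DEFAULT_CPG_FOLD = 8.0
DEFAULT_RATE_SCALE = 0.015  # mean per-opportunity diversity
DEFAULT_N_CHROMOSOMES = 2 * 6930
DEFAULT_SFS_ALPHA = 1.8
DEFAULT_MULTIALLELIC_FRACTION = 0.06

# canonical alternate-allele code of each type (on the pyrimidine strand)
_ALT_CODE = np.empty(N_TYPES, dtype=np.int16)
for _i in range(N_TYPES):
    _cls = CLASSES[_i // 16]
    _ALT_CODE[_i] = "ACGT".index(_cls[2])


def default_rate_vector(
    scale: float = DEFAULT_RATE_SCALE,
    class_weights: Optional[Mapping[str, float]] = None,
    cpg_fold: float = DEFAULT_CPG_FOLD,
) -> np.ndarray:
    """Per-opportunity base rates for the 96 types, mean-normalized to ``scale``."""
    weights = dict(class_weights or DEFAULT_CLASS_WEIGHTS)
    v = np.empty(N_TYPES)
    for c, cls in enumerate(CLASSES):
        v[CLASS_OF_TYPE == c] = weights[cls] / 16.0
    from .catalog import CPG_TYPE_MASK

    cpg_ct = CPG_TYPE_MASK & (CLASS_OF_TYPE == CLASSES.index("C>T"))
    v[cpg_ct] *= cpg_fold
    return scale * v / v.mean()


def expand_class_multipliers(
    mult: Union[None, float, Mapping[str, float], np.ndarray]
) -> np.ndarray:
    """Normalize a multiplier spec (scalar, per-class dict, 96-vector) to 96."""
    if mult is None:
        return np.ones(N_TYPES)
    if isinstance(mult, Mapping):
        v = np.ones(N_TYPES)
        for cls, value in mult.items():
            if cls not in CLASSES:
                raise ValueError(f"unknown mutation class {cls!r}")
            v[CLASS_OF_TYPE == CLASSES.index(cls)] = float(value)
        return v
    arr = np.asarray(mult, dtype=float)
    if arr.ndim == 0:
        return np.full(N_TYPES, float(arr))
    if arr.shape != (N_TYPES,):
        raise ValueError("multiplier vector must have shape (96,)")
    return arr.copy()


@dataclass
class SimulationTruth:
    """The planted ground truth of one simulated callset."""

    base_rates: np.ndarray = field(default_factory=default_rate_vector)
    multipliers: dict = field(default_factory=dict)  # compartment -> spec
    covariate_beta: dict = field(default_factory=dict)  # class -> coefficient
    sfs_alpha: float = DEFAULT_SFS_ALPHA
    n_chromosomes: int = DEFAULT_N_CHROMOSOMES
    multiallelic_fraction: float = DEFAULT_MULTIALLELIC_FRACTION
    seed: int = 0

    def __post_init__(self) -> None:
        self.base_rates = np.asarray(self.base_rates, dtype=float)
        if self.base_rates.shape != (N_TYPES,) or (self.base_rates < 0).any():
            raise ValueError("base_rates must be 96 nonnegative values")
        if self.n_chromosomes % 2 or self.n_chromosomes < 4:
            raise ValueError("n_chromosomes must be even (diploid cohort)")
        if not 0 <= self.multiallelic_fraction < 1:
            raise ValueError("multiallelic_fraction must be in [0, 1)")
        for spec in self.multipliers.values():
            if (expand_class_multipliers(spec) < 0).any():
                raise ValueError("multipliers must be nonnegative")

    @property
    def n_individuals(self) -> int:
        return self.n_chromosomes // 2

    def multiplier_vector(self, compartment: str) -> np.ndarray:
        return expand_class_multipliers(self.multipliers.get(compartment))

    def rates_for(self, compartment: str) -> np.ndarray:
        return self.base_rates * self.multiplier_vector(compartment)

    # -- frequency law --------------------------------------------------------

    def sfs_pmf(self) -> np.ndarray:
        """P(derived count = j), j = 1..n-1, truncated power law j^-alpha."""
        j = np.arange(1, self.n_chromosomes, dtype=float)
        w = j ** -self.sfs_alpha
        return w / w.sum()

    def expected_singleton_fraction(self) -> float:
        return float(self.sfs_pmf()[0])

    def expected_counts(self, opp: OpportunityTable) -> np.ndarray:
        """Closed-form E[S_i] for a compartment's opportunity table."""
        return opp.type_counts * self.rates_for(opp.compartment)

    def manifest(self) -> dict:
        return {
            "base_rates": self.base_rates.tolist(),
            "multipliers": {
                name: expand_class_multipliers(spec).tolist()
                for name, spec in self.multipliers.items()
            },
            "covariate_beta": dict(self.covariate_beta),
            "sfs_alpha": self.sfs_alpha,
            "n_chromosomes": self.n_chromosomes,
            "multiallelic_fraction": self.multiallelic_fraction,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# Genome and compartment generators
# ---------------------------------------------------------------------------


def simulate_genome(
    length: int,
    gc_fraction: float = 0.41,
    n_contigs: int = 1,
    seed: int = 0,
    prefix: str = "chr",
) -> Genome:
    """I.i.d. random genome at the requested GC content, ``length`` bp per contig."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1 - gc_fraction) / 2
    gc = gc_fraction / 2
    probs = [at, gc, gc, at]
    return Genome(
        {
            f"{prefix}{i + 1}": rng.choice(4, size=length, p=probs).astype(np.uint8)
            for i in range(n_contigs)
        }
    )


def halves(extent: Mapping[str, int], names: tuple[str, str] = ("A", "B")) -> tuple[CompartmentSet, CompartmentSet]:
    """Split every contig in half into two disjoint compartments."""
    first = [(c, 0, L // 2) for c, L in extent.items()]
    second = [(c, L // 2, L) for c, L in extent.items()]
    return CompartmentSet(names[0], first), CompartmentSet(names[1], second)


def covariate_track(
    extent: Mapping[str, int],
    step: int = 100_000,
    amplitude: float = 1.0,
    period: Optional[float] = None,
    gradient: float = 0.0,
    noise: float = 0.0,
    seed: int = 0,
) -> CompartmentSet:
    """Smooth scored track: sinusoid plus optional linear gradient and noise.

    Scores mimic a signed replication-timing coordinate (positive = early).
    The default period is half the contig length, so every contig sees two
    full oscillations and scores span the whole +-amplitude range.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for ci, (contig, length) in enumerate(extent.items()):
        per = period if period is not None else length / 2
        starts = np.arange(0, length, step)
        ends = np.minimum(starts + step, length)
        mid = (starts + ends) / 2
        score = amplitude * np.sin(2 * np.pi * (mid / per + 0.1 * ci))
        score = score + gradient * mid / max(length, 1)
        if noise:
            score = score + rng.normal(0, noise, size=len(mid))
        rows += [
            (contig, int(s), int(e), float(v))
            for s, e, v in zip(starts, ends, score)
        ]
    return CompartmentSet("covariate", rows)


def ramp_track(
    extent: Mapping[str, int],
    step: int,
    span: Mapping[str, tuple[float, float]],
    name: str = "covariate",
) -> CompartmentSet:
    """Linear covariate ramp per contig: scores run from lo to hi along it.

    Produces a uniform score distribution over each contig's windows, which
    makes quantile-bin covariate matching essentially exact.
    """
    rows = []
    for contig, (lo, hi) in span.items():
        length = extent[contig]
        starts = np.arange(0, length, step)
        ends = np.minimum(starts + step, length)
        mid = (starts + ends) / 2
        score = lo + (hi - lo) * mid / length
        rows += [
            (contig, int(s), int(e), float(v))
            for s, e, v in zip(starts, ends, score)
        ]
    return CompartmentSet(name, rows)


def hotspot_tiers(
    extent: Mapping[str, int],
    tier_scores: Sequence[float],
    n_per_tier: int = 50,
    width: int = 2_000,
    seed: int = 0,
    name: str = "hotspots",
) -> CompartmentSet:
    """Random non-overlapping scored intervals, ``n_per_tier`` per score tier."""
    rng = np.random.default_rng(seed)
    rows = []
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in extent}
    contigs = list(extent)
    for score in tier_scores:
        placed = 0
        attempts = 0
        while placed < n_per_tier:
            attempts += 1
            if attempts > 1000 * n_per_tier:
                raise RuntimeError("cannot place hotspots without overlap")
            contig = contigs[rng.integers(len(contigs))]
            length = extent[contig]
            if length <= width:
                continue
            start = int(rng.integers(0, length - width))
            end = start + width
            if any(s < end and start < e for s, e in taken[contig]):
                continue
            taken[contig].append((start, end))
            rows.append((contig, start, end, float(score)))
            placed += 1
    return CompartmentSet(name, rows)


def terminal_region(
    extent: Mapping[str, int], contig: str, length: int, name: str = "par1"
) -> CompartmentSet:
    """The first ``length`` bp of a contig (a PAR1-like terminal segment)."""
    return CompartmentSet(name, [(contig, 0, min(length, extent[contig]))])


def simulate_compartments(
    extent: Mapping[str, int], spec: Mapping, seed: int = 0
):
    """Dispatch compartment construction from a small config mapping.

    ``spec["kind"]`` selects the generator: ``halves``, ``covariate``,
    ``hotspots`` or ``terminal``; remaining keys are passed through.
    """
    kind = spec.get("kind")
    args = {k: v for k, v in spec.items() if k != "kind"}
    if kind == "halves":
        return halves(extent, **args)
    if kind == "covariate":
        return covariate_track(extent, seed=seed, **args)
    if kind == "hotspots":
        return hotspot_tiers(extent, seed=seed, **args)
    if kind == "terminal":
        return terminal_region(extent, **args)
    raise ValueError(f"unknown compartment spec kind {kind!r}")


# ---------------------------------------------------------------------------
# Variant simulation
# ---------------------------------------------------------------------------


class OpportunitySites:
    """Opportunity site positions of a compartment, grouped by context.

    For each canonical context: the contig, 0-based position and strand
    orientation (whether the genomic central base is the purine partner) of
    every opportunity site.  Built once, reused across replicates.
    """

    def __init__(self, genome: Genome, comp: CompartmentSet):
        cache = genome_context_indices(genome)
        self.compartment = comp.name
        self.contigs: list[str] = []
        per_ctx_pos: list[list[np.ndarray]] = [[] for _ in range(32)]
        per_ctx_contig: list[list[np.ndarray]] = [[] for _ in range(32)]
        per_ctx_flip: list[list[np.ndarray]] = [[] for _ in range(32)]
        for row in comp.df.itertuples():
            if row.contig not in self.contigs:
                self.contigs.append(row.contig)
            ci = self.contigs.index(row.contig)
            ctx = cache[row.contig]
            seq = genome[row.contig]
            pos = np.arange(row.start, row.end, dtype=np.int64)
            cvals = ctx[row.start : row.end]
            ok = cvals >= 0
            pos, cvals = pos[ok], cvals[ok]
            centre = seq[pos]
            flip = (centre != C) & (centre != T)
            for ctx_i in range(32):
                sel = cvals == ctx_i
                if sel.any():
                    per_ctx_pos[ctx_i].append(pos[sel])
                    per_ctx_contig[ctx_i].append(
                        np.full(int(sel.sum()), ci, dtype=np.int32)
                    )
                    per_ctx_flip[ctx_i].append(flip[sel])
        self.pos = [
            np.concatenate(p) if p else np.empty(0, dtype=np.int64)
            for p in per_ctx_pos
        ]
        self.contig_idx = [
            np.concatenate(p) if p else np.empty(0, dtype=np.int32)
            for p in per_ctx_contig
        ]
        self.flip = [
            np.concatenate(p) if p else np.empty(0, dtype=bool)
            for p in per_ctx_flip
        ]
        self.context_counts = np.array([len(p) for p in self.pos], dtype=np.int64)

    def opportunity_table(self) -> OpportunityTable:
        return OpportunityTable(self.compartment, self.context_counts)


def sample_derived_counts(
    rng: np.random.Generator, size: int, truth: SimulationTruth
) -> np.ndarray:
    """Draw derived allele counts from the truncated power law."""
    pmf = truth.sfs_pmf()
    cdf = np.cumsum(pmf)
    u = rng.random(size)
    return np.searchsorted(cdf, u, side="right") + 1


def simulate_variants(
    genome: Genome,
    regions: Sequence[tuple[Union[CompartmentSet, OpportunitySites], object]],
    truth: SimulationTruth,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate a rare-variant callset with planted per-region spectra.

    ``regions`` is a sequence of (compartment, multiplier) pairs; regions
    are assumed disjoint.  The multiplier may be None, a scalar, a
    class->factor mapping, or a 96-vector.  Returns the observation frame
    (sorted; one row per derived allele) and a truth manifest holding the
    planted parameters and closed-form expected counts per region.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    n = truth.n_chromosomes

    contig_names: list[str] = []
    parts: list[dict] = []
    expected: dict[str, list[float]] = {}
    for comp, mult in regions:
        sites = comp if isinstance(comp, OpportunitySites) else OpportunitySites(genome, comp)
        multv = expand_class_multipliers(mult)
        rates = truth.base_rates * multv
        opp96 = sites.context_counts[CONTEXT_OF_TYPE]
        expected[sites.compartment] = (opp96 * rates).tolist()
        for ctx_i in range(32):
            npos = int(sites.context_counts[ctx_i])
            if npos == 0:
                continue
            types = np.flatnonzero(CONTEXT_OF_TYPE == ctx_i)
            lam = npos * rates[types]
            counts = rng.poisson(lam)
            k = int(counts.sum())
            if k == 0:
                continue
            if k > npos:
                raise ValueError(
                    f"context {ctx_i}: {k} mutations for {npos} sites; "
                    "lower the rate or enlarge the genome"
                )
            chosen = rng.choice(npos, size=k, replace=False)
            type_arr = np.repeat(types, counts).astype(np.int16)
            pos = sites.pos[ctx_i][chosen]
            flip = sites.flip[ctx_i][chosen]
            local_contig = sites.contig_idx[ctx_i][chosen]
            # map region-local contig ids into a global list
            gmap = np.empty(len(sites.contigs), dtype=np.int32)
            for li, cname in enumerate(sites.contigs):
                if cname not in contig_names:
                    contig_names.append(cname)
                gmap[li] = contig_names.index(cname)
            canonical_ref = np.where(ctx_i < 16, C, T).astype(np.int16)
            ref = np.where(flip, 3 - canonical_ref, canonical_ref).astype(np.int16)
            alt = np.where(flip, 3 - _ALT_CODE[type_arr], _ALT_CODE[type_arr]).astype(
                np.int16
            )
            parts.append(
                {
                    "contig_idx": gmap[local_contig],
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "ctx": np.full(k, ctx_i, dtype=np.int16),
                    "type": type_arr,
                    "region": sites.compartment,
                }
            )

    if not parts:
        obs = pd.DataFrame(columns=OBS_COLUMNS).astype(
            {"pos": np.int64, "ref": np.uint8, "alt": np.uint8, "ac": np.int64, "an": np.int64}
        )
        return obs, {"truth": truth.manifest(), "expected_counts": expected}

    contig_idx = np.concatenate([p["contig_idx"] for p in parts])
    pos = np.concatenate([p["pos"] for p in parts])
    ref = np.concatenate([p["ref"] for p in parts])
    alt = np.concatenate([p["alt"] for p in parts])
    ctx = np.concatenate([p["ctx"] for p in parts])
    typ = np.concatenate([p["type"] for p in parts])
    region = np.concatenate(
        [np.full(len(p["pos"]), p["region"], dtype=object) for p in parts]
    )

    # Convert a fraction of co-located-compatible pairs into multiallelic
    # sites: within each region and context, pairs of observations with
    # different alternate alleles are merged onto one position.
    if truth.multiallelic_fraction > 0:
        for reg in expected:
            for ctx_i in range(32):
                grp = np.flatnonzero((region == reg) & (ctx == ctx_i))
                if len(grp) < 2:
                    continue
                n_merge = int(round(truth.multiallelic_fraction * len(grp) / 2))
                if n_merge == 0:
                    continue
                order = rng.permutation(len(grp))
                merged = 0
                i = 0
                while merged < n_merge and i + 1 < len(grp):
                    a, b = grp[order[i]], grp[order[i + 1]]
                    i += 2
                    if typ[a] == typ[b]:
                        continue
                    # move b onto a's site, matching a's strand orientation
                    pos[b] = pos[a]
                    contig_idx[b] = contig_idx[a]
                    ref[b] = ref[a]
                    flip_a = ref[a] not in (C, T)
                    alt[b] = 3 - _ALT_CODE[typ[b]] if flip_a else _ALT_CODE[typ[b]]
                    merged += 1

    dac = sample_derived_counts(rng, len(pos), truth)
    names = np.array(contig_names, dtype=object)
    obs = pd.DataFrame(
        {
            "contig": names[contig_idx],
            "pos": pos + 1,  # VCF 1-based
            "ref": ref.astype(np.uint8),
            "alt": alt.astype(np.uint8),
            "ac": dac.astype(np.int64),
            "an": np.int64(n),
            "true_type": typ,
            "region": region,
        }
    ).sort_values(["contig", "pos", "alt"], kind="mergesort").reset_index(drop=True)

    manifest = {
        "truth": truth.manifest(),
        "expected_counts": expected,
        "n_observations": int(len(obs)),
    }
    return obs, manifest


def covariate_regions(
    windows: CompartmentSet, beta: Mapping[str, float]
) -> list[tuple[CompartmentSet, np.ndarray]]:
    """Per-window multiplier regions for covariate-modulated rates.

    Window w with covariate x_w multiplies the rates of class c by
    ``1 + beta_c * x_w``; multipliers must stay positive over the track.
    """
    out = []
    scores = windows.scores()
    for i, row in enumerate(windows.df.itertuples()):
        mult = np.ones(N_TYPES)
        for cls, b in beta.items():
            factor = 1.0 + b * scores[i]
            if factor <= 0:
                raise ValueError(
                    f"covariate effect drives class {cls} rate nonpositive "
                    f"at window {i} (x={scores[i]:.3g})"
                )
            mult[CLASS_OF_TYPE == CLASSES.index(cls)] = factor
        comp = CompartmentSet(
            f"{windows.name}_{i}", [(row.contig, row.start, row.end)]
        )
        out.append((comp, mult))
    return out
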