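"""End-to-end runs: configuration, presets and reproducible output bundles.

A run is driven by a :class:`RunConfig`; every output directory receives the
result tables as TSV plus ``run_manifest.json`` echoing the full
configuration, the package version and SHA-256 checksums of the inputs, so
any bundle can be regenerated from config + inputs alone.

Presets realize the study designs the package exists for, at desk scale, on
synthetic data with planted truth:

* ``null-selftest``     one rate vector, two halves; expects no significant types
* ``late-vs-early``     1.2x C>A planted in the late-replicating compartment
* ``x-vs-autosome``     an X-like contig against autosomes, CpG excluded
* ``par1-vs-autosome``  C>G planted in a PAR1-like terminal region
* ``hotspot-bins``      monotone C>G multipliers across hotspot intensity tiers
* ``matched-timing``    covariate-driven rates, covariate-shifted test compartment
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .catalog import ANCESTRAL_GENOME, MAJOR_ALLELE, PolarizationMode
from .compare import (
    enrichment_test,
    matched_comparison,
    pooled_class_enrichment,
    scored_bin_enrichment,
)
from .intervals import CompartmentSet, bin_by_score
from .io import Genome, read_vcf, write_table
from .simulate import (
    SimulationTruth,
    covariate_regions,
    covariate_track,
    halves,
    hotspot_tiers,
    ramp_track,
    simulate_genome,
    simulate_variants,
    terminal_region,
)
from .spectrum import FrequencyFilter, sfs, tabulate

PRESETS = (
    "null-selftest",
    "late-vs-early",
    "x-vs-autosome",
    "par1-vs-autosome",
    "hotspot-bins",
    "matched-timing",
)


@dataclass
class RunConfig:
    """Everything a run needs; echoed verbatim into the output manifest."""

    outdir: str
    preset: Optional[str] = None
    genome: Optional[str] = None
    variants: Optional[str] = None
    test_bed: Optional[str] = None
    ref_bed: Optional[str] = None
    covariate: Optional[str] = None
    polarization: str = MAJOR_ALLELE
    ancestral: Optional[str] = None
    max_daf: Optional[float] = None
    exclude_cpg: bool = False
    alpha: float = 0.05
    tail: str = "minlike"
    seed: int = 0
    genome_length: int = 1_000_000

    def validate(self) -> list[str]:
        problems = []
        if self.preset is not None and self.preset not in PRESETS:
            problems.append(f"unknown preset {self.preset!r}")
        if self.preset is None:
            for label in ("genome", "variants", "test_bed", "ref_bed"):
                path = getattr(self, label)
                if path is None:
                    problems.append(f"{label} is required without a preset")
                elif not Path(path).exists():
                    problems.append(f"{label} path {path!r} does not exist")
        if self.polarization not in (MAJOR_ALLELE, ANCESTRAL_GENOME):
            problems.append(f"unknown polarization {self.polarization!r}")
        if self.polarization == ANCESTRAL_GENOME and not self.ancestral:
            problems.append("ancestral FASTA required for ancestral polarization")
        if not 0 < self.alpha < 1:
            problems.append("alpha must be in (0, 1)")
        return problems

    def frequency_filter(self) -> FrequencyFilter:
        return FrequencyFilter(max_daf=self.max_daf)

    def polarization_mode(self, genome: Optional[Genome] = None) -> PolarizationMode:
        if self.polarization == ANCESTRAL_GENOME:
            return PolarizationMode(
                ANCESTRAL_GENOME, Genome.from_fasta(self.ancestral)
            )
        return PolarizationMode()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(config: RunConfig, outdir: Path, inputs: list[Path]) -> None:
    manifest = {
        "config": dataclasses.asdict(config),
        "version": __version__,
        "inputs": {str(p): _sha256(p) for p in inputs if p.exists()},
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute a configured run and write its result bundle.

    Returns a dict of the in-memory results (tables keyed by stage).
    Raises ``ValueError`` listing every validation problem before any stage
    executes.
    """
    problems = config.validate()
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.preset is not None:
        return _run_preset(config, outdir)
    return _run_files(config, outdir)


def _run_files(config: RunConfig, outdir: Path) -> dict:
    genome = Genome.from_fasta(config.genome)
    variants = read_vcf(config.variants)
    test = CompartmentSet.from_bed(config.test_bed, name="test")
    ref = CompartmentSet.from_bed(config.ref_bed, name="reference")
    pol = config.polarization_mode(genome)
    filt = config.frequency_filter()
    params = {"seed": config.seed, "alpha": config.alpha, "tail": config.tail}

    t_tab = tabulate(variants, test, genome, pol=pol, filt=filt)
    r_tab = tabulate(variants, ref, genome, pol=pol, filt=filt)
    if config.exclude_cpg:
        t_tab = t_tab.exclude_types("cpg")
        r_tab = r_tab.exclude_types("cpg")
    result = enrichment_test(t_tab, r_tab, alpha=config.alpha, tail=config.tail)
    write_table(t_tab.frame, outdir / "spectrum_test.tsv", params)
    write_table(r_tab.frame, outdir / "spectrum_reference.tsv", params)
    write_table(result, outdir / "enrichment.tsv", params)
    write_table(sfs(variants, filt).to_frame(), outdir / "sfs.tsv", params)
    _write_manifest(
        config,
        outdir,
        [Path(p) for p in (config.genome, config.variants, config.test_bed, config.ref_bed)],
    )
    return {"test": t_tab, "reference": r_tab, "enrichment": result}


def _run_preset(config: RunConfig, outdir: Path) -> dict:
    seed = config.seed
    params = {"preset": config.preset, "seed": seed, "alpha": config.alpha}
    L = config.genome_length

    if config.preset == "null-selftest":
        genome = simulate_genome(L, seed=seed)
        a, b = halves(genome.extent)
        truth = SimulationTruth(seed=seed + 1)
        obs, _ = simulate_variants(genome, [(a, None), (b, None)], truth)
        res = enrichment_test(
            tabulate(obs, b, genome), tabulate(obs, a, genome), alpha=config.alpha
        )
        out = {"enrichment": res, "n_significant": int(res["significant"].sum())}
        write_table(res, outdir / "enrichment.tsv", params)

    elif config.preset == "late-vs-early":
        genome = simulate_genome(max(L, 2_000_000), seed=seed)
        track = covariate_track(genome.extent, step=50_000, amplitude=0.8, seed=seed)
        late, early = bin_by_score(track, edges=(-0.5, 0.5), names=["late", "early"])
        rest = late.complement(genome.extent, name="not-late")
        truth = SimulationTruth(seed=seed + 1, multipliers={"late": {"C>A": 1.2}})
        obs, _ = simulate_variants(genome, [(late, {"C>A": 1.2}), (rest, None)], truth)
        res = enrichment_test(
            tabulate(obs, late, genome), tabulate(obs, early, genome),
            alpha=config.alpha,
        )
        pooled = pooled_class_enrichment(
            tabulate(obs, late, genome), tabulate(obs, early, genome),
            alpha=config.alpha,
        )
        out = {"enrichment": res, "pooled": pooled}
        write_table(res, outdir / "enrichment.tsv", params)
        write_table(pooled, outdir / "enrichment_classes.tsv", params)

    elif config.preset == "x-vs-autosome":
        genome = simulate_genome(L // 2, n_contigs=4, seed=seed, prefix="auto")
        xg = simulate_genome(L // 2, seed=seed + 7, prefix="chrX_")
        genome = Genome({**{c: genome[c] for c in genome}, "chrX": xg["chrX_1"]})
        autos = CompartmentSet(
            "autosomes", [(c, 0, ln) for c, ln in genome.extent.items() if c != "chrX"]
        )
        xcomp = CompartmentSet("chrX", [("chrX", 0, genome.extent["chrX"])])
        truth = SimulationTruth(
            seed=seed + 1, multipliers={"chrX": {"C>T": 1.06, "T>C": 1.05, "C>A": 0.95}}
        )
        obs, _ = simulate_variants(
            genome, [(autos, None), (xcomp, truth.multipliers["chrX"])], truth
        )
        t_tab = tabulate(obs, xcomp, genome).exclude_types("cpg")
        r_tab = tabulate(obs, autos, genome).exclude_types("cpg")
        res = enrichment_test(t_tab, r_tab, alpha=config.alpha)
        out = {"enrichment": res}
        write_table(res, outdir / "enrichment.tsv", params)

    elif config.preset == "par1-vs-autosome":
        genome = simulate_genome(L, n_contigs=2, seed=seed, prefix="chr")
        extent = genome.extent
        par = terminal_region(extent, "chr2", L // 5, name="par1")
        autos = CompartmentSet("autosomes", [("chr1", 0, extent["chr1"])])
        xrest = CompartmentSet("xrest", [("chr2", L // 5, extent["chr2"])])
        truth = SimulationTruth(seed=seed + 1, multipliers={"par1": {"C>G": 1.3}})
        obs, _ = simulate_variants(
            genome, [(autos, None), (par, {"C>G": 1.3}), (xrest, None)], truth
        )
        t_tab = tabulate(obs, par, genome).exclude_types("cpg")
        r_tab = tabulate(obs, autos, genome).exclude_types("cpg")
        res = enrichment_test(t_tab, r_tab, alpha=config.alpha)
        out = {"enrichment": res}
        write_table(res, outdir / "enrichment.tsv", params)

    elif config.preset == "hotspot-bins":
        genome = simulate_genome(max(L, 2_000_000), seed=seed)
        tiers = hotspot_tiers(
            genome.extent, tier_scores=(1.0, 2.0, 3.0, 4.0),
            n_per_tier=60, width=2_000, seed=seed,
        )
        mults = {1.0: 1.0, 2.0: 1.1, 3.0: 1.2, 4.0: 1.3}
        bins = bin_by_score(tiers, n_bins=4)
        outside = tiers.drop_scores("outside").complement(genome.extent, name="outside")
        regions = [(outside, None)] + [
            (b, {"C>G": mults[float(b.scores().mean() if b.scored else 1)]})
            for b in bins
        ]
        truth = SimulationTruth(seed=seed + 1)
        obs, _ = simulate_variants(genome, regions, truth)
        res = scored_bin_enrichment(
            obs, genome, tiers, bins, reference=outside, alpha=config.alpha
        )
        out = {"bins": res}
        write_table(res, outdir / "bin_enrichment.tsv", params)

    elif config.preset == "matched-timing":
        genome = simulate_genome(max(L, 1_000_000), n_contigs=4, seed=seed)
        extent = genome.extent
        contigs = list(extent)
        # reference contigs span the full covariate range; the test contig
        # replicates later on average, with support inside the reference's
        span = {c: (-1.0, 1.0) for c in contigs[:-1]}
        span[contigs[-1]] = (-0.8, 0.2)
        track = ramp_track(extent, step=25_000, span=span)
        beta = {"C>A": 0.5}
        regions = covariate_regions(track, beta)
        truth = SimulationTruth(seed=seed + 1, covariate_beta=beta)
        obs, _ = simulate_variants(genome, regions, truth)
        test = CompartmentSet("test", [(contigs[-1], 0, extent[contigs[-1]])])
        ref = CompartmentSet(
            "ref", [(c, 0, extent[c]) for c in contigs[:-1]]
        )
        res, diag = matched_comparison(
            obs, genome, test, ref, track, n_bins=8, seed=seed,
            window_width=25_000, alpha=config.alpha,
        )
        out = {"enrichment": res, "diagnostics": diag}
        write_table(res, outdir / "enrichment_matched.tsv", params)

    else:  # pragma: no cover
        raise AssertionError(config.preset)

    _write_manifest(config, outdir, [])
    return out
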