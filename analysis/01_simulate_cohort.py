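#!/usr/bin/env python
"""Build the synthetic rare-variant cohort all downstream analyses use.

Generates a 2-Mb random genome, splits it into two compartments, and draws
a callset from the default truth: 13,860 sampled chromosomes (6,930 diploid
individuals), a singleton-heavy truncated power-law frequency spectrum
(alpha = 1.8), ~6% multiallelic observations, and a CpG-elevated,
transition-dominated base spectrum at realistic diversity.

Writes the FASTA/VCF/BED bundle under scratch/cohort/ and a small summary
table under results/.
"""

import json
from pathlib import Path

import pandas as pd

from mutspectra.io import write_table, write_vcf
from mutspectra.simulate import SimulationTruth, halves, simulate_genome, simulate_variants
from mutspectra.spectrum import sfs

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    genome = simulate_genome(2_000_000, seed=SEED)
    a, b = halves(genome.extent)
    truth = SimulationTruth(seed=SEED + 1)
    obs, manifest = simulate_variants(genome, [(a, None), (b, None)], truth)

    genome.to_fasta(SCRATCH / "genome.fa")
    write_vcf(obs, SCRATCH / "variants.vcf", extent=genome.extent)
    a.to_bed(SCRATCH / "compartment_A.bed")
    b.to_bed(SCRATCH / "compartment_B.bed")
    (SCRATCH / "truth_manifest.json").write_text(json.dumps(manifest, indent=2))

    hist = sfs(obs)
    total = int(hist.sum())
    summary = pd.DataFrame(
        {
            "value": {
                "n_observations": total,
                "sample_chromosomes": truth.n_chromosomes,
                "singleton_fraction": round(hist.get(1, 0) / total, 4),
                "doubleton_fraction": round(hist.get(2, 0) / total, 4),
                "three_copies_or_fewer": round(
                    hist.reindex([1, 2, 3], fill_value=0).sum() / total, 4
                ),
                "multiallelic_observation_fraction": round(
                    obs.duplicated(["contig", "pos"], keep=False).mean(), 4
                ),
                "expected_singleton_fraction": round(
                    truth.expected_singleton_fraction(), 4
                ),
            }
        }
    )
    write_table(summary, RESULTS / "cohort_summary.tsv", {"seed": SEED})
    print(f"cohort: {total} observations on 2 Mb, AN={truth.n_chromosomes}")
    print(summary)
    print(f"data bundle in {SCRATCH}, summary in {RESULTS/'cohort_summary.tsv'}")


if __name__ == "__main__":
    main()
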