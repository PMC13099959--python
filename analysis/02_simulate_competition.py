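#!/usr/bin/env python
"""Forward-simulate the pooled pH screen and emit amplicon FASTQ samples.

The pool mixes all 153 genotypes at equal frequency: P6H carries the
alkaline-activated mating profile (near-sterile at pH 5.5), P6D the
acid-activated one, everything else the flat wild-type-like profile.  Three
replicates run five mating-germination cycles on SSA at pH 4.0, 5.5 and 7.0
with a ~1.5e7-cell bottleneck per cycle; the final-cycle pools are sequenced
as 75-bp reads.

FASTQ files land under scratch/fastq (they are bulky, regenerable data); the
sample manifest is copied to results/samples.tsv for the downstream stages.
"""

import argparse
import shutil
from pathlib import Path

from mfcomp import Condition, SimConfig, enumerate_library, profiles_from_presets, simulate_experiment

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--reads", type=int, default=200_000, help="reads per sample")
    args = parser.parse_args()

    lib = enumerate_library()
    profiles = profiles_from_presets(lib, {"P6H": "P6H-like", "P6D": "P6D-like"})
    conditions = [Condition("SSA", 4.0), Condition("SSA", 5.5), Condition("SSA", 7.0)]
    cfg = SimConfig(cycles=5, replicates=3, reads_per_sample=args.reads, error_rate=0.0,
                    seed=args.seed)
    fastq_dir = ROOT / "scratch" / "fastq"
    manifest, _ = simulate_experiment(lib, profiles, conditions, cfg, outdir=fastq_dir,
                                      sample_cycles=[0, cfg.cycles])
    (ROOT / "results").mkdir(exist_ok=True)
    shutil.copy(fastq_dir / "samples.tsv", ROOT / "results" / "samples.tsv")
    print(f"simulated {len(manifest)} samples x {args.reads} reads -> {fastq_dir}")
    print("manifest -> results/samples.tsv")


if __name__ == "__main__":
    main()
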