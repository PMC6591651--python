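#!/usr/bin/env python
"""Detection power for Y-allele reactivation across reactivation fraction
and depth.

Each grid cell replays the whole pipeline (simulate case/control cohorts,
calibrate noise on the monoallelic cohort, classify, flag artifacts, count
burdens, permutation test).  f is the fraction of the gene's transcripts
from the normally silenced allele: f=0.5 is full reactivation (both alleles
at equal output).  Writes results/power.tsv.
"""

from pathlib import Path

from biallelic import PowerCell, power_analysis

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    grid = [
        PowerCell(f=f, m=5, depth=d, n=10, error_rate=0.002)
        for f in (0.0, 0.1, 0.2, 0.5)
        for d in (50, 100, 200)
    ]
    res = power_analysis(grid, n_replicates=30, seed=99, transcript_length=120)
    res.table.to_csv(ROOT / "power.tsv", sep="\t", index=False, float_format="%.4g")
    print(res.table[["f", "depth", "p_detect_sample", "p_detect_any", "p_reject"]]
          .to_string(index=False))
    print("\nper-sample detection saturates by f=0.5 at moderate depth; a "
          "reactivated allele expressed at a small fraction of the active "
          "copy can evade the 50:50 heterozygosity signature entirely")


if __name__ == "__main__":
    main()
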