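#!/usr/bin/env python
"""Simulate the study-style dataset: two male cohorts (33 cases, 38
controls, plus one female control) over four transcripts.

* SPRY3   — the test gene: a pseudoautosomal transcript whose second
            (Y-linked) copy is silenced in both cohorts (f = 0); the female
            control is genuinely heterozygous at its divergent sites.
* TMLHE   — hemizygous X-linked negative control: no divergent sites, so
            every apparent variant is technical noise.
* NPTN,
  MCM6    — autosomal positive controls: every sample heterozygous (f = 0.5).

Per-transcript total mapped reads are drawn uniformly from 653-4033 and
spread as 100-nt reads.  Transcript length is scaled to 1,200 nt to keep
the fixture compact.  Outputs: counts TSV, sample sheet, truth table and
scenario config per gene under results/sim/.
"""

from pathlib import Path

from biallelic import SimScenario, simulate_cohort, write_fixture

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"

L = 1200
ERR = 0.002  # per-base miscall probability typical of curated short-read data
N_CASE, N_CONTROL = 33, 38

GENES = {
    # gene: (divergent sites, case f, control f, female controls)
    "SPRY3": (tuple(range(150, 1200, 180)), 0.0, 0.0, 1),
    "TMLHE": ((), 0.0, 0.0, 0),
    "NPTN": (tuple(range(200, 1200, 250)), 0.5, 0.5, 0),
    "MCM6": (tuple(range(100, 1200, 300)), 0.5, 0.5, 0),
}


def main() -> None:
    for i, (gene, (sites, f_case, f_ctrl, n_female)) in enumerate(GENES.items()):
        common = dict(gene=gene, transcript_length=L, divergent_sites=sites,
                      error_rate=ERR, depth=None, total_read_range=(653, 4033),
                      read_length=100)
        case = SimScenario(y_fraction=f_case, n_samples=N_CASE, cohort="autism",
                           seed=1000 + i, **common)
        n_ctrl = N_CONTROL + n_female
        sexes = ("male",) * N_CONTROL + ("female",) * n_female
        control = SimScenario(y_fraction=f_ctrl, n_samples=n_ctrl, sexes=sexes,
                              cohort="control", seed=2000 + i, **common)
        pileups, sheet, truth = simulate_cohort(case, control)
        gene_dir = OUT / gene
        write_fixture(pileups, gene_dir, sample_sheet=sheet, truth=truth, scenario=case)
        # drop the per-sample mpileup files for the large fixture; the counts
        # TSV is the canonical interchange here
        for p in gene_dir.glob("*.mpileup"):
            p.unlink()
        depth_totals = [tp.meta["n_reads"] for tp in pileups]
        print(f"{gene}: {len(pileups)} samples, {len(sites)} divergent sites, "
              f"total reads {min(depth_totals)}-{max(depth_totals)} -> {gene_dir}")


if __name__ == "__main__":
    main()
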