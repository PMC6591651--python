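#!/usr/bin/env python
"""Calibrate the technical-noise (miscall) rate on the hemizygous negative
control.

TMLHE is X-linked and expressed from a single copy in males, so any
non-reference base there is sequencing/library/alignment noise.  Counts are
pooled per position across samples; positions above the outlier fraction
(possible true variants / RNA edits) are excluded.  Writes
results/error_estimate.json.
"""

import json
from pathlib import Path

from biallelic import estimate_error_rate, parse_counts_tsv

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    pileups = parse_counts_tsv(ROOT / "sim" / "TMLHE" / "counts.tsv")
    est = estimate_error_rate(pileups, outlier_fraction=0.2)
    payload = {
        "error_rate": est.error_rate,
        "pooled_depth": est.pooled_depth,
        "n_positions_used": est.n_positions_used,
        "n_positions_excluded": est.n_positions_excluded,
    }
    (ROOT / "error_estimate.json").write_text(json.dumps(payload, indent=2) + "\n")
    print(f"estimated miscall rate: {est.error_rate:.5f} "
          f"(pooled depth {est.pooled_depth:,}, "
          f"{est.n_positions_excluded} positions excluded as outliers)")


if __name__ == "__main__":
    main()
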