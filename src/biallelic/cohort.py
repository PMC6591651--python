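"""Cohort comparison of biallelic-expression burden and detection power.

The group test asks whether per-sample heterozygous-site burdens differ
between cohorts.  Two complementary p-values are reported:

* a two-sided permutation test on the difference in mean per-sample burden
  (exhaustive enumeration of labelings when feasible, otherwise Monte-Carlo
  with the add-one convention p = (1 + #{|Δ*| >= |Δ|}) / (n_perm + 1));
* a Fisher exact test on the 2x2 table cohort x (any het site).

The power analysis replays the full pipeline — simulate a two-cohort
dataset, calibrate ε on the monoallelic cohort, classify, flag artifacts,
count burdens, test — across a grid of reactivation fractions, divergent
site counts, depths and cohort sizes, reporting Monte-Carlo detection
probabilities with binomial standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .genotype import DEFAULT_CONFIG, ModelConfig, classify_pileup, estimate_error_rate
from .hetmap import build_map, count_het_sites, flag_artifacts, het_burdens
from .simulate import ScenarioError, SimScenario, simulate_cohort

MAX_EXACT_LABELINGS = 100_000


@dataclass(frozen=True)
class CohortResult:
    """Two-group comparison of per-sample heterozygous-site burdens."""

    gene: str
    groups: tuple[str, str]
    counts: Mapping[str, np.ndarray] = field(compare=False)
    diff_mean: float = 0.0
    n_biallelic: Mapping[str, int] = field(default_factory=dict, compare=False)
    perm_p: float = 1.0
    perm_method: str = "exact"
    n_perm: int = 0
    fisher_p: float = 1.0
    alpha: float = 0.05
    seed: Optional[int] = None

    def summary(self) -> dict:
        g1, g2 = self.groups
        return {
            "gene": self.gene,
            "group_1": g1,
            "group_2": g2,
            "n_1": int(len(self.counts[g1])),
            "n_2": int(len(self.counts[g2])),
            "mean_het_1": float(np.mean(self.counts[g1])),
            "mean_het_2": float(np.mean(self.counts[g2])),
            "n_biallelic_1": int(self.n_biallelic[g1]),
            "n_biallelic_2": int(self.n_biallelic[g2]),
            "diff_mean": self.diff_mean,
            "perm_p": self.perm_p,
            "perm_method": self.perm_method,
            "n_perm": self.n_perm,
            "fisher_p": self.fisher_p,
            "alpha": self.alpha,
        }


def _exact_perm_p(counts: np.ndarray, n1: int, observed: float) -> tuple[float, int]:
    n = len(counts)
    total_sum = counts.sum()
    total = math.comb(n, n1)
    hits = 0
    tol = 1e-12 * max(1.0, abs(observed))
    for idx in combinations(range(n), n1):
        s1 = counts[list(idx)].sum()
        delta = s1 / n1 - (total_sum - s1) / (n - n1)
        if abs(delta) >= abs(observed) - tol:
            hits += 1
    return hits / total, total


def _sampled_perm_p(
    counts: np.ndarray, n1: int, observed: float, n_perm: int, rng: np.random.Generator
) -> float:
    n = len(counts)
    tol = 1e-12 * max(1.0, abs(observed))
    hits = 0
    chunk = max(1, min(n_perm, 200_000 // max(n, 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perm = rng.permuted(np.broadcast_to(counts, (m, n)).copy(), axis=1)
        s1 = perm[:, :n1].sum(axis=1)
        delta = s1 / n1 - (perm[:, n1:].sum(axis=1)) / (n - n1)
        hits += int(np.sum(np.abs(delta) >= abs(observed) - tol))
        done += m
    return (1 + hits) / (n_perm + 1)


def compare_groups(
    counts: Sequence[float],
    labels: Sequence[str],
    n_perm: int = 9999,
    seed: Optional[int] = None,
    alpha: float = 0.05,
    gene: str = "",
    max_exact: int = MAX_EXACT_LABELINGS,
) -> CohortResult:
    """Two-sided test of equal mean per-sample het burden between two cohorts.

    Exhaustive enumeration is used automatically when the number of
    labelings C(n, n1) is at most ``max_exact``; otherwise ``n_perm``
    Monte-Carlo permutations with the add-one p-value convention.
    """
    counts = np.asarray(counts, dtype=float)
    labels = np.asarray(labels)
    if counts.shape != labels.shape:
        raise ValueError("counts and labels must have equal length")
    if np.any(counts < 0):
        raise ValueError("het-site counts must be non-negative")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    groups = list(pd.unique(labels))
    if len(groups) != 2:
        raise ValueError(f"exactly two cohorts required, got {groups}")
    g1, g2 = groups
    c1 = counts[labels == g1]
    c2 = counts[labels == g2]
    if len(c1) < 2 or len(c2) < 2:
        raise ValueError("each cohort needs >= 2 samples")

    observed = float(c1.mean() - c2.mean())
    pooled = np.concatenate([c1, c2])
    n1 = len(c1)
    if math.comb(len(pooled), n1) <= max_exact:
        perm_p, n_used = _exact_perm_p(pooled, n1, observed)
        method = "exact"
    else:
        rng = np.random.default_rng(seed)
        perm_p = _sampled_perm_p(pooled, n1, observed, n_perm, rng)
        n_used, method = n_perm, "sampled"

    table = [[int((c1 > 0).sum()), int((c1 == 0).sum())],
             [int((c2 > 0).sum()), int((c2 == 0).sum())]]
    _, fisher_p = fisher_exact(table, alternative="two-sided")

    return CohortResult(
        gene=gene,
        groups=(str(g1), str(g2)),
        counts={str(g1): c1, str(g2): c2},
        diff_mean=observed,
        n_biallelic={str(g1): table[0][0], str(g2): table[1][0]},
        perm_p=float(perm_p),
        perm_method=method,
        n_perm=int(n_used),
        fisher_p=float(fisher_p),
        alpha=alpha,
        seed=seed,
    )


def compare_burdens(
    burdens: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    gene: str,
    exclude_females: bool = True,
    n_perm: int = 9999,
    seed: Optional[int] = None,
    alpha: float = 0.05,
) -> CohortResult:
    """Cohort comparison from a per-sample burden table and a sample sheet.

    Females are excluded by default: at a pseudoautosomal test gene they are
    legitimately heterozygous, so they serve as positive controls rather
    than test samples.
    """
    merged = burdens.merge(sample_sheet, on="sample", validate="one_to_one")
    if exclude_females:
        merged = merged[merged["sex"] == "male"]
    return compare_groups(
        merged["het_sites"].to_numpy(float),
        merged["cohort"].to_numpy(),
        n_perm=n_perm,
        seed=seed,
        alpha=alpha,
        gene=gene,
    )


# --------------------------------------------------------------------------
# detection-power simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerCell:
    """One grid point of the detection-power surface."""

    f: float  # reactivation (second-allele transcript) fraction in cases
    m: int = 5  # divergent sites
    depth: int = 100  # fixed per-position depth
    n: int = 10  # samples per cohort
    error_rate: float = 0.0


@dataclass(frozen=True)
class PowerResult:
    table: pd.DataFrame
    n_replicates: int
    seed: int


POWER_COLUMNS = [
    "f", "m", "depth", "n", "error_rate",
    "p_detect_sample", "se_detect_sample",
    "p_detect_any", "se_detect_any",
    "p_reject", "se_reject",
    "n_replicates",
]


def _run_pipeline_once(
    cell: PowerCell,
    cfg: ModelConfig,
    alpha: float,
    n_perm: int,
    transcript_length: int,
    seeds: np.ndarray,
    perm_seed: int,
) -> tuple[float, bool, bool]:
    L = transcript_length
    sites = tuple(np.linspace(1, L, cell.m + 2, dtype=int)[1:-1]) if cell.m else ()
    common = dict(
        gene="POWER",
        transcript_length=L,
        divergent_sites=sites,
        error_rate=cell.error_rate,
        depth=cell.depth,
        n_samples=cell.n,
    )
    case = SimScenario(y_fraction=cell.f, cohort="case", seed=int(seeds[0]), **common)
    control = SimScenario(y_fraction=0.0, cohort="control", seed=int(seeds[1]), **common)
    pileups, sheet, _ = simulate_cohort(case, control)

    # calibrate noise on the monoallelic cohort (the hemizygous-control role)
    control_pileups = [tp for tp in pileups if tp.meta.get("cohort") == "control"]
    eps_hat = estimate_error_rate(control_pileups).error_rate

    maps = [build_map(tp, classify_pileup(tp, cfg, eps_hat)) for tp in pileups]
    artifacts = flag_artifacts(maps, sheet)
    burdens = het_burdens(maps, artifacts).merge(sheet, on="sample")

    case_counts = burdens.loc[burdens["cohort"] == "case", "het_sites"].to_numpy()
    detect_frac = float(np.mean(case_counts >= 1))
    result = compare_groups(
        burdens["het_sites"].to_numpy(float),
        burdens["cohort"].to_numpy(),
        n_perm=n_perm,
        seed=perm_seed,
        alpha=alpha,
        gene="POWER",
        max_exact=1,  # sampled permutations keep replicate cost bounded
    )
    return detect_frac, bool(case_counts.max() >= 1), bool(result.perm_p < alpha)


def power_analysis(
    grid: Iterable[PowerCell | Mapping],
    n_replicates: int,
    seed: int,
    cfg: ModelConfig = DEFAULT_CONFIG,
    alpha: float = 0.05,
    n_perm: int = 199,
    transcript_length: int = 60,
) -> PowerResult:
    """Monte-Carlo detection power over a grid of scenarios.

    Per cell and replicate the full pipeline runs end to end; reported are
    the mean fraction of case samples with >= 1 non-flagged het call
    (``p_detect_sample``), the fraction of replicates with at least one such
    sample (``p_detect_any``) and the fraction with permutation p < alpha
    (``p_reject``), each with its binomial standard error.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    cells = [c if isinstance(c, PowerCell) else PowerCell(**dict(c)) for c in grid]
    if not cells:
        raise ValueError("empty power grid")
    for c in cells:
        if not 0.0 <= c.f <= 1.0:
            raise ScenarioError(f"power grid: f must be in [0, 1], got {c.f}")
        if c.m < 1 or c.n < 2 or c.depth < 1:
            raise ScenarioError(f"power grid: invalid cell {c}")
    rng = np.random.default_rng(seed)
    rows = []
    for cell in cells:
        det_sample, det_any, reject = [], [], []
        for _ in range(n_replicates):
            seeds = rng.integers(0, 2**31 - 1, size=3)
            ds, da, rj = _run_pipeline_once(
                cell, cfg, alpha, n_perm, transcript_length, seeds[:2], int(seeds[2])
            )
            det_sample.append(ds)
            det_any.append(da)
            reject.append(rj)
        p_s = float(np.mean(det_sample))
        p_a = float(np.mean(det_any))
        p_r = float(np.mean(reject))
        se = lambda p: float(np.sqrt(p * (1 - p) / n_replicates))
        rows.append(
            (cell.f, cell.m, cell.depth, cell.n, cell.error_rate,
             p_s, se(p_s), p_a, se(p_a), p_r, se(p_r), n_replicates)
        )
    return PowerResult(
        table=pd.DataFrame(rows, columns=POWER_COLUMNS),
        n_replicates=n_replicates,
        seed=seed,
    )
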