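"""Per-position heterozygosity assessment from reference / non-reference counts.

The classifier follows the idealized expectation that reads at an expressed
heterozygous site match the reference base with probability 0.5, while at
homozygous (or hemizygous, monoallelically expressed) sites the match
probability is 1 or 0.  A per-base miscall rate ε — calibrated on a
hemizygous negative-control gene, where all apparent variation is technical
noise — perturbs those ideals:

    p_RR = 1 − ε                     (homozygous reference)
    p_RA = ½(1 − ε) + ½(ε/3)         (heterozygous)
    p_AA = ε/3                       (homozygous alternative)

With k = reference-base count out of depth d (non-reference bases collapsed),
the class log-likelihoods are binomial, posteriors combine configurable
priors in log space, and a call is issued only when the depth gate and the
posterior threshold are both met.  With ε = 0 the class probabilities reduce
exactly to {1, 0.5, 0}.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom

from .pileup_io import PileupColumn, TranscriptPileup

GENOTYPES = ("hom_ref", "het", "hom_alt")
NO_CALL = "no_call"

REPORT_COLUMNS = [
    "sample", "gene", "pos", "depth_used", "ref_fraction",
    "llRR", "llRA", "llAA", "qRR", "qRA", "qAA", "call",
]


@dataclass(frozen=True)
class ModelConfig:
    """Classifier configuration.

    priors: class prior probabilities (hom_ref, het, hom_alt); default uniform.
    min_depth: depth gate below which no call is made (stands in for the
        unknown upstream quality filtering).
    posterior_threshold: minimum posterior for the winning class.
    error_rate: a float to force ε, or "estimate" to require calibration
        from a negative control.
    """

    priors: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    min_depth: int = 20
    posterior_threshold: float = 0.95
    error_rate: Union[float, str] = "estimate"

    def __post_init__(self) -> None:
        p = np.asarray(self.priors, dtype=float)
        if p.shape != (3,) or np.any(p <= 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("priors must be 3 positive numbers summing to 1")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0.5 < self.posterior_threshold <= 1.0:
            raise ValueError("posterior_threshold must be in (0.5, 1]")
        if isinstance(self.error_rate, str) and self.error_rate != "estimate":
            raise ValueError("error_rate must be a float or 'estimate'")


DEFAULT_CONFIG = ModelConfig()


@dataclass(frozen=True)
class GenotypeCall:
    """Classification of one pileup column."""

    gene: str
    pos: int
    call: str
    log_likelihoods: tuple[float, float, float]  # (RR, RA, AA)
    posteriors: tuple[float, float, float]
    ref_fraction: float
    depth_used: int


@dataclass(frozen=True)
class NoiseEstimate:
    """Technical-noise (miscall) rate pooled over a negative-control gene."""

    error_rate: float
    pooled_depth: int
    n_positions_used: int
    n_positions_excluded: int
    excluded_positions: tuple[tuple[str, int], ...] = ()


def class_probabilities(error_rate: float) -> np.ndarray:
    """Reference-match probability per genotype class, (p_RR, p_RA, p_AA)."""
    e = float(error_rate)
    if not 0.0 <= e < 0.75:
        raise ValueError(
            f"error_rate must be in [0, 0.75) for identifiable class ordering, got {e}"
        )
    return np.array([1.0 - e, 0.5 * (1.0 - e) + 0.5 * (e / 3.0), e / 3.0])


def genotype_log_likelihoods(k, d, error_rate: float) -> np.ndarray:
    """Binomial log-likelihoods of (hom_ref, het, hom_alt) for ref counts
    ``k`` out of depths ``d``.  Broadcasts over arrays; returns (..., 3)."""
    k = np.asarray(k, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    if np.any(k > d):
        raise ValueError("reference count exceeds depth")
    if np.any(k < 0) or np.any(d < 0):
        raise ValueError("negative count or depth")
    p = class_probabilities(error_rate)
    return binom.logpmf(k[..., None], d[..., None], p)


def classify_counts(
    k, d, error_rate: float, config: ModelConfig = DEFAULT_CONFIG
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized classification of ref-count/depth pairs.

    Returns (calls, log_likelihoods, posteriors) where calls is an array of
    strings among GENOTYPES + (no_call,).  Posteriors are computed in log
    space (max-subtraction via logsumexp) and normalized to 1.
    """
    k = np.atleast_1d(np.asarray(k, dtype=np.int64))
    d = np.atleast_1d(np.asarray(d, dtype=np.int64))
    k, d = np.broadcast_arrays(k, d)
    ll = genotype_log_likelihoods(k, d, error_rate)
    log_post = ll + np.log(np.asarray(config.priors))
    log_norm = logsumexp(log_post, axis=-1, keepdims=True)
    post = np.exp(log_post - log_norm)
    best = np.argmax(post, axis=-1)
    calls = np.array(GENOTYPES, dtype=object)[best]
    qmax = np.take_along_axis(post, best[..., None], axis=-1)[..., 0]
    no_call = (d < config.min_depth) | (qmax < config.posterior_threshold)
    calls[no_call] = NO_CALL
    return calls, ll, post


def classify_site(
    column: PileupColumn, config: ModelConfig = DEFAULT_CONFIG, error_rate: float = 0.0
) -> GenotypeCall:
    """Classify a single pileup column (see :func:`classify_counts`)."""
    k = column.ref_count
    d = column.depth_used
    calls, ll, post = classify_counts([k], [d], error_rate, config)
    return GenotypeCall(
        gene=column.gene,
        pos=column.pos,
        call=str(calls[0]),
        log_likelihoods=tuple(float(x) for x in ll[0]),
        posteriors=tuple(float(x) for x in post[0]),
        ref_fraction=column.ref_fraction,
        depth_used=d,
    )


def classify_pileup(
    pileup: TranscriptPileup, config: ModelConfig = DEFAULT_CONFIG, error_rate: float = 0.0
) -> pd.DataFrame:
    """Classify every covered position of one sample's transcript pileup.

    Returns the per-site report frame (one row per position)."""
    k = pileup.ref_counts
    d = pileup.depths
    calls, ll, post = classify_counts(k, d, error_rate, config)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(d > 0, k / d, np.nan)
    return pd.DataFrame(
        {
            "sample": pileup.sample,
            "gene": pileup.gene,
            "pos": pileup.positions,
            "depth_used": d,
            "ref_fraction": frac,
            "llRR": ll[:, 0],
            "llRA": ll[:, 1],
            "llAA": ll[:, 2],
            "qRR": post[:, 0],
            "qRA": post[:, 1],
            "qAA": post[:, 2],
            "call": calls,
        }
    )


def write_site_report(report: pd.DataFrame, path) -> None:
    report[REPORT_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.8g")


# --------------------------------------------------------------------------
# noise calibration on a hemizygous negative control
# --------------------------------------------------------------------------

def estimate_error_rate(
    negcontrol: Iterable[TranscriptPileup], outlier_fraction: float = 0.2
) -> NoiseEstimate:
    """Estimate the per-base miscall rate ε from a hemizygous (or otherwise
    variant-free) control gene.

    Counts are pooled across samples per position; positions whose pooled
    non-reference fraction exceeds ``outlier_fraction`` (plausible true
    variants or RNA edits rather than noise) are excluded, and
    ε̂ = pooled non-reference count / pooled depth over the remainder.
    """
    if not 0.0 <= outlier_fraction < 1.0:
        raise ValueError("outlier_fraction must be in [0, 1)")
    frames = []
    for tp in negcontrol:
        frames.append(
            pd.DataFrame(
                {
                    "gene": tp.gene,
                    "pos": pd.Series(tp.positions, dtype=np.int64),
                    "depth": tp.depths,
                    "ref": tp.ref_counts,
                }
            )
        )
    if not frames:
        raise ValueError("no pileup columns supplied for error estimation")
    pooled = pd.concat(frames).groupby(["gene", "pos"], sort=True).sum()
    pooled = pooled[pooled["depth"] > 0]
    if len(pooled) == 0:
        raise ValueError("no usable columns (all zero depth)")
    nonref = pooled["depth"] - pooled["ref"]
    frac = nonref / pooled["depth"]
    keep = frac <= outlier_fraction
    if not keep.any():
        raise ValueError("every position exceeded the outlier fraction; cannot calibrate")
    pooled_depth = int(pooled.loc[keep, "depth"].sum())
    eps = float(nonref[keep].sum() / pooled_depth)
    if eps >= 0.75:
        raise ValueError(f"estimated error rate {eps:.3f} >= 0.75; model degenerate")
    excluded = tuple((str(g), int(p)) for g, p in pooled.index[~keep])
    return NoiseEstimate(
        error_rate=eps,
        pooled_depth=pooled_depth,
        n_positions_used=int(keep.sum()),
        n_positions_excluded=int((~keep).sum()),
        excluded_positions=excluded,
    )


def site_frequency_table(pileups: Iterable[TranscriptPileup]) -> pd.DataFrame:
    """Descriptive per-position variant frequencies (the quantity the
    heterozygosity maps plot): reference fraction, non-reference fraction
    and per-base fractions for every covered position of every sample."""
    frames = []
    for tp in pileups:
        d = tp.depths.astype(float)
        if len(tp) == 0:
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = tp.counts / d[:, None]
            ref_frac = tp.ref_counts / d
        frames.append(
            pd.DataFrame(
                {
                    "sample": tp.sample,
                    "gene": tp.gene,
                    "pos": tp.positions,
                    "ref_base": tp.ref_bases,
                    "depth_used": tp.depths,
                    "ref_fraction": ref_frac,
                    "nonref_fraction": 1.0 - ref_frac,
                    "fA": frac[:, 0],
                    "fC": frac[:, 1],
                    "fG": frac[:, 2],
                    "fT": frac[:, 3],
                }
            )
        )
    if not frames:
        raise ValueError("no pileups supplied")
    return pd.concat(frames, ignore_index=True)
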