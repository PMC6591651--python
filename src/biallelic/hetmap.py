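"""Per-sample heterozygosity maps, recurrent-artifact flagging and
heterozygous-site burdens.

A heterozygosity map is the per-position profile (reference fraction,
genotype call, depth) of one transcript in one sample.  Positions that
behave inconsistently across most samples of *both* cohorts — producing
every genotype class — are treated as recurrent sequencing/alignment
artifacts and excluded from heterozygote counts.  Two operationalizations
are provided:

* ``all_classes`` (default): a position is flagged when, within each cohort
  separately, the non-missing calls across samples contain all three
  genotype classes;
* ``majority``: a position is flagged when, within each cohort, at least
  ``majority_frac`` of the called samples disagree with that cohort's
  modal call.

Both are declared approximations of an inspection-based rule; positions
uncovered in a sample are no_call, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genotype import GENOTYPES, NO_CALL
from .pileup_io import TranscriptPileup

MAP_COLUMNS = ["sample", "gene", "pos", "ref_fraction", "call", "depth_used", "flagged"]


@dataclass
class HeterozygosityMap:
    """One sample x one gene: per-position (ref fraction, call, depth)."""

    sample: str
    gene: str
    table: pd.DataFrame  # columns: pos, ref_fraction, call, depth_used

    def __post_init__(self) -> None:
        required = {"pos", "ref_fraction", "call", "depth_used"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"map table missing columns: {sorted(missing)}")
        pos = self.table["pos"].to_numpy()
        if len(pos) and (np.any(np.diff(pos) <= 0)):
            raise ValueError("map positions must be unique and increasing")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def het_positions(self) -> np.ndarray:
        return self.table.loc[self.table["call"] == "het", "pos"].to_numpy()


@dataclass(frozen=True)
class ArtifactSet:
    """Positions flagged as recurrent artifacts for one gene, with the
    per-cohort call tallies that justified each flag."""

    gene: str
    flagged: frozenset
    rule: str
    evidence: pd.DataFrame = field(compare=False, default_factory=pd.DataFrame)

    def __contains__(self, pos: int) -> bool:
        return pos in self.flagged


EMPTY_ARTIFACTS = ArtifactSet(gene="", flagged=frozenset(), rule="none")


def build_map(pileup: TranscriptPileup, calls: pd.DataFrame) -> HeterozygosityMap:
    """Assemble a heterozygosity map from a sample's pileup and its per-site
    report (from :func:`biallelic.genotype.classify_pileup`)."""
    if len(calls) == 0:
        table = pd.DataFrame(columns=["pos", "ref_fraction", "call", "depth_used"])
        return HeterozygosityMap(sample=pileup.sample, gene=pileup.gene, table=table)
    samples = set(calls["sample"].unique())
    genes = set(calls["gene"].unique())
    if samples != {pileup.sample} or genes != {pileup.gene}:
        raise ValueError(
            f"calls are for {sorted(samples)}/{sorted(genes)}, "
            f"not {pileup.sample}/{pileup.gene}"
        )
    if not np.isin(calls["pos"].to_numpy(), pileup.positions).all():
        raise ValueError("calls contain positions absent from the pileup")
    table = calls[["pos", "ref_fraction", "call", "depth_used"]].sort_values("pos")
    return HeterozygosityMap(sample=pileup.sample, gene=pileup.gene, table=table)


def _cohort_call_tallies(
    maps: Sequence[HeterozygosityMap], sample_sheet: pd.DataFrame
) -> pd.DataFrame:
    cohort_of = dict(zip(sample_sheet["sample"], sample_sheet["cohort"]))
    missing = [m.sample for m in maps if m.sample not in cohort_of]
    if missing:
        raise ValueError(f"samples absent from sample sheet: {missing}")
    frames = []
    for m in maps:
        t = m.table.loc[m.table["call"] != NO_CALL, ["pos", "call"]].copy()
        t["cohort"] = cohort_of[m.sample]
        frames.append(t)
    long = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=["pos", "call", "cohort"])
    tally = (
        long.groupby(["pos", "cohort", "call"]).size().unstack("call", fill_value=0)
        if len(long)
        else pd.DataFrame()
    )
    for g in GENOTYPES:
        if g not in tally.columns:
            tally[g] = 0
    return tally[list(GENOTYPES)] if len(tally) else tally


def flag_artifacts(
    maps: Sequence[HeterozygosityMap],
    sample_sheet: pd.DataFrame,
    rule: str = "all_classes",
    majority_frac: float = 0.5,
) -> ArtifactSet:
    """Flag positions behaving inconsistently in every cohort (see module
    docstring for the two rules).  Requires >= 2 cohorts; maps must all
    describe the same gene."""
    if rule not in ("all_classes", "majority"):
        raise ValueError("rule must be 'all_classes' or 'majority'")
    genes = {m.gene for m in maps}
    if len(genes) > 1:
        raise ValueError(f"maps span multiple genes: {sorted(genes)}")
    gene = genes.pop() if genes else ""
    cohorts = set(sample_sheet.loc[sample_sheet["sample"].isin([m.sample for m in maps]), "cohort"])
    if len(cohorts) < 2:
        raise ValueError(
            "artifact flagging needs >= 2 cohorts; for a single cohort run "
            "without artifact exclusion (no recurrence evidence is available)"
        )
    tally = _cohort_call_tallies(maps, sample_sheet)
    flagged: set[int] = set()
    if len(tally):
        if rule == "all_classes":
            ok = (tally > 0).all(axis=1)  # all three classes present
        else:
            called = tally.sum(axis=1)
            disagree = called - tally.max(axis=1)
            ok = (called > 0) & (disagree / called >= majority_frac)
        per_pos = ok.groupby(level="pos").agg(["sum", "size"])
        n_cohorts = tally.reset_index().groupby("pos")["cohort"].nunique()
        for pos in per_pos.index:
            # inconsistent in EACH cohort, and observed in every cohort
            if n_cohorts.loc[pos] == len(cohorts) and per_pos.loc[pos, "sum"] == per_pos.loc[pos, "size"]:
                flagged.add(int(pos))
    evidence = tally.reset_index() if len(tally) else pd.DataFrame(columns=["pos", "cohort", *GENOTYPES])
    evidence = evidence[evidence["pos"].isin(flagged)].reset_index(drop=True) if len(evidence) else evidence
    return ArtifactSet(gene=gene, flagged=frozenset(flagged), rule=rule, evidence=evidence)


def count_het_sites(het_map: HeterozygosityMap, artifacts: ArtifactSet = EMPTY_ARTIFACTS) -> int:
    """Number of het-called positions excluding flagged artifact positions."""
    het = het_map.het_positions()
    return int(sum(1 for p in het if int(p) not in artifacts.flagged))


def het_burdens(
    maps: Sequence[HeterozygosityMap], artifacts: ArtifactSet = EMPTY_ARTIFACTS
) -> pd.DataFrame:
    """Per-sample heterozygous-site burden (artifact-excluded)."""
    rows = [(m.sample, m.gene, count_het_sites(m, artifacts)) for m in maps]
    return pd.DataFrame(rows, columns=["sample", "gene", "het_sites"])


def maps_to_frame(
    maps: Iterable[HeterozygosityMap], artifacts: ArtifactSet = EMPTY_ARTIFACTS
) -> pd.DataFrame:
    frames = []
    for m in maps:
        t = m.table.copy()
        t.insert(0, "gene", m.gene)
        t.insert(0, "sample", m.sample)
        t["flagged"] = t["pos"].isin(artifacts.flagged)
        frames.append(t[MAP_COLUMNS])
    if not frames:
        return pd.DataFrame(columns=MAP_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def write_map_tsv(maps, artifacts, path) -> None:
    maps_to_frame(maps, artifacts).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_artifact_tsv(artifacts: ArtifactSet, path) -> None:
    ev = artifacts.evidence.copy()
    ev.insert(0, "gene", artifacts.gene)
    ev.insert(1, "rule", artifacts.rule)
    ev.to_csv(path, sep="\t", index=False)
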