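"""Synthetic allelic-pileup generator.

Emulates uniquely-mapped RNA-seq read pileups over a single transcript for
which two gene copies (e.g. an X-linked and a normally silenced Y-linked
copy) may both contribute transcripts.  The second copy differs from the
reference at a configurable set of divergent sites.  The generative model:

* each read originates from the second allele with probability ``f``
  (``y_fraction``, the bulk reactivation fraction) and from the
  reference-bearing allele otherwise;
* each sequenced base miscalls with probability ``ε`` (``error_rate``),
  substituting uniformly among the three other bases (ε/3 each);
* per-position depth follows either a fixed-depth law (unit tests) or a
  total-mapped-read law: the per-transcript read total is drawn uniformly
  from a configurable range (default 653–4033) and reads of fixed length
  are placed uniformly along the transcript.

The per-position reference-read probability is therefore

    p_ref = (1 − f)(1 − ε) + f·ε/3      at a divergent site,
    p_ref = 1 − ε                        elsewhere,

so f = 0 reproduces monoallelic (hom-ref-looking) expression, f = 0.5
balanced biallelic expression, and f = 1 pure second-allele expression.
Female samples at a pseudoautosomal gene are genuinely heterozygous: both
alleles contribute equally regardless of ``f`` (handled via ``sexes``).

Identical scenario + seed yields bit-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .pileup_io import (
    BASES,
    BASE_INDEX,
    TranscriptPileup,
    write_counts_tsv,
    write_mpileup,
    write_sample_sheet,
)

TRUTH_COLUMNS = ["sample", "gene", "pos", "true_class", "p_ref"]

DEFAULT_READ_RANGE = (653, 4033)  # per-transcript total mapped reads


class ScenarioError(ValueError):
    """Raised when a simulation scenario fails validation; names the field."""


@dataclass(frozen=True)
class SimScenario:
    """Generative parameters for one cohort of single-transcript pileups."""

    gene: str = "SPRY3"
    transcript_length: int = 5000
    divergent_sites: tuple[int, ...] = ()
    alt_bases: Optional[Mapping[int, str]] = None
    y_fraction: float = 0.0
    error_rate: float = 0.0
    depth: Optional[int] = None  # fixed per-position depth; None -> read law
    total_read_range: tuple[int, int] = DEFAULT_READ_RANGE
    read_length: int = 100
    n_samples: int = 1
    sexes: Optional[tuple[str, ...]] = None  # default: all male
    cohort: str = "control"
    sample_prefix: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "divergent_sites", tuple(int(p) for p in self.divergent_sites))
        if self.sexes is not None:
            object.__setattr__(self, "sexes", tuple(self.sexes))
        self.validate()

    def validate(self) -> None:
        L = self.transcript_length
        if L < 1:
            raise ScenarioError(f"transcript_length must be >= 1, got {L}")
        if not 0.0 <= self.y_fraction <= 1.0:
            raise ScenarioError(f"y_fraction must be in [0, 1], got {self.y_fraction}")
        if not 0.0 <= self.error_rate < 0.75:
            raise ScenarioError(f"error_rate must be in [0, 0.75), got {self.error_rate}")
        sites = self.divergent_sites
        if len(set(sites)) != len(sites):
            raise ScenarioError("divergent_sites contains duplicates")
        for p in sites:
            if not 1 <= p <= L:
                raise ScenarioError(f"divergent_sites: position {p} outside [1, {L}]")
        ref = self.reference_sequence()
        for p, b in self.resolved_alt_bases().items():
            if p not in sites:
                raise ScenarioError(f"alt_bases: position {p} is not a divergent site")
            if b not in BASE_INDEX:
                raise ScenarioError(f"alt_bases: invalid base {b!r} at position {p}")
            if b == ref[p - 1]:
                raise ScenarioError(f"alt_bases: alt equals reference base at position {p}")
        if self.n_samples < 1:
            raise ScenarioError(f"n_samples must be >= 1, got {self.n_samples}")
        if self.sexes is not None:
            if len(self.sexes) != self.n_samples:
                raise ScenarioError("sexes must have one entry per sample")
            bad = set(self.sexes) - {"male", "female"}
            if bad:
                raise ScenarioError(f"sexes must be male/female, got {sorted(bad)}")
        if self.depth is not None:
            if self.depth < 1:
                raise ScenarioError(f"depth must be >= 1, got {self.depth}")
        else:
            lo, hi = self.total_read_range
            if not (1 <= lo <= hi):
                raise ScenarioError(f"total_read_range must satisfy 1 <= lo <= hi, got {self.total_read_range}")
            if self.read_length < 1:
                raise ScenarioError(f"read_length must be >= 1, got {self.read_length}")

    # -- transcript identity ------------------------------------------------
    def reference_sequence(self) -> str:
        """Deterministic reference sequence shared by every scenario with the
        same gene name and length (independent of the sampling seed)."""
        key = f"{self.gene}:{self.transcript_length}".encode()
        rng = np.random.default_rng(zlib.crc32(key))
        return "".join(rng.choice(list(BASES), size=self.transcript_length))

    def resolved_alt_bases(self) -> dict[int, str]:
        """Alt base per divergent site; default is the next base cyclically."""
        ref = self.reference_sequence()
        out: dict[int, str] = {}
        supplied = dict(self.alt_bases) if self.alt_bases else {}
        for p in self.divergent_sites:
            if p in supplied:
                out[p] = supplied[p]
            else:
                out[p] = BASES[(BASE_INDEX[ref[p - 1]] + 1) % 4]
        return out

    def sample_names(self) -> list[str]:
        prefix = self.sample_prefix or self.cohort
        width = max(2, len(str(self.n_samples)))
        return [f"{prefix}_{i + 1:0{width}d}" for i in range(self.n_samples)]

    def sample_sexes(self) -> tuple[str, ...]:
        return self.sexes if self.sexes is not None else ("male",) * self.n_samples


def _error_kernel(error_rate: float) -> np.ndarray:
    """4x4 matrix: row = true base, column = observed base."""
    e = error_rate
    k = np.full((4, 4), e / 3.0)
    np.fill_diagonal(k, 1.0 - e)
    return k


def _base_probabilities(scenario: SimScenario, f: float) -> np.ndarray:
    """(L, 4) per-position observed-base probabilities for allele mixture f."""
    ref = scenario.reference_sequence()
    kernel = _error_kernel(scenario.error_rate)
    ref_idx = np.array([BASE_INDEX[b] for b in ref], dtype=np.intp)
    probs = kernel[ref_idx]  # background: reads from the reference sequence
    if f > 0.0 and scenario.divergent_sites:
        alts = scenario.resolved_alt_bases()
        for p in scenario.divergent_sites:
            alt_idx = BASE_INDEX[alts[p]]
            probs[p - 1] = (1.0 - f) * kernel[ref_idx[p - 1]] + f * kernel[alt_idx]
    return probs


def _depths(scenario: SimScenario, rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    L = scenario.transcript_length
    if scenario.depth is not None:
        return np.full(L, scenario.depth, dtype=np.int64), {"depth_law": "fixed", "depth": scenario.depth}
    lo, hi = scenario.total_read_range
    n_reads = int(rng.integers(lo, hi + 1))
    R = min(scenario.read_length, L)
    starts = rng.integers(0, L - R + 1, size=n_reads) if L > R else np.zeros(n_reads, dtype=np.int64)
    cover = np.zeros(L + 1, dtype=np.int64)
    np.add.at(cover, starts, 1)
    np.add.at(cover, starts + R, -1)
    depth = np.cumsum(cover[:L])
    return depth, {"depth_law": "total_uniform", "n_reads": n_reads, "read_length": R}


def _truth_class(f: float) -> str:
    if f == 0.0:
        return "hom_ref"
    if f == 1.0:
        return "hom_alt"
    return "het"


def simulate_pileup(scenario: SimScenario) -> tuple[list[TranscriptPileup], pd.DataFrame]:
    """Simulate per-sample transcript pileups plus the generating truth table.

    Returns the pileups (zero-depth positions dropped) and a truth table with
    one row per sample x position recording the true genotype class and the
    generating reference-read probability ``p_ref``.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    L = scenario.transcript_length
    e = scenario.error_rate
    ref = scenario.reference_sequence()
    ref_arr = np.array(list(ref), dtype="U1")
    div_mask = np.zeros(L, dtype=bool)
    if scenario.divergent_sites:
        div_mask[np.array(scenario.divergent_sites) - 1] = True

    names = scenario.sample_names()
    sexes = scenario.sample_sexes()
    positions_all = np.arange(1, L + 1, dtype=np.int64)

    prob_cache: dict[float, np.ndarray] = {}
    truth_cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    pileups: list[TranscriptPileup] = []
    f_effs: list[float] = []
    for name, sex in zip(names, sexes):
        # females at a pseudoautosomal gene are true heterozygotes
        f_eff = 0.5 if sex == "female" and scenario.divergent_sites else scenario.y_fraction
        if f_eff not in prob_cache:
            prob_cache[f_eff] = _base_probabilities(scenario, f_eff)
            p_ref = np.full(L, 1.0 - e)
            p_ref[div_mask] = (1.0 - f_eff) * (1.0 - e) + f_eff * (e / 3.0)
            truth_cache[f_eff] = (np.where(div_mask, _truth_class(f_eff), "hom_ref"), p_ref)
        probs = prob_cache[f_eff]
        depth, meta = _depths(scenario, rng)
        counts = rng.multinomial(depth, probs)
        covered = depth > 0
        pileups.append(
            TranscriptPileup(
                sample=name,
                gene=scenario.gene,
                positions=positions_all[covered],
                ref_bases=ref_arr[covered],
                counts=counts[covered],
                meta={**meta, "sex": sex, "cohort": scenario.cohort, "seed": scenario.seed},
            )
        )
        f_effs.append(f_eff)
    truth = pd.DataFrame(
        {
            "sample": np.repeat(np.array(names, dtype=object), L),
            "gene": scenario.gene,
            "pos": np.tile(positions_all, len(names)),
            "true_class": np.concatenate([truth_cache[f][0] for f in f_effs]),
            "p_ref": np.concatenate([truth_cache[f][1] for f in f_effs]),
        }
    )
    return pileups, truth


def simulate_cohort(
    scenario_case: SimScenario, scenario_control: SimScenario
) -> tuple[list[TranscriptPileup], pd.DataFrame, pd.DataFrame]:
    """Simulate a labeled two-cohort dataset over a shared transcript.

    Both scenarios must agree on the transcript (gene, length) and on the
    divergent sites / alt bases, and must use distinct cohort labels.
    Returns (pileups, sample sheet, truth table).
    """
    for fld in ("gene", "transcript_length", "divergent_sites"):
        if getattr(scenario_case, fld) != getattr(scenario_control, fld):
            raise ScenarioError(f"scenarios disagree on {fld}")
    if scenario_case.resolved_alt_bases() != scenario_control.resolved_alt_bases():
        raise ScenarioError("scenarios disagree on alt_bases")
    if scenario_case.cohort == scenario_control.cohort:
        raise ScenarioError("cohort labels must differ between scenarios")
    pileups: list[TranscriptPileup] = []
    truths = []
    sheet_rows = []
    for scn in (scenario_case, scenario_control):
        p, t = simulate_pileup(scn)
        pileups.extend(p)
        truths.append(t)
        for name, sex in zip(scn.sample_names(), scn.sample_sexes()):
            sheet_rows.append((name, scn.cohort, sex))
    sheet = pd.DataFrame(sheet_rows, columns=["sample", "cohort", "sex"])
    if sheet["sample"].duplicated().any():
        raise ScenarioError("sample names collide between cohorts; set distinct sample_prefix/cohort")
    return pileups, sheet, pd.concat(truths, ignore_index=True)


# --------------------------------------------------------------------------
# fixture emission
# --------------------------------------------------------------------------

def scenario_to_toml(scenario: SimScenario) -> str:
    lines = ["[scenario]"]
    alt = scenario.resolved_alt_bases()
    items: list[tuple[str, object]] = [
        ("gene", scenario.gene),
        ("transcript_length", scenario.transcript_length),
        ("divergent_sites", list(scenario.divergent_sites)),
        ("alt_bases", alt),
        ("y_fraction", scenario.y_fraction),
        ("error_rate", scenario.error_rate),
        ("depth", scenario.depth),
        ("total_read_range", list(scenario.total_read_range)),
        ("read_length", scenario.read_length),
        ("n_samples", scenario.n_samples),
        ("sexes", list(scenario.sample_sexes())),
        ("cohort", scenario.cohort),
        ("seed", scenario.seed),
    ]
    for key, val in items:
        if val is None:
            continue
        if isinstance(val, str):
            lines.append(f'{key} = "{val}"')
        elif isinstance(val, bool):
            lines.append(f"{key} = {str(val).lower()}")
        elif isinstance(val, dict):
            inner = ", ".join(f'"{k}" = "{v}"' for k, v in sorted(val.items()))
            lines.append(f"{key} = {{{inner}}}")
        elif isinstance(val, list):
            inner = ", ".join(f'"{v}"' if isinstance(v, str) else str(v) for v in val)
            lines.append(f"{key} = [{inner}]")
        else:
            lines.append(f"{key} = {val}")
    return "\n".join(lines) + "\n"


def scenario_from_toml(stream) -> SimScenario:
    import tomllib

    if hasattr(stream, "read"):
        data = tomllib.loads(stream.read())
    else:
        with open(stream, "rb") as fh:
            data = tomllib.load(fh)
    s = data["scenario"]
    kwargs = dict(
        gene=s.get("gene", "SPRY3"),
        transcript_length=s["transcript_length"],
        divergent_sites=tuple(s.get("divergent_sites", ())),
        alt_bases={int(k): v for k, v in s.get("alt_bases", {}).items()} or None,
        y_fraction=s.get("y_fraction", 0.0),
        error_rate=s.get("error_rate", 0.0),
        depth=s.get("depth"),
        read_length=s.get("read_length", 100),
        n_samples=s.get("n_samples", 1),
        cohort=s.get("cohort", "control"),
        seed=s.get("seed", 0),
    )
    if "total_read_range" in s:
        kwargs["total_read_range"] = tuple(s["total_read_range"])
    if "sexes" in s:
        kwargs["sexes"] = tuple(s["sexes"])
    return SimScenario(**kwargs)


def write_fixture(
    pileups: Sequence[TranscriptPileup],
    directory,
    sample_sheet: Optional[pd.DataFrame] = None,
    truth: Optional[pd.DataFrame] = None,
    scenario: Optional[SimScenario] = None,
    truth_sites: str = "divergent",
) -> dict[str, Path]:
    """Write pileups (mpileup per sample/gene + combined counts TSV) and any
    accompanying sample sheet / truth table / scenario config to ``directory``.

    ``truth_sites='divergent'`` restricts the written truth rows to positions
    whose true class is not hom_ref background (keeps files small);
    ``'all'`` writes every simulated position.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for tp in pileups:
        p = directory / f"{tp.sample}.{tp.gene}.mpileup"
        write_mpileup(tp, p)
        paths[f"mpileup:{tp.sample}:{tp.gene}"] = p
    counts_path = directory / "counts.tsv"
    write_counts_tsv(pileups, counts_path)
    paths["counts"] = counts_path
    if sample_sheet is not None:
        p = directory / "samples.tsv"
        write_sample_sheet(sample_sheet, p)
        paths["samples"] = p
    if truth is not None:
        if truth_sites == "divergent":
            truth = truth[truth["true_class"] != "hom_ref"]
        elif truth_sites != "all":
            raise ValueError("truth_sites must be 'divergent' or 'all'")
        p = directory / "truth.tsv"
        truth.to_csv(p, sep="\t", index=False, float_format="%.10g")
        paths["truth"] = p
    if scenario is not None:
        p = directory / "scenario.toml"
        p.write_text(scenario_to_toml(scenario))
        paths["scenario"] = p
    return paths
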