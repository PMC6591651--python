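"""Reading and writing per-position base counts.

Two plain-text interchange formats are supported:

* samtools ``mpileup`` 6-column text (chrom, 1-based pos, ref base, depth,
  read-bases string, base qualities), the format the upstream alignment /
  pileup step emits.  The read-bases string is decoded per the mpileup
  standard; strands are merged and case is folded.
* a counts TSV with header ``sample  gene  pos  ref_base  depth  nA  nC  nG  nT``,
  a direct tabulation of per-position A/C/G/T counts.

Coordinates are 1-based inclusive throughout.  Inputs are assumed to contain
uniquely mapped reads only — multi-mapper removal happens upstream of the
pileup and is not re-applied here.  No base-quality filtering is performed;
a minimum-depth gate in the genotype model stands in for quality control.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence, TextIO, Union

import numpy as np
import pandas as pd

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

COUNTS_COLUMNS = ["sample", "gene", "pos", "ref_base", "depth", "nA", "nC", "nG", "nT"]
SHEET_COLUMNS = ["sample", "cohort", "sex"]

PathOrStream = Union[str, Path, TextIO]


class PileupFormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass(frozen=True)
class PileupColumn:
    """All read bases covering one transcript coordinate in one sample,
    summarized as A/C/G/T counts."""

    gene: str
    pos: int
    ref_base: str
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref_base not in BASE_INDEX:
            raise ValueError(f"ref_base must be one of {BASES}, got {self.ref_base!r}")
        for b in BASES:
            if self.counts.get(b, 0) < 0:
                raise ValueError(f"negative count for base {b} at pos {self.pos}")

    @property
    def depth_used(self) -> int:
        return sum(int(self.counts.get(b, 0)) for b in BASES)

    @property
    def ref_count(self) -> int:
        return int(self.counts.get(self.ref_base, 0))

    @property
    def ref_fraction(self) -> float:
        d = self.depth_used
        return self.ref_count / d if d > 0 else float("nan")


@dataclass
class TranscriptPileup:
    """Ordered per-position base counts for one transcript in one sample.

    ``counts`` is an (n, 4) integer array with columns A, C, G, T; positions
    are strictly increasing and carry one entry per covered position.
    """

    sample: str
    gene: str
    positions: np.ndarray
    ref_bases: np.ndarray
    counts: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref_bases = np.asarray(self.ref_bases, dtype="U1")
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = self.positions.shape[0]
        if self.ref_bases.shape != (n,) or self.counts.shape != (n, 4):
            raise ValueError("positions, ref_bases and counts have inconsistent shapes")
        if n and np.any(np.diff(self.positions) <= 0):
            raise ValueError(f"positions must be strictly increasing ({self.sample}/{self.gene})")
        if n and self.positions[0] < 1:
            raise ValueError("positions are 1-based; found position < 1")
        if np.any(self.counts < 0):
            raise ValueError("negative base counts")
        bad = ~np.isin(self.ref_bases, list(BASES)) if n else np.array([], bool)
        if np.any(bad):
            raise ValueError(f"invalid reference base(s): {set(self.ref_bases[bad])}")

    def __len__(self) -> int:
        return int(self.positions.shape[0])

    @property
    def depths(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def ref_index(self) -> np.ndarray:
        return np.array([BASE_INDEX[b] for b in self.ref_bases], dtype=np.intp)

    @property
    def ref_counts(self) -> np.ndarray:
        if len(self) == 0:
            return np.zeros(0, dtype=np.int64)
        return self.counts[np.arange(len(self)), self.ref_index]

    @property
    def ref_fractions(self) -> np.ndarray:
        d = self.depths
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(d > 0, self.ref_counts / d, np.nan)

    def total_depth(self) -> int:
        return int(self.counts.sum())

    def columns(self) -> Iterator[PileupColumn]:
        for i in range(len(self)):
            yield PileupColumn(
                gene=self.gene,
                pos=int(self.positions[i]),
                ref_base=str(self.ref_bases[i]),
                counts={b: int(self.counts[i, j]) for j, b in enumerate(BASES)},
            )


# --------------------------------------------------------------------------
# mpileup text
# --------------------------------------------------------------------------

_SKIPPED = frozenset("*Nn><")


def decode_read_bases(bases: str, ref_base: str) -> tuple[dict[str, int], int]:
    """Decode one mpileup read-bases string into per-base counts.

    Returns ``(counts, n_skipped)`` where ``n_skipped`` is the number of
    read symbols excluded from the counts ('*' deletions, 'N', reference
    skips).  '.'/',' count toward the reference base; 'ACGTacgt' toward the
    named base; '^' consumes the following mapping-quality character; '$'
    is consumed; '+n.../-n...' indel runs are consumed and ignored.
    """
    counts = {b: 0 for b in BASES}
    skipped = 0
    i, n = 0, len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # '^' + mapping quality char
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupFormatError(f"indel marker {c!r} without length")
            i = j + int(bases[i + 1 : j])
            continue
        if c in ".,":
            counts[ref_base] += 1
        elif c.upper() in BASE_INDEX:
            counts[c.upper()] += 1
        elif c in _SKIPPED:
            skipped += 1
        else:
            raise PileupFormatError(f"unrecognized read-base symbol {c!r}")
        i += 1
    return counts, skipped


def parse_pileup(stream: PathOrStream, sample: str = "sample") -> list[TranscriptPileup]:
    """Parse samtools mpileup text into per-gene :class:`TranscriptPileup`.

    One mpileup file describes a single sample; the chrom field names the
    transcript.  Zero-depth columns are dropped (not covered).  If the
    stated depth field disagrees with the decoded base counts by more than
    the skipped symbols, a warning is issued and the decoded counts win.
    """
    close = False
    if isinstance(stream, (str, Path)):
        handle: TextIO = open(stream, "rt")
        close = True
    else:
        handle = stream
    per_gene: dict[str, list[tuple[int, str, dict[str, int]]]] = {}
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                # samtools emits "chrom pos ref 0 * *" or shorter for empty columns
                if len(fields) >= 4 and fields[3] == "0":
                    continue
                raise PileupFormatError(f"line {lineno}: expected 6 tab-separated fields, got {len(fields)}")
            chrom, pos_s, ref, depth_s, bases = fields[0], fields[1], fields[2].upper(), fields[3], fields[4]
            try:
                pos = int(pos_s)
                stated_depth = int(depth_s)
            except ValueError as exc:
                raise PileupFormatError(f"line {lineno}: non-integer pos/depth field") from exc
            if stated_depth == 0:
                continue  # uncovered column; bases field is a placeholder
            if ref not in BASE_INDEX:
                raise PileupFormatError(f"line {lineno}: reference base {ref!r} not in {BASES}")
            try:
                counts, skipped = decode_read_bases(bases, ref)
            except PileupFormatError as exc:
                raise PileupFormatError(f"line {lineno}: {exc}") from exc
            decoded = sum(counts.values())
            if decoded + skipped != stated_depth:
                warnings.warn(
                    f"line {lineno}: stated depth {stated_depth} != decoded "
                    f"{decoded} (+{skipped} skipped); using decoded counts",
                    stacklevel=2,
                )
            if decoded == 0:
                continue
            per_gene.setdefault(chrom, []).append((pos, ref, counts))
    finally:
        if close:
            handle.close()

    out = []
    for gene, rows in per_gene.items():
        positions = np.array([r[0] for r in rows], dtype=np.int64)
        refs = np.array([r[1] for r in rows], dtype="U1")
        counts = np.array([[r[2][b] for b in BASES] for r in rows], dtype=np.int64)
        out.append(TranscriptPileup(sample=sample, gene=gene, positions=positions, ref_bases=refs, counts=counts))
    return out


def write_mpileup(pileup: TranscriptPileup, stream: PathOrStream) -> None:
    """Write one sample/transcript as 6-column mpileup text.

    Reference matches are emitted as '.', alternatives as upper-case letters,
    and qualities as a constant high-quality character ('I')."""
    close = False
    if isinstance(stream, (str, Path)):
        handle: TextIO = open(stream, "wt")
        close = True
    else:
        handle = stream
    try:
        for i in range(len(pileup)):
            pos = int(pileup.positions[i])
            ref = str(pileup.ref_bases[i])
            row = pileup.counts[i]
            parts = ["." * int(row[BASE_INDEX[ref]])]
            for b in BASES:
                if b != ref:
                    parts.append(b * int(row[BASE_INDEX[b]]))
            bases = "".join(parts)
            depth = int(row.sum())
            handle.write(f"{pileup.gene}\t{pos}\t{ref}\t{depth}\t{bases}\t{'I' * depth}\n")
    finally:
        if close:
            handle.close()


# --------------------------------------------------------------------------
# counts TSV
# --------------------------------------------------------------------------

def to_counts_frame(pileups: Iterable[TranscriptPileup]) -> pd.DataFrame:
    rows = []
    for tp in pileups:
        for i in range(len(tp)):
            rows.append(
                (
                    tp.sample,
                    tp.gene,
                    int(tp.positions[i]),
                    str(tp.ref_bases[i]),
                    int(tp.counts[i].sum()),
                    *(int(tp.counts[i, j]) for j in range(4)),
                )
            )
    df = pd.DataFrame(rows, columns=COUNTS_COLUMNS)
    return df.sort_values(["sample", "gene", "pos"], kind="stable").reset_index(drop=True)


def write_counts_tsv(pileups: Iterable[TranscriptPileup], stream: PathOrStream) -> None:
    to_counts_frame(pileups).to_csv(stream, sep="\t", index=False)


def parse_counts_tsv(stream: PathOrStream) -> list[TranscriptPileup]:
    """Parse a counts TSV into :class:`TranscriptPileup` objects.

    Validates the header, non-negative counts, depth = nA+nC+nG+nT per row,
    and uniqueness of (sample, gene, pos).
    """
    df = pd.read_csv(stream, sep="\t", dtype={"sample": str, "gene": str, "ref_base": str})
    missing = [c for c in COUNTS_COLUMNS if c not in df.columns]
    if missing:
        raise PileupFormatError(f"counts TSV missing column(s): {', '.join(missing)}")
    if len(df) == 0:
        return []
    for col in ("pos", "depth", "nA", "nC", "nG", "nT"):
        if not pd.api.types.is_integer_dtype(df[col]):
            raise PileupFormatError(f"column {col!r} must be integer")
        if (df[col] < 0).any():
            bad = df.loc[df[col] < 0].iloc[0]
            raise PileupFormatError(
                f"negative {col} at row ({bad['sample']}, {bad['gene']}, {bad['pos']})"
            )
    sums = df[["nA", "nC", "nG", "nT"]].sum(axis=1)
    mismatch = sums != df["depth"]
    if mismatch.any():
        bad = df.loc[mismatch].iloc[0]
        raise PileupFormatError(
            f"depth != nA+nC+nG+nT at row ({bad['sample']}, {bad['gene']}, {bad['pos']})"
        )
    dup = df.duplicated(subset=["sample", "gene", "pos"])
    if dup.any():
        bad = df.loc[dup].iloc[0]
        raise PileupFormatError(
            f"duplicate row for ({bad['sample']}, {bad['gene']}, {bad['pos']})"
        )
    out = []
    for (sample, gene), grp in df.groupby(["sample", "gene"], sort=True):
        grp = grp.sort_values("pos")
        out.append(
            TranscriptPileup(
                sample=str(sample),
                gene=str(gene),
                positions=grp["pos"].to_numpy(np.int64),
                ref_bases=grp["ref_base"].to_numpy("U1"),
                counts=grp[["nA", "nC", "nG", "nT"]].to_numpy(np.int64),
            )
        )
    return out


# --------------------------------------------------------------------------
# sample sheet
# --------------------------------------------------------------------------

def read_sample_sheet(stream: PathOrStream) -> pd.DataFrame:
    sheet = pd.read_csv(stream, sep="\t", dtype=str)
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise PileupFormatError(f"sample sheet missing column(s): {', '.join(missing)}")
    bad_sex = set(sheet["sex"]) - {"male", "female"}
    if bad_sex:
        raise PileupFormatError(f"sample sheet sex must be male/female, got {sorted(bad_sex)}")
    if sheet["sample"].duplicated().any():
        raise PileupFormatError("duplicate sample ids in sample sheet")
    return sheet[SHEET_COLUMNS].reset_index(drop=True)


def write_sample_sheet(sheet: pd.DataFrame, stream: PathOrStream) -> None:
    sheet[SHEET_COLUMNS].to_csv(stream, sep="\t", index=False)
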