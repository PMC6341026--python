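"""Readers/writers for the genomic text formats the pipeline touches.

Peak files (BED3+ and ENCODE narrowPeak) and BED4 chromatin-state
segmentations are normalised to small internal types with 0-based
half-open coordinates.  ``track``/``browser``/``#`` header lines are
tolerated everywhere.  Strand is deliberately ignored: downstream the
only thing that matters is the peak-center position.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import FormatError

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "StateSegmentation",
    "chrom_sort_key",
    "read_peaks",
    "write_peaks",
    "read_segmentation",
    "write_segmentation",
    "peak_centers",
]

_HEADER_RE = re.compile(r"^(track|browser|#)")


def chrom_sort_key(chrom: str):
    """Natural-sort key so that chr1 < chr2 < ... < chr10 < ... < chrX < chrY."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.isdigit():
        return (0, int(name), "")
    return (1, 0, name)


@dataclass(frozen=True, order=False)
class GenomicInterval:
    """A 0-based half-open genomic interval with an optional label.

    Parameters
    ----------
    chrom : str
        Chromosome name; must be non-empty.
    start, end : int
        0-based start (inclusive) and end (exclusive); ``end > start >= 0``.
    label : str
        Free text: a peak name or a chromatin-state label such as ``"D5"``.
    """

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self):
        return (*chrom_sort_key(self.chrom), self.start, self.end)


@dataclass(frozen=True)
class PeakSet:
    """The peak calls of one protein, sorted by (chrom, start).

    Intervals are sorted on construction; zero-length peaks are rejected
    by :class:`GenomicInterval` itself.
    """

    protein: str
    peaks: tuple[GenomicInterval, ...]
    source: str = ""

    def __post_init__(self):
        object.__setattr__(
            self, "peaks", tuple(sorted(self.peaks, key=GenomicInterval.sort_key))
        )

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def chromosomes(self) -> set[str]:
        return {p.chrom for p in self.peaks}


@dataclass(frozen=True)
class StateSegmentation:
    """A labelled, per-chromosome non-overlapping genome segmentation."""

    windows: tuple[GenomicInterval, ...]
    states: frozenset[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        object.__setattr__(
            self, "windows", tuple(sorted(self.windows, key=GenomicInterval.sort_key))
        )
        labels = frozenset(w.label for w in self.windows)
        if self.states is None:
            object.__setattr__(self, "states", labels)
        elif not labels <= self.states:
            raise ValueError(f"window labels {labels - self.states} not in states")
        _check_no_overlap(self.windows)

    def windows_of(self, state: str) -> tuple[GenomicInterval, ...]:
        return tuple(w for w in self.windows if w.label == state)

    def total_bp(self, state: str | None = None) -> int:
        ws = self.windows if state is None else self.windows_of(state)
        return sum(w.length for w in ws)


def _check_no_overlap(windows: Sequence[GenomicInterval]) -> None:
    prev: GenomicInterval | None = None
    for w in windows:  # windows already sorted by (chrom, start)
        if prev is not None and prev.chrom == w.chrom and w.start < prev.end:
            raise ValueError(
                "overlapping segmentation windows: "
                f"{prev.chrom}:{prev.start}-{prev.end} ({prev.label}) and "
                f"{w.chrom}:{w.start}-{w.end} ({w.label})"
            )
        prev = w


def _data_lines(path: Path):
    """Yield (1-based line number, stripped line), skipping headers/blank lines."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or _HEADER_RE.match(line):
                continue
            yield lineno, line


def _parse_interval(path: Path, lineno: int, fields: list[str]) -> GenomicInterval:
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        raise FormatError(
            f"{path}, line {lineno}: non-integer coordinates {fields[1]!r}/{fields[2]!r}"
        ) from None
    label = fields[3] if len(fields) > 3 else ""
    try:
        return GenomicInterval(fields[0], start, end, label)
    except ValueError as exc:
        raise FormatError(f"{path}, line {lineno}: {exc}") from None


def read_peaks(path, dialect: str = "bed", protein: str | None = None) -> PeakSet:
    """Read one protein's peak file.

    Parameters
    ----------
    path : path-like
        BED3+ or narrowPeak file.
    dialect : {"bed", "narrowPeak"}
        ``"bed"`` requires >= 3 tab-separated columns; ``"narrowPeak"``
        requires exactly 10.  The narrowPeak summit column is parsed but
        ignored: the event convention is the peak center.
    protein : str, optional
        Protein name; defaults to the file stem.

    Raises
    ------
    FormatError
        On a malformed line; the message names the 1-based line number.
    """
    path = Path(path)
    if dialect not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown dialect {dialect!r}")
    min_cols = 3 if dialect == "bed" else 10
    peaks = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) == 1:  # tolerate space-separated toy files
            fields = line.split()
        if len(fields) < min_cols:
            raise FormatError(
                f"{path}, line {lineno}: expected >= {min_cols} columns "
                f"for dialect {dialect!r}, got {len(fields)}"
            )
        peaks.append(_parse_interval(path, lineno, fields))
    return PeakSet(
        protein=protein if protein is not None else path.stem,
        peaks=tuple(peaks),
        source=f"{path}:{dialect}",
    )


def write_peaks(peakset: PeakSet, path) -> None:
    """Write a PeakSet as BED (3 or 4 columns depending on labels)."""
    with open(path, "w") as fh:
        for p in peakset.peaks:
            cols = [p.chrom, str(p.start), str(p.end)]
            if p.label:
                cols.append(p.label)
            fh.write("\t".join(cols) + "\n")


def read_segmentation(path) -> StateSegmentation:
    """Read a BED4 chromatin-state segmentation (column 4 = state label).

    Raises
    ------
    FormatError
        If the label column is missing, coordinates are malformed, or two
        windows on the same chromosome overlap (the message names the
        first offending pair).
    """
    path = Path(path)
    windows = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) == 1:
            fields = line.split()
        if len(fields) < 4:
            raise FormatError(
                f"{path}, line {lineno}: segmentation requires a 4th "
                f"(state label) column, got {len(fields)} columns"
            )
        windows.append(_parse_interval(path, lineno, fields))
    try:
        return StateSegmentation(windows=tuple(windows))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_segmentation(seg: StateSegmentation, path) -> None:
    with open(path, "w") as fh:
        for w in seg.windows:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.label}\n")


def peak_centers(peakset: PeakSet) -> list[tuple[str, int]]:
    """Return one (chrom, position) event per peak: floor((start+end)/2)."""
    return [(p.chrom, (p.start + p.end) // 2) for p in peakset.peaks]
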