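"""Map per-state genome windows onto a common interval [0, L].

All windows of one domain-level state are concatenated genome-wide
(chromosomes in natural order) and rescaled so the concatenated axis has
length ``L`` (default 50).  Peak centers falling inside the state's
windows become point events on [0, L]; centers in gaps are dropped.
"""
from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io_genomics import GenomicInterval, StateSegmentation, chrom_sort_key

__all__ = [
    "StateCoordinateMap",
    "PointPattern",
    "build_coordinate_map",
    "project_peaks",
    "write_patterns",
    "read_patterns",
]

DEFAULT_L = 50.0


@dataclass(frozen=True)
class PointPattern:
    """One protein's point events on the common interval [0, L].

    ``events`` is a sorted float array with every value in [0, L]; events
    are simple points (strictly distinct values).
    """

    protein: str
    state: str
    events: np.ndarray
    L: float = DEFAULT_L

    def __post_init__(self):
        ev = np.asarray(self.events, dtype=float)
        if ev.ndim != 1:
            raise ValueError("events must be a 1-D array")
        if ev.size and (ev.min() < 0 or ev.max() > self.L):
            raise ValueError(f"events outside [0, {self.L}]")
        if np.any(np.diff(ev) < 0):
            raise ValueError("events must be sorted ascending")
        object.__setattr__(self, "events", ev)

    @property
    def n(self) -> int:
        return int(self.events.size)

    def to_dict(self) -> dict:
        return {
            "protein": self.protein,
            "state": self.state,
            "L": self.L,
            "events": self.events.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PointPattern":
        return cls(
            protein=d["protein"],
            state=d["state"],
            events=np.asarray(d["events"], dtype=float),
            L=float(d["L"]),
        )


@dataclass(frozen=True)
class StateCoordinateMap:
    """Concatenated-window coordinate system for one state.

    ``cumulative_offsets[k]`` is the running start (in bp) of window ``k``
    on the concatenated axis; mapped position = (offset + pos - start)
    * L / total_bp.
    """

    state: str
    windows: tuple[GenomicInterval, ...]
    cumulative_offsets: np.ndarray
    total_bp: int
    L: float = DEFAULT_L

    def __post_init__(self):
        offs = np.asarray(self.cumulative_offsets, dtype=np.int64)
        if np.any(np.diff(offs) <= 0):
            raise ValueError("cumulative_offsets must be strictly increasing")
        if self.total_bp != sum(w.length for w in self.windows):
            raise ValueError("total_bp inconsistent with window lengths")
        if self.total_bp <= 0 or self.L <= 0:
            raise ValueError("total_bp and L must be positive")
        object.__setattr__(self, "cumulative_offsets", offs)

    @property
    def scale(self) -> float:
        """Dimensionless-units per bp."""
        return self.L / self.total_bp


def build_coordinate_map(
    seg: StateSegmentation, state: str, L: float = DEFAULT_L
) -> StateCoordinateMap:
    """Build the [0, L] coordinate map for one state of a segmentation.

    Windows are ordered by natural chromosome order then start position;
    offsets are the prefix sums of window lengths.
    """
    if state not in seg.states:
        raise ValueError(f"state {state!r} not present in segmentation")
    windows = sorted(seg.windows_of(state), key=GenomicInterval.sort_key)
    if not windows:
        raise ValueError(f"state {state!r} has no windows")
    lengths = np.array([w.length for w in windows], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths[:-1])])
    return StateCoordinateMap(
        state=state,
        windows=tuple(windows),
        cumulative_offsets=offsets,
        total_bp=int(lengths.sum()),
        L=float(L),
    )


def project_peaks(
    centers: Iterable[tuple[str, int]],
    cmap: StateCoordinateMap,
    protein: str = "",
) -> PointPattern:
    """Project peak-center events into the state's common interval.

    A center at genomic position ``p`` inside window ``w`` maps to
    ``(offset(w) + p - w.start) * L / total_bp``; centers outside every
    window of the state are dropped.  Duplicate mapped values are kept
    distinct by the smallest representable upward nudge (point-process
    events are simple points).
    """
    by_chrom: dict[str, tuple[list[int], list[int], list[int]]] = {}
    for w, off in zip(cmap.windows, cmap.cumulative_offsets):
        starts, ends, offs = by_chrom.setdefault(w.chrom, ([], [], []))
        starts.append(w.start)
        ends.append(w.end)
        offs.append(int(off))

    mapped = []
    for chrom, pos in centers:
        entry = by_chrom.get(chrom)
        if entry is None:
            continue
        starts, ends, offs = entry
        k = bisect_right(starts, pos) - 1
        if k < 0 or pos >= ends[k]:
            continue  # in a gap between state windows
        # integer bp offset first, one rounding at the final division
        mapped.append((offs[k] + pos - starts[k]) * cmap.L / cmap.total_bp)

    events = np.sort(np.asarray(mapped, dtype=float))
    events = _dedupe(events, cmap.L)
    return PointPattern(protein=protein, state=cmap.state, events=events, L=cmap.L)


def _dedupe(events: np.ndarray, L: float) -> np.ndarray:
    """Nudge tied values upward so every event is distinct, staying in [0, L]."""
    ev = events.copy()
    for j in range(1, ev.size):
        if ev[j] <= ev[j - 1]:
            ev[j] = np.nextafter(ev[j - 1], np.inf)
    # a run of ties ending exactly at L would spill past it: push down instead
    if ev.size and ev[-1] > L:
        ev[-1] = L
        for j in range(ev.size - 2, -1, -1):
            if ev[j] >= ev[j + 1]:
                ev[j] = np.nextafter(ev[j + 1], -np.inf)
    return ev


def write_patterns(patterns: Sequence[PointPattern], path) -> None:
    """Serialise point patterns as a JSON document."""
    doc = {"format": "coxmix-patterns", "patterns": [p.to_dict() for p in patterns]}
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_patterns(path) -> list[PointPattern]:
    doc = json.loads(Path(path).read_text())
    return [PointPattern.from_dict(d) for d in doc["patterns"]]
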