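"""Synthetic inhomogeneous-Poisson point patterns with known cluster truth.

Intensity archetypes are mixtures of Gaussian bumps (closed form, easy
supremum); patterns are drawn by Lewis-Shedler thinning.  A scenario
assigns N processes to K_true archetypes and is fully reproducible from
one seed.  Toy BED fixtures exercise the file-reading and projection
paths end-to-end.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .io_genomics import (
    GenomicInterval,
    PeakSet,
    StateSegmentation,
    write_peaks,
    write_segmentation,
)
from .projection import PointPattern

__all__ = [
    "GaussianBump",
    "BumpIntensity",
    "SyntheticScenario",
    "default_archetypes",
    "sample_ipp",
    "make_scenario",
    "make_fixtures",
]


@dataclass(frozen=True)
class GaussianBump:
    center: float
    width: float
    height: float

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("bump width must be positive")
        if self.height <= 0:
            raise ValueError("bump height must be positive")


class BumpIntensity:
    """Non-negative intensity: sum of Gaussian bumps, optional baseline."""

    def __init__(self, bumps: Sequence[GaussianBump], baseline: float = 0.0):
        if baseline < 0:
            raise ValueError("baseline must be non-negative")
        self.bumps = tuple(bumps)
        self.baseline = float(baseline)

    def __call__(self, s):
        s = np.asarray(s, dtype=float)
        out = np.full_like(s, self.baseline)
        for b in self.bumps:
            out = out + b.height * np.exp(-0.5 * ((s - b.center) / b.width) ** 2)
        return out

    @property
    def lambda_max(self) -> float:
        """An upper bound on the supremum (tight for separated bumps)."""
        return self.baseline + sum(b.height for b in self.bumps)

    def integral(self, L: float) -> float:
        """Integral over [0, L] (bump tails clipped at the boundary)."""
        from scipy.stats import norm

        total = self.baseline * L
        for b in self.bumps:
            mass = norm.cdf(L, b.center, b.width) - norm.cdf(0.0, b.center, b.width)
            total += b.height * b.width * np.sqrt(2 * np.pi) * mass
        return float(total)


@dataclass(frozen=True)
class SyntheticScenario:
    K_true: int
    intensities: tuple[BumpIntensity, ...]
    labels: np.ndarray
    N: int
    seed: int
    L: float = 50.0

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=np.int64)
        if labels.size != self.N:
            raise ValueError("one label per process required")
        if labels.min() < 0 or labels.max() >= self.K_true:
            raise ValueError("labels must lie in {0..K_true-1}")
        object.__setattr__(self, "labels", labels)


def default_archetypes(
    L: float = 50.0,
    centers: Sequence[float] = (10.0, 25.0, 40.0),
    width: float = 3.0,
    total_events: float = 150.0,
) -> list[BumpIntensity]:
    """Three unimodal archetypes with integrated mean ``total_events``."""
    height = total_events / (width * np.sqrt(2 * np.pi))
    return [
        BumpIntensity([GaussianBump(center=c, width=width, height=height)])
        for c in centers
    ]


def _numeric_sup(intensity: Callable, L: float) -> float:
    s = np.linspace(0.0, L, 4097)
    return float(np.max(intensity(s))) * 1.05


def sample_ipp(
    intensity: Callable,
    L: float = 50.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    lambda_max: float | None = None,
) -> np.ndarray:
    """Lewis-Shedler thinning sample from an intensity on [0, L].

    Homogeneous Poisson(lambda_max) candidates are kept with probability
    lambda(s)/lambda_max.  The bound comes from, in order: the explicit
    argument, the intensity's ``lambda_max`` attribute, or a numeric
    supremum over a fine grid with 5% head-room.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    if lambda_max is None:
        lambda_max = getattr(intensity, "lambda_max", None)
    if lambda_max is None:
        lambda_max = _numeric_sup(intensity, L)
    if lambda_max <= 0:
        return np.empty(0)
    n_cand = rng.poisson(lambda_max * L)
    cand = rng.uniform(0.0, L, size=n_cand)
    accept = rng.uniform(size=n_cand) < np.clip(
        np.asarray(intensity(cand)) / lambda_max, 0.0, 1.0
    )
    return np.sort(cand[accept])


def make_scenario(
    archetypes: Sequence[BumpIntensity] | None = None,
    N: int = 12,
    seed: int = 0,
    L: float = 50.0,
    labels: Sequence[int] | None = None,
) -> tuple[SyntheticScenario, list[PointPattern]]:
    """Draw N independent patterns from K archetypes (round-robin labels).

    Each process gets an independent child seed from one SeedSequence, so
    the whole scenario is reproducible from ``seed`` alone.
    """
    if archetypes is None:
        archetypes = default_archetypes(L)
    K = len(archetypes)
    if N < K:
        raise ValueError("need N >= number of archetypes")
    lab = (
        np.asarray(labels, dtype=np.int64)
        if labels is not None
        else np.arange(N, dtype=np.int64) % K
    )
    scenario = SyntheticScenario(
        K_true=K, intensities=tuple(archetypes), labels=lab, N=N, seed=seed, L=L
    )
    child_seeds = np.random.SeedSequence(seed).spawn(N)
    patterns = []
    for i in range(N):
        rng = np.random.default_rng(child_seeds[i])
        events = sample_ipp(archetypes[lab[i]], L=L, rng=rng)
        patterns.append(
            PointPattern(protein=f"P{i:02d}", state="sim", events=events, L=L)
        )
    return scenario, patterns


# Toy fixture geometry: two states on two chromosomes, peak positions chosen
# so every projected coordinate is hand-checkable.
_FIXTURE_SEGMENTATION = [
    ("chr1", 0, 1000, "D1"),
    ("chr1", 1000, 3000, "D5"),
    ("chr2", 0, 500, "D1"),
    ("chr2", 500, 1500, "D5"),
]
_FIXTURE_PEAKS = {
    "TFA": [("chr1", 100, 300), ("chr1", 1200, 1400), ("chr2", 100, 200)],
    "TFB": [("chr1", 400, 600), ("chr1", 2000, 2500), ("chr2", 700, 900)],
    "TFC": [("chr1", 50, 150), ("chr2", 300, 400), ("chr2", 1000, 1200)],
}


def make_fixtures(outdir) -> dict[str, Path]:
    """Write deterministic toy BED peak files and a 2-state segmentation.

    Peak files go under ``outdir/peaks/`` (so the directory can be handed
    to the CLI's --peaks as-is), the segmentation next to it.  Returns a
    map of logical name ("segmentation", "peaks_dir", protein names) to
    path; peak counts per protein follow the module-level fixture tables.
    """
    outdir = Path(outdir)
    peaks_dir = outdir / "peaks"
    peaks_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {"peaks_dir": peaks_dir}

    seg = StateSegmentation(
        windows=tuple(GenomicInterval(c, s, e, lab) for c, s, e, lab in _FIXTURE_SEGMENTATION)
    )
    seg_path = outdir / "segmentation.bed"
    write_segmentation(seg, seg_path)
    paths["segmentation"] = seg_path

    for protein, peaks in _FIXTURE_PEAKS.items():
        ps = PeakSet(
            protein=protein,
            peaks=tuple(GenomicInterval(c, s, e) for c, s, e in peaks),
        )
        p = peaks_dir / f"{protein}.bed"
        write_peaks(ps, p)
        paths[protein] = p
    return paths


def fixture_peak_counts() -> dict[str, int]:
    """Per-protein peak counts of the toy fixtures (for tests/CLI checks)."""
    return {name: len(peaks) for name, peaks in _FIXTURE_PEAKS.items()}
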