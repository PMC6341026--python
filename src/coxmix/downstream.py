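"""Post-clustering summaries: state enrichment of peaks, proximal-gene
assignment around the TSS, and per-group expression tables."""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError
from .io_genomics import PeakSet, StateSegmentation, peak_centers

__all__ = [
    "read_gene_table",
    "write_gene_table",
    "state_enrichment",
    "proximal_genes",
    "expression_by_group",
]

GENE_COLUMNS = ["gene", "chrom", "tss", "strand", "tpm"]


def read_gene_table(path) -> pd.DataFrame:
    """Read a TSV gene table with columns gene, chrom, tss, strand, tpm."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: gene table missing columns {missing}")
    if (df["tss"] < 0).any():
        raise FormatError(f"{path}: negative TSS position")
    if (df["tpm"] < 0).any():
        raise FormatError(f"{path}: negative TPM value")
    return df[GENE_COLUMNS].copy()


def write_gene_table(df: pd.DataFrame, path) -> None:
    df[GENE_COLUMNS].to_csv(path, sep="\t", index=False)


def state_enrichment(
    peaks: PeakSet, seg: StateSegmentation, genome_bp: int
) -> pd.DataFrame:
    """log2 enrichment of peak centers per chromatin state.

    enrichment(state) = log2[ observed center share / genomic share ]
    with a pseudocount of one center per state; the observed share is
    (n_s + 1) / (n_total + n_states) so shares still sum to one.  A state
    whose observed share equals its genomic share scores ~0 up to the
    pseudocount effect.
    """
    if genome_bp < seg.total_bp():
        raise ValueError("genome_bp must cover the segmented bp")
    centers = peak_centers(peaks)
    if not centers:
        raise ValueError(f"peak set {peaks.protein!r} has no centers")

    states = sorted(seg.states)
    by_chrom: dict[str, list] = {}
    for w in seg.windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    n_in_state = {s: 0 for s in states}
    for chrom, pos in centers:
        for w in by_chrom.get(chrom, ()):
            if w.start <= pos < w.end:
                n_in_state[w.label] += 1
                break

    total = len(centers)
    S = len(states)
    rows = []
    for s in states:
        state_bp = seg.total_bp(s)
        obs = (n_in_state[s] + 1) / (total + S)
        exp = state_bp / genome_bp
        rows.append(
            {
                "state": s,
                "protein": peaks.protein,
                "n_centers": n_in_state[s],
                "state_bp": state_bp,
                "enrichment_log2": float(np.log2(obs / exp)),
            }
        )
    return pd.DataFrame(rows)


def proximal_genes(
    genes: pd.DataFrame,
    centers_by_protein: Mapping[str, Iterable[tuple[str, int]]],
    window_bp: int = 2000,
) -> dict[str, set[str]]:
    """Map gene -> set of proteins with a peak center within +/-window_bp of
    the TSS (inclusive at both boundaries, strand-agnostic)."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    sorted_centers: dict[str, dict[str, np.ndarray]] = {}
    for protein, centers in centers_by_protein.items():
        per_chrom: dict[str, list[int]] = {}
        for chrom, pos in centers:
            per_chrom.setdefault(chrom, []).append(pos)
        sorted_centers[protein] = {
            c: np.sort(np.asarray(v)) for c, v in per_chrom.items()
        }

    out: dict[str, set[str]] = {}
    for row in genes.itertuples(index=False):
        bound = set()
        lo, hi = row.tss - window_bp, row.tss + window_bp
        for protein, per_chrom in sorted_centers.items():
            pos = per_chrom.get(row.chrom)
            if pos is None:
                continue
            j = np.searchsorted(pos, lo, side="left")
            if j < pos.size and pos[j] <= hi:
                bound.add(protein)
        out[row.gene] = bound
    return out


def expression_by_group(
    genes: pd.DataFrame, groups: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """Per-group expression summary: n, median TPM, mean log2(TPM+1).

    Empty groups are kept with n=0 and NaN summaries so downstream tables
    show them explicitly.
    """
    if not groups:
        raise ValueError("groups must be non-empty")
    tpm = genes.set_index("gene")["tpm"]
    rows = []
    for name in sorted(groups):
        members = [g for g in groups[name] if g in tpm.index]
        vals = tpm.loc[members].to_numpy(dtype=float)
        rows.append(
            {
                "group": name,
                "n": len(vals),
                "median_tpm": float(np.median(vals)) if len(vals) else np.nan,
                "mean_log2_tpm1": float(np.mean(np.log2(vals + 1.0)))
                if len(vals)
                else np.nan,
            }
        )
    return pd.DataFrame(rows)
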