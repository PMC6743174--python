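"""A/T-content features and the fragment-length x A/T-content 2D occupancy.

MNase cleaves A/T-rich linker (and nucleosomal) DNA preferentially, so the
population of mononucleosome footprints shifts from long, A/T-rich fragments
in mild digestions toward short, G/C-rich fragments in deep digestions.  The
2D occupancy summary tabulates scaled fragment weight by (fragment length,
A/T-content bin of the fragment's own footprint sequence) and makes that
drift visible.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .fragments import TARGET, FragmentRecord

__all__ = [
    "AT_BIN_EDGES",
    "at_content",
    "at_bin",
    "two_d_occupancy",
    "write_matrix_tsv",
]

#: 8 A/T-content bins: 0-0.5, then 0.05-wide steps, then 0.8-1
AT_BIN_EDGES = (0.0, 0.5, 0.55, 0.6, 0.65, 0.7, 0.75, 0.8, 1.0)


def at_content(sequence: str) -> float:
    """(#A + #T) / (length - #N); N bases excluded from both sides.

    Returns NaN (undefined) for empty or all-N sequences.
    """
    s = sequence.upper()
    n_at = s.count("A") + s.count("T")
    n_n = s.count("N")
    denom = len(s) - n_n
    if denom == 0:
        return math.nan
    return n_at / denom


def at_bin(at: float, edges: tuple[float, ...] = AT_BIN_EDGES) -> int:
    """1-based bin index for an A/T fraction.

    Bins are half-open [lo, hi) except the last, which is closed at 1, so
    every value in [0, 1] lands in exactly one bin.
    """
    if not (0.0 <= at <= 1.0):
        raise ValueError(f"A/T content must lie in [0, 1], got {at}")
    if at == edges[-1]:
        return len(edges) - 1
    return int(np.searchsorted(edges, at, side="right"))


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Footprint sequence from a pyfaidx.Fasta, a dict of strings, or similar."""
    if isinstance(genome, dict):
        seq = genome[chrom][start:end]
    else:
        seq = str(genome[chrom][start:end])
    if len(seq) != end - start:
        raise ValueError(f"fragment {chrom}:{start}-{end} extends beyond the genome")
    return seq


def two_d_occupancy(
    fragments: Iterable[FragmentRecord],
    genome,
    edges: tuple[float, ...] = AT_BIN_EDGES,
    length_range: tuple[int, int] = (100, 200),
    weight: float = 1.0,
    fraction: bool = False,
) -> pd.DataFrame:
    """Fragment weight by (length, A/T bin of the fragment's own sequence).

    ``genome`` may be a ``pyfaidx.Fasta`` (or any chrom-indexable sequence
    source).  Rows are fragment lengths over ``length_range`` (inclusive),
    columns the A/T bins.  In ``fraction`` mode the matrix is divided by the
    total weight so all cells sum to 1.
    """
    lo, hi = length_range
    n_bins = len(edges) - 1
    mat = np.zeros((hi - lo + 1, n_bins), dtype=float)
    for f in fragments:
        if f.genome != TARGET or not (lo <= f.length <= hi):
            continue
        at = at_content(_fetch(genome, f.chrom, f.start, f.end))
        if math.isnan(at):
            continue
        mat[f.length - lo, at_bin(at, edges) - 1] += weight
    if fraction:
        total = mat.sum()
        if total > 0:
            mat /= total
    cols = [f"AT_{edges[i]:g}-{edges[i+1]:g}" for i in range(n_bins)]
    return pd.DataFrame(mat, index=pd.RangeIndex(lo, hi + 1, name="length"), columns=cols)


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def plot_two_d_occupancy(matrix: pd.DataFrame, path: str | Path) -> None:
    """Optional heat-map rendering of the 2D occupancy matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(matrix.values, aspect="auto", origin="lower",
                   extent=(0, matrix.shape[1], matrix.index[0], matrix.index[-1]))
    ax.set_xticks(np.arange(matrix.shape[1]) + 0.5, matrix.columns, rotation=45, fontsize=6)
    ax.set_ylabel("fragment length (bp)")
    fig.colorbar(im, ax=ax, label="fragment weight")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
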