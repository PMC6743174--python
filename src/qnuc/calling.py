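"""Typical nucleosome position calling from pooled dyad density.

Dyad tracks from every digestion level are pooled (the union of all digestion
levels sees both the quickly released and the slowly released nucleosomes),
smoothed, and local maxima are accepted greedily by height subject to a
minimum separation of one nucleosome footprint.  Each raw dyad is then
assigned to its nearest accepted maximum and the call coordinate is the
weighted median of the assigned dyads — the "median position of a cluster of
aligned nucleosomes".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "NucleosomeCall",
    "pool_dyads",
    "call_nucleosomes",
    "match_positions",
    "footprint_coverage_fraction",
    "write_calls_bed",
]

FOOTPRINT_BP = 147


@dataclass(frozen=True)
class NucleosomeCall:
    """A typical nucleosome position.

    dyad_pos is the weighted median of the cluster's dyads; support is the
    total (scaled) dyad weight assigned to the cluster.
    """

    chrom: str
    dyad_pos: int
    support: float
    span_lo: int
    span_hi: int

    def __post_init__(self) -> None:
        if not (self.span_lo <= self.dyad_pos <= self.span_hi):
            raise ValueError("dyad_pos must lie within the cluster span")
        if not self.support > 0:
            raise ValueError("support must be positive")


def pool_dyads(samples) -> dict[str, np.ndarray]:
    """Sum scaled dyad tracks across normalized samples.

    All samples must cover the same chromosome set (they come from the same
    experiment); a mismatch is an input error and is reported, not silently intersected.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("no samples to pool")
    chroms = set(samples[0].tracks)
    for s in samples[1:]:
        if set(s.tracks) != chroms:
            raise ValueError("samples have mismatched chromosome sets")
    pooled: dict[str, np.ndarray] = {}
    for c in chroms:
        pooled[c] = np.sum([s.tracks[c] for s in samples], axis=0)
    return pooled


def _weighted_median(positions: np.ndarray, weights: np.ndarray) -> int:
    """Smallest position whose cumulative weight reaches half the total."""
    order = np.argsort(positions, kind="stable")
    pos = positions[order]
    w = weights[order]
    cum = np.cumsum(w)
    idx = int(np.searchsorted(cum, 0.5 * cum[-1]))
    return int(pos[min(idx, pos.size - 1)])


def call_nucleosomes(
    dyad_tracks: dict[str, np.ndarray],
    bandwidth: float = 30.0,
    min_separation: int = FOOTPRINT_BP,
    min_support: float | None = None,
) -> list[NucleosomeCall]:
    """Call nucleosome positions from a pooled per-base dyad track.

    Procedure per chromosome: (i) Gaussian-smooth the dyad density with the
    given bandwidth (bp); (ii) take local maxima, accepted greedily in
    decreasing height order subject to ``min_separation``; (iii) assign every
    raw dyad to the nearest accepted maximum within min_separation/2;
    (iv) report the weighted median of each cluster's dyads.  Calls whose
    support falls below ``min_support`` are dropped; the default threshold is
    1% of the genome-wide mean dyad weight per footprint-sized window.
    """
    if min_support is None:
        total = sum(float(v.sum()) for v in dyad_tracks.values())
        length = sum(v.size for v in dyad_tracks.values())
        min_support = 0.01 * total / length * FOOTPRINT_BP if length else 0.0

    calls: list[NucleosomeCall] = []
    half = min_separation / 2.0
    for chrom in sorted(dyad_tracks):
        track = np.asarray(dyad_tracks[chrom], dtype=float)
        if np.any(track < 0):
            raise ValueError("dyad track must be non-negative")
        if track.size == 0 or not np.any(track > 0):
            continue
        smooth = gaussian_filter1d(track, sigma=bandwidth, mode="constant")
        # local maxima (plateau-left convention keeps the result deterministic)
        left = np.r_[True, smooth[1:] > smooth[:-1]]
        right = np.r_[smooth[:-1] > smooth[1:], True]
        cand = np.flatnonzero(left & right & (smooth > 0))
        # greedy acceptance by decreasing smoothed height, ties to the left
        order = cand[np.lexsort((cand, -smooth[cand]))]
        accepted: list[int] = []
        for pos in order:
            if all(abs(pos - a) >= min_separation for a in accepted):
                accepted.append(int(pos))
        if not accepted:
            continue
        peaks = np.sort(np.array(accepted))
        # assign raw dyads to nearest accepted maximum within half a separation
        dyads = np.flatnonzero(track > 0)
        weights = track[dyads]
        nearest = np.searchsorted(peaks, dyads)
        nearest = np.clip(nearest, 0, peaks.size - 1)
        prev = np.clip(nearest - 1, 0, peaks.size - 1)
        pick = np.where(
            np.abs(dyads - peaks[prev]) <= np.abs(dyads - peaks[nearest]), prev, nearest
        )
        dist = np.abs(dyads - peaks[pick])
        ok = dist <= half
        chrom_calls = []
        for j in range(peaks.size):
            mask = ok & (pick == j)
            if not np.any(mask):
                continue
            p, w = dyads[mask], weights[mask]
            support = float(w.sum())
            if support < min_support:
                continue
            chrom_calls.append(
                NucleosomeCall(
                    chrom=chrom,
                    dyad_pos=_weighted_median(p, w),
                    support=support,
                    span_lo=int(p.min()),
                    span_hi=int(p.max()),
                )
            )
        # medians can drift off their maxima; enforce the separation invariant
        chrom_calls.sort(key=lambda c: (-c.support, c.dyad_pos))
        kept: list[NucleosomeCall] = []
        for c in chrom_calls:
            if all(abs(c.dyad_pos - k.dyad_pos) >= min_separation for k in kept):
                kept.append(c)
        calls.extend(sorted(kept, key=lambda c: c.dyad_pos))
    return calls


def match_positions(
    calls_a: list[NucleosomeCall],
    calls_b: list[NucleosomeCall],
    tolerance: int = 20,
) -> tuple[float, np.ndarray]:
    """Greedy one-to-one nearest matching of two call sets.

    Returns (matched fraction of ``calls_a``, signed shifts b - a of the
    matched pairs).  Pairs are accepted in order of increasing |shift|;
    only pairs within ``tolerance`` bp on the same chromosome are eligible.
    """
    if not calls_a:
        return 0.0, np.array([], dtype=int)
    by_chrom_b: dict[str, list[tuple[int, int]]] = {}
    for j, c in enumerate(calls_b):
        by_chrom_b.setdefault(c.chrom, []).append((c.dyad_pos, j))
    candidates: list[tuple[int, int, int, int]] = []  # |shift|, shift, i, j
    for i, a in enumerate(calls_a):
        for pos_b, j in by_chrom_b.get(a.chrom, ()):
            shift = pos_b - a.dyad_pos
            if abs(shift) <= tolerance:
                candidates.append((abs(shift), shift, i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    shifts: list[int] = []
    for _, shift, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        shifts.append(shift)
    return len(shifts) / len(calls_a), np.array(shifts, dtype=int)


def footprint_coverage_fraction(spacing_bp: float, footprint_bp: int = FOOTPRINT_BP) -> float:
    """Fraction of the genome covered by nucleosome footprints at a given
    repeat length: footprint/spacing (147/200 = 73.5% at fly-typical spacing)."""
    if spacing_bp <= 0:
        raise ValueError("spacing must be positive")
    return footprint_bp / spacing_bp


def write_calls_bed(calls: list[NucleosomeCall], path) -> None:
    """BED6: footprint interval, call id, support score, '.' strand."""
    half = FOOTPRINT_BP // 2
    with open(path, "w") as fh:
        for i, c in enumerate(calls):
            start = max(0, c.dyad_pos - half)
            fh.write(
                f"{c.chrom}\t{start}\t{c.dyad_pos + half + 1}\tnuc{i}\t{c.support:.6g}\t.\n"
            )
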