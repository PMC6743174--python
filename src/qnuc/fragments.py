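"""Paired-end fragment I/O, length filtering, spike-in calibration and tracks.

Fragments are strandless genomic intervals in BED convention (0-based,
half-open).  Spike-in fragments (exogenous calibrated nucleosomal DNA, e.g.
budding-yeast mononucleosomes added in equal amounts to every sample) are
distinguished from target-genome fragments either by a chromosome-name prefix
(default ``sc_``) or by loading them from a separate file.

Normalization rescales every sample so that its spike-in fragment total equals
a common target (default 10,000), making mononucleosome counts comparable
across digestion levels — the calibration that raw library-size scaling cannot
provide, because total yield itself depends on the digestion level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

import numpy as np
import pandas as pd

__all__ = [
    "FragmentRecord",
    "NormalizedSample",
    "TARGET",
    "SPIKEIN",
    "DEFAULT_SPIKEIN_PREFIX",
    "DEFAULT_SPIKEIN_TARGET",
    "read_fragments",
    "read_fragments_frame",
    "write_fragments",
    "filter_by_length",
    "count_spikein",
    "spikein_normalize",
    "dyad_track",
    "coverage_track",
    "read_chrom_sizes",
    "read_sample_sheet",
    "write_bedgraph",
]

TARGET = "target"
SPIKEIN = "spikein"
DEFAULT_SPIKEIN_PREFIX = "sc_"
DEFAULT_SPIKEIN_TARGET = 10_000.0


@dataclass(frozen=True)
class FragmentRecord:
    """One aligned paired-end fragment: a half-open interval plus genome label."""

    chrom: str
    start: int
    end: int
    genome: str = TARGET

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"fragment end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.genome not in (TARGET, SPIKEIN):
            raise ValueError(f"genome label must be '{TARGET}' or '{SPIKEIN}'")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def dyad(self) -> int:
        """Fragment midpoint (floor for even lengths)."""
        return (self.start + self.end) // 2


@dataclass
class NormalizedSample:
    """One digestion time point after spike-in calibration.

    ``tracks`` maps chromosome -> per-base float vector already multiplied by
    ``scale_factor`` (= spikein_target / raw_spikein_count).
    """

    sample_id: str
    time_min: float
    raw_spikein_count: int
    scale_factor: float
    tracks: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def normalized_spikein_total(self) -> float:
        return self.raw_spikein_count * self.scale_factor


def _label_for(chrom: str, spikein_prefix: str, genome: str | None) -> str:
    if genome is not None:
        return genome
    return SPIKEIN if chrom.startswith(spikein_prefix) else TARGET


def read_fragments(
    path: str | Path,
    format: Literal["BED", "BEDPE"] = "BED",
    spikein_prefix: str = DEFAULT_SPIKEIN_PREFIX,
    genome: str | None = None,
) -> Iterator[FragmentRecord]:
    """Stream fragments from a BED3 or BEDPE file.

    The genome label is taken from ``genome`` if given (two-file convention),
    else inferred per record from the chromosome-name prefix.  Malformed
    lines raise ValueError naming the file and line number.
    """
    path = Path(path)
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if format == "BED":
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                elif format == "BEDPE":
                    c1, s1, e1, c2, s2, e2 = fields[:6]
                    if c1 != c2:
                        raise ValueError("mates on different chromosomes")
                    chrom = c1
                    start = min(int(s1), int(s2))
                    end = max(int(e1), int(e2))
                else:
                    raise ValueError(f"unknown format {format!r}")
                rec = FragmentRecord(
                    chrom, start, end, _label_for(chrom, spikein_prefix, genome)
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed fragment line: {exc}") from exc
            n += 1
            yield rec
    if n == 0:
        warnings.warn(f"{path}: no fragments parsed (empty file?)", stacklevel=2)


def read_fragments_frame(
    path: str | Path,
    spikein_prefix: str = DEFAULT_SPIKEIN_PREFIX,
    genome: str | None = None,
) -> pd.DataFrame:
    """Bulk BED3 reader returning a chrom/start/end/genome DataFrame.

    Same labeling rules as :func:`read_fragments`; intended for large files
    where per-record streaming is too slow.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        comment="#",
        dtype={"chrom": str},
    )
    if (df["end"] <= df["start"]).any():
        bad = int((df["end"] <= df["start"]).idxmax()) + 1
        raise ValueError(f"{path}:{bad}: fragment end must exceed start")
    if genome is not None:
        df["genome"] = genome
    else:
        df["genome"] = np.where(
            df["chrom"].str.startswith(spikein_prefix), SPIKEIN, TARGET
        )
    return df


def write_fragments(fragments: Iterable[FragmentRecord], path: str | Path) -> int:
    """Write fragments as BED3 lines; returns the number written."""
    n = 0
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\n")
            n += 1
    return n


def filter_by_length(fragments, min_len: int = 100, max_len: int = 200):
    """Keep fragments with min_len <= length <= max_len (both ends inclusive).

    The 100-200 bp window selects intact mononucleosome-sized footprints.
    Accepts an iterable of FragmentRecord (returns a generator) or a
    DataFrame with chrom/start/end columns (returns a filtered DataFrame).
    """
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    if isinstance(fragments, pd.DataFrame):
        length = fragments["end"] - fragments["start"]
        return fragments[(length >= min_len) & (length <= max_len)]
    return (f for f in fragments if min_len <= f.length <= max_len)


def count_spikein(fragments) -> int:
    """Count spike-in fragments; zero spike-ins is an error (cannot calibrate)."""
    if isinstance(fragments, pd.DataFrame):
        n = int((fragments["genome"] == SPIKEIN).sum())
    else:
        n = sum(1 for f in fragments if f.genome == SPIKEIN)
    if n == 0:
        raise ValueError("no spike-in fragments found; spike-in normalization impossible")
    return n


def spikein_normalize(
    samples: Iterable[tuple[dict[str, np.ndarray], int]],
    target: float = DEFAULT_SPIKEIN_TARGET,
    sample_ids: Iterable[str] | None = None,
    times_min: Iterable[float] | None = None,
) -> list[NormalizedSample]:
    """Rescale each sample's tracks so its spike-in total equals ``target``.

    ``samples`` is a list of (tracks, raw_spikein_count).  Scale factors are
    target / raw_spikein_count; between-sample ratios of normalized counts at
    any locus equal the raw ratios rescaled by the spike-in ratios.
    """
    samples = list(samples)
    ids = list(sample_ids) if sample_ids is not None else [f"s{i}" for i in range(len(samples))]
    times = list(times_min) if times_min is not None else [float(i) for i in range(len(samples))]
    out = []
    for sid, t, (tracks, spikein_count) in zip(ids, times, samples):
        if spikein_count <= 0:
            raise ValueError(f"sample {sid}: spike-in count must be positive")
        scale = target / spikein_count
        out.append(
            NormalizedSample(
                sample_id=sid,
                time_min=t,
                raw_spikein_count=int(spikein_count),
                scale_factor=scale,
                tracks={c: np.asarray(v, dtype=float) * scale for c, v in tracks.items()},
            )
        )
    return out


def _target_positions(
    fragments: Iterable[FragmentRecord], chrom_sizes: dict[str, int]
) -> Iterator[FragmentRecord]:
    for f in fragments:
        if f.genome != TARGET:
            continue
        if f.chrom not in chrom_sizes:
            raise ValueError(f"fragment chromosome {f.chrom!r} absent from chrom sizes")
        yield f


def _target_frame(fragments: pd.DataFrame, chrom_sizes: dict[str, int]) -> pd.DataFrame:
    df = fragments
    if "genome" in df.columns:
        df = df[df["genome"] == TARGET]
    unknown = set(df["chrom"].unique()) - set(chrom_sizes)
    if unknown:
        raise ValueError(f"fragment chromosomes absent from chrom sizes: {sorted(unknown)}")
    return df


def dyad_track(
    fragments,
    chrom_sizes: dict[str, int],
    weight: float = 1.0,
) -> dict[str, np.ndarray]:
    """Per-base dyad (fragment midpoint) count vectors, one per chromosome.

    Accepts an iterable of FragmentRecord or a chrom/start/end DataFrame.
    """
    tracks = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    if isinstance(fragments, pd.DataFrame):
        df = _target_frame(fragments, chrom_sizes)
        dyads = (df["start"].to_numpy() + df["end"].to_numpy()) // 2
        for chrom, grp in pd.Series(dyads).groupby(df["chrom"].to_numpy()):
            n = chrom_sizes[chrom]
            d = grp.to_numpy()
            if d.min(initial=0) < 0 or (d.size and d.max() >= n):
                raise ValueError(f"dyad outside chromosome {chrom} (len {n})")
            tracks[chrom] += weight * np.bincount(d, minlength=n)
        return tracks
    for f in _target_positions(fragments, chrom_sizes):
        d = f.dyad
        if not (0 <= d < chrom_sizes[f.chrom]):
            raise ValueError(f"dyad {d} outside chromosome {f.chrom} (len {chrom_sizes[f.chrom]})")
        tracks[f.chrom][d] += weight
    return tracks


def coverage_track(
    fragments,
    chrom_sizes: dict[str, int],
    weight: float = 1.0,
) -> dict[str, np.ndarray]:
    """Per-base occupancy: each fragment adds ``weight`` over [start, end).

    Accepts an iterable of FragmentRecord or a chrom/start/end DataFrame.
    """
    # difference-array accumulation, then cumulative sum per chromosome
    diffs = {c: np.zeros(n + 1, dtype=float) for c, n in chrom_sizes.items()}
    if isinstance(fragments, pd.DataFrame):
        df = _target_frame(fragments, chrom_sizes)
        for chrom, grp in df.groupby("chrom"):
            n = chrom_sizes[chrom]
            s = grp["start"].to_numpy()
            e = grp["end"].to_numpy()
            if s.min(initial=0) < 0 or (e.size and e.max() > n):
                raise ValueError(f"fragment outside chromosome {chrom} (len {n})")
            np.add.at(diffs[chrom], s, weight)
            np.add.at(diffs[chrom], e, -weight)
        return {c: np.cumsum(v[:-1]) for c, v in diffs.items()}
    for f in _target_positions(fragments, chrom_sizes):
        n = chrom_sizes[f.chrom]
        if f.start < 0 or f.end > n:
            raise ValueError(f"fragment {f.chrom}:{f.start}-{f.end} outside chromosome (len {n})")
        diffs[f.chrom][f.start] += weight
        diffs[f.chrom][f.end] -= weight
    return {c: np.cumsum(v[:-1]) for c, v in diffs.items()}


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column chrom<TAB>length text file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                chrom, length = line.split("\t")[:2]
                sizes[chrom] = int(length)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed chrom sizes line") from exc
    return sizes


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet TSV with columns sample_id, time_min, fragments_path."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time_min", "fragments_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if not df["time_min"].is_monotonic_increasing:
        df = df.sort_values("time_min", kind="stable").reset_index(drop=True)
    return df


def write_bedgraph(tracks: dict[str, np.ndarray], path: str | Path) -> None:
    """Write per-base tracks as a run-length-merged bedGraph (zeros omitted)."""
    with open(path, "w") as fh:
        for chrom in sorted(tracks):
            v = tracks[chrom]
            if v.size == 0:
                continue
            # boundaries where the value changes
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [v.size]))
            for s, e in zip(starts, ends):
                val = v[s]
                if val != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{val:.6g}\n")
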