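"""Synthetic digestion time-course generator with known ground truth.

The generator plants a regularly spaced nucleosome map (one nucleosome per
~200 bp, the fly-typical repeat length) on a synthetic genome whose A/T
content fluctuates between nucleosome-sized blocks around the fly-genome
average of 0.58, assigns each locus a true (O, k1, k2), and draws paired-end
fragments for each digestion time point:

* per locus and time t the fragment count is Poisson(depth * N(t)/C), where
  N(t)/C is the closed-form apparent occupancy — the generator obeys the same
  kinetics the fitter assumes;
* fragment centers scatter around the planted dyad; fragment lengths shorten
  with digestion (mean 165 -> 140 bp across the course, trimming by
  over-digestion), emitted uncensored so the 100-200 bp analysis filter has
  work to do;
* a small fragile subpopulation carries k1 multiplied ~30-fold (weakly
  protecting non-histone complexes);
* optionally k1 is tilted by footprint A/T content, k1 *= exp(beta*(AT-mean)),
  mimicking the A/T cleavage preference of the enzyme;
* each sample receives Poisson(spikein_expected) spike-in fragments on a
  dedicated spike-in contig — the constant-expectation calibrant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fragments as fio
from .calling import NucleosomeCall, call_nucleosomes, match_positions, pool_dyads
from .fitting import FitConfig, SampleTimeCourse, extract_timecourses, fit_all, fit_locus
from .kinetics import DigestionParams, apparent_occupancy
from .seqfeat import at_content

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimSample",
    "simulate_genome",
    "simulate_timecourse",
    "simulate_dataset",
    "recovery_harness",
    "parameter_recovery_grid",
    "write_bundle",
]

TARGET_CHROM = "chr1"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic digestion experiment."""

    genome_length: int = 100_000
    at_mean: float = 0.58            # fly genome-wide A/T average
    at_sd: float = 0.10              # block-to-block A/T spread (0 = homogeneous)
    spacing: int = 200               # nucleosome repeat length, bp
    position_jitter: int = 10        # planted dyad jitter, uniform +/- bp
    times: tuple[float, ...] = (1.0, 2.0, 5.0, 15.0, 40.0, 60.0)
    depth: float = 1000.0            # expected fragments at the count maximum of a fully occupied locus
    occ_low: float = 0.2
    occ_high: float = 1.0            # O ~ Uniform(occ_low, occ_high)
    k1_median: float = 1.0
    k1_log_sd: float = 0.5           # k1 ~ LogNormal(ln median, sd)
    k2_median: float = 0.05
    k2_log_sd: float = 0.5
    fragile_fraction: float = 0.01   # < 1% of loci
    fragile_multiplier: float = 30.0
    at_coupling: float = 0.0         # beta in k1 *= exp(beta*(AT - at_mean))
    length_mean_start: float = 165.0  # mean fragment length at the first time point
    length_mean_end: float = 140.0    # ... and at the last
    length_sd: float = 10.0
    center_jitter_sd: float = 10.0   # fragment-center scatter around the dyad, bp
    spikein_expected: float = 2500.0
    spikein_prefix: str = "sc_"
    spikein_contig_length: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < self.spacing:
            raise ValueError("genome_length must be at least one spacing")
        if not 0 <= self.fragile_fraction < 1:
            raise ValueError("fragile_fraction must lie in [0, 1)")
        t = np.asarray(self.times)
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be positive and strictly increasing")
        for name in ("k1_median", "k2_median", "depth", "spikein_expected"):
            if getattr(self, name) < 0 or (name.startswith("k") and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")

    @property
    def spikein_chrom(self) -> str:
        return f"{self.spikein_prefix}spikein"


@dataclass
class SimTruth:
    """Ground-truth ledger: the genome, the planted loci, and their kinetics."""

    genome: dict[str, str]
    loci: pd.DataFrame  # position, O, k1, k2, fragile
    config: SimConfig
    spikein_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class SimSample:
    sample_id: str
    time_min: float
    fragments: pd.DataFrame  # chrom, start, end, genome
    spikein_count: int


def _apparent_vec(t: float, O: np.ndarray, k1: np.ndarray, k2: np.ndarray) -> np.ndarray:
    """Vectorized apparent occupancy over per-locus parameter arrays."""
    near = np.abs(k1 - k2) < 1e-8 * np.maximum(k1, k2)
    k2_safe = np.where(near, 0.5 * k1, k2)
    general = O * k1 / (k1 - k2_safe) * (np.exp(-k2_safe * t) - np.exp(-k1 * t))
    limiting = O * k1 * t * np.exp(-k1 * t)
    return np.where(near, limiting, general)


def simulate_genome(config: SimConfig, rng: np.random.Generator | None = None):
    """Synthetic genome plus planted dyad positions.

    Bases are i.i.d. within spacing-sized blocks; each block's A/T probability
    is drawn from Normal(at_mean, at_sd) truncated to [0.05, 0.95], so the
    genome shows the domain-scale A/T heterogeneity real chromatin has while
    keeping the genome-wide mean at ``at_mean``.  Dyads are planted every
    ``spacing`` bp with small uniform jitter.
    """
    rng = rng or np.random.default_rng(config.seed)
    L = config.genome_length
    n_blocks = -(-L // config.spacing)
    p_block = np.clip(
        rng.normal(config.at_mean, config.at_sd, size=n_blocks), 0.05, 0.95
    )
    p_base = np.repeat(p_block, config.spacing)[:L]
    is_at = rng.random(L) < p_base
    which = rng.random(L) < 0.5
    bases = np.where(is_at, np.where(which, "A", "T"), np.where(which, "C", "G"))
    sequence = "".join(bases)

    n_loci = L // config.spacing
    centers = config.spacing // 2 + config.spacing * np.arange(n_loci)
    jitter = rng.integers(-config.position_jitter, config.position_jitter + 1, size=n_loci)
    positions = np.clip(centers + jitter, 0, L - 1)

    spike_seq = "".join(
        rng.choice(np.array(["A", "C", "G", "T"]), size=config.spikein_contig_length)
    )
    genome = {TARGET_CHROM: sequence, config.spikein_chrom: spike_seq}
    return genome, positions


def plant_parameters(
    genome: dict[str, str],
    positions: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw per-locus (O, k1, k2, fragile) under the configured distributions."""
    n = positions.size
    O = rng.uniform(config.occ_low, config.occ_high, size=n)
    k1 = np.exp(rng.normal(np.log(config.k1_median), config.k1_log_sd, size=n))
    k2 = np.exp(rng.normal(np.log(config.k2_median), config.k2_log_sd, size=n))
    fragile = rng.random(n) < config.fragile_fraction
    k1 = np.where(fragile, k1 * config.fragile_multiplier, k1)
    if config.at_coupling != 0.0:
        seq = genome[TARGET_CHROM]
        half = 147 // 2
        at = np.array(
            [
                at_content(seq[max(0, p - half): p + half + 1])
                for p in positions
            ]
        )
        k1 = k1 * np.exp(config.at_coupling * (at - config.at_mean))
    return pd.DataFrame(
        {"position": positions, "O": O, "k1": k1, "k2": k2, "fragile": fragile}
    )


def simulate_timecourse(
    truth: SimTruth,
    config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[SimSample]:
    """Draw per-sample fragment sets (target + spike-in) for every time point."""
    config = config or truth.config
    rng = rng or np.random.default_rng(config.seed + 1)
    loci = truth.loci
    L = len(truth.genome[TARGET_CHROM])
    n_t = len(config.times)
    samples: list[SimSample] = []
    for i, t in enumerate(config.times):
        lam = config.depth * _apparent_vec(
            t, loci["O"].to_numpy(), loci["k1"].to_numpy(), loci["k2"].to_numpy()
        )
        counts = rng.poisson(lam)
        centers = np.repeat(loci["position"].to_numpy(), counts)
        centers = centers + np.rint(
            rng.normal(0.0, config.center_jitter_sd, size=centers.size)
        ).astype(int)
        frac = i / (n_t - 1) if n_t > 1 else 0.0
        mean_len = config.length_mean_start + frac * (
            config.length_mean_end - config.length_mean_start
        )
        lengths = np.maximum(
            np.rint(rng.normal(mean_len, config.length_sd, size=centers.size)).astype(int),
            30,
        )
        starts = centers - lengths // 2
        ends = starts + lengths
        shift = np.maximum(0, -starts) - np.maximum(0, ends - L)
        starts, ends = starts + shift, ends + shift

        n_spike = int(rng.poisson(config.spikein_expected))
        s_len = rng.integers(140, 161, size=n_spike)
        s_start = rng.integers(0, config.spikein_contig_length - 200, size=n_spike)
        df = pd.DataFrame(
            {
                "chrom": np.concatenate(
                    [
                        np.full(starts.size, TARGET_CHROM),
                        np.full(n_spike, config.spikein_chrom),
                    ]
                ),
                "start": np.concatenate([starts, s_start]),
                "end": np.concatenate([ends, s_start + s_len]),
                "genome": np.concatenate(
                    [np.full(starts.size, fio.TARGET), np.full(n_spike, fio.SPIKEIN)]
                ),
            }
        )
        sid = f"t{t:g}min"
        truth.spikein_counts[sid] = n_spike
        samples.append(SimSample(sample_id=sid, time_min=t, fragments=df, spikein_count=n_spike))
    return samples


def simulate_dataset(config: SimConfig) -> tuple[SimTruth, list[SimSample]]:
    """Genome + truth + fragment sets, all driven by config.seed."""
    rng = np.random.default_rng(config.seed)
    genome, positions = simulate_genome(config, rng)
    loci = plant_parameters(genome, positions, config, rng)
    truth = SimTruth(genome=genome, loci=loci, config=config)
    samples = simulate_timecourse(truth, config, rng)
    return truth, samples


def _truth_calls(truth: SimTruth) -> list[NucleosomeCall]:
    return [
        NucleosomeCall(TARGET_CHROM, int(p), 1.0, int(p), int(p))
        for p in truth.loci["position"]
    ]


def recovery_harness(
    config: SimConfig | None = None,
    noiseless: bool = False,
    spikein_target: float = fio.DEFAULT_SPIKEIN_TARGET,
    tolerance: int = 20,
) -> dict:
    """End-to-end validation: simulate -> normalize -> call -> fit -> compare.

    Reports the planted-position match fraction at the given tolerance,
    median relative errors of (O, k1, k2) over matched loci, and fragile
    sensitivity/specificity.  Fitted O (spike-in-normalized count units) is
    rescaled by the known depth and spike-in expectation before comparison.

    In ``noiseless`` mode the fitter is exercised on the exact expected
    counts of every planted locus (scale = depth): a degenerate-noise oracle
    that isolates fitter correctness from sampling and calling effects.
    """
    config = config or SimConfig()
    if noiseless:
        errs = {"O": [], "k1": [], "k2": []}
        fits_fragile = []
        genome, positions = simulate_genome(config)
        loci = plant_parameters(genome, positions, config, np.random.default_rng(config.seed))
        for _, row in loci.iterrows():
            p = DigestionParams(O=row["O"], k1=row["k1"], k2=row["k2"])
            counts = tuple(
                config.depth * apparent_occupancy(t, p) for t in config.times
            )
            fit = fit_locus(
                SampleTimeCourse("x", tuple(config.times), counts, scale=config.depth)
            )
            errs["O"].append(abs(fit.params.O - row["O"]) / row["O"])
            errs["k1"].append(abs(fit.params.k1 - row["k1"]) / row["k1"])
            errs["k2"].append(abs(fit.params.k2 - row["k2"]) / row["k2"])
            if row["fragile"]:
                fits_fragile.append(fit.fragile)
        return {
            "mode": "noiseless",
            "n_loci": len(errs["O"]),
            "median_rel_err_O": float(np.median(errs["O"])),
            "median_rel_err_k1": float(np.median(errs["k1"])),
            "median_rel_err_k2": float(np.median(errs["k2"])),
            "fragile_sensitivity": float(np.mean(fits_fragile)) if fits_fragile else float("nan"),
        }

    truth, samples = simulate_dataset(config)
    chrom_sizes = {TARGET_CHROM: len(truth.genome[TARGET_CHROM])}
    tracks_and_counts = []
    dyads_and_counts = []
    for s in samples:
        kept = fio.filter_by_length(s.fragments)
        n_spike = fio.count_spikein(kept)
        dyads_and_counts.append((fio.dyad_track(kept, chrom_sizes), n_spike))
        tracks_and_counts.append((fio.coverage_track(kept, chrom_sizes), n_spike))
    ids = [s.sample_id for s in samples]
    times = [s.time_min for s in samples]
    norm_dyads = fio.spikein_normalize(dyads_and_counts, spikein_target, ids, times)
    norm_cov = fio.spikein_normalize(tracks_and_counts, spikein_target, ids, times)

    pooled = pool_dyads(norm_dyads)
    calls = call_nucleosomes(pooled)
    truth_calls = _truth_calls(truth)
    match_frac, _shifts = match_positions(truth_calls, calls, tolerance=tolerance)

    # pair each call with its nearest planted locus for parameter comparison
    tcs = extract_timecourses(calls, norm_cov)
    fit_table = fit_all(tcs, FitConfig(), calls=calls)
    positions = truth.loci["position"].to_numpy()
    idx = np.searchsorted(positions, fit_table["dyad_pos"].to_numpy())
    idx = np.clip(idx, 0, positions.size - 1)
    prev = np.clip(idx - 1, 0, positions.size - 1)
    nearer_prev = np.abs(fit_table["dyad_pos"].to_numpy() - positions[prev]) <= np.abs(
        fit_table["dyad_pos"].to_numpy() - positions[idx]
    )
    match_idx = np.where(nearer_prev, prev, idx)
    dist = np.abs(fit_table["dyad_pos"].to_numpy() - positions[match_idx])
    ok = (dist <= tolerance) & fit_table["converged"].to_numpy()

    o_scale = config.depth * spikein_target / config.spikein_expected
    tl = truth.loci.iloc[match_idx[ok]]
    ft = fit_table[ok]
    rel = lambda est, tru: np.abs(est - tru) / np.abs(tru)  # noqa: E731
    err_O = rel(ft["O"].to_numpy() / o_scale, tl["O"].to_numpy())
    err_k1 = rel(ft["k1"].to_numpy(), tl["k1"].to_numpy())
    err_k2 = rel(ft["k2"].to_numpy(), tl["k2"].to_numpy())
    frag_truth = tl["fragile"].to_numpy()
    frag_fit = ft["fragile"].to_numpy()
    sens = float(np.mean(frag_fit[frag_truth])) if frag_truth.any() else float("nan")
    spec = float(np.mean(~frag_fit[~frag_truth])) if (~frag_truth).any() else float("nan")
    return {
        "mode": "noisy",
        "n_loci": int(len(truth.loci)),
        "n_calls": int(len(calls)),
        "position_match_fraction": float(match_frac),
        "n_fitted": int(ok.sum()),
        "median_rel_err_O": float(np.median(err_O)),
        "median_rel_err_k1": float(np.median(err_k1)),
        "median_rel_err_k2": float(np.median(err_k2)),
        "fragile_sensitivity": sens,
        "fragile_specificity": spec,
        "convergence_rate": float(fit_table["converged"].mean()),
    }


def parameter_recovery_grid(
    O_values=(0.2, 0.5, 0.9),
    k1_values=(0.3, 1.0, 3.0, 30.0),
    k2_values=(0.01, 0.05, 0.2),
    peak_expectation: float = 1000.0,
    n_replicates: int = 100,
    times: tuple[float, ...] = (1.0, 2.0, 5.0, 15.0, 40.0, 60.0),
    fragile_threshold: float = 10.0,
    seed: int = 0,
) -> dict:
    """Monte-Carlo recovery at the count level: Poisson noise around Eq.-exact means.

    For every truth on the grid, ``n_replicates`` count vectors are drawn as
    Poisson with the expected curve scaled so its maximum over the sampled
    time points equals ``peak_expectation``, then refitted.  Returns pooled
    median relative errors per parameter plus the fraction of high-k1 truths
    (> threshold) classified fragile.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(times)
    errs = {"O": [], "k1": [], "k2": []}
    fragile_hits = []
    n_fragile_truths = 0
    per_cell = []
    for O in O_values:
        for k1 in k1_values:
            for k2 in k2_values:
                p = DigestionParams(O=O, k1=k1, k2=k2)
                curve = np.asarray(apparent_occupancy(t, p))
                scale = peak_expectation / curve.max()
                lam = scale * curve
                cell = {"O": O, "k1": k1, "k2": k2, "err": {"O": [], "k1": [], "k2": []}}
                for _ in range(n_replicates):
                    counts = rng.poisson(lam).astype(float)
                    fit = fit_locus(
                        SampleTimeCourse("g", tuple(times), tuple(counts), scale=scale)
                    )
                    if fit.params is None:
                        continue
                    e = {
                        "O": abs(fit.params.O - O) / O,
                        "k1": abs(fit.params.k1 - k1) / k1,
                        "k2": abs(fit.params.k2 - k2) / k2,
                    }
                    for k in errs:
                        errs[k].append(e[k])
                        cell["err"][k].append(e[k])
                    if k1 > fragile_threshold:
                        fragile_hits.append(fit.fragile)
                if k1 > fragile_threshold:
                    n_fragile_truths += n_replicates
                per_cell.append(cell)
    return {
        "median_rel_err_O": float(np.median(errs["O"])),
        "median_rel_err_k1": float(np.median(errs["k1"])),
        "median_rel_err_k2": float(np.median(errs["k2"])),
        "fragile_classification_rate": float(np.mean(fragile_hits)) if fragile_hits else float("nan"),
        "n_fits": len(errs["O"]),
        "per_cell": per_cell,
    }


def write_bundle(truth: SimTruth, samples: list[SimSample], outdir: str | Path) -> dict:
    """Write FASTA genome, per-sample BED fragments, truth TSV, sample sheet."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        for chrom, seq in truth.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    sizes = outdir / "chrom.sizes"
    with open(sizes, "w") as fh:
        for chrom, seq in truth.genome.items():
            fh.write(f"{chrom}\t{len(seq)}\n")
    rows = []
    for s in samples:
        bed = outdir / f"{s.sample_id}.bed"
        s.fragments[["chrom", "start", "end"]].to_csv(
            bed, sep="\t", header=False, index=False
        )
        rows.append({"sample_id": s.sample_id, "time_min": s.time_min, "fragments_path": str(bed)})
    sheet = outdir / "samples.tsv"
    pd.DataFrame(rows).to_csv(sheet, sep="\t", index=False)
    truth_tsv = outdir / "truth.tsv"
    truth.loci.to_csv(truth_tsv, sep="\t", index=False)
    return {
        "genome_fasta": str(fasta),
        "chrom_sizes": str(sizes),
        "sample_sheet": str(sheet),
        "truth": str(truth_tsv),
    }
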