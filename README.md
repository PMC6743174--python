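# qnuc — quantitative MNase-seq analysis

Micrococcal nuclease (MNase) digestion followed by sequencing is the standard
assay for mapping nucleosomes, but the number of mononucleosome fragments
recovered from a locus is **not** proportional to nucleosome occupancy: it
depends on how far the digestion has progressed. Accessible chromatin releases
its nucleosomes early; continued digestion then destroys the free nucleosome
core particles. A single-time-point experiment therefore conflates three
distinct chromatin properties, and common normalizations (total read count)
erase exactly the signal needed to separate them.

`qnuc` implements a quantitative treatment of the digestion reaction. Each
genomic locus *x* is modeled as a chain of two consecutive first-order
reactions, B → N → ∅ (chromatin-bound nucleosomes are released as free
mononucleosomes, which are then over-digested), giving the closed form

```
B(t) = C·O·exp(−k₁[E]t)
N(t) = C·O·k₁/(k₁−k₂)·(exp(−k₂[E]t) − exp(−k₁[E]t))
```

where `C` is the number of cells, `O` the nucleosome occupancy (fraction of
cells with a nucleosome at *x*), `k₁` the release rate constant (chromatin
accessibility), `k₂` the decay rate constant, and `d = [E]t` the digestion
level. `N(d)/C` — the *apparent occupancy* — rises from zero to a maximum at
`d* = ln(k₁/k₂)/(k₁−k₂)` and then decays with asymptotic log-slope `−k₂`.
Fitting this curve to spike-in-calibrated counts measured across a digestion
time course (1, 2, 5, 15, 40, 60 min by default) yields per-nucleosome
estimates of all three parameters, separating occupancy from accessibility.
Loci with `k₁ > 10` (released and destroyed almost immediately) are flagged
as *fragile complexes* — weakly protecting non-histone particles such as
transcription-factor or remodeler footprints — as opposed to typical
nucleosomes with `k₁ ≈ 1`.

The package provides:

* `qnuc.kinetics` — the closed-form model, the maximum condition, and the
  MACC accessibility score (negative fitted slope of counts vs log enzyme);
* `qnuc.fragments` — BED/BEDPE fragment I/O, 100–200 bp mononucleosome
  filtering, spike-in normalization (every sample rescaled so its exogenous
  spike-in fragment total equals 10,000), dyad and coverage tracks;
* `qnuc.calling` — nucleosome position calling (smoothed dyad density,
  greedy maxima, cluster weighted medians) and position-set matching;
* `qnuc.fitting` — per-locus nonlinear least squares for (O, k₁, k₂),
  fragile classification, time-of-maximum classes, occupancy binning;
* `qnuc.seqfeat` — A/T content and the fragment-length × A/T 2D occupancy
  summary that visualizes the A/T-biased progression of the digestion;
* `qnuc.simulate` — a generator of synthetic genomes, planted nucleosome
  maps with known (O, k₁, k₂), digestion time-course fragment sets and
  spike-ins, plus ground-truth recovery harnesses;
* a `qnuc` command line (`simulate`, `normalize`, `call`, `fit`, `plot2do`,
  `run`).

## Worked example

Simulate a 20 kb genome with one nucleosome per 200 bp and run the full
pipeline:

```sh
qnuc simulate --out sim --seed 7 --genome-length 20000
qnuc run --samples sim/samples.tsv --genome sim/genome.fa --out out
```

```
{
  "stages": {"load": "ok", "normalize": "ok", "call": "ok", "fit": "ok", "plot2do": "ok"},
  "n_calls": 100
}
```

All 100 planted nucleosomes are called. `out/scale_factors.tsv` shows each
sample rescaled by `10000 / spike-in count` (here ≈ 3.8–4.1, since ~2,500
spike-ins were drawn per sample), and `out/fits.tsv` holds the per-locus
parameter estimates:

```
locus  chrom  dyad_pos  O        k1        k2         rss      converged  fragile  time_class  occupancy_bin
nuc0   chr1   102       1632.34  1.15243   0.0405844  5779.08  True       False    3           2
nuc1   chr1   296       1019.19  0.533916  0.0229773  2788.34  True       False    3           1
nuc2   chr1   498       2855.23  1.01959   0.0410703  3681.83  True       False    3           6
```

`k₁ ≈ 1` and `k₂ ≈ 0.04` per minute are typical-nucleosome values; `O` is
reported in spike-in-normalized count units (the absolute cells-per-count
calibration C is experiment-specific; supply it to obtain occupancy as a
fraction of cells). `time_class` is the 1-based index of the time point with
the strongest signal, and `occupancy_bin` splits loci into nine equal-count
occupancy groups. The end-to-end recovery harness
(`qnuc.simulate.recovery_harness`) reports, for the default conditions,
100% of planted positions matched within 20 bp and median relative errors of
roughly 4% (O), 10% (k₁) and 5% (k₂).

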