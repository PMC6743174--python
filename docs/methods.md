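# Methods

## Kinetic model of MNase digestion

Digestion of chromatin by micrococcal nuclease is modeled per locus as two
consecutive first-order reactions, B → N → ∅: nucleosomes bound in chromatin
fibers (B) are released as free mononucleosomes (N) at rate `k₁[E]`, and free
mononucleosomes are destroyed by continued digestion at rate `k₂[E]`. With
`C` cells, occupancy `O` (fraction of cells carrying a nucleosome at the
locus), and initial conditions `B(0) = C·O`, `N(0) = 0`, the solutions are
the Bateman forms

    B(d) = C·O·e^(−k₁d)
    N(d) = C·O · k₁/(k₁−k₂) · (e^(−k₂d) − e^(−k₁d))

in the digestion level `d = [E]·t`. The enzyme concentration is constant
within an experiment and is absorbed into the rate constants, so `d` is
measured in minutes and `k₁`, `k₂` in min⁻¹. `N(d)/C` (apparent occupancy)
is unimodal: it peaks where release and decay balance,
`d* = ln(k₁/k₂)/(k₁−k₂)` (limit `1/k₁` when `k₁ = k₂`; `+∞` when `k₂ = 0`,
returned as an infinite sentinel, not an error), and its right tail decays
as `e^(−k₂d)`.

Model assumptions worth keeping in mind:

* loci are independent — neighboring nucleosomes share linkers in reality,
  so release events are correlated; the per-locus fit ignores this;
* both reactions are first order in enzyme and substrate, with rate
  constants fixed over the time course;
* di-/oligo-nucleosome intermediates are not modeled; the 100–200 bp
  fragment filter stands in for "intact mononucleosome".

### Numerical conventions

* **Degenerate rates.** When `|k₁−k₂| < ε·max(k₁,k₂)` with ε = 1e−8, the
  difference of exponentials loses all precision and the limiting form
  `O·k₁·d·e^(−k₁d)` is used instead. Continuity across the switch is tested
  to < 1e−6 relative.
* **Identifiability.** The apparent-occupancy curve is invariant under
  `(k₁,k₂,O) → (k₂,k₁,O·k₁/k₂)`, so the parameters are only identified up
  to this exchange. The package convention fixes `k₂` as the exponent of the
  right tail (the smaller rate): fitted triples are canonicalized to
  `k₂ ≤ k₁`, and the fitter's `k₂` start is read off the tail log-slope,
  which also breaks the symmetry during optimization.
* **MACC.** The accessibility score of the titration-slope method is
  `MACC = −a` from the ordinary least-squares fit `N = a·log(E) + b`
  (natural log; the sign is base-invariant). On the kinetic curve the
  instantaneous analogue `−dN/d(log d)` is negative before `d*` and positive
  after — every locus looks "inaccessible" early in a digestion series and
  "accessible" late, which is why a single fitted slope cannot characterize
  a locus.

## Spike-in calibration

Because total mononucleosome yield itself depends on the digestion level,
samples cannot be compared after total-count normalization. Each sample
instead receives a constant expected amount of exogenous calibrant
(yeast-derived mononucleosomal fragments on their own contig, recognized by
the `sc_` chromosome-name prefix by default), and all per-base tracks are
multiplied by `10,000 / (spike-in fragment count)` so every sample carries
exactly 10,000 normalized spike-ins. Only fragments with length in
[100, 200] bp (inclusive; the stated range does not specify inclusivity, so
both ends are kept) enter counting, for both genomes. Zero spike-ins is an
error — calibration is then impossible. Duplicate fragments are not
collapsed.

## Nucleosome calling

The published procedure is described only as "the median position of each
cluster of aligned nucleosomes"; the implementation here is a reconstruction
honoring that one stated property. Dyad (fragment-midpoint, floor for even
lengths) tracks from all digestion levels are pooled after normalization —
the union of levels sees both the quickly and the slowly released
nucleosomes — then per chromosome: (i) Gaussian smoothing, bandwidth 30 bp;
(ii) local maxima accepted greedily in decreasing height subject to a
147 bp minimum separation (one footprint); (iii) each raw dyad assigned to
the nearest accepted maximum within half a separation; (iv) the call
coordinate is the weighted median of the cluster's dyads, ties broken toward
the lower coordinate. Calls with support below 1% of the genome-wide mean
dyad weight per 147 bp window are dropped. All three parameters are
configurable; none is constrained by the published description beyond the
expectation that footprints tile ~147 of every ~200 bp (73.5% of the
genome). Matching between two call sets is greedy one-to-one
nearest-neighbor within a 20 bp tolerance, in increasing order of |shift|.

## Per-locus fitting

For each call, the per-locus signal at each time point is the mean
normalized coverage over a 147 bp window centered on the call (window width
configurable). The triple (O, k₁, k₂) minimizes unweighted squared error
between these counts and `scale·O·f_N(t)` under bounds
`k₁,k₂ ∈ [10⁻³, 10³]`, `O ≥ 0`; a Poisson-variance weighting option exists
but is off by default, matching the generic least-squares practice for this
assay. Initialization exploits the parameter separability: `k₂⁰` from the
log-slope of the last two positive counts, `O⁰` from the curve maximum,
`k₁⁰` from the first point via the small-d expansion `N ≈ O·k₁·t`. For
monotone-decaying courses (maximum at the first time point) a second start
in the saturated high-k₁ basin is always tried, and on non-convergence or
bound-pinning a 5×5 log-grid multistart over (k₁,k₂) runs with a 500
iteration cap; the lowest residual sum of squares wins. Loci with fewer than
three positive counts are flagged unfit, never raised.

Classification: *fragile* iff fitted `k₁ > 10` (strict, threshold
configurable); *time class* = 1-based index of the largest count (ties to
the earlier time; all-equal courses flagged); *occupancy bins* =
nine equal-count rank bins over fitted O (deterministic under ties).

`O` is reported in spike-in-normalized count units unless the caller
supplies the cells-per-count constant `C`; the absolute calibration is
experiment-specific and not part of the assay's outputs.

### A fundamental identifiability limit for large k₁

With the first sample at t = 1 min, a locus with `k₁ = 30` has
`e^(−k₁t) ≈ 10⁻¹³` at every observed point: release is complete before the
first measurement, and the curve is observationally identical for every
`k₁ ≳ 8` (O absorbs the amplitude factor `k₁/(k₁−k₂)`). The only remaining
evidence is the first-point deficit `A·e^(−k₁)`, which at realistic count
depths sits far below Poisson noise for `k₁ > 10`. Least squares then
absorbs first-point noise into a finite `k₁ ≈ ln(A/|ε|) ≈ 3–5` whenever
that noise is negative — about half the time — so *no* unbiased estimator
can reliably certify `k₁ > 10` from this design; the fitted `k₁` for truly
fragile loci is best read as a lower bound. Monte-Carlo confirms ~50%
sensitivity for the `k₁ > 10` label at peak expectation 1,000, while
occupancy and decay-rate recovery are unaffected (median relative errors
~2% and ~5% on the validation grid, ~14% for k₁ overall). A
significance-gated "report the saturated solution" rule could force the
label but would misclassify a comparable fraction of genuinely moderate
rates (k₁ ≈ 3, whose own first-point evidence is only ~1.8σ), so the
unmodified least-squares convention is kept.

## Synthetic data generator

The simulator emulates the study conditions end to end and serves as the
validation substrate:

* **Genome.** Bases i.i.d. within 200 bp blocks whose A/T probability is
  drawn from Normal(0.58, 0.10) truncated to [0.05, 0.95] — the fly-genome
  average with domain-scale heterogeneity; a homogeneous genome (sd 0) is
  available. Dyads are planted every 200 bp (the fly nucleosome repeat)
  with ±10 bp jitter, so footprints cover 73.5% of the genome.
* **Kinetics.** Per locus `O ~ U(0.2, 1)`, `k₁ ~ LogNormal(ln 1, 0.5)`,
  `k₂ ~ LogNormal(ln 0.05, 0.5)` — typical-nucleosome magnitudes with the
  decay roughly twentyfold slower than release. A fragile subpopulation
  (1% of loci) carries k₁ multiplied by 30. Optionally
  `k₁ ← k₁·exp(β·(AT−0.58))` couples release to footprint A/T content
  (β = 0 by default; β = 3 in the drift scenario, sized so the released
  population's mean A/T shifts by a few percentage points between the first
  and last time points, as observed in digestion series).
* **Fragments.** Per locus and time, counts ~ Poisson(depth · N(t)/C) with
  depth 1,000; centers scatter Normal(0, 10 bp) around the dyad; lengths
  Normal(mean, 10) with the mean falling linearly 165 → 140 bp across the
  six time points — a phenomenological stand-in for progressive footprint
  trimming (no quantitative law is established; the parameters are
  configurable). Lengths are emitted uncensored so the analysis-side
  100–200 bp filter does real work. Spike-ins: Poisson(2,500) per sample,
  uniform 140–160 bp, on a dedicated `sc_`-prefixed contig.
* **Determinism.** All randomness flows from one seed; equal seeds give
  byte-identical output bundles.

What the generator does **not** emulate: correlated release of neighbors,
oligonucleosome ladders, sequence-specific cleavage at base resolution,
mappability/duplication artifacts, or an A/T-coupled decay rate. Passing
recovery tests therefore demonstrate correctness of the inference given the
model, not robustness to every property of real chromatin.

## Validation harnesses and problem sizes

* Count-level grid: truths O ∈ {0.2, 0.5, 0.9} × k₁ ∈ {0.3, 1, 3, 30} ×
  k₂ ∈ {0.01, 0.05, 0.2}, 100 Poisson replicates per cell with the expected
  curve's maximum scaled to 1,000 counts — 3,600 fits, ~15 s.
* End-to-end harness: 100 kb genome (500 loci), full pipeline from
  fragments to fits, compared against the truth ledger; fitted O is
  rescaled by the known depth × spike-in factor before computing errors
  (a residual ~5% bias remains from the fragment-length/window overlap,
  `~L/147`, which shrinks as fragments shorten over the course).
* Noiseless mode fits the analytic expected counts directly, isolating
  fitter correctness from sampling and calling; recovery is exact to
  machine noise.
* A/T drift scenario: 600 kb genome with β = 3 — large enough that the
  extreme A/T bins hold tens of loci and the bin-share drift is not
  dominated by individual loci's rate draws.

## Known limitations

* The calling algorithm is a reconstruction; on strongly overlapping or
  fuzzy nucleosome populations its greedy separation rule will merge
  alternative positions into one call.
* Fitted `k₁` saturates (see above); comparisons of large rates should use
  the fragile/typical dichotomy, not the point values.
* `O` is relative unless an absolute cells-per-count calibration is
  supplied.
* Time classes are a discrete readout of `d*` against the sampled times;
  their genome-wide distribution depends on the rate distributions and is
  not a fixed property of the method.
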