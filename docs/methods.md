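# Methods

## Poisson partition model

Droplet generation distributes template molecules at random into droplets,
so the number of molecules per droplet is Poisson with mean λ. A droplet is
positive when it holds at least one molecule, giving the occupancy relation
`p = 1 − e^{−λ}` and the inversion `λ̂ = −ln(1 − k/n)` for `k` positive of
`n` accepted droplets. Concentration in copies/µl of the loaded reaction is
`λ̂ / V_d`.

Assumptions: uniform droplet volume `V_d` within a run; independent droplet
occupancy; perfect amplification of any occupied droplet (detection failures
appear only through the synthetic generator's partitioning parameter, below).
`k = n` (every droplet positive) has no finite estimate; it is flagged
`saturated` rather than clipped, since a saturated well calls for diluting
the sample, not for a number.

### Confidence intervals

The 95% interval is the exact Clopper–Pearson binomial interval on `p = k/n`
mapped through the monotone occupancy inversion. The choice is deliberate:
MRD samples live at `k` of 0–5, where Wald or even Wilson intervals on `p`
misbehave and exactness (guaranteed ≥ nominal coverage) is worth its
conservatism. Two consequences are documented rather than hidden:

- Exact intervals over-cover at very small expected counts. At 0.1 copies/µl
  in a single 20,000-droplet well the exact coverage of the transformed
  interval is 99.2% (computable by direct binomial summation, no simulation
  needed); merging 4 wells brings it to 96.9%, and at ≥1 copies/µl merged
  coverage sits at 95–96%.
- Calibration is therefore validated on merged replicate groups of 4 wells,
  500 runs at each of 0.1, 1, 10 and 100 copies/µl, with the 93–97% coverage
  band asserted on the pool of all 2,000 runs: per-concentration coverage of
  an exact interval at near-zero counts is intrinsically above the band, and
  a per-concentration estimate from 500 runs has a standard error (~0.8%)
  comparable to the band margin. Bias is asserted per concentration (within
  2% at ≥1 copies/µl; the second-order bias of the log inversion is ≈ 1/(2k)
  relative, i.e. ~0.7% at the 68 expected positives of the 1 copies/µl
  condition).

### QC and merging

Wells with fewer than 9,000 accepted droplets are rejected (inclusive
boundary: exactly 9,000 passes). Replicates merge by pooling counts,
`(Σk, Σn)`, before inversion — definitionally equivalent to one large well,
strictly lowering both the variance (partition-count weighting) and the
inversion bias (∝ 1/n) relative to averaging per-well estimates.

### Threshold calling

Where per-droplet amplitudes are available, the positive threshold is set at
`median + k_sigma × σ_MAD` of the background mode (`σ_MAD` = 1.4826 × MAD,
default `k_sigma` = 5), with one refinement pass re-estimating the
background on sub-threshold droplets so a heavy positive cluster cannot
drag the first-pass median. Manual threshold curation is the field's
practice but is not reproducible; the automated rule is, and the threshold
used is returned for audit. Fewer than 100 droplets is refused — no
meaningful background estimate exists.

## Classification rules

POS / PNQ / NEG calls follow EuroMRD-style digital-PCR conventions,
deliberately parameterized because consortium thresholds are evolving:

| parameter | default | meaning |
|---|---|---|
| `min_positive_droplets_detected` | 1 | merged positives for "detected" |
| `min_positive_droplets_quantifiable` | 3 | merged positives for "quantifiable" (the usual ≥3-partition convention) |
| `min_control_copies` | 1.0 copies/µl | ABL1 floor for an evaluable sample (~17 positive droplets in a 20k-droplet well) |
| `max_background_positive` | 0 | total positives allowed across background wells for a valid run |

The rule is monotone in the merged positive count and depends only on
pooled counts, never on how replicates were grouped. A sample with an
inadequate control gene is PNQ when detected and `NEG_not_evaluable` when
not — reporting plain NEG there would be false reassurance. Background
subtraction is not performed; setting `max_background_positive` above 0
triggers a warning that the droplet thresholds should be re-derived.

A run is interpretable only when NTC, healthy-donor and Ph-negative wells
show no more than `max_background_positive` positives in total and every
plasmid positive-control well amplifies; a plate without an NTC is a
configuration error rather than an invalid run.

## LOD, specificity, reproducibility

A replicate scores positive at the detection floor (≥1 positive droplet by
default). The *maximum sensitivity* of a dilution series is the most dilute
point such that it and every less-dilute point keep ≥75% of replicates
positive — the cumulative reading ("up to this level"), so an isolated
recovery below a failing point does not count. The bundled validation
design escalates replicates as 2, 6, 8, 12, 14 across dilutions 10⁻⁴ to
10⁻⁶ and lands at 10⁻⁵ (6/8 positive).

Specificity counts background replicates with any positive droplet.
Reproducibility of duplicate concentrations uses `|log₁₀(a) − log₁₀(b)| < 1`
("within one logarithm") rather than same-integer-decade, which would call
9.9 vs 10.1 irreproducible; (0, 0) pairs are reproducible and (0, x>0)
pairs are reported as a separate discordant-detection category.

No probit/logistic LOD₅₀/LOD₉₅ curve is fitted: the rule-based LOD is the
analysis this assay family actually uses.

## Method comparison

The 3×3 cross-tab is ordered POS, PNQ, NEG with ddPCR on rows. Overall
concordance is the diagonal fraction; quantifiability recovery is the
fraction of reference-PNQ-or-NEG samples that ddPCR quantified. The
significance test for "more samples quantifiable" is an exact McNemar test
on quantifiable-vs-not — the calls are paired per sample, so a pooled
two-proportion test would be wrong as the primary analysis (one is provided
as a secondary check, and both reject far below 10⁻⁴ on the bundled table,
where the discordant counts are b = 36, c = 0 and p = 2·2⁻³⁶ ≈ 2.9×10⁻¹¹).

Pearson correlation of diagnostic values pairs each transcript separately,
so a dual-transcript sample contributes two pairs (11 pairs from 10
samples in the bundled table, r = 0.874); aggregating the two transcripts
by summation is available but collapses the correlation (r ≈ 0.58) by
averaging a near-zero p190 with a high p210 value, which is why
per-transcript pairing is the default. Percentages are reported as exact
floats plus round-half-away-from-zero values at one decimal and at integer
precision, because clinical reports mix both conventions (13/24 = 54.1666…%
appears as both 54.1% and 54.2% depending on rounding).

The diagnostic table's ddPCR values were measured on 1:5 prediluted cDNA
while the reference values were not; the dilution factor is recorded on
each measurement but never multiplied into the ratio (it cancels when
target and control come from the same dilution), and no rescaling of the
bundled values is attempted.

## Synthetic data generator

What it emulates — and its defaults:

| parameter | default | rationale |
|---|---|---|
| `n_droplets_mean` / `n_droplets_sd` | 20,000 / 1,500 | nominal droplet yield; truncated rounded Gaussian (only a lower QC bound is specified in practice) |
| `droplet_volume` | 8.5×10⁻⁴ µl (0.85 nL) | QX200 nominal partition volume |
| `partitioned_fraction` | 0.8 | fraction of the reaction's molecules ending up in read droplets; droplet generation and reading never capture the whole reaction |
| `rain_rate` | 0 | independent per-droplet false-positive flip; the validated assay showed zero background across 96 control replicates |
| amplitude clusters | 1000±50 / 8000±300 a.u. | separable by construction (config enforces a ≥6σ gap) |

Bulk wells draw `k ~ Binomial(n, 1 − e^{−C·V_d})` (occupancy, plus rain).
LOD-scale wells are built molecule-first: molecules present ~ Poisson(m),
thinned by `partitioned_fraction`, then scattered into droplets with
collisions allowed — so a replicate's detection probability at full
partitioning is exactly `1 − e^{−m}`, the property the LOD analysis assumes.

The cohort generator assigns each sample a true MRD level — high
(ratio 10⁻³–10⁻¹·⁵), low-quantifiable (10⁻⁴–10⁻³), trace (10⁻⁵–10⁻⁴) or
zero, with a default mix of 0.11/0.25/0.37/0.27 shaped like a follow-up
population dominated by grey-zone samples — an ABL1 concentration of
10¹·⁵–10²·⁵ copies/µl, and a comparator Q-RT-PCR call from a threshold
model: quantifiable above a ratio of 10⁻⁴, otherwise detected (PNQ) with
probability `1 − e^{−c·copies}` against an assumed 10⁵ control-copy input
(`c` = 0.5 per copy). This comparator is an artifact construct for
exercising the paired-analysis code; no generative model of a real
Q-RT-PCR instrument is claimed.

What the generator does *not* emulate: fluorescence drift and rain
continua between clusters, droplet coalescence, chip failures, pipetting
error across the dilution series, or inhibitor effects. Passing tests
therefore demonstrate the correctness and calibration of the *analysis*
under the stated stochastic model, not the wet-lab performance of any
instrument.

Determinism: every simulation entry point takes an explicit seed (or an
explicit `numpy` generator); identical seeds give bit-identical outputs and
there is no global random state.

## Bundled dilution-point ambiguity

The validation protocol lists four template copy numbers (5, 2, 1, 0.5)
against five dilution labels (10⁻⁴, 5×10⁻⁵, 10⁻⁵, 5×10⁻⁶, 10⁻⁶). The
package stores both labelings — the printed copy list and a
log-scale-consistent per-label mapping anchored at 10 copies for 10⁻⁴ —
and the simulation API takes explicit copy numbers, so no mapping is ever
guessed on the user's behalf. Similarly, the validation series reached 2/12
positives at 5×10⁻⁶ and 2/14 at 10⁻⁶; what "reached sensitivity" means
below the ≥75% level is left as a user interpretation: the package reports
the full positivity table and the ≥75% maximum-sensitivity label.

## Problem sizes

Defaults throughout the tests and the acceptance script: 500 runs × 4
merged wells per concentration for calibration (2,000 intervals), 2,000
replicates per point for LOD detection probabilities, 10,000 replicates for
the single-molecule sanity check, 96 background replicates (32 NTC + 4×16
donor pools) for specificity, and cohorts of 20–88 samples × 3 replicate
wells per gene. These sizes put Monte-Carlo standard errors well inside the
asserted bands while keeping a full run in seconds on one core.

## Known limitations

- `V_d` is a global constant per run; no per-well volumetric correction.
- The classifier handles fusion-transcript targets only (p190/p210 vs
  ABL1), not IG/TR rearrangement MRD.
- Exact intervals are conservative at near-zero counts (by design; see
  above).
- The comparator model and cohort mix are synthetic constructs; concordance
  statistics on simulated cohorts characterize the pipeline, not any
  clinical population.
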