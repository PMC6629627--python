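# Methods

`optogate` characterizes light-controlled bacterial gene-expression systems from
flow-cytometry data. This note records the models, the assumptions behind the
synthetic-data generators, and the numerical and design choices a maintainer
would otherwise have to reverse-engineer.

## Measurement model and event pipeline

A cytometry sample is a table of events (forward scatter, side scatter, one or
more fluorescence channels in instrument arbitrary units). The pipeline reduces
it to one calibrated reporter number per sample:

1. **Density gating.** Events are ranked by a Gaussian kernel density estimate
   on linear (FSC, SSC) with Scott's bandwidth rule, and exactly
   `round(fraction x n)` of the densest events are kept (default fraction 0.5).
   Rounding is half-away-from-zero with a minimum of one event; ties at the
   retention boundary break by ascending event index, so the count contract is
   exact and the operation deterministic. Gating discards debris, doublets and
   dead cells that sit outside the main cell cluster.
2. **Bead calibration.** A calibration-bead sample with several subpopulations
   of known fluorophore-equivalent values (MEFL for fluorescein-channel work,
   MEAP for allophycocyanin) is measured alongside the cells. Peaks are located
   as modes of a kernel density estimate of log10(channel) (bandwidth factor
   0.05, modes polished off the evaluation grid with a bounded scalar
   optimizer), matched to the assigned values in increasing order, and a
   straight line is least-squares fitted in log10-log10 space. The mapping must
   be strictly increasing (slope > 0). A top peak within 1% of a supplied
   instrument maximum is treated as saturated and excluded. Calibration is a
   one-way state transition on the event table; calibrating twice is an error.
3. **Summary statistic.** Cell fluorescence of a sample is the median of the
   gated, calibrated events (even counts: mean of the two middle values).
4. **Autofluorescence subtraction.** Reporter fluorescence is sample minus the
   same-day reporter-free control's cell fluorescence. The result may be
   negative; negatives are resolved by the detection rule rather than floored.
5. **Detection.** Day replicates (n >= 2, typically 3) are tested with a
   one-sided one-sample t-test against zero; samples failing p < 0.05 are
   reported "not detected". When the replicate sd is exactly zero the t
   statistic is undefined and the distribution limit is used: p = 0 for a
   positive mean, p = 1 otherwise, flagged `degenerate_sd`.

Comparisons between conditions use Welch's unequal-variances t-test
(Welch-Satterthwaite degrees of freedom, two-sided). Fold changes default to
the `by_day` pairing — per-day ratios, then mean ± sd — because each condition
is run once per experimental day, which naturally matches numerator and
denominator replicates; `ratio_of_means` with first-order error propagation is
available as an alternative.

Only the plain-text event CSV is ingested (one row per event, columns
`event_id, fsc, ssc, fl1..fln`, with sample metadata in `#`-prefixed header
lines). Binary FCS containers are out of scope for this package; convert
upstream.

## Steady-state transfer function

Output vs input dose is modeled as a Hill function

    y(x) = y0 + dy * x^n / (x^n + K^n)

with basal output `y0` (MEFL), span `dy` (MEFL), Hill coefficient `n`, and
half-maximum dose `K` (light intensity in umol m^-2 s^-1, or inducer
concentration). Fitting pools every replicate point and minimizes
`sum (log y_i - log yhat_i)^2` by Levenberg-Marquardt (lmfit), which balances
residuals across an output range spanning two decades. Choices:

* Parameters are optimized as their logarithms, enforcing positivity without
  hard bounds; estimates and delta-method standard errors are reported on the
  natural scale.
* Initial guesses are scale-free: `y0 = min y`, `dy = max y - min y`, `K` at
  the geometric median of the positive doses, `n = 1`.
* `x = 0` points are legitimate (the model value there is exactly `y0`).
* Residuals are unweighted. Nonpositive outputs are an error, never silently
  floored. Non-convergence is flagged on the result, not raised.
* Convergence: `ftol = xtol = 1e-12`, at most 1000 function evaluations.

Because the objective depends on outputs only through `log y`, scaling all
outputs by a constant scales `y0` and `dy` and leaves `n` and `K` untouched —
a property the tests exploit, and the reason a wrong calibration gain corrupts
the output scale but not the fitted shape parameters.

## Delayed kinetic cascade

The response to an instantaneous light switch is a linear three-stage cascade
with a delay:

    dp/dt = kp (c - p),   dg/dt = kg (p(t - tau) - g),   dG/dt = kd (g - G)

`p` is the reporter production rate, `g` immature reporter, `G` the mature,
observed reporter; `c` is the drive — the steady-state output the current
light condition sustains, in the same MEFL-equivalent units, so that at steady
state `c = p = g = G`. `tau` (min) is the delay before a production change
takes effect; `kd` is the maturation constant (alias `kG`).

**Closed form.** For a step `c0 -> c1` at t = 0 from steady state, the delay
history is the constant `c0`, so the system is piecewise analytic: `g` and `G`
remain at `c0` until `t = tau`, after which each deviation is a
sum of exponentials whose weights are the partial-fraction coefficients
`w_i = prod_{j != i} k_j / (k_j - k_i)`. Rates closer than 1e-7 relative are
grouped and evaluated with the confluent (repeated-root) formulas — e.g. the
Erlang forms `(1 + ks) e^{-ks}` and `(1 + ks + (ks)^2/2) e^{-ks}` — which
avoids the catastrophic cancellation of the distinct-rate weights near
coincidence; the switch-over error is O(delta^2) and far below the 1e-6
oracle tolerance.

**Numeric cross-check.** `simulate_step` integrates the same system with
LSODA (`rtol 1e-10`), splitting at the forcing kink `t = tau`; closed form and
integrator agree to better than 1e-6 relative over 100 random parameter draws
(rates 0.005-0.2 /min, delay 0-30 min, horizon 600 min).

**Identifiability.** The relaxation profile of `G` depends only on the
*multiset* of the three rates (stage convolution commutes), so individual rate
constants are exchangeable given `G` alone; the delay `tau` and the half-time
are identifiable. Fits therefore canonicalize the maturation pair as
`kg <= kd` and set an `exchange_symmetric` flag rather than pretending
uniqueness; recovery checks score the half-time.

**Fitting.** `fit_kinetics` uses the same pooled log-residual
Levenberg-Marquardt machinery, evaluating the model with the closed form
exactly at the observed times (no interpolation). Boundary conditions come
from the Hill fit: step ON is `c0 = y0`, drive `y0 + dy`; step OFF the
reverse. Rates are log-parameterized; `tau >= 0` via `log(tau + 1e-6 min)`.
The initial guess is derived from the observed midpoint-crossing time
(`k ~ 3 ln 2 / t50`, slightly split across the three stages to break the
exchange degeneracy, `tau ~ 0.1 t50`).

**Half-times.** `t_half` is the first time `G` crosses `(c0 + c1)/2`, found
by bracketed root-finding on the closed form (`xtol 1e-6` min). For fixed
rates the linear relaxation is direction-symmetric — ON and OFF half-times of
the *same* parameter set coincide; observed ON/OFF asymmetry in real systems
is carried by different fitted rates per direction.

## Synthetic-data generators

The generators define the study conditions under which everything is tested:

* **Events**: reporter fluorescence lognormal with stated median and CV
  (default CV 0.3 — an assumption typical of bacterial cytometry
  distributions, not a measured fact), plus additive lognormal
  autofluorescence; scatter is one elliptical Gaussian cluster (relative
  spread 0.12) plus an optional uniform background fraction standing in for
  debris. The lognormal is parameterized so the median is exact:
  `mu = ln(median)`, `sigma = sqrt(ln(1 + cv^2))`.
* **Beads**: each peak of true value v sits at channel
  `offset + gain * v^exponent` with lognormal spread (default peak CV 0.05,
  six peaks spanning ~10^2.9-10^5.1, gain 0.05).
* **Dose-response**: sample medians exactly on the Hill curve times a
  unit-median lognormal day factor (default 3 replicates, 10% CV, 8 doses
  log-spaced 0.1-50 umol m^-2 s^-1) — mean ± sd over three days is how such
  experiments are reported, and multiplicative noise respects the
  decades-spanning range.
* **Step timecourses**: noise-free medians are the closed-form `G(t)` with
  `p(0) = g(0) = G(0) = c_initial` and drive `c_final`; same multiplicative
  replicate noise (default 5% CV, 25 times over 10-600 min).

All generators take explicit integer seeds (no global state) and are
bit-reproducible. What they deliberately do **not** emulate: instrument-binary
quirks, spillover/compensation, doublet physics beyond the uniform background,
cell-cycle or growth-dilution effects, and non-lognormal heavy tails. Passing
recovery tests therefore demonstrates correctness of the estimation machinery
under the stated noise model, not robustness to every artifact of real
cytometry data.

Problem sizes used by the test suite and the acceptance script — 1,500-2,000
events per synthetic sample (50,000-100,000 for convergence checks), 50
dose-response datasets, 25 step datasets per direction — are the package's
default study sizes; medians over seeded datasets make the recovery statistics
stable at these sizes.

## Early-codon recoding and 5' window folding

Poor translation of heterologous ORFs often traces to mRNA secondary structure
between the ribosome binding site and the first codons. The implemented
heuristic synonymously recodes the first 15 codons to reduce GC and increase
AU content with A preferred over U, ignoring codon-usage frequency. The
preference statement is formalized as a total order per codon family: choose
the synonym minimizing the tuple

    (GC count ascending, A count descending, U count descending, alphabetic)

which makes the choice deterministic; whether A-over-U applies only at ties or
globally is one admissible reading of the informal rule, and this tuple
encodes the tie-only reading. The bacterial genetic code (NCBI table 11) is
used; the start codon is never altered even when synonyms exist (GTG/TTG
initiation identity is functional), the final stop is untouched, and
synonymous substitution can never introduce a stop. Internal in-frame stops
and non-ACGT characters are errors.

Scoring folds the transcript window from the transcription start site (+1)
through ORF nucleotide 90 (shorter ORFs truncate). The default backend is a
built-in simplified nested-pairing minimum-energy model — pair energies
GC -3, AU -2, GU -1 kcal/mol, minimum hairpin loop 3 nt, no pseudoknots,
solved by interval dynamic programming and verified against exhaustive
structure enumeration on short windows. It ranks pairing potential; it is not
a thermodynamic nearest-neighbor model, and its absolute energies are not
comparable to ViennaRNA/NUPACK values. A ViennaRNA-bindings backend is
available where installed; any `seq -> kcal/mol` callable plugs in. Reducing
GC content usually, but not provably always, raises (weakens) the window
energy; the tests assert the >= 90% empirical rate on GC-rich ORFs rather
than per-sequence monotonicity.

## Pipeline orchestration

A YAML manifest binds event files or generator specs to conditions. Every
non-control sample must resolve to exactly one same-day autofluorescence
control and one bead calibration; validation reports all dangling linkages
before any computation. Reports embed the manifest SHA-256 (truncated), the
global seed and the package version. The `simulate`, `fit-transfer`,
`fit-kinetics` and `recode` CLI subcommands are thin wrappers over the library
and exchange tidy CSVs, so partial pipelines compose in a shell.

## Known limitations

* Individual kinetic rate constants are reported only up to the exchange
  symmetry; experiments observing `p` or `g` directly would be needed to
  break it.
* The kinetic drive is implemented at the saturating endpoints
  (`c = y0` or `y0 + dy`); mapping intermediate green intensities through the
  fitted Hill curve is an extension point, and arbitrary time-varying light
  programs are out of scope.
* Bead-peak finding assumes well-separated, roughly lognormal peaks; heavily
  overlapping or saturated bead sets need the `saturation_limit` argument or
  manual peak curation.
* The detection rule inherits the t-test's normality assumption on day
  replicates (n is typically 3).
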