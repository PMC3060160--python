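# Methods

## The model

A binaural neuron's *tone delay function* — mean firing rate as a
function of the interaural phase difference (IPD) φ of a pure tone — is
modelled as a cyclic Gaussian

    r(φ) = r0 + A · Σ_{k=-K}^{K} exp(−(φ − φ_best + k)² / (2 w²)),

with baseline r0 (Hz), amplitude A (Hz), width w (cycles) and best IPD
φ_best (cycles).  The wrap sum makes the curve exactly 1-periodic; K = 5
keeps the truncation error below 10⁻⁶ Hz for w ≤ 0.5 cycles (validated
against a K = 50 oracle in the tests).

Across tone frequencies f the best IPD moves linearly,

    φ_best(f) = CP + CD·f,

defining the characteristic phase CP (cycles) and characteristic delay CD
(ms).  Because CD trades against the neuron's best frequency, analyses
use the frequency-scaled delay CD·BF (cycles) alongside CD.  A stimulus
at ITD τ and frequency f drives the cell at the mean rate
r(fτ − (CP + CD·f)).

Trial-to-trial variability of the rate follows a logarithmic
variance–mean law,

    σ²(r̄) = noise_scale · v1 · ln(1 + v2 · r̄),

and the conditional rate distribution is a Gaussian with this variance,
truncated at r = 0 and renormalized.  Expanding the logarithm shows that
with v1·v2 = 1/T (T the stimulus duration) the spike-count variance
equals the count mean at low rates — Poisson-consistent — while at high
rates the law saturates and counts become strongly sub-Poisson.

The stimulus side is summarized by a head geometry: interaural angle θ
maps to ITD through the path-difference (chord plus arc) form

    τ(θ) = (d / 2c) · (θ + sin θ),

whose derivative at the midline is exactly twice the lateral one.
Uniformly distributed source angles then induce an ITD prior on the
physiological range [−τmax, τmax], τmax = (d/2c)(π/2 + 1), that piles up
mass at the lateral edges.

Single-cell mutual information between ITD and rate, marginalized over a
set of tone frequencies with weights w_f (uniform by default, an f^−α
power law optionally), is evaluated by quadrature:

    p(r|τ) = Σ_f w_f · N_clip(r; r̄(f,τ), σ²(r̄)),
    I(τ; r) = Σ_τ p(τ) Σ_r p(r|τ) log2 [ p(r|τ) / p(r) ].

Evaluating I over a grid of (CP, CD·BF) with a fixed band-average tuning
shape yields the MI landscape.  Its two diagnostic properties, both
asserted in tests, are mirror symmetry — the two hemispheres are
interchangeable, so I(CP, CD·BF) = I(−CP, −CD·BF) — and high-MI ridges of
slope −1, i.e. lines of constant best phase CP + CD·BF.

Two readouts are implemented on simulated population rate tensors
(cells × ITD × frequency × trial):

* **Labelled line.**  ITDs are split into M equal bins; one linear
  soft-margin SVM per bin pair (M(M−1)/2 classifiers, features
  standardized by training statistics, C = 1) votes on each pattern;
  majority wins, ties broken by summed signed decision values then lower
  bin index.  Acuity is the RMS of (predicted bin center − true τ).
* **Two-channel difference.**  The mean rate of a mirrored population
  (CP → −CP, CD → −CD; the other hemisphere) is subtracted from the mean
  rate of the original one, and a single least-squares line pooled over
  frequencies maps the difference signal to an ITD estimate.  Acuity is
  reported as RMS and maximal error, resolved by frequency and by ITD.

## Default parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| inter-ear distance d | 0.032 | m | gives τmax ≈ 120 µs, the gerbil's physiological ITD range |
| sound speed c | 343 | m/s | airborne sound at room temperature |
| stimulus duration T | 0.2 | s | typical pure-tone duration in awake/anesthetized gerbil recordings |
| variance law v1 | 5 | Hz² | see below |
| variance law v2 | 1 | 1/Hz | see below |
| tuning baseline r0 | 10 | Hz | spontaneous/driven offset typical of DNLL units |
| tuning amplitude A | 50 | Hz | peak driven rates of tens of Hz |
| tuning width w | 0.125 | cycles | see below |
| best-phase cluster mean | 0.2 | cycles | location of the population's constant-best-phase line |
| best-phase cluster spread | 0.1 | cycles | scatter off that line |
| MI grids | 201 ITD × 200 rate bins | — | doubling either changes I by < 0.01 bits (convergence flag available) |
| landscape band | 800–1000 | Hz | best-sampled BF band; 5 uniform tone frequencies |

v1, v2 and w deserve comment because the published fit values are not
available in the text this package was built from.  They were fixed once,
jointly, by three constraints: (i) v1·v2 = 1/T so that low-rate counts
are Poisson-consistent; (ii) strong saturation of the variance at high
rates (count Fano factor ≪ 1 at the peak rate, matching the noise
suppression described for the lateral lemniscus); and (iii) the resulting
MI landscape must show the qualitative structure reported for this
system — slope −1 stripes with the best phase clustering near 0.15–0.2
cycles, a max-MI CP that decreases as the head grows, and stripes that
thin and move toward smaller CP as noise grows.  With a weakly saturating
law (e.g. v2 ≈ 0.1 /Hz) the noise trend reverses direction; this
sensitivity is a genuine property of the model, not a numerical artifact,
and is why the calibration is pinned to the reported regime.

The duration sweep emulates truncated observation windows by rescaling
the variance law (v1 → v1·T/T0), preserving Poisson consistency in the
shorter window, rather than refitting onset responses — onset data are
not modelled.  Clipping means the sampled rate distribution is *not*
Poisson at count means near zero even though the variance law is; only
the second moment is matched there.

## Circular–linear regression

The slope m of φ = c + m·x is found by maximizing the mean resultant
length of the circular residuals, R_V(m) = |⟨exp(2πi(φ_j − m x_j))⟩|,
which is independent of the offset.  The search is a coarse grid (10 µs
steps over ±3 ms for phase-frequency curves) followed by bounded local
refinement; a maximizer at the search edge is flagged, since phase data
alias at slopes beyond the reciprocal frequency spacing.  The offset is
the circular mean of the residuals at the optimal slope — the offset that
maximizes the overlap between the data cloud and the line on the
cylinder.  Population CP–CD correlations use the embedding circular–
linear correlation coefficient with its χ²₂ asymptotic p-value.

The cyclic-Gaussian fit itself is multi-start nonlinear least squares
(8 equally spaced best-IPD initializations, analytic Jacobian, bounds
w ∈ [0.02, 1] cycles, r0, A ≥ 0), with ties broken by residual then by
the lower wrapped best IPD.  Cells whose fitted amplitude is
indistinguishable from zero are flagged flat — their best IPD is
unconstrained — and left to downstream code to handle, not dropped.

## The synthetic-data generator

No recorded dataset ships with the package, so the generator emulates the
population statistics the analyses need: best frequencies uniform within
the band; a best phase BP drawn per cell from N(0.2, 0.1) cycles; CP
drawn from a positively biased wrapped mixture (half uniform over the
cycle, half wrapped-normal at 0.25 ± 0.15); and the scaled delay set to
CD·BF = BP − CP plus jitter.  This construction reproduces, by design,
the broad positively biased CP marginal, the CD distribution peaked at
zero, the negative CP–CD correlation, and the clustering along a
constant-best-phase line.  The emulated experiment presents 5 tone
frequencies log-spaced over half an octave around BF, an ITD grid
spanning 1.3 stimulus cycles per frequency (14 steps), and ≥ 3
repetitions, drawing integer spike counts through the noise model.

What passing tests on these data do **not** show: the generator has no
across-frequency shape changes (one cyclic Gaussian per cell), no
correlated noise between neurons or trials, no adaptation or onset
dynamics, no tonotopic CD gradient unless constructed explicitly, and its
marginals are idealized forms rather than empirical histograms.  Results
that depend on those features of real data are outside what this package
can certify.

## Numerical choices

* Phases live in cycles and wrap to (−0.5, 0.5] with the *right* edge
  kept, so an antiphasic cell has CP = +0.5, never −0.5.
* The ITD prior is bin-integrated (each bin receives the angular measure
  of its preimage), which normalizes exactly and absorbs the Jacobian
  singularity at ±τmax; weights are symmetrized to cancel root-finding
  round-off.
* Truncated-Gaussian sampling uses inverse-CDF transforms (no rejection),
  so runs are reproducible under a seed and vectorize cleanly.  The
  alternative convention of clipping samples to a point mass at zero is
  available (`clip="point_mass"`); the density-based analyses use the
  renormalized form, as the density definition of the noise model
  requires unit mass on r ≥ 0.
* MI quadratures renormalize the conditional on its rate grid
  ([0, peak + 6σ]); MI is clamped at ≥ 0 against round-off.
* The landscape's (CP, CD·BF) grids are symmetric about the origin so the
  mirror symmetry holds to machine precision, and landscape cells reuse
  one precomputed prior and rate grid.
* All stochastic code takes explicit seeds (`numpy.random.default_rng`);
  identical seeds give identical populations, experiments, tensors and
  classifier ensembles.

## Study sizes used in the test suite

Test-suite simulations use populations of 8–100 cells, 21–41 ITD points,
5 tone frequencies and 3–12 trials per condition; the sweep analyses use
a positive-branch CP grid at 0.005-cycle resolution with 101 ITD × 120
rate quadrature bins; the Monte-Carlo cross-checks use 2·10⁵–10⁶ draws.
These sizes make every property deterministic to well inside its asserted
tolerance while keeping the suite fast.  The inter-ear-distance trend is
asserted over d = 32, 60, 100 mm: beyond that the landscape flattens
(max − min ≲ 0.2 bits) and the argmax location ceases to be a stable
summary statistic, so larger heads are supported by the sweep machinery
but not asserted as a monotone trend.

## Known limitations

* CP/CD estimation aliases for |CD| beyond the reciprocal frequency
  spacing; the ±3 ms search window covers the physiological range but
  true delays outside it would fold in (edge hits are flagged).
* The two shuffle controls permute parameters across cells; they do not
  model uncertainty in the per-cell estimates themselves (that is the
  bootstrap's job).
* The difference decoder is frequency-blind by construction; per-frequency
  fits are available for diagnostics only.
* The classifier's absolute acuity depends on bin count and training-set
  size; only comparisons at matched settings are meaningful.
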