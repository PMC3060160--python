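# itdcode

Statistical modelling of how populations of auditory brainstem neurons
encode interaural time differences (ITDs) independently of stimulus
frequency.

Low-frequency sound is localized from the microsecond arrival-time
disparity between the two ears.  Binaural neurons in the superior olivary
complex and the dorsal nucleus of the lateral lemniscus (DNLL) are tuned
to the interaural *phase* difference (IPD), so their firing changes not
only with ITD but also with tone frequency — which raises the question of
how downstream circuits read out ITD in a frequency-invariant way.  This
package implements the full analysis chain for that question, aimed at
computational and systems neuroscientists:

* **Tuning model** — tone delay functions (rate vs IPD) fitted by a cyclic
  Gaussian `r(φ) = r0 + A Σk exp(−(φ − φbest + k)²/2w²)`.
* **Cell characterization** — the best IPD moves linearly with frequency,
  `φbest(f) = CP + CD·f`; characteristic phase CP and characteristic delay
  CD are estimated by circular–linear regression (slope maximizes the mean
  resultant length `R_V` of the circular residuals, the offset maximizes
  the data–model overlap on the cylinder).
* **Acoustics** — the interaural angle→ITD mapping
  `τ(θ) = (d/2c)(θ + sin θ)` and the ITD prior induced by uniformly
  distributed source angles (edge-heavy within the physiological range
  ±τmax).
* **Noise model** — trial-to-trial rate variance follows a logarithmic law
  `σ²(r̄) = v1 ln(1 + v2 r̄)` (Poisson-like at low rates, strongly
  sub-Poisson at high rates); conditional rate distributions are Gaussians
  clipped at zero.
* **Information theory** — single-cell mutual information
  `I(τ; r) = Στ p(τ) Σr p(r|τ) log2[p(r|τ)/p(r)]`, marginalized over tone
  frequency, mapped as a landscape over the (CP, CD·BF) plane, with
  parameter sweeps (head size, stimulus duration, noise) and shuffle
  controls.
* **Population decoders** — a labelled-line readout (one-vs-one linear
  SVMs over ITD bins with majority vote) and a two-channel readout (the
  hemispheric mean-rate difference `D(τ)` inverted by a least-squares
  line `τ̂ = gain·D + intercept`).
* **Synthetic data** — a generator for virtual DNLL populations with the
  measured statistical structure (CPs spread over the cycle with positive
  bias, CDs peaked at zero, negative CP–CD correlation from clustering
  along a constant-best-phase line) and an emulated recording protocol
  producing spike-count tables.

## Worked example

```python
import numpy as np
import itdcode as it

geom = it.HeadGeometry()                      # gerbil: tau_max ~ 120 us
noise = it.RateNoiseModel()                   # log variance-mean law, T = 0.2 s
cells = it.generate_population(it.PopulationGeneratorConfig(n_cells=100, seed=1))

# single-cell mutual information of the first generated neuron
freqs = np.linspace(800, 1000, 5)
mi = it.mutual_information(cells[0], noise, geom, freqs)
print(f"cell 0: CP={cells[0].cp:+.3f} cyc, CD={cells[0].cd:+.3f} ms, "
      f"MI={mi:.3f} bits")

# bilateral difference code: train and test the linear ITD estimator
itds = np.linspace(-geom.tau_max, geom.tau_max, 41)
mirrored = it.mirror_population(cells)
resp = it.simulate_population(cells, noise, itds, freqs, n_trials=10, seed=2)
resp_m = it.simulate_population(mirrored, noise, itds, freqs, n_trials=10, seed=3)
decoder = it.fit_difference_decoder(it.bilateral_difference_signal(resp, resp_m), itds)
test = it.bilateral_difference_signal(
    it.simulate_population(cells, noise, itds, freqs, 10, seed=4),
    it.simulate_population(mirrored, noise, itds, freqs, 10, seed=5),
)
err = it.difference_decoder_error(decoder, test, itds)
print(f"difference code: R^2={decoder.r_squared:.4f}, "
      f"RMS error={err.rms_us:.1f} us, per-frequency RMS="
      f"{np.array2string(err.rms_by_freq_us, precision=1)}")

# labelled-line classifier on the same population
train = it.simulate_population(cells, noise, itds, freqs, 6, seed=6)
ens = it.train_classifier(train, n_bins=21, n_train_per_bin=30, seed=6)
test_resp = it.simulate_population(cells, noise, itds, freqs, 12, seed=7)
print(f"labelled line: RMS acuity={it.classifier_test_error(ens, test_resp).rms_us:.1f} us")
```

Output:

```
cell 0: CP=+0.285 cyc, CD=-0.164 ms, MI=1.042 bits
difference code: R^2=0.9968, RMS error=4.0 us, per-frequency RMS=[4.4 3.6 3.8 4.1 4.1]
labelled line: RMS acuity=7.3 us
```

The first line characterizes one virtual neuron and the frequency-invariant
information its rate carries about ITD.  The difference-code block shows
the signature property of the two-channel readout on a heterogeneous
population: the ITD estimate is linear (R² ≈ 1) and its error (~4 µs RMS)
is nearly identical across the five tone frequencies.  The labelled-line
classifier reaches a comparable acuity, but — as the test suite
demonstrates — the two readouts react in opposite ways to manipulations of
the CP/CD distribution: forcing CP = 0 (a pure delay-line population)
slightly helps the classifier while destroying the linearity of the
difference code.

A `itdcode` command-line tool wraps the same analyses
(`generate`, `characterize`, `landscape`, `decode-classifier`,
`decode-difference`, `sweep-rotation`, `sweep-subset`); see
`itdcode --help`.

## Documentation

`docs/methods.md` describes the model, its assumptions, the default
parameters and their rationale, what the synthetic-data generator does and
does not emulate, and the package's numerical choices and limitations.
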