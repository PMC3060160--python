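"""Population readouts: labelled-line classifiers and the bilateral code.

Two readout mechanisms are compared on the same simulated rate patterns:

* a *labelled-line* scheme, in which one-vs-one linear support vector
  machines assign each population pattern to one of M ITD bins by
  majority vote ("grandmother neurons" for azimuth intervals), scored by
  the root-mean-square difference between predicted bin center and true
  ITD; and

* a *two-channel* scheme, in which the ITD is read from the difference D
  between the mean population rates of the two hemispheres via a single
  least-squares line tau_hat = gain*D + intercept, pooled over stimulus
  frequencies (a frequency-blind readout).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .population import PopulationResponse


# ---------------------------------------------------------------------------
# labelled-line classifier ensemble
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassifierEnsemble:
    """One-vs-one linear classifiers over M ITD bins with majority vote.

    ``weights[k]`` and ``biases[k]`` define the decision function of the
    pair ``pairs[k] = (i, j)`` (i < j); positive decision values vote for
    bin i.  Features are standardized by the training-set mean/sd.
    Ties are broken by the summed signed decision values, then by the
    lower bin index, so prediction is deterministic.
    """

    bin_edges: np.ndarray  #: us, length M+1
    pairs: tuple  #: ((i, j), ...) with i < j
    weights: np.ndarray  #: (n_pairs, n_cells)
    biases: np.ndarray  #: (n_pairs,)
    feat_mean: np.ndarray
    feat_sd: np.ndarray
    train_rms_us: float = float("nan")  #: RMS error on the training patterns

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def predict(self, patterns: np.ndarray) -> np.ndarray:
        """Predicted bin index per pattern (rows = patterns)."""
        x = (np.atleast_2d(patterns) - self.feat_mean) / self.feat_sd
        dec = x @ self.weights.T + self.biases  # (n_samples, n_pairs)
        m = self.n_bins
        votes = np.zeros((x.shape[0], m))
        margin = np.zeros((x.shape[0], m))
        for k, (i, j) in enumerate(self.pairs):
            pos = dec[:, k] > 0
            votes[pos, i] += 1
            votes[~pos, j] += 1
            margin[:, i] += dec[:, k]
            margin[:, j] -= dec[:, k]
        # lexicographic argmax: votes, then summed signed margin, then lower bin
        best = np.empty(x.shape[0], dtype=int)
        for s in range(x.shape[0]):
            v = votes[s]
            cand = np.flatnonzero(v == v.max())
            if cand.size > 1:
                g = margin[s, cand]
                cand = cand[g == g.max()]
            best[s] = int(cand.min())
        return best


def _patterns(resp: PopulationResponse):
    """Flatten a response tensor to (n_samples, n_cells) plus true ITDs."""
    # rates: (cells, itd, freq, trial) -> samples over (itd, freq, trial)
    x = np.moveaxis(resp.rates, 0, -1).reshape(-1, len(resp.cells))
    tau = np.broadcast_to(
        resp.itds_us[:, None, None],
        (len(resp.itds_us), len(resp.freqs_hz), resp.n_trials),
    ).reshape(-1)
    return x, tau


def train_classifier(
    responses: PopulationResponse,
    n_bins: int,
    n_train_per_bin: int,
    seed: int = 0,
    C: float = 1.0,
    shuffle_labels: bool = False,
) -> ClassifierEnsemble:
    """Train the one-vs-one linear SVM ensemble on labelled rate patterns.

    Patterns are labelled by the ITD bin (M equal intervals spanning the
    stimulus ITD range) containing their true ITD; ``n_train_per_bin``
    patterns per bin are drawn without replacement.  A bin with no
    available pattern raises.  ``shuffle_labels=True`` permutes the
    training labels (seeded) as a chance-level control.
    """
    if n_bins < 2:
        raise ValueError("need n_bins >= 2")
    x, tau = _patterns(responses)
    lo, hi = responses.itds_us.min(), responses.itds_us.max()
    edges = np.linspace(lo, hi, n_bins + 1)
    labels = np.clip(np.searchsorted(edges, tau, side="right") - 1, 0, n_bins - 1)

    rng = np.random.default_rng(seed)
    take = []
    for b in range(n_bins):
        idx = np.flatnonzero(labels == b)
        if idx.size == 0:
            raise ValueError(f"ITD bin {b} has no training patterns")
        if idx.size < n_train_per_bin:
            raise ValueError(
                f"ITD bin {b} has only {idx.size} patterns, "
                f"need {n_train_per_bin}"
            )
        take.append(rng.choice(idx, size=n_train_per_bin, replace=False))
    take = np.concatenate(take)
    xt, yt = x[take], labels[take]
    tau_t = tau[take]
    if shuffle_labels:
        perm = rng.permutation(yt.size)
        yt = yt[perm]

    mean = xt.mean(axis=0)
    sd = xt.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    xs = (xt - mean) / sd

    pairs, weights, biases = [], [], []
    for i in range(n_bins):
        for j in range(i + 1, n_bins):
            mask = (yt == i) | (yt == j)
            # label +1 for the lower bin index i
            yy = np.where(yt[mask] == i, 1.0, -1.0)
            clf = SVC(kernel="linear", C=C)
            clf.fit(xs[mask], yy)
            pairs.append((i, j))
            weights.append(clf.coef_[0])
            biases.append(float(clf.intercept_[0]))
    ens = ClassifierEnsemble(
        bin_edges=edges,
        pairs=tuple(pairs),
        weights=np.array(weights),
        biases=np.array(biases),
        feat_mean=mean,
        feat_sd=sd,
    )
    centers = ens.bin_centers
    train_err = centers[ens.predict(xt)] - tau_t
    object.__setattr__(ens, "train_rms_us", float(np.sqrt(np.mean(train_err**2))))
    return ens


@dataclass(frozen=True)
class ClassifierError:
    """RMS acuity (us) of the labelled-line readout plus the confusion matrix."""

    rms_us: float
    confusion: np.ndarray  #: (true bin, predicted bin) counts
    n_test: int


def classifier_test_error(
    ensemble: ClassifierEnsemble, responses: PopulationResponse
) -> ClassifierError:
    """RMS of (predicted bin center - true ITD) on held-out patterns."""
    x, tau = _patterns(responses)
    if x.shape[0] == 0:
        raise ValueError("empty test set")
    pred = ensemble.predict(x)
    err = ensemble.bin_centers[pred] - tau
    m = ensemble.n_bins
    true_bin = np.clip(
        np.searchsorted(ensemble.bin_edges, tau, side="right") - 1, 0, m - 1
    )
    conf = np.zeros((m, m), dtype=int)
    np.add.at(conf, (true_bin, pred), 1)
    return ClassifierError(
        rms_us=float(np.sqrt(np.mean(err**2))), confusion=conf, n_test=x.shape[0]
    )


def subset_acuity(
    train_responses: PopulationResponse,
    test_responses: PopulationResponse,
    mi_per_cell,
    subset_sizes,
    n_bins: int,
    n_train_per_bin: int,
    seed: int = 0,
) -> dict:
    """Labelled-line acuity as a function of population subset size.

    For each size the cells with the highest single-cell mutual
    information are retained and the ensemble is retrained.  Returns the
    sizes, RMS errors, and the smallest size whose acuity is within 5% of
    the full-population acuity.
    """
    mi = np.asarray(mi_per_cell, dtype=float)
    n = len(train_responses.cells)
    if mi.size != n:
        raise ValueError("mi_per_cell length must match the population")
    sizes = sorted(int(s) for s in subset_sizes)
    if sizes[-1] > n:
        raise ValueError("subset size exceeds population size")
    ranking = np.argsort(mi)[::-1]
    errors = []
    for s in sizes:
        idx = ranking[:s]
        ens = train_classifier(
            train_responses.subset(idx), n_bins, n_train_per_bin, seed=seed
        )
        errors.append(classifier_test_error(ens, test_responses.subset(idx)).rms_us)
    full = train_classifier(train_responses, n_bins, n_train_per_bin, seed=seed)
    full_rms = classifier_test_error(full, test_responses).rms_us
    saturation = next(
        (s for s, e in zip(sizes, errors) if e <= 1.05 * full_rms), sizes[-1]
    )
    return {
        "sizes": sizes,
        "rms_us": errors,
        "full_rms_us": full_rms,
        "saturation_size": saturation,
    }


# ---------------------------------------------------------------------------
# bilateral (two-channel) difference decoder
# ---------------------------------------------------------------------------


def bilateral_difference_signal(
    responses: PopulationResponse, mirrored: PopulationResponse
) -> np.ndarray:
    """Hemispheric rate difference D(tau, f, trial) in Hz.

    Mean rate over the cells of hemisphere 1 minus the mean over the
    mirrored hemisphere, per condition and trial.  The condition grids of
    the two responses must match.
    """
    if (
        not np.array_equal(responses.itds_us, mirrored.itds_us)
        or not np.array_equal(responses.freqs_hz, mirrored.freqs_hz)
        or responses.n_trials != mirrored.n_trials
    ):
        raise ValueError("condition grids of the two hemispheres differ")
    return responses.rates.mean(axis=0) - mirrored.rates.mean(axis=0)


@dataclass(frozen=True)
class DifferenceDecoder:
    """Linear ITD estimate tau_hat = gain*D + intercept (pooled over f)."""

    gain: float  #: us per Hz
    intercept: float  #: us
    r_squared: float  #: pooled fit quality
    per_frequency_r2: np.ndarray

    def predict(self, d_hz):
        return self.gain * np.asarray(d_hz, dtype=float) + self.intercept


def fit_difference_decoder(d_signal: np.ndarray, itds_us) -> DifferenceDecoder:
    """Least-squares line from difference signal to true ITD.

    ``d_signal`` has shape (n_itd, n_freq, n_trials); the fit pools all
    frequencies and trials (the readout is frequency-blind).
    """
    d = np.asarray(d_signal, dtype=float)
    itds = np.asarray(itds_us, dtype=float)
    tau = np.broadcast_to(itds[:, None, None], d.shape).reshape(-1)
    dd = d.reshape(-1)
    if np.ptp(dd) <= 0:
        raise ValueError("difference signal is constant; decoder is degenerate")
    gain, intercept = np.polyfit(dd, tau, 1)
    resid = tau - (gain * dd + intercept)
    ss_tot = np.sum((tau - tau.mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid**2) / ss_tot) if ss_tot > 0 else 0.0
    per_f = []
    for k in range(d.shape[1]):
        dk = d[:, k, :].reshape(-1)
        tk = np.broadcast_to(itds[:, None], d[:, k, :].shape).reshape(-1)
        rk = tk - (gain * dk + intercept)
        sst = np.sum((tk - tk.mean()) ** 2)
        per_f.append(1.0 - float(np.sum(rk**2) / sst) if sst > 0 else 0.0)
    return DifferenceDecoder(
        gain=float(gain),
        intercept=float(intercept),
        r_squared=r2,
        per_frequency_r2=np.array(per_f),
    )


@dataclass(frozen=True)
class DifferenceError:
    """Test error of the bilateral decoder, resolved by frequency and ITD."""

    rms_by_freq_us: np.ndarray
    max_by_freq_us: np.ndarray
    rms_by_itd_us: np.ndarray
    max_by_itd_us: np.ndarray
    rms_us: float
    max_us: float


def difference_decoder_error(
    decoder: DifferenceDecoder, d_signal: np.ndarray, itds_us
) -> DifferenceError:
    """Per-frequency and per-ITD RMS and maximal absolute errors (us)."""
    d = np.asarray(d_signal, dtype=float)
    if d.size == 0:
        raise ValueError("empty test set")
    itds = np.asarray(itds_us, dtype=float)
    err = decoder.predict(d) - itds[:, None, None]
    return DifferenceError(
        rms_by_freq_us=np.sqrt(np.mean(err**2, axis=(0, 2))),
        max_by_freq_us=np.max(np.abs(err), axis=(0, 2)),
        rms_by_itd_us=np.sqrt(np.mean(err**2, axis=(1, 2))),
        max_by_itd_us=np.max(np.abs(err), axis=(1, 2)),
        rms_us=float(np.sqrt(np.mean(err**2))),
        max_us=float(np.max(np.abs(err))),
    )
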