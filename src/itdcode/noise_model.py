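"""Firing-rate noise: logarithmic variance-mean law and clipped Gaussians.

Across DNLL cells the trial-to-trial variance of the firing rate grows
with the mean rate following a logarithmic law

    var(rbar) = noise_scale * v1 * ln(1 + v2 * rbar),

which is Poisson-like at low rates (expanding the log gives
var ~ v1*v2*rbar, and with v1*v2 = 1/T the spike-count variance equals
the count mean for stimulus duration T) and strongly sublinear at high
rates.  Conditional rate distributions are Gaussians with this variance,
clipped at zero rate and renormalized over r >= 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import warnings

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import ndtr, ndtri

#: default parameters of the variance law and stimulus duration.
#: v1*v2 = 1/duration makes low-rate spike counts exactly Poisson-consistent,
#: and the small v1 (strong log saturation) makes high-rate counts strongly
#: sub-Poisson, as observed in the lateral lemniscus.
DEFAULT_V1 = 5.0  # Hz^2
DEFAULT_V2 = 1.0  # 1/Hz
DEFAULT_DURATION = 0.2  # s

#: variance floor (Hz^2) so the zero-noise limit stays well defined
VARIANCE_FLOOR = 1e-12


@dataclass(frozen=True)
class RateNoiseModel:
    """Logarithmic variance-mean law with a stimulus duration.

    Attributes
    ----------
    v1 : float
        Variance scale in Hz^2.
    v2 : float
        Inverse-rate scale in 1/Hz.
    duration : float
        Stimulus (observation) duration in seconds.
    noise_scale : float
        Dimensionless multiplier of the variance (1 = as fitted).
    """

    v1: float = DEFAULT_V1
    v2: float = DEFAULT_V2
    duration: float = DEFAULT_DURATION
    noise_scale: float = 1.0

    def __post_init__(self):
        if self.v1 <= 0 or self.v2 <= 0 or self.duration <= 0:
            raise ValueError("v1, v2 and duration must be positive")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if abs(self.v1 * self.v2 * self.duration - 1.0) > 0.5:
            warnings.warn(
                f"v1*v2 = {self.v1 * self.v2:.3g} deviates from 1/duration = "
                f"{1 / self.duration:.3g}; low-rate counts are not Poisson-consistent",
                stacklevel=2,
            )

    def variance(self, mean_rate):
        """Rate variance (Hz^2) at the given mean rate(s)."""
        m = np.asarray(mean_rate, dtype=float)
        if np.any(m < 0):
            raise ValueError("mean rate must be >= 0")
        v = self.noise_scale * self.v1 * np.log1p(self.v2 * m)
        v = np.maximum(v, VARIANCE_FLOOR)
        return float(v) if np.ndim(mean_rate) == 0 else v

    def sd(self, mean_rate):
        return np.sqrt(self.variance(mean_rate))

    def with_noise_scale(self, s: float) -> "RateNoiseModel":
        return replace(self, noise_scale=float(s))

    def with_duration(self, duration_s: float) -> "RateNoiseModel":
        """Model for a truncated observation window.

        Shortening the window from T to T0 scales the rate variance by
        T/T0 (v1 is rescaled, v2 kept), preserving v1*v2 = 1/T0 in the
        Poisson-consistent regime.
        """
        if duration_s <= 0:
            raise ValueError("duration must be positive")
        return replace(
            self, v1=self.v1 * self.duration / duration_s, duration=float(duration_s)
        )

    # -- conditional densities and sampling --------------------------------

    def conditional_rate_density(self, r, mean_rate):
        """Clipped-Gaussian density p(r | mean_rate), zero for r < 0.

        The Gaussian is truncated at r = 0 and renormalized so the density
        integrates to one over r >= 0.
        """
        if np.any(np.asarray(mean_rate) < 0):
            raise ValueError("mean rate must be >= 0")
        r = np.asarray(r, dtype=float)
        mu = np.asarray(mean_rate, dtype=float)
        sigma = np.sqrt(self.variance(mu))
        z = ndtr(mu / sigma)  # mass of the untruncated Gaussian above 0
        dens = (
            np.exp(-0.5 * ((r - mu) / sigma) ** 2)
            / (sigma * np.sqrt(2 * np.pi))
            / z
        )
        return np.where(r < 0, 0.0, dens)

    def sample_rates(
        self,
        mean_rate,
        n: int | None = None,
        seed: int | None = None,
        rng: np.random.Generator | None = None,
        clip: str = "renormalize",
    ):
        """Draw rates from the clipped Gaussian around ``mean_rate``.

        Parameters
        ----------
        mean_rate : float or array_like
            Mean rate(s); with ``n`` given, a scalar mean yields ``n``
            i.i.d. draws, otherwise one draw per element.
        clip : {"renormalize", "point_mass"}
            "renormalize" samples the truncated Gaussian (matching
            :meth:`conditional_rate_density`); "point_mass" samples the
            plain Gaussian and sets negative rates to zero.
        """
        if rng is None:
            rng = np.random.default_rng(seed)
        mu = np.asarray(mean_rate, dtype=float)
        if n is not None:
            if n < 1:
                raise ValueError("n must be >= 1")
            mu = np.broadcast_to(mu, (n,) + mu.shape).astype(float)
        sigma = np.sqrt(self.variance(mu))
        if clip == "point_mass":
            return np.maximum(mu + sigma * rng.standard_normal(mu.shape), 0.0)
        if clip != "renormalize":
            raise ValueError(f"unknown clip mode {clip!r}")
        # inverse-CDF sampling of the truncated normal on [0, inf)
        lo = ndtr(-mu / sigma)  # CDF at the truncation point
        u = lo + (1.0 - lo) * rng.random(mu.shape)
        u = np.clip(u, 1e-16, 1 - 1e-16)
        return np.maximum(mu + sigma * ndtri(u), 0.0)


def fit_variance_mean(
    mean_rates,
    variances,
    duration_s: float = DEFAULT_DURATION,
    noise_scale: float = 1.0,
) -> RateNoiseModel:
    """Least-squares fit of the logarithmic variance-mean law.

    Parameters
    ----------
    mean_rates, variances : array_like
        Paired mean rates (Hz) and rate variances (Hz^2), pooled over
        cells and conditions; >= 5 pairs, variances positive.
    """
    m = np.asarray(mean_rates, dtype=float)
    v = np.asarray(variances, dtype=float)
    if m.size < 5 or m.size != v.size:
        raise ValueError("need >= 5 (mean, variance) pairs")
    if np.any(v <= 0):
        raise ValueError("variances must be positive")
    if np.any(m < 0):
        raise ValueError("mean rates must be >= 0")

    def law(mean, v1, v2):
        return v1 * np.log1p(v2 * mean)

    # moment-style initial guesses: slope at low rates and saturation level
    v2_0 = 1.0 / max(np.median(m[m > 0]), 1.0)
    v1_0 = max(np.median(v) / np.log1p(v2_0 * np.median(m)), 1e-3)
    popt, _ = curve_fit(
        law,
        m,
        v,
        p0=[v1_0, v2_0],
        bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        maxfev=20000,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = RateNoiseModel(
            v1=float(popt[0]),
            v2=float(popt[1]),
            duration=duration_s,
            noise_scale=noise_scale,
        )
    if abs(model.v1 * model.v2 * duration_s - 1.0) > 0.5:
        warnings.warn(
            "fitted v1*v2 deviates from 1/duration; "
            "low-rate counts are not Poisson-consistent",
            stacklevel=2,
        )
    return model
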