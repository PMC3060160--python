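"""Virtual DNLL populations and emulated tone-delay experiments.

The recorded gerbil dataset behind the model is not publicly deposited,
so this module generates populations with the same statistical structure:
best frequencies roughly flat within a band, characteristic phases spread
over the whole cycle with a positive bias, characteristic delays peaked
at zero, and a negative CP-CD correlation arising because the population
clusters around a line of constant best phase BP = CP + CD*BF.

The generator draws the best phase first and then positions each cell on
the constant-best-phase line given its CP, which builds the observed
correlation in by construction.  An emulated experiment then produces
spike-count tables with the recording protocol's structure (five tone
frequencies around BF, ITD grids spanning at least one stimulus cycle,
repeated trials) from the clipped-Gaussian noise model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._wrap import wrap_half
from .circstat import CellCharacteristics
from .noise_model import RateNoiseModel
from .tuning import CyclicGaussianParams


@dataclass(frozen=True)
class ShapeDistribution:
    """Mean and spread of the tuning-shape parameters across cells."""

    baseline_mean: float = 10.0  # Hz
    baseline_sd: float = 4.0
    amplitude_mean: float = 50.0  # Hz
    amplitude_sd: float = 15.0
    width_mean: float = 0.125  # cycles
    width_sd: float = 0.025


@dataclass(frozen=True)
class PopulationGeneratorConfig:
    """Study conditions of the virtual population.

    ``mean_best_phase``/``best_phase_spread`` locate the constant-best-
    phase cluster; the CP marginal is a mixture of a broad uniform
    component and a positively biased wrapped Gaussian, reproducing the
    whole-cycle spread with positive bias.  ``cd_jitter_ms`` adds Gaussian
    scatter of the characteristic delay off the cluster line.
    """

    n_cells: int = 153
    bf_band: tuple = (800.0, 1000.0)
    mean_best_phase: float = 0.2  # cycles
    best_phase_spread: float = 0.1  # cycles
    cd_jitter_ms: float = 0.05
    cp_uniform_fraction: float = 0.5
    cp_gauss_mean: float = 0.25  # cycles
    cp_gauss_sd: float = 0.15
    shapes: ShapeDistribution = field(default_factory=ShapeDistribution)
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.bf_band[1] <= self.bf_band[0]:
            raise ValueError("bf_band must be a nonempty range")
        if self.best_phase_spread < 0 or self.cd_jitter_ms < 0:
            raise ValueError("spreads must be >= 0")


@dataclass(frozen=True)
class ExperimentProtocol:
    """Structure of the emulated recording protocol.

    Five tone frequencies cover ``octave_span`` octaves centered
    (log-spaced) on BF; per frequency, ``n_itd`` ITDs span ``ipd_span``
    stimulus cycles centered on zero, each repeated ``n_reps`` times.
    """

    n_frequencies: int = 5
    octave_span: float = 0.5
    n_itd: int = 14
    ipd_span: float = 1.3  # cycles; must be >= 1 for the fits downstream
    n_reps: int = 3

    def __post_init__(self):
        if self.n_frequencies < 3:
            raise ValueError("need >= 3 frequencies")
        if self.ipd_span < 1.0:
            raise ValueError("ITD range must span at least one stimulus cycle")
        if self.n_itd < 6:
            raise ValueError("need >= 6 ITD values for the tuning fits")
        if self.n_reps < 1:
            raise ValueError("need >= 1 repetition")

    def frequencies(self, bf: float) -> np.ndarray:
        half = self.octave_span / 2.0
        return bf * 2.0 ** np.linspace(-half, half, self.n_frequencies)


def generate_population(config: PopulationGeneratorConfig) -> list:
    """Draw a virtual population of :class:`CellCharacteristics`.

    Per cell: BF uniform in the band; best phase BP normal around the
    cluster mean; CP from the positively biased wrapped mixture; the
    frequency-scaled delay follows as CD*BF = BP - CP plus jitter, and
    CD = (CD*BF)/BF.  Identical seeds give identical populations.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    bf = rng.uniform(config.bf_band[0], config.bf_band[1], size=n)
    bp = rng.normal(config.mean_best_phase, config.best_phase_spread, size=n)
    from_uniform = rng.random(n) < config.cp_uniform_fraction
    cp = np.where(
        from_uniform,
        rng.uniform(-0.5, 0.5, size=n),
        rng.normal(config.cp_gauss_mean, config.cp_gauss_sd, size=n),
    )
    cp = wrap_half(cp)
    cds = bp - cp + bf * rng.normal(0.0, config.cd_jitter_ms, size=n) * 1e-3
    sh = config.shapes
    baseline = np.clip(rng.normal(sh.baseline_mean, sh.baseline_sd, n), 0.0, None)
    amplitude = np.clip(rng.normal(sh.amplitude_mean, sh.amplitude_sd, n), 1.0, None)
    width = np.clip(rng.normal(sh.width_mean, sh.width_sd, n), 0.05, 0.5)
    cells = []
    for i in range(n):
        cells.append(
            CellCharacteristics(
                cell_id=f"syn{i:04d}",
                bf=float(bf[i]),
                cp=float(cp[i]),
                cd=float(cds[i] / (1e-3 * bf[i])),
                shape=CyclicGaussianParams(
                    baseline=float(baseline[i]),
                    amplitude=float(amplitude[i]),
                    width=float(width[i]),
                    best_ipd=0.0,
                ),
            )
        )
    return cells


def generate_experiment(
    cells,
    model: RateNoiseModel,
    protocol: ExperimentProtocol = ExperimentProtocol(),
    seed: int = 0,
) -> pd.DataFrame:
    """Emulate the recording protocol and return a spike-count table.

    Per (cell, frequency, ITD, repetition) a rate is drawn from the noise
    model around the cell's mean tuning and converted to an integer spike
    count over the stimulus duration.  Columns: cell_id, frequency_hz,
    itd_us, repetition, count, rate_hz.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cell in cells:
        freqs = protocol.frequencies(cell.bf)
        for f in freqs:
            # ITD grid spanning ipd_span cycles of this frequency
            half_span_us = 0.5 * protocol.ipd_span / f * 1e6
            itds = np.linspace(-half_span_us, half_span_us, protocol.n_itd)
            mu = cell.mean_rate(itds, f)
            for rep in range(protocol.n_reps):
                rates = model.sample_rates(mu, rng=rng)
                counts = np.rint(rates * model.duration).astype(int)
                for itd, cnt in zip(itds, counts):
                    rows.append(
                        (cell.cell_id, float(f), float(itd), rep, int(cnt))
                    )
    df = pd.DataFrame(
        rows, columns=["cell_id", "frequency_hz", "itd_us", "repetition", "count"]
    )
    df["rate_hz"] = df["count"] / model.duration
    return df


def jitter_characteristics(
    cells, sd_cp: float, sd_cds: float, seed: int = 0
) -> list:
    """Add seeded Gaussian jitter to CP (re-wrapped) and CD*BF per cell.

    ``sd_cp`` and ``sd_cds`` are standard deviations in cycles; zero
    standard deviations return identical characteristics.
    """
    if sd_cp < 0 or sd_cds < 0:
        raise ValueError("jitter standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for c in cells:
        dcp = rng.normal(0.0, sd_cp) if sd_cp > 0 else 0.0
        dcds = rng.normal(0.0, sd_cds) if sd_cds > 0 else 0.0
        if dcp == 0.0 and dcds == 0.0:
            out.append(c)  # exact identity, no wrap round-off
        else:
            out.append(c.with_cp_cds(c.cp + dcp, c.cd_scaled + dcds))
    return out
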