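"""Simulated population rate patterns across ITD, frequency and trials.

Each cell responds with its cyclic-Gaussian mean tuning evaluated at
f*tau - (CP + CD*f); trial-to-trial variability is drawn independently
per cell and condition from the clipped-Gaussian noise model.  A second,
mirror-image population (CP -> -CP, CD -> -CD) represents the opposite
brain hemisphere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._wrap import wrap_half
from .circstat import CellCharacteristics
from .noise_model import RateNoiseModel


@dataclass(frozen=True)
class PopulationResponse:
    """Rate tensor [cell, itd, frequency, trial] plus its condition grid."""

    cells: tuple
    itds_us: np.ndarray
    freqs_hz: np.ndarray
    rates: np.ndarray  #: Hz, shape (n_cells, n_itd, n_freq, n_trials)
    seed: int

    def __post_init__(self):
        expected = (
            len(self.cells),
            len(self.itds_us),
            len(self.freqs_hz),
            self.rates.shape[-1],
        )
        if self.rates.shape != expected:
            raise ValueError(
                f"rates shape {self.rates.shape} inconsistent with grid {expected}"
            )
        if np.any(self.rates < 0):
            raise ValueError("rates must be nonnegative")

    @property
    def n_trials(self) -> int:
        return int(self.rates.shape[-1])

    def subset(self, indices) -> "PopulationResponse":
        """Response restricted to a subset of cells (same conditions)."""
        idx = np.asarray(indices, dtype=int)
        return PopulationResponse(
            cells=tuple(self.cells[i] for i in idx),
            itds_us=self.itds_us,
            freqs_hz=self.freqs_hz,
            rates=self.rates[idx],
            seed=self.seed,
        )


def mean_rates(
    cells: Sequence[CellCharacteristics], itds_us, freqs_hz
) -> np.ndarray:
    """Noise-free mean tuning, shape (n_cells, n_itd, n_freq)."""
    itds = np.asarray(itds_us, dtype=float)
    freqs = np.asarray(freqs_hz, dtype=float)
    out = np.empty((len(cells), itds.size, freqs.size))
    for i, c in enumerate(cells):
        out[i] = c.mean_rate(itds[:, None], freqs[None, :])
    return out


def simulate_population(
    cells: Sequence[CellCharacteristics],
    model: RateNoiseModel,
    itds_us,
    freqs_hz,
    n_trials: int = 10,
    seed: int = 0,
) -> PopulationResponse:
    """Draw a rate tensor for a population over an (ITD, frequency) grid.

    Trials are i.i.d. across cells and conditions (no noise correlations).
    Identical seeds give identical tensors.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    mu = mean_rates(cells, itds_us, freqs_hz)
    rng = np.random.default_rng(seed)
    rates = model.sample_rates(mu[..., None] * np.ones(n_trials), rng=rng)
    return PopulationResponse(
        cells=tuple(cells),
        itds_us=np.asarray(itds_us, dtype=float),
        freqs_hz=np.asarray(freqs_hz, dtype=float),
        rates=rates,
        seed=seed,
    )


def mirror_cell(cell: CellCharacteristics) -> CellCharacteristics:
    """The contralateral twin of a cell: CP -> -CP (re-wrapped), CD -> -CD."""
    return cell.with_cp_cds(wrap_half(-cell.cp), -cell.cd_scaled)


def mirror_population(cells: Sequence[CellCharacteristics]) -> list:
    """Mirror every cell into the opposite hemisphere; an involution.

    The mirrored cell's mean tuning at ITD tau equals the original's at
    -tau, so a bilateral pair has zero expected rate difference at the
    midline.
    """
    return [mirror_cell(c) for c in cells]
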