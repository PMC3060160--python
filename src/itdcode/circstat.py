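"""Circular-linear regression and circular population statistics.

The best IPD of a binaural brainstem neuron moves approximately linearly
with stimulus frequency,

    phi_best(f) = CP + CD * f,

which defines the *characteristic phase* CP (cycles, the intercept) and
the *characteristic delay* CD (a pure time delay; here kept in ms).  CP
and CD are estimated by circular-linear regression: the slope maximizes
the mean resultant length R_V of the circular residuals (a quantity that
is independent of the offset), and the offset is then the circular mean
of the residuals, which maximizes the overlap between data cloud and
model line on the cylinder.

The same machinery quantifies the population-level relation between CP
and CD (or the frequency-scaled delay CD*BF, in cycles), the band-wise
tonotopy of CD, and bootstrap standard errors of CP/CD from surrogate
spike counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from ._wrap import circ_dist, circ_mean, resultant_length, wrap_half
from .tuning import CyclicGaussianParams, eval_cyclic_gaussian, fit_tone_delay


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhaseFrequencyCurve:
    """Best IPD (cycles) as a function of stimulus frequency for one cell."""

    cell_id: str
    frequencies_hz: tuple
    best_ipds_cycles: tuple

    def __post_init__(self):
        f = np.asarray(self.frequencies_hz, dtype=float)
        p = np.asarray(self.best_ipds_cycles, dtype=float)
        if f.size < 3 or f.size != p.size:
            raise ValueError("need >= 3 (frequency, best IPD) points")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")


@dataclass(frozen=True)
class CellCharacteristics:
    """CP/CD characterization of one neuron plus its mean tuning shape.

    ``shape`` stores the frequency-averaged cyclic-Gaussian parameters with
    ``best_ipd = 0``; the cell's actual best IPD at frequency f is
    ``cp + cd*f`` and is applied when evaluating the mean tuning.

    Units: ``bf`` Hz, ``cp`` cycles in (-0.5, 0.5], ``cd`` milliseconds,
    ``cd_scaled = cd * bf`` in cycles.
    """

    cell_id: str
    bf: float
    cp: float
    cd: float
    shape: CyclicGaussianParams
    resultant_length: float = 1.0
    flags: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if not -0.5 < self.cp <= 0.5 + 1e-12:
            raise ValueError(f"cp must lie in (-0.5, 0.5], got {self.cp}")
        if not 0.0 <= self.resultant_length <= 1.0 + 1e-12:
            raise ValueError("resultant_length must lie in [0, 1]")

    @property
    def cd_scaled(self) -> float:
        """Frequency-scaled characteristic delay CD*BF in cycles."""
        return self.cd * 1e-3 * self.bf

    def best_ipd(self, frequency_hz) -> np.ndarray:
        """Best IPD (cycles, unwrapped) at the given frequencies."""
        return self.cp + self.cd * 1e-3 * np.asarray(frequency_hz, dtype=float)

    def mean_rate(self, itd_us, frequency_hz):
        """Mean tuning r(f*tau - (cp + cd*f)) in Hz; broadcasts inputs."""
        tau = np.asarray(itd_us, dtype=float) * 1e-6
        f = np.asarray(frequency_hz, dtype=float)
        phi = f * tau - (self.cp + self.cd * 1e-3 * f)
        return eval_cyclic_gaussian(self.shape, phi - self.shape.best_ipd)

    def with_cp_cds(self, cp: float, cd_scaled: float) -> "CellCharacteristics":
        """Copy with new (cp, cd_scaled); cd is recovered as cd_scaled/bf."""
        return replace(
            self, cp=float(wrap_half(cp)), cd=float(cd_scaled / (1e-3 * self.bf))
        )


# ---------------------------------------------------------------------------
# circular-linear regression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CircLinearFit:
    """Slope/offset of a circular-linear regression phi ~ offset + slope*x."""

    slope: float  #: cycles per unit of x
    offset: float  #: cycles, wrapped to (-0.5, 0.5]
    resultant_length: float  #: R_V in [0, 1] at the optimal slope
    at_edge: bool  #: slope maximizer hit the search bound (aliasing suspected)


def _rv(slope, x, phi):
    return resultant_length(phi - slope * x)


def circ_linear_fit(
    x,
    phi,
    slope_bounds: tuple,
    grid_step: float | None = None,
) -> CircLinearFit:
    """Fit phi = offset + slope*x for circular phi (cycles) and linear x.

    The slope is found by maximizing the mean resultant length of the
    circular residuals phi - slope*x over ``slope_bounds``, using a coarse
    grid of spacing ``grid_step`` followed by bounded local refinement.
    The offset is the circular mean of the residuals at the optimal slope.

    Parameters
    ----------
    x : array_like
        Linear covariate (e.g. frequency in Hz, or CD in ms).
    phi : array_like
        Circular responses in cycles.
    slope_bounds : (float, float)
        Search interval for the slope, in cycles per unit of x.
    grid_step : float, optional
        Grid spacing of the coarse search; default spans the interval with
        601 points.

    Raises
    ------
    ValueError
        Fewer than 3 pairs, or x carries no variation while phi does.
    """
    x = np.asarray(x, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if x.size < 3 or x.size != phi.size:
        raise ValueError("need >= 3 (x, phi) pairs")
    lo, hi = map(float, slope_bounds)
    if not lo < hi:
        raise ValueError("slope_bounds must be an increasing pair")
    if np.ptp(x) == 0:
        raise ValueError("x values are all identical; slope is unidentifiable")

    if grid_step is None:
        grid = np.linspace(lo, hi, 601)
        step = grid[1] - grid[0]
    else:
        step = float(grid_step)
        grid = np.arange(lo, hi + step / 2, step)

    # vectorized coarse grid search of R_V
    z = np.exp(2j * np.pi * (phi[np.newaxis, :] - grid[:, np.newaxis] * x))
    rv_grid = np.abs(z.mean(axis=1))
    i_best = int(np.argmax(rv_grid))
    m0 = grid[i_best]

    res = minimize_scalar(
        lambda m: -_rv(m, x, phi),
        bounds=(max(lo, m0 - step), min(hi, m0 + step)),
        method="bounded",
        options={"xatol": 1e-12 + 1e-9 * step},
    )
    slope = float(res.x)
    if _rv(slope, x, phi) < rv_grid[i_best]:
        slope = float(m0)
    rv = _rv(slope, x, phi)
    at_edge = slope <= lo + step or slope >= hi - step
    if at_edge:
        warnings.warn(
            "circular-linear slope maximizer at search-bound edge; "
            "phase aliasing suspected",
            stacklevel=2,
        )
    offset = circ_mean(phi - slope * x)
    return CircLinearFit(
        slope=slope, offset=float(offset), resultant_length=float(rv), at_edge=at_edge
    )


def circ_linear_corr(phi, x) -> tuple:
    """Circular-linear correlation coefficient and p-value.

    Uses the embedding approach: correlations of x with cos and sin of the
    phase combine into a coefficient in [0, 1]; under independence
    n*r^2 is asymptotically chi-square with 2 degrees of freedom.

    Parameters
    ----------
    phi : array_like
        Circular variable in cycles.
    x : array_like
        Linear variable.
    """
    phi = np.asarray(phi, dtype=float) * 2 * np.pi
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError("need >= 5 observations")
    c, s = np.cos(phi), np.sin(phi)
    if np.ptp(x) == 0 or (np.ptp(c) == 0 and np.ptp(s) == 0):
        raise ValueError("degenerate sample: no variation in x or phi")

    def _corr(a, b):
        sa, sb = np.std(a), np.std(b)
        if sa == 0 or sb == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    rcx, rsx, rcs = _corr(x, c), _corr(x, s), _corr(c, s)
    denom = 1.0 - rcs**2
    r2 = (rcx**2 + rsx**2 - 2 * rcx * rsx * rcs) / denom if denom > 0 else max(
        rcx**2, rsx**2
    )
    r2 = min(max(r2, 0.0), 1.0)
    p = float(stats.chi2.sf(n * r2, df=2))
    return float(np.sqrt(r2)), p


# ---------------------------------------------------------------------------
# per-cell characterization
# ---------------------------------------------------------------------------

#: CD search interval (ms) and coarse grid step (ms = 10 us) for the
#: best-IPD-vs-frequency regression.  Slopes beyond ~1/(frequency spacing)
#: alias; edge hits are flagged by circ_linear_fit.
CD_SEARCH_MS = 3.0
CD_GRID_STEP_MS = 0.01


def characterize_cell(
    curve: PhaseFrequencyCurve,
    fits: Sequence[CyclicGaussianParams],
    bf: float,
) -> CellCharacteristics:
    """Derive CP/CD and the mean tuning shape for one cell.

    CP and CD come from the circular-linear regression of best IPD on
    frequency; the shape is the element-wise mean of the per-frequency
    (baseline, amplitude, width) with ``best_ipd = 0``.
    """
    f = np.asarray(curve.frequencies_hz, dtype=float)
    phi = np.asarray(curve.best_ipds_cycles, dtype=float)
    # slope in cycles/Hz = seconds; search +-CD_SEARCH_MS ms at 10 us steps
    fit = circ_linear_fit(
        f,
        phi,
        slope_bounds=(-CD_SEARCH_MS * 1e-3, CD_SEARCH_MS * 1e-3),
        grid_step=CD_GRID_STEP_MS * 1e-3,
    )
    if fits:
        shape = CyclicGaussianParams(
            baseline=float(np.mean([p.baseline for p in fits])),
            amplitude=float(np.mean([p.amplitude for p in fits])),
            width=float(np.mean([p.width for p in fits])),
            best_ipd=0.0,
        )
    else:
        raise ValueError("need at least one per-frequency fit for the shape")
    flags = ("cd_at_search_edge",) if fit.at_edge else ()
    return CellCharacteristics(
        cell_id=curve.cell_id,
        bf=float(bf),
        cp=float(fit.offset),
        cd=float(fit.slope * 1e3),
        shape=shape,
        resultant_length=fit.resultant_length,
        flags=flags,
    )


def characterize_from_measurements(
    measurements: pd.DataFrame,
    duration_s: float,
    bf: float | None = None,
    cell_id: str | None = None,
) -> CellCharacteristics:
    """Full single-cell pipeline: tone-delay fits -> phase-frequency -> CP/CD.

    ``measurements`` holds one cell's spike-count table (columns
    cell_id, frequency_hz, itd_us, repetition, count).  BF defaults to the
    median stimulus frequency.
    """
    df = measurements.copy()
    if cell_id is None:
        ids = df["cell_id"].unique()
        if ids.size != 1:
            raise ValueError("pass cell_id when the table holds several cells")
        cell_id = str(ids[0])
    else:
        df = df[df["cell_id"] == cell_id]
    df["rate_hz"] = df["count"] / duration_s
    df["ipd_cycles"] = df["frequency_hz"] * df["itd_us"] * 1e-6
    freqs, params = [], []
    for freq, grp in df.groupby("frequency_hz", sort=True):
        fit = fit_tone_delay(grp["ipd_cycles"].to_numpy(), grp["rate_hz"].to_numpy())
        freqs.append(float(freq))
        params.append(fit.params)
    curve = PhaseFrequencyCurve(
        cell_id=cell_id,
        frequencies_hz=tuple(freqs),
        best_ipds_cycles=tuple(p.best_ipd for p in params),
    )
    if bf is None:
        bf = float(np.median(freqs))
    return characterize_cell(curve, params, bf)


# ---------------------------------------------------------------------------
# population statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CpCdPopulationStats:
    """Population-level CP-vs-CD line and circular-linear correlation."""

    slope: float  #: cycles per unit of the delay covariate
    offset: float  #: cycles
    ms_per_cycle: float  #: |1/slope| when the covariate is CD in ms, else nan
    correlation: float  #: circular-linear correlation coefficient in [0, 1]
    p_value: float
    resultant_length: float


def population_cp_cd_stats(
    cells: Sequence[CellCharacteristics],
    use_scaled: bool = False,
    slope_bounds: tuple | None = None,
) -> CpCdPopulationStats:
    """CP-vs-CD (or CP-vs-CD*BF) regression and correlation across cells.

    With ``use_scaled=False`` the covariate is CD in ms and the slope is in
    cycles/ms; ``ms_per_cycle`` reports the magnitude of its reciprocal.
    With ``use_scaled=True`` the covariate is the dimensionless CD*BF.
    """
    if len(cells) < 5:
        raise ValueError("need >= 5 cells")
    cp = np.array([c.cp for c in cells])
    xv = np.array([c.cd_scaled if use_scaled else c.cd for c in cells])
    if slope_bounds is None:
        slope_bounds = (-3.0, 3.0) if use_scaled else (-2.0, 2.0)
    fit = circ_linear_fit(xv, cp, slope_bounds=slope_bounds)
    rho, p = circ_linear_corr(cp, xv)
    ms_per_cycle = (
        float("nan") if use_scaled or fit.slope == 0 else abs(1.0 / fit.slope)
    )
    return CpCdPopulationStats(
        slope=fit.slope,
        offset=fit.offset,
        ms_per_cycle=ms_per_cycle,
        correlation=rho,
        p_value=p,
        resultant_length=fit.resultant_length,
    )


@dataclass(frozen=True)
class BandSlopes:
    """Band-wise CP-vs-CD slopes and their correlation with band BF."""

    band_edges: tuple  #: Hz, len = n_bands + 1
    mean_bf: tuple  #: Hz per retained band
    slope: tuple  #: cycles/ms per retained band
    n_cells: tuple
    bf_slope_correlation: float  #: Pearson r between mean BF and slope


def quarter_octave_bands(f_lo: float, n_bands: int = 4) -> np.ndarray:
    """Edges of ``n_bands`` adjacent 1/4-octave bands starting at ``f_lo``."""
    return f_lo * 2.0 ** (np.arange(n_bands + 1) / 4.0)


def bandwise_cd_tonotopy(
    cells: Sequence[CellCharacteristics],
    band_edges,
    min_cells: int = 3,
) -> BandSlopes:
    """CP-vs-CD slope per BF band and its correlation with the band BF.

    Bands with fewer than ``min_cells`` cells are skipped with a warning.
    """
    edges = np.asarray(band_edges, dtype=float)
    if edges.size < 2:
        raise ValueError("need at least one band (two edges)")
    bf = np.array([c.bf for c in cells])
    mean_bfs, slopes, ns = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (bf >= lo) & (bf < hi)
        if mask.sum() < min_cells:
            warnings.warn(
                f"band [{lo:.0f}, {hi:.0f}) Hz has {int(mask.sum())} cells; skipped",
                stacklevel=2,
            )
            continue
        sub = [c for c, m in zip(cells, mask) if m]
        fit = circ_linear_fit(
            np.array([c.cd for c in sub]),
            np.array([c.cp for c in sub]),
            slope_bounds=(-2.0, 2.0),
        )
        mean_bfs.append(float(bf[mask].mean()))
        slopes.append(fit.slope)
        ns.append(int(mask.sum()))
    if not mean_bfs:
        raise ValueError("no band retained enough cells")
    if len(mean_bfs) >= 2 and np.ptp(slopes) > 0:
        corr = float(np.corrcoef(mean_bfs, slopes)[0, 1])
    else:
        corr = 0.0
    return BandSlopes(
        band_edges=tuple(edges),
        mean_bf=tuple(mean_bfs),
        slope=tuple(slopes),
        n_cells=tuple(ns),
        bf_slope_correlation=corr,
    )


# ---------------------------------------------------------------------------
# bootstrap SEM of CP and CD
# ---------------------------------------------------------------------------


def bootstrap_cp_cd_sem(
    measurements: pd.DataFrame,
    noise_model,
    duration_s: float,
    n_surrogates: int = 4,
    seed: int = 0,
    bf: float | None = None,
) -> tuple:
    """Standard error of (CP, CD*BF) from surrogate spike counts.

    For each surrogate, spike counts are redrawn from the cell's clipped
    Gaussian rate distribution around the fitted mean tuning, the whole
    pipeline is re-run, and the spread of the re-estimated CP and CD*BF
    across surrogates is returned as (sem_cp_cycles, sem_cd_scaled_cycles).
    CP spread is measured circularly around the circular mean.

    Surrogates whose refit fails are dropped with a warning; if all fail a
    RuntimeError is raised.
    """
    if n_surrogates < 2:
        raise ValueError("need n_surrogates >= 2")
    base = characterize_from_measurements(measurements, duration_s, bf=bf)
    df = measurements.copy()
    df["ipd_cycles"] = df["frequency_hz"] * df["itd_us"] * 1e-6
    # per-frequency fitted means at the measured conditions
    mean_rate = base.mean_rate(df["itd_us"].to_numpy(), df["frequency_hz"].to_numpy())
    rng = np.random.default_rng(seed)
    cps, cdss = [], []
    for _ in range(n_surrogates):
        rates = noise_model.sample_rates(mean_rate, rng=rng)
        surr = df.copy()
        surr["count"] = np.rint(rates * duration_s).astype(int).clip(min=0)
        try:
            est = characterize_from_measurements(surr, duration_s, bf=base.bf)
        except (ValueError, RuntimeError) as err:
            warnings.warn(f"surrogate refit failed: {err}", stacklevel=2)
            continue
        cps.append(est.cp)
        cdss.append(est.cd_scaled)
    if not cps:
        raise RuntimeError("all surrogate refits failed")
    cps = np.array(cps)
    cdss = np.array(cdss)
    dev = circ_dist(cps, circ_mean(cps))
    ddof = 1 if len(cps) > 1 else 0
    sem_cp = float(np.sqrt(np.sum(dev**2) / max(len(cps) - 1, 1)))
    sem_cds = float(np.std(cdss, ddof=ddof))
    return sem_cp, sem_cds


# ---------------------------------------------------------------------------
# cell-table I/O
# ---------------------------------------------------------------------------

CELL_TABLE_COLUMNS = [
    "cell_id",
    "bf_hz",
    "cp_cycles",
    "cd_ms",
    "cd_scaled_cycles",
    "baseline_hz",
    "amplitude_hz",
    "width_cycles",
    "resultant_length",
]


def cells_to_table(cells: Sequence[CellCharacteristics]) -> pd.DataFrame:
    rows = [
        {
            "cell_id": c.cell_id,
            "bf_hz": c.bf,
            "cp_cycles": c.cp,
            "cd_ms": c.cd,
            "cd_scaled_cycles": c.cd_scaled,
            "baseline_hz": c.shape.baseline,
            "amplitude_hz": c.shape.amplitude,
            "width_cycles": c.shape.width,
            "resultant_length": c.resultant_length,
        }
        for c in cells
    ]
    return pd.DataFrame(rows, columns=CELL_TABLE_COLUMNS)


def cells_from_table(df: pd.DataFrame) -> list:
    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns and c != "cd_scaled_cycles"]
    if missing:
        raise ValueError(f"cell table missing columns: {missing}")
    cells = []
    for _, row in df.iterrows():
        cells.append(
            CellCharacteristics(
                cell_id=str(row["cell_id"]),
                bf=float(row["bf_hz"]),
                cp=float(wrap_half(row["cp_cycles"])),
                cd=float(row["cd_ms"]),
                shape=CyclicGaussianParams(
                    baseline=float(row["baseline_hz"]),
                    amplitude=float(row["amplitude_hz"]),
                    width=float(row["width_cycles"]),
                    best_ipd=0.0,
                ),
                resultant_length=float(row["resultant_length"]),
            )
        )
    return cells
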