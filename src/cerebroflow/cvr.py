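"""Cerebrovascular reactivity (CVR) mapping from hypercapnic BOLD MRI.

CVR is estimated by ordinary least squares of the BOLD signal on the
end-tidal CO2 (EtCO2) regressor and the scan number (linear drift term),
repeated over a grid of candidate delays; the delay minimising the
residual sum of squares is kept.  The amplitude is expressed as percent
BOLD signal change per mmHg EtCO2, normalised by the mean of the series.

The fitted ``delay`` is reported separately from the fixed instrument
offset (EtCO2 sample-line transit time, 4 s by default); the physiological
shift applied to the regressor is ``delay + instrument_offset``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .exceptions import (
    CoverageError,
    DegenerateDesignError,
    EmptyMaskError,
    EmptyTraceError,
    NormalizationError,
)

logger = logging.getLogger(__name__)

#: default candidate delays (s) for the RSS search
DEFAULT_DELAY_GRID = np.arange(0.0, 31.0, 1.0)

#: default EtCO2 sample-tubing transit time (s)
DEFAULT_INSTRUMENT_OFFSET = 4.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EtCO2Trace:
    """End-tidal CO2 partial pressure (mmHg) sampled at breath times (s)."""

    time: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "value", v)
        if t.ndim != 1 or t.size < 2 or v.shape != t.shape:
            raise ValueError("trace needs >=2 (time, value) samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("trace times must be strictly increasing")
        if not (np.all(v > 0.0) and np.all(v < 100.0)):
            raise ValueError("EtCO2 values must lie in (0, 100) mmHg")

    def sample_at(self, times: np.ndarray) -> np.ndarray:
        """Linear interpolation with nearest-edge hold outside the trace."""
        return np.interp(np.asarray(times, dtype=float), self.time, self.value)

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time, "etco2_mmhg": self.value}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "EtCO2Trace":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(), df["etco2_mmhg"].to_numpy())


@dataclass(frozen=True)
class BoldSeries:
    """4D BOLD array (x, y, z, volume) with its volume repetition time (s)."""

    data: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", d)
        if d.ndim != 4:
            raise ValueError("BOLD data must be 4D (x, y, z, volume)")
        if d.shape[-1] < 20:
            raise ValueError("BOLD series needs >=20 volumes")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not np.all(np.isfinite(d)):
            raise ValueError("BOLD data must be finite")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]

    @property
    def shape(self) -> tuple:
        return self.data.shape[:3]


@dataclass(frozen=True)
class CVRResult:
    """Single CVR fit: amplitude, optimal delay and diagnostics."""

    cvr: float                 # % BOLD per mmHg
    delay: float               # fitted delay (s), on the search grid
    intercept: float           # signal units
    drift_slope: float         # signal units per volume
    rss: float                 # residual sum of squares
    r_squared: float
    instrument_offset: float = DEFAULT_INSTRUMENT_OFFSET

    @property
    def total_delay(self) -> float:
        """Physiological + instrument shift applied to the regressor (s)."""
        return self.delay + self.instrument_offset


@dataclass
class CVRMap:
    """Voxel-wise CVR, delay and fit quality volumes on the BOLD grid."""

    cvr: np.ndarray
    delay: np.ndarray
    r_squared: np.ndarray
    mask: np.ndarray
    instrument_offset: float = DEFAULT_INSTRUMENT_OFFSET
    n_failed: int = 0
    failed_voxels: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# regressor construction
# ---------------------------------------------------------------------------

def extract_end_tidal(
    time: np.ndarray,
    co2: np.ndarray,
    min_breath_interval: float = 2.0,
    already_end_tidal: bool = False,
) -> EtCO2Trace:
    """Reduce a raw capnogram to one end-tidal sample per expiratory peak.

    Parameters
    ----------
    time, co2
        Raw capnogram samples (s, mmHg), regularly or near-regularly sampled.
    min_breath_interval
        Minimum separation between successive expiratory peaks (s).
    already_end_tidal
        If True the input is passed through unchanged (it is already one
        sample per breath).
    """
    time = np.asarray(time, dtype=float)
    co2 = np.asarray(co2, dtype=float)
    if already_end_tidal:
        return EtCO2Trace(time, co2)
    if time.size < 3:
        raise EmptyTraceError("capnogram too short to contain breaths")
    dt = float(np.median(np.diff(time)))
    distance = max(1, int(round(min_breath_interval / dt)))
    peaks, _ = find_peaks(co2, distance=distance)
    if peaks.size == 0:
        raise EmptyTraceError("no expiratory peaks detected in capnogram")
    return EtCO2Trace(time[peaks], co2[peaks])


def build_regressor(
    trace: EtCO2Trace,
    tr: float,
    n_volumes: int,
    delay: float,
    instrument_offset: float = DEFAULT_INSTRUMENT_OFFSET,
) -> np.ndarray:
    """EtCO2 regressor sampled at volume acquisition times.

    ``regressor[v] = EtCO2(v*tr - delay - instrument_offset)`` with linear
    interpolation; times outside the trace are held at the nearest edge
    value.  Raises :class:`CoverageError` when every shifted sample time
    falls outside the trace (the regressor would be meaningless).
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    times = np.arange(n_volumes, dtype=float) * tr - delay - instrument_offset
    if times[-1] < trace.time[0] or times[0] > trace.time[-1]:
        raise CoverageError(
            "shifted volume times entirely outside the EtCO2 trace"
        )
    return trace.sample_at(times)


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def _grid_fit(Y, trace, tr, delay_grid, instrument_offset):
    """OLS of each column of Y on [1, regressor, volume index] per delay.

    Returns per-column arrays (beta 3xV at best delay, best delay, rss, tss).
    Ties in RSS resolve to the smallest delay (ascending scan, strict <).
    """
    n, n_vox = Y.shape
    if n < 4:
        raise ValueError("need at least 4 volumes to fit the 3-term model")
    delays = np.sort(np.asarray(delay_grid, dtype=float))
    if delays.size == 0:
        raise ValueError("delay grid must be nonempty")
    vol = np.arange(n, dtype=float)

    best_rss = np.full(n_vox, np.inf)
    best_beta = np.zeros((3, n_vox))
    best_delay = np.full(n_vox, np.nan)
    n_usable = 0
    for d in delays:
        reg = build_regressor(trace, tr, n, d, instrument_offset)
        if np.ptp(reg) == 0.0:
            continue  # flat regressor at this shift: no CO2 information
        n_usable += 1
        X = np.column_stack([np.ones(n), reg, vol])
        Q, R = np.linalg.qr(X)
        beta = np.linalg.solve(R, Q.T @ Y)
        resid = Y - X @ beta
        rss = np.einsum("ij,ij->j", resid, resid)
        upd = rss < best_rss
        if np.any(upd):
            best_rss[upd] = rss[upd]
            best_beta[:, upd] = beta[:, upd]
            best_delay[upd] = d
    if n_usable == 0:
        raise DegenerateDesignError(
            "EtCO2 regressor has zero variance at every candidate delay"
        )
    tss = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    return best_beta, best_delay, np.maximum(best_rss, 0.0), tss


def _r_squared(rss, tss):
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(tss > 0, 1.0 - rss / tss, 0.0)
    return np.clip(r2, 0.0, 1.0)


def fit_cvr(
    series: np.ndarray,
    trace: EtCO2Trace,
    tr: float,
    delay_grid: np.ndarray | None = None,
    instrument_offset: float = DEFAULT_INSTRUMENT_OFFSET,
) -> CVRResult:
    """Fit the CVR model to one (voxel or ROI-mean) BOLD time series.

    For each candidate delay the signal is regressed on the shifted EtCO2
    regressor plus an intercept and the scan number; the delay with minimal
    RSS wins.  ``cvr = 100 * beta_etco2 / mean(series)`` (% per mmHg).
    """
    y = np.asarray(series, dtype=float).ravel()
    if delay_grid is None:
        delay_grid = DEFAULT_DELAY_GRID
    mean_sig = y.mean()
    if mean_sig == 0.0:
        raise NormalizationError("zero mean signal: percent CVR undefined")
    beta, delay, rss, tss = _grid_fit(
        y[:, None], trace, tr, delay_grid, instrument_offset
    )
    return CVRResult(
        cvr=float(100.0 * beta[1, 0] / mean_sig),
        delay=float(delay[0]),
        intercept=float(beta[0, 0]),
        drift_slope=float(beta[2, 0]),
        rss=float(rss[0]),
        r_squared=float(_r_squared(rss, tss)[0]),
        instrument_offset=instrument_offset,
    )


def fit_cvr_map(
    series: BoldSeries,
    trace: EtCO2Trace,
    mask: np.ndarray,
    delay_grid: np.ndarray | None = None,
    instrument_offset: float = DEFAULT_INSTRUMENT_OFFSET,
) -> CVRMap:
    """Voxel-wise CVR fit over ``mask``; failed voxels become NaN.

    A voxel fails when its mean signal is zero (percent normalisation
    undefined); failures are logged and counted, never silently zeroed.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != series.shape:
        raise ValueError("mask shape does not match BOLD grid")
    if not mask.any():
        raise EmptyMaskError("mask selects no voxels")
    if delay_grid is None:
        delay_grid = DEFAULT_DELAY_GRID

    Y = series.data[mask].T  # (volumes, voxels)
    mean_sig = Y.mean(axis=0)
    ok = mean_sig != 0.0
    beta, delay, rss, tss = _grid_fit(
        Y, trace, series.tr, delay_grid, instrument_offset
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        cvr_flat = np.where(ok, 100.0 * beta[1] / mean_sig, np.nan)
    delay_flat = np.where(ok, delay, np.nan)
    r2_flat = np.where(ok, _r_squared(rss, tss), np.nan)

    shape = series.shape
    out = CVRMap(
        cvr=np.full(shape, np.nan),
        delay=np.full(shape, np.nan),
        r_squared=np.full(shape, np.nan),
        mask=mask,
        instrument_offset=instrument_offset,
        n_failed=int((~ok).sum()),
    )
    out.cvr[mask] = cvr_flat
    out.delay[mask] = delay_flat
    out.r_squared[mask] = r2_flat
    if out.n_failed:
        idx = np.argwhere(mask)[~ok]
        out.failed_voxels = [tuple(v) for v in idx]
        logger.warning("fit_cvr_map: %d voxel(s) failed normalisation", out.n_failed)
    return out


def roi_cvr(
    series: BoldSeries,
    roi_masks: dict,
    trace: EtCO2Trace,
    exclusion_mask: np.ndarray | None = None,
    delay_grid: np.ndarray | None = None,
    instrument_offset: float = DEFAULT_INSTRUMENT_OFFSET,
    groups: dict | None = None,
) -> pd.DataFrame:
    """Fit the CVR model to ROI-mean time series.

    Each ROI's voxel series are averaged over ``roi - exclusion`` (large
    vessels / stroke lesion voxels excluded), then a single CVR model is
    fitted to the mean series.  ``groups`` (e.g. white_matter -> ROI names)
    adds combined rows whose CVR/delay/r2 are unweighted means of the
    constituent ROI values, ignoring failed ROIs.

    Returns a table with columns
    ``roi, cvr_pct_per_mmhg, delay_s, r2, n_voxels, error``.
    """
    if exclusion_mask is None:
        exclusion_mask = np.zeros(series.shape, dtype=bool)
    exclusion_mask = np.asarray(exclusion_mask).astype(bool)

    rows = []
    for name, roi in roi_masks.items():
        eff = np.asarray(roi).astype(bool) & ~exclusion_mask
        n_vox = int(eff.sum())
        if n_vox == 0:
            logger.warning("ROI %s fully excluded; skipping", name)
            rows.append(
                dict(roi=name, cvr_pct_per_mmhg=np.nan, delay_s=np.nan,
                     r2=np.nan, n_voxels=0, error="fully excluded")
            )
            continue
        mean_series = series.data[eff].mean(axis=0)
        try:
            res = fit_cvr(mean_series, trace, series.tr, delay_grid,
                          instrument_offset)
            rows.append(
                dict(roi=name, cvr_pct_per_mmhg=res.cvr, delay_s=res.delay,
                     r2=res.r_squared, n_voxels=n_vox, error="")
            )
        except (NormalizationError, DegenerateDesignError) as exc:
            logger.warning("ROI %s fit failed: %s", name, exc)
            rows.append(
                dict(roi=name, cvr_pct_per_mmhg=np.nan, delay_s=np.nan,
                     r2=np.nan, n_voxels=n_vox, error=str(exc))
            )
    table = pd.DataFrame(rows)

    if groups:
        combined = []
        for gname, members in groups.items():
            sub = table[table["roi"].isin(members)]
            sub = sub[sub["cvr_pct_per_mmhg"].notna()]
            combined.append(
                dict(
                    roi=gname,
                    cvr_pct_per_mmhg=sub["cvr_pct_per_mmhg"].mean(),
                    delay_s=sub["delay_s"].mean(),
                    r2=sub["r2"].mean(),
                    n_voxels=int(sub["n_voxels"].sum()),
                    error="" if len(sub) else "no member ROI succeeded",
                )
            )
        table = pd.concat([table, pd.DataFrame(combined)], ignore_index=True)
    return table
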