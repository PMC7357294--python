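"""Pulsatility, resistivity, total CBF and CSF flow dynamics.

All computations work on cardiac-gated flow waveforms: one composite
cardiac cycle of flow (mL/s) at P phases (P = 32 for the standard cine
phase-contrast acquisition).  Cranial flow is positive by convention;
waveform files declare their orientation and are sign-flipped on read if
caudal-positive.

Pulsatility index  PI = (Fmax - Fmin) / Fmean
Resistivity index  RI = (Fmax - Fmin) / Fmax
CSF net flow and stroke volume come from cyclic trapezoidal integration of
the positive (cranial) and negative (caudal) parts of the waveform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    MissingAreaError,
    MissingStructureError,
    WrongStructureWarning,
)

#: structures measured at the three phase-contrast slice locations
ARTERIAL_STRUCTURES = ("ICA-L", "ICA-R", "VA-L", "VA-R")
VENOUS_STRUCTURES = ("SSS", "StS", "TS-L", "TS-R", "IJV-L", "IJV-R")
CSF_STRUCTURES = ("aqueduct", "foramen-magnum")
BILATERAL_PAIRS = {
    "ICA": ("ICA-L", "ICA-R"),
    "VA": ("VA-L", "VA-R"),
    "TS": ("TS-L", "TS-R"),
    "IJV": ("IJV-L", "IJV-R"),
}


@dataclass(frozen=True)
class FlowWaveform:
    """One composite cardiac cycle of flow (mL/s) for a named structure."""

    structure: str
    flow: np.ndarray            # mL/s per cardiac phase, cranial positive
    cycle_duration: float       # s
    background_velocity: float | None = None   # cm/s
    roi_area: float | None = None              # cm^2

    def __post_init__(self) -> None:
        f = np.asarray(self.flow, dtype=float)
        object.__setattr__(self, "flow", f)
        if f.ndim != 1 or f.size < 8:
            raise ValueError("waveform needs >=8 cardiac phases")
        if self.cycle_duration <= 0:
            raise ValueError("cycle_duration must be positive")
        if not np.all(np.isfinite(f)):
            raise ValueError("flow values must be finite")

    @property
    def n_phases(self) -> int:
        return self.flow.size

    @property
    def mean_flow(self) -> float:
        return float(self.flow.mean())


@dataclass(frozen=True)
class PulsatilityMetrics:
    flow_max: float
    flow_min: float
    flow_mean: float
    pi: float
    ri: float


@dataclass(frozen=True)
class CSFDynamics:
    net_flow: float         # mL/min, cranial positive
    stroke_volume: float    # mL per cardiac cycle
    cranial_volume: float   # mL per cycle
    caudal_volume: float    # mL per cycle


# ---------------------------------------------------------------------------
# corrections and composition
# ---------------------------------------------------------------------------

def correct_background(
    waveform: FlowWaveform,
    background: float | None = None,
    roi_area: float | None = None,
) -> FlowWaveform:
    """Subtract the background phase-error velocity from a waveform.

    The background velocity (cm/s, measured in static tissue next to the
    ROI) times the ROI area (cm^2) is a constant spurious flow (mL/s)
    removed from every phase.  Arguments default to the waveform's own
    ``background_velocity`` / ``roi_area`` fields.
    """
    if background is None:
        background = waveform.background_velocity
    if roi_area is None:
        roi_area = waveform.roi_area
    if background is None or background == 0.0:
        return waveform
    if roi_area is None:
        raise MissingAreaError(
            f"{waveform.structure}: background velocity given without ROI area"
        )
    if roi_area <= 0:
        raise ValueError("roi_area must be positive")
    return replace(waveform, flow=waveform.flow - background * roi_area,
                   background_velocity=0.0)


def sum_bilateral(left: FlowWaveform, right: FlowWaveform,
                  name: str | None = None) -> FlowWaveform:
    """Phase-wise sum of a bilateral pair (e.g. ICA-L + ICA-R)."""
    if left.n_phases != right.n_phases:
        raise ValueError("bilateral waveforms must share the phase count")
    if abs(left.cycle_duration - right.cycle_duration) > 1e-9:
        raise ValueError("bilateral waveforms must share the cycle duration")
    return FlowWaveform(
        structure=name or f"{left.structure}+{right.structure}",
        flow=left.flow + right.flow,
        cycle_duration=left.cycle_duration,
    )


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def pulsatility_metrics(waveform: FlowWaveform) -> PulsatilityMetrics:
    """Max/min/mean flow with pulsatility and resistivity indices.

    PI requires a nonzero mean flow, RI a nonzero maximum; an all-equal
    waveform has PI = RI = 0.  Zero mean with varying flow (a CSF-like
    waveform) raises: PI is undefined there.
    """
    f = waveform.flow
    fmax, fmin, fmean = float(f.max()), float(f.min()), float(f.mean())
    spread = fmax - fmin
    if spread == 0.0:
        pi = ri = 0.0
    else:
        if abs(fmean) < 1e-12 * spread:  # zero up to float round-off
            raise ZeroDivisionError(
                f"{waveform.structure}: PI undefined for zero mean flow"
            )
        pi = spread / fmean
        ri = spread / fmax if fmax != 0.0 else float("nan")
    return PulsatilityMetrics(fmax, fmin, fmean, pi, ri)


def total_cbf(waveforms: dict, brain_volume: float) -> float:
    """Total cerebral blood flow normalised to brain volume.

    Sum of mean ICA-L/R + VA-L/R flow converted to mL/min, per 100 mL of
    brain tissue: ``(sum of mean flows * 60) / brain_volume * 100``.
    """
    if brain_volume <= 0:
        raise ValueError("brain_volume must be positive")
    missing = [s for s in ARTERIAL_STRUCTURES if s not in waveforms]
    if missing:
        raise MissingStructureError(
            "total CBF needs all four arterial inputs; missing: "
            + ", ".join(missing)
        )
    total_ml_min = 60.0 * sum(
        waveforms[s].mean_flow for s in ARTERIAL_STRUCTURES
    )
    return total_ml_min / brain_volume * 100.0


def csf_dynamics(waveform: FlowWaveform) -> CSFDynamics:
    """Net CSF flow and stroke volume over one composite cardiac cycle.

    Cranial (positive) and caudal (negative) flow are integrated separately
    by the cyclic trapezoidal rule (the cycle wraps from the last phase back
    to the first).  Net flow is expressed in mL/min; stroke volume is the
    mean of the absolute cranial and caudal per-cycle volumes, i.e. the
    volume of CSF moved back and forth per heartbeat.
    """
    if waveform.structure not in CSF_STRUCTURES:
        warnings.warn(
            f"csf_dynamics on non-CSF structure {waveform.structure!r}",
            WrongStructureWarning,
            stacklevel=2,
        )
    f = waveform.flow
    T = waveform.cycle_duration
    closed = np.append(f, f[0])          # cyclic closure
    dt = T / waveform.n_phases
    pos = np.clip(closed, 0.0, None)
    neg = np.clip(-closed, 0.0, None)
    cranial = float(np.trapezoid(pos, dx=dt))
    caudal = float(np.trapezoid(neg, dx=dt))
    return CSFDynamics(
        net_flow=(cranial - caudal) * 60.0 / T,
        stroke_volume=0.5 * (cranial + caudal),
        cranial_volume=cranial,
        caudal_volume=caudal,
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------
# Format: leading "key=value" header lines (structure=, cycle_duration_s=,
# orientation=, optionally background_velocity_cm_s=, roi_area_cm2=), then a
# CSV table with either phase_index,flow_ml_s or
# phase_index,velocity_cm_s,area_cm2.

def write_waveform_csv(waveform: FlowWaveform, path,
                       orientation: str = "cranial-positive") -> None:
    path = Path(path)
    lines = [
        f"structure={waveform.structure}",
        f"cycle_duration_s={float(waveform.cycle_duration)!r}",
        f"orientation={orientation}",
    ]
    if waveform.background_velocity is not None:
        lines.append(
            f"background_velocity_cm_s={float(waveform.background_velocity)!r}")
    if waveform.roi_area is not None:
        lines.append(f"roi_area_cm2={float(waveform.roi_area)!r}")
    lines.append("phase_index,flow_ml_s")
    flow = waveform.flow if orientation == "cranial-positive" else -waveform.flow
    lines += [f"{k},{float(v)!r}" for k, v in enumerate(flow)]
    path.write_text("\n".join(lines) + "\n")


def read_waveform_csv(path) -> FlowWaveform:
    """Parse a waveform file; caudal-positive input is sign-flipped."""
    text = Path(path).read_text().strip().splitlines()
    header = {}
    i = 0
    while "=" in text[i] and "," not in text[i]:
        key, _, val = text[i].partition("=")
        header[key.strip()] = val.strip()
        i += 1
    df = pd.read_csv(Path(path), skiprows=i)
    if "flow_ml_s" in df.columns:
        flow = df["flow_ml_s"].to_numpy(dtype=float)
    elif {"velocity_cm_s", "area_cm2"} <= set(df.columns):
        flow = (df["velocity_cm_s"] * df["area_cm2"]).to_numpy(dtype=float)
    else:
        raise ValueError(f"{path}: no flow_ml_s or velocity_cm_s/area_cm2 columns")
    orientation = header.get("orientation", "cranial-positive")
    if orientation == "caudal-positive":
        flow = -flow
    elif orientation != "cranial-positive":
        raise ValueError(f"{path}: unknown orientation {orientation!r}")
    bg = header.get("background_velocity_cm_s")
    area = header.get("roi_area_cm2")
    return FlowWaveform(
        structure=header["structure"],
        flow=flow,
        cycle_duration=float(header["cycle_duration_s"]),
        background_velocity=float(bg) if bg is not None else None,
        roi_area=float(area) if area is not None else None,
    )


def metrics_table(waveforms: dict, brain_volume: float | None = None) -> pd.DataFrame:
    """Summary table over a waveform set.

    Bilateral structures are summed phase-wise before PI/RI; CSF structures
    additionally get net flow and stroke volume.  A ``total_cbf`` row (in
    mL/min/100 mL) is appended when all four arterial structures and a brain
    volume are available.
    """
    corrected = {}
    for name, wf in waveforms.items():
        corrected[name] = correct_background(wf) if wf.background_velocity else wf

    entries = dict(corrected)
    for name, (l, r) in BILATERAL_PAIRS.items():
        if l in corrected and r in corrected:
            entries[name] = sum_bilateral(corrected[l], corrected[r], name)

    rows = []
    for name, wf in entries.items():
        row = dict(structure=name, flow_mean=wf.mean_flow,
                   pi=np.nan, ri=np.nan, net_flow=np.nan, stroke_volume=np.nan)
        if name in CSF_STRUCTURES:
            dyn = csf_dynamics(wf)
            row.update(net_flow=dyn.net_flow, stroke_volume=dyn.stroke_volume)
        else:
            try:
                m = pulsatility_metrics(wf)
                row.update(pi=m.pi, ri=m.ri)
            except ZeroDivisionError:
                pass
        rows.append(row)

    if brain_volume is not None and all(
        s in corrected for s in ARTERIAL_STRUCTURES
    ):
        rows.append(dict(structure="total_cbf",
                         flow_mean=total_cbf(corrected, brain_volume),
                         pi=np.nan, ri=np.nan,
                         net_flow=np.nan, stroke_volume=np.nan))
    return pd.DataFrame(rows)
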