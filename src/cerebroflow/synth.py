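"""Synthetic data generation with recorded ground truth.

Every generator mirrors one acquisition of the study design — the
block-paradigm EtCO2 recording, the BOLD series during the CO2 challenge,
cardiac-gated flow waveforms, FLAIR images with implanted hyperintense
lesions, and the per-subject cohort table — and returns the
:class:`GroundTruth` it was built from, so each downstream analysis stage
can be validated by parameter recovery.

All randomness flows through an explicit integer seed (one
``numpy.random.default_rng`` per call); no global random state is touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cvr import EtCO2Trace, BoldSeries, build_regressor
from .exceptions import CoverageError, InvalidSpecError
from .flow import FlowWaveform

#: air/CO2 alternation of the 12-minute hypercapnic challenge:
#: 2 min air, 3 min CO2, 2 min air, 3 min CO2, 2 min air (720 s total)
DEFAULT_BLOCKS = (
    ("air", 120.0),
    ("co2", 180.0),
    ("air", 120.0),
    ("co2", 180.0),
    ("air", 120.0),
)


@dataclass(frozen=True)
class ParadigmSpec:
    """Gas-delivery paradigm for the hypercapnic challenge.

    ``hypercapnic_delta`` is the EtCO2 rise (mmHg) produced by breathing
    the CO2 mixture (6% CO2 in air raises EtCO2 by roughly 10 mmHg);
    ``breath_period`` sets one end-tidal sample per simulated breath.
    """

    block_sequence: tuple = DEFAULT_BLOCKS
    baseline_etco2: float = 40.0
    hypercapnic_delta: float = 10.0
    breath_period: float = 4.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not self.block_sequence:
            raise InvalidSpecError("block sequence is empty")
        for label, dur in self.block_sequence:
            if dur <= 0:
                raise InvalidSpecError(f"block {label!r} has duration {dur}")
        if self.hypercapnic_delta < 0:
            raise InvalidSpecError("hypercapnic_delta must be >= 0")
        if self.breath_period <= 0:
            raise InvalidSpecError("breath_period must be positive")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")

    @property
    def total_duration(self) -> float:
        return float(sum(d for _, d in self.block_sequence))

    def level_at(self, t: np.ndarray) -> np.ndarray:
        """Noise-free EtCO2 level at time(s) t (block lookup)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        edges, levels = [0.0], []
        for label, dur in self.block_sequence:
            edges.append(edges[-1] + dur)
            levels.append(
                self.baseline_etco2
                + (self.hypercapnic_delta if label == "co2" else 0.0)
            )
        idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0,
                      len(levels) - 1)
        return np.asarray(levels)[idx]


@dataclass
class GroundTruth:
    """Generating parameters carried alongside every synthetic dataset."""

    cvr_gain: dict = field(default_factory=dict)        # %/mmHg per tissue
    true_delay: dict = field(default_factory=dict)      # s per tissue
    drift_slope: float = 0.0                            # signal per volume
    pi_true: dict = field(default_factory=dict)
    ri_true: dict = field(default_factory=dict)
    stroke_volume_true: float | None = None             # mL
    cohort_coefficients: dict = field(default_factory=dict)
    residual_sd: float | None = None

    def to_sidecar(self, path) -> None:
        """Flat key-value JSON sidecar next to the dataset."""
        flat = {}
        for key, val in asdict(self).items():
            if isinstance(val, dict):
                for k, v in val.items():
                    if isinstance(v, dict):   # nested outcome -> term -> slope
                        for kk, vv in v.items():
                            flat[f"{key}.{k}.{kk}"] = vv
                    else:
                        flat[f"{key}.{k}"] = v
            elif val is not None:
                flat[key] = val
        Path(path).write_text(json.dumps(flat, indent=1, sort_keys=True))

    @classmethod
    def from_sidecar(cls, path) -> "GroundTruth":
        flat = json.loads(Path(path).read_text())
        out = cls()
        for key, val in flat.items():
            parts = key.split(".")
            target = getattr(out, parts[0])
            if len(parts) == 1:
                setattr(out, key, val)
            else:
                for p in parts[1:-1]:
                    target = target.setdefault(p, {})
                target[parts[-1]] = val
        return out


# ---------------------------------------------------------------------------
# EtCO2 and BOLD
# ---------------------------------------------------------------------------

def gen_etco2_trace(spec: ParadigmSpec | None = None, seed: int = 0) -> EtCO2Trace:
    """Breath-by-breath end-tidal CO2 trace for a block paradigm.

    One sample per simulated breath (``spec.breath_period`` apart) spanning
    the whole paradigm; the value is the block level plus Gaussian
    measurement noise.
    """
    if spec is None:
        spec = ParadigmSpec()
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, spec.total_duration + spec.breath_period / 2,
                  spec.breath_period)
    v = spec.level_at(t)
    if spec.noise_sd > 0:
        v = v + rng.normal(0.0, spec.noise_sd, size=t.shape)
    return EtCO2Trace(t, v)


def gen_bold_series(
    trace: EtCO2Trace,
    truth: GroundTruth,
    tr: float = 3.0,
    shape: tuple = (10, 10, 6),
    n_volumes: int | None = None,
    baseline: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    label_image: np.ndarray | None = None,
) -> tuple[BoldSeries, np.ndarray]:
    """Forward-model a BOLD series from an EtCO2 trace and tissue truths.

    Each voxel of tissue ``lab`` follows::

        baseline * (1 + gain[lab]/100 * (EtCO2(t - delay[lab]) - mean))
        + drift_slope * volume_index + Normal(0, noise_sd)

    where ``mean`` is the scan-average of the shifted EtCO2 regressor, so
    the gain is percent signal change per mmHg relative to the voxel's mean
    signal — the convention the CVR fit uses for its normalisation, making
    the noiseless round trip exact.

    Returns the series and an integer label image (0 = background /
    outside brain is absent by default: all voxels are labelled, tissues
    split as contiguous slabs along the first axis unless ``label_image``
    is given; labels index ``sorted(truth.cvr_gain)`` from 1).
    """
    if tr <= 0:
        raise InvalidSpecError("tr must be positive")
    labels = sorted(truth.cvr_gain)
    if not labels:
        raise InvalidSpecError("truth.cvr_gain must name at least one tissue")
    if n_volumes is None:
        n_volumes = int(trace.duration // tr)
    if (n_volumes - 1) * tr > trace.time[-1]:
        raise CoverageError(
            f"trace spans {trace.time[-1]:.1f} s but series needs "
            f"{(n_volumes - 1) * tr:.1f} s"
        )
    if label_image is None:
        label_image = np.zeros(shape, dtype=int)
        slabs = np.array_split(np.arange(shape[0]), len(labels))
        for i, sl in enumerate(slabs):
            label_image[sl] = i + 1
    else:
        label_image = np.asarray(label_image, dtype=int)
        if label_image.shape != tuple(shape):
            raise InvalidSpecError("label_image shape must match grid shape")
        if not set(np.unique(label_image)) - {0} <= set(
            range(1, len(labels) + 1)
        ):
            raise InvalidSpecError("label_image values exceed tissue labels")

    rng = np.random.default_rng(seed)
    vol_idx = np.arange(n_volumes, dtype=float)
    data = np.zeros((*shape, n_volumes))
    for i, lab in enumerate(labels, start=1):
        vox = label_image == i
        if not vox.any():
            continue
        reg = build_regressor(trace, tr, n_volumes,
                              delay=truth.true_delay.get(lab, 0.0),
                              instrument_offset=0.0)
        clean = baseline * (1.0 + truth.cvr_gain[lab] / 100.0
                            * (reg - reg.mean()))
        clean = clean + truth.drift_slope * vol_idx
        data[vox] = clean
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, size=data.shape)
    return BoldSeries(data, tr), label_image


# ---------------------------------------------------------------------------
# flow waveforms
# ---------------------------------------------------------------------------

def gen_flow_waveform(
    mean_flow: float,
    pulse_amplitude: float,
    phases: int = 32,
    cycle: float = 1.0,
    structure: str = "SSS",
    waveform: str = "sinusoid",
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[FlowWaveform, GroundTruth]:
    """Cardiac-cycle flow waveform with closed-form pulsatility truth.

    The canonical shape is the sinusoid ``flow(k) = mean + A*sin(2*pi*k/P)``
    whose PI is ``2A/mean`` (mean > 0), RI ``2A/(mean+A)``, and — for a
    zero-mean CSF-like cycle — stroke volume ``A*cycle/pi``.  The optional
    ``waveform="systolic"`` shape is a systolic-peaked von Mises pulse
    (more realistic arterial shape) with no closed form; it is validated
    against brute-force numerical oracles only.
    """
    if phases < 8:
        raise InvalidSpecError("phases must be >= 8")
    if pulse_amplitude < 0:
        raise InvalidSpecError("pulse_amplitude must be >= 0")
    if cycle <= 0:
        raise InvalidSpecError("cycle must be positive")
    theta = 2.0 * np.pi * np.arange(phases) / phases
    if waveform == "sinusoid":
        flow = mean_flow + pulse_amplitude * np.sin(theta)
    elif waveform == "systolic":
        # von Mises bump at early systole, centred so the cycle mean stays
        # mean_flow and the peak-to-trough span stays 2*pulse_amplitude
        kappa = 4.0
        bump = np.exp(kappa * (np.cos(theta - np.pi / 4) - 1.0))
        bump = bump - bump.mean()
        span = bump.max() - bump.min()
        flow = mean_flow + 2.0 * pulse_amplitude * bump / span
    else:
        raise InvalidSpecError(f"unknown waveform shape {waveform!r}")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        flow = flow + rng.normal(0.0, noise_sd, size=flow.shape)

    truth = GroundTruth()
    if waveform == "sinusoid":
        if mean_flow > 0:
            truth.pi_true[structure] = 2.0 * pulse_amplitude / mean_flow
            truth.ri_true[structure] = (
                2.0 * pulse_amplitude / (mean_flow + pulse_amplitude)
                if mean_flow + pulse_amplitude > 0 else 0.0
            )
        if mean_flow == 0.0:
            truth.stroke_volume_true = pulse_amplitude * cycle / np.pi
    return FlowWaveform(structure, flow, cycle), truth


# ---------------------------------------------------------------------------
# structural images
# ---------------------------------------------------------------------------

def sphere_coords(center: tuple, radius: float, shape: tuple) -> np.ndarray:
    """Integer voxel coordinates of a ball, clipped to the grid."""
    grids = np.indices(shape)
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return np.argwhere(d2 <= radius**2)


def gen_structural_images(
    shape: tuple = (40, 40, 40),
    wm_mean: float = 100.0,
    wm_sd: float = 10.0,
    lesion_voxels: np.ndarray | list = (),
    lesion_z: float = 3.0,
    seed: int = 0,
    wm_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """FLAIR-like image with implanted hyperintense lesions.

    Background white matter is Normal(wm_mean, wm_sd); lesion voxels are
    Normal(wm_mean + lesion_z * wm_sd, wm_sd) — the same acquisition noise
    on a shifted mean.  Returns (flair, wm_mask, truth_lesion_mask).
    """
    if wm_sd < 0:
        raise InvalidSpecError("wm_sd must be >= 0")
    if wm_mask is None:
        wm_mask = np.ones(shape, dtype=bool)
    else:
        wm_mask = np.asarray(wm_mask).astype(bool)
        if wm_mask.shape != tuple(shape):
            raise InvalidSpecError("wm_mask shape must match grid shape")
    rng = np.random.default_rng(seed)
    flair = rng.normal(wm_mean, wm_sd, size=shape) if wm_sd > 0 else np.full(
        shape, float(wm_mean)
    )
    truth = np.zeros(shape, dtype=bool)
    coords = np.asarray(list(lesion_voxels), dtype=int)
    if coords.size:
        if coords.ndim != 2 or coords.shape[1] != len(shape):
            raise InvalidSpecError("lesion_voxels must be (n, ndim) coordinates")
        if (coords < 0).any() or (coords >= np.asarray(shape)).any():
            raise InvalidSpecError("lesion voxel outside the grid")
        ijk = tuple(coords.T)
        if not wm_mask[ijk].all():
            raise InvalidSpecError("lesion voxel outside the white matter mask")
        flair[ijk] = rng.normal(wm_mean + lesion_z * wm_sd, wm_sd,
                                size=len(coords))
        truth[ijk] = True
    return flair, wm_mask, truth


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

#: covariate distributions mirroring the study cohort (n=53, age 68.0±8.8,
#: 74% male; SBP spread typical of a treated hypertensive stroke cohort)
DEFAULT_COVARIATES = {
    "age": ("normal", 68.0, 8.8),
    "sex": ("bernoulli", 0.74),
    "sbp": ("normal", 140.0, 15.0),
    "log10_wmh": ("normal", 1.0, 1.0),
}

DEFAULT_COEFFICIENTS = {
    "wm_cvr": {"intercept": 0.20, "log10_wmh": -0.013},
}


def calibrate_residual_sd(ci_half_width: float, n: int,
                          predictor_sd: float) -> float:
    """Residual SD reproducing a printed univariate 95% CI half-width.

    For OLS of y on one predictor with SD ``predictor_sd``,
    ``half_width = t_{0.975,n-2} * sigma / (predictor_sd * sqrt(n-1))``;
    invert for sigma.
    """
    if ci_half_width <= 0 or predictor_sd <= 0 or n < 4:
        raise InvalidSpecError("need positive half-width/SD and n >= 4")
    tcrit = sps.t.ppf(0.975, n - 2)
    return ci_half_width * predictor_sd * np.sqrt(n - 1) / tcrit


def _draw(spec, n, rng):
    kind = spec[0]
    if kind == "normal":
        return rng.normal(spec[1], spec[2], size=n)
    if kind == "bernoulli":
        return (rng.random(n) < spec[1]).astype(float)
    if kind == "lognormal":
        return rng.lognormal(spec[1], spec[2], size=n)
    if kind == "uniform":
        return rng.uniform(spec[1], spec[2], size=n)
    raise InvalidSpecError(f"unknown covariate distribution {kind!r}")


def gen_cohort_table(
    n: int = 53,
    coefficients: dict | None = None,
    covariate_spec: dict | None = None,
    residual_sd: float | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Cohort table with independently drawn covariates and linear outcomes.

    ``coefficients`` maps each outcome to ``{"intercept": c, predictor:
    slope, ...}``; every named predictor must appear in ``covariate_spec``.
    Outcomes are ``intercept + sum(slope * predictor) + Normal(0,
    residual_sd)``.  Covariates are mutually independent, so marginal and
    covariate-adjusted slopes share the same generative truth.
    """
    if coefficients is None:
        coefficients = DEFAULT_COEFFICIENTS
    if covariate_spec is None:
        covariate_spec = DEFAULT_COVARIATES
    if residual_sd is None:
        residual_sd = calibrate_residual_sd(0.0075, n=53, predictor_sd=1.0)
    if residual_sd < 0:
        raise InvalidSpecError("residual_sd must be >= 0")
    n_pred = max(
        (len([k for k in terms if k != "intercept"])
         for terms in coefficients.values()),
        default=0,
    )
    if n < 3 + n_pred:
        raise InvalidSpecError(f"n={n} too small for {n_pred} predictor(s)")

    rng = np.random.default_rng(seed)
    table = pd.DataFrame({"id": [f"S{i:03d}" for i in range(1, n + 1)]})
    for name, spec in covariate_spec.items():
        table[name] = _draw(spec, n, rng)
    for outcome, terms in coefficients.items():
        y = np.full(n, float(terms.get("intercept", 0.0)))
        for pred, slope in terms.items():
            if pred == "intercept":
                continue
            if pred not in table.columns:
                raise InvalidSpecError(
                    f"outcome {outcome!r} references unknown predictor {pred!r}"
                )
            y = y + slope * table[pred].to_numpy()
        if residual_sd > 0:
            y = y + rng.normal(0.0, residual_sd, size=n)
        table[outcome] = y
    truth = GroundTruth(cohort_coefficients=coefficients,
                        residual_sd=residual_sd)
    return table, truth
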