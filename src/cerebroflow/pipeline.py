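"""End-to-end orchestration: simulate -> cvr -> flow -> structural -> cohort.

A :class:`PipelineConfig` (YAML or dict) toggles stages and carries their
parameters.  The master seed is expanded deterministically into per-stage
seeds, so any stage is reproducible in isolation; every stage directory
gets a provenance sidecar (config hash, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cvr import (
    DEFAULT_INSTRUMENT_OFFSET,
    BoldSeries,
    EtCO2Trace,
    fit_cvr_map,
    roi_cvr,
)
from .exceptions import ConfigError, StageDependencyError
from .flow import metrics_table, read_waveform_csv, write_waveform_csv
from .stats import diagnostics, fit_association, run_model_grid
from .structural import segment_wmh
from .synth import (
    GroundTruth,
    ParadigmSpec,
    gen_bold_series,
    gen_cohort_table,
    gen_etco2_trace,
    gen_flow_waveform,
    gen_structural_images,
    sphere_coords,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "cvr", "flow", "structural", "cohort")

DEFAULT_MODELS = [
    {"outcome": "wm_cvr", "predictor": "log10_wmh", "adjust": []},
    {"outcome": "wm_cvr", "predictor": "log10_wmh",
     "adjust": ["age", "sex", "sbp"]},
]


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``from_yaml``)."""

    out_dir: str = "results"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    simulate: dict = field(default_factory=lambda: {
        "n_subjects": 53,
        "bold_shape": [12, 12, 6],
        "tr": 3.0,
        "bold_noise_sd": 2.0,
        "etco2_noise_sd": 0.5,
        "cvr_gain": {"gm": 0.10, "wm": 0.03},
        "true_delay": {"gm": 4.0, "wm": 8.0},
    })
    cvr: dict = field(default_factory=lambda: {
        "delay_min": 0.0, "delay_max": 30.0, "delay_step": 1.0,
        "instrument_offset": DEFAULT_INSTRUMENT_OFFSET,
    })
    flow: dict = field(default_factory=lambda: {"brain_volume_ml": 1200.0})
    structural: dict = field(default_factory=lambda: {
        "z_threshold": 1.5, "smooth_sigma": 0.75,
    })
    cohort: dict = field(default_factory=lambda: {"models": DEFAULT_MODELS})

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, False)
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")
        c = self.cvr
        if c["delay_step"] <= 0 or c["delay_max"] < c["delay_min"]:
            raise ConfigError("invalid delay grid")
        if self.structural["z_threshold"] <= 0:
            raise ConfigError("z_threshold must be positive")
        for m in self.cohort["models"]:
            if "outcome" not in m or "predictor" not in m:
                raise ConfigError(f"model needs outcome and predictor: {m}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        base = cls()
        for key in ("simulate", "cvr", "flow", "structural", "cohort", "stages"):
            if key in raw:
                merged = dict(getattr(base, key))
                merged.update(raw[key])
                raw[key] = merged
        return cls(**{**{k: getattr(base, k) for k in known}, **raw})

    @property
    def delay_grid(self) -> np.ndarray:
        c = self.cvr
        return np.arange(c["delay_min"], c["delay_max"] + c["delay_step"] / 2,
                         c["delay_step"])

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def stage_seeds(self) -> dict:
        """Deterministic per-stage seeds spawned from the master seed."""
        children = np.random.SeedSequence(self.seed).spawn(len(STAGES))
        return {s: int(c.generate_state(1)[0] % 2**31)
                for s, c in zip(STAGES, children)}


def _save_nii(arr, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), np.eye(4)),
             str(path))


def _load_nii(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)


def _provenance(cfg: PipelineConfig, stage: str, path: Path, seed: int) -> None:
    path.write_text(json.dumps({
        "stage": stage,
        "config_hash": cfg.config_hash(),
        "master_seed": cfg.seed,
        "stage_seed": seed,
        "version": __version__,
    }, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, out: Path, seed: int) -> None:
    sim = cfg.simulate
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed).spawn(6)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss]

    spec = ParadigmSpec(noise_sd=sim["etco2_noise_sd"])
    trace = gen_etco2_trace(spec, seed=seeds[0])
    trace.to_csv(out / "etco2.csv")

    # the recorded EtCO2 lags the lungs by the sample-tubing transit time,
    # so the generative delay = tissue delay + instrument offset
    offset = cfg.cvr["instrument_offset"]
    truth = GroundTruth(
        cvr_gain=dict(sim["cvr_gain"]),
        true_delay={k: v + offset for k, v in sim["true_delay"].items()},
    )
    bold, labels = gen_bold_series(
        trace, truth, tr=sim["tr"], shape=tuple(sim["bold_shape"]),
        noise_sd=sim["bold_noise_sd"], seed=seeds[1],
    )
    _save_nii(bold.data, out / "bold.nii.gz")
    _save_nii(labels, out / "labels.nii.gz")
    _save_nii(labels > 0, out / "brain_mask.nii.gz")
    with open(out / "bold_meta.json", "w") as fh:
        json.dump({"tr": sim["tr"],
                   "labels": {str(i + 1): lab
                              for i, lab in enumerate(sorted(truth.cvr_gain))}},
                  fh)

    wf_dir = out / "waveforms"
    wf_dir.mkdir(exist_ok=True)
    specs = {  # (mean mL/s, amplitude mL/s): plausible adult values
        "ICA-L": (4.0, 1.2), "ICA-R": (4.0, 1.2),
        "VA-L": (1.0, 0.3), "VA-R": (1.0, 0.3),
        "SSS": (5.0, 1.0),
        "aqueduct": (0.0, 0.05), "foramen-magnum": (0.0, 0.8),
    }
    for k, (name, (m, a)) in enumerate(specs.items()):
        wf, wf_truth = gen_flow_waveform(m, a, structure=name, seed=seeds[2] + k)
        write_waveform_csv(wf, wf_dir / f"{name}.csv")
        truth.pi_true.update(wf_truth.pi_true)
        truth.ri_true.update(wf_truth.ri_true)
        if name == "foramen-magnum":
            truth.stroke_volume_true = wf_truth.stroke_volume_true

    lesion = sphere_coords((20, 20, 20), 5.0, (40, 40, 40))
    flair, wm_mask, lesion_truth = gen_structural_images(
        shape=(40, 40, 40), lesion_voxels=lesion, lesion_z=3.0, seed=seeds[3],
    )
    _save_nii(flair, out / "flair.nii.gz")
    _save_nii(wm_mask, out / "wm_mask.nii.gz")
    _save_nii(lesion_truth, out / "lesion_truth.nii.gz")
    _save_nii(np.zeros_like(wm_mask), out / "stroke_mask.nii.gz")

    cohort, cohort_truth = gen_cohort_table(n=sim["n_subjects"], seed=seeds[4])
    cohort.to_csv(out / "cohort.csv", index=False)
    truth.cohort_coefficients = cohort_truth.cohort_coefficients
    truth.residual_sd = cohort_truth.residual_sd
    truth.to_sidecar(out / "truth.json")


def stage_cvr(cfg: PipelineConfig, data: Path, out: Path, seed: int) -> None:
    out.mkdir(parents=True, exist_ok=True)
    trace = EtCO2Trace.from_csv(data / "etco2.csv")
    meta = json.loads((data / "bold_meta.json").read_text())
    bold = BoldSeries(_load_nii(data / "bold.nii.gz"), tr=meta["tr"])
    mask = _load_nii(data / "brain_mask.nii.gz") > 0.5
    labels = _load_nii(data / "labels.nii.gz").astype(int)
    offset = cfg.cvr["instrument_offset"]

    cvr_map = fit_cvr_map(bold, trace, mask, cfg.delay_grid, offset)
    _save_nii(cvr_map.cvr, out / "cvr.nii.gz")
    _save_nii(cvr_map.delay, out / "delay.nii.gz")
    _save_nii(cvr_map.r_squared, out / "r2.nii.gz")

    rois = {name: labels == int(i) for i, name in meta["labels"].items()}
    table = roi_cvr(bold, rois, trace, delay_grid=cfg.delay_grid,
                    instrument_offset=offset)
    table.to_csv(out / "roi_cvr.csv", index=False)


def stage_flow(cfg: PipelineConfig, data: Path, out: Path, seed: int) -> None:
    out.mkdir(parents=True, exist_ok=True)
    waveforms = {
        wf.structure: wf
        for wf in (read_waveform_csv(p)
                   for p in sorted((data / "waveforms").glob("*.csv")))
    }
    table = metrics_table(waveforms,
                          brain_volume=cfg.flow["brain_volume_ml"])
    table.to_csv(out / "flow_metrics.csv", index=False)


def stage_structural(cfg: PipelineConfig, data: Path, out: Path,
                     seed: int) -> None:
    out.mkdir(parents=True, exist_ok=True)
    flair = _load_nii(data / "flair.nii.gz")
    wm_mask = _load_nii(data / "wm_mask.nii.gz") > 0.5
    stroke = _load_nii(data / "stroke_mask.nii.gz") > 0.5
    wmh, volume = segment_wmh(
        flair, wm_mask, stroke,
        z_threshold=cfg.structural["z_threshold"],
        smooth_sigma=cfg.structural["smooth_sigma"],
    )
    _save_nii(wmh, out / "wmh_mask.nii.gz")
    pd.DataFrame([{"wmh_volume_ml": volume,
                   "log10_wmh": np.log10(volume) if volume > 0 else np.nan,
                   "n_voxels": int(wmh.sum())}]).to_csv(
        out / "wmh_volume.csv", index=False)


def stage_cohort(cfg: PipelineConfig, data: Path, out: Path, seed: int) -> None:
    out.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(data / "cohort.csv")
    results = run_model_grid(table, cfg.cohort["models"])
    results.to_csv(out / "cohort_results.csv", index=False)
    for i, m in enumerate(cfg.cohort["models"]):
        res = fit_association(table, m["outcome"], m["predictor"],
                              tuple(m.get("adjust", ())))
        diag = diagnostics(res)
        diag.to_frame().to_csv(out / f"diagnostics_model{i}.csv", index=False)


_STAGE_INPUTS = {
    "cvr": ("etco2.csv", "bold.nii.gz", "brain_mask.nii.gz",
            "labels.nii.gz", "bold_meta.json"),
    "flow": ("waveforms",),
    "structural": ("flair.nii.gz", "wm_mask.nii.gz", "stroke_mask.nii.gz"),
    "cohort": ("cohort.csv",),
}


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the toggled stages in order; returns the output directory.

    Raises :class:`StageDependencyError` when a stage is enabled but its
    inputs were neither produced by the simulate stage nor already present.
    """
    out_root = Path(config.out_dir)
    data_dir = out_root / "simulate"
    seeds = config.stage_seeds()

    for stage in STAGES:
        if not config.stages.get(stage):
            continue
        needed = _STAGE_INPUTS.get(stage, ())
        missing = [f for f in needed if not (data_dir / f).exists()]
        if stage != "simulate" and missing:
            raise StageDependencyError(
                f"stage {stage!r} requires {missing} from stage 'simulate' "
                "(toggled off and outputs absent)"
            )
        stage_dir = out_root / stage
        logger.info("running stage %s -> %s", stage, stage_dir)
        fn = {
            "simulate": lambda: stage_simulate(config, data_dir,
                                               seeds["simulate"]),
            "cvr": lambda: stage_cvr(config, data_dir, out_root / "cvr",
                                     seeds["cvr"]),
            "flow": lambda: stage_flow(config, data_dir, out_root / "flow",
                                       seeds["flow"]),
            "structural": lambda: stage_structural(
                config, data_dir, out_root / "structural",
                seeds["structural"]),
            "cohort": lambda: stage_cohort(config, data_dir,
                                           out_root / "cohort",
                                           seeds["cohort"]),
        }[stage]
        fn()
        _provenance(config, stage, stage_dir / "provenance.json",
                    seeds[stage])
    return out_root
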