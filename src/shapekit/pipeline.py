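"""End-to-end orchestration: config, seeded runs, fixtures.

A run is: generate synthetic RF for every (pressure, output, replicate)
cell of the protocol grid -> pulse-inversion combination -> subharmonic
extraction -> measurement table -> per-output pressure regressions on the
ascending and descending limbs -> growth-phase segmentation of the 0-mmHg
drive curve.  Everything is deterministic given the master seed; the
serialized config is stored next to the outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .data import ROI, measurements_to_frame, save_rf
from .extraction import extract, pi_combine
from .response import (ASCENDING_RANGE, DESCENDING_RANGE,
                       GrowthPhaseModel, PressureSensitivityModel)
from .synth import AcquisitionConfig, ResponseModel, generate_dataset

__all__ = ["RunConfig", "run_experiment", "make_fixtures"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of one synthetic experiment."""

    name: str = "default"
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    response: ResponseModel = field(default_factory=ResponseModel)
    ascending_range: tuple[float, float] = ASCENDING_RANGE
    descending_range: tuple[float, float] = DESCENDING_RANGE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed != self.acquisition.seed:
            object.__setattr__(self, "acquisition",
                               replace(self.acquisition, seed=self.seed))

    # -- serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        # YAML-friendly: tuples and numpy scalars to plain lists/floats
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return clean(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        acq = dict(d.get("acquisition", {}))
        if "roi" in acq and not isinstance(acq["roi"], ROI):
            acq["roi"] = ROI(**acq["roi"])
        for key in ("pressures", "outputs_kpa"):
            if key in acq:
                acq[key] = tuple(acq[key])
        d["acquisition"] = AcquisitionConfig(**acq)
        resp = dict(d.get("response", {}))
        for key in ("growth_breaks", "plateau_range"):
            if key in resp:
                resp[key] = tuple(resp[key])
        d["response"] = ResponseModel(**resp)
        for key in ("ascending_range", "descending_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _measure_grid(cfg: RunConfig):
    """Synthesise + extract the full protocol grid -> measurement frame."""
    acq, model = cfg.acquisition, cfg.response
    measurements = []
    for pressure in acq.pressures:
        for output in acq.outputs_kpa:
            for rep in range(acq.n_replicates):
                ds = generate_dataset(acq, model, float(pressure),
                                      float(output), rep)
                measurements.append(extract(pi_combine(ds)))
    return measurements_to_frame(measurements)


def run_experiment(cfg: RunConfig, outdir) -> dict:
    """Run the full pipeline; write CSV/JSON outputs; return the bundle.

    Outputs in ``outdir``: ``measurements.csv``, ``fits.json`` (per-output
    regressions and the max-sensitivity pick per pressure range),
    ``segmentation.json`` (growth-phase breakpoints of the 0-mmHg curve)
    and ``config.yaml`` (the serialized configuration).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    log.info("run_experiment name=%s seed=%d grid=%dx%dx%d", cfg.name,
             cfg.seed, len(cfg.acquisition.pressures),
             len(cfg.acquisition.outputs_kpa), cfg.acquisition.n_replicates)

    df = _measure_grid(cfg)
    df.to_csv(outdir / "measurements.csv", index=False)

    model = PressureSensitivityModel(df)
    fits: dict = {}
    for label, prange in (("ascending", cfg.ascending_range),
                          ("descending", cfg.descending_range)):
        try:
            per_output = model.fit_per_output(prange)
            best = model.max_sensitivity(prange)
        except ValueError as err:
            log.warning("range=%s fit skipped: %s", label, err)
            fits[label] = None
            continue
        fits[label] = {
            "range_mmHg": list(prange),
            "per_output": [dataclasses.asdict(f) for f in per_output],
            "max_sensitivity": dataclasses.asdict(best),
        }
    (outdir / "fits.json").write_text(json.dumps(fits, indent=2))

    segmentation = None
    p0 = min(cfg.acquisition.pressures, key=abs)
    curve = (df[df["pressure_mmHg"] == p0]
             .groupby("p_neg_kPa")["sha_dB"].mean())
    try:
        seg = GrowthPhaseModel(curve.index.to_numpy(),
                               curve.to_numpy()).fit()
        segmentation = dataclasses.asdict(seg)
    except ValueError as err:
        log.warning("segmentation skipped: %s", err)
    (outdir / "segmentation.json").write_text(
        json.dumps(segmentation, indent=2))

    return {"measurements": df, "fits": fits, "segmentation": segmentation}


def make_fixtures(size: str, outdir, seed: int = 0) -> Path:
    """Generate a seeded fixture directory (``tiny`` or ``study-scale``).

    tiny: 4 pressures x 5 outputs x 1 frame x 1 replicate — seconds.
    study-scale: 9 pressures x 20 outputs x 3 frames x 2 replicates.
    Both include one sample RF container alongside the pipeline outputs.
    """
    if size == "tiny":
        acq = AcquisitionConfig(
            pressures=(0.0, 37.5, 75.0, 150.0),
            outputs_kpa=tuple(np.geomspace(60.0, 220.0, 5)),
            n_frames=1, n_replicates=1, seed=seed)
    elif size == "study-scale":
        acq = AcquisitionConfig(seed=seed)
    else:
        raise ValueError(f"unknown fixture size {size!r}")
    cfg = RunConfig(name=f"fixture-{size}", acquisition=acq, seed=seed)
    outdir = Path(outdir)
    run_experiment(cfg, outdir)
    sample = generate_dataset(acq, cfg.response,
                              float(acq.pressures[0]),
                              float(acq.outputs_kpa[0]), 0)
    save_rf(sample, outdir / "sample_rf.h5")
    return outdir
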