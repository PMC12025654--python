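"""Reproducible simulate -> quantify -> analyze orchestration.

A :class:`RunConfig` is a single serializable record; one global seed
fans out to independent per-stage child seeds through
``numpy.random.SeedSequence`` spawn keys, so each stage can be re-run
in isolation and still reproduce its outputs bit for bit.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import analyze_cohort
from .errors import MnvQuantError, ParameterError
from .io import (
    MnvRoi,
    read_angiogram,
    read_cohort,
    read_roi,
    write_angiogram,
    write_cohort,
    write_results,
    write_roi,
)
from .morphometry import QuantConfig, quantify
from .synthetic import (
    CohortParams,
    DEFAULT_PIXEL_SCALE_MM,
    GrowthParams,
    NoiseParams,
    generate_cohort,
    generate_vessel_tree,
    rasterize_network,
    synthesize_angiogram,
)

log = logging.getLogger("mnvquant")

_STAGES = {"cohort": 0, "tree": 1, "angiogram": 2, "analysis": 3}


def stage_seed(seed: int, stage: str, index: int = 0) -> int:
    """Deterministic child seed (< 2^31) for one pipeline stage."""
    if stage not in _STAGES:
        raise ParameterError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence(seed, spawn_key=(_STAGES[stage], index))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclasses.dataclass
class RunConfig:
    """Everything needed to reproduce one full run."""

    seed: int = 0
    out_dir: str = "runs/out"
    n_eyes: int = 68
    images: bool = False
    paired: bool = False
    pixel_scale_mm: float = DEFAULT_PIXEL_SCALE_MM
    vessel_width_px: int = 3
    roi_dilation_px: int = 4
    alpha: float = 0.05
    weights: str = "fence"
    cohort_path: str | None = None
    growth: GrowthParams = dataclasses.field(default_factory=GrowthParams)
    noise: NoiseParams = dataclasses.field(default_factory=NoiseParams)
    cohort: CohortParams = dataclasses.field(default_factory=CohortParams)
    quant: QuantConfig = dataclasses.field(default_factory=QuantConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (
            ("growth", GrowthParams),
            ("noise", NoiseParams),
            ("cohort", CohortParams),
            ("quant", QuantConfig),
        ):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                for tup_key in ("type_probs", "fd_bounds", "flow_bounds"):
                    if tup_key in sub and isinstance(sub[tup_key], list):
                        sub[tup_key] = tuple(sub[tup_key])
                d[key] = typ(**sub)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _log_run_header(cfg: RunConfig, stage: str) -> None:
    import networkx
    import scipy
    import skimage
    import statsmodels

    log.info(
        "%s | mnvquant %s | numpy %s scipy %s skimage %s statsmodels %s networkx %s "
        "| seed %d | config %s",
        stage,
        __version__,
        np.__version__,
        scipy.__version__,
        skimage.__version__,
        statsmodels.__version__,
        networkx.__version__,
        cfg.seed,
        cfg.config_hash(),
    )


def _eye_paths(out: Path, eye_id: str) -> dict[str, Path]:
    return {
        "image": out / f"{eye_id}.tif",
        "roi": out / f"{eye_id}_roi.png",
        "truth": out / f"{eye_id}_truth.json",
    }


def cmd_simulate(cfg: RunConfig) -> dict:
    """Emit a cohort CSV (and optionally paired images + ground truth)."""
    from skimage.morphology import dilation, disk

    t0 = time.perf_counter()
    _log_run_header(cfg, "simulate")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    params = dataclasses.replace(cfg.cohort, n_eyes=cfg.n_eyes)
    cohort = generate_cohort(params, seed=stage_seed(cfg.seed, "cohort"))
    artifacts: dict = {"cohort": out / "cohort.csv", "config": out / "config.yaml"}

    if cfg.images:
        for i, eye_id in enumerate(cohort["eye_id"]):
            net = generate_vessel_tree(stage_seed(cfg.seed, "tree", i), cfg.growth)
            mask = rasterize_network(
                net, cfg.pixel_scale_mm, cfg.vessel_width_px
            )
            roi = MnvRoi(dilation(mask, disk(cfg.roi_dilation_px)) if mask.any() else mask)
            img = synthesize_angiogram(
                mask, cfg.noise, stage_seed(cfg.seed, "angiogram", i), cfg.pixel_scale_mm
            )
            paths = _eye_paths(out, eye_id)
            write_angiogram(img, paths["image"])
            write_roi(roi, paths["roi"])
            paths["truth"].write_text(net.to_json())
            if cfg.paired:
                metrics = quantify(img, roi, cfg.quant)
                for col, value in (
                    ("area_mm2", metrics.area_mm2),
                    ("suml_mm", metrics.suml_mm),
                    ("fd", metrics.fd),
                    ("flow_density_pct", metrics.flow_density_pct),
                ):
                    cohort.loc[cohort["eye_id"] == eye_id, col] = value

    write_cohort(cohort, artifacts["cohort"])
    cfg.to_yaml(artifacts["config"])
    log.info("simulate done in %.2fs (%d eyes)", time.perf_counter() - t0, len(cohort))
    return {k: str(v) for k, v in artifacts.items()}


def cmd_quantify(cfg: RunConfig) -> pd.DataFrame:
    """Measure every eye with images in the output directory.

    Per-eye failures become failure records; the run continues.
    Returns the metrics table (also written to ``metrics.csv``; failures
    to ``failures.json``).
    """
    t0 = time.perf_counter()
    _log_run_header(cfg, "quantify")
    out = Path(cfg.out_dir)
    cohort = read_cohort(cfg.cohort_path or out / "cohort.csv")
    rows = []
    failures = []
    for eye_id in cohort["eye_id"]:
        paths = _eye_paths(out, eye_id)
        try:
            img = read_angiogram(paths["image"], cfg.pixel_scale_mm)
            roi = read_roi(paths["roi"], img.shape)
            metrics = quantify(img, roi, cfg.quant)
            rows.append(
                {
                    "eye_id": eye_id,
                    "area_mm2": metrics.area_mm2,
                    "suml_mm": metrics.suml_mm,
                    "fd": metrics.fd,
                    "flow_density_pct": metrics.flow_density_pct,
                }
            )
        except (MnvQuantError, OSError) as exc:
            failures.append({"eye_id": eye_id, "error": f"{type(exc).__name__}: {exc}"})
    metrics_df = pd.DataFrame(
        rows, columns=["eye_id", "area_mm2", "suml_mm", "fd", "flow_density_pct"]
    )
    metrics_df.to_csv(out / "metrics.csv", index=False)
    (out / "failures.json").write_text(json.dumps(failures, indent=2))
    log.info(
        "quantify done in %.2fs (%d ok, %d failed)",
        time.perf_counter() - t0,
        len(rows),
        len(failures),
    )
    return metrics_df


def cmd_analyze(cfg: RunConfig):
    """Run the association battery on the configured cohort.

    Writes ``report.json`` and ``models.csv``.  Validation problems
    raise; statistical non-significance never affects the exit status.
    """
    t0 = time.perf_counter()
    _log_run_header(cfg, "analyze")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = read_cohort(cfg.cohort_path or out / "cohort.csv")
    report = analyze_cohort(cohort, alpha=cfg.alpha, weights=cfg.weights)
    write_results(report.to_dict(), out / "report.json")
    report.to_frame().to_csv(out / "models.csv", index=False)
    log.info("analyze done in %.2fs (%d models)", time.perf_counter() - t0, len(report.models))
    return report


def run_all(cfg: RunConfig):
    """simulate -> (quantify if images) -> analyze."""
    cmd_simulate(cfg)
    if cfg.images:
        cmd_quantify(cfg)
    return cmd_analyze(cfg)
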