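"""End-to-end orchestration: simulate -> analyze -> report.

A run is driven by a single config mapping (YAML on disk) with one
block per stage; every source of randomness derives from the manifest
seed, and each output table row carries the seed and config hash that
produced it, so reruns with the same manifest are bit-identical for
the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ALL_STAGES = ("morphometry", "cytometry", "imaging", "behavior")


@dataclass
class RunConfig:
    seed: int = 1
    stages: tuple = ALL_STAGES
    out_dir: str = "ploidyscale_run"
    morphometry: dict = field(default_factory=dict)
    cytometry: dict = field(default_factory=dict)
    imaging: dict = field(default_factory=dict)
    behavior: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        if "stages" in known:
            known["stages"] = tuple(known["stages"])
        return cls(**known)

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _morphometry_stage(cfg: dict, seed: int) -> pd.DataFrame:
    from .morphometry import compartment_summary, population_folds
    from .simulate.neurons import NeuronSimParams, simulate_population

    params = NeuronSimParams(**cfg.get("params", {}))
    n = int(cfg.get("n_neurons", 50))
    dip = [compartment_summary(t) for t in simulate_population(params, n, "diploid", seed)]
    tri = [compartment_summary(t) for t in simulate_population(params, n, "triploid", seed + 1)]
    folds = population_folds(dip, tri, seed=seed)
    folds.insert(0, "metric", "fold_triploid_over_diploid")
    return folds


def _cytometry_stage(cfg: dict, seed: int) -> pd.DataFrame:
    from .cytometry import count_cells, fit_djf, gate, qc_batch
    from .simulate.flow import FlowSimParams, simulate_flow_batch

    params = FlowSimParams(**cfg.get("params", {}))
    n = int(cfg.get("n_samples_per_ploidy", 3))
    tables = simulate_flow_batch(params, n, seed=seed)
    gated = [gate(t) for t in tables]
    qc = qc_batch(gated)
    rows = []
    for g, q in zip(gated, qc):
        if not q.passed:
            continue
        cpb = count_cells(g.n_cell_events, g.n_bead_events, g.cells.n_brains)
        fit = fit_djf(g.cells.data["hoechst"].to_numpy())
        rows.append(dict(
            sample_id=g.cells.sample_id, ploidy=g.cells.ploidy,
            clutch=g.cells.clutch, cells_per_brain=cpb,
            g1_mean=fit.g1_mean, g2_mean=fit.g2_mean,
            frac_g0g1=fit.weights["g0g1"], frac_s=fit.weights["s"],
            frac_g2m=fit.weights["g2m"],
        ))
    return pd.DataFrame(rows)


def _imaging_stage(cfg: dict, seed: int) -> pd.DataFrame:
    from .imaging import ratio_mask_measure
    from .simulate.images import default_brain_rois, simulate_ratio_images

    shape = tuple(cfg.get("shape", (128, 96)))
    folds = dict(cfg.get("perk_fold_by_roi", {"midbrain": 1.3}))
    noise = float(cfg.get("noise_sd", 20.0))
    perk, erk, truth = simulate_ratio_images(
        shape=shape, perk_fold_by_roi=folds, noise_sd=noise, seed=seed,
    )
    _, means = ratio_mask_measure(perk, erk, default_brain_rois(shape))
    return means.merge(truth[["region", "fold"]], on="region", how="left")


def _behavior_stage(cfg: dict, seed: int) -> pd.DataFrame:
    from .behavior import summarize_session
    from .simulate.swim import SwimSimParams, simulate_trajectories

    params = SwimSimParams(**cfg.get("params", {}))
    traj = simulate_trajectories(params, seed=seed)
    return summarize_session(traj)


_STAGE_FNS = {
    "morphometry": _morphometry_stage,
    "cytometry": _cytometry_stage,
    "imaging": _imaging_stage,
    "behavior": _behavior_stage,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages; write tables and a JSON manifest.

    Returns {stage: DataFrame}; on stage failure raises
    :class:`StageError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    rng = np.random.default_rng(config.seed)
    stage_seeds = {s: int(rng.integers(0, 2**31 - 1)) for s in ALL_STAGES}

    tables = {}
    for stage in config.stages:
        if stage not in _STAGE_FNS:
            raise StageError(stage, ValueError("unknown stage"))
        try:
            df = _STAGE_FNS[stage](getattr(config, stage), stage_seeds[stage])
        except Exception as exc:  # noqa: BLE001 - structured stage error
            raise StageError(stage, exc) from exc
        df = df.assign(seed=stage_seeds[stage], config_hash=chash)
        df.to_csv(out / f"{stage}.csv", index=False)
        tables[stage] = df

    manifest = dict(
        seed=config.seed, config_hash=chash, stages=list(config.stages),
        stage_seeds={s: stage_seeds[s] for s in config.stages},
        outputs={s: f"{s}.csv" for s in config.stages},
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return tables
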