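"""End-to-end orchestration: scale grading, feature extraction, the two
classification branches, fusion and evaluation, with a provenance
manifest.

Every stochastic stage derives its seed from one master seed so a rerun
with an identical configuration reproduces every intermediate file
byte-for-byte.  Each stage reads its inputs from, and writes its outputs
to, the working directory, so the pipeline is resumable per stage.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .features import extract_chip, extract_timeseries
from .fusion import decide, evaluate, fuse
from .geometry import grade_and_partition
from .ki import KIPipeline, PhenologyReference
from .simulate import SceneConfig, build_scene
from .texture import (
    SemiTextureClassifier,
    build_kspice1_labelset,
    finetune_texture_pseudolabels,
    predict_proba_texture,
    texture_cluster,
    texture_embed,
)

STAGES = ("simulate", "grade", "extract", "ki", "chips", "kspice", "fuse", "eval")


@dataclass
class PipelineConfig:
    """Flat run configuration; round-trips losslessly through YAML."""

    seed: int = 7
    workdir: str = "pitt_run"
    # scene generation (ignored when input paths are given)
    simulate: bool = True
    parcels_per_level_per_class: int = 50
    # grading
    pixel_side: float = 10.0
    # extraction
    extract_method: str = "full"
    # KI stage
    n_clusters: int = 9
    prob_kshape: float = 0.97
    delta: float = 3.0
    min_fraction: float = 0.01
    twdtw_alpha: float = 0.1
    twdtw_beta: float = 5.0
    ki_epochs: int = 120
    # texture stage
    chip_side_small: int = 96
    chip_side_micro: int = 8
    prob_ki_threshold: float = 0.99
    texture_k: int = 6
    sim_threshold: float = 0.8
    merge_threshold: float = 0.8
    tau: float = 0.95
    texture_epochs: int = 20
    # fusion
    w_small: float = 0.5
    w_micro: float = 0.5
    verbose: bool = True

    def stage_seed(self, offset: int) -> int:
        return int((self.seed * 1009 + offset) % 2**31)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log(config: PipelineConfig, stage: str, msg: str) -> None:
    if config.verbose:
        print(f"[pitt:{stage}] {msg}", file=sys.stderr)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, stages=STAGES) -> dict:
    """Run the requested stages; returns the provenance manifest."""
    work = Path(config.workdir)
    work.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "seeds": {s: config.stage_seed(i) for i, s in enumerate(STAGES)},
        "stages": {},
    }
    for stage in stages:
        _log(config, stage, "running")
        try:
            outputs = _STAGE_FUNCS[stage](config, work)
        except Exception as exc:  # partial outputs are retained on disk
            raise PipelineError(stage, exc) from exc
        manifest["stages"][stage] = {
            "outputs": {str(p.relative_to(work)): _sha256(p) for p in outputs}
        }
    io.write_csv(
        pd.DataFrame(
            [
                {"stage": s, "file": f, "sha256": h}
                for s, d in manifest["stages"].items()
                for f, h in d["outputs"].items()
            ]
        ),
        work / "manifest.csv",
    )
    (work / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _stage_simulate(config: PipelineConfig, work: Path) -> list[Path]:
    n = config.parcels_per_level_per_class
    scene = build_scene(
        SceneConfig(
            seed=config.stage_seed(0),
            pixel_side=config.pixel_side,
            parcels_per_level_per_class={0: n, 1: n, 5: n, 9: n},
        )
    )
    io.parcels_to_geojson(scene.parcels, work / "parcels.geojson")
    io.stack_to_dir(scene.stack, work / "stack")
    io.image_write(scene.hires, scene.hires_grid, work / "hires.tif")
    io.write_csv(scene.truth, work / "truth.csv")
    refs = scene.references
    io.write_csv(
        pd.DataFrame(
            [
                {"class": c, "date": int(d), "value": v}
                for c in refs.class_names
                for d, v in zip(refs.dates, refs.curves[c])
            ]
        ),
        work / "refs.csv",
    )
    return [
        work / "parcels.geojson",
        work / "truth.csv",
        work / "refs.csv",
        work / "hires.tif",
        *sorted((work / "stack").glob("*")),
    ]


def _stage_grade(config: PipelineConfig, work: Path) -> list[Path]:
    parcels = io.parcels_from_geojson(work / "parcels.geojson")
    stack = io.stack_from_dir(work / "stack")
    parcels, small, micro = grade_and_partition(parcels, stack.grid)
    _log(config, "grade", f"{len(small)} small / {len(micro)} micro parcels")
    io.parcels_to_geojson(parcels, work / "graded.geojson")
    return [work / "graded.geojson"]


def _stage_extract(config: PipelineConfig, work: Path) -> list[Path]:
    parcels = io.parcels_from_geojson(work / "graded.geojson")
    stack = io.stack_from_dir(work / "stack")
    records = [
        extract_timeseries(p, stack, method=config.extract_method) for p in parcels
    ]
    io.write_csv(io.records_to_frame(records), work / "ts.csv")
    return [work / "ts.csv"]


def _stage_ki(config: PipelineConfig, work: Path) -> list[Path]:
    parcels = io.parcels_from_geojson(work / "graded.geojson")
    records = {r.parcel_id: r for r in io.records_from_frame(pd.read_csv(work / "ts.csv"))}
    refs = PhenologyReference.from_frame(pd.read_csv(work / "refs.csv"))
    small = [records[p.id] for p in parcels if p.branch == "small"]
    ki = KIPipeline(
        n_clusters=config.n_clusters,
        prob_kshape=config.prob_kshape,
        delta=config.delta,
        min_fraction=config.min_fraction,
        twdtw_alpha=config.twdtw_alpha,
        twdtw_beta=config.twdtw_beta,
        epochs=config.ki_epochs,
        random_state=config.stage_seed(3),
    ).fit(small, refs)
    _log(config, "ki", f"{len(ki.pseudolabels_)} pseudolabels from {len(small)} small parcels")
    io.write_csv(ki.pseudolabels_.to_frame(), work / "pseudolabels_ki.csv")
    all_records = [records[p.id] for p in parcels]
    io.write_csv(ki.predict_proba(all_records), work / "prob_ki.csv")
    return [work / "pseudolabels_ki.csv", work / "prob_ki.csv"]


def _stage_chips(config: PipelineConfig, work: Path) -> list[Path]:
    parcels = io.parcels_from_geojson(work / "graded.geojson")
    image, hires_grid = io.image_read(work / "hires.tif")
    out = []
    for branch, side in (("small", config.chip_side_small), ("micro", config.chip_side_micro)):
        chips = [
            extract_chip(p, image, hires_grid, side=side)
            for p in parcels
            if p.branch == branch
        ]
        io.chips_to_dir(chips, work / f"chips_{branch}")
        out.extend(sorted((work / f"chips_{branch}").glob("*")))
    return out


def _stage_kspice(config: PipelineConfig, work: Path) -> list[Path]:
    prob_ki = pd.read_csv(work / "prob_ki.csv")
    classes = tuple(c[2:] for c in prob_ki.columns if c.startswith("p_"))
    out = []
    # mode 1 (small parcels): no clustering stage
    chips_small = io.chips_from_dir(work / "chips_small")
    small_ids = {c.parcel_id for c in chips_small}
    labelset1 = build_kspice1_labelset(
        prob_ki[prob_ki["parcel_id"].astype(str).isin(small_ids)],
        threshold=config.prob_ki_threshold,
    )
    clf1 = SemiTextureClassifier(
        classes=classes,
        tau=config.tau,
        epochs=config.texture_epochs,
        random_state=config.stage_seed(5),
    ).fit(chips_small, labelset1)
    io.write_csv(predict_proba_texture(clf1, chips_small, classes), work / "prob_tex_small.csv")
    out.append(work / "prob_tex_small.csv")
    # mode 2 (micro parcels): cluster, then refine with KI predictions
    chips_micro = io.chips_from_dir(work / "chips_micro")
    micro_ids = {c.parcel_id for c in chips_micro}
    emb = texture_embed(chips_micro, seed=config.stage_seed(5))
    protos = texture_cluster(emb, k=config.texture_k, seed=config.stage_seed(5))
    ki_arg = decide(prob_ki[prob_ki["parcel_id"].astype(str).isin(micro_ids)])
    ki_classes = dict(zip(ki_arg["parcel_id"].astype(str), ki_arg["class"]))
    labelset2, _ = finetune_texture_pseudolabels(
        protos, ki_classes, emb,
        sim_threshold=config.sim_threshold,
        merge_threshold=config.merge_threshold,
    )
    _log(config, "kspice", f"mode1 labels={len(labelset1)} mode2 labels={len(labelset2)}")
    clf2 = SemiTextureClassifier(
        classes=classes,
        tau=config.tau,
        epochs=config.texture_epochs,
        random_state=config.stage_seed(5) + 1,
    ).fit(chips_micro, labelset2)
    io.write_csv(predict_proba_texture(clf2, chips_micro, classes), work / "prob_tex_micro.csv")
    out.append(work / "prob_tex_micro.csv")
    return out


def _stage_fuse(config: PipelineConfig, work: Path) -> list[Path]:
    prob_ki = pd.read_csv(work / "prob_ki.csv", dtype={"parcel_id": str})
    out = []
    for branch, w in (("small", config.w_small), ("micro", config.w_micro)):
        tex = pd.read_csv(work / f"prob_tex_{branch}.csv", dtype={"parcel_id": str})
        sub = prob_ki[prob_ki["parcel_id"].isin(set(tex["parcel_id"]))]
        fused = fuse(sub, tex, w)
        io.write_csv(fused, work / f"prob_pitt_{branch}.csv")
        out.append(work / f"prob_pitt_{branch}.csv")
    return out


def _stage_eval(config: PipelineConfig, work: Path) -> list[Path]:
    truth = pd.read_csv(work / "truth.csv", dtype={"parcel_id": str})
    report = {}
    for branch in ("small", "micro"):
        fused = pd.read_csv(work / f"prob_pitt_{branch}.csv", dtype={"parcel_id": str})
        preds = decide(fused)
        sub = truth[truth["parcel_id"].isin(set(preds["parcel_id"]))]
        report[branch] = evaluate(preds, sub[["parcel_id", "class"]])
        _log(config, "eval", f"{branch}: mF1={report[branch]['mf1']:.4f}")
    (work / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return [work / "report.json"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "grade": _stage_grade,
    "extract": _stage_extract,
    "ki": _stage_ki,
    "chips": _stage_chips,
    "kspice": _stage_kspice,
    "fuse": _stage_fuse,
    "eval": _stage_eval,
}
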