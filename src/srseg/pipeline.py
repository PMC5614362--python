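"""End-to-end runs from a single declarative config.

``run`` executes the protocol stages in their natural order — load (or
generate a phantom), select ROI, compute feature channels, build
supervoxels and megavoxels, apply scribble annotations, train/refine/commit
a classifier, morphologically refine labels, split objects by rules, and
export — logging every stage's parameters and timing so a run log is
sufficient to reproduce the run.  Any stage may be omitted: a config with
no stages just loads the workspace (the cryoSXT-style configs, for
instance, skip model training entirely).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import annotation, feature_channels, label_splitter, model_training, phantoms
from . import super_regions, volume_io

logger = logging.getLogger("srseg")

_STAGE_ORDER = ("input", "roi", "channels", "supervoxels", "megavoxels",
                "annotate", "train", "refine_labels", "split", "export")


def load_config(path) -> dict:
    path = Path(path)
    with open(path) as f:
        if path.suffix in (".yaml", ".yml"):
            return yaml.safe_load(f)
        return json.load(f)


class RunResult:
    def __init__(self, workspace, log, exports, extras):
        self.workspace = workspace
        self.log = log
        self.exports = exports
        self.extras = extras


def run(config, seed: int = None, log_path=None) -> RunResult:
    """Execute a run config (dict or path to YAML/JSON)."""
    if not isinstance(config, dict):
        config = load_config(config)
    config = dict(config)
    if seed is not None:
        config["seed"] = seed
    seed = int(config.get("seed", 0))

    unknown = set(config) - set(_STAGE_ORDER) - {"seed", "log_level", "name"}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "input" not in config:
        raise ValueError("config needs an 'input' stage")

    log = {"config": _jsonable(config), "seed": seed, "stages": []}
    t_all = time.perf_counter()

    def stage(name, **params):
        logger.info("stage %s: %s", name, params)
        log["stages"].append({"stage": name, "params": _jsonable(params),
                              "t": time.perf_counter() - t_all})

    extras = {}

    # -- input ------------------------------------------------------------
    inp = config["input"]
    if "phantom" in inp:
        p = dict(inp["phantom"])
        kind = p.pop("kind", "multiregion")
        p.setdefault("seed", seed)
        if kind == "multiregion":
            phantom = phantoms.make_multiregion(**p)
        elif kind == "organelle_cell":
            phantom = phantoms.make_organelle_cell(**p)
        elif kind == "two_phase":
            phantom = phantoms.make_two_phase(**p)
        else:
            raise ValueError(f"unknown phantom kind {kind!r}")
        ws = volume_io.Workspace(volume=volume_io.Volume(phantom.volume))
        extras["phantom"] = phantom
        stage("input", phantom=kind, **p)
    else:
        ws = volume_io.load_volume(inp["path"],
                                   orientation=inp.get("orientation", "zyx"),
                                   dataset=inp.get("dataset"),
                                   impute_nonfinite=inp.get("impute_nonfinite", False))
        stage("input", path=str(inp["path"]))

    # -- roi --------------------------------------------------------------
    if "roi" in config:
        volume_io.set_roi(ws, config["roi"])
        stage("roi", bounds=list(config["roi"]))

    # -- channels ---------------------------------------------------------
    if "channels" in config:
        feature_channels.compute_queue(ws, config["channels"])
        stage("channels", specs=config["channels"])

    # -- supervoxels ------------------------------------------------------
    if "supervoxels" in config:
        sv = dict(config["supervoxels"])
        src = sv.pop("source", "__data__")
        source = ws.channels.get(src, ws.channel_data(src))
        ws.supervoxels = super_regions.compute_supervoxels(source, **sv)
        stage("supervoxels", source=src, **sv)

    # -- megavoxels -------------------------------------------------------
    if "megavoxels" in config:
        mv = dict(config["megavoxels"])
        src = mv.pop("source", "__data__")
        source = ws.channels.get(src, ws.channel_data(src))
        ws.megavoxels = super_regions.compute_megavoxels(source, ws.supervoxels, **mv)
        stage("megavoxels", source=src, **mv)

    # -- annotate ---------------------------------------------------------
    if "annotate" in config:
        ann = config["annotate"]
        for lvl in ann.get("levels", [{}]):
            level = annotation.add_level(ws)
            for lab in lvl.get("labels", []):
                annotation.add_label(level, lab["name"], lab.get("color", "#ffffff"),
                                     parent=tuple(lab["parent"]) if lab.get("parent") else None)
        strokes = []
        if "stroke_file" in ann:
            strokes = annotation.load_strokes(ann["stroke_file"])
        for s in ann.get("strokes", []):
            strokes.append(annotation.Stroke(level=s["level"], label=s["label"],
                                             seeds=np.asarray(s["seeds"]),
                                             pen_width=s.get("pen_width", 1),
                                             mode=s.get("mode", "supervoxel")))
        for s in strokes:
            annotation.annotate(ws, s)
        stage("annotate", n_strokes=len(strokes))

    # -- train ------------------------------------------------------------
    if "train" in config:
        tr = dict(config["train"])
        rounds = tr.pop("rounds", 3)
        tr.setdefault("seed", seed)
        cfg = model_training.TrainConfig(**tr)
        extras["train"] = model_training.iterate_training(ws, cfg, rounds=rounds)
        stage("train", rounds=rounds, **tr)

    # -- refine_labels ----------------------------------------------------
    if "refine_labels" in config:
        for step in config["refine_labels"]:
            annotation.refine_label(ws, step["level"], step["label"],
                                    step["method"], radius=step.get("radius", 1),
                                    scope=step.get("scope", "all_slices_2d"),
                                    slice_index=step.get("slice_index"))
        stage("refine_labels", steps=config["refine_labels"])

    # -- split ------------------------------------------------------------
    if "split" in config:
        sp = config["split"]
        level = ws.level(sp["level"])
        query = ws.channels.get(sp.get("query", "__data__"),
                                ws.channel_data(sp.get("query", "__data__")))
        objects = label_splitter.extract_objects(
            level, sp["labels"], query,
            connectivity=sp.get("connectivity", 26),
            voxel_size=tuple(sp.get("voxel_size", (1.0, 1.0, 1.0))))
        rule_labels = label_splitter.rules_from_config(sp.get("rule_labels", []))
        assignment = label_splitter.apply_split(objects, rule_labels)
        extras["objects"] = objects
        extras["assignment"] = assignment
        if sp.get("save_to_level") is not None:
            target = annotation.add_level(ws)
            label_splitter.save_split(assignment, objects, target, rule_labels)
            extras["split_level"] = target.id
        if sp.get("measures"):
            table, pairs = label_splitter.label_statistics(
                objects, sp["measures"], assignment=assignment,
                csv_path=sp.get("csv_path"), plot_dir=sp.get("plot_dir"))
            extras["statistics"] = table
        stage("split", level=sp["level"], labels=sp["labels"])

    # -- export -----------------------------------------------------------
    exports = []
    if "export" in config:
        for ex in config["export"]:
            exports += volume_io.export(
                ws, ex["output"], ex.get("format", "hdf5"), ex["out_dir"],
                levels=ex.get("levels"), scale=ex.get("scale"),
                invert=ex.get("invert", False), mask_source=ex.get("mask_source"))
        stage("export", n_files=len(exports))

    log["elapsed_s"] = time.perf_counter() - t_all
    if log_path is not None:
        with open(log_path, "w") as f:
            json.dump(log, f, indent=2)
    return RunResult(ws, log, exports, extras)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj
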