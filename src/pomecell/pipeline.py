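"""End-to-end experiment orchestration.

``run_experiment`` drives the whole pipeline from a single declarative
config: simulate phantoms -> extract matrix/pores -> ground-truth labels
-> build the 2D slice dataset -> train the flow network -> segment the
held-out volumes -> watershed benchmark -> AJI evaluation -> morphometric
parameter vectors.  Every intermediate artifact lands in the run
directory; phantoms are cached by config hash so parameter sweeps reuse
them; the summary (per-sample AJI for the flow model and the benchmark,
plus morphometrics) is machine-readable JSON/CSV, and the log records the
config hash and all seeds, so re-running a config reproduces the summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .benchmark import sweep_extents
from .dataset import SplitConfig, build_split, get_slice
from .evaluation import aji
from .flow.net import (FlowPredictor, TrainConfig, build_network, save_model,
                       train)
from .flow.predict import predict_volume
from .flow.targets import labels_to_flows
from .flow.tracking import mask_and_cluster
from .groundtruth import GTConfig, annotate_structures, cells_only, label_gt_cells
from .labeling import (PoreLabelingConfig, extract_matrix, label_pores,
                       pore_space, select_marker_extent)
from .morphometry import assemble_parameter_vector, object_level, sample_level
from .phantom import PhantomConfig, generate_phantom

__all__ = ["run_experiment", "load_config"]

REQUIRED_KEYS = ("out_dir", "seed", "phantoms", "train")


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _check(config: dict) -> None:
    for key in REQUIRED_KEYS:
        if key not in config:
            raise KeyError(f"missing config key: {key!r}")


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _phantom_cached(cfg: PhantomConfig, cache_dir: Path):
    key = _hash(dataclasses.asdict(cfg))
    pdir = cache_dir / f"phantom_{key}"
    if (pdir / "config.json").exists():
        return pio.load_phantom(pdir)
    ph = generate_phantom(cfg)
    pio.save_phantom(ph, pdir)
    return ph


def run_experiment(config: dict | str | Path) -> Path:
    """Run a full experiment; returns the run directory.

    ``config`` is a mapping (or path to a YAML file) with keys:

    - ``out_dir``, ``seed``
    - ``phantoms``: {style, n_train, n_test, shape, and any PhantomConfig
      override}
    - ``dataset``: {train_spacing, val_spacing} (optional)
    - ``train``: TrainConfig overrides (epochs, base_feature_maps, ...)
    - ``gt``: GTConfig overrides (optional)
    - ``segmentation``: {roi_threshold, n_iter, min_size} (optional)
    - ``benchmark_extents``: list of marker extents (optional)
    """
    if not isinstance(config, dict):
        config = load_config(config)
    _check(config)
    run_dir = Path(config["out_dir"])
    run_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {"config_hash": _hash(config), "seed": config["seed"],
                 "started": time.strftime("%Y-%m-%d %H:%M:%S"), "stages": {}}
    (run_dir / "config_echo.json").write_text(json.dumps(config, indent=2, default=str))

    def stage(name):
        log["stages"][name] = time.strftime("%H:%M:%S")
        (run_dir / "run_log.json").write_text(json.dumps(log, indent=2))

    seed = int(config["seed"])
    pcfg = dict(config["phantoms"])
    style = pcfg.pop("style", "apple")
    n_train = int(pcfg.pop("n_train", 2))
    n_test = int(pcfg.pop("n_test", 1))
    if "shape" in pcfg:
        pcfg["shape"] = tuple(pcfg["shape"])

    stage("simulate")
    cache = run_dir / "phantoms"
    train_ph, test_ph = [], []
    for i in range(n_train + n_test):
        cfg = PhantomConfig(style=style, seed=seed + i, **pcfg)
        (train_ph if i < n_train else test_ph).append(_phantom_cached(cfg, cache))

    stage("ground_truth")
    gt_cfg = GTConfig(**config.get("gt", {}))
    gt_labels = {}
    for i, ph in enumerate(train_ph + test_ph):
        labels = label_gt_cells(ph.contrast_enhanced, gt_cfg)
        labels, table = annotate_structures(labels, ph.masks)
        gt_labels[i] = cells_only(labels, table)

    stage("dataset")
    ds = config.get("dataset", {})
    shape = (train_ph + test_ph)[0].cell_labels.shape
    split_cfg = SplitConfig(train_spacing=int(ds.get("train_spacing", 8)),
                            val_spacing=int(ds.get("val_spacing", max(shape))),
                            volume_extent=shape[0])
    samples = [{"id": f"train{i}", "role": "train", "shape": shape}
               for i in range(n_train)]
    samples += [{"id": f"test{i}", "role": "test", "shape": shape}
                for i in range(n_test)]
    manifest = build_split(samples, split_cfg)
    manifest.to_json(run_dir / "manifest.jsonl", orient="records", lines=True)

    pairs, val_pairs = [], []
    for _, rec in manifest.iterrows():
        if rec["split"] == "test":
            continue
        idx = int(rec["sample_id"].removeprefix("train"))
        ph = train_ph[idx]
        img = get_slice(ph.conventional, rec["orientation"], rec["index"])
        lab = get_slice(gt_labels[idx], rec["orientation"], rec["index"])
        (pairs if rec["split"] == "train" else val_pairs).append(
            (img, labels_to_flows(lab)))

    stage("train")
    tr = dict(config["train"])
    tcfg = TrainConfig(seed=seed, **tr)
    model = build_network(tcfg)
    losses = train(model, pairs, tcfg, val_pairs or None)
    losses.to_csv(run_dir / "losses.csv", index=False)
    save_model(model, tcfg, run_dir / "model")

    stage("segment_and_evaluate")
    seg = config.get("segmentation", {})
    extents = tuple(config.get("benchmark_extents", (0, 1, 2, 3, 4)))
    pl_cfg = PoreLabelingConfig(candidate_marker_extents=extents)
    rows = []
    for i, ph in enumerate(test_ph):
        gt = gt_labels[n_train + i]
        matrix = extract_matrix(ph.conventional, pl_cfg)
        field = predict_volume(FlowPredictor(model), ph.conventional)
        pred = mask_and_cluster(field, matrix,
                                roi_threshold=float(seg.get("roi_threshold", 0.5)),
                                n_iter=int(seg.get("n_iter", 200)),
                                min_size=int(seg.get("min_size", 64)))
        pio.write_volume(run_dir / f"test{i}_labels.tif", pred, np.uint16)
        dl_aji, _ = aji(gt, pred)
        best_ext, bench = sweep_extents(matrix, gt, extents)
        bench.to_csv(run_dir / f"test{i}_benchmark.csv", index=False)
        rows.append({"sample": f"test{i}", "dl_aji": dl_aji,
                     "benchmark_aji": float(bench["aji"].max()),
                     "benchmark_extent": best_ext})
    summary = pd.DataFrame(rows)
    summary.to_csv(run_dir / "summary.csv", index=False)

    stage("morphometrics")
    vectors = []
    for i, ph in enumerate(test_ph):
        matrix = extract_matrix(ph.conventional, pl_cfg)
        pores = pore_space(matrix)
        try:
            ext, _ = select_marker_extent(pores, pl_cfg)
        except ValueError:
            ext = 0
        plab = label_pores(pores, ext)
        gt = gt_labels[n_train + i]
        sm = sample_level(ph.masks, plab, gt, ph.config.voxel_size)
        cells = object_level(gt, ph.config.voxel_size)
        pores_t = object_level(plab, ph.config.voxel_size) if plab.max() else None
        vec = assemble_parameter_vector(sm, cells, pores_t)
        vec.name = f"test{i}"
        vectors.append(vec)
    pd.DataFrame(vectors).to_csv(run_dir / "morphometrics.csv")

    log["summary"] = {"mean_dl_aji": float(summary["dl_aji"].mean()),
                      "mean_benchmark_aji": float(summary["benchmark_aji"].mean())}
    log["finished"] = time.strftime("%Y-%m-%d %H:%M:%S")
    (run_dir / "run_log.json").write_text(json.dumps(log, indent=2))
    return run_dir
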