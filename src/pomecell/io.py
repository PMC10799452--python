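"""Volume I/O: multi-page TIFF stacks and phantom directories."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile

from .phantom import Phantom, PhantomConfig, TissueMasks

__all__ = ["read_volume", "write_volume", "save_phantom", "load_phantom"]


def read_volume(path) -> np.ndarray:
    """Read a (Z, Y, X) volume from a multi-page TIFF."""
    return tifffile.imread(str(path))


def write_volume(path, volume: np.ndarray, dtype=None) -> None:
    """Write a (Z, Y, X) volume as a multi-page TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(volume)
    if dtype is not None:
        if np.issubdtype(np.dtype(dtype), np.integer):
            info = np.iinfo(dtype)
            arr = np.clip(np.rint(arr), info.min, info.max)
        arr = arr.astype(dtype)
    tifffile.imwrite(str(path), arr)


def _label_dtype(labels: np.ndarray):
    return np.uint16 if labels.max() < 2**16 else np.uint32


def save_phantom(phantom: Phantom, outdir) -> Path:
    """Write a phantom as TIFF stacks plus a JSON config echo.

    Layout: conventional/volume.tif and contrast/volume.tif (8-bit),
    labels/cells.tif (16- or 32-bit), masks/{matrix,pore,stone,vascular}.tif
    (8-bit 0/255), config.json.
    """
    outdir = Path(outdir)
    write_volume(outdir / "conventional" / "volume.tif", phantom.conventional, np.uint8)
    write_volume(outdir / "contrast" / "volume.tif", phantom.contrast_enhanced, np.uint8)
    write_volume(outdir / "labels" / "cells.tif", phantom.cell_labels,
                 _label_dtype(phantom.cell_labels))
    m = phantom.masks
    for name, mask in (("matrix", m.cell_matrix), ("pore", m.pore),
                       ("stone", m.stone), ("vascular", m.vascular)):
        write_volume(outdir / "masks" / f"{name}.tif", mask.astype(np.uint8) * 255)
    cfg = dataclasses.asdict(phantom.config)
    cfg["n_pore_components"] = phantom.n_pore_components
    cfg["n_pores_constructed"] = phantom.n_pores_constructed
    (outdir / "config.json").write_text(json.dumps(cfg, indent=2))
    return outdir


def load_phantom(outdir) -> Phantom:
    outdir = Path(outdir)
    cfg = json.loads((outdir / "config.json").read_text())
    n_comp = cfg.pop("n_pore_components", 0)
    n_constructed = cfg.pop("n_pores_constructed", 0)
    cfg["shape"] = tuple(cfg["shape"])
    cfg["anisotropy_stretch"] = tuple(cfg["anisotropy_stretch"])
    masks = TissueMasks(
        cell_matrix=read_volume(outdir / "masks" / "matrix.tif") > 0,
        pore=read_volume(outdir / "masks" / "pore.tif") > 0,
        stone=read_volume(outdir / "masks" / "stone.tif") > 0,
        vascular=read_volume(outdir / "masks" / "vascular.tif") > 0,
    )
    return Phantom(
        cell_labels=read_volume(outdir / "labels" / "cells.tif").astype(np.int32),
        masks=masks,
        conventional=read_volume(outdir / "conventional" / "volume.tif").astype(np.float32),
        contrast_enhanced=read_volume(outdir / "contrast" / "volume.tif").astype(np.float32),
        config=PhantomConfig(**cfg),
        n_pore_components=n_comp,
        n_pores_constructed=n_constructed,
    )
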