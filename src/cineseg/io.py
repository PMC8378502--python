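"""On-disk formats: TIFF stacks, PNG masks, CSV manifests, checkpoints.

A simulated dataset directory looks like::

    out/
      manifest.csv              sequence, frame, state_label, wall_area
      seq_000.tif               multi-page 8-bit grayscale images
      masks/seq_000/frame_00.png  ...
      params/seq_000.json       the phantom parameters used

Checkpoints are NumPy ``.npz`` archives of named parameter tensors plus
an embedded JSON config; the config's SHA-256 prefix is stored alongside
so a checkpoint can be matched to the run that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .dense_rnn import DenseRNNModel
from .phantom import LabeledSequence, PhantomParams

__all__ = [
    "write_sequence",
    "write_dataset",
    "load_dataset",
    "read_image_stack",
    "write_image_stack",
    "save_checkpoint",
    "load_checkpoint",
]


def _to_uint8(images: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(images) * 255.0, 0, 255).round().astype(np.uint8)


def write_image_stack(path: Path | str, images: np.ndarray) -> None:
    """Write (T, H, W) float-in-[0,1] images as a multi-page 8-bit TIFF."""
    tifffile.imwrite(str(path), _to_uint8(images), photometric="minisblack")


def read_image_stack(path: Path | str) -> np.ndarray:
    """Read a multi-page TIFF back to (T, H, W) floats in [0, 1]."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / np.iinfo(arr.dtype).max
    return arr.astype(float)


def _params_to_json(params: PhantomParams) -> dict:
    d = dataclasses.asdict(params)
    if d.get("distractor_spec") is not None:
        d["distractor_spec"] = [dataclasses.asdict(s) if dataclasses.is_dataclass(s) else s
                                for s in params.distractor_spec]
    return d


def write_sequence(out_dir: Path | str, seq_id: str, seq: LabeledSequence) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_image_stack(out / f"{seq_id}.tif", seq.images)
    mask_dir = out / "masks" / seq_id
    mask_dir.mkdir(parents=True, exist_ok=True)
    for t, mask in enumerate(seq.masks):
        iio.imwrite(mask_dir / f"frame_{t:02d}.png", (mask * 255).astype(np.uint8))
    param_dir = out / "params"
    param_dir.mkdir(exist_ok=True)
    (param_dir / f"{seq_id}.json").write_text(
        json.dumps(_params_to_json(seq.params), indent=2, default=float))


def write_dataset(out_dir: Path | str, dataset: list[LabeledSequence]) -> pd.DataFrame:
    """Write all sequences plus a manifest CSV; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, seq in enumerate(dataset):
        seq_id = f"seq_{i:03d}"
        write_sequence(out, seq_id, seq)
        areas = seq.masks.reshape(len(seq.masks), -1).sum(axis=1)
        for t in range(len(seq.images)):
            rows.append({"sequence": seq_id, "frame": t,
                         "state_label": seq.state_labels[t],
                         "wall_area": int(areas[t])})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_dataset(data_dir: Path | str) -> list[LabeledSequence]:
    """Read a simulated dataset directory back into labelled sequences."""
    data = Path(data_dir)
    manifest = pd.read_csv(data / "manifest.csv")
    out: list[LabeledSequence] = []
    for seq_id, group in manifest.groupby("sequence", sort=True):
        images = read_image_stack(data / f"{seq_id}.tif")
        mask_dir = data / "masks" / str(seq_id)
        masks = np.stack([
            (iio.imread(mask_dir / f"frame_{t:02d}.png") > 127).astype(np.uint8)
            for t in range(len(images))
        ])
        labels = list(group.sort_values("frame")["state_label"])
        pjson = json.loads((data / "params" / f"{seq_id}.json").read_text())
        pjson.pop("distractor_spec", None)
        if pjson.get("center") is not None:
            pjson["center"] = tuple(pjson["center"])
        params = PhantomParams(**pjson)
        out.append(LabeledSequence(images=images, masks=masks,
                                   state_labels=labels, params=params))
    return out


def save_checkpoint(path: Path | str, model: DenseRNNModel,
                    config: dict | None = None) -> str:
    """Save named model tensors and the run config; returns the config hash."""
    cfg_json = json.dumps(config or {}, sort_keys=True, default=float)
    cfg_hash = hashlib.sha256(cfg_json.encode()).hexdigest()[:16]
    arrays = dict(model.to_dict())
    arrays["__config_json__"] = np.frombuffer(cfg_json.encode(), dtype=np.uint8)
    arrays["__config_hash__"] = np.frombuffer(cfg_hash.encode(), dtype=np.uint8)
    np.savez(str(path), **arrays)
    return cfg_hash


def load_checkpoint(path: Path | str) -> tuple[DenseRNNModel, dict]:
    """Load a checkpoint; returns (model, config dict)."""
    with np.load(str(path)) as npz:
        arrays = {k: npz[k] for k in npz.files}
    cfg = json.loads(bytes(arrays.pop("__config_json__")).decode()) \
        if "__config_json__" in arrays else {}
    arrays.pop("__config_hash__", None)
    return DenseRNNModel.from_dict(arrays), cfg
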