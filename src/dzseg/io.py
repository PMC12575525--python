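"""Dataset readers/writers, configuration files, and run logging.

On-disk conventions, project-wide:

* images: 8-bit RGB PNG; masks: single-channel PNG with labels {0, 1}
  (a colorized view is for humans only and never read back);
* prompts: JSON ``{"kind": ..., "point"|"polyline"|"rect": ...}`` with
  0-based (row, col) coordinates, rectangles inclusive on both bounds;
* a dataset manifest is JSON listing entries {id, image_path, mask_path,
  optional prompt_path, split} plus free-form metadata (native resolution,
  UI crop rectangle, frame-rate note);
* configs: YAML; per-epoch training logs: CSV.
"""

from __future__ import annotations

import csv
import json
import logging
import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .errors import ValidationError
from .prompts import PromptGeometry
from .synthetic import ImageSample

__all__ = [
    "save_dataset", "load_dataset", "save_manifest", "load_manifest",
    "write_mask_png", "read_mask_png", "read_image", "write_image",
    "save_prompt", "load_prompt", "crop_ui", "write_epoch_log",
    "write_report", "load_config", "save_config", "setup_logging",
]

log = logging.getLogger("dzseg")


def setup_logging(level: str = "INFO", logfile: str | Path | None = None,
                  seed: int | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers, force=True)
    if seed is not None:
        log.info("seed=%d", seed)


# ---------------------------------------------------------------------------
# images and masks


def write_image(path: str | Path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)


def read_image(path: str | Path) -> np.ndarray:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"image file not found: {p}")
    return np.asarray(Image.open(p).convert("RGB"), dtype=np.uint8)


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    Image.fromarray(np.asarray(mask, dtype=np.uint8), mode="L").save(path)


def read_mask_png(path: str | Path) -> np.ndarray:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"mask file not found: {p}")
    mask = np.asarray(Image.open(p), dtype=np.uint8)
    bad = sorted(set(np.unique(mask)) - {0, 1})
    if bad:
        raise ValidationError(
            f"mask {p} contains labels outside {{0, 1}}: {bad}")
    return mask


# ---------------------------------------------------------------------------
# prompts


def save_prompt(path: str | Path, prompt: PromptGeometry) -> None:
    Path(path).write_text(json.dumps(prompt.to_dict()))


def load_prompt(path: str | Path) -> PromptGeometry:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"prompt file not found: {p}")
    return PromptGeometry.from_dict(json.loads(p.read_text()))


# ---------------------------------------------------------------------------
# datasets and manifests


def save_dataset(samples: list[ImageSample], out_dir: str | Path,
                 split: str = "train", metadata: dict | None = None,
                 prompts: dict[str, PromptGeometry] | None = None) -> Path:
    """Write paired ``<id>.png`` / ``<id>_mask.png`` files plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in samples:
        img_path = out / f"{s.id}.png"
        mask_path = out / f"{s.id}_mask.png"
        write_image(img_path, s.image)
        write_mask_png(mask_path, s.mask)
        entry = {"id": s.id, "image_path": img_path.name,
                 "mask_path": mask_path.name, "split": split}
        if prompts and s.id in prompts:
            prompt_path = out / f"{s.id}_prompt.json"
            save_prompt(prompt_path, prompts[s.id])
            entry["prompt_path"] = prompt_path.name
        entries.append(entry)
    manifest_path = out / "manifest.json"
    save_manifest(manifest_path, entries, metadata or {})
    return manifest_path


def save_manifest(path: str | Path, entries: list[dict], metadata: dict) -> None:
    ids = [e["id"] for e in entries]
    if len(ids) != len(set(ids)):
        raise ValidationError("manifest ids are not unique")
    Path(path).write_text(json.dumps(
        {"entries": entries, "metadata": metadata}, indent=2))


def load_manifest(path: str | Path) -> dict:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"manifest not found: {p}")
    manifest = json.loads(p.read_text())
    ids = [e["id"] for e in manifest["entries"]]
    if len(ids) != len(set(ids)):
        raise ValidationError("manifest ids are not unique")
    return manifest


def load_dataset(manifest_path: str | Path, split: str | None = None,
                 ) -> list[tuple[ImageSample, PromptGeometry | None]]:
    """Load samples (and their prompts, when present) from a manifest."""
    p = Path(manifest_path)
    manifest = load_manifest(p)
    base = p.parent
    out = []
    for entry in manifest["entries"]:
        if split is not None and entry.get("split") != split:
            continue
        image = read_image(base / entry["image_path"])
        mask = read_mask_png(base / entry["mask_path"])
        sample = ImageSample(image=image, mask=mask, id=entry["id"])
        sample.validate()
        prompt = (load_prompt(base / entry["prompt_path"])
                  if entry.get("prompt_path") else None)
        out.append((sample, prompt))
    return out


# ---------------------------------------------------------------------------
# UI cropping


def crop_ui(image: np.ndarray, crop_rect: tuple[int, int, int, int]) -> np.ndarray:
    """Cut the surgical field out of a full frame (drops UI side panels).

    ``crop_rect`` is (row_min, col_min, row_max, col_max), inclusive.
    """
    r0, c0, r1, c1 = crop_rect
    h, w = image.shape[:2]
    if not (0 <= r0 <= r1 < h and 0 <= c0 <= c1 < w):
        raise ValueError(f"crop rect {crop_rect} outside image of shape {(h, w)}")
    return image[r0:r1 + 1, c0:c1 + 1]


# ---------------------------------------------------------------------------
# configs, logs, reports


def save_config(path: str | Path, config: dict) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))


def load_config(path: str | Path) -> dict:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config not found: {p}")
    return yaml.safe_load(p.read_text()) or {}


def write_epoch_log(path: str | Path, log_entries: list[dict]) -> None:
    fields = ["epoch", "lr", "train_loss", "val_mean_iou", "val_mean_dice"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for entry in log_entries:
            writer.writerow({k: entry.get(k) for k in fields})


def write_report(path: str | Path, rows: list[dict]) -> None:
    """Metric rows (one per image or aggregate) as CSV, plus a JSON twin."""
    path = Path(path)
    if rows:
        fields = list(rows[0].keys())
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fields)
            writer.writeheader()
            writer.writerows(rows)
    path.with_suffix(".json").write_text(json.dumps(rows, indent=2))
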