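"""File formats: video TIFF+CSV round trip, YAML configs, run manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .scanner import Frame, ScannerConfig, SyntheticVideo

__all__ = [
    "write_video",
    "read_video",
    "load_yaml_config",
    "write_manifest",
    "format_position",
]

VERSION = "0.1.0"


def format_position(p: float) -> str:
    """Grid-aligned positions serialize as integers for bit-exact round trips."""
    if float(p).is_integer():
        return str(int(p))
    return repr(float(p))


def write_video(video: SyntheticVideo, stem: Path) -> tuple[Path, Path]:
    """Write one sweep as multi-page TIFF + sidecar CSV of frame positions."""
    stem = Path(stem)
    tiff_path = stem.with_suffix(".tiff")
    csv_path = stem.with_suffix(".csv")
    stack = np.stack([f.pixels for f in video.frames]).astype(np.float32)
    tifffile.imwrite(tiff_path, stack)
    with open(csv_path, "w", newline="") as fh:
        fh.write("frame_index,position_um\n")
        for i, f in enumerate(video.frames):
            fh.write(f"{i},{format_position(f.position)}\n")
    return tiff_path, csv_path


def read_video(stem: Path, texture_seed: int = -1) -> SyntheticVideo:
    stem = Path(stem)
    stack = tifffile.imread(stem.with_suffix(".tiff")).astype(np.float64)
    table = pd.read_csv(stem.with_suffix(".csv"))
    frames = [
        Frame(pixels=stack[int(row.frame_index)], position=float(row.position_um))
        for row in table.itertuples()
    ]
    return SyntheticVideo(frames=frames, texture_seed=texture_seed)


def load_yaml_config(path: Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return data


def scanner_config_from_yaml(path: Path) -> ScannerConfig:
    data = load_yaml_config(path)
    try:
        return ScannerConfig.from_dict(data)
    except TypeError as err:
        raise ValueError(f"malformed scanner config {path}: {err}") from err


def _file_sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_manifest(outdir: Path, config: dict, seeds: dict, outputs: list[Path]) -> Path:
    """One manifest per run directory; sufficient to re-run bit-identically."""
    outdir = Path(outdir)
    manifest = {
        "version": VERSION,
        "config": config,
        "seeds": seeds,
        "outputs": {
            str(p.relative_to(outdir)): _file_sha256(p) for p in outputs if p.exists()
        },
    }
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
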