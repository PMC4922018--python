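"""Shared I/O: frame-stack and label-stack readers, report writers, configs.

Physical units (fps, pixel size, section thickness) always come from
configuration or sidecar metadata, never from filenames.  Reports embed a
provenance block (package version, seed, configuration echo) so repeated
runs are byte-comparable.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np

from .cardiometry import FrameStack, Rect, RoiSet
from .morphometry3d import SectionStack

__all__ = [
    "read_frame_stack",
    "read_label_stack",
    "read_rois",
    "write_mask",
    "read_mask",
    "write_report",
    "read_report",
    "load_config",
]

_FRAME_EXTS = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}


def _numbered_files(directory: Path) -> list[Path]:
    """Image files sorted by the numeric part of their stem."""

    def key(p: Path):
        m = re.search(r"(\d+)", p.stem)
        if m is None:
            raise ValueError(f"frame file {p.name} has no numeric index")
        return int(m.group(1))

    files = [p for p in directory.iterdir() if p.suffix.lower() in _FRAME_EXTS]
    if not files:
        raise ValueError(f"no image files found in {directory}")
    return sorted(files, key=key)


def read_frame_stack(path: str | Path, fps: float | None = None) -> FrameStack:
    """Read a video as a multipage TIFF or a directory of numbered frames.

    ``fps`` is required — frame rate is metadata the files do not carry.
    RGB frames are converted to luminance by the :class:`FrameStack`
    constructor.
    """
    if fps is None:
        raise ValueError("missing required parameter 'fps' (frames per second)")
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        frames = [np.asarray(iio.imread(p), dtype=float) for p in _numbered_files(path)]
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise ValueError(f"mixed frame shapes in {path}: {sorted(shapes)}")
        return FrameStack(frames=np.stack(frames), fps=fps)
    import tifffile

    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return FrameStack(frames=np.asarray(arr, dtype=float), fps=fps)


def read_label_stack(path: str | Path, meta: Mapping[str, Any] | str | Path) -> SectionStack:
    """Read an ordered labeled section stack plus its sidecar metadata.

    ``meta`` is a mapping or a JSON file providing ``pixel_size_um`` and
    ``section_thickness_um``.  Pixel values must be integers in {0, 1, 2};
    offending values are reported.
    """
    if isinstance(meta, (str, Path)):
        with open(meta) as fh:
            meta = json.load(fh)
    for key in ("pixel_size_um", "section_thickness_um"):
        if key not in meta:
            raise ValueError(f"missing required metadata key '{key}'")
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        sections = [np.asarray(iio.imread(p)) for p in _numbered_files(path)]
    else:
        import tifffile

        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        sections = [arr[i] for i in range(arr.shape[0])]
    return SectionStack(
        sections=sections,
        pixel_size_um=float(meta["pixel_size_um"]),
        section_thickness_um=float(meta["section_thickness_um"]),
    )


def read_rois(path: str | Path) -> RoiSet:
    """Read an ROI set from JSON.

    Expected form::

        {"heart_rois": [[row0, col0, row1, col1], ...3 of them...],
         "reference_roi": [row0, col0, row1, col1]}

    Rectangles are 0-based with half-open bounds.
    """
    with open(path) as fh:
        data = json.load(fh)
    hearts = tuple(Rect(*r) for r in data["heart_rois"])
    return RoiSet(heart_rois=hearts, reference_roi=Rect(*data["reference_roi"]))  # type: ignore[arg-type]


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as a single-page PNG/TIFF (0 outside, 255 inside)."""
    import imageio.v3 as iio

    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask written by :func:`write_mask` back to boolean."""
    import imageio.v3 as iio

    return np.asarray(iio.imread(path)) > 0


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_report(
    results: Mapping[str, Any],
    path: str | Path,
    format: str = "json",
    seed: int | None = None,
    config: Mapping[str, Any] | None = None,
) -> None:
    """Write an analysis report with a provenance block.

    JSON reports carry stable key order and full float precision; CSV
    reports are flat tables of the top-level scalar entries.
    """
    from . import __version__

    path = Path(path)
    payload = {
        "provenance": {
            "package": "fishbeam",
            "version": __version__,
            "seed": seed,
            "config": _jsonable(config) if config is not None else None,
        },
        "results": _jsonable(dict(results)),
    }
    try:
        if format == "json":
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=2, sort_keys=True)
                fh.write("\n")
        elif format == "csv":
            import pandas as pd

            flat = {
                k: v
                for k, v in payload["results"].items()
                if np.isscalar(v) or v is None
            }
            df = pd.DataFrame([flat]).sort_index(axis=1)
            df.insert(0, "version", __version__)
            df.insert(1, "seed", seed)
            df.to_csv(path, index=False)
        else:
            raise ValueError(f"unknown report format '{format}' (use csv or json)")
    except OSError as exc:
        raise OSError(f"failed writing report to {path}: {exc}") from exc


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)
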