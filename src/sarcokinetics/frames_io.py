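"""Movie ingestion: convert input movies into an ordered stack of 2D
grayscale frames in [0, 1], the unit of all downstream processing.

Supported inputs are multi-page TIFF stacks and directories of
lexicographically ordered single-frame images (PNG/TIFF). Color frames
are converted to grayscale with ITU-R BT.601 luma weights. Integer
pixel data is rescaled to [0, 1] by the global min/max over the whole
stack (global, not per-frame, so intensity dynamics across the beat are
preserved); float data already within [0, 1] is left untouched so that
a written stack reloads bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile

__all__ = ["FrameStack", "load_movie", "save_stack"]

_BT601 = np.array([0.299, 0.587, 0.114])

_FRAME_SUFFIXES = {".png", ".tif", ".tiff"}


@dataclass
class FrameStack:
    """Ordered grayscale frames of one movie.

    ``frames`` is (n_frames, rows, cols) float in [0, 1]; frame order is
    temporal order.
    """

    frames: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, rows, cols) array")
        if self.frames.min() < 0 or self.frames.max() > 1:
            raise ValueError("frame values must lie in [0, 1]")

    @property
    def frame_count(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, idx):
        return self.frames[idx]


def load_movie(path: str | Path, format_hint: str | None = None) -> FrameStack:
    """Load a movie into a FrameStack.

    ``path`` may be a multi-page TIFF file or a directory of per-frame
    images ordered by file name. ``format_hint`` ("tiff" or "dir")
    overrides auto-detection.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"movie not found: {path}")
    if format_hint == "dir" or (format_hint is None and path.is_dir()):
        raw = _read_frame_dir(path)
    else:
        raw = _read_tiff(path)
    frames = _to_grayscale_stack(raw, str(path))
    return FrameStack(frames=_normalize(frames, raw[0].dtype), source=str(path))


def _read_tiff(path: Path) -> list[np.ndarray]:
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - exercised via bad files
        raise IOError(f"unreadable TIFF: {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None]
    return list(arr)


def _read_frame_dir(path: Path) -> list[np.ndarray]:
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES
    )
    if not files:
        raise IOError(f"no frame images found in {path}")
    frames = []
    for f in files:
        try:
            frames.append(np.asarray(iio.imread(f)))
        except Exception as exc:
            raise IOError(f"unreadable frame: {f}: {exc}") from exc
    return frames


def _to_grayscale_stack(raw: list[np.ndarray], source: str) -> np.ndarray:
    shapes = {f.shape[:2] for f in raw}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent frame shapes in {source}: {shapes}")
    out = []
    for f in raw:
        f = np.asarray(f, dtype=float)
        if f.ndim == 3:
            f = f[..., :3] @ _BT601
        out.append(f)
    return np.asarray(out)


def _normalize(frames: np.ndarray, dtype: np.dtype) -> np.ndarray:
    lo, hi = frames.min(), frames.max()
    if np.issubdtype(dtype, np.floating) and lo >= 0 and hi <= 1:
        return frames
    if hi == lo:
        return np.zeros_like(frames)
    return (frames - lo) / (hi - lo)


def save_stack(stack: FrameStack, path: str | Path) -> Path:
    """Write a FrameStack as a multi-page float32 TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    return path
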