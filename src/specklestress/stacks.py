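"""Frame-stack container and readers/writers for speckle video data.

A :class:`FrameStack` is the raw unit of measurement: a timed sequence of
2-D grayscale speckle images together with the acquisition frame rate and
bit depth.  Stacks can be stored either as multi-page grayscale TIFF (one
page per frame, metadata in the image description) or as a raw binary dump
with a JSON sidecar header.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "FrameStack",
    "read_tiff_stack",
    "write_tiff_stack",
    "read_raw_stack",
    "write_raw_stack",
]


@dataclass(frozen=True)
class FrameStack:
    """A timed sequence of 2-D grayscale speckle frames.

    Parameters
    ----------
    frames
        3-D integer intensity array indexed ``(time, row, col)``.
    fps
        Acquisition frame rate in Hz; must be positive.
    bit_depth
        Number of bits per pixel; intensities must lie in
        ``[0, 2**bit_depth - 1]``.
    source_id
        Free-text provenance label.
    """

    frames: np.ndarray
    fps: float
    bit_depth: int = 8
    source_id: str = ""

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (time, row, col), got ndim={frames.ndim}")
        if frames.shape[0] < 2:
            raise ValueError(f"need at least 2 frames, got {frames.shape[0]}")
        if not np.issubdtype(frames.dtype, np.integer):
            raise ValueError(f"frames must be integer grayscale, got dtype {frames.dtype}")
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.bit_depth < 1:
            raise ValueError(f"bit_depth must be >= 1, got {self.bit_depth}")
        lo, hi = frames.min(), frames.max()
        if lo < 0 or hi > self.max_intensity:
            raise ValueError(
                f"intensities [{lo}, {hi}] outside [0, {self.max_intensity}] "
                f"for bit_depth={self.bit_depth}"
            )
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(row, col) shape of a single frame."""
        return self.frames.shape[1:]

    @property
    def max_intensity(self) -> int:
        return 2 ** self.bit_depth - 1

    @property
    def duration_s(self) -> float:
        return (self.n_frames - 1) / self.fps


def _meta_dict(stack: FrameStack) -> dict:
    return {
        "fps": stack.fps,
        "bit_depth": stack.bit_depth,
        "source_id": stack.source_id,
        "shape": list(stack.frames.shape),
        "dtype": str(stack.frames.dtype),
    }


def write_tiff_stack(stack: FrameStack, path: str | Path) -> Path:
    """Write a stack as multi-page grayscale TIFF with JSON metadata."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames, description=json.dumps(_meta_dict(stack)))
    return path


def read_tiff_stack(
    path: str | Path,
    fps: float | None = None,
    bit_depth: int | None = None,
    source_id: str | None = None,
) -> FrameStack:
    """Read a multi-page grayscale TIFF as a :class:`FrameStack`.

    Metadata embedded in the TIFF description (as written by
    :func:`write_tiff_stack`) is used unless overridden by arguments.
    Foreign TIFFs without embedded metadata require explicit ``fps``.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray()
        meta: dict = {}
        desc = tif.pages[0].description
        if desc:
            try:
                meta = json.loads(desc)
            except (json.JSONDecodeError, TypeError):
                meta = {}
    if frames.ndim == 2:
        frames = frames[np.newaxis]
    fps = fps if fps is not None else meta.get("fps")
    if fps is None:
        raise ValueError(f"{path}: no fps metadata found; pass fps explicitly")
    if bit_depth is None:
        bit_depth = meta.get("bit_depth", int(frames.dtype.itemsize * 8))
    if source_id is None:
        source_id = meta.get("source_id", path.stem)
    return FrameStack(frames=frames, fps=float(fps), bit_depth=int(bit_depth), source_id=source_id)


def write_raw_stack(stack: FrameStack, path: str | Path) -> tuple[Path, Path]:
    """Write a stack as raw binary plus a JSON sidecar header.

    The sidecar is ``<path>.json`` and records shape, dtype, fps and
    bit depth so the raw file is self-describing.
    """
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    stack.frames.tofile(path)
    sidecar.write_text(json.dumps(_meta_dict(stack), indent=2))
    return path, sidecar


def read_raw_stack(path: str | Path) -> FrameStack:
    """Read a raw binary stack using its ``<path>.json`` sidecar header."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"sidecar header {sidecar} not found for raw stack {path}")
    meta = json.loads(sidecar.read_text())
    frames = np.fromfile(path, dtype=np.dtype(meta["dtype"])).reshape(meta["shape"])
    return FrameStack(
        frames=frames,
        fps=float(meta["fps"]),
        bit_depth=int(meta["bit_depth"]),
        source_id=meta.get("source_id", path.stem),
    )
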