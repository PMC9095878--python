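"""Height-map container and file I/O.

A topograph is a 2-D grid of surface heights in nanometres. Rows run along
the slow (y) scan axis, columns along the fast (x) axis; values are heights
relative to an arbitrary reference until leveling pins the membrane to 0 nm.
The on-disk dialect is a 32-bit float TIFF next to a JSON sidecar carrying
the pixel size, membrane reference level, scan channel and generator seed;
tiny fixtures may instead be stored as plain whitespace-delimited matrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["Topograph", "read_topograph", "write_topograph"]

#: Valid scan-channel roles.
CHANNELS = ("trace", "retrace", "averaged")


@dataclass
class Topograph:
    """A calibrated AFM height map.

    Parameters
    ----------
    heights
        2-D array of heights in nm, row-major, ``heights[row, col]`` with the
        row index along the slow/y axis and pixel centres on the grid.
    pixel_size
        Pixel size in nm/px, ``(dy, dx)``. A scalar is broadcast to both axes;
        the two may differ after drift unwarping.
    channel
        Scan-channel role: ``trace``, ``retrace`` or ``averaged``.
    provenance
        Free-text processing log, one entry per operation applied.
    """

    heights: np.ndarray
    pixel_size: tuple[float, float]
    channel: str = "trace"
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2-D array")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite")
        if np.isscalar(self.pixel_size):
            self.pixel_size = (float(self.pixel_size), float(self.pixel_size))
        else:
            self.pixel_size = (float(self.pixel_size[0]), float(self.pixel_size[1]))
        if min(self.pixel_size) <= 0:
            raise ValueError("pixel_size must be positive on both axes")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")

    # -- geometry helpers ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    @property
    def extent_nm(self) -> tuple[float, float]:
        """Physical field of view (y, x) in nm."""
        return (
            self.shape[0] * self.pixel_size[0],
            self.shape[1] * self.pixel_size[1],
        )

    def nm_to_px(self, y_nm: float, x_nm: float) -> tuple[float, float]:
        """Convert physical coordinates (nm) to fractional pixel indices."""
        return (y_nm / self.pixel_size[0], x_nm / self.pixel_size[1])

    def px_to_nm(self, row: float, col: float) -> tuple[float, float]:
        return (row * self.pixel_size[0], col * self.pixel_size[1])

    def with_heights(self, heights: np.ndarray, note: str | None = None,
                     **changes) -> "Topograph":
        """Derived topograph with new heights and an appended provenance note."""
        prov = list(self.provenance)
        if note:
            prov.append(note)
        return replace(self, heights=np.asarray(heights, dtype=float),
                       provenance=prov, **changes)


def write_topograph(t: Topograph, path: str | Path, *,
                    membrane_level_nm: float = 0.0,
                    seed: int | None = None) -> Path:
    """Write ``t`` to disk.

    ``path`` ending in ``.tif``/``.tiff`` selects the float32 TIFF + JSON
    sidecar dialect; ``.txt`` writes a plain whitespace-delimited matrix
    (only sensible for small fixtures) with the same sidecar.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, t.heights.astype(np.float32))
    elif path.suffix == ".txt":
        np.savetxt(path, t.heights, fmt="%.6f")
    else:
        raise ValueError(f"unsupported topograph extension: {path.suffix}")
    sidecar = {
        "pixel_size_nm": list(t.pixel_size),
        "membrane_level_nm": membrane_level_nm,
        "channel": t.channel,
        "seed": seed,
        "provenance": t.provenance,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1))
    return path


def read_topograph(path: str | Path) -> Topograph:
    """Read a topograph written by :func:`write_topograph`."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        heights = tifffile.imread(path).astype(float)
    elif path.suffix == ".txt":
        heights = np.loadtxt(path)
    else:
        raise ValueError(f"unsupported topograph extension: {path.suffix}")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        pixel_size = tuple(np.atleast_1d(meta["pixel_size_nm"]).tolist()
                           * (2 if np.isscalar(meta["pixel_size_nm"]) else 1))
        if len(pixel_size) == 1:
            pixel_size = (pixel_size[0], pixel_size[0])
        t = Topograph(heights, pixel_size, meta.get("channel", "trace"),
                      list(meta.get("provenance", [])))
    else:
        t = Topograph(heights, (1.0, 1.0))
    return t
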