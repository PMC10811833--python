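"""Core image currency: 2-D CT slices with spacing and intensity-unit
metadata, plus lossless PNG/JSON round-trip I/O."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["CTSlice", "UNITS"]

UNITS = ("gray8", "normalized01", "hounsfield")


@dataclass
class CTSlice:
    """A single axial slice.

    pixels: 2-D intensity matrix; gray8 stores uint8 in [0,255],
    normalized01 stores float in [0,1], hounsfield stores float HU.
    spacing: isotropic pixel spacing in mm.
    """

    pixels: np.ndarray
    spacing: float
    unit: str = "gray8"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D matrix")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive (mm)")
        if self.unit not in UNITS:
            raise ValueError(f"unit must be one of {UNITS}")
        if self.unit == "gray8":
            if self.pixels.dtype != np.uint8:
                p = np.asarray(self.pixels)
                if p.min() < 0 or p.max() > 255:
                    raise ValueError("gray8 values must lie in [0, 255]")
                self.pixels = np.round(p).astype(np.uint8)
        elif self.unit == "normalized01":
            p = self.pixels.astype(np.float32)
            if p.min() < -1e-6 or p.max() > 1 + 1e-6:
                raise ValueError("normalized01 values must lie in [0, 1]")
            self.pixels = np.clip(p, 0.0, 1.0)

    @property
    def grid_size(self) -> int:
        return self.pixels.shape[0]

    def to_normalized01(self) -> "CTSlice":
        if self.unit == "normalized01":
            return CTSlice(self.pixels.copy(), self.spacing, "normalized01")
        if self.unit == "gray8":
            return CTSlice(self.pixels.astype(np.float32) / 255.0,
                           self.spacing, "normalized01")
        raise ValueError("window Hounsfield data to gray8 before normalizing")

    def to_gray8(self) -> "CTSlice":
        if self.unit == "gray8":
            return CTSlice(self.pixels.copy(), self.spacing, "gray8")
        if self.unit == "normalized01":
            return CTSlice(np.round(self.pixels * 255.0).astype(np.uint8),
                           self.spacing, "gray8")
        raise ValueError("window Hounsfield data with preprocess.hu_to_gray8")

    # ---------------------------------------------------------------- I/O

    def save_png(self, path) -> None:
        """8-bit grayscale PNG plus a JSON sidecar holding spacing/unit."""
        g = self.to_gray8()
        Image.fromarray(g.pixels, mode="L").save(path)
        Path(str(path) + ".json").write_text(
            json.dumps({"spacing": self.spacing, "unit": "gray8"})
        )

    @classmethod
    def load_png(cls, path) -> "CTSlice":
        img = np.asarray(Image.open(path).convert("L"))
        sidecar = Path(str(path) + ".json")
        spacing = 1.0
        if sidecar.exists():
            spacing = float(json.loads(sidecar.read_text())["spacing"])
        return cls(img, spacing, "gray8")
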