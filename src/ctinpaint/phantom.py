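"""Synthetic thorax phantom generator.

Each phantom is a single axial slice built from the minimal anatomy that
exercises lung-site completion: an elliptical soft-tissue body, two
low-density elliptical lungs, and one high-density spine disk, on an air
background. Geometry is jittered per seed so a dataset spans a range of
body sizes; truncating the lateral columns of a wide phantom then emulates
a patient larger than the scanner field of view.

Default geometry approximates an adult thorax on a 128 x 128 grid at 3 mm
pixels (384 mm field): body semiaxes 170 x 110 mm (+/- jitter), lungs
45 x 70 mm offset laterally, spine radius 15 mm posterior. Gray levels use
an 8-bit scale with air 0, lung 30, soft tissue 100 (water-like), bone 220.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
import json

import numpy as np

from .image import CTSlice

__all__ = ["PhantomSpec", "generate_phantom", "generate_dataset",
           "save_phantom", "load_phantom"]


@dataclass
class PhantomSpec:
    grid_size: int = 128
    pixel_spacing: float = 3.0  # mm
    body_semiaxes: tuple[float, float] = (170.0, 110.0)  # mm (lateral, AP)
    body_jitter: tuple[float, float] = (20.0, 15.0)  # uniform +/- mm
    lung_semiaxes: tuple[float, float] = (45.0, 70.0)  # mm
    lung_offsets: tuple[float, float] = (60.0, -10.0)  # mm (+/-lateral, AP)
    spine_radius: float = 15.0  # mm
    spine_offset: float = 75.0  # mm posterior of center
    tissue_gray: int = 100
    lung_gray: int = 30
    bone_gray: int = 220
    air_gray: int = 0
    noise_sd: float = 4.0  # additive Gaussian, gray levels
    seed: int = 0

    def validate(self) -> None:
        grays = {"air_gray": self.air_gray, "lung_gray": self.lung_gray,
                 "tissue_gray": self.tissue_gray, "bone_gray": self.bone_gray}
        for name, g in grays.items():
            if not 0 <= g <= 255:
                raise ValueError(f"{name}={g} outside [0, 255]")
        if not (self.air_gray < self.lung_gray < self.tissue_gray < self.bone_gray):
            raise ValueError(
                "gray levels must satisfy air_gray < lung_gray < tissue_gray < bone_gray"
            )
        half = self.grid_size * self.pixel_spacing / 2.0
        for axis, (a, j) in enumerate(zip(self.body_semiaxes, self.body_jitter)):
            if a + j >= half:
                raise ValueError(
                    f"body_semiaxes[{axis}] + jitter = {a + j} mm does not fit "
                    f"inside the half-grid {half} mm"
                )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.grid_size < 8:
            raise ValueError("grid_size must be at least 8")


def _ellipse(xx, yy, cx, cy, ax, ay):
    if ax <= 0 or ay <= 0:
        return np.zeros_like(xx, dtype=bool)
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec):
    """Return (CTSlice, body mask). Deterministic for a fixed spec.seed;
    the body mask is exactly the set of non-air pixels before noise."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.grid_size
    # pixel centers in mm, origin at grid center
    c = (n - 1) / 2.0
    coords = (np.arange(n) - c) * spec.pixel_spacing
    xx, yy = np.meshgrid(coords, coords)  # xx lateral, yy AP (rows)

    ja, jb = spec.body_jitter
    ax = spec.body_semiaxes[0] + rng.uniform(-ja, ja)
    ay = spec.body_semiaxes[1] + rng.uniform(-jb, jb)

    body = _ellipse(xx, yy, 0.0, 0.0, ax, ay)
    img = np.full((n, n), float(spec.air_gray))
    img[body] = spec.tissue_gray

    lx, ly = spec.lung_semiaxes
    ox, oy = spec.lung_offsets
    # shrink lungs if a thin jittered body would not contain them
    sx = min(1.0, max(0.1, (ax - 10.0 - ox) / lx)) if lx > 0 else 0.0
    sy = min(1.0, max(0.1, (ay - 10.0 - abs(oy)) / ly)) if ly > 0 else 0.0
    for side in (-1.0, 1.0):
        lung = _ellipse(xx, yy, side * ox, oy, lx * sx, ly * sy)
        img[lung & body] = spec.lung_gray

    if spec.spine_radius > 0:
        oy_s = min(spec.spine_offset, ay - spec.spine_radius - 5.0)
        spine = _ellipse(xx, yy, 0.0, oy_s, spec.spine_radius, spec.spine_radius)
        img[spine & body] = spec.bone_gray

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return CTSlice(img, spec.pixel_spacing, "gray8"), body


def _item_seed(seed: int, i: int) -> int:
    return int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2 ** 31))


def generate_dataset(spec: PhantomSpec, n: int, seed: int):
    """n phantoms; item i is reproducible on its own from (seed, i)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [generate_phantom(replace(spec, seed=_item_seed(seed, i)))
            for i in range(n)]


def save_phantom(path, slice_: CTSlice, outline: np.ndarray, spec: PhantomSpec | None = None):
    """8-bit PNG + JSON sidecar carrying the spec and run-length-encoded
    outline; lossless round trip."""
    slice_.save_png(path)
    flat = np.asarray(outline, dtype=bool).ravel()
    # run-length encode [value0, run0, run1, ...]
    change = np.flatnonzero(np.diff(flat.astype(np.int8)))
    runs = np.diff(np.concatenate([[0], change + 1, [flat.size]])).tolist()
    side = json.loads(Path(str(path) + ".json").read_text())
    side["outline_rle"] = {"first": bool(flat[0]), "runs": runs,
                           "shape": list(outline.shape)}
    if spec is not None:
        d = spec.__dict__.copy()
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        side["phantom_spec"] = d
    Path(str(path) + ".json").write_text(json.dumps(side))


def load_phantom(path):
    """Inverse of save_phantom: returns (CTSlice, outline, PhantomSpec|None)."""
    slice_ = CTSlice.load_png(path)
    side = json.loads(Path(str(path) + ".json").read_text())
    rle = side["outline_rle"]
    vals = []
    v = rle["first"]
    for r in rle["runs"]:
        vals.append(np.full(r, v, dtype=bool))
        v = not v
    outline = np.concatenate(vals).reshape(rle["shape"])
    spec = None
    if "phantom_spec" in side:
        d = side["phantom_spec"]
        for k in ("body_semiaxes", "body_jitter", "lung_semiaxes", "lung_offsets"):
            d[k] = tuple(d[k])
        spec = PhantomSpec(**d)
    return slice_, outline, spec
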