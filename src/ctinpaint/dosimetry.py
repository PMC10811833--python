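"""Toy arc-dose engine and 2-D gamma-index analysis.

The dose engine exists to make dosimetric comparison of completed slices
exercisable: for each of ``n_beams`` equispaced gantry angles a parallel
beam, collimated to the target width (a crude conformal arc), is attenuated
exponentially along its rays with an attenuation coefficient linear in gray
value (water gray maps to 0.005/mm); the locally deposited dose is
proportional to mu times the arriving fluence, beams are summed and the
field is scaled so the target-centre dose equals the prescription. It
ignores scatter and divergence — it is not a clinical dose algorithm.

The gamma analysis is the standard global-normalization gamma: for every
reference pixel above the dose threshold,

    gamma(r) = min over r' within the search radius of
               sqrt( (D_eval(r') - D_ref(r))^2 / dd^2 + |r' - r|^2 / dta^2 ),

with dd expressed as a percentage of the maximum reference dose, the
evaluated dose bilinearly interpolated on a fine sub-grid, and the pass
rate the percentage of evaluated pixels with gamma <= 1.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import CTSlice

__all__ = ["DoseGrid", "GammaCriteria", "GammaResult", "toy_arc_dose",
           "gamma_map", "gamma_suite", "write_dose", "read_dose",
           "DEFAULT_CRITERIA_GRID"]

MU_WATER_PER_MM = 0.005


@dataclass
class DoseGrid:
    dose: np.ndarray  # cGy
    spacing: float  # mm
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.dose = np.asarray(self.dose, dtype=np.float64)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if (self.dose < 0).any():
            raise ValueError("dose must be nonnegative everywhere")


@dataclass
class GammaCriteria:
    dd_percent: float  # % of max reference dose
    dta_mm: float
    threshold_percent: float = 10.0  # % of max reference dose
    search_radius_mm: float | None = None  # default 3 * dta
    interp_step_mm: float | None = None  # default dta / 10

    def __post_init__(self):
        if self.dd_percent <= 0 or self.dta_mm <= 0:
            raise ValueError("dd_percent and dta_mm must be positive")
        if not 0 <= self.threshold_percent < 100:
            raise ValueError("threshold_percent must be in [0, 100)")
        if self.search_radius_mm is None:
            self.search_radius_mm = 3.0 * self.dta_mm
        if self.interp_step_mm is None:
            self.interp_step_mm = self.dta_mm / 10.0
        if self.search_radius_mm < self.dta_mm:
            raise ValueError("search_radius_mm must be >= dta_mm")


@dataclass
class GammaResult:
    gamma: np.ndarray  # NaN where excluded by the dose threshold
    pass_rate: float  # % of evaluated pixels with gamma <= 1
    n_evaluated: int
    criteria: GammaCriteria | None = None


def toy_arc_dose(ct: CTSlice, target_center: tuple[int, int],
                 target_diameter_mm: float = 20.0,
                 prescription_cGy: float = 200.0, n_beams: int = 36,
                 water_gray: int = 100, start_angle_deg: float = 0.0,
                 scale: float | None = None) -> DoseGrid:
    """Arc dose on one slice; target_center is a (row, col) pixel index.

    With ``scale`` unset the plan is normalized so the target-centre dose
    equals the prescription. Passing the ``scale`` recorded in a reference
    plan's meta applies *that same plan* (same monitor units) to another
    image, which is how a completed slice is dosimetrically compared against
    the ground-truth plan.
    """
    g = ct.to_gray8().pixels.astype(np.float64)
    n = g.shape[0]
    r0, c0 = target_center
    if not (0 <= r0 < n and 0 <= c0 < n):
        raise ValueError("target center outside the grid")
    mu = MU_WATER_PER_MM * g / float(water_gray)  # per mm
    center = (n - 1) / 2.0
    half_width = target_diameter_mm / 2.0 / ct.spacing  # pixels
    cols = np.arange(n)
    dose = np.zeros_like(mu)
    angles = start_angle_deg + np.arange(n_beams) * (360.0 / n_beams)
    for ang in angles:
        mur = ndimage.rotate(mu, ang, reshape=False, order=1, mode="constant")
        mur = np.clip(mur, 0.0, None)
        # target position in the rotated frame: the content (and with it the
        # target point) rotates by +ang about the grid centre in (row, col)
        # space.
        t = math.radians(ang)
        dr, dc = r0 - center, c0 - center
        tc = center + (dr * math.sin(t) + dc * math.cos(t))
        aperture = (np.abs(cols - tc) <= half_width).astype(np.float64)
        # beam travels down the rows; attenuation of material above each pixel
        path = np.vstack([np.zeros(n), np.cumsum(mur[:-1], axis=0)]) * ct.spacing
        fluence = np.exp(-path)
        dep = mur * fluence * aperture[None, :]
        dose += ndimage.rotate(dep, -ang, reshape=False, order=1, mode="constant")
    dose = np.clip(dose, 0.0, None)
    if scale is None:
        d0 = dose[r0, c0]
        if d0 <= 0:
            raise ValueError("zero dose at the target centre; target outside all beams?")
        scale = prescription_cGy / d0
    dose *= scale
    return DoseGrid(dose=dose, spacing=ct.spacing,
                    meta={"scale": scale,
                          "prescription_cGy": prescription_cGy,
                          "n_beams": n_beams,
                          "target_center": [int(r0), int(c0)],
                          "target_diameter_mm": target_diameter_mm})


def _bilinear_upsample(d: np.ndarray, f: int) -> np.ndarray:
    """Separable linear interpolation onto an f-times finer grid whose
    nodes include the original pixel centres ((n-1)*f + 1 per side)."""
    if f == 1:
        return np.asarray(d, dtype=np.float64)

    def axis0(a):
        n0 = a.shape[0]
        w = (np.arange(f) / f)[None, :, None]
        seg = a[:-1, None, :] * (1 - w) + a[1:, None, :] * w
        out = np.empty(((n0 - 1) * f + 1, a.shape[1]), dtype=np.float64)
        out[:-1] = seg.reshape(-1, a.shape[1])
        out[-1] = a[-1]
        return out

    return axis0(axis0(np.asarray(d, dtype=np.float64)).T).T


def gamma_map(ref: DoseGrid, eval_: DoseGrid, crit: GammaCriteria,
              _fine: np.ndarray | None = None) -> GammaResult:
    """Global-normalization gamma index of ``eval_`` against ``ref``.

    ``_fine`` optionally supplies the precomputed fine-grid interpolation of
    the evaluated dose (gamma_suite shares it between criteria cells).
    """
    if ref.dose.shape != eval_.dose.shape or ref.spacing != eval_.spacing:
        raise ValueError("reference and evaluated grids must match")
    n_r, n_c = ref.dose.shape
    dmax = float(ref.dose.max())
    if dmax <= 0:
        raise ValueError("reference dose is identically zero")
    dd_abs = crit.dd_percent / 100.0 * dmax
    thresh = crit.threshold_percent / 100.0 * dmax

    f = max(1, int(round(ref.spacing / crit.interp_step_mm)))
    step = ref.spacing / f  # mm per fine step
    fine = _bilinear_upsample(eval_.dose, f) if _fine is None else _fine
    nfr, nfc = fine.shape

    sel = ref.dose >= thresh
    ri, ci = np.nonzero(sel)
    refv = ref.dose[ri, ci]
    base_r, base_c = ri * f, ci * f

    rf = int(round(crit.search_radius_mm / step))
    di, dj = np.meshgrid(np.arange(-rf, rf + 1), np.arange(-rf, rf + 1),
                         indexing="ij")
    keep = di ** 2 + dj ** 2 <= rf ** 2
    offs = np.stack([di[keep], dj[keep]], axis=1)
    r2 = (offs[:, 0] ** 2 + offs[:, 1] ** 2).astype(np.float64)
    order = np.argsort(r2)
    offs, r2 = offs[order], r2[order]
    spatial2 = r2 * (step / crit.dta_mm) ** 2

    g2 = np.full(refv.shape, np.inf)
    for (oi, oj), s2 in zip(offs, spatial2):
        if g2.size and s2 >= g2.max():
            break  # spatial term alone already exceeds every current minimum
        pr, pc = base_r + oi, base_c + oj
        ok = (pr >= 0) & (pr < nfr) & (pc >= 0) & (pc < nfc)
        if not ok.any():
            continue
        dv = fine[pr[ok], pc[ok]] - refv[ok]
        cand = (dv / dd_abs) ** 2 + s2
        sub = g2[ok]
        g2[ok] = np.minimum(sub, cand)

    gamma = np.full(ref.dose.shape, np.nan)
    gamma[ri, ci] = np.sqrt(g2)
    n_eval = int(sel.sum())
    pass_rate = 100.0 * float(np.count_nonzero(gamma[sel] <= 1.0)) / n_eval if n_eval else math.nan
    return GammaResult(gamma=gamma, pass_rate=pass_rate, n_evaluated=n_eval,
                       criteria=crit)


DEFAULT_CRITERIA_GRID = tuple(
    (dd, dta, th) for (dd, dta) in ((1.0, 1.0), (2.0, 2.0)) for th in (1.0, 10.0, 50.0)
)


def gamma_suite(ref: DoseGrid, eval_: DoseGrid,
                grid=DEFAULT_CRITERIA_GRID) -> dict:
    """The six-cell criteria/threshold table: {1%/1mm, 2%/2mm} x
    {1%, 10%, 50%} by default; keys are ((dd, dta), threshold)."""
    out = {}
    fines: dict[int, np.ndarray] = {}
    for dd, dta, th in grid:
        crit = GammaCriteria(dd_percent=dd, dta_mm=dta, threshold_percent=th)
        f = max(1, int(round(ref.spacing / crit.interp_step_mm)))
        if f not in fines:
            fines[f] = _bilinear_upsample(eval_.dose, f)
        out[((dd, dta), th)] = gamma_map(ref, eval_, crit, _fine=fines[f])
    return out


def summarize_pass_rates(results: list[dict]) -> dict:
    """Mean and SD of pass rates per table cell over multiple cases."""
    keys = results[0].keys()
    out = {}
    for k in keys:
        rates = np.array([r[k].pass_rate for r in results], dtype=np.float64)
        out[k] = {"mean": float(rates.mean()), "sd": float(rates.std(ddof=0)),
                  "n_cases": len(rates)}
    return out


def write_dose(path, grid: DoseGrid) -> None:
    """Plain-text matrix with a JSON header line (# prefixed)."""
    header = json.dumps({"spacing": grid.spacing, "meta": grid.meta})
    np.savetxt(path, grid.dose, header=header)


def read_dose(path) -> DoseGrid:
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("#"):
        raise ValueError(f"{path}: missing JSON header at byte 0")
    info = json.loads(first[1:].strip())
    dose = np.loadtxt(path)
    return DoseGrid(dose=dose, spacing=float(info["spacing"]),
                    meta=info.get("meta", {}))
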