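"""Areas of Interest: geometry, area corrections and data-driven derivation.

Two AoI families exist per stimulus. *Experimental* AoIs (``kind
"experimental"``) are authored a priori around the explicit socio-emotional
content of a picture. *Pilot* AoIs (``kind "pilot"``) are larger regions
derived from where observers actually looked: the pooled gaze samples for a
stimulus are binned on a pixel grid, smoothed with a Gaussian kernel, and
the super-threshold density region — unioned with the experimental AoI so
that it always spatially contains it — becomes the pilot AoI.

Shapes are unions of axis-aligned pixel rectangles, 0-based, origin
top-left, half-open ``[x0, x1) x [y0, y1)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import box
from shapely.ops import unary_union

from .config import ScreenGeometry

log = logging.getLogger(__name__)

Rect = tuple[float, float, float, float]  # x0, y0, x1, y1


class AoiError(ValueError):
    pass


@dataclass(frozen=True)
class AoI:
    """One Area of Interest: a union of rectangles on one stimulus."""

    id: str
    stimulus_id: str
    kind: str  # "experimental" | "pilot"
    rects: tuple[Rect, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.kind not in ("experimental", "pilot"):
            raise AoiError(f"unknown AoI kind {self.kind!r}")
        if not self.rects:
            raise AoiError("AoI has an empty shape")
        for x0, y0, x1, y1 in self.rects:
            if x1 <= x0 or y1 <= y0:
                raise AoiError(f"degenerate rectangle {(x0, y0, x1, y1)}")

    @property
    def area_px(self) -> float:
        return union_area(self.rects)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorized point-in-region test (half-open rectangles)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        inside = np.zeros(x.shape, dtype=bool)
        for x0, y0, x1, y1 in self.rects:
            inside |= (x >= x0) & (x < x1) & (y >= y0) & (y < y1)
        return inside

    def distance_to(self, x: float, y: float) -> float:
        """Euclidean distance from a point to the nearest point of the AoI.

        Zero when the point lies inside. Used by the first-fixation-time
        distance correction.
        """
        best = np.inf
        for x0, y0, x1, y1 in self.rects:
            dx = max(x0 - x, 0.0, x - x1)
            dy = max(y0 - y, 0.0, y - y1)
            best = min(best, float(np.hypot(dx, dy)))
        return best

    def bounding_rect(self) -> Rect:
        xs0, ys0, xs1, ys1 = zip(*self.rects)
        return (min(xs0), min(ys0), max(xs1), max(ys1))


def union_area(rects: tuple[Rect, ...] | list[Rect]) -> float:
    """Area of a union of axis-aligned rectangles, overlaps counted once."""
    if not rects:
        raise AoiError("empty rectangle list")
    return float(unary_union([box(x0, y0, x1, y1) for x0, y0, x1, y1 in rects]).area)


def area_fraction(aoi: AoI, screen: ScreenGeometry) -> float:
    """AoI area as a fraction of the screen, in (0, 1].

    The size correction of the gaze indexes divides by this constant, so
    indexes on small AoIs are scaled up commensurately.
    """
    bx0, by0, bx1, by1 = aoi.bounding_rect()
    if bx0 < 0 or by0 < 0 or bx1 > screen.width_px or by1 > screen.height_px:
        raise AoiError("AoI extends beyond the screen")
    frac = aoi.area_px / screen.area_px
    if not 0.0 < frac <= 1.0:
        raise AoiError(f"degenerate area fraction {frac}")
    return frac


def derive_pilot_aoi(
    gaze_x: np.ndarray,
    gaze_y: np.ndarray,
    experimental: AoI,
    screen: ScreenGeometry,
    sigma_px: float = 50.0,
    threshold_frac: float = 0.2,
    grid_step: int = 4,
) -> AoI:
    """Derive the pilot AoI for one stimulus from pooled gaze samples.

    Gaze points are counted on a ``grid_step``-px grid, smoothed with a
    Gaussian kernel of standard deviation ``sigma_px``, and cells whose
    smoothed density reaches ``threshold_frac`` of the peak are kept. The
    bounding rectangles of the connected super-threshold components,
    unioned with the experimental AoI (which enforces the containment
    invariant), form the pilot region. If no cell passes the threshold the
    experimental AoI is returned unchanged and the fallback is logged.
    """
    gaze_x = np.asarray(gaze_x, dtype=float)
    gaze_y = np.asarray(gaze_y, dtype=float)
    if gaze_x.size == 0:
        raise AoiError("need at least one gaze point")
    if sigma_px <= 0:
        raise AoiError("sigma_px must be positive")
    if not 0.0 < threshold_frac < 1.0:
        raise AoiError("threshold_frac must lie in (0, 1)")

    nx = int(np.ceil(screen.width_px / grid_step))
    ny = int(np.ceil(screen.height_px / grid_step))
    ix = np.clip((gaze_x // grid_step).astype(int), 0, nx - 1)
    iy = np.clip((gaze_y // grid_step).astype(int), 0, ny - 1)
    grid = np.zeros((ny, nx), dtype=float)
    np.add.at(grid, (iy, ix), 1.0)

    density = ndimage.gaussian_filter(grid, sigma=sigma_px / grid_step)
    peak = density.max()
    mask = density >= threshold_frac * peak if peak > 0 else np.zeros_like(density, bool)

    rects: list[Rect] = []
    if mask.any():
        labels, n_comp = ndimage.label(mask)
        for sl_y, sl_x in ndimage.find_objects(labels):
            rects.append(
                (
                    float(sl_x.start * grid_step),
                    float(sl_y.start * grid_step),
                    float(min(sl_x.stop * grid_step, screen.width_px)),
                    float(min(sl_y.stop * grid_step, screen.height_px)),
                )
            )
    else:
        log.warning(
            "no density cell passed threshold for stimulus %s; "
            "falling back to the experimental AoI",
            experimental.stimulus_id,
        )

    rects.extend(experimental.rects)
    return AoI(
        id=f"{experimental.stimulus_id}_pilot",
        stimulus_id=experimental.stimulus_id,
        kind="pilot",
        rects=tuple(rects),
    )


# ---------------------------------------------------------------------------
# aoi.json I/O


def save_aois(aois: list[AoI], path: str) -> None:
    payload = [
        {
            "id": a.id,
            "stimulus_id": a.stimulus_id,
            "kind": a.kind,
            "rects": [list(r) for r in a.rects],
        }
        for a in aois
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_aois(path: str) -> list[AoI]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        AoI(
            id=entry["id"],
            stimulus_id=entry["stimulus_id"],
            kind=entry["kind"],
            rects=tuple(tuple(r) for r in entry["rects"]),
        )
        for entry in payload
    ]
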