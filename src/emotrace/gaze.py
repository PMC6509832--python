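"""Fixation detection and per-trial AoI gaze indexes.

Four indexes are computed per trial and AoI family:

* **prop gaze** — fraction of the trial's gaze samples falling inside the
  family's AoIs (optionally: fraction of fixations);
* **mean time** — mean, over the family's AoIs, of the total fixation
  time spent inside each AoI;
* **time 1st fixation** — onset-relative start time of the first fixation
  landing in an AoI;
* **1st fixation duration** — duration of that fixation.

With several AoIs on one picture the per-AoI values are summed, except
*mean time* which is averaged. Size correction divides prop gaze, mean
time and 1st-fixation duration by the family's screen-area fraction; the
first-fixation time is instead divided by the pixel distance between the
trial's first gaze sample and the AoI first fixated (1-px floor), so that
a remote small region is not penalized for travel time.

Delta scores (pilot minus experimental, on the corrected indexes) isolate
attention paid to pilot-only picture elements: positive deltas mean
attention predominantly outside the explicit socio-emotional content.

Fixations come from a dispersion-based (I-DT) segmentation: maximal
sample runs whose coordinate spread ``(max x - min x) + (max y - min y)``
stays within a dispersion threshold and that last at least a minimum
duration. Invalid samples (blinks, tracking loss) break runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aoi import AoI, area_fraction
from .config import FixationParams, ScreenGeometry

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@dataclass(frozen=True)
class Fixation:
    start_s: float
    end_s: float
    centroid_px: tuple[float, float]

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class GazeIndexSet:
    """Raw and corrected per-trial visual indexes for one AoI family."""

    aoi_kind: str
    raw_prop_gaze: float
    raw_mean_time: float
    raw_time_1st_fix: float  # NaN when no fixation reached an AoI
    raw_fix1_duration: float
    prop_gaze: float
    mean_time: float
    time_1st_fix: float
    fix1_duration: float


@dataclass(frozen=True)
class DeltaIndexSet:
    """Pilot-minus-experimental differences of the corrected indexes."""

    prop_gaze: float
    mean_time: float
    time_1st_fix: float
    fix1_duration: float


@njit(cache=True)
def _idt_core(t, x, y, dispersion, min_duration):  # pragma: no cover - jitted
    n = t.shape[0]
    starts = np.empty(n, np.int64)
    ends = np.empty(n, np.int64)
    m = 0
    i = 0
    while i < n:
        j = i
        while j < n and t[j] - t[i] < min_duration:
            j += 1
        if j >= n:
            break
        xmin = x[i]
        xmax = x[i]
        ymin = y[i]
        ymax = y[i]
        for k in range(i + 1, j + 1):
            if x[k] < xmin:
                xmin = x[k]
            if x[k] > xmax:
                xmax = x[k]
            if y[k] < ymin:
                ymin = y[k]
            if y[k] > ymax:
                ymax = y[k]
        if (xmax - xmin) + (ymax - ymin) > dispersion:
            i += 1
            continue
        while j + 1 < n:
            nx_lo = min(xmin, x[j + 1])
            nx_hi = max(xmax, x[j + 1])
            ny_lo = min(ymin, y[j + 1])
            ny_hi = max(ymax, y[j + 1])
            if (nx_hi - nx_lo) + (ny_hi - ny_lo) > dispersion:
                break
            xmin, xmax, ymin, ymax = nx_lo, nx_hi, ny_lo, ny_hi
            j += 1
        starts[m] = i
        ends[m] = j
        m += 1
        i = j + 1
    return starts[:m], ends[:m]


def detect_fixations(
    samples: pd.DataFrame,
    dispersion_px: float = 60.0,
    min_duration_s: float = 0.1,
) -> list[Fixation]:
    """I-DT fixation detection on one trial's gaze stream.

    ``samples`` needs time-sorted columns ``t_s``, ``x_px``, ``y_px`` and
    ``valid``; invalid samples split the stream into independent runs.
    Returns time-ordered, non-overlapping fixations (possibly empty).
    """
    if len(samples) == 0:
        return []
    return _fixations_from_arrays(
        samples["t_s"].to_numpy(dtype=np.float64),
        samples["x_px"].to_numpy(dtype=np.float64),
        samples["y_px"].to_numpy(dtype=np.float64),
        samples["valid"].to_numpy().astype(bool),
        dispersion_px,
        min_duration_s,
    )


def _fixations_from_arrays(
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    valid: np.ndarray,
    dispersion_px: float,
    min_duration_s: float,
) -> list[Fixation]:
    if t.size == 0:
        return []
    fixations: list[Fixation] = []
    # contiguous valid runs
    boundaries = np.flatnonzero(np.diff(valid.astype(np.int8)) != 0) + 1
    run_edges = np.concatenate(([0], boundaries, [valid.size]))
    for a, b in zip(run_edges[:-1], run_edges[1:]):
        if not valid[a]:
            continue
        starts, ends = _idt_core(
            t[a:b], x[a:b], y[a:b], float(dispersion_px), float(min_duration_s)
        )
        for s, e in zip(starts, ends):
            sl = slice(a + s, a + e + 1)
            fixations.append(
                Fixation(
                    start_s=float(t[a + s]),
                    end_s=float(t[a + e]),
                    centroid_px=(float(x[sl].mean()), float(y[sl].mean())),
                )
            )
    return fixations


def trial_indexes(
    fixations: list[Fixation],
    samples: pd.DataFrame,
    aois: list[AoI],
    screen: ScreenGeometry,
    onset_s: float,
    prop_gaze_mode: str = "samples",
) -> GazeIndexSet:
    """Compute the four visual indexes for one trial and one AoI family."""
    valid = samples[samples["valid"] == 1]
    return _indexes_from_arrays(
        fixations,
        valid["x_px"].to_numpy(dtype=float),
        valid["y_px"].to_numpy(dtype=float),
        aois,
        screen,
        onset_s,
        prop_gaze_mode,
    )


def _indexes_from_arrays(
    fixations: list[Fixation],
    xs: np.ndarray,
    ys: np.ndarray,
    aois: list[AoI],
    screen: ScreenGeometry,
    onset_s: float,
    prop_gaze_mode: str = "samples",
    frac: float | None = None,
) -> GazeIndexSet:
    if not aois:
        raise ValueError("no AoIs supplied")
    kinds = {a.kind for a in aois}
    if len(kinds) != 1:
        raise ValueError("AoIs of mixed kinds passed to trial_indexes")
    kind = kinds.pop()

    # prop gaze: per-AoI counts, summed over the family
    if prop_gaze_mode == "samples":
        total = xs.size
        hits = sum(int(a.contains(xs, ys).sum()) for a in aois)
    else:
        total = len(fixations)
        hits = sum(
            1
            for f in fixations
            for a in aois
            if a.contains(np.array([f.centroid_px[0]]), np.array([f.centroid_px[1]]))[0]
        )
    raw_prop = hits / total if total else np.nan

    fx = np.array([f.centroid_px[0] for f in fixations])
    fy = np.array([f.centroid_px[1] for f in fixations])

    mean_times = []
    t1f_parts: list[float] = []
    f1d_parts: list[float] = []
    first_global: tuple[float, AoI] | None = None  # (start, AoI) of 1st in-AoI fixation
    for a in aois:
        if fixations:
            in_a = a.contains(fx, fy)
        else:
            in_a = np.zeros(0, dtype=bool)
        mean_times.append(sum(f.duration_s for f, hit in zip(fixations, in_a) if hit))
        idx = np.flatnonzero(in_a)
        if idx.size:
            first = fixations[int(idx[0])]
            t1f_parts.append(first.start_s - onset_s)
            f1d_parts.append(first.duration_s)
            if first_global is None or first.start_s < first_global[0]:
                first_global = (first.start_s, a)
    raw_mean_time = float(np.mean(mean_times))
    raw_t1f = float(sum(t1f_parts)) if t1f_parts else np.nan
    raw_f1d = float(sum(f1d_parts)) if f1d_parts else np.nan

    if frac is None:
        frac = family_area_fraction(aois, screen)

    if first_global is not None and xs.size:
        dist = max(1.0, first_global[1].distance_to(float(xs[0]), float(ys[0])))
    else:
        dist = np.nan
    return GazeIndexSet(
        aoi_kind=kind,
        raw_prop_gaze=raw_prop,
        raw_mean_time=raw_mean_time,
        raw_time_1st_fix=raw_t1f,
        raw_fix1_duration=raw_f1d,
        prop_gaze=raw_prop / frac,
        mean_time=raw_mean_time / frac,
        time_1st_fix=raw_t1f / dist if not math.isnan(raw_t1f) else np.nan,
        fix1_duration=raw_f1d / frac,
    )


def delta_scores(pilot: GazeIndexSet, experimental: GazeIndexSet) -> DeltaIndexSet:
    """Pilot-minus-experimental deltas on the corrected indexes.

    A missing value on either side yields a missing delta.
    """
    if pilot.aoi_kind != "pilot" or experimental.aoi_kind != "experimental":
        raise ValueError("expected (pilot, experimental) index sets")
    return DeltaIndexSet(
        prop_gaze=pilot.prop_gaze - experimental.prop_gaze,
        mean_time=pilot.mean_time - experimental.mean_time,
        time_1st_fix=pilot.time_1st_fix - experimental.time_1st_fix,
        fix1_duration=pilot.fix1_duration - experimental.fix1_duration,
    )


def family_area_fraction(aois: list[AoI], screen: ScreenGeometry) -> float:
    """Screen-area fraction of the union of an AoI family's rectangles."""
    return area_fraction(
        AoI(
            id="family",
            stimulus_id=aois[0].stimulus_id,
            kind=aois[0].kind,
            rects=tuple(r for a in aois for r in a.rects),
        ),
        screen,
    )


INDEX_NAMES = ("prop_gaze", "mean_time", "time_1st_fix", "fix1_duration")


def compute_gaze_tables(
    trials: pd.DataFrame,
    gaze: dict[str, pd.DataFrame],
    aois_by_kind: dict[str, dict[str, list[AoI]]],
    screen: ScreenGeometry,
    fixation: FixationParams | None = None,
    prop_gaze_mode: str = "samples",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-trial index and delta tables for a whole cohort.

    ``aois_by_kind`` maps AoI kind -> stimulus_id -> AoI list. Returns
    ``(gaze_indexes, gaze_deltas)`` in long format.
    """
    fixation = fixation or FixationParams()
    fracs = {
        (kind, stim): family_area_fraction(aois, screen)
        for kind, by_stim in aois_by_kind.items()
        for stim, aois in by_stim.items()
    }
    index_rows = []
    delta_rows = []
    for pid, stream in gaze.items():
        t = stream["t_s"].to_numpy(dtype=np.float64)
        x = stream["x_px"].to_numpy(dtype=np.float64)
        y = stream["y_px"].to_numpy(dtype=np.float64)
        valid = stream["valid"].to_numpy().astype(bool)
        ptrials = trials[trials["participant_id"] == pid]
        for trial in ptrials.itertuples():
            lo = np.searchsorted(t, trial.onset_s)
            hi = np.searchsorted(t, trial.onset_s + trial.duration_s)
            sl = slice(lo, hi)
            ok = valid[sl]
            fixations = _fixations_from_arrays(
                t[sl], x[sl], y[sl], ok,
                fixation.dispersion_px, fixation.min_duration_s,
            )
            sets: dict[str, GazeIndexSet] = {}
            for kind, by_stim in aois_by_kind.items():
                aois = by_stim.get(trial.stimulus_id)
                if not aois:
                    continue
                idx = _indexes_from_arrays(
                    fixations, x[sl][ok], y[sl][ok], aois, screen,
                    trial.onset_s, prop_gaze_mode,
                    frac=fracs[(kind, trial.stimulus_id)],
                )
                sets[kind] = idx
                row = {
                    "participant_id": pid,
                    "group": trial.group,
                    "stimulus_id": trial.stimulus_id,
                    "block": trial.block,
                    "category": trial.category,
                    "aoi_kind": kind,
                }
                for name in INDEX_NAMES:
                    row[f"raw_{name}"] = getattr(idx, f"raw_{name}")
                    row[name] = getattr(idx, name)
                index_rows.append(row)
            if "pilot" in sets and "experimental" in sets:
                deltas = delta_scores(sets["pilot"], sets["experimental"])
                delta_rows.append(
                    {
                        "participant_id": pid,
                        "group": trial.group,
                        "stimulus_id": trial.stimulus_id,
                        "block": trial.block,
                        "category": trial.category,
                        **{
                            f"delta_{name}": getattr(deltas, name)
                            for name in INDEX_NAMES
                        },
                    }
                )
    return pd.DataFrame(index_rows), pd.DataFrame(delta_rows)
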