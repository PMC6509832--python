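"""Physiological indexes: skin conductance and heart-rate variability.

Electrodermal traces are low-pass filtered at 2 Hz (zero phase) and, per
trial, a 5 s post-onset response window yields three indexes: the tonic
level SCL (window mean), the phasic response amplitude SCR and its onset
latency. SCR extraction is trough-to-peak: the onset is the first local
minimum in the window from which the rise to the following local maximum
exceeds a small threshold; the amplitude is the trough-to-peak rise
within the window, reported on a log(1 + amplitude) scale so that
zero-response trials are well-defined. Trials with no qualifying rise get
amplitude 0 and a missing latency.

Cardiac indexes come from inter-beat (NN) interval series: HR as
60000 / mean(NN) and RMSSD as the root mean square of successive NN
differences, the standard short-term vagal HRV index. An optional
smoothness-priors detrending (a regularized second-difference smoother)
removes slow trends before RMSSD.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, sparse
from scipy.sparse.linalg import spsolve

from .config import ConfigError

NN_MIN_MS = 200.0
NN_MAX_MS = 3000.0


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class PhysioIndexSet:
    """Per-segment physiological indexes (trial or baseline)."""

    segment: str
    scr: float
    scl: float
    latency_s: float  # NaN when no qualifying response
    hr_bpm: float
    rmssd_ms: float


def lowpass_eda(trace: np.ndarray, fs: float, cutoff_hz: float = 2.0) -> np.ndarray:
    """Zero-phase 2 Hz low-pass; preserves length and DC level.

    A second-order Bessel design (magnitude-normalized, applied forward
    and backward) is used rather than a sharper filter: its monotone step
    response does not ring ahead of the steep SCR rise, which matters
    because the onset detector reads trough positions off the filtered
    trace.
    """
    if fs <= 2.0 * cutoff_hz:
        raise ConfigError(
            f"sampling rate {fs} Hz too low for a {cutoff_hz} Hz low-pass"
        )
    b, a = signal.bessel(2, cutoff_hz, fs=fs, norm="mag")
    return signal.filtfilt(b, a, np.asarray(trace, dtype=float))


def scr_features(
    trace: np.ndarray,
    fs: float,
    onset_s: float,
    trace_start_s: float = 0.0,
    window_s: float = 5.0,
    onset_threshold: float = 0.01,
) -> tuple[float, float, float]:
    """Tonic level, phasic amplitude and onset latency in a response window.

    Returns ``(scl, scr, latency_s)`` where ``scr`` is log(1 + trough-to-
    peak amplitude) and ``latency_s`` is the time from ``onset_s`` to the
    response onset (NaN when no rise reaches ``onset_threshold``).
    """
    trace = np.asarray(trace, dtype=float)
    i0 = int(round((onset_s - trace_start_s) * fs))
    i1 = int(round((onset_s + window_s - trace_start_s) * fs)) + 1
    if i0 < 0 or i1 > trace.size:
        raise ValueError("response window outside the recorded trace")
    w = trace[i0:i1]
    scl = float(w.mean())

    # first peak whose prominence reaches the threshold; a rise truncated
    # by the window end counts as a peak too
    peaks, _ = signal.find_peaks(w, prominence=onset_threshold)
    if peaks.size:
        pk = int(peaks[0])
    else:
        minima, _ = signal.find_peaks(-w)
        end_rise = w[-1] - (w[minima].min() if minima.size else w[0])
        if end_rise >= onset_threshold and w[-1] > w[-2]:
            pk = w.size - 1
        else:
            return scl, 0.0, math.nan

    # onset: the local minimum from which the qualifying rise starts
    minima, _ = signal.find_peaks(-w[: pk + 1])
    m = int(minima[-1]) if minima.size else 0
    amp = float(w[m:].max() - w[m])
    if amp < onset_threshold:
        return scl, 0.0, math.nan

    # tangent refinement: zero-phase smoothing smears the rise foot
    # symmetrically backward, so intersect the maximum-slope tangent of
    # the rising limb with the trough level to recover the onset time
    t_on = float(m)
    if pk > m + 1:
        d = np.gradient(w[m : pk + 1])
        ms = int(np.argmax(d))
        if d[ms] > 0:
            t_on = max(float(m), (m + ms) - (w[m + ms] - w[m]) / d[ms])
    t_on = max(t_on, 0.5)  # keep latency strictly positive
    return scl, float(np.log1p(amp)), t_on / fs


def clean_nn(nn_ms: np.ndarray) -> np.ndarray:
    """Drop physiologically impossible intervals (outside 200-3000 ms)."""
    nn = np.asarray(nn_ms, dtype=float)
    return nn[(nn > NN_MIN_MS) & (nn < NN_MAX_MS)]


def hr(nn_ms: np.ndarray) -> float:
    """Mean heart rate, beats/min, from NN intervals in ms."""
    nn = np.asarray(nn_ms, dtype=float)
    if nn.size < 2:
        raise InsufficientDataError("need at least 2 NN intervals for HR")
    return 60000.0 / float(nn.mean())


def rmssd(nn_ms: np.ndarray) -> float:
    """Root mean square of successive NN-interval differences, ms."""
    nn = np.asarray(nn_ms, dtype=float)
    if nn.size < 2:
        raise InsufficientDataError("need at least 2 NN intervals for RMSSD")
    d = np.diff(nn)
    return float(np.sqrt(np.mean(d**2)))


def detrend_rr(nn_ms: np.ndarray, lambda_sp: float = 500.0) -> np.ndarray:
    """Smoothness-priors detrending of an NN series, mean restored.

    Removes the trend ``(I + lambda^2 D2'D2)^{-1} z`` (a regularized
    second-difference smoother); larger ``lambda_sp`` removes only slower
    trends. Series shorter than 10 intervals pass through with a warning.
    """
    z = np.asarray(nn_ms, dtype=float)
    n = z.size
    if n < 10:
        warnings.warn("NN series too short to detrend; passing through")
        return z.copy()
    d2 = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    a = sparse.identity(n, format="csc") + lambda_sp**2 * (d2.T @ d2)
    trend = spsolve(a, z)
    return z - trend + float(z.mean())


# ---------------------------------------------------------------------------
# cohort-level extraction


def _nn_in_window(
    beat_t: np.ndarray, nn: np.ndarray, t0: float, t1: float
) -> np.ndarray:
    mask = (beat_t >= t0) & (beat_t < t1)
    return clean_nn(nn[mask])


def _cardiac(nn: np.ndarray, detrend_lambda: float | None) -> tuple[float, float]:
    if nn.size < 2:
        return math.nan, math.nan
    series = nn
    if detrend_lambda is not None and nn.size >= 10:
        series = detrend_rr(nn, detrend_lambda)
    return hr(nn), rmssd(series)


def compute_physio_table(
    trials: pd.DataFrame,
    eda: dict[str, pd.DataFrame],
    rr: dict[str, pd.DataFrame],
    eda_hz: float,
    baseline_s: float,
    window_s: float = 5.0,
    onset_threshold: float = 0.01,
    lowpass_hz: float = 2.0,
    detrend_lambda: float | None = None,
) -> pd.DataFrame:
    """Per-trial and baseline physiological indexes for a whole cohort.

    Participants without an EDA trace keep their cardiac indexes; their
    electrodermal columns are missing. Rows with ``segment == "baseline"``
    cover the pre-task recording.
    """
    rows: list[dict] = []
    pids = sorted(set(eda) | set(rr))
    for pid in pids:
        ptrials = trials[trials["participant_id"] == pid]
        group = ptrials["group"].iloc[0] if len(ptrials) else ""
        filt = None
        if pid in eda:
            filt = lowpass_eda(eda[pid]["eda"].to_numpy(), eda_hz, lowpass_hz)
        beat_t = nn = None
        if pid in rr:
            beat_t = rr[pid]["t_s"].to_numpy()
            nn = rr[pid]["rr_ms"].to_numpy()

        def segment_row(segment: str, t0: float, t1: float, win: float) -> dict:
            row: dict = {
                "participant_id": pid,
                "group": group,
                "segment": segment,
                "scr": math.nan,
                "scl": math.nan,
                "latency_s": math.nan,
                "hr_bpm": math.nan,
                "rmssd_ms": math.nan,
            }
            if filt is not None:
                scl, scr, lat = scr_features(
                    filt, eda_hz, t0, 0.0, win, onset_threshold
                )
                row.update(scl=scl, scr=scr, latency_s=lat)
            if beat_t is not None:
                seg_nn = _nn_in_window(beat_t, nn, t0, t1)
                row["hr_bpm"], row["rmssd_ms"] = _cardiac(seg_nn, detrend_lambda)
            return row

        base = segment_row("baseline", 0.0, baseline_s, baseline_s - 1.0 / eda_hz)
        base["latency_s"] = math.nan  # latency is stimulus-locked only
        rows.append(base)
        for trial in ptrials.itertuples():
            row = segment_row(
                trial.stimulus_id,
                trial.onset_s,
                trial.onset_s + trial.duration_s,
                window_s,
            )
            row.update(block=trial.block, category=trial.category)
            rows.append(row)
    return pd.DataFrame(rows)
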