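"""Synthetic affective-picture cohort generator.

Emulates a two-group (clinical BPD vs healthy control) picture-viewing
study: 48 socio-emotional stimuli in two presentation blocks (5 s and
15 s), three valence categories, per-participant randomized trial order
with 10-15 s inter-trial intervals, a 2-min physiological baseline, and
four synchronized data channels — gaze samples, electrodermal activity,
inter-beat (RR) intervals and post-trial affective-slider ratings.

Group differences are *planted* through :class:`~emotrace.config.EffectSpec`
so the downstream extraction and inference stages can be validated against
known ground truth: an earlier SCR onset in the clinical group, reduced
in-AoI gaze occupancy, and opposite-signed block crossovers on valence
ratings and RMSSD. With ``null_mode=True`` the two groups are exchangeable
and the generator doubles as a type-I-error null model.

Noise models (rationale in docs/methods.md):

* gaze — alternating in-AoI / off-AoI attractor dwells (exponential
  holding times) with isotropic Gaussian jitter, which yields I-DT
  detectable fixations and a tunable in-AoI occupancy;
* EDA — smoothly drifting tonic level plus Bateman-shaped phasic
  responses (rise 0.75 s, decay 2 s) at stimulus-locked onsets;
* RR — independent normal intervals around a participant-specific mean,
  with the successive-difference SD set per segment so RMSSD is
  controlled directly;
* ratings — category-anchored means with participant intercepts and
  trial noise, clipped to the [0, 1] slider range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aoi import AoI
from .config import CohortConfig, ConfigError

GROUPS = ("BPD", "HC")

#: category-anchored mean ratings (slider units in [0, 1])
RATING_MEANS = {
    "valence": {"negative": 0.27, "neutral": 0.41, "positive": 0.66},
    "arousal": {"negative": 0.50, "neutral": 0.40, "positive": 0.43},
    "dominance": {"negative": 0.35, "neutral": 0.25, "positive": 0.25},
}
RATING_PARTICIPANT_SD = 0.08
RATING_TRIAL_SD = 0.12

#: questionnaire summary-score profiles: scale -> (BPD mean, sd, HC mean, sd, lo, hi)
QUESTIONNAIRE_PROFILES = {
    "ders_total": (3.01, 0.69, 2.05, 0.60, 1.0, 5.0),
    "pid5_negative_affectivity": (1.97, 0.30, 0.96, 0.24, 0.0, 3.0),
    "panas_pa_pre": (28.6, 6.4, 26.0, 4.2, 10.0, 50.0),
    "panas_na_pre": (29.0, 6.5, 25.9, 3.2, 10.0, 50.0),
}

#: picture mean-valence rating profiles per category (9-point scale)
VALENCE_PROFILES = {
    "negative": (2.64, 0.77, 1.0, 3.99),
    "neutral": (4.56, 0.62, 4.0, 6.0),
    "positive": (7.31, 0.73, 6.01, 9.0),
}

BATEMAN_RISE_S = 0.75
BATEMAN_DECAY_S = 2.0
#: median phasic amplitude (instrument units): with a 0.9 response
#: probability this puts the mean log(1+amplitude) near 1.85, the scale
#: of the reference descriptive tables
SCR_AMPLITUDE_LOGMEAN = np.log(7.0)
SCR_AMPLITUDE_LOGSD = 0.4
SPONTANEOUS_SCR_RATE_HZ = 0.02   # outside stimulus windows only
EDA_NOISE_SD = 0.003
GAZE_INVALID_P = 0.02
LATENCY_CLIP_S = (0.5, 3.9)


def classify_stimulus(mean_valence: float) -> str:
    """Valence-category rule on the 9-point picture rating scale.

    Ratings below 4 are negative, between 4 and 6 (inclusive) neutral,
    above 6 positive.
    """
    if not 1.0 <= mean_valence <= 9.0:
        raise ValueError(f"mean valence {mean_valence} outside [1, 9]")
    if mean_valence < 4.0:
        return "negative"
    if mean_valence <= 6.0:
        return "neutral"
    return "positive"


@dataclass
class Cohort:
    """One generated study: design tables plus raw data channels."""

    config: CohortConfig
    participants: pd.DataFrame
    stimuli: pd.DataFrame
    trials: pd.DataFrame
    aois: list[AoI]
    gaze: dict[str, pd.DataFrame] = field(default_factory=dict)
    eda: dict[str, pd.DataFrame] = field(default_factory=dict)
    rr: dict[str, pd.DataFrame] = field(default_factory=dict)
    ratings: pd.DataFrame | None = None
    #: planted per-trial SCR ground truth (for parameter-recovery checks)
    scr_truth: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# design tables


def _make_stimuli(rng: np.random.Generator, config: CohortConfig) -> pd.DataFrame:
    n_ids = len(config.block_durations_s) * len(config.categories)
    n_ids *= config.pictures_per_category_per_block
    numbers = rng.choice(np.arange(1, 400), size=n_ids, replace=False)
    rows = []
    k = 0
    for block in config.block_durations_s:
        for category in config.categories:
            lo_mean, sd, lo, hi = VALENCE_PROFILES[category]
            for _ in range(config.pictures_per_category_per_block):
                valence = float(np.clip(rng.normal(lo_mean, sd), lo, hi))
                assert classify_stimulus(valence) == category
                rows.append(
                    {
                        "stimulus_id": f"Faces_{numbers[k]:03d}",
                        "block": block,
                        "category": category,
                        "mean_valence": round(valence, 2),
                    }
                )
                k += 1
    return pd.DataFrame(rows)


def _make_aois(
    rng: np.random.Generator, stimuli: pd.DataFrame, config: CohortConfig
) -> list[AoI]:
    """1-2 disjoint experimental rectangles per stimulus (faces, dyads)."""
    W, H = config.screen.width_px, config.screen.height_px
    aois = []
    for stimulus_id in stimuli["stimulus_id"]:
        n_rects = int(rng.integers(1, 3))
        rects = []
        # place in separate horizontal halves so rectangles stay disjoint
        for j in range(n_rects):
            w = rng.uniform(0.12, 0.22) * W / n_rects
            h = rng.uniform(0.18, 0.30) * H
            lo_x = j * W / n_rects + 0.05 * W
            hi_x = (j + 1) * W / n_rects - 0.05 * W - w
            x0 = rng.uniform(lo_x, max(hi_x, lo_x + 1))
            y0 = rng.uniform(0.15 * H, 0.85 * H - h)
            rects.append(
                (round(x0), round(y0), round(x0 + w), round(y0 + h))
            )
        aois.append(
            AoI(
                id=f"{stimulus_id}_aoi",
                stimulus_id=stimulus_id,
                kind="experimental",
                rects=tuple(rects),
            )
        )
    return aois


def _make_participants(
    rng: np.random.Generator, config: CohortConfig
) -> pd.DataFrame:
    rows = []
    for g, group in enumerate(GROUPS):
        for i in range(config.n_per_group):
            pid = f"{group}{i + 1:02d}"
            row = {"participant_id": pid, "group": group, "eda_ok": True}
            for scale, (mb, sb, mh, sh, lo, hi) in QUESTIONNAIRE_PROFILES.items():
                mean, sd = (mb, sb) if group == "BPD" else (mh, sh)
                row[scale] = round(float(np.clip(rng.normal(mean, sd), lo, hi)), 2)
            rows.append(row)
    df = pd.DataFrame(rows)
    if config.n_missing_eda_bpd:
        bpd_ids = df.loc[df["group"] == "BPD", "participant_id"]
        drop = rng.choice(bpd_ids, size=config.n_missing_eda_bpd, replace=False)
        df.loc[df["participant_id"].isin(drop), "eda_ok"] = False
    return df


def _make_trials(
    rng: np.random.Generator,
    participants: pd.DataFrame,
    stimuli: pd.DataFrame,
    config: CohortConfig,
) -> pd.DataFrame:
    rows = []
    lo, hi = config.iti_range_s
    for _, p in participants.iterrows():
        order = rng.permutation(len(stimuli))
        t = config.baseline_s + 2.0
        for idx in order:
            stim = stimuli.iloc[idx]
            duration = config.block_durations_s[stim["block"]]
            iti = float(rng.uniform(lo, hi))
            rows.append(
                {
                    "participant_id": p["participant_id"],
                    "group": p["group"],
                    "stimulus_id": stim["stimulus_id"],
                    "block": stim["block"],
                    "category": stim["category"],
                    "onset_s": round(t, 3),
                    "duration_s": duration,
                    "iti_s": round(iti, 3),
                }
            )
            t += duration + iti
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# data channels


def _gaze_for_participant(
    rng: np.random.Generator,
    trials: pd.DataFrame,
    aoi_by_stim: dict[str, AoI],
    occupancy: float,
    config: CohortConfig,
) -> pd.DataFrame:
    dt = 1.0 / config.gaze_hz
    d_in = config.gaze_dwell_mean_s
    d_out = d_in * (1.0 - occupancy) / occupancy
    W, H = config.screen.width_px, config.screen.height_px
    jitter = config.gaze_jitter_px

    out_t, out_x, out_y, out_valid = [], [], [], []
    for trial in trials.itertuples():
        dur = trial.duration_s
        aoi = aoi_by_stim[trial.stimulus_id]
        # alternating off-AoI / in-AoI attractor dwells covering the trial
        n_seg = int(np.ceil(dur / min(d_in, d_out))) + 8
        dwells = np.empty(2 * n_seg)
        dwells[0::2] = rng.exponential(d_out, n_seg)  # even segments: off-AoI
        dwells[1::2] = rng.exponential(d_in, n_seg)
        dwells += 0.08  # refractory floor: no instantaneous shifts
        edges = np.cumsum(dwells)
        n_seg_used = int(np.searchsorted(edges, dur)) + 1

        # one attractor per segment
        ax = np.empty(n_seg_used)
        ay = np.empty(n_seg_used)
        bx0, by0, bx1, by1 = aoi.bounding_rect()
        for s in range(n_seg_used):
            if s % 2 == 1:  # in-AoI: uniform point inside a random rectangle
                r = aoi.rects[rng.integers(len(aoi.rects))]
                ax[s] = rng.uniform(r[0], r[2])
                ay[s] = rng.uniform(r[1], r[3])
            else:  # off-AoI: rejection-sample outside the bounding box
                for _ in range(20):
                    cx, cy = rng.uniform(0, W), rng.uniform(0, H)
                    if not (bx0 <= cx < bx1 and by0 <= cy < by1):
                        break
                ax[s], ay[s] = cx, cy
        ax[0], ay[0] = W / 2.0, H / 2.0  # trial starts on the fixation cross

        t_rel = np.arange(0.0, dur, dt)
        seg = np.searchsorted(edges, t_rel, side="right")
        x = ax[seg] + rng.normal(0.0, jitter, t_rel.size)
        y = ay[seg] + rng.normal(0.0, jitter, t_rel.size)
        np.clip(x, 0, W - 1, out=x)
        np.clip(y, 0, H - 1, out=y)
        valid = rng.random(t_rel.size) >= GAZE_INVALID_P
        out_t.append(trial.onset_s + t_rel)
        out_x.append(x)
        out_y.append(y)
        out_valid.append(valid)

    return pd.DataFrame(
        {
            "t_s": np.round(np.concatenate(out_t), 4),
            "x_px": np.round(np.concatenate(out_x), 2),
            "y_px": np.round(np.concatenate(out_y), 2),
            "valid": np.concatenate(out_valid).astype(int),
        }
    )


def _bateman_kernel(hz: float) -> np.ndarray:
    t = np.arange(0.0, 10.0, 1.0 / hz)
    k = np.exp(-t / BATEMAN_DECAY_S) - np.exp(-t / BATEMAN_RISE_S)
    return k / k.max()


def _eda_for_participant(
    rng: np.random.Generator,
    trials: pd.DataFrame,
    latency_mean_s: float,
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    from scipy.ndimage import gaussian_filter1d

    hz = config.eda_hz
    last = trials.iloc[-1]
    session_end = last["onset_s"] + last["duration_s"] + last["iti_s"] + 5.0
    n = int(session_end * hz)
    t = np.arange(n) / hz

    # slow tonic drift (~100 s correlation length), built on a coarse 0.5 Hz
    # grid and interpolated up for speed
    coarse_t = np.arange(0.0, session_end + 2.0, 2.0)
    coarse = gaussian_filter1d(
        rng.normal(0.0, 1.0, coarse_t.size), sigma=50.0, mode="nearest"
    )
    sd = coarse.std()
    drift = np.interp(t, coarse_t, coarse * (config.scl_drift / sd if sd > 0 else 0.0))
    tonic = config.scl_level + rng.normal(0.0, config.scl_between_sd) + drift

    kernel = _bateman_kernel(hz)
    phasic = np.zeros(n)
    lat_lo, lat_hi = LATENCY_CLIP_S
    p_lat_shift = rng.normal(0.0, config.scr_latency_between_sd_s)
    p_amp_factor = rng.lognormal(0.0, 0.3)  # participant reactivity trait

    truth_rows = []
    for trial in trials.itertuples():
        responded = rng.random() < config.scr_response_prob
        latency = float(
            np.clip(
                rng.normal(latency_mean_s + p_lat_shift, config.scr_latency_sd_s),
                lat_lo,
                lat_hi,
            )
        )
        amplitude = p_amp_factor * float(
            rng.lognormal(SCR_AMPLITUDE_LOGMEAN, SCR_AMPLITUDE_LOGSD)
        )
        if responded:
            i0 = int(round((trial.onset_s + latency) * hz))
            seg = min(kernel.size, n - i0)
            if seg > 0:
                phasic[i0 : i0 + seg] += amplitude * kernel[:seg]
        truth_rows.append(
            {
                "participant_id": trial.participant_id,
                "stimulus_id": trial.stimulus_id,
                "responded": responded,
                "latency_s": latency if responded else np.nan,
                "amplitude": amplitude if responded else 0.0,
            }
        )

    # spontaneous fluctuations, kept clear of the stimulus response windows
    windows = [(tr.onset_s, tr.onset_s + 5.0) for tr in trials.itertuples()]
    n_spont = rng.poisson(SPONTANEOUS_SCR_RATE_HZ * session_end)
    for _ in range(n_spont):
        for _ in range(20):
            t0 = rng.uniform(0.0, session_end - 10.0)
            if not any(lo - 10.0 <= t0 <= hi for lo, hi in windows):
                break
        else:
            continue
        amp = float(rng.lognormal(SCR_AMPLITUDE_LOGMEAN - 1.0, 0.5))
        i0 = int(t0 * hz)
        seg = min(kernel.size, n - i0)
        phasic[i0 : i0 + seg] += amp * kernel[:seg]

    trace = tonic + phasic + rng.normal(0.0, EDA_NOISE_SD, n)
    eda = pd.DataFrame({"t_s": np.round(t, 4), "eda": np.round(trace, 4)})
    return eda, pd.DataFrame(truth_rows)


def _rr_for_participant(
    rng: np.random.Generator,
    trials: pd.DataFrame,
    group: str,
    config: CohortConfig,
) -> pd.DataFrame:
    """Beat-to-beat intervals with segment-wise RMSSD control.

    Intervals within a segment are independent normals around the
    participant mean, so the expected RMSSD equals the segment's
    successive-difference SD target.
    """
    effects = config.effects.resolved()
    mu = max(400.0, rng.normal(config.mean_rr_ms, config.rr_between_sd_ms))
    last = trials.iloc[-1]
    session_end = last["onset_s"] + last["duration_s"] + last["iti_s"] + 5.0

    # participant traits: resting RMSSD and own crossover magnitude
    base = max(8.0, rng.normal(config.rmssd_base_ms, config.rmssd_between_sd_ms))
    crossover = rng.normal(
        effects.rmssd_block_crossover, config.rmssd_crossover_between_sd_ms
    )

    # time-ordered segments: (end_time, rmssd target)
    segments: list[tuple[float, float]] = []
    for trial in trials.itertuples():
        segments.append((trial.onset_s, base))  # preceding dead time
        sign = 1.0 if trial.block == "long" else -1.0
        if group == "BPD":
            sign = -sign
        target = max(5.0, base + sign * crossover / 2.0)
        segments.append((trial.onset_s + trial.duration_s, target))
    segments.append((session_end, base))

    times, intervals = [], []
    t_cur = 0.0
    for end, target in segments:
        if end <= t_cur:
            continue
        sigma = target / np.sqrt(2.0)
        n = int(np.ceil((end - t_cur) * 1000.0 / mu)) + 3
        ivals = np.maximum(250.0, rng.normal(mu, sigma, n))
        beats = t_cur + np.cumsum(ivals) / 1000.0
        keep = beats <= end
        times.append(beats[keep])
        intervals.append(ivals[keep])
        if keep.any():
            t_cur = float(beats[keep][-1])
    return pd.DataFrame(
        {
            "t_s": np.round(np.concatenate(times), 4),
            "rr_ms": np.round(np.concatenate(intervals), 2),
        }
    )


def _ratings_for_participant(
    rng: np.random.Generator,
    trials: pd.DataFrame,
    group: str,
    config: CohortConfig,
) -> pd.DataFrame:
    effects = config.effects.resolved()
    intercepts = {
        dim: rng.normal(0.0, RATING_PARTICIPANT_SD) for dim in RATING_MEANS
    }
    rows = []
    for trial in trials.itertuples():
        row = {
            "participant_id": trial.participant_id,
            "stimulus_id": trial.stimulus_id,
        }
        for dim, means in RATING_MEANS.items():
            val = means[trial.category] + intercepts[dim]
            if dim == "valence":
                sign = -1.0 if trial.block == "long" else 1.0
                if group == "HC":
                    sign = -sign
                val += sign * effects.valence_block_crossover / 2.0
            val += rng.normal(0.0, RATING_TRIAL_SD)
            row[dim] = round(float(np.clip(val, 0.0, 1.0)), 4)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# top level


ALL_CHANNELS = frozenset({"gaze", "eda", "rr", "ratings"})


def generate_cohort(
    seed: int,
    config: CohortConfig | None = None,
    channels: frozenset[str] = ALL_CHANNELS,
) -> Cohort:
    """Generate a full synthetic study, deterministically for a fixed seed.

    ``channels`` restricts which raw data streams are materialized (design
    tables are always built); a channel's data is identical whether or not
    the other channels are generated.
    """
    config = config or CohortConfig()
    if unknown := set(channels) - ALL_CHANNELS:
        raise ConfigError(f"unknown channels {sorted(unknown)}")
    effects = config.effects.resolved()

    ss = np.random.SeedSequence(seed)
    (
        ss_stim,
        ss_part,
        ss_sched,
        ss_aoi,
        ss_gaze,
        ss_eda,
        ss_rr,
        ss_rate,
    ) = ss.spawn(8)

    stimuli = _make_stimuli(np.random.default_rng(ss_stim), config)
    participants = _make_participants(np.random.default_rng(ss_part), config)
    trials = _make_trials(
        np.random.default_rng(ss_sched), participants, stimuli, config
    )
    aois = _make_aois(np.random.default_rng(ss_aoi), stimuli, config)
    aoi_by_stim = {a.stimulus_id: a for a in aois}

    cohort = Cohort(
        config=config,
        participants=participants,
        stimuli=stimuli,
        trials=trials,
        aois=aois,
    )

    pids = participants["participant_id"].tolist()
    gaze_ss = ss_gaze.spawn(len(pids))
    eda_ss = ss_eda.spawn(len(pids))
    rr_ss = ss_rr.spawn(len(pids))
    rate_ss = ss_rate.spawn(len(pids))

    truth_frames = []
    for i, (pid, prow) in enumerate(
        zip(pids, participants.itertuples(), strict=True)
    ):
        ptrials = trials[trials["participant_id"] == pid].reset_index(drop=True)
        group = prow.group
        if "gaze" in channels:
            g_rng = np.random.default_rng(gaze_ss[i])
            occupancy = config.gaze_base_occupancy * g_rng.lognormal(
                0.0, config.gaze_occupancy_log_sd
            )
            if group == "BPD":
                occupancy *= effects.aoi_dwell_ratio
            occupancy = float(np.clip(occupancy, 0.05, 0.9))
            cohort.gaze[pid] = _gaze_for_participant(
                g_rng,
                ptrials,
                aoi_by_stim,
                occupancy,
                config,
            )
        if "eda" in channels and prow.eda_ok:
            latency_mean = config.scr_latency_mean_s
            if group == "BPD":
                latency_mean -= effects.latency_shift
            cohort.eda[pid], truth = _eda_for_participant(
                np.random.default_rng(eda_ss[i]), ptrials, latency_mean, config
            )
            truth_frames.append(truth)
        if "rr" in channels:
            cohort.rr[pid] = _rr_for_participant(
                np.random.default_rng(rr_ss[i]), ptrials, group, config
            )
        if "ratings" in channels:
            frame = _ratings_for_participant(
                np.random.default_rng(rate_ss[i]), ptrials, group, config
            )
            cohort.ratings = (
                frame
                if cohort.ratings is None
                else pd.concat([cohort.ratings, frame], ignore_index=True)
            )
    if truth_frames:
        cohort.scr_truth = pd.concat(truth_frames, ignore_index=True)
    return cohort


# ---------------------------------------------------------------------------
# on-disk layout


def write_cohort(cohort: Cohort, outdir: str) -> None:
    """Write the cohort in the pipeline's plain-CSV/JSON layout."""
    import os

    from . import aoi as aoi_mod
    from .config import StudyConfig, save_config

    os.makedirs(outdir, exist_ok=True)
    cohort.participants.to_csv(os.path.join(outdir, "participants.csv"), index=False)
    cohort.stimuli.to_csv(os.path.join(outdir, "stimuli.csv"), index=False)
    cohort.trials.to_csv(os.path.join(outdir, "trials.csv"), index=False)
    aoi_mod.save_aois(cohort.aois, os.path.join(outdir, "aoi.json"))
    save_config(StudyConfig(cohort=cohort.config), os.path.join(outdir, "config.yaml"))
    if cohort.ratings is not None:
        cohort.ratings.to_csv(os.path.join(outdir, "ratings.csv"), index=False)
    for pid, frame in cohort.gaze.items():
        frame.to_csv(os.path.join(outdir, f"gaze_{pid}.csv"), index=False)
    for pid, frame in cohort.eda.items():
        frame.to_csv(os.path.join(outdir, f"eda_{pid}.csv"), index=False)
    for pid, frame in cohort.rr.items():
        frame.to_csv(os.path.join(outdir, f"rr_{pid}.csv"), index=False)


def read_cohort(outdir: str) -> Cohort:
    import glob
    import os

    from . import aoi as aoi_mod
    from .config import load_config

    config = load_config(os.path.join(outdir, "config.yaml")).cohort
    cohort = Cohort(
        config=config,
        participants=pd.read_csv(os.path.join(outdir, "participants.csv")),
        stimuli=pd.read_csv(os.path.join(outdir, "stimuli.csv")),
        trials=pd.read_csv(os.path.join(outdir, "trials.csv")),
        aois=aoi_mod.load_aois(os.path.join(outdir, "aoi.json")),
    )
    ratings_path = os.path.join(outdir, "ratings.csv")
    if os.path.exists(ratings_path):
        cohort.ratings = pd.read_csv(ratings_path)
    for prefix, store in (("gaze", cohort.gaze), ("eda", cohort.eda), ("rr", cohort.rr)):
        for path in sorted(glob.glob(os.path.join(outdir, f"{prefix}_*.csv"))):
            pid = os.path.basename(path)[len(prefix) + 1 : -4]
            store[pid] = pd.read_csv(path)
    return cohort
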