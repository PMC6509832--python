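"""Study configuration objects with YAML round-trip.

The configuration is split along the pipeline's stages: :class:`CohortConfig`
describes the synthetic study design (participants, stimulus set, trial
timing, recording rates and the planted group effects), while
:class:`StudyConfig` adds the analysis-side parameters (fixation detection,
AoI derivation, SCR extraction, post-hoc plan).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised for internally inconsistent configurations."""


@dataclass(frozen=True)
class ScreenGeometry:
    """Display raster in pixels, origin top-left, 0-based."""

    width_px: int = 1920
    height_px: int = 1080

    @property
    def area_px(self) -> int:
        return self.width_px * self.height_px


@dataclass(frozen=True)
class EffectSpec:
    """Planted group effects of the synthetic cohort.

    Defaults are calibrated to the between-group cell-mean differences the
    pipeline is meant to be able to resolve: a 0.13 s earlier electrodermal
    response onset in the clinical group, a 20% reduction of its in-AoI
    dwell occupancy, and opposite-signed long-vs-short block shifts of
    0.03 slider units (valence) and 5.5 ms (RMSSD) in the two groups.

    ``null_mode=True`` zeroes every planted effect; the generator is then a
    pure noise model used for type-I-error calibration.
    """

    latency_shift: float = 0.13      # s subtracted from BPD SCR latency
    aoi_dwell_ratio: float = 0.8     # multiplies BPD in-AoI dwell occupancy
    valence_block_crossover: float = 0.03   # slider units, sign flips by group
    rmssd_block_crossover: float = 5.5      # ms, sign flips by group
    null_mode: bool = False

    def resolved(self) -> "EffectSpec":
        """Return a copy with all effects forced to zero under null_mode."""
        if not self.null_mode:
            return self
        return EffectSpec(
            latency_shift=0.0,
            aoi_dwell_ratio=1.0,
            valence_block_crossover=0.0,
            rmssd_block_crossover=0.0,
            null_mode=True,
        )


@dataclass(frozen=True)
class CohortConfig:
    """Design of one synthetic cohort.

    The default values reproduce the study design the pipeline targets:
    14 participants per group, 48 affective pictures (2 blocks of 24; 3
    valence categories x 8 pictures per block), 5 s / 15 s presentation,
    10-15 s inter-trial intervals and a 120 s pre-task physiological
    baseline. Recording rates are configurable because consumer-grade
    eye trackers vary; 30 Hz is the class of hardware emulated.
    """

    n_per_group: int = 14
    pictures_per_category_per_block: int = 8
    categories: tuple[str, ...] = ("negative", "neutral", "positive")
    block_durations_s: dict[str, float] = field(
        default_factory=lambda: {"short": 5.0, "long": 15.0}
    )
    iti_range_s: tuple[float, float] = (10.0, 15.0)
    baseline_s: float = 120.0
    gaze_hz: float = 30.0
    eda_hz: float = 32.0
    screen: ScreenGeometry = field(default_factory=ScreenGeometry)
    effects: EffectSpec = field(default_factory=EffectSpec)
    #: BPD participants whose EDA channel is marked unusable (emulates
    #: recording failures; they stay in all non-EDA analyses).
    n_missing_eda_bpd: int = 0

    # --- noise-model parameters (see docs/methods.md) ---
    #: stationary in-AoI occupancy of the gaze dwell process, control group
    gaze_base_occupancy: float = 0.55
    #: between-participant log-scale SD of the occupancy (trait-like
    #: differences in preference for socio-emotional content)
    gaze_occupancy_log_sd: float = 0.2
    #: mean dwell per attractor visit, s (sets fixation durations)
    gaze_dwell_mean_s: float = 0.45
    #: isotropic gaze jitter around the current attractor, px
    gaze_jitter_px: float = 18.0
    #: control-group mean SCR onset latency, s; trial-level SD; and the
    #: between-participant SD of the latency trait
    scr_latency_mean_s: float = 1.68
    scr_latency_sd_s: float = 0.25
    scr_latency_between_sd_s: float = 0.12
    #: probability a trial elicits a measurable SCR
    scr_response_prob: float = 0.9
    #: tonic skin-conductance level (instrument units), between-participant
    #: SD, and the SD of the slow within-session drift (drift is kept far
    #: slower than phasic rises so onset detection stays meaningful)
    scl_level: float = 810.0
    scl_between_sd: float = 100.0
    scl_drift: float = 0.5
    #: mean NN interval, ms (~77 bpm), between-participant SD
    mean_rr_ms: float = 780.0
    rr_between_sd_ms: float = 100.0
    #: target RMSSD common to both groups before the block crossover, ms,
    #: its between-participant SD, and the between-participant SD of each
    #: participant's own block-crossover magnitude
    rmssd_base_ms: float = 38.0
    rmssd_between_sd_ms: float = 13.0
    rmssd_crossover_between_sd_ms: float = 4.0

    def __post_init__(self) -> None:
        if self.n_per_group < 3:
            raise ConfigError("n_per_group must be >= 3")
        if min(self.block_durations_s.values()) < 5.0:
            raise ConfigError(
                "trial duration shorter than the 5 s SCR response window"
            )
        if self.iti_range_s[0] > self.iti_range_s[1]:
            raise ConfigError("iti_range_s must be (lo, hi) with lo <= hi")
        if self.eda_hz <= 4.0:
            raise ConfigError("eda_hz must exceed twice the 2 Hz low-pass cutoff")

    @property
    def n_trials(self) -> int:
        return (
            len(self.block_durations_s)
            * len(self.categories)
            * self.pictures_per_category_per_block
        )

    @staticmethod
    def calibration_profile(**overrides: Any) -> "CohortConfig":
        """A scaled-down design for replicate simulations.

        Keeps the group sizes (the quantity the inference is calibrated
        for) but trims trial counts, recording rates and dead time so a
        full generate-extract-test cycle runs in well under a second.
        """
        params: dict[str, Any] = dict(
            pictures_per_category_per_block=2,
            iti_range_s=(2.0, 4.0),
            baseline_s=60.0,
            gaze_hz=15.0,
            eda_hz=16.0,
        )
        params.update(overrides)
        return CohortConfig(**params)


@dataclass(frozen=True)
class FixationParams:
    """I-DT dispersion-based fixation detection parameters."""

    dispersion_px: float = 60.0
    min_duration_s: float = 0.1


@dataclass(frozen=True)
class AoiParams:
    """Pilot-AoI derivation from pooled gaze density."""

    sigma_px: float = 50.0       # Gaussian kernel SD, px
    threshold_frac: float = 0.2  # cells >= frac * peak density are kept
    grid_step: int = 4           # density-grid cell size, px


@dataclass(frozen=True)
class ScrParams:
    """Trough-to-peak SCR extraction."""

    window_s: float = 5.0
    onset_threshold: float = 0.01  # minimum trough-to-peak rise (signal units)
    lowpass_hz: float = 2.0


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to run one synthetic study end to end."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    fixation: FixationParams = field(default_factory=FixationParams)
    aoi: AoiParams = field(default_factory=AoiParams)
    scr: ScrParams = field(default_factory=ScrParams)
    #: count gaze samples ("samples") or detected fixations ("fixations")
    #: when forming prop-gaze numerators
    prop_gaze_mode: str = "samples"
    #: use corrected (area/distance-normalized) indexes in group contrasts
    use_corrected: bool = True
    #: smoothness-priors RR detrending before RMSSD (lambda), None disables
    rr_detrend_lambda: float | None = None
    #: post-hoc family sizes for the Bonferroni thresholds
    m_category: int = 3
    m_block: int = 2
    alpha: float = 0.05
    n_mc: int = 10000

    def __post_init__(self) -> None:
        if self.prop_gaze_mode not in ("samples", "fixations"):
            raise ConfigError("prop_gaze_mode must be 'samples' or 'fixations'")


# ---------------------------------------------------------------------------
# YAML round-trip


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _to_plain(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def _build(cls: type, data: dict[str, Any]) -> Any:
    kwargs: dict[str, Any] = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        val = data[f.name]
        if f.name == "screen":
            val = ScreenGeometry(**val)
        elif f.name == "effects":
            val = EffectSpec(**val)
        elif f.name == "cohort":
            val = _build(CohortConfig, val)
        elif f.name == "fixation":
            val = FixationParams(**val)
        elif f.name == "aoi":
            val = AoiParams(**val)
        elif f.name == "scr":
            val = ScrParams(**val)
        elif f.name in ("iti_range_s", "categories"):
            val = tuple(val)
        kwargs[f.name] = val
    return cls(**kwargs)


def save_config(config: StudyConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=False)


def load_config(path: str) -> StudyConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return _build(StudyConfig, data)
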