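"""End-to-end study pipeline: generate -> extract -> test -> report.

The analysis plan mirrors a two-group affective-picture study: for every
outcome (three self-report sliders, five physiological indexes, four
visual indexes per AoI family) an ART factorial ANOVA tests the group
main effect and the group-by-category and group-by-block interactions;
significant effects are followed by Mann-Whitney post-hocs with
Bonferroni-corrected thresholds (three category contrasts, two-block
trend contrast); pilot-minus-experimental delta scores and baseline
physiology get direct group contrasts; and a Spearman screen checks
cross-modality coherence within each group.

Trial-level outcomes are aggregated to participant x cell means before
testing, so the inference is at the participant level throughout.
Participants lacking an EDA recording are excluded from electrodermal
analyses only.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .aoi import AoI, derive_pilot_aoi
from .cohort import Cohort, generate_cohort
from .config import CohortConfig, EffectSpec, StudyConfig
from .gaze import INDEX_NAMES, compute_gaze_tables
from .physio import compute_physio_table
from .stats import DesignError, art_anova, bonferroni, mann_whitney, spearman

log = logging.getLogger(__name__)

GAZE_OUTCOMES = {
    "experimental": "aois",
    "pilot": "aoip",
}
PHYSIO_OUTCOMES = ("scr", "scl", "latency_s", "hr_bpm", "rmssd_ms")
RATING_OUTCOMES = ("valence", "arousal", "dominance")
QUESTIONNAIRES = (
    "ders_total",
    "pid5_negative_affectivity",
    "panas_pa_pre",
    "panas_na_pre",
)
BASELINE_OUTCOMES = ("scr", "scl", "hr_bpm", "rmssd_ms")

#: outcomes used by the replicate calibration runs (one per modality
#: family, spanning all three data channels)
CALIBRATION_OUTCOMES = (
    "valence",
    "latency_s",
    "rmssd_ms",
    "prop_gaze_aois",
    "fix1_duration_aois",
)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class Features:
    """Extracted per-trial feature tables, long format."""

    gaze_indexes: pd.DataFrame
    gaze_deltas: pd.DataFrame
    physio: pd.DataFrame
    ratings: pd.DataFrame
    pilot_aois: dict[str, AoI]


@dataclass
class ReportBundle:
    """All statistics of one study run, traceable to the feature tables."""

    descriptives: pd.DataFrame
    effects: pd.DataFrame
    contrasts: pd.DataFrame
    correlations: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def save(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.descriptives.to_csv(os.path.join(outdir, "descriptives.csv"), index=False)
        self.effects.to_csv(os.path.join(outdir, "effects.csv"), index=False)
        self.contrasts.to_csv(os.path.join(outdir, "contrasts.csv"), index=False)
        self.correlations.to_csv(
            os.path.join(outdir, "correlations.csv"), index=False
        )
        with open(os.path.join(outdir, "run.json"), "w") as fh:
            json.dump(self.meta, fh, indent=1)
        with open(os.path.join(outdir, "report.md"), "w") as fh:
            fh.write(self.to_markdown())

    def to_markdown(self) -> str:
        def table(df: pd.DataFrame) -> str:
            return df.round(2).to_markdown(index=False)

        sig = self.effects[self.effects["p"] < self.meta.get("alpha", 0.05)]
        parts = [
            "# Study report",
            f"seed: {self.meta.get('seed')}  |  emotrace {self.meta.get('version')}",
            "## Factorial effects (significant)",
            table(sig) if len(sig) else "_none_",
            "## Group contrasts",
            table(self.contrasts),
            "## Cross-modality Spearman screen (significant)",
        ]
        sig_rho = self.correlations[self.correlations["p"] < 0.05]
        parts.append(table(sig_rho) if len(sig_rho) else "_none_")
        return "\n\n".join(parts) + "\n"


# ---------------------------------------------------------------------------
# extraction


def derive_pilot_aois(cohort: Cohort, config: StudyConfig) -> dict[str, AoI]:
    """Pilot AoI per stimulus from the cohort's pooled gaze samples."""
    pools_x: dict[str, list[np.ndarray]] = {}
    pools_y: dict[str, list[np.ndarray]] = {}
    for pid, stream in cohort.gaze.items():
        t = stream["t_s"].to_numpy()
        x = stream["x_px"].to_numpy()
        y = stream["y_px"].to_numpy()
        valid = stream["valid"].to_numpy().astype(bool)
        ptrials = cohort.trials[cohort.trials["participant_id"] == pid]
        for trial in ptrials.itertuples():
            lo = np.searchsorted(t, trial.onset_s)
            hi = np.searchsorted(t, trial.onset_s + trial.duration_s)
            ok = valid[lo:hi]
            pools_x.setdefault(trial.stimulus_id, []).append(x[lo:hi][ok])
            pools_y.setdefault(trial.stimulus_id, []).append(y[lo:hi][ok])
    out = {}
    for aoi in cohort.aois:
        stim = aoi.stimulus_id
        out[stim] = derive_pilot_aoi(
            np.concatenate(pools_x.get(stim, [np.empty(0)])),
            np.concatenate(pools_y.get(stim, [np.empty(0)])),
            aoi,
            cohort.config.screen,
            sigma_px=config.aoi.sigma_px,
            threshold_frac=config.aoi.threshold_frac,
            grid_step=config.aoi.grid_step,
        )
    return out


def extract_features(cohort: Cohort, config: StudyConfig) -> Features:
    """Run the feature-extraction stages on a generated or loaded cohort."""
    try:
        pilot = derive_pilot_aois(cohort, config) if cohort.gaze else {}
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError(f"pilot-AoI derivation failed: {exc}") from exc

    aois_by_kind: dict[str, dict[str, list[AoI]]] = {
        "experimental": {a.stimulus_id: [a] for a in cohort.aois}
    }
    if pilot:
        aois_by_kind["pilot"] = {s: [a] for s, a in pilot.items()}

    try:
        gaze_indexes, gaze_deltas = compute_gaze_tables(
            cohort.trials,
            cohort.gaze,
            aois_by_kind,
            cohort.config.screen,
            config.fixation,
            config.prop_gaze_mode,
        )
    except Exception as exc:
        raise StageError(f"gaze-index extraction failed: {exc}") from exc

    try:
        physio = compute_physio_table(
            cohort.trials,
            cohort.eda,
            cohort.rr,
            cohort.config.eda_hz,
            cohort.config.baseline_s,
            config.scr.window_s,
            config.scr.onset_threshold,
            config.scr.lowpass_hz,
            config.rr_detrend_lambda,
        )
    except Exception as exc:
        raise StageError(f"physiological extraction failed: {exc}") from exc

    if cohort.ratings is not None:
        ratings = cohort.ratings.merge(
            cohort.trials[
                ["participant_id", "stimulus_id", "group", "block", "category"]
            ],
            on=["participant_id", "stimulus_id"],
        )
    else:
        ratings = pd.DataFrame(
            columns=["participant_id", "stimulus_id", "group", "block", "category"]
        )
    return Features(gaze_indexes, gaze_deltas, physio, ratings, pilot)


# ---------------------------------------------------------------------------
# outcome tables


def _outcome_frames(features: Features, config: StudyConfig) -> dict[str, pd.DataFrame]:
    """Map outcome name -> long trial table with a ``value`` column."""
    frames: dict[str, pd.DataFrame] = {}
    for outcome in RATING_OUTCOMES:
        if outcome in features.ratings:
            frames[outcome] = features.ratings.rename(columns={outcome: "value"})[
                ["participant_id", "group", "block", "category", "value"]
            ]
    for kind, suffix in GAZE_OUTCOMES.items():
        sub = features.gaze_indexes
        if len(sub) == 0:
            continue
        sub = sub[sub["aoi_kind"] == kind]
        if len(sub) == 0:
            continue
        for name in INDEX_NAMES:
            col = name if config.use_corrected else f"raw_{name}"
            frames[f"{name}_{suffix}"] = sub.rename(columns={col: "value"})[
                ["participant_id", "group", "block", "category", "value"]
            ]
    physio_trials = features.physio[features.physio["segment"] != "baseline"]
    for outcome in PHYSIO_OUTCOMES:
        if len(physio_trials) == 0:
            continue
        frames[outcome] = physio_trials.rename(columns={outcome: "value"})[
            ["participant_id", "group", "block", "category", "value"]
        ].dropna(subset=["value"])
    for name in INDEX_NAMES:
        deltas = features.gaze_deltas
        if len(deltas) == 0:
            continue
        frames[f"delta_{name}"] = deltas.rename(
            columns={f"delta_{name}": "value"}
        )[["participant_id", "group", "block", "category", "value"]]
    return {name: frame for name, frame in frames.items() if len(frame)}


def participant_cell_means(
    frame: pd.DataFrame, within: str | None
) -> pd.DataFrame:
    """Trial -> participant(-by-cell) means; drops incomplete participants.

    Cell means use the trials available to each participant; a participant
    missing an entire cell (e.g. no measurable SCR in any trial of a cell)
    is excluded from this outcome's factorial test and logged.
    """
    keys = ["participant_id", "group"] + ([within] if within else [])
    agg = frame.groupby(keys, observed=True)["value"].mean().reset_index()
    if within:
        n_levels = frame[within].nunique()
        counts = agg.groupby("participant_id", observed=True).size()
        incomplete = counts[counts < n_levels].index
        if len(incomplete):
            log.info(
                "dropping %d participant(s) with empty %s cells",
                len(incomplete),
                within,
            )
            agg = agg[~agg["participant_id"].isin(incomplete)]
    return agg


# ---------------------------------------------------------------------------
# inference


def _effects_for_outcome(
    outcome: str, frame: pd.DataFrame
) -> tuple[list[dict], dict[str, float]]:
    """ART effects: group and group:category from the category model,
    group:block from the block model."""
    rows: list[dict] = []
    pvals: dict[str, float] = {}
    by_cat = participant_cell_means(frame, "category")
    by_block = participant_cell_means(frame, "block")
    plans = [
        (by_cat, "category", ["group", "group:category"]),
        (by_block, "block", ["group:block"]),
    ]
    for table, within, effects in plans:
        try:
            results = art_anova(
                table, "value", "group", within, "participant_id", effects
            )
        except DesignError as exc:
            log.warning("ART on %s (%s) skipped: %s", outcome, within, exc)
            continue
        for res in results:
            rows.append(
                {
                    "outcome": outcome,
                    "effect": res.effect.replace("participant_id", ""),
                    "F": res.F,
                    "df1": res.df1,
                    "df2": res.df2,
                    "p": res.p,
                    "partial_eta2": res.partial_eta2,
                }
            )
            pvals[res.effect] = res.p
    return rows, pvals


def _contrast_row(
    outcome: str,
    label: str,
    x: np.ndarray,
    y: np.ndarray,
    m: int,
    alpha: float,
    n_mc: int,
    rng: np.random.Generator,
) -> dict:
    comp = mann_whitney(x, y, n_mc=n_mc, seed=rng)
    threshold = bonferroni(alpha, m)
    return {
        "outcome": outcome,
        "contrast": label,
        "n1": int(np.sum(~np.isnan(np.asarray(x, float)))),
        "n2": int(np.sum(~np.isnan(np.asarray(y, float)))),
        "U": comp.u,
        "Z": comp.z,
        "p_exact": comp.p_exact,
        "p_mc": comp.p_mc,
        "mc_ci_lo": comp.mc_ci99[0],
        "mc_ci_hi": comp.mc_ci99[1],
        "r": comp.r,
        "m": m,
        "threshold": threshold,
        "significant": comp.p < threshold,
    }


def _group_values(
    table: pd.DataFrame, value: str = "value"
) -> tuple[np.ndarray, np.ndarray]:
    x = table.loc[table["group"] == "BPD", value].to_numpy(dtype=float)
    y = table.loc[table["group"] == "HC", value].to_numpy(dtype=float)
    return x, y


def compare_baseline(
    physio: pd.DataFrame,
    alpha: float = 0.05,
    n_mc: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Group contrasts on the pre-task baseline physiology (4 indexes)."""
    rng = np.random.default_rng(rng)
    base = physio[physio["segment"] == "baseline"]
    rows = []
    for outcome in BASELINE_OUTCOMES:
        sub = base.dropna(subset=[outcome])
        missing = len(base) - len(sub)
        if missing:
            log.info("baseline %s: %d participant(s) without data", outcome, missing)
        x, y = _group_values(sub, outcome)
        if x.size == 0 or y.size == 0:
            log.warning("baseline %s skipped: a group has no data", outcome)
            continue
        rows.append(
            _contrast_row(outcome, "baseline", x, y, 1, alpha, n_mc, rng)
        )
    return pd.DataFrame(rows)


def _descriptives(frames: dict[str, pd.DataFrame]) -> pd.DataFrame:
    rows = []
    for outcome, frame in frames.items():
        cells = participant_cell_means(
            frame.assign(cell=frame["block"] + "/" + frame["category"]), "cell"
        )
        cells[["block", "category"]] = cells["cell"].str.split("/", expand=True)
        stats_tbl = (
            cells.groupby(["group", "block", "category"], observed=True)["value"]
            .agg(["mean", "std", "median"])
            .reset_index()
        )
        stats_tbl.insert(0, "outcome", outcome)
        rows.append(stats_tbl)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()


def analyze(
    features: Features,
    participants: pd.DataFrame,
    config: StudyConfig,
    seed: int,
) -> ReportBundle:
    """Inference stage: factorial effects, post-hocs, deltas, baseline,
    questionnaires and the cross-modality Spearman screen."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    alpha, n_mc = config.alpha, config.n_mc
    frames = _outcome_frames(features, config)

    effect_rows: list[dict] = []
    contrast_rows: list[dict] = []
    delta_outcomes = {k for k in frames if k.startswith("delta_")}

    for outcome, frame in frames.items():
        if outcome in delta_outcomes:
            continue
        rows, pvals = _effects_for_outcome(outcome, frame)
        effect_rows.extend(rows)
        # post-hoc families within significant effects
        if min(pvals.get("group", 1.0), pvals.get("group:category", 1.0)) < alpha:
            by_cat = participant_cell_means(frame, "category")
            for category in sorted(frame["category"].unique()):
                sub = by_cat[by_cat["category"] == category]
                x, y = _group_values(sub)
                contrast_rows.append(
                    _contrast_row(
                        outcome, f"category:{category}", x, y,
                        config.m_category, alpha, n_mc, rng,
                    )
                )
        if pvals.get("group:block", 1.0) < alpha:
            by_block = participant_cell_means(frame, "block")
            wide = by_block.pivot_table(
                index=["participant_id", "group"], columns="block", values="value"
            ).reset_index()
            if {"long", "short"} <= set(wide.columns):
                wide["trend"] = wide["long"] - wide["short"]
                x, y = _group_values(wide, "trend")
                contrast_rows.append(
                    _contrast_row(
                        outcome, "block_trend:long-short", x, y,
                        config.m_block, alpha, n_mc, rng,
                    )
                )

    # delta scores: direct group contrasts on participant means
    for outcome in sorted(delta_outcomes):
        means = participant_cell_means(frames[outcome], None)
        x, y = _group_values(means)
        contrast_rows.append(
            _contrast_row(outcome, "delta", x, y, 1, alpha, n_mc, rng)
        )

    # questionnaire contrasts
    for scale in QUESTIONNAIRES:
        if scale not in participants:
            continue
        x, y = _group_values(participants, scale)
        contrast_rows.append(
            _contrast_row(scale, "questionnaire", x, y, 1, alpha, n_mc, rng)
        )

    baseline = compare_baseline(features.physio, alpha, n_mc, rng)
    contrast_rows.extend(baseline.to_dict("records"))

    correlations = _spearman_screen(frames)

    return ReportBundle(
        descriptives=_descriptives(frames),
        effects=pd.DataFrame(effect_rows),
        contrasts=pd.DataFrame(contrast_rows),
        correlations=correlations,
        meta={"seed": seed, "version": __version__, "alpha": alpha},
    )


MODALITY = {
    **{o: "self-report" for o in RATING_OUTCOMES},
    **{o: "physiology" for o in PHYSIO_OUTCOMES},
}


def _spearman_screen(frames: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Within-group Spearman correlations across response modalities."""
    screen_outcomes = [
        o
        for o in frames
        if not o.startswith("delta_") and not o.endswith("_aoip")
    ]
    means = {}
    for o in screen_outcomes:
        m = participant_cell_means(frames[o], None).set_index("participant_id")
        means[o] = m
    rows = []
    for i, a in enumerate(screen_outcomes):
        for b_name in screen_outcomes[i + 1 :]:
            mod_a = MODALITY.get(a, "eye-tracking")
            mod_b = MODALITY.get(b_name, "eye-tracking")
            if mod_a == mod_b:
                continue
            joined = means[a][["group", "value"]].join(
                means[b_name]["value"], rsuffix="_b", how="inner"
            )
            for group, sub in joined.groupby("group"):
                if len(sub) < 3:
                    continue
                rho, p = spearman(
                    sub["value"].to_numpy(), sub["value_b"].to_numpy()
                )
                rows.append(
                    {
                        "group": group,
                        "outcome_a": a,
                        "outcome_b": b_name,
                        "n": len(sub),
                        "rho": rho,
                        "p": p,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# top-level runs


def run_study(
    seed: int, config: StudyConfig | None = None, outdir: str | None = None
) -> ReportBundle:
    """Generate a synthetic cohort, extract features and run the analysis.

    With ``outdir`` the raw cohort, feature tables and report are written
    beneath it (``cohort/``, ``features/``, ``report/``).
    """
    config = config or StudyConfig()
    cohort = generate_cohort(seed, config.cohort)
    features = extract_features(cohort, config)
    bundle = analyze(features, cohort.participants, config, seed)
    if outdir is not None:
        from .cohort import write_cohort

        write_cohort(cohort, os.path.join(outdir, "cohort"))
        fdir = os.path.join(outdir, "features")
        os.makedirs(fdir, exist_ok=True)
        features.gaze_indexes.to_csv(
            os.path.join(fdir, "gaze_indexes.csv"), index=False
        )
        features.gaze_deltas.to_csv(
            os.path.join(fdir, "gaze_deltas.csv"), index=False
        )
        features.physio.to_csv(os.path.join(fdir, "physio_indexes.csv"), index=False)
        bundle.save(os.path.join(outdir, "report"))
    return bundle


def calibration_config(null: bool = True, **effect_overrides) -> StudyConfig:
    """Scaled-down study used for replicate simulations."""
    effects = EffectSpec(null_mode=True) if null else EffectSpec(**effect_overrides)
    return StudyConfig(
        cohort=CohortConfig.calibration_profile(effects=effects)
    )


def null_group_pvalues(
    seed: int,
    config: StudyConfig | None = None,
    outcomes: tuple[str, ...] = CALIBRATION_OUTCOMES,
) -> dict[str, float]:
    """Group-main-effect ART p-values for one null replicate cohort.

    Runs the full generate -> extract -> test chain on the scaled-down
    null cohort and returns the group-effect p per outcome.
    """
    config = config or calibration_config(null=True)
    cohort = generate_cohort(seed, config.cohort)
    features = extract_features(cohort, config)
    frames = _outcome_frames(features, config)
    out = {}
    for outcome in outcomes:
        table = participant_cell_means(frames[outcome], "category")
        res = art_anova(
            table, "value", "group", "category", "participant_id", ["group"]
        )
        out[outcome] = res[0].p
    return out


def recovered_latency_shift(
    seed: int, config: StudyConfig | None = None
) -> float:
    """Extracted HC-minus-BPD mean SCR latency for one replicate cohort.

    Generates only the EDA channel, extracts per-trial latencies with the
    trough-to-peak detector and returns the difference of the group means
    of the participant mean latencies (positive = earlier BPD onset).
    """
    config = config or calibration_config(null=False)
    cohort = generate_cohort(seed, config.cohort, channels=frozenset({"eda"}))
    physio = compute_physio_table(
        cohort.trials,
        cohort.eda,
        {},
        cohort.config.eda_hz,
        cohort.config.baseline_s,
        config.scr.window_s,
        config.scr.onset_threshold,
        config.scr.lowpass_hz,
    )
    trials = physio[physio["segment"] != "baseline"].dropna(subset=["latency_s"])
    means = trials.groupby(["participant_id", "group"], observed=True)[
        "latency_s"
    ].mean().reset_index()
    x, y = _group_values(means, "latency_s")
    return float(np.mean(y) - np.mean(x))
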