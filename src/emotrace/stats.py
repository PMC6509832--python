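"""Nonparametric inference: aligned rank transform factorial ANOVA,
exact / Monte-Carlo Mann-Whitney tests, rank-based effect sizes.

The Aligned Rank Transform (ART) makes factorial designs amenable to
rank-based testing. For each effect of interest (main or interaction) the
response is *aligned*: the full-model cell mean is subtracted and the
marginal-mean estimate of that one effect added back, so every other
effect is stripped from the column. The aligned values are then ranked
with midranks and submitted to an ordinary factorial ANOVA, whose F-test
for the target effect is the reported statistic. Here the factorial ANOVA
is the split-plot (mixed) layout of a between-participant group factor
crossed with one within-participant factor: the group effect is tested
against the participant-within-group mean square, within and interaction
effects against the participant-by-factor residual.

Group contrasts use the Mann-Whitney U statistic with midranks. The
two-sided exact p-value enumerates all group-label assignments whenever
that is feasible (at most 10^6 assignments) and otherwise falls back to a
seeded Monte-Carlo permutation p, reported with its two-tailed 99%
Clopper-Pearson confidence interval. The standardized Z uses the
tie-corrected normal approximation without continuity correction, and the
rank effect size is r = Z / sqrt(N).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, islice

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import comb

EXACT_ENUMERATION_LIMIT = 1_000_000


class DesignError(ValueError):
    """Raised for incomplete or singular factorial designs."""


# ---------------------------------------------------------------------------
# aligned rank transform


def _check_cells(table: pd.DataFrame, factors: list[str]) -> None:
    counts = table.groupby(factors, observed=True).size()
    levels = [table[f].unique() for f in factors]
    n_expected = int(np.prod([len(lv) for lv in levels]))
    if len(counts) != n_expected:
        present = set(counts.index if len(factors) > 1 else [(i,) for i in counts.index])
        from itertools import product

        for cell in product(*levels):
            if tuple(cell) not in present:
                raise DesignError(f"empty design cell {dict(zip(factors, cell))}")


def _marginal_means(cell_means: pd.Series, factor: str) -> pd.Series:
    """Unweighted marginal means from the cell-mean table (EMM-style)."""
    return cell_means.groupby(level=factor).mean()


def art_align(
    table: pd.DataFrame,
    value: str,
    factors: list[str],
    effect: str,
) -> pd.Series:
    """Aligned ranks of ``value`` for one effect of a factorial model.

    ``factors`` are the model's factor columns (one or two); ``effect`` is
    either a factor name or ``"A:B"`` for the two-factor interaction.
    Residuals from the full-model cell means are computed per observation,
    the marginal-mean estimate of the target effect is added back, and the
    aligned column is ranked with midranks.
    """
    _check_cells(table, factors)
    cell_means = table.groupby(factors, observed=True)[value].mean()
    grand = float(cell_means.mean())  # unweighted over cells
    y = table[value].to_numpy(dtype=float)
    keys = pd.MultiIndex.from_frame(table[factors])
    fitted = cell_means.reindex(keys).to_numpy()

    if ":" in effect:
        a, b = effect.split(":")
        if sorted([a, b]) != sorted(factors):
            raise DesignError(f"interaction {effect!r} not in model {factors}")
        ma = _marginal_means(cell_means, a).reindex(table[a]).to_numpy()
        mb = _marginal_means(cell_means, b).reindex(table[b]).to_numpy()
        estimate = fitted - ma - mb + grand
    else:
        if effect not in factors:
            raise DesignError(f"effect {effect!r} not in model {factors}")
        est = _marginal_means(cell_means, effect) - grand
        estimate = est.reindex(table[effect]).to_numpy()

    aligned = y - fitted + estimate
    ranks = sps.rankdata(aligned)
    return pd.Series(ranks, index=table.index, name=f"art_{effect}")


def estimated_effects(
    table: pd.DataFrame, value: str, factors: list[str]
) -> dict[str, float]:
    """Magnitude (sum of squared estimates) of each effect of a 1-2 factor
    model, from unweighted marginal means. Used to verify the alignment
    property: after aligning for one effect, all others are zero."""
    cell_means = table.groupby(factors, observed=True)[value].mean()
    grand = float(cell_means.mean())
    out: dict[str, float] = {}
    for f in factors:
        est = _marginal_means(cell_means, f) - grand
        out[f] = float((est**2).sum())
    if len(factors) == 2:
        a, b = factors
        ma = _marginal_means(cell_means, a)
        mb = _marginal_means(cell_means, b)
        resid = (
            cell_means.to_numpy()
            - ma.reindex(cell_means.index.get_level_values(a)).to_numpy()
            - mb.reindex(cell_means.index.get_level_values(b)).to_numpy()
            + grand
        )
        out[f"{a}:{b}"] = float((resid**2).sum())
    return out


# ---------------------------------------------------------------------------
# split-plot ANOVA


@dataclass(frozen=True)
class EffectResult:
    """One factorial-ANOVA effect."""

    effect: str
    F: float
    df1: int
    df2: int
    p: float

    @property
    def partial_eta2(self) -> float:
        return self.F * self.df1 / (self.F * self.df1 + self.df2)


def mixed_anova(
    table: pd.DataFrame,
    dv: str,
    between: str,
    within: str,
    subject: str,
) -> dict[str, EffectResult]:
    """Split-plot ANOVA: one between- and one within-participant factor.

    Requires one value per participant x within-level (aggregate trials
    first). Group sizes may differ; every participant must have every
    within level. Error terms: participants-within-groups for the between
    effect, the participant-by-factor residual for the rest.
    """
    wide = table.pivot_table(
        index=[subject, between], columns=within, values=dv, aggfunc="mean"
    )
    if wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index.tolist()
        raise DesignError(f"incomplete within-participant cells for {missing}")
    groups = wide.index.get_level_values(between)
    y = wide.to_numpy(dtype=float)
    n_subj, b = y.shape
    labels = pd.unique(groups)
    a = len(labels)
    if a < 2 or b < 2 or n_subj <= a:
        raise DesignError("degenerate design")

    grand = y.mean()
    subj_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    group_means = np.array([subj_means[groups == g].mean() for g in labels])
    n_per = np.array([(groups == g).sum() for g in labels])
    cell = np.vstack([y[groups == g].mean(axis=0) for g in labels])

    ss_a = b * float(np.sum(n_per * (group_means - grand) ** 2))
    group_of = pd.Categorical(groups, categories=labels).codes
    ss_subj = b * float(np.sum((subj_means - group_means[group_of]) ** 2))
    ss_b = n_subj * float(np.sum((col_means - grand) ** 2))
    inter = cell - group_means[:, None] - col_means[None, :] + grand
    ss_ab = float(np.sum(n_per[:, None] * inter**2))
    resid = y - subj_means[:, None] - cell[group_of] + group_means[group_of, None]
    ss_err = float(np.sum(resid**2))

    df_a, df_subj = a - 1, n_subj - a
    df_b, df_ab = b - 1, (a - 1) * (b - 1)
    df_err = (n_subj - a) * (b - 1)

    def result(name: str, ss: float, df1: int, ss_e: float, df2: int) -> EffectResult:
        ms, ms_e = ss / df1, ss_e / df2
        if ms_e <= 0:
            raise DesignError("zero error mean square (singular design)")
        F = ms / ms_e
        return EffectResult(name, float(F), df1, df2, float(sps.f.sf(F, df1, df2)))

    return {
        between: result(between, ss_a, df_a, ss_subj, df_subj),
        within: result(within, ss_b, df_b, ss_err, df_err),
        f"{between}:{within}": result(
            f"{between}:{within}", ss_ab, df_ab, ss_err, df_err
        ),
    }


def art_anova(
    table: pd.DataFrame,
    dv: str,
    between: str,
    within: str,
    subject: str,
    effects: list[str] | None = None,
) -> list[EffectResult]:
    """ART factorial ANOVA: each effect tested on its own aligned ranks.

    ``table`` holds one row per participant x within-level (aggregate
    repeated trials to cell means first).
    """
    factors = [between, within]
    if effects is None:
        effects = [between, within, f"{between}:{within}"]
    out = []
    for effect in effects:
        work = table[[subject, between, within, dv]].copy()
        work["_ranks"] = art_align(work, dv, factors, effect)
        res = mixed_anova(work, "_ranks", between, within, subject)
        key = effect if effect in res else f"{between}:{within}"
        out.append(res[key])
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney


@dataclass(frozen=True)
class GroupComparison:
    """One Mann-Whitney group contrast.

    ``u`` is the smaller of the two U statistics (the convention of
    common statistical software); ``z`` is signed by the direction of the
    first sample's ranks (positive when the first sample ranks higher).
    ``p`` is the exact enumeration p when feasible, otherwise the
    Monte-Carlo permutation p.
    """

    u: float
    z: float
    p_exact: float
    p_mc: float
    mc_ci99: tuple[float, float]
    r: float
    n_total: int

    @property
    def p(self) -> float:
        return self.p_exact if not math.isnan(self.p_exact) else self.p_mc


def effect_size_r(z: float, n_total: int) -> float:
    """Rank-biserial-style effect size r = Z / sqrt(N)."""
    if n_total < 2:
        raise ValueError("need n_total >= 2")
    return z / math.sqrt(n_total)


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-comparison threshold, 4 decimals."""
    if m < 1:
        raise ValueError("need m >= 1 comparisons")
    return round(alpha / m, 4)


def _tie_sigma(pooled: np.ndarray, n1: int, n2: int) -> float:
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    return math.sqrt(max(var, 0.0))


def mann_whitney(
    x: np.ndarray,
    y: np.ndarray,
    mode: str = "auto",
    n_mc: int = 10_000,
    seed: int | None = None,
) -> GroupComparison:
    """Mann-Whitney U contrast of two independent samples.

    mode "exact" enumerates all label assignments (feasible for at most
    10^6 of them, otherwise it falls back to Monte Carlo), "monte_carlo"
    skips enumeration; "auto" behaves like "exact". The Monte-Carlo p and
    its 99% Clopper-Pearson CI are always computed from ``n_mc`` seeded
    resamples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    sigma = _tie_sigma(pooled, n1, n2)
    z = (u1 - mu) / sigma if sigma > 0 else 0.0
    obs_dev = abs(u1 - mu)
    eps = 1e-9

    all_tied = sigma == 0.0
    n_assign = comb(n, n1, exact=True)
    p_exact = math.nan
    if mode not in ("auto", "exact", "monte_carlo"):
        raise ValueError(f"unknown mode {mode!r}")
    if all_tied:
        p_exact = 1.0
    elif mode in ("auto", "exact") and n_assign <= EXACT_ENUMERATION_LIMIT:
        offset = n1 * (n1 + 1) / 2.0
        count = 0
        combo_iter = combinations(range(n), n1)
        while chunk := list(islice(combo_iter, 200_000)):
            idx = np.asarray(chunk, dtype=np.intp)
            sums = ranks[idx].sum(axis=1) - offset
            count += int(np.sum(np.abs(sums - mu) >= obs_dev - eps))
        p_exact = count / n_assign

    rng = np.random.default_rng(seed)
    if all_tied:
        k, p_mc = n_mc, 1.0
    else:
        order = rng.random((n_mc, n)).argsort(axis=1)[:, :n1]
        sums = ranks[order].sum(axis=1) - n1 * (n1 + 1) / 2.0
        k = int(np.sum(np.abs(sums - mu) >= obs_dev - eps))
        p_mc = k / n_mc
    lo = float(sps.beta.ppf(0.005, k, n_mc - k + 1)) if k > 0 else 0.0
    hi = float(sps.beta.ppf(0.995, k + 1, n_mc - k)) if k < n_mc else 1.0

    return GroupComparison(
        u=float(min(u1, n1 * n2 - u1)),
        z=float(z),
        p_exact=p_exact,
        p_mc=float(p_mc),
        mc_ci99=(lo, hi),
        r=effect_size_r(z, n),
        n_total=n,
    )


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation (midranks) with t-approximation p.

    Returns (nan, nan) when either variable has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return (math.nan, math.nan)
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)
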