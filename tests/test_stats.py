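import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from emotrace.stats import (
    DesignError,
    EffectResult,
    art_align,
    art_anova,
    bonferroni,
    effect_size_r,
    estimated_effects,
    mann_whitney,
    mixed_anova,
    spearman,
)


def long_table(cells, reps_per_cell):
    """cells: {(a, b): [values]} -> long DataFrame with subject ids."""
    rows = []
    for (a, b), values in cells.items():
        for i, v in enumerate(values):
            rows.append({"A": a, "B": b, "subject": f"{a}{i}", "y": float(v)})
    return pd.DataFrame(rows)


class TestArtAlign:
    def toy(self):
        return long_table(
            {
                ("a1", "b1"): [1, 2],
                ("a1", "b2"): [3, 5],
                ("a2", "b1"): [2, 4],
                ("a2", "b2"): [10, 12],
            },
            2,
        )

    def test_2x2_toy_matches_hand_enumeration(self):
        """Aligned ranks for effect A, enumerated by hand from the cell
        means (1.5, 4, 3, 11), grand 4.875 and margins (2.75, 7)."""
        ranks = art_align(self.toy(), "y", ["A", "B"], "A")
        expected = [2.0, 3.0, 1.0, 4.0, 5.5, 7.5, 5.5, 7.5]
        assert list(ranks) == expected

    def test_translation_invariance(self):
        table = self.toy()
        shifted = table.assign(y=table["y"] + 1000.0)
        for effect in ("A", "B", "A:B"):
            assert list(art_align(table, "y", ["A", "B"], effect)) == list(
                art_align(shifted, "y", ["A", "B"], effect)
            )

    @pytest.mark.parametrize(
        "b_levels", [("b1", "b2"), ("b1", "b2", "b3")]
    )
    def test_alignment_strips_all_other_effects(self, b_levels):
        """On noiseless cell-mean data with only a B effect, the column
        aligned for A (or A:B) carries zero B effect, and vice versa."""
        b_effect = {lvl: 3.0 * i for i, lvl in enumerate(b_levels)}
        cells = {
            (a, b): [10.0 + b_effect[b]] * 3
            for a in ("a1", "a2")
            for b in b_levels
        }
        table = long_table(cells, 3)
        for target in ("A", "A:B"):
            # rebuild the aligned (pre-rank) column explicitly
            work = table.copy()
            cell = work.groupby(["A", "B"])["y"].transform("mean")
            grand = work.groupby(["A", "B"])["y"].mean().mean()
            if target == "A":
                est = work.groupby("A")["y"].transform("mean") - grand
            else:
                est = (
                    cell
                    - work.groupby("A")["y"].transform("mean")
                    - work.groupby("B")["y"].transform("mean")
                    + grand
                )
            work["aligned"] = work["y"] - cell + est
            effects = estimated_effects(work, "aligned", ["A", "B"])
            for name, magnitude in effects.items():
                if name != target:
                    assert magnitude == pytest.approx(0.0, abs=1e-12)

    def test_empty_cell_raises_named_error(self):
        table = self.toy()
        table = table[~((table["A"] == "a2") & (table["B"] == "b2"))]
        with pytest.raises(DesignError, match="a2"):
            art_align(table, "y", ["A", "B"], "A")


class TestMixedAnova:
    def test_matches_r_aov_on_unbalanced_design(self):
        """Frozen oracle: R `aov(y ~ group*cond + Error(subject/cond))`
        on this exact table gives F = 0.092, 2.759, 1.061."""
        rng = np.random.default_rng(5)
        rows = []
        subj = 0
        for g, n in [("A", 4), ("B", 6)]:
            for _ in range(n):
                subj += 1
                base = rng.normal(0, 1)
                for w, off in [("w1", 0.0), ("w2", 0.7), ("w3", 0.2)]:
                    rows.append(
                        {
                            "subject": f"s{subj}",
                            "group": g,
                            "cond": w,
                            "y": round(
                                base + off + (0.5 if g == "B" else 0)
                                + rng.normal(0, 0.6),
                                4,
                            ),
                        }
                    )
        table = pd.DataFrame(rows)
        res = mixed_anova(table, "y", "group", "cond", "subject")
        assert res["group"].F == pytest.approx(0.091608, abs=1e-4)
        assert (res["group"].df1, res["group"].df2) == (1, 8)
        assert res["cond"].F == pytest.approx(2.758976, abs=1e-4)
        assert (res["cond"].df1, res["cond"].df2) == (2, 16)
        assert res["group:cond"].F == pytest.approx(1.060758, abs=1e-4)

    def test_matches_pingouin_on_balanced_design(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(12)
        rows = []
        for g in ("x", "y"):
            for i in range(8):
                for w in ("w1", "w2", "w3"):
                    rows.append(
                        {
                            "subject": f"{g}{i}",
                            "group": g,
                            "cond": w,
                            "y": rng.normal(0, 1),
                        }
                    )
        table = pd.DataFrame(rows)
        mine = mixed_anova(table, "y", "group", "cond", "subject")
        theirs = pingouin.mixed_anova(
            data=table, dv="y", within="cond", subject="subject", between="group"
        ).set_index("Source")
        assert mine["group"].F == pytest.approx(theirs.loc["group", "F"], rel=1e-6)
        assert mine["cond"].F == pytest.approx(theirs.loc["cond", "F"], rel=1e-6)
        assert mine["group:cond"].F == pytest.approx(
            theirs.loc["Interaction", "F"], rel=1e-6
        )

    def test_incomplete_within_cells_rejected(self):
        table = pd.DataFrame(
            {
                "subject": ["s1", "s1", "s2"],
                "group": ["A", "A", "B"],
                "cond": ["w1", "w2", "w1"],
                "y": [1.0, 2.0, 3.0],
            }
        )
        with pytest.raises(DesignError):
            mixed_anova(table, "y", "group", "cond", "subject")


class TestArtAnova:
    def _random_table(self, rng, n=14, b=("short", "long")):
        rows = []
        for g in ("BPD", "HC"):
            for i in range(n):
                for w in b:
                    rows.append(
                        {
                            "participant_id": f"{g}{i}",
                            "group": g,
                            "block": w,
                            "value": rng.normal(0, 1),
                        }
                    )
        return pd.DataFrame(rows)

    def test_partial_eta2_identity(self):
        assert EffectResult("e", 5.73, 1, 26, 0.02).partial_eta2 == pytest.approx(
            0.18, abs=0.005
        )
        assert EffectResult("e", 4.39, 1, 21, 0.04).partial_eta2 == pytest.approx(
            0.17, abs=0.005
        )

    def test_invariance_under_affine_transform(self):
        """Alignment is linear in the response, so any positive affine
        rescaling leaves the aligned ranks — and every F — unchanged."""
        rng = np.random.default_rng(3)
        table = self._random_table(rng)
        res1 = art_anova(table, "value", "group", "block", "participant_id")
        transformed = table.assign(value=3.7 * table["value"] - 12.0)
        res2 = art_anova(transformed, "value", "group", "block", "participant_id")
        for r1, r2 in zip(res1, res2):
            assert r1.F == pytest.approx(r2.F, rel=1e-9)

    def test_group_effect_type_I_error_calibrated(self):
        """Pure-noise 2 groups x 2 blocks: rejection near the nominal 5%."""
        rng = np.random.default_rng(77)
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            table = self._random_table(rng)
            res = art_anova(
                table, "value", "group", "block", "participant_id", ["group"]
            )
            hits += res[0].p < 0.05
        assert 0.032 <= hits / n_sim <= 0.068

    def test_detects_planted_group_shift(self):
        rng = np.random.default_rng(5)
        table = self._random_table(rng)
        table.loc[table["group"] == "BPD", "value"] += 2.0
        res = art_anova(table, "value", "group", "block", "participant_id")
        by_name = {r.effect: r for r in res}
        assert by_name["group"].p < 0.001
        assert by_name["group:block"].p > 0.05


def mw_oracle(x, y):
    """Independent full-enumeration oracle for the two-sided exact p."""
    pooled = np.concatenate([x, y])
    n, n1 = len(pooled), len(x)
    ranks = sps.rankdata(pooled)
    mu = n1 * (n - n1) / 2.0
    obs = abs(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0 - mu)
    count = total = 0
    for combo in itertools.combinations(range(n), n1):
        u = sum(ranks[i] for i in combo) - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - mu) >= obs - 1e-9:
            count += 1
    return count / total


class TestMannWhitney:
    def test_separated_samples(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.u == 0.0
        assert res.p_exact == pytest.approx(0.1)

    def test_identical_multisets(self):
        res = mann_whitney([1, 2, 2, 5], [1, 2, 2, 5])
        assert res.u == 8.0  # n1*n2/2
        assert res.p_exact == pytest.approx(1.0)
        assert res.z == pytest.approx(0.0, abs=1e-12)

    def test_all_tied_degenerate(self):
        res = mann_whitney([3, 3, 3], [3, 3, 3])
        assert res.p == 1.0
        assert res.z == 0.0

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            x = rng.normal(size=6)
            y = rng.normal(0.8, size=5)
            mine = mann_whitney(x, y)
            ref = sps.mannwhitneyu(x, y, method="exact", alternative="two-sided")
            assert mine.p_exact == pytest.approx(ref.pvalue, abs=1e-12)

    def test_matches_enumeration_oracle_with_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = rng.integers(0, 4, size=5).astype(float)
            y = rng.integers(0, 4, size=4).astype(float)
            if np.unique(np.concatenate([x, y])).size == 1:
                continue
            assert mann_whitney(x, y).p_exact == pytest.approx(mw_oracle(x, y))

    def test_z_sign_follows_first_sample_direction(self):
        up = mann_whitney([5, 6, 7, 8], [1, 2, 3, 4])
        down = mann_whitney([1, 2, 3, 4], [5, 6, 7, 8])
        assert up.z > 0 > down.z
        assert up.r == pytest.approx(-down.r)

    def test_large_samples_fall_back_to_monte_carlo(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=14), rng.normal(size=14)  # C(28,14) > 1e6
        res = mann_whitney(x, y, seed=0)
        assert math.isnan(res.p_exact)
        assert 0.0 <= res.p_mc <= 1.0
        assert res.mc_ci99[0] <= res.p_mc <= res.mc_ci99[1]

    def test_monte_carlo_converges_to_exact(self):
        """|p_mc - p_exact| stays within the 99% CI half-width for almost
        every seed on a small two-sample problem."""
        x = [1.0, 2.0, 3.0, 7.0, 9.0]
        y = [4.0, 5.0, 6.0, 8.0, 10.0]
        p_exact = mann_whitney(x, y).p_exact
        outside = 0
        for seed in range(50):
            res = mann_whitney(x, y, mode="monte_carlo", seed=seed)
            half = (res.mc_ci99[1] - res.mc_ci99[0]) / 2.0
            if abs(res.p_mc - p_exact) >= half:
                outside += 1
        assert outside <= 2

    def test_ci_is_seeded_and_deterministic(self):
        a = mann_whitney([1, 2, 3, 4], [2, 3, 4, 5], seed=42)
        b = mann_whitney([1, 2, 3, 4], [2, 3, 4, 5], seed=42)
        assert a.p_mc == b.p_mc
        assert a.mc_ci99 == b.mc_ci99

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestEffectSizes:
    @pytest.mark.parametrize(
        "z,n,expected",
        [(3.155, 28, 0.60), (0.731, 28, 0.14), (2.17, 28, 0.41), (0.0, 12, 0.0)],
    )
    def test_r_from_z(self, z, n, expected):
        assert round(effect_size_r(z, n), 2) == expected

    def test_r_needs_two_observations(self):
        with pytest.raises(ValueError):
            effect_size_r(1.0, 1)

    @pytest.mark.parametrize(
        "alpha,m,expected", [(0.05, 3, 0.0167), (0.05, 1, 0.05), (0.05, 2, 0.025)]
    )
    def test_bonferroni(self, alpha, m, expected):
        assert bonferroni(alpha, m) == expected

    def test_bonferroni_rejects_bad_m(self):
        with pytest.raises(ValueError):
            bonferroni(0.05, 0)


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p = spearman([1, 2, 3, 4], [10, 100, 1000, 10000])
        assert rho == pytest.approx(1.0)
        assert p < 0.05

    def test_tie_heavy_matches_rank_then_pearson(self):
        x = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 5.0, 5.0])
        y = np.array([4.0, 4.0, 4.0, 6.0, 2.0, 9.0, 9.0])
        rho, _ = spearman(x, y)
        oracle = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_null_calibration(self):
        rng = np.random.default_rng(6)
        rhos = [
            spearman(rng.normal(size=28), rng.normal(size=28))[0]
            for _ in range(1000)
        ]
        assert abs(np.mean(rhos)) < 0.02

    def test_zero_variance_returns_missing(self):
        rho, p = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(rho)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 2.0], [1.0, 2.0])
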