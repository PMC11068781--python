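import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from divekin.errors import DegenerateTestError, DesignError, PairingError
from divekin.stats import (
    cohens_d,
    cohens_d_from_samples,
    mixed_anova,
    paired_t,
    spm_paired_t,
)


class TestCohensD:
    @pytest.mark.parametrize(
        "m1, s1, m2, s2, expected",
        [
            # published group summaries: frontal step distance post,
            # departure angle post, time-to-peak post, step distance by leg side
            (0.336, 0.15, 0.49, 0.247, 0.75),
            (12.064, 6.102, 15.708, 6.791, 0.56),
            (0.572, 0.085, 0.517, 0.075, 0.69),
            (0.343, 0.181, 0.439, 0.239, 0.45),
        ],
    )
    def test_reproduces_published_effect_sizes(self, m1, s1, m2, s2, expected):
        assert round(cohens_d(m1, s1, m2, s2), 2) == expected

    def test_equal_means_give_zero(self):
        assert cohens_d(1.0, 0.5, 1.0, 0.7) == 0.0

    def test_non_positive_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d(1.0, 0.0, 2.0, 1.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        m1=st.floats(-10, 10), m2=st.floats(-10, 10),
        s1=st.floats(0.1, 10), s2=st.floats(0.1, 10),
        c=st.floats(0.1, 100),
    )
    def test_symmetric_and_scale_invariant(self, m1, m2, s1, s2, c):
        d = cohens_d(m1, s1, m2, s2)
        assert d == pytest.approx(cohens_d(m2, s2, m1, s1))
        assert cohens_d(c * m1, c * s1, c * m2, c * s2) == pytest.approx(d, rel=1e-9)


class TestPairedT:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0])
        res = paired_t(x, x.copy())
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_closed_form_on_five_pairs(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 2.0, 4.0, 3.0, 7.0])
        d = x - y
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        res = paired_t(x, y)
        assert res.statistic == pytest.approx(t_hand, abs=1e-10)
        assert res.df == 4

    def test_null_p_values_are_uniform(self, rng):
        ps = []
        for _ in range(2000):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            ps.append(paired_t(x, y).p_value)
        from scipy.stats import kstest

        assert kstest(ps, "uniform").pvalue > 0.01

    def test_constant_nonzero_differences_rejected(self):
        with pytest.raises(DegenerateTestError):
            paired_t(np.array([1.0, 2.0, 3.0]), np.array([0.0, 1.0, 2.0]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(PairingError):
            paired_t(np.zeros(3), np.zeros(4))


def _exhaustive_spm_oracle(D, alpha=0.05):
    """Literal enumeration of all sign flips: t field, max-|t| threshold,
    and max suprathreshold-cluster extents, computed with plain loops."""
    n, nodes = D.shape
    t_fields = []
    for signs in itertools.product([1.0, -1.0], repeat=n):
        S = np.asarray(signs)[:, None] * D
        m, s = S.mean(0), S.std(0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(s > 0, m / (s / np.sqrt(n)), 0.0)
        t_fields.append(t)
    t_fields = np.asarray(t_fields)
    t_max = np.abs(t_fields).max(axis=1)
    t_crit = float(np.quantile(t_max, 1 - alpha))
    extents = []
    for t in t_fields:
        best = run = 0
        for val in np.abs(t) > t_crit:
            run = run + 1 if val else 0
            best = max(best, run)
        extents.append(best)
    return t_crit, np.asarray(extents)


class TestSpmPairedT:
    def test_identical_curve_sets_yield_flat_null_field(self):
        a = np.tile(np.linspace(0, 1, 101), (5, 1))
        res = spm_paired_t(a, a.copy(), n_perm=2000, seed=0)
        assert np.allclose(res.t_curve, 0.0)
        assert res.clusters == []

    def test_localized_offset_detected_and_matches_enumeration_oracle(self, rng):
        n, nodes = 8, 101
        a = rng.normal(size=(n, nodes))
        b = a + rng.normal(0, 0.2, size=(n, nodes))
        b[:, 40:61] += 3.0
        res = spm_paired_t(a, b, n_perm=1000, seed=0)
        assert res.exhaustive  # 2^8 = 256 <= 1000
        spans = [(c.start_pct, c.end_pct) for c in res.clusters]
        assert any(s <= 60 and e >= 40 for s, e in spans)

        t_crit, extents = _exhaustive_spm_oracle(a - b)
        assert res.t_crit == pytest.approx(t_crit, abs=1e-10)
        main = max(res.clusters, key=lambda c: c.extent)
        assert main.p_value == pytest.approx(np.mean(extents >= main.extent), abs=1e-12)

    def test_nodewise_t_matches_scalar_paired_t(self, rng):
        a = rng.normal(size=(8, 101))
        b = rng.normal(size=(8, 101))
        res = spm_paired_t(a, b, n_perm=1000, seed=0)
        for j in (0, 17, 50, 100):
            assert res.t_curve[j] == pytest.approx(
                paired_t(a[:, j], b[:, j]).statistic, abs=1e-10
            )

    def test_reproducible_under_fixed_seed_with_sampled_permutations(self, rng):
        a = rng.normal(size=(15, 101))
        b = rng.normal(size=(15, 101))
        r1 = spm_paired_t(a, b, n_perm=2000, seed=42)
        r2 = spm_paired_t(a, b, n_perm=2000, seed=42)
        assert not r1.exhaustive
        assert r1.t_crit == r2.t_crit
        assert [c.p_value for c in r1.clusters] == [c.p_value for c in r2.clusters]

    def test_unpaired_shapes_rejected(self):
        with pytest.raises(PairingError):
            spm_paired_t(np.zeros((4, 101)), np.zeros((5, 101)), n_perm=1000)


def _cellmeans_anova_oracle(df):
    """Independent mixed-design sums-of-squares computation, textbook style."""
    groups = sorted(df["group"].unique())
    times = sorted(df["time"].unique())
    a, b = len(groups), len(times)
    N = df["subject"].nunique()
    grand = df["value"].mean()

    ss_cells = {}
    for g in groups:
        for t in times:
            ss_cells[(g, t)] = df[(df.group == g) & (df.time == t)]["value"].mean()
    ng = {g: df[df.group == g]["subject"].nunique() for g in groups}
    mg = {g: df[df.group == g]["value"].mean() for g in groups}
    mt = {t: df[df.time == t]["value"].mean() for t in times}

    ss_group = b * sum(ng[g] * (mg[g] - grand) ** 2 for g in groups)
    ss_time = N * sum((mt[t] - grand) ** 2 for t in times)
    ss_inter = sum(
        ng[g] * (ss_cells[(g, t)] - mg[g] - mt[t] + grand) ** 2
        for g in groups for t in times
    )
    subj_means = df.groupby("subject")["value"].mean()
    ss_bs = b * sum((subj_means[s] - grand) ** 2 for s in subj_means.index)
    ss_sw = ss_bs - ss_group
    ss_total = sum((df["value"] - grand) ** 2)
    ss_err = ss_total - ss_bs - ss_time - ss_inter

    f_group = (ss_group / (a - 1)) / (ss_sw / (N - a))
    f_time = (ss_time / (b - 1)) / (ss_err / ((N - a) * (b - 1)))
    f_inter = (ss_inter / ((a - 1) * (b - 1))) / (ss_err / ((N - a) * (b - 1)))
    return f_group, f_time, f_inter


def _balanced_design(values_by_cell, n_per_group):
    rows = []
    i = 0
    for g, cells in values_by_cell.items():
        for s in range(n_per_group):
            i += 1
            for t, vals in cells.items():
                rows.append(
                    {"subject": f"S{i}", "group": g, "time": t, "value": vals[s]}
                )
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_all_equal_values_give_null_f(self):
        df = _balanced_design(
            {"CG": {"pre": [1.0] * 3, "post": [1.0] * 3},
             "VG": {"pre": [1.0] * 3, "post": [1.0] * 3}},
            3,
        )
        anova, posthoc = mixed_anova(df)
        assert np.allclose(anova["F"], 0.0)
        assert np.allclose(anova["p"], 1.0)
        assert np.allclose(posthoc["p_bonferroni"], 1.0)

    def test_pure_interaction_detected(self, rng):
        base = {"CG": {"pre": 0.0, "post": 1.0}, "VG": {"pre": 1.0, "post": 0.0}}
        rows = []
        i = 0
        for g, cells in base.items():
            for _ in range(6):
                i += 1
                for t, mu in cells.items():
                    rows.append(
                        {"subject": f"S{i}", "group": g, "time": t,
                         "value": mu + rng.normal(0, 0.05)}
                    )
        anova, _ = mixed_anova(pd.DataFrame(rows))
        by = anova.set_index("effect")
        assert by.loc["group x time", "p"] < 0.05
        assert by.loc["group", "p"] > 0.5
        assert by.loc["time", "p"] > 0.5

    def test_matches_cellmeans_oracle_on_balanced_toy(self, rng):
        df = _balanced_design(
            {"CG": {"pre": rng.normal(0, 1, 4), "post": rng.normal(0.5, 1, 4)},
             "VG": {"pre": rng.normal(0, 1, 4), "post": rng.normal(-0.5, 1, 4)}},
            4,
        )
        anova, _ = mixed_anova(df)
        f_g, f_t, f_i = _cellmeans_anova_oracle(df)
        assert anova.loc[0, "F"] == pytest.approx(f_g, abs=1e-8)
        assert anova.loc[1, "F"] == pytest.approx(f_t, abs=1e-8)
        assert anova.loc[2, "F"] == pytest.approx(f_i, abs=1e-8)

    def test_cross_checked_against_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        df = _balanced_design(
            {"CG": {"pre": rng.normal(0, 1, 5), "post": rng.normal(0.8, 1, 5)},
             "VG": {"pre": rng.normal(0, 1, 5), "post": rng.normal(-0.3, 1, 5)}},
            5,
        )
        anova, _ = mixed_anova(df)
        pg = pingouin.mixed_anova(
            data=df, dv="value", within="time", between="group", subject="subject"
        ).set_index("Source")
        assert anova.loc[0, "F"] == pytest.approx(pg.loc["group", "F"], rel=1e-6)
        assert anova.loc[1, "F"] == pytest.approx(pg.loc["time", "F"], rel=1e-6)
        assert anova.loc[2, "F"] == pytest.approx(pg.loc["Interaction", "F"], rel=1e-6)

    def test_unbalanced_within_subject_rejected(self):
        df = _balanced_design(
            {"CG": {"pre": [1.0, 2.0], "post": [1.5, 2.5]},
             "VG": {"pre": [1.0, 2.0], "post": [1.5, 2.5]}},
            2,
        )
        anova_ok, _ = mixed_anova(df)  # sanity: balanced passes
        with pytest.raises(DesignError):
            mixed_anova(df.drop(index=1))

    def test_bonferroni_adjustment_is_fourfold(self, rng):
        df = _balanced_design(
            {"CG": {"pre": rng.normal(0, 1, 4), "post": rng.normal(0, 1, 4)},
             "VG": {"pre": rng.normal(0, 1, 4), "post": rng.normal(0, 1, 4)}},
            4,
        )
        _, posthoc = mixed_anova(df)
        assert len(posthoc) == 4
        assert np.allclose(
            posthoc["p_bonferroni"],
            np.minimum(1.0, posthoc["p_uncorrected"] * 4),
        )

    def test_subject_level_effect_size_from_samples(self, rng):
        x = rng.normal(0, 1, 200)
        y = rng.normal(1, 1, 200)
        d = cohens_d_from_samples(x, y)
        assert d == pytest.approx(1.0, abs=0.25)
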