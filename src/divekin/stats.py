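"""Curve-level and scalar statistics for dive comparisons.

* One-dimensional statistical parametric mapping (SPM): a paired t statistic
  at every node of the 101-point normalized curves, with family-wise
  inference by sign-flip permutations of the paired differences.  The
  critical threshold is the (1 - alpha) quantile of the permutation
  distribution of the maximum |t| across nodes (max-statistic control), and
  each suprathreshold cluster receives a p-value from the permutation
  distribution of the maximum cluster extent.  When the number of pairs is
  small enough, all 2^n sign flips are enumerated exactly.
* Scalar paired t test, Cohen's d with the equal-weight pooled-SD
  convention d = |m1 - m2| / sqrt((sd1^2 + sd2^2) / 2).
* Balanced mixed-design (one between x one within factor) repeated-measures
  ANOVA with Bonferroni-adjusted pairwise contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateTestError, DesignError, PairingError

__all__ = [
    "CurveSet",
    "SpmCluster",
    "SpmResult",
    "ScalarTestResult",
    "cohens_d",
    "cohens_d_from_samples",
    "paired_t",
    "spm_paired_t",
    "mixed_anova",
]


@dataclass
class CurveSet:
    """A set of per-unit normalized curves (rows) sharing a node grid."""

    curves: np.ndarray  # (n_units, n_nodes)
    unit_ids: list | None = None

    def __post_init__(self) -> None:
        self.curves = np.atleast_2d(np.asarray(self.curves, dtype=float))
        if self.unit_ids is not None and len(self.unit_ids) != self.curves.shape[0]:
            raise PairingError("unit_ids length does not match curve count")


@dataclass
class SpmCluster:
    start_pct: float
    end_pct: float
    p_value: float
    extent: int


@dataclass
class SpmResult:
    t_curve: np.ndarray = field(repr=False)
    t_crit: float = 0.0
    clusters: list[SpmCluster] = field(default_factory=list)
    alpha: float = 0.05
    n_permutations: int = 0
    exhaustive: bool = False


@dataclass
class ScalarTestResult:
    statistic: float
    p_value: float
    df: float
    effect_size_d: float | None = None
    label: str = ""


def cohens_d(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """Cohen's d from summary statistics, equal-weight pooled SD."""
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError(f"standard deviations must be positive, got {sd1}, {sd2}")
    return abs(mean1 - mean2) / np.sqrt((sd1**2 + sd2**2) / 2.0)


def cohens_d_from_samples(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return cohens_d(x.mean(), x.std(ddof=1), y.mean(), y.std(ddof=1))


def paired_t(x: np.ndarray, y: np.ndarray, label: str = "") -> ScalarTestResult:
    """Classical two-sided paired Student's t test with Cohen's d."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise PairingError(f"paired samples must be equal-length 1D, got {x.shape}, {y.shape}")
    n = x.size
    if n < 2:
        raise DegenerateTestError(f"paired t needs n >= 2, got {n}")
    d = x - y
    if np.allclose(d, d[0]) and np.isclose(d[0], 0.0):
        # identical samples: t = 0 by convention
        return ScalarTestResult(statistic=0.0, p_value=1.0, df=n - 1, effect_size_d=0.0, label=label)
    if d.std(ddof=1) == 0:
        raise DegenerateTestError("zero-variance paired differences")
    t, p = sps.ttest_rel(x, y)
    return ScalarTestResult(
        statistic=float(t),
        p_value=float(p),
        df=n - 1,
        effect_size_d=cohens_d_from_samples(x, y),
        label=label,
    )


def _as_curves(a) -> CurveSet:
    return a if isinstance(a, CurveSet) else CurveSet(curves=np.asarray(a))


def _sign_matrix(n: int, n_perm: int, rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """All 2^n sign-flip patterns when feasible, else a random sample."""
    if 2**n <= n_perm:
        bits = np.arange(2**n, dtype=np.uint32)
        signs = 1.0 - 2.0 * ((bits[:, None] >> np.arange(n)) & 1)
        return signs, True
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    signs[0] = 1.0  # include the observed labeling
    return signs, False


def _t_from_signs(D: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Node-wise paired t for every sign-flip of the difference rows.

    Sign flips leave each node's sum of squares unchanged, so the flipped
    sample variance follows from the flipped mean alone.
    """
    n = D.shape[0]
    sumsq = np.sum(D**2, axis=0)  # (nodes,)
    means = signs @ D / n  # (perms, nodes)
    var = (sumsq[None, :] - n * means**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / np.sqrt(var / n)
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def _max_run_lengths(mask: np.ndarray) -> np.ndarray:
    """Longest True run per row of a boolean matrix (perms x nodes)."""
    best = np.zeros(mask.shape[0], dtype=int)
    run = np.zeros(mask.shape[0], dtype=int)
    for j in range(mask.shape[1]):
        run = (run + 1) * mask[:, j]
        best = np.maximum(best, run)
    return best


def _clusters_from_curve(
    t_obs: np.ndarray, t_crit: float, perm_max_extent: np.ndarray
) -> list[SpmCluster]:
    supra = np.abs(t_obs) > t_crit
    clusters = []
    padded = np.concatenate([[False], supra, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    n_nodes = t_obs.size
    for start, stop in zip(edges[0::2], edges[1::2]):
        extent = int(stop - start)
        p = float(np.mean(perm_max_extent >= extent))
        clusters.append(
            SpmCluster(
                start_pct=100.0 * start / (n_nodes - 1),
                end_pct=100.0 * (stop - 1) / (n_nodes - 1),
                p_value=max(p, 1.0 / perm_max_extent.size),
                extent=extent,
            )
        )
    return clusters


def spm_paired_t(
    a,
    b,
    alpha: float = 0.05,
    n_perm: int = 10000,
    seed: int | None = None,
) -> SpmResult:
    """Paired-t SPM over normalized curves with permutation inference.

    ``a`` and ``b`` are CurveSets (or plain (n, nodes) arrays) of paired
    units.  The node-wise paired t statistic is thresholded at the
    (1 - alpha) quantile of the sign-flip permutation distribution of
    max |t|; each suprathreshold cluster's p-value is the fraction of
    permutations whose largest suprathreshold cluster is at least as long.
    """
    A = _as_curves(a)
    B = _as_curves(b)
    if A.unit_ids is not None and B.unit_ids is not None and A.unit_ids != B.unit_ids:
        raise PairingError("curve sets are not paired: unit ids differ")
    if A.curves.shape != B.curves.shape:
        raise PairingError(
            f"curve sets must have equal shape, got {A.curves.shape} vs {B.curves.shape}"
        )
    n = A.curves.shape[0]
    if n < 2:
        raise DegenerateTestError(f"SPM paired t needs n >= 2 pairs, got {n}")
    if n_perm < 1000:
        raise ValueError(f"n_perm must be >= 1000, got {n_perm}")

    D = A.curves - B.curves
    rng = np.random.default_rng(seed)
    signs, exhaustive = _sign_matrix(n, n_perm, rng)
    t_all = _t_from_signs(D, signs)
    t_obs = _t_from_signs(D, np.ones((1, n)))[0]

    if not np.any(np.abs(t_all) > 0):
        # a == b exactly: a flat null field with no threshold to cross
        return SpmResult(
            t_curve=t_obs,
            t_crit=np.inf,
            clusters=[],
            alpha=alpha,
            n_permutations=signs.shape[0],
            exhaustive=exhaustive,
        )

    t_max = np.abs(t_all).max(axis=1)
    t_crit = float(np.quantile(t_max, 1.0 - alpha))
    perm_max_extent = _max_run_lengths(np.abs(t_all) > t_crit)
    clusters = _clusters_from_curve(t_obs, t_crit, perm_max_extent)
    return SpmResult(
        t_curve=t_obs,
        t_crit=t_crit,
        clusters=clusters,
        alpha=alpha,
        n_permutations=signs.shape[0],
        exhaustive=exhaustive,
    )


def _f_p(ss_effect: float, df_effect: float, ss_error: float, df_error: float):
    """F statistic and p with the convention F = 0, p = 1 for a null effect."""
    if ss_effect <= 1e-12:
        return 0.0, 1.0
    if ss_error <= 1e-12 or df_error <= 0:
        return np.inf, 0.0
    f = (ss_effect / df_effect) / (ss_error / df_error)
    return float(f), float(sps.f.sf(f, df_effect, df_error))


def mixed_anova(
    data: pd.DataFrame,
    dv: str = "value",
    between: str = "group",
    within: str = "time",
    subject: str = "subject",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-way mixed-design repeated-measures ANOVA with Bonferroni contrasts.

    One between-subject factor (e.g. control vs video group) crossed with one
    within-subject factor (e.g. pre vs post); one value per subject per
    within level.  Returns the ANOVA table (between, within, interaction)
    and the four Bonferroni-adjusted pairwise contrasts used in 2x2 designs
    (pre-vs-post within each group, between groups at each time).

    Raises DesignError for unbalanced within-subject data or groups with
    fewer than two subjects.
    """
    df = data[[subject, between, within, dv]].copy()
    if df.duplicated([subject, within]).any():
        raise DesignError("multiple values per subject x within cell; aggregate first")
    groups = sorted(df[between].unique())
    times = sorted(df[within].unique())
    counts = df.groupby(subject)[within].nunique()
    if (counts != len(times)).any():
        missing = counts[counts != len(times)].index.tolist()
        raise DesignError(f"subjects missing within-factor levels: {missing}")
    per_group = df.groupby(between)[subject].nunique()
    if (per_group < 2).any():
        raise DesignError(f"each group needs >= 2 subjects, got {per_group.to_dict()}")

    a, b = len(groups), len(times)
    N = df[subject].nunique()
    grand = df[dv].mean()
    subj_means = df.groupby(subject)[dv].mean()
    subj_group = df.groupby(subject)[between].first()
    group_means = df.groupby(between)[dv].mean()
    time_means = df.groupby(within)[dv].mean()
    cell_means = df.groupby([between, within])[dv].mean()
    n_per_group = df.groupby(between)[subject].nunique()

    ss_between_subj = b * float(((subj_means - grand) ** 2).sum())
    ss_group = b * float(sum(n_per_group[g] * (group_means[g] - grand) ** 2 for g in groups))
    ss_subj_within = ss_between_subj - ss_group
    ss_total = float(((df[dv] - grand) ** 2).sum())
    ss_time = float(sum(N * (time_means[t] - grand) ** 2 for t in times))
    ss_inter = float(
        sum(
            n_per_group[g]
            * (cell_means[(g, t)] - group_means[g] - time_means[t] + grand) ** 2
            for g in groups
            for t in times
        )
    )
    ss_error_within = ss_total - ss_between_subj - ss_time - ss_inter

    df_group, df_sw = a - 1, N - a
    df_time, df_ew = b - 1, (N - a) * (b - 1)
    f_g, p_g = _f_p(ss_group, df_group, ss_subj_within, df_sw)
    f_t, p_t = _f_p(ss_time, df_time, ss_error_within, df_ew)
    f_i, p_i = _f_p(ss_inter, (a - 1) * (b - 1), ss_error_within, df_ew)

    anova = pd.DataFrame(
        {
            "effect": [between, within, f"{between} x {within}"],
            "ss": [ss_group, ss_time, ss_inter],
            "df1": [df_group, df_time, (a - 1) * (b - 1)],
            "df2": [df_sw, df_ew, df_ew],
            "F": [f_g, f_t, f_i],
            "p": [p_g, p_t, p_i],
        }
    )

    posthoc = _bonferroni_contrasts(df, dv, between, within, subject, groups, times)
    return anova, posthoc


def _scalar_t_safe(x: np.ndarray, y: np.ndarray, paired: bool):
    if paired:
        d = x - y
        if d.std(ddof=1) == 0:
            return (0.0, 1.0) if np.allclose(d, 0) else (np.inf, 0.0)
        t, p = sps.ttest_rel(x, y)
    else:
        if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
            return (0.0, 1.0) if np.isclose(x.mean(), y.mean()) else (np.inf, 0.0)
        t, p = sps.ttest_ind(x, y)
    return float(t), float(p)


def _bonferroni_contrasts(df, dv, between, within, subject, groups, times) -> pd.DataFrame:
    """The four cell contrasts of a 2x2 mixed design, Bonferroni-adjusted."""
    wide = df.pivot_table(index=[subject, between], columns=within, values=dv).reset_index()
    rows = []
    # within-group: pre vs post (paired)
    for g in groups:
        sub = wide[wide[between] == g]
        for i in range(len(times)):
            for j in range(i + 1, len(times)):
                t, p = _scalar_t_safe(
                    sub[times[i]].to_numpy(float), sub[times[j]].to_numpy(float), paired=True
                )
                rows.append((f"{g}:{times[i]} x {g}:{times[j]}", t, p))
    # between-group at each time (independent)
    for t_level in times:
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                xi = wide.loc[wide[between] == groups[i], t_level].to_numpy(float)
                xj = wide.loc[wide[between] == groups[j], t_level].to_numpy(float)
                t, p = _scalar_t_safe(xi, xj, paired=False)
                rows.append(
                    (f"{groups[i]}:{t_level} x {groups[j]}:{t_level}", t, p)
                )
    out = pd.DataFrame(rows, columns=["contrast", "t", "p_uncorrected"])
    m = len(out)
    out["p_bonferroni"] = np.minimum(1.0, out["p_uncorrected"] * m)
    return out
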