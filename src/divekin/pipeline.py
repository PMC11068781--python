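"""End-to-end orchestration: calibrate -> read -> gap-fill -> smooth ->
reconstruct -> centre of mass -> events -> variables -> statistics.

Stages run in the field-processing order: 2D keypoints are gap-filled and
low-pass filtered per camera, then triangulated into 3D landmark
trajectories, from which the segmental CM, the dive cycle and the six
outcome variables follow.  Trials that fail a quality rule (over-long gap,
ambiguous side, missing events) are not errors: they are flagged discarded
with a machine-readable reason and excluded from statistics, so
``n_processed = n_kept + n_discarded`` always holds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import stats as dstats
from .body_model import (
    AnthropometricTable,
    CMTrajectory,
    Trajectory3D,
    load_anthropometric_table,
    whole_body_cm,
)
from .calibration import DLTCamera, reconstruct_series
from .dive_events import (
    DiveCycle,
    FootEvents,
    detect_dive_side,
    detect_foot_events,
    estimate_ground_z,
    find_prv,
)
from .dive_variables import DiveVariables, compute_dive_variables
from .errors import (
    AmbiguousSideError,
    BadTrialError,
    DesignError,
    EventWindowError,
    NoDiveError,
    TrialUnusableError,
    UndefinedAngleError,
)
from .pose_io import PoseSequence, fill_gaps
from .smoothing import FilterSpec, butter_lowpass_zerolag, residual_analysis_cutoff
from .synthetic_data import (
    GroundTruth,
    SyntheticDiveSpec,
    generate_dive_3d,
    render_views,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "TrialResult",
    "analyze_trial",
    "analyze_synthetic_trial",
    "trials_to_table",
    "run_study",
    "plot_spm_comparison",
]

VARIABLE_COLUMNS = ["prv", "trprv", "fsd", "dblpp", "fda"]


@dataclass
class RunConfig:
    """Every tunable constant of the pipeline, with its field default."""

    fs: float = 120.0
    conf_min: float = 0.1
    max_gap: int = 12
    filter_fc: float = 7.0
    filter_auto: bool = False
    filter_order: int = 4
    eps: float = 0.03
    k: int = 3
    lookahead: int = 6
    min_side_displacement: float = 0.2
    y_positive_side: str = "left"
    standing_window_s: float = 0.4
    ground_percentile: float = 5.0
    n_nodes: int = 101
    alpha: float = 0.05
    n_perm: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 0.5:
            raise ValueError(f"alpha must lie in (0, 0.5], got {self.alpha}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


@dataclass
class TrialResult:
    """Outcome of one trial: either the variables or a discard reason."""

    trial_id: str
    ok: bool
    reason: str | None = None
    side: str | None = None
    variables: DiveVariables | None = None
    cycle: DiveCycle | None = None
    events: FootEvents | None = None
    trajectory: Trajectory3D | None = field(default=None, repr=False)
    cm: CMTrajectory | None = field(default=None, repr=False)
    filter_fc_used: float | None = None


def _smooth_sequences(
    sequences: list[PoseSequence], config: RunConfig
) -> tuple[list[PoseSequence], float]:
    """Zero-lag filter every keypoint coordinate of every camera stream."""
    fs = sequences[0].fs
    fc = config.filter_fc
    if config.filter_auto:
        # the mid-hip horizontal track of the first camera is a robust,
        # always-visible probe for the residual analysis
        probe = sequences[0].data[:, 8, 0]
        fc = residual_analysis_cutoff(probe, fs, fallback_fc=config.filter_fc)
    spec = FilterSpec(fc=fc, order_net=config.filter_order, fs=fs)
    out = []
    for seq in sequences:
        data = seq.data.copy()
        data[:, :, 0] = butter_lowpass_zerolag(data[:, :, 0], spec, axis=0)
        data[:, :, 1] = butter_lowpass_zerolag(data[:, :, 1], spec, axis=0)
        out.append(PoseSequence(camera_id=seq.camera_id, fs=seq.fs, data=data))
    return out, fc


def analyze_trial(
    sequences: list[PoseSequence],
    cameras: list[DLTCamera],
    config: RunConfig | None = None,
    trial_id: str = "trial",
    table: AnthropometricTable | None = None,
) -> TrialResult:
    """Run the full per-trial chain on in-memory keypoint streams.

    Returns a TrialResult; quality failures come back as
    ``ok=False`` with a reason (``gap``, ``side``, ``events``, ``cycle``)
    rather than raising.
    """
    config = config or RunConfig()
    if len(sequences) < 2 or len(cameras) < 2:
        raise ValueError("analyze_trial needs >= 2 camera streams and cameras")
    if table is None:
        table = load_anthropometric_table()

    try:
        filled = [fill_gaps(s, config.conf_min, config.max_gap)[0] for s in sequences]
    except TrialUnusableError as exc:
        logger.warning("trial %s discarded (gap): %s", trial_id, exc)
        return TrialResult(trial_id=trial_id, ok=False, reason="gap")

    smoothed, fc_used = _smooth_sequences(filled, config)

    uv = np.stack([s.data[:, :, :2] for s in smoothed])  # (C, T, 25, 2)
    by_cam_order = {c.camera_id: i for i, c in enumerate(cameras)}
    order = [by_cam_order[s.camera_id] for s in smoothed]
    cams = [cameras[i] for i in order]
    positions = reconstruct_series(cams, uv)
    traj = Trajectory3D(fs=sequences[0].fs, positions=positions)

    ground_z = estimate_ground_z(
        traj,
        standing_frames=int(round(config.standing_window_s * traj.fs)),
        percentile=config.ground_percentile,
    )
    cm = whole_body_cm(traj, table)

    try:
        side = detect_dive_side(cm, config.min_side_displacement, config.y_positive_side)
    except AmbiguousSideError as exc:
        logger.warning("trial %s discarded (side): %s", trial_id, exc)
        return TrialResult(trial_id=trial_id, ok=False, reason="side")

    try:
        events = detect_foot_events(traj, side, ground_z, config.eps, config.k)
        prv, t_prv = find_prv(
            cm.v_res, events.t_start, events.t_last_contact, config.lookahead
        )
        cycle = DiveCycle(
            side=side,
            t_start=events.t_start,
            t_last_contact=events.t_last_contact,
            t_prv=t_prv,
            n_nodes=config.n_nodes,
        )
    except (NoDiveError, BadTrialError) as exc:
        logger.warning("trial %s discarded (events): %s", trial_id, exc)
        return TrialResult(trial_id=trial_id, ok=False, reason="events", side=side)
    except EventWindowError as exc:
        logger.warning("trial %s discarded (cycle): %s", trial_id, exc)
        return TrialResult(trial_id=trial_id, ok=False, reason="cycle", side=side)

    leg_ref = max(0, int(round(0.5 * config.standing_window_s * traj.fs)))
    try:
        variables = compute_dive_variables(
            traj, cm, side, events, prv, t_prv,
            leg_ref_frame=leg_ref, t_first_contact=0, n_nodes=config.n_nodes,
        )
    except UndefinedAngleError as exc:
        logger.warning("trial %s discarded (angle): %s", trial_id, exc)
        return TrialResult(trial_id=trial_id, ok=False, reason="angle", side=side)

    logger.info(
        "trial %s: side=%s fc=%.2f Hz events=(%d, %d, %d)",
        trial_id, side, fc_used, events.t_start, events.t_last_contact, t_prv,
    )
    return TrialResult(
        trial_id=trial_id,
        ok=True,
        side=side,
        variables=variables,
        cycle=cycle,
        events=events,
        trajectory=traj,
        cm=cm,
        filter_fc_used=fc_used,
    )


def analyze_synthetic_trial(
    spec: SyntheticDiveSpec,
    cameras: list[DLTCamera],
    config: RunConfig | None = None,
    trial_id: str = "synthetic",
) -> tuple[TrialResult, GroundTruth]:
    """Generate a dive, render it through the cameras, run the pipeline."""
    traj, gt = generate_dive_3d(spec)
    sequences = render_views(
        traj, cameras,
        noise_px=spec.noise_px, dropout_rate=spec.dropout_rate, seed=spec.seed,
    )
    result = analyze_trial(sequences, cameras, config, trial_id=trial_id)
    return result, gt


def trials_to_table(results: list[tuple[dict, TrialResult]]) -> pd.DataFrame:
    """Flatten labelled trial results into the per-trial variables table.

    Discarded trials appear with ``ok=False`` and their reason; statistics
    functions only consume the kept rows.
    """
    rows = []
    for labels, res in results:
        row = dict(labels)
        row["trial_id"] = res.trial_id
        row["ok"] = res.ok
        row["reason"] = res.reason
        if res.ok:
            v = res.variables
            row.update(
                prv=v.prv, trprv=v.trprv, fsd=v.fsd, dblpp=v.dblpp, fda=v.fda
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _subject_means(table: pd.DataFrame, value: str, extra: list[str]) -> pd.DataFrame:
    return table.groupby(["subject", *extra], as_index=False)[value].mean()


def run_study(
    table: pd.DataFrame,
    curves: dict[str, np.ndarray] | None = None,
    config: RunConfig | None = None,
) -> dict:
    """The study-level statistics on a per-trial variables table.

    ``table`` needs columns subject, group (CG/VG), condition (pre/post),
    side_class (DLL/NDLL) and the five scalar variables; trials are averaged
    per subject per condition (the pairing unit is the subject).  Produces,
    per variable, the mixed two-way repeated-measures ANOVA with Bonferroni
    contrasts; the DLL-vs-NDLL paired t with Cohen's d; and, when normalized
    curves are supplied (arrays aligned with the table rows under keys like
    ``"v"`` and ``"knee"``), permutation SPM paired-t comparisons for the
    four group/condition contrasts and for laterality.
    """
    config = config or RunConfig()
    required = {"subject", "group", "condition", "side_class"}
    if not required.issubset(table.columns):
        raise DesignError(f"variables table needs columns {sorted(required)}")
    if "ok" in table.columns:
        table = table[table["ok"].astype(bool)]
    groups = set(table["group"].unique())
    if groups != {"CG", "VG"}:
        raise DesignError(f"need both CG and VG groups, found {sorted(groups)}")
    conditions = set(table["condition"].unique())
    if conditions != {"pre", "post"}:
        raise DesignError(f"need both pre and post conditions, found {sorted(conditions)}")

    report: dict = {"anova": {}, "posthoc": {}, "laterality": {}, "spm": {}}
    variables = [c for c in VARIABLE_COLUMNS if c in table.columns]

    for var in variables:
        means = _subject_means(table, var, ["group", "condition"])
        means = means.rename(columns={var: "value", "condition": "time"})
        anova, posthoc = dstats.mixed_anova(means, alpha=config.alpha)
        report["anova"][var] = anova
        report["posthoc"][var] = posthoc

        lat = _subject_means(table, var, ["side_class"]).pivot(
            index="subject", columns="side_class", values=var
        )
        if {"DLL", "NDLL"}.issubset(lat.columns) and lat.notna().all().all():
            report["laterality"][var] = dstats.paired_t(
                lat["DLL"].to_numpy(), lat["NDLL"].to_numpy(), label=f"{var} DLL vs NDLL"
            )

    if curves:
        report["spm"] = _spm_comparisons(table, curves, config)
    return report


def _mean_curves(table, curves_arr, mask_col_values):
    """Per-subject mean curve over the rows matching the given labels."""
    mask = np.ones(len(table), dtype=bool)
    for col, val in mask_col_values.items():
        mask &= (table[col] == val).to_numpy()
    sub = table[mask]
    subjects = sorted(sub["subject"].unique())
    rows = [curves_arr[mask.nonzero()[0]][(sub["subject"] == s).to_numpy()].mean(axis=0)
            for s in subjects]
    return subjects, np.asarray(rows)


def _spm_comparisons(table, curves, config) -> dict:
    """SPM paired-t for the study's curve comparisons, per curve family.

    Within-group pre-vs-post and DLL-vs-NDLL pair subjects with themselves;
    the between-group contrasts at fixed condition pair subjects by their
    within-group order (both groups have the same size in the study design).
    """
    table = table.reset_index(drop=True)
    out: dict = {}
    comparisons = [
        ("CGpre_vs_CGpost", {"group": "CG", "condition": "pre"}, {"group": "CG", "condition": "post"}),
        ("VGpre_vs_VGpost", {"group": "VG", "condition": "pre"}, {"group": "VG", "condition": "post"}),
        ("CGpre_vs_VGpre", {"group": "CG", "condition": "pre"}, {"group": "VG", "condition": "pre"}),
        ("CGpost_vs_VGpost", {"group": "CG", "condition": "post"}, {"group": "VG", "condition": "post"}),
        ("DLL_vs_NDLL", {"side_class": "DLL"}, {"side_class": "NDLL"}),
    ]
    for family, arr in curves.items():
        arr = np.asarray(arr)
        if arr.shape[0] != len(table):
            raise DesignError(
                f"curve family {family!r} has {arr.shape[0]} rows for "
                f"{len(table)} trials"
            )
        out[family] = {}
        for name, sel_a, sel_b in comparisons:
            subs_a, a = _mean_curves(table, arr, sel_a)
            subs_b, b = _mean_curves(table, arr, sel_b)
            if a.shape[0] != b.shape[0] or a.shape[0] < 2:
                continue
            out[family][name] = dstats.spm_paired_t(
                a, b, alpha=config.alpha, n_perm=config.n_perm, seed=config.seed
            )
    return out


def report_to_frames(report: dict) -> dict[str, pd.DataFrame]:
    """Flatten a study report into named DataFrames ready for CSV export."""
    frames: dict[str, pd.DataFrame] = {}
    anova_rows, posthoc_rows, lat_rows, spm_rows = [], [], [], []
    for var, anova in report["anova"].items():
        a = anova.copy()
        a.insert(0, "variable", var)
        anova_rows.append(a)
    for var, ph in report["posthoc"].items():
        p = ph.copy()
        p.insert(0, "variable", var)
        posthoc_rows.append(p)
    for var, res in report["laterality"].items():
        lat_rows.append(
            {
                "variable": var,
                "t": res.statistic,
                "df": res.df,
                "p": res.p_value,
                "d": res.effect_size_d,
            }
        )
    for family, comps in report.get("spm", {}).items():
        for name, spm in comps.items():
            for cl in spm.clusters:
                spm_rows.append(
                    {
                        "family": family,
                        "comparison": name,
                        "t_crit": spm.t_crit,
                        "cluster_start_pct": cl.start_pct,
                        "cluster_end_pct": cl.end_pct,
                        "cluster_p": cl.p_value,
                    }
                )
            if not spm.clusters:
                spm_rows.append(
                    {
                        "family": family,
                        "comparison": name,
                        "t_crit": spm.t_crit,
                        "cluster_start_pct": np.nan,
                        "cluster_end_pct": np.nan,
                        "cluster_p": np.nan,
                    }
                )
    if anova_rows:
        frames["anova"] = pd.concat(anova_rows, ignore_index=True)
    if posthoc_rows:
        frames["posthoc"] = pd.concat(posthoc_rows, ignore_index=True)
    if lat_rows:
        frames["laterality"] = pd.DataFrame(lat_rows)
    if spm_rows:
        frames["spm"] = pd.DataFrame(spm_rows)
    return frames


def write_report(report: dict, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, frame in report_to_frames(report).items():
        frame.to_csv(outdir / f"{name}.csv", index=False)
    manifest = {"tables": sorted(report_to_frames(report))}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def plot_spm_comparison(
    curves_a: np.ndarray,
    curves_b: np.ndarray,
    spm: "dstats.SpmResult",
    path: str | Path,
    labels: tuple[str, str] = ("A", "B"),
    ylabel: str = "value",
) -> None:
    """Two-panel figure: mean +/- SD curves on top, SPM{t} underneath."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.linspace(0, 100, curves_a.shape[1])
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(6, 6), sharex=True)
    for curves, label, color in ((curves_a, labels[0], "C0"), (curves_b, labels[1], "C1")):
        m, s = curves.mean(axis=0), curves.std(axis=0, ddof=1)
        ax1.plot(x, m, color=color, label=label)
        ax1.fill_between(x, m - s, m + s, color=color, alpha=0.25)
    ax1.set_ylabel(ylabel)
    ax1.legend()
    ax2.plot(x, spm.t_curve, "k")
    if np.isfinite(spm.t_crit):
        ax2.axhline(spm.t_crit, ls="--", color="r")
        ax2.axhline(-spm.t_crit, ls="--", color="r")
        for cl in spm.clusters:
            ax2.axvspan(cl.start_pct, cl.end_pct, color="0.8")
    ax2.set_xlabel("dive impulse cycle (%)")
    ax2.set_ylabel("SPM{t}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
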