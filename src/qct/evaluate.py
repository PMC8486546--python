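"""Group comparisons, ROC analysis and the end-to-end study pipeline.

The analysis anchors every subject at the termination time of their tilt
test and evaluates three candidate predictors of (pre)syncope — the windowed
complexity (bits), heart rate (bpm) and mean arterial pressure (mmHg) — at a
fixed grid of offsets before termination (default 300…30 s). Per time point
it reports fainting-vs-non-fainting group comparisons (Student t when both
groups pass a Lilliefors normality gate, Mann–Whitney U otherwise),
empirical ROC curves with DeLong 95% CIs, Youden-optimal and
sensitivity/specificity-constrained cutoffs, and paired DeLong tests of
complexity against each traditional predictor.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.diagnostic import lilliefors

from .complexity import sliding_complexity
from .core import BeatSeries, ComplexitySeries, Outcome
from .dependency import NullEntropyCache
from .errors import InsufficientDataError, ValidationError

__all__ = [
    "Cutoffs",
    "EvaluationTables",
    "GroupComparisonRow",
    "ROCResult",
    "compare_auc_paired",
    "compare_groups",
    "cutoff_analysis",
    "extract_timepoints",
    "mann_whitney_p",
    "normality_gate",
    "roc_auc",
    "run_study",
]

logger = logging.getLogger(__name__)

TIMEPOINTS_DEFAULT: tuple[float, ...] = (300, 270, 240, 210, 180, 150, 120, 90, 60, 30)
VARIABLES: tuple[str, ...] = ("complexity_bits", "hr_bpm", "map_mmhg")


# ---------------------------------------------------------------------------
# Time-point extraction


def extract_timepoints(
    cseries: ComplexitySeries,
    beats: BeatSeries,
    outcome: Outcome,
    timepoints=TIMEPOINTS_DEFAULT,
) -> pd.DataFrame:
    """Sample the three predictors at fixed offsets before termination.

    For each offset tau the target time is hutt_end - tau; values are
    linearly interpolated between the bracketing samples. A target time
    before the first available complexity point yields NaN with a warning; a
    target after the last sample is a hard inconsistency.
    """
    if len(cseries) == 0:
        raise ValidationError(f"{outcome.subject_id}: empty complexity series")
    t_end = outcome.hutt_end_s
    tol = 5.0  # s; termination may fall just past the last emitted beat
    rows = []
    bt = beats.t_s
    hr = beats.beats["hr"].to_numpy(float)
    mp = beats.map_mmhg()
    for tau in timepoints:
        t_star = t_end - tau
        for var, xs, ys in (
            ("complexity_bits", cseries.t_s, cseries.c_bits),
            ("hr_bpm", bt, hr),
            ("map_mmhg", bt, mp),
        ):
            if t_star > xs[-1] + tol:
                raise ValidationError(
                    f"{outcome.subject_id}: target {t_star:.1f}s after last "
                    f"{var} sample ({xs[-1]:.1f}s); termination time "
                    "inconsistent with data"
                )
            if t_star < xs[0]:
                warnings.warn(
                    f"{outcome.subject_id}: {var} unavailable {tau:.0f}s "
                    "before termination",
                    stacklevel=2,
                )
                val = math.nan
            else:
                val = float(np.interp(min(t_star, xs[-1]), xs, ys))
            rows.append(
                {
                    "subject_id": outcome.subject_id,
                    "timepoint_s": float(tau),
                    "variable": var,
                    "value": val,
                    "syncope": bool(outcome.syncope),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Distribution tests


def normality_gate(values) -> bool:
    """Lilliefors-corrected KS normality gate at the 5% level.

    True iff the sample is consistent with a normal whose mean/SD are
    estimated from it (p > 0.05). Degenerate samples (n < 4 or zero
    variance) fail the gate with a warning.
    """
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if len(v) < 4:
        warnings.warn("normality gate: n < 4, returning False", stacklevel=2)
        return False
    if np.ptp(v) == 0:
        return False
    _, p = lilliefors(v, dist="norm")
    return bool(p > 0.05)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x over y via midranks (ties count 1/2)."""
    ranks = stats.rankdata(np.concatenate([x, y]))
    n1 = len(x)
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


_ENUM_LIMIT = 200_000


def mann_whitney_p(x, y) -> tuple[float, str]:
    """Two-sided Mann-Whitney U p-value and the path used.

    Exact by full enumeration of group assignments (valid with ties, via
    midranks) when C(n1+n2, n1) is small; exact by the no-ties recurrence
    when n1*n2 <= 400 and there are no ties; otherwise the tie-corrected
    normal approximation. The two-sided exact p is P(|U - mu| >= |U_obs - mu|),
    which matches the doubled-tail convention for the symmetric null.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    u_obs = _u_statistic(x, y)
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < n1 + n2

    if math.comb(n1 + n2, n1) <= _ENUM_LIMIT:
        ranks = stats.rankdata(pooled)
        dev_obs = abs(u_obs - mu)
        hits = total = 0
        offset = n1 * (n1 + 1) / 2.0
        for idx in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - offset
            hits += abs(u - mu) >= dev_obs - 1e-12
            total += 1
        return hits / total, "exact-enumeration"
    if not has_ties and n1 * n2 <= 400:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.pvalue), "exact"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue), "asymptotic"


@dataclass(frozen=True)
class GroupComparisonRow:
    mean_yes: float
    sd_yes: float
    n_yes: int
    mean_no: float
    sd_no: float
    n_no: int
    test_used: str  # "t" or "mann_whitney"
    p_value: float


def compare_groups(values_yes, values_no) -> GroupComparisonRow:
    """Fainting-vs-non-fainting comparison with a normality-gated test.

    Pooled-variance two-sided Student t when both groups pass the
    normality gate, else two-sided Mann-Whitney U.
    """
    vy = np.asarray(values_yes, float)
    vn = np.asarray(values_no, float)
    vy = vy[np.isfinite(vy)]
    vn = vn[np.isfinite(vn)]
    if len(vy) < 2 or len(vn) < 2:
        raise ValidationError("both groups need n >= 2 finite values")
    if normality_gate(vy) and normality_gate(vn):
        test = "t"
        _, p = stats.ttest_ind(vy, vn, equal_var=True)
        p = float(p)
    else:
        test = "mann_whitney"
        p, _ = mann_whitney_p(vy, vn)
    return GroupComparisonRow(
        mean_yes=float(vy.mean()),
        sd_yes=float(vy.std(ddof=1)),
        n_yes=len(vy),
        mean_no=float(vn.mean()),
        sd_no=float(vn.std(ddof=1)),
        n_no=len(vn),
        test_used=test,
        p_value=min(1.0, p),
    )


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong variance


def _placements(pos: np.ndarray, neg: np.ndarray):
    """DeLong structural components (placement values) and the AUC."""
    m, n = len(pos), len(neg)
    all_r = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    v10 = (all_r[:m] - r_pos) / n          # per-positive placements
    v01 = 1.0 - (all_r[m:] - r_neg) / m    # per-negative placements
    auc = float(v10.mean())
    return auc, v10, v01


def _split(values: np.ndarray, labels: np.ndarray):
    values = np.asarray(values, float)
    labels = np.asarray(labels).astype(bool)
    if values.shape != labels.shape:
        raise ValidationError("values/labels length mismatch")
    if not np.all(np.isfinite(values)):
        raise ValidationError("non-finite predictor values")
    pos = values[labels]
    neg = values[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both classes must be present")
    return pos, neg


@dataclass
class Cutoffs:
    """Youden-optimal and constrained operating points of one ROC."""

    optimal_cutoff: float
    sens: float
    spec: float
    cutoff_sens_floor: float | None
    spec_at_sens_floor: float | None
    cutoff_spec_floor: float | None
    sens_at_spec_floor: float | None


@dataclass
class ROCResult:
    auc: float
    ci95_low: float
    ci95_high: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    var_auc: float
    pos: np.ndarray = field(repr=False, default=None)
    neg: np.ndarray = field(repr=False, default=None)
    cutoffs: Cutoffs | None = None


def roc_auc(values, labels) -> ROCResult:
    """Empirical ROC with trapezoid AUC and DeLong 95% CI.

    The orientation is fixed a priori — higher values point toward syncope —
    so an anti-predictive variable yields AUC < 0.5 rather than being
    silently flipped. Ties between a positive and a negative contribute 1/2.
    """
    pos, neg = _split(np.asarray(values, float), np.asarray(labels))
    auc, v10, v01 = _placements(pos, neg)
    var = 0.0
    if len(pos) > 1:
        var += v10.var(ddof=1) / len(pos)
    if len(neg) > 1:
        var += v01.var(ddof=1) / len(neg)
    se = math.sqrt(var)
    lo = max(0.0, auc - 1.959963984540054 * se)
    hi = min(1.0, auc + 1.959963984540054 * se)
    fpr, tpr, thr = _sk_roc_curve(
        np.concatenate([np.ones(len(pos)), np.zeros(len(neg))]),
        np.concatenate([pos, neg]),
        drop_intermediate=False,
    )
    return ROCResult(
        auc=auc, ci95_low=lo, ci95_high=hi,
        fpr=fpr, tpr=tpr, thresholds=thr, var_auc=var, pos=pos, neg=neg,
    )


def compare_auc_paired(values_a, values_b, labels) -> float:
    """Two-sided paired DeLong test for two predictors on the same subjects."""
    values_a = np.asarray(values_a, float)
    values_b = np.asarray(values_b, float)
    labels = np.asarray(labels).astype(bool)
    if values_a.shape != values_b.shape or values_a.shape != labels.shape:
        raise ValidationError("paired comparison needs matched subject sets")
    pos_a, neg_a = _split(values_a, labels)
    pos_b, neg_b = _split(values_b, labels)
    auc_a, v10_a, v01_a = _placements(pos_a, neg_a)
    auc_b, v10_b, v01_b = _placements(pos_b, neg_b)
    m, n = len(pos_a), len(neg_a)
    var = 0.0
    if m > 1:
        s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
        var += (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
    if n > 1:
        s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
        var += (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        return 1.0 if diff == 0 else 0.0
    z = diff / math.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def cutoff_analysis(
    roc: ROCResult, sens_floor: float = 0.80, spec_floor: float = 0.80
) -> Cutoffs:
    """Operating-point tables for one ROC.

    Candidate thresholds are the midpoints between consecutive distinct
    observed values; a subject is called positive when value >= threshold.
    "Optimal" maximises Youden's J = sens + spec - 1 (ties: lowest
    threshold); the constrained cutoffs are the highest threshold whose
    sensitivity still exceeds ``sens_floor`` and the lowest whose
    specificity exceeds ``spec_floor``. Unattainable constraints are
    reported as None.
    """
    pos, neg = roc.pos, roc.neg
    uniq = np.unique(np.concatenate([pos, neg]))
    if len(uniq) < 2:
        raise ValidationError("cutoff analysis needs >= 2 distinct values")
    thr = (uniq[:-1] + uniq[1:]) / 2.0
    sens = (pos[None, :] >= thr[:, None]).mean(axis=1)
    spec = (neg[None, :] < thr[:, None]).mean(axis=1)
    j = sens + spec - 1.0
    best = int(np.flatnonzero(j == j.max())[0])  # ties -> lowest threshold

    ok_sens = np.flatnonzero(sens > sens_floor)
    if len(ok_sens):
        k = int(ok_sens[-1])  # highest qualifying threshold
        c_sens, s_at = float(thr[k]), float(spec[k])
    else:
        c_sens = s_at = None
    ok_spec = np.flatnonzero(spec > spec_floor)
    if len(ok_spec):
        k = int(ok_spec[0])  # lowest qualifying threshold
        c_spec, sn_at = float(thr[k]), float(sens[k])
    else:
        c_spec = sn_at = None
    return Cutoffs(
        optimal_cutoff=float(thr[best]),
        sens=float(sens[best]),
        spec=float(spec[best]),
        cutoff_sens_floor=c_sens,
        spec_at_sens_floor=s_at,
        cutoff_spec_floor=c_spec,
        sens_at_spec_floor=sn_at,
    )


# ---------------------------------------------------------------------------
# Study orchestration


@dataclass
class EvaluationTables:
    """All study outputs: long value table plus the three report tables."""

    timepoint_values: pd.DataFrame
    group_comparison: pd.DataFrame
    roc: pd.DataFrame
    cutoffs: pd.DataFrame
    summary: dict
    exclusions: list


def run_study(
    series_list: list[BeatSeries],
    outcomes: list[Outcome],
    config=None,
    complexity_series: dict[str, ComplexitySeries] | None = None,
) -> EvaluationTables:
    """End-to-end analysis of a cohort.

    Computes (or accepts precomputed) sliding complexity per subject,
    extracts the predictor values at the configured time points, and builds
    the group-comparison, ROC and cutoff tables. Subjects that fail
    (insufficient beats, inconsistent termination time) are excluded and
    reported, not fatal.
    """
    from .io_core import StudyConfig  # local import to avoid a cycle

    cfg = config or StudyConfig()
    by_id = {o.subject_id: o for o in outcomes}
    dep_cfg = cfg.dependency_config()
    cache = NullEntropyCache(seed=dep_cfg.seed, n_null=dep_cfg.null_permutations)

    frames = []
    exclusions = []
    for series in series_list:
        outcome = by_id.get(series.subject_id)
        if outcome is None:
            exclusions.append((series.subject_id, "no outcome row"))
            continue
        try:
            if complexity_series and series.subject_id in complexity_series:
                cs = complexity_series[series.subject_id]
            else:
                start = (
                    outcome.hutt_end_s - cfg.tail_s
                    if cfg.tail_s is not None
                    else None
                )
                cs = sliding_complexity(
                    series,
                    window_size=cfg.window_size,
                    stride=cfg.stride,
                    dep_cfg=dep_cfg,
                    cache=cache,
                    start_t_s=start,
                )
            frames.append(extract_timepoints(cs, series, outcome, cfg.timepoints))
        except (ValidationError, InsufficientDataError) as exc:
            logger.warning("excluding %s: %s", series.subject_id, exc)
            exclusions.append((series.subject_id, str(exc)))
    if not frames:
        raise InsufficientDataError("no subject produced usable time-point data")
    values = pd.concat(frames, ignore_index=True)

    n_yes = values.loc[values["syncope"], "subject_id"].nunique()
    n_no = values.loc[~values["syncope"], "subject_id"].nunique()
    if n_yes < 2 or n_no < 2:
        raise InsufficientDataError(
            f"need >= 2 subjects per group (got {n_yes} syncope / {n_no} control)"
        )

    gc_rows, roc_rows, cut_rows = [], [], []
    for tau in cfg.timepoints:
        sub = values[values["timepoint_s"] == float(tau)]
        wide = sub.pivot(index="subject_id", columns="variable", values="value")
        lab = sub.drop_duplicates("subject_id").set_index("subject_id")["syncope"]
        lab = lab.reindex(wide.index)
        roc_by_var: dict[str, ROCResult] = {}
        complete = wide.dropna()
        lab_c = lab.reindex(complete.index).to_numpy()
        for var in VARIABLES:
            col = wide[var]
            ok = col.notna()
            row = compare_groups(col[ok & lab], col[ok & ~lab])
            gc_rows.append(
                {"timepoint_s": float(tau), "variable": var,
                 "mean_yes": row.mean_yes, "sd_yes": row.sd_yes,
                 "n_yes": row.n_yes, "mean_no": row.mean_no,
                 "sd_no": row.sd_no, "n_no": row.n_no,
                 "test": row.test_used, "p": row.p_value}
            )
            roc_by_var[var] = roc_auc(
                complete[var].to_numpy(), lab_c
            )
        for var in VARIABLES:
            r = roc_by_var[var]
            p_vs = (
                math.nan
                if var == "complexity_bits"
                else compare_auc_paired(
                    complete["complexity_bits"].to_numpy(),
                    complete[var].to_numpy(),
                    lab_c,
                )
            )
            roc_rows.append(
                {"timepoint_s": float(tau), "variable": var, "auc": r.auc,
                 "ci_low": r.ci95_low, "ci_high": r.ci95_high,
                 "p_vs_complexity": p_vs}
            )
        cuts = cutoff_analysis(
            roc_by_var["complexity_bits"], cfg.sens_floor, cfg.spec_floor
        )
        cut_rows.append(
            {"timepoint_s": float(tau),
             "optimal_cutoff": cuts.optimal_cutoff,
             "sens": cuts.sens, "spec": cuts.spec,
             "cutoff_sens80": _na(cuts.cutoff_sens_floor),
             "spec_at_sens80": _na(cuts.spec_at_sens_floor),
             "cutoff_spec80": _na(cuts.cutoff_spec_floor),
             "sens_at_spec80": _na(cuts.sens_at_spec_floor)}
        )

    group_comparison = pd.DataFrame(gc_rows)
    roc_df = pd.DataFrame(roc_rows)
    cutoffs_df = pd.DataFrame(cut_rows)
    summary = {
        "n_syncope": int(n_yes),
        "n_control": int(n_no),
        "n_excluded": len(exclusions),
        "exclusions": [list(e) for e in exclusions],
        "timepoints_s": [float(t) for t in cfg.timepoints],
        "auc": {
            var: {
                str(int(t)): float(
                    roc_df.loc[
                        (roc_df.timepoint_s == float(t)) & (roc_df.variable == var),
                        "auc",
                    ].iloc[0]
                )
                for t in cfg.timepoints
            }
            for var in VARIABLES
        },
    }
    return EvaluationTables(
        timepoint_values=values,
        group_comparison=group_comparison,
        roc=roc_df,
        cutoffs=cutoffs_df,
        summary=summary,
        exclusions=exclusions,
    )


def _na(v):
    return math.nan if v is None else v
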