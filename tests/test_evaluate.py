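"""Tests for the statistical evaluation stage."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from qct.core import ComplexitySeries, Outcome
from qct.errors import ValidationError
from qct.evaluate import (
    compare_auc_paired,
    compare_groups,
    cutoff_analysis,
    extract_timepoints,
    mann_whitney_p,
    normality_gate,
    roc_auc,
)
from tests.conftest import make_beats


# --- time-point extraction ---------------------------------------------------

def make_cseries(t, c):
    return ComplexitySeries(
        t_s=np.asarray(t, float), c_bits=np.asarray(c, float),
        window_size=100, stride=1, subject_id="s1",
    )


def test_extraction_at_knot_and_midpoint():
    beats = make_beats(n=700, hr=60.0)  # beats at t = 0..699 s
    t_end = beats.t_s[-1]
    outcome = Outcome("test", True, float(t_end))
    cs = make_cseries(np.arange(99.0, 700.0), np.linspace(400, 1001, 601))
    rows = extract_timepoints(cs, beats, outcome, timepoints=(0.0, 300.0))
    df = rows.set_index(["timepoint_s", "variable"])["value"]
    # tau = 0 on a series ending exactly at hutt_end -> last sample
    assert df[(0.0, "complexity_bits")] == pytest.approx(cs.c_bits[-1])
    assert df[(0.0, "hr_bpm")] == pytest.approx(60.0)
    assert df[(0.0, "map_mmhg")] == pytest.approx(80.0 + 40.0 / 3.0)

    # midway between two complexity samples with values 400 and 600 -> 500
    cs2 = make_cseries([100.0, 200.0], [400.0, 600.0])
    out2 = Outcome("s1", True, 450.0)
    rows2 = extract_timepoints(cs2, beats, out2, timepoints=(300.0,))
    v = rows2.loc[rows2.variable == "complexity_bits", "value"].iloc[0]
    assert v == pytest.approx(500.0)


def test_extraction_missing_and_inconsistent():
    beats = make_beats(n=700, hr=60.0)
    cs = make_cseries([600.0, 650.0], [1.0, 2.0])
    out = Outcome("s1", True, 699.0)
    with pytest.warns(UserWarning, match="unavailable"):
        rows = extract_timepoints(cs, beats, out, timepoints=(300.0,))
    assert math.isnan(
        rows.loc[rows.variable == "complexity_bits", "value"].iloc[0]
    )
    with pytest.raises(ValidationError, match="inconsistent"):
        extract_timepoints(cs, beats, Outcome("s1", True, 2000.0),
                           timepoints=(30.0,))


# --- normality gate ----------------------------------------------------------

def test_normality_gate_level():
    passed = sum(
        normality_gate(np.random.default_rng(s).standard_normal(500))
        for s in range(100)
    )
    assert passed >= 90


def test_normality_gate_rejects_gross_nonnormality():
    rng = np.random.default_rng(0)
    two_point = rng.choice([0.0, 10.0], size=200)
    assert not normality_gate(two_point)
    assert not normality_gate(np.full(50, 3.0))
    with pytest.warns(UserWarning):
        assert not normality_gate([1.0, 2.0, 3.0])


# --- group comparison --------------------------------------------------------

def test_identical_samples_p_one():
    row = compare_groups([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
    assert row.p_value == pytest.approx(1.0)


def test_mwu_matches_rank_assignment_enumeration():
    """Exact p on (4,3) data equals brute-force enumeration of C(7,4) splits."""
    x = [1.2, 3.4, 5.6, 9.9]
    y = [0.7, 2.2, 8.8]
    p, path = mann_whitney_p(x, y)
    assert path.startswith("exact")

    pooled = np.array(x + y)
    n1 = len(x)
    mu = n1 * len(y) / 2.0

    def u_of(idx):
        grp = pooled[list(idx)]
        rest = pooled[[i for i in range(len(pooled)) if i not in idx]]
        return sum((a > b) + 0.5 * (a == b) for a in grp for b in rest)

    u_obs = u_of(range(n1))
    hits = [
        abs(u_of(c) - mu) >= abs(u_obs - mu)
        for c in itertools.combinations(range(len(pooled)), n1)
    ]
    assert p == pytest.approx(np.mean(hits), abs=1e-12)


def test_group_shift_detected_with_power():
    """2-SD mean shift at n = 54 vs 27 gives p < 0.001 in >= 99% of seeds."""
    hits = 0
    for s in range(100):
        rng = np.random.default_rng(s)
        a = rng.normal(2.0, 1.0, 54)
        b = rng.normal(0.0, 1.0, 27)
        hits += compare_groups(a, b).p_value < 0.001
    assert hits >= 99


def test_compare_groups_validation():
    with pytest.raises(ValidationError):
        compare_groups([1.0], [1.0, 2.0])


# --- ROC / AUC ---------------------------------------------------------------

def pairwise_auc_oracle(pos, neg):
    s = 0.0
    for p in pos:
        for n in neg:
            s += 1.0 if p > n else (0.5 if p == n else 0.0)
    return s / (len(pos) * len(neg))


def test_auc_matches_pairwise_oracle(rng):
    for trial in range(20):
        n1, n2 = rng.integers(2, 26, 2)
        pos = np.round(rng.normal(0.5, 1, n1), 1)  # rounding creates ties
        neg = np.round(rng.normal(0.0, 1, n2), 1)
        values = np.concatenate([pos, neg])
        labels = np.r_[np.ones(n1), np.zeros(n2)].astype(bool)
        r = roc_auc(values, labels)
        assert r.auc == pytest.approx(pairwise_auc_oracle(pos, neg), abs=1e-12)
        # trapezoid over the empirical curve agrees with the pair count
        assert np.trapezoid(r.tpr, r.fpr) == pytest.approx(r.auc, abs=1e-12)


def test_perfect_separation():
    r = roc_auc([1, 2, 3, 10, 11, 12], [True] * 3 + [False] * 3)
    assert r.auc == 0.0  # higher-value-positive orientation is fixed
    r = roc_auc([10, 11, 12, 1, 2, 3], [True] * 3 + [False] * 3)
    assert r.auc == 1.0 and r.ci95_high == 1.0 and r.ci95_low <= 1.0


def test_roc_curve_contract(rng):
    for _ in range(10):
        v = np.round(rng.normal(size=30), 1)
        lab = rng.random(30) < 0.4
        if lab.all() or not lab.any():
            continue
        r = roc_auc(v, lab)
        assert (r.fpr[0], r.tpr[0]) == (0.0, 0.0)
        assert (r.fpr[-1], r.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)


def test_null_auc_calibration():
    aucs = []
    for s in range(1000):
        rng = np.random.default_rng(s)
        v = rng.normal(size=30)
        lab = np.r_[np.ones(10), np.zeros(20)].astype(bool)
        aucs.append(roc_auc(v, lab).auc)
    se = np.std(aucs) / np.sqrt(len(aucs))
    assert abs(np.mean(aucs) - 0.5) <= 3 * se


def test_single_class_rejected():
    with pytest.raises(ValidationError):
        roc_auc([1.0, 2.0], [True, True])


# --- cutoffs -----------------------------------------------------------------

def test_cutoffs_perfect_separation():
    r = roc_auc([10, 11, 12, 1, 2, 3], [True] * 3 + [False] * 3)
    c = cutoff_analysis(r)
    assert 3 < c.optimal_cutoff < 10
    assert c.sens == 1.0 and c.spec == 1.0


def test_cutoff_exhaustive_scan():
    r = roc_auc([1.0, 2.0, 3.0, 4.0], [False, False, True, True])
    c = cutoff_analysis(r)
    assert 2.0 < c.optimal_cutoff < 3.0
    # exhaustive scan over midpoint thresholds confirms the Youden optimum
    pos, neg = np.array([3.0, 4.0]), np.array([1.0, 2.0])
    best = max(
        (np.mean(pos >= t) + np.mean(neg < t) - 1, -t)
        for t in (1.5, 2.5, 3.5)
    )
    assert -best[1] == c.optimal_cutoff


def test_cutoff_unattainable_floor():
    r = roc_auc([1.0, 2.0, 3.0, 4.0], [False, False, True, True])
    c = cutoff_analysis(r, sens_floor=1.01)
    assert c.cutoff_sens_floor is None and c.spec_at_sens_floor is None


# --- paired DeLong -----------------------------------------------------------

def test_paired_delong_identity_and_symmetry(rng):
    v = rng.normal(size=40)
    lab = np.r_[np.ones(15), np.zeros(25)].astype(bool)
    assert compare_auc_paired(v, v, lab) == pytest.approx(1.0)
    w = rng.normal(size=40)
    assert compare_auc_paired(v, w, lab) == pytest.approx(
        compare_auc_paired(w, v, lab)
    )


def test_paired_delong_power():
    """Perfect predictor vs noise at n = 81: significant in >= 95% of seeds."""
    hits = 0
    lab = np.r_[np.ones(54), np.zeros(27)].astype(bool)
    for s in range(100):
        rng = np.random.default_rng(s)
        a = lab + 0.1 * rng.random(81)  # separates perfectly
        b = rng.normal(size=81)
        hits += compare_auc_paired(a, b, lab) < 0.05
    assert hits >= 95


def test_paired_delong_unmatched_rejected(rng):
    with pytest.raises(ValidationError):
        compare_auc_paired(rng.normal(size=10), rng.normal(size=9),
                           np.r_[np.ones(5), np.zeros(5)].astype(bool))
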