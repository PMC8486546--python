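"""Unit and property tests for the generalised-correlation detector."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qct.dependency import (
    DependencyConfig,
    NullEntropyCache,
    adjacency_and_entropy,
    image_entropy,
    quantile_bin_indices,
    scatter_to_image,
    structure_test,
)
from qct.errors import ValidationError


# --- oracles -----------------------------------------------------------------

def oracle_bin_assignment(x, bins):
    """Independent rank binning: position in the stable sort order."""
    n = len(x)
    order = sorted(range(n), key=lambda i: (x[i], i))
    b = [0] * n
    for pos, i in enumerate(order):
        b[i] = pos * bins // n
    return b


def oracle_image(x, y, bins):
    """Direct double-loop 2-D histogram of the rank-binned scatter."""
    bx = oracle_bin_assignment(x, bins)
    by = oracle_bin_assignment(y, bins)
    counts = np.zeros((bins, bins), dtype=int)
    for i in range(len(x)):
        counts[bx[i], by[i]] += 1
    return counts


def oracle_entropy(counts):
    n = counts.sum()
    h = 0.0
    for c in counts.ravel():
        if c > 0:
            p = c / n
            h -= p * np.log2(p)
    return h


# --- scatter_to_image --------------------------------------------------------

def test_monotone_pair_fills_diagonal():
    x = np.linspace(0.0, 5.0, 100)
    img = scatter_to_image(x, x, bins=10)
    assert np.array_equal(np.diag(img.counts), np.full(10, 10))
    assert img.counts.sum() == 100 and np.count_nonzero(img.counts) == 10


def test_image_matches_bruteforce_histogram():
    x = np.arange(1.0, 13.0)
    y = np.repeat([1.0, 2.0, 3.0, 4.0], 3)
    img = scatter_to_image(x, y, bins=4)
    assert np.array_equal(img.counts, oracle_image(x, y, 4))

    rng = np.random.default_rng(5)
    for n, bins in ((37, 5), (100, 10), (200, 8)):
        xs = rng.normal(size=n)
        ys = np.round(rng.normal(size=n), 1)  # ties on y
        got = scatter_to_image(xs, ys, bins=bins)
        assert np.array_equal(got.counts, oracle_image(xs, ys, bins))
        assert got.counts.sum() == n


def test_scatter_validation():
    with pytest.raises(ValidationError):
        scatter_to_image([1.0, 2.0], [1.0], bins=2)
    with pytest.raises(ValidationError):
        scatter_to_image([1.0, np.nan, 3.0], [1.0, 2.0, 3.0], bins=2)
    with pytest.warns(UserWarning, match="constant"):
        img = scatter_to_image(np.ones(20), np.arange(20.0), bins=4)
    # a constant vector still conserves mass (spread by order of occurrence)
    assert img.counts.sum() == 20


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    st.lists(st.integers(-10**6, 10**6), min_size=12, max_size=80, unique=True),
    st.lists(st.integers(-10**6, 10**6), min_size=12, max_size=80, unique=True),
    st.sampled_from(
        [lambda v: 2.0 * v + 1.0, lambda v: v**3, lambda v: np.tanh(v / 1e6)]
    ),
)
def test_monotone_transform_invariance(xs, ys, f):
    """Rank binning makes the image invariant under increasing transforms.

    Inputs are well-separated values, so the transforms stay strictly
    increasing in floating point too.
    """
    n = min(len(xs), len(ys))
    x = np.array(xs[:n], dtype=float)
    y = np.array(ys[:n], dtype=float)
    base = scatter_to_image(x, y, bins=4).counts
    assert np.array_equal(scatter_to_image(f(x), y, bins=4).counts, base)
    assert np.array_equal(scatter_to_image(x, f(y), bins=4).counts, base)


# --- image_entropy -----------------------------------------------------------

def test_entropy_examples():
    one = np.zeros((10, 10), dtype=int)
    one[3, 7] = 57
    assert image_entropy(type("I", (), {"counts": one, "n": 57})) == 0.0
    uniform = scatter_to_image(np.arange(100.0), np.arange(100.0), bins=10)
    # 10 diagonal pixels with 10 points each -> entropy log2(10)
    assert image_entropy(uniform) == pytest.approx(np.log2(10), abs=1e-12)
    three = np.array([[50, 25, 25]])
    assert image_entropy(type("I", (), {"counts": three, "n": 100})) == pytest.approx(
        1.5, abs=1e-12
    )


def test_entropy_and_mi_match_double_loop_oracle(rng):
    for n in (20, 57, 100, 200):
        for bins in (4, 10):
            if n < bins:
                continue
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            img = scatter_to_image(x, y, bins=bins)
            assert image_entropy(img) == pytest.approx(
                oracle_entropy(img.counts), abs=1e-12
            )
            res = structure_test(x, y, bins=bins, rng_seed=3)
            hx = oracle_entropy(img.counts.sum(axis=1))
            hy = oracle_entropy(img.counts.sum(axis=0))
            mi_oracle = hx + hy - oracle_entropy(img.counts)
            assert res.mi_bits == pytest.approx(max(0.0, mi_oracle), abs=1e-12)


def test_entropy_bounds_quantile_binning(rng):
    """For n a multiple of bins: log2(B) <= H <= 2 log2(B), MI in [0, log2 B]."""
    for _ in range(20):
        x = rng.normal(size=100)
        y = rng.normal(size=100)
        img = scatter_to_image(x, y, bins=10)
        h = image_entropy(img)
        assert np.log2(10) - 1e-12 <= h <= 2 * np.log2(10) + 1e-12
        res = structure_test(x, y, bins=10, rng_seed=1)
        assert 0.0 <= res.mi_bits <= np.log2(10) + 1e-12


# --- structure_test ----------------------------------------------------------

def test_perfect_dependence():
    x = np.linspace(0, 1, 100)
    res = structure_test(x, x, bins=10, rng_seed=0)
    assert res.structured
    assert res.strength == pytest.approx(1.0)
    assert res.mi_bits == pytest.approx(np.log2(10), abs=1e-12)


def test_nonmonotone_dependence_detected(rng):
    """A symmetric U-shape has Pearson r ~ 0 but a structured image."""
    x = np.linspace(-1, 1, 100)
    y = x**2
    assert abs(np.corrcoef(x, y)[0, 1]) < 0.05
    res = structure_test(x, y, bins=10, rng_seed=0)
    assert res.structured
    assert res.mi_bits > 1.0


def test_false_positive_rate_under_independence():
    alpha, trials = 0.05, 500
    hits = 0
    for t in range(trials):
        r = np.random.default_rng(1000 + t)
        res = structure_test(
            r.normal(size=100), r.normal(size=100), bins=10, n_null=200,
            alpha=alpha, rng_seed=2000 + t,
        )
        hits += res.structured
    bound = alpha + 3 * np.sqrt(alpha * (1 - alpha) / trials)
    assert hits / trials <= bound


def test_degenerate_constant_channel():
    with pytest.warns(UserWarning, match="degenerate"):
        res = structure_test(np.ones(50), np.arange(50.0), bins=5, rng_seed=0)
    assert not res.structured and res.strength == 0.0 and res.mi_bits == 0.0


def test_structure_test_reproducible(rng):
    x, y = rng.normal(size=100), rng.normal(size=100)
    a = structure_test(x, y, rng_seed=42)
    b = structure_test(x, y, rng_seed=42)
    assert a == b


# --- adjacency_and_entropy ---------------------------------------------------

def test_adjacency_symmetry_and_diagonal(rng):
    w = rng.normal(size=(100, 5))
    s, e = adjacency_and_entropy(w, DependencyConfig(seed=1))
    assert np.array_equal(s, s.T) and np.allclose(e, e.T)
    assert np.all(np.diag(s) == 0) and np.all(np.diag(e) == 0)
    s2, e2 = adjacency_and_entropy(w, DependencyConfig(seed=1, include_diagonal=True))
    assert np.all(np.diag(s2) == 1)
    assert np.all(np.diag(e2) > 3.3)  # marginal entropies ~ log2(10)


def test_adjacency_duplicate_channel(rng):
    w = rng.normal(size=(100, 4))
    w[:, 3] = w[:, 0]
    s, e = adjacency_and_entropy(w, DependencyConfig(seed=0))
    assert s[0, 3] == 1
    assert e[0, 3] == pytest.approx(np.log2(10), abs=1e-9)


def test_adjacency_noise_density(rng):
    """Off-diagonal density of S under independence stays near alpha."""
    cfg = DependencyConfig(seed=9, alpha=0.05)
    cache = NullEntropyCache(seed=9, n_null=200)
    dens = []
    for _ in range(40):
        s, _ = adjacency_and_entropy(rng.normal(size=(100, 6)), cfg, cache=cache)
        dens.append(s.sum() / (6 * 5))
    n_pairs = 40 * 15
    assert np.mean(dens) <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_pairs)


def test_adjacency_modes_agree_on_strong_structure(rng):
    """Shared-cache and fresh-permutation nulls make the same calls on
    clearly structured and clearly independent pairs."""
    w = rng.normal(size=(100, 3))
    w[:, 1] = w[:, 0] + 0.1 * rng.normal(size=100)
    s_shared, _ = adjacency_and_entropy(w, DependencyConfig(seed=4))
    s_fresh, _ = adjacency_and_entropy(
        w, DependencyConfig(seed=4, null_mode="fresh"), end_t_s=10.0
    )
    assert s_shared[0, 1] == 1 and s_fresh[0, 1] == 1


def test_adjacency_degenerate_zero_row():
    w = np.column_stack([np.ones(100), np.arange(100.0), np.arange(100.0) ** 2])
    s, e = adjacency_and_entropy(w, DependencyConfig(seed=0))
    assert np.all(s[0] == 0) and np.all(e[0] == 0)
    assert s[1, 2] == 1  # monotone pair still detected
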