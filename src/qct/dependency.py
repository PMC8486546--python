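"""Generalised-correlation detection between channel pairs.

A pair of channels is tested for interdependency by turning their scatter
plot into a small image: each axis is rank-binned into ``bins`` classes of
near-equal occupancy and the joint bin counts form a ``bins x bins`` pixel
grid whose intensity is the number of points per pixel. A *structured* image
(mass concentrated in few pixels, hence low Shannon entropy) indicates
dependence of any form — linear, non-linear or non-monotone — whereas an
independent pair produces a near-uniform, high-entropy image. Because the
binning is by rank, the detector is invariant under any strictly increasing
transform of either variable and insensitive to outliers and units.

The structured/chaotic decision is made against a permutation null: the
entropy of the observed image is compared with the empirical distribution of
entropies obtained by randomly re-pairing the two variables. The pair's
information content is the plug-in mutual information of the binned image,
in bits, which is the entry written into the entropy matrix E; the binary
structured flag is the entry of the adjacency matrix S.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, ValidationError

__all__ = [
    "DependencyConfig",
    "DependencyImage",
    "DependencyResult",
    "NullEntropyCache",
    "adjacency_and_entropy",
    "image_entropy",
    "quantile_bin_indices",
    "scatter_to_image",
    "structure_test",
]


@dataclass
class DependencyConfig:
    """Settings for the pairwise dependency test.

    bins
        Image resolution per axis (default 10: ~10 points per marginal bin
        for the default 100-sample window, and an entropy floor of exactly
        log2(10) bits under perfect monotone dependence).
    null_permutations
        Monte-Carlo sample size for the permutation null.
    alpha
        Significance level of the structured/chaotic decision.
    include_diagonal
        If True, S_ii = 1 and E_ii = marginal bin entropy H(x_i); by default
        the diagonal is zero so a fully independent system has complexity 0.
    null_mode
        "shared": reuse one cached null entropy sample per distinct
        (n, bins, marginal occupancies) signature — exact under rank binning,
        since the null law depends on the data only through those margins.
        "fresh": draw a new seeded null per (window, pair).
    """

    bins: int = 10
    null_permutations: int = 200
    alpha: float = 0.05
    include_diagonal: bool = False
    seed: int = 0
    null_mode: str = "shared"

    def __post_init__(self) -> None:
        if self.bins < 2:
            raise ConfigError("bins must be >= 2")
        if self.null_permutations < 39:
            raise ConfigError("null_permutations must be >= 39")
        if not 0.0 < self.alpha < 0.5:
            raise ConfigError("alpha must lie in (0, 0.5)")
        if self.null_mode not in ("shared", "fresh"):
            raise ConfigError(f"unknown null_mode {self.null_mode!r}")


@dataclass(frozen=True)
class DependencyImage:
    """Binned scatter image: counts[i, j] = points in pixel (i, j)."""

    counts: np.ndarray  # (bins, bins) non-negative ints
    n: int


@dataclass(frozen=True)
class DependencyResult:
    """Outcome of the structure test for one channel pair."""

    image_entropy_bits: float
    structured: bool
    strength: float
    mi_bits: float
    null_entropy_quantile_bits: float


def _as_finite_vector(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0 or not np.all(np.isfinite(x)):
        raise ValidationError(f"{name} must be a non-empty finite vector")
    return x


def quantile_bin_indices(x: np.ndarray, bins: int) -> np.ndarray:
    """Rank-bin ``x`` into ``bins`` classes of near-equal occupancy.

    Ties are broken by stable order of occurrence (ordinal ranks), so the
    assignment — and everything downstream — is platform-independent and
    invariant under strictly increasing transforms.
    """
    n = len(x)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n, dtype=np.intp)
    ranks[order] = np.arange(n)
    return (ranks * bins) // n


def _entropy_bits(counts: np.ndarray, n: int) -> float:
    """Plug-in Shannon entropy of counts/n in bits, with 0*log0 = 0."""
    c = counts[counts > 0].astype(float)
    p = c / n
    return float(-(p * np.log2(p)).sum())


def _row_entropies_bits(count_rows: np.ndarray, n: int) -> np.ndarray:
    """Vectorised plug-in entropy per row of a count matrix."""
    p = count_rows / float(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(count_rows > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -t.sum(axis=1)


def scatter_to_image(x, y, bins: int = 10) -> DependencyImage:
    """Bin the (x, y) scatter plot into a ``bins x bins`` pixel image.

    Each axis is quantile-binned independently; the pixel count is the
    number of points falling into each cell, so counts sum to n.
    """
    x = _as_finite_vector(x, "x")
    y = _as_finite_vector(y, "y")
    if len(x) != len(y):
        raise ValidationError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < bins:
        raise ValidationError(f"need at least bins={bins} points, got {len(x)}")
    for v, name in ((x, "x"), (y, "y")):
        if np.ptp(v) == 0:
            warnings.warn(
                f"constant {name} vector: all mass falls into one bin row/column",
                stacklevel=2,
            )
    bx = quantile_bin_indices(x, bins)
    by = quantile_bin_indices(y, bins)
    counts = np.bincount(bx * bins + by, minlength=bins * bins).reshape(bins, bins)
    return DependencyImage(counts=counts, n=len(x))


def image_entropy(image: DependencyImage) -> float:
    """Shannon entropy (bits) of the normalised pixel intensity distribution."""
    if image.n <= 0:
        raise ValidationError("empty image")
    return _entropy_bits(np.asarray(image.counts).ravel(), image.n)


def _null_entropy_sample(
    ix: np.ndarray, iy: np.ndarray, bins: int, n_null: int, rng: np.random.Generator
) -> np.ndarray:
    """Entropies of ``n_null`` images obtained by randomly re-pairing y with x.

    Permuting the raw y values induces exactly a permutation of the y bin
    indices (rank binning commutes with reordering up to tie-breaking), so
    the permutation acts on ``iy`` directly.
    """
    n = len(ix)
    order = np.argsort(rng.random((n_null, n)), axis=1)
    codes = ix[None, :] * bins + iy[order]
    offset = np.arange(n_null)[:, None] * (bins * bins)
    flat = np.bincount((codes + offset).ravel(), minlength=n_null * bins * bins)
    return _row_entropies_bits(flat.reshape(n_null, bins * bins), n)


def _degenerate_result(h_obs: float = 0.0) -> DependencyResult:
    return DependencyResult(
        image_entropy_bits=h_obs,
        structured=False,
        strength=0.0,
        mi_bits=0.0,
        null_entropy_quantile_bits=float("nan"),
    )


def _result_from_stats(
    h_obs: float, hx: float, hy: float, q_alpha: float, h_med: float,
    bins: int,
) -> DependencyResult:
    floor = float(np.log2(bins))
    denom = h_med - floor
    strength = 0.0 if denom <= 0 else float(np.clip((h_med - h_obs) / denom, 0.0, 1.0))
    mi = max(0.0, hx + hy - h_obs)
    return DependencyResult(
        image_entropy_bits=h_obs,
        structured=bool(h_obs <= q_alpha),
        strength=strength,
        mi_bits=mi,
        null_entropy_quantile_bits=q_alpha,
    )


def _result_from_null(
    h_obs: float, hx: float, hy: float, null: np.ndarray, bins: int, alpha: float
) -> DependencyResult:
    return _result_from_stats(
        h_obs, hx, hy, float(np.quantile(null, alpha)), float(np.median(null)), bins
    )


def structure_test(
    x,
    y,
    bins: int = 10,
    n_null: int = 200,
    alpha: float = 0.05,
    rng_seed: int = 0,
) -> DependencyResult:
    """Test a channel pair for generalised correlation.

    The observed image entropy is compared with the empirical
    ``alpha``-quantile of entropies under ``n_null`` random re-pairings of y
    (seeded, hence reproducible). ``strength`` rescales the entropy deficit
    between the null median and the perfect-dependence floor log2(bins) onto
    [0, 1]; ``mi_bits`` is the plug-in mutual information
    H(X) + H(Y) - H(X, Y) of the binned image.
    """
    cfg = DependencyConfig(bins=bins, null_permutations=n_null, alpha=alpha)
    x = _as_finite_vector(x, "x")
    y = _as_finite_vector(y, "y")
    if len(x) != len(y):
        raise ValidationError(f"length mismatch: {len(x)} vs {len(y)}")
    n = len(x)
    if n < bins:
        raise ValidationError(f"need at least bins={bins} points, got {n}")
    if n < bins * bins // 2:
        warnings.warn(
            f"n={n} is small for a {bins}x{bins} image; test will be weak",
            stacklevel=2,
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("degenerate (constant) channel: no structure testable",
                      stacklevel=2)
        return _degenerate_result()
    ix = quantile_bin_indices(x, bins)
    iy = quantile_bin_indices(y, bins)
    counts = np.bincount(ix * bins + iy, minlength=bins * bins)
    h_obs = _entropy_bits(counts, n)
    hx = _entropy_bits(np.bincount(ix, minlength=bins), n)
    hy = _entropy_bits(np.bincount(iy, minlength=bins), n)
    rng = np.random.default_rng(rng_seed)
    null = _null_entropy_sample(ix, iy, bins, cfg.null_permutations, rng)
    return _result_from_null(h_obs, hx, hy, null, bins, alpha)


class NullEntropyCache:
    """Cache of permutation-null entropy samples keyed by bin margins.

    Under rank binning, the null distribution of the joint image entropy for
    independent re-pairings depends on (x, y) only through the marginal bin
    occupancy vectors, so one seeded Monte-Carlo sample per distinct
    (n, bins, margins) signature serves every window and pair sharing it.
    The key is symmetric in the two margin vectors.
    """

    def __init__(self, seed: int = 0, n_null: int = 200) -> None:
        self.seed = int(seed)
        self.n_null = int(n_null)
        self._store: dict[tuple, np.ndarray] = {}
        self._stats: dict[tuple, tuple[float, float]] = {}

    @staticmethod
    def _key(mx: np.ndarray, my: np.ndarray, bins: int) -> tuple:
        return (int(np.sum(mx)), bins) + tuple(
            sorted((tuple(int(v) for v in mx), tuple(int(v) for v in my)))
        )

    def null_sample(self, mx: np.ndarray, my: np.ndarray, bins: int) -> np.ndarray:
        key = self._key(mx, my, bins)
        sample = self._store.get(key)
        if sample is None:
            ss = np.random.SeedSequence([self.seed & 0x7FFFFFFF, *key[:2],
                                         *key[2], *key[3]])
            rng = np.random.default_rng(ss)
            ix = np.repeat(np.arange(bins), mx)
            iy = np.repeat(np.arange(bins), my)
            sample = _null_entropy_sample(ix, iy, bins, self.n_null, rng)
            self._store[key] = sample
        return sample

    def null_stats(
        self, mx: np.ndarray, my: np.ndarray, bins: int, alpha: float
    ) -> tuple[float, float]:
        """(alpha-quantile, median) of the null entropy sample, memoised."""
        skey = self._key(mx, my, bins) + (float(alpha),)
        st = self._stats.get(skey)
        if st is None:
            sample = self.null_sample(mx, my, bins)
            st = (float(np.quantile(sample, alpha)), float(np.median(sample)))
            self._stats[skey] = st
        return st


def adjacency_and_entropy(
    window_values: np.ndarray,
    cfg: DependencyConfig | None = None,
    cache: NullEntropyCache | None = None,
    end_t_s: float = 0.0,
    return_details: bool = False,
):
    """Build the adjacency matrix S and entropy matrix E for one window.

    ``window_values`` is an (n_samples, N) matrix of beat-aligned channel
    values. For every unordered channel pair the structure test is run;
    S_ij = S_ji = 1 iff the pair is structured, E_ij = E_ji = its mutual
    information in bits. Constant (degenerate) channels yield zero
    rows/columns. With ``return_details=True`` a per-pair record list
    (i, j, entropy_bits, mi_bits, structured) is returned as a third value.
    """
    cfg = cfg or DependencyConfig()
    v = np.asarray(window_values, dtype=float)
    if v.ndim != 2 or v.shape[1] < 2:
        raise ValidationError("window must be a 2-D (n_samples, N>=2) matrix")
    if not np.all(np.isfinite(v)):
        raise ValidationError("window contains non-finite values")
    n, n_ch = v.shape
    bins = cfg.bins
    if n < bins:
        raise ValidationError(f"window has {n} samples; need >= bins={bins}")
    if cache is None and cfg.null_mode == "shared":
        cache = NullEntropyCache(seed=cfg.seed, n_null=cfg.null_permutations)

    constant = np.ptp(v, axis=0) == 0
    bidx = np.empty((n_ch, n), dtype=np.intp)
    margins = np.empty((n_ch, bins), dtype=np.intp)
    h_marg = np.empty(n_ch)
    for c in range(n_ch):
        bidx[c] = quantile_bin_indices(v[:, c], bins)
        margins[c] = np.bincount(bidx[c], minlength=bins)
        h_marg[c] = _entropy_bits(margins[c], n)

    pairs = [(i, j) for i in range(n_ch) for j in range(i + 1, n_ch)]
    codes = np.empty((len(pairs), n), dtype=np.intp)
    for k, (i, j) in enumerate(pairs):
        codes[k] = bidx[i] * bins + bidx[j]
    offset = np.arange(len(pairs))[:, None] * (bins * bins)
    flat = np.bincount((codes + offset).ravel(), minlength=len(pairs) * bins * bins)
    h_joint = _row_entropies_bits(flat.reshape(len(pairs), bins * bins), n)

    s = np.zeros((n_ch, n_ch))
    e = np.zeros((n_ch, n_ch))
    details = [] if return_details else None
    for k, (i, j) in enumerate(pairs):
        if constant[i] or constant[j]:
            res = _degenerate_result(h_joint[k])
        else:
            if cfg.null_mode == "shared":
                q_alpha, h_med = cache.null_stats(
                    margins[i], margins[j], bins, cfg.alpha
                )
                res = _result_from_stats(
                    h_joint[k], h_marg[i], h_marg[j], q_alpha, h_med, bins
                )
            else:
                ss = np.random.SeedSequence(
                    [cfg.seed & 0x7FFFFFFF, int(round(end_t_s * 1000)) & 0x7FFFFFFF,
                     i, j]
                )
                null = _null_entropy_sample(
                    bidx[i], bidx[j], bins, cfg.null_permutations,
                    np.random.default_rng(ss),
                )
                res = _result_from_null(
                    h_joint[k], h_marg[i], h_marg[j], null, bins, cfg.alpha
                )
        if res.structured:
            s[i, j] = s[j, i] = 1.0
        e[i, j] = e[j, i] = res.mi_bits
        if details is not None:
            details.append(
                {
                    "i": i,
                    "j": j,
                    "entropy_bits": res.image_entropy_bits,
                    "mi_bits": res.mi_bits,
                    "structured": bool(res.structured),
                }
            )
    if cfg.include_diagonal:
        np.fill_diagonal(s, 1.0)
        np.fill_diagonal(e, np.where(constant, 0.0, h_marg))
    if return_details:
        return s, e, details
    return s, e
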