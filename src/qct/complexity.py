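"""The windowed complexity statistic C = ||S o E||_2, in bits.

For each moving window of beat-to-beat samples, the interdependency
structure of the twelve-channel state vector is summarised by a binary
adjacency matrix S (which pairs are coupled) and an entropy matrix E (how
much information each coupled pair shares, in bits). The complexity of the
window is the spectral norm of their Hadamard (entrywise) product: since
S o E is symmetric and non-negative, this is its largest eigenvalue (Perron
root). C is zero for a fully independent system and grows both with the
number of coupled pairs and with the information they carry.
"""

from __future__ import annotations

import logging

import numpy as np

from .core import BeatSeries, ComplexitySeries
from .dependency import DependencyConfig, NullEntropyCache, adjacency_and_entropy
from .errors import InsufficientDataError, ValidationError

__all__ = ["complexity_value", "nominal_window_duration_s", "sliding_complexity"]

logger = logging.getLogger(__name__)


def complexity_value(s: np.ndarray, e: np.ndarray) -> float:
    """Spectral norm of the Hadamard product S o E, in bits.

    Validates shapes, symmetry and finiteness; the result is the largest
    singular value of M = S o E, computed by symmetric eigendecomposition.
    """
    s = np.asarray(s, dtype=float)
    e = np.asarray(e, dtype=float)
    if s.shape != e.shape or s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValidationError(f"S/E shape mismatch: {s.shape} vs {e.shape}")
    if not np.all(np.isfinite(e)) or not np.all(np.isfinite(s)):
        raise ValidationError("S/E contain non-finite entries")
    if not np.array_equal(s, s.T) or not np.allclose(e, e.T):
        raise ValidationError("S and E must be symmetric")
    m = s * e
    if not np.any(m):
        return 0.0
    return float(np.abs(np.linalg.eigvalsh(m)).max())


def nominal_window_duration_s(window_size: int, hr_bpm: float) -> float:
    """Nominal window duration: window_size beats at one beat per 60/hr s."""
    if hr_bpm <= 0:
        raise ValidationError("hr_bpm must be positive")
    return window_size * 60.0 / hr_bpm


def sliding_complexity(
    series: BeatSeries,
    window_size: int = 100,
    stride: int = 1,
    dep_cfg: DependencyConfig | None = None,
    cache: NullEntropyCache | None = None,
    start_t_s: float | None = None,
) -> ComplexitySeries:
    """Moving-window complexity over one subject's beat series.

    Beats with any non-finite channel value are dropped first; windows then
    cover ``window_size`` consecutive *retained* beats, advanced by
    ``stride``. Each point is stamped with the time of the window's last
    beat, so the statistic at time t uses only past samples. If
    ``start_t_s`` is given, only windows whose last beat is at or after it
    are computed (the per-window values are unaffected — windows are
    independent of one another).
    """
    if window_size < 2 or stride < 1:
        raise ValidationError("window_size must be >= 2 and stride >= 1")
    dep_cfg = dep_cfg or DependencyConfig()
    if cache is None and dep_cfg.null_mode == "shared":
        cache = NullEntropyCache(seed=dep_cfg.seed, n_null=dep_cfg.null_permutations)

    mask = series.complete_mask()
    dropped = int((~mask).sum())
    if dropped:
        frac = dropped / series.n_beats
        msg = f"{series.subject_id}: dropped {dropped} incomplete beats ({frac:.1%})"
        if frac > 0.05:
            logger.warning(msg)
        else:
            logger.info(msg)
    values = series.channel_matrix()[mask]
    times = series.t_s[mask]
    n = len(times)
    if n < window_size:
        raise InsufficientDataError(
            f"{series.subject_id}: {n} usable beats < window size {window_size}"
        )

    ends = np.arange(window_size - 1, n, stride)
    if start_t_s is not None:
        ends = ends[times[ends] >= start_t_s]
    t_out = np.empty(len(ends))
    c_out = np.empty(len(ends))
    for k, end in enumerate(ends):
        w = values[end - window_size + 1 : end + 1]
        s, e = adjacency_and_entropy(w, dep_cfg, cache=cache, end_t_s=times[end])
        t_out[k] = times[end]
        c_out[k] = complexity_value(s, e)
    logger.info("%s: %d windows (stride %d)", series.subject_id, len(ends), stride)
    return ComplexitySeries(
        t_s=t_out,
        c_bits=c_out,
        window_size=window_size,
        stride=stride,
        subject_id=series.subject_id,
    )
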