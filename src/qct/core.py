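"""Core data containers for beat-to-beat tilt-test records.

A subject's record is one observation per cardiac cycle ("beat-to-beat"
sampling, so the sampling rate tracks the heart rate) across twelve
haemodynamic channels: heart rate, systolic/diastolic blood pressure, pulse
pressure, the systolic time intervals (pre-ejection period, left-ventricular
ejection time), stroke volume, cardiac output, Heather index, systemic
vascular resistance, total arterial compliance and thoracic fluid content.
Mean arterial pressure is deliberately *not* a channel: it is an algebraic
derivative of the pressures (MAP = DBP + PP/3) and is computed on demand as a
comparator variable only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

#: The twelve analysis channels, in fixed order.
CHANNELS: tuple[str, ...] = (
    "hr",    # heart rate, bpm
    "sbp",   # systolic blood pressure, mmHg
    "dbp",   # diastolic blood pressure, mmHg
    "pp",    # pulse pressure = sbp - dbp, mmHg
    "pep",   # pre-ejection period, ms
    "lvet",  # left ventricular ejection time, ms
    "sv",    # stroke volume, mL
    "co",    # cardiac output, L/min
    "hi",    # Heather index, 1/s^2
    "svr",   # systemic vascular resistance, dyn*s/cm^5
    "tac",   # total arterial compliance, mL/mmHg
    "tfc",   # thoracic fluid content, 1/kOhm
)

#: Full beat-table column set (time first).
BEAT_COLUMNS: tuple[str, ...] = ("t_s",) + CHANNELS

_PP_ATOL = 1e-6


@dataclass
class BeatSeries:
    """One subject's beat-by-beat multichannel record.

    ``beats`` is a DataFrame with columns :data:`BEAT_COLUMNS`; one row per
    beat, ``t_s`` in seconds since tilt-test start. Rows may contain NaN
    channel values (flagged for downstream dropping) but timestamps must be
    finite and strictly increasing, and pressure ordering must hold wherever
    the pressures are finite.
    """

    subject_id: str
    beats: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in BEAT_COLUMNS if c not in self.beats.columns]
        if missing:
            raise ValidationError(
                f"{self.subject_id}: beat table missing column(s) {missing}"
            )
        self.beats = self.beats.loc[:, list(BEAT_COLUMNS)].reset_index(drop=True)
        t = self.beats["t_s"].to_numpy(float)
        if len(t) == 0:
            raise ValidationError(f"{self.subject_id}: empty beat table")
        if not np.all(np.isfinite(t)):
            raise ValidationError(f"{self.subject_id}: non-finite timestamps")
        if np.any(np.diff(t) <= 0):
            row = int(np.argmax(np.diff(t) <= 0)) + 1
            raise ValidationError(
                f"{self.subject_id}: t_s not strictly increasing at row {row}"
            )
        sbp = self.beats["sbp"].to_numpy(float)
        dbp = self.beats["dbp"].to_numpy(float)
        pp = self.beats["pp"].to_numpy(float)
        ok = np.isfinite(sbp) & np.isfinite(dbp)
        if np.any(sbp[ok] <= dbp[ok]):
            row = int(np.flatnonzero(ok)[np.argmax(sbp[ok] <= dbp[ok])])
            raise ValidationError(
                f"{self.subject_id}: sbp <= dbp at row {row}"
            )
        okp = ok & np.isfinite(pp)
        if np.any(np.abs(pp[okp] - (sbp[okp] - dbp[okp])) > _PP_ATOL):
            raise ValidationError(
                f"{self.subject_id}: pp != sbp - dbp beyond tolerance"
            )
        hr = self.beats["hr"].to_numpy(float)
        if np.any(hr[np.isfinite(hr)] <= 0):
            raise ValidationError(f"{self.subject_id}: non-positive heart rate")

    @property
    def n_beats(self) -> int:
        return len(self.beats)

    @property
    def t_s(self) -> np.ndarray:
        return self.beats["t_s"].to_numpy(float)

    def channel_matrix(self) -> np.ndarray:
        """Return the (n_beats, 12) channel value matrix in fixed order."""
        return self.beats.loc[:, list(CHANNELS)].to_numpy(float)

    def map_mmhg(self) -> np.ndarray:
        """Mean arterial pressure, derived as dbp + pp/3 (never a channel)."""
        dbp = self.beats["dbp"].to_numpy(float)
        pp = self.beats["pp"].to_numpy(float)
        return dbp + pp / 3.0

    def complete_mask(self) -> np.ndarray:
        """Boolean mask of beats with all twelve channels finite."""
        return np.isfinite(self.channel_matrix()).all(axis=1)


@dataclass(frozen=True)
class Outcome:
    """Tilt-test outcome for one subject.

    ``hutt_end_s`` is the termination time (protocol completion for negative
    tests, (pre)syncope for positive ones), in seconds since test start.
    """

    subject_id: str
    syncope: bool
    hutt_end_s: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.hutt_end_s) or self.hutt_end_s <= 400.0:
            raise ValidationError(
                f"{self.subject_id}: hutt_end_s must be finite and > 400 s "
                f"(got {self.hutt_end_s!r})"
            )


@dataclass
class ComplexitySeries:
    """Time-aligned moving-window complexity values, in bits.

    Each point is (time of the window's last beat, complexity of that
    window); the series therefore only ever uses past samples.
    """

    t_s: np.ndarray
    c_bits: np.ndarray
    window_size: int
    stride: int
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, float)
        self.c_bits = np.asarray(self.c_bits, float)
        if self.t_s.shape != self.c_bits.shape:
            raise ValidationError("complexity series: t_s/c_bits length mismatch")
        if len(self.t_s) and np.any(np.diff(self.t_s) <= 0):
            raise ValidationError("complexity series: t_s not strictly increasing")
        if np.any(self.c_bits < 0):
            raise ValidationError("complexity series: negative complexity")

    def __len__(self) -> int:
        return len(self.t_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t_s, "c_bits": self.c_bits})
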