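"""Configuration handling and CSV interchange.

All data crosses module boundaries as small, reviewable CSV tables:
one ``<subject_id>.csv`` per subject (header ``t_s,hr,sbp,dbp,pp,pep,lvet,
sv,co,hi,svr,tac,tfc``, one row per beat), an ``outcomes.csv`` with
``subject_id,syncope,hutt_end_s``, and per-subject complexity series with
header ``t_s,c_bits``. Floats are serialised with shortest round-trip
formatting and rows in a fixed order, so writers are byte-deterministic and
round-trip tests are exact. A single master seed in :class:`StudyConfig`
governs every stochastic stage through derived substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .core import BEAT_COLUMNS, BeatSeries, ComplexitySeries, Outcome
from .dependency import DependencyConfig
from .errors import ConfigError, ValidationError

__all__ = [
    "StudyConfig",
    "read_beat_csv",
    "read_complexity_csv",
    "read_outcomes_csv",
    "write_beat_csv",
    "write_complexity_csv",
    "write_outcomes_csv",
    "write_evaluation",
]

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Every tunable of the pipeline, with validated defaults."""

    window_size: int = 100
    stride: int = 1
    bins: int = 10
    null_permutations: int = 200
    alpha: float = 0.05
    include_diagonal: bool = False
    null_mode: str = "shared"
    timepoints: tuple = tuple(float(t) for t in (300, 270, 240, 210, 180,
                                                 150, 120, 90, 60, 30))
    sens_floor: float = 0.80
    spec_floor: float = 0.80
    seed: int = 0
    #: Restrict the sliding-window computation to the last tail_s seconds
    #: before termination (None = whole record). Windows are independent, so
    #: this changes runtime, never values at the analysed time points.
    tail_s: float | None = 480.0

    def __post_init__(self) -> None:
        if self.window_size < 2 or self.stride < 1:
            raise ConfigError("window_size must be >= 2 and stride >= 1")
        if not 0.0 < self.sens_floor and self.sens_floor > 2.0:
            raise ConfigError("sens_floor out of range")
        self.timepoints = tuple(float(t) for t in self.timepoints)
        if len(set(self.timepoints)) != len(self.timepoints):
            raise ConfigError("duplicate timepoints")
        if self.tail_s is not None:
            need = max(self.timepoints) + 180.0
            if self.tail_s < need:
                raise ConfigError(
                    f"tail_s={self.tail_s} too short for the latest timepoint "
                    f"(need >= {need:.0f} s)"
                )
        # Delegate dependency-key validation.
        self.dependency_config()

    def dependency_config(self) -> DependencyConfig:
        return DependencyConfig(
            bins=self.bins,
            null_permutations=self.null_permutations,
            alpha=self.alpha,
            include_diagonal=self.include_diagonal,
            seed=self.seed,
            null_mode=self.null_mode,
        )

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ConfigError(f"{path}: unknown config key(s) {unknown}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["timepoints"] = list(self.timepoints)
        return d

    def echo(self, out_dir) -> Path:
        """Write the effective config as ``config.used.yaml`` into out_dir."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "config.used.yaml"
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Beat series


def write_beat_csv(series: BeatSeries, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    series.beats.to_csv(path, index=False)
    return path


def read_beat_csv(path, subject_id: str | None = None) -> BeatSeries:
    """Read one subject's beat table.

    The header must contain exactly the beat-series columns
    (order-insensitive, case-insensitive); rows with non-finite channel
    values are retained (they are dropped downstream), but structural
    violations — non-increasing time, sbp <= dbp — are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    df = pd.read_csv(path)
    if df.empty:
        raise ValidationError(f"{path}: empty beat table")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in BEAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in BEAT_COLUMNS]
    if extra:
        raise ValidationError(f"{path}: unexpected column(s) {extra}")
    sid = subject_id or path.stem
    return BeatSeries(subject_id=sid, beats=df)


# ---------------------------------------------------------------------------
# Outcomes

_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no"}


def write_outcomes_csv(outcomes: list[Outcome], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "subject_id": [o.subject_id for o in outcomes],
            "syncope": [int(o.syncope) for o in outcomes],
            "hutt_end_s": [o.hutt_end_s for o in outcomes],
        }
    )
    df.to_csv(path, index=False)
    return path


def read_outcomes_csv(path) -> list[Outcome]:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    df = pd.read_csv(path, dtype={"subject_id": str, "syncope": str})
    expected = ["subject_id", "syncope", "hutt_end_s"]
    if list(df.columns) != expected:
        raise ValidationError(f"{path}: header must be {','.join(expected)}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate subject_id {dup!r}")
    outcomes = []
    for _, row in df.iterrows():
        token = str(row["syncope"]).strip().lower()
        if token in _TRUE:
            flag = True
        elif token in _FALSE:
            flag = False
        else:
            raise ValidationError(
                f"{path}: unknown syncope token {row['syncope']!r} "
                f"for subject {row['subject_id']!r}"
            )
        outcomes.append(
            Outcome(
                subject_id=str(row["subject_id"]),
                syncope=flag,
                hutt_end_s=float(row["hutt_end_s"]),
            )
        )
    return outcomes


# ---------------------------------------------------------------------------
# Complexity series


def write_complexity_csv(cseries: ComplexitySeries, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cseries.to_frame().to_csv(path, index=False)
    return path


def read_complexity_csv(
    path, window_size: int = 100, stride: int = 1, subject_id: str | None = None
) -> ComplexitySeries:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    df = pd.read_csv(path)
    if list(df.columns) != ["t_s", "c_bits"]:
        raise ValidationError(f"{path}: header must be t_s,c_bits")
    return ComplexitySeries(
        t_s=df["t_s"].to_numpy(float),
        c_bits=df["c_bits"].to_numpy(float),
        window_size=window_size,
        stride=stride,
        subject_id=subject_id or path.stem,
    )


# ---------------------------------------------------------------------------
# Evaluation outputs


def write_evaluation(tables, out_dir) -> dict[str, Path]:
    """Write the three report CSVs plus summary.json into ``out_dir``."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("group_comparison", tables.group_comparison),
        ("roc", tables.roc),
        ("cutoffs", tables.cutoffs),
        ("timepoint_values", tables.timepoint_values),
    ):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    p = out / "summary.json"
    p.write_text(json.dumps(tables.summary, indent=2, sort_keys=True) + "\n")
    paths["summary"] = p
    return paths
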