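"""Seeded synthetic tilt-test cohorts.

Real head-up tilt recordings with beat-to-beat impedance-cardiography
channels are not publicly deposited, so this module generates cohorts with
the statistical structure the downstream analysis assumes:

* a protocol clock of three phases — supine rest (300 s), passive 60–70°
  tilt (900 s), and a nitroglycerine-sensitised provocation phase (900 s);
* beat-to-beat sampling, with the inter-beat interval equal to 60/HR of the
  preceding beat, so the sampling rate tracks heart rate;
* twelve haemodynamic channels, each a phase-dependent deterministic trend
  plus subject-level random offsets plus AR(1) beat-to-beat noise; pulse
  pressure is derived exactly as SBP − DBP (DBP and PP are generated, SBP is
  their sum);
* fainting subjects terminate early, and in their final ``coupling_ramp_s``
  seconds a single shared latent AR(1) factor is injected into *all*
  channels with linearly ramping weight — the rising interdependency network
  that the complexity statistic is designed to detect — followed in the last
  30 s by a linear heart-rate and blood-pressure fall (the vasovagal
  collapse);
* non-fainting subjects stay stationary (apart from nitroglycerine
  tachycardia) until scheduled protocol completion.

Group-level channel means and between-subject SDs default to values close
to the published upright-phase group statistics (e.g. heart rate
88.9 ± 16.2 bpm in non-fainters during provocation); everything is
configurable through :class:`CohortSpec` and generation is a pure function
of (spec, group, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .core import BEAT_COLUMNS, BeatSeries, Outcome
from .errors import ConfigError, ValidationError

__all__ = ["CohortSpec", "simulate_cohort", "simulate_subject"]

#: Channels drawn directly by the generator (sbp = dbp + pp is derived).
GEN_CHANNELS: tuple[str, ...] = (
    "hr", "dbp", "pp", "pep", "lvet", "sv", "co", "hi", "svr", "tac", "tfc",
)

# Upright-phase (tilted) group means. HR targets: non-fainters reach
# 88.9 bpm under nitroglycerine (80.9 + 8 drug delta); fainters centre near
# 77.6 bpm across the passive/provoked mix. MAP = dbp + pp/3 lands near
# 103 mmHg (fainters) vs 99 mmHg (non-fainters).
DEFAULT_MEANS: dict[str, dict[str, float]] = {
    "syncope": {
        "hr": 74.0, "dbp": 89.5, "pp": 41.0, "pep": 100.0, "lvet": 280.0,
        "sv": 80.0, "co": 6.0, "hi": 12.0, "svr": 1200.0, "tac": 1.5,
        "tfc": 28.0,
    },
    "control": {
        "hr": 80.9, "dbp": 85.4, "pp": 41.0, "pep": 100.0, "lvet": 280.0,
        "sv": 80.0, "co": 6.0, "hi": 12.0, "svr": 1200.0, "tac": 1.5,
        "tfc": 28.0,
    },
}

#: Between-subject SDs (cross-sectional spread at a fixed time point).
DEFAULT_BETWEEN_SD: dict[str, dict[str, float]] = {
    "syncope": {
        "hr": 13.0, "dbp": 14.0, "pp": 9.0, "pep": 12.0, "lvet": 25.0,
        "sv": 15.0, "co": 1.2, "hi": 3.0, "svr": 250.0, "tac": 0.4,
        "tfc": 4.0,
    },
    "control": {
        "hr": 16.2, "dbp": 14.0, "pp": 9.0, "pep": 12.0, "lvet": 25.0,
        "sv": 15.0, "co": 1.2, "hi": 3.0, "svr": 250.0, "tac": 0.4,
        "tfc": 4.0,
    },
}

#: Beat-to-beat (within-subject) noise SDs.
DEFAULT_NOISE_SD: dict[str, float] = {
    "hr": 3.0, "dbp": 3.0, "pp": 3.0, "pep": 4.0, "lvet": 6.0, "sv": 4.0,
    "co": 0.35, "hi": 0.8, "svr": 60.0, "tac": 0.08, "tfc": 0.4,
}

#: Additive offsets while supine (before tilt): slower, fuller heart.
DEFAULT_SUPINE_DELTA: dict[str, float] = {
    "hr": -12.0, "dbp": -3.0, "pp": 2.0, "sv": 10.0, "co": 0.3, "svr": -100.0,
}

#: Additive offsets after nitroglycerine (reflex tachycardia, vasodilation).
DEFAULT_DRUG_DELTA: dict[str, float] = {"hr": 8.0, "svr": -80.0, "tac": 0.1}


@dataclass
class CohortSpec:
    """Study-condition parameters for one synthetic cohort.

    Defaults encode the study conditions: 54 fainting vs 27 non-fainting
    subjects, a 150 s pre-syncope coupling ramp, and the three-phase tilt
    protocol (300 s supine, 900 s passive tilt, 900 s provocation).
    """

    n_syncope: int = 54
    n_control: int = 27
    seed: int = 0
    coupling_ramp_s: float = 150.0
    coupling_max: float = 0.8
    #: Injection gain: the latent factor enters channel c with amplitude
    #: w(t) * coupling_gain * noise_sd_c, so at full ramp the shared-factor
    #: variance is (coupling_max*gain)^2 times the beat-to-beat noise variance.
    coupling_gain: float = 2.5
    supine_s: float = 300.0
    passive_s: float = 900.0
    drug_s: float = 900.0
    #: Fainting subjects terminate uniformly inside this absolute window (s).
    syncope_end_range: tuple[float, float] = (900.0, 2100.0)
    ar_phi: float = 0.3
    collapse_s: float = 30.0
    collapse_hr_bpm: float = 25.0
    collapse_dbp_mmhg: float = 15.0
    collapse_pp_mmhg: float = 10.0
    channel_means: dict = field(default_factory=lambda: _copy2(DEFAULT_MEANS))
    channel_sds: dict = field(default_factory=lambda: _copy2(DEFAULT_BETWEEN_SD))
    noise_sds: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    supine_delta: dict = field(default_factory=lambda: dict(DEFAULT_SUPINE_DELTA))
    drug_delta: dict = field(default_factory=lambda: dict(DEFAULT_DRUG_DELTA))

    def __post_init__(self) -> None:
        if self.n_syncope < 0 or self.n_control < 0 or \
                self.n_syncope + self.n_control < 1:
            raise ConfigError("need at least one subject")
        if not 0.0 <= self.coupling_max <= 1.0:
            raise ConfigError("coupling_max must lie in [0, 1]")
        if not 0.0 <= self.ar_phi < 1.0:
            raise ConfigError("ar_phi must lie in [0, 1)")
        total = self.supine_s + self.passive_s + self.drug_s
        lo, hi = self.syncope_end_range
        if not (400.0 < lo <= hi <= total):
            raise ConfigError(
                f"syncope_end_range must lie in (400, {total}] (got {lo}, {hi})"
            )
        for group in ("syncope", "control"):
            for ch in GEN_CHANNELS:
                for table, name in (
                    (self.channel_means[group], "mean"),
                    (self.channel_sds[group], "sd"),
                ):
                    v = table.get(ch)
                    if v is None or not np.isfinite(v):
                        raise ConfigError(
                            f"non-finite calibration {name} for {group}/{ch}: {v!r}"
                        )
        for ch in GEN_CHANNELS:
            if not np.isfinite(self.noise_sds.get(ch, np.nan)):
                raise ConfigError(f"non-finite noise sd for {ch}")

    @property
    def protocol_end_s(self) -> float:
        return self.supine_s + self.passive_s + self.drug_s

    @property
    def drug_start_s(self) -> float:
        return self.supine_s + self.passive_s


def _copy2(d: dict) -> dict:
    return {k: dict(v) for k, v in d.items()}


def _ar1(rng: np.random.Generator, n: int, phi: float, cols: int) -> np.ndarray:
    """(n, cols) stationary AR(1) noise with unit marginal variance."""
    burn = 64
    inn = rng.standard_normal((n + burn, cols))
    out = lfilter([1.0], [1.0, -phi], inn, axis=0)[burn:]
    return out * np.sqrt(1.0 - phi * phi)


def simulate_subject(
    spec: CohortSpec,
    group: str,
    subject_seed: int,
    subject_id: str | None = None,
) -> tuple[BeatSeries, Outcome]:
    """Generate one subject's beat series and outcome.

    Deterministic: identical (spec, group, subject_seed) reproduce
    bit-identical output. The beat clock advances by 60/HR of the beat just
    generated; all channels are sampled once per beat.
    """
    if group not in ("syncope", "control"):
        raise ValidationError(f"unknown group {group!r}")
    if subject_seed < 0:
        raise ValidationError("subject_seed must be >= 0")
    if subject_id is None:
        subject_id = f"{group[:3]}-{subject_seed:010d}"
    rng = np.random.default_rng(subject_seed)

    means = spec.channel_means[group]
    between = spec.channel_sds[group]
    noise_sd = np.array([spec.noise_sds[c] for c in GEN_CHANNELS])

    # Subject-level channel offsets (fixed draw order: GEN_CHANNELS).
    z = rng.standard_normal(len(GEN_CHANNELS))
    mu = {c: means[c] + between[c] * z[k] for k, c in enumerate(GEN_CHANNELS)}

    syncope = group == "syncope"
    if syncope:
        lo, hi = spec.syncope_end_range
        end = float(rng.uniform(lo, hi))
    else:
        end = spec.protocol_end_s

    # Pre-generate noise: hr beyond ~220 bpm is clipped away, so a 0.25 s
    # minimum inter-beat interval bounds the number of beats.
    n_max = int(end / 0.25) + 8
    latent = _ar1(rng, n_max, spec.ar_phi, 1)[:, 0]
    noise = _ar1(rng, n_max, spec.ar_phi, len(GEN_CHANNELS)) * noise_sd

    sd_hr = spec.noise_sds["hr"]
    hr_noise = noise[:, GEN_CHANNELS.index("hr")]
    ramp_start = end - spec.coupling_ramp_s
    collapse_start = end - spec.collapse_s
    drug_start = spec.drug_start_s
    supine_hr = spec.supine_delta.get("hr", 0.0)
    drug_hr = spec.drug_delta.get("hr", 0.0)
    gain = spec.coupling_gain * spec.coupling_max

    # Scalar clock loop: only HR is needed to advance time.
    ts = np.empty(n_max)
    t = 0.0
    k = 0
    while t <= end and k < n_max:
        trend = mu["hr"]
        if t < spec.supine_s:
            trend += supine_hr
        elif t >= drug_start:
            trend += drug_hr
        hr_k = trend + hr_noise[k]
        if syncope and t >= ramp_start:
            w = gain * min((t - ramp_start) / spec.coupling_ramp_s, 1.0)
            hr_k += w * sd_hr * latent[k]
        if syncope and t > collapse_start:
            hr_k -= spec.collapse_hr_bpm * (t - collapse_start) / spec.collapse_s
        hr_k = max(hr_k, 25.0)
        ts[k] = t
        t += 60.0 / hr_k
        k += 1
    n = k
    ts = ts[:n]

    # Vectorised channel construction on the realised beat times.
    supine_mask = ts < spec.supine_s
    drug_mask = ts >= drug_start
    if syncope:
        w = np.clip((ts - ramp_start) / spec.coupling_ramp_s, 0.0, 1.0) * gain
        cfrac = np.clip((ts - collapse_start) / spec.collapse_s, 0.0, 1.0)
    else:
        w = np.zeros(n)
        cfrac = np.zeros(n)

    cols: dict[str, np.ndarray] = {}
    for ci, ch in enumerate(GEN_CHANNELS):
        base = np.full(n, mu[ch])
        base[supine_mask] += spec.supine_delta.get(ch, 0.0)
        base[drug_mask] += spec.drug_delta.get(ch, 0.0)
        vals = base + noise[:n, ci] + w * spec.noise_sds[ch] * latent[:n]
        cols[ch] = vals
    cols["hr"] -= spec.collapse_hr_bpm * cfrac
    cols["dbp"] -= spec.collapse_dbp_mmhg * cfrac
    cols["pp"] -= spec.collapse_pp_mmhg * cfrac

    cols["hr"] = np.maximum(cols["hr"], 25.0)
    cols["dbp"] = np.maximum(cols["dbp"], 20.0)
    cols["pp"] = np.maximum(cols["pp"], 5.0)
    cols["sbp"] = cols["dbp"] + cols["pp"]
    for ch, floor in (("pep", 30.0), ("lvet", 100.0), ("sv", 20.0),
                      ("co", 1.0), ("hi", 1.0), ("svr", 300.0),
                      ("tac", 0.3), ("tfc", 10.0)):
        cols[ch] = np.maximum(cols[ch], floor)

    beats = pd.DataFrame({"t_s": ts, **{c: cols[c] for c in BEAT_COLUMNS[1:]}})
    series = BeatSeries(subject_id=subject_id, beats=beats)
    outcome = Outcome(subject_id=subject_id, syncope=syncope, hutt_end_s=end)
    return series, outcome


def simulate_cohort(spec: CohortSpec) -> tuple[list[BeatSeries], list[Outcome]]:
    """Generate a full cohort: fainters first, then non-fainters.

    Per-subject seeds are spawned from ``spec.seed`` via NumPy seed
    sequences, so the cohort is a pure function of the spec and subjects are
    statistically independent.
    """
    n_total = spec.n_syncope + spec.n_control
    children = np.random.SeedSequence(spec.seed).spawn(n_total)
    seeds = [int(c.generate_state(1)[0]) for c in children]
    series: list[BeatSeries] = []
    outcomes: list[Outcome] = []
    for k in range(n_total):
        group = "syncope" if k < spec.n_syncope else "control"
        idx = k + 1 if group == "syncope" else k - spec.n_syncope + 1
        sid = f"{'syn' if group == 'syncope' else 'ctl'}{idx:03d}"
        s, o = simulate_subject(spec, group, seeds[k], subject_id=sid)
        series.append(s)
        outcomes.append(o)
    return series, outcomes
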