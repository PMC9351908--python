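"""Synthetic AF surface-ECG and cohort generation.

Every downstream stage of the pipeline (QRST cancellation, complexity
metrics, outcome statistics) is exercised against signals and cohorts with
known ground truth.  Two generators live here:

* waveform level — quasi-periodic fibrillatory waves (a decaying harmonic
  series with amplitude and frequency modulation) summed with beat-locked
  QRST complexes at irregular RR intervals plus configurable noise;
* cohort level — per-patient metric tables whose group means/SDs and
  endpoint prevalences are planted, so the statistical pipeline can be
  calibrated against known effects.

Amplitudes are in microvolts (uV) throughout; frequencies in Hz; times in
seconds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "FWaveParams",
    "VentricularParams",
    "NoiseSpec",
    "GroundTruth",
    "CohortSimParams",
    "gen_fwave",
    "gen_ventricular",
    "gen_af_ecg",
    "gen_cohort",
    "median_peak_to_trough",
    "DEFAULT_LEADS",
    "DEFAULT_FWAVE_AMPLITUDES",
    "DEFAULT_VENTRICULAR_GAINS",
    "TERMINATION_GROUP_MOMENTS",
    "RECURRENCE_GROUP_MOMENTS",
    "LA_CT_VOLUME_MOMENTS",
    "PREVALENCE_TERMINATION",
    "PREVALENCE_RECURRENCE",
]

DEFAULT_LEADS = ("I", "II", "V1", "V6")

#: Per-lead f-wave peak-to-trough targets (uV), matching the overall-cohort
#: FWA means observed on the four analyzed leads.
DEFAULT_FWAVE_AMPLITUDES = {"I": 45.0, "II": 65.0, "V1": 70.0, "V6": 57.0}

#: Relative ventricular (QRST) gain per lead; lead II carries the largest R.
DEFAULT_VENTRICULAR_GAINS = {"I": 0.6, "II": 1.0, "V1": 0.8, "V6": 0.9}

#: Procedural-termination endpoint prevalence (86 of 130 terminated).
PREVALENCE_TERMINATION = 86.0 / 130.0
#: Late-recurrence endpoint prevalence (71 of 130 recurred).
PREVALENCE_RECURRENCE = 71.0 / 130.0

# Planted per-metric (mean, SD) by procedural-termination group.
# Keys: metric column -> {1: (mean, sd) terminated, 0: (mean, sd) not}.
TERMINATION_GROUP_MOMENTS = {
    "fwa_i":    {1: (44.93, 16.08), 0: (44.78, 17.10)},
    "fwa_ii":   {1: (68.28, 22.30), 0: (60.30, 21.21)},
    "fwa_v1":   {1: (75.47, 26.18), 0: (64.76, 29.79)},
    "fwa_v6":   {1: (56.50, 21.38), 0: (58.97, 33.26)},
    "df_i":     {1: (5.549, 1.011), 0: (6.036, 1.057)},
    "df_ii":    {1: (5.505, 0.918), 0: (5.886, 0.992)},
    "df_v1":    {1: (5.793, 1.316), 0: (5.968, 0.998)},
    "df_v6":    {1: (5.551, 1.248), 0: (5.650, 1.305)},
    "oi_i":     {1: (0.707, 0.115), 0: (0.679, 0.092)},
    "oi_ii":    {1: (0.708, 0.082), 0: (0.698, 0.102)},
    "oi_v1":    {1: (0.754, 0.141), 0: (0.748, 0.099)},
    "oi_v6":    {1: (0.718, 0.102), 0: (0.702, 0.101)},
    "se_i":     {1: (3.281, 0.506), 0: (3.314, 0.514)},
    "se_ii":    {1: (3.009, 0.579), 0: (3.277, 0.482)},
    "se_v1":    {1: (2.649, 0.754), 0: (2.844, 0.640)},
    "se_v6":    {1: (3.274, 0.556), 0: (3.381, 0.426)},
    "sampen_i":  {1: (0.127, 0.015), 0: (0.129, 0.018)},
    "sampen_ii": {1: (0.123, 0.014), 0: (0.125, 0.013)},
    "sampen_v1": {1: (0.123, 0.019), 0: (0.129, 0.012)},
    "sampen_v6": {1: (0.119, 0.016), 0: (0.117, 0.015)},
}

# Same metrics keyed by late-recurrence group (1 = recurred).
RECURRENCE_GROUP_MOMENTS = {
    "fwa_v1": {0: (77.96, 27.51), 1: (66.80, 27.24)},
    "se_v1":  {0: (2.625, 0.706), 1: (2.925, 0.721)},
}

#: Left-atrial CT volume (mL) by termination group; the clinical covariate
#: that independently predicts termination failure.
LA_CT_VOLUME_MOMENTS = {"la_ct_volume": {1: (139.0, 34.4), 0: (173.2, 44.7)}}


@dataclass(frozen=True)
class FWaveParams:
    """Parameters of the quasi-periodic fibrillatory-wave model.

    The f-wave is a harmonic series at fundamental ``f0`` whose harmonic
    amplitudes decay geometrically (a sawtooth-like shape), modulated in
    amplitude and in instantaneous frequency to emulate the waxing/waning
    of real fibrillatory activity.
    """

    f0: float = 6.0
    n_harmonics: int = 3
    harmonic_decay: float = 0.5
    peak_to_peak: float = 60.0
    am_depth: float = 0.15
    am_freq: float = 0.5
    fm_depth: float = 0.02
    fm_freq: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (3.0 <= self.f0 <= 12.0):
            raise ValueError(f"f0 must lie in [3, 12] Hz, got {self.f0}")
        if self.peak_to_peak <= 0:
            raise ValueError("peak_to_peak must be positive")
        if not (0.0 <= self.am_depth < 1.0):
            raise ValueError("am_depth must lie in [0, 1)")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")


@dataclass(frozen=True)
class VentricularParams:
    """Beat-train parameters: lognormal RR intervals and a fixed QRST shape."""

    mean_rr: float = 0.8
    rr_cv: float = 0.15
    qrs_amp: float = 1000.0
    t_amp: float = 200.0
    qrst_duration: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_rr <= self.qrst_duration:
            raise ValueError("mean_rr must exceed qrst_duration")
        if self.rr_cv < 0:
            raise ValueError("rr_cv must be >= 0")
        if self.qrs_amp <= 0:
            raise ValueError("qrs_amp must be positive")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise: baseline wander (<0.5 Hz), a powerline tone, white noise.

    Each component is specified by its RMS in uV.
    """

    baseline_rms: float = 20.0
    powerline_rms: float = 5.0
    powerline_freq: float = 60.0
    white_rms: float = 10.0
    seed: int = 0


@dataclass
class GroundTruth:
    """What the generator actually produced: true R sample indices, the pure
    per-lead atrial signals, and the generating parameters."""

    r_times: np.ndarray
    atrial_true: dict[str, np.ndarray]
    params: dict


@dataclass(frozen=True)
class CohortSimParams:
    """Tabular-cohort simulation: endpoint prevalences and planted per-group
    metric moments (defaults follow the observed group means/SDs and
    endpoint counts of the 130-patient cohort)."""

    n_patients: int = 130
    prevalence_termination: float = PREVALENCE_TERMINATION
    prevalence_recurrence: float = PREVALENCE_RECURRENCE
    group_moments: dict = field(
        default_factory=lambda: dict(TERMINATION_GROUP_MOMENTS)
    )
    covariate_moments: dict = field(
        default_factory=lambda: dict(LA_CT_VOLUME_MOMENTS)
    )
    stratify_by: str = "endpoint_termination"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.prevalence_termination < 1):
            raise ValueError("prevalence_termination must lie in (0, 1)")
        if not (0 < self.prevalence_recurrence < 1):
            raise ValueError("prevalence_recurrence must lie in (0, 1)")
        for metric, groups in {**self.group_moments, **self.covariate_moments}.items():
            for g, (_, sd) in groups.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {metric!r} group {g}")


def median_peak_to_trough(x: np.ndarray, fs: float, min_sep_s: float = 0.04) -> float:
    """Median absolute difference between successive alternating local extrema.

    This is the amplitude convention shared by the generator and the FWA
    estimator: for a pure sinusoid of amplitude A it equals 2A.
    """
    dist = max(1, int(round(min_sep_s * fs)))
    peaks, _ = find_peaks(x, distance=dist)
    troughs, _ = find_peaks(-x, distance=dist)
    idx = np.sort(np.concatenate([peaks, troughs]))
    if idx.size < 2:
        return 0.0
    vals = x[idx]
    return float(np.median(np.abs(np.diff(vals))))


def gen_fwave(params: FWaveParams, fs: float, duration: float) -> np.ndarray:
    """Generate one lead's pure fibrillatory wave.

    Returns a waveform of ``round(fs * duration)`` samples whose median
    successive peak-to-trough amplitude equals ``params.peak_to_peak`` uV.
    Deterministic given ``params.seed``.
    """
    if fs < 4.0 * params.f0 * params.n_harmonics:
        raise ValueError(
            f"fs={fs} Hz aliases the modelled harmonics: need "
            f"fs >= 4*f0*n_harmonics = {4.0 * params.f0 * params.n_harmonics} Hz"
        )
    n = int(round(fs * duration))
    t = np.arange(n) / fs
    rng = np.random.default_rng(params.seed)
    phi0 = rng.uniform(0, 2 * np.pi)

    # instantaneous fundamental f0*(1 + fm_depth*sin(2*pi*fm_freq*t));
    # its phase integral, shared (scaled by k) across harmonics so the
    # sawtooth shape is preserved under FM
    if params.fm_depth > 0 and params.fm_freq > 0:
        phase = 2 * np.pi * params.f0 * (
            t - params.fm_depth / (2 * np.pi * params.fm_freq)
            * (np.cos(2 * np.pi * params.fm_freq * t) - 1.0)
        )
    else:
        phase = 2 * np.pi * params.f0 * t

    x = np.zeros(n)
    for k in range(1, params.n_harmonics + 1):
        a_k = params.harmonic_decay ** (k - 1)
        x += a_k * np.sin(k * (phase + phi0))
    x *= 1.0 + params.am_depth * np.sin(2 * np.pi * params.am_freq * t)

    measured = median_peak_to_trough(x, fs)
    if measured > 0:
        x *= params.peak_to_peak / measured
    return x


def _qrst_template(fs: float, params: VentricularParams) -> tuple[np.ndarray, int]:
    """Fixed-shape QRST built from raised-cosine bumps.

    Returns ``(template, r_offset)`` where ``r_offset`` is the sample index
    of the R apex within the template.  Support is
    [-0.05 s, qrst_duration - 0.05 s] around R.
    """
    pre = 0.05
    post = params.qrst_duration - pre
    n = int(round((pre + post) * fs))
    t = np.arange(n) / fs - pre  # time relative to R apex
    tmpl = np.zeros(n)

    def bump(center: float, width: float, amp: float) -> None:
        m = np.abs(t - center) < width / 2
        tmpl[m] += amp * 0.5 * (1 + np.cos(2 * np.pi * (t[m] - center) / width))

    bump(-0.030, 0.020, -0.10 * params.qrs_amp)   # Q
    bump(0.000, 0.040, params.qrs_amp)            # R
    bump(0.035, 0.030, -0.20 * params.qrs_amp)    # S
    t_center = 0.05 + 0.65 * post                 # T inside the post-R span
    bump(t_center, min(0.20, 0.5 * post), params.t_amp)
    return tmpl, int(round(pre * fs))


def gen_ventricular(
    params: VentricularParams, fs: float, duration: float
) -> tuple[np.ndarray, np.ndarray]:
    """Generate the ventricular (QRST) component and true R sample indices.

    RR intervals are i.i.d. lognormal with the requested mean and
    coefficient of variation, truncated below at ``qrst_duration`` (AF-like
    irregular but physiologic intervals).  ``rr_cv=0`` gives a strictly
    periodic train.
    """
    if duration < 3 * params.mean_rr:
        raise ValueError("duration must cover at least 3 mean RR intervals")
    n = int(round(fs * duration))
    rng = np.random.default_rng(params.seed)

    def draw_rr() -> float:
        if params.rr_cv == 0:
            return params.mean_rr
        sigma2 = np.log(1.0 + params.rr_cv**2)
        mu = np.log(params.mean_rr) - sigma2 / 2.0
        while True:
            rr = float(rng.lognormal(mu, np.sqrt(sigma2)))
            if rr > params.qrst_duration:
                return rr

    tmpl, r_offset = _qrst_template(fs, params)
    wav = np.zeros(n)
    r_indices: list[int] = []
    # first R placed so the full template fits
    t_r = 0.06 + (0.0 if params.rr_cv == 0 else 0.2 * draw_rr())
    while True:
        idx = int(round(t_r * fs))
        start = idx - r_offset
        if start + tmpl.size > n:
            break
        if start >= 0:
            wav[start : start + tmpl.size] += tmpl
            r_indices.append(idx)
        t_r += draw_rr()
    return wav, np.asarray(r_indices, dtype=np.int64)


def gen_af_ecg(
    fwave_params: dict[str, FWaveParams] | None = None,
    ventricular: VentricularParams | None = None,
    noise: NoiseSpec | None = None,
    fs: float = 2000.0,
    duration: float = 10.0,
    leads: tuple[str, ...] = DEFAULT_LEADS,
    ventricular_gains: dict[str, float] | None = None,
    seed: int = 0,
):
    """Generate a multi-lead AF ECG epoch plus its ground truth.

    Per lead: f-wave + gain-scaled QRST train + noise.  The R times and the
    pure atrial signals are returned so cancellation and metric recovery can
    be scored exactly.  Returns ``(EcgEpoch, GroundTruth)``.

    Derived per-lead seeds keep the leads' f-waves and noise independent
    while the whole epoch stays a pure function of ``seed``.
    """
    from .io import EcgEpoch  # local import to avoid a cycle

    required = {"I", "II", "V1", "V6"}
    if not required.issubset({l.upper() for l in leads}):
        raise ValueError(f"lead set must include {sorted(required)}, got {leads}")
    known = {"I", "II", "III", "AVR", "AVL", "AVF", "V1", "V2", "V3", "V4", "V5", "V6"}
    for l in leads:
        if l.upper() not in known:
            raise ValueError(f"unknown lead label {l!r}")

    gains = dict(DEFAULT_VENTRICULAR_GAINS)
    if ventricular_gains:
        gains.update({k.upper(): v for k, v in ventricular_gains.items()})
    if ventricular is None:
        ventricular = dataclasses.replace(VentricularParams(), seed=seed)
    if noise is None:
        noise = dataclasses.replace(NoiseSpec(), seed=seed + 1)

    if fwave_params is None:
        fwave_params = {}
    fw: dict[str, FWaveParams] = {}
    for i, lead in enumerate(leads):
        lu = lead.upper()
        if lu in {k.upper() for k in fwave_params}:
            fw[lu] = next(v for k, v in fwave_params.items() if k.upper() == lu)
        else:
            fw[lu] = FWaveParams(
                peak_to_peak=DEFAULT_FWAVE_AMPLITUDES.get(lu, 50.0),
                seed=seed * 1009 + 13 * i + 2,
            )

    n = int(round(fs * duration))
    t = np.arange(n) / fs
    vent, r_idx = gen_ventricular(ventricular, fs, duration)

    samples: dict[str, np.ndarray] = {}
    atrial_true: dict[str, np.ndarray] = {}
    rng = np.random.default_rng(noise.seed)
    for lead in leads:
        lu = lead.upper()
        atr = gen_fwave(fw[lu], fs, duration)
        x = atr + gains.get(lu, 1.0) * vent
        # baseline wander: two slow random-phase sinusoids below 0.5 Hz
        if noise.baseline_rms > 0:
            bw = np.zeros(n)
            for f_b in (0.15, 0.33):
                bw += np.sin(2 * np.pi * f_b * t + rng.uniform(0, 2 * np.pi))
            bw *= noise.baseline_rms / max(np.sqrt(np.mean(bw**2)), 1e-12)
            x = x + bw
        if noise.powerline_rms > 0:
            x = x + noise.powerline_rms * np.sqrt(2) * np.sin(
                2 * np.pi * noise.powerline_freq * t + rng.uniform(0, 2 * np.pi)
            )
        if noise.white_rms > 0:
            x = x + rng.normal(0.0, noise.white_rms, n)
        samples[lead] = x
        atrial_true[lead] = atr

    epoch = EcgEpoch(leads=list(leads), fs=fs, samples=samples, t0=0.0)
    truth = GroundTruth(
        r_times=r_idx,
        atrial_true=atrial_true,
        params={"fwave": fw, "ventricular": ventricular, "noise": noise},
    )
    return epoch, truth


_NONNEGATIVE_PREFIXES = ("fwa", "df", "oi", "se", "sampen", "la_ct")


def gen_cohort(params: CohortSimParams) -> pd.DataFrame:
    """Simulate a patient cohort table with planted group effects.

    Endpoint labels are Bernoulli draws at the requested prevalences; each
    metric is then drawn from the normal law of the patient's group under
    the stratifying endpoint (truncated at 0 for nonnegative quantities).
    Columns: ``id``, ``endpoint_termination``, ``endpoint_recurrence``,
    one column per planted metric/covariate.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    term = (rng.random(n) < params.prevalence_termination).astype(int)
    recur = (rng.random(n) < params.prevalence_recurrence).astype(int)
    strat = term if params.stratify_by == "endpoint_termination" else recur

    data = {
        "id": [f"P{i:04d}" for i in range(n)],
        "endpoint_termination": term,
        "endpoint_recurrence": recur,
    }
    all_moments = {**params.group_moments, **params.covariate_moments}
    for metric, groups in all_moments.items():
        missing = set(np.unique(strat)) - set(groups)
        if missing:
            raise ValueError(f"group moments missing for {metric!r}, groups {missing}")
        vals = np.empty(n)
        for g, (mean, sd) in groups.items():
            mask = strat == g
            vals[mask] = rng.normal(mean, sd, int(mask.sum()))
        if metric.startswith(_NONNEGATIVE_PREFIXES):
            vals = np.clip(vals, 0.0, None)
        data[metric] = vals
    return pd.DataFrame(data)
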